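"""Thresholding, segmentation, feature and registration behavior."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

import rarescan as rs
from rarescan.detectcore import MAD_TO_SD
from conftest import make_record


class TestEstimateThreshold:
    def test_small_plane_oracle(self):
        # brute-force oracle: sorted medians of the nine values 1..9
        vals = np.arange(1, 10, dtype=float)
        med = sorted(vals)[4]
        mad = sorted(abs(v - med) for v in vals)[4]
        model = rs.estimate_threshold(vals.reshape(3, 3), k=2.0)
        assert model.background_median == med == 5
        assert model.background_mad == mad == 2
        assert model.threshold == pytest.approx(5 + 2 * 1.4826 * 2) == pytest.approx(10.9304)

    def test_constant_plane_is_degenerate(self):
        model = rs.estimate_threshold(np.full((8, 8), 7.0), k=6.0)
        assert model.degenerate
        assert model.threshold == model.background_median == 7.0

    @given(
        plane=hnp.arrays(
            float, (6, 6), elements=st.floats(0, 1e4, allow_nan=False, width=32)
        ),
        c=st.floats(-100, 100, allow_nan=False, width=32),
    )
    def test_shift_equivariance(self, plane, c):
        base = rs.estimate_threshold(plane, k=3.0)
        shifted = rs.estimate_threshold(plane + c, k=3.0)
        assert shifted.threshold == pytest.approx(base.threshold + c, abs=1e-6)

    def test_empty_plane_rejected(self):
        with pytest.raises(ValueError):
            rs.estimate_threshold(np.empty((0, 0)))


def _hard_disk(shape, cx, cy, radius, level, bg):
    plane = np.full(shape, bg, dtype=float)
    ys, xs = np.mgrid[: shape[0], : shape[1]]
    plane[(xs - cx) ** 2 + (ys - cy) ** 2 <= radius**2] = level
    return plane


class TestSegmentPrimary:
    pitch = 0.65

    def model(self, bg=100.0):
        return rs.ThresholdModel("ck", bg, 10.0, 6.0, bg + 6 * MAD_TO_SD * 10.0)

    def test_single_disk_oracle(self):
        plane = _hard_disk((128, 128), 60.25, 64.5, 8.0, 2000.0, 100.0)
        objs = rs.segment_primary(plane, self.model(), self.pitch)
        assert len(objs) == 1
        cx, cy = objs[0].centroid_px
        assert cx == pytest.approx(60.25, abs=0.5)
        assert cy == pytest.approx(64.5, abs=0.5)
        assert objs[0].area_um2 == pytest.approx(np.pi * 8**2 * self.pitch**2, rel=0.05)

    def test_two_separated_disks(self):
        plane = _hard_disk((128, 128), 30, 30, 8.0, 2000.0, 100.0)
        plane = np.maximum(plane, _hard_disk((128, 128), 90, 95, 8.0, 2000.0, 100.0))
        objs = rs.segment_primary(plane, self.model(), self.pitch)
        assert len(objs) == 2
        # deterministic row-major order by bounding-box origin
        assert objs[0].bbox[0] < objs[1].bbox[0]

    def test_blank_noise_tile_yields_nothing(self):
        rng = np.random.default_rng(1)
        plane = 500.0 + rng.normal(0, 50, (512, 512))
        model = rs.estimate_threshold(plane, k=6.0)
        assert rs.segment_primary(plane, model, self.pitch) == []

    def test_area_gates(self):
        big = _hard_disk((256, 256), 128, 128, 60.0, 2000.0, 100.0)  # ~4778 um2
        assert rs.segment_primary(big, self.model(), self.pitch) == []
        speck = _hard_disk((128, 128), 64, 64, 2.0, 2000.0, 100.0)  # ~5 um2
        assert rs.segment_primary(speck, self.model(), self.pitch) == []

    def test_holes_are_filled(self):
        plane = _hard_disk((128, 128), 64, 64, 10.0, 2000.0, 100.0)
        plane[62:66, 62:66] = 100.0  # punch a hole
        objs = rs.segment_primary(plane, self.model(), self.pitch)
        assert len(objs) == 1
        full = objs[0].full_mask(plane.shape)
        assert full[64, 64]

    def test_threshold_monotonic_in_k(self):
        cfg = rs.SimConfig(
            grid_rows=1, grid_cols=1, tile_px=512,
            counts={"wbc": 30, "mctc": 2, "squamous": 1, "debris": 0}, seed=4,
        )
        tiles, _ = rs.generate_slide(cfg)
        plane = tiles[0].planes["ck"].astype(float)
        counts = []
        for k in (2.0, 4.0, 6.0, 10.0, 20.0):
            model = rs.estimate_threshold(plane, k=k)
            # upper area gate off: it would re-admit objects as k shrinks them
            counts.append(
                len(rs.segment_primary(plane, model, cfg.pixel_pitch, max_area_um2=np.inf))
            )
        assert counts == sorted(counts, reverse=True)

    def test_translation_equivariance(self, quiet_cfg):
        centroids = []
        for x_px in (100, 140):
            rec = make_record("MCTC", x_um=x_px * 0.65, y_um=83.2)
            truth = rs.TruthManifest(records=[rec], config=quiet_cfg, seed=0)
            tile = rs.render_slide(truth, quiet_cfg)[0]
            plane = tile.planes["ck"].astype(float)
            model = rs.ThresholdModel("ck", 500.0, 30.0, 6.0, 800.0)
            (obj,) = rs.segment_primary(plane, model, quiet_cfg.pixel_pitch)
            centroids.append(obj.centroid_px)
        assert centroids[1][0] - centroids[0][0] == pytest.approx(40.0, abs=1e-3)
        assert centroids[1][1] - centroids[0][1] == pytest.approx(0.0, abs=1e-3)


def _square_mask(r0, c0, size):
    return rs.ObjectMask(
        tile_row=0, tile_col=0, bbox=(r0, c0, r0 + size, c0 + size),
        mask=np.ones((size, size), dtype=bool), area_px=size * size,
        area_um2=size * size * 0.65**2, centroid_px=(c0 + size / 2, r0 + size / 2),
        pixel_pitch=0.65,
    )


class TestNuclearMeasures:
    model = rs.ThresholdModel("nuclear", 0.0, 1.0, 6.0, 100.0)

    def test_blank_nuclear_plane(self):
        mask = _square_mask(10, 10, 20)
        plane = np.zeros((64, 64))
        assert rs.nuclear_overlap(mask, plane, self.model) == 0.0
        assert rs.nc_ratio(mask, plane, self.model) == 0.0

    def test_nucleus_fully_inside(self):
        mask = _square_mask(10, 10, 20)
        plane = np.zeros((64, 64))
        plane[15:25, 15:25] = 200.0  # nucleus well inside the mask
        assert rs.nuclear_overlap(mask, plane, self.model) == 1.0
        assert rs.nc_ratio(mask, plane, self.model) == pytest.approx(100 / 400)

    def test_half_covered_nucleus(self):
        # nucleus straddles the mask edge: half its pixels inside
        mask = _square_mask(10, 10, 20)  # rows/cols 10..29
        plane = np.zeros((64, 64))
        plane[14:24, 20:40] = 200.0  # 10 x 20 nucleus, cols 20..29 inside
        frac = rs.nuclear_overlap(mask, plane, self.model)
        assert frac == pytest.approx(0.5, abs=1 / mask.area_px)

    def test_supra_over_whole_mask(self):
        mask = _square_mask(10, 10, 20)
        plane = np.zeros((64, 64))
        plane[10:30, 10:30] = 200.0
        assert rs.nuclear_overlap(mask, plane, self.model) == 1.0
        assert rs.nc_ratio(mask, plane, self.model) == 1.0


class TestCd45Correlation:
    def setup_method(self):
        rng = np.random.default_rng(3)
        self.mask = _square_mask(20, 20, 16)
        self.ck = rng.uniform(100, 1000, (64, 64))

    def test_positive_affine_gives_one(self):
        assert rs.cd45_correlation(self.mask, self.ck, 2.0 * self.ck + 5.0) == pytest.approx(1.0)

    def test_constant_cd45_is_zero_by_convention(self):
        assert rs.cd45_correlation(self.mask, self.ck, np.full((64, 64), 7.0)) == 0.0

    def test_negative_affine_gives_minus_one(self):
        assert rs.cd45_correlation(self.mask, self.ck, -self.ck + 2000.0) == pytest.approx(-1.0)

    @given(a=st.floats(0.1, 10), b=st.floats(-50, 50))
    def test_invariant_under_positive_rescaling(self, a, b):
        rng = np.random.default_rng(5)
        cd45 = rng.uniform(100, 1000, (64, 64))
        base = rs.cd45_correlation(self.mask, self.ck, cd45)
        scaled = rs.cd45_correlation(self.mask, a * self.ck + b, cd45)
        assert scaled == pytest.approx(base, abs=1e-9)
        assert -1.0 <= scaled <= 1.0


class TestExtractFeatures:
    def test_lone_mctc_features(self, lone_mctc):
        tiles, rec, cfg = lone_mctc
        tile = tiles[0]
        models = {ch: rs.estimate_threshold(tile.planes[ch], 6.0, ch) for ch in tile.channels}
        # noise-free background makes the CK MAD zero; use a fixed threshold
        ck_model = rs.ThresholdModel("ck", 500.0, 30.0, 6.0, 800.0)
        nuc_model = rs.ThresholdModel("nuclear", 500.0, 30.0, 6.0, 800.0)
        models.update(ck=ck_model, nuclear=nuc_model)
        (mask,) = rs.segment_primary(tile.planes["ck"], ck_model, cfg.pixel_pitch)
        feats = rs.extract_features(tile, mask, models)
        assert feats.means["ck"] > ck_model.threshold
        assert abs(feats.cd45_correlation) < 0.3
        assert feats.nuclear_overlap_fraction > 0.2
        assert feats.nc_ratio > 0.15
        assert feats.nuclear_components == 1
        assert 0 <= feats.nuclear_overlap_fraction <= 1
        assert np.isfinite(list(feats.means.values())).all()

    def test_lone_wbc_yields_no_ck_object(self):
        cfg = rs.SimConfig(
            grid_rows=1, grid_cols=1, tile_px=256,
            counts={"wbc": 1, "mctc": 0, "squamous": 0, "debris": 0}, seed=2,
        )
        tiles, _ = rs.generate_slide(cfg)
        model = rs.estimate_threshold(tiles[0].planes["ck"], 6.0, "ck")
        assert rs.segment_primary(tiles[0].planes["ck"], model, cfg.pixel_pitch) == []


class TestRegistration:
    def _calibration(self, shifts, noise=20.0, seed=9):
        cfg = rs.SimConfig(chromatic_shift=shifts, noise_sd=noise, seed=seed)
        return rs.simulate_calibration_tile(cfg, seed=42)

    def test_recovers_injected_shift(self):
        cal = self._calibration({"ck": (3.0, -2.0)})
        dx, dy = rs.register_channels(cal, "nuclear")["ck"]
        assert dx == pytest.approx(3.0, abs=0.5)
        assert dy == pytest.approx(-2.0, abs=0.5)

    def test_matches_phase_correlation_oracle(self):
        from skimage.registration import phase_cross_correlation

        cal = self._calibration({"ck": (2.5, 1.25)})
        dx, dy = rs.register_channels(cal, "nuclear")["ck"]
        sh, _, _ = phase_cross_correlation(
            cal.planes["nuclear"].astype(float),
            cal.planes["ck"].astype(float),
            upsample_factor=50,
        )
        assert dx == pytest.approx(-sh[1], abs=0.2)
        assert dy == pytest.approx(-sh[0], abs=0.2)

    def test_zero_shift(self):
        cal = self._calibration({})
        for dx, dy in rs.register_channels(cal, "nuclear").values():
            assert abs(dx) <= 0.25 and abs(dy) <= 0.25

    def test_residual_after_compensation(self):
        cal = self._calibration({"ck": (1.6, -2.4)})
        est = rs.register_channels(cal, "nuclear")
        neg = {ch: (-dx, -dy) for ch, (dx, dy) in est.items()}
        fixed = rs.apply_chromatic_shift(cal, neg)
        for dx, dy in rs.register_channels(fixed, "nuclear").values():
            assert np.hypot(dx, dy) <= 0.5

    def test_flat_image_raises(self):
        planes = {ch: np.full((64, 64), 5.0) for ch in rs.CHANNELS}
        tile = rs.TileImage(0, 0, planes, 0.65)
        with pytest.raises(rs.CalibrationError):
            rs.register_channels(tile, "nuclear")
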
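import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import rarescan as rs

settings.register_profile(
    "ci", derandomize=True, max_examples=40, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture
def quiet_cfg():
    """Small noise-free slide config for constructions with exact pixel values."""
    return rs.SimConfig(
        grid_rows=1,
        grid_cols=1,
        tile_px=256,
        noise_sd=0.0,
        background_gradient=0.0,
        counts={"wbc": 0, "mctc": 0, "squamous": 0, "debris": 0},
        seed=0,
    )


@pytest.fixture
def small_cfg():
    """2x2 slide with a light WBC carpet, fast to generate and scan."""
    return rs.SimConfig(
        grid_rows=2,
        grid_cols=2,
        counts={"wbc": 300, "mctc": 4, "squamous": 0, "debris": 0},
        seed=7,
    )


def make_record(pop="MCTC", x_um=83.2, y_um=83.2, amps=None, nuc_r=5.0, cyt_r=7.5, **kw):
    """A pixel-aligned truth record (83.2 um = pixel 128 at 0.65 um/px)."""
    default_amps = {"nuclear": 8000.0, "ck": 8000.0, "cd45": 0.0, "marker": 4000.0}
    if pop == "WBC":
        default_amps = {"nuclear": 8000.0, "ck": 0.0, "cd45": 8000.0, "marker": 0.0}
    return rs.TruthRecord(
        cell_id=f"{pop}-00000",
        population=pop,
        x_um=x_um,
        y_um=y_um,
        nuclear_radius_um=nuc_r,
        cytoplasm_radius_um=cyt_r,
        amplitudes=amps or default_amps,
        **kw,
    )


@pytest.fixture
def lone_mctc(quiet_cfg):
    """(tiles, record, cfg) for a single noise-free mCTC at pixel (128, 128)."""
    rec = make_record("MCTC")
    truth = rs.TruthManifest(records=[rec], config=quiet_cfg, seed=0)
    tiles = rs.render_slide(truth, quiet_cfg)
    return tiles, rec, quiet_cfg
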
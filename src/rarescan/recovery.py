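"""Spike-in recovery statistics.

A spike-in experiment adds a precisely counted number of tumor cells (``N``
spiked) to a whole-blood sample and counts how many the platform identifies.
This module computes the statistics used to validate recovery: per-experiment
percent recovery, per-line mean/SD summaries, ordinary least squares of
identified against spiked counts, tallies for single-digit spike experiments,
and a seeded binomial simulator of the whole design.

Display percentages are floored to whole percent (81.48% -> 81%), matching the
reporting convention for spike-in tallies; full precision is kept internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class SpikeExperiment:
    """One spike-in replicate: cell line, cells spiked in, cells identified.

    ``n_identified`` may exceed ``n_spiked`` — contaminating cells can be
    mistaken for spiked cells before expert review.
    """

    line: str
    n_spiked: int
    n_identified: int

    def __post_init__(self) -> None:
        if self.n_spiked < 0 or self.n_identified < 0:
            raise ValueError("spiked and identified counts must be >= 0")


#: The ten single-digit PC3 spike-in experiments (A-J): (spiked, identified).
#: In experiment F the initial evaluation flagged two additional cytokeratin-
#: positive objects that expert review recognised as squamous contaminants;
#: the confirmed identified count is 3.
SINGLE_DIGIT_SPIKES: Tuple[SpikeExperiment, ...] = tuple(
    SpikeExperiment("PC3", s, i)
    for s, i in [(1, 1), (1, 1), (1, 0), (2, 2), (2, 2), (3, 3), (3, 3), (3, 2), (5, 4), (6, 4)]
)

#: Published per-line mean percent recoveries of the ~100-cell spike series.
LINE_MEAN_RECOVERY: Dict[str, float] = {
    "A549": 90.5,
    "LNCaP": 90.0,
    "PC3": 90.2,
    "MCF7": 91.3,
}


def percent_recovery(n_identified: int, n_spiked: int) -> float:
    """Percent of spiked cells identified, at full precision."""
    if n_spiked <= 0:
        raise ValueError("percent recovery is undefined for n_spiked = 0")
    return 100.0 * n_identified / n_spiked


def display_percent(percent: float) -> int:
    """Reporting convention: floor to whole percent (81.48 -> 81)."""
    return int(math.floor(percent))


@dataclass
class LineSummary:
    line: str
    n: int
    mean: float
    sd: float  # sample SD (n-1); 0 with degenerate=True when n == 1
    degenerate: bool


@dataclass
class RecoverySummary:
    """Per-line and pooled recovery statistics plus the identified~spiked OLS."""

    per_line: Dict[str, LineSummary]
    grand_mean_of_line_means: float
    pooled_mean: float  # unweighted mean over all experiments
    slope: Optional[float] = None
    intercept: Optional[float] = None
    r2: Optional[float] = None


def summarize_lines(experiments: Sequence[SpikeExperiment]) -> RecoverySummary:
    """Summarize recoveries per cell line and overall.

    The grand mean is reported two ways, both defensible for "average
    recovery": the unweighted mean of the per-line means, and the pooled mean
    over all experiments. The regression of identified on spiked counts is
    attached when at least two distinct spike counts are present.
    """
    if not experiments:
        raise ValueError("no experiments to summarize")
    by_line: Dict[str, List[float]] = {}
    for e in experiments:
        by_line.setdefault(e.line, []).append(percent_recovery(e.n_identified, e.n_spiked))
    per_line: Dict[str, LineSummary] = {}
    for line, recs in by_line.items():
        arr = np.asarray(recs, dtype=float)
        degenerate = arr.size < 2
        sd = 0.0 if degenerate else float(arr.std(ddof=1))
        per_line[line] = LineSummary(
            line=line, n=arr.size, mean=float(arr.mean()), sd=sd, degenerate=degenerate
        )
    line_means = np.asarray([s.mean for s in per_line.values()])
    all_recs = np.asarray(
        [percent_recovery(e.n_identified, e.n_spiked) for e in experiments]
    )
    summary = RecoverySummary(
        per_line=per_line,
        grand_mean_of_line_means=float(line_means.mean()),
        pooled_mean=float(all_recs.mean()),
    )
    spiked = {e.n_spiked for e in experiments}
    if len(spiked) >= 2:
        slope, intercept, r2 = fit_regression(experiments)
        summary.slope, summary.intercept, summary.r2 = slope, intercept, r2
    return summary


def fit_regression(
    experiments: Sequence[SpikeExperiment],
) -> Tuple[float, float, float]:
    """OLS of identified (response) on spiked (predictor): (slope, intercept, R²)."""
    x = np.asarray([e.n_spiked for e in experiments], dtype=float)
    y = np.asarray([e.n_identified for e in experiments], dtype=float)
    if np.unique(x).size < 2:
        raise ValueError("regression needs at least two distinct spiked counts")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


def simulate_spikein(
    p: float,
    n_min: int,
    n_max: int,
    n_experiments: int,
    seed: int,
    line: str = "SIM",
) -> List[SpikeExperiment]:
    """Binomial model of a spike-in series.

    Each experiment spikes a uniform-integer count in [n_min, n_max]; every
    spiked cell is independently identified with probability ``p`` (losses
    from sample processing, staining and review folded into one rate).
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError("identification probability p must be in [0, 1]")
    if n_min <= 0 or n_max < n_min:
        raise ValueError("need 0 < n_min <= n_max")
    rng = np.random.default_rng(seed)
    spiked = rng.integers(n_min, n_max + 1, size=n_experiments)
    identified = rng.binomial(spiked, p)
    return [
        SpikeExperiment(line, int(s), int(i)) for s, i in zip(spiked, identified)
    ]


@dataclass
class SingleDigitSummary:
    """Tally of single-digit spike-in outcomes by identified minus spiked."""

    n_full: int  # identified == spiked
    n_minus1: int
    n_minus2: int
    n_over: int  # identified > spiked (contaminant suspects)
    n_other: int  # shortfall of 3 or more
    total_spiked: int
    total_identified: int
    percent_identified: float
    percent_display: int


def single_digit_summary(experiments: Sequence[SpikeExperiment]) -> SingleDigitSummary:
    """Categorize single-digit spike experiments and total the recovery."""
    if not experiments:
        raise ValueError(
            "single-digit summary undefined for empty input (percent has no denominator)"
        )
    diffs = [e.n_identified - e.n_spiked for e in experiments]
    total_spiked = sum(e.n_spiked for e in experiments)
    total_identified = sum(e.n_identified for e in experiments)
    pct = percent_recovery(total_identified, total_spiked)
    return SingleDigitSummary(
        n_full=sum(d == 0 for d in diffs),
        n_minus1=sum(d == -1 for d in diffs),
        n_minus2=sum(d == -2 for d in diffs),
        n_over=sum(d > 0 for d in diffs),
        n_other=sum(d <= -3 for d in diffs),
        total_spiked=total_spiked,
        total_identified=total_identified,
        percent_identified=pct,
        percent_display=display_percent(pct),
    )
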
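"""Bias-corrected diel activity metrics via inverse-effort-weighted bootstrap.

For each SSCY sample, observations are resampled with replacement B times
with probabilities proportional to inverse observer effort; the 10th, 50th
and 90th percentile solar hours of each resample are averaged across
bootstraps. The averages are the activity onset, median (a proxy for peak)
and offset; duration is offset minus onset.
"""

from __future__ import annotations

import dataclasses
import hashlib
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .grid import SSCYSample

DEFAULT_QUANTILES = (0.1, 0.5, 0.9)


@dataclasses.dataclass(frozen=True)
class ActivityMetrics:
    species: str
    season: str
    cell_id: tuple[int, int]
    year: int
    n: int
    onset: float
    median: float
    offset: float
    sd_onset: float
    sd_median: float
    sd_offset: float
    B: int
    seed: int

    @property
    def duration(self) -> float:
        return duration(self.onset, self.offset)

    @property
    def key(self) -> tuple[str, str, tuple[int, int], int]:
        return (self.species, self.season, self.cell_id, self.year)


@dataclasses.dataclass(frozen=True)
class CorrectionSummary:
    """Average shifts introduced by the bias correction (corrected - raw)."""

    n_sscy: int
    onset_shift: float
    offset_shift: float
    duration_change: float
    duration_change_pct: float


def weighted_quantile(
    values: Sequence[float] | np.ndarray,
    weights: Sequence[float] | np.ndarray,
    q: float,
) -> float:
    """Left-continuous weighted inverse CDF.

    Returns the smallest value whose cumulative weight reaches q. Ties in
    values pool their weights implicitly because the scan runs over sorted
    values. No interpolation: on hour-binned data the result is always an
    observed hour, which keeps the estimator oracle-checkable.
    """
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if v.size == 0:
        raise ValueError("empty sample")
    if v.shape != w.shape:
        raise ValueError("values and weights differ in length")
    if np.any(w < 0):
        raise ValueError("negative weight")
    if not 0.0 <= q <= 1.0:
        raise ValueError("q outside [0, 1]")
    order = np.argsort(v, kind="stable")
    cw = np.cumsum(w[order])
    cw /= cw[-1]
    idx = int(np.searchsorted(cw, q - 1e-12, side="left"))
    idx = min(idx, v.size - 1)
    return float(v[order[idx]])


def duration(onset: float, offset: float) -> float:
    """Activity duration in hours; offset must not precede onset."""
    if offset < onset:
        raise ValueError(f"offset {offset} earlier than onset {onset}")
    return offset - onset


def sscy_substream_seed(
    key: tuple[str, str, tuple[int, int], int], seed: int
) -> int:
    """Stable per-SSCY seed so results do not depend on processing order."""
    digest = hashlib.sha256(repr((key, seed)).encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def bootstrap_metrics(
    sample: SSCYSample,
    weights: np.ndarray,
    B: int = 50,
    quantiles: tuple[float, float, float] = DEFAULT_QUANTILES,
    seed: int = 0,
) -> ActivityMetrics:
    """Weighted-bootstrap activity metrics for one SSCY sample.

    Each of the B bootstraps draws n observations with replacement with
    probability proportional to the supplied weights, then takes the
    empirical (left-continuous, uniform-weight) quantiles of the resampled
    hours; metrics are the means of each quantile over bootstraps.
    Deterministic given (sample key, seed).
    """
    if sample.n == 0:
        raise ValueError("cannot bootstrap an empty sample")
    w = np.asarray(weights, dtype=float)
    if np.any(w < 0):
        raise ValueError("negative weight")
    if w.size != sample.n:
        raise ValueError("weights length does not match sample size")
    w = w / w.sum()

    hours = np.asarray(sample.hours, dtype=float)
    rng = np.random.default_rng(sscy_substream_seed(sample.key, seed))
    draws = rng.choice(hours, size=(B, sample.n), replace=True, p=w)
    draws.sort(axis=1)
    # left-continuous quantile of a uniform-weight sample = order statistic
    # at index ceil(q*n) - 1
    stats = np.empty((B, len(quantiles)))
    for j, q in enumerate(quantiles):
        k = max(int(np.ceil(q * sample.n - 1e-12)) - 1, 0)
        stats[:, j] = draws[:, k]

    means = stats.mean(axis=0)
    sds = stats.std(axis=0, ddof=0)
    return ActivityMetrics(
        species=sample.species,
        season=sample.season,
        cell_id=sample.cell_id,
        year=sample.year,
        n=sample.n,
        onset=float(means[0]),
        median=float(means[1]),
        offset=float(means[2]),
        sd_onset=float(sds[0]),
        sd_median=float(sds[1]),
        sd_offset=float(sds[2]),
        B=B,
        seed=seed,
    )


def correction_summary(
    corrected: Sequence[ActivityMetrics],
    raw: Sequence[ActivityMetrics],
    pct_mode: str = "ratio_of_means",
) -> CorrectionSummary:
    """Average corrected-minus-raw shifts over matched SSCYs.

    ``pct_mode`` controls the percent duration change: 'ratio_of_means'
    (mean duration delta over mean raw duration, the default) or
    'mean_of_ratios' (per-SSCY percent change averaged, skipping zero raw
    durations).
    """
    raw_by_key: Mapping[tuple, ActivityMetrics] = {m.key: m for m in raw}
    if set(m.key for m in corrected) != set(raw_by_key):
        raise ValueError("corrected and raw metric lists have mismatched SSCY keys")
    onset_deltas, offset_deltas, dur_deltas, raw_durs = [], [], [], []
    for cm in corrected:
        rm = raw_by_key[cm.key]
        onset_deltas.append(cm.onset - rm.onset)
        offset_deltas.append(cm.offset - rm.offset)
        dur_deltas.append(cm.duration - rm.duration)
        raw_durs.append(rm.duration)
    onset_deltas = np.array(onset_deltas)
    offset_deltas = np.array(offset_deltas)
    dur_deltas = np.array(dur_deltas)
    raw_durs = np.array(raw_durs)
    if pct_mode == "ratio_of_means":
        pct = 100.0 * dur_deltas.mean() / raw_durs.mean() if raw_durs.mean() > 0 else 0.0
    elif pct_mode == "mean_of_ratios":
        ok = raw_durs > 0
        pct = 100.0 * float(np.mean(dur_deltas[ok] / raw_durs[ok])) if ok.any() else 0.0
    else:
        raise ValueError(f"unknown pct_mode {pct_mode!r}")
    return CorrectionSummary(
        n_sscy=len(corrected),
        onset_shift=float(onset_deltas.mean()),
        offset_shift=float(offset_deltas.mean()),
        duration_change=float(dur_deltas.mean()),
        duration_change_pct=float(pct),
    )


def metrics_frame(metrics: Sequence[ActivityMetrics]) -> pd.DataFrame:
    """Flat metrics table (one row per SSCY)."""
    return pd.DataFrame(
        {
            "species": [m.species for m in metrics],
            "season": [m.season for m in metrics],
            "cell_row": [m.cell_id[0] for m in metrics],
            "cell_col": [m.cell_id[1] for m in metrics],
            "year": [m.year for m in metrics],
            "n": [m.n for m in metrics],
            "onset": [m.onset for m in metrics],
            "median": [m.median for m in metrics],
            "offset": [m.offset for m in metrics],
            "duration": [m.duration for m in metrics],
            "sd_onset": [m.sd_onset for m in metrics],
            "sd_median": [m.sd_median for m in metrics],
            "sd_offset": [m.sd_offset for m in metrics],
            "B": [m.B for m in metrics],
            "seed": [m.seed for m in metrics],
        }
    )
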
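"""Polysome-profile quantification.

A sucrose-gradient A254 trace shows, top to bottom, the 40S and 60S
subunits, the 80S monosome, and polysome peaks of increasing ribosome
number.  This module baseline-corrects the trace, segments it at the
valleys between detected peaks, integrates each segment by the trapezoid
rule, and tests for a linear trend of peak-area ratios (as percent of a
control cohort) across ribosome loading.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal, stats

__all__ = [
    "PolysomeTrace",
    "PeakSet",
    "PeakAreas",
    "baseline_correct",
    "detect_peaks",
    "peak_areas",
    "loading_trend_test",
    "percent_of_control",
]

#: Segment labels top-to-bottom: subunits, monosome, polysome classes.
SEGMENT_LABELS = ("40S", "60S", "80S", "2", "3", "4", ">=5")


@dataclass
class PolysomeTrace:
    positions: np.ndarray
    absorbance: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.positions.size != self.absorbance.size:
            raise ValueError("positions and absorbance differ in length")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")


@dataclass
class PeakSet:
    """Ordered non-overlapping segments, top of gradient first."""

    labels: tuple[str, ...]
    boundaries: list[tuple[float, float]]  # (start, end) positions per segment
    peak_positions: list[float]


@dataclass
class PeakAreas:
    labels: tuple[str, ...]
    auc: np.ndarray
    ratio_to_total: np.ndarray


def baseline_correct(trace: PolysomeTrace, flank_fraction: float = 0.0) -> PolysomeTrace:
    """Subtract a linear baseline anchored at the flanking minima.

    The anchors are the minimum-absorbance samples within the leading and
    trailing flanks of the trace (by default the end samples themselves,
    where a gradient trace sits on pure baseline; widen ``flank_fraction``
    for noisy ends).  Corrected absorbance is clipped at zero.  The rule is
    exactly invariant to adding any linear function to the trace as long as
    the flank minima stay at the same positions, which the single-sample
    default guarantees.
    """
    n = trace.positions.size
    if n < 50:
        raise ValueError(f"trace has {n} samples; need >= 50")
    k = max(int(round(flank_fraction * n)), 1)
    i_left = int(np.argmin(trace.absorbance[:k]))
    i_right = n - k + int(np.argmin(trace.absorbance[n - k :]))
    x1, y1 = trace.positions[i_left], trace.absorbance[i_left]
    x2, y2 = trace.positions[i_right], trace.absorbance[i_right]
    if x2 == x1:
        baseline = np.full(n, y1)
    else:
        slope = (y2 - y1) / (x2 - x1)
        baseline = y1 + slope * (trace.positions - x1)
    corrected = np.clip(trace.absorbance - baseline, 0.0, None)
    return PolysomeTrace(trace.positions.copy(), corrected)


def detect_peaks(
    trace: PolysomeTrace,
    n_expected_segments: int = 7,
    prominence_fraction: float = 0.02,
) -> PeakSet:
    """Detect peaks and delimit segments at the valleys between them.

    Local maxima above ``prominence_fraction`` of the trace maximum are
    found; segment boundaries sit at the minimum between consecutive maxima.
    The first peaks are labeled 40S/60S/80S then 2, 3, 4; peaks beyond the
    expected count pool into the terminal >=5 segment.
    """
    y = trace.absorbance
    prominence = prominence_fraction * float(y.max()) if y.max() > 0 else None
    idx, _ = signal.find_peaks(y, prominence=prominence)
    if idx.size < n_expected_segments:
        found = [float(trace.positions[i]) for i in idx]
        raise ValueError(
            f"found {idx.size} peaks, expected >= {n_expected_segments}: "
            f"peak positions {found}"
        )
    # Valley between consecutive kept peaks; extra trailing peaks merge into
    # the final (>=5) segment.
    labels = SEGMENT_LABELS[:n_expected_segments]
    kept = list(idx[: n_expected_segments - 1]) + [idx[n_expected_segments - 1]]
    cut_idx = []
    for a, b in zip(kept[:-1], kept[1:]):
        cut_idx.append(a + int(np.argmin(y[a : b + 1])))
    cuts = [float(trace.positions[0])]
    cuts += [float(trace.positions[i]) for i in cut_idx]
    cuts.append(float(trace.positions[-1]))
    boundaries = list(zip(cuts[:-1], cuts[1:]))
    return PeakSet(
        labels=tuple(labels),
        boundaries=boundaries,
        peak_positions=[float(trace.positions[i]) for i in idx],
    )


def peak_areas(trace: PolysomeTrace, peaks: PeakSet) -> PeakAreas:
    """Trapezoidal AUC per segment and each segment's fraction of the total."""
    aucs = []
    for start, end in peaks.boundaries:
        mask = (trace.positions >= start) & (trace.positions <= end)
        aucs.append(float(np.trapezoid(trace.absorbance[mask], trace.positions[mask])))
    auc = np.array(aucs)
    total = auc.sum()
    if total <= 0:
        raise ValueError("zero total area over segments")
    return PeakAreas(labels=peaks.labels, auc=auc, ratio_to_total=auc / total)


def percent_of_control(
    treated: np.ndarray, control_replicates: np.ndarray
) -> np.ndarray:
    """Peak ratios as percent of the control-cohort mean, per segment."""
    control_mean = np.asarray(control_replicates, dtype=float).mean(axis=0)
    return 100.0 * np.asarray(treated, dtype=float) / control_mean


def loading_trend_test(
    percent_values: np.ndarray,
    loading_index: np.ndarray,
    min_classes: int = 4,
    min_replicates: int = 2,
) -> tuple[float, float, bool]:
    """Linear trend of percent-of-control across ribosome loading.

    ``percent_values[i]`` is one replicate's percent-of-control for loading
    class ``loading_index[i]`` (integers ordered by ribosome number).
    Returns ``(slope, two_sided_p, degenerate)``; a zero-residual fit
    reports p below machine precision with the degenerate flag.
    """
    x = np.asarray(loading_index, dtype=float)
    y = np.asarray(percent_values, dtype=float)
    classes, counts = np.unique(x, return_counts=True)
    if classes.size < min_classes:
        raise ValueError(f"{classes.size} loading classes < {min_classes}")
    if np.any(counts < min_replicates):
        raise ValueError(f"every loading class needs >= {min_replicates} replicates")
    res = stats.linregress(x, y)
    resid = y - (res.intercept + res.slope * x)
    if float(resid @ resid) < 1e-12 * max(float(y @ y), 1.0):
        return float(res.slope), float(np.finfo(float).tiny), True
    return float(res.slope), float(res.pvalue), False
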
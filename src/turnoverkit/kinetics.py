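"""First-order turnover kinetics and half-life estimation.

At steady state (synthesis equals degradation) the fraction of newly
synthesized protein follows ``f(t) = 1 - exp(-k t)``, so
``y = -ln(1 - f)`` is linear in time through the origin with slope ``k``.
The half-time of appearance of new protein, ``HL = ln 2 / k``, is the
protein half-life.  Peptide-level fractions are pooled per protein and
mouse with chromatographic-AUC weights before fitting; only peptides that
map uniquely to a single protein contribute.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .deconvolution import FractionNewEstimate

__all__ = [
    "ProteinTimeCourse",
    "TurnoverFit",
    "SteadyStateCheck",
    "pool_protein_fraction_new",
    "fit_first_order",
    "half_life",
    "steady_state_slopes",
]

logger = logging.getLogger(__name__)

LN2 = math.log(2.0)

#: f this close to 1 is excluded from the log transform (singularity).
F_SATURATION = 1.0 - 1e-6


@dataclass
class ProteinTimeCourse:
    """Pooled fraction-new points for one protein in one cohort.

    ``points`` holds one entry per mouse: (time days, pooled f,
    weight = summed unique-peptide AUC, n_peptides).
    """

    protein: str
    cohort: str
    points: list[tuple[float, float, float, int]] = field(default_factory=list)


@dataclass
class TurnoverFit:
    """First-order rate constant and half-life for one protein/cohort."""

    protein: str
    cohort: str
    k: float
    half_life: float
    slope_se: float
    r_squared: float
    n_points: int
    flags: list[str] = field(default_factory=list)


@dataclass
class SteadyStateCheck:
    """Abundance-versus-time regression for one peptide."""

    peptide: str
    slope: float
    p_value: float


def pool_protein_fraction_new(
    estimates: list[FractionNewEstimate],
    drop_clipped: bool = False,
) -> dict[tuple[str, str], ProteinTimeCourse]:
    """Pool per-peptide fraction-new into per-protein time courses.

    Non-unique peptides are discarded.  Per mouse (sample), the pooled f is
    the AUC-weighted mean over that protein's unique peptides.  Proteins
    with no unique peptides are dropped with a log entry.
    """
    by_protein: dict[tuple[str, str], dict[str, list[FractionNewEstimate]]] = {}
    dropped_nonunique: set[str] = set()
    for est in estimates:
        if not est.is_unique:
            dropped_nonunique.add(est.protein)
            continue
        if drop_clipped and est.clipped:
            continue
        key = (est.protein, est.cohort)
        by_protein.setdefault(key, {}).setdefault(est.sample, []).append(est)
    for protein in dropped_nonunique:
        if not any(k[0] == protein for k in by_protein):
            logger.info("protein %s dropped: no unique peptides", protein)
    courses: dict[tuple[str, str], ProteinTimeCourse] = {}
    for (protein, cohort), by_sample in sorted(by_protein.items()):
        course = ProteinTimeCourse(protein=protein, cohort=cohort)
        for sample in sorted(by_sample):
            ests = by_sample[sample]
            weights = np.array([e.total_auc for e in ests])
            fs = np.array([e.f for e in ests])
            wsum = weights.sum()
            pooled = float((weights * fs).sum() / wsum) if wsum > 0 else float(fs.mean())
            course.points.append((ests[0].time, pooled, float(wsum), len(ests)))
        courses[(protein, cohort)] = course
    return courses


def fit_first_order(
    course: ProteinTimeCourse,
    min_points: int = 4,
    zero_intercept: bool = True,
    weighting: str = "delta",
) -> TurnoverFit:
    """Fit ``-ln(1 - f)`` against time; slope is the rate constant ``k``.

    Points with ``f`` at the log singularity (f >= 1 - 1e-6) are excluded
    and flagged.  ``k <= 0`` yields an infinite half-life with a
    ``non-positive-rate`` flag.  The default regression is through the
    origin because ``f(0) = 0`` is physical; ``zero_intercept=False``
    switches to a free intercept.

    ``weighting="delta"`` (default) weights each point by ``(1 - f)^2``,
    the delta-method inverse variance of the log transform when the
    fraction-new noise is homoscedastic; this is what keeps the slope
    standard error honest where ``f`` approaches 1 and the transform
    amplifies noise.  ``weighting="none"`` gives ordinary least squares.
    """
    flags: list[str] = []
    pts = [(t, f) for (t, f, _w, _n) in course.points if f < F_SATURATION]
    if len(pts) < len(course.points):
        flags.append("saturated-points-excluded")
    if len(pts) < min_points:
        raise ValueError(
            f"{course.protein}/{course.cohort}: {len(pts)} usable points "
            f"< min_points={min_points}"
        )
    t = np.array([p[0] for p in pts])
    f_arr = np.array([p[1] for p in pts])
    y = -np.log1p(-f_arr)
    n = len(pts)
    if weighting == "delta":
        w = (1.0 - f_arr) ** 2
    elif weighting == "none":
        w = np.ones(n)
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    if zero_intercept:
        swtt = float(w @ (t * t))
        k = float((w * t) @ y) / swtt
        resid = y - k * t
        dof = max(n - 1, 1)
        se = math.sqrt(float(w @ resid**2) / dof / swtt)
        ss_tot = float(w @ y**2)  # uncentered: the origin is part of the model
    else:
        import statsmodels.api as sm

        res = sm.WLS(y, sm.add_constant(t), weights=w).fit()
        k, se = float(res.params[1]), float(res.bse[1])
        resid = y - res.fittedvalues
        ybar = float(w @ y) / float(w.sum())
        ss_tot = float(w @ (y - ybar) ** 2)
    ss_res = float(w @ resid**2)
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    if k <= 0:
        flags.append("non-positive-rate")
        hl = math.inf
    else:
        hl = half_life(k)
    return TurnoverFit(
        protein=course.protein,
        cohort=course.cohort,
        k=k,
        half_life=hl,
        slope_se=se,
        r_squared=r2,
        n_points=n,
        flags=flags,
    )


def half_life(k: float) -> float:
    """Half-life in days, ``ln 2 / k``; infinite for non-positive rates."""
    if k <= 0:
        return math.inf
    return LN2 / k


def steady_state_slopes(
    observations_by_peptide: dict[str, list[tuple[float, float]]],
    min_timepoints: int = 3,
) -> tuple[list[SteadyStateCheck], float, float]:
    """Regress per-peptide total AUC on time to verify steady state.

    ``observations_by_peptide`` maps peptide -> list of (time, total_auc).
    Returns the per-peptide checks plus a one-sample t-test (t, p) that the
    slope distribution is centered at zero.
    """
    checks: list[SteadyStateCheck] = []
    for peptide in sorted(observations_by_peptide):
        obs = observations_by_peptide[peptide]
        times = np.array([t for t, _ in obs])
        if len(np.unique(times)) < min_timepoints:
            continue
        auc = np.array([a for _, a in obs])
        res = stats.linregress(times, auc)
        checks.append(
            SteadyStateCheck(
                peptide=peptide, slope=float(res.slope), p_value=float(res.pvalue)
            )
        )
    slopes = np.array([c.slope for c in checks])
    if slopes.size >= 2 and np.std(slopes) > 0:
        t_stat, p = stats.ttest_1samp(slopes, 0.0)
        return checks, float(t_stat), float(p)
    return checks, math.nan, math.nan
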
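"""Two-component mixture deconvolution of isotopologue envelopes.

An observed intensity vector over nominal offsets is modeled as

    intensities ~ A * [ (1 - f) * natural + f * labeled(p) ]

where ``f`` is the fraction of molecules synthesized after label
introduction, ``p`` the precursor-pool enrichment at synthesis time, and
``A`` the total chromatographic abundance.  With ``p`` known the problem is
linear in ``(A(1-f), Af)`` and solved in closed form under nonnegativity;
with ``p`` free it is solved by a deterministic coarse grid over ``p``
followed by golden-section refinement.

A peptide with a single leucine cannot separate ``f`` from ``p`` (only the
product of the per-site heavy probability is observable), so pool-enrichment
estimation uses peptides with at least two leucines and takes the median of
their per-peptide ``p`` fits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from math import comb

from .isotope_model import (
    HEAVY_LEUCINE_OFFSET,
    count_label_sites,
    default_max_offset,
    mixture_basis,
)
from .isotope_model import _cached_natural

__all__ = [
    "PeptideObservation",
    "EnrichmentEstimate",
    "FractionNewEstimate",
    "fit_mixture",
    "estimate_sample_enrichment",
    "percent_new_per_peptide",
]

COHORTS = ("YCL", "YCR", "YRP", "OCL", "OCR", "ORP")


@dataclass
class PeptideObservation:
    """One peptide's isotopologue intensity vector in one mouse at one time."""

    peptide: str
    protein: str
    is_unique: bool
    sample: str
    cohort: str
    time: float
    intensities: np.ndarray
    n_leucines: int = -1

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if np.any(self.intensities < 0):
            raise ValueError(f"negative intensity for peptide {self.peptide!r}")
        if self.time < 0:
            raise ValueError("labeling time must be >= 0 days")
        if self.n_leucines < 0:
            self.n_leucines = count_label_sites(self.peptide)

    @property
    def total_auc(self) -> float:
        """Summed chromatographic area over labeled plus unlabeled species."""
        return float(self.intensities.sum())


@dataclass
class EnrichmentEstimate:
    """Per-sample precursor-pool enrichment."""

    sample: str
    p: float
    n_peptides_used: int
    dispersion: float  # median absolute deviation of per-peptide p

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("enrichment outside [0, 1]")
        if self.n_peptides_used < 1:
            raise ValueError("n_peptides_used must be >= 1")


@dataclass
class FractionNewEstimate:
    """Per-peptide fraction newly synthesized with fit diagnostics."""

    peptide: str
    protein: str
    is_unique: bool
    sample: str
    cohort: str
    time: float
    f: float
    scale: float
    residual: float
    total_auc: float
    clipped: bool = False
    low_signal: bool = False
    flags: list[str] = field(default_factory=list)


def _solve_two_component(
    y: np.ndarray, nat: np.ndarray, lab: np.ndarray
) -> tuple[float, float, float, bool]:
    """Nonnegative least squares for y ~ a*nat + b*lab, 2x2 closed form.

    Returns (a, b, rms_residual, clipped) where clipped marks an active
    nonnegativity constraint (the unconstrained optimum had a negative
    coefficient).
    """
    g11 = float(nat @ nat)
    g22 = float(lab @ lab)
    g12 = float(nat @ lab)
    c1 = float(nat @ y)
    c2 = float(lab @ y)
    det = g11 * g22 - g12 * g12
    clipped = False
    if det > 1e-300:
        a = (c1 * g22 - c2 * g12) / det
        b = (c2 * g11 - c1 * g12) / det
    else:
        a, b = -1.0, -1.0  # collinear basis: force single-component fallback
    if a < 0.0 or b < 0.0:
        clipped = True
        # best single-component fits, coefficients clipped at zero
        a1 = max(c1 / g11, 0.0) if g11 > 0 else 0.0
        b1 = max(c2 / g22, 0.0) if g22 > 0 else 0.0
        r_a = float(np.sum((y - a1 * nat) ** 2))
        r_b = float(np.sum((y - b1 * lab) ** 2))
        a, b = (a1, 0.0) if r_a <= r_b else (0.0, b1)
    resid = y - a * nat - b * lab
    rms = float(np.sqrt(np.mean(resid**2)))
    return a, b, rms, clipped


def _mixture_rms(obs: PeptideObservation, p: float, max_offset: int) -> tuple[float, float, float, bool]:
    nat, lab = mixture_basis(obs.peptide, p, max_offset)
    y = _padded(obs.intensities, max_offset + 1)
    if np.allclose(nat, lab, atol=1e-12):
        # p ~ 0: old and new components coincide, f is unidentifiable -> 0
        a = max(float(nat @ y) / float(nat @ nat), 0.0)
        rms = float(np.sqrt(np.mean((y - a * nat) ** 2)))
        return 0.0, a, rms, False
    a, b, rms, clipped = _solve_two_component(y, nat, lab)
    A = a + b
    f = b / A if A > 0 else 0.0
    return f, A, rms, clipped


def _padded(y: np.ndarray, n: int) -> np.ndarray:
    if y.size >= n:
        return y[:n]
    return np.pad(y, (0, n - y.size))


def _rms_over_grid(obs: PeptideObservation, grid: np.ndarray, max_offset: int) -> np.ndarray:
    """Mixture RMS residual at every grid enrichment, vectorized.

    Builds all labeled envelopes at once (binomial weight matrix times the
    stack of 3-offset-shifted natural envelopes), then solves each 2x2
    nonnegative least-squares problem in closed form.
    """
    L = obs.n_leucines
    nat = _cached_natural(obs.peptide, max_offset)
    n = max_offset + 1
    y = _padded(obs.intensities, n)
    shifts = np.zeros((L + 1, n))
    for h in range(L + 1):
        s = HEAVY_LEUCINE_OFFSET * h
        if s > max_offset:
            break
        shifts[h, s:] = nat[: n - s]
    hs = np.arange(L + 1)
    binom = np.array([comb(L, h) for h in hs], dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        W = binom * grid[:, None] ** hs * (1.0 - grid[:, None]) ** (L - hs)
    W = np.nan_to_num(W)
    labs = W @ shifts
    labs /= labs.sum(axis=1, keepdims=True)

    g11 = float(nat @ nat)
    g22 = np.einsum("ij,ij->i", labs, labs)
    g12 = labs @ nat
    c1 = float(nat @ y)
    c2 = labs @ y
    yy = float(y @ y)
    det = g11 * g22 - g12**2
    safe = det > 1e-300
    a = np.where(safe, (c1 * g22 - c2 * g12) / np.where(safe, det, 1.0), -1.0)
    b = np.where(safe, (c2 * g11 - c1 * g12) / np.where(safe, det, 1.0), -1.0)
    ss = yy - 2.0 * (a * c1 + b * c2) + a**2 * g11 + b**2 * g22 + 2.0 * a * b * g12
    # active nonnegativity constraint: best single-component fit
    bad = (a < 0) | (b < 0)
    if np.any(bad):
        a1 = max(c1 / g11, 0.0)
        ss_nat = yy - 2.0 * a1 * c1 + a1**2 * g11
        b1 = np.clip(c2 / g22, 0.0, None)
        ss_lab = yy - 2.0 * b1 * c2 + b1**2 * g22
        ss = np.where(bad, np.minimum(ss_nat, ss_lab), ss)
    return np.sqrt(np.clip(ss, 0.0, None) / n)


_GOLDEN = (np.sqrt(5.0) - 1.0) / 2.0


def _golden_section(fun, lo: float, hi: float, tol: float = 1e-6) -> float:
    """Minimize a unimodal scalar function on [lo, hi] by golden section."""
    x1 = hi - _GOLDEN * (hi - lo)
    x2 = lo + _GOLDEN * (hi - lo)
    f1, f2 = fun(x1), fun(x2)
    while hi - lo > tol:
        if f1 <= f2:
            hi, x2, f2 = x2, x1, f1
            x1 = hi - _GOLDEN * (hi - lo)
            f1 = fun(x1)
        else:
            lo, x1, f1 = x1, x2, f2
            x2 = lo + _GOLDEN * (hi - lo)
            f2 = fun(x2)
    return 0.5 * (lo + hi)


def fit_mixture(
    obs: PeptideObservation,
    p_fixed: float | None = None,
    grid_size: int = 101,
    p_tol: float = 1e-6,
) -> tuple[float, float, float, float]:
    """Fit the old/new mixture; returns ``(f, p, A, rms_residual)``.

    With ``p_fixed`` given only ``(f, A)`` are fitted.  With ``p`` free the
    residual is scanned on a ``grid_size``-point grid over [0, 1] (ties going
    to the smallest ``p``) and refined by golden section to ``p_tol``.
    """
    if obs.n_leucines == 0:
        raise ValueError(
            f"peptide {obs.peptide!r} has no leucine: carries no label information"
        )
    if obs.total_auc <= 0:
        raise ValueError(f"peptide {obs.peptide!r}: all-zero intensity vector")
    if p_fixed is not None and not 0.0 <= p_fixed <= 1.0:
        raise ValueError("p_fixed outside [0, 1]")
    max_offset = max(
        default_max_offset(obs.n_leucines), int(obs.intensities.size) - 1
    )
    if p_fixed is not None:
        f, A, rms, _ = _mixture_rms(obs, p_fixed, max_offset)
        return f, float(p_fixed), A, rms

    grid = np.linspace(0.0, 1.0, grid_size)
    rms_grid = _rms_over_grid(obs, grid, max_offset)
    i = int(np.argmin(rms_grid))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, grid_size - 1)]
    p_refined = _golden_section(
        lambda p: _mixture_rms(obs, p, max_offset)[2], lo, hi, p_tol
    )
    # Final choice among refined point, best grid point, and p = 0, using the
    # direct residual (the vectorized grid uses a cancellation-prone closed
    # form).  On a flat objective -- e.g. an unlabeled t=0 sample fits every
    # p equally well -- ties resolve to the smallest p.
    scale = float(np.sqrt(np.mean(_padded(obs.intensities, max_offset + 1) ** 2)))
    tol = 1e-9 * scale
    candidates = sorted({0.0, float(grid[i]), float(p_refined)})
    rms_cand = [_mixture_rms(obs, p, max_offset)[2] for p in candidates]
    best = min(rms_cand)
    p_hat = next(p for p, r in zip(candidates, rms_cand) if r <= best + tol)
    f, A, rms, _ = _mixture_rms(obs, p_hat, max_offset)
    return f, float(p_hat), A, rms


def estimate_sample_enrichment(
    observations: list[PeptideObservation],
    signal_floor: float = 0.0,
    max_peptides: int | None = 200,
) -> EnrichmentEstimate:
    """Estimate one sample's precursor-pool enrichment.

    Joint ``(f, p)`` fits are run on peptides with at least two leucines
    (single-leucine peptides confound ``f`` with ``p``); the sample ``p`` is
    the median of the per-peptide estimates.  When more than ``max_peptides``
    candidates exist a deterministic subset (ordered by peptide sequence) is
    used.
    """
    if not observations:
        raise ValueError("no observations for sample")
    sample = observations[0].sample
    usable = [
        o
        for o in observations
        if o.n_leucines >= 2 and o.total_auc > signal_floor
    ]
    if not usable:
        raise ValueError(
            f"sample {sample!r}: no peptides with >= 2 leucines above the signal "
            "floor; supply the pool enrichment externally"
        )
    usable.sort(key=lambda o: (o.peptide, o.protein))
    if max_peptides is not None and len(usable) > max_peptides:
        stride = len(usable) / max_peptides
        usable = [usable[int(i * stride)] for i in range(max_peptides)]
    p_values = np.array([fit_mixture(o)[1] for o in usable])
    p_med = float(np.median(p_values))
    mad = float(np.median(np.abs(p_values - p_med)))
    return EnrichmentEstimate(
        sample=sample, p=p_med, n_peptides_used=len(usable), dispersion=mad
    )


def percent_new_per_peptide(
    obs: PeptideObservation,
    enrichment: EnrichmentEstimate,
    signal_floor: float = 0.0,
) -> FractionNewEstimate:
    """Fraction newly synthesized with the sample enrichment held fixed."""
    if obs.n_leucines == 0:
        raise ValueError(
            f"peptide {obs.peptide!r} has no leucine: carries no label information"
        )
    if obs.total_auc <= 0:
        raise ValueError(f"peptide {obs.peptide!r}: all-zero intensity vector")
    if obs.time > 0 and enrichment.p <= 0:
        raise ValueError(
            f"sample {obs.sample!r}: zero pool enrichment for a t > 0 sample"
        )
    max_offset = max(default_max_offset(obs.n_leucines), int(obs.intensities.size) - 1)
    f, A, rms, clipped = _mixture_rms(obs, enrichment.p, max_offset)
    f_clipped = min(max(f, 0.0), 1.0)
    flags = []
    if clipped:
        flags.append("clipped")
    low_signal = obs.total_auc <= signal_floor
    if low_signal:
        flags.append("low-signal")
    return FractionNewEstimate(
        peptide=obs.peptide,
        protein=obs.protein,
        is_unique=obs.is_unique,
        sample=obs.sample,
        cohort=obs.cohort,
        time=obs.time,
        f=f_clipped,
        scale=A,
        residual=rms,
        total_auc=obs.total_auc,
        clipped=clipped,
        low_signal=low_signal,
        flags=flags,
    )
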
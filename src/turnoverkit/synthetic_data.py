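"""Synthetic study generator with known ground truth.

Emulates the labeling study design: six cohorts (young/old crossed with
control, calorie-restricted and rapamycin diets), twelve mice per cohort
(three euthanized at each of labeling days 3, 7, 12 and 17), log-normally
distributed protein half-lives, multiplicative cohort effects on half-life
and abundance, a saturating precursor-pool enrichment curve, and
multiplicative log-normal noise on each isotopologue intensity.  Also
produces synthetic polysome traces as sums of Gaussian peaks on a linear
baseline.

Every draw flows from a single seed, so tables are reproducible
byte-for-byte.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .isotope_model import default_max_offset, mixture_basis
from .polysome import PolysomeTrace

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_enrichment_curve",
    "simulate_cohort",
    "simulate_study",
    "simulate_polysome_trace",
]

AMINO_ACIDS = "ACDEFGHIKMNPQRSTVWY"  # leucines are inserted separately

DEFAULT_COHORTS = ("YCL", "YCR", "YRP", "OCL", "OCR", "ORP")


@dataclass
class SimulationConfig:
    """Study-design constants and noise levels for the generator.

    Defaults mirror the labeling design: timepoints 3/7/12/17 days with
    three mice each, half-lives log-normal around a 3-day median, pool
    enrichment saturating toward ~0.5, and 5% multiplicative intensity
    noise.  ``hl_multipliers`` and ``abundance_multipliers`` inject
    per-cohort effects relative to the control.
    """

    n_proteins: int = 300
    peptides_per_protein: tuple[int, int] = (2, 5)  # inclusive range
    leucine_weights: tuple[float, ...] = (0.1, 0.25, 0.35, 0.2, 0.1)  # L = 0..4
    hl_median_days: float = 3.0
    hl_sigma: float = 0.8  # log-scale sd of the half-life distribution
    hl_multipliers: dict[str, float] = field(default_factory=dict)
    abundance_multipliers: dict[str, float] = field(default_factory=dict)
    abundance_median: float = 1e6
    abundance_sigma: float = 1.0
    p_max: float = 0.5
    p_rate_per_day: float = 0.5
    timepoints: tuple[float, ...] = (3.0, 7.0, 12.0, 17.0)
    mice_per_timepoint: int = 3
    cohorts: tuple[str, ...] = DEFAULT_COHORTS
    noise_cv: float = 0.05
    peptide_length: tuple[int, int] = (8, 16)
    shared_peptide_fraction: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be positive")
        if not 0.0 < self.p_max <= 1.0:
            raise ValueError("p_max must lie in (0, 1]")
        if self.p_rate_per_day <= 0:
            raise ValueError("enrichment rate must be positive")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        for name, mult in {**self.hl_multipliers, **self.abundance_multipliers}.items():
            if mult <= 0:
                raise ValueError(f"multiplier for {name} must be > 0")


@dataclass
class GroundTruth:
    """True parameters behind a simulated table."""

    half_life: pd.DataFrame  # index protein, columns cohorts
    abundance: pd.DataFrame  # index protein, columns cohorts
    enrichment: pd.DataFrame  # index sample, columns [cohort, time, p]
    config: SimulationConfig

    def to_json_dict(self) -> dict:
        return {
            "half_life": self.half_life.to_dict(),
            "abundance": self.abundance.to_dict(),
            "enrichment": self.enrichment.to_dict(orient="index"),
            "config": {
                k: list(v) if isinstance(v, tuple) else v
                for k, v in asdict(self.config).items()
            },
        }


def simulate_enrichment_curve(p_max: float, rate: float, t: np.ndarray | float):
    """Saturating pool-enrichment curve ``p(t) = p_max (1 - exp(-rate t))``."""
    if not 0.0 < p_max <= 1.0:
        raise ValueError("p_max must lie in (0, 1]")
    if rate <= 0:
        raise ValueError("rate must be positive")
    return p_max * (1.0 - np.exp(-rate * np.asarray(t, dtype=float)))


def _random_peptide(rng: np.random.Generator, length: int, n_leu: int) -> str:
    body = rng.choice(list(AMINO_ACIDS), size=length - n_leu)
    seq = list(body)
    for pos in sorted(rng.choice(length, size=n_leu, replace=False)):
        seq.insert(pos, "L")
    return "".join(seq[:length])


def _protein_peptides(cfg: SimulationConfig, rng: np.random.Generator):
    """Per protein: list of (sequence, n_leucines, relative ionization)."""
    proteins = {}
    weights = np.asarray(cfg.leucine_weights, dtype=float)
    weights = weights / weights.sum()
    for i in range(cfg.n_proteins):
        name = f"P{i:04d}"
        n_pep = int(rng.integers(cfg.peptides_per_protein[0], cfg.peptides_per_protein[1] + 1))
        peps = []
        for _ in range(n_pep):
            length = int(rng.integers(cfg.peptide_length[0], cfg.peptide_length[1] + 1))
            n_leu = int(rng.choice(weights.size, p=weights))
            n_leu = min(n_leu, length - 1)
            peps.append(
                (_random_peptide(rng, length, n_leu), n_leu, float(rng.lognormal(0.0, 0.5)))
            )
        proteins[name] = peps
    return proteins


def simulate_study(cfg: SimulationConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate the full multi-cohort peptide quant table with ground truth.

    Protein half-lives are drawn once for the control condition and scaled
    by each cohort's multiplier; peptide repertoires are shared across
    cohorts so pairwise ratios are well defined.  For each mouse at time t
    the fraction new is ``1 - exp(-t ln2 / HL)`` and the expected envelope
    is the old/new mixture at the sample's pool enrichment; each
    isotopologue intensity then receives independent log-normal noise at
    the configured CV.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    proteins = _protein_peptides(cfg, rng)
    names = sorted(proteins)

    base_hl = np.exp(
        rng.normal(math.log(cfg.hl_median_days), cfg.hl_sigma, size=len(names))
    )
    base_ab = np.exp(
        rng.normal(math.log(cfg.abundance_median), cfg.abundance_sigma, size=len(names))
    )
    hl = pd.DataFrame(
        {c: base_hl * cfg.hl_multipliers.get(c, 1.0) for c in cfg.cohorts}, index=names
    )
    ab = pd.DataFrame(
        {c: base_ab * cfg.abundance_multipliers.get(c, 1.0) for c in cfg.cohorts},
        index=names,
    )

    sigma_noise = math.sqrt(math.log(1.0 + cfg.noise_cv**2)) if cfg.noise_cv > 0 else 0.0
    rows = []
    enrich_rows = []
    for cohort in cfg.cohorts:
        mouse_no = 0
        for t in cfg.timepoints:
            for _rep in range(cfg.mice_per_timepoint):
                mouse_no += 1
                sample = f"{cohort}-m{mouse_no:02d}"
                p_t = float(simulate_enrichment_curve(cfg.p_max, cfg.p_rate_per_day, t))
                enrich_rows.append({"sample": sample, "cohort": cohort, "time": t, "p": p_t})
                for prot in names:
                    hl_true = float(hl.loc[prot, cohort])
                    f_true = 1.0 - math.exp(-t * math.log(2.0) / hl_true)
                    ab_true = float(ab.loc[prot, cohort])
                    for seq, n_leu, ionization in proteins[prot]:
                        max_off = default_max_offset(n_leu)
                        nat, lab = mixture_basis(seq, p_t, max_off)
                        expected = ab_true * ionization * (
                            (1.0 - f_true) * nat + f_true * lab
                        )
                        if sigma_noise > 0:
                            noise = rng.lognormal(
                                -0.5 * sigma_noise**2, sigma_noise, size=expected.size
                            )
                            observed = expected * noise
                        else:
                            observed = expected
                        rows.append(
                            {
                                "peptide": seq,
                                "protein": prot,
                                "unique": 1,
                                "sample": sample,
                                "cohort": cohort,
                                "day": t,
                                "intensities": ";".join(
                                    format(v, ".8g") for v in observed
                                ),
                            }
                        )
    table = pd.DataFrame(rows)
    truth = GroundTruth(
        half_life=hl,
        abundance=ab,
        enrichment=pd.DataFrame(enrich_rows).set_index("sample"),
        config=cfg,
    )
    return table, truth


def simulate_cohort(cfg: SimulationConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Alias of :func:`simulate_study` (one or more cohorts per config)."""
    return simulate_study(cfg)


def simulate_polysome_trace(
    areas: np.ndarray,
    centers: np.ndarray,
    widths: np.ndarray,
    baseline: tuple[float, float] = (0.0, 0.0),
    noise_sd: float = 0.0,
    seed: int = 0,
    n_points: int = 1000,
    span: tuple[float, float] = (0.0, 10.0),
) -> tuple[PolysomeTrace, bool]:
    """Sum-of-Gaussians polysome trace with linear baseline and iid noise.

    ``areas`` are the true segment areas; ``baseline`` is (intercept,
    slope).  Returns the trace and a flag warning when adjacent centers sit
    closer than one width apart (valley segmentation may merge them).
    """
    areas = np.asarray(areas, dtype=float)
    centers = np.asarray(centers, dtype=float)
    widths = np.asarray(widths, dtype=float)
    if np.any(areas < 0):
        raise ValueError("areas must be >= 0")
    if np.any(np.diff(centers) <= 0):
        raise ValueError("centers must be strictly increasing")
    overlap_warning = bool(np.any(np.diff(centers) < np.maximum(widths[:-1], widths[1:])))
    x = np.linspace(span[0], span[1], n_points)
    y = baseline[0] + baseline[1] * x
    for area, mu, sd in zip(areas, centers, widths):
        y = y + area / (sd * math.sqrt(2.0 * math.pi)) * np.exp(
            -0.5 * ((x - mu) / sd) ** 2
        )
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, noise_sd, size=y.size)
    return PolysomeTrace(x, np.clip(y, 0.0, None)), overlap_warning
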
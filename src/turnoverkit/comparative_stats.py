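"""Between-group comparisons of half-lives and abundances.

Covers the pairwise half-life-ratio analysis (per-protein HL_A/HL_B with a
z-test on the proportion of ratios above 1), per-protein rate-difference
tests with Benjamini-Hochberg FDR control, differential abundance from
summed chromatographic AUC, pathway/compartment half-life summaries with
one-way ANOVA, log2-ratio matrices for heatmap export, and Spearman
correlations between comparisons.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .deconvolution import PeptideObservation
from .kinetics import TurnoverFit

__all__ = [
    "HLRatioTable",
    "PathwaySummary",
    "CorrelationResult",
    "compute_hl_ratios",
    "ratio_proportion_ztest",
    "hl_difference_test",
    "bh_fdr",
    "differential_abundance",
    "select_extreme_hl",
    "pathway_summary",
    "comparison_matrix",
    "spearman_comparison",
]

logger = logging.getLogger(__name__)


@dataclass
class HLRatioTable:
    """Per-protein half-life ratios between two groups (A over B)."""

    group_a: str
    group_b: str
    table: pd.DataFrame  # index protein; columns hl_a, hl_b, ratio, log2_ratio

    @property
    def median_ratio(self) -> float:
        return float(self.table["ratio"].median())


@dataclass
class PathwaySummary:
    name: str
    category: str
    per_group: pd.DataFrame  # index group; box statistics columns
    anova_f: float
    anova_p: float
    n_proteins: int


@dataclass
class CorrelationResult:
    label_x: str
    label_y: str
    rho: float
    p_value: float
    n: int
    degenerate: bool = False


def _fits_frame(fits: list[TurnoverFit]) -> pd.DataFrame:
    rows = [
        {
            "protein": f.protein,
            "cohort": f.cohort,
            "k": f.k,
            "half_life": f.half_life,
            "slope_se": f.slope_se,
            "n_points": f.n_points,
        }
        for f in fits
        if math.isfinite(f.half_life)
    ]
    return pd.DataFrame(rows)


def compute_hl_ratios(
    fits_a: list[TurnoverFit], fits_b: list[TurnoverFit]
) -> HLRatioTable:
    """Half-life ratio A/B per protein present with a finite HL in both groups."""
    fa, fb = _fits_frame(fits_a), _fits_frame(fits_b)
    if fa.empty or fb.empty:
        raise ValueError("no finite half-life fits in one of the groups")
    merged = fa.set_index("protein")[["half_life"]].join(
        fb.set_index("protein")[["half_life"]], how="inner", lsuffix="_a", rsuffix="_b"
    )
    if merged.empty:
        raise ValueError("groups share no proteins with finite half-lives")
    merged = merged.rename(columns={"half_life_a": "hl_a", "half_life_b": "hl_b"})
    merged["ratio"] = merged["hl_a"] / merged["hl_b"]
    merged["log2_ratio"] = np.log2(merged["ratio"])
    group_a = fits_a[0].cohort if fits_a else "A"
    group_b = fits_b[0].cohort if fits_b else "B"
    return HLRatioTable(group_a=group_a, group_b=group_b, table=merged.sort_index())


def ratio_proportion_ztest(ratios: "HLRatioTable | np.ndarray") -> tuple[float, float, float]:
    """z-test that the proportion of ratios above 1 is 0.5.

    Returns ``(proportion_above_1, z, two_sided_p)``.  Ties at exactly 1 are
    dropped.  Refuses n < 10 where the normal approximation is invalid.
    """
    values = (
        ratios.table["ratio"].to_numpy()
        if isinstance(ratios, HLRatioTable)
        else np.asarray(ratios, dtype=float)
    )
    values = values[values != 1.0]
    n = values.size
    if n < 10:
        raise ValueError(f"n={n} < 10: normal approximation to the proportion invalid")
    prop = float(np.mean(values > 1.0))
    z = (prop - 0.5) / math.sqrt(0.25 / n)
    p = 2.0 * stats.norm.sf(abs(z))
    return prop, float(z), float(p)


def log_ratio_ttest(ratios: HLRatioTable) -> tuple[float, float]:
    """One-sample t-test that log2 ratios are centered at 0 (cross-check)."""
    t, p = stats.ttest_1samp(ratios.table["log2_ratio"].to_numpy(), 0.0)
    return float(t), float(p)


def hl_difference_test(
    fits_a: list[TurnoverFit], fits_b: list[TurnoverFit]
) -> pd.DataFrame:
    """Per-protein Welch-style t-test on the rate-constant difference.

    Uses each group's regression slope and its standard error; degrees of
    freedom by Welch-Satterthwaite with n_points - 1 per side.  Returns a
    frame indexed by protein with k_a, k_b, t, p_value, q_value.
    """
    fa = {f.protein: f for f in fits_a if f.slope_se > 0}
    fb = {f.protein: f for f in fits_b if f.slope_se > 0}
    shared = sorted(set(fa) & set(fb))
    rows = []
    for protein in shared:
        a, b = fa[protein], fb[protein]
        se2 = a.slope_se**2 + b.slope_se**2
        t_stat = (a.k - b.k) / math.sqrt(se2)
        df_num = se2**2
        df_den = a.slope_se**4 / (a.n_points - 1) + b.slope_se**4 / (b.n_points - 1)
        df = df_num / df_den if df_den > 0 else a.n_points + b.n_points - 2
        p = 2.0 * stats.t.sf(abs(t_stat), df)
        rows.append(
            {"protein": protein, "k_a": a.k, "k_b": b.k, "t": t_stat, "p_value": p}
        )
    out = pd.DataFrame(rows).set_index("protein")
    out["q_value"] = bh_fdr(out["p_value"].to_numpy()) if len(out) else []
    out.attrs["method"] = "welch-t-on-regression-slopes"
    return out


def bh_fdr(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-preserving, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def differential_abundance(
    observations_a: list[PeptideObservation],
    observations_b: list[PeptideObservation],
    min_mice: int = 3,
) -> pd.DataFrame:
    """Differential protein abundance between two groups of mice.

    Per mouse, a protein's abundance is the summed total AUC of its unique
    peptides.  Samples are put on a common scale by median-of-ratios size
    factors (per sample, the median across proteins of the ratio to each
    protein's geometric-mean reference — robust to a minority of genuinely
    changed proteins), abundances are log2-transformed, and groups compared
    by a two-sided Welch t-test with BH q-values.  Returns a frame indexed
    by protein with log2_fc, p_value, q_value, n_a, n_b.
    """
    mat_a = _abundance_matrix(observations_a)
    mat_b = _abundance_matrix(observations_b)
    joint = pd.concat([mat_a, mat_b], axis=1)
    with np.errstate(divide="ignore"):
        log_ref = np.log(joint.where(joint > 0)).mean(axis=1, skipna=True)
    ratios = joint.div(np.exp(log_ref), axis=0)
    size_factors = ratios.median(axis=0, skipna=True)
    mat_a = mat_a / size_factors[mat_a.columns]
    mat_b = mat_b / size_factors[mat_b.columns]
    # second pass: recenter so the median protein shows zero fold change,
    # absorbing the residual shift a one-sided set of true changes leaves
    # in quantile-based size factors
    with np.errstate(divide="ignore"):
        la_mean = np.log2(mat_a.where(mat_a > 0)).mean(axis=1, skipna=True)
        lb_mean = np.log2(mat_b.where(mat_b > 0)).mean(axis=1, skipna=True)
    shift = float((la_mean - lb_mean).dropna().median())
    mat_a = mat_a / 2.0**shift
    shared = sorted(set(mat_a.index) & set(mat_b.index))
    rows = []
    for protein in shared:
        va = mat_a.loc[protein].dropna().to_numpy()
        vb = mat_b.loc[protein].dropna().to_numpy()
        va, vb = va[va > 0], vb[vb > 0]
        if va.size < min_mice or vb.size < min_mice:
            logger.info("protein %s skipped: insufficient mice with signal", protein)
            continue
        la, lb = np.log2(va), np.log2(vb)
        if np.var(la) == 0 and np.var(lb) == 0:
            p = 1.0 if np.isclose(la.mean(), lb.mean()) else 0.0
        else:
            p = float(stats.ttest_ind(la, lb, equal_var=False).pvalue)
        rows.append(
            {
                "protein": protein,
                "log2_fc": float(la.mean() - lb.mean()),
                "p_value": p,
                "n_a": va.size,
                "n_b": vb.size,
            }
        )
    out = pd.DataFrame(rows).set_index("protein")
    out["q_value"] = bh_fdr(out["p_value"].to_numpy()) if len(out) else []
    return out


def _abundance_matrix(observations: list[PeptideObservation]) -> pd.DataFrame:
    """Proteins x samples matrix of summed unique-peptide total AUC."""
    records = [
        {"protein": o.protein, "sample": o.sample, "auc": o.total_auc}
        for o in observations
        if o.is_unique
    ]
    frame = pd.DataFrame(records)
    if frame.empty:
        raise ValueError("no unique-peptide observations")
    return frame.pivot_table(
        index="protein", columns="sample", values="auc", aggfunc="sum"
    )


def select_extreme_hl(
    fits: list[TurnoverFit], fraction: float, end: str = "shortest"
) -> list[str]:
    """Proteins in the shortest- or longest-lived ``fraction`` of half-lives.

    Returns floor(fraction * n) protein ids; ties on half-life break by
    protein id for determinism.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    if end not in ("shortest", "longest"):
        raise ValueError("end must be 'shortest' or 'longest'")
    finite = [f for f in fits if math.isfinite(f.half_life)]
    n_take = int(math.floor(fraction * len(finite)))
    reverse = end == "longest"
    ordered = sorted(
        finite,
        key=lambda f: (-f.half_life if reverse else f.half_life, f.protein),
    )
    return [f.protein for f in ordered[:n_take]]


def pathway_summary(
    fits_by_group: dict[str, list[TurnoverFit]],
    mapping: pd.DataFrame,
) -> list[PathwaySummary]:
    """Half-life box statistics per pathway/compartment and one-way ANOVA.

    ``mapping`` needs columns protein_id, pathway_name, category.  Pathways
    with no measured mapped proteins are omitted with a log entry.
    """
    hl: dict[str, dict[str, float]] = {
        group: {f.protein: f.half_life for f in fits if math.isfinite(f.half_life)}
        for group, fits in fits_by_group.items()
    }
    summaries: list[PathwaySummary] = []
    for (name, category), sub in mapping.groupby(["pathway_name", "category"], sort=True):
        proteins = sub["protein_id"].tolist()
        groups, samples = [], []
        per_group_rows = {}
        for group in sorted(hl):
            values = np.array([hl[group][p] for p in proteins if p in hl[group]])
            if values.size == 0:
                continue
            groups.append(group)
            samples.append(values)
            q1, med, q3 = np.percentile(values, [25, 50, 75])
            p5, p95 = np.percentile(values, [5, 95])
            per_group_rows[group] = {
                "n": values.size,
                "mean": float(values.mean()),
                "median": float(med),
                "q1": float(q1),
                "q3": float(q3),
                "p5": float(p5),
                "p95": float(p95),
            }
        if not groups:
            logger.info("pathway %s omitted: no mapped measured proteins", name)
            continue
        if len(groups) >= 2 and all(s.size >= 2 for s in samples):
            f_stat, p = stats.f_oneway(*samples)
            f_stat, p = float(f_stat), float(p)
            if math.isnan(p):  # zero within-group variance
                f_stat, p = 0.0, 1.0
        else:
            f_stat, p = math.nan, math.nan
        summaries.append(
            PathwaySummary(
                name=name,
                category=category,
                per_group=pd.DataFrame(per_group_rows).T,
                anova_f=f_stat,
                anova_p=p,
                n_proteins=len(set().union(*(set(hl[g]) & set(proteins) for g in groups))),
            )
        )
    return summaries


def comparison_matrix(
    comparisons: dict[str, pd.DataFrame],
    q_threshold: float = 0.05,
) -> pd.DataFrame:
    """Proteins x comparisons matrix of log2 ratios for heatmap export.

    ``comparisons`` maps a label (e.g. ``"YCR/YCL"``) to a frame indexed by
    protein with columns ``log2_ratio`` (or ``log2_fc``) and ``q_value``.
    The protein universe is every protein significant (q < threshold) in at
    least one comparison; missing cells are NaN.
    """
    selected: set[str] = set()
    for frame in comparisons.values():
        selected |= set(frame.index[frame["q_value"] < q_threshold])
    cols = {}
    for label, frame in comparisons.items():
        value_col = "log2_ratio" if "log2_ratio" in frame.columns else "log2_fc"
        cols[label] = frame[value_col]
    out = pd.DataFrame(cols).reindex(sorted(selected))
    return out


def spearman_comparison(
    x: pd.Series,
    y: pd.Series,
    label_x: str = "x",
    label_y: str = "y",
    min_n: int = 5,
) -> CorrelationResult:
    """Spearman rank correlation of two per-protein log-ratio vectors.

    Pairs over shared proteins (index intersection); average ranks for ties;
    two-sided p by the t approximation.  A constant input yields an
    undefined rho, returned as NaN with the degenerate flag set.
    """
    shared = x.index.intersection(y.index)
    if len(shared) < min_n:
        raise ValueError(f"only {len(shared)} shared proteins; need >= {min_n}")
    xv = x.loc[shared].to_numpy(dtype=float)
    yv = y.loc[shared].to_numpy(dtype=float)
    if np.all(xv == xv[0]) or np.all(yv == yv[0]):
        return CorrelationResult(label_x, label_y, math.nan, math.nan, len(shared), True)
    rho, p = stats.spearmanr(xv, yv)
    return CorrelationResult(label_x, label_y, float(rho), float(p), len(shared))
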
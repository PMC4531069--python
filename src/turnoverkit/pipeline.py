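"""End-to-end pipeline: enrichment -> percent new -> pooling -> kinetics ->
group comparisons -> pathway summaries, with TSV outputs and a JSON run
manifest."""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict
from itertools import combinations
from pathlib import Path

import pandas as pd

from . import __version__
from .comparative_stats import (
    bh_fdr,
    compute_hl_ratios,
    hl_difference_test,
    pathway_summary,
    ratio_proportion_ztest,
)
from .deconvolution import (
    EnrichmentEstimate,
    PeptideObservation,
    estimate_sample_enrichment,
    percent_new_per_peptide,
)
from .io import read_pathway_mapping, read_peptide_table
from .kinetics import fit_first_order, pool_protein_fraction_new

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "fit_all_turnover"]


@dataclass
class RunConfig:
    """Paths and stage parameters for one pipeline run."""

    peptide_table: str
    out_dir: str
    pathway_mapping: str | None = None
    q_threshold: float = 0.05
    min_points: int = 4
    enrichment_grid_size: int = 101
    enrichment_max_peptides: int | None = 200
    signal_floor: float = 0.0
    drop_clipped: bool = False
    seed: int = 0
    log_level: str = "INFO"
    extra: dict = field(default_factory=dict)

    def validate(self) -> None:
        if not 0.0 < self.q_threshold < 1.0:
            raise ValueError("q_threshold must lie in (0, 1)")
        if not Path(self.peptide_table).exists():
            raise FileNotFoundError(f"peptide table not found: {self.peptide_table}")
        if self.pathway_mapping and not Path(self.pathway_mapping).exists():
            raise FileNotFoundError(
                f"pathway mapping not found: {self.pathway_mapping}"
            )


def estimate_all_enrichments(
    observations: list[PeptideObservation],
    signal_floor: float = 0.0,
    max_peptides: int | None = 200,
) -> dict[str, EnrichmentEstimate]:
    by_sample: dict[str, list[PeptideObservation]] = {}
    for obs in observations:
        by_sample.setdefault(obs.sample, []).append(obs)
    return {
        sample: estimate_sample_enrichment(
            by_sample[sample], signal_floor=signal_floor, max_peptides=max_peptides
        )
        for sample in sorted(by_sample)
    }


def fit_all_turnover(
    observations: list[PeptideObservation],
    enrichments: dict[str, EnrichmentEstimate] | None = None,
    min_points: int = 4,
    signal_floor: float = 0.0,
    drop_clipped: bool = False,
    max_peptides: int | None = 200,
):
    """Library-level shortcut: observations -> per-cohort turnover fits.

    Returns ``(fits_by_cohort, fraction_new_estimates, enrichments)``.
    """
    if enrichments is None:
        enrichments = estimate_all_enrichments(
            observations, signal_floor=signal_floor, max_peptides=max_peptides
        )
    estimates = []
    logged_drops: set[str] = set()
    for obs in observations:
        if obs.n_leucines == 0 or obs.total_auc <= 0:
            reason = "no leucine" if obs.n_leucines == 0 else "zero signal"
            if obs.peptide not in logged_drops:
                logged_drops.add(obs.peptide)
                logger.info("peptide %s dropped: %s", obs.peptide, reason)
            continue
        estimates.append(percent_new_per_peptide(obs, enrichments[obs.sample]))
    courses = pool_protein_fraction_new(estimates, drop_clipped=drop_clipped)
    fits_by_cohort: dict[str, list] = {}
    for (protein, cohort), course in courses.items():
        try:
            fit = fit_first_order(course, min_points=min_points)
        except ValueError as exc:
            logger.info("fit skipped for %s/%s: %s", protein, cohort, exc)
            continue
        fits_by_cohort.setdefault(cohort, []).append(fit)
    return fits_by_cohort, estimates, enrichments


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage in order and write TSV outputs plus a manifest."""
    config.validate()
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    stage = "read"
    try:
        observations = read_peptide_table(config.peptide_table)
        stage = "enrich"
        enrichments = estimate_all_enrichments(
            observations,
            signal_floor=config.signal_floor,
            max_peptides=config.enrichment_max_peptides,
        )
        enr_frame = pd.DataFrame(
            [
                {
                    "sample": e.sample,
                    "p": e.p,
                    "n_peptides_used": e.n_peptides_used,
                    "dispersion": e.dispersion,
                }
                for e in enrichments.values()
            ]
        )
        enr_frame.to_csv(out / "enrichment.tsv", sep="\t", index=False)

        stage = "turnover"
        fits_by_cohort, estimates, _ = fit_all_turnover(
            observations,
            enrichments=enrichments,
            min_points=config.min_points,
            drop_clipped=config.drop_clipped,
        )
        est_frame = pd.DataFrame(
            [
                {
                    "peptide": e.peptide,
                    "protein": e.protein,
                    "sample": e.sample,
                    "cohort": e.cohort,
                    "day": e.time,
                    "f": e.f,
                    "scale": e.scale,
                    "residual": e.residual,
                    "flags": ",".join(e.flags),
                }
                for e in estimates
            ]
        )
        est_frame.to_csv(out / "fraction_new.tsv", sep="\t", index=False)
        fit_frame = pd.DataFrame(
            [
                {
                    "protein": f.protein,
                    "cohort": f.cohort,
                    "k": f.k,
                    "half_life": f.half_life,
                    "slope_se": f.slope_se,
                    "r_squared": f.r_squared,
                    "n_points": f.n_points,
                    "flags": ",".join(f.flags),
                }
                for fits in fits_by_cohort.values()
                for f in fits
            ]
        )
        fit_frame.to_csv(out / "half_lives.tsv", sep="\t", index=False)

        stage = "compare"
        comparisons = {}
        for a, b in combinations(sorted(fits_by_cohort), 2):
            try:
                ratios = compute_hl_ratios(fits_by_cohort[a], fits_by_cohort[b])
                prop, z, p = ratio_proportion_ztest(ratios)
            except ValueError as exc:
                logger.info("comparison %s/%s skipped: %s", a, b, exc)
                continue
            tests = hl_difference_test(fits_by_cohort[a], fits_by_cohort[b])
            comparisons[f"{a}/{b}"] = {
                "median_ratio": ratios.median_ratio,
                "proportion_above_1": prop,
                "z": z,
                "p": p,
                "n": len(ratios.table),
                "n_q_below_threshold": int(
                    (tests["q_value"] < config.q_threshold).sum()
                ),
            }
            ratios.table.to_csv(out / f"hl_ratio_{a}_vs_{b}.tsv", sep="\t")
            tests.to_csv(out / f"hl_test_{a}_vs_{b}.tsv", sep="\t")

        stage = "pathways"
        n_pathways = 0
        if config.pathway_mapping:
            mapping = read_pathway_mapping(config.pathway_mapping)
            summaries = pathway_summary(fits_by_cohort, mapping)
            n_pathways = len(summaries)
            rows = []
            for s in summaries:
                for group, stats_row in s.per_group.iterrows():
                    rows.append(
                        {
                            "pathway": s.name,
                            "category": s.category,
                            "group": group,
                            **stats_row.to_dict(),
                            "anova_f": s.anova_f,
                            "anova_p": s.anova_p,
                        }
                    )
            pd.DataFrame(rows).to_csv(out / "pathway_summary.tsv", sep="\t", index=False)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "parameters": {
            k: v for k, v in asdict(config).items() if k not in ("extra",)
        },
        "n_observations": len(observations),
        "n_samples": len(enrichments),
        "n_fits": int(len(fit_frame)),
        "comparisons": comparisons,
        "n_pathways": n_pathways,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
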
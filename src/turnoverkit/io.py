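"""Readers and writers for the pipeline's plain-text tables.

The peptide quant table is TSV/CSV with columns: peptide, protein, unique
(0/1), sample, cohort, day, intensities (semicolon-delimited floats,
offset 0 first).  All stage outputs are TSV so runs diff cleanly.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .deconvolution import PeptideObservation

__all__ = [
    "REQUIRED_COLUMNS",
    "read_peptide_table",
    "write_peptide_table",
    "observations_to_frame",
    "observations_from_frame",
    "read_pathway_mapping",
]

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("peptide", "protein", "unique", "sample", "cohort", "day", "intensities")


def _read_delimited(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    return pd.read_csv(path, sep=sep, dtype=str)


def read_peptide_table(path: str | Path) -> list[PeptideObservation]:
    """Read and validate a peptide quant table.

    Raises on a missing required column (named in the error); malformed
    rows (unparseable or negative intensities) are rejected with their line
    numbers reported in one error.
    """
    frame = _read_delimited(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"peptide table {path}: missing required column(s) {missing}")
    observations: list[PeptideObservation] = []
    bad_rows: list[tuple[int, str]] = []
    for i, row in frame.iterrows():
        lineno = i + 2  # header is line 1
        try:
            intensities = np.array(
                [float(v) for v in str(row["intensities"]).split(";")]
            )
            obs = PeptideObservation(
                peptide=row["peptide"],
                protein=row["protein"],
                is_unique=str(row["unique"]).strip() in ("1", "True", "true"),
                sample=row["sample"],
                cohort=row["cohort"],
                time=float(row["day"]),
                intensities=intensities,
            )
        except (ValueError, TypeError) as exc:
            bad_rows.append((lineno, str(exc)))
            continue
        observations.append(obs)
    if bad_rows:
        details = "; ".join(f"line {ln}: {msg}" for ln, msg in bad_rows[:10])
        raise ValueError(f"peptide table {path}: {len(bad_rows)} malformed row(s): {details}")
    return observations


def observations_to_frame(observations: list[PeptideObservation]) -> pd.DataFrame:
    rows = [
        {
            "peptide": o.peptide,
            "protein": o.protein,
            "unique": int(o.is_unique),
            "sample": o.sample,
            "cohort": o.cohort,
            "day": o.time,
            "intensities": ";".join(format(v, ".8g") for v in o.intensities),
        }
        for o in observations
    ]
    return pd.DataFrame(rows)


def observations_from_frame(frame: pd.DataFrame) -> list[PeptideObservation]:
    """In-memory counterpart of :func:`read_peptide_table`."""
    return [
        PeptideObservation(
            peptide=r.peptide,
            protein=r.protein,
            is_unique=bool(int(r.unique)),
            sample=r.sample,
            cohort=r.cohort,
            time=float(r.day),
            intensities=np.array([float(v) for v in str(r.intensities).split(";")]),
        )
        for r in frame.itertuples()
    ]


def write_peptide_table(observations: list[PeptideObservation], path: str | Path) -> None:
    observations_to_frame(observations).to_csv(path, sep="\t", index=False)


def read_pathway_mapping(path: str | Path) -> pd.DataFrame:
    """Pathway mapping TSV with columns protein_id, pathway_name, category."""
    frame = _read_delimited(path)
    required = ("protein_id", "pathway_name", "category")
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ValueError(f"pathway mapping {path}: missing column(s) {missing}")
    bad = ~frame["category"].isin(["pathway", "compartment"])
    if bad.any():
        raise ValueError(
            f"pathway mapping {path}: category must be 'pathway' or 'compartment'"
        )
    return frame
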
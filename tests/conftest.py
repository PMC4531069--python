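import numpy as np
import pytest

import turnoverkit as tk
from turnoverkit.deconvolution import PeptideObservation
from turnoverkit.isotope_model import default_max_offset, mixture_basis


def table_to_observations(table):
    """Parse a simulated peptide quant frame into observations."""
    from turnoverkit.io import observations_from_frame

    return observations_from_frame(table)


def make_observation(
    sequence: str,
    f: float,
    p: float,
    scale: float = 1e6,
    sample: str = "s1",
    cohort: str = "YCL",
    time: float = 7.0,
    protein: str = "P1",
    is_unique: bool = True,
) -> PeptideObservation:
    """Forward-simulate a noiseless mixture observation."""
    L = sequence.count("L")
    nat, lab = mixture_basis(sequence, p, default_max_offset(L))
    return PeptideObservation(
        peptide=sequence,
        protein=protein,
        is_unique=is_unique,
        sample=sample,
        cohort=cohort,
        time=time,
        intensities=scale * ((1.0 - f) * nat + f * lab),
    )


@pytest.fixture(scope="session")
def small_study():
    """Two-cohort noisy study with a known 1.6x half-life effect."""
    cfg = tk.SimulationConfig(
        n_proteins=40,
        cohorts=("YCL", "YCR"),
        hl_multipliers={"YCR": 1.6},
        noise_cv=0.05,
        seed=11,
    )
    table, truth = tk.simulate_study(cfg)
    return table, truth


@pytest.fixture(scope="session")
def small_study_fits(small_study):
    table, truth = small_study
    observations = table_to_observations(table)
    fits_by_cohort, estimates, enrichments = tk.fit_all_turnover(observations)
    return fits_by_cohort, estimates, enrichments, truth
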
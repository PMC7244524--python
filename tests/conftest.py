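import pandas as pd
import pytest

from lfqdiff import SimulationTruth, generate_design
from lfqdiff.simulate import simulate_peptide_intensities


@pytest.fixture(scope="session")
def design():
    """The study layout: 2 strains x 2 media x 3 times x 4 replicates."""
    return generate_design(2, 2, 3, 4)


@pytest.fixture(scope="session")
def small_design():
    return generate_design(2, 1, 2, 3)


@pytest.fixture(scope="session")
def null_peptide_table(design):
    """50 proteins, 4 peptides each, no fixed effects, default noise."""
    truth = SimulationTruth(sigma_theta=0.1, sigma_eps=0.2, seed=1234)
    return simulate_peptide_intensities(truth, design, 50, 4)


def toy_peptide_row(peptide, charge, protein, rt, sample, value):
    return {
        "peptide": peptide,
        "charge": charge,
        "protein": protein,
        "rt_seconds": float(rt),
        "sample_id": sample,
        "log10_intensity": float(value),
    }


@pytest.fixture()
def toy_table():
    """Tiny handmade long table over 3 samples."""
    rows = []
    for s in ("A", "B", "C"):
        rows.append(toy_peptide_row("pep1", 2, "P1", 100, s, 5.0))
        rows.append(toy_peptide_row("pep2", 2, "P1", 200, s, 6.0))
        rows.append(toy_peptide_row("pep3", 3, "P2", 300, s, 4.5))
    return pd.DataFrame(rows)
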
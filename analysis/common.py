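"""Shared configuration of the synthetic comparative-proteomics study
driven by the numbered analysis scripts.

Two strains grown on two carbon sources, sampled at three culture times
with four biological replicates (48 LC-MS runs). A fifth of the proteins
carry a planted strain effect, smaller fractions carry medium and time
effects, the rest are null. Large intermediate tables live under
scratch/ (regenerated by 01_simulate_dataset.py); per-protein summary
tables land in results/.
"""

from pathlib import Path

import numpy as np

ROOT = Path(__file__).resolve().parent.parent
SCRATCH = ROOT / "scratch" / "study"
RESULTS = ROOT / "results"

SEED = 2024
N_PROTEINS = 120
PEPTIDES_PER_PROTEIN = 3

# planted per-group truths (log10 scale for XIC; the spectral-count route
# reuses the strain groups on the natural-log scale). Differential groups
# come in both directions, as in real proteomes — RT-local normalization
# assumes changes roughly balance out across the proteome — and make up
# about a quarter of the proteins, as in typical comparative studies
GROUPS = {
    "background": dict(n=90),
    "strain_up": dict(n=6, strain=np.array([0.25, -0.25])),
    "strain_down": dict(n=6, strain=np.array([-0.25, 0.25])),
    "medium_up": dict(n=4, medium=np.array([0.2, -0.2])),
    "medium_down": dict(n=4, medium=np.array([-0.2, 0.2])),
    "time_up": dict(n=5, time=np.array([0.25, 0.0, -0.25])),
    "time_down": dict(n=5, time=np.array([-0.25, 0.0, 0.25])),
}

NOISE = dict(sigma_theta=0.1, sigma_eps=0.2)


def ensure_dirs() -> None:
    SCRATCH.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(parents=True, exist_ok=True)
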
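"""Simulate the synthetic comparative study: peptide XIC intensities and
spectral counts over the 2 strains x 2 media x 3 times x 4 replicates
design, with planted differential proteins, RT-dependent bias and
missingness, plus promoter sequences with planted Pho boxes.

Writes the design and ground truth to results/, the (large) quantitative
tables to scratch/study/.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import GROUPS, NOISE, PEPTIDES_PER_PROTEIN, RESULTS, SCRATCH, SEED, ensure_dirs

from lfqdiff import io as lio
from lfqdiff.simulate import (
    PlantedBox,
    SimulationTruth,
    generate_design,
    plant_pho_boxes,
    simulate_peptide_intensities,
    simulate_spectral_counts,
    sinusoidal_rt_bias,
)


def main() -> None:
    ensure_dirs()
    design = generate_design(2, 2, 3, 4)
    lio.write_design(design, RESULTS / "design.tsv")
    ref_id = sorted(design["sample_id"])[0]
    bias = sinusoidal_rt_bias(0.3, 3600.0, seed=SEED, exempt=[ref_id])

    pep_parts, sc_parts, truth_rows = [], [], []
    offset = 0
    for gi, (group, spec) in enumerate(GROUPS.items()):
        n = spec["n"]
        effects = {k: v for k, v in spec.items() if k != "n"}
        truth = SimulationTruth(
            **effects, **NOISE, rt_bias=bias, missing_rate=0.05, seed=SEED + gi
        )
        pep = simulate_peptide_intensities(truth, design, n, PEPTIDES_PER_PROTEIN)
        sc_strain = None
        if group == "strain_up":
            sc_strain = np.log(2) * np.array([1.0, -1.0])
        elif group == "strain_down":
            sc_strain = np.log(2) * np.array([-1.0, 1.0])
        sc_truth = SimulationTruth(
            mu=np.log(12), strain=sc_strain, seed=SEED + 50 + gi
        )
        sc = simulate_spectral_counts(sc_truth, design, n)

        def relabel(name: str) -> str:
            i = int(name[1:].split("_")[0])
            rest = name[name.index("_"):] if "_" in name else ""
            return f"PROT{offset + i:03d}{rest}"

        pep["protein"] = pep["protein"].map(relabel)
        pep["peptide"] = pep["peptide"].map(relabel)
        sc["protein"] = sc["protein"].map(relabel)
        pep_parts.append(pep)
        sc_parts.append(sc)
        truth_rows += [
            {"protein": f"PROT{offset + i:03d}", "group": group} for i in range(1, n + 1)
        ]
        offset += n

    peptides = pd.concat(pep_parts, ignore_index=True)
    counts = pd.concat(sc_parts, ignore_index=True)
    peptides.to_csv(SCRATCH / "peptides_raw.tsv", sep="\t", index=False)
    counts.to_csv(SCRATCH / "spectral_counts.tsv", sep="\t", index=False)
    pd.DataFrame(truth_rows).to_csv(RESULTS / "planted_truth.tsv", sep="\t", index=False)

    # promoters: one with a canonical box, one with a half box, one empty
    records = []
    planted = []
    for k, (sid, boxes) in enumerate(
        (
            ("prom_canonical", [PlantedBox(start=120, klass="canonical")]),
            ("prom_half", [PlantedBox(start=150, klass="half")]),
            ("prom_minus", [PlantedBox(start=90, strand="-", klass="canonical")]),
            ("prom_empty", []),
        )
    ):
        rec, truth = plant_pho_boxes(400, 0.72, boxes, seed=SEED + k, sequence_id=sid)
        records.append(rec)
        planted += [
            {"sequence_id": sid, "start": s, "strand": st, "klass": kl}
            for s, st, kl in truth.positions
        ]
    lio.write_fasta(records, SCRATCH / "promoters.fasta")
    pd.DataFrame(planted).to_csv(RESULTS / "planted_pho_boxes.tsv", sep="\t", index=False)

    print(f"design: {len(design)} samples, reference candidate {ref_id}")
    print(f"peptide table: {len(peptides)} rows, {peptides['protein'].nunique()} proteins")
    print(f"spectral counts: {len(counts)} rows")
    print(f"promoters: {len(records)} sequences, {len(planted)} planted boxes")


if __name__ == "__main__":
    main()
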
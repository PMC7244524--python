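"""Per-protein differential abundance: Poisson GLMs on spectral counts
(after the 10-spectra prefilter) and REML mixed models on the filtered
XIC table, BH adjustment per term within each method, and the merged
significant set with its Venn partition.

Writes the per-(protein, term) result table and the partition to
results/, and prints detection against the planted truth.
"""

import json
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import RESULTS, SCRATCH, ensure_dirs

from lfqdiff import io as lio
from lfqdiff.diff import fit_all_sc, fit_all_xic, merge_methods, results_to_frame, significant_proteins


def main() -> None:
    ensure_dirs()
    pep_path = SCRATCH / "peptides_filtered.tsv"
    if not pep_path.exists():
        raise SystemExit("run 02_normalize_and_filter.py first")
    design = lio.read_design(RESULTS / "design.tsv")
    peptides = lio.read_peptide_table(pep_path, design)
    counts = lio.read_spectral_counts(SCRATCH / "spectral_counts.tsv", design)

    sc_fits = fit_all_sc(counts, design, min_avg_diff=10)
    print(f"spectral counts: {len(sc_fits)} proteins pass the 10-spectra prefilter")
    xic_fits = fit_all_xic(peptides, design)
    print(f"XIC: {len(xic_fits)} proteins modeled")

    merged, partition = merge_methods(sc_fits, xic_fits, alpha=0.05)
    frame = pd.concat(
        [results_to_frame(sc_fits), results_to_frame(xic_fits)], ignore_index=True
    )
    lio.write_results(frame, RESULTS / "differential_abundance.tsv", float_format="%.5g")
    with open(RESULTS / "venn_partition.json", "w") as fh:
        json.dump(partition, fh, indent=2)
    print("partition:", partition)

    truth = pd.read_csv(RESULTS / "planted_truth.tsv", sep="\t")
    truth["factor"] = truth["group"].str.replace(r"_(up|down)$", "", regex=True)
    sig = significant_proteins(merged, 0.05)
    for factor, sub in truth.groupby("factor"):
        hits = len(set(sub["protein"]) & sig)
        print(f"  {factor:>10}: {hits}/{len(sub)} called significant")


if __name__ == "__main__":
    main()
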
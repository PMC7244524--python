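"""Sample-level QC (peptide counts + PCA distance from design-cell
centroids) and protein-profile clustering of the significant set:
hierarchical with Euclidean distances for the heatmap ordering, SOTA for
temporal profile groups.

Writes sample flags and cluster assignments to results/.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import RESULTS, SCRATCH, ensure_dirs

from lfqdiff import io as lio
from lfqdiff.cluster import flag_outlier_samples, hierarchical_cluster, scale_profiles, sota_cluster


def main() -> None:
    ensure_dirs()
    pep_path = SCRATCH / "peptides_filtered.tsv"
    if not pep_path.exists():
        raise SystemExit("run 02 and 03 first")
    design = lio.read_design(RESULTS / "design.tsv")
    peptides = lio.read_peptide_table(pep_path, design)
    results = lio.read_results(RESULTS / "differential_abundance.tsv")

    flags = flag_outlier_samples(peptides, design, min_peptides=10)
    flags.to_csv(RESULTS / "sample_qc.tsv", sep="\t", index=False)
    print(f"sample QC: {int(flags['flagged'].sum())}/{len(flags)} samples flagged")

    sig = set(
        results.loc[
            (results["method"] == "XIC") & (results["p_adj"] < 0.05), "protein"
        ]
    )
    print(f"clustering {len(sig)} XIC-significant proteins")
    abundance = peptides[peptides["protein"].isin(sig)].pivot_table(
        index="protein", columns="sample_id", values="log10_intensity", aggfunc="mean"
    )
    abundance = abundance.fillna(abundance.mean(axis=0))
    scaled = scale_profiles(abundance)

    hc = hierarchical_cluster(scaled, n_clusters=3)
    sota = sota_cluster(scaled, max_clusters=4, seed=1)
    out = pd.DataFrame(
        {
            "protein": list(scaled.index),
            "hierarchical_cluster": hc.labels,
            "sota_cluster": sota.labels,
        }
    )
    out.to_csv(RESULTS / "protein_clusters.tsv", sep="\t", index=False)
    print(out.groupby(["hierarchical_cluster", "sota_cluster"]).size().to_string())


if __name__ == "__main__":
    main()
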
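"""Normalize the simulated peptide table over retention time and run the
peptide QC ladder (RT stability -> shared peptides -> reproducibility ->
intra-protein correlation).

Reads scratch/study/peptides_raw.tsv, writes the normalized+filtered
table back to scratch/ and the per-stage filter report to results/.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import RESULTS, SCRATCH, ensure_dirs

from lfqdiff import io as lio
from lfqdiff.normalize import choose_reference, normalize_table
from lfqdiff.qc import apply_filter_ladder, reports_to_frame


def main() -> None:
    ensure_dirs()
    raw_path = SCRATCH / "peptides_raw.tsv"
    if not raw_path.exists():
        raise SystemExit("run 01_simulate_dataset.py first")
    design = lio.read_design(RESULTS / "design.tsv")
    table = lio.read_peptide_table(raw_path, design)

    reference = choose_reference(table)
    normalized, curves = normalize_table(table, reference=reference)
    print(f"reference sample: {reference} ({len(curves)} samples corrected)")

    filtered, reports = apply_filter_ladder(normalized, design)
    report = reports_to_frame(reports)
    report.drop(columns="removed_peptide_charges").to_csv(
        RESULTS / "filter_report.tsv", sep="\t", index=False
    )
    filtered.to_csv(SCRATCH / "peptides_filtered.tsv", sep="\t", index=False)
    print(report.drop(columns="removed_peptide_charges").to_string(index=False))
    print(
        f"{filtered['protein'].nunique()} proteins with "
        f"{filtered[['peptide', 'charge']].drop_duplicates().shape[0]} "
        "peptide-charges survive the ladder"
    )


if __name__ == "__main__":
    main()
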
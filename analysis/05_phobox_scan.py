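"""Scan the simulated promoter set for canonical and half Pho boxes on
both strands, annotate hits by position relative to the TSS, and check
recovery of the planted boxes.

Writes hits (TSV + BED) to results/.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import RESULTS, SCRATCH, ensure_dirs

from lfqdiff import io as lio
from lfqdiff.phobox import annotate_hits, hits_to_bed, hits_to_frame, scan_pho_boxes


def main() -> None:
    ensure_dirs()
    fasta = SCRATCH / "promoters.fasta"
    if not fasta.exists():
        raise SystemExit("run 01_simulate_dataset.py first")
    records = lio.read_fasta(fasta)
    hits = []
    for rec in records:
        hits += scan_pho_boxes(rec, max_mismatch_per_unit=2)
    frame = hits_to_frame(hits)
    features = pd.DataFrame(
        {"sequence_id": [r.id for r in records], "tss": [300] * len(records)}
    )
    annotated = annotate_hits(hits, features)
    merged = frame.merge(
        annotated[["sequence_id", "start", "strand", "position_class"]],
        on=["sequence_id", "start", "strand"],
    )
    merged.to_csv(RESULTS / "phobox_hits.tsv", sep="\t", index=False)
    hits_to_bed(hits, RESULTS / "phobox_hits.bed")

    planted = pd.read_csv(RESULTS / "planted_pho_boxes.tsv", sep="\t")
    found = {
        (r.sequence_id, r.start, r.strand, r.klass) for r in frame.itertuples()
    }
    recovered = sum(
        (r.sequence_id, r.start, r.strand, r.klass) in found
        for r in planted.itertuples()
    )
    print(merged.to_string(index=False))
    print(f"planted boxes recovered: {recovered}/{len(planted)}")


if __name__ == "__main__":
    main()
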
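"""PhoP binding-site (Pho box) scanning of promoter sequences.

A Pho box unit is the 8-bp direct-repeat consensus GTTCACCC whose CA
dinucleotide (unit offsets 4-5) is highly conserved: reported units must
match the CA exactly and may carry a limited number of mismatches at the
six remaining positions. A canonical Pho box is two units whose CA start
positions are 9 bp apart (tandem direct repeats with one spacer base); a
single unit without a partner at that spacing is a half box. Both strands
are scanned; coordinates are 1-based inclusive on the forward strand, a
hit's ``start`` being the leftmost base of its span.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from Bio.Seq import Seq

CONSENSUS = "GTTCACCC"
CA_OFFSETS = (4, 5)
UNIT_LEN = len(CONSENSUS)

__all__ = ["PhoBoxHit", "scan_pho_boxes", "annotate_hits", "hits_to_frame", "hits_to_bed"]

_VALID = set("ACGTN")


@dataclass
class PhoBoxHit:
    sequence_id: str
    start: int  # 1-based inclusive, leftmost base of the span, forward strand
    end: int  # 1-based inclusive
    strand: str  # "+" or "-"
    klass: str  # "canonical" or "half"
    unit_mismatches: tuple[int, ...]
    ca_period: int | None = None  # observed CA-CA spacing (canonical only)


def _unit_matches(seq: str, pos: int, max_mismatch: int) -> int | None:
    """Mismatch count of the 8-mer at 0-based ``pos`` against the
    consensus, or None if the CA is not exact, an N occurs, or the budget
    is exceeded."""
    window = seq[pos : pos + UNIT_LEN]
    if len(window) < UNIT_LEN:
        return None
    mism = 0
    for i, (a, b) in enumerate(zip(window, CONSENSUS)):
        if a == "N":
            return None
        if i in CA_OFFSETS:
            if a != b:
                return None
        elif a != b:
            mism += 1
            if mism > max_mismatch:
                return None
    return mism


def _scan_strand(seq: str, max_mismatch: int, ca_period: int, tolerance: int):
    """Unit positions and (canonical, half) grouping on one strand.

    Returns a list of (unit_start_0based, mismatches) plus the canonical
    pairings (i, j) of unit indices at the required CA spacing.
    """
    units = []
    for pos in range(len(seq) - UNIT_LEN + 1):
        m = _unit_matches(seq, pos, max_mismatch)
        if m is not None:
            units.append((pos, m))
    pairs = []
    paired = set()
    for i, (p1, _) in enumerate(units):
        for j in range(i + 1, len(units)):
            p2 = units[j][0]
            spacing = p2 - p1  # unit-start spacing == CA-start spacing
            if spacing > ca_period + tolerance:
                break
            if abs(spacing - ca_period) <= tolerance:
                pairs.append((i, j))
                paired.update((i, j))
    return units, pairs, paired


def scan_pho_boxes(
    sequence,
    sequence_id: str | None = None,
    max_mismatch_per_unit: int = 2,
    ca_period: int = 9,
    period_tolerance: int = 0,
    both_strands: bool = True,
) -> list[PhoBoxHit]:
    """Scan a sequence for canonical and half Pho boxes.

    ``sequence`` may be a string, Seq or SeqRecord. Minus-strand hits are
    found by scanning the reverse complement and mapping coordinates back
    to the forward strand. Hits are sorted by (start, strand); units used
    by any canonical pair are not additionally reported as half boxes.
    """
    if hasattr(sequence, "seq"):  # SeqRecord
        sequence_id = sequence_id or sequence.id
        seq = str(sequence.seq).upper()
    else:
        seq = str(sequence).upper()
        sequence_id = sequence_id or "seq"
    bad = set(seq) - _VALID
    if bad:
        raise ValueError(f"invalid characters in sequence: {sorted(bad)}")

    L = len(seq)
    hits: list[PhoBoxHit] = []
    strands = ("+", "-") if both_strands else ("+",)
    for strand in strands:
        s = seq if strand == "+" else str(Seq(seq).reverse_complement())
        units, pairs, paired = _scan_strand(
            s, max_mismatch_per_unit, ca_period, period_tolerance
        )
        for i, j in pairs:
            p1, m1 = units[i]
            p2, m2 = units[j]
            span_start, span_end = p1, p2 + UNIT_LEN - 1  # 0-based on strand s
            if strand == "+":
                start, end = span_start + 1, span_end + 1
            else:
                start, end = L - span_end, L - span_start
            hits.append(
                PhoBoxHit(
                    sequence_id, start, end, strand, "canonical",
                    (m1, m2), ca_period=p2 - p1,
                )
            )
        for idx, (p, m) in enumerate(units):
            if idx in paired:
                continue
            span_start, span_end = p, p + UNIT_LEN - 1
            if strand == "+":
                start, end = span_start + 1, span_end + 1
            else:
                start, end = L - span_end, L - span_start
            hits.append(
                PhoBoxHit(sequence_id, start, end, strand, "half", (m,))
            )
    hits.sort(key=lambda h: (h.start, h.strand, h.klass))
    return hits


def annotate_hits(
    hits: list[PhoBoxHit],
    features: pd.DataFrame,
    promoter_window: tuple[int, int] = (40, 0),
) -> pd.DataFrame:
    """Label each hit by its position relative to the transcription start.

    ``features`` has columns ``sequence_id, tss`` (1-based TSS coordinate
    on the promoter sequence). Classes: ``upstream-activator`` (entirely
    upstream of the -35 element), ``promoter-overlap`` (overlapping the
    -35/-10 region, a repressor position), ``downstream-roadblock``
    (downstream of the TSS, where a bound PhoP blocks elongation). Hits on
    sequences without annotation are labeled ``unannotated``.
    """
    tss_of = dict(zip(features["sequence_id"], features["tss"]))
    up, down = promoter_window
    rows = []
    for h in hits:
        if h.sequence_id not in tss_of:
            klass, offset = "unannotated", None
        else:
            tss = int(tss_of[h.sequence_id])
            offset = h.start - tss
            if h.end < tss - up:
                klass = "upstream-activator"
            elif h.start > tss + down:
                klass = "downstream-roadblock"
            else:
                klass = "promoter-overlap"
        rows.append(
            {
                "sequence_id": h.sequence_id,
                "start": h.start,
                "end": h.end,
                "strand": h.strand,
                "klass": h.klass,
                "offset_from_tss": offset,
                "position_class": klass,
            }
        )
    return pd.DataFrame(rows)


def hits_to_frame(hits: list[PhoBoxHit]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sequence_id": [h.sequence_id for h in hits],
            "start": [h.start for h in hits],
            "end": [h.end for h in hits],
            "strand": [h.strand for h in hits],
            "klass": [h.klass for h in hits],
            "unit_mismatches": [
                ",".join(map(str, h.unit_mismatches)) for h in hits
            ],
            "ca_period": [h.ca_period for h in hits],
        }
    )


def hits_to_bed(hits: list[PhoBoxHit], path) -> None:
    """Write hits as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for h in hits:
            name = f"phobox_{h.klass}"
            fh.write(
                f"{h.sequence_id}\t{h.start - 1}\t{h.end}\t{name}\t"
                f"{sum(h.unit_mismatches)}\t{h.strand}\n"
            )
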
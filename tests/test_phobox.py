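"""Pho-box scanning: planted-motif recovery, strand involution, CA
conservation, and positional annotation."""

import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq

from lfqdiff.phobox import annotate_hits, hits_to_bed, hits_to_frame, scan_pho_boxes
from lfqdiff.simulate import PlantedBox, plant_pho_boxes

UNIT = "GTTCACCC"


def random_at_rich(n, seed):
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list("AT"), size=n))  # cannot contain units


class TestScanner:
    def test_tandem_repeat_is_one_canonical_hit(self):
        seq = random_at_rich(30, 1) + UNIT + "G" + UNIT + random_at_rich(30, 2)
        hits = scan_pho_boxes(seq, both_strands=False)
        canonical = [h for h in hits if h.klass == "canonical"]
        assert len(canonical) == 1
        h = canonical[0]
        assert h.start == 31 and h.ca_period == 9
        assert h.unit_mismatches == (0, 0)

    def test_no_unit_empty(self):
        assert scan_pho_boxes(random_at_rich(200, 3)) == []

    def test_single_unit_is_half_box(self):
        seq = random_at_rich(20, 4) + UNIT + random_at_rich(20, 5)
        hits = scan_pho_boxes(seq, both_strands=False)
        assert len(hits) == 1 and hits[0].klass == "half"
        assert hits[0].start == 21

    def test_mismatch_budget(self):
        unit_2mm = "GATCACCG"  # mismatches at offsets 1 and 7, CA intact
        seq = random_at_rich(20, 6) + unit_2mm + random_at_rich(20, 7)
        assert len(scan_pho_boxes(seq, max_mismatch_per_unit=2, both_strands=False)) == 1
        assert scan_pho_boxes(seq, max_mismatch_per_unit=1, both_strands=False) == []

    def test_ca_mismatch_never_reported(self):
        broken_ca = "GTTCGCCC"  # A of CA mutated
        seq = random_at_rich(20, 8) + broken_ca + random_at_rich(20, 9)
        assert scan_pho_boxes(seq, max_mismatch_per_unit=3, both_strands=False) == []

    def test_minus_strand_mapped_to_forward(self):
        fwd = random_at_rich(25, 10) + UNIT + random_at_rich(25, 11)
        seq = str(Seq(fwd).reverse_complement())
        hits = scan_pho_boxes(seq)
        assert len(hits) == 1
        h = hits[0]
        assert h.strand == "-"
        # the unit occupies forward positions len-25-8+1 .. len-25 on seq
        assert str(Seq(seq[h.start - 1 : h.end]).reverse_complement()) == UNIT

    def test_invalid_alphabet_rejected(self):
        with pytest.raises(ValueError):
            scan_pho_boxes("ACGTXACGT")

    def test_n_never_matches(self):
        seq = random_at_rich(10, 12) + "GTTCACCN" + random_at_rich(10, 13)
        assert scan_pho_boxes(seq, max_mismatch_per_unit=6, both_strands=False) == []

    def test_period_tolerance(self):
        seq = random_at_rich(20, 14) + UNIT + "GG" + UNIT + random_at_rich(20, 15)
        strict = scan_pho_boxes(seq, both_strands=False)
        assert all(h.klass == "half" for h in strict)
        loose = [
            h for h in scan_pho_boxes(seq, period_tolerance=1, both_strands=False)
            if h.klass == "canonical"
        ]
        assert len(loose) == 1 and loose[0].ca_period == 10


class TestPlantedRecovery:
    def test_exact_canonical_recovered(self):
        rec, truth = plant_pho_boxes(
            500, 0.72, [PlantedBox(start=200, klass="canonical")], seed=5
        )
        hits = [h for h in scan_pho_boxes(rec, max_mismatch_per_unit=0)
                if h.klass == "canonical" and h.strand == "+"]
        assert any(h.start == 200 for h in hits)

    def test_reverse_strand_planting_recovered(self):
        rec, _ = plant_pho_boxes(
            400, 0.72, [PlantedBox(start=150, strand="-", klass="canonical")], seed=6
        )
        hits = [h for h in scan_pho_boxes(rec, max_mismatch_per_unit=0)
                if h.klass == "canonical" and h.strand == "-"]
        assert any(h.start == 150 for h in hits)

    def test_zero_false_negatives_over_many_seeds(self):
        for seed in range(15):
            start = 50 + 10 * seed
            rec, _ = plant_pho_boxes(
                600, 0.72,
                [PlantedBox(start=start, klass="canonical"),
                 PlantedBox(start=start + 100, klass="half")],
                seed=seed,
            )
            hits = scan_pho_boxes(rec)
            starts = {(h.start, h.klass) for h in hits}
            assert (start, "canonical") in starts
            # the planted half unit is reported (as half, or canonical if
            # background chance produced a partner unit)
            assert any(h.start <= start + 100 <= h.end for h in hits)


def map_hit(h, L):
    """Coordinate-map a hit to the reverse-complemented sequence."""
    return (L - h.end + 1, L - h.start + 1, "-" if h.strand == "+" else "+", h.klass)


class TestInvolution:
    def test_revcomp_scan_is_strand_swapped(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            n = int(rng.integers(60, 300))
            seq = "".join(rng.choice(list("ACGT"), size=n, p=[0.14, 0.36, 0.36, 0.14]))
            fwd = scan_pho_boxes(seq)
            rc = scan_pho_boxes(str(Seq(seq).reverse_complement()))
            a = sorted(map_hit(h, n) for h in fwd)
            b = sorted((h.start, h.end, h.strand, h.klass) for h in rc)
            assert a == b


class TestAnnotate:
    def make_hits(self):
        seq = (
            random_at_rich(40, 20) + UNIT  # ends at 48, upstream of -35
            + random_at_rich(52, 21) + UNIT  # 101-108: around TSS region
            + random_at_rich(52, 22) + UNIT  # 161-168: downstream
            + random_at_rich(40, 23)
        )
        return scan_pho_boxes(seq, sequence_id="prom", both_strands=False)

    def test_positional_classes(self):
        hits = self.make_hits()
        features = pd.DataFrame({"sequence_id": ["prom"], "tss": [130]})
        ann = annotate_hits(hits, features)
        assert list(ann["position_class"]) == [
            "upstream-activator", "promoter-overlap", "downstream-roadblock"
        ]

    def test_unannotated_label(self):
        hits = self.make_hits()
        ann = annotate_hits(hits, pd.DataFrame({"sequence_id": [], "tss": []}))
        assert (ann["position_class"] == "unannotated").all()

    def test_planted_classes_recovered(self):
        rec, truth = plant_pho_boxes(
            400, 0.72,
            [PlantedBox(start=40, klass="canonical"),
             PlantedBox(start=230, klass="half")],
            seed=9,
        )
        hits = scan_pho_boxes(rec, max_mismatch_per_unit=0)
        features = pd.DataFrame({"sequence_id": [rec.id], "tss": [150]})
        ann = annotate_hits(hits, features).set_index("start")
        assert ann.loc[40, "position_class"] == "upstream-activator"
        assert ann.loc[230, "position_class"] == "downstream-roadblock"


def test_writers(tmp_path):
    seq = random_at_rich(20, 30) + UNIT + random_at_rich(20, 31)
    hits = scan_pho_boxes(seq, sequence_id="s1", both_strands=False)
    frame = hits_to_frame(hits)
    assert list(frame["start"]) == [21]
    bed = tmp_path / "hits.bed"
    hits_to_bed(hits, bed)
    line = bed.read_text().strip().split("\t")
    assert line[0] == "s1" and int(line[1]) == 20 and int(line[2]) == 28
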
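"""Domain-architecture classification rules and catalog structure analysis."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_protein
from pubclass.classify import (RuleConfig, classify_protein, classify_proteome,
                               find_tandem_clusters, subclassify_class_ii,
                               subclassify_class_iv)
from pubclass.io import CatalogEntry, ValidationError


class TestClassRules:
    @pytest.mark.parametrize("length,hits,expected", [
        # UFD2 plus U-box at the C-terminus
        (1000, [("UFD2", 50, 350), ("U_BOX", 900, 960)], "I"),
        # U-box only
        (400, [("U_BOX", 100, 170)], "V"),
        # cyclophilin accessory domain
        (450, [("U_BOX", 30, 100), ("CYCLOPHILIN", 200, 380)], "III"),
        # ARM-like region does not qualify for II: regrouped with V
        (500, [("U_BOX", 20, 90), ("ARM_LIKE", 200, 450)], "V"),
        # TPR plus a kinase domain
        (600, [("U_BOX", 40, 110), ("TPR", 200, 300), ("PKC", 350, 580)], "VIII"),
        (600, [("U_BOX", 40, 110), ("TPR", 200, 300)], "VII"),
        (700, [("U_BOX", 30, 100), ("WD40", 400, 650)], "VI"),
        (800, [("U_BOX", 400, 470), ("MIF4G", 30, 250)], "IX"),
        (700, [("U_BOX", 350, 420), ("DJ1", 20, 200)], "X"),
        (800, [("U_BOX", 380, 450), ("ARM", 500, 540), ("ARM", 560, 600)], "II"),
        (800, [("U_BOX", 380, 450), ("HEAT", 500, 540)], "II"),
        (600, [("U_BOX", 200, 270), ("PKC", 350, 580)], "IV"),
    ])
    def test_class_assignment(self, length, hits, expected):
        a = classify_protein(make_protein(length=length, hits=hits))
        assert a.pub_class == expected
        assert a.rationale  # every decision is traced

    def test_no_ubox_is_unclassified(self):
        a = classify_protein(make_protein(hits=[("ARM", 100, 150)]))
        assert a.pub_class == "UNCLASSIFIED"
        assert a.subclass is None

    def test_arm_like_promotes_to_ii_when_configured(self):
        rec = make_protein(length=500, hits=[("U_BOX", 20, 90), ("ARM_LIKE", 200, 450)])
        cfg = RuleConfig(arm_like_counts_as_arm=True)
        a = classify_protein(rec, cfg)
        assert (a.pub_class, a.subclass) == ("II", "IIb")

    def test_ufd2_beats_everything(self):
        rec = make_protein(length=900, hits=[
            ("U_BOX", 800, 860), ("UFD2", 50, 300), ("ARM", 400, 440), ("PKC", 500, 700)])
        assert classify_protein(rec).pub_class == "I"


class TestClassIISubtyping:
    def test_central_ubox_is_iia(self):
        rec = make_protein(length=800, hits=[("U_BOX", 380, 450), ("ARM", 500, 560)])
        sub, _ = subclassify_class_ii(rec)   # midpoint 415 > 200
        assert sub == "IIa"

    def test_n_terminal_ubox_is_iib(self):
        rec = make_protein(length=800, hits=[("U_BOX", 40, 110), ("ARM", 300, 360)])
        sub, _ = subclassify_class_ii(rec)   # midpoint 75 <= 200
        assert sub == "IIb"

    def test_boundary_midpoint_is_iib(self):
        # midpoint exactly 0.25 * length: boundary included by <=
        rec = make_protein(length=800, hits=[("U_BOX", 160, 240), ("ARM", 400, 460)])
        sub, _ = subclassify_class_ii(rec)
        assert sub == "IIb"

    def test_multiple_ubox_uses_most_n_terminal(self):
        rec = make_protein(length=800, hits=[
            ("U_BOX", 40, 110), ("U_BOX", 500, 560), ("ARM", 600, 660)])
        sub, trace = subclassify_class_ii(rec)
        assert sub == "IIb"
        assert any("multiple_ubox" in t for t in trace)

    def test_start_point_option(self):
        rec = make_protein(length=800, hits=[("U_BOX", 190, 290), ("ARM", 400, 460)])
        # start 190 <= 200 -> IIb; midpoint 240 > 200 -> IIa
        assert subclassify_class_ii(rec, RuleConfig(ubox_point="start"))[0] == "IIb"
        assert subclassify_class_ii(rec, RuleConfig(ubox_point="midpoint"))[0] == "IIa"

    @settings(max_examples=80, deadline=None)
    @given(length=st.integers(300, 2000), data=st.data())
    def test_monotone_boundary(self, length, data):
        """Moving the U-box toward the N-terminus can flip IIa->IIb, never back."""
        width = 70
        hi = data.draw(st.integers(1, length - width), label="pos_far")
        lo = data.draw(st.integers(1, hi), label="pos_near")
        def sub_at(start):
            rec = make_protein(length=length, hits=[
                ("U_BOX", start, start + width - 1)])
            return subclassify_class_ii(rec)[0]
        if sub_at(hi) == "IIb":
            assert sub_at(lo) == "IIb"


class TestClassIVSubtyping:
    @pytest.mark.parametrize("labels,expected", [
        (("PKC", "STK_N"), "IV_1"),
        (("PKC",), "IV_2"),
        (("STK_N",), "IV_3"),
    ])
    def test_subgroups(self, labels, expected):
        hits = [("U_BOX", 200, 270)]
        pos = 300
        for l in labels:
            hits.append((l, pos, pos + 80))
            pos += 100
        rec = make_protein(length=700, hits=hits)
        assert subclassify_class_iv(rec)[0] == expected
        a = classify_protein(rec)
        assert (a.pub_class, a.subclass) == ("IV", expected)


_DOMAIN_POOL = ["U_BOX", "UFD2", "ARM", "HEAT", "ARM_LIKE", "CYCLOPHILIN",
                "PKC", "STK_N", "WD40", "TPR", "MIF4G", "DJ1", "OTHER"]


class TestPartitionProperties:
    @settings(max_examples=150, deadline=None)
    @given(present=st.sets(st.sampled_from(_DOMAIN_POOL), max_size=6),
           length=st.integers(400, 1500))
    def test_every_record_gets_exactly_one_class(self, present, length):
        hits, pos = [], 1
        for label in sorted(present):
            hits.append((label, pos, pos + 59))
            pos += 70
        rec = make_protein(length=max(length, pos + 10), hits=hits)
        a1 = classify_protein(rec)
        a2 = classify_protein(rec)
        assert a1 == a2  # pure function of (record, config)
        assert (a1.pub_class == "UNCLASSIFIED") == ("U_BOX" not in present)
        assert (a1.subclass is not None) == (a1.pub_class in ("II", "IV"))

    def test_counts_sum_to_input_size(self):
        recs = [make_protein(pid=f"P{i}", hits=[("U_BOX", 10, 80)]) for i in range(5)]
        recs.append(make_protein(pid="P9", hits=[("ARM", 10, 80)]))
        res = classify_proteome(recs)
        assert sum(res.class_counts.values()) == 6
        assert res.class_counts["UNCLASSIFIED"] == 1
        assert res.n_classified == 5

    def test_all_unclassified_when_no_ubox(self):
        recs = [make_protein(pid=f"P{i}", hits=[("ARM", 10, 80)]) for i in range(4)]
        res = classify_proteome(recs)
        assert res.class_counts == {"UNCLASSIFIED": 4}
        assert res.n_classified == 0

    def test_duplicate_ids_rejected(self):
        recs = [make_protein(pid="P1"), make_protein(pid="P1")]
        with pytest.raises(ValidationError, match="duplicate"):
            classify_proteome(recs)


def _entry(name, chrom, start, end):
    return CatalogEntry(name=name, gene_id=name, chromosome=chrom,
                        start_bp=start, end_bp=end)


class TestTandemClusters:
    def test_published_tandem_pair_arithmetic(self):
        # printed coordinates: gap 102,438,361 - 102,375,777 = 62,584 <= 100 kb
        cat = [_entry("HvPUB11", "chr5H", 102370756, 102375777),
               _entry("HvPUB12", "chr5H", 102438361, 102442824)]
        assert find_tandem_clusters(cat, 100_000) == [["HvPUB11", "HvPUB12"]]

    def test_barley_catalog_has_exactly_two_pairs(self, barley_catalog):
        clusters = find_tandem_clusters(barley_catalog, 100_000)
        assert clusters == [["HvPUB11", "HvPUB12"], ["HvPUB58", "HvPUB59"]]

    def test_different_chromosomes_never_cluster(self):
        cat = [_entry("A", "chr1H", 100, 200), _entry("B", "chr2H", 100, 200)]
        assert find_tandem_clusters(cat, 100_000) == []

    def test_chains_are_maximal(self):
        cat = [_entry("A", "chr1H", 1000, 2000),
               _entry("B", "chr1H", 2500, 3000),
               _entry("C", "chr1H", 3200, 4000),
               _entry("D", "chr1H", 9_000_000, 9_000_100)]
        assert find_tandem_clusters(cat, 1000) == [["A", "B", "C"]]

    @settings(max_examples=50, deadline=None)
    @given(perm=st.permutations(list(range(6))), gap=st.integers(1, 10**6))
    def test_order_invariance_and_disjointness(self, perm, gap):
        base = [_entry(f"G{i}", "chr1H", 10_000 * i + 1, 10_000 * i + 5_000)
                for i in range(6)]
        shuffled = [base[i] for i in perm]
        c1 = find_tandem_clusters(base, gap)
        c2 = find_tandem_clusters(shuffled, gap)
        assert c1 == c2
        seen = [g for c in c1 for g in c]
        assert len(seen) == len(set(seen))
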
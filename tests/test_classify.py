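import numpy as np
import pytest

from mirorigin.annotation_io import (
    GeneModel,
    GenomicInterval,
    Pseudogene,
    RepeatFeature,
    revcomp,
)
from mirorigin.classify import (
    classify_pseudogene_related,
    classify_te_related,
    detect_inverted_duplication,
    detect_tandem_duplication,
    finalize,
)
from mirorigin.config import PipelineConfig
from mirorigin.synth import SynthConfig, generate_genome

from conftest import make_mirna


def iv(s, e, strand="+"):
    return GenomicInterval("chr1", s, e, strand)


def repeat(s, e, fam="rep1", klass="LTR/Gypsy", strand="+"):
    return RepeatFeature(iv(s, e, strand), fam, klass, 10.0)


class TestCoverageRules:
    def setup_method(self):
        self.m = make_mirna(start=1000, seq="ACGT" * 25)  # 100 bp precursor

    def test_half_coverage_is_te_related(self):
        flag, cov = classify_te_related(self.m, [repeat(1000, 1050)])
        assert flag and cov == 50

    def test_just_below_half_is_not(self):
        flag, cov = classify_te_related(self.m, [repeat(1000, 1049)])
        assert not flag and cov == 49

    def test_contained_precursor(self):
        flag, cov = classify_te_related(self.m, [repeat(500, 5000)])
        assert flag and cov == 100

    def test_union_of_fragments(self):
        flag, cov = classify_te_related(
            self.m, [repeat(1000, 1030), repeat(1020, 1060)]
        )
        assert flag and cov == 60

    def test_any_overlap_switch(self):
        flag, _ = classify_te_related(self.m, [repeat(1000, 1001)], any_overlap=True)
        assert flag

    def test_pseudogene_rule_mirrors(self):
        ps_half = [Pseudogene("p", iv(1000, 1050), "g")]
        ps_low = [Pseudogene("p", iv(1000, 1049), "g")]
        ps_all = [Pseudogene("p", iv(0, 9000), "g")]
        assert classify_pseudogene_related(self.m, ps_half)[0]
        assert not classify_pseudogene_related(self.m, ps_low)[0]
        assert classify_pseudogene_related(self.m, ps_all) == (True, 100)


def _hairpin_mirna(rng, arm_len=80, loop="AACGAAA", mature_offset=10):
    arm = "".join(rng.choice(list("ACGT"), size=arm_len))
    seq = arm + loop + revcomp(arm)
    return make_mirna(seq=seq, mature_offset=mature_offset), arm


class TestInvertedDuplication:
    def test_exact_planted_match(self, rng):
        m, arm = _hairpin_mirna(rng)
        cdna = "".join(rng.choice(list("ACGT"), size=200)) + arm + "".join(
            rng.choice(list("ACGT"), size=200)
        )
        gene = GeneModel("g1", iv(50_000, 50_000 + len(cdna)), cdna, "M" * 100)
        hits = detect_inverted_duplication(m, [gene])
        assert [h[0] for h in hits] == ["g1"]
        assert hits[0][1].identity == 1.0

    def test_degraded_identity_rejected(self, rng):
        m, arm = _hairpin_mirna(rng)
        degraded = list(arm)
        for p in rng.choice(len(arm), size=len(arm) // 4, replace=False):
            degraded[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[degraded[p]]
        cdna = "".join(rng.choice(list("ACGT"), size=200)) + "".join(degraded)
        gene = GeneModel("g1", iv(50_000, 50_000 + len(cdna)), cdna, "M" * 100)
        assert detect_inverted_duplication(m, [gene]) == []

    def test_mature_outside_matched_region_rejected(self, rng):
        # a long loop separates the arms; mature sits in the loop, outside
        # both matched arm regions
        arm = "".join(rng.choice(list("ACGT"), size=80))
        loop = "".join(rng.choice(list("ACGT"), size=60))
        m = make_mirna(seq=arm + loop + revcomp(arm), mature_offset=95)
        cdna = "".join(rng.choice(list("ACGT"), size=150)) + arm
        gene = GeneModel("g1", iv(50_000, 50_000 + len(cdna)), cdna, "M" * 100)
        assert detect_inverted_duplication(m, [gene]) == []

    def test_random_gene_not_hit(self, rng):
        m, _ = _hairpin_mirna(rng)
        cdna = "".join(rng.choice(list("ACGT"), size=1000))
        gene = GeneModel("g1", iv(50_000, 51_000), cdna, "M" * 100)
        assert detect_inverted_duplication(m, [gene]) == []


class TestTandemDuplication:
    def _pair(self, gap, fam_a="F1", fam_b="F1", rng=None):
        seq = "ACGT" * 40
        a = make_mirna(mid="a", start=1000, seq=seq, family=fam_a)
        b = make_mirna(mid="b", start=1000 + 160 + gap, seq=seq, family=fam_b)
        return [a, b]

    def test_same_family_under_15kb(self):
        assert detect_tandem_duplication(self._pair(14_999)) == [("a", "b")]

    def test_boundary_15kb_excluded(self):
        assert detect_tandem_duplication(self._pair(15_000)) == []

    def test_evalue_clause_for_unrelated_families(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=150))
        a = make_mirna(mid="a", start=1000, seq=seq, family="F1")
        b = make_mirna(mid="b", start=2500, seq=seq, family="F2")
        assert detect_tandem_duplication([a, b]) == [("a", "b")]

    def test_unrelated_sequences_different_family_excluded(self, rng):
        a = make_mirna(
            mid="a", start=1000, seq="".join(rng.choice(list("ACGT"), size=150)), family="F1"
        )
        b = make_mirna(
            mid="b", start=2500, seq="".join(rng.choice(list("ACGT"), size=150)), family="F2"
        )
        assert detect_tandem_duplication([a, b]) == []

    def test_different_chroms_never_pair(self):
        seq = "ACGT" * 40
        a = make_mirna(mid="a", start=1000, seq=seq)
        b = make_mirna(mid="b", chrom="chr2", start=1200, seq=seq)
        assert detect_tandem_duplication([a, b]) == []


@pytest.fixture(scope="module")
def bundle_and_calls():
    from mirorigin.pipeline import run_bundle

    cfg = SynthConfig(
        n_nonmite_id=3,
        n_mite_id=3,
        n_pseudo_same_parent=3,
        n_pseudo_paralog=3,
        n_tandem_pairs=1,
        n_segmental_pairs=0,
        n_background_mirna=2,
        n_coding_genes=6,
        genome_length=60_000,
        seed=21,
    )
    b = generate_genome(cfg)
    res = run_bundle(b, PipelineConfig(mc_reps=1000))
    return b, {c.mirna_id: c for c in res.calls}


class TestMechanisms:
    def test_mechanism_a_recovered(self, bundle_and_calls):
        b, calls = bundle_and_calls
        for t in b.truth:
            if t.true_mechanism == "A":
                assert calls[t.mirna_id].mechanism == "A"
                assert {"TR", "ID"} <= calls[t.mirna_id].labels

    def test_mechanism_b_recovered(self, bundle_and_calls):
        b, calls = bundle_and_calls
        for t in b.truth:
            if t.true_mechanism == "B":
                assert calls[t.mirna_id].mechanism == "B"

    def test_mechanism_c_recovered(self, bundle_and_calls):
        b, calls = bundle_and_calls
        for t in b.truth:
            if t.true_mechanism == "C":
                assert calls[t.mirna_id].mechanism == "C"
                assert "PR" in calls[t.mirna_id].labels

    def test_mechanism_d_recovered(self, bundle_and_calls):
        b, calls = bundle_and_calls
        for t in b.truth:
            if t.true_mechanism == "D":
                assert calls[t.mirna_id].mechanism == "D"

    def test_background_is_ot(self, bundle_and_calls):
        b, calls = bundle_and_calls
        for t in b.truth:
            if t.true_origin == "OT":
                assert calls[t.mirna_id].labels == {"OT"}
                assert calls[t.mirna_id].mechanism == "none"

    def test_high_mutation_plants_not_typed_a(self):
        from mirorigin.pipeline import run_bundle

        cfg = SynthConfig(
            n_nonmite_id=4,
            n_mite_id=0,
            n_pseudo_same_parent=0,
            n_pseudo_paralog=0,
            n_tandem_pairs=0,
            n_segmental_pairs=0,
            n_background_mirna=0,
            n_coding_genes=4,
            genome_length=60_000,
            mutation_rate_per_site=0.15,
            verify_hairpins=False,
            seed=23,
        )
        b = generate_genome(cfg)
        res = run_bundle(b, PipelineConfig(mc_reps=1000))
        # arm similarity ~72% < 80%: the copy-similarity clause must reject A
        for c in res.calls:
            assert c.mechanism != "A", c


class TestFinalize:
    def test_ot_iff_no_other_label(self):
        m = make_mirna(mid="x")
        calls = finalize([m], {}, {}, {}, [], [])
        assert calls[0].labels == {"OT"}

    def test_labels_are_multilabels(self):
        m = make_mirna(mid="x")
        calls = finalize([m], {"x": True}, {"x": True}, {"x": [("g", None, None)]}, [], [])
        assert calls[0].labels == {"TR", "PR", "ID"}
        assert "OT" not in calls[0].labels

    def test_empty_input(self):
        assert finalize([], {}, {}, {}, [], []) == []

    def test_primary_label_precedence(self):
        m = make_mirna(mid="x")
        [c] = finalize([m], {"x": True}, {}, {"x": [("g", None, None)]}, [("x", "y")], [])
        assert c.primary_label == "TR"
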
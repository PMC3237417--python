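import numpy as np
import pytest

from mirorigin.annotation_io import GeneModel, GenomicInterval, revcomp
from mirorigin.features import (
    build_feature_table,
    build_group_table,
    conservation_count,
    count_flank_ssrs,
    count_sirnas,
    find_ssrs,
    predict_targets,
    scan_target_sites,
    track_density,
)

from conftest import make_mirna


def iv(s, e, chrom="chr1", strand="+"):
    return GenomicInterval(chrom, s, e, strand)


class TestTargetMatcher:
    def test_perfect_site_scores_zero_with_cleave_pairings(self, rng):
        mature = "".join(rng.choice(list("ACGT"), size=21))
        cdna = "".join(rng.choice(list("ACGT"), size=100)) + revcomp(mature) + "".join(
            rng.choice(list("ACGT"), size=100)
        )
        gene = GeneModel("g", iv(0, len(cdna)), cdna, "")
        sites = [s for s in predict_targets(mature, [gene]) if s.score == 0.0]
        assert len(sites) == 1
        site = sites[0]
        assert (site.start, site.end) == (100, 121)
        assert all(site.pairing_profile)
        assert site.cleaving_site_pairings == 2

    def test_single_gu_wobble_outside_seed_scores_half(self):
        mature = "A" * 21
        mature = mature[:14] + "G" + mature[15:]  # G at 1-based position 15
        site = revcomp(mature)  # perfect complement
        # give the G a U (=T) partner instead of C: wobble pair
        pos_in_site = 21 - 1 - 14
        site = site[:pos_in_site] + "T" + site[pos_in_site + 1 :]
        hits = scan_target_sites(mature, site)
        assert len(hits) == 1
        assert hits[0][2] == 0.5

    def test_seed_mismatch_doubled(self):
        mature = "ACGTACGTACGTACGTACGTA"
        site = list(revcomp(mature))
        # mismatch facing mature position 5 (1-based), inside 2..13
        j = 21 - 1 - 4
        site[j] = {"A": "C", "C": "G", "G": "T", "T": "A"}[site[j]]
        hits = scan_target_sites(mature, "".join(site))
        assert hits and hits[0][2] == 2.0

    def test_mature_length_validated(self):
        with pytest.raises(ValueError):
            predict_targets("ACGT", [], 4.0)

    def test_planted_mechanism_b_target_recovered(self, small_bundle):
        truth = {t.mirna_id: t for t in small_bundle.truth}
        mirnas = {m.id: m for m in small_bundle.mirnas}
        for t in small_bundle.truth:
            if t.true_mechanism == "B":
                sites = predict_targets(mirnas[t.mirna_id].mature_seq, small_bundle.genes)
                assert t.planted_target_gene in {s.gene_id for s in sites}


class TestSirnaCount:
    def test_discard_rule(self):
        m = make_mirna(start=1000, seq="ACGT" * 40, mature_offset=50)
        track = [
            (iv(1005, 1026), "s1"),
            (iv(1100, 1121), "s2"),
            (iv(1055, 1076), "s3"),  # overlaps the mature (1050..1071)
        ]
        assert count_sirnas(m, track) == 2

    def test_none_in_precursor(self):
        m = make_mirna(start=1000, seq="ACGT" * 40)
        assert count_sirnas(m, [(iv(5000, 5021), "s")]) == 0

    def test_abutting_mature_counted(self):
        # mature occupies [1050, 1071); an siRNA ending exactly at 1050 abuts
        m = make_mirna(start=1000, seq="ACGT" * 40, mature_offset=50)
        assert count_sirnas(m, [(iv(1029, 1050), "s")]) == 1


class TestSsrs:
    def test_planted_dinucleotide_run(self, rng):
        flank = "".join(rng.choice(list("ACGT"), size=400)) + "AT" * 10 + "".join(
            rng.choice(list("ACGT"), size=400)
        )
        genome = {"chr1": flank + "G" * 200}
        n = count_flank_ssrs(genome, iv(len(flank), len(flank) + 150))
        assert n >= 1

    def test_random_sequence_rarely_has_ssrs(self, rng):
        counts = [len(find_ssrs("".join(rng.choice(list("ACGT"), size=1000)))) for _ in range(100)]
        assert np.mean(counts) < 0.5

    def test_below_thresholds_not_counted(self):
        assert find_ssrs("ACGT" + "AT" * 3 + "ACGT") == []  # only 3 units / 6 bp
        assert len(find_ssrs("A" * 12)) == 1  # mononucleotide run

    def test_chromosome_edge_truncation(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=300))
        genome = {"chr1": seq}
        # interval at the chromosome start: left flank is empty, right flank
        # truncates to the remaining 200 bp
        n = count_flank_ssrs(genome, iv(0, 100))
        assert n == len(find_ssrs(seq[100:300]))


class TestTrackDensity:
    def test_five_sites_in_hundred_bp(self):
        pre = iv(1000, 1100)
        track = [(iv(1000 + i * 10, 1001 + i * 10), f"x{i}") for i in range(5)]
        assert track_density(pre, track) == pytest.approx(0.05)

    def test_empty_track(self):
        assert track_density(iv(0, 100), []) == 0.0

    def test_sites_outside_ignored(self):
        assert track_density(iv(0, 100), [(iv(200, 201), "x")]) == 0.0


def test_conservation_count():
    mature = "ACGTACGTACGTACGTACGTA"
    near = "C" + mature[1:]
    catalogs = {
        "speciesA": [mature],
        "speciesB": ["TTTT" + near + "GGGG"],
        "speciesC": ["GGGGGGGGGGGGGGGGGGGGGGGG"],
    }
    assert conservation_count(mature, catalogs) == 2


class TestGroupTable:
    def test_null_p_values_roughly_uniform(self, rng):
        from scipy.stats import kstest

        from mirorigin.stats import welch_t

        ps = []
        for _ in range(200):
            a = rng.normal(0, 1, 30)
            b = rng.normal(0, 1, 30)
            ps.append(welch_t(a, b)[1])
        assert kstest(ps, "uniform").pvalue > 0.01

    def test_planted_shift_detected(self, rng):
        from mirorigin.stats import welch_t

        hits = 0
        for _ in range(200):
            a = rng.normal(170, 10, 30)
            b = rng.normal(150, 10, 30)  # 20-nt shift at sigma=10
            if welch_t(a, b)[1] < 0.01:
                hits += 1
        assert hits / 200 >= 0.9

    def test_empty_group_row_has_nan_p(self, small_bundle, small_result):
        import pandas as pd

        from mirorigin.classify import OriginCall

        calls = [OriginCall(mirna_id=m.id, labels={"TR"}) for m in small_bundle.mirnas]
        tbl = build_group_table(small_result.features, calls)
        assert tbl["p_value"].isna().all()  # conserved group empty
        assert (tbl["n_conserved"] == 0).all()

    def test_feature_table_pure(self, small_bundle, small_result):
        from mirorigin.features import predict_targets

        sites = {
            m.id: predict_targets(m.mature_seq, small_bundle.genes)
            for m in small_bundle.mirnas
        }
        t1 = build_feature_table(small_bundle, sites)
        t2 = build_feature_table(small_bundle, sites)
        assert t1.equals(t2)

    def test_table1_rows_present(self, small_result):
        expected = {
            "first_nt_is_A",
            "mirna_length",
            "precursor_length",
            "stem_length",
            "loop_length",
            "mir_loop_distance",
            "match_ratio",
            "sirna_count",
            "multi_mirna",
            "genic_location",
            "promoter_count",
            "ssr_count_1kb",
            "target_number",
            "target_expression_mean",
            "cleaving_site_pairings",
            "family_size",
            "conservation",
            "methylcytosine_density",
            "polymorphic_density_pre",
            "polymorphic_density_mature",
            "mirna_expression_mean",
        }
        assert expected <= set(small_result.table1.index)

    def test_table2_structure(self, small_result):
        t2 = small_result.table2
        assert list(t2.index) == ["de_novo_targets", "conserved_targets", "all_genes"]
        pct = t2[["pct_in_segmental_blocks", "pct_in_tandem_arrays"]].to_numpy(float)
        ok = np.isnan(pct) | ((pct >= 0) & (pct <= 100))
        assert ok.all()
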
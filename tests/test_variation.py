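"""SNP depletion, co-evolution, mutagenesis overlap, and paralog divergence."""

import numpy as np
import pandas as pd
import pytest

from ppimotifs import (
    InteractionNetwork,
    ProteinRecord,
    SiteAnnotation,
    alignment_identities,
    coevolution_test,
    flag_proteins_with_snp_in_site,
    mutagenesis_overlap_report,
    paralog_divergence,
    snp_depletion_test,
)
from ppimotifs.io import ValidationError
from ppimotifs.variation import make_global_aligner


def make_record(pid, seq):
    n = len(seq)
    return ProteinRecord(pid, seq, np.full(n, 9), np.full(n, 9))


def site(pid, start, end, partners=()):
    length = end - start + 1
    return SiteAnnotation(pid, start, end, "A" * length, frozenset(partners),
                          1.0, 9.0, 9.0)


def snp_frame(rows):
    return pd.DataFrame(rows, columns=["protein_id", "position"])


class TestSnpDepletion:
    def test_observed_fractions_hand_counted(self):
        records = {"P1": make_record("P1", "A" * 10)}
        sites = [site("P1", 1, 4)]
        snps = snp_frame([("P1", 1), ("P1", 8)])
        res = snp_depletion_test(sites, records, snps, n_trials=50,
                                 rng=np.random.default_rng(0))
        assert res.observed_overlap == 1
        assert res.frac_in_sites == pytest.approx(1 / 4)
        assert res.frac_overall == pytest.approx(2 / 10)
        assert 0 < res.p_value <= 1

    def test_residue_level_counting(self):
        """Two SNP records at one residue count once."""
        records = {"P1": make_record("P1", "A" * 10)}
        sites = [site("P1", 1, 4)]
        snps = snp_frame([("P1", 2), ("P1", 2)])
        res = snp_depletion_test(sites, records, snps, n_trials=50,
                                 rng=np.random.default_rng(0))
        assert res.observed_overlap == 1
        assert res.frac_overall == pytest.approx(1 / 10)

    def test_depleted_snps_give_small_p(self):
        """SNPs packed outside a large site: null overlap is rarely as low."""
        records = {"P1": make_record("P1", "A" * 100)}
        sites = [site("P1", 1, 50)]
        snps = snp_frame([("P1", p) for p in range(60, 65)])
        res = snp_depletion_test(sites, records, snps, n_trials=2000,
                                 rng=np.random.default_rng(1))
        assert res.observed_overlap == 0
        # P(5 uniform draws all miss half the sequence) is about 0.028
        assert res.p_value < 0.1

    def test_enriched_snps_give_large_p(self):
        records = {"P1": make_record("P1", "A" * 100)}
        sites = [site("P1", 1, 50)]
        snps = snp_frame([("P1", p) for p in range(1, 6)])
        res = snp_depletion_test(sites, records, snps, n_trials=500,
                                 rng=np.random.default_rng(2))
        assert res.p_value > 0.9

    def test_deterministic_under_seed(self):
        records = {"P1": make_record("P1", "A" * 60)}
        sites = [site("P1", 10, 30)]
        snps = snp_frame([("P1", 5), ("P1", 20), ("P1", 50)])
        a = snp_depletion_test(sites, records, snps, 200, np.random.default_rng(7))
        b = snp_depletion_test(sites, records, snps, 200, np.random.default_rng(7))
        assert a == b

    def test_snp_beyond_sequence_rejected(self):
        records = {"P1": make_record("P1", "A" * 10)}
        with pytest.raises(ValidationError, match="exceed"):
            snp_depletion_test([site("P1", 1, 4)], records,
                               snp_frame([("P1", 11)]), 10,
                               np.random.default_rng(0))

    def test_no_sites_rejected(self):
        with pytest.raises(ValidationError):
            snp_depletion_test([], {}, snp_frame([]), 10, np.random.default_rng(0))


class TestCoevolution:
    def _net(self):
        return InteractionNetwork(
            [("P1", "P2"), ("P2", "P3"), ("P1", "P3"), ("P4", "P5"), ("P5", "P6")]
        )

    def test_triangle_observed_count(self):
        res = coevolution_test({"P1", "P2", "P3"}, self._net(), n_trials=1000,
                               rng=np.random.default_rng(0))
        assert res.observed_count == 3
        assert res.n_flagged == 3
        # only 1 of the 20 possible triples achieves 3 edges
        assert res.p_value < 0.2
        assert res.null_mean < 3

    def test_uninteracting_flagged_set_not_significant(self):
        res = coevolution_test({"P1", "P4", "P6"}, self._net(), n_trials=500,
                               rng=np.random.default_rng(0))
        assert res.observed_count == 0
        assert res.p_value == 1.0  # every null draw has >= 0 edges

    def test_fewer_than_two_flagged_degenerate(self):
        res = coevolution_test({"P1"}, self._net(), n_trials=100)
        assert res.p_value == 1.0 and res.observed_count == 0

    def test_stray_protein_rejected(self):
        with pytest.raises(ValidationError, match="not in network"):
            coevolution_test({"P1", "ZZ"}, self._net())

    def test_flagging_from_sites_and_snps(self):
        sites = [site("P1", 5, 12), site("P2", 1, 8)]
        snps = snp_frame([("P1", 7), ("P2", 20), ("P3", 1)])
        assert flag_proteins_with_snp_in_site(sites, snps) == {"P1"}


class TestMutagenesisOverlap:
    def test_point_and_region_intersection(self):
        sites = [site("P1", 208, 220), site("P2", 10, 17)]
        regions = {"P1": [(213, 213), (200, 207)], "P2": [(15, 30)], "P3": [(1, 5)]}
        report = mutagenesis_overlap_report(sites, regions)
        by_id = report.set_index("protein_id")
        assert bool(by_id.loc["P1", "coincides"]) is True
        assert by_id.loc["P1", "n_intersections"] == 1
        assert by_id.loc["P1", "intersections"] == [((213, 213), (208, 220))]
        assert bool(by_id.loc["P2", "coincides"]) is True
        assert bool(by_id.loc["P3", "coincides"]) is False

    def test_adjacent_but_disjoint_region_does_not_coincide(self):
        report = mutagenesis_overlap_report([site("P1", 10, 17)], {"P1": [(18, 20)]})
        assert not report["coincides"].iloc[0]

    def test_inverted_interval_rejected(self):
        with pytest.raises(ValidationError, match="inverted"):
            mutagenesis_overlap_report([site("P1", 10, 17)], {"P1": [(5, 3)]})


class TestAlignmentIdentities:
    def test_identical_sequences(self):
        whole, site_id = alignment_identities("ACDEFGHIKL", "ACDEFGHIKL",
                                              [(1, 4)], [(1, 4)])
        assert whole == pytest.approx(1.0)
        assert site_id == pytest.approx(1.0)

    def test_single_substitution_hand_counted(self):
        # one mismatch in 10 gapless columns
        whole, site_id = alignment_identities("ACDEFGHIKL", "ACDEFGHIKV",
                                              [(7, 10)], [])
        assert whole == pytest.approx(9 / 10)
        assert site_id == pytest.approx(3 / 4)  # mismatch inside the motif

    def test_motif_outside_mismatch_scores_one(self):
        whole, site_id = alignment_identities("ACDEFGHIKL", "ACDEFGHIKV",
                                              [(1, 4)], [])
        assert whole == pytest.approx(9 / 10)
        assert site_id == pytest.approx(1.0)

    def test_motif_spanning_gap_excluded(self):
        # deleting F forces a gap under the E-F-G motif; the intact motif
        # away from the gap still defines the site identity
        a, b = "ACDEFGHIKLW", "ACDEGHIKLW"
        whole, site_id = alignment_identities(a, b, [(4, 6)], [])
        assert site_id is None
        whole2, site_id2 = alignment_identities(a, b, [(4, 6), (7, 10)], [])
        assert whole2 == whole
        assert site_id2 == pytest.approx(1.0)

    def test_no_motifs_gives_undefined_site_identity(self):
        whole, site_id = alignment_identities("ACDEFGHIKL", "ACDEFGHIKL")
        assert site_id is None

    def test_symmetry_of_whole_identity(self):
        a, b = "ACDEFGHIKLMNPQ", "ACDEWGHIKLMNP"
        wa, _ = alignment_identities(a, b)
        wb, _ = alignment_identities(b, a)
        assert wa == pytest.approx(wb)


class TestParalogDivergence:
    def _fixture(self):
        base = "ACDEFGHIKLMNPQRSTVWYACDEFGHIKLMNPQRSTVWY"
        # conservative substitutions keep the global alignment gapless
        mildly = base.replace("L", "I")          # 2 of 40 columns differ
        strongly = (base.replace("L", "I").replace("D", "E")
                    .replace("K", "R").replace("F", "Y").replace("S", "T"))
        records = {
            "N1": make_record("N1", base), "N2": make_record("N2", base),
            "N3": make_record("N3", base), "N4": make_record("N4", mildly),
            "H1": make_record("H1", base), "H2": make_record("H2", strongly),
            "H3": make_record("H3", mildly), "H4": make_record("H4", strongly),
        }
        sites = [site(pid, 1, 8) for pid in records]
        pairs = [("N1", "N2", "no"), ("N3", "N4", "no"),
                 ("H1", "H2", "high"), ("H3", "H4", "high")]
        return records, sites, pairs

    def test_identities_and_fits(self):
        records, sites, pairs = self._fixture()
        out, fits = paralog_divergence(pairs, records, sites)
        by_key = {(p.id_a, p.id_b): p for p in out}
        assert by_key[("N1", "N2")].whole_identity == pytest.approx(1.0)
        assert by_key[("N1", "N2")].site_identity == pytest.approx(1.0)
        assert by_key[("N3", "N4")].whole_identity == pytest.approx(38 / 40)
        # diverged pairs sit well below the near-identical ones
        assert by_key[("H1", "H2")].whole_identity < 0.8
        assert set(fits.whole) == {"no", "high"}
        assert set(fits.site) == {"no", "high"}
        mean_no = fits.whole["no"][0]
        mean_high = fits.whole["high"][0]
        assert mean_no > mean_high

    def test_classification_by_maximum_density(self):
        records, sites, pairs = self._fixture()
        _, fits = paralog_divergence(pairs, records, sites)
        assert fits.classify(0.99, kind="whole") == "no"
        assert fits.classify(fits.whole["high"][0], kind="whole") == "high"

    def test_unknown_class_rejected(self):
        records, sites, _ = self._fixture()
        with pytest.raises(ValidationError, match="divergence class"):
            paralog_divergence([("N1", "N2", "medium")], records, sites)

    def test_missing_sequence_rejected(self):
        records, sites, _ = self._fixture()
        with pytest.raises(ValidationError, match="missing sequence"):
            paralog_divergence([("N1", "ZZ", "no")], records, sites)

    def test_aligner_uses_needle_defaults(self):
        aligner = make_global_aligner()
        assert aligner.open_internal_gap_score == -10.0
        assert aligner.extend_internal_gap_score == -0.5
        assert aligner.end_gap_score == 0.0  # free end gaps
        assert aligner.mode == "global"
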
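"""Match decisions, degree of similarity, and motif-pair mapping."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ppimotifs import (
    InteractionNetwork,
    MinerConfig,
    Motif,
    MotifPair,
    ProteinRecord,
    degree_of_similarity,
    find_matches,
    map_motif_pairs,
    merge_site_intervals,
)
from ppimotifs.io import AMINO_ACIDS, ValidationError
from ppimotifs.matching import MatchEngine
from tests.conftest import random_record


def make_record(pid, seq, cons=None, rsa=None):
    n = len(seq)
    cons = np.full(n, 9) if cons is None else np.asarray(cons)
    rsa = np.full(n, 9) if rsa is None else np.asarray(rsa)
    return ProteinRecord(pid, seq, cons, rsa)


class TestDegreeOfSimilarity:
    def test_single_position(self, S):
        assert degree_of_similarity(Motif("A"), "S", S) == pytest.approx(4 / 7)

    def test_average_over_specified_positions(self, S):
        # (sim(A,S) + sim(A,A)) / 2
        assert degree_of_similarity(Motif("AA"), "SA", S) == pytest.approx((4 / 7 + 1) / 2)

    def test_wildcards_excluded_from_average(self, S):
        # "A*" against "AW": the wildcard position does not drag the score down
        assert degree_of_similarity(Motif("A*"), "AW", S) == pytest.approx(1.0)
        assert degree_of_similarity(Motif("AW"), "AW", S) == pytest.approx(1.0)
        assert degree_of_similarity(Motif("AA"), "AW", S) == pytest.approx(0.5)

    def test_perfect_match_is_one(self, S):
        assert degree_of_similarity(Motif("ACDEFGHK"), "ACDEFGHK", S) == 1.0

    def test_length_mismatch_rejected(self, S):
        with pytest.raises(ValidationError):
            degree_of_similarity(Motif("AC"), "ACD", S)

    def test_all_wildcard_motif_rejected(self):
        with pytest.raises(ValidationError):
            Motif("***")

    @given(st.text(alphabet=AMINO_ACIDS, min_size=4, max_size=10), st.data())
    @settings(max_examples=40, deadline=None)
    def test_adding_wildcards_never_decreases_self_similarity(self, seq, data):
        """Replacing positions with wildcards keeps sim(window vs itself) at 1,
        and against any other window the specified-average is over a subset."""
        S = __import__("ppimotifs").build_similarity_matrix()
        other = data.draw(st.text(alphabet=AMINO_ACIDS, min_size=len(seq), max_size=len(seq)))
        n_wild = data.draw(st.integers(0, len(seq) - 1))
        positions = data.draw(st.permutations(range(len(seq))))[:n_wild]
        pat = "".join("*" if i in positions else c for i, c in enumerate(seq))
        assert degree_of_similarity(Motif(pat), seq, S) == pytest.approx(1.0)
        full = degree_of_similarity(Motif(seq), other, S)
        assert 0.0 <= degree_of_similarity(Motif(pat), other, S) <= 1.0
        assert 0.0 <= full <= 1.0


class TestMatchDecisions:
    def test_exact_match_threshold_none(self, S):
        rec = make_record("P", "MKTAYIAKQR")
        cfg = MinerConfig(l=4, d=2, sim_threshold=None, cons_threshold=None, rsa_threshold=None)
        decisions = find_matches(Motif("TAYI"), rec, cfg, S)
        assert [d.passed for d in decisions] == [False, False, True] + [False] * 4
        assert decisions[2].start == 2
        assert decisions[2].mean_similarity == pytest.approx(1.0)

    def test_none_threshold_equals_threshold_one(self, S):
        """Disabling the similarity relaxation is exactly the perfect-match rule."""
        rng = np.random.default_rng(0)
        cfg_none = MinerConfig(l=5, d=3, sim_threshold=None, cons_threshold=None, rsa_threshold=None)
        cfg_one = MinerConfig(l=5, d=3, sim_threshold=1.0, cons_threshold=None, rsa_threshold=None)
        for _ in range(20):
            rec = random_record("P", 30, rng)
            start = int(rng.integers(0, 26))
            pat = list(rec.sequence[start:start + 5])
            pat[int(rng.integers(0, 5))] = "*"
            motif = Motif("".join(pat))
            a = [d.passed for d in find_matches(motif, rec, cfg_none, S)]
            b = [d.passed for d in find_matches(motif, rec, cfg_one, S)]
            assert a == b
            assert a[start]  # the source window always matches

    def test_lower_threshold_matches_superset(self, S):
        rng = np.random.default_rng(1)
        rec = random_record("P", 60, rng)
        motif = Motif(rec.sequence[10:18])
        passed = {}
        for thr in (None, 0.7, 0.6, 0.5, 0.4):
            cfg = MinerConfig(sim_threshold=thr, cons_threshold=None, rsa_threshold=None)
            passed[thr] = {d.start for d in find_matches(motif, rec, cfg, S) if d.passed}
        assert passed[None] <= passed[0.7] <= passed[0.6] <= passed[0.5] <= passed[0.4]

    def test_track_filters_use_window_mean_with_geq(self, S):
        seq = "AAAAAAAAAA"
        cons = [9, 9, 9, 9, 5, 5, 5, 5, 5, 5]
        rec = make_record("P", seq, cons=cons)
        # windows of length 4: means 9, 8, 7, 6, 5.75(?) ...
        cfg = MinerConfig(l=4, d=2, sim_threshold=1.0, cons_threshold=7, rsa_threshold=None)
        got = [d.passed for d in find_matches(Motif("AAAA"), rec, cfg, S)]
        means = [np.mean(cons[i:i + 4]) for i in range(7)]
        assert got == [m >= 7 for m in means]
        # boundary: mean exactly 7.0 passes, 6.75 fails
        assert means[2] == 7.0 and got[2]
        assert means[3] == 6.0 and not got[3]

    def test_wildcard_positions_still_count_in_track_means(self, S):
        seq = "ACDE"
        cons = [9, 0, 9, 9]  # mean 6.75 over the full window
        rec = make_record("P", seq, cons=cons)
        cfg = MinerConfig(l=4, d=2, sim_threshold=1.0, cons_threshold=7, rsa_threshold=None)
        # the low-conservation residue sits under a wildcard, but the window
        # mean is still 6.75 < 7: no match
        decisions = find_matches(Motif("A*DE"), rec, cfg, S)
        assert decisions[0].mean_conservation == pytest.approx(6.75)
        assert not decisions[0].passed

    def test_rsa_filter_independent_of_conservation(self, S):
        rec = make_record("P", "AAAA", cons=[9] * 4, rsa=[3] * 4)
        cfg = MinerConfig(l=4, d=2, sim_threshold=1.0, cons_threshold=6, rsa_threshold=7)
        assert not any(d.passed for d in find_matches(Motif("AAAA"), rec, cfg, S))
        cfg_off = MinerConfig(l=4, d=2, sim_threshold=1.0, cons_threshold=6, rsa_threshold=None)
        assert any(d.passed for d in find_matches(Motif("AAAA"), rec, cfg_off, S))

    def test_protein_shorter_than_motif_has_no_windows(self, S):
        rec = make_record("P", "ACD")
        cfg = MinerConfig(l=8, sim_threshold=1.0, cons_threshold=None, rsa_threshold=None)
        assert find_matches(Motif("ACDEFGHK"), rec, cfg, S) == []


class TestEngineConsistency:
    def test_profile_matches_scalar_function(self, S):
        rng = np.random.default_rng(3)
        rec = random_record("P", 40, rng)
        cfg = MinerConfig(sim_threshold=0.5, cons_threshold=None, rsa_threshold=None)
        engine = MatchEngine({"P": rec}, S, cfg)
        motif = Motif(rec.sequence[5:11] + "**")
        profile = engine.similarity_profile(motif, "P")
        for i in range(len(profile)):
            window = rec.sequence[i:i + 8]
            assert profile[i] == pytest.approx(degree_of_similarity(motif, window, S))


class TestMapping:
    def _network(self):
        recs = {
            "P1": make_record("P1", "MKTAYIAKQRCWDE"),
            "P2": make_record("P2", "GGGGNPLTGGGG"),
            "P3": make_record("P3", "TAYIAKQRGGGGGG"),
            "P4": make_record("P4", "HHHHHHHHHHHHHH"),
        }
        net = InteractionNetwork([("P1", "P2"), ("P2", "P3"), ("P1", "P4")])
        cfg = MinerConfig(l=4, d=2, sim_threshold=1.0, cons_threshold=None, rsa_threshold=None)
        return recs, net, cfg

    def test_pair_explains_edges_in_either_orientation(self, S):
        recs, net, cfg = self._network()
        pair = MotifPair(Motif("AYIA"), Motif("NPLT"))
        sites, edge_map = map_motif_pairs([pair], net, recs, cfg, S)
        # AYIA occurs in P1 and P3, NPLT in P2: both P2 edges explained
        assert set(edge_map) == {("P1", "P2"), ("P2", "P3")}
        by_protein = {(s.protein_id, s.start, s.end, s.pattern) for s in sites}
        assert ("P1", 4, 7, "AYIA") in by_protein
        assert ("P3", 2, 5, "AYIA") in by_protein
        assert ("P2", 5, 8, "NPLT") in by_protein

    def test_occurrence_partner_accumulation(self, S):
        recs, net, cfg = self._network()
        pair = MotifPair(Motif("AYIA"), Motif("NPLT"))
        sites, _ = map_motif_pairs([pair], net, recs, cfg, S)
        p2_sites = [s for s in sites if s.protein_id == "P2"]
        assert len(p2_sites) == 1  # one occurrence, two partners
        assert p2_sites[0].partners == frozenset({"P1", "P3"})

    def test_homodimeric_pattern_counted_once_per_edge(self, S):
        recs = {
            "P1": make_record("P1", "AAAAYIAK"),
            "P2": make_record("P2", "GGAYIAKG"),
        }
        net = InteractionNetwork([("P1", "P2")])
        cfg = MinerConfig(l=4, d=2, sim_threshold=1.0, cons_threshold=None, rsa_threshold=None)
        pair = MotifPair(Motif("AYIA"), Motif("AYIA"))
        sites, edge_map = map_motif_pairs([pair], net, recs, cfg, S)
        assert set(edge_map) == {("P1", "P2")}
        assert {(s.protein_id, s.start) for s in sites} == {("P1", 4), ("P2", 3)}

    def test_unexplained_edge_absent(self, S):
        recs, net, cfg = self._network()
        pair = MotifPair(Motif("AYIA"), Motif("NPLT"))
        _, edge_map = map_motif_pairs([pair], net, recs, cfg, S)
        assert ("P1", "P4") not in edge_map

    def test_site_coordinates_one_based_inclusive(self, S):
        recs, net, cfg = self._network()
        pair = MotifPair(Motif("MKTA"), Motif("NPLT"))
        sites, _ = map_motif_pairs([pair], net, recs, cfg, S)
        first = [s for s in sites if s.protein_id == "P1"][0]
        assert (first.start, first.end) == (1, 4)
        assert recs["P1"].sequence[first.start - 1:first.end] == "MKTA"


def test_overlapping_and_adjacent_site_intervals_merge():
    from ppimotifs import SiteAnnotation

    def mk(pid, s, e):
        return SiteAnnotation(pid, s, e, "AAAA", frozenset(), 1.0, 9.0, 9.0)

    sites = [
        mk("P1", 1, 4), mk("P1", 3, 7), mk("P1", 8, 10),  # adjacent joins
        mk("P1", 20, 23), mk("P2", 2, 5),
    ]
    assert merge_site_intervals(sites) == {"P1": [(1, 10), (20, 23)], "P2": [(2, 5)]}
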
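"""Motif presence decisions and mapping of motif pairs onto interactions.

A motif of length ``l`` is present in a sequence window when three
conditions hold simultaneously:

1. the *degree of similarity* — the average row-rescaled substitution score
   over the motif's specified (non-wildcard) positions — reaches the
   similarity threshold; with the similarity relaxation disabled
   (threshold ``None``) a perfect match at every specified position is
   required instead;
2. the window's mean conservation (over all ``l`` residues) reaches the
   conservation threshold, if one is active;
3. the window's mean accessibility reaches the RSA threshold, if active.

Thresholds compare with >=. Wildcard positions impose no similarity
constraint but still contribute their residues to the two track averages:
the track filters are a property of the matched sequence region, not of the
motif.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .features import (
    SimilarityMatrix,
    WILDCARD_CODE,
    encode_motif,
    encode_sequence,
)
from .io import (
    WILDCARD,
    InteractionNetwork,
    MinerConfig,
    ProteinRecord,
    SiteAnnotation,
    ValidationError,
)


@dataclass(frozen=True)
class Motif:
    """A length-``l`` pattern over amino acids and the wildcard character."""

    pattern: str

    def __post_init__(self) -> None:
        if len(self.pattern) < 1:
            raise ValidationError("empty motif pattern")
        if self.n_wildcards >= len(self.pattern):
            raise ValidationError("motif must have at least one specified position")

    @property
    def l(self) -> int:
        return len(self.pattern)

    @property
    def n_wildcards(self) -> int:
        return self.pattern.count(WILDCARD)

    @property
    def codes(self) -> np.ndarray:
        return encode_motif(self.pattern)

    def __str__(self) -> str:
        return self.pattern


class MotifPair:
    """An unordered pair of motifs with its network-overrepresentation score."""

    __slots__ = ("a", "b", "score")

    def __init__(self, a: Motif, b: Motif, score: float = 0.0) -> None:
        # canonical order makes (a, b) and (b, a) the same object value
        if b.pattern < a.pattern:
            a, b = b, a
        self.a = a
        self.b = b
        self.score = score

    @property
    def key(self) -> tuple[str, str]:
        return (self.a.pattern, self.b.pattern)

    @property
    def n_wildcards(self) -> int:
        return self.a.n_wildcards + self.b.n_wildcards

    def __eq__(self, other) -> bool:
        return isinstance(other, MotifPair) and self.key == other.key

    def __hash__(self) -> int:
        return hash(self.key)

    def __repr__(self) -> str:
        return f"MotifPair({self.a.pattern!r}, {self.b.pattern!r}, support={self.score:g})"


@dataclass(frozen=True)
class MatchDecision:
    """Outcome of testing one motif against one sequence window."""

    protein_id: str
    start: int  # 0-based window start
    mean_similarity: float
    mean_conservation: float
    mean_rsa: float
    passed: bool


def degree_of_similarity(motif: Motif, window: str, S: SimilarityMatrix) -> float:
    """Average similarity over the motif's specified positions (wildcards excluded)."""
    if len(window) != motif.l:
        raise ValidationError(f"window length {len(window)} != motif length {motif.l}")
    total = 0.0
    n = 0
    for m, w in zip(motif.pattern, window):
        if m == WILDCARD:
            continue
        total += S.sim(m, w)
        n += 1
    if n == 0:
        raise ValidationError("motif is all wildcards; similarity undefined")
    return total / n


class MatchEngine:
    """Vectorized motif matching over a fixed set of protein records.

    Precomputes, per protein, the integer-encoded sliding windows and the
    window means of the conservation and accessibility tracks, and caches
    per-pattern match results — the mining search re-tests the same patterns
    many times.
    """

    def __init__(
        self,
        records: Mapping[str, ProteinRecord],
        S: SimilarityMatrix,
        config: MinerConfig,
    ) -> None:
        self.records = records
        self.S = S
        self.config = config
        l = config.l
        self._windows: dict[str, np.ndarray] = {}
        self._track_ok: dict[str, np.ndarray] = {}
        self._cons_mean: dict[str, np.ndarray] = {}
        self._rsa_mean: dict[str, np.ndarray] = {}
        for pid, rec in records.items():
            n_win = len(rec) - l + 1
            if n_win <= 0:
                continue
            codes = encode_sequence(rec.sequence)
            self._windows[pid] = np.lib.stride_tricks.sliding_window_view(codes, l)
            kernel = np.ones(l) / l
            cons_mean = np.convolve(rec.conservation, kernel, mode="valid")
            rsa_mean = np.convolve(rec.rsa, kernel, mode="valid")
            self._cons_mean[pid] = cons_mean
            self._rsa_mean[pid] = rsa_mean
            ok = np.ones(n_win, dtype=bool)
            if config.cons_threshold is not None:
                ok &= cons_mean >= config.cons_threshold - 1e-9
            if config.rsa_threshold is not None:
                ok &= rsa_mean >= config.rsa_threshold - 1e-9
            self._track_ok[pid] = ok
        self._match_cache: dict[str, frozenset[str]] = {}
        self._passed_cache: dict[tuple[str, str], np.ndarray] = {}

    # -- per-protein window scoring -------------------------------------

    def similarity_profile(self, motif: Motif, protein_id: str) -> np.ndarray:
        """Degree of similarity of ``motif`` against every window of one protein."""
        W = self._windows.get(protein_id)
        if W is None:
            return np.empty(0, dtype=float)
        codes = motif.codes
        specified = codes != WILDCARD_CODE
        if not specified.any():
            raise ValidationError("motif is all wildcards; similarity undefined")
        mc = codes[specified].astype(int)
        sub = self.S.extended[mc[None, :], W[:, specified].astype(int)]
        return sub.sum(axis=1) / specified.sum()

    def passed_windows(self, motif: Motif, protein_id: str) -> np.ndarray:
        """Boolean mask over windows of ``protein_id`` that satisfy all criteria."""
        key = (motif.pattern, protein_id)
        cached = self._passed_cache.get(key)
        if cached is not None:
            return cached
        W = self._windows.get(protein_id)
        if W is None:
            result = np.empty(0, dtype=bool)
        else:
            sims = self.similarity_profile(motif, protein_id)
            thr = self.config.sim_threshold
            if thr is None:
                # similarity relaxation off: perfect match at specified positions
                passed = sims >= 1.0 - 1e-12
            else:
                passed = sims >= thr - 1e-12
            result = passed & self._track_ok[protein_id]
        self._passed_cache[key] = result
        return result

    def find_matches(self, motif: Motif, protein: ProteinRecord | str) -> list[MatchDecision]:
        """One MatchDecision per window of the protein (possibly empty)."""
        pid = protein if isinstance(protein, str) else protein.id
        if pid not in self._windows:
            return []
        sims = self.similarity_profile(motif, pid)
        passed = self.passed_windows(motif, pid)
        cons = self._cons_mean[pid]
        rsa = self._rsa_mean[pid]
        return [
            MatchDecision(
                protein_id=pid,
                start=i,
                mean_similarity=float(sims[i]),
                mean_conservation=float(cons[i]),
                mean_rsa=float(rsa[i]),
                passed=bool(passed[i]),
            )
            for i in range(len(sims))
        ]

    def matches(self, motif: Motif) -> frozenset[str]:
        """The set of protein ids containing the motif."""
        cached = self._match_cache.get(motif.pattern)
        if cached is not None:
            return cached
        hits = frozenset(
            pid for pid in self._windows if self.passed_windows(motif, pid).any()
        )
        self._match_cache[motif.pattern] = hits
        return hits

    def matches_protein(self, motif: Motif, protein_id: str) -> bool:
        return bool(self.passed_windows(motif, protein_id).any())

    # -- seeding helpers used by the miner --------------------------------

    def eligible_seed_windows(self) -> list[tuple[str, int]]:
        """Windows whose own track averages pass the active filters.

        A motif occurrence at a window failing the conservation/accessibility
        filters can never be a match, so seeds are drawn from the passing
        windows; when no filter is active (or none passes) all windows are
        eligible.
        """
        if self.config.cons_threshold is None and self.config.rsa_threshold is None:
            return self.all_windows()
        out = [
            (pid, int(i))
            for pid in sorted(self._track_ok)
            for i in self._track_ok[pid].nonzero()[0]
        ]
        return out if out else self.all_windows()

    def all_windows(self) -> list[tuple[str, int]]:
        return [
            (pid, i)
            for pid in sorted(self._windows)
            for i in range(len(self._windows[pid]))
        ]

    def window_pattern(self, protein_id: str, start: int) -> str:
        return self.records[protein_id].sequence[start : start + self.config.l]


# ---------------------------------------------------------------------------
# module-level surface mirroring the engine, for one-off calls
# ---------------------------------------------------------------------------


def find_matches(
    motif: Motif,
    protein: ProteinRecord,
    config: MinerConfig,
    S: SimilarityMatrix,
) -> list[MatchDecision]:
    engine = MatchEngine({protein.id: protein}, S, config)
    return engine.find_matches(motif, protein)


def motif_matches_protein(
    motif: Motif,
    protein: ProteinRecord,
    config: MinerConfig,
    S: SimilarityMatrix,
) -> bool:
    return any(d.passed for d in find_matches(motif, protein, config, S))


def map_motif_pairs(
    pairs: Sequence[MotifPair],
    net: InteractionNetwork,
    records: Mapping[str, ProteinRecord],
    config: MinerConfig,
    S: SimilarityMatrix,
    engine: MatchEngine | None = None,
) -> tuple[list[SiteAnnotation], dict[tuple[str, str], list[MotifPair]]]:
    """Map motif pairs onto the interactions they explain.

    A pair (a, b) explains edge {p, q} when a matches p and b matches q, or
    vice versa (both orientations are recorded when both hold). Every passed
    window of the matched motif on the matched protein becomes a
    SiteAnnotation carrying the partner id.
    """
    if engine is None:
        engine = MatchEngine(records, S, config)
    edge_map: dict[tuple[str, str], list[MotifPair]] = {}
    # accumulate partners per (protein, window, pattern) before materializing
    occ_partners: dict[tuple[str, int, str], set[str]] = {}

    for pair in pairs:
        hits_a = engine.matches(pair.a)
        hits_b = engine.matches(pair.b)
        for edge in net.edges:
            p, q = edge
            fwd = p in hits_a and q in hits_b
            rev = p in hits_b and q in hits_a
            if not (fwd or rev):
                continue
            edge_map.setdefault(edge, []).append(pair)
            orientations = []
            if fwd:
                orientations.append((pair.a, p, q))
                orientations.append((pair.b, q, p))
            if rev and pair.a.pattern != pair.b.pattern:
                orientations.append((pair.b, p, q))
                orientations.append((pair.a, q, p))
            for motif, host, partner in orientations:
                for i in engine.passed_windows(motif, host).nonzero()[0]:
                    occ_partners.setdefault((host, int(i), motif.pattern), set()).add(partner)

    sites: list[SiteAnnotation] = []
    l = config.l
    for (pid, start, pattern), partners in sorted(occ_partners.items()):
        decisions = engine.find_matches(Motif(pattern), pid)
        d = decisions[start]
        sites.append(
            SiteAnnotation(
                protein_id=pid,
                start=start + 1,
                end=start + l,
                pattern=pattern,
                partners=frozenset(partners),
                mean_similarity=d.mean_similarity,
                mean_conservation=d.mean_conservation,
                mean_rsa=d.mean_rsa,
            )
        )
    return sites, edge_map


def merge_site_intervals(sites: Iterable[SiteAnnotation]) -> dict[str, list[tuple[int, int]]]:
    """Per-protein union of site intervals (1-based inclusive), overlaps merged."""
    by_protein: dict[str, list[tuple[int, int]]] = {}
    for s in sites:
        by_protein.setdefault(s.protein_id, []).append((s.start, s.end))
    merged: dict[str, list[tuple[int, int]]] = {}
    for pid, intervals in by_protein.items():
        intervals.sort()
        out = [intervals[0]]
        for start, end in intervals[1:]:
            if start <= out[-1][1] + 1:
                out[-1] = (out[-1][0], max(out[-1][1], end))
            else:
                out.append((start, end))
        merged[pid] = out
    return merged
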
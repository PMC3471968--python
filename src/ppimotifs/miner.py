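"""The correlated motif-pair search.

The miner repeatedly seeds a motif pair from actual sequence windows and
improves it by steepest-ascent local search ("sliding") on an
overrepresentation objective, until a wall-clock budget or restart cap is
reached; the top-N distinct pairs by support are emitted.

Objective
---------
The default objective is *support*: the number of network edges {p, q} such
that one motif of the pair is present in p and the other in q (either
orientation). A frequency-corrected variant (support minus the expected
number of co-occurring edges if the two motifs' protein sets were placed
independently) is available via ``objective="corrected"``.

Move set (per pair member)
--------------------------
* shift the source window one residue left or right within its sequence,
  keeping the wildcard mask;
* toggle one position to a wildcard (while at most ``d`` wildcards and at
  least one specified position remain) or back to its source residue;
* re-seed the partner motif as the best-scoring window among sequences of
  the matched proteins' interaction partners.

Only strictly support-improving moves are taken; ties among candidate moves
are broken by fewer total wildcards, then lexicographic pattern order, which
makes the search deterministic given the RNG state.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .io import (
    AMINO_ACIDS,
    WILDCARD,
    InteractionNetwork,
    MinerConfig,
    ProteinRecord,
    ValidationError,
)
from .features import SimilarityMatrix, build_similarity_matrix
from .matching import MatchEngine, Motif, MotifPair

logger = logging.getLogger(__name__)

_STANDARD = frozenset(AMINO_ACIDS)


@dataclass(frozen=True)
class ObjectiveValue:
    """Value of the overrepresentation objective for one motif pair."""

    support: int
    corrected: float

    def value(self, objective: str = "support") -> float:
        return self.support if objective == "support" else self.corrected


def score_motif_pair(
    pair: MotifPair,
    net: InteractionNetwork,
    records: Mapping[str, ProteinRecord] | None,
    config: MinerConfig,
    S: SimilarityMatrix,
    engine: MatchEngine | None = None,
) -> ObjectiveValue:
    """Count the network edges explained by a motif pair.

    An edge {p, q} is explained when one motif matches p and the other q,
    in either orientation, under the active thresholds.
    """
    if engine is None:
        engine = MatchEngine(records, S, config)
    ha = engine.matches(pair.a)
    hb = engine.matches(pair.b)
    support = 0
    for p, q in net.edges:
        if (p in ha and q in hb) or (p in hb and q in ha):
            support += 1
    n = len(net)
    expected = 0.0
    if n > 1:
        # expected explained edges if the two hit sets were placed independently
        pa, pb = len(ha) / n, len(hb) / n
        # chance a random edge is explained if hit sets were independent;
        # union of the two orientations of the (a, b) placement
        p_edge = min(1.0, 1.0 - (1.0 - pa * pb) ** 2)
        expected = net.n_edges * p_edge
    return ObjectiveValue(support=support, corrected=support - expected)


def _window_is_clean(seq: str) -> bool:
    return all(c in _STANDARD for c in seq)


@dataclass(frozen=True)
class _MotifState:
    """A motif anchored to its source window plus a wildcard mask."""

    protein_id: str
    start: int
    mask: tuple[bool, ...]  # True = wildcard at that position

    def pattern(self, engine: MatchEngine) -> str:
        window = engine.window_pattern(self.protein_id, self.start)
        return "".join(
            WILDCARD if w else c for c, w in zip(window, self.mask)
        )

    def motif(self, engine: MatchEngine) -> Motif:
        return Motif(self.pattern(engine))


def _fresh_state(pid: str, start: int, l: int) -> _MotifState:
    return _MotifState(pid, start, (False,) * l)


def _pair_from_states(sa: _MotifState, sb: _MotifState, engine: MatchEngine) -> MotifPair:
    return MotifPair(sa.motif(engine), sb.motif(engine))


def _member_moves(state: _MotifState, engine: MatchEngine, config: MinerConfig):
    """Shift and wildcard-toggle neighbours of one pair member."""
    rec = engine.records[state.protein_id]
    l = config.l
    out: list[_MotifState] = []
    for delta in (-1, 1):
        s = state.start + delta
        if 0 <= s <= len(rec) - l and _window_is_clean(rec.sequence[s : s + l]):
            out.append(_MotifState(state.protein_id, s, state.mask))
    n_wild = sum(state.mask)
    for i in range(l):
        mask = list(state.mask)
        if state.mask[i]:
            mask[i] = False
        elif n_wild < config.d and (l - n_wild) > 1:
            mask[i] = True
        else:
            continue
        out.append(_MotifState(state.protein_id, state.start, tuple(mask)))
    return out


def _reseed_candidates(
    anchor: _MotifState,
    engine: MatchEngine,
    net: InteractionNetwork,
    rng: np.random.Generator,
    cap: int,
) -> list[_MotifState]:
    """Windows of the anchor's matched proteins' interaction partners."""
    matched = engine.matches(anchor.motif(engine))
    partners: set[str] = set()
    for pid in matched:
        partners |= net.partners(pid)
    if not partners:
        return []
    pool = [
        (pid, start)
        for pid, start in engine.eligible_seed_windows()
        if pid in partners and _window_is_clean(engine.window_pattern(pid, start))
    ]
    if not pool:
        return []
    if len(pool) > cap:
        idx = rng.choice(len(pool), size=cap, replace=False)
        pool = [pool[i] for i in sorted(idx)]
    return [_fresh_state(pid, start, engine.config.l) for pid, start in pool]


def _rank_key(pair: MotifPair, value: float) -> tuple:
    # higher objective, then fewer wildcards, then lexicographic patterns
    return (-value, pair.n_wildcards, pair.key)


def slide_optimize(
    seed: tuple[_MotifState, _MotifState] | MotifPair,
    net: InteractionNetwork,
    records: Mapping[str, ProteinRecord] | None,
    config: MinerConfig,
    S: SimilarityMatrix,
    rng: np.random.Generator,
    engine: MatchEngine | None = None,
    deadline: float | None = None,
    reseed_cap: int = 40,
    objective: str = "support",
) -> MotifPair:
    """Steepest-ascent local search from a seed pair.

    Returns the locally optimal pair; its ``score`` attribute equals an
    independent re-evaluation of the objective on the returned pair. When
    the deadline passes mid-search the best pair so far is returned.
    """
    if engine is None:
        engine = MatchEngine(records, S, config)
    if isinstance(seed, MotifPair):
        raise ValidationError(
            "slide_optimize requires window-anchored seed states; use mine() "
            "or build states from sequence windows"
        )
    sa, sb = seed
    current = _pair_from_states(sa, sb, engine)
    current_val = score_motif_pair(current, net, None, config, S, engine).value(objective)

    while True:
        if deadline is not None and time.monotonic() > deadline:
            logger.warning("time budget exhausted mid-search; returning best-so-far")
            break
        candidates: list[tuple[_MotifState, _MotifState]] = []
        for m_idx, state in ((0, sa), (1, sb)):
            for new_state in _member_moves(state, engine, config):
                candidates.append((new_state, sb) if m_idx == 0 else (sa, new_state))
            for new_other in _reseed_candidates(state, engine, net, rng, reseed_cap):
                candidates.append((state, new_other) if m_idx == 0 else (new_other, state))
        best = None
        for cand in candidates:
            pair = _pair_from_states(cand[0], cand[1], engine)
            val = score_motif_pair(pair, net, None, config, S, engine).value(objective)
            if val <= current_val:
                continue
            key = _rank_key(pair, val)
            if best is None or key < best[0]:
                best = (key, cand, pair, val)
        if best is None:
            break
        _, (sa, sb), current, current_val = best

    final = score_motif_pair(current, net, None, config, S, engine)
    return MotifPair(current.a, current.b, score=final.value(objective))


def mine(
    net: InteractionNetwork,
    records: Mapping[str, ProteinRecord],
    config: MinerConfig,
    S: SimilarityMatrix | None = None,
    *,
    objective: str = "support",
    stagnation_limit: int = 50,
    reseed_cap: int = 40,
) -> list[MotifPair]:
    """Mine the top-N overrepresented motif pairs from a PPI network.

    Restarts (random eligible seed window -> local search) accumulate a pool
    of distinct pairs until the time budget elapses, the restart cap is hit,
    or no new pair has been found for ``stagnation_limit`` restarts.
    """
    if net.n_edges == 0:
        raise ValidationError("cannot mine an empty network")
    if config.time_limit <= 0:
        raise ValidationError("time budget must be positive")
    if S is None:
        S = build_similarity_matrix()
    engine = MatchEngine(records, S, config)
    seeds = [
        (pid, start)
        for pid, start in engine.eligible_seed_windows()
        if _window_is_clean(engine.window_pattern(pid, start))
    ]
    if not seeds:
        raise ValidationError(f"no sequence offers a clean window of length {config.l}")

    rng = np.random.default_rng(config.seed)
    deadline = time.monotonic() + config.time_limit
    pool: dict[tuple[str, str], MotifPair] = {}
    restarts = 0
    since_new = 0
    while time.monotonic() < deadline:
        if config.max_restarts is not None and restarts >= config.max_restarts:
            break
        if since_new >= stagnation_limit and len(pool) >= config.n_pairs:
            break
        restarts += 1
        pid, start = seeds[int(rng.integers(len(seeds)))]
        sa = _fresh_state(pid, start, config.l)
        partner_pool = [
            (q, s) for q, s in seeds if q in net.partners(pid)
        ] or seeds
        qid, qstart = partner_pool[int(rng.integers(len(partner_pool)))]
        sb = _fresh_state(qid, qstart, config.l)
        pair = slide_optimize(
            (sa, sb), net, None, config, S, rng,
            engine=engine, deadline=deadline, reseed_cap=reseed_cap,
            objective=objective,
        )
        if pair.key not in pool:
            pool[pair.key] = pair
            since_new = 0
        else:
            since_new += 1

    ranked = sorted(pool.values(), key=lambda p: _rank_key(p, p.score))
    if len(ranked) < config.n_pairs:
        logger.info(
            "discovered %d distinct pairs (< requested %d)", len(ranked), config.n_pairs
        )
    return ranked[: config.n_pairs]


def generate_random_motif_pairs(
    records: Mapping[str, ProteinRecord],
    l: int,
    d: int,
    n: int,
    rng: np.random.Generator,
    max_attempts_factor: int = 100,
) -> list[MotifPair]:
    """The random-pair null: sample substrings and mask exactly ``d`` wildcards.

    Each motif is drawn by choosing a sequence uniformly, a start position
    uniformly, and ``d`` wildcard positions uniformly without replacement;
    two independent draws form a pair.
    """
    if not 0 <= d < l:
        raise ValidationError("need 0 <= d < l")
    seqs = [rec.sequence for rec in records.values() if len(rec) >= l]
    if not seqs:
        raise ValidationError(f"no sequence of length >= {l}")

    def draw_motif() -> Motif:
        for _ in range(max_attempts_factor):
            seq = seqs[int(rng.integers(len(seqs)))]
            start = int(rng.integers(len(seq) - l + 1))
            window = seq[start : start + l]
            positions = set(rng.choice(l, size=d, replace=False).tolist()) if d else set()
            if not _window_is_clean("".join(
                c for i, c in enumerate(window) if i not in positions
            )):
                continue
            pattern = "".join(
                WILDCARD if i in positions else c for i, c in enumerate(window)
            )
            return Motif(pattern)
        raise ValidationError("could not draw a motif free of non-standard residues")

    return [MotifPair(draw_motif(), draw_motif()) for _ in range(n)]
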
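"""Evaluation of predicted motif pairs against known interfaces.

Quality measures
----------------
* **Accuracy of predicted motifs** — the fraction of mapped motif
  occurrences that touch the interface: an occurrence is correct when at
  least one of its residues is an interface residue of its protein (for the
  interacting pair it was mapped to, when pair-specific labels exist).
* **Coverage of protein-protein interfaces** — the fraction of interacting
  pairs carrying at least one occurrence that overlaps the interface on
  either endpoint.
* **F-score** — the harmonic mean 2·A·C / (A + C), 0 when A·C == 0.

Interface residues are called from solvent-accessible surface areas: a
residue is interface when its area in the complex is strictly smaller than
in the unbound protein. Structure-homology hits are screened by the
four-criteria filter (bit score > 70, both coverages >= 30%, identity > 40%).

Significance is assessed against sets of randomly generated motif pairs via
an add-one empirical p-value, and the threshold grid sweep reproduces the
5 x 6 x 6 parameter exploration (similarity in {none, .4, .5, .6, .7};
conservation and accessibility each in {none, 3..7}).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import (
    InteractionNetwork,
    InterfaceLabels,
    MinerConfig,
    ProteinRecord,
    ValidationError,
)
from .features import SimilarityMatrix, build_similarity_matrix
from .matching import MatchEngine, MotifPair, map_motif_pairs
from .miner import generate_random_motif_pairs, mine

logger = logging.getLogger(__name__)

SIM_GRID: tuple = (None, 0.4, 0.5, 0.6, 0.7)
TRACK_GRID: tuple = (None, 3, 4, 5, 6, 7)


@dataclass(frozen=True)
class ParamSetting:
    """One point of the threshold grid; ``None`` switches a criterion off."""

    s_thresh: float | None
    c_thresh: float | None
    a_thresh: float | None

    def label(self) -> str:
        fmt = lambda v: "none" if v is None else f"{v:g}"  # noqa: E731
        return f"sim={fmt(self.s_thresh)},cons={fmt(self.c_thresh)},rsa={fmt(self.a_thresh)}"


@dataclass(frozen=True)
class AssessmentResult:
    """Accuracy / Coverage / F-score with the counts backing each ratio."""

    accuracy: float
    coverage: float
    fscore: float
    n_occurrences: int
    n_correct: int
    n_edges: int
    n_covered_edges: int

    def summary_row(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "coverage": self.coverage,
            "fscore": self.fscore,
            "n_occurrences": self.n_occurrences,
            "n_correct": self.n_correct,
            "n_edges": self.n_edges,
            "n_covered_edges": self.n_covered_edges,
        }


def fscore(accuracy: float, coverage: float) -> float:
    """Harmonic mean of accuracy and coverage; 0 when either is 0."""
    if accuracy + coverage == 0:
        return 0.0
    return 2 * accuracy * coverage / (accuracy + coverage)


def identify_interface_residues(
    asa_complex: Mapping[int, float],
    asa_unbound: Mapping[int, float],
) -> set[int]:
    """Residues whose accessible surface area shrinks upon complex formation.

    A residue is interface when its area in the complex is strictly smaller
    than in the unbound protein; equal areas (and the numerical artifact of a
    larger complexed area) are non-interface.
    """
    if set(asa_complex) != set(asa_unbound):
        raise ValidationError("complex and unbound ASA tables cover different residues")
    interface = set()
    for pos, area_c in asa_complex.items():
        area_u = asa_unbound[pos]
        if area_c < 0 or area_u < 0:
            raise ValidationError(f"negative surface area at residue {pos}")
        if area_c < area_u:
            interface.add(pos)
        elif area_c > area_u:
            logger.debug("residue %d more exposed in complex (%.2f > %.2f)", pos, area_c, area_u)
    return interface


_HIT_COLUMNS = ("bit_score", "query_cov_fraction", "target_cov_fraction", "identity_fraction")


def filter_structural_hits(hits: pd.DataFrame) -> pd.DataFrame:
    """Screen sequence-to-structure homology hits by the four-criteria rule.

    Keep a hit iff bit score > 70, the aligned region covers at least 30% of
    both query and target lengths, and the aligned identity exceeds 40%.
    """
    missing = [c for c in _HIT_COLUMNS if c not in hits.columns]
    if missing:
        raise ValidationError(f"hits table missing column(s): {', '.join(missing)}")
    keep = (
        (hits["bit_score"] > 70)
        & (hits["query_cov_fraction"] >= 0.30)
        & (hits["target_cov_fraction"] >= 0.30)
        & (hits["identity_fraction"] > 0.40)
    )
    return hits.loc[keep].copy()


def evaluate(
    pairs: Sequence[MotifPair],
    net: InteractionNetwork,
    records: Mapping[str, ProteinRecord],
    labels: InterfaceLabels,
    config: MinerConfig,
    S: SimilarityMatrix,
    engine: MatchEngine | None = None,
    unit: str = "occurrence",
) -> AssessmentResult:
    """Score a prediction set against interface labels.

    ``unit`` chooses the accuracy counting unit: ``"occurrence"`` (default)
    counts every mapped motif occurrence on an interacting pair;
    ``"motif"`` counts unique (protein, interval, pattern) occurrences once
    regardless of how many partners they explain.
    """
    if unit not in ("occurrence", "motif"):
        raise ValidationError(f"unknown accuracy unit {unit!r}")
    if engine is None:
        engine = MatchEngine(records, S, config)
    l = config.l

    # window-overlap counting from cached pass masks and interface prefix sums
    iface_cum: dict[tuple[str, str | None], np.ndarray] = {}

    def overlap_counts(motif, host: str, partner: str | None) -> tuple[int, int]:
        """(n passed windows, n passed windows touching the interface)."""
        idx = engine.passed_windows(motif, host).nonzero()[0]
        if idx.size == 0:
            return 0, 0
        key = (host, partner)
        cum = iface_cum.get(key)
        if cum is None:
            n = len(records[host])
            mask = np.zeros(n, dtype=int)
            for pos in labels.residues(host, partner):
                if pos <= n:
                    mask[pos - 1] = 1
            cum = np.concatenate(([0], np.cumsum(mask)))
            iface_cum[key] = cum
        hit = cum[idx + l] - cum[idx] > 0
        return int(idx.size), int(hit.sum())

    n_occ = 0
    n_correct = 0
    covered_edges: set[tuple[str, str]] = set()
    counted: set[tuple] = set()
    for pair in pairs:
        ha = engine.matches(pair.a)
        hb = engine.matches(pair.b)
        for edge in net.edges:
            p, q = edge
            fwd = p in ha and q in hb
            rev = p in hb and q in ha
            if not (fwd or rev):
                continue
            orientations = []
            if fwd:
                orientations += [(pair.a, p, q), (pair.b, q, p)]
            if rev and pair.a.pattern != pair.b.pattern:
                orientations += [(pair.b, p, q), (pair.a, q, p)]
            for motif, host, partner in orientations:
                pkey = partner if labels.has_pair_labels else None
                n_pass, n_hit = overlap_counts(motif, host, pkey)
                if n_hit:
                    covered_edges.add(edge)
                if unit == "occurrence":
                    key = (motif.pattern, host, partner)
                    if key in counted:
                        continue
                    counted.add(key)
                    n_occ += n_pass
                    n_correct += n_hit
                else:  # unique-motif unit: count each (pattern, host) once
                    key = (motif.pattern, host)
                    if key in counted:
                        continue
                    counted.add(key)
                    n_pass_u, n_hit_u = overlap_counts(motif, host, None)
                    n_occ += n_pass_u
                    n_correct += n_hit_u

    if n_occ == 0:
        logger.debug("no mapped motif occurrences; accuracy set to 0")
        accuracy = 0.0
    else:
        accuracy = n_correct / n_occ
    n_edges = net.n_edges
    coverage = len(covered_edges) / n_edges if n_edges else 0.0
    return AssessmentResult(
        accuracy=accuracy,
        coverage=coverage,
        fscore=fscore(accuracy, coverage),
        n_occurrences=n_occ,
        n_correct=n_correct,
        n_edges=n_edges,
        n_covered_edges=len(covered_edges),
    )


def empirical_pvalue(observed: float, null_values: Sequence[float]) -> float:
    """Add-one empirical p-value: (1 + #{null >= observed}) / (1 + n_null).

    Ties count against the observed value, and p can never reach 0 — with
    1000 null sets the smallest attainable p is 1/1001.
    """
    null_values = list(null_values)
    if not null_values:
        raise ValidationError("empirical p-value needs at least one null value")
    ge = sum(1 for v in null_values if v >= observed)
    return (1 + ge) / (1 + len(null_values))


def parameter_grid() -> list[ParamSetting]:
    """The full 5 x 6 x 6 Cartesian grid of threshold settings (180 points)."""
    return [
        ParamSetting(s, c, a)
        for s, c, a in itertools.product(SIM_GRID, TRACK_GRID, TRACK_GRID)
    ]


def null_fscores(
    net: InteractionNetwork,
    records: Mapping[str, ProteinRecord],
    labels: InterfaceLabels,
    config: MinerConfig,
    S: SimilarityMatrix,
    n_sets: int,
    n_pairs_per_set: int,
    rng: np.random.Generator,
    engine: MatchEngine | None = None,
) -> list[float]:
    """F-scores of randomly generated motif-pair sets (the randomization null)."""
    if engine is None:
        engine = MatchEngine(records, S, config)
    out = []
    for _ in range(n_sets):
        pairs = generate_random_motif_pairs(records, config.l, config.d, n_pairs_per_set, rng)
        out.append(evaluate(pairs, net, records, labels, config, S, engine=engine).fscore)
    return out


def grid_sweep(
    net: InteractionNetwork,
    records: Mapping[str, ProteinRecord],
    labels: InterfaceLabels,
    base_config: MinerConfig,
    S: SimilarityMatrix | None = None,
    settings: Sequence[ParamSetting] | None = None,
    n_null_sets: int = 0,
    base_seed: int = 0,
    **mine_kwargs,
) -> pd.DataFrame:
    """Mine + evaluate at every grid setting, one reproducible seed per setting.

    Returns one row per setting with the counts, Accuracy, Coverage, F-score
    and (when ``n_null_sets`` > 0) the randomization p-value.
    """
    if S is None:
        S = build_similarity_matrix()
    if settings is None:
        settings = parameter_grid()
    rows = []
    for idx, setting in enumerate(settings):
        config = base_config.with_thresholds(
            setting.s_thresh, setting.c_thresh, setting.a_thresh
        )
        config = replace(config, seed=base_seed + idx)
        pairs = mine(net, records, config, S, **mine_kwargs)
        engine = MatchEngine(records, S, config)
        result = evaluate(pairs, net, records, labels, config, S, engine=engine)
        row = {
            "setting": setting.label(),
            "s_thresh": setting.s_thresh,
            "c_thresh": setting.c_thresh,
            "a_thresh": setting.a_thresh,
            "seed": base_seed + idx,
            "n_pairs": len(pairs),
            **result.summary_row(),
        }
        if n_null_sets > 0:
            rng = np.random.default_rng(base_seed + idx)
            nulls = null_fscores(
                net, records, labels, config, S,
                n_sets=n_null_sets, n_pairs_per_set=max(1, len(pairs)),
                rng=rng, engine=engine,
            )
            row["p_value"] = empirical_pvalue(result.fscore, nulls)
        rows.append(row)
    return pd.DataFrame(rows)
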
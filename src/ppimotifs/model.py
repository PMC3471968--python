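"""Model-style front end: build a miner from data, fit, inspect results.

`MotifPairMiner` bundles a network, its protein records and a configuration;
`fit()` runs the motif-pair search and returns a `MiningResults` object that
carries the mined pairs and their supports and exposes mapping, evaluation
and a text summary.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import (
    InteractionNetwork,
    InterfaceLabels,
    MinerConfig,
    ProteinRecord,
    SiteAnnotation,
)
from .features import SimilarityMatrix, build_similarity_matrix
from .matching import MatchEngine, MotifPair, map_motif_pairs
from .miner import generate_random_motif_pairs, mine
from .assessment import AssessmentResult, empirical_pvalue, evaluate, null_fscores


class MotifPairMiner:
    """Correlated motif-pair model over a protein interaction network.

    Parameters
    ----------
    network : InteractionNetwork
    records : mapping of id -> ProteinRecord
    config : MinerConfig, optional
        Defaults: motif length 8, up to 5 wildcards, similarity threshold
        0.6, conservation threshold 6, accessibility threshold 7.
    similarity : SimilarityMatrix, optional
        Row-rescaled BLOSUM62 by default.
    """

    def __init__(
        self,
        network: InteractionNetwork,
        records: Mapping[str, ProteinRecord],
        config: MinerConfig | None = None,
        similarity: SimilarityMatrix | None = None,
    ) -> None:
        self.network = network
        self.records = dict(records)
        self.config = config or MinerConfig()
        self.similarity = similarity or build_similarity_matrix()

    @classmethod
    def from_files(
        cls,
        fasta_path,
        network_path,
        conservation_path,
        rsa_path,
        config: MinerConfig | None = None,
    ) -> "MotifPairMiner":
        from .io import load_dataset

        records, net = load_dataset(fasta_path, network_path, conservation_path, rsa_path)
        return cls(net, records, config=config)

    def fit(self, seed: int | None = None, **mine_kwargs) -> "MiningResults":
        """Run the search and return the mined pairs as a results object."""
        config = self.config
        if seed is not None:
            from dataclasses import replace

            config = replace(config, seed=seed)
        pairs = mine(self.network, self.records, config, self.similarity, **mine_kwargs)
        return MiningResults(self, pairs, config)


class MiningResults:
    """Mined motif pairs with their supports, plus mapping and evaluation."""

    def __init__(
        self,
        model: MotifPairMiner,
        pairs: Sequence[MotifPair],
        config: MinerConfig,
    ) -> None:
        self.model = model
        self.pairs = list(pairs)
        self.config = config
        self._engine = MatchEngine(model.records, model.similarity, config)
        self._sites: list[SiteAnnotation] | None = None
        self._edge_map = None

    @property
    def supports(self) -> np.ndarray:
        return np.array([p.score for p in self.pairs])

    def sites(self) -> list[SiteAnnotation]:
        """All mapped motif occurrences, with their interaction partners."""
        self._map()
        return self._sites

    def edge_map(self):
        """Mapping edge -> list of motif pairs explaining it."""
        self._map()
        return self._edge_map

    def _map(self) -> None:
        if self._sites is None:
            self._sites, self._edge_map = map_motif_pairs(
                self.pairs, self.model.network, self.model.records,
                self.config, self.model.similarity, engine=self._engine,
            )

    def evaluate(self, labels: InterfaceLabels, unit: str = "occurrence") -> AssessmentResult:
        """Accuracy / Coverage / F-score against known interface residues."""
        return evaluate(
            self.pairs, self.model.network, self.model.records, labels,
            self.config, self.model.similarity, engine=self._engine, unit=unit,
        )

    def significance(
        self,
        labels: InterfaceLabels,
        n_null_sets: int = 1000,
        rng: np.random.Generator | None = None,
    ) -> tuple[float, float]:
        """(observed F-score, randomization p-value) against random pair sets."""
        if rng is None:
            rng = np.random.default_rng(self.config.seed)
        observed = self.evaluate(labels).fscore
        nulls = null_fscores(
            self.model.network, self.model.records, labels, self.config,
            self.model.similarity, n_sets=n_null_sets,
            n_pairs_per_set=max(1, len(self.pairs)), rng=rng, engine=self._engine,
        )
        return observed, empirical_pvalue(observed, nulls)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "pattern_a": [p.a.pattern for p in self.pairs],
                "pattern_b": [p.b.pattern for p in self.pairs],
                "support": [p.score for p in self.pairs],
            }
        )

    def summary(self) -> str:
        cfg = self.config
        fmt = lambda v: "none" if v is None else f"{v:g}"  # noqa: E731
        lines = [
            "Motif-pair mining results",
            "=" * 48,
            f"proteins: {len(self.model.records)}   edges: {self.model.network.n_edges}",
            f"motif length l={cfg.l}, wildcard budget d={cfg.d}",
            f"thresholds: similarity={fmt(cfg.sim_threshold)}, "
            f"conservation={fmt(cfg.cons_threshold)}, rsa={fmt(cfg.rsa_threshold)}",
            f"seed: {cfg.seed}",
            f"pairs mined: {len(self.pairs)}",
        ]
        if self.pairs:
            lines.append("-" * 48)
            lines.append(f"{'pattern_a':<12}{'pattern_b':<12}{'support':>8}")
            for p in self.pairs[:10]:
                lines.append(f"{p.a.pattern:<12}{p.b.pattern:<12}{p.score:>8g}")
            if len(self.pairs) > 10:
                lines.append(f"... and {len(self.pairs) - 10} more")
        return "\n".join(lines)
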
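"""Shared fixtures: tiny deterministic protein sets and networks."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from ppimotifs import (
    InteractionNetwork,
    MinerConfig,
    ProteinRecord,
    build_similarity_matrix,
)
from ppimotifs.io import AMINO_ACIDS


@pytest.fixture(scope="session")
def S():
    return build_similarity_matrix()


def random_record(pid: str, length: int, rng: np.random.Generator,
                  cons_high: bool = False, rsa_high: bool = False) -> ProteinRecord:
    seq = "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, length))
    cons = np.full(length, 9) if cons_high else rng.integers(0, 10, length)
    rsa = np.full(length, 9) if rsa_high else rng.integers(0, 10, length)
    return ProteinRecord(pid, seq, cons, rsa)


@pytest.fixture()
def permissive_config():
    """All filters off, similarity threshold 1.0 (exact matching)."""
    return MinerConfig(sim_threshold=1.0, cons_threshold=None, rsa_threshold=None)


@pytest.fixture()
def tiny_dataset():
    """Six random 30-mers with maximal tracks and a 5-edge network."""
    rng = np.random.default_rng(42)
    ids = [f"P{i}" for i in range(1, 7)]
    records = {
        pid: random_record(pid, 30, rng, cons_high=True, rsa_high=True)
        for pid in ids
    }
    edges = [("P1", "P2"), ("P3", "P4"), ("P1", "P3"), ("P5", "P6"), ("P2", "P5")]
    return records, InteractionNetwork(edges)


def random_tiny_problem(seed: int, n_proteins: int = 6, n_edges: int = 6,
                        min_len: int = 15, max_len: int = 25):
    """A small random mining problem for oracle-equivalence checks."""
    rng = np.random.default_rng(seed)
    ids = [f"T{i}" for i in range(n_proteins)]
    records = {
        pid: random_record(pid, int(rng.integers(min_len, max_len + 1)), rng)
        for pid in ids
    }
    all_pairs = list(itertools.combinations(ids, 2))
    idx = rng.choice(len(all_pairs), size=n_edges, replace=False)
    net = InteractionNetwork([all_pairs[i] for i in idx])
    return records, net
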
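"""Synthetic benchmark generator with known ground truth.

Emulates the statistical structure the mining method assumes: an undirected
interaction network in which a fraction of edges is carried by a planted
motif pair — a slightly mutated copy of one pattern inserted into each
endpoint — whose occurrences sit in regions that are both conserved and
surface-exposed, while the background is i.i.d. sequence with unremarkable
tracks. Interface labels are the planted intervals, and a SNP table can be
drawn with a configurable in-site rate multiplier (set it to 0 to construct
depletion, to 1 for a calibration null).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io import (
    AMINO_ACIDS,
    InteractionNetwork,
    InterfaceLabels,
    ProteinRecord,
    ValidationError,
)

#: BLOSUM62 background amino-acid frequencies (Robinson & Robinson order ACDE...)
BLOSUM62_FREQS = {
    "A": 0.074, "C": 0.025, "D": 0.054, "E": 0.054, "F": 0.047,
    "G": 0.074, "H": 0.026, "I": 0.068, "K": 0.058, "L": 0.099,
    "M": 0.025, "N": 0.045, "P": 0.039, "Q": 0.034, "R": 0.052,
    "S": 0.057, "T": 0.051, "V": 0.073, "W": 0.013, "Y": 0.032,
}


@dataclass(frozen=True)
class PlantedPair:
    """One motif pair planted on a fraction of the network's edges.

    ``interface=True`` plants a genuine binding site: occurrences get
    elevated conservation *and* accessibility and are recorded as interface
    ground truth. ``interface=False`` plants a decoy — a conserved but
    buried recurring segment (elevated conservation, background
    accessibility, no interface label), the classic confound that
    overrepresentation mining without a surface-accessibility filter
    cannot reject.
    """

    pattern_a: str | None = None  # None: drawn at generation time
    pattern_b: str | None = None
    edge_fraction: float = 0.3
    substitution_prob: float = 0.1
    interface: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.edge_fraction <= 1:
            raise ValidationError("edge_fraction must lie in (0, 1]")
        if not 0 <= self.substitution_prob < 1:
            raise ValidationError("substitution_prob must lie in [0, 1)")


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for one synthetic benchmark.

    Defaults give the standard desk-scale benchmark: 50 proteins, 150 edges,
    one genuine (interface) planted pair of 8-mers carried by 30% of the
    edges with a 10% per-position substitution rate, plus two decoy pairs —
    conserved but buried — at the same prevalence. Background tracks are
    uniform on 0..6 and interface-site windows are elevated to 8-9 on both
    tracks, so genuine occurrences clear the default thresholds (similarity
    0.6, conservation 6, RSA 7) while background windows and decoys do not.
    """

    n_proteins: int = 50
    n_edges: int = 150
    length_range: tuple[int, int] = (80, 120)
    motif_length: int = 8
    planted: tuple[PlantedPair, ...] = (
        PlantedPair(),
        PlantedPair(interface=False),
        PlantedPair(interface=False),
    )
    cons_background: tuple[int, int] = (0, 6)
    rsa_background: tuple[int, int] = (0, 6)
    cons_site: tuple[int, int] = (8, 9)
    rsa_site: tuple[int, int] = (8, 9)
    snp_rate: float = 0.0  # per-residue probability of an nsSNP
    snp_in_site_multiplier: float = 1.0
    background_frequencies: str = "uniform"  # or "blosum62"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.length_range[0] < self.motif_length:
            raise ValidationError("minimum sequence length shorter than the motif")
        cap = self.n_proteins * (self.n_proteins - 1) // 2
        if self.n_edges > cap:
            raise ValidationError(f"{self.n_edges} edges exceed simple-graph capacity {cap}")


@dataclass
class Benchmark:
    """A generated dataset plus its ground truth."""

    records: dict[str, ProteinRecord]
    network: InteractionNetwork
    labels: InterfaceLabels
    snps: pd.DataFrame
    truth_intervals: dict[str, list[tuple[int, int]]]  # 1-based inclusive
    truth_edges: list[set[tuple[str, str]]]  # per planted pair: edges planted on
    realized_edges: list[set[tuple[str, str]]]  # per pair: all edges the planted
    # occurrences explain (one endpoint carries a copy of pattern_a, the other
    # of pattern_b) -- a superset of truth_edges once proteins host copies for
    # several edges
    planted_patterns: list[tuple[str, str]]
    decoy_patterns: list[tuple[str, str]]
    decoy_intervals: dict[str, list[tuple[int, int]]]


def _draw_pattern(length: int, rng: np.random.Generator, letters: str, probs) -> str:
    idx = rng.choice(len(letters), size=length, p=probs)
    return "".join(letters[i] for i in idx)


def _mutate(pattern: str, prob: float, rng: np.random.Generator, letters: str) -> str:
    """Substitute positions independently, never at two adjacent positions."""
    out = list(pattern)
    last_mutated = -2
    for i in range(len(out)):
        if i - last_mutated == 1:
            continue
        if rng.random() < prob:
            choices = [c for c in letters if c != out[i]]
            out[i] = choices[int(rng.integers(len(choices)))]
            last_mutated = i
    return "".join(out)


def generate_benchmark(spec: SyntheticSpec, out_dir: str | Path | None = None) -> Benchmark:
    """Generate a benchmark dataset; optionally write it in the standard formats.

    When ``out_dir`` is given, writes sequences.fasta, network.tsv,
    conservation.tsv, rsa.tsv, interface_labels.tsv, snps.tsv and
    ground_truth.tsv.
    """
    rng = np.random.default_rng(spec.seed)
    letters = AMINO_ACIDS
    if spec.background_frequencies == "blosum62":
        probs = np.array([BLOSUM62_FREQS[c] for c in letters])
        probs = probs / probs.sum()
    else:
        probs = np.full(len(letters), 1 / len(letters))

    ids = [f"P{i:04d}" for i in range(1, spec.n_proteins + 1)]

    # --- network: uniform random simple graph with exactly n_edges ---
    all_pairs_count = spec.n_proteins * (spec.n_proteins - 1) // 2
    chosen = rng.choice(all_pairs_count, size=spec.n_edges, replace=False)
    edge_list = []
    pair_index = {}
    k = 0
    for i in range(spec.n_proteins):
        for j in range(i + 1, spec.n_proteins):
            pair_index[k] = (ids[i], ids[j])
            k += 1
    for c in sorted(int(c) for c in chosen):
        edge_list.append(pair_index[c])
    network = InteractionNetwork(edge_list, proteins=ids)

    # --- background sequences and tracks ---
    lo, hi = spec.length_range
    sequences = {}
    cons = {}
    rsa = {}
    for pid in ids:
        n = int(rng.integers(lo, hi + 1))
        sequences[pid] = list(_draw_pattern(n, rng, letters, probs))
        cons[pid] = rng.integers(spec.cons_background[0], spec.cons_background[1] + 1, size=n)
        rsa[pid] = rng.integers(spec.rsa_background[0], spec.rsa_background[1] + 1, size=n)

    # --- plant motif pairs ---
    truth_intervals: dict[str, list[tuple[int, int]]] = {pid: [] for pid in ids}
    decoy_intervals: dict[str, list[tuple[int, int]]] = {pid: [] for pid in ids}
    truth_edges: list[set[tuple[str, str]]] = []
    realized_edges: list[set[tuple[str, str]]] = []
    planted_patterns: list[tuple[str, str]] = []
    decoy_patterns: list[tuple[str, str]] = []
    labels = InterfaceLabels()
    l = spec.motif_length
    edges = network.edges
    occupied: dict[str, list[tuple[int, int]]] = {pid: [] for pid in ids}  # 0-based half-open

    def free_starts(pid: str) -> list[int]:
        n = len(sequences[pid])
        return [
            start
            for start in range(n - l + 1)
            if all(start + l <= s or start >= e for s, e in occupied[pid])
        ]

    def place(pid: str, pattern: str, pp: PlantedPair, start: int) -> None:
        seq = sequences[pid]
        mutated = _mutate(pattern, pp.substitution_prob, rng, letters)
        seq[start : start + l] = list(mutated)
        cons[pid][start : start + l] = rng.integers(
            spec.cons_site[0], spec.cons_site[1] + 1, size=l
        )
        if pp.interface:
            rsa[pid][start : start + l] = rng.integers(
                spec.rsa_site[0], spec.rsa_site[1] + 1, size=l
            )
        # decoys keep background accessibility: conserved but buried
        occupied[pid].append((start, start + l))
        if pp.interface:
            truth_intervals[pid].append((start + 1, start + l))
            for pos in range(start + 1, start + l + 1):
                labels.add(pid, pos)
        else:
            decoy_intervals[pid].append((start + 1, start + l))

    for pp in spec.planted:
        pattern_a = pp.pattern_a or _draw_pattern(l, rng, letters, probs)
        pattern_b = pp.pattern_b or _draw_pattern(l, rng, letters, probs)
        n_carry = max(1, int(round(pp.edge_fraction * len(edges))))
        idx = rng.choice(len(edges), size=n_carry, replace=False)
        carried = set()
        hosts_a: set[str] = set()
        hosts_b: set[str] = set()
        for i in sorted(int(i) for i in idx):
            p, q = edges[i]
            starts_p, starts_q = free_starts(p), free_starts(q)
            if not starts_p or not starts_q:
                # sequence too crowded to host another occurrence; skip edge
                continue
            place(p, pattern_a, pp, starts_p[int(rng.integers(len(starts_p)))])
            place(q, pattern_b, pp, starts_q[int(rng.integers(len(starts_q)))])
            carried.add((p, q))
            hosts_a.add(p)
            hosts_b.add(q)
        if pp.interface:
            planted_patterns.append((pattern_a, pattern_b))
            truth_edges.append(carried)
            realized_edges.append(
                {
                    (p, q)
                    for p, q in edges
                    if (p in hosts_a and q in hosts_b) or (p in hosts_b and q in hosts_a)
                }
            )
        else:
            decoy_patterns.append((pattern_a, pattern_b))

    records = {
        pid: ProteinRecord(
            id=pid,
            sequence="".join(sequences[pid]),
            conservation=np.asarray(cons[pid], dtype=int),
            rsa=np.asarray(rsa[pid], dtype=int),
        )
        for pid in ids
    }

    # --- SNP table ---
    snp_rows = []
    site_pos = {
        pid: {p for s, e in truth_intervals[pid] for p in range(s, e + 1)}
        for pid in ids
    }
    if spec.snp_rate > 0:
        for pid in ids:
            n = len(records[pid])
            for pos in range(1, n + 1):
                rate = spec.snp_rate
                if pos in site_pos[pid]:
                    rate *= spec.snp_in_site_multiplier
                if rng.random() < rate:
                    snp_rows.append({"protein_id": pid, "position": pos,
                                     "snp_class": "nonsynonymous"})
    snps = pd.DataFrame(snp_rows, columns=["protein_id", "position", "snp_class"])

    bench = Benchmark(
        records=records,
        network=network,
        labels=labels,
        snps=snps,
        truth_intervals={pid: iv for pid, iv in truth_intervals.items() if iv},
        truth_edges=truth_edges,
        realized_edges=realized_edges,
        planted_patterns=planted_patterns,
        decoy_patterns=decoy_patterns,
        decoy_intervals={pid: iv for pid, iv in decoy_intervals.items() if iv},
    )
    if out_dir is not None:
        _write_benchmark(bench, Path(out_dir))
    return bench


def _write_benchmark(bench: Benchmark, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    with open(out_dir / "sequences.fasta", "w") as fh:
        for pid, rec in bench.records.items():
            fh.write(f">{pid}\n{rec.sequence}\n")
    with open(out_dir / "network.tsv", "w") as fh:
        for p, q in bench.network.edges:
            fh.write(f"{p}\t{q}\n")
    for name, attr in (("conservation", "conservation"), ("rsa", "rsa")):
        with open(out_dir / f"{name}.tsv", "w") as fh:
            for pid, rec in bench.records.items():
                for i, v in enumerate(getattr(rec, attr), start=1):
                    fh.write(f"{pid}\t{i}\t{int(v)}\n")
    with open(out_dir / "interface_labels.tsv", "w") as fh:
        for pid in sorted(bench.labels.proteins):
            for pos in sorted(bench.labels.residues(pid)):
                fh.write(f"{pid}\t{pos}\n")
    bench.snps.to_csv(out_dir / "snps.tsv", sep="\t", index=False, header=False)
    with open(out_dir / "ground_truth.tsv", "w") as fh:
        fh.write("# planted intervals (protein, start, end, 1-based) and carrying edges\n")
        for pid, intervals in sorted(bench.truth_intervals.items()):
            for s, e in intervals:
                fh.write(f"interval\t{pid}\t{s}\t{e}\n")
        for k, carried in enumerate(bench.truth_edges):
            a, b = bench.planted_patterns[k]
            fh.write(f"pair\t{a}\t{b}\n")
            for p, q in sorted(carried):
                fh.write(f"edge\t{p}\t{q}\n")
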
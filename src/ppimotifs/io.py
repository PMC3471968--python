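"""Domain types and readers/writers for the external formats the toolkit touches.

Conventions
-----------
* Sequences are upper-case strings over the 20 standard amino-acid letters;
  ambiguous residues (X, B, Z, U, O) are retained but contribute zero
  similarity wherever a motif is scored against them.
* Per-residue tracks (evolutionary conservation and relative solvent
  accessibility) are integers on a 0-9 scale: 0 = least conserved / fully
  buried, 9 = most conserved / fully exposed.
* Coordinates are 0-based half-open internally; every user-facing TSV is
  1-based inclusive, and BED output is 0-based half-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: motif position that matches any residue and imposes no similarity constraint
WILDCARD = "*"


class ValidationError(ValueError):
    """Raised when an input file violates a documented invariant."""


# ---------------------------------------------------------------------------
# core records
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with aligned per-residue annotation tracks.

    Parameters
    ----------
    id : str
        Unique protein identifier.
    sequence : str
        Amino-acid sequence, upper case.
    conservation : numpy.ndarray of int
        Per-residue conservation score in [0, 9], high = conserved.
    rsa : numpy.ndarray of int
        Per-residue relative solvent accessibility in [0, 9],
        0 = fully buried, 9 = fully exposed.
    """

    id: str
    sequence: str
    conservation: np.ndarray
    rsa: np.ndarray

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValidationError(f"{self.id}: empty sequence")
        cons = np.asarray(self.conservation, dtype=int)
        rsa = np.asarray(self.rsa, dtype=int)
        object.__setattr__(self, "conservation", cons)
        object.__setattr__(self, "rsa", rsa)
        for name, track in (("conservation", cons), ("rsa", rsa)):
            if len(track) != len(self.sequence):
                raise ValidationError(
                    f"{self.id}: {name} track length {len(track)} != "
                    f"sequence length {len(self.sequence)}"
                )
            if track.size and (track.min() < 0 or track.max() > 9):
                raise ValidationError(f"{self.id}: {name} value outside [0, 9]")

    def __len__(self) -> int:
        return len(self.sequence)


class InteractionNetwork:
    """Undirected protein-protein interaction graph.

    Edges are stored canonically: ``{p, q}`` appears once regardless of input
    order. Self-interactions (homodimers) are representable.
    """

    def __init__(
        self,
        edges: Iterable[tuple[str, str]] = (),
        proteins: Iterable[str] = (),
    ) -> None:
        self._g = nx.Graph()
        self._g.add_nodes_from(proteins)
        for p, q in edges:
            self._g.add_edge(p, q)

    @property
    def proteins(self) -> set[str]:
        return set(self._g.nodes)

    @property
    def edges(self) -> list[tuple[str, str]]:
        """Canonical (sorted-tuple) edge list in deterministic order."""
        return sorted(tuple(sorted((p, q))) for p, q in self._g.edges)

    @property
    def n_edges(self) -> int:
        return self._g.number_of_edges()

    def partners(self, protein_id: str) -> set[str]:
        if protein_id not in self._g:
            return set()
        return set(self._g.neighbors(protein_id))

    def has_edge(self, p: str, q: str) -> bool:
        return self._g.has_edge(p, q)

    def subgraph_edge_count(self, proteins: Iterable[str]) -> int:
        return self._g.subgraph(list(proteins)).number_of_edges()

    def restrict_to(self, proteins: Iterable[str]) -> "InteractionNetwork":
        keep = set(proteins)
        net = InteractionNetwork(proteins=keep & self.proteins)
        for p, q in self.edges:
            if p in keep and q in keep:
                net._g.add_edge(p, q)
        return net

    def __contains__(self, protein_id: str) -> bool:
        return protein_id in self._g

    def __len__(self) -> int:
        return self._g.number_of_nodes()


@dataclass(frozen=True)
class SiteAnnotation:
    """A motif occurrence mapped onto a protein interval.

    ``start``/``end`` are 1-based inclusive (the convention used in all
    TSV output); ``partners`` lists the interaction partners this
    occurrence helps explain.
    """

    protein_id: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    pattern: str
    partners: frozenset[str] = frozenset()
    mean_similarity: float = float("nan")
    mean_conservation: float = float("nan")
    mean_rsa: float = float("nan")

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValidationError(
                f"{self.protein_id}: bad interval {self.start}-{self.end}"
            )

    @property
    def interval0(self) -> tuple[int, int]:
        """0-based half-open interval."""
        return self.start - 1, self.end

    @property
    def residues(self) -> set[int]:
        """The 1-based residue positions covered."""
        return set(range(self.start, self.end + 1))


@dataclass(frozen=True)
class MinerConfig:
    """Parameters controlling motif mining and match filtering.

    Attributes
    ----------
    l : int
        Motif length (default 8).
    d : int
        Maximum number of wildcard positions allowed in a mined motif
        (default 5). The random-pair null places exactly ``d`` wildcards.
    n_pairs : int
        Number of motif pairs to emit (default 1000).
    time_limit : float
        Wall-clock search budget in seconds (default 3600).
    sim_threshold : float or None
        Minimum average row-rescaled substitution similarity over the
        motif's specified positions. ``None`` disables the similarity
        relaxation entirely: a perfect match is then required.
    cons_threshold, rsa_threshold : float or None
        Minimum average conservation / accessibility over the matched
        window (all ``l`` residues); ``None`` switches the filter off.
    seed : int or None
        RNG seed for reproducible mining.
    max_restarts : int or None
        Optional cap on local-search restarts (besides the time budget).
    """

    l: int = 8
    d: int = 5
    n_pairs: int = 1000
    time_limit: float = 3600.0
    sim_threshold: float | None = 0.6
    cons_threshold: float | None = 6.0
    rsa_threshold: float | None = 7.0
    seed: int | None = None
    max_restarts: int | None = None

    def __post_init__(self) -> None:
        if self.l < 1:
            raise ValidationError("motif length l must be >= 1")
        if not (0 <= self.d < self.l):
            raise ValidationError("wildcard budget d must satisfy 0 <= d < l")
        if self.n_pairs < 1:
            raise ValidationError("n_pairs must be >= 1")
        if self.sim_threshold is not None and not (0 <= self.sim_threshold <= 1):
            raise ValidationError("sim_threshold must lie in [0, 1] or be None")
        for name in ("cons_threshold", "rsa_threshold"):
            v = getattr(self, name)
            if v is not None and not (0 <= v <= 9):
                raise ValidationError(f"{name} must lie in [0, 9] or be None")

    def with_thresholds(
        self,
        sim: float | None,
        cons: float | None,
        rsa: float | None,
    ) -> "MinerConfig":
        return replace(
            self, sim_threshold=sim, cons_threshold=cons, rsa_threshold=rsa
        )


class InterfaceLabels:
    """Known interface residues, per protein and optionally per interacting pair.

    Positions are 1-based. When pair-specific labels exist they are used for
    that pair; the per-protein view is the union over all pairs.
    """

    def __init__(self) -> None:
        self._by_protein: dict[str, set[int]] = {}
        self._by_pair: dict[tuple[str, str], dict[str, set[int]]] = {}

    def add(self, protein_id: str, position: int, partner_id: str | None = None) -> None:
        if position < 1:
            raise ValidationError(
                f"{protein_id}: interface position {position} is not 1-based"
            )
        self._by_protein.setdefault(protein_id, set()).add(position)
        if partner_id is not None:
            key = tuple(sorted((protein_id, partner_id)))
            self._by_pair.setdefault(key, {}).setdefault(protein_id, set()).add(position)

    @property
    def proteins(self) -> set[str]:
        return set(self._by_protein)

    @property
    def has_pair_labels(self) -> bool:
        return bool(self._by_pair)

    def residues(self, protein_id: str, partner_id: str | None = None) -> set[int]:
        """Interface residues of ``protein_id``; pair-specific when available."""
        if partner_id is not None and self._by_pair:
            key = tuple(sorted((protein_id, partner_id)))
            if key in self._by_pair:
                return set(self._by_pair[key].get(protein_id, set()))
        return set(self._by_protein.get(protein_id, set()))

    def validate_against(self, records: Mapping[str, ProteinRecord]) -> None:
        for pid, positions in self._by_protein.items():
            if pid in records and positions and max(positions) > len(records[pid]):
                raise ValidationError(
                    f"{pid}: interface position {max(positions)} beyond "
                    f"sequence length {len(records[pid])}"
                )


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an id -> sequence map; duplicate ids are an error."""
    sequences: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in sequences:
            raise ValidationError(f"duplicate FASTA id {rec.id!r} in {path}")
        seq = str(rec.seq).upper()
        if not seq:
            raise ValidationError(f"FASTA record {rec.id!r} in {path} is empty")
        sequences[rec.id] = seq
    return sequences


def read_network(path: str | Path) -> InteractionNetwork:
    """Read a 2-column TSV edge list ('#' comments allowed)."""
    edges = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 2:
                raise ValidationError(f"{path}:{ln}: expected two protein ids")
            edges.append((parts[0], parts[1]))
    return InteractionNetwork(edges)


def read_track(path: str | Path) -> dict[str, dict[int, int]]:
    """Read a per-residue track TSV with columns (protein_id, position_1based, value)."""
    track: dict[str, dict[int, int]] = {}
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=["protein_id", "position", "value"])
    for pid, pos, val in df.itertuples(index=False):
        pos, val = int(pos), int(val)
        if not 0 <= val <= 9:
            raise ValidationError(f"{path}: track value {val} for {pid}:{pos} outside [0, 9]")
        if pos < 1:
            raise ValidationError(f"{path}: position {pos} for {pid} is not 1-based")
        track.setdefault(str(pid), {})[pos] = val
    return track


def _track_to_array(pid: str, length: int, values: dict[int, int], name: str) -> np.ndarray:
    if set(values) != set(range(1, length + 1)):
        raise ValidationError(
            f"{pid}: {name} track covers {len(values)} positions, "
            f"sequence has {length} residues"
        )
    return np.array([values[i] for i in range(1, length + 1)], dtype=int)


def load_dataset(
    fasta_path: str | Path,
    network_path: str | Path,
    conservation_path: str | Path,
    rsa_path: str | Path,
) -> tuple[dict[str, ProteinRecord], InteractionNetwork]:
    """Load sequences, network and annotation tracks into validated records.

    Network proteins lacking a sequence are dropped with a logged warning
    (their edges go with them); every retained record satisfies the
    track-length invariant.
    """
    sequences = read_fasta(fasta_path)
    net = read_network(network_path)
    cons = read_track(conservation_path)
    rsa = read_track(rsa_path)

    records: dict[str, ProteinRecord] = {}
    for pid, seq in sequences.items():
        if pid not in cons or pid not in rsa:
            raise ValidationError(f"{pid}: missing conservation or rsa track")
        records[pid] = ProteinRecord(
            id=pid,
            sequence=seq,
            conservation=_track_to_array(pid, len(seq), cons[pid], "conservation"),
            rsa=_track_to_array(pid, len(seq), rsa[pid], "rsa"),
        )

    missing = net.proteins - set(records)
    if missing:
        logger.warning(
            "dropping %d network protein(s) without a sequence: %s",
            len(missing), ", ".join(sorted(missing)[:10]),
        )
        net = net.restrict_to(set(records))
    return records, net


def read_interface_labels(path: str | Path) -> InterfaceLabels:
    """Read interface residues from a 2-column (protein, pos) or 3-column
    (protein, partner, pos) TSV."""
    labels = InterfaceLabels()
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) == 2:
                labels.add(parts[0], int(parts[1]))
            elif len(parts) >= 3:
                labels.add(parts[0], int(parts[2]), partner_id=parts[1])
            else:
                raise ValidationError(f"{path}:{ln}: expected 2 or 3 columns")
    return labels


def read_snp_table(path: str | Path) -> pd.DataFrame:
    """Read a SNP TSV (protein_id, position_1based, class in {synonymous, nonsynonymous})."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=["protein_id", "position", "snp_class"])
    df["position"] = df["position"].astype(int)
    bad = ~df["snp_class"].isin(["synonymous", "nonsynonymous"])
    if bad.any():
        raise ValidationError(f"{path}: unknown SNP class {df.loc[bad, 'snp_class'].iloc[0]!r}")
    if (df["position"] < 1).any():
        raise ValidationError(f"{path}: SNP positions must be 1-based")
    return df


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

_SITE_COLUMNS = [
    "protein_id", "start", "end", "pattern", "partners",
    "mean_similarity", "mean_conservation", "mean_rsa",
]


def write_sites(sites: Sequence[SiteAnnotation], path: str | Path, format: str = "tsv") -> None:
    """Write predicted sites as TSV (1-based inclusive) or BED (0-based half-open)."""
    path = Path(path)
    if format == "tsv":
        rows = [
            {
                "protein_id": s.protein_id,
                "start": s.start,
                "end": s.end,
                "pattern": s.pattern,
                "partners": ",".join(sorted(s.partners)),
                "mean_similarity": f"{s.mean_similarity:.6g}",
                "mean_conservation": f"{s.mean_conservation:.6g}",
                "mean_rsa": f"{s.mean_rsa:.6g}",
            }
            for s in sites
        ]
        pd.DataFrame(rows, columns=_SITE_COLUMNS).to_csv(path, sep="\t", index=False)
    elif format == "bed":
        with open(path, "w") as fh:
            for s in sites:
                start0, end0 = s.interval0
                fh.write(f"{s.protein_id}\t{start0}\t{end0}\t{s.pattern}\n")
    else:
        raise ValueError(f"unknown site format {format!r}")


def read_sites(path: str | Path, format: str = "tsv") -> list[SiteAnnotation]:
    """Read back a site file written by :func:`write_sites`."""
    path = Path(path)
    sites: list[SiteAnnotation] = []
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", dtype={"partners": str})
        for row in df.itertuples(index=False):
            partners = frozenset(
                p for p in str(row.partners).split(",") if p and p != "nan"
            ) if not pd.isna(row.partners) else frozenset()
            sites.append(
                SiteAnnotation(
                    protein_id=str(row.protein_id),
                    start=int(row.start),
                    end=int(row.end),
                    pattern=str(row.pattern),
                    partners=partners,
                    mean_similarity=float(row.mean_similarity),
                    mean_conservation=float(row.mean_conservation),
                    mean_rsa=float(row.mean_rsa),
                )
            )
    elif format == "bed":
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                chrom, start0, end0, *rest = line.split("\t")
                sites.append(
                    SiteAnnotation(
                        protein_id=chrom,
                        start=int(start0) + 1,
                        end=int(end0),
                        pattern=rest[0] if rest else "",
                    )
                )
    else:
        raise ValueError(f"unknown site format {format!r}")
    return sites


def write_pairs(pairs, path: str | Path, metadata: Mapping[str, object] | None = None) -> None:
    """Write mined motif pairs as TSV: pattern_a, pattern_b, support."""
    with open(Path(path), "w") as fh:
        for key, value in (metadata or {}).items():
            fh.write(f"# {key}={value}\n")
        fh.write("pattern_a\tpattern_b\tsupport\n")
        for pair in pairs:
            fh.write(f"{pair.a.pattern}\t{pair.b.pattern}\t{pair.score:g}\n")
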
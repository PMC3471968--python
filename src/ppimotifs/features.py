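"""Sequence-derived features: substitution similarity, conservation, accessibility.

The match criterion used throughout the package replaces exact substring
matching with a *degree of similarity* computed from a row-rescaled BLOSUM62
table: within each row ``a``, raw scores are mapped linearly so that the
self-substitution ``(a, a)`` scores exactly 1 and the worst substitution in
that row scores exactly 0. The matrix is therefore not symmetric.

Conservation is an entropy-based score computed from a multiple sequence
alignment of homologs, sign-flipped so that high = conserved, min-max
rescaled over the target-covering columns and binned to integers 0-9.
Relative solvent accessibility (RSA) arrives on the same 0-9 integer scale,
either precomputed (the usual case) or rescaled here from [0, 1] fractions.
"""

from __future__ import annotations

import logging
import math
from typing import Mapping, Sequence

import numpy as np
from Bio import AlignIO
from Bio.Align import substitution_matrices

from .io import AMINO_ACIDS, WILDCARD, ValidationError

logger = logging.getLogger(__name__)

GAP_CHARS = frozenset("-.")

#: integer codes: 0..19 the standard residues, 20 the wildcard, 21 unknown
AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
WILDCARD_CODE = len(AMINO_ACIDS)
UNKNOWN_CODE = WILDCARD_CODE + 1


def encode_sequence(seq: str) -> np.ndarray:
    """Integer-encode a sequence; non-standard residues get UNKNOWN_CODE."""
    return np.array([AA_INDEX.get(c, UNKNOWN_CODE) for c in seq], dtype=np.int8)


def encode_motif(pattern: str) -> np.ndarray:
    codes = []
    for c in pattern:
        if c == WILDCARD:
            codes.append(WILDCARD_CODE)
        elif c in AA_INDEX:
            codes.append(AA_INDEX[c])
        else:
            raise ValidationError(f"motif pattern contains invalid character {c!r}")
    return np.array(codes, dtype=np.int8)


class SimilarityMatrix:
    """Row-rescaled substitution similarity.

    ``sim(a, b)`` is the score of matching motif residue ``a`` against
    sequence residue ``b``: 1 for a perfect match, down to 0 for the worst
    substitution of row ``a``. Matching against an unknown residue scores 0.
    """

    def __init__(self, table: np.ndarray, alphabet: str = AMINO_ACIDS) -> None:
        table = np.asarray(table, dtype=float)
        n = len(alphabet)
        if table.shape != (n, n):
            raise ValidationError(f"similarity table must be {n}x{n}, got {table.shape}")
        if not np.allclose(np.diag(table), 1.0):
            raise ValidationError("similarity diagonal must equal 1")
        if table.min() < 0 or table.max() > 1:
            raise ValidationError("similarity entries must lie in [0, 1]")
        self.alphabet = alphabet
        self.table = table
        # extended lookup: rows/cols for wildcard (never consulted) and unknown
        ext = np.zeros((n + 2, n + 2), dtype=float)
        ext[:n, :n] = table
        self._ext = ext

    @property
    def extended(self) -> np.ndarray:
        """(n+2)x(n+2) lookup indexed by integer codes; unknown residues score 0."""
        return self._ext

    def sim(self, motif_residue: str, sequence_residue: str) -> float:
        i = AA_INDEX.get(motif_residue, UNKNOWN_CODE)
        j = AA_INDEX.get(sequence_residue, UNKNOWN_CODE)
        return float(self._ext[i, j])


def build_similarity_matrix(raw: Mapping | None = None) -> SimilarityMatrix:
    """Rescale a raw substitution matrix (default BLOSUM62) row by row.

    For each row ``a``: ``sim(a, b) = (raw(a, b) - min_b' raw(a, b')) /
    (raw(a, a) - min_b' raw(a, b'))``, so the diagonal is exactly 1 and each
    row's minimum exactly 0.
    """
    if raw is None:
        raw = substitution_matrices.load("BLOSUM62")
        lookup = lambda a, b: float(raw[a, b])  # noqa: E731
    elif callable(getattr(raw, "get", None)) and not hasattr(raw, "alphabet"):
        lookup = lambda a, b: float(raw[(a, b)])  # noqa: E731
    else:
        lookup = lambda a, b: float(raw[a, b])  # noqa: E731

    n = len(AMINO_ACIDS)
    table = np.empty((n, n), dtype=float)
    for i, a in enumerate(AMINO_ACIDS):
        row = np.array([lookup(a, b) for b in AMINO_ACIDS])
        lo, diag = row.min(), row[i]
        if diag <= lo:
            raise ValidationError(f"degenerate substitution row {a!r}: diagonal == row minimum")
        table[i] = (row - lo) / (diag - lo)
    return SimilarityMatrix(table)


def round_half_up(x: float) -> int:
    """Round to nearest integer, ties away from zero-point-five upward."""
    return int(math.floor(x + 0.5))


def rescale_unit_track(values: Sequence[float]) -> np.ndarray:
    """Map fractional [0, 1] values onto the integer 0-9 scale (half-up rounding)."""
    arr = np.asarray(values, dtype=float)
    if arr.size and (arr.min() < 0 or arr.max() > 1):
        raise ValidationError("unit-track values must lie in [0, 1]")
    return np.array([round_half_up(9 * v) for v in arr], dtype=int)


def _column_entropy(column: Sequence[str]) -> tuple[float, int]:
    """Shannon entropy of the residue frequencies in one alignment column.

    Gaps are excluded from the frequency denominator. Returns (H, n_gaps).
    """
    counts: dict[str, int] = {}
    n_gaps = 0
    for c in column:
        if c in GAP_CHARS:
            n_gaps += 1
        else:
            counts[c] = counts.get(c, 0) + 1
    total = sum(counts.values())
    if total == 0:
        return 0.0, n_gaps
    h = 0.0
    for k in counts.values():
        p = k / total
        h -= p * math.log(p)
    return h, n_gaps


def conservation_from_msa(
    msa,
    target_id: str,
    *,
    max_gap_fraction: float = 0.5,
) -> np.ndarray:
    """Integer conservation track for one sequence of a multiple alignment.

    Parameters
    ----------
    msa : Bio.Align.MultipleSeqAlignment, mapping id -> aligned str, or path
        The alignment of the target with its homologs (aligned FASTA).
    target_id : str
        The sequence whose ungapped residues receive scores.
    max_gap_fraction : float
        Columns in which more than this fraction of sequences are gapped are
        assigned the least-conserved raw score of the alignment (sparsely
        aligned positions carry little evidence of conservation).

    Returns
    -------
    numpy.ndarray of int
        One score in [0, 9] per ungapped target residue: the negated column
        entropy, min-max rescaled over the target-covering columns and
        binned with half-up rounding.
    """
    if isinstance(msa, (str,)) or hasattr(msa, "__fspath__"):
        msa = AlignIO.read(str(msa), "fasta")
    if hasattr(msa, "items"):  # plain dict of aligned strings
        aligned = {str(k): str(v).upper() for k, v in msa.items()}
    else:
        aligned = {rec.id: str(rec.seq).upper() for rec in msa}

    if target_id not in aligned:
        raise ValidationError(f"target {target_id!r} not present in the alignment")
    if len(aligned) < 2:
        raise ValidationError("conservation is undefined for a single-sequence alignment")
    lengths = {len(s) for s in aligned.values()}
    if len(lengths) != 1:
        raise ValidationError("aligned sequences have unequal lengths")

    target = aligned[target_id]
    n_seqs = len(aligned)
    columns = list(zip(*aligned.values()))

    raw: list[float] = []
    sparse: list[int] = []  # indices (into raw) of over-gapped columns
    for i, col_chars in enumerate(columns):
        if target[i] in GAP_CHARS:
            continue
        h, n_gaps = _column_entropy(col_chars)
        if n_gaps / n_seqs > max_gap_fraction:
            sparse.append(len(raw))
            raw.append(math.nan)  # filled with the minimum afterwards
        else:
            raw.append(-h)

    scores = np.array(raw, dtype=float)
    finite = scores[~np.isnan(scores)]
    floor = finite.min() if finite.size else 0.0
    for idx in sparse:
        scores[idx] = floor

    lo, hi = scores.min(), scores.max()
    if hi == lo:
        # degenerate rescale: no variation among columns
        if lo == 0.0:  # zero entropy everywhere: perfectly conserved
            return np.full(scores.size, 9, dtype=int)
        logger.warning(
            "alignment for %s has uniform column entropy; conservation set to 5",
            target_id,
        )
        return np.full(scores.size, 5, dtype=int)
    rescaled = (scores - lo) / (hi - lo)
    return np.array([round_half_up(9 * v) for v in rescaled], dtype=int)
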
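"""Downstream variation and divergence analyses of predicted binding sites.

Four analyses connect predicted interface motifs to sequence variation:

* :func:`snp_depletion_test` — are non-synonymous SNPs depleted in predicted
  sites relative to the rest of the sequence? (randomization test,
  depletion-sided);
* :func:`coevolution_test` — do proteins whose predicted sites carry an
  nsSNP preferentially interact with each other? (randomization test,
  enrichment-sided);
* :func:`mutagenesis_overlap_report` — which experimentally mutated
  residues/regions coincide with predicted sites;
* :func:`paralog_divergence` — whole-sequence vs binding-site sequence
  identity of paralog pairs, with per-divergence-class normal density fits.

Both randomization tests use add-one empirical p-values, so p lies in
(0, 1]; counting is residue-level (multiple SNPs at one residue count once).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices
from scipy import stats
from statsmodels.stats.diagnostic import lilliefors

from .io import InteractionNetwork, ProteinRecord, SiteAnnotation, ValidationError
from .matching import merge_site_intervals

logger = logging.getLogger(__name__)


def _site_positions(sites: Iterable[SiteAnnotation]) -> dict[str, set[int]]:
    """Per-protein set of 1-based residue positions covered by predicted sites."""
    merged = merge_site_intervals(sites)
    return {
        pid: {pos for start, end in intervals for pos in range(start, end + 1)}
        for pid, intervals in merged.items()
    }


@dataclass(frozen=True)
class DepletionResult:
    frac_in_sites: float
    frac_overall: float
    observed_overlap: int
    p_value: float
    n_trials: int


def snp_depletion_test(
    sites: Sequence[SiteAnnotation],
    records: Mapping[str, ProteinRecord],
    snps: pd.DataFrame,
    n_trials: int = 1000,
    rng: np.random.Generator | None = None,
) -> DepletionResult:
    """Test whether nsSNPs are depleted in predicted binding sites.

    ``snps`` must already be restricted to non-synonymous SNPs (columns
    ``protein_id``, ``position``). Only proteins with predictions enter the
    computation. The null redraws, per protein, the same number of SNP
    positions uniformly without replacement; the p-value is the add-one
    fraction of trials whose site-overlap count is <= the observed count.
    """
    if rng is None:
        rng = np.random.default_rng()
    site_pos = _site_positions(sites)
    if not site_pos:
        raise ValidationError("no predicted-site residues to test")

    snp_pos: dict[str, set[int]] = {}
    for pid, group in snps.groupby("protein_id"):
        pid = str(pid)
        if pid not in site_pos or pid not in records:
            continue
        positions = set(int(p) for p in group["position"])
        length = len(records[pid])
        if len(positions) > length or (positions and max(positions) > length):
            raise ValidationError(f"{pid}: SNP positions exceed sequence length")
        snp_pos[pid] = positions

    n_site_residues = sum(len(s) for s in site_pos.values())
    n_residues = sum(len(records[pid]) for pid in site_pos if pid in records)
    observed = sum(len(site_pos[pid] & snp_pos.get(pid, set())) for pid in site_pos)
    n_snp_residues = sum(len(v) for v in snp_pos.values())

    frac_in_sites = observed / n_site_residues
    frac_overall = n_snp_residues / n_residues if n_residues else 0.0

    le = 0
    per_protein = [
        (len(records[pid]), len(snp_pos[pid]), site_pos[pid])
        for pid in sorted(snp_pos)
        if snp_pos[pid]
    ]
    for _ in range(n_trials):
        overlap = 0
        for length, k, spos in per_protein:
            draw = rng.choice(length, size=k, replace=False)
            overlap += sum(1 for p in draw if (int(p) + 1) in spos)
        if overlap <= observed:
            le += 1
    p = (1 + le) / (1 + n_trials)
    return DepletionResult(
        frac_in_sites=frac_in_sites,
        frac_overall=frac_overall,
        observed_overlap=observed,
        p_value=p,
        n_trials=n_trials,
    )


@dataclass(frozen=True)
class CoevolutionResult:
    observed_count: int
    null_mean: float
    p_value: float
    n_flagged: int
    n_trials: int


def coevolution_test(
    flagged_proteins: Iterable[str],
    net: InteractionNetwork,
    n_trials: int = 1000,
    rng: np.random.Generator | None = None,
) -> CoevolutionResult:
    """Test whether flagged proteins (nsSNP in a predicted site) inter-interact.

    The observed statistic is the number of edges with *both* endpoints
    flagged; the null draws the same number of proteins uniformly from the
    network. Enrichment-sided add-one p-value.
    """
    if rng is None:
        rng = np.random.default_rng()
    flagged = set(flagged_proteins)
    stray = flagged - net.proteins
    if stray:
        raise ValidationError(f"flagged proteins not in network: {sorted(stray)[:5]}")
    if len(flagged) < 2:
        logger.info("fewer than two flagged proteins; co-evolution test degenerate")
        return CoevolutionResult(0, 0.0, 1.0, len(flagged), n_trials)

    observed = net.subgraph_edge_count(flagged)
    proteins = sorted(net.proteins)
    k = len(flagged)
    null_counts = np.empty(n_trials, dtype=int)
    for t in range(n_trials):
        idx = rng.choice(len(proteins), size=k, replace=False)
        null_counts[t] = net.subgraph_edge_count(proteins[i] for i in idx)
    ge = int((null_counts >= observed).sum())
    p = (1 + ge) / (1 + n_trials)
    return CoevolutionResult(
        observed_count=observed,
        null_mean=float(null_counts.mean()),
        p_value=p,
        n_flagged=k,
        n_trials=n_trials,
    )


def flag_proteins_with_snp_in_site(
    sites: Sequence[SiteAnnotation],
    snps: pd.DataFrame,
) -> set[str]:
    """Proteins in which at least one nsSNP position falls inside a predicted site."""
    site_pos = _site_positions(sites)
    flagged = set()
    for pid, group in snps.groupby("protein_id"):
        pid = str(pid)
        if pid in site_pos and any(int(p) in site_pos[pid] for p in group["position"]):
            flagged.add(pid)
    return flagged


def mutagenesis_overlap_report(
    sites: Sequence[SiteAnnotation],
    annotated_regions: Mapping[str, Sequence[tuple[int, int]]],
) -> pd.DataFrame:
    """Which annotated mutagenesis regions coincide with predicted sites.

    ``annotated_regions`` maps protein id to 1-based inclusive intervals (a
    single mutated residue is the interval (pos, pos)). Returns one row per
    annotated protein with the coinciding (region, site) interval pairs.
    """
    merged = merge_site_intervals(sites)
    rows = []
    for pid in sorted(annotated_regions):
        intersections = []
        for a_start, a_end in annotated_regions[pid]:
            if a_start > a_end:
                raise ValidationError(f"{pid}: inverted annotation interval")
            for s_start, s_end in merged.get(pid, []):
                if a_start <= s_end and s_start <= a_end:
                    intersections.append(((a_start, a_end), (s_start, s_end)))
        rows.append(
            {
                "protein_id": pid,
                "coincides": bool(intersections),
                "n_intersections": len(intersections),
                "intersections": intersections,
            }
        )
    return pd.DataFrame(rows, columns=["protein_id", "coincides", "n_intersections", "intersections"])


# ---------------------------------------------------------------------------
# paralog divergence
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ParalogPair:
    id_a: str
    id_b: str
    divergence_class: str  # "no" | "low" | "high"
    whole_identity: float
    site_identity: float | None  # None when no ungapped-mapped motif survives


def make_global_aligner(gap_open: float = 10.0, gap_extend: float = 0.5) -> Align.PairwiseAligner:
    """Needleman-Wunsch aligner with BLOSUM62 and needle-default gap costs.

    End gaps are free, matching the cited global-alignment tool's defaults.
    """
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    aligner.end_gap_score = 0.0
    return aligner


def _aligned_strings(alignment) -> tuple[str, str]:
    text = str(alignment).splitlines()
    # Bio.Align pretty-printer: prefer the coordinate API
    a, b = alignment[0], alignment[1]
    return str(a), str(b)


def alignment_identities(
    seq_a: str,
    seq_b: str,
    intervals_a: Sequence[tuple[int, int]] = (),
    intervals_b: Sequence[tuple[int, int]] = (),
    aligner: Align.PairwiseAligner | None = None,
) -> tuple[float, float | None]:
    """Whole-alignment and binding-site identity of two sequences.

    ``intervals_*`` are 1-based inclusive motif intervals on each ungapped
    sequence. The site identity is computed over alignment columns covered by
    any motif interval of either sequence, after discarding every motif whose
    aligned span contains a gap (in either row). Whole identity counts
    identical columns over the full alignment length (gap columns included in
    the denominator).
    """
    if aligner is None:
        aligner = make_global_aligner()
    alignment = aligner.align(seq_a, seq_b)[0]
    row_a, row_b = _aligned_strings(alignment)
    n_cols = len(row_a)
    identical = np.fromiter(
        (ca == cb and ca != "-" for ca, cb in zip(row_a, row_b)),
        dtype=bool, count=n_cols,
    )
    whole_identity = identical.sum() / n_cols

    # residue index (0-based) -> alignment column, per row
    col_of_a, col_of_b = {}, {}
    ia = ib = 0
    for col, (ca, cb) in enumerate(zip(row_a, row_b)):
        if ca != "-":
            col_of_a[ia] = col
            ia += 1
        if cb != "-":
            col_of_b[ib] = col
            ib += 1

    site_cols: set[int] = set()
    any_motif = False
    for intervals, col_of, this_row, other_row in (
        (intervals_a, col_of_a, row_a, row_b),
        (intervals_b, col_of_b, row_a, row_b),
    ):
        for start, end in intervals:
            any_motif = True
            cols = [col_of[i] for i in range(start - 1, end)]
            span = range(min(cols), max(cols) + 1)
            if any(this_row[c] == "-" or other_row[c] == "-" for c in span):
                logger.debug("motif %d-%d maps across a gap; excluded", start, end)
                continue
            site_cols.update(cols)

    if not any_motif or not site_cols:
        return whole_identity, None
    cols = sorted(site_cols)
    site_identity = identical[cols].sum() / len(cols)
    return whole_identity, float(site_identity)


@dataclass
class DivergenceFits:
    """Per-class normal density fits for whole and site identities."""

    whole: dict[str, tuple[float, float]]
    site: dict[str, tuple[float, float]]
    lilliefors_whole: dict[str, tuple[float, float]]
    lilliefors_site: dict[str, tuple[float, float]]

    def classify(self, identity: float, kind: str = "site") -> str:
        """Maximum-density divergence class at the given identity value."""
        fits = self.site if kind == "site" else self.whole
        if not fits:
            raise ValidationError("no density fits available")
        return max(
            fits,
            key=lambda cls: stats.norm.pdf(identity, *fits[cls]),
        )


DIVERGENCE_CLASSES = ("no", "low", "high")


def paralog_divergence(
    pairs: Sequence[tuple[str, str, str]],
    records: Mapping[str, ProteinRecord],
    sites: Sequence[SiteAnnotation],
    aligner: Align.PairwiseAligner | None = None,
) -> tuple[list[ParalogPair], DivergenceFits]:
    """Whole vs binding-site identity of paralog pairs, by divergence class.

    ``pairs`` rows are (id_a, id_b, divergence_class). Pairs whose motifs all
    map across alignment gaps get an undefined site identity and are excluded
    from the site-identity density fits (logged).
    """
    if aligner is None:
        aligner = make_global_aligner()
    merged = merge_site_intervals(sites)
    out: list[ParalogPair] = []
    for id_a, id_b, cls in pairs:
        if cls not in DIVERGENCE_CLASSES:
            raise ValidationError(f"unknown divergence class {cls!r}")
        if id_a not in records or id_b not in records:
            raise ValidationError(f"missing sequence for pair ({id_a}, {id_b})")
        whole, site = alignment_identities(
            records[id_a].sequence,
            records[id_b].sequence,
            merged.get(id_a, []),
            merged.get(id_b, []),
            aligner=aligner,
        )
        if site is None:
            logger.info("pair (%s, %s): no ungapped-mapped motif; site identity undefined", id_a, id_b)
        out.append(ParalogPair(id_a, id_b, cls, whole, site))

    def fit(values: list[float]) -> tuple[float, float]:
        mu = float(np.mean(values))
        sigma = float(np.std(values, ddof=1)) if len(values) > 1 else 0.0
        return mu, max(sigma, 1e-12)

    whole_fits, site_fits, lf_whole, lf_site = {}, {}, {}, {}
    for cls in DIVERGENCE_CLASSES:
        wvals = [p.whole_identity for p in out if p.divergence_class == cls]
        svals = [p.site_identity for p in out if p.divergence_class == cls and p.site_identity is not None]
        if len(wvals) >= 2:
            whole_fits[cls] = fit(wvals)
            if len(set(wvals)) >= 4:
                lf_whole[cls] = tuple(map(float, lilliefors(np.array(wvals), dist="norm")))
        if len(svals) >= 2:
            site_fits[cls] = fit(svals)
            if len(set(svals)) >= 4:
                lf_site[cls] = tuple(map(float, lilliefors(np.array(svals), dist="norm")))
    return out, DivergenceFits(whole_fits, site_fits, lf_whole, lf_site)
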
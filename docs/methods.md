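# Methods

This note records the precise definitions, parameter semantics, generator
behavior, and numerical conventions implemented by `ppimotifs`. It makes no
empirical claims beyond what the test suite and `scripts/acceptance.py`
compute.

## Data model

- **Protein record**: an identifier, an amino-acid sequence over the 20
  standard residues (non-standard characters are tolerated in sequences but
  never match a motif position), and two integer per-residue tracks on a
  0–9 scale: conservation (high = conserved) and relative solvent
  accessibility (0 = buried, 9 = exposed).
- **Interaction network**: an undirected simple graph over protein ids.
  Edges are stored canonically (lexicographically sorted endpoint tuples);
  self-interactions are representable.
- **Positions** are 1-based inclusive everywhere in the API and in TSV
  output; BED output uses the conventional 0-based half-open intervals.

## Motifs and the match criterion

A motif is a length-`l` pattern (default `l = 8`) over the amino-acid
alphabet plus the wildcard `*`, with at most `d` wildcards (default
`d = 5`) and at least one specified position.

A motif is **present** in a protein when at least one sequence window of
length `l` satisfies all of:

1. **Similarity.** The *degree of similarity* is the mean, over the motif's
   specified positions, of `sim(m_i, w_i)`, where `sim` is the row-rescaled
   BLOSUM62 table: for row `a`,
   `sim(a, b) = (raw(a, b) − min_b' raw(a, b')) / (raw(a, a) − min_b' raw(a, b'))`.
   The diagonal is exactly 1 and each row's minimum exactly 0; the table is
   not symmetric. Because every BLOSUM62 diagonal is the strict row maximum,
   a similarity threshold of 1.0 is exactly the perfect-match rule. The
   window passes when the degree of similarity is ≥ the threshold
   (default 0.6). Threshold `none` means the relaxation is disabled: a
   perfect match at every specified position is required.
2. **Conservation.** The mean conservation over all `l` window residues
   (wildcard positions included — the track criteria are properties of the
   matched sequence region) is ≥ the threshold (default 6), when one is set.
   `none` disables the criterion.
3. **Accessibility.** Same rule for the RSA track (default threshold 7).

All comparisons are ≥ with a small epsilon guard against floating-point
representation of thresholds.

## Conservation scoring from alignments

Given a multiple alignment of the target with homologs, each column covering
an ungapped target residue receives the negated Shannon entropy of its
residue frequencies (natural log; gaps excluded from the frequency
denominator). Columns in which more than half the sequences are gapped carry
little evidence and are floored to the alignment's least-conserved raw
score. Raw scores are min–max rescaled over the target-covering columns and
binned to integers with half-up rounding (`floor(9x + 0.5)`). Degenerate
alignments with no score variation collapse to 9 when the shared entropy is
zero (perfect conservation) and to 5 otherwise (logged).

RSA tracks are expected precomputed on the 0–9 scale; a helper rescales
fractional [0, 1] accessibilities with the same half-up rounding.

## Mining

The **support** of a motif pair (a, b) is the number of network edges
{p, q} with a present in p and b in q, or vice versa. An optional corrected
objective subtracts the expected support under independent placement of the
two hit sets.

The search is steepest-ascent local search over window-anchored motif
states:

- **Seeding.** A restart draws a seed window uniformly from the windows
  that themselves pass the active conservation/accessibility filters
  (an occurrence in a failing window can never match, so such seeds are
  dead; with no active filter all clean windows are eligible). The partner
  seed is drawn from windows of the seed protein's interaction partners
  when possible.
- **Moves.** Shift either motif's window by ±1, toggle a wildcard on or off
  (respecting the budget and the ≥ 1 specified position rule), or re-seed
  either member from windows of proteins interacting with the other
  member's matched proteins. The best strictly improving candidate is taken
  (ties broken by fewer wildcards, then lexicographic patterns); the search
  stops at a local optimum.
- **Termination.** Restarts accumulate distinct locally optimal pairs until
  the wall-clock budget elapses, an optional restart cap is hit, or no new
  pair has appeared for a stagnation window. The top `N` pairs by
  (support, fewer wildcards, pattern) are returned; each pair's reported
  support is an independent re-evaluation.

Matching is vectorized: per protein, integer-encoded sliding windows and
window track means are precomputed, and per-pattern results are cached
across the search.

## Evaluation

- **Interface residues** (when complex structures are available) are those
  whose solvent-accessible surface area is strictly smaller in the complex
  than in the unbound protein. Sequence-to-structure homology hits are
  screened by: bit score > 70, alignment covering ≥ 30% of both query and
  target, identity > 40%.
- **Accuracy** is the fraction of mapped motif occurrences touching at
  least one interface residue of their protein (pair-specific labels are
  used when available). The counting unit is the (pattern, protein,
  partner) occurrence by default; a "motif" unit counts each
  (pattern, protein) once.
- **Coverage** is the fraction of interacting pairs carrying at least one
  interface-overlapping occurrence.
- **F-score** is the harmonic mean `2AC/(A + C)`, 0 when either is 0.
- **Significance** compares the observed F-score with F-scores of sets of
  randomly generated motif pairs (uniform window draw, exactly `d` wildcard
  positions without replacement). Empirical p-values are add-one:
  `(1 + #{null ≥ observed}) / (1 + n)` — ties count against the observed
  value and p is never 0.
- The **grid sweep** explores similarity ∈ {none, 0.4, 0.5, 0.6, 0.7} ×
  conservation ∈ {none, 3..7} × RSA ∈ {none, 3..7} — 180 settings, each
  mined with its own derived seed.

## Variation analyses

- **SNP depletion**: residue-level overlap between non-synonymous SNP
  positions and predicted-site residues, compared with a null that redraws
  each protein's SNP count uniformly without replacement over its sequence;
  depletion-sided add-one p-value (trials with overlap ≤ observed).
- **Co-evolution**: the number of edges whose two endpoints both carry an
  nsSNP inside a predicted site, against random protein sets of the same
  size; enrichment-sided add-one p-value. Fewer than two flagged proteins
  yields p = 1.
- **Mutagenesis overlap**: interval intersection (1-based inclusive)
  between annotated mutated regions and merged predicted sites.
- **Paralog divergence**: Needleman–Wunsch global alignment with BLOSUM62,
  gap open 10, gap extend 0.5, free end gaps. Whole identity = identical
  columns / alignment length (gap columns in the denominator). Site
  identity is computed over alignment columns covered by either protein's
  merged motif intervals, after discarding any motif whose aligned span
  contains a gap; it is undefined (None) when no motif survives. Per
  divergence class ("no", "low", "high"), normal densities are fitted to
  both identity samples (Lilliefors statistics reported where the sample
  allows), and a query identity is classified by maximum density.

## Synthetic benchmark

`generate_benchmark(SyntheticSpec(...))` draws a uniform random simple
graph (default 50 proteins, 150 edges), i.i.d. background sequences
(uniform residue frequencies by default; BLOSUM62 marginals optional) of
length 80–120, and background tracks uniform on 0–6. It then plants motif
pairs; by default one **genuine** pair and two **decoys**, each carried by
30% of the edges:

- For each selected edge, a copy of pattern a is written into one endpoint
  and a copy of pattern b into the other, at a collision-free position
  (edges whose endpoint has no free slot left are skipped, not errors).
  Copies are mutated at 10% per position, never at adjacent positions.
- **Genuine** occurrences get conservation and RSA drawn from 8–9 and are
  recorded as interface labels (per protein: the union of its planted
  interface intervals — the planted surface is reused across partners, so
  pair-restricted labels would penalize genuine reuse).
- **Decoy** occurrences get the same elevated conservation but keep
  background accessibility and receive no labels: conserved-but-buried
  recurrences that only the accessibility criterion can reject.

Ground truth records the planted intervals, the planted-on edges, and the
**realized** edge set of each genuine pair — every edge whose endpoints
carry complementary copies. Because proteins host copies for several edges,
the planted pair genuinely explains this superset, which is the correct
referent for recovery measurements. An optional SNP table draws per-residue
nsSNPs at a configurable rate with an in-site rate multiplier (1 = null,
< 1 = depletion, 0 = none in sites).

## Numerical conventions and limitations

- Rounding to the 0–9 scales is half-up (`floor(x + 0.5)`), never banker's
  rounding.
- All stochastic components take explicit seeds or `numpy.random.Generator`
  instances; identical seeds reproduce identical results.
- The local search is a heuristic: it carries no optimality guarantee on
  large instances, and the returned pool depends on the restart budget.
- Empirical p-values are bounded below by `1/(n_trials + 1)`; discreteness
  of the underlying count statistics makes them mildly conservative in
  small fixtures.
- The entropy score ignores residue similarity (a column of I/L/V scores as
  diverse as one of G/W/P) and treats sequences as independent (no
  phylogenetic weighting).
- The conserved/exposed thresholds operate on coarse integer tracks; real
  predictors' calibration of those tracks is outside the package's scope.
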
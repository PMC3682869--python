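# Methods

This note documents the statistical model, the defaults and why they are
set as they are, the synthetic benchmark, and the numerical and design
choices made where the method leaves room.

## Model and assumptions

The analysis treats each gene independently and asks, word by word,
whether over-representation of the word in individual sequences is
correlated with the gene's position in a ranked list (most
down-regulated first).

**Per-sequence background.** Each sequence gets its own order-*k* Markov
model estimated from overlapping windows on the given strand only
(mRNA motif search is strand-specific, so no reverse-complement
pooling). The word probability factorizes as
P_k(W) = μ(w₁…w_k)·Π π(next | context), with μ estimated from the
sequence's k-windows and π from its (k+1)-windows. Because every gene is
its own background, composition bias — GC content in UTRs, codon usage
in CDS — cancels gene by gene rather than being modeled globally.
Windows containing N contribute to neither word counts nor background
counts, and N-containing windows never match a word; sequences with N
are kept rather than discarded, since dropping whole genes would distort
the ranked list.

**Binomial score.** Occurrences are counted with overlap, consistent
with the independence assumption of the binomial model: with
n = lₛ − l_W + 1 match positions, p-value = binomial upper tail
P(q ≥ m | n, P_k(W)). A gene shorter than the word contributes p = 1
(no information) instead of being excluded, so the gene count u is the
same for every word length — a requirement for comparing Z-scores across
lengths. Log-scores ls = −ln(p + α) cap the influence of vanishingly
small p-values at −ln α.

**Bridge statistic.** The running sum of mean-centered log-scores over
the ranked list starts and ends at 0; under the null (scores
exchangeable with respect to rank) it approximates a Brownian bridge.
D = max|r| is referred to the two-sided Brownian-bridge max
(Kolmogorov-type) distribution via the alternating series, replacing
explicit score permutation. The statistic is two-sided; the direction
("down"/"up") is reported from the sign of r at the maximum. The ES
index is the gene rank attaining the maximum (smallest such rank on
ties). Z normalizes D/σ by the closed-form moments
E[Y] = √(πt/2)·ln2, Var[Y] = tπ²/12 − E[Y]², with t = u, the number of
genes in the analysis. σ is the population (1/u) standard deviation of
the word's log-scores; because σ rescales with D, Z is invariant to
rescaling all log-scores, and the normalized and unnormalized renderings
of the Z formula coincide algebraically.

## Parameters

| parameter | default | meaning / rationale |
|---|---|---|
| word lengths | 6, 7, 8 | covers 6mer, 7mer-A1/7mer-m8 and 8mer seed-match site types |
| background order k | 1 (UTR), 2 recommended for CDS | di-nucleotide background for UTRs; tri-nucleotide absorbs codon-usage bias in coding sequence |
| pseudocount c | 1 | added to (k+1)-mer window counts (denominator +4c, and +c·4^k for μ) so every word probability is strictly positive even on short sequences; the estimator is otherwise a plain window-frequency estimate |
| α | 10⁻⁵ | log-score regularizer; bounds a single gene's score at −ln α ≈ 11.5 nats |
| sort | ascending rank value | most down-regulated first; `--descending` for IP-style data where large values mean "bound" |
| top words clustered | 100 | display-level grouping of the word-cluster plot |
| UPGMA cut distance | 0.5 | flat motif labels for coloring; a visualization aid, not an inferential threshold |
| series guard | x = D/(σ√t) < 0.05 → p = 1 | the alternating series converges too slowly below this point and such words are never significant |

Ties in rank values are broken by lexicographic gene id; gene ids are
matched exactly (no transcript-version stripping); inputs must be
pre-collapsed to one sequence per gene.

## Synthetic benchmark

The generator emulates exactly the structure the statistic assumes: per
gene a GC fraction is drawn from [0.3, 0.6] (heterogeneity the
per-sequence background must absorb), a sequence of 400–1200 nt is drawn
i.i.d. with that composition, and rank values are an equally spaced grid
on [−3, 3] plus N(0, 0.25 sd) noise, which produces realistic near-ties
at the list center. The planted word (default ACCAAAG, the miR-9
7mer-m8 seed match) overwrites a uniformly chosen window with
probability 0.8 in the 100 most down-regulated of 500 genes;
overwriting rather than inserting keeps sequence lengths, and hence the
binomial trial counts, unchanged. Everything is a pure function of the
seed.

What the generator does **not** emulate: phylogenetic conservation,
3′UTR compositional structure (AU-rich elements, poly-A signals),
multiple cooperating motifs, site-position effects, and dose-dependent
repression. Passing the planted-recovery and null-specificity tests
therefore demonstrates the statistical machinery (counting, background
correction, bridge calibration, ranking) on data matching the model's
assumptions — not performance on real transcriptome measurements.

## Numerical choices

- Binomial tails are computed via the regularized incomplete beta
  (scipy), exact to ~1e-15 relative against direct summation and stable
  for n up to 1e5 and p down to 1e-8.
- The bridge survival series is truncated when terms drop below 1e-12
  (cap |h| ≤ 1000); the vectorized engine uses a fixed 120 terms, which
  bounds the truncated tail below 1e-12 for all x ≥ 0.05.
- A word whose log-score column is exactly constant (typically: the word
  occurs in no gene) is flagged degenerate and reported with D = 0,
  p = 1, Z = 0. Constancy is detected exactly (max = min) rather than
  via σ ≈ 0, because the computed standard deviation of a constant
  vector can be rounding noise (~1e-20) which would otherwise produce
  huge spurious Z.
- The exhaustive engine evaluates binomial tails only where m > 0
  (m = 0 gives p = 1 identically), scoring all 86,016 default words over
  500 genes in seconds; it is verified elementwise against the per-word
  reference path (scalar counting → binomial → running sum).
- Work is partitioned over contiguous gene chunks when `workers > 1`;
  the reduction preserves chunk order, so output is bit-identical for
  any worker count.
- UPGMA input words are canonicalised (sorted lexicographically) before
  linkage, making tree and labels independent of caller order; flat
  cluster ids are renumbered contiguously from 1 by first appearance in
  lexicographic order. Under exact ties in average distances several
  UPGMA trees are equally valid; the canonical ordering makes the choice
  deterministic.
- The ungapped local alignment maximizes matches − mismatches over every
  diagonal by maximum-subarray with an empty-segment floor of 0, so
  fully dissimilar words score 0 and similarity is always in [0, 1]
  after shortest-length normalization.

## Known limitations

- **Finite-list accuracy of the analytic null.** The running sum is a
  bridge on a discrete grid of t steps; its maximum undershoots the
  continuous bridge max by O(1/√t). At t = 200 the analytic survival
  function evaluated at the empirical permutation median is ≈ 0.55
  rather than 0.50; at t = 1000 the deviation falls to ≈ 0.02. Analytic
  p-values at moderate list sizes are therefore conservative in the
  bulk; extreme tails (the regime that decides rankings) are less
  affected, and Z-based ranking is unaffected by any monotone
  miscalibration. For small gene lists, score-permutation p-values
  remain the exact alternative.
- The binomial model ignores overlap dependence of self-overlapping
  words (e.g. AAAAAA), which makes their per-sequence p-values
  approximate.
- FDR is computed by Benjamini–Hochberg over all words pooled across
  lengths; words are strongly inter-correlated (nested and shifted
  variants), so FDR values are interpretable as a ranking guide rather
  than exact error rates.
- One sequence per gene is required; isoform collapse is upstream of
  this package.
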
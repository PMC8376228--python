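# Methods

## Model

`ddiminer` treats DDI inference as link prediction in a tripartite graph.
For one PPI source, let *Z* be the set of distinct PPIs, each an ordered
protein pair (*L*, *R*) with *L* ≤ *R* in raw lexicographic byte order (so
`"Q10" < "Q9"`; identifier order is a convention, fixed once so results are
reproducible). *D<sub>L</sub>* and *D<sub>R</sub>* are the domains annotated
on left and right proteins — overlapping but distinct sets that are never
merged at the graph layer. The binary incidence matrices *M<sub>X</sub>*
(|*D<sub>L</sub>*| × |*Z*|) and *M<sub>Y</sub>* record which PPIs each
domain touches.

A candidate DDI is any (*x* ∈ *D<sub>L</sub>*, *y* ∈ *D<sub>R</sub>*) with
at least one common PPI column. Its cosine score
*K<sub>x,y</sub>*/√(*N<sub>x</sub>N<sub>y</sub>*) rewards a large common
neighborhood relative to each domain's total connectivity; the
hypergeometric tail P(*K* ≥ *K<sub>x,y</sub>* | *N<sub>x</sub>*,
*N<sub>y</sub>*, *N<sub>z</sub>*) quantifies how surprising the overlap is
under random placement. Because candidate pairs are tested in bulk, a
Bonferroni correction over the *merged* candidate union across sources (one
global family, the same for every source) converts p-values into
significance flags at level α = 0.05 (strict `<`).

Assumptions worth stating: incidence is binary (a protein either carries a
domain or not — no copy numbers); a PPI with only one annotated protein
stays in *Z* so *N<sub>z</sub>* reflects the source's true PPI count; and
a candidate's two orientations (a domain can appear on both sides) are
collapsed to one canonical unordered pair by keeping the orientation with
the larger cosine (ties: larger common-neighbor count, then the orientation
whose left-role domain has the smaller identifier).

## Multi-source consensus

Per-source cosine matrices are fused by a non-zero weighted average: sources
that do not score a pair contribute to neither numerator nor denominator, so
a pair seen in a single source keeps its cosine untouched regardless of
weights. Weights live on the grid {0.01, …, 1.00}. Exhaustive grid search is
only offered for up to three sources (100<sup>D</sup> combinations);
otherwise a seeded coordinate ascent with random restarts sweeps one source
at a time until no sweep improves the AUC. The AUC is computed with the
midrank (Mann–Whitney) convention; positives are the gold-standard DDIs that
received a score, the background is every other scored pair. Ties between
equally good weight vectors break toward the lexicographically smallest
tuple, which makes the optimizer deterministic and pins the single-source
case at weight 0.01.

## Threshold calibration

Negative examples are made by degree-preserving double-edge swaps of the
gold-standard edge set: each domain keeps its endpoint multiplicity (a
homo-DDI counts 2), no produced edge may equal an original positive, no new
self-edges are created (a conservative null; self-edges can only disappear
by recombination), and originals that cannot be rewired within the proposal
budget are dropped with a logged count. Positives and negatives that carry a
nonzero consensus score form the learning set.

The learning set is split 2:1 into Training and Test with stratification;
5-fold stratified cross-validation on Training picks, per fold, the
threshold maximizing F1 on the other four folds over the three-phase grid
(0–1 by 0.01, 0–0.04 by 0.001, 0.01–0.02 by 0.0001, as a sorted union —
a union contains every point any sequential zooming scheme could visit).
Equal-F1 ties break toward the smallest threshold (recall-preserving). The
mean of the five fold optima, *T<sub>m</sub>*, is evaluated on the whole
Training set and the untouched Test set, then filters the consensus matrix
with a strict `>` comparison. Learning sets with fewer than five scored
positives or negatives per training split cannot be folded; the pipeline
then falls back, loudly, to a single F1-optimal grid threshold on the whole
learning set so that toy examples remain runnable.

## Categories

With *D* configured sources, a filtered DDI scored in *m* sources is *Gold*
if *m* ≥ ⌈*D*/2⌉ and every scored source is significant, *Silver* if
*m* < ⌈*D*/2⌉ and every scored source is significant, *Bronze* otherwise.
The breadth cutoff is exposed as a parameter (`min_sources`) because "half
of the sources" is a convention, not a law. Note that at small corpus sizes
(hundreds of PPIs per source) hypergeometric tails are much flatter than at
interactome scale, so weakly supported pairs often fail the Bonferroni bar
and the Bronze class dominates; this is a scale effect, not a property of
the data sources.

## Synthetic worlds

The generator emulates the full input suite: `PF0001…`-style domains;
proteins carrying 1 + Poisson(`domains_per_protein_mean`) distinct domains
(capped at the universe size); `n_true_ddis` hidden true DDIs drawn
uniformly over canonical pairs with a configurable homo-DDI share; a
configurable fraction of the truth exposed as the gold standard; and per
source, `signal_fraction` of the PPIs drawn by sampling a true DDI and one
carrier protein per side, the rest uniform random protein pairs, all
canonicalized and deduplicated. Defaults — 50 domains, 200 proteins, mean
parameter 2, 30 true DDIs, half gold, 10% homo-DDIs, 3 sources × 500 PPIs at
80% signal — define the package's standard benchmark conditions: large
enough for calibration to operate, small enough to run in seconds.

What the simulator does **not** model: real Pfam frequency distributions
(heavy-tailed), inter-database overlap structure, study bias, or
promiscuous hub domains. Passing the planted-truth benchmark therefore shows
the pipeline's machinery is sound, not that its precision on real
interactomes matches the benchmark's.

### The bystander effect and calibration limits

Because synthetic proteins carry several domains, every signal PPI for a
true DDI (*dA*, *dB*) also links *dA*'s co-carried domains to *dB*'s —
"bystander" pairs that genuinely share the true pair's neighborhood. Their
consensus scores form a tail that reaches into the planted pairs' score
range. The shuffle-based negatives, by contrast, are *typical* random pairs,
so the learning set is often perfectly separable and the F1 criterion cannot
distinguish thresholds inside the gap between the highest sampled negative
and the lowest gold positive. The recall-preserving tie-break then places
*T<sub>m</sub>* at the bottom of that gap, which keeps every planted DDI
(held-out recall ≈ 1) but admits the bystander tail, so held-out precision
on the default benchmark is low (≈ 0.1–0.4 across seeds). No choice of
equal-F1 tie-break fixes this — the learning set simply carries no
information about the bystander null — and the effect shrinks as corpora
grow and annotation density thins. Users who need a purer output set should
rank by consensus score or restrict to the Gold category rather than rely on
the F1 threshold alone.

## Numerical choices

- Hypergeometric tails use `scipy.stats.hypergeom.sf(k-1, N, n_x, n_y)`
  (log-space stable at interactome scale), clamped to [0, 1].
- Cosines are computed from integer counts (`k/sqrt(n_x*n_y)`), exact to
  rounding, and cross-checked in tests against the raw-vector definition.
- AUC uses `scipy.stats.rankdata` midranks; brute-force pairwise comparison
  is the test oracle.
- All stochastic steps (shuffle, splits, folds, optimizer restarts, world
  generation) take explicit integer seeds; identical seeds give
  byte-identical outputs.
- Degenerate inputs raise typed errors (`CalibrationError`,
  `EvaluationError`, …) rather than returning NaNs; the pipeline reports the
  failing stage.

## Known limitations

- Coverage counts only inter-protein domain pairs (left × right cross
  product): a homo-DDI covers a PPI only if its domain occurs on both sides.
  Within-protein pairs cannot mediate a binary PPI.
- Degree semantics in network statistics: a node's degree is its number of
  distinct partners, a self-loop adding 1, so a self-only domain is a
  degree-1, 1-node component; the 99th-percentile degree is read at rank
  ⌈0.99 *n*⌉ of the ascending degree sort.
- Exhaustive weight search beyond three sources is refused by design;
  coordinate ascent is a heuristic and is only guaranteed optimal where the
  tests verify it (small fixtures, two sources).
- The package does not parse PSI-MI TAB or map database-specific protein
  identifiers; inputs are plain two-column TSVs of already-harmonized
  identifiers.
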
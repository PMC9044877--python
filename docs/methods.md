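# Methods

This note documents the models, conventions and design choices behind
`entdef-forge`, in the order the pipeline uses them.

## Coordinates and interval algebra

All coordinates are 0-based, half-open, everywhere — BED files, BEDPE
anchors, the gene-registry TSV, and all in-memory types.  Interval
operations have *coverage* semantics: touching intervals (end == start)
merge, and duplicate records are preserved by readers and collapsed only by
`merge_intervals`.  Subtraction acts per input record against the merged
subtrahend, so labeled records keep their identity while splitting.

The nearest-TSS partition places the boundary between adjacent TSSs
t_left < t_right at `(t_left + t_right + 1) // 2`: bases strictly closer to
the left TSS go left and an exactly equidistant base goes to the right
gene.  This is an arbitrary but fixed convention; determinism is the point.
Interval correctness is established against per-base boolean-array oracles
(≥ 1000 randomized cases on ≤ 10 kb toys) rather than against another
interval library, so the oracle shares no code with the implementation.

## Definition assembly

The TSS, not the gene body, anchors everything: promoter windows are
[tss − w, tss + w) with w = 5000 by default; loop gene membership means
"TSS inside the loop span"; the fallback partition is by TSS distance.
For minus-strand genes the registry supplies the TSS explicitly — it is
never recomputed from the body, because strand arithmetic is the classic
off-by-one source.

Assembly order: union + merge the selected sources' regions → trim promoter
windows → optionally extend short regions to the 1 kb floor around their
midpoint and re-trim → derive links from each selected evidence → union
links (deduplicated per enhancer/gene/method) → optionally append
nearest-TSS fallback records over the remaining distal bases.  Decisions
worth calling out:

- **Extension is a floor.** Regions already ≥ 1 kb pass through unchanged;
  extension can invade a promoter window, so trimming is re-applied
  afterwards and the distal invariant (no locus base within a promoter
  window) always holds.  Links are computed post-extension.
- **Merged multi-source enhancers inherit source labels** from every raw
  region overlapping them by ≥ 1 bp; ≥ 1 bp is the overlap convention for
  every pairing decision in the package.
- **Enhancers with no link are dropped** (a record must map a locus to a
  gene); with the fallback enabled their bases re-enter as nearest-TSS
  territory flagged `fallback=1`.
- Loop links require 1 ≤ |genes in span| ≤ L; a loop with more genes
  contributes nothing rather than being truncated.

The configuration enumerator is pure combinatorics: non-empty source
subsets × [non-empty non-loop link subsets × (no loop + one loop variant)
+ loop-only variants] × extension toggle × fallback toggle, i.e.
(2^s − 1) × [(2^k − 1)(1 + v) + v] × 2 × 2; the cell-type-restricted mode
allows only {interaction}, {L_x} and {interaction, L_x}, giving
(2^s − 1) × (1 + 2v) × 4.

## Peak assignment

A peak is represented by its midpoint, `floor((start + end) / 2)`, and
increments the count of every gene owning a record containing that
midpoint; this matches the locus-definition convention of the enrichment
framework this package builds on.  A ≥ 1 bp overlap rule is available
(`overlap_rule="any"`).  Per-gene locus length is the merged (unique-base)
length of that gene's records.  Optional per-peak weights replace unit
counts; they are passed through linearly, which is the minimal reading of a
weighted-count model, and are documented as such.

## Enrichment model

Counts per gene are modeled as NB2: Var = μ + μ²/θ, with
log μ = β₀ + β₁·membership + f(log₁₀ locus length).  The default f is a
natural cubic regression spline with df = 5 (knots at quantiles, linear
beyond the boundary knots); `linear_log_length` and `none` are available.
Degenerate designs (constant lengths) drop the uninformative columns
automatically.

θ is estimated **once per peak set on the null model** (intercept +
length), by alternating GLM fits with profile maximum likelihood over
log α (α = 1/θ, bounded in e⁻¹²…e⁶), and is reused across terms.  This is
what makes the score test cheap: one null fit, then each term costs a few
matrix products.  If the profile likelihood prefers α = 0 the model falls
back to Poisson with a warning (θ = ∞).

The score test residualizes the membership vector against the null design
in the working-weight metric (W = μ/(1 + αμ)) and uses
z = x̃'(y − μ)/(1 + αμ) / sqrt(x̃'Wx̃); it is vectorized over all terms at
once.  The LRT refits the alternative GLM per term with α held fixed and
compares χ²(1).  Both report two-sided p-values with the direction
(enriched/depleted) carried separately, so a depleted term can never be
classified enriched.  Calibration is verified on null simulations
(θ = 5, length-dependent means): both tests hold size at α = 0.05 within
[0.03, 0.07] over 2000 replicates and their p-values are rank-correlated
above 0.99, with the score test the faster of the two.

Fisher's exact test (has_peak × membership, two-sided) and a binomial test
(k = peaks hitting member-gene loci, n = assigned peaks, p₀ = member locus
bp / total locus bp, one-sided upper, depletion flagged when k/n < p₀) are
the baselines.  In the binomial test a peak counts at most once per term
even when it hits several member genes.

## Evaluation against TF annotations

Positives for a TF: under the standard scheme, the lowest-level assigned
terms plus all their DAG ancestors; under the conservative scheme,
IEA-only assignments are removed first and positives stop at parents and
grandparents.  Both are size-filtered to [15, 2000] genes after
intersection with the profile's gene universe (the same filter is applied
to the negative pool — implied by symmetry, and documented here as a
choice).

Negatives are sampled one per positive, without replacement within a
repetition and fresh per repetition (default 10), from terms that are not
positives and not offspring or siblings of the assigned terms (the
conservative scheme additionally excludes ancestors of positives, siblings
of those ancestors, and offspring of positives).  Sampling is size-matched
in fixed half-open bins of 20 genes, [0,20), [20,40), …, falling back to
the nearest non-empty bin; the RNG is keyed by (seed, TF id, repetition) so
every draw is reproducible in isolation.

Confusion counts: TP = significantly enriched (FDR < 0.05 **and**
direction enriched) positives; FN = the rest of the positives (including
significant-but-depleted ones); FP/TN analogously over the sampled
negatives.  F1 is defined 0 when precision + recall = 0.  Aggregation runs
repetitions → peak sets → TFs → definition, averaging at each level, so a
TF with many datasets does not dominate; this ordering is a documented
choice, switchable by operating on the returned row table directly.

The signed-rank test used for ranking walks and baseline contrasts uses the
exact permutation distribution (dynamic programming over doubled mid-ranks)
for up to 25 non-zero pairs, Pratt's treatment of zero differences, and the
normal approximation with tie/zero corrections above that.  It is checked
against full 2^n enumeration for n ≤ 12 and against scipy's exact path
where that path applies.

ROC uses trapezoidal area; PR uses step interpolation (average precision) —
linear interpolation in PR space overstates area and is avoided.  The
regulome-vs-expression concordance score takes the top ≤ 100 significant
expression terms (q < 0.05) as positives, repeatedly samples size-matched
insignificant terms (p > 0.5) as negatives, scores terms by the regulome
FDR, and averages AUROC over samplings.

## Pair benchmarking

Benchmark pairs are preprocessed exactly like definitions: promoter-window
trimming (pairs whose enhancer vanishes are dropped) and within-dataset
merging, with gene links carried onto the merged enhancers.  A pair is
predicted positive when some definition locus overlaps its enhancer by
≥ 1 bp and is linked to its gene; we require the link on an overlapping
locus record, not merely anywhere on a merged enhancer.  The overlap
coefficient counts matches of the smaller set in the larger (numerator and
denominator commensurate).  Fixed-ratio subsampling (1:4) touches only
negatives, so sensitivity is invariant to it while precision is not.

## Interceding-gene analysis

For each non-fallback link the query span runs from the outermost
coordinates of the enhancer and the target's gene body; interceding genes
are other genes whose bodies overlap the span by ≥ 1 bp (a gene overlapping
the enhancer itself therefore counts — the enhancer lies inside the span by
construction).  Fallback records are excluded: nearest-TSS territory
carries no looping information.  Per-gene means are transformed by the
rank-based inverse normal transform with the Blom offset 3/8 and mid-ranks
for ties; a named reference implementation of this transform uses the same
default.  Term enrichment is a per-term logistic regression of membership
on the INT score (Wald, two-sided); the exponential/log transform
round-trip described for the reference workflow cancels and is implemented
as regression directly on the scores.  The reported coefficient is the
negated slope, so positive values mark functions enriched among genes with
*fewer* interceding genes; this sign convention is stated in the output.
Perfect separation triggers a Firth-penalized refit, flagged per term.
Results from several definitions combine by the plain unweighted
harmonic-mean p-value, BH-adjusted; significant terms are ranked by
combined p within each direction and a term is filtered when any parent,
child or sibling ranks higher — on a strictly ranked significant chain
exactly one term survives.

## Synthetic data

The generator (`entdef_forge.simulate`) emulates the statistical structure
the evaluation relies on: TFs bind enhancers linked to genes of the
processes they are annotated to.  Defaults: one 10 Mb chromosome, 300 genes
(TSSs near-uniform, ≥ 12 kb apart — scaled to match the human genome's
~1 gene per 30 kb while keeping promoter anchors unambiguous), 120 terms in
a 4-level DAG whose internal terms contain their children's genes, 3
enhancer sources of ~400 regions (200–2000 bp) sampled with jitter from a
shared master pool, each enhancer linked to 1–2 nearby genes (≤ 300 kb,
distance-weighted; 15 % dual-target rate), 3 TFs annotated to 3–8 terms of
10–60 genes, 2000 peaks per TF, and an enhancer-signal fraction of 0.6: a
signal peak picks one of the TF's annotated-term genes uniformly, then one
of that gene's enhancers, so per-target binding rates are comparable.
Evidence (two pair tables, interaction anchors, loops) is derived from the
planted links with true links dropped at rate 0.10 and false links added at
rate 0.05.

What the generator does **not** model: multi-chromosome structure by
default, TAD/CTCF geometry, sequence content, signal-strength variation
between peaks, or correlated noise between evidence types.  Passing tests
therefore demonstrate that the pipeline recovers planted enhancer-gene
structure under idealized noise, not that any particular real-data ranking
is correct.

On these defaults the definition assembled from the generating evidence
outranks a link-shuffled decoy (gene labels permuted across records — same
loci, same per-gene link counts, destroyed correspondence) in ≥ 95 % of 20
seeded runs, and enrichment on the truth definition recovers the planted
annotation terms with mean F1 above 0.6.

## Problem sizes and numerics

Test and script problem sizes (300-gene toys, 2000 peaks, 200 × 10 null
replicates for calibration, 20 seeds for recovery) were chosen so the whole
suite runs in about a minute on one CPU while keeping every statistical
check at a sample size where its tolerance band is meaningful.  p-values
are clipped to [tiny, 1]; empty-remnant intervals are dropped; all RNGs are
`numpy.random.default_rng` seeded explicitly, with string labels hashed by
CRC32 into the seed sequence so per-component streams are independent.

## Known limitations

- The NB dispersion is estimated on the null model, so strong true
  enrichment inflates θ̂ and makes both NB tests conservative; this is the
  price of the one-null-fit design and is shared by the framework this
  package models.
- Loop-variant linking is deliberately promiscuous (every enhancer in the
  span links to every gene in the span); on dense toy genomes this dilutes
  per-gene counts, which is visible in the rankings.
- The weighted-count path treats weights linearly and reuses the NB
  likelihood unchanged; for heavily weighted data a quasi-likelihood would
  be more defensible.
- `run_full_evaluation` caches per-stage artifacts by overwriting; it does
  not hash inputs, so a changed input with an unchanged path must be run
  into a fresh output directory.
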
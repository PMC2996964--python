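# Methods

This note documents the models, conventions and design choices behind
`tissuespec`, and what the synthetic-data tests do and do not demonstrate
about real data.

## Expression measure

All quantification uses count-proportion TPM: reads assigned to an entity
divided by the library's total reads, × 10⁶. This is the tag-counting
normalisation of EST/454 digital expression, *not* the modern
length-normalised RNA-seq TPM; with short 3'-biased contigs each read is
treated as one transcript tag. Counts are integers throughout; when a TPM
table printed to limited precision is ingested, integer counts are
recovered by nearest-integer rounding (half away from zero) of
`tpm × library_size / 10⁶` and exact TPM is recomputed from those counts.
This count round trip matters: τ printed alongside a one-decimal TPM
table can differ in the third decimal if computed from the rounded values
rather than from the underlying counts.

## The τ index and its conventions

τ = Σ(1 − x_i/x_max)/(N − 1) with x_i = log2(TPM_i). Conventions, pinned
by the bundled MHC worked example:

- **Floor.** Tissues with TPM exactly 0 are set to 2 TPM before the log.
  Small positive TPM enters unfloored. The floor keeps the log defined
  and damps specificity attributed to absences at shallow depth.
- **Log base.** Base 2. Together with the floor of 2 this reproduces all
  six reference τ values to three decimals.
- **Read filter.** Profiles with ≤ 3 total reads get no τ and no tissue
  of maximal expression ("fewer than four reads" and "3 or fewer reads"
  are the same rule). The maximal tissue is the argmax of read counts,
  ties broken by library order and flagged.
- **Range.** The result is clipped into [0, 1]: an unfloored positive TPM
  below 1 (possible only at library sizes far beyond the floor's design
  regime) would otherwise push the sum above 1.
- **Comparability.** τ depends on N and on overall scale (below); results
  carry N, and τ from different library panels should not be mixed.

### Scale dependence of τ

τ is *not* invariant to multiplying all TPM by a common factor: the
numerator Σ(x_max − x_i) is a difference of logs and thus scale-free, but
the denominator (N−1)·x_max grows with depth, so deeper profiles with
identical tissue proportions get slightly lower τ. This intrinsic
property matters for interpreting the bias simulation (below) and is
asserted, rather than an invariance, in the tests.

## Annotation mapping

Tabular 12-column alignments are filtered at e-value ≤ 1e-10 (inclusive,
the community norm for a stated "cutoff"). Per contig the best hit is the
minimum e-value, ties broken by maximum aligned length, then by
lexicographic subject id for determinism. Contamination is input-driven:
contigs whose *best* hit subject is in a user-supplied foreign-taxon set
are removed and reported. Gene coverage is
`100 × Σ(contig lengths)/gene length`, capped at 100 when overlapping
contigs exceed the gene length. Splice-variant screening flags a
query/reference pair when consecutive aligned segments leave a reference
gap of strictly more than 15 bases; overlapping segments are reported,
never silently merged. Coordinates are 1-based inclusive internally, with
a BED (0-based half-open) export for gaps.

## Bias simulation

Shallow totals inflate τ: a multinomial split of few reads is sparse even
for a broadly expressed contig. The null quantifies this. For the
observed contigs passing the read filter, each simulated dataset keeps
the observed multiset of total-read levels and redraws every contig's
tissue split as Multinomial(level, p), with p the tissue-proportion
vector of a template contig drawn uniformly with replacement from all
observed contigs. Per dataset, Pearson r between log10(total) and τ is
computed with the standard floor/filter conventions; the default produces
one dataset per distinct observed level (the study-design analogue), and
`n_datasets` can reduce this for Monte-Carlo work. The alternative mode
(`points-per-level`) redraws each replicate's totals i.i.d. from the
empirical level distribution instead of cloning the exact multiset.

The observed correlation is compared to the simulated ones with a
one-sample t-test, t = (mean(sim) − observed)/(sd/√n), df = n − 1. Two
caveats, both verified by simulation in the test suite:

- **Calibration.** The classical ('mean') form treats the observed r as a
  constant, but the observed r carries the same dataset-level sampling
  variance as each simulated r, so under a true null the test
  over-rejects severely. `compare_observed_vs_null(style="prediction")`
  inflates the standard error to sd·√(1 + 1/n), asking whether the
  observed r is a plausible draw from the null; that version is
  approximately calibrated and is the right choice when the question is
  "does anything beyond sampling bias exist". The 'mean' form remains the
  default because it is the field's reported statistic.
- **Deep coverage.** Multinomial noise vanishes at depth (the simulated τ
  of a template converges to the τ of its exact proportions), but the
  mean simulated correlation does *not* go to zero whenever levels span a
  nontrivial range, because of τ's intrinsic scale dependence: at totals
  of 10⁴–10⁵ the scale term alone contributes a mean simulated r of about
  −0.1. The test suite verifies the correct decomposition — at depth the
  simulated mean matches the scale-only prediction to within 0.02 —
  rather than the naive "≈ 0" expectation.

## Enrichment and statistics

GO terms are flat labels (no ancestor propagation). Overrepresentation of
a term in a gene set is one-sided hypergeometric:
P[X ≥ k], X ~ Hypergeom(universe, term-annotated, set size), validated
against exhaustive subset enumeration for small universes. The universe
defaults to the *detected* genes (those with a τ estimate); p-values are
Benjamini–Hochberg adjusted across terms (Bonferroni available), with
significance at adjusted p < 0.05. The τ-extreme sets are the top and
bottom k = 500 genes by τ (reduced to half the detected genes when fewer
are available), boundary ties broken by gene id.

Correlations use Pearson or Spearman (average ranks on ties) with df =
n − 2; expression levels and ω are heavily skewed, so the analyses
involving them default to Spearman. Group comparisons across tissues of
maximal expression use tie-corrected Kruskal–Wallis (ω) and one-way ANOVA
(τ). The per-tissue summary reports gene counts, exclusively-expressed
counts, and means of ω and τ with 95% nonparametric bootstrap percentile
CIs (10,000 resamples by default; a t-interval is available by flag; NA
below 3 genes) — percentile bootstrap because ω is far from normal.

## Synthetic data generator

The generator emulates the study design the analysis assumes: six tissue
cDNA libraries of ~0.25–0.4 M reads (the default library sizes), heavily
skewed per-gene depth, tissue profiles from housekeeping-like to
single-tissue, fragmented contigs, rare contaminants.

- **Profiles.** Per gene a symmetric Dirichlet draw; by default a
  two-component mixture (α = 0.35 specific with probability 0.6, α = 5
  broad with probability 0.4) giving the broad, mildly bimodal τ range
  seen in real tissue panels. Proportions below `profile_zero_threshold`
  (default 0.02) are set to exactly 0 and the profile renormalised:
  tissues holding under ~2% of a gene's expression are treated as off.
  Exact zeros are what the floor convention presumes; without them the
  "true" τ of a profile would hinge on logs of arbitrarily small
  expected TPM and parameter recovery would be ill-posed.
- **Abundance.** Log-normal with σ = 1.6, reproducing a long-tailed depth
  distribution (median contig depth of a few reads, maxima in the
  thousands at the default library sizes).
- **Counts.** One multinomial draw per library with probabilities ∝
  abundance × proportion; column sums equal library sizes exactly.
- **Truth.** Expected TPM is the noise-free normalised weight matrix;
  true τ is computed by the *same* routine as estimated τ, so generator
  and specificity module cannot drift apart.
- **ω.** `exp(−2.2 + coupling·(τ−0.5) + N(0, 0.5²)) − 0.02`, clipped at
  0: median ω ≈ 0.1–0.2, right-skewed, with log(ω+1) positively
  correlated with true τ at the default coupling of 1 — the
  specificity-vs-constraint relationship is recoverable by construction.
- **Contigs.** max(1, Poisson(2)) contigs per expressed gene, reads
  apportioned multinomially over random weights (per-gene per-tissue
  totals conserved), lengths from random transcript breakpoints.
  Contaminants (0.05% by default) look ordinary in the count table —
  single-tissue bursts of reads — and are identifiable only through
  their alignment subjects, as in real data.
- **Alignments.** Every real contig hits its true gene at e-value 1e-50;
  ~20% of contigs also get decoy hits, all strictly above the 1e-10
  cutoff, so best-hit mapping is 100% accurate by construction and the
  mapping tests are exact. Contaminants hit foreign-taxon subjects.
- **Seeding.** The seed is a config field; every stage derives its own
  `numpy.random.Generator` from (seed, stage), never global state, so
  runs are byte-reproducible.
- A separate helper, `simulate_coupled_contigs`, plants a depth–
  specificity coupling through a Gaussian copula between log total reads
  and a Beta-distributed specificity score; it drives the bias-simulation
  power and calibration tests.

**What the generator does not model:** actual sequence (bases, flowgram
noise, assembly errors), cDNA normalisation chemistry (which compresses
real dynamic range and biases τ downward), library-protocol differences
such as an EST library sequenced differently, correlated expression
across tissues, or the exact empirical bimodality of real τ
distributions. Passing tests therefore demonstrate correctness of the
estimators and the internal consistency of the pipeline under its
stated sampling model — not that real 454 data meet that model.

## Problem sizes and numerical choices

Test and acceptance runs use 300–5,000 genes/contigs, 25–50 simulated
null datasets and 300–10,000 bootstrap resamples; these sizes give
Monte-Carlo error comfortably below the asserted tolerances while keeping
the suite quick. Parameter recovery is checked at library size 10⁶ and
2,000 genes (MAE(τ̂, τ) < 0.02). Degenerate inputs are defined rather
than accidental: all-equal profiles give τ = 0; a library in which no
gene carries mass falls back to uniform allocation; zero-variance
correlations and sub-minimum groups raise errors; simulated-r draws that
are numerically constant yield t = 0, p = 1 against an equal observed
value.
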
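# Methods

## Scope and model

`neoprior` implements a protein-level neoantigen prioritization
pipeline for somatic missense substitutions. It deliberately starts
*after* variant calling: a variant is a gene symbol plus a 1-based
protein substitution (`Mapkbp1_W204C`) carrying its RNA evidence (VAF,
read depth, parent-gene TPM). Genomic coordinates, indels and
frameshifts are out of scope (the package's canonical use case — a
vaccine short-list of missense targets — involves substitutions only),
and one protein per gene is assumed (no isoform handling).

## Expression filter

Retain a variant iff VAF ≥ `min_vaf` (default 0.10), depth ≥
`min_depth` (20 reads) and TPM ≥ `min_tpm` (1.0). All comparisons are
inclusive, read directly off the "≥" operating points. The three rules
are evaluated independently (no short-circuit) so the report lists
every failed rule per variant; the kept set is provably the
intersection of the three single-rule filters, which the tests exploit
as a brute-force oracle. A gene missing from the expression table fails
the TPM rule — absence of expression evidence is treated as absence of
expression — with a logged warning.

## Peptide design

The long synthesis form is `long_peptide_len` = 17 aa (must be odd),
centered on the mutation with 8 residues of flank per side. At a
terminus the short side is truncated and the long side is *not*
re-extended: this keeps the peptide's natural flanking context rather
than maximizing length, a choice made where the design was open. The
wild-type partner covers the identical interval, so the pair differs at
exactly the mutation offset.

Short MHC-I candidates are every k-mer of the *mutant* protein covering
the mutated position, for each k in the allele's preferred lengths.
H-2Kb defaults to lengths (8, 9) — the allele canonically presents
8–9-mers and the validated tetramer epitope is an 8-mer — configurable
within [8, 11]. The window count per length has the closed form
`min(pos, L−k+1) − max(1, pos−k+1) + 1`, checked against brute-force
substring scans in the tests. Peptides containing non-standard residues
(X, U, ...) are dropped with a warning: they can be neither synthesized
nor scored.

## Binding consensus

Percentile ranks (percent, [0, 100], lower = stronger) are the
interchange currency; affinities in nM never enter. Per peptide the
consensus is the ordinary median across predictors (even count → mean
of the two central values); per mutation the minimum over its windows
(the field's best-epitope convention — the aggregation was an open
choice). The pass cutoff `max_median_rank` = 2% is inclusive.

Partial predictor coverage: a peptide scored by at least
`min_predictors` (default 4, capped at the matrix's predictor count)
still receives a median, flagged low-coverage; fewer leaves it
unscored. A mutation with no scored peptide is excluded from the pass
set with a warning rather than silently failed.

Prioritization sorts passing mutations by ascending best median rank,
breaking ties by descending TPM, then descending VAF, then mutation id
(a deterministic total order), and returns the first
`top_n` = 20.

### Mock predictor ensemble

Eight mock predictors (named after the published algorithms with a
`mock-` prefix, to exercise the 8-column median exactly) are
position-specific scoring matrices: per predictor and length, an
independent standard-normal (k × 20) weight matrix. Raw scores are
calibrated to percentile ranks against a background of B (default
10,000) k-mers sampled uniformly from the proteome:
`rank = 100 · #{background ≥ score} / B`, ties counting against the
candidate (the conservative choice). Ranks of random peptides are then
approximately uniform on (0, 100] and independent across predictors.

One numerical constraint matters: the number of *distinct* proteome
windows should well exceed B. When the proteome is small relative to
B, background draws overlap heavily, the empirical background CDF
carries correlated sampling error, and rank uniformity degrades
detectably at large test sample sizes. The default synthetic proteome
(800 proteins, 120–600 aa) gives ≈ 280k distinct 8-mers against
B = 10,000.

### Planting binders

The synthetic generator pins chosen epitopes to chosen ranks through
per-sequence score offsets: the offset places the epitope's raw score
on the background quantile of the target rank (target 0 → above the
whole background). Because an offset applies to one exact sequence,
background calibration and all other peptides' ranks are untouched,
and the planted rank is hit exactly (up to the 100/B rank grid) with no
iteration. This is the generator's mechanism for constructing ground
truth, not a claim about real predictors.

## ELISPOT selection and cross-reactivity

Selection is per-peptide: mean mutant-arm spot count across replicates
**strictly greater** than `min_spots` = 100 ("more than" read as a
strict inequality; the boundary mean of exactly 100 is excluded).
Counts are used raw — no background subtraction — with negative-control
counts reported alongside; whether the threshold should apply to
subtracted counts was left open, and raw is the choice documented here.

Cross-reactivity is a compound rule operationalizing "no significant
immunogenic cross-reactivity": a peptide is cross-reactive when the
wild-type arm itself clears `min_spots`, **or** when the Welch t-test
(two-sided, α = 0.05) cannot distinguish wild-type from mutant arms
*and* the wild-type mean exceeds the negative-control mean + 3·SD. Both
guards are configurable. Fewer than two replicates in either arm →
"not assessed" rather than a verdict.

## Single-cell read-outs

**Signature score.** The binned-control module score: genes ranked by
mean expression over all cells and cut into `n_bins` = 25 equal-size
bins; each signature gene draws `n_ctrl` = 100 control genes (with
replacement) from its bin, excluding the signature genes themselves
from the pools; score(cell) = mean(signature) − mean(controls). The
score is exactly zero on a constant matrix and invariant to a shift
applied to all genes; seeded control draws make it deterministic.
No method was named for the published "enrichment score", so this
standard construction is the package's choice; scanpy's `score_genes`
(the same construction, independently implemented) serves as a
cross-check in the tests.

**Mutant-cell proportion.** Denominator per group: tumor cells (an
input label — tumor identity is upstream of this package) with ≥ 1
read covering *any* queried mutation site (per-cell pooling over
sites, following the inclusion rule "at least one of these sites").
Numerator: those with ≥ `min_alt_reads` = 1 mutant-supporting reads at
any site. Groups with empty denominators are reported as undefined
rather than 0.

**Group comparisons.** Proportions: two-sided Fisher's exact test on
the 2×2 table vs the reference group (chi-square available); a table
with a zero margin yields p = 1 with a flag. Scores: two-sided Wilcoxon
rank-sum (Welch t available). The published analysis does not name its
tests; these are the package's defaults, exposed in config.

## Synthetic study generator

Generation is a pure function of `SimConfig`; identical configs yield
byte-identical bundles, and an infeasible config fails before any file
is written. The default config mirrors the published screening funnel
as a convenience fixture — 762 variants, 224 expressed, 60 predicted
binders (20 strong + 40 moderate), top 20, 16 synthesized, 7
immunogenic — which is a statement about the fixture's shape, not a
re-derivation of those counts from raw data.

* **Variants.** One gene per variant; proteins i.i.d. uniform over the
  20 residues (no codon model — sufficient for peptide-level work).
  Filter fate is planted per variant; VAF ~ Beta(2, 3), depth ~
  NB(mean 60, dispersion 5), TPM ~ LogNormal(µ = 1, σ = 1.5) are then
  sampled *conditioned on the planted fate* (rejection sampling on the
  4-decimal values written to disk), so the filter recovers the planted
  224 exactly at any seed.
* **Binders.** Strong binders are planted at rank 0, moderate binders
  at a target drawn from (0.3, 1.8] — inside the 2% cutoff but clearly
  separated from the strong set, so the top-20 list is determined by
  construction. Every *other* candidate window of an expressed variant
  whose natural rank falls below 5% on some predictor is lifted to rank
  50 on that predictor ("suppression plants"). This floor keeps the
  planted binder set exactly what the pipeline recovers: without it, a
  random window clears the 2% median cutoff with probability ~1e-5,
  enough to corrupt the truth sets in a few percent of runs at this
  scale. All plants (positive and suppression) are written to
  `plants.json`, which the pipeline's mock-rank stage replays.
* **ELISPOT.** Negative-binomial replicate counts (dispersion 50,
  variance/mean ≈ 7 at the immunogenic mean — over-dispersed as real
  spot counts are), immunogenic mean 300 vs non-immunogenic 20,
  straddling the 100-spot cutoff by > 7 replicate-mean SDs, so the
  planted 7-of-16 selection is recovered at any seed. Wild-type arms
  at mean 10 and controls at mean 5 make the selected peptides
  non-cross-reactive.
* **Single cell.** Four groups (PBS, vaccine, checkpoint, combined),
  900 cells/group, 90% tumor-labelled; per-site coverage Bernoulli(0.3)
  over the detectable sites (3 queried + the remaining immunogenic
  sites as decoys). Mutant detection among covered cells is an exact
  Bernoulli draw at the planted per-group fraction (PBS 0.30, vaccine
  0.15, checkpoint 0.20, combined 0.05) — the generator plants the
  *detection outcome*, not a read-level allele model — so the estimator
  is exactly binomial around truth. With these defaults each group has
  ~500 covered tumor cells. The expression matrix carries gene
  baselines Uniform(0, 3) log-units, cell noise N(0, 0.4), and the
  per-group signature shift (0 / −0.3 / −0.3 / −1.0 log-units) on the
  7 parent genes.

What the generator does **not** emulate: read-level artifacts
(alignment error, strand bias), codon structure and realistic amino-acid
composition, transcript isoforms, allele-specific expression, doublets
and ambient RNA, dropout structure beyond Bernoulli site coverage, and
correlated predictor errors (real MHC predictors err in correlated
ways; the mock ensemble's errors are independent). Tests passing on
this generator therefore validate the pipeline's logic and statistics,
not the biological fidelity of any upstream caller or predictor.

## Problem sizes and numerical notes

The test suite exercises the default funnel (762 variants, B = 10,000
backgrounds) once and otherwise uses a scaled study (80 variants, 30
expressed, 13 binders, B = 2,000) — chosen so the full suite completes
in well under a minute while keeping every planted set non-trivial.
Power and type-I checks use 200 Fisher replicates at n = 500/group and
1,000 label permutations respectively. Monte-Carlo tolerances: planted
signature shift recovered within ±0.15 log-units; permutation type-I
rate accepted in [0.025, 0.075] (±3 binomial SDs around 0.05 at 1,000
replicates).

Seeds: every stochastic component takes an explicit seed;
sub-component seeds are derived, not reused, so stages stay
independent. Median of an even predictor count is the mean of the two
central values; best-peptide ties break lexicographically; prioritize's
full sort key makes output order deterministic.

## Known limitations

* VAF is taken as given; whether it is DNA- or RNA-derived is the
  caller's concern.
* The mock ensemble is a calibration stand-in with independent errors;
  it cannot reproduce predictor-specific biases, and planted ranks are
  a generator construct.
* Cross-reactivity at n = 3 replicates has little power; the Welch
  clause of the compound rule is honest about that but cannot fix it.
* The Fisher/Wilcoxon defaults are choices, not re-derivations of the
  published (unnamed) tests, and exact published p-values are not
  reproduction targets.
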
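# Methods

`credive` implements a comparative analysis of cis-regulatory element (CRE)
divergence between closely related nematode species. A CRE here is the full
upstream intergenic region of a gene, fused to a reporter; heterologous CREs
(orthologous regions from other species) are assayed in the reference
species' trans-regulatory environment, and any difference between the
pattern a heterologous CRE drives and the pattern the reference-species CRE
drives — whether missing ("loss") or extra ("gain"/ectopic) expression —
reveals functional divergence of the element itself. "Gain" and "loss" are
labels relative to the reference CRE's pattern, not claims about endogenous
expression in the donor species.

## Sequence conservation (`credive.seqcons`)

**Alignment.** Orthologous upstream sequences are aligned end-to-end with a
Gotoh global affine-gap dynamic program. DNA defaults: match +1, mismatch
−1, gap open −4, gap extend −1 (the first column of a gap run pays the open
score, each further column the extend score). The parameters are exposed in
`ScoringScheme`; the defaults were chosen for determinism and
oracle-testability, not to reproduce any particular aligner's output.
Traceback ties are broken by preferring a match/mismatch column over a
gap-in-reference column over a gap-in-query column, which makes block
boundaries reproducible. The kernel is JIT-compiled with numba when
available and falls back to the identical pure-Python code otherwise.

**Windowed identity profile.** For each reference position, the fraction of
identical alignment columns in a window of `window_len` reference positions
(default 20) centred on it. Gap-in-query columns count as non-identical;
ambiguity codes (N/X) never count as identical; gap-in-reference columns
carry no reference coordinate and do not enter any window. Near the edges
the window slides inward so it always covers exactly
`min(window_len, ref_len)` positions rather than shrinking. This choice
(over shrinking the edge windows) keeps a useful invariant: with the window
as long as the reference, the profile equals the overall alignment identity
at every position. Conserved segments are maximal runs of positions at or
above `identity_threshold` (default 0.70).

**Perfect blocks and metrics.** Perfect-conservation blocks are maximal
gapless runs of identical columns, reported in 0-based half-open reference
coordinates; an indel terminates a block. Per ortholog pair the package
reports the longest perfect block, the total nucleotides in perfect blocks
of at least `min_block_short` (default 7) nt, and the fraction of the
reference CRE covered by conserved blocks of at least `min_block_long`
(default 20) nt. For the covered fraction, perfect blocks and windowed
segments are merged (interval union) before measuring coverage, since
"conserved block" is meaningful under either definition and double-counting
overlaps would inflate the fraction.

**Protein conservation.** Orthologous proteins are scored as the global
BLOSUM62 alignment score (gap open −11, extend −1) divided by the reference
self-score, yielding 1.0 for identical sequences and smaller values as
substitutions accumulate. The matrix name is configurable.

## Expression scoring (`credive.expression`)

Raw data are one row per (gene, CRE species, host species, strain,
individual, cell) with a presence/absence flag for binary cells, or an
integer count for counted classes (cell classes such as the ventral nerve
cord scored as "number of expressing cells"). A cell ontology declares each
unit's counting mode and named groups of binary cells aggregated as
"expressed in at least one member".

Summaries per transgene: binary-cell frequency = expressing individuals /
individuals scored for that cell; group frequency counts an individual once
if any member expresses; counted classes are summarized by the median count
over individuals. All statistics are also computed per strain. Two
conventions follow the survey's scoring practice:

* individuals with no expression anywhere are assumed to have lost the
  (extrachromosomal) transgene and are dropped before summarization;
* an individual without a row for a cell is excluded from that cell's
  denominator rather than counted as non-expressing. Whether obscured cells
  should instead count in the denominator is not derivable from the data
  model; the convention is recorded here and flagged in output metadata.

`ScoringPolicy` carries the design minima — at least 50 individuals from at
least 2 independent strains per transgene — and the classification
thresholds below. Transgenes failing the minima are reported and excluded.

## Gain/loss classification (`credive.divergence`)

The reference pattern of a gene is the set of cells/groups whose frequency
under the reference-species CRE reaches `reference_inclusion_freq`
(default 0.5), plus counted classes with positive median. Explicit
include/exclude overrides — declarative config entries, never code — mirror
the judgment calls a curator makes for borderline cells; applied overrides
are recorded on the entry.

For each scored cell of a heterologous transgene:

* in-pattern, frequency-type: strict loss if observed frequency ≤
  `strict_loss_max_freq` (0.10); reduction if below
  `liberal_reduction_ratio` (0.5) × reference frequency; else conserved;
* in-pattern, counted: strict loss at median 0; reduction below half the
  reference median;
* out-of-pattern: gain if observed frequency ≥ `gain_min_freq` (0.10), or,
  for counted classes, any positive median.

The thresholds have no published values; they are config-exposed defaults
chosen so that clearly planted events are unambiguous, and reproducing any
specific published tally would require calibrating them against the
original scoring tables.

**Consistency rule.** A non-conserved call must be supported by
`consistency_min_strains` (default 2) independent strains: a strain
supports a gain if its strain-level frequency is positive, and a
loss/reduction if its strain-level value satisfies the same threshold rule
as the overall call. Unsupported calls are demoted to conserved and
flagged. This is the conservative guard against strain-private
transgene-array artifacts.

**Tallies, sweep, recurrence.** Tallies count gains, strict losses and
liberal losses (strict + reductions) per transgene, per CRE species and
overall, with optional restriction to a gene/species subset (e.g. genes
tested from all heterologous species). The threshold sweep ranks called
gains by observed frequency and called losses by the frequency of
endogenous cells *not* expressing (1 − observed), and reports, for every
threshold below 100%, how many events of each kind lie above it; the
dominance flag is evaluated exactly at every breakpoint. Counted classes
never enter the sweep (medians are not frequencies) but do enter tallies.
Recurrent gains list the cells receiving gain calls from two or more
distinct (gene, species) CREs.

## Correlations (`credive.correlate`)

Per heterologous CRE: functional divergence = number of non-conserved
calls; complexity = number of cell types in the gene's reference pattern;
conservation = fraction of the reference CRE in conserved blocks ≥ 20 nt;
length difference = |reference CRE length − query CRE length|. Association
is measured by Spearman rank correlation (midranks for ties) with a
two-sided permutation p-value (default 10 000 seeded permutations, add-one
estimator). Spearman was chosen because the analysis asserts the *absence*
of correlation without assuming linearity; Pearson is available through
scipy for comparison. Constant series are reported as undefined rather
than zero.

## Synthetic data (`credive.synthetic`)

**Sequence families.** One ancestor (uniform ACGT) evolves independently
along each species branch: per-site substitution with branch-specific
probability, uniform over the three alternative bases; indels start at a
per-site rate, insertion/deletion equiprobable, geometric length of mean 3
nt. Planted blocks substitute at their own (lower) rate and indels never
land inside them — blocks model constrained elements, and this keeps the
planted-truth guarantee exact (a zero-divergence block is literally
identical across species). Under this model the expected pairwise identity
outside blocks between branches with substitution probabilities p₁, p₂ is
(1−p₁)(1−p₂) + p₁p₂/3, which the tests use as a closed-form oracle.

**Expression datasets.** Per transgene, per strain, per individual: one
Bernoulli draw per binary cell at the transgene's cell probability (the
reference pattern modified by planted gain/loss/reduction events) and one
binomial draw over member cells per counted class. With `strain_noise` > 0,
one randomly chosen silent cell per heterologous transgene expresses at
that rate in exactly one strain — a strain-private artifact for auditing
the consistency rule; artifacts are recorded in the ground truth.

**The default cohort** (`study_cohort`) mirrors the survey design: 8 genes
× (reference + 4 heterologous species), 2 strains × 25 individuals per
transgene (satisfying the 50/2 minima exactly), reference cells expressing
at 0.9, planted gains at 0.8, reductions at 0.25, losses at 0, with 44
gains, 12 strict losses and 4 reductions spread over the 32 heterologous
transgenes — the shape of a survey in which gains outnumber strict losses
roughly 3.7:1 (liberal losses 16). Sequence families are 400 nt with two
planted conserved blocks (50 and 30 nt) in a background of 0.2 per-branch
substitution and 0.02 indel rate. All randomness derives deterministically
from a single seed; identical seeds give byte-identical fixture bundles.

What the generator does *not* emulate: realistic substitution processes
(no transition/transversion bias, no rate heterogeneity), expression
intensity (weak/strong), correlated scoring errors between cells, host
trans-environment differences beyond a host-species column, and
phylogenetic structure beyond independent branches. Passing planted-truth
tests therefore demonstrates correctness of the scoring and classification
machinery under the stated statistical model, not robustness to every
failure mode of real reporter assays.

## Experiment sizes and numerical choices

The packaged experiments (test suite and `scripts/acceptance.py`) use: the
full default cohort for event recovery and artifact audits; 100 random
pairs of length ≤ 8 against the alignment enumeration oracle; 1 000 random
gapped alignments against the brute-force perfect-block scan; 200
replicates of a 300-nt family with a planted 50-nt zero-divergence block in
a 0.4-per-branch background for profile recovery; and 100 four-gene
cohorts planted at a 3:1 gain:loss ratio for ratio recovery. These sizes
give comfortable statistical resolution for every check while keeping a
full run to a couple of minutes on one core.

Degenerate inputs: empty sequences and invalid alphabets are rejected at
record construction; a window longer than the reference collapses to one
full-length window; zero-denominator cells are marked unscored and excluded
from classification; constant series make rank correlation undefined
(reported as such); tie-breaks in the aligner are fixed by the stated
column-priority rule.

## Known limitations

* Alignment is pairwise and global; long insertions in either species
  produce gap-heavy alignments rather than local anchoring, so profiles of
  wildly length-mismatched CREs are conservative about conservation.
* Classification thresholds are heuristics over frequencies; with
  reference frequencies near the inclusion boundary, pattern membership
  (and hence gain-vs-loss orientation) can flip between datasets.
* The strain-support rule treats strains symmetrically and ignores
  per-strain sample-size imbalance.
* Counted classes are compared only through medians; distributional shifts
  that preserve the median are invisible.
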
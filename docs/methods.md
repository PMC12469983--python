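# Methods notes

This note records the models, defaults and numerical choices behind
`tcrdyn`, and what the synthetic cohorts do and do not establish about
real data.

## Input model and chain filtering

A contig table carries one row per assembled V(D)J contig; cells may have
zero, one or several candidate chains per locus. The pipeline keeps, per
barcode, the single highest-UMI productive chain of each locus and
requires both a TRA and a TRB, yielding exactly one αβ pair per cell —
the unit every downstream statistic assumes. UMI ties are broken by
lexicographically smallest CDR3 nucleotide sequence (then V/J/C calls) so
filtering is a pure function of the record *set*, not its order. Allele
suffixes (`*01`) are stripped because all analyses are at gene level.
Every removal (non-productive, foreign locus, bad CDR3 alphabet, missing
locus, missing metadata) is counted in a filter log, so discrepancies
between "cells sequenced" and "cells analyzed" are auditable.

## Clonotype definition

Four key modes are supported. `strict` (gene segments of both chains plus
both nucleotide CDR3s) is the default: two cells agreeing on all of these
are clonally related with near certainty, whereas gene-level keys merge
distinct clones and aa-level keys merge convergent recombination.
`gene` mode is retained because repertoire tools commonly quantify at
that level; every output records the mode used. Refining the mode can
only split clones, never merge them (tested property).

Clone-size bins are Single (1), Small (2–5), Medium (6–20), Large
(21–100) and Hyperexpanded (>100) cells; the only externally anchored
edge is the >100 hyperexpansion threshold, the others are the
conventional vocabulary and are configurable. The unique-clone fraction
defaults to singleton clonotypes / total clonotypes; a cell-denominator
variant is available because "percentage of unique clones" is ambiguous
in common usage.

## Diversity

All six indices are computed by direct summation from the clone-size
vector; natural logarithms throughout. Normalized entropy is defined 0
for a single-clone sample (0/0 case). Chao1 uses the bias-corrected form
S + f₁(f₁−1)/(2(f₂+1)), which is defined when f₂ = 0; the classic form is
a flag. ACE uses the standard rare-clone cutoff of 10; when the rare-clone
coverage C_ACE is 0 (all rare clones singletons) ACE is undefined and the
estimate falls back to Chao1.

Richness-type estimators grow mechanically with sample size, so
cross-sample comparison uses bootstrap resampling of cells with
replacement at a common depth (default: the smallest sample's N,
B = 100), reporting mean and sd per index next to the point estimates.
Resampling *with* replacement at full depth still perturbs the
composition, so bootstrap means are biased low relative to point
estimates — by design, identically for all samples at equal depth.
Condition contrasts use the classical paired t-test on per-patient
differences (df = n − 1); zero-variance difference vectors are flagged
rather than given a p-value.

"Morisita" is implemented as Morisita–Horn on proportions: the classic
Morisita index requires integer counts and can exceed 1, which
contradicts the [0, 1] interpretation the overlap heatmap relies on. The
value is clamped to [0, 1] against floating-point rounding.

## CDR3 sequence features

Positional profiles left-align sequences; the denominator at position p
is the total weight of sequences of length ≥ p, so every covered position
is a proper distribution (the alternative — a global denominator with
NA-padding — makes trailing positions sum to < 1). Weights default to
clone cell counts (repertoire-level composition); unique-clonotype
weighting is a flag. Positional entropy is normalized by ln 20 to [0, 1].
Biochemical profiles use the published five-factor amino-acid table
(Atchley et al. 2005, PNAS 102:6395), shipped as package data. K-mer
spectra slide a window of k (default 3) over nucleotide or amino-acid
CDR3s, weight by clone size and normalize to percentages within sample.

## Pairing enrichment

The scientific claim under test is *combinatorial*: marginal V-gene usage
can be stable while the joint TRAV–TRBV distribution reorganizes.
Counts are assembled into dense gene × gene × stratum arrays (strata:
condition or patient; unit: cells, or clonotypes where each clone counts
once — both implemented since "presence" may reasonably mean either; the
unit is recorded in every output).

Two Cochran–Mantel–Haenszel arrangements are emitted: the default tests
pairing-category × condition stratified by patient — the direct form of
"does the pairing distribution differ between conditions, controlling
for patient" — and a TRAV × TRBV × condition arrangement for comparison.
The 2×2×K statistic follows the textbook form with optional continuity
correction; the generalized I×J×K statistic is Q = G′V⁻¹G over the
stratum-summed observed−expected vectors with multiple-hypergeometric
covariance, df = (I−1)(J−1), using a pseudo-inverse with df = rank(V)
when V is singular (logged). Degenerate strata are skipped and logged.
The implementation is cross-checked in the test suite against an
independent reference implementation of the stratified
general-association test on a frozen 3×3×2 fixture, and against the
2×2×K closed form on random arrays.

Per-pair 2×2 tables (pair / not-pair × pre / post) get two-sided Fisher
exact tests. Odds ratios use the Haldane–Anscombe 0.5 correction when any
cell is zero — simpler and fully specified, unlike the conditional MLE;
a pair observed in neither condition is reported OR = 1, p = 1. With the
(pair, not-pair) × (pre, post) orientation OR < 1 means enriched post.
Adjustment is Benjamini–Hochberg step-up (Bonferroni available),
monotone and order-preserving.

## Clonal networks

Nodes are deduplicated CDR3 amino-acid sequences of the chosen chain
(TRA default) within a patient, pooled across conditions so "shared"
status is well defined; per-cell multiplicity is kept as node weight.
Similarity is 1 − d/max(len) with d the Levenshtein distance (max-length
normalization bounds it in [0, 1]); the edge threshold default is 0.85.
The O(n²) scan applies exact lower-bound prefilters — length difference,
and half the L1 distance between residue-composition vectors — which
cannot exclude a true edge (tested equivalence against the full scan).
Components are clusters; cluster ids are assigned by smallest member so
the graph is independent of input order.

## The synthetic cohort

The generator emulates the paired five-patient study design rather than
any particular dataset:

- **Usage.** Cohort-level V/J usage is Dirichlet-distributed
  (concentration 1 per gene over pools of 20 TRAV / 20 TRBV / 15 TRAJ /
  13 TRBJ genes); patient-level vectors are Dirichlet around the cohort
  mean with concentration mean/0.01.
- **Clone sizes.** Each pre-intervention clone is expanded with
  probability 0.08 (size uniform on [6, 100]) and otherwise drawn from a
  truncated geometric on [1, 5] (p = 0.5); sizes are trimmed so each
  sample hits its cell target exactly, and no clone exceeds 100 cells.
  Per-sample targets default to a uniform draw in [1500, 3500].
- **Dynamics.** Every pre clone persists with probability 0.6; persisting
  expanded clones contract to max(1, round(0.3 × size)); the remainder of
  the post sample is filled with novel singletons. (Persistence applies
  to all clones, not only expanded ones — otherwise the fully null
  configuration, contraction 1 and persistence 1, would not reproduce the
  pre-intervention size multiset exactly, which it must.)
- **Pairing.** Joint TRAV×TRBV probabilities are p_i·q_j tilted
  multiplicatively by exp(β) for configured (pair, condition) effects;
  the default injects |β| = ln 8 on four pairs, two per direction.
- **CDR3s.** Lengths are triangular on [8, 20] with mode 14; sequences
  are anchored 'C'…'F' with uniform interior residues (so positional
  entropy is 0 at the termini and ≈ 1 inside — a joint generator/profiler
  test); nucleotide junctions are uniform synonymous back-translations.
  UMIs are 1 + Poisson(3) per chain.
- **Subsets.** Expanded clones are labelled CD8 with probability 0.8;
  body clones CD4/CD8/Treg at 58/37/5%, matching the rough compartment
  proportions of peripheral blood T cells.

Draws follow a documented fixed order from one seeded generator, so a
config + seed pair is byte-reproducible.

What the synthetic cohort does **not** model: thymic selection and HLA
restriction (real CDR3s are far from uniform), convergent recombination,
biological relatedness between clones (so similarity networks on
synthetic data are nearly edge-free), sequencing error, and transcriptome
noise in subset labels. Passing recovery tests therefore demonstrates the
estimators' correctness and power under known truth — not that real
repertoires satisfy the generator's assumptions.

## Evaluation configurations and problem sizes

The recovery experiments fix nuisance parameters on statistical grounds:
pairing-shift recovery uses turnover without expansion (expansion
fraction 0, persistence 0) so pairing shifts are not confounded by
clone-size structure, clonotype-unit counting (clones are the independent
units), and near-uniform usage (concentration 50) because ranking odds
ratios across pairs is ill-posed when some pairs have expected counts
near zero; samples are 2000 cells per condition. Contraction recovery
and overlap experiments run the full default cohort. Bootstrap and
seed-replication counts (B = 100; 50–100 cohort seeds per property) give
rate estimates with standard errors of a few percent while keeping the
whole suite in the minutes range on a single CPU.

## Known limitations

- The generalized CMH statistic inverts a (I−1)(J−1)-dimensional
  covariance; for very large gene pools with sparse strata the
  pseudo-inverse path (df = rank) is the norm rather than the exception.
- Cell-unit Fisher tests treat cells as independent, which clonal
  expansion violates; the clonotype unit is the statistically safer
  default for inference and is what the recovery analyses use.
- Chao1/ACE extrapolate richness from rare clones and are sensitive to
  the singleton count; with UMI-based data, sequencing artifacts that
  inflate singletons inflate both estimators.
- The paired t-test assumes approximately normal per-patient differences;
  with n = 5 patients it is powered only for large, consistent effects.
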
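# Methods

## Problem setting

A microRNA bound to an mRNA does not always degrade it. Perfect Watson–Crick
pairing of the miRNA seed (nucleotides 2–7/2–8 from the 5′ end) to a site on
the transcript triggers decay; seed-like sites interrupted by a bulged
nucleotide can bind the miRNA without triggering decay, so abundant
transcripts carrying such sites act as *sponges* that sequester the miRNA and
blunt its activity on genuine targets (the ceRNA model). spongescope
implements the computational side of distinguishing the two from (i) a
biotinylated-miRNA pull-down read-count table, (ii) a kinetic transcriptome
response to miRNA transfection, (iii) transcript sequences, and (iv) a
survival cohort for prognostic modelling — all exercised on synthetic data
with known ground truth.

## Interactome filter cascade

Genes are classified from four observables with strict-inequality thresholds:

| quantity | threshold | role |
|---|---|---|
| bait pull-down reads | > 100 | gene is physically recovered with the miRNA |
| late kinetic logFC | < −0.5 / > +0.5 | decayed (target-like) vs up-regulated |
| control-bait reads | > 500 → excluded | sticky/background pull-down false positive |
| basal expression | > 10 | abundant enough to act as a sponge |

Composition order: window assignment (b = bound & down, c = bound & up) →
control-bait exclusion → basal filter (window c only). Labels partition the
gene set: `target`, `interactant_up`, `sponge_candidate`,
`excluded_false_positive`, `none`.

Design choices that the data description leaves open, fixed here and
configurable:

- **Late-window summary** = arithmetic mean of the 24 h and 48 h logFC
  (the kinetic design contrasts an early 6–12 h and a late 24–48 h window
  without an aggregation rule). Alternatives `last` (last timepoint) and
  `all_mean` are provided.
- **Strict inequalities everywhere**, reading "threshold 500" as "> 500
  excluded"; boundary behaviour (reads = 100, logFC = ±0.5, ctr = 500,
  basal = 10) is pinned by unit tests so the convention is explicit.
- Fold changes are taken as log2 and as already computed upstream; the module
  performs no count normalisation.

## MRE scanning

All motif strings are canonicalised to **target-strand 5′→3′ DNA**, derived
from the miRNA by reverse complement; published motif figures mix 3′→5′ and
5′→3′ orientation labels, and canonicalising removes the ambiguity. T and U
are interchangeable on input; coordinates are 0-based half-open on the sense
strand, and the full transcript is scanned (not only the 3′UTR).

Canonical classes for a miRNA with seed window [s, e] (default [2, 8]):
6mer = rc(positions s..e−1), 7mer-m8 = rc(s..e), 7mer-A1 = 6mer + `A`,
8mer = 7mer-m8 + `A`. At one locus the longest applicable class wins
(8mer ⊃ 7mers ⊃ 6mer), preventing double counting; overlapping *distinct*
loci are all reported.

The bulged sponge motif is the 6mer with one extra nucleotide inserted at
position 5 of the 7-long motif (configurable), restricted to G/T/A — an
inserted C would extend perfect pairing with miR-16 rather than create a
bulge. Position 5 is counted on the motif string, not the miRNA. A bulged
window that fully contains a canonical match is reported as canonical, never
as bulged. Deleting the inserted base from any bulged hit restores an exact
canonical 6mer (tested property).

**Duplex score.** A deliberately simple surrogate for hybridisation
stability, not a nearest-neighbour MFE: the full miRNA is aligned gapless and
antiparallel against the window at the best offset; opposed positions score
+2 (Watson–Crick), +1 (G:U wobble), −1 (mismatch), and at most one window
base may loop out of the duplex for a −3 bulge-opening penalty. Overhangs are
unscored. The weights are declared constants. Note that the score is
invariant under reverse-complementing both strands only for wobble-free
duplexes: rc maps a G:U opposition to A:C, which is a mismatch, so the
invariance is exact only on Watson–Crick-pure alignments. Discrimination
between a real site and a composition-matched scramble is strongest on
site-focused windows (a few nt of context, as scored by the scanner) and
dilutes as flanks grow, because the best gapless offset may then ignore the
site region; the tested ≥95% win rate refers to ±3 nt context.

## ΔΔCt quantification

Fold change = 2^(−ΔΔCt) with ΔCt = Ct(target) − Ct(reference) per condition
and ΔΔCt = ΔCt(treated) − ΔCt(control); amplification efficiency is fixed at
the ideal 2 (no efficiency correction). Replicate Cts are averaged before
ΔΔCt and the replicate SD is propagated as the range
[2^(−ΔΔCt−SD), 2^(−ΔΔCt+SD)]. Ct > 40 means "not detected": the computation
raises instead of returning a silent zero.

## Survival primitives

Implemented from their defining formulas (and cross-checked against lifelines
in the tests, which is the independent oracle, never the implementation):

- **Kaplan–Meier**: S(t) = Π_{tᵢ≤t} (1 − dᵢ/nᵢ) over distinct event times;
  subjects censored at tᵢ remain in that risk set. Median survival is the
  smallest event time with S ≤ 0.5 (undefined if never reached).
- **Log-rank** (k groups): per event time, observed minus hypergeometric
  expectation and covariance over the first k−1 groups; the normalised
  quadratic form is χ²(k−1). A pseudo-inverse guards near-singular
  covariance.
- **Cox regression**: Newton–Raphson on the partial likelihood with Breslow
  ties by default (Efron optional; the two coincide without ties).
  Convergence when max |score| < 1e−8, cap 50 iterations, step-halving if the
  likelihood does not improve; |β| > 50 or a non-finite step flags
  non-convergence (monotone likelihood / perfect separation). Standard errors
  come from the inverse observed information; CIs are Wald on the log-hazard
  scale. Constant covariate columns are rejected.
- **Median split**: strictly below the median → `low`, strictly above →
  `high`; values exactly at the median go to `low` by default (configurable),
  because "below/above median" does not cover equality. An empty group is a
  degenerate split: flagged, no test run.

## Sponge risk model

Repeated-holdout forward selection in the style of rbsurv. The exact variant
behind "sequential selection by repetition of a training/validation
separation" is underdetermined, so the implemented reading is stated
explicitly:

- `n_iterations` (default 1,000) random train/validation splits at
  `train_fraction` = 2/3 (the documented rbsurv default), **stratified on
  event status** so every training set contains events (resampling capped at
  10 tries per split); the same splits are reused across steps and candidates
  so candidate scores are paired.
- At each step, each remaining candidate g is fitted (Cox, selected + g) on
  every training part; the fitted coefficients are scored by their partial
  log-likelihood **evaluated on the validation part** (Verweij–van
  Houwelingen style). The candidate with the best mean validation
  log-likelihood is accepted if it beats the current model by more than
  `improvement_tolerance` (default 0); selection stops at `max_genes`
  (default 4) or on no improvement.
- Final coefficients come from a single full-cohort Cox refit — matching the
  classical risk-formula description — not from averaging split fits.
- Risk score η = Σ β_g x_g; cutoff = median(η) on the training cohort,
  applied unchanged to validation cohorts; ties at the cutoff go to low risk.

Under all-null candidates the *maximum* over candidates of the mean
validation improvement is positive more often than a single-gene comparison
would suggest (selection bias of the max), so null selection typically
accepts a few spurious genes before the validation log-likelihood stops
improving; the relevant null property, which the tests check, is that
selection terminates by lack of improvement rather than by exhausting the
gene budget, and that the first-step improvement distribution matches a
permutation null.

## Synthetic-data generator

The generator produces every input the pipeline consumes, with the hidden
truth (class labels, site registry, hazard coefficients) returned separately
from the observables; pipeline code never sees the truth.

- **Kinetic class mix**: ~88% stable / 5% down / 7% up by default, the class
  structure of the motivating 14,842-gene experiment; cascade class sizes
  (targets, sponges, control-bait decoys, low-basal decoys) default to that
  experiment's cascade counts (476→327 targets; 497→403→57 sponges) scaled to
  `n_genes`.
- **Pull-down counts** are negative binomial (Var = μ + φμ², dispersion φ a
  parameter, default 0.3) — the standard overdispersed RNA-seq count model;
  no count model is given by the data description. Bait-bound genes draw at
  `enrichment_factor` × background (default 8 × 30).
- **Label-consistency contract**: a gene's observables are rejection-resampled
  within its class distribution until they fall on the correct side of every
  threshold for its truth label (e.g. a planted target's IP reads are
  conditioned > 100 and its late logFC < −0.5). This makes planted counts
  exactly recoverable — the cascade is deterministic, so exact recovery is a
  property of the generator, and the tests rely on it. With
  `enrichment_factor` = 1 there is no enrichment and no such guarantee: both
  baits draw from the same background distribution (the symmetry case).
- **Kinetic trajectories** ramp linearly from 0 at t=0 to ±1.2 (amplitude
  parameter) with i.i.d. Gaussian noise, SD 0.15 per timepoint; the late-mean
  class condition is re-enforced by re-noising violating rows.
- **Transcripts** are uniform random DNA in which *every* site-equivalent
  substring (four canonical strings + three bulged motifs) is rejected and
  resampled, so the background is provably site-free and the planted-site
  registry is the exact ground truth; planting overwrites bases (length
  preserved) and the transcript is resampled if a junction accidentally
  creates a new motif occurrence. Planted fractions use exact counts
  (`round(fraction × n)`), not binomial draws, so class-level site fractions
  (30% canonical in targets, 2% in sponges) are recovered exactly. The
  rejection sampling is a deliberate deviation from natural sequence
  composition: real transcripts have correlated base composition and
  incidental seed matches, so scanner *specificity* on real data is not
  established by these tests — only correctness of the declared matching
  rules.
- **Survival cohorts**: expression standard normal per gene; event times
  exponential with hazard = `baseline_hazard` · exp(Σ β x) (proportional
  hazards by construction); independent exponential censoring. Log-normal
  basal expression and the unit-variance expression model are stand-ins:
  nothing is claimed about realistic inter-gene correlation, and risk-model
  recovery rates on real, correlated cohorts will be lower.

## Problem sizes and numerics

Tests and the acceptance script use: 10,000 random records for the cascade
oracle; 1,500 genes for planted-count recovery; 1,000 transcripts of 200 nt
for scanner identity; 1,000 replicates for log-rank null calibration; n=30
(grid oracle, 1e−4 grid, agreement to 1e−3) and n=500 (planted β=0.8, ±0.15 ≈
3 empirical SDs) for Cox; and 20 replicate cohorts (n=200 training, n=300
held-out, 100 holdout iterations, 2 planted genes |β|=1 among 48 nulls) for
the risk model. Sub-seeds are spawned from one master seed; all generators
are bit-reproducible under it.

## Known limitations

- The duplex score is rank-useful but not an energy; it will not reproduce
  RNAhybrid energies and makes no claim to.
- The scanner searches the sense strand only and reports exact motif matches;
  no conservation, context or accessibility features.
- The cascade operates on already-summarised per-gene values: no replicate
  modelling, no differential-expression testing, no library-size model.
- The risk model assumes proportional hazards and uncorrelated candidate
  expression in its validated operating regime; the selection variant is one
  defensible reading of the underdetermined original description.
- External cohort results (TCGA/GEO signatures, specific gene lists) are out
  of scope by design; everything here is validated against planted ground
  truth.
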
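# spongescope

Tools for telling apart the two things a microRNA can do to an mRNA it binds:
degrade it (a **target**) or be sequestered by it (a **sponge**). The package
re-implements, as a tested and fully synthetic-data-driven pipeline, the
computational workflow used to discover miR-16 sponge RNAs in uveal melanoma
from biotinylated-miRNA pull-down plus kinetic transcriptome data, to scan
transcripts for canonical and bulged (non-canonical) miR-16 binding sites,
and to build a sponge-based survival risk signature.

It is aimed at computational biologists who want a reproducible, inspectable
version of each analysis step — every stage can be exercised end to end on
generated data with known ground truth, without downloading any cohort.

## What it computes

**Interactome cascade.** Each gene carries pull-down read counts for a
biotinylated miR-16 bait and a control bait, basal expression, and a kinetic
log₂ fold-change vector (0/6/12/24/48 h after miR-16 transfection). With the
late-window summary L = mean(logFC₂₄ₕ, logFC₄₈ₕ):

- window *b* (candidate targets): IP reads > 100 and L < −0.5
- window *c* (up-regulated interactants): IP reads > 100 and L > +0.5
- false-positive exclusion: control-bait reads > 500
- sponge candidates: window *c* survivors with basal expression > 10

All comparisons are strict; the boundary semantics are unit-tested.

**MRE scanning.** Canonical miR-16 response elements follow the standard
seed-match taxonomy derived from the miRNA by reverse complement (for
miR-16, seed AGCAGC): 6mer `GCTGCT`, 7mer-m8 `TGCTGCT`, 7mer-A1 `GCTGCTA`,
8mer `TGCTGCTA`. The *bulged* sponge motif is the 6mer with one extra base
(G/T/A, not C) inserted at motif position 5 — `GCTG(G/T/A)CT` — which loops
out of the duplex when the seed binds, letting the miRNA bind without
triggering decay. A simple duplex score (+2 Watson–Crick, +1 G:U wobble,
−1 mismatch, −3 per bulged base) ranks site strength; it is a surrogate,
not a thermodynamic MFE.

**Survival machinery.** Kaplan–Meier product-limit curves, the k-group
log-rank test and Cox proportional-hazards regression (Newton–Raphson on the
partial likelihood, Breslow or Efron ties) are implemented from their
defining formulas and cross-checked against lifelines in the test suite.

**Sponge risk model.** Greedy forward gene selection maximising the mean
*validation* Cox partial log-likelihood over repeated random 2:1
train/validation splits (rbsurv-style, default 1,000 iterations), followed by
a full-cohort Cox refit. The risk score is the linear predictor
η = Σ β_g·x_g, dichotomised at its training-cohort median; validation cohorts
are stratified with the training cutoff and compared by KM + log-rank.

## Worked example

```bash
python analysis/01_simulate_inputs.py
python analysis/02_call_interactome.py
python analysis/03_scan_sites.py
python analysis/04_risk_model.py
python analysis/05_full_pipeline.py
```

Actual output (seed 20221006):

```
cascade counts: {'n_b': 48, 'n_c': 51, 'n_targets': 33, 'n_interactants_up': 35,
                 'n_sponge_candidates': 6, 'n_excluded_false_positive': 25}
agreement with planted truth: 1500/1500 genes

scanner vs registry: 426 hits, 0 false positives, 0 false negatives
  sponge       n=300  canonical 2.00%   bulged 100.00%
  target       n=400  canonical 30.00%  bulged 0.00%

selected genes (in order): ['S0001', 'S0002', 'S0037', 'S0042']  [stop: max_genes]
coefficients: {'S0001': 1.065, 'S0002': -0.963, ...}; cutoff -0.130
held-out stratification: log-rank chi2=104.62, p=1.48e-24 (low n=129, high n=171)
```

Reading this: the threshold cascade recovered exactly the planted class
structure of a 1,500-gene table (33 targets, 6 sponge candidates, decoys
correctly excluded); the site scanner reproduced the planted-site registry
with zero errors, including the 30%-canonical target class versus the
bulged-only sponge class; and forward selection put the two genuinely
prognostic genes (planted log-hazard ±1) in the first two ranks, with the
resulting median-cutoff risk groups strongly separated on a held-out cohort.

The same steps are available as a CLI (`spongescope simulate / interactome /
scan / ddct / km / risk-model / run`); `spongescope run --seed N --out DIR`
executes the whole chain into a run directory with a checksummed provenance
manifest.

## Layout

- `src/spongescope/` — the library (simulation, cascade, scanner, survival,
  risk model, IO, pipeline, CLI)
- `analysis/` — numbered narrative scripts writing summaries to `results/`
- `tests/` — unit, property and acceptance tests
- `docs/methods.md` — models, assumptions, parameter choices, limitations
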
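# Methods

This note documents the models, algorithms and design choices behind
`permtask`, in the order data flow through the package.

## Curation

**Structure standardization.** SMILES are canonicalized with RDKit's
MolStandardize (cleanup → largest fragment → uncharge → canonical SMILES).
Unparsable inputs are rejected with a logged reason, never silently dropped.

**Values.** Assay values are strictly positive (P_app in 1 × 10⁻⁶ cm/s, ER
dimensionless) and converted to log₁₀ — the scale the field reports
(LogP_app, LogER).  Out-of-quantification-range readings keep their numeric
payload with the bound direction (`lower_bound`/`upper_bound`) recorded;
qualified values enter aggregation like any other measurement, with
`any_qualifier` carried as metadata.  Mixed-direction qualifiers within a
replicate group aggregate anyway with a warning.

**Aggregation.** Replicates are grouped per (standardized SMILES, endpoint):
arithmetic mean of log values, sample (n−1) SD when n ≥ 2, earliest
timestamp (temporal splits need a single date per record), measurement
count.  Count conservation (Σn over groups = accepted measurements) is a
tested invariant.

**Noise model and outlier removal.**  Replicate noise is heteroscedastic:
σ is larger at low permeability, where concentrations approach the
quantification limit.  An OLS regression of replicate SD (dependent) on
replicate mean (independent) is fitted per endpoint from groups with n ≥ 2
(at least three required).  A replicated group is flagged as an outlier when
its observed SD exceeds k·max(σ_floor, σ̂(mean)), with k = 2 and
σ_floor = 0.01 log units by default; the floor keeps the rule meaningful
where the regression line approaches zero.  Singletons carry no SD and are
never flagged — their variability is assumed comparable to replicated
compounds, so they are retained.  Because outliers inflate the very
regression used to detect them, `curate` refits once on the surviving
records and flags again (`sigma_refits=1`); the reported σ-model is the
final refit.  Per-endpoint (rather than pooled) regressions are used since
the endpoints' noise regimes differ.

The direction of the rule (observed > k·predicted) is the one that serves
the stated purpose — identifying unusually *inconsistent* replicate groups —
and is configurable.

**External data.**  CycPeptMPDB/NMMPDB-style CSV layouts are mapped through
per-source column configurations.  Sentinel permeabilities marking
undetectable compounds (the −10 × 10⁻¹⁰ cm/s convention) and any
non-positive value are dropped; the rest are unit-normalized to
1 × 10⁻⁶ cm/s before log transformation.

## Splitting

All plans assign (compound, endpoint) records to train/test per round, never
both; serialized plans are byte-identical under a fixed seed.

* **Stratified-random** (repeated holdout): strata are the endpoint-
  availability patterns (which subset of the four endpoints a compound has),
  so each endpoint's test share stays near the target fraction.  Compounds
  move whole.  Default 5 repeats at 80:20.
* **Scaffold-balanced**: Bemis–Murcko scaffold groups (acyclic molecules
  form one shared empty-scaffold group) are assigned greedily — groups
  visited by descending size, equal-size blocks shuffled per repeat under
  the seed — to the split with the largest remaining deficit against its
  80:20 target; ties go to train.  Train and test never share a scaffold.
* **Temporal**: records are sorted globally by acquisition date (ties broken
  by SMILES then endpoint for a total order); round r trains on the oldest
  cumulative fraction f_r = 0.8·r/5 → 16/32/48/64/80% and tests on the
  rest, so training sets are nested.  *Leaky* mode leaves cross-endpoint
  compound sharing in place; *all-for-one* removes from training every
  record of any compound present in that round's test set.  Chunking is
  global over all endpoints' records, so per-endpoint test percentages vary
  — which is exactly what the leakage report surfaces.
* **Modality / k-fold CV**: compound-level partitions; modality evaluation
  is keyed by (endpoint, modality) with single-compound groups flagged as
  small-sample.

**Leakage report.** Per endpoint and round: the share of the endpoint's
records in the test set, and the share of its test compounds whose SMILES
appears anywhere in the training set.  Computed by exact set arithmetic;
all-for-one plans report 0 identically.

## Modeling

**Masked multitask regressor.**  `MultitaskRegressor(table, ...)` is built
from the curated table (optionally restricted to training cells) and
`fit(seed)` returns a results object (predictions, per-task scales,
history, `summary()`).  The reference encoder is hashed Morgan fingerprints
(radius 2, 512 bits); descriptor blocks can be concatenated after
train-median imputation and train-statistics standardization.  The head is
a two-hidden-layer ReLU network (128, 64) whose readout is a shared linear
component plus task-specific linear offsets initialized at zero and
L2-penalized (1e−3).  On per-task standardized targets the shared component
absorbs what the endpoints have in common, so a task with few or no labels
inherits the shared signal — the mechanism behind cross-task transfer and
zero-shot predictions for late-introduced assays.  For a task with no
training labels the standardization statistics are unidentified and fall
back to pooled values across observed tasks (rank-based metrics are
unaffected; absolute scale is a declared approximation).

Training: Adam (lr 1e−3) on minibatches of 256, masked MSE, early stopping
on a 10% compound-level holdout with patience 20, max 200 epochs; every
random draw flows from the fit seed.  The implementation is plain float32
numpy — at desk scale (thousands of compounds, ~600 features) no autodiff
framework is needed, and the masked loss over a 4-column target is a few
lines of backprop.

**Single-task baseline.**  Per-endpoint random forests (500 trees,
scikit-learn) on the full RDKit 2D descriptor set with degenerate columns
dropped and training-median imputation.  Descriptor attribution
(`rank_descriptors`) uses permutation importance — mean absolute fit
degradation when a column is shuffled — to rank descriptors per endpoint.

**Descriptor tiers.**  `plus` = logD/pKa proxies; `plusplus` = proxies plus
PEOE_VSA1, MolWt, SlogP_VSA1, qed, TPSA, BertzCT, NHOHCount, RingCount;
`baseline_full` = all available 2D descriptors.  The pKa proxies are a
SMARTS lookup of typical values for common ionizable groups (strongest acid
= minimum, strongest base = maximum over matches); the logD proxy is
Crippen logP with a Henderson–Hasselbalch correction at pH 7.4 using those
proxies.  They capture the ordering of ionization classes, not quantitative
pKa — adequate for their role as permeability-relevant features.

**Metrics.**  RMSE per endpoint across rounds/folds (mean ± SD via
`benchmark`/`summarize_benchmark`, with leakage columns joined for temporal
strategies) and Spearman ρ with average-rank ties for external rank
comparisons (undefined on constant vectors, returned as absent with a
warning).

## Synthetic data generator

The generator emulates the *statistical* structure of multitask
permeability data; it makes no attempt at assay physics, 3D conformers or
transporter binding.

* **Molecules** come from a packaged fragment grammar (aromatic/aliphatic
  cores × substituents, macrocyclic lactams, 2–4-residue peptides,
  linker-joined bifunctional molecules), validated through RDKit and
  de-duplicated; modality labels follow the construction class
  (85/7/5/3% small molecule/macrocycle/peptide/PROTAC by default).
* **Truth.**  A shared latent factor is a descriptor score
  (0.8·z(logD) − 0.5·z(TPSA) − 0.3·z(MolWt)) passed through a rank-based
  inverse-normal transform, so it preserves the descriptor ordering but is
  exactly standard-normal shaped.  Endpoint t's true log value is
  μ_t + s_t·(√ρ·g + √(1−ρ)·ε_t) with ρ = 0.8 by default; the P_app-like
  endpoint's specific factor is a standardized lognormal (σ_ln = 0.6),
  giving the right-skewed shape permeability data show while keeping true
  values physically plausible; ER-like endpoints stay unimodal near low
  values.  All loadings are positive, so pairwise correlations equal ρ with
  positive sign (real ER and P_app anti-correlate; the sign convention is a
  deliberate simplification).  Truth is retained for *all* four endpoints
  per compound, enabling evaluation against truth for zero-shot endpoints.
* **Coverage and time.**  Endpoint counts per compound follow
  57/37/5/1% for 1/2/3/4 endpoints; measured endpoints are drawn uniformly.
  Timestamps are uniform over a 10-year timeline except the late endpoint
  (NIH-MDCK-like), whose measurements all postdate 70% of the timeline.
  With ~25% of records on the late endpoint, its first record sits at
  ≈52% of the sorted record stream, so temporal rounds 1–3 (train fractions
  16/32/48%) contain no late-endpoint training data — reproducing the
  100/100/100/declining test-occupancy signature of a late-introduced assay.
* **Noise.**  Replicate SD follows σ(m) = max(floor, a + b·m) with
  b = −0.09, a = 0.26 for the P_app-like endpoint (zero crossing at
  m ≈ 2.9, beyond ~99% of the truth support, so the law is positive where
  data live) and constant σ = 0.05 for ER-like endpoints; floor 0.02.
  Replicate counts are 1 with probability 0.65, else uniform on {2, 3, 4}.
  This calibration reproduces the data-quality pattern of well-run assay
  platforms: >90% of ER replicate groups have SD < 0.1 and >75% of P_app
  groups have SD < 0.2.
* **Censoring.**  Values outside per-endpoint quantification limits are
  reported at the limit with the bound direction as qualifier.
* **Planted outliers.**  An optional fraction of cells is generated with
  σ inflated 5× and 4–6 replicates (inconsistent compounds get remeasured);
  the affected cells are recorded so recall/precision of the outlier filter
  can be measured.

Everything flows from one seed (via spawned seed sequences per stage);
regeneration is byte-identical.

### What passing tests do and do not show

The generator reproduces coverage sparsity, endpoint correlation,
heteroscedastic replicates, temporal asymmetry, censoring and modality
imbalance — the features the curation/splitting/modeling machinery is
sensitive to.  It does not reproduce real structure–activity landscapes
(truth is a smooth function of three descriptors plus noise), activity
cliffs, assay drift, batch effects, or the true anti-correlation between
efflux and permeability.  Passing tests therefore validate the *machinery*
(splits leak-free, estimators recover planted parameters, multitask
transfer works when endpoints share signal), not predictive performance on
real chemistry.

## Numerical and statistical notes

* The σ-regression of sample SDs on means recovers a generator noise slope
  with a known ~13% attenuation: E[sample SD] = c₄(n)·σ, and c₄ averages
  ≈ 0.87 over replicate counts {2, 3, 4}.  The parameter-recovery experiment
  inherits this bias; it is a property of regressing sample SDs, not a bug.
* With n = 2 replicates a 5×-inflated σ passes the 2σ̂ rule ~31% of the
  time (sample SD = 5σ|z|); recall of planted outliers is therefore driven
  by their replicate count, which is why the generator gives them 4–6.
* Scaffold greedy ties (equal deficits) go to train; equal-size scaffold
  groups are shuffled per repeat so repeated holdouts differ under one seed.
* Timestamp ties are broken by canonical SMILES then endpoint, making the
  temporal sort a total order and plans reproducible.
* Degenerate inputs: empty masks in the loss return 0 with a warning;
  constant vectors make Spearman ρ undefined (absent, warning); a scaffold
  split where all compounds share one scaffold yields an empty test set
  with a warning; single-endpoint training data degrade the multitask model
  to single-task with a warning.

## Problem sizes

Validation experiments run at 2 000 compounds (split hygiene, modeling
comparisons, 5 seeds), ~5 000 replicate groups (noise-slope recovery) and
10 000 compounds (coverage), chosen so the full suite and the acceptance
script each complete in minutes on one CPU while leaving the statistical
margins (binomial/multinomial noise, seed-to-seed variation) comfortably
inside the tested tolerances.

## Known limitations

* The masked network is a deliberately small reference implementation; the
  encoder interface accepts richer molecular encoders, but none ships here.
* pKa/logD proxies are heuristic; do not interpret them quantitatively.
* The generator's modality classes affect molecule construction only, not
  the truth function; modality-stratified performance differences on
  synthetic data reflect chemistry-space coverage, not biology.
* Absolute predictions for endpoints with zero training labels are on a
  pooled scale (see above); only rank information is meaningful there.
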
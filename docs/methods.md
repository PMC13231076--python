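# Methods

This note records the modelling choices behind enmkit: the estimators as
implemented, the defaults and why, what the synthetic generators do and do
not emulate, and the numerical conventions that affect results.

## Maximum-entropy model

**Objective.** Given m presence records and a background sample of the
landscape, the model is the Gibbs density `q_β(x) = exp(β·f(x))/Z` over the
normalization set, fitted by minimizing

    log Z(β) − (1/m) Σᵢ β·f(xᵢ) + Σⱼ λⱼ |βⱼ| .

The presence records are **added to the normalization set** (background ∪
presences). This matters: without it the penalized likelihood is unbounded
whenever some feature direction separates presences from every background
point, and coefficients diverge. Adding samples to the background bounds
the objective for any data and is also the long-standing default of the
reference MaxEnt implementation. Consequently `n_background` on a fitted
model counts background plus presences, the raw output sums to 1 over that
combined set, and the entropy H used by the cloglog transform is computed
on it.

**Features.** Continuous variables are clamp-scaled to [0,1] by their
background range. Families: linear (the scaled variable), quadratic
(square), product (pairwise products), hinge (forward and reverse
piecewise-linear ramps at quantile knots; default 50 knots per direction,
reduced in desk-scale runs), threshold (step indicators at quantile knots),
and categorical indicators (one per observed level; categorical layers such
as land-use codes are exempt from Q/P/H/T expansion). All features evaluate
into [0,1] on the background by construction.

**Regularization.** `λⱼ = RM · β_class(m) · max(sdⱼ, 10⁻³) / √m`, with sdⱼ
the feature's standard deviation over presences and `β_class` interpolated
against presence sample size from the published per-class default tables
(linear 1.0→0.05 over m = 10→100; quadratic/product 1.3→0.05 over
m = 0→100; hinge 0.5 flat; threshold 2.0→1.0 over m = 0→100; categorical
0.65→0.25 over m = 0→17). RM scales all penalties uniformly.

**Optimizer.** The objective is convex; it is solved by L-BFGS-B on the
split β = u − v with u, v ≥ 0, which handles the L1 term exactly and yields
exact zeros (sparse models) at the bound. Convergence: relative objective
tolerance 10⁻⁷, gradient tolerance 10⁻⁷, iteration cap 2000 (a cap hit
raises a convergence error). A coordinate-descent pass over the same
objective is kept separately because the *percent contribution* diagnostic
is defined path-wise: walking from β = 0 to the optimum, each accepted
coordinate step's objective gain is credited to the feature's source
variable (product features split credit evenly). Contributions are
heuristic (path-dependent); permutation importance — the normalized
training-AUC drop when one variable is shuffled across presences and
background — is always reported alongside.

**Outputs.** `raw` (normalized density) and `cloglog = 1 − exp(−e^H·raw)`,
the display default. Both are monotone in β·f, so rank-based metrics (AUC,
CBI) are identical between them. Note a structural property relevant to
tiering: for a density that is approximately uniform over an occupied core,
e^H·raw ≈ 1 there, so the cloglog surface plateaus near 1 − 1/e ≈ 0.63, and
for a d-dimensional gaussian-like density the ceiling is roughly
1 − exp(−e^(d/2)). Single-driver models therefore cannot reach cloglog
values near 1, and absolute tier cuts in the 0.8–0.95 range can be empty
even for excellent models. This is faithful behavior, not a defect; see
"Tiering" below.

**AICc.** `−2 ln L + 2k + 2k(k+1)/(n−k−1)` with ln L the sum of log
standardized raw probabilities at presences and k the count of non-zero
coefficients; candidates with n ≤ k+1 get an infinite sentinel
(disqualified, not an error).

**Tuning.** The default grid crosses RM ∈ {0.5, …, 4.0} (step 0.5) with
FC ∈ {L, LQ, H, LQH, LQHP, LQHPT}. Features are built once for the union
set and column-subset per candidate. Each candidate is fitted on all data
(AICc) and cross-validated over random occurrence folds (10% training
omission rate, train/test AUC). Selection: minimum AICc; among candidates
within 2 units, omission rate closest to 0.1 from below, then minimum
|AUC_train − AUC_test|, then smallest k, then grid order — fully
deterministic.

## Evaluation

AUC is the rank probability that a presence outscores a background point
(ties ½). TSS uses background points as pseudo-absences (the presence-only
convention) with the rule `score ≥ t → predicted presence` everywhere.
MTSS maximizes sensitivity + specificity over all observed scores, ties
resolving to the lowest maximizer. The continuous Boyce index slides 101
overlapping windows of width 10% of the landscape score range, computes the
predicted-to-expected presence ratio per window (zero-expectation windows
skipped), and reports the Spearman correlation against window midpoints.
Because windows are value-based, CBI is only approximately invariant to
monotone transforms of the score scale; the calibration verdict is stable,
the third decimal is not. Cross-validation partitions occurrences into
random folds with sizes differing by at most one; each fold's model trains
on the complement with the full background.

## Tiering

Two published anchoring rules, both cutting the lowest class at the MTSS
threshold t: *threshold-multiples* (boundaries t, 2t, 3t; requires
3t < 1) and *equal-above-threshold* (t, t+(1−t)/3, t+2(1−t)/3). Intervals
are left-closed with the top class closed at 1. The two rules reproduce
two different printed boundary sets and are kept as explicit named schemes.
Per-class areas are cell counts × cell area and always conserve the valid
area. Cross-model tier concordance (per-tier Jaccard) is reported, with the
caveat from the cloglog ceiling above: top-tier overlap between a cloglog
MaxEnt map and a vote-fraction RF map depends on each model's score
calibration and is structurally weak on low-dimensional synthetic species,
while binary suitable/unsuitable agreement (both models at their own MTSS)
is high on the same data.

## Random-forest cross-check

Presences vs background are heavily imbalanced, so each of 10 iterations
draws, without replacement, pseudo-absences equal in number to the
presences (exact 1:1 balance, asserted), trains a forest (defaults
ntree = 70, mtry = 1, nodesize = 1), and scores presences against the
held-out background. Metrics are averaged across iterations; the mean
probability map is thresholded at its own MTSS and tiered with the
equal-above-threshold scheme. The tree learner is scikit-learn's
`RandomForestClassifier`; the protocol around it is the bespoke content.

## Novelty diagnostics

MESS follows the standard piecewise similarity with "fraction below"
counting reference values *strictly* less than the cell value (ties are not
below). The per-cell score is the minimum over variables; the arg-minimum
is the most-dissimilar variable (ties → first variable in envelope order).
Risk tiers: MESS > 0 reliable, −10 ≤ MESS ≤ 0 moderate, MESS < −10 high
(boundaries 0 and −10 fall in the moderate tier). The reference envelope is
built from occurrence records by default; any environmental table works.
Envelope drift uses histograms on shared Freedman–Diaconis bins over the
pooled baseline+future values, reporting mean and median displacement, the
overlap coefficient Σ min(p, q) (symmetric), and a direction label from the
sign of the mean displacement.

## Synthetic generators

Smooth fields are gaussian-filtered white noise (smoothness = kernel sd in
cells — the spatial autocorrelation length is a free choice, default 5–6
cells), standardized, mixed through the Cholesky factor of the requested
correlation matrix, and rescaled to the requested moments; realized
cross-correlations are approximate when smoothing lengths differ. Virtual
species combine per-variable gaussian/logistic/flat responses by product
(or geometric mean). Two occupancy modes exist because they answer
different questions:

* **quantile labels** (`gen_classifier_output`): the top-prevalence
  fraction of suitability is "true", and predicted labels corrupt truth by
  deleting positives (recall) and adding false positives (precision), so
  segmentation metrics are exactly computable. This emulates the
  remote-sensing map that feeds occurrence sampling.
* **graded occupancy** (`sample_presences`): presence cells are drawn with
  probability proportional to suitability — the canonical virtual-species
  protocol — so occurrence density tapers away from the optimum. This is
  the mode used for parameter-recovery experiments, because quantile
  labels make within-core density uniform and degenerate the upper range
  of cloglog-based thresholds.

Default study conditions for the recovery experiment: a 150×150 landscape
(cell size 1), six bioclim-like layers, driver response gaussian
(optimum 876, breadth 8 against a landscape sd of 60 — a sharply defined
niche, comparable in relative width to published seasonality responses), a
weak secondary response on a second layer, 900 drawn presences thinned on
the model grid, and a 10,000-point background. Desk-scale runs reduce hinge
knots to 10 and cross-validation to 2 folds inside the tuning loop; these
sizes keep a full 48-candidate grid under a minute while leaving the
selection behavior representative. What the generators do **not** emulate:
anisotropic terrain effects, spatially structured classifier errors,
sampling bias fields, or temporal autocorrelation between baseline and
future stacks — conclusions about those belong to real data.

## File formats

ESRI ASCII grid (6-field header, 6 significant digits, corner-registered)
is the canonical text format; GeoTIFF (single band, float64, written via
tifffile with ModelPixelScale/ModelTiepoint/GDAL_NODATA tags) stores full
precision. No implicit resampling anywhere: stacked layers must share a
grid exactly, and mismatches fail loudly naming the layer. Cell membership
is half-open [left, right) × [bottom, top); points on the far right/top
edge are outside. A cell that is nodata in any layer is nodata in all
layers of a stack.

## Known limitations

* Percent contribution depends on the coordinate-update path; different
  but equally valid paths redistribute a few percent between correlated
  variables.
* The cloglog ceiling (above) makes absolute top-tier cuts conservative
  for models driven by one or two variables.
* The RF protocol's mtry = 1 default produces noisy per-tree splits by
  design (it mirrors a published tuned configuration); per-iteration AUC
  varies accordingly and only the across-iteration mean is meaningful.
* VIF is computed on the combined presence+background environmental
  matrix — the larger, more stable sample — and screening decisions use
  contribution priorities from a light LQ model, not the final tuned one.
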
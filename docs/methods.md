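# Methods

This note records the model, the numerical choices, the synthetic-data
conditions and the known limitations of `cesep`, in the order a user meets
them in the pipeline.

## Separation scoring

Resolution uses the baseline-width definition Rs = 2·(MT_b − MT_a)/(w_a +
w_b); a half-height variant (factor 1.18) is available via
`resolution(..., half_height=True)`. The choice affects only the absolute
Rs scale, not the workflow.

The efficiency index caps every resolution at 1.5 before averaging and
multiplies by the penalty P = (Σ Rs_j²/m)^1.25 over the m values strictly
below 1. Two readings of the penalty typography are defensible; the default
attaches the 1.25 exponent to the *mean* of squared sub-1 resolutions
(keeping P ≤ 1 with a clean damped-mean interpretation), while
`penalty(..., reading="sum")` exposes the alternative Σ Rs²/m^1.25. Both
stay within (0, 1] for sub-1 inputs, so 0 ≤ E ≤ 1.5 holds under either.
Values exactly equal to 1.0 are not penalized. The index is deliberately
discontinuous where a component crosses Rs = 1 (the penalty set changes
size); improving one pair from 0.999 to 1.0 can lower E when other pairs
are badly resolved. This is inherent to the definition and is preserved,
not smoothed.

Corrected peak area is CPA = area/(60·MT) with MT in minutes — i.e. area
divided by migration time in seconds — the standard correction for the
velocity with which each analyte crosses the detector window.

## Peak detection

`detect_peaks` targets clean synthetic-style traces: running-median
baseline (default 201 points, wider than any peak), noise as 1.4826·MAD of
the baseline-subtracted trace, peaks as local maxima above min_snr·noise
with half that as prominence, and peak extent between the surrounding
zero-crossings of the baseline-subtracted signal. The zero-crossing width
is a noise-floor width: for a Gaussian peak at SNR s it measures
≈ σ·2√(2 ln s) rather than the 4σ baseline width, an overestimate of up to
~40 % at high SNR. Downstream analyses in this package take widths from
integrated peak tables, so this bias only matters if detection output is
fed straight into resolution scoring. Baseline drift correction and
deconvolution of genuinely overlapping peaks are out of scope.

Spectral identification interpolates both UV-VIS spectra onto a 1-nm grid
inside the comparison window (default 192–600 nm) and reports their Pearson
correlation; a match requires ≥ 0.95.

## D-optimal design

Designs are built by classic Fedorov point exchange over a full-factorial
candidate grid (default 5 levels per factor) for the full quadratic model
(15 terms in 4 factors), maximizing det(XᵀX); candidates may repeat.
The exchange uses the rank-one delta formula with the determinant
recomputed exactly each step and asserted non-decreasing; 10 random starts
(seeded) guard against local optima, and for tiny problems the result is
verified against exhaustive enumeration in the tests. The run count
defaults to p + 5 lack-of-fit points + 5 replicates = 25; replicates are
appended after convergence by duplicating the highest-leverage distinct
points, supplying the pure-error degrees of freedom for the lack-of-fit
test. Factor coding is the usual (x − center)/half-range map onto [−1, 1];
slightly out-of-range settings warn rather than fail. I-, A- and
G-optimality, split-plot and mixture designs are out of scope.

## Response-surface fitting and diagnostics

Fits are ordinary least squares on the model-expanded coded matrix; rank
deficiency raises an error naming the aliased terms (pivoted QR). Term
p-values are partial (Type III) t-tests on the coded coefficients.
Backward elimination removes the single largest-p term above α = 0.1 and
refits, repeating until all removable terms clear α; with hierarchy on
(default) a linear term is retained while any of its interaction or
quadratic children remain, and the intercept always stays.

Diagnostics per model: ANOVA F-test; lack-of-fit vs pure error whenever
replicate rows exist (groups of identical coded rows); R², adjusted R²;
PRESS via the leverage identity e_i/(1 − h_ii) (runs with h_ii = 1 are
excluded with a warning) and predicted R² = 1 − PRESS/SST; Adequate
Precision = (max ŷ − min ŷ)/√(p·MSE/n) at the fitted design points.
Health flags mark models with adjusted-minus-predicted R² gaps above 0.2
or Adequate Precision at or below 4. Residual normality is a Shapiro–Wilk
test recorded at α = 0.05; fewer than 3 residual degrees of freedom or
numerically constant residuals are flagged not-computable.

Two properties of the elimination step are worth stating because they are
easy to over-expect. First, a truly zero coefficient has a uniform p-value
no matter how small the noise, so each null term survives a p > α screen
with probability near α (in practice somewhat above it: design columns
correlate and hierarchy protects linear parents). Elimination is therefore
a good pruner but not a consistent selector — with five null terms,
removing *all* of them happens in only roughly half of replicates. Second,
regression residuals are (I − H)ε; with p/n ≈ 0.5 the projection mixes the
errors strongly enough that even a heavy bimodal error distribution leaves
near-normal-looking residuals, so the Shapiro–Wilk check has real power
only when the fitted model is small relative to n.

## Constrained optimization

The refined E model is maximized over the coded box subject to the refined
last-analyte MT model staying at or below the time limit (default 15 min):
a coarse 11-points-per-axis scan of the whole box, then successive local
refinement that shrinks the box by 0.35 around the best feasible point and
re-grids, ten times. The refinement is derivative-free, handles the
constraint exactly by masking, converges geometrically (final step ~1e-5
coded units), and is fully deterministic — the `seed` argument exists only
for interface symmetry. The returned optimum provably dominates every
feasible coarse-grid point (asserted). If no grid point is feasible the
result is flagged infeasible with the smallest constraint violation. E is
modeled directly as its own response (default) rather than recomposed from
the Rs models; both models must share the factor space.

## Validation statistics

Calibration regresses CPA on concentration (≥ 3 points, ≥ 2 distinct
levels). LOD = 3·noise/slope and LOQ = 10·noise/slope, with the noise SD
taken deterministically over a stated blank region rather than by visual
assessment. Repeatability reports per-analyte MT mean/SD/RSD% and CPA RSD%
across replicate runs, flagging analytes at or above 10 % RSD; analytes
missing from some runs are excluded with a warning. Accuracy/recovery and
intermediate precision are out of scope.

## Chemometrics

Species profiles are compared by Pearson correlation distance d = 1 − r.
This is not a metric (the triangle inequality can fail); it is used
descriptively, as is standard in chemotaxonomy. Linkage defaults to
average (UPGMA) — the method is selectable since the choice is a
convention, not a result. Dendrograms export to Newick. PCA runs on
column-standardized concentrations by default (the scaling is a choice;
covariance PCA via `standardize=False`), with a deterministic sign
convention (largest-magnitude loading positive). Semiquantitative content
categories: absent (0), * (0–2], ** (2–10], *** (> 10) mg/g DW. Clustering
can be run on raw concentrations, category codes or presence/absence;
no significance testing of clusters is attempted.

## Synthetic-data conditions

The generator fixes the study conditions used by all tests:

- Factor space: boric acid 20–60 mM, DOC 30–100 mM, MeOH 0–25 %, pH
  9.0–9.6; design of 25 runs (20 exchange + 5 replicates).
- `easy` preset: one shared concave quadratic bowl (depth 0.18 over the
  box, interior maximum drawn in [−0.5, 0.5]⁴) plus per-pair offsets in
  [1.22, 1.30], keeping every Rs inside (1, 1.5). Capping and penalty are
  then inactive, E is exactly the mean of the resolutions, and the planted
  argmax is available in closed form — the basis of all recovery tests.
  Resolution noise SD 0.02.
- `realistic` preset: independent random surfaces per resolution with
  noise SD drawn as U(0.6, 1.5) times the on-grid signal SD, calibrated so
  the refined-model R² lands in the 0.5–0.95 range typical of real
  campaigns of this size (median ≈ 0.78 over seeds); resolutions may dip
  below 1, engaging the penalty.
- `null` preset: all non-intercept coefficients exactly zero.
- Per-run E is always computed from the simulated resolutions through the
  efficiency module, never planted directly.
- The DoE migration-time response is a quadratic increasing in boric acid,
  DOC and MeOH (intercept 11.5–12.5 min), so the 15-min constraint is
  active over part of the box. The electropherogram generator is a separate
  channel: seven Gaussian peaks at base migration times 7.5–14.6 min scaled
  multiplicatively by the factors (all increasing in boric, DOC, MeOH),
  widths growing linearly with MT (0.05 + 0.02·MT min, a plate-count-like
  trend), white detector noise. A deliberately weak MeOH response for the
  second peak compresses the leading pair toward co-elution at high
  boric + MeOH, exercising the penalty path. Absolute levels of the two
  channels are not coupled.
- Species matrices: disjoint per-group core compounds with log-normal
  abundances (median ≈ 5 mg/g DW) over a small noisy background, so
  planted blocks are recoverable and no profile is constant.

What passing these tests shows — and does not. The generator produces
exactly quadratic surfaces with Gaussian noise, symmetric Gaussian peaks on
a flat baseline, and cleanly blocked profiles. Recovery there validates the
estimators and the plumbing; it does not certify behavior under model
misspecification, drifting baselines, asymmetric/tailing peaks or weak
cluster structure, which real CE campaigns exhibit.

## Problem sizes

Defaults are chosen at desk scale: 25-run designs, 11-point optimization
grids, simulation batches of 50–500 seeds for calibration-style checks.
All are parameters, and the reported statistics (e.g. elimination rates,
error medians) refer to these sizes.

## Known limitations

- The Rs cap, penalty exponent 1.25 and the 0/1/1.5 breakpoints are taken
  as fixed conventions of the index, not fitted.
- The exchange algorithm optimizes over a finite candidate grid; a finer
  grid trades determinant for time.
- `reanalyze_deposit` expects the external raw-data deposit to be exported
  to a documented CSV layout; the package does not fetch it.
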
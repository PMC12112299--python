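# cesep

DoE-driven optimization, validation and chemometric profiling for micellar
electrokinetic capillary electrophoresis (MEKC) separations.

Separating many structurally similar polyphenols (e.g. lichen depsides and
depsidones) in one CE run hinges on the background electrolyte: buffer
concentration, surfactant level, organic modifier and pH interact, so
one-factor-at-a-time tuning misses the true optimum. `cesep` implements the
full design-of-experiments workflow for this problem: it scores each run
with a single separation-quality number, builds D-optimal experimental
designs over the buffer factors, fits and diagnoses quadratic response
surfaces, numerically optimizes the buffer under a separation-time
constraint, computes method-validation statistics, and classifies species
by their metabolite profiles. A seeded synthetic-data generator makes every
stage testable end to end.

## The separation efficiency index

A run with critical peak pairs at resolutions Rs₁…Rsₙ
(Rs = 2·ΔMT/(w₁+w₂)) is scored as

```
E = mean(min(Rsᵢ, 1.5)) · P
P = ( Σⱼ Rsⱼ² / m )^1.25   over the m values with Rs < 1;  P = 1 if m = 0
```

E ranges from 0 (total co-elution) to 1.5 (all pairs at or beyond baseline
resolution): capping stops over-resolved pairs from masking bad ones, and
the quadratic penalty punishes any under-resolved pair. When every Rs ≥ 1,
E is exactly the mean of the capped resolutions.

Around the index, the package provides (one module each): peak
tables/electropherograms with detection, resolution, corrected peak area
(CPA = area/(60·MT)) and spectral-similarity identification; factor coding
and Fedorov-exchange D-optimal designs; quadratic RSM fits with ANOVA,
lack-of-fit, R²/adjusted/predicted R² (PRESS), Adequate Precision,
Shapiro–Wilk residual checks and hierarchy-preserving backward elimination
at p > 0.1; constrained maximization of the modeled E subject to a
last-analyte migration-time limit (default 15 min); calibration with
LOD/LOQ at S/N = 3/10 and repeatability RSDs; Pearson-distance hierarchical
clustering and PCA of species × metabolite matrices.

## Worked example

Score a run whose five critical pairs resolved at 1.5, 1.2, 0.9, 1.0, 1.3:

```
$ cesep score 1.5 1.2 0.9 1.0 1.3
E = 0.906751
P = 0.768433  (n = 5, m = 1)
```

One pair (0.9) is under-resolved, so the penalty P = (0.9²)^1.25 ≈ 0.768
pulls E below the capped mean of 1.18.

Simulate a full campaign and run the pipeline (25-run D-optimal design with
5 replicates, quadratic models for Rs1–Rs5, E and MT, refinement at p > 0.1,
then constrained optimization):

```
$ cesep simulate --seed 7 --outdir sim
$ cesep run --design sim/design.csv --responses sim/responses.csv --out report.json
optimum: {'boric_acid': 42.79, 'doc': 77.14, 'meoh': 16.47, 'ph': 9.23}  predicted E = 1.2737
```

The reported optimum is the buffer composition (boric acid mM, DOC mM,
MeOH %, pH) maximizing the fitted E surface while the fitted last-analyte
migration time stays ≤ 15 min; `report.json` carries every model's
coefficients, ANOVA, fit statistics and health flags.

Library use mirrors the CLI:

```python
from cesep import (FactorSpace, ModelSpec, build_candidate_set, d_optimal,
                   default_n_runs, make_truth, simulate_doe_responses,
                   PipelineConfig, run_pipeline)

fs = FactorSpace.default()            # boric 20-60 mM, DOC 30-100 mM, MeOH 0-25 %, pH 9.0-9.6
spec = ModelSpec.full_quadratic(fs.names)
design = d_optimal(build_candidate_set(fs), default_n_runs(spec), spec,
                   n_replicates=5, seed=0)
design.factor_space = fs
truth = make_truth(seed=7, fs=fs)
responses = simulate_doe_responses(truth, design, seed=8)
report = run_pipeline(PipelineConfig(), design, responses=responses)
```

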
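# Methods

This note records the models, parameter choices and numerical decisions
behind `chromasense`, and what its tests do and do not demonstrate.

## The monitoring problem

Optical density at 600 nm is linear in yeast cell concentration only in
a narrow absorbance window (0.1–0.65 here), so a reference measurement
dilutes dense suspensions by the smallest admissible factor, reads the
diluted aliquot three times, and reports the dilution factor times the
mean read. The sensing side replaces the spectrophotometer with a 4×3
colorimetric dye array whose 36 pre/post-exposure ΔRGB components form
the predictor vector. The analysis regresses ΔRGB onto OD with a small
neural network and asks which of the 36 components are worth
manufacturing — a wrapper feature-selection problem solved with ant
colony optimization and a cross-run selection-frequency protocol.
Cell concentration itself is never computed; OD is the target
throughout, as the reference method reports it.

## Synthetic study design

No raw data accompany the study design this package emulates, so
`chromasense.synthetic` generates datasets with the statistical
structure the analysis assumes. What it emulates, and how:

- **Growth.** OD(t) = baseline + K/(1+exp(−r(t−t₀))), a logistic batch
  curve. Defaults (K = 9.118, r = 0.22 h⁻¹, t₀ = 30 h, baseline 0.001)
  are calibrated so one 0–72 h culture spans OD 0.001–9.12, the range
  the emulated study covers. Only the range is matched; the time course
  itself is the standard batch-culture shape, not a fitted model.
  Batch-to-batch variability is a small lognormal jitter on K (2%) and
  r (8%) and ±1.5 h on t₀ — enough that batches differ but every batch
  still sweeps the full range.
- **Reference OD.** Dilution ladder {1, 2, 5}×10ᵏ, smallest factor
  bringing the read at or below 0.65; samples already below 0.1 are
  reported undiluted, since dilution cannot raise a low read. Read
  noise sd 0.005 OD per read, three reads averaged — a realistic
  bench-spectrophotometer repeatability.
- **Sensor response.** Component c responds
  coef_c · OD/(OD + K_m) + N(0, σ²), a saturating Michaelis-type link
  (K_m = 1.5 OD) with additive Gaussian pixel noise (σ = 2 gray
  levels, typical 8-bit camera noise). The default response has two
  strongly informative components, FTPPFeCl:B (+60 gray levels at
  saturation) and MTPPTE:B (−45), two weakly informative ones,
  TPPMnCl:B (+12) and BTB:B (−10), and 32 pure-noise components;
  `ResponseModel.two_component()` keeps only the strong pair. The
  saturating link bounds responses inside 8-bit range and makes them
  monotone in concentration.
- **Images.** Each sample can be rendered as a pre/post image pair:
  flat discs (radius 22 px on a 300×400 canvas, centers on a 100-px
  grid) of fixed per-dye base colors with ±1.5 gray-level jitter, the
  post image adding the integer-rounded ΔRGB. This is deliberately the
  exact inverse of the extraction contract, so the imaging stage is
  testable end to end.

What the generator does **not** emulate: correlated drift between dye
spots (temperature, humidity, illumination), spot shape irregularity,
camera optics, or any mechanistic VOC chemistry. Passing tests
therefore show that the pipeline recovers structure of this idealized
kind; they do not certify performance on real sensor images, where
non-informative channels drift in correlated ways that make both
regression and selection harder.

## Feature extraction

Channel-max grayscale → 3×3 median filter → global Otsu threshold →
morphological opening then closing with a radius-3 disc. The operation
sequence is fixed; the sizes are free parameters exposed in
`ExtractionConfig`. Spot centers are connected-component centroids
ordered row-major; if the component count differs from 12 (weak spots
can vanish at thresholding), each layout-hint center takes the nearest
detected centroid within the render radius or falls back to the hinted
position. ROI membership is the inclusive disc over integer pixel
centers, (x−cx)² + (y−cy)² ≤ r² with r = 15 — chosen for exactly
reproducible pixel counts, and tested against brute-force enumeration.
The sign convention is Δ = after − before, recorded in output metadata;
the min–max-normalized |Δ| map exists for visualization only and is
never a model input, since normalization across components destroys the
signed, scaled information the regressor needs.

## BPNN regressor

One sigmoid hidden layer (10 neurons) into a linear output node. The
output is linear because the target spans ~9 OD units; a sigmoid output
could not represent it without target rescaling. Inputs are min–max
scaled to [0, 1] on calibration ranges (raw ±255 gray-level differences
would saturate the hidden layer); the target stays on its natural
scale. Weights initialize uniform in ±0.3, thresholds at zero.

Training is classic sequential back-propagation: one gradient step with
momentum after every sample, in fixed presentation order, which keeps
training deterministic given the seed. Full-batch updates were tried
first and converge far too slowly at the fixed learning rate of 0.1 to
be usable (R² ≈ 0.97 where ≥ 0.99 is required of a representable map).
The tracked error is E = mean over samples of ½(Ô−y)², so the stopping
goal of 0.01 is sample-size independent; training stops at E ≤ 0.01 or
1000 epochs. Divergence (non-finite E) raises with the epoch index.
The per-epoch trace also carries the cumulative error term that the
classic formulation books between iterations; it plays no role in the
updates. Analytic gradients are verified against central differences
(relative error < 10⁻⁴, typically ~10⁻⁸) on random small networks.

## ACO feature selection

Encoding: each of the 36 components is a node with two states, include
and exclude (Λ = {include, exclude}); pheromone τ and visibility η live
on (component, state) pairs; an ant samples every component's state
independently with p ∝ τ^α η^β and its path is the subset mask. At
least one component is always forced in.

Scoring: a BPNN is trained on the calibration samples restricted to the
mask (one training seed per run, so every subset evaluation within a
run is deterministic and memoizable) and the subset cost is
BestCost = 0.75·mean|e_cal| + 0.25·mean|e_val|. The validation set
inside the objective leaks the validation batches into selection; it is
implemented as specified, with the weights configurable.

Updates: every ant deposits Q/BestCost (Q = 1, ε-guarded at 10⁻¹²) on
the states it chose; pheromone then evaporates. The printed update rule
multiplies old pheromone by ρ = 0.05 itself, i.e. 95% loss per
iteration, which contradicts the usual meaning of an evaporation
coefficient; the default is the conventional (1−ρ)·τ rule and a
`literal` mode preserves the printed rule exactly. τ is floored at
10⁻⁶ so selection probabilities stay defined. The best-so-far solution
is tracked elitistically; the convergence iteration is the last
improving the best cost by more than 10⁻⁶.

Visibility is the one genuinely open design choice. With uninformative
(uniform) η, every component starts at p(include) = 0.5, every
evaluated subset has ~18 components, and the elitist minimum is won by
large subsets: their wrapper costs have several times the variance of
lean subsets (more weights, more initialization-dependent fits), and at
long training the 0.75 calibration weight actively rewards their
overfitting. Measured on the default design, informative-pair recovery
then fails in every replicate. The default is therefore the
correlation-based visibility: η(include) = |Pearson r(component, OD)|
on the calibration set, η(exclude) = 1 − |r|, both floored at 0.01.
This aims the initial search at plausibly informative components — the
standard role of heuristic desirability in ant systems — after which
pheromone does the fine discrimination; recovery then succeeds in
10/10 replicates. Uniform visibility remains available, and the
pure-pheromone engine (`run_on_costs`) uses it by default, which is
also how the exhaustive-enumeration oracle test runs.

The frequency protocol repeats the optimization from seeds
base+1…base+n (50 in the full protocol) and counts how many best
subsets include each component; thresholding the counts (25/20/15 of 50
in the full protocol, scaled proportionally in reduced runs) gives
nested component sets, each then re-evaluated by refitting the BPNN 50
times from fresh seeds and summarizing Rc², RMSECV, Rp², RMSEP.

## Evaluation conventions

Splits are always by whole culture batch — samples within a batch share
a growth trajectory, so a within-batch split would leak batch identity.
"RMSECV" is the calibration-set error of the single fitted model; no
k-fold scheme is implemented because the protocol fixes one
calibration/validation partition. Run summaries report mean, sample
(n−1) variance and sd, so either convention of a "mean ± spread" table
can be read off.

## Problem sizes and determinism

Test and acceptance runs use reduced scales chosen as the package's
own desk-scale defaults: selection-time BPNN trainings cap at 200
epochs (costs at 200 epochs rank subsets the same way as longer
training, without its overfitting pathology under the 0.75/0.25
objective), recovery experiments use 10 ants × 30 iterations × 10 runs,
and the reduced end-to-end study uses 10 runs with thresholds 5/4/3 of
10. The full protocol scale (20 ants, 100 iterations, 50 runs,
thresholds 25/20/15, 1000-epoch refits) is the default of
`PipelineConfig` and runs unchanged, just longer. Every stochastic
stage takes an explicit seed; pipeline bundles are byte-identical
across reruns of the same config and seed, and record the config hash.

## Known limitations

- The generator's non-informative components are iid noise; real dye
  cross-sensitivity is correlated, and selection on real arrays will be
  harder than these tests suggest.
- The BestCost objective's use of the validation set inside selection
  is faithful to the protocol but optimistic; an honest generalization
  estimate needs a third, untouched test set.
- The BPNN is deliberately minimal (no regularization, no early
  stopping on held-out loss, single output); it is the protocol's
  model, not a recommendation.
- OD above ~6 sits deep in the response saturation, where feature noise
  maps to large OD uncertainty; prediction errors concentrate there.
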
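# chromasense

Colorimetric sensor-array analysis for monitoring cell concentration in
batch yeast (*Saccharomyces cerevisiae*) culture.

A 4×3 array of chemo-responsive dyes — eleven porphyrins and one pH
indicator — changes color when exposed to the volatile compounds above a
culture. Imaging the array before and after exposure and averaging the
R, G, B gray levels inside a 15-px circular region of each spot yields
12 spots × 3 channels = 36 signed color differences (ΔR, ΔG, ΔB) per
sample: an odor fingerprint that tracks the optical density (OD₆₀₀) of
the culture, the standard proxy for cell concentration. Because dye
spots are cross-sensitive and expensive, only a few of the 36 components
carry real information; finding that subset means a cheaper sensor with
no loss of accuracy.

`chromasense` implements that whole analysis as a tested Python package:

- **`chromasense.synthetic`** — a generator for the full study design
  (8 culture batches × 19 time points at 0–72 h, OD spanning
  0.001–9.12 with the dilution bookkeeping of spectrophotometry, and
  renderable pre/post sensor-image pairs), so every stage is testable
  with known ground truth.
- **`chromasense.features`** — image preprocessing (median filter, Otsu
  threshold, morphological opening/closing), spot localization, and
  ΔRGB feature extraction with an exact circular-ROI mean.
- **`chromasense.bpnn`** — `BPNNRegressor`, a scikit-learn estimator:
  one sigmoid hidden layer (10 neurons) into a linear output,

  H_j = σ(Σᵢ w_ij xᵢ − θ_j),  Ô = Σⱼ H_j w_j − b,

  trained by sequential back-propagation with learning rate η = 0.1,
  momentum 0.1, initial weights uniform in ±0.3, error goal
  E = ½·mean(Ô−y)² ≤ 0.01, at most 1000 epochs.
- **`chromasense.aco`** — `ACOFeatureSelector` and a functional API:
  ant-colony-optimization wrapper selection over the 36 components.
  Each component is an include/exclude node; ant k picks states with
  probability p ∝ τ^α η^β, its subset is scored by a freshly trained
  BPNN through the weighted absolute-deviation objective

  BestCost = 0.75 · mean|e_cal| + 0.25 · mean|e_val|,

  and pheromone evaporates (ρ = 0.05) and is reinforced by Q/BestCost
  deposits (20 ants, 100 iterations, τ₀ = 1, α = β = 1 by default).
  Repeated seeded runs give a per-component selection-frequency table;
  thresholding it yields the final sensor component sets.
- **`chromasense.evaluation`** — batch-complete calibration/validation
  splitting (first 6 of 8 batches calibrate: 114/38 samples), Rc²/RMSECV
  and Rp²/RMSEP metrics, and mean/variance summaries over repeated runs.
- **`chromasense.pipeline` + `chromasense` CLI** — the end-to-end study
  (simulate → extract → split → select → case comparison) from one YAML
  config and seed, with byte-identical reruns.

## Worked example

```python
import numpy as np
import chromasense as cs
from chromasense import aco
from chromasense.bpnn import TrainConfig

# 8 culture batches x 19 time points -> 152 samples, 36 color features
frame = cs.synthetic.dataset_to_frame(cs.generate_dataset(8, seed=0))
split = cs.split_by_batch(frame, n_cal_batches=6)
print(f"{len(frame)} samples: {len(split.calibration)} calibration / "
      f"{len(split.validation)} validation")

# 10 seeded ACO runs, each scoring subsets with a freshly trained BPNN
results, freq = aco.repeat_runs(
    split, aco.ACOConfig(n_ants=10, max_iterations=30),
    TrainConfig(max_epochs=200), n_runs=10, base_seed=0)
order = np.argsort(-freq.counts)
for i in order[:4]:
    print(f"{cs.FEATURE_NAMES[i]:<12} selected in {freq.counts[i]}/10 runs")
best = min(results, key=lambda r: r.best_solution.cost)
print(f"best BestCost {best.best_solution.cost:.4f} "
      f"(converged at iteration {best.convergence_iteration})")

# refit the regressor on the two most frequently selected components
comps = sorted(order[:2])
Xc, yc = split.xy("calibration"); Xv, yv = split.xy("validation")
est = cs.BPNNRegressor(random_state=0).fit(Xc[:, comps], yc)
print(f"Rc2 {cs.r2(yc, est.predict(Xc[:, comps])):.4f}  "
      f"RMSEP {cs.rmse(yv, est.predict(Xv[:, comps])):.4f}")
```

prints

```
152 samples: 114 calibration / 38 validation
FTPPFeCl:B   selected in 10/10 runs
MTPPTE:B     selected in 10/10 runs
TPPMnCl:B    selected in 7/10 runs
BTB:B        selected in 4/10 runs
best BestCost 0.3305 (converged at iteration 0)
Rc2 0.9821  RMSEP 0.4489
```

The two strongly informative dye/channel components built into the
default synthetic design (FTPPFeCl:B and MTPPTE:B) are selected in every
run, the two weakly informative ones appear at intermediate frequency,
and a 2-component regressor already explains 98% of the calibration
variance with a validation error of ~0.45 OD units.

The same study runs from the shell:

```sh
chromasense simulate --n-batches 8 --seed 0 --out dataset.csv
chromasense select --features dataset.csv --runs 10 --ants 10 \
    --iterations 30 --out runs.json --freq-out frequency.csv
chromasense report --out study/        # full pipeline + case comparison
```

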
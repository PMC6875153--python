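# stngrad

Is protein expression in the human subthalamic nucleus (STN) organized into
discrete functional territories, or does it change gradually across the
nucleus?  `stngrad` implements the quantitative pipeline for answering this
from 3D reconstructions of immunostained serial sections: it rasterizes a
masked staining volume into equal-volume sectors along anatomically defined
axes, tests whether sector patterns are consistent across specimens, and
then asks which of four spatial models best describes each specimen/marker
combination.

It is aimed at neuroanatomists and imaging methodologists who have
densitometric 3D maps (stained-pixel counts in a nucleus mask) for several
specimens and markers — or who want to study the behavior of this model
comparison on simulated data, which the package generates itself.

## The model family

Sector counts `y` are modeled as negative-binomial (gamma–Poisson) with
dispersion `α` (variance `μ + μ²/α`; Poisson as `α → ∞`) and a log-linear
spatial mean over normalized sector coordinates `x₁, x₂, x₃` (rostrocaudal,
and two PCA-derived in-plane axes):

- **A — homogeneous**: `μ = exp(λ₀)`
- **B — linear gradient**: `μ = exp(λ₀ + λ₁x₁ + λ₂x₂ + λ₃x₃)`
- **C — three subdivisions**: locations project onto a fitted axis
  `p = β₁x₁ + β₂′x₂ + β₃′x₃` (simplex weights, `β₂′ = β₂(1−β₁)`,
  `β₃′ = 1−β₁−β₂′`); sectors below boundary `τ₁` get offset `λ₁` and above
  `τ₂` get `λ₂`: `μ = exp(λ₀ + λ₁d₁ + λ₂d₂)`
- **D — sigmoidal gradient**: the two steps become logistic ramps with
  smoothness `κ`:
  `μ = exp(λ₀ + λ₁σ(κ(τ₁−p)) + λ₂σ(κ(τ₂−p)))`

Each model is fitted by maximum likelihood with differential evolution
(population 20× the parameter count, up to 5000 generations) plus a bounded
local refinement, and the models are compared by BIC and BIC weights
(`wBIC = exp(−ΔBIC/2)/Σexp(−ΔBIC/2)`); the preferred model of a cell is the
lowest-BIC one.

The coarse 3×3×3 stage standardizes each specimen's 27 sectors (mean 0,
SD 1) and runs per-sector one-sample t tests across specimens with
Benjamini–Hochberg FDR correction at q < 0.05.

## Worked example

```python
import numpy as np
from stngrad import (ModelParams, SectorGrid, compare_models, FitOptions,
                     sector_center_coords, simulate_intensities)

truth = ModelParams("B", lambda0=3.0, alpha=10.0,
                    lambda1=1.0, lambda2=-1.0, lambda3=1.5)
rec = sector_center_coords((10, 10, 10))
rec["y"] = simulate_intensities(truth, rec[["x1", "x2", "x3"]].to_numpy(), 42)
rec["included"] = True
grid = SectorGrid("S1", "TH", (10, 10, 10), rec)

row = compare_models(grid, seed=1, options=FitOptions(maxiter=60))
print(row["preferred"])
print({m: round(b, 1) for m, b in row["bic"].items()})
fit = row["fits"]["B"].params
print(round(fit.lambda1, 2), round(fit.lambda2, 2), round(fit.lambda3, 2))
```

prints

```
B
{'A': 9532.7, 'B': 8217.4, 'C': 8937.2, 'D': 8725.5}
0.99 -0.98 1.5
```

— the linear-gradient model wins by more than 500 BIC points over the
nearest alternative on data simulated from a linear gradient, and the
fitted gradient weights recover the generating values (1.0, −1.0, 1.5) to
two decimals.

The same workflow is available as a CLI
(`stngrad simulate | preprocess | sectorize | consistency | fit | compare |
tally`, or `stngrad run` for the whole pipeline on a simulated study).

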
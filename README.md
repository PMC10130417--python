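# vpikit

Quantitative single-vesicle TIRF imaging of vesicle–protein interactions
(VPIs): the binding of intact membrane vesicles (extracellular vesicles,
cell-derived vesicles, proteoliposomes) to cell-surface proteins displayed
on a coverslip, measured one vesicle at a time.

`vpikit` is aimed at single-molecule biophysicists and EV researchers who
count fluorescently labelled vesicles docking onto protein-decorated
surfaces and want to turn those counts into equilibrium constants. It
provides the full analysis chain — and a matched synthetic-data generator
with known ground truth, so every stage can be validated end to end:

- **Synthetic data** (`vpikit.synthetic_data`): spatial-Poisson protein
  surfaces, model-driven vesicle docking, diffraction-limited image
  rendering with shot/read noise and spectral bleed-through, stepwise
  photobleaching traces, and named fixture bundles (TIFF + CSV + JSON).
- **Spot analysis** (`vpikit.spot_analysis`): frame averaging, local-maxima
  detection with sub-pixel 2-D Gaussian refinement, total-intensity
  measurement, and threshold-based VPI counting (one spot above threshold =
  one vesicle, independent of brightness).
- **Calibration** (`vpikit.calibration`): spots are countable only up to
  ~1 spot/μm² (diffraction limit), so a linear intensity-vs-density
  calibration built in the resolvable regime converts dense-field
  fluorescence into molecular densities, with a self-quenching diagnostic.
- **Photobleaching** (`vpikit.photobleaching`): changepoint-based step
  counting to estimate fluorophores per spot (monomer/multimer verdicts).
- **Colocalization** (`vpikit.colocalization`): crosstalk estimation from
  pure-species fields, per-pixel linear unmixing, one-to-one spot matching
  with the analytic chance baseline 1 − exp(−ρπr²), fold-enrichment, and
  per-class vesicle-bound fractions.
- **Binding models and inference** (`vpikit.binding_models`,
  `vpikit.inference`): model fitting, AICc model selection, bootstrap
  confidence intervals, and parameter-recovery experiments.

## The adsorption models

For protein surface density ρ (molecules/μm²) and free vesicle
concentration V, the bound-vesicle density N_b (vesicles/μm²) is modelled
either as simple **Langmuir adsorption** on independent sites,

    N_b = α · ρ · V / (V + K_d),

or by a **density-dependent cooperation model**: proteins placed at random
form paired sites whenever a neighbour lies within a geometric reach *d*
(set by the vesicle's contact footprint, default 0.1 μm). On a Poisson
field the site densities are

    s₁ = ρ·e^(−λ),   s₂ = ρ·(1 − e^(−λ))/2,   λ = ρπd²,

with s₁ + 2s₂ = ρ exactly, and

    N_b = α·[ s₁·V/(V + K_d,1) + s₂·V/(V + K_d,2) ].

With K_d,2 ≪ K_d,1 the pair term grows super-linearly in ρ (log–log slope
approaching 2), which is the signature distinguishing cooperative vesicle
capture from simple adsorption. Hill curves for vesicle-concentration
dependence, sigmoidal IC50 inhibition, and single-exponential binding
kinetics round out the model set.

## Worked example

Generate a cooperative binding curve under realistic assay conditions
(vesicle stock 2×10⁹ particles/ml, densities 0.5–40 molecules/μm², five
replicates, 10% measurement noise), then let the package decide which
adsorption model the data support:

```python
import numpy as np
from vpikit import (generate_binding_table, select_model,
                    CooperativeParams, particles_per_ml_to_pM)
from vpikit.synthetic_data import DENSITY_GRID

V = particles_per_ml_to_pM(2e9)          # vesicle stock, pM
print(f"vesicle concentration: {V:.2f} pM")

rng = np.random.default_rng(0)
truth = CooperativeParams(K_d1=130.0, K_d2=0.09, d=0.1, alpha=0.1)
curve = generate_binding_table(truth, DENSITY_GRID, x_kind="density",
                               n_rep=5, cv=0.10, vesicle_conc_pM=V, rng=rng)

comparison = select_model(curve, alpha=0.1, seed=0)
print(f"selected model: {comparison.selected}  (delta AICc = {comparison.delta_aicc:.1f})")

fit = comparison.fits["cooperative"]
print(f"K_d1 = {10**fit.params['log10_Kd1_nM']:.0f} nM, "
      f"K_d2 = {10**fit.params['log10_Kd2_nM']:.3f} nM")
```

Output:

```
vesicle concentration: 3.32 pM
selected model: cooperative  (delta AICc = 39.3)
K_d1 = 105 nM, K_d2 = 0.092 nM
```

The particle-to-molar conversion shows why picomolar vesicle stocks need
dense protein surfaces; the AICc comparison rejects simple adsorption by a
wide margin, and the two equilibrium constants come back close to the
generator truth — K_d,2 (the paired-site constant) is pinned tightly, while
K_d,1 is softer because isolated sites contribute only a few percent of the
binding signal at picomolar vesicle concentrations.

A command-line interface mirrors the library:

```bash
vpikit simulate --scenario nk-like-cooperative --seed 1 --out fixture/
vpikit fit --curve fixture/binding_curve.csv --model cooperative \
       --vesicle-conc-pm 3.32 --alpha 0.1 --seed 0 --out fit.json
```

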
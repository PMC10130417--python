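# Methods

This note records the models implemented in `vpikit`, the defaults and why
they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical decisions a maintainer would want to know.

## Measurement model

A TIRF field of view is summarised by two complementary observables:

1. **Spot counts.** Diffraction-limited spots are detected on the average
   of the initial frames (default 10, matching typical acquisition at
   100-ms frames) as local maxima exceeding a threshold above the image
   median, then refined by least-squares 2-D Gaussian fits in a 7×7 px
   window. Counting is reliable only below ~1 spot/μm²; beyond that,
   neighbours merge under the point-spread function.
2. **Total intensity.** The background-subtracted, zero-floored pixel sum
   keeps growing linearly with density (fluorescent-protein labels show no
   self-quenching in this range — `check_linearity` tests that assumption
   on each dataset), so a line fitted to (measured spot density, total
   intensity) pairs in the resolvable regime converts dense-field
   intensities to molecular densities by extrapolation.

VPI counting is thresholded, not photometric: a detected spot whose
integrated intensity clears the threshold contributes exactly one count.
This makes the count invariant to labelling heterogeneity and robust to dim
contaminants, at the price of ignoring brightness information.

## Adsorption models

Site occupancy follows the equilibrium V/(V + K_d) with the vesicle
concentration V and K_d expressed in common molar units (internally pM;
constants are printed in nM). The equilibrium constants are *operational*:
they are formulated against vesicle concentration and surface-protein
density, not bimolecular protein–protein affinities.

The cooperation model partitions a spatial-Poisson protein field by a
geometric reach d: a molecule with no neighbour within d (probability
e^(−ρπd²)) is an isolated site with constant K_d,1; the rest are booked as
paired sites, s₂ = ρ(1 − e^(−ρπd²))/2, with constant K_d,2. The identity
s₁ + 2s₂ = ρ holds exactly. In the simulator the same geometry is realised
by greedy distance-ascending mutual pairing within d: the closest mutual
neighbours pair first, and leftover members of triplets or larger cliques
act as single sites. This keeps the generator and the fitted model
self-consistent; the analytic s₂ slightly overstates pairing inside dense
cliques, an O(λ²) effect that is negligible at the densities used here.

Defaults: d = 0.1 μm, the contact footprint implied by a ~140 nm median
vesicle diameter. d is fittable (`vary_d=True`, bounds 0.02–0.5 μm) but
fixed by default: at a single vesicle concentration it is strongly
confounded with K_d,2 (amplitude ∝ d²·V/K_d,2 at low density).

**Identifiability of the scale α.** The capture efficiency α multiplies
every site term. At a single V ≪ K_d the data constrain only α·V/K_d, so
fits treat α as known — in practice an experimentally calibrated constant —
and the recovery experiments pass the generator's α (0.1 in the named
scenarios, which puts bound-vesicle densities in the observed
10⁻²–10⁻¹ vesicles/μm² range) through to the fitter.

**Fitting.** Weighted nonlinear least squares (lmfit, Levenberg–Marquardt)
on replicate means with weights 1/SEM² when replicate scatter is available;
dissociation constants, IC50 and Hill midpoints are optimised in log space;
five seeded starts (log-spaced constants) guard against local minima; 95%
CIs come from resampling replicates and refitting from the point estimate.
Model selection uses AICc (k = free parameters + 1) and prefers the larger
model only when ΔAICc > 2; candidates with more free parameters than the
data can identify (fewer than k + 2 distinct x values) are dropped.

A precision note: with V ≈ 3.3 pM the isolated-site pathway of the
NK-like scenario (K_d,1 = 130 nM) carries at most ~8% of the binding
signal, and the Cramér–Rao bound on log₁₀K_d,1 under 10% replicate noise
is ≈ 0.25. Joint recovery of both constants to ±0.3 log₁₀ therefore
succeeds in only ~70–76% of runs no matter the estimator; K_d,2 by
contrast recovers to ±0.01 log₁₀. Pinning K_d,1 tightly requires either
higher vesicle concentrations or lower protein densities than the
cooperative assay regime provides.

## Synthetic data

The generator emulates a 60× TIRF setup with an sCMOS camera: 0.108 μm
pixels, isotropic Gaussian PSF with σ = 0.13 μm integrated over pixels via
error functions, 100-ms frames, camera offset 100 counts, Gaussian read
noise (sd 2 counts), per-frame Poisson shot noise, and linear spectral
mixing applied to the ideal photon images before noise. Emitter photon
budgets default to 500 counts/frame per fluorophore (a bright, GFP-like
setting used for calibration scenarios); detection-fidelity scenarios use
182 counts/frame, which puts the peak amplitude at 10× the read noise.
Per-vesicle label brightness is log-normal (σ_log = 0.3, mean 1), giving
the peaked-with-a-bright-tail intensity histogram seen in dye-labelled
vesicle preparations. Fixture scenarios render reduced 25.6-μm fields so
that full bundles stay light; the optics are unchanged.

All randomness derives from one integer seed through
`numpy.random.SeedSequence` substreams; identical (config, seed) pairs are
bit-identical, and fixture manifests carry SHA-256 checksums.

Deliberately **not** modelled: lateral diffusion of proteins or vesicles,
evanescent-field depth, stage drift, fluorophore blinking, vesicle size
dispersion beyond the brightness factor, and steric competition between
vesicles for nearby sites. Passing tests on this generator therefore
validate the analysis chain (detection, calibration, unmixing, counting,
fitting) under idealised optics; they do not certify performance on real
data with drift, uneven illumination, or autofluorescent backgrounds.

Scenario parameters (binding): vesicle stock 2×10⁹ particles/ml (3.32 pM),
protein densities {0.5, 1, 2, 5, 10, 20, 40} molecules/μm², 5 replicates,
10% multiplicative measurement noise per replicate. The Langmuir scenario
uses K_d = 0.25 nM; the cooperative scenario K_d,1 = 130 nM,
K_d,2 = 0.09 nM, d = 0.1 μm. The calibration ladder spans
0.01–40 molecules/μm² with six levels at or below 0.25/μm² reserved for the
calibration line (see below). The inhibition scenario uses IC50 = 1 μM,
Hill slope 1, floor 0.005 and plateau 0.06 vesicles/μm², doses
0.01–100 μM.

## Numerical choices

- **Spot detection.** Threshold default 5× the robust noise sd
  (1.4826 × MAD) above the image median; local-maximum suppression and the
  pairwise minimum separation both default to 2 px. A 3-px radius was
  rejected: it merges genuinely resolvable neighbours out to 0.32 μm,
  deflating measured spot densities by ~14% already at 1 spot/μm² and
  visibly biasing the calibration slope. Gaussian fits are accepted when
  the centre moves ≤ 2 px and σ stays within [0.5, 3]× the nominal PSF;
  plateau ties break toward the lexicographically smallest (row, col).
  Sub-pixel RMSE is < 0.25 px at SNR ≥ 10.
- **Calibration.** Levels above 1 spot/μm² are always excluded (hard cut);
  the shipped ladder keeps its calibration levels at ≤ 0.25/μm² because
  PSF merging already removes ~10% of maxima at 0.5/μm² and ~25% at
  1/μm², which would propagate into the slope. Weights are inverse
  replicate variances of the level means, with an OLS fallback; the
  intercept is fitted (not forced through zero) to absorb camera offset
  and clipping bias. Background for total-intensity measurements must come
  from a blank field; on dense fields the image median is
  signal-contaminated. The round trip density → image → intensity →
  density is accurate to better than 10% across 0.1–40/μm²; the residual
  ~5–7% systematic comes from diffraction merging inside the calibration
  levels.
- **Photobleaching.** Binary segmentation on a piecewise-constant model;
  penalty 3σ̂²·ln n per changepoint with σ̂ from the robust scale of first
  differences (exact-RSS splits when σ̂ = 0, so noiseless staircases are
  recovered exactly); minimum segment 2 frames. Steps are downward level
  changes exceeding half the median |level change|. Re-brightening or a
  net upward trend flags the trace `non_bleaching` instead of producing
  negative steps. Two fluorophores bleaching within the same frame are
  counted once — an SNR-independent error floor of a few percent at the
  default bleach rate (1/6 s⁻¹, 400 frames at 100 ms).
- **Colocalization.** Match radius default 0.216 μm (2 px), one-to-one
  greedy matching by ascending distance with index tie-breaks, so the
  matched count is reference-independent. The chance fraction
  1 − exp(−ρπr²) is reported alongside, never subtracted, keeping
  fractions comparable to raw experimental numbers. Crosstalk unmixing
  inverts the bleed matrix on background-subtracted pixels and floors
  negatives at zero.
- **Degenerate inputs.** Constant images, rank-deficient calibrations,
  non-positive slopes, single-class intensity comparisons, and
  monotone-increasing "inhibition" curves are rejected or flagged rather
  than silently fitted.

## Known limitations

- Exactly two site classes: triplets and larger clusters are collapsed to
  one pair plus singles. Avidity beyond pairwise cooperation is out of
  scope.
- The channel registration between colour channels is assumed perfect (the
  simulator emits pre-registered channels); a rigid-offset registration
  hook is left to future work.
- Kinetic analysis covers a single-exponential approach to equilibrium
  only; no rebinding or depletion effects.
- The intensity-threshold VPI count discards brightness information that
  could, in principle, separate single vesicles from aggregates; the
  photobleaching module covers stoichiometry for surface proteins instead.
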
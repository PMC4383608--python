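# Methods

## Reconstruction model

Each respiratory phase is reconstructed independently by solving

    min_u (1 − α)‖∇u‖₁ + α‖T₂(u − u_p)‖₁
    s.t.  ‖F u − f‖₂ ≤ σ,  u ≥ 0,  u ∈ Ω

* `u` — attenuation image (1/mm) on a square grid;
* `F` — discrete 2-D parallel-beam projector;
* `f` — measured line integrals for this phase;
* `σ` — noise bound on the data misfit;
* `u_p` — prior image (all phases combined, Gaussian-smoothed);
* `α` — prior weight: α = 0 is plain constrained-TV compressed sensing,
  α → 1 trusts the prior entirely;
* `T₂` — identity, gradient or orthonormal symmlet-8 wavelet;
* `Ω` — circular field of view inscribed in the grid.

The model assumes a monoenergetic Beer–Lambert acquisition (no scatter,
beam hardening or detector blur), parallel-beam geometry on a single
axial slice, and phase-independent anatomy within each gate.

### Split Bregman iteration

Auxiliary variables `(d_x, d_y) = ∇u`, `w = T₂(u − u_p)` and `v = u`
(for the positivity/support set) decouple the non-smooth terms. One outer
sweep performs:

1. **Quadratic step.** Solve `K u = r` with
   `K = μFᵀF + λ(DₓᵀDₓ + DᵧᵀDᵧ) + λT₂ᵀT₂ + γI` and the right-hand side
   assembled from the current auxiliary and Bregman variables. `K` is
   symmetric positive definite (γ > 0), so a matrix-free conjugate
   gradient is used, started from zero, with relative-residual tolerance
   δ and an iteration cap (30). At δ = 10⁻², 4–9 CG iterations per sweep
   are typical. (A transpose-free BiCGStab would solve the same system;
   CG is used because symmetry is guaranteed by the matched projector
   pair.)
2. **Shrinkage.** Isotropic shrinkage of `(∇u + b)` at threshold
   `(1 − α)/λ`; scalar soft shrinkage of `T₂(u − u_p) + b_w` at `α/λ`.
   Pixels with zero gradient magnitude map to zero (the limit value).
3. **Projection.** `v = max(u + b_v, 0)`, zeroed outside Ω.
4. **Bregman updates.** Each Bregman vector accumulates its constraint
   residual; the working data accumulate the data misfit,
   `f^{k+1} = f^k + f − F u^{k+1}`, applied every outer sweep.

Initialisation: zero image and zero auxiliary/Bregman variables; working
data start at the measured (normalised) data.

### Scaling conventions (load-bearing)

Two normalisations make one parameter set work across dose levels and
problem sizes:

* **Data normalisation.** `f → f / ‖f/n‖₂` with `n = √(pixel count)`;
  the returned image is scaled back. σ and the prior are scaled
  consistently.
* **Operator normalisation.** Inside the solver, `F` is rescaled to unit
  spectral norm (power iteration on FᵀF, deterministic start). This
  leaves the constrained problem unchanged — it solves for a rescaled
  image — but is what makes the conventional weights meaningful: the
  Split Bregman parameter folklore (μ ≈ 10, λ ≈ 1) comes from settings
  where the measurement operator is (sub)orthonormal. A raw CT projector
  has ‖F‖² of order 10³–10⁴, and with it μFᵀF swamps the splitting terms:
  the iterates behave like barely-regularised least squares for tens of
  sweeps and the shrinkage never acts at the right scale. With unit-norm
  F the solver reproduces the expected behaviour (strong prior
  anchoring, TV denoising, data enforcement) at the default parameters.

### Parameters

| name | default | meaning / why |
|------|---------|---------------|
| α | 0.8 | prior weight; the retained operating point of the study design (0.2/0.5 give progressively more TV-like texture) |
| μ | 10 | data weight; results are insensitive for sufficiently small μ, larger μ converges in fewer sweeps |
| λ | 1 | splitting weight; sets the shrinkage thresholds (1−α)/λ and α/λ |
| γ | 0.1 | constraint-set weight; small values preferred, large ones impair convergence |
| δ | 10⁻² | CG relative-residual tolerance; 10⁻² accelerates convergence, tighter values buy exactness at the cost of small residual oscillations |
| max outer sweeps | 50 (solver), 250 (experiment runner) | oracle-stopped runs settle between ~40 and ~220 sweeps depending on dose |
| T₂ wavelet levels | 4 | symmlet-8, periodised; grids not divisible by 2⁴ are symmetrically zero-padded (the pad lies outside Ω and is inert) |

Stopping rules: `discrepancy` (‖Fu − f‖ ≤ σ, with σ estimated from the
counts unless given), `fixed_iters`, or `oracle_mse` — return the iterate
with minimum MSE against a reference inside Ω. The experiment runner uses
`oracle_mse` against the noiseless phantom phase, mirroring the study
design of choosing the iteration with minimum error against a reference.

σ estimation: the variance of `−log(counts/I₀)` is ≈ 1/counts per ray, so
`σ² = Σ_rays 1/max(counts, 0.5)`; this matches the realised noise residual
to within ~1% in simulation.

## Projector

Joseph's ray-driven method: each ray steps along its dominant axis one
grid line at a time, linearly interpolating between the two straddled
pixels, weighted by the intersection length (mm). The operator is
materialised as a sparse CSR matrix per (grid, geometry) pair, so the
backprojector is the exact matrix transpose — this keeps `K` symmetric,
which the Krylov solve relies on. Detector: `ceil(√2·nx)` bins at pixel
pitch (no truncation); angles in degrees, counter-clockwise; image centre
at the grid centre.

FBP: frequency-domain ramp built from the band-limited spatial kernel
(correct DC handling), Hann-apodised by default (`ram-lak` available),
backprojected with the matched adjoint and scaled by `π/(n_angles·Δs)`
(divided by the pixel-area weight the adjoint carries). A noiseless
360-view disk reconstructs to ≈0.6% in-disk RMSE.

Discretisation note: projections of piecewise-constant objects show
angle-dependent edge aliasing of a few percent; rotation-consistency
checks therefore use smooth phantoms.

## Synthetic study generator

The generator emulates a gated rodent-thorax acquisition: 350×350 pixels
over a 70 mm field of view (0.2 mm pixels) by default, 360 candidate
angles over 360°, I₀ = 4.5·10⁴ photons per ray, 4 phases, 120/80/60
randomly subsampled projections per phase, and 0.5 mm peak lung motion.
Scaled-down runs (128 px, 0.547 mm pixels) keep the same physical
geometry. The phantom is procedural — ellipses in mm coordinates — so
region masks (soft tissue, lung, bone, vessel, nodule) are exact at any
resolution. Across phases only the lung fields and the intra-lung vessel
and nodule translate vertically (raised-cosine cycle: phases 0 and 2 of 4
differ by the full amplitude); the body outline and bone are static.
Attenuation values (1/mm): soft 0.025, lung 0.006, bone 0.065,
vessel/nodule 0.032 — plausible for ~30–40 keV micro-CT.

Counts are `Poisson(I₀·exp(−Fu))` per ray, independent across rays and
phases, from named seed streams (scenario seed × phase × purpose), so a
scenario is bit-reproducible. Line integrals are `−log(max(counts, 0.5)/I₀)`
(half-count floor for photon-starved rays).

The prior averages the per-phase FBP images (the pooled-sinogram variant
is available; the two differ when phase angle sets overlap) and smooths
with an isotropic Gaussian. The smoothing width is held at 1 mm physical —
5 pixels at the reference 350-px grid — across resolutions; interpreting
"5 pixels" literally at 128 px would smooth 2.7 mm and erase rat-scale
bone, an artifact of rescaling rather than a study condition.

What the generator does *not* emulate: cone-beam geometry and FDK, the
gating-signal binning of real acquisitions (32 frames per angle), detector
electronics noise, scatter/beam hardening, non-rigid motion and real
anatomical texture. Passing tests therefore demonstrate algorithmic
correctness and the direction and rough size of the dose/undersampling
trade-offs — not performance on real animal data.

## Evaluation

* MSE inside lung and bone masks against the noiseless phase image.
* Noise: coefficient of variation (sample sd / mean), averaged over three
  seeded oval ROIs auto-placed fully inside the soft-tissue mask. ROI area
  is fixed physically at 12.48 mm² (a 312-pixel oval at 0.2 mm pixels) so
  the statistic is comparable across grid sizes.
* CNR: |vessel mean − lung mean| / sd(soft-tissue ROI).
* Peak-to-valley of bilinear line profiles (ratio by default; difference
  mode available).
* Motion: displacement between per-phase profiles through the lung
  vessel — coarse cross-correlation peak (search within ±¼ profile
  length) refined by least-squares sub-sample fitting of the shifted,
  interpolated profile. Recovered displacement on reconstructions matches
  the programmed 0.5 mm to well within 0.1 mm.

The experiment runner reproduces the five-scenario grid — (I₀, I₀/2,
I₀/4) × 120 projections and (80, 60) projections × I₀ — with per-cell
seeds derived from a master seed, and writes images (float32 TIFF),
sinograms (HDF5), metrics and a manifest sufficient to recompute any cell.

## Design choices where the design was open

* **Gradient boundary.** Forward differences with replicate (Neumann)
  boundary — zero difference at the far edge — so DᵀD is the standard
  Neumann Laplacian and constants are in the TV null space.
* **Wavelet boundary.** Periodisation, preserving exact orthonormality
  (Parseval to 10⁻¹⁰); symmetric zero-padding for non-dyadic grids.
* **Isotropic shrinkage.** The common factor `max(s − t, 0)/s` is applied
  to both gradient components (the standard isotropic form); the (0,0)
  output at s = 0 is the limit value.
* **Output convention.** The returned image is the final `u` iterate
  clipped at zero and masked to Ω (the constraint set), in physical units.
* **FBP filter.** Hann default; this is deliberately favourable to the
  FBP baseline (a sharper ramp would be noisier), so the PICCS-vs-FBP
  improvement ratios reported here are conservative.

## Numerical behaviour and limitations

* The data-residual trace decreases monotonically in the undersampled
  regimes; TV-PICCS can show a single early bump of a few percent around
  sweeps 4–6 in well-sampled, high-flux configurations as the shrinkage
  variables first activate. Tight CG tolerances (δ ≤ 10⁻³) trade small
  late-stage residual oscillations for accuracy.
* With the oracle stop referenced to the *sharp* synthetic ground truth,
  reconstructions retain more noise than a stop referenced to a smooth
  high-dose reconstruction would: the stop favours edge fidelity. Two
  consequences observed on the scenario grid: soft-tissue CoV grows
  noticeably (≈70–90%) when going from 120 to 60 projections, and the
  CNR gain of PICCS over FBP is ≈3–6× rather than an order of magnitude.
  Both effects are properties of the scaled-down analogue (sharp
  reference, matched-projector 2-D FBP baseline on coarse pixels), not of
  the solver; the masked-MSE improvement ratios, which normalise by the
  same baseline, are large and stable.
* Bone-mask MSE of *any* FBP variant is dominated by edge discretisation
  on coarse grids, which is why even a 4×-dose, fully sampled FBP barely
  improves it while the iterative solver (which can fit the discrete
  model exactly) does.
* Problem sizes: tests and the acceptance script run the 128-px grid
  (five scenarios, three methods, ≈4 minutes end to end); the 350-px
  paper-scale grid runs through the same code paths (`--nx 350`) in a few
  minutes per reconstruction.
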
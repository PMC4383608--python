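# piccsct

Prior image constrained compressed sensing (PICCS) reconstruction for
respiratory-gated low-dose micro-CT, solved with the Split Bregman method.

## The problem

Retrospective respiratory gating sorts the projections of a small-animal CT
scan into breathing phases. At a dose comparable to a static scan, each
phase is left with few, noisy, irregularly spaced projections, and filtered
backprojection (FBP) of a single phase is dominated by streaks and noise.
All phases together, however, contain plenty of photons — they just blur
the moving lung. PICCS exploits this: a low-noise but motion-blurred
*prior image* u_p, built from all phases combined, anchors the
reconstruction of each individual phase.

For phase image u with data f, the reconstruction solves

    min_u  (1 − α)‖∇u‖₁ + α‖T₂(u − u_p)‖₁
    s.t.   ‖F u − f‖₂ ≤ σ,  u ≥ 0,  u ∈ Ω

where F is the forward projector, Ω the circular field of view, ∇ the
discrete gradient (isotropic total variation), α ∈ [0, 1] the prior
weight, and T₂ the prior-term sparsity transform — identity (L1-PICCS),
gradient (TV-PICCS) or an orthonormal symmlet-8 wavelet (WT-PICCS). The
constrained problem is solved with Split Bregman: auxiliary variables
decouple the L1 and L2 terms, the quadratic step is a matrix-free
conjugate-gradient solve of an SPD system, the L1 steps are closed-form
(isotropic/scalar) shrinkage, and Bregman vectors add the constraint
residuals back each sweep.

The package is self-contained: a `synthetic` study generator builds a
4-phase moving-thorax phantom (sub-millimetre lung/diaphragm motion,
static bone), simulates photon counts f ~ Poisson(I₀·exp(−∫u)) along each
ray, randomly subsamples the 360 candidate view angles per phase, and
constructs the prior (average of per-phase FBPs, Gaussian-filtered). A
metric suite scores reconstructions: peak-to-valley profile contrast,
coefficient of variation in soft-tissue ROIs, contrast-to-noise ratio of
lung vessels, masked MSE against the noiseless phantom, and inter-phase
profile displacement.

## Worked example

Reconstruct one gated phase at quarter flux (I₀/4 = 1.125·10⁴ photons/ray,
120 projections) on a 128-pixel grid and compare with FBP:

```python
import numpy as np
from piccsct import ScenarioSpec, simulate_scenario, solve_piccs, PICCSConfig
from piccsct.transforms import TransformChoice

spec = ScenarioSpec(i0=1.125e4, n_proj_per_phase=120, nx=128, seed=1002)
data = simulate_scenario(spec)          # phantom, noisy sinograms, prior
truth = data.phantom.phases[0]
bone = data.phantom.masks[0]["bone"]

fbp = data.projectors[0].fbp(data.sinograms[0].values)
cfg = PICCSConfig(alpha=0.8, t2=TransformChoice("wavelet"),
                  stop_mode="oracle_mse", max_outer_iter=250)
rec, report = solve_piccs(data.sinograms[0], data.prior, spec.grid, cfg,
                          reference=truth, projector=data.projectors[0])

mse = lambda img: np.mean((img[bone] - truth[bone]) ** 2)
print(f"stopped at iteration {report.stop_iteration}")
print(f"bone-mask MSE  FBP: {mse(fbp):.3e}   WT-PICCS: {mse(rec):.3e}")
print(f"MSE reduction: {100 * (mse(fbp) - mse(rec)) / mse(fbp):.1f}%")
```

Output:

```
stopped at iteration 44
bone-mask MSE  FBP: 8.626e-05   WT-PICCS: 1.524e-05
MSE reduction: 82.3%
```

The prior-anchored reconstruction removes most of the noise-driven error
in the (static) bone while still following the moving lung; the same
pipeline at α = 0 reduces to plain constrained-TV compressed sensing.

The equivalent shell workflow uses the `piccsct` CLI
(`piccsct simulate`, `piccsct reconstruct`, `piccsct evaluate`,
`piccsct run-all` for the full five-scenario dose/projection grid).

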
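import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from piccsct.errors import ConfigurationError, ContractViolationError, DegenerateInputError
from piccsct.grid import ImageGrid, ProjectionGeometry, Sinogram
from piccsct.projector import Projector
from piccsct.solver import (
    PICCSConfig,
    SolverState,
    bregman_update,
    normalize_data,
    positivity_support_project,
    shrink_isotropic,
    shrink_soft,
    solve_piccs,
    u_update,
)
from piccsct.transforms import GradientField, TransformChoice, grad, make_transform

from conftest import dense_matrix


# ---------------------------------------------------------------- shrinkage
@pytest.mark.parametrize(
    "x,t,expected",
    [(0.3, 0.5, 0.0), (2.0, 0.5, 1.5), (-1.2, 0.2, -1.0), (0.0, 0.0, 0.0)],
)
def test_shrink_soft_closed_form(x, t, expected):
    assert shrink_soft(np.array([x]), t)[0] == pytest.approx(expected)


def test_shrink_isotropic_closed_form():
    gx, gy = shrink_isotropic(np.array([3.0]), np.array([4.0]), 1.0)
    assert gx[0] == pytest.approx(2.4) and gy[0] == pytest.approx(3.2)
    gx, gy = shrink_isotropic(np.array([0.0]), np.array([0.0]), 0.7)
    assert gx[0] == 0.0 and gy[0] == 0.0
    gx, gy = shrink_isotropic(np.array([0.3]), np.array([0.4]), 0.5)
    assert gx[0] == 0.0 and gy[0] == 0.0  # t >= magnitude


def test_shrink_negative_threshold_rejected():
    with pytest.raises(ContractViolationError):
        shrink_soft(np.ones(3), -0.1)
    with pytest.raises(ContractViolationError):
        shrink_isotropic(np.ones(3), np.ones(3), -1.0)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    arrays(float, 16, elements=st.floats(-50, 50)),
    arrays(float, 16, elements=st.floats(-50, 50)),
    st.floats(0, 10),
)
def test_shrinkage_is_nonexpansive(x, y, t):
    assert np.linalg.norm(shrink_soft(x, t) - shrink_soft(y, t)) <= (
        np.linalg.norm(x - y) + 1e-9
    )
    ax, ay = shrink_isotropic(x[:8], x[8:], t)
    bx, by = shrink_isotropic(y[:8], y[8:], t)
    lhs = np.sqrt(np.sum((ax - bx) ** 2 + (ay - by) ** 2))
    rhs = np.sqrt(np.sum((x[:8] - y[:8]) ** 2 + (x[8:] - y[8:]) ** 2))
    assert lhs <= rhs + 1e-9


# ------------------------------------------------------------ normalization
def test_normalize_data_unit_cases(small_grid, small_geometry, rng):
    n = np.sqrt(small_grid.n_pixels)
    values = rng.normal(size=small_geometry.shape)
    values *= n / np.linalg.norm(values)
    sino = Sinogram(small_geometry, values, sigma=0.3)
    out, scale = normalize_data(sino, small_grid)
    assert scale == pytest.approx(1.0)
    np.testing.assert_allclose(out.values, values)
    # scale invariance: 10x data normalises to the identical sinogram
    out10, scale10 = normalize_data(
        Sinogram(small_geometry, 10 * values, sigma=3.0), small_grid
    )
    np.testing.assert_allclose(out10.values, out.values)
    assert scale10 == pytest.approx(10.0)
    assert out10.sigma == pytest.approx(out.sigma)


def test_normalize_rejects_zero_data(small_grid, small_geometry):
    with pytest.raises(DegenerateInputError):
        normalize_data(Sinogram(small_geometry, np.zeros(small_geometry.shape)), small_grid)


def test_reconstruction_scales_linearly_with_data():
    """De-normalised output of c*f equals c times the output of f."""
    grid = ImageGrid(32, 32, 1.0)
    geom = ProjectionGeometry.for_grid(grid, np.arange(0, 360, 10.0))
    proj = Projector(grid, geom)
    xx, yy = grid.coords()
    truth = ((xx**2 + yy**2) <= 100.0).astype(float)
    f = proj.forward(truth)
    cfg = PICCSConfig(alpha=0.0, stop_mode="fixed_iters", max_outer_iter=30,
                      t2=TransformChoice("gradient"))
    rec1, _ = solve_piccs(Sinogram(geom, f), np.zeros(grid.shape), grid, cfg, projector=proj)
    rec3, _ = solve_piccs(Sinogram(geom, 3.0 * f), np.zeros(grid.shape), grid, cfg, projector=proj)
    np.testing.assert_allclose(rec3, 3.0 * rec1, atol=1e-8 * rec3.max())


# ----------------------------------------------------------------- u-update
@pytest.fixture(scope="module")
def tiny_problem(rng):
    grid = ImageGrid(8, 8, 1.0)
    geom = ProjectionGeometry.for_grid(grid, np.arange(0, 360, 60.0))
    proj = Projector(grid, geom)
    t2 = make_transform(TransformChoice("gradient"), grid)
    return grid, geom, proj, t2


def _dense_K_and_r(grid, proj, t2, state, prior, cfg):
    """Assemble Eq-style K and r explicitly from the operators."""
    n = grid.n_pixels
    F = dense_matrix(lambda v: proj.forward(v.reshape(grid.shape)), n)

    def apply_D(vec):
        g = grad(vec.reshape(grid.shape))
        return np.concatenate([g.gx.ravel(), g.gy.ravel()])

    D = dense_matrix(apply_D, n)
    Dx, Dy = D[: n], D[n:]
    T = dense_matrix(lambda v: t2.apply(v.reshape(grid.shape)), n)
    K = (
        cfg.mu * F.T @ F
        + cfg.lam * (Dx.T @ Dx + Dy.T @ Dy)
        + cfg.lam * T.T @ T
        + cfg.gamma * np.eye(n)
    )
    r = (
        cfg.mu * F.T @ state.fk.ravel()
        + cfg.lam * Dx.T @ (state.dx - state.bx).ravel()
        + cfg.lam * Dy.T @ (state.dy - state.by).ravel()
        + cfg.lam * T.T @ (state.w + t2.apply(prior) - state.bw)
        + cfg.gamma * (state.v - state.bv).ravel()
    )
    return K, r


def test_u_update_matches_dense_solve(tiny_problem, rng):
    grid, geom, proj, t2 = tiny_problem
    cfg = PICCSConfig(delta=1e-8, max_inner_iter=500, t2=TransformChoice("gradient"))
    state = SolverState.initial(grid, t2, rng.normal(size=geom.shape))
    # random interior state, as mid-iteration
    for name in ("dx", "dy", "v", "bx", "by", "bv"):
        setattr(state, name, rng.normal(size=grid.shape))
    state.w = rng.normal(size=state.w.size)
    state.bw = rng.normal(size=state.bw.size)
    prior = rng.normal(size=grid.shape)
    K, r = _dense_K_and_r(grid, proj, t2, state, prior, cfg)
    expected = np.linalg.solve(K, r)
    u_new, _, converged = u_update(state, prior, proj, t2, cfg)
    assert converged
    rel = np.linalg.norm(u_new.ravel() - expected) / np.linalg.norm(expected)
    assert rel < 1e-4


def test_K_operator_is_spd(tiny_problem, rng):
    grid, geom, proj, t2 = tiny_problem
    cfg = PICCSConfig(t2=TransformChoice("gradient"))
    state = SolverState.initial(grid, t2, np.zeros(geom.shape))
    K, _ = _dense_K_and_r(grid, proj, t2, state, np.zeros(grid.shape), cfg)
    np.testing.assert_allclose(K, K.T, atol=1e-8)
    for _ in range(5):
        x = rng.normal(size=grid.n_pixels)
        assert x @ K @ x > 0


def test_u_update_identity_operator_limit(rng):
    """With F = I and the other terms tiny, K u = r collapses to u ~ f."""

    class EyeProj:
        def __init__(self, grid):
            self.grid = grid
            self.geometry = type("G", (), {"shape": grid.shape})()

        def forward(self, x):
            return np.asarray(x, dtype=float)

        def back(self, y):
            return np.asarray(y, dtype=float)

    grid = ImageGrid(8, 8, 1.0)
    t2 = make_transform(TransformChoice("unitary"), grid)
    f = rng.normal(size=grid.shape)
    cfg = PICCSConfig(mu=10.0, lam=1e-12, gamma=1e-12, delta=1e-8,
                      max_inner_iter=500, t2=TransformChoice("unitary"))
    state = SolverState.initial(grid, t2, f)
    u_new, _, _ = u_update(state, np.zeros(grid.shape), EyeProj(grid), t2, cfg)
    np.testing.assert_allclose(u_new, f, atol=1e-6)


# ----------------------------------------------------- projection & Bregman
def test_positivity_support_projection(small_grid, rng):
    omega = small_grid.support_mask
    u = rng.normal(size=small_grid.shape)
    bv = rng.normal(size=small_grid.shape)
    v = positivity_support_project(u, bv, omega)
    assert np.all(v >= 0)
    assert np.all(v[~omega] == 0)
    inside = omega & (u + bv >= 0)
    np.testing.assert_allclose(v[inside], (u + bv)[inside])
    v_allneg = positivity_support_project(-np.abs(u) - 1.0, np.zeros_like(u), omega)
    assert np.all(v_allneg == 0)


def test_bregman_update_identities(small_grid, small_geometry, small_projector, rng):
    t2 = make_transform(TransformChoice("unitary"), small_grid)
    f = rng.normal(size=small_geometry.shape)
    state = SolverState.initial(small_grid, t2, f.copy())
    u_new = rng.normal(size=small_grid.shape)
    g = grad(u_new)
    prior = rng.normal(size=small_grid.shape)
    w_new = t2.apply(u_new - prior)  # exact tracking
    v_new = u_new.copy()
    f_exact = small_projector.forward(u_new)
    state = bregman_update(
        state, u_new, GradientField(g.gx.copy(), g.gy.copy()), w_new, v_new,
        f_exact, prior, small_projector, t2,
    )
    # d == grad(u), w == T2(u - up), v == u, f_measured == F u: all b's stay
    # zero and the working data fk is unchanged
    assert np.all(state.bx == 0) and np.all(state.by == 0)
    np.testing.assert_allclose(state.bw, 0, atol=1e-12)
    assert np.all(state.bv == 0)
    np.testing.assert_allclose(state.fk, f, atol=1e-12)
    # one update from zero b with mismatched d gives bx == grad(u) - dx
    state2 = SolverState.initial(small_grid, t2, f.copy())
    d_off = GradientField(np.zeros(small_grid.shape), np.zeros(small_grid.shape))
    state2 = bregman_update(
        state2, u_new, d_off, w_new, v_new, f_exact, prior, small_projector, t2
    )
    np.testing.assert_allclose(state2.bx, g.gx)
    np.testing.assert_allclose(state2.by, g.gy)


# ------------------------------------------------------------- full solves
def test_zero_data_returns_zero_image(small_grid, small_geometry):
    sino = Sinogram(small_geometry, np.zeros(small_geometry.shape))
    rec, report = solve_piccs(sino, np.zeros(small_grid.shape), small_grid)
    assert np.all(rec == 0)
    assert report.stop_reason == "zero data"


@pytest.fixture(scope="module")
def noiseless_64():
    grid = ImageGrid(64, 64, 1.0)
    geom = ProjectionGeometry.for_grid(grid, np.arange(0, 360, 3.0))
    proj = Projector(grid, geom)
    xx, yy = grid.coords()
    truth = np.zeros(grid.shape)
    truth[(xx**2 + yy**2) <= 24**2] = 1.0
    truth[((xx - 6) ** 2 + (yy - 4) ** 2) <= 8**2] = 0.5
    sino = Sinogram(geom, proj.forward(truth), sigma=0.0)
    return grid, proj, truth, sino


def test_output_respects_positivity_and_support(noiseless_64):
    grid, proj, truth, sino = noiseless_64
    cfg = PICCSConfig(alpha=0.0, stop_mode="fixed_iters", max_outer_iter=10,
                      t2=TransformChoice("gradient"))
    rec, _ = solve_piccs(sino, np.zeros(grid.shape), grid, cfg, projector=proj)
    assert rec.min() >= -1e-9
    assert np.all(rec[~grid.support_mask] == 0)


def test_perfect_prior_beats_no_prior(noiseless_64):
    """alpha=1 with the true image as prior is closer to truth than alpha=0
    at equal iteration count."""
    grid, proj, truth, sino = noiseless_64
    omega = grid.support_mask

    def run(alpha, prior):
        cfg = PICCSConfig(alpha=alpha, stop_mode="fixed_iters", max_outer_iter=15,
                          t2=TransformChoice("gradient"))
        rec, _ = solve_piccs(sino, prior, grid, cfg, projector=proj)
        return np.mean((rec[omega] - truth[omega]) ** 2)

    assert run(1.0, truth.copy()) < run(0.0, np.zeros(grid.shape))


def test_solution_invariant_to_mu():
    """mu in {1, 10} converges to the same noiseless solution; smaller mu
    only needs more iterations, so both runs are stopped at the same data
    residual level rather than the same iteration count."""
    grid = ImageGrid(48, 48, 1.0)
    geom = ProjectionGeometry.for_grid(grid, np.arange(0, 360, 4.0))
    proj = Projector(grid, geom)
    xx, yy = grid.coords()
    truth = np.zeros(grid.shape)
    truth[(xx**2 + yy**2) <= 18**2] = 1.0
    truth[((xx - 5) ** 2 + (yy - 3) ** 2) <= 6**2] = 0.5
    sino = Sinogram(geom, proj.forward(truth), sigma=0.0)
    omega = grid.support_mask
    sig = 1e-3 * np.linalg.norm(sino.values)
    recs = []
    for mu in (1.0, 10.0):
        cfg = PICCSConfig(alpha=0.0, mu=mu, sigma=sig, stop_mode="discrepancy",
                          max_outer_iter=3000, t2=TransformChoice("gradient"))
        rec, report = solve_piccs(sino, np.zeros(grid.shape), grid, cfg, projector=proj)
        assert report.stop_reason == "discrepancy"
        recs.append(rec)
    diff = np.linalg.norm((recs[0] - recs[1])[omega]) / np.linalg.norm(recs[1][omega])
    assert diff < 0.01


def test_discrepancy_stop_uses_sigma(noiseless_64):
    """With a loose explicit sigma the solver stops once the residual
    crosses it, well before the iteration cap."""
    grid, proj, truth, sino = noiseless_64
    loose = Sinogram(sino.geometry, sino.values, sigma=0.0)
    cfg = PICCSConfig(alpha=0.0, sigma=0.05 * np.linalg.norm(sino.values),
                      stop_mode="discrepancy", max_outer_iter=200,
                      t2=TransformChoice("gradient"))
    rec, report = solve_piccs(loose, np.zeros(grid.shape), grid, cfg, projector=proj)
    assert report.stop_reason == "discrepancy"
    assert report.stop_iteration < 200


def test_oracle_stop_requires_reference(noiseless_64):
    grid, proj, truth, sino = noiseless_64
    cfg = PICCSConfig(stop_mode="oracle_mse")
    with pytest.raises(ConfigurationError):
        solve_piccs(sino, np.zeros(grid.shape), grid, cfg, projector=proj)


def test_config_validation():
    with pytest.raises(ConfigurationError):
        PICCSConfig(alpha=1.5)
    with pytest.raises(ConfigurationError):
        PICCSConfig(mu=0.0)
    with pytest.raises(ConfigurationError):
        PICCSConfig(stop_mode="energy")
    with pytest.raises(ConfigurationError):
        PICCSConfig(delta=1.0)
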
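import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import ionscale as isc
from ionscale import _kernels
from ionscale.errors import InvalidStatisticsError, IonscaleError
from ionscale.fictitious import (
    FictitiousParams,
    _scaled,
    build_extended,
    cg_to_fp,
    diffusion_fp,
    fit_vacf,
    fp_to_cg,
    moments_fp,
    project_to_constraints,
    simulate_fp,
    stationary_covariance,
    vacf_fp,
    _vacf_expm,
)
from conftest import ALPHA_K_N3

coef = st.floats(min_value=0.05, max_value=500.0, allow_nan=False)


def random_stable_fp(rng, N=2, max_tries=50):
    for _ in range(max_tries):
        alpha = np.exp(rng.uniform(np.log(0.5), np.log(50.0), size=(N, 4)))
        try:
            build_extended(FictitiousParams(alpha=alpha))
            return FictitiousParams(alpha=alpha)
        except IonscaleError:
            continue
    raise RuntimeError("no stable draw found")


def test_n1_extended_drift_equals_cg_drift(kplus_params):
    """alpha = (eta1, eta2, eta3, eta4/eta1) reassembles the CG matrix."""
    fp = cg_to_fp(kplus_params)
    ed = build_extended(fp)
    assert np.allclose(ed.B, isc.linear.drift_matrix(kplus_params))
    assert ed.G[2, 0] == pytest.approx(kplus_params.eta4)


@settings(derandomize=True, max_examples=30)
@given(coef, coef, coef, coef, coef, coef, coef, coef)
def test_trace_is_total_damping(a11, a12, a13, a14, a21, a22, a23, a24):
    fp = FictitiousParams(alpha=np.array([[a11, a12, a13, a14], [a21, a22, a23, a24]]))
    ed = build_extended(fp, check_spectrum=False)
    assert np.trace(ed.B) == pytest.approx(-(a12 + a22), rel=1e-12)


def test_published_n3_coefficients_are_stable_and_decay():
    fp = FictitiousParams(alpha=ALPHA_K_N3)
    ed = build_extended(fp)
    assert np.all(ed.eigenvalues.real < 0)
    t = np.linspace(0, 1.0, 101)
    C = vacf_fp(fp, t)
    assert abs(C[-1]) < 0.01 * C[0]  # decayed below 1% of C(0) by 1 ps
    # the published moment constraints are carried by these coefficients
    D, v2, u2 = moments_fp(fp)
    assert D == pytest.approx(0.183, rel=0.01)
    assert v2 == pytest.approx(6.32, rel=0.01)
    assert u2 == pytest.approx(4.86e3, rel=0.01)


def test_lyapunov_solution_properties(kplus_params):
    fp = cg_to_fp(kplus_params)
    ed = build_extended(fp)
    S = stationary_covariance(ed)
    Q = ed.G @ ed.G.T
    residual = ed.B @ S + S @ ed.B.T + Q
    assert np.linalg.norm(residual) < 1e-8 * np.linalg.norm(Q)
    assert S[0, 0] == pytest.approx(6.32, rel=2e-3)
    doubled = FictitiousParams(alpha=fp.alpha * [1, 1, 1, 2])
    S2 = stationary_covariance(build_extended(doubled))
    assert np.allclose(S2, 4 * S, rtol=1e-9)


def test_vacf_fp_matches_cg_and_c0(kplus_params):
    fp = cg_to_fp(kplus_params)
    t = np.linspace(0, 1.0, 101)
    C_fp = vacf_fp(fp, t)
    C_cg = isc.vacf_cg(kplus_params, t)
    assert np.max(np.abs(C_fp - C_cg)) < 1e-10
    S = stationary_covariance(build_extended(fp))
    assert C_fp[0] == pytest.approx(S[0, 0], rel=1e-12)


def test_vacf_eigen_vs_expm_route():
    fp = FictitiousParams(alpha=ALPHA_K_N3)
    t = np.linspace(0, 0.5, 26)
    assert np.max(np.abs(vacf_fp(fp, t) - _vacf_expm(fp, t))) < 1e-9


def test_diffusion_closed_form_vs_quadrature():
    """Green-Kubo closed form equals the numerical VACF integral on random
    stable parameter sets."""
    rng = np.random.default_rng(12)
    for _ in range(20):
        fp = random_stable_fp(rng)
        ed = build_extended(fp, check_spectrum=False)
        lam = ed.eigenvalues
        horizon = 35.0 / abs(np.max(lam.real))
        # resolve the fastest mode (real or oscillatory) on the grid
        n_pts = min(int(20 * horizon * np.max(np.abs(lam))) + 1000, 400_000)
        t = np.linspace(0, horizon, n_pts)
        D_quad = np.trapezoid(vacf_fp(fp, t), t)
        assert diffusion_fp(fp) == pytest.approx(D_quad, rel=1e-4, abs=1e-12)


def test_time_dilation_rescales_diffusion(kplus_params):
    fp = cg_to_fp(kplus_params)
    D0 = diffusion_fp(fp)
    slowed = _scaled(fp, 0.0, np.log(2.0), 0.0)  # time unit doubled
    assert diffusion_fp(slowed) == pytest.approx(2 * D0, rel=1e-9)


def test_cg_fp_round_trip(kplus_params):
    fp = cg_to_fp(kplus_params)
    assert fp.alpha[0] == pytest.approx(
        [768.7, 152.5, 3393.0, 7.094e4 / 768.7], rel=1e-12
    )
    back = fp_to_cg(fp)
    assert back.as_tuple() == pytest.approx(kplus_params.as_tuple(), rel=1e-12)
    with pytest.raises(IonscaleError):
        fp_to_cg(FictitiousParams(alpha=np.ones((2, 4))))
    with pytest.raises(InvalidStatisticsError):
        FictitiousParams(alpha=np.array([[1.0, -1.0, 1.0, 1.0]]))


def test_zero_noise_zero_init_stays_zero():
    alpha = np.array([[10.0, 5.0, 20.0, 1.0]])
    X, V, Ut, Zt, bad = _kernels.fp_path(
        alpha, 1e-3, np.zeros((100, 1, 3)), np.zeros(3), np.zeros(3),
        np.zeros((1, 3)), np.zeros((1, 3)),
    )
    assert bad == -1
    assert not V.any() and not Ut.any() and not Zt.any()


def test_n1_pathwise_equivalence_with_common_noise(kplus_params):
    traj_fp, _, _ = simulate_fp(cg_to_fp(kplus_params), dt=1e-3, n_steps=2000, seed=77)
    traj_cg = isc.simulate_cg(kplus_params, dt=1e-3, n_steps=2000, seed=77)
    assert np.array_equal(traj_fp.V, traj_cg.V)
    assert np.array_equal(traj_fp.U, traj_cg.U)
    assert np.array_equal(traj_fp.X, traj_cg.X)


def test_simulated_moments_match_lyapunov_solution():
    """Euler-Maruyama sampling of a moderately stiff N=2 model reproduces the
    stationary covariance diagonal."""
    alpha = np.array([[50.0, 10.0, 80.0, 5.0], [20.0, 6.0, 30.0, 2.0]])
    fp = FictitiousParams(alpha=alpha)
    ed = build_extended(fp)
    S = stationary_covariance(ed)
    rng = np.random.default_rng(4)
    chol = np.linalg.cholesky(S + 1e-12 * np.eye(5))
    y0 = chol @ rng.standard_normal((5, 3))
    init = (np.zeros(3), y0[0], y0[1::2], y0[2::2])
    traj, Ut, Zt = simulate_fp(fp, init=init, dt=2e-4, n_steps=400_000, seed=4)
    sim_diag = [
        np.mean(traj.V[1000:] ** 2),
        np.mean(Ut[1000:, 0] ** 2),
        np.mean(Zt[1000:, 0] ** 2),
        np.mean(Ut[1000:, 1] ** 2),
        np.mean(Zt[1000:, 1] ** 2),
    ]
    assert sim_diag == pytest.approx(np.diag(S), rel=0.10)


def test_projection_restores_constraints_exactly(kplus_stats):
    constraints = (kplus_stats.D, kplus_stats.v2, kplus_stats.u2)
    rng = np.random.default_rng(2)
    fp = FictitiousParams(alpha=ALPHA_K_N3 * np.exp(0.2 * rng.standard_normal((3, 4))))
    projected = project_to_constraints(fp, constraints)
    assert moments_fp(projected) == pytest.approx(constraints, rel=1e-9)
    with pytest.raises(ValueError):
        project_to_constraints(fp, (-1.0, 1.0, 1.0))


def test_fit_vacf_n1_identifiability(kplus_params):
    """Fitting an N=1 model to the CG model's own VACF under the CG moment
    constraints drives the L1 error towards zero."""
    stats = isc.implied_stats(kplus_params)
    t = np.linspace(0, 1.0, 101)
    target = isc.vacf_cg(kplus_params, t)
    res = fit_vacf(
        t, target, constraints=(stats.D, stats.v2, stats.u2),
        N=1, seed=3, max_iter=600,
    )
    span = t[-1] - t[0]
    assert res.error < 0.02 * target[0] * span
    assert np.all(np.diff(res.error_trace) <= 0)
    assert moments_fp(res.fp) == pytest.approx((stats.D, stats.v2, stats.u2), rel=1e-8)
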
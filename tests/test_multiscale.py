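import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad

import ionscale as isc
from ionscale.multiscale import (
    BDParams,
    HalfspaceDecomposition,
    HybridParticle,
    RegionDecomposition,
    analytic_halfspace_density,
    attenuated_distance_args,
    bd_first_passage_times,
    bd_step,
    box_distance,
    classify_region,
    escape_theory,
    escape_time_experiment,
    hybrid_step_cg_bd,
    run_halfspace_experiment,
)

L = 24.83


@pytest.fixture(scope="module")
def dec():
    return RegionDecomposition(L=L)


def test_bd_step_definition():
    bd = BDParams(D=0.183, dT=0.5)
    X = np.array([1.0, 2.0, 3.0])
    assert np.array_equal(bd_step(X, bd, np.zeros(3)), X)
    rng = np.random.default_rng(0)
    inc = bd_step(np.zeros(3), bd, rng.standard_normal((100_000, 3)))
    var = np.var(inc)
    expected = 2 * bd.D * bd.dT
    assert var == pytest.approx(expected, rel=3 * np.sqrt(2 / 3e5))


def test_bd_warns_on_tiny_timestep():
    with pytest.warns(UserWarning, match="unusually small"):
        BDParams(D=0.1, dT=1e-3)


def test_bd_msd_matches_brownian_law():
    """10^4 walkers over 10^3 ps: component MSD tracks 2 D t."""
    bd = BDParams(D=0.183, dT=0.5)
    rng = np.random.default_rng(1)
    n, n_steps = 10_000, 2000
    X = np.sqrt(2 * bd.D * bd.dT) * rng.standard_normal((n_steps, n, 3)).cumsum(axis=0)
    t = bd.dT * np.arange(1, n_steps + 1)
    msd = np.mean(X**2, axis=(1, 2))
    band = 3 * np.sqrt(2.0 / (3 * n))  # 3-sigma for chi^2 mean at each time
    assert np.all(np.abs(msd / (2 * bd.D * t) - 1) < band)


def test_halfspace_density_symmetry_mass_and_value():
    D, t, h, n = 0.183, 1e3, 1.0, 1e6
    x = np.linspace(-80, 80, 41)
    rho = analytic_halfspace_density(x, t, D, h, n)
    assert np.allclose(rho, rho[::-1])
    total, _ = quad(lambda y: analytic_halfspace_density(y, t, D, h, n), -np.inf, np.inf)
    assert total == pytest.approx(n, rel=1e-9)
    # per-angstrom density at x1 = 1; the published curve absorbs the 2 A bin
    assert analytic_halfspace_density(1.0, t, D, h, n) == pytest.approx(4.16e4 / 2, rel=2e-3)
    with pytest.raises(ValueError):
        analytic_halfspace_density(0.0, 0.0, D, h, n)


def test_region_classification_and_closure(dec):
    assert classify_region(np.zeros(3), dec) == 1
    assert classify_region(np.array([L / 2, 0, 0]), dec) == 1  # closed inner box
    r1, r2, r3, r4 = dec.half_sides
    assert classify_region(np.array([r2, 0, 0]), dec) == 2
    assert classify_region(np.array([0, r3, 0]), dec) == 3
    assert classify_region(np.array([0, 0, r4]), dec) == 4
    assert classify_region(np.array([r4 + 1e-9, 0, 0]), dec) == 5
    assert classify_region(np.array([100.0, 0, 0]), dec) == 5


@settings(derandomize=True, max_examples=200)
@given(st.lists(st.floats(-60, 60), min_size=3, max_size=3))
def test_partition_is_exhaustive_and_consistent(point):
    """Every point gets exactly one region, consistent with sup-norm nesting."""
    dec = RegionDecomposition(L=L)
    X = np.array(point)
    region = classify_region(X, dec)
    sup = np.max(np.abs(X))
    bounds = (0.0,) + dec.half_sides + (np.inf,)
    assert bounds[region - 1] <= sup <= bounds[region] or (
        region == 1 and sup <= bounds[1]
    )


def test_shell_volumes(dec):
    r1, r2, r3, r4 = dec.half_sides
    assert dec.shell_volume(1) == pytest.approx(L**3)
    assert dec.shell_volume(2) == pytest.approx((2 * r2) ** 3 - L**3)
    assert dec.shell_volume(4) == pytest.approx((2 * r4) ** 3 - (2 * r3) ** 3)
    with pytest.raises(ValueError):
        dec.shell_volume(5)


def test_attenuated_distance_rule(dec):
    inside = np.array([1.0, -2.0, 3.0])
    r_att, beyond = attenuated_distance_args(2.5, inside, dec)
    assert r_att == 2.5 and not beyond
    assert box_distance(np.array([L / 2 + 3, 0, 0]), dec) == pytest.approx(3.0)
    # omega * dist == cutoff exactly at dist = L/(2*omega)
    at_cut = np.array([L / 2 + L / (2 * dec.omega), 0, 0])
    r_att, beyond = attenuated_distance_args(1.0, at_cut, dec)
    assert r_att == pytest.approx(1.0 + L / 2)
    assert beyond


def test_hybrid_step_tags_and_switching(dec, kplus_params):
    bd = BDParams(D=kplus_params.implied_D, dT=0.5)
    rng = np.random.default_rng(0)
    r1, r2, r3, r4 = dec.half_sides
    # CG particle deep in the CG shell: plain step, tag unchanged
    p = HybridParticle(X=np.array([(r2 + r3) / 2, 0, 0]), tag="cg")
    p = hybrid_step_cg_bd(p, kplus_params, bd, 1e-3, dec, rng)
    assert p.tag == "cg" and p.V is not None
    # BD particle stepping into the CG shell: re-entry with zero auxiliaries
    p = HybridParticle(X=np.array([r3 - 1e-6, 0, 0]), tag="bd")
    p = hybrid_step_cg_bd(p, kplus_params, bd, 1e-3, dec, rng)
    if p.tag == "cg":  # switch happens unless the step left the shell again
        assert np.all(p.V == 0) and np.all(p.U == 0) and np.all(p.Z == 0)
    # overlap keeps the current description for both models
    mid4 = np.array([(r3 + r4) / 2, 0, 0])
    assert classify_region(mid4, dec) == 4
    p_cg = hybrid_step_cg_bd(
        HybridParticle(X=mid4.copy(), tag="cg"), kplus_params, bd, 1e-3, dec, rng
    )
    assert p_cg.tag == "cg"
    p_bd = hybrid_step_cg_bd(
        HybridParticle(X=mid4.copy(), tag="bd"), kplus_params, bd, 1e-3, dec, rng
    )
    assert p_bd.tag == "bd"
    with pytest.raises(Exception, match="fine"):
        hybrid_step_cg_bd(
            HybridParticle(X=np.zeros(3), tag="fine"), kplus_params, bd, 1e-3, dec, rng
        )


def test_hybrid_reduces_to_pure_models_without_switching(kplus_params):
    """With an unreachable switching plane the hybrid stepper replays the
    pure CG simulator (and the pure BD walk) bit for bit."""
    bd = BDParams(D=kplus_params.implied_D, dT=0.5)
    far = HalfspaceDecomposition(h=1e9)
    n = 200
    p = HybridParticle(X=np.zeros(3), tag="cg")
    rng = np.random.default_rng(123)
    for _ in range(n):
        p = hybrid_step_cg_bd(p, kplus_params, bd, 1e-3, far, rng)
    ref = isc.simulate_cg(kplus_params, dt=1e-3, n_steps=n, seed=123)
    assert np.array_equal(p.X, ref.X[-1])
    assert np.array_equal(p.V, ref.V[-1])
    q = HybridParticle(X=np.zeros(3), tag="bd")
    rng = np.random.default_rng(321)
    for _ in range(n):
        q = hybrid_step_cg_bd(q, kplus_params, bd, 1e-3, far, rng)
    rng2 = np.random.default_rng(321)
    ref_bd = np.sqrt(2 * bd.D * bd.dT) * rng2.standard_normal((n, 3))
    assert np.array_equal(q.X, ref_bd.sum(axis=0))


def test_halfspace_experiment_counts_and_zero_duration(kplus_params):
    bd = BDParams(D=kplus_params.implied_D, dT=0.5)
    res = run_halfspace_experiment(
        kplus_params, bd, n_particles=400, t_end=50.0, seed=0
    )
    assert res.counts.sum() == 400  # particle count conserved
    # analytic mass over the covered bins accounts for (almost) everything
    assert 0.95 * 400 < res.expected.sum() <= 400 + 1e-9
    frozen = run_halfspace_experiment(kplus_params, bd, n_particles=100, t_end=0.0)
    assert frozen.counts.sum() == 100
    assert (frozen.counts > 0).sum() == 2  # delta masses at +-h
    with pytest.raises(ValueError):
        run_halfspace_experiment(kplus_params, bd, n_particles=3, t_end=1.0)


def test_halfspace_symmetry_at_long_times(kplus_params):
    """Released symmetrically, the final marginal is symmetric within noise."""
    bd = BDParams(D=kplus_params.implied_D, dT=0.5)
    res = run_halfspace_experiment(
        kplus_params, bd, n_particles=4000, t_end=200.0, seed=2
    )
    assert abs(np.mean(res.x1)) < 3 * np.sqrt(2 * bd.D * 200.0 / 4000)


def test_escape_theory_closed_forms():
    assert escape_theory(0.183, 0.0).mean == 0.0
    th = escape_theory(0.183, 4 * L)
    assert th.mean == pytest.approx((4 * L) ** 2 / (6 * 0.183), rel=1e-12)
    assert th.mean == pytest.approx(8.98e3, rel=1e-3)
    assert th.sd == pytest.approx((4 * L) ** 2 / (3 * np.sqrt(10) * 0.183), rel=1e-12)
    # CI width scales as r^2
    w1 = np.diff(escape_theory(0.2, 10.0).ci95)[0]
    w2 = np.diff(escape_theory(0.2, 20.0).ci95)[0]
    assert w2 / w1 == pytest.approx(4.0, rel=1e-12)


@pytest.mark.parametrize("ion", ["K+", "Na+", "Ca2+", "Cl-"])
def test_pure_bd_escape_matches_theory(ion):
    """Analytic first-passage mean validated against the plain BD walk."""
    stats, _ = isc.get_ion(ion)
    r = 4 * L
    T = bd_first_passage_times(stats.D, r, n_realizations=100, dT=0.5, seed=7)
    th = escape_theory(stats.D, r, n_samples=100)
    assert th.ci95[0] <= np.mean(T) <= th.ci95[1]


def test_escape_experiment_monotone_and_reproducible(dec, kplus_params):
    bd = BDParams(D=kplus_params.implied_D, dT=0.5)
    res1 = escape_time_experiment(
        dec, kplus_params, bd, r_max=2 * L, n_realizations=2, seed=9
    )
    res2 = escape_time_experiment(
        dec, kplus_params, bd, r_max=2 * L, n_realizations=2, seed=9
    )
    assert np.array_equal(res1.T, res2.T)
    assert not res1.truncated.any()
    for row in res1.T:
        assert np.all(np.diff(row) >= 0)  # first-passage times non-decreasing
    # the truncation budget is honoured
    res3 = escape_time_experiment(
        dec, kplus_params, bd, r_max=2 * L, n_realizations=2, seed=9, max_steps=50
    )
    assert res3.truncated.all()
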
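import numpy as np
import pytest

from cardiokit.hemodynamics import (MU_BLOOD, CarreauYasuda, FlowSolver2D,
                                    LagrangianSurface, MLSSampler,
                                    WindkesselRegion, distribute_face_forces,
                                    effective_viscosity, hydrodynamic_loads,
                                    windkessel_forcing)
from cardiokit.registries import lookup_windkessel


# ---------------------------------------------------------------------------
# viscosity
# ---------------------------------------------------------------------------
def test_newtonian_mode_returns_blood_viscosity():
    assert effective_viscosity(0.0) == 0.0035
    assert effective_viscosity(1e6) == 0.0035


def test_carreau_yasuda_limits():
    p = CarreauYasuda()
    assert effective_viscosity(0.0, p, newtonian=False) \
        == pytest.approx(p.mu0)
    assert effective_viscosity(1e9, p, newtonian=False) \
        == pytest.approx(p.mu_inf, rel=1e-3)
    # shear-thinning: monotone decreasing
    g = np.logspace(-2, 4, 30)
    mu = effective_viscosity(g, p, newtonian=False)
    assert np.all(np.diff(mu) < 0)


def test_negative_shear_rate_rejected():
    with pytest.raises(ValueError):
        effective_viscosity(-1.0)


# ---------------------------------------------------------------------------
# MLS transfer
# ---------------------------------------------------------------------------
def _sampler(n, periodic=True):
    h = 1.0 / n
    return MLSSampler((0.5 * h, 0.5 * h), h, (n, n),
                      (periodic, periodic)), h


def test_mls_reproduces_constants_exactly():
    s, _ = _sampler(16)
    f = np.full((16, 16), 3.7)
    pts = np.random.default_rng(0).uniform(0, 1, (40, 2))
    assert np.allclose(s.interpolate(f, pts), 3.7, atol=1e-12)


def test_mls_reproduces_linear_fields_exactly():
    s, h = _sampler(16)
    X = (np.arange(16) + 0.5) * h
    XX, YY = np.meshgrid(X, X, indexing="ij")
    f = 0.3 + 1.7 * XX - 0.4 * YY
    pts = np.random.default_rng(1).uniform(0.2, 0.8, (60, 2))
    exact = 0.3 + 1.7 * pts[:, 0] - 0.4 * pts[:, 1]
    assert np.abs(s.interpolate(f, pts) - exact).max() < 1e-12


def test_mls_second_order_convergence_on_smooth_field():
    rng = np.random.default_rng(2)
    pts = rng.uniform(0.1, 0.9, (200, 2))
    exact = np.sin(2 * np.pi * pts[:, 0]) * np.cos(2 * np.pi * pts[:, 1])
    errs = []
    for n in (16, 32, 64):
        s, h = _sampler(n)
        X = (np.arange(n) + 0.5) * h
        XX, YY = np.meshgrid(X, X, indexing="ij")
        f = np.sin(2 * np.pi * XX) * np.cos(2 * np.pi * YY)
        errs.append(np.abs(s.interpolate(f, pts) - exact).max())
    orders = np.log2(np.array(errs[:-1]) / errs[1:])
    assert np.all(orders > 1.7)


def test_mls_spread_interpolate_adjoint_identity():
    s, _ = _sampler(20)
    rng = np.random.default_rng(3)
    pts = rng.uniform(0, 1, (50, 2))
    vals = rng.standard_normal(50)
    g = rng.standard_normal((20, 20))
    lhs = np.sum(s.spread(pts, vals) * g)
    rhs = np.sum(vals * s.interpolate(g, pts))
    assert lhs == pytest.approx(rhs, abs=1e-12)


def test_mls_spreading_preserves_totals():
    s, _ = _sampler(20)
    rng = np.random.default_rng(4)
    pts = rng.uniform(0, 1, (30, 2))
    vals = rng.standard_normal(30)
    assert s.spread(pts, vals).sum() == pytest.approx(vals.sum(), abs=1e-12)


def test_mls_marker_outside_bounded_domain_raises():
    h = 1.0 / 16
    s = MLSSampler((0.5 * h, 0.5 * h), h, (16, 16), (False, False))
    with pytest.raises(ValueError):
        s.interpolate(np.zeros((16, 16)), [[0.5, 2.5]])


# ---------------------------------------------------------------------------
# flow solver
# ---------------------------------------------------------------------------
def test_uniform_flow_in_periodic_box_is_steady():
    s = FlowSolver2D(16, 16, 1, 1, rho=1.0, mu=0.01)
    s.u[:] = 1.0
    s.v[:] = 0.5
    for _ in range(10):
        s.step(0.01)
    assert np.abs(s.u - 1.0).max() < 1e-12
    assert np.abs(s.v - 0.5).max() < 1e-12


def _taylor_green(n=64, nu=0.01, T=None, dt=0.02):
    L = 2 * np.pi
    s = FlowSolver2D(n, n, L, L, rho=1.0, mu=nu)
    xf = np.arange(n) * s.dx
    yc = (np.arange(n) + 0.5) * s.dy
    XU, YU = np.meshgrid(xf, yc, indexing="ij")
    XV, YV = np.meshgrid(xf + 0.5 * s.dx, yc - 0.5 * s.dy, indexing="ij")
    s.u = np.cos(XU) * np.sin(YU)
    s.v = -np.sin(XV) * np.cos(YV)
    if T is None:
        T = 2 * np.pi     # one eddy turnover at unit velocity scale
    for _ in range(int(round(T / dt))):
        s.step(dt)
    return s, T


def test_taylor_green_energy_decay_within_1_percent():
    """Kinetic energy decays as exp(-4 nu k^2 t) (k=1); < 1% error at
    64^2 after one eddy turnover."""
    nu = 0.01
    s, T = _taylor_green(nu=nu)
    E0 = 0.5 * (2 * np.pi) ** 2 / 2      # integral of u0^2/2 over the box
    ratio = s.kinetic_energy() / E0
    assert ratio == pytest.approx(np.exp(-4 * nu * T), rel=0.01)


def test_divergence_free_after_every_projection():
    s, _ = _taylor_green(n=32, T=0.5)
    assert np.abs(s.divergence()).max() < 1e-8


def test_plane_poiseuille_profile():
    """Constant body force between no-slip walls: steady parabolic
    profile with < 1% peak-velocity error."""
    n = 32
    s = FlowSolver2D(n, n, 1.0, 1.0, rho=1.0, mu=0.05, bc_y="noslip")
    g = 1.0
    for _ in range(3000):
        s.step(0.01, body_force=(g, 0.0))
    yc = (np.arange(n) + 0.5) * s.dy
    u_exact = g / (2 * 0.05) * yc * (1.0 - yc)
    err = np.abs(s.u.mean(axis=0) - u_exact).max() / u_exact.max()
    assert err < 0.01


def test_global_momentum_balance_with_body_force():
    s = FlowSolver2D(32, 32, 1, 1, rho=2.0, mu=0.01)
    f = (0.3, -0.1)
    T, dt = 0.5, 0.01
    for _ in range(int(T / dt)):
        s.step(dt, body_force=f)
    cell = s.dx * s.dy
    mom = (2.0 * s.u.sum() * cell, 2.0 * s.v.sum() * cell)
    assert mom[0] == pytest.approx(f[0] * T, rel=1e-6)
    assert mom[1] == pytest.approx(f[1] * T, rel=1e-6)


def test_cfl_violation_warns():
    s = FlowSolver2D(16, 16, 1, 1, rho=1.0, mu=0.01)
    s.u[:] = 10.0
    with pytest.warns(RuntimeWarning):
        s.step(0.1)


def test_ib_plate_slip_below_5_percent():
    """Stationary plate in a uniform stream: post-step interpolated slip
    at the markers under 5% of the free stream at 64^2."""
    s = FlowSolver2D(64, 64, 1, 1, rho=1.0, mu=0.002)
    U = 1.0
    s.u[:] = U
    ys = np.linspace(0.3, 0.7, 33)
    markers = np.column_stack([np.full_like(ys, 0.5), ys])
    targets = np.zeros((33, 2))
    for _ in range(100):
        s.step(0.2 / 64, ib_markers=markers, ib_velocities=targets)
    um = s.sampler_u().interpolate(s.u, markers)
    vm = s.sampler_v().interpolate(s.v, markers)
    assert np.abs(np.stack([um, vm])).max() < 0.05 * U


def test_ib_zero_forcing_when_targets_match_flow():
    s = FlowSolver2D(32, 32, 1, 1, rho=1.0, mu=0.01)
    s.u[:] = 0.7
    markers = np.array([[0.5, 0.5], [0.3, 0.6]])
    targets = np.tile([0.7, 0.0], (2, 1))
    s.step(0.01, ib_markers=markers, ib_velocities=targets)
    assert np.abs(s.last_ib_force).max() < 1e-10


def test_ib_total_spread_force_equals_marker_force():
    """Weight normalization: the integral of the spread forcing equals
    the sum of the marker forces."""
    s = FlowSolver2D(32, 32, 1, 1, rho=1.0, mu=0.01)
    sampler = s.sampler_u()
    rng = np.random.default_rng(5)
    pts = rng.uniform(0.2, 0.8, (20, 2))
    vals = rng.standard_normal(20)
    assert sampler.spread(pts, vals).sum() == pytest.approx(vals.sum(),
                                                            abs=1e-12)


# ---------------------------------------------------------------------------
# Windkessel
# ---------------------------------------------------------------------------
def test_windkessel_zero_history_zero_gamma_is_zero():
    reg = WindkesselRegion("x", alpha=1e6, beta=1e6, gamma=0.0,
                           normal=[1.0, 0.0])
    assert windkessel_forcing(reg, 0.0, 0.0) == 0.0


def test_windkessel_aorta_parameters_from_registry():
    wk = lookup_windkessel("omega_ao")
    assert wk == {"alpha": 3.13e6, "beta": 2.96e6, "gamma": 18.43e6}


def test_windkessel_constant_plug_flow_grows_affinely():
    """Constant plug flow U: the opposing force is alpha U + beta U t."""
    reg = WindkesselRegion("ao", **lookup_windkessel("ao"),
                           normal=[1.0, 0.0])
    U = 0.2
    for t in (0.0, 0.1, 0.5):
        f = windkessel_forcing(reg, U, U * t)
        expected = reg.alpha * U + reg.beta * U * t + reg.gamma
        assert -f == pytest.approx(expected, rel=1e-12)


def test_windkessel_region_in_solver_opposes_flow():
    """A forced region inside a periodic box decelerates a plug flow."""
    s = FlowSolver2D(32, 32, 1, 1, rho=1000.0, mu=0.01)
    s.u[:] = 0.5
    reg = WindkesselRegion("outlet", alpha=1e5, beta=0.0, gamma=0.0,
                           normal=np.array([1.0, 0.0]),
                           predicate=lambda p: (p[:, 0] > 0.4)
                           & (p[:, 0] < 0.6))
    s.add_windkessel(reg)
    for _ in range(50):
        s.step(1e-3)
    assert s.u.mean() < 0.5


# ---------------------------------------------------------------------------
# hydrodynamic loads
# ---------------------------------------------------------------------------
def test_equal_pressure_both_sides_gives_zero_leaflet_force():
    pts = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0]])
    nrm = np.tile([0.0, 0.0, 1.0], (2, 1))
    surf = LagrangianSurface(pts, nrm, [1.0, 1.0], two_sided=True)
    F = hydrodynamic_loads(surf, lambda x: np.full(len(x), 7.0),
                           probe_offset=0.1)
    assert np.allclose(F, 0.0)


def test_zero_fields_zero_force():
    pts = np.array([[0.0, 0.0, 0.0]])
    surf = LagrangianSurface(pts, [[0, 0, 1.0]], [2.0])
    F = hydrodynamic_loads(surf, lambda x: np.zeros(len(x)))
    assert np.allclose(F, 0.0)


def test_hydrostatic_load_on_closed_sphere_matches_divergence_theorem():
    """p = rho g z sampled on a closed sphere: resultant equals
    -rho g V z_hat within 2% at moderate marker density."""
    npts = 2000                      # Fibonacci sphere: uniform markers
    k = np.arange(npts) + 0.5
    phi = np.arccos(1 - 2 * k / npts)
    theta = np.pi * (1 + 5 ** 0.5) * k
    u = np.column_stack([np.cos(theta) * np.sin(phi),
                         np.sin(theta) * np.sin(phi), np.cos(phi)])
    R, rho_g = 0.5, 9810.0
    surf = LagrangianSurface(u * R, u, np.full(npts, 4 * np.pi * R ** 2
                                               / npts))
    F = hydrodynamic_loads(surf, lambda p: rho_g * p[:, 2]).sum(axis=0)
    V = 4 / 3 * np.pi * R ** 3
    assert F[2] == pytest.approx(-rho_g * V, rel=0.02)
    assert np.abs(F[:2]).max() < 0.02 * rho_g * V


def test_face_force_distribution_conserves_totals():
    faces = np.array([[0, 1, 2], [1, 2, 3]])
    Ff = np.array([[3.0, 0.0, 0.0], [0.0, 6.0, 0.0]])
    nodal = distribute_face_forces(faces, Ff, 4)
    assert np.allclose(nodal.sum(axis=0), Ff.sum(axis=0))


def test_surface_validation():
    with pytest.raises(ValueError):
        LagrangianSurface([[0, 0, 0]], [[0, 0, 2.0]], [1.0])
    with pytest.raises(ValueError):
        LagrangianSurface([[0, 0, 0]], [[0, 0, 1.0]], [0.0])
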
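import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cardiokit.mechanics import (FungMaterial, GreenStrainTriple,
                                 SpringNetwork, active_forces,
                                 advance_structure, fung_energy,
                                 green_strains, internal_forces,
                                 total_energy, uniaxial_response)

LV = FungMaterial(c=11.59, a_par=9.97, a_sheet=3.17, a_norm=3.17)


def two_tet_network():
    X0 = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1],
                   [1, 1, 1.0]]) * 0.01
    net = SpringNetwork(X0, np.full(5, 1e-3))
    net.add_block("tet", [[0, 1, 2, 3], [1, 2, 3, 4]], LV)
    return net


# ---------------------------------------------------------------------------
# Green strains
# ---------------------------------------------------------------------------
def test_rest_configuration_has_zero_strain():
    net = two_tet_network()
    for ep, es, en in green_strains(net):
        assert np.allclose([ep, es, en], 0.0)


def test_uniaxial_stretch_green_strain_value():
    """Stretch ratio 1.1 along the fiber: e_par = (1.1^2 - 1)/2."""
    net = two_tet_network()
    x = net.X0.copy()
    x[:, 0] *= 1.1
    ep, es, en = green_strains(net, x)[0]
    assert np.allclose(ep, (1.1 ** 2 - 1) / 2)
    assert np.allclose(es, 0.0) and np.allclose(en, 0.0)


@settings(max_examples=25, deadline=None)
@given(st.integers(0, 2 ** 31 - 1))
def test_affine_deformation_matches_explicit_F_oracle(seed):
    """E computed element-wise equals 1/2(F^T F - I) for the exact affine
    map applied to the nodes."""
    rng = np.random.default_rng(seed)
    F = np.eye(3) + 0.05 * rng.standard_normal((3, 3))
    if np.linalg.det(F) <= 0.1:
        return
    net = two_tet_network()
    x = net.X0 @ F.T
    E = 0.5 * (F.T @ F - np.eye(3))
    ep, es, en = green_strains(net, x)[0]
    assert np.allclose(ep, E[0, 0], atol=1e-12)
    assert np.allclose(es, E[1, 1], atol=1e-12)
    assert np.allclose(en, E[2, 2], atol=1e-12)


def test_inverted_element_raises():
    net = two_tet_network()
    x = net.X0.copy()
    x[:, 0] *= -1.0
    with pytest.raises(ValueError):
        green_strains(net, x)


def test_green_strain_lower_bound_enforced():
    with pytest.raises(ValueError):
        GreenStrainTriple(-0.6)


# ---------------------------------------------------------------------------
# Fung energy
# ---------------------------------------------------------------------------
def test_zero_strain_zero_energy():
    assert fung_energy(GreenStrainTriple(0.0), LV) == 0.0


def test_lv_energy_closed_form():
    """c/2 (exp(a_par e^2) - 1) at e_par = 0.1 for the left-ventricle
    constants: 11.59/2 (e^0.0997 - 1)."""
    W = fung_energy(GreenStrainTriple(0.1), LV)
    assert W == pytest.approx(11.59 / 2 * (np.exp(0.0997) - 1.0),
                              rel=1e-12)


def test_transverse_symmetry_when_exponents_equal():
    W1 = fung_energy((0.0, 0.07, 0.02), LV)
    W2 = fung_energy((0.0, 0.02, 0.07), LV)
    assert W1 == pytest.approx(W2, rel=1e-14)


def test_overflow_guard():
    stiff = FungMaterial(c=1.0, a_par=1e5, a_sheet=1.0, a_norm=1.0)
    with pytest.raises(OverflowError):
        fung_energy((0.3, 0.0, 0.0), stiff)


def test_material_validation():
    with pytest.raises(ValueError):
        FungMaterial(c=-1.0, a_par=1.0, a_sheet=1.0)
    with pytest.raises(ValueError):
        FungMaterial(c=1.0, a_par=-1.0, a_sheet=1.0)


# ---------------------------------------------------------------------------
# internal forces
# ---------------------------------------------------------------------------
def test_internal_forces_zero_at_rest():
    net = two_tet_network()
    assert np.allclose(internal_forces(net), 0.0)


def test_internal_forces_are_exact_energy_gradient():
    """Central finite differences of the assembled energy reproduce the
    analytic nodal forces to 1e-6 relative."""
    rng = np.random.default_rng(0)
    net = two_tet_network()
    x = net.X0 + 0.002 * rng.standard_normal(net.X0.shape)
    f = internal_forces(net, x)
    eps = 1e-8
    fd = np.zeros_like(f)
    for i in range(net.n_nodes):
        for d in range(3):
            xp, xm = x.copy(), x.copy()
            xp[i, d] += eps
            xm[i, d] -= eps
            fd[i, d] = -(total_energy(net, xp)
                         - total_energy(net, xm)) / (2 * eps)
    assert np.abs(f - fd).max() <= 1e-6 * np.abs(fd).max()


def test_rigid_translation_leaves_forces_unchanged():
    rng = np.random.default_rng(1)
    net = two_tet_network()
    x = net.X0 + 0.002 * rng.standard_normal(net.X0.shape)
    f1 = internal_forces(net, x)
    f2 = internal_forces(net, x + np.array([0.3, -0.1, 0.7]))
    assert np.allclose(f1, f2, atol=1e-12)


def test_momentum_conservation_internal_plus_active():
    rng = np.random.default_rng(2)
    net = two_tet_network()
    x = net.X0 + 0.002 * rng.standard_normal(net.X0.shape)
    f = internal_forces(net, x) + active_forces(net, 12.0, x)
    assert np.abs(f.sum(axis=0)).max() < 1e-12 * np.abs(f).max()


# ---------------------------------------------------------------------------
# active forces
# ---------------------------------------------------------------------------
def test_zero_tension_zero_force():
    net = two_tet_network()
    assert np.allclose(active_forces(net, 0.0), 0.0)


def test_single_tet_active_force_self_equilibrated():
    X0 = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1.0]]) * 0.01
    net = SpringNetwork(X0, np.full(4, 1e-3))
    net.add_block("tet", [[0, 1, 2, 3]], LV)
    f = active_forces(net, 10.0)
    scale = np.abs(f).max()
    assert scale > 0
    assert np.abs(f.sum(axis=0)).max() < 1e-12 * scale
    torque = np.cross(net.x, f).sum(axis=0)
    assert np.abs(torque).max() < 1e-12 * scale * np.abs(net.x).max()


def test_negative_tension_rejected():
    net = two_tet_network()
    with pytest.raises(ValueError):
        active_forces(net, -1.0)


def test_fiber_aligned_bar_shortens_under_tension():
    """Quasi-static (heavily damped) relaxation of a free bar with
    uniform active tension ends shorter along the fiber axis."""
    X0 = np.array([[0, 0, 0], [0.01, 0, 0], [0.02, 0, 0.0]])
    net = SpringNetwork(X0, np.full(3, 1e-3))
    mat = FungMaterial(c=5.0, a_par=4.0, a_sheet=4.0)
    net.add_block("bar", [[0, 1], [1, 2]], mat, cross_section=1e-4)
    L0 = net.x[-1, 0] - net.x[0, 0]
    for _ in range(20000):
        F = internal_forces(net) + active_forces(net, 2.0)
        advance_structure(net, F, 1e-4, damping=0.05)
    L = np.linalg.norm(net.x[-1] - net.x[0])
    assert L < 0.95 * L0
    # energy-minimization oracle: equilibrium strain satisfies
    # dW/de + Ta = 0 (per unit volume, 1D)
    lam = L / L0
    e = 0.5 * (lam ** 2 - 1.0)
    residual = mat.c * mat.a_par * e * np.exp(mat.a_par * e ** 2) + 2.0
    assert abs(residual) < 0.05 * 2.0


# ---------------------------------------------------------------------------
# time integration
# ---------------------------------------------------------------------------
def test_force_free_motion_is_uniform():
    net = SpringNetwork(np.zeros((1, 3)), [2.0])
    net.vel[0] = [1.0, 0.5, -0.2]
    for _ in range(100):
        advance_structure(net, np.zeros((1, 3)), 0.01)
    assert np.allclose(net.x[0], [1.0, 0.5, -0.2], rtol=1e-12)


def test_harmonic_oscillator_period_within_1_percent():
    """Linear spring-mass integrated with the two-step Adams–Bashforth
    update: period within 1% of 2 pi sqrt(m/k) at dt = T/1000."""
    m, k = 0.5, 200.0
    T = 2 * np.pi * np.sqrt(m / k)
    dt = T / 1000
    net = SpringNetwork(np.array([[1.0, 0, 0]]), [m])
    crossings = []
    x_prev = net.x[0, 0]
    for i in range(5000):
        F = np.array([[-k * net.x[0, 0], 0.0, 0.0]])
        advance_structure(net, F, dt)
        if x_prev > 0 >= net.x[0, 0]:
            frac = x_prev / (x_prev - net.x[0, 0])
            crossings.append((i + frac) * dt)
        x_prev = net.x[0, 0]
    periods = np.diff(crossings)
    assert np.mean(periods) == pytest.approx(T, rel=0.01)


def test_oscillator_energy_drift_below_1_percent_over_10_periods():
    m, k = 0.5, 200.0
    T = 2 * np.pi * np.sqrt(m / k)
    dt = T / 1000
    net = SpringNetwork(np.array([[1.0, 0, 0]]), [m])
    E0 = 0.5 * k * 1.0 ** 2
    for _ in range(10000):
        F = np.array([[-k * net.x[0, 0], 0.0, 0.0]])
        advance_structure(net, F, dt)
    E = 0.5 * k * net.x[0, 0] ** 2 + 0.5 * m * net.vel[0, 0] ** 2
    assert abs(E - E0) / E0 < 0.01


def test_damping_dissipates_energy():
    net = two_tet_network()
    net.x = net.X0 * 1.05
    E_hist = []
    for _ in range(200):
        F = internal_forces(net)
        advance_structure(net, F, 1e-5, damping=0.05)
        E = total_energy(net) + 0.5 * np.sum(net.mass[:, None]
                                             * net.vel ** 2)
        E_hist.append(E)
    assert E_hist[-1] < E_hist[0]


def test_nonfinite_force_rejected():
    net = two_tet_network()
    with pytest.raises(ValueError):
        advance_structure(net, np.full((5, 3), np.nan), 0.01)


# ---------------------------------------------------------------------------
# uniaxial response / membranes
# ---------------------------------------------------------------------------
def test_uniaxial_zero_stress_at_unit_stretch():
    e, s = uniaxial_response(LV, [1.0])
    assert s[0] == 0.0


def test_fiber_stiffer_than_cross_fiber():
    """All myocardial rows have a_par > a_perp, so the fiber-direction
    stress exceeds the cross-fiber stress at equal strain."""
    from cardiokit.registries import FUNG_MATERIALS
    grid = np.linspace(1.01, 1.15, 10)
    for name in ("LV", "LA", "RV"):
        mat = FUNG_MATERIALS[name]
        _, s_par = uniaxial_response(mat, grid)
        _, s_perp = uniaxial_response(mat, grid, axis="norm")
        assert np.all(s_par > s_perp)
    # arteries are near-isotropic: ratio close to one
    art = FUNG_MATERIALS["vessels"]
    _, sp = uniaxial_response(art, grid)
    _, sn = uniaxial_response(art, grid, axis="norm")
    assert np.all(sp / sn < 1.15)


def test_exponential_stiffening_convex():
    stretches = np.sqrt(1 + 2 * np.linspace(0.001, 0.2, 50))
    e, s = uniaxial_response(LV, stretches)
    d2 = np.diff(s, 2)
    assert np.all(d2 > 0)


def test_membrane_elements_use_valve_materials():
    """Triangulated membrane with a valve row: forces are an exact energy
    gradient with no sheet-normal strain."""
    from cardiokit.registries import lookup_material
    mat = lookup_material("aortic_pulmonary_valve")
    X0 = np.array([[0, 0, 0], [1e-3, 0, 0], [0, 1e-3, 0],
                   [1e-3, 1e-3, 1e-4]])
    net = SpringNetwork(X0, np.full(4, 1e-6))
    net.add_block("tri", [[0, 1, 2], [1, 3, 2]], mat,
                  fibers=np.tile([1.0, 0, 0], (2, 1)), thickness=5e-4)
    rng = np.random.default_rng(5)
    x = X0 + 5e-6 * rng.standard_normal(X0.shape)
    f = internal_forces(net, x)
    eps = 1e-10
    fd = np.zeros_like(f)
    for i in range(4):
        for d in range(3):
            xp, xm = x.copy(), x.copy()
            xp[i, d] += eps
            xm[i, d] -= eps
            fd[i, d] = -(total_energy(net, xp)
                         - total_energy(net, xm)) / (2 * eps)
    assert np.abs(f - fd).max() <= 1e-5 * max(np.abs(fd).max(), 1e-30)
    ep, es, en = green_strains(net, x)[0]
    assert np.allclose(en, 0.0)
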
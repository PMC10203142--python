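import numpy as np
import pytest

from cardiokit.cell_models import MinimalModel, get_model
from cardiokit.ep_solver import (EPSystem, ConductionSegment, FiberFrame,
                                 ConductivitySet, PassiveCell, Stimulus,
                                 StimulusProtocol, TissueMesh,
                                 assemble_conductivity, av_transit_delay,
                                 build_conduction_system,
                                 calibrate_av_conductivity,
                                 measure_cv, monodomain_equivalent)
from cardiokit.fixtures import FixtureSpec, make_fixture

from conftest import isotropic_tensors, run_cable_wave


# ---------------------------------------------------------------------------
# conductivity assembly
# ---------------------------------------------------------------------------
def test_isotropic_components_give_identity():
    frames = FiberFrame.axis_aligned(3)
    M = assemble_conductivity(frames, (1.0, 1.0, 1.0))
    assert np.allclose(M, np.eye(3))


def test_ventricular_intracellular_tensor_is_diagonal_in_fiber_frame():
    """Axis-aligned fibers with the ventricular intracellular triple give
    diag(0.17, 0.019, 0.019) mS/mm."""
    frames = FiberFrame.axis_aligned(1)
    M = assemble_conductivity(frames, (0.17, 0.019, 0.019))
    assert np.allclose(M[0], np.diag([0.17, 0.019, 0.019]))


def test_rotated_frame_preserves_eigenvalues():
    rng = np.random.default_rng(3)
    A = rng.standard_normal((3, 3))
    Q, _ = np.linalg.qr(A)
    if np.linalg.det(Q) < 0:
        Q[:, 0] *= -1
    frames = FiberFrame(Q.T[None, :, :])
    M = assemble_conductivity(frames, (0.17, 0.019, 0.019))
    ev = np.sort(np.linalg.eigvalsh(M[0]))
    assert np.allclose(ev, [0.019, 0.019, 0.17], atol=1e-12)
    # symmetric positive definite
    assert np.allclose(M[0], M[0].T)
    assert np.all(ev > 0)


def test_non_orthonormal_frame_rejected():
    with pytest.raises(ValueError):
        FiberFrame(np.ones((1, 3, 3)))


def test_monodomain_reduction_factor():
    M = np.diag([0.17, 0.019, 0.019])
    assert np.allclose(monodomain_equivalent(M, 1.0),
                       np.diag([0.085, 0.0095, 0.0095]))
    assert np.allclose(monodomain_equivalent(M, 1e9), M, rtol=1e-8)
    with pytest.raises(ValueError):
        monodomain_equivalent(M, 0.0)


def test_monodomain_only_registry_rows_pass_through():
    from cardiokit.registries import lookup_conductivity
    row = lookup_conductivity("purkinje")["conductivity"]
    assert row.monodomain_only
    assert row.m_int == (3.95, 3.95, 3.95)


# ---------------------------------------------------------------------------
# diffusion / reaction-diffusion
# ---------------------------------------------------------------------------
def test_uniform_field_evolves_like_single_cell(cable20, minimal_model):
    """Spatially uniform v: the diffusion term vanishes exactly and the
    tissue follows the single-cell ODE."""
    mesh = cable20.mesh
    sys_ = EPSystem(mesh, isotropic_tensors(mesh.n_cells, 0.2),
                    minimal_model, chi_cm=0.5)
    sys_.v[:] = 0.4
    sys_.s[0][0, :] = 0.1
    from cardiokit.cell_models import CellState, step_cell
    cell = CellState(0.4, np.array([0.1]))
    for _ in range(200):
        sys_.step(0.05)
        cell = step_cell(minimal_model, cell, 0.05)
    assert np.ptp(sys_.v) < 1e-12
    assert sys_.v[0] == pytest.approx(cell.v, abs=1e-9)


def test_diffusion_conserves_total_charge(cable20):
    mesh = cable20.mesh
    sys_ = EPSystem(mesh, isotropic_tensors(mesh.n_cells, 0.2),
                    PassiveCell(), chi_cm=0.5)
    x = mesh.centroids[:, 0]
    sys_.v = np.exp(-0.5 * ((x - 10.0) / 1.0) ** 2)
    mass0 = (sys_.v * mesh.volumes).sum()
    for _ in range(500):
        sys_.step(0.02)
    drift = abs((sys_.v * mesh.volumes).sum() - mass0) / mass0
    assert drift < 1e-10


def test_gaussian_variance_grows_like_heat_kernel():
    """Diffusion only: Var grows as 2 (m / chi Cm) t within 2%."""
    fix = make_fixture(FixtureSpec("cable", (40.0,), 0.1))
    mesh = fix.mesh
    m_s, chicm = 0.1, 0.5
    sys_ = EPSystem(mesh, isotropic_tensors(mesh.n_cells, m_s),
                    PassiveCell(), chi_cm=chicm)
    x = mesh.centroids[:, 0]
    sys_.v = np.exp(-0.5 * (x - 20.0) ** 2)

    def variance():
        w = sys_.v * mesh.volumes
        mu = (w * x).sum() / w.sum()
        return ((x - mu) ** 2 * w).sum() / w.sum()

    v0 = variance()
    T = 20.0
    for _ in range(int(T / 0.01)):
        sys_.step(0.01)
    growth = variance() - v0
    assert growth == pytest.approx(2.0 * (m_s / chicm) * T, rel=0.02)


def test_quartering_conductivity_halves_conduction_velocity(minimal_model):
    fix = make_fixture(FixtureSpec("cable", (20.0,), 0.05))
    cv1 = _measured_cv(fix, minimal_model, 0.2, 0.4)
    cv2 = _measured_cv(fix, minimal_model, 0.05, 0.4)
    assert cv2 == pytest.approx(0.5 * cv1, rel=0.03)


def _measured_cv(fix, model, m_s, chicm, dt=0.01):
    sys_ = run_cable_wave(fix.mesh, model, m_s, chicm, dt=dt, T=250.0)
    L = fix.mesh.centroids[:, 0].max()
    return measure_cv(sys_.activation, fix.mesh.centroids,
                      window=(L / 4, 3 * L / 4))


def test_cv_scales_with_sqrt_conductivity(minimal_model):
    """Fitted power-law exponent over a decade of m equals 1/2."""
    fix = make_fixture(FixtureSpec("cable", (20.0,), 0.05))
    ms = np.geomspace(0.04, 0.4, 5)
    cvs = [_measured_cv(fix, minimal_model, m_, 0.4) for m_ in ms]
    slope = np.polyfit(np.log(ms), np.log(cvs), 1)[0]
    assert slope == pytest.approx(0.5, abs=0.02)


# ---------------------------------------------------------------------------
# bidomain
# ---------------------------------------------------------------------------
def _bidomain_cv(mesh, model, Mi, Me=None, mode="bidomain", chicm=0.1):
    proto = StimulusProtocol([Stimulus(cells=tuple(range(5)), onset=0.0,
                                       duration=2.0, amplitude=5.0)])
    sys_ = EPSystem(mesh, Mi, model, chi_cm=chicm, mode=mode,
                    tensors_ext=Me, protocol=proto)
    while sys_.t < 150.0:
        sys_.step(0.05)
        if sys_.activation.activated.all():
            break
    return measure_cv(sys_.activation, mesh.centroids, window=(5, 15))


def test_bidomain_with_proportional_tensors_matches_reduced_monodomain(
        cable20, minimal_model):
    mesh = cable20.mesh
    lam = 2.0
    Mi = isotropic_tensors(mesh.n_cells, 0.15)
    cv_bi = _bidomain_cv(mesh, minimal_model, Mi, lam * Mi)
    cv_mono = _bidomain_cv(mesh, minimal_model,
                           monodomain_equivalent(Mi, lam), mode="monodomain")
    assert cv_bi == pytest.approx(cv_mono, rel=0.01)


def test_1d_bidomain_equals_harmonic_mean_monodomain(cable20, minimal_model):
    """Unequal anisotropy ratios (atrial longitudinal values 0.18/0.66):
    planar 1D bidomain CV equals monodomain with m_i m_e/(m_i + m_e)."""
    mesh = cable20.mesh
    mi, me = 0.18, 0.66
    cv_bi = _bidomain_cv(mesh, minimal_model,
                         isotropic_tensors(mesh.n_cells, mi),
                         isotropic_tensors(mesh.n_cells, me))
    cv_h = _bidomain_cv(mesh, minimal_model,
                        isotropic_tensors(mesh.n_cells, mi * me / (mi + me)),
                        mode="monodomain")
    assert cv_bi == pytest.approx(cv_h, rel=0.01)


def test_bidomain_requires_extracellular_tensors(cable20, minimal_model):
    with pytest.raises(ValueError):
        EPSystem(cable20.mesh,
                 isotropic_tensors(cable20.mesh.n_cells, 0.1),
                 minimal_model, mode="bidomain")


# ---------------------------------------------------------------------------
# activation maps and CV measurement
# ---------------------------------------------------------------------------
def test_measure_cv_synthetic_plane_wave():
    """t(x) = x in (ms, mm) is a 1 m/s wave."""
    from cardiokit.ep_solver import ActivationMap
    n = 50
    amap = ActivationMap(n, 0.5)
    pos = np.column_stack([np.arange(n) * 1.0, np.zeros(n), np.zeros(n)])
    amap.times = pos[:, 0].copy()
    assert measure_cv(amap, pos) == pytest.approx(1.0)


def test_measure_cv_simultaneous_activation_raises():
    from cardiokit.ep_solver import ActivationMap
    amap = ActivationMap(10, 0.5)
    amap.times = np.zeros(10)
    pos = np.column_stack([np.arange(10.0), np.zeros(10), np.zeros(10)])
    with pytest.raises(ValueError):
        measure_cv(amap, pos)


def test_measure_cv_unactivated_probes_raise():
    from cardiokit.ep_solver import ActivationMap
    amap = ActivationMap(10, 0.5)
    pos = np.column_stack([np.arange(10.0), np.zeros(10), np.zeros(10)])
    with pytest.raises(ValueError):
        measure_cv(amap, pos)


def test_activation_map_invariant_under_cell_relabelling(minimal_model):
    fix = make_fixture(FixtureSpec("cable", (10.0,), 0.1))
    mesh = fix.mesh
    n = mesh.n_cells
    rng = np.random.default_rng(11)
    perm = rng.permutation(n)
    inv = np.argsort(perm)
    mesh2 = TissueMesh(
        volumes=mesh.volumes[perm], centroids=mesh.centroids[perm],
        face_cells=inv[mesh.face_cells], face_area=mesh.face_area,
        face_dist=mesh.face_dist, face_normal=mesh.face_normal)
    stim = tuple(int(inv[c]) for c in range(3))
    p1 = StimulusProtocol([Stimulus(cells=(0, 1, 2), onset=0.0,
                                    duration=2.0, amplitude=5.0)])
    p2 = StimulusProtocol([Stimulus(cells=stim, onset=0.0, duration=2.0,
                                    amplitude=5.0)])
    s1 = EPSystem(mesh, isotropic_tensors(n, 0.1), minimal_model,
                  chi_cm=0.25, protocol=p1)
    s2 = EPSystem(mesh2, isotropic_tensors(n, 0.1), minimal_model,
                  chi_cm=0.25, protocol=p2)
    for _ in range(1000):
        s1.step(0.05)
        s2.step(0.05)
    assert np.allclose(s1.activation.times, s2.activation.times[inv],
                       equal_nan=True, atol=1e-9)


# ---------------------------------------------------------------------------
# stimulus protocols
# ---------------------------------------------------------------------------
def test_empty_protocol_is_noop():
    p = StimulusProtocol()
    assert np.all(p.currents(10.0, 5) == 0.0)


def test_stimulus_inactive_before_onset():
    p = StimulusProtocol([Stimulus(cells=(0,), onset=0.0, duration=2.0,
                                   amplitude=1.0)])
    assert np.all(p.currents(-1.0, 3) == 0.0)
    assert p.currents(1.0, 3)[0] == 1.0
    assert p.currents(2.0, 3)[0] == 0.0   # half-open interval


def test_stimulus_validation():
    with pytest.raises(ValueError):
        Stimulus(cells=(0,), onset=-1.0, duration=2.0, amplitude=1.0)
    with pytest.raises(ValueError):
        Stimulus(cells=(0,), onset=0.0, duration=0.0, amplitude=1.0)
    with pytest.raises(ValueError):
        Stimulus(cells=(0,), onset=0.0, duration=1.0, amplitude=np.inf)


def test_two_leads_with_delay_produce_offset_early_sites(minimal_model):
    """Two stimulus sites 50 ms apart appear as two early-activation
    islands whose onset difference reads back as 50 ms (+- dt)."""
    fix = make_fixture(FixtureSpec("cable", (30.0,), 0.1))
    mesh = fix.mesh
    n = mesh.n_cells
    p = StimulusProtocol([
        Stimulus(cells=(0, 1, 2), onset=0.0, duration=2.0, amplitude=5.0,
                 name="lead1"),
        Stimulus(cells=(n - 3, n - 2, n - 1), onset=0.0, duration=2.0,
                 amplitude=5.0, name="lead2")],
        lead_delays={"lead2": 50.0})
    sys_ = EPSystem(mesh, isotropic_tensors(n, 0.05), minimal_model,
                    chi_cm=0.4, protocol=p)
    while sys_.t < 150.0:
        sys_.step(0.05)
        if sys_.activation.activated.all():
            break
    t0 = sys_.activation.times[0]
    t1 = sys_.activation.times[n - 1]
    assert t1 - t0 == pytest.approx(50.0, abs=0.2)


# ---------------------------------------------------------------------------
# conduction system
# ---------------------------------------------------------------------------
def _tiny_host():
    return TissueMesh(volumes=[1.0], centroids=[[100.0, 0, 0]],
                      face_cells=np.empty((0, 2), dtype=int),
                      face_area=np.empty(0), face_dist=np.empty(0),
                      face_normal=np.empty((0, 3)))


def test_block_switch_stops_activation(minimal_model):
    """Two chained segments; blocking the second keeps it at rest."""
    segs = [ConductionSegment("a", start="s", end="j", length=5.0, n=10,
                              m=0.3, area=1.0),
            ConductionSegment("b", start="j", end="", length=5.0, n=10,
                              m=0.3, area=1.0)]
    host = _tiny_host()
    for blocks, expect_b in (((), True), (("b",), False)):
        mesh, tensors, _ = build_conduction_system(
            host, segs, np.eye(3)[None] * 0.1, blocks=blocks)
        first = int(mesh.segment_cells["a"][0])
        proto = StimulusProtocol([Stimulus(cells=(first,), onset=0.0,
                                           duration=2.0, amplitude=5.0)])
        sys_ = EPSystem(mesh, tensors, minimal_model, chi_cm=0.25,
                        protocol=proto)
        for _ in range(3000):
            sys_.step(0.05)
        b_cells = mesh.segment_cells["b"]
        activated = np.isfinite(sys_.activation.times[b_cells]).any()
        assert activated == expect_b


def test_dangling_segment_warns():
    host = _tiny_host()
    segs = [ConductionSegment("solo", start="s", end="e", length=2.0, n=2,
                              m=0.3)]
    with pytest.warns(RuntimeWarning):
        build_conduction_system(host, segs, np.eye(3)[None] * 0.1)


def test_insertion_outside_mesh_rejected():
    host = _tiny_host()
    segs = [ConductionSegment("a", start="s", end="", length=2.0, n=2,
                              m=0.3, insertion_cells=(5,))]
    with pytest.raises(ValueError):
        build_conduction_system(host, segs, np.eye(3)[None] * 0.1)


def test_av_node_conductivity_calibrates_to_100ms_delay():
    """The AV-segment conductivity is a free knob; bisection hits the
    ~100 ms transit delay used as the physiological calibration target."""
    m_av = calibrate_av_conductivity(100.0, tol=2.0)
    delay = av_transit_delay(m_av)
    assert delay == pytest.approx(100.0, abs=2.5)


def test_lbbb_block_prolongs_activation_spread():
    """Severing the left bundle forces the left side to activate through
    slow myocardial spread: completion is strictly later."""
    fix = make_fixture(FixtureSpec("mini_heart", resolution=1.5))
    q_healthy = _mini_heart_spread(fix, blocks=())
    q_lbbb = _mini_heart_spread(fix, blocks=("left_branch",))
    assert q_lbbb > q_healthy


def _mini_heart_spread(fix, blocks=(), crt_cells=None, crt_onset=5.0):
    mesh0 = fix.mesh
    mesh, tensors, net_slice = build_conduction_system(
        mesh0, fix.extra["segments"],
        isotropic_tensors(mesh0.n_cells, fix.extra["myocardial_m"]),
        blocks=blocks)
    his0 = int(mesh.segment_cells["his"][0])
    stims = [Stimulus(cells=(his0,), onset=0.0, duration=2.0,
                      amplitude=5.0, name="av")]
    if crt_cells is not None:
        stims.append(Stimulus(cells=crt_cells, onset=crt_onset,
                              duration=2.0, amplitude=5.0, name="lv_lead"))
    proto = StimulusProtocol(stims, blocks=blocks)
    myo = np.arange(mesh0.n_cells)
    net = np.arange(net_slice.start, net_slice.stop)
    groups = [(MinimalModel(), myo),
              (MinimalModel(time_scale=fix.extra["network_time_scale"]),
               net)]
    sys_ = EPSystem(mesh, tensors, groups, chi_cm=fix.extra["chi_cm"],
                    protocol=proto)
    while sys_.t < 500.0:
        sys_.step(0.1)
        if sys_.activation.activated.all():
            break
    t_myo = sys_.activation.times[myo]
    assert np.isfinite(t_myo).all()
    return float(np.nanmax(t_myo) - np.nanmin(t_myo))


# ---------------------------------------------------------------------------
# mesh validation
# ---------------------------------------------------------------------------
def test_mesh_rejects_nonpositive_geometry():
    with pytest.raises(ValueError):
        TissueMesh(volumes=[-1.0], centroids=[[0, 0, 0]],
                   face_cells=np.empty((0, 2), dtype=int),
                   face_area=np.empty(0), face_dist=np.empty(0),
                   face_normal=np.empty((0, 3)))
    with pytest.raises(ValueError):
        TissueMesh(volumes=[1.0, 1.0], centroids=[[0, 0, 0], [1, 0, 0]],
                   face_cells=[[0, 1]], face_area=[0.0], face_dist=[1.0],
                   face_normal=[[1.0, 0, 0]])


def test_conductivity_set_validation():
    with pytest.raises(ValueError):
        ConductivitySet(m_int=(0.1, -0.1, 0.1), monodomain_only=True)
    with pytest.raises(ValueError):
        ConductivitySet(m_int=(0.1, 0.1, 0.1))   # bidomain without ext
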
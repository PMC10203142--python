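"""Finite-volume monodomain/bidomain electrophysiology on synthetic meshes.

The transmembrane potential v obeys (monodomain)

    chi (Cm dv/dt + I_ion(s) + I_s) = div(M grad v)

and in bidomain form the pair

    chi (Cm dv/dt + I_ion + I_s) = div(Mi grad v) + div(Mi grad ve)
    0 = div(Mi grad v) + div((Mi + Me) grad ve)

with orthotropic conductivity tensors built from per-cell fiber triads.
Space is discretized with a two-point-flux finite-volume scheme on a
generic cell/face mesh (1D cables, 2D sheets, 3D slabs and 1D conduction
networks all share the same assembly); time uses Godunov splitting —
a Rush–Larsen/forward-Euler reaction step per cell followed by a
theta-implicit diffusion solve (Crank–Nicolson by default).  Outer
boundaries are zero-flux; the bidomain elliptic solve uses a zero-mean
gauge for the extracellular potential.

Stimulus amplitudes are expressed per unit membrane capacitance
(mV/ms); a volumetric current density I_s in uA/mm^3 converts as
I_s / (chi * Cm).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .cell_models.base import IonicModel

__all__ = [
    "TissueMesh", "FiberFrame", "ConductivitySet", "StimulusProtocol",
    "Stimulus", "ActivationMap", "assemble_conductivity",
    "monodomain_equivalent", "EPSystem", "measure_cv",
    "build_conduction_system", "ConductionSegment", "calibrate_chi_cm",
    "PassiveCell",
]


# ---------------------------------------------------------------------------
# mesh and fields
# ---------------------------------------------------------------------------
@dataclass
class TissueMesh:
    """Generic finite-volume mesh: cells with volumes/centroids plus an
    internal-face list.  Faces are stored once (i < j not required); the
    flux on a face enters cell i positively and cell j negatively, which
    makes the diffusion operator conservative by construction.  Outer
    boundaries carry no faces (zero-flux)."""

    volumes: np.ndarray          # (n,) mm^3
    centroids: np.ndarray        # (n, 3) mm
    face_cells: np.ndarray       # (nf, 2) int, the two cells sharing a face
    face_area: np.ndarray        # (nf,) mm^2
    face_dist: np.ndarray        # (nf,) mm, centroid-to-centroid distance
    face_normal: np.ndarray      # (nf, 3) unit vector from cell i to cell j
    region: np.ndarray = None    # (n,) int labels
    region_names: dict = field(default_factory=dict)

    def __post_init__(self):
        self.volumes = np.asarray(self.volumes, dtype=float)
        self.centroids = np.atleast_2d(np.asarray(self.centroids, float))
        if self.centroids.shape[1] != 3:
            raise ValueError("centroids must be (n, 3); embed 1D/2D meshes "
                             "in 3D coordinates")
        self.face_cells = np.asarray(self.face_cells, dtype=int).reshape(-1, 2)
        self.face_area = np.asarray(self.face_area, dtype=float)
        self.face_dist = np.asarray(self.face_dist, dtype=float)
        self.face_normal = np.atleast_2d(np.asarray(self.face_normal, float))
        if self.region is None:
            self.region = np.zeros(self.n_cells, dtype=int)
        self.region = np.asarray(self.region, dtype=int)
        self.validate()

    @property
    def n_cells(self) -> int:
        return self.volumes.size

    @property
    def n_faces(self) -> int:
        return self.face_cells.shape[0]

    def validate(self) -> None:
        if np.any(self.volumes <= 0):
            raise ValueError("cell volumes must be positive")
        if np.any(self.face_area <= 0) or np.any(self.face_dist <= 0):
            raise ValueError("face areas and distances must be positive")
        if self.face_cells.size and self.face_cells.max() >= self.n_cells:
            raise ValueError("face refers to a cell outside the mesh")
        nrm = np.linalg.norm(self.face_normal, axis=1)
        if self.n_faces and not np.allclose(nrm, 1.0, atol=1e-8):
            raise ValueError("face normals must be unit vectors")

    def region_cells(self, name: str) -> np.ndarray:
        inv = {v: k for k, v in self.region_names.items()}
        if name not in inv:
            raise KeyError(f"unknown region {name!r}")
        return np.where(self.region == inv[name])[0]


@dataclass
class FiberFrame:
    """Per-cell orthonormal triad (fiber, sheet, sheet-normal) as rows of a
    (n, 3, 3) array."""

    triads: np.ndarray

    def __post_init__(self):
        self.triads = np.asarray(self.triads, dtype=float)
        if self.triads.ndim == 2:
            self.triads = self.triads[None, :, :]
        gram = np.einsum("nij,nkj->nik", self.triads, self.triads)
        eye = np.eye(3)
        if not np.allclose(gram, eye, atol=1e-10):
            raise ValueError("fiber triads must be orthonormal to 1e-10")

    @classmethod
    def axis_aligned(cls, n: int) -> "FiberFrame":
        return cls(np.broadcast_to(np.eye(3), (n, 3, 3)).copy())

    @property
    def n(self) -> int:
        return self.triads.shape[0]


@dataclass(frozen=True)
class ConductivitySet:
    """Principal conductivity components (mS/mm) along the fiber, sheet and
    sheet-normal directions.  ``monodomain_only`` marks rows (fast bundles,
    Purkinje) whose table values are already the reduced monodomain
    conductivities; for those only the intracellular triple is used."""

    m_int: tuple                 # (m_par, m_sheet, m_norm)
    m_ext: tuple = None
    monodomain_only: bool = False

    def __post_init__(self):
        if any(m <= 0 for m in self.m_int):
            raise ValueError("conductivity components must be positive")
        if self.m_ext is not None and any(m <= 0 for m in self.m_ext):
            raise ValueError("conductivity components must be positive")
        if not self.monodomain_only and self.m_ext is None:
            raise ValueError("bidomain tissue needs extracellular components")


def assemble_conductivity(frames: FiberFrame, comps) -> np.ndarray:
    """Per-cell 3x3 conductivity tensors M = sum_i m_i e_i e_i^T.

    ``comps`` is a length-3 sequence (m_par, m_sheet, m_norm) applied to
    every cell, or an (n, 3) array of per-cell components.  The result is
    symmetric positive definite by construction.
    """
    m = np.asarray(comps, dtype=float)
    if m.ndim == 1:
        m = np.broadcast_to(m, (frames.n, 3))
    if m.shape != (frames.n, 3):
        raise ValueError("components must be (3,) or (n, 3)")
    if np.any(m <= 0):
        raise ValueError("conductivity components must be positive")
    e = frames.triads  # (n, 3, 3), rows are the directions
    return np.einsum("nd,ndi,ndj->nij", m, e, e)


def monodomain_equivalent(M_int: np.ndarray, lam: float) -> np.ndarray:
    """Monodomain tensor M = lam/(1+lam) * M_int for proportional
    extracellular conductivity M_ext = lam * M_int."""
    if lam <= 0:
        raise ValueError("proportionality constant lambda must be positive")
    return (lam / (1.0 + lam)) * np.asarray(M_int, dtype=float)


# ---------------------------------------------------------------------------
# stimuli and blocks
# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class Stimulus:
    """Timed current injection on a set of cells.

    ``amplitude`` is per unit membrane capacitance (mV/ms); ``delay`` lets
    CRT-style lead schedules shift a shared onset.
    """
    cells: tuple
    onset: float        # ms
    duration: float     # ms
    amplitude: float    # mV/ms
    name: str = ""

    def __post_init__(self):
        if self.onset < 0:
            raise ValueError("stimulus onset must be >= 0")
        if self.duration <= 0:
            raise ValueError("stimulus duration must be positive")
        if not np.isfinite(self.amplitude):
            raise ValueError("stimulus amplitude must be finite")


@dataclass
class StimulusProtocol:
    """Stimuli plus named conduction-block switches and per-lead delays."""

    stimuli: list = field(default_factory=list)
    blocks: tuple = ()           # names of disabled conduction-system links
    lead_delays: dict = field(default_factory=dict)  # name -> extra delay ms

    def currents(self, t: float, n_cells: int) -> np.ndarray:
        """Stimulus current per cell at time ``t`` (mV/ms)."""
        out = np.zeros(n_cells)
        for s in self.stimuli:
            onset = s.onset + self.lead_delays.get(s.name, 0.0)
            if onset <= t < onset + s.duration:
                out[list(s.cells)] += s.amplitude
        return out


apply_protocol = StimulusProtocol.currents  # spec-level alias


# ---------------------------------------------------------------------------
# activation diagnostics
# ---------------------------------------------------------------------------
class ActivationMap:
    """Per-cell first upward crossing of v through the model threshold,
    linearly interpolated in time.  Unactivated cells hold NaN."""

    def __init__(self, n_cells: int, threshold: float):
        self.threshold = float(threshold)
        self.times = np.full(n_cells, np.nan)

    def update(self, t_prev: float, t_new: float, v_prev, v_new) -> None:
        fresh = (np.isnan(self.times) & (v_prev < self.threshold)
                 & (v_new >= self.threshold))
        if np.any(fresh):
            f = (self.threshold - v_prev[fresh]) / (v_new[fresh]
                                                    - v_prev[fresh])
            self.times[fresh] = t_prev + f * (t_new - t_prev)

    @property
    def activated(self) -> np.ndarray:
        return ~np.isnan(self.times)

    def spread_duration(self) -> float:
        """Last minus first activation time over activated cells (ms)."""
        act = self.times[self.activated]
        if act.size == 0:
            raise ValueError("no cell activated")
        return float(act.max() - act.min())


def measure_cv(amap: ActivationMap, positions, axis=None,
               window=(None, None)) -> float:
    """Conduction velocity (m/s) from the least-squares slope of position
    vs activation time along ``axis``.

    ``positions`` is (n, 3) centroids (mm); ``axis`` a direction vector
    (default x).  ``window`` restricts to axial coordinates within
    [lo, hi], excluding boundary-affected ends.  mm/ms equals m/s.
    """
    positions = np.atleast_2d(np.asarray(positions, float))
    axis = np.array([1.0, 0.0, 0.0]) if axis is None else \
        np.asarray(axis, float) / np.linalg.norm(axis)
    x = positions @ axis
    lo = -np.inf if window[0] is None else window[0]
    hi = np.inf if window[1] is None else window[1]
    sel = (x >= lo) & (x <= hi) & amap.activated
    if sel.sum() < 2:
        raise ValueError("need at least two activated probes in the window")
    t = amap.times[sel]
    if np.ptp(t) == 0:
        raise ValueError("all probes activate simultaneously "
                         "(infinite speed)")
    # slope of x on t is the propagation speed
    slope = np.polyfit(t, x[sel], 1)[0]
    return float(slope)


class PassiveCell(IonicModel):
    """Membrane with no ionic currents: dv/dt = I_stim only.  Used for
    pure-diffusion studies (heat-kernel checks) and as a placeholder in
    non-excitable regions."""

    name = "passive"
    state_names = ()
    gate_idx = ()
    rest_v = 0.0
    rest_s = ()
    activation_threshold = 0.5
    Cm = 1.0

    def rates(self, v, s, I_stim=0.0):
        empty = np.empty((0,) + np.shape(v))
        return np.zeros_like(v) + I_stim, empty, empty, empty


# ---------------------------------------------------------------------------
# the reaction-diffusion system
# ---------------------------------------------------------------------------
def _face_transmissibility(mesh: TissueMesh, tensors: np.ndarray):
    """Two-point flux transmissibilities T_f = A_f * g_harm / d (mS*mm)."""
    i, j = mesh.face_cells[:, 0], mesh.face_cells[:, 1]
    n = mesh.face_normal
    gi = np.einsum("fi,fij,fj->f", n, tensors[i], n)
    gj = np.einsum("fi,fij,fj->f", n, tensors[j], n)
    g = 2.0 * gi * gj / (gi + gj)
    return mesh.face_area * g / mesh.face_dist


def _laplacian(mesh: TissueMesh, tensors: np.ndarray) -> sp.csr_matrix:
    """Conservative FV diffusion matrix: (L v)_i = net conductive influx."""
    nf, n = mesh.n_faces, mesh.n_cells
    if nf == 0:
        return sp.csr_matrix((n, n))
    tf = _face_transmissibility(mesh, tensors)
    i, j = mesh.face_cells[:, 0], mesh.face_cells[:, 1]
    rows = np.concatenate([i, j, i, j])
    cols = np.concatenate([j, i, i, j])
    vals = np.concatenate([tf, tf, -tf, -tf])
    return sp.csr_matrix((vals, (rows, cols)), shape=(n, n))


class EPSystem:
    """Reaction–diffusion solver bound to a mesh, conductivities and one or
    more ionic models.

    Parameters
    ----------
    mesh, tensors_int:
        FV mesh and per-cell intracellular (or reduced monodomain) tensors.
    models:
        A single ``IonicModel`` applied everywhere, or a list of
        ``(model, cell_index_array)`` partitioning the mesh.  All models in
        one system must share a potential scale.
    chi_cm:
        chi * Cm per cell (uF/mm^3); scalar or (n,).  The tables behind the
        tissue conductivities do not fix chi and Cm individually, so the
        product is treated as a single calibration constant (see
        ``calibrate_chi_cm``).
    mode:
        ``"monodomain"`` or ``"bidomain"`` (the latter needs
        ``tensors_ext``).
    theta:
        Implicitness of the diffusion step (0.5 = Crank–Nicolson, 1 =
        backward Euler).
    """

    def __init__(self, mesh: TissueMesh, tensors_int: np.ndarray, models,
                 chi_cm=1.0, mode: str = "monodomain", tensors_ext=None,
                 protocol: StimulusProtocol | None = None, theta: float = 0.5):
        if mode not in ("monodomain", "bidomain"):
            raise ValueError("mode must be 'monodomain' or 'bidomain'")
        if mode == "bidomain" and tensors_ext is None:
            raise ValueError("bidomain mode requires extracellular tensors")
        self.mesh = mesh
        self.mode = mode
        self.theta = float(theta)
        self.protocol = protocol or StimulusProtocol()
        n = mesh.n_cells
        self.chi_cm = np.broadcast_to(np.asarray(chi_cm, float), (n,)).copy()
        if np.any(self.chi_cm <= 0):
            raise ValueError("chi*Cm must be positive")

        if isinstance(models, IonicModel):
            models = [(models, np.arange(n))]
        self.groups = [(m, np.asarray(idx, dtype=int)) for m, idx in models]
        covered = np.concatenate([idx for _, idx in self.groups])
        if sorted(covered.tolist()) != list(range(n)):
            raise ValueError("model groups must partition the mesh cells")

        self.L_int = _laplacian(mesh, np.asarray(tensors_int, float))
        # dv/dt contribution scale: 1/(chi Cm V)
        self._inv_cap = 1.0 / (self.chi_cm * mesh.volumes)
        self._dt_cached = None
        if mode == "bidomain":
            both = np.asarray(tensors_int, float) + np.asarray(tensors_ext,
                                                               float)
            L_ie = _laplacian(mesh, both).tolil()
            # zero-flux Neumann problem: pin one cell, restore zero mean
            L_ie[0, :] = 0.0
            L_ie[0, 0] = 1.0
            self._solve_ext = spla.factorized(L_ie.tocsc())
        self.reset()

    # -- state ------------------------------------------------------------
    def reset(self) -> None:
        n = self.mesh.n_cells
        self.v = np.empty(n)
        self.s = []
        for model, idx in self.groups:
            self.v[idx] = model.rest_v
            rest = np.asarray(model.rest_s, dtype=float)
            self.s.append(np.tile(rest[:, None], (1, idx.size)))
        self.v_ext = np.zeros(n) if self.mode == "bidomain" else None
        self.t = 0.0
        thr = self.groups[0][0].activation_threshold
        self.activation = ActivationMap(n, thr)

    # -- stepping ----------------------------------------------------------
    def _reaction(self, dt: float, I_stim: np.ndarray) -> None:
        for (model, idx), s in zip(self.groups, self.s):
            v = self.v[idx]
            dv, ds, g_inf, g_tau = model.rates(v, s, I_stim=I_stim[idx])
            s += dt * ds
            if len(model.gate_idx):
                gi = np.asarray(model.gate_idx)
                s[gi] = g_inf + (s[gi] - g_inf) * np.exp(-dt / g_tau)
                np.clip(s[gi], 0.0, 1.0, out=s[gi])
            self.v[idx] = v + dt * dv

    def _diffusion_matrixes(self, dt: float):
        if self._dt_cached != dt:
            n = self.mesh.n_cells
            D = sp.diags(self._inv_cap) @ self.L_int
            eye = sp.identity(n, format="csr")
            A = (eye - dt * self.theta * D).tocsc()
            self._B = (eye + dt * (1.0 - self.theta) * D).tocsr()
            self._solve_A = spla.factorized(A)
            self._dt_cached = dt
        return self._solve_A, self._B

    def step(self, dt: float) -> None:
        """Advance the whole system by ``dt`` (ms): reaction then
        diffusion (Godunov splitting)."""
        if dt <= 0:
            raise ValueError("dt must be positive")
        v_old = self.v.copy()
        I_stim = self.protocol.currents(self.t, self.mesh.n_cells)
        self._reaction(dt, I_stim)
        solve_A, B = self._diffusion_matrixes(dt)
        rhs = B @ self.v
        if self.mode == "bidomain":
            # elliptic extracellular solve with zero-mean gauge
            b = -(self.L_int @ self.v)
            b[0] = 0.0
            ve = self._solve_ext(b)
            ve -= ve.mean()
            self.v_ext = ve
            rhs = rhs + dt * self._inv_cap * (self.L_int @ ve)
        self.v = solve_A(rhs)
        t_new = self.t + dt
        self.activation.update(self.t, t_new, v_old, self.v)
        self.t = t_new

    def run(self, T: float, dt: float, record_every: int = 0,
            probes=None):
        """March to time ``T``; optionally record full v frames every
        ``record_every`` steps and/or v at ``probes`` (cell indices) every
        step.  Returns a dict with times, frames, probe traces and the
        activation map."""
        n_steps = int(round(T / dt))
        frames, frame_times = [], []
        probe_trace = [] if probes is not None else None
        times = []
        for k in range(n_steps):
            self.step(dt)
            times.append(self.t)
            if probes is not None:
                probe_trace.append(self.v[list(probes)].copy())
            if record_every and (k + 1) % record_every == 0:
                frames.append(self.v.copy())
                frame_times.append(self.t)
        return {
            "t": np.asarray(times),
            "frames": frames,
            "frame_times": np.asarray(frame_times),
            "probes": None if probe_trace is None else np.asarray(probe_trace),
            "activation": self.activation,
        }


# ---------------------------------------------------------------------------
# conduction-system graph
# ---------------------------------------------------------------------------
@dataclass
class ConductionSegment:
    """One slender bundle of the conduction network: a 1D chain of FV cells
    between two named junctions, with its own conductivity (already the
    reduced monodomain value)."""

    name: str
    start: str                  # junction name
    end: str                    # junction name, or "" for a free end
    length: float               # mm
    n: int
    m: float                    # mS/mm
    area: float = 0.01          # mm^2 cross-section
    insertion_cells: tuple = ()  # host-mesh cells coupled to the END cell

    def __post_init__(self):
        if self.length <= 0 or self.n < 1 or self.m <= 0 or self.area <= 0:
            raise ValueError(f"segment {self.name}: invalid geometry")


def build_conduction_system(host: TissueMesh, segments, host_tensors,
                            blocks=(), coupling_area: float = 1.0,
                            coupling_dist: float = 0.5,
                            network_positions=None):
    """Composite mesh: host myocardium plus a 1D conduction-network graph.

    Segments sharing a junction name are joined cell-to-cell; a segment's
    ``insertion_cells`` couple its last cell to host cells through small
    coupling faces, which is the only place network and myocardium exchange
    current.  ``blocks`` lists segment names whose *start*-junction link is
    severed (conduction-block switch, e.g. a left-bundle block).

    Returns ``(mesh, tensors, network_slice)`` where ``tensors`` extends
    ``host_tensors`` with isotropic per-cell network tensors and
    ``network_slice`` indexes the appended network cells.

    Raises on a dangling segment (junction named by exactly one segment and
    no insertion) or an insertion outside the host mesh.
    """
    segments = list(segments)
    n_host = host.n_cells
    blocks = set(blocks)
    for s in segments:
        if s.insertion_cells and max(s.insertion_cells) >= n_host:
            raise ValueError(f"segment {s.name}: insertion site outside mesh")

    volumes = [host.volumes]
    centroids = [host.centroids]
    fc = [host.face_cells] if host.n_faces else []
    fa = [host.face_area] if host.n_faces else []
    fd = [host.face_dist] if host.n_faces else []
    fn = [host.face_normal] if host.n_faces else []
    scalars = []
    offset = n_host
    seg_cells = {}
    junction_ends = {}

    for s in segments:
        h = s.length / s.n
        vol = np.full(s.n, h * s.area)
        if network_positions and s.name in network_positions:
            p0, p1 = (np.asarray(p, float)
                      for p in network_positions[s.name])
        else:
            p0, p1 = np.zeros(3), np.array([s.length, 0.0, 0.0])
        frac = (np.arange(s.n) + 0.5) / s.n
        cent = p0[None, :] + frac[:, None] * (p1 - p0)[None, :]
        direction = (p1 - p0) / max(np.linalg.norm(p1 - p0), 1e-30)
        idx = np.arange(offset, offset + s.n)
        seg_cells[s.name] = idx
        volumes.append(vol)
        centroids.append(cent)
        if s.n > 1:
            fc.append(np.column_stack([idx[:-1], idx[1:]]))
            fa.append(np.full(s.n - 1, s.area))
            fd.append(np.full(s.n - 1, h))
            fn.append(np.tile(direction, (s.n - 1, 1)))
        scalars.append(np.full(s.n, s.m))
        junction_ends.setdefault(s.start, []).append((s.name, idx[0], "start"))
        if s.end:
            junction_ends.setdefault(s.end, []).append((s.name, idx[-1],
                                                        "end"))
        offset += s.n

    # join segments at shared junctions (star coupling: every 'end' cell to
    # every 'start' cell at that junction)
    for junc, members in junction_ends.items():
        starts = [m for m in members if m[2] == "start"]
        ends = [m for m in members if m[2] == "end"]
        if len(members) == 1 and not _has_insertion(segments, members[0][0]):
            warnings.warn(f"junction {junc!r} touches only segment "
                          f"{members[0][0]!r} (free end)", RuntimeWarning)
        for ename, ecell, _ in ends:
            for sname, scell, _ in starts:
                if sname in blocks or ename in blocks:
                    continue
                fc.append(np.array([[ecell, scell]]))
                fa.append(np.array([coupling_area]))
                fd.append(np.array([coupling_dist]))
                fn.append(_unit_between(centroids, ecell, scell, n_host))

    # insertions into the host myocardium, distributed over the distal
    # cells of the segment (one host per network cell where possible) so a
    # single junction cell is not clamped by the cold myocardial load
    for s in segments:
        cells_ = seg_cells[s.name]
        n_ins = len(s.insertion_cells)
        for k, hc in enumerate(s.insertion_cells):
            net_cell = cells_[-1 - (k % min(n_ins, len(cells_)))]
            fc.append(np.array([[int(net_cell), int(hc)]]))
            fa.append(np.array([coupling_area]))
            fd.append(np.array([coupling_dist]))
            fn.append(_unit_between(centroids, int(net_cell), int(hc),
                                    n_host))

    mesh = TissueMesh(
        volumes=np.concatenate(volumes),
        centroids=np.concatenate(centroids),
        face_cells=(np.concatenate(fc) if fc
                    else np.empty((0, 2), dtype=int)),
        face_area=np.concatenate(fa) if fa else np.empty(0),
        face_dist=np.concatenate(fd) if fd else np.empty(0),
        face_normal=np.concatenate(fn) if fn else np.empty((0, 3)),
        region=np.concatenate([host.region,
                               np.full(offset - n_host, -1)]),
        region_names={**host.region_names, -1: "conduction_system"},
    )
    scal = np.concatenate(scalars)
    net_tensors = scal[:, None, None] * np.eye(3)[None, :, :]
    tensors = np.concatenate([np.asarray(host_tensors, float), net_tensors])
    mesh.segment_cells = seg_cells
    return mesh, tensors, slice(n_host, offset)


def _has_insertion(segments, name):
    return any(s.name == name and s.insertion_cells for s in segments)


def _unit_between(centroid_blocks, a, b, n_host):
    cents = np.concatenate(centroid_blocks)
    d = cents[b] - cents[a]
    nrm = np.linalg.norm(d)
    if nrm < 1e-12:
        d, nrm = np.array([1.0, 0.0, 0.0]), 1.0
    return (d / nrm)[None, :]


# ---------------------------------------------------------------------------
# chi*Cm calibration
# ---------------------------------------------------------------------------
def _cable_cv(model, m_scalar: float, chi_cm: float, length=20.0, h=0.1,
              dt=0.02, stim_amp=None, stim_dur=2.0, T=None) -> float:
    """CV (m/s) on a 1D monodomain cable, measured over its central half."""
    from .fixtures import make_fixture, FixtureSpec  # local import (cycle)

    if stim_amp is None:
        # suprathreshold end stimulus: mV-scale models need ~100 mV/ms to
        # overcome diffusive dilution; the dimensionless minimal model ~5
        stim_amp = 100.0 if model.rest_v < -40.0 else 5.0

    spec = FixtureSpec(kind="cable", dimensions=(length,), resolution=h)
    fix = make_fixture(spec)
    mesh = fix.mesh
    tensors = m_scalar * np.broadcast_to(np.eye(3),
                                         (mesh.n_cells, 3, 3)).copy()
    protocol = StimulusProtocol([Stimulus(cells=tuple(range(5)), onset=0.0,
                                          duration=stim_dur,
                                          amplitude=stim_amp)])
    sys_ = EPSystem(mesh, tensors, model, chi_cm=chi_cm, protocol=protocol)
    if T is None:
        T = 40.0 + length / 0.03  # upper bound on transit at CV 0.03 m/s
    n_steps = int(round(T / dt))
    for _ in range(n_steps):
        sys_.step(dt)
        if sys_.activation.activated.all():
            break
    return measure_cv(sys_.activation, mesh.centroids,
                      window=(length / 4, 3 * length / 4))


def calibrate_chi_cm(model, m_scalar: float, target_cv: float,
                     length=20.0, h=0.1, dt=0.02, tol=1e-3,
                     bracket=(0.01, 10.0), max_iter=60) -> float:
    """Bisection on chi*Cm so a cable with conductivity ``m_scalar``
    conducts at ``target_cv`` (m/s).  CV decreases monotonically with
    chi*Cm (CV ~ sqrt(m / chi*Cm)), which guarantees the bracket."""
    lo, hi = bracket
    cv_lo = _cable_cv(model, m_scalar, lo, length, h, dt)
    cv_hi = _cable_cv(model, m_scalar, hi, length, h, dt)
    if not (cv_hi <= target_cv <= cv_lo):
        raise ValueError(f"target CV {target_cv} outside achievable range "
                         f"[{cv_hi:.3g}, {cv_lo:.3g}] for bracket {bracket}")
    for _ in range(max_iter):
        mid = np.sqrt(lo * hi)  # geometric: CV is a power law in chi*Cm
        cv = _cable_cv(model, m_scalar, mid, length, h, dt)
        if abs(cv - target_cv) < tol:
            return mid
        if cv > target_cv:
            lo = mid
        else:
            hi = mid
    return float(np.sqrt(lo * hi))


def av_transit_delay(m_av: float, model=None, length=40.0, n=200,
                     area=4.0, chi_cm=0.25, dt=0.1, T=500.0) -> float:
    """Transit delay (ms) across an AV-node-like slow bundle: time from
    stimulus onset at one end to activation of the far end.  The nodal
    tissue uses the standard (slow-kinetics) minimal model, which is the
    physiological picture — nodal cells conduct decrementally slowly.
    Returns NaN when conduction blocks."""
    from .cell_models import MinimalModel

    segs = [ConductionSegment("av_node", start="sa", end="",
                              length=length, n=n, m=m_av, area=area)]
    host = TissueMesh(volumes=[1.0], centroids=[[1e3, 1e3, 1e3]],
                      face_cells=np.empty((0, 2), dtype=int),
                      face_area=np.empty(0), face_dist=np.empty(0),
                      face_normal=np.empty((0, 3)))
    tensors0 = np.eye(3)[None, :, :] * 0.1
    mesh, tensors, _ = build_conduction_system(host, segs, tensors0)
    model = model or MinimalModel()
    cells_ = mesh.segment_cells["av_node"]
    end = int(cells_[-1])
    proto = StimulusProtocol([Stimulus(cells=tuple(int(c)
                                                   for c in cells_[:5]),
                                       onset=0.0, duration=2.0,
                                       amplitude=5.0)])
    sys_ = EPSystem(mesh, tensors, model, chi_cm=chi_cm, protocol=proto)
    while sys_.t < T:
        sys_.step(dt)
        if np.isfinite(sys_.activation.times[end]):
            return float(sys_.activation.times[end])
    return float("nan")


def calibrate_av_conductivity(target_delay_ms: float = 100.0,
                              bracket=(0.05, 1.29), tol=2.0,
                              max_iter=40, **kw) -> float:
    """Bisection on the AV-node conductivity so the transit delay matches
    a configurable target (default 100 ms).  Delay decreases
    monotonically with conductivity (CV ~ sqrt(m))."""
    lo, hi = bracket
    d_lo = av_transit_delay(lo, **kw)
    d_hi = av_transit_delay(hi, **kw)
    if np.isnan(d_lo):
        raise ValueError(f"conduction blocks at m={lo}: raise the lower "
                         "bracket")
    if not (d_hi <= target_delay_ms <= d_lo):
        raise ValueError(f"target delay {target_delay_ms} ms outside "
                         f"achievable range [{d_hi:.1f}, {d_lo:.1f}]")
    for _ in range(max_iter):
        mid = np.sqrt(lo * hi)
        d = av_transit_delay(mid, **kw)
        if abs(d - target_delay_ms) < tol:
            return float(mid)
        if d > target_delay_ms:
            lo = mid
        else:
            hi = mid
    return float(np.sqrt(lo * hi))
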
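"""Synthetic surface ECG from the transmembrane-potential field.

Under the assumption of an isotropic, infinite conducting medium around
the heart, the potential recorded by a surface lead at x_s is the
lead-field integral

    V_s(x_s, t) = -K \\int_heart  grad v(x, t) . grad(1 / |x - x_s|)  dx

with K absorbing the intracellular-to-torso conductivity ratio.  The
integral is evaluated cell-wise with one-point (centroid) quadrature on
the finite-volume mesh; per-cell gradients of v come from a weighted
least-squares reconstruction over face neighbours.  A two-lead trace
takes the difference V(lead1) - V(lead2); wavefronts travelling toward
a lead deflect it positive, so with the apex lead subtracted a wave
moving apex-ward reads negative.

K is not observable at desk scale, so it defaults to 1 and traces are in
arbitrary units; timing and ratio quantities (QRS-like durations,
symmetry, decay exponents) are the meaningful outputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ep_solver import ActivationMap, TissueMesh

__all__ = ["LeadSet", "ECGTrace", "surface_potential", "ecg_trace",
           "measure_intervals", "qrs_duration_from_map", "cell_gradients"]

#: minimum lead clearance, in multiples of the local cell size
CLEARANCE_CELLS = 5.0


@dataclass
class LeadSet:
    """Surface lead positions (n_leads, 3) (mm) and gain constant K."""

    positions: np.ndarray
    K: float = 1.0

    def __post_init__(self):
        self.positions = np.atleast_2d(np.asarray(self.positions, float))
        if self.positions.shape[1] != 3:
            raise ValueError("lead positions must be (n, 3)")


@dataclass
class ECGTrace:
    """Per-lead potentials (n_t, n_leads) plus the first-minus-second
    lead difference when two leads are present."""

    t: np.ndarray
    leads: np.ndarray

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.leads = np.atleast_2d(np.asarray(self.leads, float))
        if not np.all(np.isfinite(self.leads)):
            raise ValueError("non-finite ECG samples")
        if self.t.size > 1 and np.any(np.diff(self.t) <= 0):
            raise ValueError("sampling times must increase")

    @property
    def difference(self) -> np.ndarray:
        if self.leads.shape[1] < 2:
            raise ValueError("lead-pair difference needs two leads")
        return self.leads[:, 0] - self.leads[:, 1]


def cell_gradients(mesh: TissueMesh, v: np.ndarray) -> np.ndarray:
    """Per-cell gradient of a cell field by weighted least squares over
    face neighbours (the finite-volume reconstruction)."""
    n = mesh.n_cells
    grads = np.zeros((n, 3))
    if mesh.n_faces == 0:
        return grads
    i, j = mesh.face_cells[:, 0], mesh.face_cells[:, 1]
    d = mesh.centroids[j] - mesh.centroids[i]
    w = 1.0 / (np.einsum("fi,fi->f", d, d) + 1e-30)
    dv = v[j] - v[i]
    # normal equations accumulated per cell (both orientations)
    A = np.zeros((n, 3, 3))
    b = np.zeros((n, 3))
    contrib = w[:, None, None] * d[:, :, None] * d[:, None, :]
    np.add.at(A, i, contrib)
    np.add.at(A, j, contrib)
    np.add.at(b, i, (w * dv)[:, None] * d)
    np.add.at(b, j, (w * dv)[:, None] * d)
    # regularize rank-deficient cells (1D/2D meshes embedded in 3D)
    A += 1e-12 * np.eye(3)[None, :, :]
    return np.linalg.solve(A, b[:, :, None])[:, :, 0]


def surface_potential(mesh: TissueMesh, v: np.ndarray, lead_pos,
                      K: float = 1.0, gradients: np.ndarray = None) -> float:
    """Lead potential V_s for one lead position (mm), arbitrary units.

    Cell-wise quadrature of -K grad(v) . grad(1/r) with
    grad(1/r) = -(x - x_s)/r^3.  Raises if the lead sits closer to any
    cell than the clearance (5 local cell sizes).
    """
    lead = np.asarray(lead_pos, dtype=float)
    r_vec = mesh.centroids - lead
    r = np.linalg.norm(r_vec, axis=1)
    clearance = CLEARANCE_CELLS * np.cbrt(mesh.volumes)
    if np.any(r < clearance):
        raise ValueError("lead inside the clearance zone of the cardiac "
                         "mesh")
    if gradients is None:
        gradients = cell_gradients(mesh, np.asarray(v, float))
    grad_invr = -r_vec / r[:, None] ** 3
    return float(-K * np.sum(
        np.einsum("ci,ci->c", gradients, grad_invr) * mesh.volumes))


def ecg_trace(mesh: TissueMesh, frames, frame_times, leads: LeadSet) \
        -> ECGTrace:
    """Evaluate all leads for a sequence of v frames."""
    frames = list(frames)
    if len(frames) != len(frame_times):
        raise ValueError("one frame per time sample required")
    if len(frames) == 0:
        raise ValueError("no frames recorded")
    out = np.empty((len(frames), leads.positions.shape[0]))
    for k, v in enumerate(frames):
        g = cell_gradients(mesh, np.asarray(v, float))
        for m, pos in enumerate(leads.positions):
            out[k, m] = surface_potential(mesh, v, pos, K=leads.K,
                                          gradients=g)
    return ECGTrace(frame_times, out)


def qrs_duration_from_map(amap: ActivationMap, cells=None) -> float:
    """Activation-based QRS analogue: last minus first activation time
    (ms) over ``cells`` (default: all activated cells).  Raises when any
    selected cell never activates (incomplete activation)."""
    times = amap.times if cells is None else amap.times[list(cells)]
    if np.any(np.isnan(times)):
        raise ValueError("incomplete activation in the selected region")
    return float(times.max() - times.min())


def measure_intervals(source, cells=None, threshold_frac: float = 0.05):
    """QRS-like duration (ms) from an ActivationMap or an ECGTrace.

    Map-based: activation spread (last minus first activation).
    Trace-based: time between the first and last excursion of the
    lead-difference |V| above ``threshold_frac`` of its beat maximum.
    """
    if isinstance(source, ActivationMap):
        return qrs_duration_from_map(source, cells)
    trace: ECGTrace = source
    sig = np.abs(trace.difference)
    vmax = sig.max()
    if vmax == 0:
        raise ValueError("flat trace: no depolarization signal")
    above = sig >= threshold_frac * vmax
    idx = np.where(above)[0]
    return float(trace.t[idx[-1]] - trace.t[idx[0]])
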
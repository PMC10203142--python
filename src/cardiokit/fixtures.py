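"""Synthetic geometry and protocol generators (desk-scale fixtures).

Every study in this package runs on geometry generated here: 1D cables,
2D sheets, 3D slabs with transmural fiber rotation, a truncated-ellipsoid
ventricle, a flexible membrane in a fluid channel, torso lead positions,
and a "mini heart" combining a ventricle shell with a conduction network
and ECG leads.  Generation is pure: the same spec and seed always produce
identical output (the seed is recorded in the run manifest; the
generators themselves are deterministic).

Lengths in mm for EP meshes (matching mS/mm conductivities); the membrane
channel is specified in SI (m) because it feeds the fluid/structure
solvers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ep_solver import (ConductionSegment, FiberFrame, Stimulus,
                        StimulusProtocol, TissueMesh)

__all__ = ["FixtureSpec", "Fixture", "make_fixture"]

_KINDS = ("cable", "sheet", "slab", "ellipsoid_ventricle",
          "membrane_channel", "torso_leads", "mini_heart")


@dataclass(frozen=True)
class FixtureSpec:
    """What to generate: kind, physical dimensions (mm unless noted),
    resolution (cell size), fiber rule and seed."""

    kind: str
    dimensions: tuple = ()
    resolution: float = 0.1
    fiber_rule: str = "default"
    seed: int = 0
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise ValueError(f"unknown fixture kind {self.kind!r}; "
                             f"known: {_KINDS}")
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        if any(d <= 0 for d in self.dimensions):
            raise ValueError("dimensions must be positive")


@dataclass
class Fixture:
    spec: FixtureSpec
    mesh: TissueMesh = None
    frames: FiberFrame = None
    protocol: StimulusProtocol = None
    leads: np.ndarray = None
    extra: dict = field(default_factory=dict)


def make_fixture(spec: FixtureSpec) -> Fixture:
    builder = {
        "cable": _cable, "sheet": _sheet, "slab": _slab,
        "ellipsoid_ventricle": _ellipsoid, "membrane_channel": _membrane,
        "torso_leads": _torso_leads, "mini_heart": _mini_heart,
    }[spec.kind]
    return builder(spec)


# ---------------------------------------------------------------------------
def _structured_mesh(shape, h, thickness=None):
    """Voxel/pixel/segment mesh on a structured lattice; returns the mesh
    plus the lattice index array for region labelling."""
    nx, ny, nz = shape
    n = nx * ny * nz
    ii, jj, kk = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz),
                             indexing="ij")
    idx = np.arange(n).reshape(nx, ny, nz)
    cents = np.column_stack([(ii.ravel() + 0.5) * h,
                             (jj.ravel() + 0.5) * h,
                             (kk.ravel() + 0.5) * h])
    tz = h if thickness is None else thickness
    cellvol = h * h * tz if nz == 1 and ny > 1 else \
        (h * tz * tz if ny == 1 and nz == 1 else h ** 3)
    fc, fa, fd, fn = [], [], [], []
    for axis, nvec in ((0, (1.0, 0, 0)), (1, (0, 1.0, 0)), (2, (0, 0, 1.0))):
        if shape[axis] < 2:
            continue
        sl_lo = [slice(None)] * 3
        sl_hi = [slice(None)] * 3
        sl_lo[axis] = slice(0, -1)
        sl_hi[axis] = slice(1, None)
        a = idx[tuple(sl_lo)].ravel()
        b = idx[tuple(sl_hi)].ravel()
        fc.append(np.column_stack([a, b]))
        area = cellvol / h
        fa.append(np.full(a.size, area))
        fd.append(np.full(a.size, h))
        fn.append(np.tile(np.asarray(nvec), (a.size, 1)))
    mesh = TissueMesh(
        volumes=np.full(n, cellvol), centroids=cents,
        face_cells=np.concatenate(fc),
        face_area=np.concatenate(fa),
        face_dist=np.concatenate(fd),
        face_normal=np.concatenate(fn))
    return mesh, idx


def _frames_from_angles(theta_deg):
    """In-plane fiber angles (deg, about z) -> orthonormal triads."""
    th = np.deg2rad(np.asarray(theta_deg, float))
    c, s = np.cos(th), np.sin(th)
    z = np.zeros_like(th)
    o = np.ones_like(th)
    e_par = np.stack([c, s, z], axis=-1)
    e_sheet = np.stack([-s, c, z], axis=-1)
    e_norm = np.stack([z, z, o], axis=-1)
    return FiberFrame(np.stack([e_par, e_sheet, e_norm], axis=1))


def _cable(spec: FixtureSpec) -> Fixture:
    (length,) = spec.dimensions or (20.0,)
    h = spec.resolution
    n = int(round(length / h))
    mesh, _ = _structured_mesh((n, 1, 1), h)
    frames = _frames_from_angles(np.zeros(n))
    protocol = StimulusProtocol([Stimulus(cells=(0, 1, 2), onset=0.0,
                                          duration=2.0, amplitude=2.0,
                                          name="proximal")])
    return Fixture(spec, mesh=mesh, frames=frames, protocol=protocol)


def _sheet(spec: FixtureSpec) -> Fixture:
    Lx, Ly = spec.dimensions or (10.0, 10.0)
    h = spec.resolution
    nx, ny = int(round(Lx / h)), int(round(Ly / h))
    thickness = spec.params.get("thickness", h)
    mesh, _ = _structured_mesh((nx, ny, 1), h, thickness=thickness)
    # atrial-style rule: fiber orientation uniform through the thickness
    angle = spec.params.get("fiber_angle", 0.0)
    frames = _frames_from_angles(np.full(mesh.n_cells, angle))
    protocol = StimulusProtocol([Stimulus(cells=(0,), onset=0.0,
                                          duration=2.0, amplitude=2.0,
                                          name="corner")])
    return Fixture(spec, mesh=mesh, frames=frames, protocol=protocol)


def _slab(spec: FixtureSpec) -> Fixture:
    Lx, Ly, Lz = spec.dimensions or (10.0, 10.0, 3.0)
    h = spec.resolution
    nx, ny, nz = (int(round(d / h)) for d in (Lx, Ly, Lz))
    mesh, idx = _structured_mesh((nx, ny, nz), h)
    # ventricular rule: fiber angle rotates linearly across the wall,
    # +60 deg at one face to -60 deg at the other
    a_hi, a_lo = spec.params.get("angle_range", (60.0, -60.0))
    layer = np.empty(mesh.n_cells)
    kk = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz),
                     indexing="ij")[2].ravel()
    if nz > 1:
        layer = kk / (nz - 1.0)
    else:
        layer[:] = 0.5
    angles = a_hi + (a_lo - a_hi) * layer
    frames = _frames_from_angles(angles)
    protocol = StimulusProtocol([Stimulus(cells=tuple(idx[0, :2, :].ravel()),
                                          onset=0.0, duration=2.0,
                                          amplitude=2.0, name="edge")])
    fix = Fixture(spec, mesh=mesh, frames=frames, protocol=protocol)
    fix.extra["fiber_angles"] = angles
    fix.extra["lattice"] = idx
    return fix


def _ellipsoid(spec: FixtureSpec) -> Fixture:
    """Truncated prolate-spheroid shell: an idealized single ventricle.

    dimensions = (outer equatorial radius a, outer long semi-axis c,
    wall thickness w), mm.  The shell is truncated at the base plane
    z = base_fraction * c (apex at z = -c).
    """
    a, c, w = spec.dimensions or (15.0, 25.0, 4.0)
    h = spec.resolution
    base_frac = spec.params.get("base_fraction", 0.35)
    xs = np.arange(-a, a + h, h)
    zs = np.arange(-c, base_frac * c + h, h)
    X, Y, Z = np.meshgrid(xs + 0.5 * h, xs + 0.5 * h, zs + 0.5 * h,
                          indexing="ij")
    outer = (X / a) ** 2 + (Y / a) ** 2 + (Z / c) ** 2
    ai, ci = a - w, c - w
    inner = (X / ai) ** 2 + (Y / ai) ** 2 + (Z / ci) ** 2
    keep = (outer <= 1.0) & (inner >= 1.0) & (Z <= base_frac * c)
    coords = np.column_stack([X[keep], Y[keep], Z[keep]])
    n = coords.shape[0]
    # faces: link lattice neighbours among kept voxels
    lin = -np.ones(keep.shape, dtype=int)
    lin[keep] = np.arange(n)
    fc, fn = [], []
    for axis, nvec in ((0, (1.0, 0, 0)), (1, (0, 1.0, 0)), (2, (0, 0, 1.0))):
        sl_lo = [slice(None)] * 3
        sl_hi = [slice(None)] * 3
        sl_lo[axis] = slice(0, -1)
        sl_hi[axis] = slice(1, None)
        a_ = lin[tuple(sl_lo)].ravel()
        b_ = lin[tuple(sl_hi)].ravel()
        ok = (a_ >= 0) & (b_ >= 0)
        fc.append(np.column_stack([a_[ok], b_[ok]]))
        fn.append(np.tile(np.asarray(nvec), (ok.sum(), 1)))
    fc = np.concatenate(fc)
    region = np.zeros(n, dtype=int)
    region[coords[:, 2] < -0.8 * c] = 1           # apex
    region[coords[:, 2] > base_frac * c - 1.5 * h] = 2  # base ring
    mesh = TissueMesh(
        volumes=np.full(n, h ** 3), centroids=coords,
        face_cells=fc, face_area=np.full(len(fc), h * h),
        face_dist=np.full(len(fc), h), face_normal=np.concatenate(fn),
        region=region, region_names={0: "wall", 1: "apex", 2: "base"})
    # fibers: circumferential direction rotated transmurally
    radial = np.column_stack([coords[:, 0] / a ** 2, coords[:, 1] / a ** 2,
                              coords[:, 2] / c ** 2])
    radial /= np.linalg.norm(radial, axis=1, keepdims=True) + 1e-30
    zhat = np.array([0.0, 0.0, 1.0])
    circ = np.cross(np.broadcast_to(zhat, radial.shape), radial)
    bad = np.linalg.norm(circ, axis=1) < 1e-8     # on the axis (apex tip)
    circ[bad] = [1.0, 0.0, 0.0]
    circ /= np.linalg.norm(circ, axis=1, keepdims=True)
    longi = np.cross(radial, circ)
    longi /= np.linalg.norm(longi, axis=1, keepdims=True)
    # normalized wall depth: 0 at the endocardial (inner) surface, 1 at
    # the epicardial (outer) surface, from the two level functions
    u_out = np.sqrt(outer[keep])   # <= 1 inside the outer ellipsoid
    u_in = np.sqrt(inner[keep])    # >= 1 outside the inner ellipsoid
    depth = np.clip((u_in - 1.0) / ((u_in - 1.0) + (1.0 - u_out) + 1e-30),
                    0.0, 1.0)
    ang = np.deg2rad(60.0 - 120.0 * depth)
    e_par = np.cos(ang)[:, None] * circ + np.sin(ang)[:, None] * longi
    e_sheet = -np.sin(ang)[:, None] * circ + np.cos(ang)[:, None] * longi
    e_norm = np.cross(e_par, e_sheet)
    # re-orthonormalize against round-off
    e_par /= np.linalg.norm(e_par, axis=1, keepdims=True)
    e_sheet -= np.einsum("ni,ni->n", e_sheet, e_par)[:, None] * e_par
    e_sheet /= np.linalg.norm(e_sheet, axis=1, keepdims=True)
    e_norm = np.cross(e_par, e_sheet)
    frames = FiberFrame(np.stack([e_par, e_sheet, e_norm], axis=1))
    apex_cells = tuple(np.where(region == 1)[0][:4].tolist())
    protocol = StimulusProtocol([Stimulus(cells=apex_cells, onset=0.0,
                                          duration=2.0, amplitude=2.0,
                                          name="apex")])
    return Fixture(spec, mesh=mesh, frames=frames, protocol=protocol)


def _membrane(spec: FixtureSpec) -> Fixture:
    """Flexible membrane (cantilevered flag) in a 2D channel, SI units.

    dimensions = (channel length, channel height, membrane length), m.
    The membrane is a chain of bar elements clamped at the bottom wall a
    quarter of the way along the channel.  The 2D convention is
    per-unit-depth: the membrane has a physical thickness (default 1 mm)
    and all masses, sections and loads are per metre of depth.
    """
    from .mechanics import FungMaterial, SpringNetwork

    Lx, Ly, Lm = spec.dimensions or (0.04, 0.01, 0.004)
    n_seg = spec.params.get("n_segments", 8)
    x0 = spec.params.get("anchor_x", 0.25 * Lx)
    rho_tissue = spec.params.get("density", 1060.0)
    thickness = spec.params.get("thickness", 1e-3)   # m
    nodes = np.column_stack([
        np.full(n_seg + 1, x0),
        np.linspace(0.0, Lm, n_seg + 1),
        np.zeros(n_seg + 1)])
    seg_mass = rho_tissue * thickness * (Lm / n_seg)  # kg per m depth
    masses = np.full(n_seg + 1, seg_mass)
    masses[0] = 1e9  # clamped anchor: effectively immobile
    net = SpringNetwork(nodes, masses)
    mat = FungMaterial(c=spec.params.get("c_kpa", 20.0), a_par=2.0,
                       a_sheet=2.0, a_norm=0.0)
    net.add_block("bar", np.column_stack([np.arange(n_seg),
                                          np.arange(1, n_seg + 1)]),
                  mat, cross_section=thickness)
    fix = Fixture(spec)
    fix.extra.update(network=net, fixed_nodes=(0,),
                     channel=dict(Lx=Lx, Ly=Ly), thickness=thickness,
                     material=mat)
    return fix


def _torso_leads(spec: FixtureSpec) -> Fixture:
    """Two ECG leads on a torso box around a cardiac mesh.

    dimensions = bounding extents of the heart (mm); leads sit along the
    long (z) axis, one above the base and one below the apex, at the
    configured heart-to-skin clearance (default 35 mm).
    """
    clearance = spec.params.get("heart_to_skin", 35.0)
    if spec.dimensions:
        ext = np.asarray(spec.dimensions, dtype=float)
    else:
        ext = np.array([30.0, 30.0, 50.0])
    center = spec.params.get("center", (0.0, 0.0, 0.0))
    cz = np.asarray(center, float)
    top = cz + np.array([0.0, 0.0, ext[2] / 2 + clearance])
    bottom = cz - np.array([0.0, 0.0, ext[2] / 2 + clearance])
    return Fixture(spec, leads=np.stack([top, bottom]))


def _mini_heart(spec: FixtureSpec) -> Fixture:
    """One ventricle shell + conduction-graph spec + ECG leads.

    The conduction system is returned as segment specs (trunk/AV node,
    left and right bundle branches inserting into opposite sides of the
    shell); the EP driver assembles it with
    ``ep_solver.build_conduction_system``.
    """
    h = spec.resolution if spec.resolution != 0.1 else 1.0
    vent = _ellipsoid(FixtureSpec("ellipsoid_ventricle",
                                  spec.dimensions or (12.0, 18.0, 4.0),
                                  resolution=h, seed=spec.seed,
                                  params=spec.params))
    mesh = vent.mesh
    cents = mesh.centroids
    mid = (cents[:, 2] > -0.3 * 18.0) & (cents[:, 2] < 0.2 * 18.0)
    left = np.where(mid & (cents[:, 0] < -0.5 * np.abs(cents[:, 1])))[0]
    right = np.where(mid & (cents[:, 0] > 0.5 * np.abs(cents[:, 1])))[0]
    # bundle conductivity from the fast-conduction registry row; a 1 mm^2
    # cross-section and ~10 insertion cells per branch keep the
    # Purkinje-myocardial junctions suprathreshold at this coarse scale
    m_bundle = 1.29
    segments = [
        ConductionSegment("his", start="av", end="bifurcation",
                          length=8.0, n=8, m=m_bundle, area=4.0),
        ConductionSegment("left_branch", start="bifurcation", end="",
                          length=12.0, n=12, m=m_bundle, area=4.0,
                          insertion_cells=tuple(left[:10].tolist())),
        ConductionSegment("right_branch", start="bifurcation", end="",
                          length=12.0, n=12, m=m_bundle, area=4.0,
                          insertion_cells=tuple(right[:10].tolist())),
    ]
    leads = _torso_leads(FixtureSpec(
        "torso_leads", dimensions=tuple(np.ptp(cents, axis=0)),
        params={"center": tuple(cents.mean(axis=0))})).leads
    fix = Fixture(spec, mesh=mesh, frames=vent.frames, leads=leads)
    fix.extra.update(segments=segments, left_cells=left, right_cells=right,
                     windkessel="omega_ao",
                     # runner settings matched to the coarse shell: the
                     # conduction network uses the fast-kinetics minimal
                     # model so the bundles stay regenerative
                     network_time_scale=2.0, chi_cm=0.25,
                     myocardial_m=0.1)
    return fix
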
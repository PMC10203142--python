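"""Spring-network tissue mechanics with a Fung orthotropic energy.

The structural model is Lagrangian: lumped-mass nodes connected by linear
elements — tetrahedra for myocardial walls, triangles for thin membranes
(valve leaflets), two-node bars for 1D benchmark structures.  Each element
stores its rest metric and a material fiber triad; the passive response
derives from the Fung strain-energy density

    W = c/2 (exp(Q) - 1),   Q = a_par e_par^2 + a_sheet e_sheet^2
                                + a_norm e_norm^2

where e_* are Green strain components in the fiber/sheet/sheet-normal
directions.  Internal forces are the exact negative gradient of the
assembled energy (energetically consistent by construction, hence exactly
momentum-conserving).  Active contraction enters as a fiber-aligned
first-Piola stress Ta * (F e_par) (x) e_par, the gradient of the objective
energy Ta * e_par per unit rest volume, so each element's active force set
has zero net force and zero net torque.

Nodes obey m_n d2x_n/dt2 = F_ext + F_int + F_act, advanced with a two-step
Adams–Bashforth update (matching the fluid–structure coupling scheme) and
optional linear velocity damping.

Units: positions m, masses kg, stresses kPa with geometry in mm would mix
scales, so this module works in SI throughout (m, kg, s, Pa); the material
constants from the registries (kPa) are converted on use (1 kPa = 1e3 Pa).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["FungMaterial", "GreenStrainTriple", "ElementBlock",
           "SpringNetwork", "green_strains", "fung_energy", "total_energy",
           "internal_forces", "active_forces", "advance_structure",
           "uniaxial_response"]

_Q_OVERFLOW = 700.0


@dataclass(frozen=True)
class FungMaterial:
    """Fung constants: c (kPa) and dimensionless exponents per direction."""

    c: float
    a_par: float
    a_sheet: float
    a_norm: float = 0.0

    def __post_init__(self):
        if self.c <= 0:
            raise ValueError("Fung scale c must be positive")
        if min(self.a_par, self.a_sheet, self.a_norm) < 0:
            raise ValueError("Fung exponents must be non-negative")


@dataclass(frozen=True)
class GreenStrainTriple:
    """Green strain components in the fiber frame; each >= -1/2."""

    e_par: float
    e_sheet: float = 0.0
    e_norm: float = 0.0

    def __post_init__(self):
        if min(self.e_par, self.e_sheet, self.e_norm) < -0.5:
            raise ValueError("Green strain components cannot fall below "
                             "-1/2 (degenerate deformation)")


def fung_energy(strains, mat: FungMaterial) -> float:
    """Strain-energy density W = c/2 (exp(Q) - 1) in the units of ``c``.

    ``strains`` is a GreenStrainTriple or any (e_par, e_sheet, e_norm)
    triple (arrays allowed).  Q > 700 signals a nonphysical strain and
    raises OverflowError.
    """
    if isinstance(strains, GreenStrainTriple):
        ep, es, en = strains.e_par, strains.e_sheet, strains.e_norm
    else:
        ep, es, en = strains
    Q = mat.a_par * np.square(ep) + mat.a_sheet * np.square(es) \
        + mat.a_norm * np.square(en)
    if np.any(np.asarray(Q) > _Q_OVERFLOW):
        raise OverflowError("Fung exponent Q exceeds overflow guard: "
                            "nonphysical strain state")
    return 0.5 * mat.c * (np.exp(Q) - 1.0)


# ---------------------------------------------------------------------------
# element blocks
# ---------------------------------------------------------------------------
class ElementBlock:
    """A homogeneous batch of elements (one kind, one material).

    kind:
        ``"tet"`` (4 nodes, volumetric), ``"tri"`` (3 nodes, membrane with
        a thickness), ``"bar"`` (2 nodes, uniaxial with a cross-section).
    fibers:
        per-element fiber triad.  Tets: (ne, 3, 3) orthonormal rows
        (fiber, sheet, sheet-normal) in the rest configuration.  Tris: a
        (ne, 3) rest-plane fiber direction (the in-plane perpendicular
        serves as the sheet direction; no sheet-normal strain).  Bars:
        ignored (the axis is the fiber).
    """

    def __init__(self, kind: str, conn, rest_positions, material: FungMaterial,
                 fibers=None, thickness: float = 1e-3,
                 cross_section: float = 1e-6):
        self.kind = kind
        self.conn = np.asarray(conn, dtype=int).reshape(
            -1, {"tet": 4, "tri": 3, "bar": 2}[kind])
        self.material = material
        self.thickness = float(thickness)
        self.cross_section = float(cross_section)
        X0 = np.asarray(rest_positions, dtype=float)
        ne = self.conn.shape[0]
        if kind == "tet":
            d = X0[self.conn[:, 1:]] - X0[self.conn[:, :1]]   # (ne, 3, 3)
            Dm = np.swapaxes(d, 1, 2)                          # cols = edges
            det = np.linalg.det(Dm)
            if np.any(det <= 0):
                raise ValueError("tetrahedron with non-positive rest volume")
            self.Bm = np.linalg.inv(Dm)
            self.V0 = det / 6.0
            if fibers is None:
                fibers = np.broadcast_to(np.eye(3), (ne, 3, 3)).copy()
            self.frame = np.asarray(fibers, dtype=float)
        elif kind == "tri":
            d1 = X0[self.conn[:, 1]] - X0[self.conn[:, 0]]
            d2 = X0[self.conn[:, 2]] - X0[self.conn[:, 0]]
            t1 = d1 / np.linalg.norm(d1, axis=1, keepdims=True)
            nrm = np.cross(d1, d2)
            a2 = np.linalg.norm(nrm, axis=1)
            if np.any(a2 <= 0):
                raise ValueError("degenerate rest triangle")
            t2 = np.cross(nrm / a2[:, None], t1)
            self.A0 = 0.5 * a2
            self.tangent = np.stack([t1, t2], axis=1)          # (ne, 2, 3)
            Dm = np.stack([
                np.stack([np.einsum("ei,ei->e", t1, d1),
                          np.einsum("ei,ei->e", t1, d2)], axis=-1),
                np.stack([np.einsum("ei,ei->e", t2, d1),
                          np.einsum("ei,ei->e", t2, d2)], axis=-1),
            ], axis=1)                                          # (ne, 2, 2)
            self.Bm = np.linalg.inv(Dm)
            if fibers is None:
                f2 = np.tile(np.array([1.0, 0.0]), (ne, 1))
            else:
                f3 = np.asarray(fibers, dtype=float)
                f2 = np.stack([np.einsum("ei,ei->e", t1, f3),
                               np.einsum("ei,ei->e", t2, f3)], axis=-1)
                norms = np.linalg.norm(f2, axis=1, keepdims=True)
                if np.any(norms < 1e-12):
                    raise ValueError("membrane fiber has no in-plane "
                                     "component")
                f2 = f2 / norms
            g2 = np.stack([-f2[:, 1], f2[:, 0]], axis=-1)
            self.frame = np.stack([f2, g2], axis=1)             # (ne, 2, 2)
        elif kind == "bar":
            d = X0[self.conn[:, 1]] - X0[self.conn[:, 0]]
            self.L0 = np.linalg.norm(d, axis=1)
            if np.any(self.L0 <= 0):
                raise ValueError("zero-length rest bar")
        else:
            raise ValueError(f"unknown element kind {kind!r}")

    @property
    def n_elements(self) -> int:
        return self.conn.shape[0]

    # -- kinematics --------------------------------------------------------
    def deformation_gradient(self, x):
        if self.kind == "tet":
            d = x[self.conn[:, 1:]] - x[self.conn[:, :1]]
            Ds = np.swapaxes(d, 1, 2)
            F = Ds @ self.Bm
            if np.any(np.linalg.det(F) <= 0):
                raise ValueError("inverted tetrahedral element")
            return F
        if self.kind == "tri":
            d1 = x[self.conn[:, 1]] - x[self.conn[:, 0]]
            d2 = x[self.conn[:, 2]] - x[self.conn[:, 0]]
            Ds = np.stack([d1, d2], axis=2)                    # (ne, 3, 2)
            return Ds @ self.Bm                                # (ne, 3, 2)
        d = x[self.conn[:, 1]] - x[self.conn[:, 0]]
        return np.linalg.norm(d, axis=1) / self.L0             # (ne,)

    def green_strain_components(self, x):
        """(e_par, e_sheet, e_norm) arrays; absent components are zero."""
        F = self.deformation_gradient(x)
        if self.kind == "tet":
            E = 0.5 * (np.swapaxes(F, 1, 2) @ F
                       - np.eye(3)[None, :, :])
            e = np.einsum("edi,eij,edj->ed", self.frame, E, self.frame)
            return e[:, 0], e[:, 1], e[:, 2]
        if self.kind == "tri":
            E = 0.5 * (np.swapaxes(F, 1, 2) @ F
                       - np.eye(2)[None, :, :])
            e = np.einsum("edi,eij,edj->ed", self.frame, E, self.frame)
            return e[:, 0], e[:, 1], np.zeros(self.n_elements)
        lam = F
        e = 0.5 * (lam ** 2 - 1.0)
        z = np.zeros(self.n_elements)
        return e, z, z

    def _measure(self):
        if self.kind == "tet":
            return self.V0
        if self.kind == "tri":
            return self.A0 * self.thickness
        return self.L0 * self.cross_section

    def energy(self, x) -> float:
        """Assembled elastic energy (J, with c read as kPa = 1e3 Pa)."""
        ep, es, en = self.green_strain_components(x)
        W = fung_energy((ep, es, en), self.material)    # kPa
        return float(np.sum(W * self._measure()) * 1e3)

    # -- forces ------------------------------------------------------------
    def _assemble(self, forces_out, P_times_measure):
        """Scatter -dW/dDs to nodes given P*measure per element."""
        if self.kind == "bar":
            return
        G = P_times_measure @ np.swapaxes(self.Bm, 1, 2)       # (ne, 3, k-1)
        for a in range(G.shape[2]):
            np.add.at(forces_out, self.conn[:, a + 1], -G[:, :, a])
        np.add.at(forces_out, self.conn[:, 0], G.sum(axis=2))

    def add_internal_forces(self, x, forces_out) -> None:
        mat = self.material
        ep, es, en = self.green_strain_components(x)
        Q = mat.a_par * ep ** 2 + mat.a_sheet * es ** 2 + mat.a_norm * en ** 2
        if np.any(Q > _Q_OVERFLOW):
            raise OverflowError("Fung exponent overflow in force assembly")
        coef = mat.c * 1e3 * np.exp(Q)                          # Pa
        if self.kind == "bar":
            d = x[self.conn[:, 1]] - x[self.conn[:, 0]]
            dWde = coef * mat.a_par * ep                        # Pa
            f = (dWde * self.cross_section / self.L0)[:, None] * d
            np.add.at(forces_out, self.conn[:, 0], f)
            np.add.at(forces_out, self.conn[:, 1], -f)
            return
        F = self.deformation_gradient(x)
        if self.kind == "tet":
            ee = self.frame
            S = np.einsum("e,ed,edi,edj->eij", coef,
                          np.stack([mat.a_par * ep, mat.a_sheet * es,
                                    mat.a_norm * en], axis=1), ee, ee)
        else:
            ee = self.frame
            S = np.einsum("e,ed,edi,edj->eij", coef,
                          np.stack([mat.a_par * ep, mat.a_sheet * es],
                                   axis=1), ee, ee)
        P = F @ S
        self._assemble(forces_out, P * self._measure()[:, None, None])

    def add_active_forces(self, x, Ta, forces_out) -> None:
        """Fiber-tension forces for per-element tension Ta (Pa)."""
        Ta = np.broadcast_to(np.asarray(Ta, float), (self.n_elements,))
        if np.any(Ta < 0):
            raise ValueError("active tension must be non-negative")
        if self.kind == "bar":
            d = x[self.conn[:, 1]] - x[self.conn[:, 0]]
            f = (Ta * self.cross_section / self.L0)[:, None] * d
            np.add.at(forces_out, self.conn[:, 0], f)
            np.add.at(forces_out, self.conn[:, 1], -f)
            return
        F = self.deformation_gradient(x)
        fib = self.frame[:, 0, :]                               # (ne, dim)
        Ff = np.einsum("eij,ej->ei", F, fib)
        P = Ta[:, None, None] * Ff[:, :, None] * fib[:, None, :]
        self._assemble(forces_out, P * self._measure()[:, None, None])


class SpringNetwork:
    """Lagrangian structure: nodes + element blocks + wet-surface tagging.

    ``wet_faces`` (optional, (m, 3) node triples) marks the fluid-loaded
    triangulated surface used by the immersed-boundary coupling.
    """

    def __init__(self, rest_positions, masses, blocks=None, wet_faces=None):
        self.X0 = np.asarray(rest_positions, dtype=float).reshape(-1, 3)
        self.x = self.X0.copy()
        self.vel = np.zeros_like(self.x)
        self.mass = np.asarray(masses, dtype=float)
        if np.any(self.mass <= 0):
            raise ValueError("node masses must be positive")
        if self.mass.size != self.X0.shape[0]:
            raise ValueError("one mass per node required")
        self.blocks: list[ElementBlock] = list(blocks or [])
        self.wet_faces = (None if wet_faces is None
                          else np.asarray(wet_faces, dtype=int))
        self._accel_prev = None
        self._vel_prev = None

    @property
    def n_nodes(self) -> int:
        return self.X0.shape[0]

    def add_block(self, kind, conn, material, **kw) -> ElementBlock:
        blk = ElementBlock(kind, conn, self.X0, material, **kw)
        self.blocks.append(blk)
        return blk


# ---------------------------------------------------------------------------
# module-level operations
# ---------------------------------------------------------------------------
def green_strains(net: SpringNetwork, positions=None):
    """Per-block lists of (e_par, e_sheet, e_norm) component arrays."""
    x = net.x if positions is None else np.asarray(positions, float)
    return [blk.green_strain_components(x) for blk in net.blocks]


def total_energy(net: SpringNetwork, positions=None) -> float:
    x = net.x if positions is None else np.asarray(positions, float)
    return sum(blk.energy(x) for blk in net.blocks)


def internal_forces(net: SpringNetwork, positions=None) -> np.ndarray:
    """Passive elastic nodal forces (N): exact -grad of the total energy."""
    x = net.x if positions is None else np.asarray(positions, float)
    f = np.zeros_like(net.x)
    for blk in net.blocks:
        blk.add_internal_forces(x, f)
    return f


def active_forces(net: SpringNetwork, Ta, positions=None) -> np.ndarray:
    """Active fiber-tension nodal forces (N).

    ``Ta`` is the active tension in kPa, one value per element block (scalar
    or per-element array per block, in block order).
    """
    x = net.x if positions is None else np.asarray(positions, float)
    if np.isscalar(Ta):
        Ta = [Ta] * len(net.blocks)
    f = np.zeros_like(net.x)
    for blk, ta in zip(net.blocks, Ta):
        blk.add_active_forces(x, np.asarray(ta, float) * 1e3, f)
    return f


def advance_structure(net: SpringNetwork, F_total, dt: float,
                      damping: float = 0.0) -> None:
    """Two-step Adams–Bashforth update of velocities then positions.

    ``F_total`` is the summed nodal force (external + internal + active, N);
    ``damping`` is a linear velocity-damping coefficient (kg/s per node).
    The first call falls back to forward Euler (no force history yet).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    F_total = np.asarray(F_total, dtype=float)
    if not np.all(np.isfinite(F_total)):
        raise ValueError("non-finite force input")
    a = F_total / net.mass[:, None] - damping * net.vel / net.mass[:, None]
    if net._accel_prev is None:
        v_new = net.vel + dt * a
        x_new = net.x + dt * net.vel
    else:
        v_new = net.vel + dt * (1.5 * a - 0.5 * net._accel_prev)
        x_new = net.x + dt * (1.5 * net.vel - 0.5 * net._vel_prev)
    net._accel_prev = a
    net._vel_prev = net.vel
    net.vel = v_new
    net.x = x_new


def uniaxial_response(mat: FungMaterial, stretches, axis: str = "par"):
    """Quasi-static stress–strain curve for a uniaxial test along one
    material axis with the transverse directions free (their strains relax
    to zero because the energy has no cross terms).

    Returns ``(green_strain, stress_kPa)`` arrays; stress is the energy
    conjugate dW/de along the chosen axis.
    """
    stretches = np.asarray(stretches, dtype=float)
    if np.any(stretches < 1.0):
        raise ValueError("stretch ratios must be >= 1")
    e = 0.5 * (stretches ** 2 - 1.0)
    a = {"par": mat.a_par, "sheet": mat.a_sheet, "norm": mat.a_norm}[axis]
    stress = mat.c * a * e * np.exp(a * e ** 2)
    return e, stress
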
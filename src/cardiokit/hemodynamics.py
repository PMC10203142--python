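"""Incompressible hemodynamics on a staggered Cartesian grid.

Blood is an incompressible fluid (rho = 1060 kg/m^3, mu = 3.5 mPa s in
Newtonian mode) obeying

    rho (du/dt + div(u u)) = -grad p + div(tau) + f_IB + f_WK,  div u = 0.

Spatial discretization is second-order central differences on a marker-
and-cell staggered grid; time advances with a fractional step — explicit
two-step Adams–Bashforth convection, implicit Crank–Nicolson viscosity,
then a pressure-Poisson projection that restores a discretely
divergence-free field (residual at the direct-solver level).

Moving tissue enters through a moving-least-squares (MLS) immersed
boundary: velocities are interpolated at Lagrangian markers with a
linear-basis MLS over a three-cell support, the direct forcing
(U_target - u)/dt is spread back with the transposed weights, and the
same transfer samples pressure and viscous stress for the hydrodynamic
loads returned to the structural solver.  Open outlets are modelled by
the three-element-Windkessel volume forcing
-f_WK = alpha u + beta int_0^t u dtau + gamma n applied on cylindrical
subdomains.

The solver is 2D (x periodic; y periodic, free-slip or no-slip); the MLS
transfer and load evaluation are dimension-generic (2D/3D).  SI units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

__all__ = ["RHO_BLOOD", "MU_BLOOD", "CarreauYasuda", "effective_viscosity",
           "MLSSampler", "WindkesselRegion", "windkessel_forcing",
           "FlowSolver2D", "hydrodynamic_loads", "distribute_face_forces",
           "LagrangianSurface"]

RHO_BLOOD = 1060.0    # kg/m^3
MU_BLOOD = 3.5e-3     # Pa s


# ---------------------------------------------------------------------------
# viscosity model
# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class CarreauYasuda:
    """Carreau–Yasuda shear-thinning parameters (defaults for blood from
    the rheological literature; the Newtonian mode bypasses them)."""

    mu0: float = 0.056      # Pa s, zero-shear viscosity
    mu_inf: float = 3.5e-3  # Pa s, infinite-shear viscosity
    lam: float = 3.313      # s, relaxation time
    a: float = 2.0          # Yasuda transition exponent
    n: float = 0.3568       # power-law index

    def __post_init__(self):
        if self.a <= 0 or self.lam < 0 or self.mu0 <= 0 or self.mu_inf <= 0:
            raise ValueError("invalid Carreau-Yasuda parameters")


def effective_viscosity(shear_rate, params: CarreauYasuda | None = None,
                        newtonian: bool = True):
    """Dynamic viscosity (Pa s) at shear rate gamma-dot (1/s).

    Newtonian mode (the default) returns the constant blood viscosity
    3.5 mPa s; otherwise the Carreau–Yasuda law
    mu_inf + (mu0 - mu_inf) [1 + (lam*g)^a]^((n-1)/a).
    """
    g = np.asarray(shear_rate, dtype=float)
    if np.any(g < 0):
        raise ValueError("shear rate must be non-negative")
    if newtonian:
        return np.broadcast_to(MU_BLOOD, g.shape).copy() if g.ndim \
            else MU_BLOOD
    p = params or CarreauYasuda()
    return p.mu_inf + (p.mu0 - p.mu_inf) \
        * (1.0 + (p.lam * g) ** p.a) ** ((p.n - 1.0) / p.a)


# ---------------------------------------------------------------------------
# moving-least-squares transfer
# ---------------------------------------------------------------------------
class MLSSampler:
    """Linear-basis MLS interpolation/spreading on a uniform grid.

    The grid is defined by an origin, spacing h (isotropic) and shape;
    ``periodic`` flags each axis.  The support is the 3-wide node stencil
    around the marker with a Gaussian weight; linear polynomials are
    reproduced exactly, so interpolation is O(h^2) and the spread/interp
    pair is an exact adjoint (same weights, transposed).
    """

    def __init__(self, origin, h: float, shape, periodic):
        self.origin = np.asarray(origin, dtype=float)
        self.h = float(h)
        self.shape = tuple(shape)
        self.dim = len(self.shape)
        self.periodic = tuple(periodic)
        if len(self.periodic) != self.dim:
            raise ValueError("one periodic flag per axis")

    # -- stencils ----------------------------------------------------------
    def _stencil(self, xm):
        """Node multi-indices (k, dim) and their coordinates for marker."""
        base = np.floor((xm - self.origin) / self.h).astype(int)
        axes = []
        for d in range(self.dim):
            ids = base[d] + np.arange(-1, 2)
            if self.periodic[d]:
                ids = ids % self.shape[d]
            elif base[d] < -1 or base[d] > self.shape[d]:
                raise ValueError("MLS support stencil outside the domain "
                                 f"(marker at {xm})")
            else:
                # one-sided stencil next to a wall
                shift = int(np.clip(ids[0], 0, self.shape[d] - 3) - ids[0])
                ids = ids + shift
            axes.append(ids)
        grids = np.meshgrid(*axes, indexing="ij")
        idx = np.stack([g.ravel() for g in grids], axis=1)
        # coordinates: unwrap periodic images to stay near the marker
        coords = self.origin + idx * self.h
        for d in range(self.dim):
            if self.periodic[d]:
                L = self.shape[d] * self.h
                coords[:, d] += L * np.round((xm[d] - coords[:, d]) / L)
        return idx, coords

    def shape_functions(self, xm):
        """(node_indices, weights phi) with sum(phi)=1 and exact linear
        reproduction."""
        xm = np.asarray(xm, dtype=float)
        idx, coords = self._stencil(xm)
        r = (coords - xm) / (1.5 * self.h)
        w = np.exp(-4.5 * np.sum(r * r, axis=1))
        P = np.column_stack([np.ones(len(coords)), coords - xm])
        A = P.T @ (w[:, None] * P)
        try:
            lam = np.linalg.solve(A, np.eye(self.dim + 1)[:, 0])
        except np.linalg.LinAlgError:
            raise ValueError("degenerate MLS moment matrix (marker has no "
                             "valid fluid support)") from None
        phi = w * (P @ lam)
        return idx, phi

    # -- transfer ----------------------------------------------------------
    def interpolate(self, grid_values: np.ndarray, markers) -> np.ndarray:
        markers = np.atleast_2d(np.asarray(markers, dtype=float))
        out = np.empty(markers.shape[0])
        for k, xm in enumerate(markers):
            idx, phi = self.shape_functions(xm)
            out[k] = phi @ grid_values[tuple(idx.T)]
        return out

    def spread(self, markers, values, out: np.ndarray | None = None):
        """Transpose of ``interpolate``: scatter marker values to the grid
        with the same weights (the weighted sum over markers of each value
        is preserved node-wise: total spread equals total marker value)."""
        markers = np.atleast_2d(np.asarray(markers, dtype=float))
        values = np.broadcast_to(np.asarray(values, float),
                                 (markers.shape[0],))
        if out is None:
            out = np.zeros(self.shape)
        for xm, val in zip(markers, values):
            idx, phi = self.shape_functions(xm)
            np.add.at(out, tuple(idx.T), phi * val)
        return out


# ---------------------------------------------------------------------------
# Windkessel outlet forcing
# ---------------------------------------------------------------------------
@dataclass
class WindkesselRegion:
    """Outlet subdomain carrying the three-element-Windkessel forcing.

    ``alpha`` (kg m^-3 s^-1), ``beta`` (kg m^-3 s^-2) and ``gamma``
    (kg m^-2 s^-2) follow the built-in registry; ``normal`` is the outward
    normal n_Omega of the outlet; ``predicate(points) -> bool mask``
    selects the (cylindrical) subdomain."""

    name: str
    alpha: float
    beta: float
    gamma: float
    normal: np.ndarray
    predicate: object = None

    def __post_init__(self):
        self.normal = np.asarray(self.normal, dtype=float)
        if not np.all(np.isfinite([self.alpha, self.beta, self.gamma])):
            raise ValueError("Windkessel parameters must be finite")


def windkessel_forcing(region: WindkesselRegion, u, u_integral,
                       component: int = 0):
    """Momentum forcing density f_WK (N/m^3) for one velocity component:
    f = -(alpha u + beta int u dt + gamma n).  ``u_integral`` is the
    accumulated time integral of u (maintained by the caller with the
    trapezoidal rule)."""
    n_c = region.normal[component]
    return -(region.alpha * np.asarray(u)
             + region.beta * np.asarray(u_integral)
             + region.gamma * n_c)


# ---------------------------------------------------------------------------
# the 2D staggered solver
# ---------------------------------------------------------------------------
class FlowSolver2D:
    """MAC-grid fractional-step solver on [0,Lx) x [0,Ly].

    x is periodic; ``bc_y`` is ``"periodic"``, ``"slip"`` (free-slip walls)
    or ``"noslip"``.  Fields: u (nx, ny) on x-faces, v on y-faces
    ((nx, ny) periodic / (nx, ny+1) with walls), p (nx, ny) cell-centred.
    """

    def __init__(self, nx: int, ny: int, Lx: float, Ly: float,
                 rho: float = RHO_BLOOD, mu: float = MU_BLOOD,
                 bc_y: str = "periodic"):
        if bc_y not in ("periodic", "slip", "noslip"):
            raise ValueError("bc_y must be periodic, slip or noslip")
        self.nx, self.ny = int(nx), int(ny)
        self.Lx, self.Ly = float(Lx), float(Ly)
        self.dx, self.dy = Lx / nx, Ly / ny
        if abs(self.dx - self.dy) > 1e-12 * self.dx:
            raise ValueError("grid must be isotropic (dx == dy)")
        self.h = self.dx
        self.rho, self.mu = float(rho), float(mu)
        self.bc_y = bc_y
        self.wall = bc_y != "periodic"
        self.u = np.zeros((self.nx, self.ny))
        self.v = np.zeros((self.nx, self.ny + 1) if self.wall
                          else (self.nx, self.ny))
        self.p = np.zeros((self.nx, self.ny))
        self.t = 0.0
        self._conv_prev = None
        self._dt_cached = None
        self._build_poisson()
        self.wk_regions: list = []
        self._wk_int_u = {}
        self._wk_int_v = {}
        #: direct-forcing passes per step (residual slip shrinks with each)
        self.ib_iterations = 6

    # -- samplers (cell/face node lattices for the MLS transfer) ----------
    def sampler_u(self) -> MLSSampler:
        return MLSSampler((0.0, 0.5 * self.dy), self.h,
                          self.u.shape, (True, not self.wall))

    def sampler_v(self) -> MLSSampler:
        return MLSSampler((0.5 * self.dx, 0.0), self.h,
                          self.v.shape, (True, not self.wall))

    def sampler_p(self) -> MLSSampler:
        return MLSSampler((0.5 * self.dx, 0.5 * self.dy), self.h,
                          self.p.shape, (True, not self.wall))

    # -- helpers -----------------------------------------------------------
    def _pad_y_u(self, u):
        """u with one ghost layer in y according to bc_y."""
        if not self.wall:
            return np.concatenate([u[:, -1:], u, u[:, :1]], axis=1)
        g0 = -u[:, :1] if self.bc_y == "noslip" else u[:, :1]
        g1 = -u[:, -1:] if self.bc_y == "noslip" else u[:, -1:]
        return np.concatenate([g0, u, g1], axis=1)

    def _interior_v(self, v):
        return v[:, 1:-1] if self.wall else v

    def divergence(self, u=None, v=None):
        u = self.u if u is None else u
        v = self.v if v is None else v
        du = (np.roll(u, -1, axis=0) - u) / self.dx
        if self.wall:
            dv = (v[:, 1:] - v[:, :-1]) / self.dy
        else:
            dv = (np.roll(v, -1, axis=1) - v) / self.dy
        return du + dv

    # -- operators ---------------------------------------------------------
    def _convection(self, u, v):
        dx, dy = self.dx, self.dy
        # u-momentum: d(uu)/dx + d(uv)/dy at x-faces
        u_c = 0.5 * (u + np.roll(u, -1, axis=0))          # cell centres
        uu = u_c * u_c
        dudx = (uu - np.roll(uu, 1, axis=0)) / dx
        if self.wall:
            # u at y-face corners: average u in x-face pairs and y
            up = self._pad_y_u(u)
            u_yf = 0.5 * (up[:, :-1] + up[:, 1:])          # (nx, ny+1)
            v_xf = 0.5 * (v + np.roll(v, 1, axis=0))       # (nx, ny+1)
            if self.bc_y == "noslip":
                u_yf[:, 0] = 0.0
                u_yf[:, -1] = 0.0
            uv = u_yf * v_xf
            dudy = (uv[:, 1:] - uv[:, :-1]) / dy
        else:
            u_yf = 0.5 * (u + np.roll(u, 1, axis=1))
            v_xf = 0.5 * (v + np.roll(v, 1, axis=0))
            uv = u_yf * v_xf
            dudy = (np.roll(uv, -1, axis=1) - uv) / dy
        conv_u = dudx + dudy

        # v-momentum: d(uv)/dx + d(vv)/dy at y-faces
        if self.wall:
            up = self._pad_y_u(u)
            u_yf = 0.5 * (up[:, :-1] + up[:, 1:])          # (nx, ny+1)
            v_xf = 0.5 * (v + np.roll(v, 1, axis=0))
            uv = u_yf * v_xf                               # at corners
            dvdx = (np.roll(uv, -1, axis=0) - uv) / dx
            v_c = 0.5 * (v[:, :-1] + v[:, 1:])             # cell centres
            vv = v_c * v_c
            dvdy = np.zeros_like(v)
            dvdy[:, 1:-1] = (vv[:, 1:] - vv[:, :-1]) / dy
            conv_v = dvdx + dvdy
            conv_v[:, 0] = 0.0
            conv_v[:, -1] = 0.0
        else:
            u_yf = 0.5 * (u + np.roll(u, 1, axis=1))
            v_xf = 0.5 * (v + np.roll(v, 1, axis=0))
            uv = u_yf * v_xf
            dvdx = (np.roll(uv, -1, axis=0) - uv) / dx
            v_c = 0.5 * (v + np.roll(v, -1, axis=1))
            vv = v_c * v_c
            dvdy = (vv - np.roll(vv, 1, axis=1)) / dy
            conv_v = dvdx + dvdy
        return conv_u, conv_v

    def _laplacian_u(self, u):
        up = self._pad_y_u(u)
        return ((np.roll(u, -1, axis=0) - 2 * u + np.roll(u, 1, axis=0))
                / self.dx ** 2
                + (up[:, 2:] - 2 * u + up[:, :-2]) / self.dy ** 2)

    def _laplacian_v(self, v):
        lx = (np.roll(v, -1, axis=0) - 2 * v + np.roll(v, 1, axis=0)) \
            / self.dx ** 2
        if self.wall:
            ly = np.zeros_like(v)
            ly[:, 1:-1] = (v[:, 2:] - 2 * v[:, 1:-1] + v[:, :-2]) \
                / self.dy ** 2
            out = lx + ly
            out[:, 0] = 0.0
            out[:, -1] = 0.0
            return out
        ly = (np.roll(v, -1, axis=1) - 2 * v + np.roll(v, 1, axis=1)) \
            / self.dy ** 2
        return lx + ly

    # -- implicit CN matrices ---------------------------------------------
    def _helmholtz(self, nu_dt_half):
        """Factorized (I - nu*dt/2 * L) for u and v grids."""
        nx, ny, dx2 = self.nx, self.ny, self.dx ** 2

        def _circulant(n):
            e = np.ones(n)
            A = sp.diags([e[:-1], -2 * e, e[:-1]], (-1, 0, 1),
                         format="lil")
            A[0, -1] = 1.0
            A[-1, 0] = 1.0
            return A.tocsr()

        Cx = _circulant(nx) / dx2
        Ix = sp.identity(nx, format="csr")
        if not self.wall:
            Cy = _circulant(ny) / dx2
            Iy = sp.identity(ny, format="csr")
            L = sp.kron(Cx, Iy) + sp.kron(Ix, Cy)
            A = (sp.identity(nx * ny) - nu_dt_half * L).tocsc()
            f = spla.factorized(A)
            return f, f
        # u: cell-centred in y with ghost folding
        diag = np.full(ny, -2.0)
        if self.bc_y == "noslip":
            diag[0] = diag[-1] = -3.0
        else:
            diag[0] = diag[-1] = -1.0
        Cy_u = sp.diags([np.ones(ny - 1), diag, np.ones(ny - 1)],
                        (-1, 0, 1)) / dx2
        Iy = sp.identity(ny, format="csr")
        Lu = sp.kron(Cx, Iy) + sp.kron(Ix, Cy_u)
        Au = (sp.identity(nx * ny) - nu_dt_half * Lu).tocsc()
        # v: interior y-faces only (ny-1), Dirichlet 0 at walls
        m = ny - 1
        Cy_v = sp.diags([np.ones(m - 1), np.full(m, -2.0),
                         np.ones(m - 1)], (-1, 0, 1)) / dx2
        Im = sp.identity(m, format="csr")
        Lv = sp.kron(Cx, Im) + sp.kron(Ix, Cy_v)
        Av = (sp.identity(nx * m) - nu_dt_half * Lv).tocsc()
        return spla.factorized(Au), spla.factorized(Av)

    def _build_poisson(self):
        nx, ny, dx2 = self.nx, self.ny, self.dx ** 2

        def _circulant(n):
            e = np.ones(n)
            A = sp.diags([e[:-1], -2 * e, e[:-1]], (-1, 0, 1), format="lil")
            A[0, -1] = 1.0
            A[-1, 0] = 1.0
            return A.tocsr()

        Cx = _circulant(nx) / dx2
        if self.wall:
            diag = np.full(ny, -2.0)
            diag[0] = diag[-1] = -1.0       # Neumann (zero-gradient) walls
            Cy = sp.diags([np.ones(ny - 1), diag, np.ones(ny - 1)],
                          (-1, 0, 1)) / dx2
        else:
            Cy = _circulant(ny) / dx2
        L = (sp.kron(Cx, sp.identity(ny))
             + sp.kron(sp.identity(nx), Cy)).tolil()
        L[0, :] = 0.0
        L[0, 0] = 1.0                        # pin the nullspace
        self._poisson = spla.factorized(L.tocsc())

    # -- Windkessel --------------------------------------------------------
    def add_windkessel(self, region: WindkesselRegion) -> None:
        """Register an outlet region; masks are evaluated on face nodes."""
        xu = np.stack(np.meshgrid(
            np.arange(self.nx) * self.dx,
            (np.arange(self.ny) + 0.5) * self.dy, indexing="ij"), axis=-1)
        shape_v = self.v.shape
        xv = np.stack(np.meshgrid(
            (np.arange(self.nx) + 0.5) * self.dx,
            np.arange(shape_v[1]) * self.dy, indexing="ij"), axis=-1)
        mask_u = region.predicate(xu.reshape(-1, 2)).reshape(self.u.shape)
        mask_v = region.predicate(xv.reshape(-1, 2)).reshape(shape_v)
        self.wk_regions.append((region, mask_u, mask_v))
        self._wk_int_u[region.name] = np.zeros(self.u.shape)
        self._wk_int_v[region.name] = np.zeros(shape_v)

    def _wk_force(self):
        fu = np.zeros_like(self.u)
        fv = np.zeros_like(self.v)
        for region, mu_, mv_ in self.wk_regions:
            fu[mu_] += windkessel_forcing(region, self.u[mu_],
                                          self._wk_int_u[region.name][mu_],
                                          component=0)
            fv[mv_] += windkessel_forcing(region, self.v[mv_],
                                          self._wk_int_v[region.name][mv_],
                                          component=1)
        return fu, fv

    def _wk_advance_integrals(self, dt, u_old, v_old):
        for region, mu_, mv_ in self.wk_regions:
            self._wk_int_u[region.name][mu_] += 0.5 * dt * (
                u_old[mu_] + self.u[mu_])
            self._wk_int_v[region.name][mv_] += 0.5 * dt * (
                v_old[mv_] + self.v[mv_])

    def _project(self, u_star, v_star, dt, store_pressure=False):
        """Pressure-Poisson projection restoring discrete divergence."""
        div = self.divergence(u_star, v_star)
        rhs = (div / dt).ravel()
        rhs[0] = 0.0
        phi = self._poisson(rhs).reshape(self.nx, self.ny)
        phi -= phi.mean()
        dpx = (phi - np.roll(phi, 1, axis=0)) / self.dx
        u_new = u_star - dt * dpx
        if self.wall:
            dpy = (phi[:, 1:] - phi[:, :-1]) / self.dy
            v_new = v_star.copy()
            v_new[:, 1:-1] -= dt * dpy
        else:
            dpy = (phi - np.roll(phi, 1, axis=1)) / self.dy
            v_new = v_star - dt * dpy
        if store_pressure:
            self.p = self.p + self.rho * phi
        return u_new, v_new

    # -- time step ---------------------------------------------------------
    def step(self, dt: float, body_force=(0.0, 0.0), ib_markers=None,
             ib_velocities=None) -> None:
        """One fractional step.  ``body_force`` is a constant (fx, fy) in
        N/m^3; ``ib_markers``/``ib_velocities`` impose no-slip targets at
        Lagrangian markers through MLS direct forcing."""
        if dt <= 0:
            raise ValueError("dt must be positive")
        cfl = dt * max(np.abs(self.u).max(), np.abs(self.v).max(), 1e-30) \
            / self.h
        if cfl > 1.0:
            import warnings
            warnings.warn(f"convective CFL {cfl:.2f} > 1", RuntimeWarning)
        u_old, v_old = self.u.copy(), self.v.copy()
        nu = self.mu / self.rho
        conv = self._convection(self.u, self.v)
        if self._conv_prev is None:
            ab_u, ab_v = conv
        else:
            ab_u = 1.5 * conv[0] - 0.5 * self._conv_prev[0]
            ab_v = 1.5 * conv[1] - 0.5 * self._conv_prev[1]
        self._conv_prev = conv

        fu_wk, fv_wk = self._wk_force() if self.wk_regions else (0.0, 0.0)
        rhs_u = self.u + dt * (-ab_u + 0.5 * nu * self._laplacian_u(self.u)
                               + (body_force[0] + fu_wk) / self.rho)
        rhs_v = self.v + dt * (-ab_v + 0.5 * nu * self._laplacian_v(self.v)
                               + (body_force[1] + fv_wk) / self.rho)

        if self._dt_cached != dt:
            self._solve_u, self._solve_v = self._helmholtz(0.5 * nu * dt)
            self._dt_cached = dt
        u_star = self._solve_u(rhs_u.ravel()).reshape(self.u.shape)
        if self.wall:
            v_star = self.v.copy()
            v_star[:, 1:-1] = self._solve_v(
                rhs_v[:, 1:-1].ravel()).reshape(self.nx, self.ny - 1)
            v_star[:, 0] = 0.0
            v_star[:, -1] = 0.0
        else:
            v_star = self._solve_v(rhs_v.ravel()).reshape(self.v.shape)

        self.last_ib_force = None
        if ib_markers is not None:
            su, sv = self.sampler_u(), self.sampler_v()
            targets = np.atleast_2d(np.asarray(ib_velocities, float))
            du_tot = np.zeros(targets.shape[0])
            dv_tot = np.zeros(targets.shape[0])
            # iterated direct forcing *around the projection*: forcing
            # alone leaves interp(spread(du)) != du, and projecting alone
            # re-opens through-flow at the markers, so alternate the two
            for _ in range(self.ib_iterations):
                du = targets[:, 0] - su.interpolate(u_star, ib_markers)
                dv = targets[:, 1] - sv.interpolate(v_star, ib_markers)
                u_star = u_star + su.spread(ib_markers, du)
                v_star = v_star + sv.spread(ib_markers, dv)
                du_tot += du
                dv_tot += dv
                u_star, v_star = self._project(u_star, v_star, dt)
            # diagnostic: equivalent volume force density
            self.last_ib_force = (self.rho / dt) * np.stack(
                [du_tot, dv_tot], axis=1)
        self.u, self.v = self._project(u_star, v_star, dt,
                                       store_pressure=True)
        if self.wk_regions:
            self._wk_advance_integrals(dt, u_old, v_old)
        self.t += dt

    # -- diagnostics -------------------------------------------------------
    def kinetic_energy(self) -> float:
        cell = self.dx * self.dy
        ke = 0.5 * self.rho * (np.sum(self.u ** 2)
                               + np.sum(self._interior_v(self.v) ** 2
                                        if self.wall else self.v ** 2))
        return float(ke * cell)

    def cell_center_velocity(self):
        uc = 0.5 * (self.u + np.roll(self.u, -1, axis=0))
        if self.wall:
            vc = 0.5 * (self.v[:, :-1] + self.v[:, 1:])
        else:
            vc = 0.5 * (self.v + np.roll(self.v, -1, axis=1))
        return uc, vc

    def stress_tensor(self):
        """Viscous stress components (tau_xx, tau_xy, tau_yy) at cell
        centres (Pa), from central differences of the collocated field."""
        uc, vc = self.cell_center_velocity()
        dudx = (np.roll(uc, -1, 0) - np.roll(uc, 1, 0)) / (2 * self.dx)
        dvdy_ = (np.roll(vc, -1, 1) - np.roll(vc, 1, 1)) / (2 * self.dy)
        dudy = (np.roll(uc, -1, 1) - np.roll(uc, 1, 1)) / (2 * self.dy)
        dvdx = (np.roll(vc, -1, 0) - np.roll(vc, 1, 0)) / (2 * self.dx)
        txx = 2 * self.mu * dudx
        tyy = 2 * self.mu * dvdy_
        txy = self.mu * (dudy + dvdx)
        return txx, txy, tyy


# ---------------------------------------------------------------------------
# Lagrangian surfaces and hydrodynamic loads
# ---------------------------------------------------------------------------
@dataclass
class LagrangianSurface:
    """Wet-surface markers: positions, unit normals n+, face areas, and a
    two-sided flag (leaflets are wet on both sides; chamber walls only on
    the inner side)."""

    positions: np.ndarray
    normals: np.ndarray
    areas: np.ndarray
    two_sided: bool = False
    faces: np.ndarray = None     # optional (m, 3) node ids of wet faces

    def __post_init__(self):
        self.positions = np.atleast_2d(np.asarray(self.positions, float))
        self.normals = np.atleast_2d(np.asarray(self.normals, float))
        self.areas = np.asarray(self.areas, dtype=float)
        nrm = np.linalg.norm(self.normals, axis=1)
        if not np.allclose(nrm, 1.0, atol=1e-8):
            raise ValueError("marker normals must be unit vectors")
        if np.any(self.areas <= 0):
            raise ValueError("marker areas must be positive")


def hydrodynamic_loads(surface: LagrangianSurface, pressure,
                       stress=None, probe_offset: float = 0.0) -> np.ndarray:
    """Per-face hydrodynamic force (N).

    ``pressure``: callable(points (m, d)) -> p (Pa).  ``stress``: callable
    returning the viscous stress tensor (m, d, d) or None for an inviscid
    load.  Probes are offset by ``probe_offset`` along +/-n (1.5 grid
    spacings when sampling a discrete field; 0 for analytic fields).

    Two-sided (leaflet): F = [-(p+ - p-) n+ + (tau+ - tau-).n+] A.
    One-sided (closed surface, n pointing into the fluid):
    F = [-p n + tau.n] A.
    """
    x, n, A = surface.positions, surface.normals, surface.areas
    d = probe_offset
    if surface.two_sided:
        pp = np.asarray(pressure(x + d * n), dtype=float)
        pm = np.asarray(pressure(x - d * n), dtype=float)
        F = -(pp - pm)[:, None] * n
        if stress is not None:
            tp = np.asarray(stress(x + d * n), dtype=float)
            tm = np.asarray(stress(x - d * n), dtype=float)
            F = F + np.einsum("mij,mj->mi", tp - tm, n)
    else:
        pp = np.asarray(pressure(x + d * n), dtype=float)
        F = -pp[:, None] * n
        if stress is not None:
            tp = np.asarray(stress(x + d * n), dtype=float)
            F = F + np.einsum("mij,mj->mi", tp, n)
    return F * A[:, None]


def distribute_face_forces(faces: np.ndarray, face_forces: np.ndarray,
                           n_nodes: int) -> np.ndarray:
    """Spread per-face forces to the face nodes (equal thirds of each
    triangular wet face, i.e. area weighting for a uniform triangulation)."""
    faces = np.asarray(faces, dtype=int)
    out = np.zeros((n_nodes, face_forces.shape[1]))
    share = face_forces / faces.shape[1]
    for a in range(faces.shape[1]):
        np.add.at(out, faces[:, a], share)
    return out
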
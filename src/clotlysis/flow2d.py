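"""Volume-averaged incompressible channel flow with a permeable clot.

A single momentum equation is solved over fluid and clot alike
(superficial-velocity porous-media formulation): inside clot cells a Darcy
resistance −(µ/k)·u penalizes the flow, while fully lysed cells recover
unobstructed flow.  Continuity carries a prescribed per-cell volume source
(the lysis mass sink −∂ε/∂t supplied by the coupled tier).

Discretization: staggered (MAC) grid — u on vertical faces, v on
horizontal faces, p at cell centers; first-order upwind convection,
second-order central viscous terms; fixed pressures at the inlet/outlet
faces, no-slip impermeable walls.  The steady state is obtained from a
monolithic sparse linear solve (direct LU) with Picard iteration on the
convective terms, which is robust against the extremely stiff Darcy term
(µ/ρk exceeds 1e5 s⁻¹ in an intact clot).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .errors import ConfigError, ConvergenceError, DomainError

DEFAULT_LYSED_VOIDAGE = 0.9999


@dataclass(frozen=True)
class FluidProps:
    """Newtonian blood: density (kg/m³) and dynamic viscosity (Pa·s)."""

    rho: float = 1050.0
    mu: float = 3.5e-3

    def __post_init__(self):
        if self.rho <= 0 or self.mu <= 0:
            raise ConfigError("fluid density and viscosity must be > 0")


@dataclass(frozen=True)
class Grid2D:
    """Uniform cell-centered 2-D grid; x streamwise, y cross-stream.

    Cells own the half-open box [x_i, x_i+dx) × [y_j, y_j+dy).  The clot
    mask marks the initially occluding region (full channel height).
    """

    nx: int
    ny: int
    length: float
    height: float
    clot_x0: float
    clot_width: float

    def __post_init__(self):
        if self.nx < 4 or self.ny < 4:
            raise ConfigError("grid needs at least 4x4 cells")
        if not (0.0 <= self.clot_x0 and self.clot_x0 + self.clot_width <= self.length):
            raise ConfigError("clot interval must lie inside the channel")

    @property
    def dx(self) -> float:
        return self.length / self.nx

    @property
    def dy(self) -> float:
        return self.height / self.ny

    @property
    def x(self) -> np.ndarray:
        return (np.arange(self.nx) + 0.5) * self.dx

    @property
    def y(self) -> np.ndarray:
        return (np.arange(self.ny) + 0.5) * self.dy

    @property
    def clot_mask(self) -> np.ndarray:
        x = self.x
        col = (x >= self.clot_x0) & (x < self.clot_x0 + self.clot_width)
        return np.repeat(col[:, None], self.ny, axis=1)

    @property
    def clot_exit_index(self) -> int:
        """Index of the last cell column inside the initial clot."""
        cols = np.nonzero(self.clot_mask[:, 0])[0]
        return int(cols[-1])


def build_channel(height: float = 5e-3, length: float = 20e-3,
                  clot_x0: float = 5e-3, clot_width: float = 2.5e-3,
                  nx: int = 120, ny: int = 30) -> Grid2D:
    """Occluded-artery geometry: clot spanning the full channel height.

    Defaults follow a cerebral-artery scale: 5 mm channel height and a
    2.5 mm wide fully occluding clot.  Requires at least 8 cells across
    the clot width.
    """
    grid = Grid2D(nx=nx, ny=ny, length=length, height=height,
                  clot_x0=clot_x0, clot_width=clot_width)
    n_across = int(round(clot_width / grid.dx))
    if n_across < 8:
        raise ConfigError(
            f"clot resolved by only {n_across} cells across; need >= 8"
        )
    return grid


@dataclass
class FlowField:
    """Superficial velocity (staggered faces) and pressure (centers)."""

    grid: Grid2D
    u: np.ndarray  # (nx+1, ny)
    v: np.ndarray  # (nx, ny+1); wall rows are zero
    p: np.ndarray  # (nx, ny)

    def cell_velocity(self):
        """Cell-centered (u, v) by face averaging."""
        uc = 0.5 * (self.u[:-1, :] + self.u[1:, :])
        vc = 0.5 * (self.v[:, :-1] + self.v[:, 1:])
        return uc, vc

    def max_speed(self) -> float:
        uc, vc = self.cell_velocity()
        return float(np.sqrt(uc**2 + vc**2).max())


def _resistance_field(grid: Grid2D, k_field, eps_field, mu: float,
                      lysed_voidage: float) -> np.ndarray:
    """Per-cell Darcy coefficient µ/k; zero outside the clot and in
    recanalized (ε ≥ threshold) cells."""
    r = np.zeros((grid.nx, grid.ny))
    mask = grid.clot_mask & (np.asarray(eps_field) < lysed_voidage)
    k = np.asarray(k_field)
    with np.errstate(divide="ignore"):
        r[mask] = mu / k[mask]
    return r


def solve_flow(
    grid: Grid2D,
    clot_field,
    dp: float,
    fluid: FluidProps = FluidProps(),
    mass_source: np.ndarray | None = None,
    *,
    lysed_voidage: float = DEFAULT_LYSED_VOIDAGE,
    include_inertia: bool = True,
    picard_tol: float = 1e-6,
    max_picard: int = 40,
    relax: float = 0.8,
    initial: FlowField | None = None,
    strict: bool = True,
) -> FlowField:
    """Steady volume-averaged flow for a given clot state and pressure drop.

    ``clot_field`` is a :class:`clotlysis.microstructure.ClotState` whose
    ``k`` and ``eps`` entries are (nx, ny) arrays (or scalars for a uniform
    clot).  ``dp`` ≥ 0 is the inlet-minus-outlet pressure difference (Pa).
    ``mass_source`` is the prescribed per-cell divergence (s⁻¹); the
    coupled tier passes the lysis sink −∂ε/∂t.

    Convective terms are Picard-linearized; with ``strict`` the solver
    raises :class:`ConvergenceError` (with residual history) if the
    nonlinear iteration does not settle, otherwise it returns the best
    available iterate (quasi-steady coupling keeps the error transient).
    """
    if dp < 0:
        raise DomainError("pressure drop must be >= 0")
    nx, ny, dx, dy = grid.nx, grid.ny, grid.dx, grid.dy
    mu, rho = fluid.mu, fluid.rho

    k_field = np.broadcast_to(np.asarray(clot_field.k, dtype=float), (nx, ny))
    eps_field = np.broadcast_to(np.asarray(clot_field.eps, dtype=float), (nx, ny))
    if np.any(k_field <= 0):
        raise DomainError("permeabilities must be > 0")
    r_cell = _resistance_field(grid, k_field, eps_field, mu, lysed_voidage)

    m = np.zeros((nx, ny)) if mass_source is None else np.asarray(mass_source, dtype=float)

    Nu = (nx + 1) * ny
    Nv = nx * (ny - 1)
    Np = nx * ny
    N = Nu + Nv + Np

    def iu(i, j):
        return i * ny + j

    def iv(i, j):  # j in 1..ny-1
        return Nu + i * (ny - 1) + (j - 1)

    def ip(i, j):
        return Nu + Nv + i * ny + j

    p_in, p_out = float(dp), 0.0

    # face Darcy coefficients (arithmetic mean of adjacent cells)
    r_u = np.zeros((nx + 1, ny))
    r_u[1:nx, :] = 0.5 * (r_cell[:-1, :] + r_cell[1:, :])
    r_u[0, :] = r_cell[0, :]
    r_u[nx, :] = r_cell[-1, :]
    r_v = np.zeros((nx, ny + 1))
    r_v[:, 1:ny] = 0.5 * (r_cell[:, :-1] + r_cell[:, 1:])

    u = np.zeros((nx + 1, ny)) if initial is None else initial.u.copy()
    v = np.zeros((nx, ny + 1)) if initial is None else initial.v.copy()

    IU = np.arange(Nu).reshape(nx + 1, ny)
    IV = Nu + np.arange(Nv).reshape(nx, ny - 1)  # column jj <-> face j = jj + 1
    IP = Nu + Nv + np.arange(Np).reshape(nx, ny)
    cx, cy = mu / dx**2, mu / dy**2

    residuals = []
    sol = None
    for it in range(max_picard):
        rows, cols, vals = [], [], []
        rhs = np.zeros(N)

        def add(r, c, a):
            rows.append(np.broadcast_to(r, np.broadcast(r, c, a).shape).ravel())
            cols.append(np.broadcast_to(c, np.broadcast(r, c, a).shape).ravel())
            vals.append(np.broadcast_to(a, np.broadcast(r, c, a).shape).ravel())

        # ---- u-momentum (rows IU) ------------------------------------------
        diag_u = r_u + cy * np.where(
            (np.arange(ny) == 0) | (np.arange(ny) == ny - 1), 3.0, 2.0)
        diag_u[1:nx, :] += 2 * cx
        diag_u[[0, nx], :] += cx
        add(IU[1:nx], IU[0:nx - 1], -cx)   # west u neighbor
        add(IU[1:nx], IU[2:], -cx)         # east u neighbor
        add(IU[0], IU[1], -cx)
        add(IU[nx], IU[nx - 1], -cx)
        add(IU[:, 1:], IU[:, :-1], -cy)
        add(IU[:, :-1], IU[:, 1:], -cy)

        if include_inertia:
            a = rho * u / dx
            up = (u > 0)
            dn = (u < 0)
            diag_u[1:][up[1:]] += a[1:][up[1:]]
            add(IU[1:][up[1:]], IU[:-1][up[1:]], -a[1:][up[1:]])
            diag_u[:-1][dn[:-1]] += -a[:-1][dn[:-1]]
            add(IU[:-1][dn[:-1]], IU[1:][dn[:-1]], a[:-1][dn[:-1]])

            vL = v[np.clip(np.arange(nx + 1) - 1, 0, nx - 1)]
            vR = v[np.clip(np.arange(nx + 1), 0, nx - 1)]
            Vf = 0.25 * (vL[:, :-1] + vL[:, 1:] + vR[:, :-1] + vR[:, 1:])
            b = rho * Vf / dy
            vp = Vf > 0
            vn = Vf < 0
            diag_u[:, 1:][vp[:, 1:]] += b[:, 1:][vp[:, 1:]]
            add(IU[:, 1:][vp[:, 1:]], IU[:, :-1][vp[:, 1:]], -b[:, 1:][vp[:, 1:]])
            diag_u[:, 0][vp[:, 0]] += 2 * b[:, 0][vp[:, 0]]  # wall ghost u=-u
            diag_u[:, :-1][vn[:, :-1]] += -b[:, :-1][vn[:, :-1]]
            add(IU[:, :-1][vn[:, :-1]], IU[:, 1:][vn[:, :-1]], b[:, :-1][vn[:, :-1]])
            diag_u[:, -1][vn[:, -1]] += -2 * b[:, -1][vn[:, -1]]

        add(IU[1:nx], IP[1:], 1.0 / dx)
        add(IU[1:nx], IP[:-1], -1.0 / dx)
        add(IU[0], IP[0], 2.0 / dx)
        rhs[IU[0]] += 2.0 * p_in / dx
        add(IU[nx], IP[nx - 1], -2.0 / dx)
        rhs[IU[nx]] -= 2.0 * p_out / dx
        add(IU, IU, diag_u)

        # ---- v-momentum (rows IV; physical faces j = 1..ny-1) --------------
        diag_v = r_v[:, 1:ny] + 2 * cy
        diag_v[1:nx - 1, :] += 2 * cx
        diag_v[[0, nx - 1], :] += cx
        add(IV[:, 1:], IV[:, :-1], -cy)
        add(IV[:, :-1], IV[:, 1:], -cy)
        add(IV[1:nx - 1], IV[0:nx - 2], -cx)
        add(IV[1:nx - 1], IV[2:], -cx)
        add(IV[0], IV[1], -cx)
        add(IV[nx - 1], IV[nx - 2], -cx)

        if include_inertia:
            Vc = v[:, 1:ny]
            b = rho * Vc / dy
            vp = Vc > 0
            vn = Vc < 0
            diag_v[vp] += b[vp]
            add(IV[:, 1:][vp[:, 1:]], IV[:, :-1][vp[:, 1:]], -b[:, 1:][vp[:, 1:]])
            diag_v[vn] += -b[vn]
            add(IV[:, :-1][vn[:, :-1]], IV[:, 1:][vn[:, :-1]], b[:, :-1][vn[:, :-1]])

            Uf = 0.25 * (u[:-1, :-1] + u[:-1, 1:] + u[1:, :-1] + u[1:, 1:])
            a = rho * Uf / dx
            up = Uf > 0
            un = Uf < 0
            diag_v[1:][up[1:]] += a[1:][up[1:]]
            add(IV[1:][up[1:]], IV[:-1][up[1:]], -a[1:][up[1:]])
            diag_v[:-1][un[:-1]] += -a[:-1][un[:-1]]
            add(IV[:-1][un[:-1]], IV[1:][un[:-1]], a[:-1][un[:-1]])

        add(IV, IP[:, 1:], 1.0 / dy)
        add(IV, IP[:, :-1], -1.0 / dy)
        add(IV, IV, diag_v)

        # ---- continuity (rows IP) ------------------------------------------
        add(IP, IU[1:], 1.0 / dx)
        add(IP, IU[:-1], -1.0 / dx)
        add(IP[:, :-1], IV, 1.0 / dy)
        add(IP[:, 1:], IV, -1.0 / dy)
        rhs[IP.ravel()] = m.ravel()

        A = sp.csc_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(N, N),
        )
        lu = spla.splu(A)
        sol = lu.solve(rhs)

        u_new = sol[:Nu].reshape(nx + 1, ny)
        v_new = np.zeros((nx, ny + 1))
        v_new[:, 1:ny] = sol[Nu:Nu + Nv].reshape(nx, ny - 1)

        scale = max(np.abs(u_new).max(), np.abs(v_new).max(), 1e-300)
        change = max(np.abs(u_new - u).max(), np.abs(v_new - v).max()) / scale
        residuals.append(change)
        if not include_inertia:
            u, v = u_new, v_new
            break
        u = relax * u_new + (1 - relax) * u
        v = relax * v_new + (1 - relax) * v
        if change < picard_tol:
            u, v = u_new, v_new
            break
    else:
        if strict:
            raise ConvergenceError(
                f"flow solver did not converge in {max_picard} Picard "
                f"iterations (last change {residuals[-1]:.2e})",
                residuals=residuals,
            )

    p = sol[Nu + Nv:].reshape(nx, ny)
    return FlowField(grid=grid, u=u, v=v, p=p)


def divergence(f: FlowField, grid: Grid2D | None = None) -> np.ndarray:
    """Discrete divergence of the superficial velocity, per cell (s⁻¹)."""
    g = grid or f.grid
    return (np.diff(f.u, axis=0) / g.dx) + (np.diff(f.v, axis=1) / g.dy)


def _interp_velocity(f: FlowField, x: float, y: float):
    g = f.grid
    dx, dy = g.dx, g.dy
    # u: nodes at (i*dx, (j+1/2)*dy)
    fx = x / dx
    fy = y / dy - 0.5
    i0 = int(np.clip(math.floor(fx), 0, g.nx - 1))
    j0 = int(np.clip(math.floor(fy), 0, g.ny - 2))
    tx, ty = fx - i0, np.clip(fy - j0, 0.0, 1.0)
    uu = ((1 - tx) * (1 - ty) * f.u[i0, j0] + tx * (1 - ty) * f.u[i0 + 1, j0]
          + (1 - tx) * ty * f.u[i0, j0 + 1] + tx * ty * f.u[i0 + 1, j0 + 1])
    # v: nodes at ((i+1/2)*dx, j*dy)
    fx = x / dx - 0.5
    fy = y / dy
    i0 = int(np.clip(math.floor(fx), 0, g.nx - 2))
    j0 = int(np.clip(math.floor(fy), 0, g.ny - 1))
    tx, ty = np.clip(fx - i0, 0.0, 1.0), fy - j0
    vv = ((1 - tx) * (1 - ty) * f.v[i0, j0] + tx * (1 - ty) * f.v[i0 + 1, j0]
          + (1 - tx) * ty * f.v[i0, j0 + 1] + tx * ty * f.v[i0 + 1, j0 + 1])
    return float(uu), float(vv)


def streamlines(f: FlowField, seeds, *, max_steps: int = 2000,
                step_fraction: float = 0.5) -> list:
    """Integral curves of the velocity field (fixed-step RK4).

    ``seeds`` is an iterable of (x, y) points; seeds outside the domain
    are skipped.  Integration stops when a curve leaves the domain or
    stagnates.  Returns a list of (n, 2) arrays.
    """
    import warnings

    g = f.grid
    h_ref = step_fraction * min(g.dx, g.dy)
    out = []
    for x0, y0 in seeds:
        if not (0 <= x0 <= g.length and 0 <= y0 <= g.height):
            warnings.warn(f"streamline seed ({x0:g}, {y0:g}) outside domain; skipped")
            continue
        pts = [(x0, y0)]
        x, y = x0, y0
        for _ in range(max_steps):
            def vel(xx, yy):
                if not (0 <= xx <= g.length and 0 <= yy <= g.height):
                    return None
                return _interp_velocity(f, xx, yy)

            k1 = vel(x, y)
            if k1 is None:
                break
            speed = math.hypot(*k1)
            if speed < 1e-300:
                break
            h = h_ref / speed
            k2 = vel(x + 0.5 * h * k1[0], y + 0.5 * h * k1[1])
            k3 = vel(x + 0.5 * h * k2[0], y + 0.5 * h * k2[1]) if k2 else None
            k4 = vel(x + h * k3[0], y + h * k3[1]) if k3 else None
            if k4 is None:
                break
            x += h / 6.0 * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0])
            y += h / 6.0 * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1])
            if not (0 <= x <= g.length and 0 <= y <= g.height):
                break
            pts.append((x, y))
        out.append(np.asarray(pts))
    return out


def recirculation_metrics(f: FlowField, grid: Grid2D | None = None,
                          clot_mask: np.ndarray | None = None):
    """Reversed-flow (u < 0) area distal to the clot, split by channel half.

    Returns ``(area_top, area_bottom, asymmetry)`` with areas in m² and
    asymmetry = |A_top − A_bottom| / (A_top + A_bottom) (zero when no flow
    reversal exists).
    """
    g = grid or f.grid
    mask = g.clot_mask if clot_mask is None else clot_mask
    uc, _ = f.cell_velocity()
    distal_start = int(np.nonzero(mask[:, 0])[0][-1]) + 1 if mask.any() else 0
    rev = uc[distal_start:, :] < 0
    cell_area = g.dx * g.dy
    jmid = g.ny // 2
    a_bottom = float(rev[:, :jmid].sum() * cell_area)
    a_top = float(rev[:, jmid:].sum() * cell_area)
    total = a_top + a_bottom
    asym = abs(a_top - a_bottom) / total if total > 0 else 0.0
    return a_top, a_bottom, asym
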
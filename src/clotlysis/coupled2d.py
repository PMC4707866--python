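"""Coupled 2-D clot lysis under flow.

The full lytic sequence of an occlusive clot in a pressure-driven channel:

1. steady flow is solved around/through the occlusion (Darcy-resisted);
2. free species (tPA, PLG, PLS) are advected and dispersed by the flow and
   react with the fibrin surface; bound species evolve locally;
3. lysis opens the microstructure (voidage up, permeability up), the flow
   is re-solved quasi-steadily, and the widening channel feeds back on
   transport — through recanalization and into mural-clot washout.

Transport is implicit in time (backward Euler, first-order upwind advection
+ central diffusion, solved by a reused sparse LU), so the post-breakthrough
jet imposes no CFL limit; kinetics are sub-stepped explicitly per cell.
The flow is re-solved whenever the lysis pattern has changed materially
(max per-cell change of L/n0 above a threshold), which matches the
minutes-to-hours separation between lytic and hydrodynamic time scales.

Time is normalized for cross-scenario comparison by the breakthrough ratio
(BTR): BTR = 0 when the first cell reaches 1.0% lysis and BTR = 1 when a
cell of the clot-exit column first exceeds 95.0% lysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from . import kinetics as kin
from .errors import DomainError, StabilityError
from .flow2d import FlowField, FluidProps, Grid2D, build_channel, recirculation_metrics, solve_flow
from .history import SimulationHistory
from .kinetics import KineticParameters, equilibrate_plg
from .microstructure import SPECIES, ClotState, MicrostructureParams, update_from_lysis

I_TPA, I_PLG, I_PLS = 0, 1, 2


@dataclass(frozen=True)
class CoupledScenario:
    """Configuration of a 2-D occlusion-lysis run."""

    grid: Grid2D
    kp: KineticParameters
    mp: MicrostructureParams
    fluid: FluidProps = FluidProps()
    dp: float = 1.0
    D: float = 1e-10
    inlet_tPA: float = 0.05
    inlet_PLG: float = 2.0
    dt: float = 1.0
    t_max: float = 40000.0
    btr_stop: float = 1.6
    flow_update_dfrac: float = 0.02
    flow_update_min_interval: float = 30.0
    record_interval: float = 20.0
    snapshot_btr: tuple = (0.5, 0.75, 1.0, 1.25, 1.5)
    lysis_start_fraction: float = 0.01
    breakthrough_fraction: float = 0.95

    @staticmethod
    def reference(dp: float = 1.0, nx: int = 150, ny: int = 30,
                  **kw) -> "CoupledScenario":
        """5 mm channel, 2.5 mm occlusive clot 10 mm from the inlet.

        The long upstream reach keeps the tPA supply to the clot face
        advective (parabolic across the channel), which is what shapes
        the centered lysis funnel; the downstream reach accommodates the
        post-recanalization jet and its recirculation zones."""
        grid = build_channel(height=5e-3, length=25e-3, clot_x0=10e-3,
                             clot_width=2.5e-3, nx=nx, ny=ny)
        return CoupledScenario(grid=grid, kp=KineticParameters(),
                               mp=MicrostructureParams(), dp=dp, **kw)


@dataclass
class LysisMetrics:
    """Derived metrics of an occlusion-lysis run."""

    t_start: float = math.nan       # first cell >= 1.0% lysed
    t_breakthrough: float = math.nan  # first clot-exit cell >= 95% lysed
    start_cell: tuple | None = None
    breakthrough_cell: tuple | None = None
    asymmetry_at: dict = field(default_factory=dict)   # BTR -> lysed asymmetry
    recirculation_at: dict = field(default_factory=dict)  # BTR -> (top, bottom, asym)
    funnel_widths: np.ndarray | None = None  # lysed-channel width per clot column at BT
    final_lysis_fraction: float = math.nan

    @property
    def reached_breakthrough(self) -> bool:
        return math.isfinite(self.t_breakthrough)

    def btr(self, t) -> float:
        """Breakthrough ratio of a simulation time."""
        if not self.reached_breakthrough:
            return math.nan
        return (t - self.t_start) / (self.t_breakthrough - self.t_start)


class _Transport2D:
    """Backward-Euler upwind advection–diffusion operator on cell centers.

    Solves (ε/dt + A) C = q/dt + boundary terms per species, with the LU
    factorization reused until the flow field or clot state changes
    materially.  Inlet Dirichlet, outlet zero-gradient (pure outflow),
    impermeable walls.
    """

    def __init__(self, grid: Grid2D, D: float, dt: float):
        self.grid = grid
        self.D = D
        self.dt = dt
        self._lu = None

    def rebuild(self, flow: FlowField, eps: np.ndarray):
        g = self.grid
        nx, ny, dx, dy = g.nx, g.ny, g.dx, g.dy
        D, dt = self.D, self.dt
        n = nx * ny
        IDX = np.arange(n).reshape(nx, ny)
        u, v = flow.u, flow.v

        diag = np.array(eps, dtype=float) / dt
        rows, cols, vals = [], [], []

        def add(r, c, a):
            rows.append(r.ravel())
            cols.append(c.ravel())
            vals.append(np.broadcast_to(a, r.shape).ravel())

        bc_coeff = np.zeros((nx, ny))
        # west faces: inlet (i = 0) ties to C_in, else couples to cell i-1
        uf = u[:nx, :]
        bc_coeff[0, :] = np.maximum(uf[0], 0.0) / dx + 2 * D / dx**2
        diag[0, :] += -np.minimum(uf[0], 0.0) / dx + 2 * D / dx**2
        diag[1:, :] += -np.minimum(uf[1:], 0.0) / dx + D / dx**2
        add(IDX[1:], IDX[:-1], -np.maximum(uf[1:], 0.0) / dx - D / dx**2)
        # east faces: pure outflow at i = nx-1
        uf = u[1:, :]
        diag[-1, :] += np.maximum(uf[-1], 0.0) / dx
        diag[:-1, :] += np.maximum(uf[:-1], 0.0) / dx + D / dx**2
        add(IDX[:-1], IDX[1:], np.minimum(uf[:-1], 0.0) / dx - D / dx**2)
        # south faces (wall no-flux at j = 0)
        vf = v[:, 1:ny]  # faces below cells j = 1..ny-1
        diag[:, 1:] += -np.minimum(vf, 0.0) / dy + D / dy**2
        add(IDX[:, 1:], IDX[:, :-1], -np.maximum(vf, 0.0) / dy - D / dy**2)
        # north faces (wall no-flux at j = ny-1)
        diag[:, :-1] += np.maximum(vf, 0.0) / dy + D / dy**2
        add(IDX[:, :-1], IDX[:, 1:], np.minimum(vf, 0.0) / dy - D / dy**2)

        add(IDX, IDX, diag)
        A = sp.csc_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(n, n),
        )
        self._lu = spla.splu(A)
        self._bc = bc_coeff.ravel()
        self._eps = eps

    def step(self, q: np.ndarray, c_in: float) -> np.ndarray:
        """Advance one species: returns updated superficial field ε·C."""
        rhs = q.ravel() / self.dt + c_in * self._bc
        C = self._lu.solve(rhs)
        return (C.reshape(self.grid.nx, self.grid.ny) * self._eps)


def transport_step_2d(fields: dict, flow: FlowField, dt: float,
                      sc: CoupledScenario, op: _Transport2D | None = None) -> dict:
    """One operator-split macro-step: implicit transport then sub-stepped
    kinetics.  ``fields`` holds ``q`` (3, nx, ny) superficial free
    concentrations, ``S`` (3, nx, ny) bound and ``L`` (nx, ny).

    For explicit use (tests, single steps) an operator is built on the
    fly; :func:`simulate_occlusion_lysis` reuses one across steps.
    """
    if dt <= 0:
        raise StabilityError("dt must be > 0", dt=dt)
    mp = sc.mp
    eps = 1.0 - mp.solid_fraction_initial * (1.0 - fields["L"] / mp.n0)
    if op is None:
        op = _Transport2D(sc.grid, sc.D, dt)
        op.rebuild(flow, eps)
    inlet = {"tPA": sc.inlet_tPA, "PLG": sc.inlet_PLG, "PLS": 0.0}
    q = fields["q"]
    for a, s in enumerate(SPECIES):
        q[a] = op.step(q[a], inlet[s])
    np.clip(q, 0.0, None, out=q)
    _react_2d(fields, dt, sc)
    return fields


def _react_2d(fields: dict, dt: float, sc: CoupledScenario,
              kin_safety: float = 0.5) -> None:
    """Sub-stepped explicit kinetics, restricted to clot columns."""
    mp, kp = sc.mp, sc.kp
    sl = sc.grid.clot_mask.any(axis=1)
    sl = slice(int(np.argmax(sl)), int(len(sl) - np.argmax(sl[::-1])))
    q = fields["q"][:, sl, :]
    S = fields["S"][:, sl, :]
    L = fields["L"][sl, :]
    lam = kin.kinetics_stiffness_bound(kp, mp)
    n_sub = max(1, math.ceil(dt * lam / kin_safety))
    h = dt / n_sub
    nq, nS = q.reshape(3, -1), S.reshape(3, -1)
    nL = L.ravel()
    for _ in range(n_sub):
        C = nq / (1.0 - mp.solid_fraction_initial * (1.0 - nL / mp.n0))
        dq, dS, dL = kin.spatial_reaction_rates(C, nS, nL, kp, mp)
        nq += h * dq
        nS += h * dS
        np.minimum(nL + h * dL, mp.n0, out=nL)
        np.clip(nq, 0.0, None, out=nq)
        np.clip(nS, 0.0, None, out=nS)
    # complete-lysis regularization: spent cells release all bound protein
    done = nL >= mp.n0 * (1.0 - kp.lysis_cutoff)
    if done.any():
        nq[:, done] += mp.solid_fraction_initial * nS[:, done]
        nS[:, done] = 0.0
        nL[done] = mp.n0
    fields["q"][:, sl, :] = nq.reshape(q.shape)
    fields["S"][:, sl, :] = nS.reshape(S.shape)
    fields["L"][sl, :] = nL.reshape(L.shape)


def initial_fields(sc: CoupledScenario) -> dict:
    """Occluding PLG-equilibrated clot; no tPA anywhere yet."""
    g, mp = sc.grid, sc.mp
    mask = g.clot_mask
    if sc.inlet_PLG > 0:
        C_free, S_bound = equilibrate_plg(sc.kp, mp, sc.inlet_PLG)
    else:
        C_free, S_bound = 0.0, 0.0
    L = np.where(mask, 0.0, mp.n0)
    eps = 1.0 - mp.solid_fraction_initial * (1.0 - L / mp.n0)
    C = np.zeros((3, g.nx, g.ny))
    C[I_PLG] = np.where(mask, C_free, sc.inlet_PLG)
    S = np.zeros((3, g.nx, g.ny))
    S[I_PLG] = np.where(mask, S_bound, 0.0)
    return {"q": C * eps, "S": S, "L": L}


def clot_state_fields(L: np.ndarray, mp: MicrostructureParams) -> ClotState:
    return update_from_lysis(L, mp)


def simulate_occlusion_lysis(sc: CoupledScenario, progress=None):
    """Run the coupled occlusion-lysis scenario.

    Returns ``(history, metrics)``.  The run stops at ``btr_stop`` times
    the breakthrough time (or at ``t_max`` if breakthrough never occurs).
    The scalar timeline records overall lysed fraction, front column, flow
    rate and recirculation areas; full L/C_tPA/velocity snapshots are
    stored at the configured BTR values.
    """
    g, mp, kp = sc.grid, sc.mp, sc.kp
    mask = g.clot_mask
    exit_col = g.clot_exit_index
    fields = initial_fields(sc)
    metrics = LysisMetrics()

    clot = clot_state_fields(fields["L"], mp)
    flow = solve_flow(g, clot, sc.dp, sc.fluid, strict=False)
    op = _Transport2D(g, sc.D, sc.dt)
    eps_prev = np.asarray(clot.eps)
    op.rebuild(flow, eps_prev)

    frac_at_update = fields["L"] / mp.n0
    times, rows = [], []
    snapshots = []
    pending_btr = sorted(sc.snapshot_btr)
    t = 0.0
    prev_frac = fields["L"] / mp.n0

    def lysed_asymmetry(frac):
        jmid = g.ny // 2
        bottom = float(frac[mask[:, 0], :jmid].sum())
        top = float(frac[mask[:, 0], jmid:].sum())
        return abs(top - bottom) / (top + bottom) if top + bottom > 0 else 0.0

    def record():
        frac = fields["L"] / mp.n0
        a_top, a_bot, _ = recirculation_metrics(flow, g, mask)
        inflow = float(flow.u[0, :].sum() * g.dy)
        times.append(t)
        rows.append((float(frac[mask].mean()), lysed_asymmetry(frac),
                     a_top, a_bot, inflow))

    def snapshot(label):
        uc, vc = flow.cell_velocity()
        snapshots.append((t, {
            "btr": label,
            "lysis_fraction": (fields["L"] / mp.n0).copy(),
            "C_tPA": (fields["q"][I_TPA] /
                      (1.0 - mp.solid_fraction_initial * (1.0 - fields["L"] / mp.n0))).copy(),
            "u": uc, "v": vc, "p": flow.p.copy(),
        }))

    record()
    next_record = sc.record_interval
    n_steps_max = int(math.ceil(sc.t_max / sc.dt))
    for _ in range(n_steps_max):
        transport_step_2d(fields, flow, sc.dt, sc, op)
        t += sc.dt
        frac = fields["L"] / mp.n0

        # ---- BTR anchors (interpolated to sub-dt accuracy) --------------
        if not math.isfinite(metrics.t_start):
            hit = mask & (frac >= sc.lysis_start_fraction)
            if hit.any():
                cells = np.argwhere(hit)
                i, j = min(map(tuple, cells))
                f1, f0 = frac[i, j], prev_frac[i, j]
                dt_back = sc.dt * (f1 - sc.lysis_start_fraction) / max(f1 - f0, 1e-300)
                metrics.t_start = t - min(max(dt_back, 0.0), sc.dt)
                metrics.start_cell = (int(i), int(j))
        if math.isfinite(metrics.t_start) and not metrics.reached_breakthrough:
            col = frac[exit_col, :]
            if (col >= sc.breakthrough_fraction).any():
                j = int(np.argmax(col >= sc.breakthrough_fraction))
                f1, f0 = col[j], prev_frac[exit_col, j]
                dt_back = sc.dt * (f1 - sc.breakthrough_fraction) / max(f1 - f0, 1e-300)
                metrics.t_breakthrough = t - min(max(dt_back, 0.0), sc.dt)
                metrics.breakthrough_cell = (exit_col, j)
                lysed = frac >= sc.breakthrough_fraction
                metrics.funnel_widths = lysed[mask[:, 0], :].sum(axis=1) * g.dy
        prev_frac = frac.copy()

        # ---- quasi-steady flow update ------------------------------------
        since_flow = t - getattr(op, "_t_flow", 0.0)
        if (np.max(np.abs(frac - frac_at_update)) >= sc.flow_update_dfrac
                and since_flow >= sc.flow_update_min_interval):
            clot = clot_state_fields(fields["L"], mp)
            eps_now = np.asarray(clot.eps)
            m_src = -(eps_now - eps_prev) / max(t - getattr(op, "_t_flow", 0.0), sc.dt)
            flow = solve_flow(g, clot, sc.dp, sc.fluid, mass_source=m_src,
                              strict=False, initial=flow)
            op.rebuild(flow, eps_now)
            op._t_flow = t
            eps_prev = eps_now
            frac_at_update = frac.copy()

        if t >= next_record - 1e-9:
            record()
            next_record += sc.record_interval
            if progress is not None:
                progress(t, float(frac[mask].mean()), metrics.btr(t))

        # ---- BTR snapshots & metrics -------------------------------------
        if metrics.reached_breakthrough:
            b = metrics.btr(t)
            while pending_btr and b >= pending_btr[0]:
                label = pending_btr.pop(0)
                snapshot(label)
                metrics.asymmetry_at[label] = lysed_asymmetry(frac)
                metrics.recirculation_at[label] = recirculation_metrics(flow, g, mask)
            if b >= sc.btr_stop:
                break

    record_needed = not times or times[-1] < t
    if record_needed:
        record()
    metrics.final_lysis_fraction = float((fields["L"] / mp.n0)[mask].mean())

    data = np.asarray(rows)
    hist = SimulationHistory(
        t=np.asarray(times),
        columns={
            "mean_lysis_fraction": data[:, 0],
            "lysed_asymmetry": data[:, 1],
            "recirc_area_top": data[:, 2],
            "recirc_area_bottom": data[:, 3],
            "inlet_flow_rate": data[:, 4],
        },
        snapshots=snapshots,
        metadata={
            "tier": "coupled2d", "dp": sc.dp, "nx": g.nx, "ny": g.ny,
            "dt": sc.dt, "D": sc.D, "t_start": metrics.t_start,
            "t_breakthrough": metrics.t_breakthrough,
        },
    )
    return hist, metrics


def breakthrough_ratio(history: SimulationHistory) -> np.ndarray:
    """BTR timeline of a coupled run: (t − t_start)/(t_bt − t_start).

    NaN where undefined (before lysis onset or if breakthrough was never
    reached).
    """
    t0 = history.metadata.get("t_start", math.nan)
    tb = history.metadata.get("t_breakthrough", math.nan)
    t = history.t
    if not (math.isfinite(t0) and math.isfinite(tb)):
        return np.full_like(t, math.nan)
    return (t - t0) / (tb - t0)


def peak_recirculation(history: SimulationHistory, metrics: LysisMetrics,
                       btr_max: float = 1.5) -> float:
    """Largest total distal reversed-flow area (m²) developed up to
    ``btr_max``; 0.0 if breakthrough was never reached."""
    if not metrics.reached_breakthrough:
        return 0.0
    btr = breakthrough_ratio(history)
    sel = btr <= btr_max
    tot = history.column("recirc_area_top") + history.column("recirc_area_bottom")
    return float(tot[sel].max()) if sel.any() else 0.0


def compare_pressure_drops(dp_list, base: CoupledScenario, progress=None):
    """Run the occlusion scenario at each pressure drop.

    Returns a list of report dicts (one per Δp, in input order) with
    breakthrough times and matched-BTR asymmetry/recirculation metrics.
    Failures are reported per scenario rather than aborting the sweep.
    """
    if not dp_list:
        raise DomainError("dp_list must be non-empty")
    reports = []
    for dp in dp_list:
        scenario = replace(base, dp=float(dp))
        entry = {"dp": float(dp)}
        try:
            hist, met = simulate_occlusion_lysis(scenario, progress=progress)
            entry.update(
                t_start=met.t_start,
                t_breakthrough=met.t_breakthrough,
                breakthrough_duration=met.t_breakthrough - met.t_start,
                peak_recirculation=peak_recirculation(hist, met),
                breakthrough_reached=met.reached_breakthrough,
                asymmetry_at=dict(met.asymmetry_at),
                recirculation_at=dict(met.recirculation_at),
                final_lysis_fraction=met.final_lysis_fraction,
                history=hist,
                metrics=met,
            )
        except Exception as exc:  # partial report on per-scenario failure
            entry["error"] = repr(exc)
        reports.append(entry)
    return reports
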
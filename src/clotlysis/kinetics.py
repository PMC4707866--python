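"""Well-mixed fibrinolysis reaction system.

The lytic cascade is driven by three proteins exchanging between a free
(fluid) phase and a bound (fibrin-surface) phase:

* adsorption/desorption of tPA, plasminogen (PLG) and plasmin (PLS) onto
  fibrin binding sites, ``A_α = k_ads,α C_α (θ_α − occupied) − k_rev,α S_α``;
* Michaelis–Menten plasmin generation on the surface from bound tPA and
  bound PLG, ``G = k2 S_tPA S_PLG / (K_M + S_PLG)``;
* irreversible inhibition of *free* plasmin by α₂-antiplasmin (AP),
  second order, forming an inactive AP–PLS complex;
* fibrin lysis by bound plasmin, ``dL/dt = (k_cat/γ) S_PLS`` where γ is the
  number of plasmin cuts needed per fibrin unit;
* solubilization: as fibrin dissolves, bound protein is released back to
  the free phase at rate ``κ S_α (dL/dt)/(n0 − L)``, which guarantees that
  no bound protein remains once the clot is fully lysed.

Free concentrations C_α are per fluid volume; bound concentrations S_α and
the lysed amount L are per initial-solid volume (φ0 basis, see
:mod:`clotlysis.microstructure`), so the conserved amount of a species per
total volume is ε·C_α + φ0·S_α.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import solve_ivp

from . import microstructure as micro
from .errors import DomainError, IntegrationError, StateError
from .history import SimulationHistory
from .microstructure import SPECIES, MicrostructureParams

FREE_SPECIES = ("tPA", "PLG", "PLS", "AP", "AP_PLS")


@dataclass(frozen=True)
class KineticParameters:
    """Rate constants of the fibrinolysis network.

    Adsorption constants are µM⁻¹ s⁻¹, first-order constants s⁻¹,
    Michaelis constant µM.  The defaults are the package's reference set:
    dissociation constants follow the classical porous-clot lysis
    literature (tPA 0.58 µM, PLG 38 µM, PLS 0.057 µM), the surface
    Michaelis–Menten pair is (k2 = 0.3 s⁻¹, K_M = 0.16 µM), and the lysis
    pair (k_cat, γ) is calibrated so that 50 nM tPA dissolves a 0.28 mg/ml
    PLG-equilibrated clot in about 90 s.
    """

    k_ads: dict = field(
        default_factory=lambda: {"tPA": 0.1, "PLG": 0.01, "PLS": 0.01}
    )
    k_rev: dict = field(
        default_factory=lambda: {"tPA": 0.058, "PLG": 0.38, "PLS": 0.00057}
    )
    k2: float = 0.3
    K_M: float = 0.16
    k_cat: float = 12.0
    gamma: float = 10.0
    kappa: float = 1.0
    k_AP: float = 10.0
    plasmin_decay: float = 0.0  # optional loss of plasmin activity, s⁻¹
    lysis_cutoff: float = 1e-6  # solubilization regularized below (n0−L)/n0

    def __post_init__(self):
        for name in ("k2", "k_cat", "gamma", "kappa", "k_AP", "plasmin_decay"):
            if getattr(self, name) < 0:
                raise DomainError(f"{name} must be >= 0")
        if self.K_M <= 0:
            raise DomainError("K_M must be > 0")
        if self.gamma <= 0:
            raise DomainError("gamma must be > 0")
        for s in SPECIES:
            if self.k_ads[s] < 0 or self.k_rev[s] < 0:
                raise DomainError("rate constants must be >= 0")

    @property
    def lysis_rate_constant(self) -> float:
        """k_cat/γ, the first-order lysis rate per unit bound plasmin."""
        return self.k_cat / self.gamma

    def replace(self, **kw) -> "KineticParameters":
        return replace(self, **kw)


@dataclass
class WellMixedState:
    """Concentrations of a spatially uniform clot + plasma system.

    ``C`` maps free species (tPA, PLG, PLS, AP, AP_PLS) to µM (fluid
    basis); ``S`` maps bound species (tPA, PLG, PLS) to µM (φ0 basis);
    ``L`` is the lysed fibrin (µM, φ0 basis).
    """

    C: dict
    S: dict
    L: float = 0.0

    def clot(self, mp: MicrostructureParams) -> micro.ClotState:
        return micro.update_from_lysis(self.L, mp)

    @classmethod
    def initial(
        cls,
        kp: KineticParameters,
        mp: MicrostructureParams,
        tPA: float = 0.05,
        PLG_total: float = 2.0,
        AP: float = 1.0,
        equilibrate: bool = True,
    ) -> "WellMixedState":
        """Reference initial condition: PLG-equilibrated clot plus a tPA bolus.

        ``tPA``, ``PLG_total`` and ``AP`` in µM.  With ``equilibrate`` the
        plasminogen is first partitioned between phases at the adsorption
        steady state (the clot's pre-treatment condition).
        """
        if equilibrate:
            C_free, S_bound = equilibrate_plg(kp, mp, PLG_total)
        else:
            C_free, S_bound = PLG_total, 0.0
        return cls(
            C={"tPA": tPA, "PLG": C_free, "PLS": 0.0, "AP": AP, "AP_PLS": 0.0},
            S={"tPA": 0.0, "PLG": S_bound, "PLS": 0.0},
            L=0.0,
        )


# ---- elementary rates ------------------------------------------------------


def _occupied(S: dict, species: str, mp: MicrostructureParams):
    """Total occupancy of the site class that ``species`` binds to."""
    cls = mp._class_of(species)
    occ = 0.0
    for other in SPECIES:
        if mp.site_class[other] == cls:
            occ = occ + S[other]
    return occ


def adsorption_rate(C_alpha, S: dict, theta_alpha, kp: KineticParameters,
                    mp: MicrostructureParams, species: str):
    """Net adsorption rate A_α (µM/s, φ0 basis); positive = onto fibrin."""
    if np.any(np.asarray(C_alpha) < 0) or any(np.any(np.asarray(v) < 0) for v in S.values()):
        raise StateError("concentrations must be non-negative")
    free_sites = theta_alpha - _occupied(S, species, mp)
    return kp.k_ads[species] * C_alpha * free_sites - kp.k_rev[species] * S[species]


def plasmin_generation_rate(S_tPA, S_PLG, kp: KineticParameters):
    """Surface plasmin generation G (µM/s); consumes bound PLG 1:1."""
    return kp.k2 * S_tPA * S_PLG / (kp.K_M + S_PLG)


def plasmin_inhibition_rate(C_PLS, C_AP, kp: KineticParameters):
    """Free-phase AP inhibition rate (µM/s, fluid basis); 1:1:1 to complex."""
    return kp.k_AP * C_AP * C_PLS


def lysis_rate(S_PLS, kp: KineticParameters, L=0.0, n0=math.inf):
    """Fibrin lysis rate dL/dt = (k_cat/γ)·S_PLS, forced to 0 at L = n0."""
    rate = kp.lysis_rate_constant * np.asarray(S_PLS, dtype=float)
    out = np.where(np.asarray(L) < n0, rate, 0.0)
    return out if out.ndim else float(out)


def solubilization_rates(S: dict, L, dLdt, kp: KineticParameters, n0: float) -> dict:
    """Release fluxes Φ_α = κ S_α (dL/dt)/(n0 − L), µM/s on the φ0 basis.

    The 1/(n0−L) singularity is regularized by flooring the remaining
    fibrin at ``kp.lysis_cutoff·n0``; because S_α itself scales with the
    remaining fibrin, the flux stays bounded and drives every bound
    concentration to zero exactly when the clot is spent.
    """
    remaining = np.maximum(n0 - np.asarray(L, dtype=float), kp.lysis_cutoff * n0)
    return {s: kp.kappa * S[s] * dLdt / remaining for s in SPECIES}


# ---- assembled ODE system --------------------------------------------------

_NV = 9  # q_tPA q_PLG q_PLS q_AP q_cplx S_tPA S_PLG S_PLS L


def _pack(state: WellMixedState, mp: MicrostructureParams) -> np.ndarray:
    eps = micro.voidage(micro.fibre_radius(state.L, mp), mp)
    q = [state.C[s] * eps for s in FREE_SPECIES]
    return np.array(q + [state.S[s] for s in SPECIES] + [state.L], dtype=float)


def _unpack(y: np.ndarray, mp: MicrostructureParams):
    L = min(max(y[8], 0.0), mp.n0)
    eps = 1.0 - mp.solid_fraction_initial * (1.0 - L / mp.n0)
    C = {s: max(y[i], 0.0) / eps for i, s in enumerate(FREE_SPECIES)}
    S = {s: max(y[5 + i], 0.0) for i, s in enumerate(SPECIES)}
    return C, S, L, eps


def _rhs(t, y, kp: KineticParameters, mp: MicrostructureParams) -> np.ndarray:
    C, S, L, eps = _unpack(y, mp)
    n0 = mp.n0
    phi0 = mp.solid_fraction_initial
    frac = 1.0 - L / n0

    theta = {s: mp.theta0(s) * frac for s in SPECIES}
    A = {}
    for s in SPECIES:
        free_sites = theta[s] - _occupied(S, s, mp)
        A[s] = kp.k_ads[s] * C[s] * free_sites - kp.k_rev[s] * S[s]

    G = plasmin_generation_rate(S["tPA"], S["PLG"], kp)
    dL = kp.lysis_rate_constant * S["PLS"] if L < n0 else 0.0
    phi = solubilization_rates(S, L, dL, kp, n0)
    inhib = plasmin_inhibition_rate(C["PLS"], C["AP"], kp)

    dy = np.empty(_NV)
    # free phase (superficial concentrations q = ε·C)
    dy[0] = -phi0 * (A["tPA"] - phi["tPA"])
    dy[1] = -phi0 * (A["PLG"] - phi["PLG"])
    dy[2] = (-phi0 * (A["PLS"] - phi["PLS"]) - eps * inhib
             - kp.plasmin_decay * eps * C["PLS"])
    dy[3] = -eps * inhib
    dy[4] = eps * inhib
    # bound phase
    dy[5] = A["tPA"] - phi["tPA"]
    dy[6] = A["PLG"] - G - phi["PLG"]
    dy[7] = A["PLS"] + G - phi["PLS"] - kp.plasmin_decay * S["PLS"]
    dy[8] = dL
    return dy


def rhs_well_mixed(state: WellMixedState, kp: KineticParameters,
                   mp: MicrostructureParams) -> WellMixedState:
    """Time derivative of a well-mixed state (same container, d/dt values).

    Raises :class:`StateError` if the state is inconsistent (negative
    concentrations, or site-class occupancy exceeding θ beyond tolerance).
    """
    validate_state(state, mp)
    y = _pack(state, mp)
    dy = _rhs(0.0, y, kp, mp)
    # free-phase entries are derivatives of the superficial concentration ε·C
    dC = {s: dy[i] for i, s in enumerate(FREE_SPECIES)}
    dS = {s: dy[5 + i] for i, s in enumerate(SPECIES)}
    return WellMixedState(C=dC, S=dS, L=dy[8])


def validate_state(state: WellMixedState, mp: MicrostructureParams,
                   tol: float = 1e-6) -> None:
    for s, v in list(state.C.items()) + list(state.S.items()):
        if v < -tol:
            raise StateError(f"negative concentration for {s}: {v:g}")
    if not 0.0 <= state.L <= mp.n0 * (1 + 1e-9):
        raise StateError(f"L = {state.L:g} outside [0, n0 = {mp.n0:g}]")
    frac = 1.0 - state.L / mp.n0
    for cls in set(mp.site_class.values()):
        theta = mp.binding_sites_per_monomer[cls] * mp.n0 * frac
        occ = sum(state.S[s] for s in SPECIES if mp.site_class[s] == cls)
        if occ > theta + tol * mp.binding_sites_per_monomer[cls] * mp.n0 + tol:
            raise StateError(
                f"bound occupancy {occ:g} exceeds theta_{cls} = {theta:g}"
            )


def simulate_well_mixed(
    init: WellMixedState,
    kp: KineticParameters,
    mp: MicrostructureParams,
    t_end: float,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    n_snapshots: int = 600,
    method: str = "LSODA",
) -> SimulationHistory:
    """Integrate the well-mixed system to ``t_end`` (s).

    Uses a stiff-capable adaptive integrator (the solubilization term near
    complete lysis and fast AP inhibition are stiff).  Returns a history
    with free/bound concentrations, lysed fraction, normalized fibre
    radius, voidage and permeability.
    """
    if t_end <= 0:
        raise DomainError("t_end must be > 0")
    validate_state(init, mp)
    y0 = _pack(init, mp)
    t_eval = np.linspace(0.0, t_end, n_snapshots)
    sol = solve_ivp(
        _rhs, (0.0, t_end), y0, args=(kp, mp), method=method,
        rtol=rtol, atol=atol, t_eval=t_eval, dense_output=False,
    )
    if not sol.success:
        raise IntegrationError(
            f"well-mixed integration failed: {sol.message}",
            t_last=sol.t[-1] if sol.t.size else 0.0,
        )
    cols = {}
    eps = 1.0 - mp.solid_fraction_initial * (1.0 - np.clip(sol.y[8], 0, mp.n0) / mp.n0)
    for i, s in enumerate(FREE_SPECIES):
        cols[f"C_{s}"] = np.maximum(sol.y[i], 0.0) / eps
    for i, s in enumerate(SPECIES):
        cols[f"S_{s}"] = np.maximum(sol.y[5 + i], 0.0)
    L = np.clip(sol.y[8], 0.0, mp.n0)
    cols["L"] = L
    cols["lysis_fraction"] = L / mp.n0
    cols["R_f_ratio"] = np.sqrt(1.0 - L / mp.n0)
    cols["eps"] = eps
    cols["permeability"] = micro.permeability(
        eps, mp.fibre_radius_initial * cols["R_f_ratio"], mp
    )
    return SimulationHistory(
        t=sol.t, columns=cols,
        metadata={"tier": "well_mixed", "t_end": t_end, "rtol": rtol, "atol": atol},
    )


def spatial_reaction_rates(C: np.ndarray, S: np.ndarray, L: np.ndarray,
                           kp: KineticParameters, mp: MicrostructureParams):
    """Vectorized reaction RHS for the spatial tiers (tPA/PLG/PLS only).

    ``C`` and ``S`` are (3, n) arrays ordered like
    :data:`clotlysis.microstructure.SPECIES`; ``L`` is (n,).  AP inhibition
    is dropped, matching the reduced species set of the transport models.
    Returns ``(dq, dS, dL)`` where dq is the rate of change of the
    superficial free concentration ε·C per total volume.

    Non-clot locations are encoded as L = n0 (pure fluid): all surface
    terms vanish there identically.
    """
    n0 = mp.n0
    phi0 = mp.solid_fraction_initial
    frac = 1.0 - L / n0

    i_t, i_p, i_l = 0, 1, 2  # tPA, PLG, PLS
    theta_t = mp.theta0("tPA") * frac
    theta_p = mp.theta0("PLG") * frac  # shared PLG/PLS site class

    occ_p = S[i_p] + S[i_l]
    A = np.empty_like(S)
    A[i_t] = kp.k_ads["tPA"] * C[i_t] * (theta_t - S[i_t]) - kp.k_rev["tPA"] * S[i_t]
    A[i_p] = kp.k_ads["PLG"] * C[i_p] * (theta_p - occ_p) - kp.k_rev["PLG"] * S[i_p]
    A[i_l] = kp.k_ads["PLS"] * C[i_l] * (theta_p - occ_p) - kp.k_rev["PLS"] * S[i_l]

    G = kp.k2 * S[i_t] * S[i_p] / (kp.K_M + S[i_p])
    dL = np.where(frac > 0.0, kp.lysis_rate_constant * S[i_l], 0.0)
    remaining = np.maximum(n0 - L, kp.lysis_cutoff * n0)
    phi = kp.kappa * S * dL / remaining  # broadcast over species axis

    dS = A.copy()
    dS[i_p] -= G
    dS[i_l] += G - kp.plasmin_decay * S[i_l]
    dS -= phi

    dq = -phi0 * (A - phi)
    return dq, dS, dL


def kinetics_stiffness_bound(kp: KineticParameters, mp: MicrostructureParams) -> float:
    """Conservative bound on the fastest local reaction rate (s⁻¹), used to
    size the explicit kinetics sub-step of the spatial tiers."""
    lam_ads = max(
        kp.k_ads[s] * mp.theta0(s) + kp.k_rev[s] for s in SPECIES
    )
    lam_gen = kp.k2 * max(mp.theta0("tPA") / kp.K_M, 1.0)
    lam_sol = kp.kappa * kp.lysis_rate_constant * mp.theta0("PLG") / mp.n0
    return max(lam_ads, lam_gen, lam_sol, kp.plasmin_decay)


def equilibrate_plg(kp: KineticParameters, mp: MicrostructureParams,
                    C_PLG_total: float = 2.0):
    """Partition of plasminogen between phases before treatment.

    Solves the adsorption steady state of a closed clot loaded with
    ``C_PLG_total`` µM plasminogen in its pore fluid:
    ``ε0·C + φ0·S = ε0·C_tot`` with ``S = θ0·C/(K_d + C)``.
    Returns ``(C_free, S_bound)`` in µM (fluid / φ0 bases respectively).
    """
    if C_PLG_total <= 0:
        raise DomainError("C_PLG_total must be > 0")
    theta0 = mp.theta0("PLG")
    eps0 = mp.voidage_initial
    phi0 = mp.solid_fraction_initial
    k_ads, k_rev = kp.k_ads["PLG"], kp.k_rev["PLG"]
    if k_ads == 0.0:
        return C_PLG_total, 0.0
    Kd = k_rev / k_ads
    # ε0·C² + (ε0·Kd + φ0·θ0 − ε0·C_tot)·C − ε0·C_tot·Kd = 0
    a = eps0
    b = eps0 * Kd + phi0 * theta0 - eps0 * C_PLG_total
    c = -eps0 * C_PLG_total * Kd
    disc = b * b - 4 * a * c
    C_free = (-b + math.sqrt(disc)) / (2 * a)
    S_bound = theta0 * C_free / (Kd + C_free) if Kd + C_free > 0 else theta0
    return C_free, S_bound


def time_to_lysis(history: SimulationHistory, fraction: float = 0.95) -> float:
    """First time the lysed fraction reaches ``fraction``, linearly
    interpolated between snapshots; NaN if never reached."""
    if not 0.0 < fraction <= 1.0:
        raise DomainError("fraction must lie in (0, 1]")
    if len(history.t) == 0:
        raise DomainError("history is empty")
    f = np.asarray(history.columns["lysis_fraction"])
    t = np.asarray(history.t)
    idx = np.nonzero(f >= fraction)[0]
    if idx.size == 0:
        return math.nan
    i = idx[0]
    if i == 0:
        return float(t[0])
    t0, t1, f0, f1 = t[i - 1], t[i], f[i - 1], f[i]
    if f1 == f0:
        return float(t1)
    return float(t0 + (fraction - f0) / (f1 - f0) * (t1 - t0))
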
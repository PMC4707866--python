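"""Fibrin microstructure model.

Lysis is represented as homogeneous radial shrinkage of the fibrin fibres:
the amount of lysed fibrin L drives the fibre radius R_f, which in turn sets
the clot voidage ε (fluid volume fraction), the surface binding-site
densities θ_α available to the lytic proteins, and the Darcy permeability k
of the clot as a fibrous porous medium.

Unit basis
----------
Bound-phase quantities (L, n0, θ_α and the bound concentrations S_α that
live in :mod:`clotlysis.kinetics`) are expressed per unit *initial solid
volume* of the clot, a fixed reference basis with solid fraction
φ0 = 1 − ε0.  Free-phase concentrations are per unit fluid volume, so the
amount of a species per total clot volume is ε·C_α + φ0·S_α.  This is the
convention under which a closed clot equilibrated with 2 µM plasminogen
holds ~35 µM in the bound phase while the free phase sits near 1.65 µM: the
fibre phase is only ~1% of the clot volume but is densely decorated with
binding sites.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigError, DomainError

#: species transported in the free phase and adsorbed onto fibrin
SPECIES = ("tPA", "PLG", "PLS")

#: binding-site classes; PLG and PLS compete for the same (lysine) sites,
#: tPA has its own site class.  Configurable via MicrostructureParams.
DEFAULT_SITE_CLASS = {"tPA": "tPA", "PLG": "PLG", "PLS": "PLG"}


@dataclass(frozen=True)
class MicrostructureParams:
    """Geometry and composition of the intact fibrin network.

    Parameters
    ----------
    fibrin_density : float
        Clot fibrin content in g/l (mg/ml).  Default 0.28 mg/ml, a coarse
        plasma clot.
    fibre_radius_initial : float
        Initial fibre radius R_f0 in m (default 250 nm).
    fibrin_monomer_molar_mass : float
        g/mol; 340 kDa fibrin(ogen) monomer.
    fibre_protein_density : float
        Protein mass per unit fibre volume, g/l.  Sets the initial solid
        fraction φ0 = fibrin_density / fibre_protein_density and hence the
        initial voidage ε0 = 1 − φ0.  The default (28.2 mg/ml) puts ε0 at
        0.9901, the porosity implied by the equilibrium plasminogen
        partition of a 0.28 mg/ml clot.
    binding_sites_per_monomer : dict
        Effective adsorption sites per fibrin monomer for each site class.
    theta_scaling_exponent : float
        θ_α(R_f) = θ_α0 · (R_f/R_f0)**p.  p = 2 ties sites to remaining
        fibrin mass (default); p = 1 is the surface-area alternative.
    permeability_cap : float
        Upper bound k_max (m²) regularizing the k → ∞ limit of a fully
        lysed clot.
    voidage_lysed_threshold : float
        Cells with ε above this are treated as fully recanalized fluid
        (Darcy resistance dropped entirely).
    """

    fibrin_density: float = 0.28
    fibre_radius_initial: float = 250e-9
    fibrin_monomer_molar_mass: float = 340_000.0
    fibre_protein_density: float = 28.2
    binding_sites_per_monomer: dict = field(
        default_factory=lambda: {"tPA": 0.06, "PLG": 10.0}
    )
    site_class: dict = field(default_factory=lambda: dict(DEFAULT_SITE_CLASS))
    theta_scaling_exponent: float = 2.0
    permeability_cap: float = 1e-6
    voidage_lysed_threshold: float = 0.9999

    def __post_init__(self):
        if self.fibrin_density <= 0:
            raise ConfigError("fibrin_density must be > 0")
        if self.fibre_radius_initial <= 0:
            raise ConfigError("fibre_radius_initial must be > 0")
        if self.fibrin_monomer_molar_mass <= 0:
            raise ConfigError("fibrin_monomer_molar_mass must be > 0")
        if not 0 < self.solid_fraction_initial < 1:
            raise ConfigError(
                "fibre_protein_density must exceed fibrin_density so that "
                "the initial voidage lies in (0, 1); got "
                f"phi0 = {self.solid_fraction_initial:g}"
            )
        if not 0 < self.voidage_lysed_threshold < 1:
            raise ConfigError("voidage_lysed_threshold must lie in (0, 1)")

    # ---- derived constants -------------------------------------------------

    @property
    def solid_fraction_initial(self) -> float:
        """φ0, fibre volume per clot volume of the intact clot."""
        return self.fibrin_density / self.fibre_protein_density

    @property
    def voidage_initial(self) -> float:
        """ε0 = 1 − φ0."""
        return 1.0 - self.solid_fraction_initial

    @property
    def n0(self) -> float:
        """Initial fibrin monomer concentration, µM on the φ0 basis."""
        molar = self.fibrin_density / self.fibrin_monomer_molar_mass  # mol/l
        return molar * 1e6 / self.solid_fraction_initial

    def theta0(self, species: str) -> float:
        """Initial binding-site density θ_α0 (µM, φ0 basis) for a species."""
        cls = self._class_of(species)
        return self.binding_sites_per_monomer[cls] * self.n0

    def _class_of(self, species: str) -> str:
        try:
            return self.site_class[species]
        except KeyError:
            raise DomainError(
                f"unknown species {species!r}; valid species are {list(self.site_class)}"
            ) from None

    def with_fibrin_density(self, density: float) -> "MicrostructureParams":
        return replace(self, fibrin_density=density)


# ---- microstructure maps ---------------------------------------------------


def fibre_radius(L, p: MicrostructureParams):
    """Fibre radius R_f(L) under homogeneous radial shrinkage.

    Fibrin mass per unit fibre length scales with the cross-section R_f²,
    so R_f = R_f0 · sqrt(1 − L/n0).  Accepts scalars or arrays.
    """
    L = np.asarray(L, dtype=float)
    n0 = p.n0
    if np.any(L < -1e-12 * n0) or np.any(L > n0 * (1 + 1e-12)):
        raise DomainError(f"lysed fibrin L must lie in [0, n0 = {n0:g} uM]")
    frac = np.clip(1.0 - L / n0, 0.0, 1.0)
    out = p.fibre_radius_initial * np.sqrt(frac)
    return out if out.ndim else float(out)


def voidage(R_f, p: MicrostructureParams):
    """Voidage ε(R_f) = 1 − φ0·(R_f/R_f0)²."""
    R_f = np.asarray(R_f, dtype=float)
    R0 = p.fibre_radius_initial
    if np.any(R_f < -1e-12 * R0) or np.any(R_f > R0 * (1 + 1e-12)):
        raise DomainError(f"fibre radius must lie in [0, R_f0 = {R0:g} m]")
    ratio2 = np.clip((R_f / R0) ** 2, 0.0, 1.0)
    out = 1.0 - p.solid_fraction_initial * ratio2
    return out if out.ndim else float(out)


def binding_site_density(R_f, species: str, p: MicrostructureParams):
    """Binding-site density θ_α(R_f) = θ_α0 · (R_f/R_f0)**p_exp.

    With the default exponent 2 the sites track the remaining fibrin mass;
    θ_α(0) = 0, so a fully lysed clot carries no bound protein.
    """
    theta0 = p.theta0(species)
    R_f = np.asarray(R_f, dtype=float)
    R0 = p.fibre_radius_initial
    if np.any(R_f < -1e-12 * R0) or np.any(R_f > R0 * (1 + 1e-12)):
        raise DomainError(f"fibre radius must lie in [0, R_f0 = {R0:g} m]")
    ratio = np.clip(R_f / R0, 0.0, 1.0)
    out = theta0 * ratio**p.theta_scaling_exponent
    return out if out.ndim else float(out)


def permeability(eps, R_f, p: MicrostructureParams):
    """Darcy permeability of the fibre bed (Davies correlation).

    k = R_f² / (16 φ^1.5 (1 + 56 φ³)) with solid fraction φ = 1 − ε,
    clipped to ``p.permeability_cap``.  As ε → 1 the correlation diverges;
    the cap represents the unobstructed-flow limit of a lysed clot.
    """
    eps = np.asarray(eps, dtype=float)
    R_f = np.asarray(R_f, dtype=float)
    if np.any(eps < p.voidage_initial - 1e-9) or np.any(eps > 1.0 + 1e-12):
        raise DomainError(
            f"voidage must lie in [eps0 = {p.voidage_initial:g}, 1]"
        )
    phi = np.clip(1.0 - eps, 0.0, None)
    with np.errstate(divide="ignore", invalid="ignore"):
        k = np.where(
            phi > 0.0,
            R_f**2 / (16.0 * phi**1.5 * (1.0 + 56.0 * phi**3)),
            np.inf,
        )
    out = np.minimum(k, p.permeability_cap)
    return out if out.ndim else float(out)


@dataclass
class ClotState:
    """Per-location state of the fibrin network.

    All fields accept scalars (well-mixed tier) or arrays (spatial tiers).
    ``theta`` maps species name → available binding-site density (µM, φ0
    basis).
    """

    L: object
    R_f: object
    eps: object
    theta: dict
    k: object
    lysis_fraction: object = None


def _build_state(L, p: MicrostructureParams) -> ClotState:
    R_f = fibre_radius(L, p)
    eps = voidage(R_f, p)
    theta = {s: binding_site_density(R_f, s, p) for s in SPECIES}
    k = permeability(eps, R_f, p)
    frac = np.asarray(L, dtype=float) / p.n0
    return ClotState(L=L, R_f=R_f, eps=eps, theta=theta, k=k,
                     lysis_fraction=frac if frac.ndim else float(frac))


def initial_state(p: MicrostructureParams) -> ClotState:
    """Intact clot: L = 0, R_f = R_f0, ε = ε0, θ = θ0, k = k0."""
    return _build_state(0.0, p)


def update_from_lysis(L, p: MicrostructureParams) -> ClotState:
    """Recompute the full microstructure state from the lysed amount L."""
    return _build_state(L, p)
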
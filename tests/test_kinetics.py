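"""Well-mixed fibrinolysis kinetics: rates, conservation, lysis dynamics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clotlysis import (
    DomainError,
    KineticParameters,
    MicrostructureParams,
    SimulationHistory,
    StateError,
    WellMixedState,
    equilibrate_plg,
    simulate_well_mixed,
    time_to_lysis,
)
from clotlysis.kinetics import (
    SPECIES,
    adsorption_rate,
    lysis_rate,
    plasmin_generation_rate,
    plasmin_inhibition_rate,
    rhs_well_mixed,
    solubilization_rates,
)


@pytest.fixture(scope="module")
def mp():
    return MicrostructureParams()


@pytest.fixture(scope="module")
def kp():
    return KineticParameters()


def total_inventory(h, mp, species):
    """ε·C + φ0·S (+ complexed forms), the conserved amount per total volume."""
    phi0 = mp.solid_fraction_initial
    eps = h.column("eps")
    tot = eps * h.column(f"C_{species}") + phi0 * h.column(f"S_{species}")
    if species == "PLS":
        tot = tot + eps * h.column("C_AP_PLS")
    return tot


class TestAdsorption:
    def test_zero_everything(self, kp, mp):
        S = {s: 0.0 for s in SPECIES}
        assert adsorption_rate(0.0, S, mp.theta0("tPA"), kp, mp, "tPA") == 0.0

    def test_saturated_sites(self, kp, mp):
        theta = mp.theta0("PLG")
        S = {"tPA": 0.0, "PLG": theta, "PLS": 0.0}
        # no free sites and no desorption contribution from other species
        rate = adsorption_rate(1.0, S, theta, kp, mp, "PLS")
        assert rate == pytest.approx(0.0)

    def test_equilibrium_ratio(self, kp, mp):
        """At steady state S/(C·(θ−S)) = k_ads/k_rev (oracle: Langmuir)."""
        theta, C = mp.theta0("tPA"), 0.05
        Keq = kp.k_ads["tPA"] / kp.k_rev["tPA"]
        S_eq = theta * Keq * C / (1 + Keq * C)
        S = {"tPA": S_eq, "PLG": 0.0, "PLS": 0.0}
        assert adsorption_rate(C, S, theta, kp, mp, "tPA") == pytest.approx(0.0, abs=1e-12)

    def test_negative_concentration_rejected(self, kp, mp):
        with pytest.raises(StateError):
            adsorption_rate(-1.0, {s: 0.0 for s in SPECIES}, 1.0, kp, mp, "tPA")


class TestElementaryRates:
    def test_michaelis_menten(self, kp):
        assert plasmin_generation_rate(1.0, 0.0, kp) == 0.0
        assert plasmin_generation_rate(2.0, kp.K_M, kp) == pytest.approx(kp.k2 * 2.0 / 2)
        assert plasmin_generation_rate(1.0, 1e9, kp) == pytest.approx(kp.k2, rel=1e-6)

    def test_inhibition(self, kp):
        assert plasmin_inhibition_rate(0.0, 1.0, kp) == 0.0
        assert plasmin_inhibition_rate(1.0, 0.0, kp) == 0.0

    def test_inhibition_conserves_pls_pool(self, kp):
        """Explicit Euler step: PLS + AP–PLS complex total is unchanged."""
        C_PLS, C_AP, cplx, dt = 0.3, 0.8, 0.1, 1e-3
        r = plasmin_inhibition_rate(C_PLS, C_AP, kp)
        assert (C_PLS - dt * r) + (cplx + dt * r) == pytest.approx(C_PLS + cplx)

    def test_lysis_rate(self, kp, mp):
        assert lysis_rate(0.0, kp) == 0.0
        assert lysis_rate(2.0, kp) == pytest.approx(2 * lysis_rate(1.0, kp))
        assert lysis_rate(5.0, kp, L=mp.n0, n0=mp.n0) == 0.0

    def test_solubilization(self, kp, mp):
        S = {"tPA": 1.0, "PLG": 2.0, "PLS": 3.0}
        assert all(v == 0.0 for v in solubilization_rates(S, 0.0, 0.0, kp, mp.n0).values())
        zero = {s: 0.0 for s in SPECIES}
        assert all(v == 0.0 for v in solubilization_rates(zero, 0.0, 1.0, kp, mp.n0).values())


class TestRHS:
    def test_all_zero_state(self, kp, mp):
        state = WellMixedState(C={s: 0.0 for s in ("tPA", "PLG", "PLS", "AP", "AP_PLS")},
                               S={s: 0.0 for s in SPECIES}, L=0.0)
        d = rhs_well_mixed(state, kp, mp)
        assert all(v == 0.0 for v in d.C.values())
        assert all(v == 0.0 for v in d.S.values())
        assert d.L == 0.0

    def test_overfull_sites_rejected(self, kp, mp):
        state = WellMixedState(
            C={s: 0.0 for s in ("tPA", "PLG", "PLS", "AP", "AP_PLS")},
            S={"tPA": 0.0, "PLG": 2 * mp.theta0("PLG"), "PLS": 0.0}, L=0.0)
        with pytest.raises(StateError):
            rhs_well_mixed(state, kp, mp)

    def test_no_tpa_no_lysis(self, kp, mp):
        init = WellMixedState.initial(kp, mp, tPA=0.0)
        h = simulate_well_mixed(init, kp, mp, 60.0, n_snapshots=50)
        assert h.column("L").max() == pytest.approx(0.0, abs=1e-9)

    def test_tpa_conserved_without_lysis(self, mp):
        """With k_cat = 0 the total tPA inventory ε·C + φ0·S is constant."""
        kp0 = KineticParameters(k_cat=0.0)
        init = WellMixedState.initial(kp0, mp)
        h = simulate_well_mixed(init, kp0, mp, 100.0, n_snapshots=100)
        tot = total_inventory(h, mp, "tPA")
        assert tot == pytest.approx(tot[0], rel=1e-6)


@pytest.fixture(scope="module")
def reference_run(kp, mp):
    init = WellMixedState.initial(kp, mp)
    return simulate_well_mixed(init, kp, mp, 200.0, n_snapshots=800)


class TestSimulation:
    def test_nonnegative_trajectories(self, reference_run):
        for name, col in reference_run.columns.items():
            assert np.all(np.asarray(col) >= -1e-9), name

    def test_lysis_fraction_monotone(self, reference_run):
        f = reference_run.column("lysis_fraction")
        assert np.all(np.diff(f) >= -1e-12)

    def test_bound_below_theta(self, reference_run, mp):
        frac = 1.0 - reference_run.column("lysis_fraction")
        occ = reference_run.column("S_PLG") + reference_run.column("S_PLS")
        theta = mp.theta0("PLG") * frac
        assert np.all(occ <= theta + 1e-6 * mp.theta0("PLG"))
        assert np.all(
            reference_run.column("S_tPA") <= mp.theta0("tPA") * frac + 1e-6 * mp.theta0("tPA")
        )

    def test_terminal_state_fully_solubilized(self, reference_run):
        """Once the clot is spent no bound protein remains."""
        assert reference_run.column("lysis_fraction")[-1] > 0.999
        for s in SPECIES:
            assert reference_run.column(f"S_{s}")[-1] == pytest.approx(0.0, abs=1e-3)

    def test_species_conservation_with_lysis(self, reference_run, mp):
        """PLG + PLS + AP–PLS inventory is conserved through generation,
        lysis and solubilization (only phase transfers and 1:1 conversions)."""
        phi0 = mp.solid_fraction_initial
        eps = reference_run.column("eps")
        tot = (eps * (reference_run.column("C_PLG") + reference_run.column("C_PLS")
                      + reference_run.column("C_AP_PLS"))
               + phi0 * (reference_run.column("S_PLG") + reference_run.column("S_PLS")))
        assert tot == pytest.approx(tot[0], rel=1e-5)

    def test_tolerance_convergence(self, kp, mp):
        """Halving (squaring down) integrator tolerances moves the lysis
        time by far less than 1%."""
        init = WellMixedState.initial(kp, mp)
        h1 = simulate_well_mixed(init, kp, mp, 150.0, rtol=1e-6, atol=1e-9)
        h2 = simulate_well_mixed(init, kp, mp, 150.0, rtol=1e-9, atol=1e-12)
        t1, t2 = time_to_lysis(h1, 0.95), time_to_lysis(h2, 0.95)
        assert abs(t1 - t2) / t2 < 0.01

    def test_zero_t_end_rejected(self, kp, mp):
        with pytest.raises(DomainError):
            simulate_well_mixed(WellMixedState.initial(kp, mp), kp, mp, 0.0)


class TestEquilibratePLG:
    def test_no_adsorption_limit(self, mp):
        kp0 = KineticParameters(k_ads={"tPA": 0.1, "PLG": 0.0, "PLS": 0.01})
        free, bound = equilibrate_plg(kp0, mp, 2.0)
        assert free == 2.0 and bound == 0.0

    def test_against_ode_relaxation(self, kp, mp):
        """Oracle: integrating the adsorption dynamics reaches the same
        fixed point as the closed-form partition."""
        free, bound = equilibrate_plg(kp, mp, 2.0)
        init = WellMixedState(
            C={"tPA": 0.0, "PLG": 2.0, "PLS": 0.0, "AP": 0.0, "AP_PLS": 0.0},
            S={s: 0.0 for s in SPECIES}, L=0.0)
        h = simulate_well_mixed(init, kp, mp, 2000.0, n_snapshots=50)
        assert h.column("C_PLG")[-1] == pytest.approx(free, rel=1e-4)
        assert h.column("S_PLG")[-1] == pytest.approx(bound, rel=1e-4)

    def test_bad_total_rejected(self, kp, mp):
        with pytest.raises(DomainError):
            equilibrate_plg(kp, mp, -2.0)


class TestTimeToLysis:
    def _history(self, t, f):
        return SimulationHistory(t=np.asarray(t, float),
                                 columns={"lysis_fraction": np.asarray(f, float)})

    def test_linear_interpolation_oracle(self):
        h = self._history([0, 10, 20], [0.0, 0.5, 1.0])
        assert time_to_lysis(h, 0.75) == pytest.approx(15.0)

    def test_not_reached_sentinel(self):
        h = self._history([0, 10], [0.0, 0.3])
        assert math.isnan(time_to_lysis(h, 0.95))

    def test_full_lysis_after_95(self, kp, mp):
        init = WellMixedState.initial(kp, mp)
        h = simulate_well_mixed(init, kp, mp, 200.0, n_snapshots=400)
        assert time_to_lysis(h, 1.0) >= time_to_lysis(h, 0.95)

    @given(st.floats(max_value=0.0, allow_nan=False), )
    @settings(deadline=None, max_examples=20)
    def test_bad_fraction_rejected(self, frac):
        h = self._history([0, 1], [0, 1])
        with pytest.raises(DomainError):
            time_to_lysis(h, frac)


class TestValidationMode:
    def test_dose_response_monotone(self):
        """Thin-clot validation conditions (fibrin 5.88 µM, K_M 2.42 µM,
        k2 0.22 s⁻¹): time to 95% lysis decreases with tPA dose."""
        mp_v = MicrostructureParams(fibrin_density=2.0)  # 5.88 µM monomer
        kp_v = KineticParameters(K_M=2.42, k2=0.22)
        assert mp_v.fibrin_density / mp_v.fibrin_monomer_molar_mass * 1e6 == pytest.approx(
            5.88, rel=1e-2
        )
        times = []
        for dose in (0.01, 0.05, 0.3):
            init = WellMixedState.initial(kp_v, mp_v, tPA=dose)
            h = simulate_well_mixed(init, kp_v, mp_v, 3000.0, n_snapshots=600)
            times.append(time_to_lysis(h, 0.95))
        assert not any(math.isnan(t) for t in times)
        assert times[0] > times[1] > times[2]
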
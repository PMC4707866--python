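"""1-D diffusion-limited lysis: scheme oracles and front dynamics."""

import math

import numpy as np
import pytest
from scipy.special import erfc

from clotlysis import DomainError, KineticParameters, MicrostructureParams, SimulationHistory
from clotlysis.errors import ConfigError, StabilityError
from clotlysis.transport1d import (
    Field1D,
    Grid1D,
    Scenario1D,
    diffusion_stability_limit,
    dose_sweep_1d,
    front_velocity,
    lysis_front_position,
    peak_metrics,
    simulate_1d,
    step_diffusion_reaction,
)

INERT = KineticParameters(
    k_ads={"tPA": 0.0, "PLG": 0.0, "PLS": 0.0},
    k_rev={"tPA": 0.0, "PLG": 0.0, "PLS": 0.0},
    k2=0.0, k_cat=0.0, k_AP=0.0,
)


@pytest.fixture()
def small_grid():
    return Grid1D(length=2e-3, n_cells=100, clot_start=1.5e-3, clot_end=2e-3)


class TestGrid:
    def test_geometry(self, small_grid):
        assert small_grid.dx == pytest.approx(2e-5)
        assert np.all(np.diff(small_grid.x) > 0)
        assert small_grid.clot_mask.sum() == 25

    def test_bad_configs(self):
        with pytest.raises(ConfigError):
            Grid1D(length=-1.0, n_cells=10, clot_start=0, clot_end=0.5)
        with pytest.raises(ConfigError):
            Grid1D(length=1.0, n_cells=10, clot_start=0.6, clot_end=0.5)


class TestStep:
    def test_zero_diffusion_zero_reactions_is_identity(self, small_grid):
        mp = MicrostructureParams()
        f = Field1D.initial(small_grid, INERT, mp, D=0.0)
        f.q[0, 10:20] = 0.03  # a tPA blob
        q0 = f.q.copy()
        step_diffusion_reaction(f, 5.0)
        assert np.allclose(f.q, q0, atol=0)

    def test_stability_bound_enforced_and_named(self, small_grid):
        mp = MicrostructureParams()
        f = Field1D.initial(small_grid, INERT, mp, D=1e-10)
        dt_max = diffusion_stability_limit(f)
        with pytest.raises(StabilityError, match="stability bound") as exc:
            step_diffusion_reaction(f, 2 * dt_max)
        assert exc.value.dt_max == pytest.approx(dt_max)

    def test_step_diffusion_matches_erfc_solution(self):
        """Pure diffusion from a constant-concentration face follows the
        semi-infinite similarity solution C = C_in·erfc(x/(2√(Dt)))."""
        D = 1e-10
        grid = Grid1D(length=4e-3, n_cells=200, clot_start=3.9e-3, clot_end=4e-3)
        mp = MicrostructureParams()
        f = Field1D.initial(grid, INERT, mp, D=D,
                            inlet={"tPA": 1.0, "PLG": None, "PLS": None})
        f.q[1] = 0.0  # clear the PLG background for a clean comparison
        t_end, dt = 2000.0, 0.5
        for _ in range(int(t_end / dt)):
            step_diffusion_reaction(f, dt)
        expected = erfc(grid.x / (2.0 * math.sqrt(D * t_end)))
        assert np.max(np.abs(f.C[0] - expected)) < 0.01

    def test_uniform_sealed_field_is_stationary(self, small_grid):
        mp = MicrostructureParams()
        f = Field1D.initial(small_grid, INERT, mp, D=1e-10,
                            inlet={"tPA": None, "PLG": None, "PLS": None})
        f.q[0, :] = 0.02 * f.eps  # uniform free concentration C
        q0 = f.q[0].copy()
        step_diffusion_reaction(f, 0.5)
        assert np.allclose(f.q[0], q0, rtol=1e-9)

    def test_sealed_boundaries_conserve_mass_with_reactions(self, small_grid):
        """With zero-flux boundaries the per-species inventory ε·C + φ0·S
        changes only by reaction stoichiometry; total tPA is conserved."""
        mp = MicrostructureParams()
        kp = KineticParameters()
        f = Field1D.initial(small_grid, kp, mp, D=1e-10,
                            inlet={"tPA": None, "PLG": None, "PLS": None})
        f.q[0, :50] = 0.05 * f.eps[:50]
        phi0 = mp.solid_fraction_initial

        def tpa_total():
            return float((f.q[0] + phi0 * f.S[0]).sum())

        before = tpa_total()
        for _ in range(400):
            step_diffusion_reaction(f, 0.5)
        assert tpa_total() == pytest.approx(before, rel=1e-7)


class TestFrontPosition:
    def test_sentinel_when_nothing_lysed(self, small_grid):
        mp = MicrostructureParams()
        L = np.zeros(small_grid.n_cells)
        assert lysis_front_position(L, small_grid, mp.n0) == -math.inf

    def test_fully_lysed_returns_distal_edge_cell(self, small_grid):
        mp = MicrostructureParams()
        L = np.full(small_grid.n_cells, mp.n0)
        pos = lysis_front_position(L, small_grid, mp.n0)
        last = np.nonzero(small_grid.clot_mask)[0][-1]
        assert pos == pytest.approx(small_grid.x[last])

    def test_hand_built_profile_linear_scan_oracle(self):
        grid = Grid1D(length=1e-3, n_cells=20, clot_start=0.0, clot_end=1e-3)
        mp = MicrostructureParams()
        L = np.zeros(20)
        L[:10] = mp.n0  # cells 0..9 lysed
        assert lysis_front_position(L, grid, mp.n0) == pytest.approx(grid.x[9])


class TestFrontVelocity:
    def _history(self, t, pos):
        return SimulationHistory(t=np.asarray(t, float),
                                 columns={"front_position": np.asarray(pos, float)})

    def test_linear_motion_recovers_exact_speed(self):
        t = np.linspace(0, 6000, 100)
        v_true = 30e-6 / 60.0  # 30 µm/min in m/s
        h = self._history(t, v_true * t)
        assert front_velocity(h, 600, 4800) == pytest.approx(30.0)

    def test_stationary_front_zero_velocity(self):
        t = np.linspace(0, 6000, 50)
        h = self._history(t, np.full_like(t, 1e-3))
        assert front_velocity(h, 600, 4800) == 0.0

    def test_unformed_front_advises_spin_up(self):
        t = np.linspace(0, 6000, 50)
        h = self._history(t, np.where(t < 3000, -math.inf, 1e-3))
        with pytest.raises(DomainError, match="spin-up"):
            front_velocity(h, 600, 4800)

    def test_window_coverage_required(self):
        h = self._history([0, 100], [0, 1e-4])
        with pytest.raises(DomainError):
            front_velocity(h, 600, 4800)


class TestReferenceRun:
    def test_front_position_monotone(self, reference_1d):
        _, h = reference_1d
        pos = h.column("front_position")
        formed = np.isfinite(pos)
        assert np.all(np.diff(pos[formed]) >= 0)

    def test_zero_tpa_inlet_no_lysis(self):
        sc = Scenario1D.reference(tPA=0.0, n_cells=60, t_end=600.0,
                                  snapshot_times=())
        h = simulate_1d(sc)
        assert h.column("mean_lysis_fraction").max() == 0.0
        assert not np.isfinite(h.column("front_position")[-1])

    def test_free_tpa_approaches_inlet_uniformity(self, reference_1d):
        """The free tPA profile climbs toward the uniform inlet level:
        its RMS distance from that level decreases across snapshots."""
        sc, h = reference_1d
        rms = [float(np.sqrt(np.mean((snap["C_tPA"] - sc.inlet_tPA) ** 2)))
               for _, snap in h.snapshots]
        assert all(a > b for a, b in zip(rms, rms[1:]))

    def test_bound_protein_zero_behind_the_front(self, reference_1d):
        """Fully lysed cells carry no residual bound protein."""
        sc, h = reference_1d
        _, last = h.snapshots[-1]
        done = last["L"] >= sc.mp.n0 * (1 - 1e-9)
        assert done.any()
        for name in ("S_tPA", "S_PLG", "S_PLS"):
            assert np.all(last[name][done] < 1e-6)

    def test_grid_convergence_of_front_velocity(self):
        """Halving dx moves the measured front velocity by < 5%."""
        vels = []
        for n in (100, 200):
            g = Grid1D(length=2.5e-3, n_cells=n, clot_start=0.0, clot_end=2e-3)
            sc = Scenario1D(grid=g, kp=KineticParameters(),
                            mp=MicrostructureParams(), t_end=2400.0,
                            snapshot_times=())
            vels.append(front_velocity(simulate_1d(sc), 600.0, 2400.0))
        assert abs(vels[0] - vels[1]) / vels[1] < 0.05


class TestDoseSweep:
    def test_single_dose_reduces_to_simulate_1d(self):
        sc = Scenario1D(
            grid=Grid1D(length=2.5e-3, n_cells=100, clot_start=0.0, clot_end=2e-3),
            kp=KineticParameters(), mp=MicrostructureParams(),
            t_end=2400.0, snapshot_times=())
        (dose, v), = dose_sweep_1d([0.05], sc, 600.0, 2400.0)
        direct = front_velocity(simulate_1d(sc), 600.0, 2400.0)
        assert dose == 0.05 and v == direct

    def test_determinism_identical_doses(self):
        sc = Scenario1D(
            grid=Grid1D(length=2e-3, n_cells=80, clot_start=0.0, clot_end=1.5e-3),
            kp=KineticParameters(), mp=MicrostructureParams(),
            t_end=1800.0, snapshot_times=())
        out = dose_sweep_1d([0.05, 0.05], sc, 600.0, 1800.0)
        assert out[0][1] == out[1][1]

    def test_nonpositive_dose_rejected(self):
        sc = Scenario1D.reference()
        with pytest.raises(DomainError):
            dose_sweep_1d([0.0], sc)


class TestPeakMetrics:
    def test_triangle_profile(self):
        y = np.array([0, 1, 2, 3, 2, 1, 0], dtype=float)
        h, w = peak_metrics(y, 1.0)
        assert h == 3.0
        assert w == pytest.approx(3.0)

    def test_flat_zero_profile(self):
        assert peak_metrics(np.zeros(5), 1.0) == (0.0, 0.0)
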
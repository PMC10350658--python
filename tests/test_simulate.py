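"""Simulation layer: initial states, integration, yields, export."""

from dataclasses import replace

import numpy as np
import pytest

import algakin as ak
from algakin.mechanisms import PRETREATMENT_MECHANISM, SACCHARIFICATION_MECHANISM
from algakin.simulate import _fast_rhs


class TestBuildInitialState:
    def test_pretreatment_substrate_fractions(self, pretreat30_config):
        """Cellulose/hemicellulose split onto the carbohydrate-normalized
        scale: 10.2/59.74 and 49.54/59.74."""
        y0 = ak.build_initial_state(pretreat30_config)
        mech = PRETREATMENT_MECHANISM
        assert y0[mech.index("S_cel")] == pytest.approx(10.2 / 59.74, abs=1e-12)
        assert y0[mech.index("S_hem")] == pytest.approx(49.54 / 59.74, abs=1e-12)
        assert y0[mech.index("S_cel")] + y0[mech.index("S_hem")] == \
            pytest.approx(1.0, abs=1e-12)
        # 30% w/w dose on the mass-ratio scale: 30/59.74 per enzyme
        assert y0[mech.index("E_cel")] == pytest.approx(30 / 59.74, abs=1e-12)
        assert np.all(y0[[mech.index("ES_cel"), mech.index("ES_hem"),
                          mech.index("P")]] == 0)

    def test_saccharification_single_substrate(self, sacc55_config):
        y0 = ak.build_initial_state(sacc55_config)
        mech = SACCHARIFICATION_MECHANISM
        assert y0[mech.index("S")] == 1.0
        for sp in ("ES1", "D", "ES2", "G"):
            assert y0[mech.index(sp)] == 0
        # unit-pool scale at the study's reference doses
        assert y0[mech.index("E_a")] == 1.0
        assert y0[mech.index("E_g")] == 1.0

    def test_zero_dose_gives_zero_enzyme(self):
        cfg = ak.SimulationConfig(
            model=ak.PRETREATMENT,
            rate_constants=ak.PRETREATMENT_BY_LOADING[10],
            enzyme_doses_pct={"cellulase": 0.0, "xylanase": 10.0})
        y0 = ak.build_initial_state(cfg)
        assert y0[PRETREATMENT_MECHANISM.index("E_cel")] == 0

    def test_missing_dose_and_negative_dose_rejected(self):
        with pytest.raises(ValueError, match="missing enzyme dose"):
            ak.SimulationConfig(model=ak.PRETREATMENT,
                                rate_constants=np.ones(8),
                                enzyme_doses_pct={"cellulase": 10.0})
        with pytest.raises(ValueError, match=">= 0"):
            ak.SimulationConfig(
                model=ak.PRETREATMENT, rate_constants=np.ones(8),
                enzyme_doses_pct={"cellulase": -1.0, "xylanase": 10.0})

    def test_missing_substrate_in_composition_rejected(self):
        with pytest.raises(ValueError, match="starch"):
            ak.SimulationConfig(model=ak.SACCHARIFICATION,
                                rate_constants=np.ones(8),
                                composition_pct={"cellulose": 10.0})


class TestConfigValidation:
    def test_time_grid_must_start_at_zero_and_increase(self):
        for bad in ([10, 20, 30], [0, 10, 10], [0, 20, 10]):
            with pytest.raises(ValueError, match="time grid"):
                ak.SimulationConfig(model=ak.PRETREATMENT,
                                    rate_constants=np.ones(8),
                                    t_grid=np.array(bad, dtype=float))

    def test_tolerances_positive(self):
        with pytest.raises(ValueError, match="tolerances"):
            ak.SimulationConfig(model=ak.PRETREATMENT,
                                rate_constants=np.ones(8), rtol=0.0)

    def test_composition_percent_range(self):
        with pytest.raises(ValueError, match="outside"):
            ak.SimulationConfig(
                model=ak.PRETREATMENT, rate_constants=np.ones(8),
                composition_pct={"cellulose": 120.0, "hemicellulose": 40.0})


class TestIntegrate:
    def test_zero_constants_constant_trajectory(self, pretreat30_config):
        cfg = pretreat30_config.with_constants(np.zeros(8))
        traj = ak.integrate(cfg)
        y0 = ak.build_initial_state(cfg)
        np.testing.assert_allclose(traj.states, np.tile(y0, (7, 1)),
                                   atol=1e-12)

    def test_first_row_is_initial_state(self, sacc55_config):
        traj = ak.integrate(sacc55_config)
        np.testing.assert_array_equal(traj.states[0],
                                      ak.build_initial_state(sacc55_config))

    @pytest.mark.parametrize("which", ["pretreat", "sacc"])
    def test_conservation_along_trajectory(self, which, pretreat30_config,
                                           sacc55_config):
        cfg = pretreat30_config if which == "pretreat" else sacc55_config
        traj = ak.integrate(cfg)
        for row in traj.states:
            res = ak.conservation_residuals(row, traj.states[0], cfg.model)
            assert all(abs(v) <= 1e-8 for v in res.values())

    def test_tolerance_refinement_convergence(self, sacc55_config):
        """Tightening rtol/atol tenfold moves final glucose by < 1e-6."""
        g1 = ak.integrate(sacc55_config).glucose_fraction()[-1]
        tight = replace(sacc55_config, rtol=sacc55_config.rtol / 10,
                        atol=sacc55_config.atol / 10)
        g2 = ak.integrate(tight).glucose_fraction()[-1]
        assert abs(g1 - g2) < 1e-6

    def test_grid_refinement_does_not_change_values(self, pretreat30_config):
        """Dense output: halving the sampling step leaves shared times
        unchanged."""
        coarse = ak.integrate(pretreat30_config)
        fine = ak.integrate(replace(pretreat30_config,
                                    t_grid=np.arange(0.0, 61.0, 5.0)))
        np.testing.assert_allclose(fine.states[::2], coarse.states,
                                   rtol=0, atol=1e-12)

    def test_matches_fixed_step_rk4_oracle(self, sacc55_config):
        """Adaptive solution vs a brute-force fixed-step RK4 at dt=0.001."""
        f = _fast_rhs(ak.SACCHARIFICATION, sacc55_config.rate_array())
        y = ak.build_initial_state(sacc55_config).copy()
        dt = 0.001
        for i in range(60000):
            t = i * dt
            k1 = np.asarray(f(t, y))
            k2 = np.asarray(f(t + dt / 2, y + dt / 2 * k1))
            k3 = np.asarray(f(t + dt / 2, y + dt / 2 * k2))
            k4 = np.asarray(f(t + dt, y + dt * k3))
            y = y + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        traj = ak.integrate(sacc55_config)
        mech = SACCHARIFICATION_MECHANISM
        assert abs(traj.states[-1, mech.index("G")] -
                   y[mech.index("G")]) < 1e-6

    def test_nonnegativity_within_solver_tolerance(self, pretreat30_config,
                                                   sacc55_config):
        for cfg in (pretreat30_config, sacc55_config):
            traj = ak.integrate(cfg)
            assert traj.states.min() >= -cfg.atol * 10


class TestYield:
    def test_zero_product_zero_yield(self, pretreat30_config):
        cfg = pretreat30_config.with_constants(np.zeros(8))
        traj = ak.integrate(cfg)
        assert np.all(traj.yield_pct == 0)

    def test_complete_conversion_is_100_percent(self, sacc55_config):
        traj = ak.integrate(sacc55_config)
        mech = SACCHARIFICATION_MECHANISM
        states = traj.states.copy()
        states[-1] = 0
        states[-1, mech.index("G")] = 1.0  # all substrate turned to glucose
        full = replace(traj, states=states)
        y = ak.yield_curve(full, ak.YieldDefinition())
        assert y[-1] == pytest.approx(100.0, abs=1e-12)

    def test_dimensionless_product_maps_to_percent(self, pretreat30_config):
        """P(t) = 0.359 reads as a 35.9% yield on the carbohydrate basis —
        the scale of the reported pretreatment optimum."""
        traj = ak.integrate(pretreat30_config)
        states = traj.states.copy()
        states[4, PRETREATMENT_MECHANISM.index("P")] = 0.359
        y = ak.yield_curve(replace(traj, states=states),
                           ak.YieldDefinition())
        assert y[4] == pytest.approx(35.9, abs=1e-12)

    def test_yield_capped_at_100_on_carbohydrate_basis(self, sacc55_config,
                                                       pretreat30_config):
        for cfg in (sacc55_config, pretreat30_config):
            traj = ak.integrate(cfg)
            assert np.all(traj.yield_pct <= 100.0 + 1e-9)

    def test_monotone_glucose_without_reverse_steps(self, pretreat30_config):
        k = ak.PRETREATMENT_BY_LOADING[30].as_array().copy()
        k[[1, 3, 5, 7]] = 0.0  # remove all reverse steps
        traj = ak.integrate(pretreat30_config.with_constants(k))
        assert np.all(np.diff(traj.glucose_fraction()) >= -1e-12)

    def test_per_substrate_and_biomass_bases(self, pretreat30_config):
        traj = ak.integrate(pretreat30_config)
        p = traj.glucose_fraction()
        y_cel = ak.yield_curve(traj, ak.YieldDefinition(
            basis="per-substrate", substrate="cellulose"))
        np.testing.assert_allclose(y_cel, 100 * p / (10.2 / 59.74), rtol=1e-12)
        y_bio = ak.yield_curve(traj, ak.YieldDefinition(basis="total-biomass"))
        np.testing.assert_allclose(y_bio, 100 * p * 59.74 / 100.0, rtol=1e-12)


class TestGlucoseConcentration:
    def test_full_conversion_of_500mg_in_100ml_is_5_g_per_l(self):
        cfg = ak.SimulationConfig(
            model=ak.SACCHARIFICATION, rate_constants=np.zeros(8),
            composition_pct={"starch": 100.0}, biomass_mg=500, volume_ml=100)
        traj = ak.integrate(cfg)
        states = traj.states.copy()
        states[:, SACCHARIFICATION_MECHANISM.index("G")] = 1.0
        g = ak.glucose_concentration(replace(traj, states=states), cfg)
        np.testing.assert_allclose(g, 5.0, rtol=1e-12)

    def test_round_trips_with_normalization(self, sacc55_config, rng):
        traj = ak.integrate(sacc55_config)
        g = ak.glucose_concentration(traj, sacc55_config)
        mass_g = sacc55_config.substrate_mass_mg / 1000
        vol_l = sacc55_config.volume_ml / 1000
        np.testing.assert_allclose(g * vol_l / mass_g,
                                   traj.glucose_fraction(), rtol=1e-12)


class TestPssaReduction:
    def test_reduced_matches_full_in_pssa_regime(self):
        """Small enzyme pool + fast binding: reduced and full glucose
        curves agree within 1% at all sampled times after the initial
        complex-formation transient."""
        k = ak.PretreatmentRateConstants(20, 20, 0.05, 0.05,
                                         20, 20, 0.05, 0.05)
        cfg = ak.SimulationConfig(
            model=ak.PRETREATMENT, rate_constants=k,
            enzyme_doses_pct={"cellulase": 0.5974, "xylanase": 0.5974})
        full = ak.integrate(cfg).glucose_fraction()
        red = ak.integrate_pssa(cfg).glucose_fraction()
        rel = np.abs(full[1:] - red[1:]) / np.abs(full[1:])
        assert np.all(rel < 0.01)

    def test_reduced_trajectory_reconstructs_complexes(self, sacc55_config):
        traj = ak.integrate_pssa(sacc55_config)
        mech = SACCHARIFICATION_MECHANISM
        # enzyme conservation holds exactly in the reconstruction
        ea = traj.states[:, mech.index("E_a")] + traj.states[:, mech.index("ES1")]
        np.testing.assert_allclose(ea, ea[0], rtol=1e-12)

    def test_degenerate_constants_rejected(self, pretreat30_config):
        k = np.array([1.0, 0, 0, 0, 1, 1, 1, 0])
        with pytest.raises(ZeroDivisionError, match="degenerate"):
            ak.integrate_pssa(pretreat30_config.with_constants(k))


def test_trajectory_export_round_trip(tmp_path, sacc55_config):
    import pandas as pd
    traj = ak.integrate(sacc55_config)
    out = tmp_path / "traj.tsv"
    ak.write_trajectory(traj, out, header_lines=("seed: 1",))
    df = pd.read_csv(out, sep="\t", comment="#")
    assert list(df.columns[:1]) == ["time_min"]
    assert {"glucose_g_per_L", "yield_pct"} <= set(df.columns)
    np.testing.assert_allclose(df["yield_pct"].to_numpy(), traj.yield_pct,
                               rtol=1e-6)
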
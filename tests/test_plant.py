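import numpy as np
import pandas as pd
import pytest

from perfusiontwin import (apply_disturbance, compute_vcv,
                           sample_with_noise, simulate_fedbatch_run,
                           CLONE_A, CLONE_B, CLONE_X, CLONE_Y,
                           DisturbanceEvent, PerfusionPlant)
from perfusiontwin.plant import REFERENCE_SETPOINTS
from dataclasses import replace

from conftest import noiseless_config


def reference_run(params=CLONE_A, days=20, seed=None, post_soc=None, **cfg_kw):
    plant = PerfusionPlant(params=params, config=noiseless_config(**cfg_kw),
                           seed=seed)
    for _ in range(days):
        plant.sample()
        sp = plant.protocol_setpoints()
        if plant.in_soc and post_soc is not None:
            sp = dict(post_soc)
        plant.advance_day(sp)
    plant.sample()
    return plant


class TestConservation:
    def test_inert_tracer_mass_balance(self):
        """An inert tracer's concentration change equals net flow exactly."""
        plant = PerfusionPlant(config=noiseless_config(),
                               extra_solubles={"Trc": 0.8})
        V = plant.state["V"]
        for day in range(8):
            c0 = plant.state["Trc"]
            plant.sample()
            flows = plant.advance_day(plant.protocol_setpoints())
            c1 = plant.state["Trc"]
            net = flows["feed_Trc"] - flows["bleed_Trc"] - flows["perm_Trc"]
            assert (c1 - c0) * V == pytest.approx(net, rel=1e-8, abs=1e-12)

    def test_perfusion_volume_constant(self):
        plant = reference_run(days=10)
        rec = plant.to_run_record("r", observed=False)
        assert np.allclose(rec.states["V"], 0.213)

    def test_viability_identity_everywhere(self):
        plant = reference_run(days=12, seed=3)
        for row in plant._truth_rows.values():
            expect = 100.0 * row["VCD"] / (row["VCD"] + row["DCD"])
            assert row["Via"] == pytest.approx(expect, rel=1e-9)
        for row in plant._obs_rows.values():
            expect = 100.0 * row["VCD"] / (row["VCD"] + row["DCD"])
            assert row["Via"] == pytest.approx(expect, rel=1e-9)


class TestProtocol:
    def test_growth_ramp_caps_at_protocol_rate(self):
        plant = reference_run(days=15)
        rec = plant.to_run_record("r", observed=False)
        growth = rec.states.loc[:plant.soc_day - 1, "VVD"]
        assert growth.max() == pytest.approx(1.3)
        assert growth.iloc[0] == 0.0

    def test_state_of_control_reached_before_control_start(self):
        plant = reference_run(days=12)
        assert plant.soc_day is not None and plant.soc_day <= 8

    def test_bolus_recorded_as_glucose_feed(self):
        plant = PerfusionPlant(config=noiseless_config(),
                               initial_state={"Glc": 1.0})
        plant.sample()
        flows = plant.advance_day(plant.protocol_setpoints())
        _, v = __import__("perfusiontwin").bolus_volume(0.213, 1.0)
        assert flows["feed_Glc"] >= v * 200.0 * 0.999

    def test_bleed_pins_vcv_at_ceiling(self):
        plant = PerfusionPlant(config=noiseless_config(bleed_ceiling=10.0))
        bled = False
        for _ in range(12):
            plant.sample()
            flows = plant.advance_day(plant.protocol_setpoints())
            if flows["bleed_VCD"] > 0:
                bled = True
                assert plant.vcv <= 10.0 * (1 + 1e-6)
        assert bled

    def test_out_of_bounds_setpoint_rejected(self):
        from perfusiontwin import simulate_perfusion_day
        plant = PerfusionPlant(config=noiseless_config())
        with pytest.raises(ValueError, match="outside"):
            simulate_perfusion_day(plant, {"Temp": 35.0, "Stir": 2000.0,
                                           "VVD": 1.0, "Pyr": 0.0})


class TestDirectionalResponses:
    def test_higher_perfusion_rate_raises_steady_vcd(self):
        lo = reference_run(days=18, post_soc={**REFERENCE_SETPOINTS, "VVD": 0.5})
        hi = reference_run(days=18, post_soc={**REFERENCE_SETPOINTS, "VVD": 2.0})
        assert hi.state["VCD"] > 1.3 * lo.state["VCD"]

    def test_pyruvate_feed_suppresses_ammonium(self):
        off = reference_run(days=15, post_soc={**REFERENCE_SETPOINTS, "Pyr": 0.0})
        on = reference_run(days=15, post_soc={**REFERENCE_SETPOINTS, "Pyr": 2.0})
        assert on.state["Amm"] < 0.5 * off.state["Amm"]

    def test_excess_agitation_lowers_viability(self):
        calm = reference_run(days=14, post_soc={**REFERENCE_SETPOINTS, "Stir": 900.0})
        harsh = reference_run(days=14, post_soc={**REFERENCE_SETPOINTS, "Stir": 1400.0})
        assert harsh._truth_rows[14]["Via"] < calm._truth_rows[14]["Via"] - 0.5

    def test_mild_hypothermia_raises_viability_lowers_growth(self):
        cold = reference_run(days=16, post_soc={**REFERENCE_SETPOINTS, "Temp": 34.0})
        warm = reference_run(days=16, post_soc={**REFERENCE_SETPOINTS, "Temp": 36.5})
        assert cold._truth_rows[16]["Via"] > warm._truth_rows[16]["Via"]
        # specific growth under ample nutrients is slower when cold
        day1 = {}
        for temp in (34.0, 36.5):
            plant = PerfusionPlant(config=noiseless_config())
            plant.sample()
            plant.advance_day({"Temp": temp, "Stir": 1050.0, "VVD": 0.8,
                               "Pyr": 0.0})
            day1[temp] = plant.state["VCD"]
        assert day1[34.0] < day1[36.5]

    def test_reference_calibration_anchors(self):
        plant = reference_run(days=27, post_soc=REFERENCE_SETPOINTS)
        rec = plant.to_run_record("r", observed=False)
        post = rec.states.loc[plant.soc_day:]
        vcv = compute_vcv(post["Diam"].to_numpy(), post["VCD"].to_numpy())
        assert vcv.mean() < 20.0
        assert 3.0 < rec.states.loc[9, "Amm"] < 5.0   # ~4 mM by day 9, no Pyr


class TestDisturbance:
    def test_spike_arithmetic(self):
        plant = PerfusionPlant(config=noiseless_config(),
                               initial_state={"Amm": 0.5})
        plant.sample()
        new = apply_disturbance(plant, DisturbanceEvent(0, "Amm", 1.5))
        assert new == pytest.approx(0.5 + 1.5 / 0.213, rel=1e-9)

    def test_zero_amount_is_noop(self):
        plant = PerfusionPlant(config=noiseless_config())
        before = dict(plant.state)
        plant.inject("Amm", 0.0)
        assert plant.state == before

    def test_wrong_day_rejected(self):
        plant = PerfusionPlant(config=noiseless_config())
        with pytest.raises(ValueError, match="day"):
            apply_disturbance(plant, DisturbanceEvent(3, "Amm", 1.0))

    def test_unknown_species_rejected(self):
        plant = PerfusionPlant(config=noiseless_config())
        with pytest.raises(ValueError, match="unknown"):
            plant.inject("Caffeine", 1.0)


class TestMeasurementNoise:
    TRUE = {"VCD": 50.0, "DCD": 1.0, "Via": 100.0 * 50 / 51, "Diam": 18.0, "Glc": 3.0,
            "Gln": 1.0, "Glu": 0.5, "Lac": 1.2, "Amm": 4.0, "Titer": 80.0,
            "V": 0.213}

    def test_zero_cvs_identity(self):
        obs = sample_with_noise(self.TRUE, {k: 0.0 for k in self.TRUE}, rng=0,
                                via_noise_pp=0.0)
        assert obs == self.TRUE

    def test_monte_carlo_cv(self):
        rng = np.random.default_rng(7)
        draws = np.array([sample_with_noise(self.TRUE, {"VCD": 0.05}, rng,
                                            via_noise_pp=0.0)["VCD"]
                          for _ in range(10_000)])
        cv = draws.std() / draws.mean()
        assert 0.045 < cv < 0.055

    def test_viability_capped_and_consistent(self):
        rng = np.random.default_rng(1)
        for _ in range(300):
            obs = sample_with_noise(self.TRUE, None, rng)
            assert 0 < obs["Via"] <= 100.0
            expect = 100.0 * obs["VCD"] / (obs["VCD"] + obs["DCD"])
            assert obs["Via"] == pytest.approx(expect, rel=1e-9)


class TestFedBatch:
    CONTROLS = {"Stir": 900.0, "DO": 50.0, "VCD0": 0.5, "Glc0": 7.0,
                "Gln0": 5.0, "feed_volumes": np.zeros(14)}

    def test_batch_rise_and_fall_lysed_monotone(self):
        rec = simulate_fedbatch_run(CLONE_X, self.CONTROLS, seed=0,
                                    noise_cvs={})
        vcd = rec.states["VCD"]
        peak = vcd.idxmax()
        assert 1 < peak < 14                      # rises, then substrate runs out
        assert vcd.iloc[-1] < 0.8 * vcd.max()
        assert rec.states["Lysed"].is_monotonic_increasing

    def test_lactate_consumption_contrast(self):
        feeds = dict(self.CONTROLS, feed_volumes=np.full(14, 0.004))
        x = simulate_fedbatch_run(CLONE_X, feeds, seed=5, noise_cvs={})
        y = simulate_fedbatch_run(CLONE_Y, feeds, seed=5, noise_cvs={})
        assert x.states["Lac"].iloc[-1] < y.states["Lac"].iloc[-1]
        assert x.states["Amm"].iloc[-1] < y.states["Amm"].iloc[-1]

    def test_no_growth_without_mu(self):
        dead = replace(CLONE_X, mu_max=0.0)
        rec = simulate_fedbatch_run(dead, self.CONTROLS, seed=0, noise_cvs={})
        assert (rec.states["VCD"].diff().dropna() <= 1e-9).all()

    def test_negative_feed_rejected(self):
        bad = dict(self.CONTROLS, feed_volumes=np.full(14, -0.001))
        with pytest.raises(ValueError, match="feed"):
            simulate_fedbatch_run(CLONE_X, bad, seed=0)


class TestDeterminism:
    def test_same_seed_same_campaign(self):
        import perfusiontwin as pt
        a = pt.generate_training_campaign(seed=5, t_f=6)
        b = pt.generate_training_campaign(seed=5, t_f=6)
        for ra, rb in zip(a, b):
            pd.testing.assert_frame_equal(ra.states, rb.states)
            pd.testing.assert_frame_equal(ra.flows, rb.flows)

    def test_center_replicates_differ_only_by_noise(self):
        import perfusiontwin as pt
        camp = pt.generate_training_campaign(seed=5, t_f=10)
        centers = camp.design_table.query("VVD == 1.25 and Pyr == 1.0")
        reps = [camp.run(r) for r in centers["run_id"]][:4]
        assert len(reps) >= 3
        finals = np.array([r.states["VCD"].iloc[-1] for r in reps])
        spread = finals.std() / finals.mean()
        assert 0 < spread < 2 * 0.05              # within 2x the VCD noise CV
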
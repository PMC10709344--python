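import numpy as np
import pandas as pd
import pytest
from dataclasses import replace

from orgscreen import (
    CloneParams,
    ConfigError,
    SimConfig,
    default_scenarios,
    organoid_trajectory,
    plate_well_metrics,
    simulate_plate,
)
from orgscreen.simulate import STAUROSPORINE


def fast_clone(**kw):
    defaults = dict(name="c", fraction=1.0, growth_rate=np.log(2) / 24.0,
                    ec50={"drug": 10.0}, max_growth_inhibition=1.0, max_death_rate=0.1)
    defaults.update(kw)
    return CloneParams(**defaults)


class TestOrganoidTrajectory:
    def test_exponential_doubling_without_drug(self):
        traj = organoid_trajectory(
            fast_clone(), {}, [0.0, 24.0], None, init_area=1000.0
        )
        np.testing.assert_allclose(traj["bf_area"], [1000.0, 2000.0])
        assert traj["green_area"][1] == 0.0

    def test_saturating_dose_drives_death_fraction_to_one(self):
        traj = organoid_trajectory(
            fast_clone(), {"drug": 1e5}, [0.0, 24.0, 48.0, 72.0, 96.0, 120.0], None
        )
        fa = traj["green_area"] / traj["bf_area"]
        assert fa[-1] > 0.99
        assert np.all(np.diff(fa) >= 0)

    def test_zero_invasion_propensity_means_no_annulus(self):
        traj = organoid_trajectory(
            fast_clone(invasion_propensity=0.0), {"drug": 50.0},
            [0.0, 48.0, 120.0], None, invasion_induction={"drug": 5.0},
        )
        assert np.all(traj["inv_area"] == 0.0)

    def test_killed_organoid_stops_invading(self):
        # same propensity, one clone killed fast: far less annulus by the end
        alive = organoid_trajectory(
            fast_clone(invasion_propensity=1.0, max_death_rate=0.0), {},
            [0.0, 120.0], None,
        )
        killed = organoid_trajectory(
            fast_clone(invasion_propensity=1.0, max_death_rate=0.3), {"drug": 1e5},
            [0.0, 120.0], None,
        )
        assert killed["inv_area"][-1] < 0.1 * alive["inv_area"][-1]

    def test_negative_parameters_rejected(self):
        with pytest.raises(ConfigError):
            organoid_trajectory(fast_clone(max_death_rate=-0.1), {}, [0.0, 24.0], None)
        with pytest.raises(ConfigError):
            organoid_trajectory(fast_clone(), {}, [24.0, 0.0], None)

    def test_final_area_nonincreasing_in_concentration(self):
        # death-dominant clone: higher dose never yields a larger final mask
        clone = fast_clone(max_death_rate=0.05)
        finals = [
            organoid_trajectory(clone, {"drug": c}, [0.0, 120.0], None)["bf_area"][-1]
            for c in [0.0, 1.0, 10.0, 100.0, 1000.0]
        ]
        assert np.all(np.diff(finals) <= 1e-9)


class TestSimulatePlate:
    def test_same_seed_reproduces_tables_exactly(self):
        cfg = replace(default_scenarios(7)["cytotoxic_responder"], organoids_per_well=20.0)
        m1, l1, t1 = simulate_plate(cfg)
        m2, l2, t2 = simulate_plate(cfg)
        pd.testing.assert_frame_equal(m1, m2)
        pd.testing.assert_frame_equal(t1.organoids, t2.organoids)
        assert m1.to_csv(index=False) == m2.to_csv(index=False)
        assert l1.wells == l2.wells

    def test_staurosporine_wells_fully_dead_by_endpoint(self, hetero_plate):
        m, layout, _ = hetero_plate
        endpoint = m["time_h"].max()
        for well in layout.positive_controls:
            sub = m[(m["well"] == well) & (m["time_h"] == endpoint)]
            assert sub["green_area"].sum() / sub["bf_area"].sum() >= 0.95

    def test_noise_free_vehicle_ndr_is_one(self):
        cfg = replace(default_scenarios(0)["heterogeneous"], noise_sd=0.0,
                      init_area_sd=0.0, organoids_per_well=30.0)
        m, layout, _ = simulate_plate(cfg)
        wm = plate_well_metrics(m, layout)
        vehicle_end = wm[(wm["role"] == "negative_control")
                         & (wm["time_h"] == wm["time_h"].max())]
        assert np.all(np.abs(vehicle_end["ndr"] - 1.0) < 1e-6)

    def test_planted_resistant_fraction_recovered(self):
        cfg = replace(
            default_scenarios(13)["heterogeneous"],
            regimens={"gem-pac": [{"gemcitabine": 400.0, "paclitaxel": 80.0}]},
        )
        m, layout, truth = simulate_plate(cfg)
        endpoint = m["time_h"].max()
        trt_wells = [w for w, e in layout.wells.items() if e.role == "treatment"]
        sub = m[m["well"].isin(trt_wells) & (m["time_h"] == endpoint)]
        fa = sub["green_area"] / sub["bf_area"]
        estimated = float((fa < 0.15).mean())
        assert estimated == pytest.approx(0.30, abs=0.10)

    def test_truth_death_fraction_matches_emitted_signal(self, hetero_plate):
        m, _, truth = hetero_plate
        merged = m.merge(
            truth.organoids, on=["plate_id", "well", "organoid_id", "time_h"]
        )
        emitted_fa = (merged["green_area"] / merged["bf_area"]).to_numpy()
        # multiplicative noise on both channels: agreement within a few sd
        assert np.nanmean(np.abs(emitted_fa - merged["true_death_fraction"])) < 3 * 0.05

    def test_config_validation(self):
        bad = SimConfig(clones=(CloneParams(name="a", fraction=0.5),))
        with pytest.raises(ConfigError, match="sum to 1"):
            bad.validate()
        with pytest.raises(ConfigError, match="EC50"):
            CloneParams(name="a", fraction=1.0, ec50={"x": -1.0}).validate()


class TestDefaultScenarios:
    def test_ships_the_response_taxonomy(self):
        scenarios = default_scenarios(0)
        assert {"cytotoxic_responder", "cytostatic_responder", "heterogeneous",
                "invasion_inducer"} <= set(scenarios)

    def test_cytostatic_scenario_expected_class(self):
        cfg = replace(default_scenarios(0)["cytostatic_responder"], organoids_per_well=5.0)
        _, _, truth = simulate_plate(cfg)
        trt = truth.wells[truth.wells["role"] == "treatment"]
        top = trt[trt["total_conc"] == trt["total_conc"].max()]
        assert (top["expected_ndr_class"] == "cytostatic").all()
        assert np.all(np.abs(top["expected_ndr"]) < 0.2)

    def test_cytotoxic_scenario_expected_ndr_below_threshold(self):
        cfg = replace(default_scenarios(0)["cytotoxic_responder"], organoids_per_well=5.0)
        _, _, truth = simulate_plate(cfg)
        trt = truth.wells[truth.wells["role"] == "treatment"]
        top = trt[trt["total_conc"] == trt["total_conc"].max()]
        assert (top["expected_ndr"] < -0.5).all()
        assert (top["expected_ndr_class"] == "cytotoxic").all()

    def test_invasion_induction_only_in_paclitaxel_like_arm(self):
        cfg = default_scenarios(0)["invasion_inducer"]
        assert cfg.invasion_induction.get("paclitaxel", 0) > 0
        assert cfg.invasion_induction.get("gemcitabine", 0) == 0
        assert cfg.invasion_induction.get(STAUROSPORINE[0], 0) == 0
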
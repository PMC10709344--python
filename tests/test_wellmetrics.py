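import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from orgscreen import (
    DataError,
    auc_ratio,
    classify_signature,
    control_anchors,
    dose_response_auc,
    dose_response_table,
    gr_metric,
    ndr_metric,
    percent_viability,
    plate_well_metrics,
    well_signal,
)
from orgscreen.errors import DegenerateWellError, SlowGrowthError

from conftest import make_measurements

anchors_st = st.tuples(
    st.floats(1.2, 16.0),  # growing negative control
    st.floats(1e-6, 0.9),  # shrinking positive control
)


class TestWellSignal:
    def test_net_signal_and_fold_change(self):
        m = make_measurements([
            ("P1", "A01", 0, 1, 1000.0, 100.0, 0.0, 0.0),
            ("P1", "A01", 24, 1, 2000.0, 400.0, 0.0, 0.0),
        ])
        series = well_signal(m, "A01")
        np.testing.assert_allclose(series.signal, [900.0, 1600.0])
        assert series.fold_change[1] == pytest.approx(1600 / 900)

    def test_fully_dead_well_hits_zero(self):
        m = make_measurements([
            ("P1", "A01", 0, 1, 1000.0, 0.0, 0.0, 0.0),
            ("P1", "A01", 24, 1, 1000.0, 1000.0, 0.0, 0.0),
        ])
        series = well_signal(m, "A01")
        assert series.signal[1] == 0.0
        assert series.fold_change[1] == 0.0
        assert series.cell_death_pct[1] == 100.0

    def test_single_timepoint_rejected(self):
        m = make_measurements([("P1", "A01", 0, 1, 1000.0, 0.0, 0.0, 0.0)])
        with pytest.raises(DataError, match="timepoints"):
            well_signal(m, "A01")

    def test_degenerate_first_timepoint_rejected(self):
        m = make_measurements([
            ("P1", "A01", 0, 1, 100.0, 100.0, 0.0, 0.0),
            ("P1", "A01", 24, 1, 200.0, 0.0, 0.0, 0.0),
        ])
        with pytest.raises(DegenerateWellError):
            well_signal(m, "A01")


class TestViability:
    @pytest.mark.parametrize("f_trt,expected", [(4.0, 100.0), (0.25, 0.0), (2.125, 50.0)])
    def test_anchor_scale(self, f_trt, expected):
        assert percent_viability(f_trt, 4.0, 0.25) == pytest.approx(expected)

    def test_fallback_without_positive_control(self):
        assert percent_viability(2.0, 4.0) == pytest.approx(50.0)

    def test_degenerate_anchors(self):
        with pytest.raises(DataError, match="degenerate"):
            percent_viability(1.0, 2.0, 2.0)

    @given(st.floats(0.1, 10.0), st.floats(0.1, 10.0), anchors_st)
    @settings(max_examples=50, deadline=None)
    def test_affine_and_order_preserving(self, f_a, f_b, anchors):
        f_neg, f_pos = anchors
        v_a = percent_viability(f_a, f_neg, f_pos)
        v_b = percent_viability(f_b, f_neg, f_pos)
        if f_a < f_b:
            assert v_a < v_b
        mid = percent_viability((f_a + f_b) / 2, f_neg, f_pos)
        assert mid == pytest.approx((v_a + v_b) / 2, rel=1e-9, abs=1e-9)


class TestGR:
    @pytest.mark.parametrize("f_trt,f_neg,expected", [
        (2.0, 2.0, 1.0),  # control-like growth
        (1.0, 2.0, 0.0),  # complete arrest
        (1.5, 2.0, 0.5),  # closed form: 2^(log2 1.5) - 1
    ])
    def test_values(self, f_trt, f_neg, expected):
        assert gr_metric(f_trt, f_neg) == pytest.approx(expected)

    def test_slow_growing_control_flagged(self):
        with pytest.raises(SlowGrowthError) as err:
            gr_metric(1.5, 0.9)
        assert err.value.slow_growth
        assert err.value.fold_change == 0.9


class TestNDR:
    def test_printed_anchor_scale(self):
        assert ndr_metric(0.25, 4.0, 0.25) == -1.0  # tracks the kill control
        assert ndr_metric(1.0, 4.0, 0.25) == 0.0  # complete growth inhibition
        assert ndr_metric(2.0, 4.0, 0.25) == pytest.approx(0.8284271247)

    def test_control_like_well_with_dead_positive_control(self):
        assert round(ndr_metric(4.0, 4.0, 2.0**-40), 2) == 1.00

    @given(anchors_st)
    @settings(max_examples=100, deadline=None)
    def test_anchor_exactness_for_any_valid_anchors(self, anchors):
        f_neg, f_pos = anchors
        assert ndr_metric(f_pos, f_neg, f_pos) == pytest.approx(-1.0, abs=1e-12)
        assert ndr_metric(1.0, f_neg, f_pos) == pytest.approx(0.0, abs=1e-12)

    @given(st.floats(0.05, 10.0), anchors_st)
    @settings(max_examples=100, deadline=None)
    def test_sign_agreement_with_gr(self, f_trt, anchors):
        f_neg, f_pos = anchors
        ndr = ndr_metric(f_trt, f_neg, f_pos)
        gr = gr_metric(f_trt, f_neg)
        assert np.sign(ndr) == np.sign(gr)

    def test_invalid_anchors(self):
        with pytest.raises(DataError):
            ndr_metric(1.0, 4.0, 0.0)
        with pytest.raises(SlowGrowthError):
            ndr_metric(1.0, 1.0, 0.25)


class TestAUC:
    def test_constant_curves(self):
        c = [1.0, 10.0, 100.0]
        assert dose_response_auc(c, [1.0, 1.0, 1.0]) == pytest.approx(1.0)
        assert dose_response_auc(c, [0.0, 0.0, 0.0]) == pytest.approx(0.0)

    def test_linear_symmetric_curve_integrates_to_zero(self):
        c = np.logspace(0, 2, 5)
        y = np.linspace(1.0, -1.0, 5)
        assert dose_response_auc(c, y) == pytest.approx(0.0, abs=1e-12)

    def test_bad_concentration_grids(self):
        with pytest.raises(DataError):
            dose_response_auc([10.0, 1.0], [0.0, 0.0])
        with pytest.raises(DataError):
            dose_response_auc([1.0, 1.0], [0.0, 0.0])
        with pytest.raises(DataError):
            dose_response_auc([1.0], [0.0])

    def test_auc_ratio(self):
        assert auc_ratio(0.4, 0.8) == pytest.approx(0.5)
        assert auc_ratio(0.8, 0.8) == 1.0
        with pytest.raises(DataError):
            auc_ratio(0.4, 0.0)


class TestSignature:
    @pytest.mark.parametrize("ndr,death,label", [
        (-0.7, 60.0, "cytotoxic"),
        (-0.1, 55.0, "mixed"),
        (0.2, 10.0, "cytostatic"),
        (-0.3, 10.0, "indeterminate"),
    ])
    def test_rules(self, ndr, death, label):
        assert classify_signature(ndr, death).label == label

    @given(st.floats(-2.0, 2.0), st.floats(0.0, 100.0))
    @settings(max_examples=200, deadline=None)
    def test_every_input_is_classified(self, ndr, death):
        sig = classify_signature(ndr, death)
        assert sig.label in {"cytotoxic", "mixed", "cytostatic", "indeterminate"}
        assert sig.proliferative == (ndr > 1)


class TestPlateMetrics:
    def test_simulated_vehicle_wells_score_near_one(self, hetero_plate):
        measurements, layout, _ = hetero_plate
        wm = plate_well_metrics(measurements, layout)
        vehicle = wm[(wm["role"] == "negative_control")
                     & (wm["time_h"] == wm["time_h"].max())]
        # noise sd 0.05 per channel; control-vs-self NDR stays within a few sd
        assert np.all(np.abs(vehicle["ndr"] - 1.0) < 3 * 0.05)

    def test_ndr_monotone_in_simulated_death_rate(self):
        # fixed growth, increasing kill: NDR must not increase
        from orgscreen.simulate import CloneParams, organoid_trajectory

        ndrs = []
        times = [0.0, 120.0]
        neg = organoid_trajectory(
            CloneParams(name="v", fraction=1.0), {}, times, None)
        pos_fold = 1e-9
        f_neg = (neg["bf_area"][-1] - neg["green_area"][-1]) / neg["bf_area"][0]
        for delta in [0.0, 0.005, 0.01, 0.02, 0.05]:
            clone = CloneParams(name="c", fraction=1.0, ec50={"d": 1.0},
                                max_growth_inhibition=1.0, max_death_rate=delta)
            traj = organoid_trajectory(clone, {"d": 1e6}, times, None)
            f = (traj["bf_area"][-1] - traj["green_area"][-1]) / traj["bf_area"][0]
            ndrs.append(ndr_metric(max(f, 1e-300), f_neg, pos_fold))
        assert np.all(np.diff(ndrs) <= 1e-12)

    def test_dose_response_table_shapes(self, hetero_plate):
        measurements, layout, _ = hetero_plate
        wm = plate_well_metrics(measurements, layout)
        dr = dose_response_table(wm)
        assert set(dr["regimen"]) == {"gemcitabine+paclitaxel"}
        assert len(dr) == 4  # four dose levels
        assert dr["auc"].notna().all()
        assert (dr["endpoint_h"] == 120.0).all()
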
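import numpy as np
import pandas as pd
import pytest

import hcscreen as h
from hcscreen.errors import ScreenError


@pytest.fixture(scope="module")
def standard_curve():
    return h.FourPL(bottom=10.0, top=2000.0, ec50=300.0, hill=1.0)


class TestQuantifyPanel:
    def test_midpoint_signal_maps_to_ec50(self, standard_curve):
        mid = (standard_curve.top + standard_curve.bottom) / 2
        raw = pd.DataFrame([{"analyte": "IL6", "condition": "s", "signal": mid}])
        out = h.quantify_panel(raw, {"IL6": standard_curve})
        assert out["concentration"].iloc[0] == pytest.approx(300.0)

    def test_below_bottom_flagged_without_value(self, standard_curve):
        raw = pd.DataFrame([{"analyte": "IL6", "condition": "s", "signal": 5.0}])
        out = h.quantify_panel(raw, {"IL6": standard_curve})
        assert out["detection"].iloc[0] == "below_lod"
        assert np.isnan(out["concentration"].iloc[0])

    def test_above_top_censored_at_top_standard(self, standard_curve):
        raw = pd.DataFrame([{"analyte": "IL6", "condition": "s", "signal": 5000.0}])
        out = h.quantify_panel(raw, {"IL6": standard_curve})
        assert out["detection"].iloc[0] == "above_range"
        assert out["concentration"].iloc[0] == 10_000.0

    def test_missing_curve_names_analyte(self, standard_curve):
        raw = pd.DataFrame([{"analyte": "TNF", "condition": "s", "signal": 50.0}])
        with pytest.raises(ScreenError, match="TNF"):
            h.quantify_panel(raw, {"IL6": standard_curve})

    def test_end_to_end_recovery_zero_noise(self, standard_curve):
        panel = h.simulate_cba_panel({"CCL2": 500.0}, standard_curve)
        fitted = h.fit_4pl(panel.standards["conc_pgml"],
                           panel.standards["signal"]).curve
        out = h.quantify_panel(panel.samples, {"CCL2": fitted})
        assert out["concentration"].iloc[0] == pytest.approx(500.0, rel=1e-6)

    def test_end_to_end_recovery_under_noise(self, standard_curve):
        """Median relative recovery error across seeds stays within twice
        the injected noise CV for a sample in the informative region of the
        curve (near the EC50, where inverse propagation is best behaved)."""
        errs = []
        for seed in range(50):
            panel = h.simulate_cba_panel({"CCL2": 300.0}, standard_curve,
                                         noise_cv=0.05, seed=seed)
            fitted = h.fit_4pl(panel.standards["conc_pgml"],
                               panel.standards["signal"]).curve
            out = h.quantify_panel(panel.samples, {"CCL2": fitted})
            errs.append(abs(out["concentration"].iloc[0] - 300.0) / 300.0)
        assert np.median(errs) <= 0.10


class TestNormalizePerCell:
    def test_per_cell_arithmetic(self, standard_curve):
        m = pd.DataFrame([{"analyte": "CCL2", "condition": "s",
                           "concentration": 200.0, "detection": "ok"}])
        out = h.normalize_per_cell(m, cells=5000)
        assert out["per_cell_conc"].iloc[0] == pytest.approx(400.0)
        assert out["log10_per_cell"].iloc[0] == pytest.approx(np.log10(400.0))

    def test_identity_at_reference_count(self):
        m = pd.DataFrame([{"analyte": "CCL2", "condition": "s",
                           "concentration": 200.0, "detection": "ok"}])
        out = h.normalize_per_cell(m, cells=10_000)
        assert out["per_cell_conc"].iloc[0] == pytest.approx(200.0)

    def test_below_lod_passes_through_unlogged(self):
        m = pd.DataFrame([{"analyte": "GCSF", "condition": "s",
                           "concentration": np.nan, "detection": "below_lod"}])
        out = h.normalize_per_cell(m, cells=5000)
        assert out["detection"].iloc[0] == "below_lod"
        assert np.isnan(out["per_cell_conc"].iloc[0])
        assert np.isnan(out["log10_per_cell"].iloc[0])

    def test_zero_cells_is_error(self):
        m = pd.DataFrame([{"analyte": "CCL2", "condition": "s",
                           "concentration": 200.0, "detection": "ok"}])
        with pytest.raises(ScreenError):
            h.normalize_per_cell(m, cells=0)


class TestFoldVsVehicle:
    def _m(self, rows):
        return pd.DataFrame([{"analyte": a, "condition": c, "concentration": v,
                              "detection": d} for a, c, v, d in rows])

    def test_sixfold_induction(self):
        m = self._m([("IL6", "veh", 100.0, "ok"), ("IL6", "drug", 600.0, "ok")])
        out = h.fold_vs_vehicle(m, "veh").set_index("condition")
        assert out.loc["drug", "value"] == pytest.approx(6.0)
        assert out.loc["veh", "value"] == pytest.approx(1.0)
        assert (out["mode"] == "fold").all()

    def test_vehicle_below_detection_switches_to_absolute(self):
        m = self._m([("GCSF", "veh", np.nan, "below_lod"),
                     ("GCSF", "drug", 80.0, "ok")])
        out = h.fold_vs_vehicle(m, "veh").set_index("condition")
        assert (out["mode"] == "absolute").all()
        assert out.loc["drug", "value"] == pytest.approx(80.0)

    def test_unit_equivariance(self):
        m = self._m([("IL6", "veh", 100.0, "ok"), ("IL6", "drug", 600.0, "ok")])
        m2 = m.copy()
        m2["concentration"] *= 1000.0  # pg/mL -> ng/L-equivalent rescale
        a = h.fold_vs_vehicle(m, "veh")
        b = h.fold_vs_vehicle(m2, "veh")
        assert np.allclose(a["value"], b["value"])

    def test_missing_vehicle_is_error(self):
        m = self._m([("IL6", "drug", 600.0, "ok")])
        with pytest.raises(ScreenError, match="vehicle"):
            h.fold_vs_vehicle(m, "veh")


class TestNormalizeBlot:
    def test_duplicate_ordering_irrelevant(self):
        rows = [{"row": 0, "col": i, "label": "REF", "intensity": 45.0}
                for i in range(6)]
        rows += [{"row": 1, "col": 0, "label": "A01", "intensity": 80.0},
                 {"row": 1, "col": 1, "label": "A01", "intensity": 100.0}]
        fwd = h.normalize_blot(h.SpotBlot(pd.DataFrame(rows)))
        rev = h.normalize_blot(h.SpotBlot(pd.DataFrame(rows[::-1])))
        pd.testing.assert_frame_equal(fwd, rev)
        assert fwd["normalized"].iloc[0] == pytest.approx(2.0)

    def test_planted_effects_recovered(self):
        effects = {"A01": 0.5, "A02": 1.0, "A03": 3.0}
        blot, _ = h.simulate_blot(3, effects=effects)
        out = h.normalize_blot(blot).set_index("analyte")["normalized"]
        for label, eff in effects.items():
            assert out[label] == pytest.approx(eff, rel=1e-12)


class TestDeltaCt:
    def test_reference_has_fold_one_and_doubling_per_cycle(self):
        rec = pd.DataFrame({
            "gene": ["NFKB1"] * 3, "condition": ["t0", "fast", "slow"],
            "ct_target": [25.0, 24.0, 26.5], "ct_gapdh": [20.0, 20.0, 20.0]})
        out = h.delta_ct_fold(rec, "t0").set_index("condition")
        assert out.loc["t0", "fold_vs_reference"] == pytest.approx(1.0)
        assert out.loc["fast", "fold_vs_reference"] == pytest.approx(2.0)
        assert out.loc["slow", "fold_vs_reference"] == pytest.approx(2 ** -1.5)

    def test_gapdh_shift_cancels(self):
        """A uniform shift in GAPDH Ct leaves folds unchanged (that is the
        point of housekeeping normalization)."""
        rec = pd.DataFrame({
            "gene": ["X"] * 2, "condition": ["t0", "t1"],
            "ct_target": [25.0, 23.0], "ct_gapdh": [20.0, 20.0]})
        shifted = rec.copy()
        shifted[["ct_target", "ct_gapdh"]] += 1.0
        a = h.delta_ct_fold(rec, "t0")["fold_vs_reference"]
        b = h.delta_ct_fold(shifted, "t0")["fold_vs_reference"]
        assert np.allclose(a, b)

    def test_missing_gapdh_is_error(self):
        rec = pd.DataFrame({"gene": ["X"], "condition": ["t0"],
                            "ct_target": [25.0], "ct_gapdh": [np.nan]})
        with pytest.raises(ScreenError, match="GAPDH"):
            h.delta_ct_fold(rec, "t0")

    def test_missing_reference_condition_is_error(self):
        rec = pd.DataFrame({"gene": ["X"], "condition": ["t1"],
                            "ct_target": [25.0], "ct_gapdh": [20.0]})
        with pytest.raises(ScreenError, match="reference"):
            h.delta_ct_fold(rec, "t0")
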
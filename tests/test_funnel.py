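import numpy as np
import pandas as pd
import pytest

import hcscreen as h
from hcscreen.errors import ConfigError, InsufficientReplicatesError, ScreenError
from hcscreen.funnel import hit_ids


def frame(*rows):
    return pd.DataFrame(list(rows))


class TestPrimaryFilter:
    def test_clear_inhibitor_is_hit_down(self, summary_builder):
        res = h.primary_filter(frame(summary_builder("A", [0.74, 0.76],
                                                     cell_ratio=0.9)))
        assert res["verdict"].iloc[0] == "hit_down"
        assert res["percent_change_ccl2"].iloc[0] == pytest.approx(-25.0)

    def test_subthreshold_effect_is_not_hit(self, summary_builder):
        res = h.primary_filter(frame(summary_builder("A", [1.10, 1.10])))
        assert res["verdict"].iloc[0] == "not_hit"

    def test_cytotoxicity_preempts_effect(self, summary_builder):
        """A 60% inhibition with 65% cell loss must be reported as
        cytotoxic, never as a hit."""
        res = h.primary_filter(frame(summary_builder("A", [0.40, 0.44],
                                                     cell_ratio=0.35)))
        assert res["verdict"].iloc[0] == "excluded_cytotoxic"

    def test_variable_qualifying_channel_is_excluded(self, summary_builder):
        res = h.primary_filter(frame(summary_builder("A", [0.60, 1.00])))
        assert res["verdict"].iloc[0] == "excluded_variable"

    def test_high_cv_on_nonqualifying_channel_is_ignored(self, summary_builder):
        # ICAM-1 is noisy but sub-threshold; the clean CCL2 effect carries
        row = summary_builder("A", [0.70, 0.72], activities_icam1=[0.9, 1.2])
        res = h.primary_filter(frame(row))
        assert res["verdict"].iloc[0] == "hit_down"

    def test_direction_from_larger_magnitude_channel(self, summary_builder):
        row = summary_builder("A", [0.75, 0.75], activities_icam1=[1.40, 1.40])
        res = h.primary_filter(frame(row))
        assert res["verdict"].iloc[0] == "hit_up"   # +40% beats -25%

    def test_threshold_sharpness_inclusive_at_20_percent(self, summary_builder):
        rows = [summary_builder("DOWN", [0.80, 0.80]),
                summary_builder("UP", [1.20, 1.20]),
                summary_builder("DOWNSHY", [0.801, 0.801]),
                summary_builder("UPSHY", [1.199, 1.199]),
                summary_builder("TOX", [0.70, 0.70], cell_ratio=0.5)]
        res = h.primary_filter(frame(*rows)).set_index("compound_id")
        assert res.loc["DOWN", "verdict"] == "hit_down"
        assert res.loc["UP", "verdict"] == "hit_up"
        assert res.loc["DOWNSHY", "verdict"] == "not_hit"
        assert res.loc["UPSHY", "verdict"] == "not_hit"
        assert res.loc["TOX", "verdict"] == "excluded_cytotoxic"

    def test_single_replicate_rejected(self, summary_builder):
        with pytest.raises(InsufficientReplicatesError, match="LONE"):
            h.primary_filter(frame(summary_builder("LONE", [0.7])))

    def test_permutation_invariance(self, noisy_screen):
        ds, _ = noisy_screen
        norm = h.normalize_screen(ds)
        shuffled = norm.sample(frac=1.0, random_state=5).reset_index(drop=True)
        a = h.primary_filter(h.summarize_tier(norm))
        b = h.primary_filter(h.summarize_tier(shuffled))
        pd.testing.assert_frame_equal(a, b)


class TestSecondaryFilter:
    def test_primary_hit_confirms_on_clean_triplicate(self, summary_builder):
        summ = frame(summary_builder("A", [0.70, 0.75, 0.72], cell_ratio=0.8))
        res = h.secondary_filter(summ, ["A"])
        assert res["verdict"].iloc[0] == "hit_down"

    def test_variable_triplicate_excluded(self, summary_builder):
        summ = frame(summary_builder("A", [0.60, 1.00, 1.10]))
        res = h.secondary_filter(summ, ["A"])
        assert res["verdict"].iloc[0] == "excluded_variable"

    def test_non_primary_hit_not_evaluated(self, summary_builder):
        summ = frame(summary_builder("A", [0.70, 0.72, 0.71]),
                     summary_builder("B", [0.70, 0.72, 0.71]))
        res = h.secondary_filter(summ, ["A"])
        assert list(res["compound_id"]) == ["A"]

    def test_duplicates_insufficient_at_secondary_tier(self, summary_builder):
        summ = frame(summary_builder("A", [0.70, 0.72]))
        with pytest.raises(InsufficientReplicatesError):
            h.secondary_filter(summ, ["A"])


class TestDoseSelect:
    def _dose_rows(self, cid, effects, ratios):
        rows = []
        for d, pc, cr in zip((0.1, 1.0, 10.0), effects, ratios):
            rows.append({"compound_id": cid, "concentration_um": d, "n_rep": 2,
                         "cell_ratio": cr, "mean_ccl2": 1 + pc / 100,
                         "percent_change_ccl2": pc, "cv_ccl2": 1.0,
                         "mean_icam1": 1.0, "percent_change_icam1": 0.0,
                         "cv_icam1": 1.0})
        return rows

    def test_toxic_top_dose_falls_back_to_next_best(self):
        summ = frame(*self._dose_rows("A", [-10, -30, -45], [1.0, 0.9, 0.3]))
        res = h.dose_select(summ)
        assert res["chosen_dose"].iloc[0] == 1.0
        assert res["verdict"].iloc[0] == "hit_down"

    def test_all_inert_reports_not_hit_at_max_effect_dose(self):
        summ = frame(*self._dose_rows("A", [-5, -10, -15], [1.0, 1.0, 1.0]))
        res = h.dose_select(summ)
        assert res["verdict"].iloc[0] == "not_hit"
        assert res["chosen_dose"].iloc[0] == 10.0

    def test_tie_broken_by_higher_cell_ratio(self):
        summ = frame(*self._dose_rows("A", [-30, -30, -5], [0.7, 0.9, 1.0]))
        res = h.dose_select(summ)
        assert res["chosen_dose"].iloc[0] == 1.0   # ratio 0.9 beats 0.7

    def test_no_viable_dose_is_cytotoxic(self):
        summ = frame(*self._dose_rows("A", [-30, -40, -50], [0.4, 0.3, 0.2]))
        res = h.dose_select(summ)
        assert res["verdict"].iloc[0] == "excluded_cytotoxic"

    def test_single_dose_rejected(self):
        summ = frame(self._dose_rows("A", [-30, -30, -30], [1, 1, 1])[0])
        with pytest.raises(ScreenError):
            h.dose_select(summ)


class TestIndependenceCheck:
    def test_inert_basal_not_flagged(self, summary_builder):
        res = h.independence_check(frame(summary_builder("A", [1.02, 1.02])))
        assert res["flag"].iloc[0] == "none"

    def test_basal_induction_flagged(self, summary_builder):
        res = h.independence_check(frame(summary_builder("A", [1.45, 1.45])))
        assert res["flag"].iloc[0] == "basal_up"

    def test_simulator_with_unit_basal_gives_zero_flags(self, small_config):
        from hcscreen.simulate import zero_noise
        ds, truth = h.simulate_screen(small_config, zero_noise(),
                                      tier="independence")
        summ = h.summarize_tier(h.normalize_screen(ds))
        res = h.independence_check(summ)
        assert (res["flag"] == "none").all()

    def test_empty_input_rejected(self):
        with pytest.raises(ScreenError):
            h.independence_check(pd.DataFrame())


class TestRankAndDiversify:
    def _confirmed(self, summary_builder):
        effects = {"A": 0.50, "B": 0.55, "C": 0.60, "D": 0.70, "E": 0.72, "F": 0.74}
        rows = []
        for cid, act in effects.items():
            r = summary_builder(cid, [act, act, act])
            r["verdict"], r["reason"] = "hit_down", ""
            rows.append(r)
        ann = pd.DataFrame({"compound_id": list("ABCDEF"),
                            "therapeutic_class": ["cardiotonic"] * 3
                            + ["anti-bacterial", "anti-asthmatic", "anti-septic"]})
        return frame(*rows), ann

    def test_greedy_class_cap(self, summary_builder):
        confirmed, ann = self._confirmed(summary_builder)
        out = h.rank_and_diversify(confirmed, ann, k=4, max_per_class=2)
        # efficacy order A(50%) B(45%) C(40%) D(30%)...; cardiotonic capped at 2
        assert list(out["compound_id"]) == ["A", "B", "D", "E"]

    def test_k_exceeding_pool_notes_shortfall(self, summary_builder):
        confirmed, ann = self._confirmed(summary_builder)
        out = h.rank_and_diversify(confirmed, ann, k=10, max_per_class=6)
        assert len(out) == 6
        assert out.attrs["shortfall"] == 4

    def test_lexicographic_tie_break(self, summary_builder):
        rows = []
        for cid in ("ZZ", "AA"):
            r = summary_builder(cid, [0.7, 0.7, 0.7])
            r["verdict"], r["reason"] = "hit_down", ""
            rows.append(r)
        out = h.rank_and_diversify(frame(*rows), None, k=1)
        assert list(out["compound_id"]) == ["AA"]

    def test_unannotated_compounds_fall_in_unknown_class(self, summary_builder):
        confirmed, _ = self._confirmed(summary_builder)
        out = h.rank_and_diversify(confirmed, None, k=3, max_per_class=2)
        assert set(out["therapeutic_class"]) == {"unknown"}
        assert len(out) == 2  # unknown class capped too

    def test_nonpositive_k_rejected(self, summary_builder):
        confirmed, ann = self._confirmed(summary_builder)
        with pytest.raises(ConfigError):
            h.rank_and_diversify(confirmed, ann, k=0)


class TestFunnelEndToEnd:
    def test_zero_noise_oracle_equivalence(self, noiseless_screen, small_config):
        ds, truth = noiseless_screen
        res = h.primary_filter(h.summarize_tier(h.normalize_screen(ds)))
        assert hit_ids(res) == truth.expected_hits(effect_threshold=0.2)

    def test_monotonicity_and_determinism(self):
        cfg = h.SimConfig(n_compounds=120, fraction_modulators=0.15, seed=21)
        a = h.run_funnel(cfg, h.NoiseModel(), shortlist_k=5)
        b = h.run_funnel(cfg, h.NoiseModel(), shortlist_k=5)
        screened = set(a.truth.table.index)
        assert set(a.primary_hits) <= screened
        assert set(a.confirmed_hits) <= set(a.primary_hits)
        assert set(a.shortlist["compound_id"]) <= set(a.confirmed_hits)
        pd.testing.assert_frame_equal(a.primary, b.primary, check_exact=True)
        pd.testing.assert_frame_equal(a.secondary, b.secondary, check_exact=True)
        pd.testing.assert_frame_equal(a.doses, b.doses, check_exact=True)

    def test_byte_identical_reports_for_identical_seeds(self, tmp_path):
        cfg = h.SimConfig(n_compounds=60, seed=13)
        payload = []
        for sub in ("r1", "r2"):
            fr = h.run_funnel(cfg, h.NoiseModel())
            h.write_funnel_report(fr.tier_tables(), tmp_path / sub,
                                  n_screened=len(fr.truth))
            payload.append({p.name: p.read_bytes()
                            for p in sorted((tmp_path / sub).iterdir())})
        assert payload[0] == payload[1]
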
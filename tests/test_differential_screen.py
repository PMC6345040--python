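"""Screen-scoring chain: plate normalization, averaging, differential Z."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from platescreen import differential_screen as ds
from platescreen.errors import (
    ControlError,
    DegenerateScreenError,
    MismatchedCompoundsError,
)

from conftest import make_viability_table


def norm_frame(compound_ids, norms, means=None):
    """A screen-mean-normalized compound viability frame for direct Z input."""
    if means is None:
        means = [100.0 * v for v in norms]
    return pd.DataFrame({
        "compound_id": compound_ids,
        "condition": "x",
        "mean_percent_viability": means,
        "n_wells": 4,
        "norm_viability": norms,
    })


class TestPlateDmsoNormalization:
    def test_compound_expressed_as_percent_of_plate_dmso(self):
        table = make_viability_table([{
            "plate_id": "p1", "condition": "ref", "run": 1, "replicate": 1,
            "wells": [("A1", "blank", "", 100.0), ("A2", "dmso", "", 1100.0),
                      ("A3", "dmso", "", 1100.0), ("B1", "compound", "c001", 350.0),
                      ("B2", "compound", "c002", 1100.0)],
        }])
        out = ds.normalize_to_plate_dmso(table).set_index("well")
        assert out.loc["B1", "percent_viability"] == pytest.approx(25.0)
        assert out.loc["B2", "percent_viability"] == pytest.approx(100.0)

    def test_missing_dmso_wells_error_names_plate(self):
        table = make_viability_table([{
            "plate_id": "p9", "condition": "ref",
            "wells": [("A1", "blank", "", 100.0),
                      ("B1", "compound", "c001", 350.0)],
        }])
        with pytest.raises(ControlError, match="p9"):
            ds.normalize_to_plate_dmso(table)

    def test_nonpositive_dmso_mean_rejected(self):
        table = make_viability_table([{
            "plate_id": "p1", "condition": "ref",
            "wells": [("A1", "blank", "", 100.0), ("A2", "dmso", "", 80.0),
                      ("B1", "compound", "c001", 350.0)],
        }])
        with pytest.raises(ControlError, match="p1"):
            ds.normalize_to_plate_dmso(table)


class TestAverageReplicates:
    def table_for(self, well_viabilities):
        rows = []
        for i, v in enumerate(well_viabilities):
            rows.append({
                "plate_id": f"p{i}", "well": "B1", "role": "compound",
                "compound_id": "c001", "concentration_nM": 1000.0,
                "condition": "ref", "run": 1 + i % 2, "replicate": 1 + i // 2,
                "reading": np.nan, "percent_viability": v,
            })
        return pd.DataFrame(rows)

    @pytest.mark.parametrize("wells,expected", [
        ([40.0, 60.0, 50.0, 50.0], 50.0),
        ([0.0, 100.0], 50.0),
    ])
    def test_unweighted_mean_over_wells(self, wells, expected):
        out = ds.average_replicates(self.table_for(wells))
        assert out.loc[0, "mean_percent_viability"] == pytest.approx(expected)
        assert out.loc[0, "n_wells"] == len(wells)

    def test_single_surviving_well_warns(self):
        with pytest.warns(UserWarning, match="single-well"):
            out = ds.average_replicates(self.table_for([70.0]))
        assert out.loc[0, "mean_percent_viability"] == 70.0


class TestScreenMeanNormalization:
    def test_norms_are_means_over_screen_mean(self):
        df = norm_frame(["a", "b", "c"], [np.nan] * 3, means=[50.0, 100.0, 150.0])
        out = ds.normalize_to_screen_mean(df.drop(columns="norm_viability"))
        np.testing.assert_allclose(out["norm_viability"], [0.5, 1.0, 1.5])
        assert out["norm_viability"].mean() == pytest.approx(1.0, abs=1e-15)

    def test_identical_compounds_all_norm_one(self):
        df = norm_frame(["a", "b"], [np.nan] * 2, means=[80.0, 80.0])
        out = ds.normalize_to_screen_mean(df.drop(columns="norm_viability"))
        np.testing.assert_allclose(out["norm_viability"], [1.0, 1.0])

    def test_two_compounds(self):
        df = norm_frame(["a", "b"], [np.nan] * 2, means=[10.0, 30.0])
        out = ds.normalize_to_screen_mean(df.drop(columns="norm_viability"))
        np.testing.assert_allclose(out["norm_viability"], [0.5, 1.5])


class TestDifferentialZscore:
    def test_hand_computed_four_compound_example(self):
        e = math.e
        ref = norm_frame(list("abcd"), [1.0, 1.0, 1.0, 1.0])
        tst = norm_frame(list("abcd"), [e, 1 / e, e, 1 / e])
        out = ds.differential_zscore(ref, tst)
        np.testing.assert_allclose(out["log_ratio"], [-1.0, 1.0, -1.0, 1.0],
                                   atol=1e-12)
        # SD(n-1) of [-1,1,-1,1] = 2/sqrt(3); Z = +/- sqrt(3)/2
        expected_z = math.sqrt(3) / 2
        np.testing.assert_allclose(
            out["zscore"], [-expected_z, expected_z, -expected_z, expected_z],
            atol=1e-12,
        )

    def test_zero_spread_is_degenerate(self):
        ref = norm_frame(list("abcd"), [1.0, 0.5, 2.0, 1.0])
        with pytest.raises(DegenerateScreenError, match="SD = 0"):
            ds.differential_zscore(ref, ref.copy())

    def test_mismatched_compound_sets_listed(self):
        ref = norm_frame(list("abc"), [1.0, 1.0, 1.0])
        tst = norm_frame(list("abd"), [1.0, 1.0, 1.0])
        with pytest.raises(MismatchedCompoundsError, match="d"):
            ds.differential_zscore(ref, tst)

    def test_needs_three_compounds(self):
        ref = norm_frame(list("ab"), [1.0, 2.0])
        tst = norm_frame(list("ab"), [2.0, 1.0])
        with pytest.raises(DegenerateScreenError, match=">= 3"):
            ds.differential_zscore(ref, tst)

    def test_mean_zero_sd_one_by_construction(self):
        rng = np.random.default_rng(5)
        ids = [f"c{i}" for i in range(50)]
        ref = norm_frame(ids, rng.lognormal(0, 0.2, 50))
        tst = norm_frame(ids, rng.lognormal(0, 0.2, 50))
        out = ds.differential_zscore(ref, tst)
        assert out["zscore"].mean() == pytest.approx(0.0, abs=1e-12)
        assert out["zscore"].std(ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_compound_order_never_changes_z(self):
        rng = np.random.default_rng(6)
        ids = [f"c{i}" for i in range(20)]
        ref = norm_frame(ids, rng.lognormal(0, 0.2, 20))
        tst = norm_frame(ids, rng.lognormal(0, 0.2, 20))
        base = ds.differential_zscore(ref, tst).set_index("compound_id")["zscore"]
        perm = rng.permutation(20)
        shuffled = ds.differential_zscore(
            ref.iloc[perm].reset_index(drop=True), tst
        ).set_index("compound_id")["zscore"]
        pd.testing.assert_series_equal(base.sort_index(), shuffled.sort_index())

    def test_swapping_conditions_negates_z_and_swaps_calls(self):
        rng = np.random.default_rng(7)
        ids = [f"c{i}" for i in range(40)]
        ref = norm_frame(ids, rng.lognormal(0, 0.1, 40))
        tst_vals = rng.lognormal(0, 0.1, 40)
        tst_vals[0] *= 0.05  # strong kill in test
        tst = norm_frame(ids, tst_vals)
        fwd = ds.call_hits(ds.differential_zscore(ref, tst)).set_index("compound_id")
        rev = ds.call_hits(ds.differential_zscore(tst, ref)).set_index("compound_id")
        np.testing.assert_allclose(fwd["zscore"].sort_index(),
                                   -rev["zscore"].sort_index(), atol=1e-12)
        assert fwd.loc["c0", "hit_call"] == "selective_in_test"
        assert rev.loc["c0", "hit_call"] == "selective_in_reference"

    @settings(derandomize=True, max_examples=20)
    @given(seed=st.integers(min_value=0, max_value=10_000))
    def test_log_base_invariance(self, seed):
        rng = np.random.default_rng(seed)
        ids = [f"c{i}" for i in range(30)]
        ref_vals = rng.lognormal(0, 0.3, 30)
        tst_vals = rng.lognormal(0, 0.3, 30)
        out = ds.differential_zscore(norm_frame(ids, ref_vals),
                                     norm_frame(ids, tst_vals))
        for base in (2.0, 10.0):
            logr = np.log(ref_vals / tst_vals) / np.log(base)
            z = (logr - logr.mean()) / logr.std(ddof=1)
            np.testing.assert_allclose(np.sort(out["zscore"]), np.sort(z),
                                       atol=1e-12)

    def test_planted_tenfold_kill_detected_in_at_least_99_of_100_screens(self):
        # 1 compound with 10-fold lower test viability among 327 nulls,
        # lognormal viability noise with ln-SD 0.1: ln(10)/0.1 ~ 23 SDs
        # before dilution of the screen SD by the planted tail.
        detected = 0
        ids = [f"c{i:03d}" for i in range(328)]
        for seed in range(100):
            rng = np.random.default_rng(seed)
            ref_vals = rng.lognormal(0, 0.1, 328)
            tst_vals = rng.lognormal(0, 0.1, 328)
            tst_vals[0] *= 0.1
            out = ds.differential_zscore(norm_frame(ids, ref_vals),
                                         norm_frame(ids, tst_vals))
            z = out.set_index("compound_id").loc["c000", "zscore"]
            detected += z >= 2.0
        assert detected >= 99

    def test_total_kill_compound_floored_and_flagged(self):
        ids = list("abcd")
        ref = norm_frame(ids, [1.0, 1.1, 0.9, 1.0])
        tst = norm_frame(ids, [0.0, 1.0, 1.0, 1.1])  # total kill for 'a'
        out = ds.differential_zscore(ref, tst).set_index("compound_id")
        assert bool(out.loc["a", "flag_floored"])
        assert np.isfinite(out.loc["a", "log_ratio"])
        assert out.loc["a", "log_ratio"] == pytest.approx(math.log(1.0 / 1e-3))


class TestCallHits:
    def scores(self, zvals):
        return pd.DataFrame({
            "compound_id": [f"c{i}" for i in range(len(zvals))],
            "zscore": zvals,
        })

    def test_boundaries_are_inclusive(self):
        out = ds.call_hits(self.scores([2.0, -2.5, 1.99, -2.0, 0.0]))
        calls = out.set_index("compound_id")["hit_call"]
        assert calls["c0"] == "selective_in_test"
        assert calls["c1"] == "selective_in_reference"
        assert calls["c2"] == "none"
        assert calls["c3"] == "selective_in_reference"
        assert calls["c4"] == "none"

    def test_output_ranked_by_z_descending(self):
        out = ds.call_hits(self.scores([0.5, 2.5, -1.0]))
        assert list(out["zscore"]) == sorted(out["zscore"], reverse=True)

    def test_custom_threshold(self):
        out = ds.call_hits(self.scores([1.5, -1.5]), threshold=1.5)
        assert set(out["hit_call"]) == {"selective_in_test",
                                        "selective_in_reference"}


class TestScoreScreenEndToEnd:
    def test_small_screen_scores_and_summary(self, small_screen_table):
        scores, summary = ds.score_screen(small_screen_table, "ref", "tst")
        assert summary["n_compounds"] == 4
        assert scores["zscore"].mean() == pytest.approx(0.0, abs=1e-12)
        # c003 is killed in test relative to reference, c004 the reverse
        by_id = scores.set_index("compound_id")
        assert by_id.loc["c003", "zscore"] > 0
        assert by_id.loc["c004", "zscore"] < 0

    def test_unknown_condition_rejected(self, small_screen_table):
        with pytest.raises(MismatchedCompoundsError, match="nope"):
            ds.score_screen(small_screen_table, "ref", "nope")
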
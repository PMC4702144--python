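"""Dive detection, shape metrics, classification and summaries."""
import numpy as np
import pandas as pd
import pytest

from sympatry import dives, simulate
from sympatry.config import DiveShapeParams
from sympatry.exceptions import (DegenerateDiveError, InputError,
                                 SchemaError, UndefinedResultError)


def trace_df(depth, dt=1.0, individual="x1"):
    depth = np.asarray(depth, dtype=float)
    return pd.DataFrame({
        "individual": individual, "species": "adelie", "sex": "F",
        "time": np.arange(depth.size) * dt, "depth": depth})


def v_profile(depth=40.0, rate=1.5):
    return simulate.build_v_dive(depth, rate, 1.0)


class TestDriftCorrection:
    def test_constant_offset_recovered(self):
        d = np.zeros(4000)
        prof = v_profile(30.0)
        d[1000:1000 + prof.size] = prof
        tr = trace_df(d + 1.5)
        out = dives.correct_drift(tr, window=600.0)
        surface = out["depth"].to_numpy()[:900]
        assert abs(np.median(surface)) < 0.05

    def test_drift_free_trace_unchanged(self):
        d = np.zeros(4000)
        prof = v_profile(60.0)
        d[500:500 + prof.size] = prof
        tr = trace_df(d)
        out = dives.correct_drift(tr, window=600.0)
        assert np.abs(out["depth"].to_numpy() - d).max() < 0.05

    def test_linear_drift_recovered_within_tolerance(self):
        rng = np.random.default_rng(0)
        n = 6 * 3600
        t = np.arange(n, dtype=float)
        d = np.zeros(n)
        for start in range(600, n - 200, 900):
            prof = v_profile(rng.uniform(20, 50))
            d[start:start + prof.size] = prof
        planted = 2.0 * t / n
        tr = trace_df(d + planted + rng.normal(0, 0.1, n))
        _, offsets = dives.correct_drift(tr, return_offsets=True)
        est = np.interp(offsets["time"], t, planted)
        assert np.abs(offsets["offset"] - est).max() < 0.2

    def test_window_longer_than_trace_warns(self):
        tr = trace_df(np.zeros(100))
        with pytest.warns(UserWarning, match="global offset"):
            dives.correct_drift(tr, window=1e6)


class TestDetection:
    def test_flat_trace_yields_no_dives(self):
        assert dives.detect_dives(trace_df(np.zeros(500))).empty

    def test_single_v_dive_recovered(self):
        prof = v_profile(40.0)
        d = np.concatenate([np.zeros(60), prof, np.zeros(60)])
        out = dives.detect_dives(trace_df(d))
        assert len(out) == 1
        assert out.iloc[0]["max_depth"] == pytest.approx(40.0)
        assert out.iloc[0]["duration"] == pytest.approx(prof.size, abs=1)

    def test_close_dives_not_merged(self):
        prof = v_profile(20.0)
        d = np.concatenate([np.zeros(30), prof, np.zeros(5), prof,
                            np.zeros(30)])
        assert len(dives.detect_dives(trace_df(d))) == 2

    def test_shallow_or_short_dives_discarded(self):
        blip = np.concatenate([np.zeros(30), [2.0, 2.5, 2.0], np.zeros(30)])
        assert dives.detect_dives(trace_df(blip)).empty

    def test_unsorted_time_raises(self):
        tr = trace_df(np.zeros(50))
        tr.loc[10, "time"] = 5.0
        with pytest.raises(InputError):
            dives.detect_dives(tr)

    def test_missing_column_raises_schema_error(self):
        tr = trace_df(np.zeros(50)).drop(columns=["depth"])
        with pytest.raises(SchemaError, match="depth"):
            dives.analyze(tr)


class TestShape:
    def test_v_dive_has_no_signatures(self):
        s = dives.extract_shape(v_profile(30.0, rate=2.5), 1.0)
        assert s["n_wiggles"] == 0
        assert s["n_plateaus"] == 0
        assert not s["has_bottom"]

    def test_planted_wiggles_counted_exactly(self):
        p = DiveShapeParams()
        for k in (1, 2, 3, 4):
            prof = simulate.build_bottom_dive(40.0, 30.0 + 9 * k, k,
                                              False, p, 1.0)
            s = dives.extract_shape(prof, 1.0)
            assert s["n_wiggles"] == k

    def test_planted_ascent_shelf_is_one_plateau(self):
        p = DiveShapeParams()
        prof = simulate.build_shallow_plateau_dive(16.0, p, 1.0)
        s = dives.extract_shape(prof, 1.0)
        assert s["n_plateaus"] == 1
        assert not s["has_bottom"]

    def test_bottom_time_measured_on_flat_bottom(self):
        p = DiveShapeParams()
        prof = simulate.build_bottom_dive(40.0, 30.0, 0, False, p, 1.0)
        s = dives.extract_shape(prof, 1.0)
        assert s["bottom_time"] >= 30.0
        assert s["has_bottom"]

    def test_degenerate_segment_raises(self):
        with pytest.raises(DegenerateDiveError):
            dives.extract_shape(np.array([5.0, 6.0]), 1.0)


class TestClassification:
    @pytest.mark.parametrize("row,expected", [
        (dict(has_bottom=True, has_wiggle=False, has_plateau=False,
              max_depth=40.0), "forage"),
        (dict(has_bottom=False, has_wiggle=True, has_plateau=False,
              max_depth=40.0), "forage"),
        (dict(has_bottom=False, has_wiggle=False, has_plateau=True,
              max_depth=15.0), "forage"),
        (dict(has_bottom=False, has_wiggle=False, has_plateau=False,
              max_depth=5.0), "transit"),
        (dict(has_bottom=False, has_wiggle=False, has_plateau=False,
              max_depth=30.0), "search"),
    ])
    def test_rule(self, row, expected):
        assert dives.classify(row) == expected

    def test_every_dive_gets_exactly_one_label(self, noisy_tdr):
        tdr, _ = noisy_tdr
        out = dives.analyze(tdr)
        assert out["behavior"].isin(["transit", "search", "forage"]).all()
        flags = out[["has_bottom", "has_wiggle", "has_plateau"]].any(axis=1)
        assert ((out["behavior"] == "forage") == flags).all()

    def test_constant_offset_does_not_change_labels(self, quiet_tdr):
        tdr, _ = quiet_tdr
        one = tdr[tdr["individual"] == tdr["individual"].iloc[0]]
        base = dives.analyze(one)
        for off in (0.7, 2.0):
            shifted = one.assign(depth=one["depth"] + off)
            out = dives.analyze(shifted)
            assert list(out["behavior"]) == list(base["behavior"])


class TestRoundTrip:
    def test_noise_free_recovery_is_exact(self, quiet_tdr):
        tdr, truth = quiet_tdr
        det = dives.analyze(tdr, correct=False).sort_values(
            ["individual", "start"]).reset_index(drop=True)
        td = truth.dives.sort_values(
            ["individual", "start"]).reset_index(drop=True)
        assert len(det) == len(td)
        assert (det["behavior"].values == td["behavior"].values).all()
        assert (det["n_wiggles"].values == td["n_wiggles"].values).all()
        assert (det["n_plateaus"].values == td["n_plateaus"].values).all()
        assert np.allclose(det["bottom_time"], td["bottom_time"])
        assert np.allclose(det["max_depth"], td["max_depth"])


class TestSummaries:
    def test_depth_mode_of_constant_sample(self):
        assert dives.foraging_depth_mode([30.0] * 8) == 30.0

    def test_depth_mode_of_normal_sample(self):
        rng = np.random.default_rng(1)
        mode = dives.foraging_depth_mode(rng.normal(50, 5, 500))
        assert 47.0 <= mode <= 53.0

    def test_depth_mode_bimodal_prefers_heavier_mode(self):
        rng = np.random.default_rng(2)
        depths = np.concatenate([rng.normal(20, 2, 100),
                                 rng.normal(80, 2, 200)])
        mode = dives.foraging_depth_mode(depths)
        # independent brute-force density evaluation
        bw = 1.06 * min(depths.std(ddof=1),
                        np.subtract(*np.percentile(depths, [75, 25])) / 1.34
                        ) * depths.size ** -0.2
        grid = np.arange(0, 100, 0.5)
        dens = [np.exp(-0.5 * ((g - depths) / bw) ** 2).sum() for g in grid]
        assert mode == pytest.approx(grid[int(np.argmax(dens))], abs=0.5)
        assert 75.0 <= mode <= 85.0

    def test_depth_mode_requires_dives(self):
        with pytest.raises(UndefinedResultError):
            dives.foraging_depth_mode([])

    def test_proportions_and_frequency_arithmetic(self):
        rows = []
        for i, (ind, nb) in enumerate([("a1", 3), ("a2", 0)]):
            for k in range(4):
                rows.append({
                    "individual": ind, "species": "adelie",
                    "behavior": "forage", "max_depth": 30.0 + k,
                    "duration": 60.0,
                    "has_bottom": k < nb or (ind == "a2" and k < 4),
                    "has_wiggle": False, "has_plateau": False})
        df = pd.DataFrame(rows)
        hours = pd.Series({"a1": 2.0, "a2": 2.0})
        per_ind, per_sp = dives.summarize(df, hours)
        a1 = per_ind[per_ind["individual"] == "a1"].iloc[0]
        assert a1["p_bottom"] == pytest.approx(0.75)
        assert a1["dive_frequency"] == pytest.approx(2.0)
        row = per_sp.iloc[0]
        assert row["p_bottom_mean"] == pytest.approx((0.75 + 1.0) / 2)
        assert row["p_bottom_std"] == pytest.approx(
            np.std([0.75, 1.0], ddof=1))

    def test_species_mean_sd_of_two_individuals(self):
        vals = [0.6, 1.0]
        assert np.mean(vals) == pytest.approx(0.8)
        assert np.std(vals, ddof=1) == pytest.approx(0.283, abs=0.001)

    def test_individuals_without_forage_dives_are_excluded(self):
        df = pd.DataFrame([{
            "individual": "a1", "species": "adelie", "behavior": "transit",
            "max_depth": 5.0, "duration": 20.0, "has_bottom": False,
            "has_wiggle": False, "has_plateau": False}])
        per_ind, per_sp = dives.summarize(df)
        assert per_ind.empty
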
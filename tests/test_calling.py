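"""Threshold selection and call matrices."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from rampscreen.calling import (
    ThresholdSet,
    aggregate_replicate_rz,
    apply_thresholds,
    candidate_grid,
    density_mad_threshold,
    endogenous_call,
    select_intersection_threshold,
    sens_spec_curves,
)
from rampscreen.errors import CalibrationError, DegenerateScaleError, ValidationError
from rampscreen.simulate import SimulationConfig, simulate_endogenous


def _truth(interactors, non_interactors):
    rows = [dict(gpcr_id=g, ramp_id="RAMP1", label="interacting") for g in interactors]
    rows += [dict(gpcr_id=g, ramp_id="RAMP1", label="non_interacting") for g in non_interactors]
    return pd.DataFrame(rows)


def _scores(mapping):
    return pd.Series({(g, "RAMP1"): v for g, v in mapping.items()})


class TestSensSpecCurves:
    def test_hand_counted_perfect_separation(self):
        scores = _scores({"a": 5, "b": 6, "c": 7, "d": 0, "e": 1, "f": 2})
        truth = _truth(["a", "b", "c"], ["d", "e", "f"])
        out = sens_spec_curves(scores, truth, thresholds=[3.0])
        row = out.iloc[0]
        assert (row.tp, row.fn, row.tn, row.fp) == (3, 0, 3, 0)
        assert row.sensitivity == 1.0 and row.specificity == 1.0

    def test_extreme_thresholds(self):
        scores = _scores({"a": 5, "d": 0})
        truth = _truth(["a"], ["d"])
        out = sens_spec_curves(scores, truth, thresholds=[-1.0, 10.0])
        assert out.iloc[0].sensitivity == 1.0 and out.iloc[0].specificity == 0.0
        assert out.iloc[1].sensitivity == 0.0 and out.iloc[1].specificity == 1.0

    def test_monotone_in_threshold(self, rng):
        vals = rng.normal(size=30)
        names = [f"g{i}" for i in range(30)]
        scores = _scores(dict(zip(names, vals)))
        truth = _truth(names[:15], names[15:])
        out = sens_spec_curves(scores, truth)
        assert (np.diff(out["sensitivity"]) <= 1e-12).all()
        assert (np.diff(out["specificity"]) >= -1e-12).all()

    def test_one_class_truth_rejected(self):
        scores = _scores({"a": 5, "b": 6})
        with pytest.raises(CalibrationError):
            sens_spec_curves(scores, _truth(["a", "b"], []))


def brute_force_intersection(score_label_pairs):
    """Independent oracle: evaluate every grid threshold directly and apply
    the tie-break rules by explicit comparison."""
    s = np.array([v for v, _ in score_label_pairs], dtype=float)
    y = np.array([l for _, l in score_label_pairs], dtype=bool)
    grid = sorted(set(s)) + [
        (a + b) / 2 for a, b in zip(sorted(set(s))[:-1], sorted(set(s))[1:])
    ]
    best = None
    for t in sorted(grid):
        sens = float(((s > t) & y).sum() / y.sum())
        spec = float((~(s > t) & ~y).sum() / (~y).sum())
        key = (abs(sens - spec), -(sens + spec), t)
        if best is None or key < best[0]:
            best = (key, t)
    return best[1]


class TestIntersectionThreshold:
    def test_perfect_separation_crossing(self):
        scores = _scores({"a": 5, "b": 6, "c": 7, "d": 0, "e": 1, "f": 2})
        truth = _truth(["a", "b", "c"], ["d", "e", "f"])
        curves = sens_spec_curves(scores, truth)
        t = select_intersection_threshold(curves)
        # hits are strict (score > t), so any t in [2, 5) separates perfectly;
        # the smallest-threshold tie-break lands on the lowest such grid point
        assert 2 <= t < 5
        at = curves[curves["threshold"] == t].iloc[0]
        assert at.sensitivity == 1.0 and at.specificity == 1.0

    def test_interleaved_case_matches_oracle(self):
        scores = _scores({"a": 1, "b": 3, "c": 0, "d": 2})
        truth = _truth(["a", "b"], ["c", "d"])
        curves = sens_spec_curves(scores, truth)
        t = select_intersection_threshold(curves)
        at = curves[curves["threshold"] == t].iloc[0]
        assert abs(at.sensitivity - at.specificity) == 0.0
        assert at.sensitivity == 0.5
        pairs = [(1, True), (3, True), (0, False), (2, False)]
        assert t == brute_force_intersection(pairs)

    def test_flipped_labels_anticalibrated(self):
        scores = _scores({"a": 5, "b": 6, "c": 7, "d": 0, "e": 1, "f": 2})
        truth = _truth(["d", "e", "f"], ["a", "b", "c"])  # flipped
        curves = sens_spec_curves(scores, truth)
        t = select_intersection_threshold(curves)
        at = curves[curves["threshold"] == t].iloc[0]
        assert at.sensitivity + at.specificity <= 1.0

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.integers(0, 10_000))
    def test_oracle_equivalence_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 30))
        s = np.round(rng.normal(size=n), 2)
        y = rng.random(n) < 0.5
        if y.all() or not y.any():
            y[0] = True
            y[-1] = False
        names = [f"g{i}" for i in range(n)]
        scores = _scores(dict(zip(names, s)))
        truth = _truth(
            [g for g, yy in zip(names, y) if yy], [g for g, yy in zip(names, y) if not yy]
        )
        t = select_intersection_threshold(sens_spec_curves(scores, truth))
        assert t == brute_force_intersection(list(zip(s, y)))


class TestDensityMadThreshold:
    def test_standard_normal_near_six(self):
        x = np.random.default_rng(1).normal(size=10_000)
        t = density_mad_threshold(x)
        assert 5.4 <= t <= 6.6

    def test_translation_equivariance(self):
        x = np.random.default_rng(2).normal(size=500)
        assert density_mad_threshold(x + 7.5) == pytest.approx(
            density_mad_threshold(x) + 7.5, abs=1e-9
        )

    def test_outlier_fixture_with_kde_oracle(self):
        x = np.array([0.0, 1.0, 2.0, 3.0, 4.0, 100.0, 0.5, 1.5])
        # oracle: recompute the KDE mode on a very dense grid
        kde = stats.gaussian_kde(x, bw_method="silverman")
        dense = np.linspace(x.min(), x.max(), 50_001)
        mode = dense[np.argmax(kde(dense))]
        med = np.median(x)
        mad = np.median(np.abs(x - med))
        t = density_mad_threshold(x)
        assert t == pytest.approx(mode + 6 * 1.4826 * mad, abs=0.05)

    def test_mad_zero_falls_back_to_sd(self):
        x = np.array([1.0] * 6 + [2.0, 3.0])  # MAD 0, SD > 0
        t = density_mad_threshold(x)
        assert np.isfinite(t) and t > 1.0
        with pytest.raises(DegenerateScaleError):
            density_mad_threshold(np.ones(10))

    def test_needs_enough_scores(self):
        with pytest.raises(ValidationError):
            density_mad_threshold(np.arange(5.0))


def _scored_frame(entries):
    return pd.DataFrame(
        entries,
        columns=["gpcr_id", "ramp_id", "scheme_id", "capture_family", "capture_antibody_id", "score", "on_target"],
    )


class TestApplyThresholds:
    def _thresholds(self):
        return ThresholdSet(epitope={("RAMP1", "scheme_a"): 3.5})

    def test_strict_inequality_at_boundary(self):
        scored = _scored_frame(
            [
                ("g1", "RAMP1", "scheme_a", "epitope_based", "ab", 3.6, True),
                ("g2", "RAMP1", "scheme_a", "epitope_based", "ab", 3.5, True),
            ]
        )
        out = apply_thresholds(scored, self._thresholds())
        assert out.set_index("gpcr_id")["hit"].to_dict() == {"g1": True, "g2": False}

    def test_empty_scores_empty_calls(self):
        out = apply_thresholds(_scored_frame([]), ThresholdSet())
        assert out.empty

    def test_missing_threshold_raises(self):
        scored = _scored_frame([("g1", "RAMP2", "scheme_a", "epitope_based", "ab", 1.0, True)])
        with pytest.raises(ValidationError, match="missing threshold"):
            apply_thresholds(scored, self._thresholds())

    def test_raising_threshold_never_increases_hits(self, rng):
        scored = _scored_frame(
            [(f"g{i}", "RAMP1", "scheme_a", "epitope_based", "ab", v, True) for i, v in enumerate(rng.normal(size=50))]
        )
        hits = []
        for t in (-2.0, 0.0, 1.0, 3.0):
            out = apply_thresholds(scored, ThresholdSet(epitope={("RAMP1", "scheme_a"): t}))
            hits.append(out["hit"].sum())
        assert hits == sorted(hits, reverse=True)


class TestEndogenousCall:
    def test_technical_duplicates_averaged_before_thresholding(self):
        mean, hit = aggregate_replicate_rz([4.0, 2.0])
        assert mean == pytest.approx(3.0) and hit is False
        mean, hit = aggregate_replicate_rz([4.0, 4.0])
        assert hit is True

    def test_all_buffer_input_zero_calls(self):
        cfg = SimulationConfig(n_gpcrs=5, seed=3)
        mfi, panel, sheet, _ = simulate_endogenous(cfg, n_cell_lines=1)
        buf_ids = set(sheet.loc[sheet["is_buffer"], "sample_id"])
        only_buffer = mfi[mfi["sample_id"].isin(buf_ids)]
        out = endogenous_call(only_buffer, panel, sheet)
        assert out.empty or not out["hit"].any()

    def test_strong_effect_recovers_true_pairs(self):
        cfg = SimulationConfig(
            n_gpcrs=40, interact_prob=0.05, log_effect=3.0, noise_sd=0.15, ab_affinity_sd=0.5, seed=5
        )
        mfi, panel, sheet, truth = simulate_endogenous(cfg, n_cell_lines=2)
        calls = endogenous_call(mfi, panel, sheet)
        m = calls.merge(truth, on=["gpcr_id", "ramp_id"])
        assert m.loc[m["interacting"], "hit"].all()
        assert m.loc[~m["interacting"], "hit"].mean() <= 0.01

    def test_grid_contains_scores_and_midpoints(self):
        grid = candidate_grid([1.0, 2.0, 4.0])
        np.testing.assert_allclose(grid, [1.0, 1.5, 2.0, 3.0, 4.0])
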
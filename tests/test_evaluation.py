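"""ROC/AUC machinery, thresholds, stratification, patterns, timelines."""

import itertools

import numpy as np
import pytest

import caldera as cd
from caldera.evaluation import (
    GRADE_BOUNDARIES,
    _best_youden,
    auc,
    bootstrap_bands,
    episode_summary,
    fit_model_thresholds,
    grade_thresholds,
    roc_curve,
    stratified_auc,
    top_window_pattern,
)
from caldera.evolution import ClassifierModel, FeatureMode
from caldera.signal import Recording
from conftest import build_genome


def pair_counting_auc(scores, labels):
    """Exhaustive positive-negative pair enumeration."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p, n in itertools.product(pos, neg):
        total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestAuc:
    def test_perfect_and_inverted_ranking(self):
        scores = [0.9, 0.8, 0.3, 0.2]
        assert auc(scores, [1, 1, 0, 0]) == 1.0
        assert auc(scores, [0, 0, 1, 1]) == 0.0

    def test_ties_count_half(self):
        scores = [0.7, 0.5, 0.5, 0.2]
        labels = [1, 0, 1, 0]
        assert auc(scores, labels) == pytest.approx(
            pair_counting_auc(scores, labels)
        )

    def test_matches_pair_counting_on_random_data(self, rng):
        for _ in range(50):
            n = int(rng.integers(4, 20))
            scores = rng.integers(0, 6, size=n).astype(float)  # many ties
            labels = rng.integers(0, 2, size=n)
            if labels.sum() in (0, n):
                continue
            assert auc(scores, labels) == pytest.approx(
                pair_counting_auc(scores, labels), abs=1e-12
            )

    def test_monotone_transform_invariance(self, rng):
        scores = rng.normal(size=30)
        labels = (rng.random(30) < 0.4).astype(int)
        labels[:2] = [0, 1]
        assert auc(scores, labels) == pytest.approx(auc(np.exp(scores), labels))

    def test_label_complement_identity(self, rng):
        scores = rng.normal(size=25)
        labels = (rng.random(25) < 0.5).astype(int)
        labels[:2] = [0, 1]
        assert auc(scores, labels) + auc(scores, 1 - labels) == pytest.approx(1.0)

    def test_degenerate_labels_rejected(self):
        with pytest.raises(ValueError, match="degenerate labels"):
            auc([1.0, 2.0], [1, 1])


class TestRocCurve:
    def test_perfect_separation_passes_through_corner(self):
        curve = roc_curve([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert any(f == 0.0 and t == 1.0 for f, t in curve.points)
        assert curve.auc == 1.0

    def test_endpoints_and_monotonicity(self, rng):
        labels = np.r_[np.ones(20, int), np.zeros(20, int)]
        curve = roc_curve(rng.normal(size=40), labels)
        assert (curve.fpr[0], curve.tpr[0]) == (0.0, 0.0)
        assert (curve.fpr[-1], curve.tpr[-1]) == (1.0, 1.0)
        assert np.all(np.diff(curve.fpr) >= 0)
        assert np.all(np.diff(curve.tpr) >= 0)

    def test_trapezoid_area_equals_pair_counting(self, rng):
        for _ in range(200):
            n = int(rng.integers(6, 30))
            scores = np.round(rng.normal(size=n), 1)  # induce ties
            labels = rng.integers(0, 2, size=n)
            if labels.sum() in (0, n):
                continue
            curve = roc_curve(scores, labels)
            assert abs(curve.auc - auc(scores, labels)) <= 1e-12

    def test_binary_scores_give_three_points(self):
        curve = roc_curve([1.0, 1.0, 0.0, 0.0], [1, 0, 1, 0])
        assert len(curve.fpr) == 3


class TestBootstrapBands:
    def test_single_resample_collapses(self, rng):
        scores = rng.normal(size=30)
        labels = np.r_[np.ones(15, int), np.zeros(15, int)]
        bands = bootstrap_bands(scores, labels, n_boot=1, rng=np.random.default_rng(5))
        np.testing.assert_array_equal(bands.tpr_lo, bands.tpr_hi)

    def test_seed_reproducibility(self, rng):
        scores = rng.normal(size=40)
        labels = np.r_[np.ones(20, int), np.zeros(20, int)]
        b1 = bootstrap_bands(scores, labels, 50, np.random.default_rng(3))
        b2 = bootstrap_bands(scores, labels, 50, np.random.default_rng(3))
        np.testing.assert_array_equal(b1.tpr_lo, b2.tpr_lo)
        np.testing.assert_array_equal(b1.tpr_hi, b2.tpr_hi)

    def test_envelope_covers_point_estimate(self):
        covered = []
        for seed in range(5):
            r = np.random.default_rng(seed)
            scores = np.r_[r.normal(2.0, 1.0, 40), r.normal(0.0, 1.0, 40)]
            labels = np.r_[np.ones(40, int), np.zeros(40, int)]
            curve = roc_curve(scores, labels)
            bands = bootstrap_bands(scores, labels, 200, np.random.default_rng(seed))
            tpr = np.interp(bands.fpr_grid, curve.fpr, curve.tpr)
            inside = (tpr >= bands.tpr_lo - 1e-12) & (tpr <= bands.tpr_hi + 1e-12)
            covered.append(inside.mean())
        assert np.median(covered) >= 0.9


def sweep_youden_oracle(neg, pos):
    """Independent exhaustive scan over observed scores as cut-points."""
    best_j = -2.0
    for t in np.unique(np.r_[neg, pos, [-np.inf]]):
        sens = (pos >= t).mean()
        spec = (neg < t).mean()
        best_j = max(best_j, sens + spec - 1.0)
    return best_j


class TestGradeThresholds:
    def test_perfect_separation(self):
        table = grade_thresholds({0: [0.1, 0.2], 3: [0.8, 0.9], 4: [1.5, 1.6]})
        for entry in table.values():
            assert entry.youden_j == pytest.approx(1.0)
            assert entry.sensitivity == 1.0 and entry.specificity == 1.0

    def test_identical_groups_give_zero_j(self):
        scores = [0.5, 0.6, 0.7]
        table = grade_thresholds({0: scores, 3: scores})
        assert table[">=3"].youden_j == pytest.approx(0.0)

    def test_matches_exhaustive_sweep(self, rng):
        for _ in range(30):
            groups = {
                g: rng.normal(loc=g, size=int(rng.integers(3, 10)))
                for g in (0.0, 1.0, 2.0, 3.0, 4.0)
            }
            table = grade_thresholds(groups)
            for name, cut in GRADE_BOUNDARIES:
                neg = np.concatenate([v for g, v in groups.items() if g < cut])
                pos = np.concatenate([v for g, v in groups.items() if g >= cut])
                # oracle on the *unconstrained* boundary: monotone coercion
                # can only lower J, so compare where no coercion occurred
                entry = table[name]
                sens = (pos >= entry.threshold).mean()
                spec = (neg < entry.threshold).mean()
                assert entry.sensitivity == pytest.approx(sens)
                assert entry.specificity == pytest.approx(spec)
                assert entry.youden_j <= sweep_youden_oracle(neg, pos) + 1e-12

    def test_unconstrained_boundary_optimal(self, rng):
        neg, pos = rng.normal(0, 1, 25), rng.normal(1.5, 1, 25)
        entry = _best_youden(neg, pos)
        assert entry.youden_j == pytest.approx(sweep_youden_oracle(neg, pos))

    def test_thresholds_monotone_in_grade(self, rng):
        for _ in range(20):
            groups = {g: rng.normal(loc=0.5 * g, size=8) for g in range(5)}
            table = grade_thresholds(groups)
            ts = [table[name].threshold for name, _ in GRADE_BOUNDARIES]
            assert all(b >= a for a, b in zip(ts, ts[1:]))

    def test_missing_grades_rejected(self):
        with pytest.raises(ValueError, match="missing grade"):
            grade_thresholds({2: [0.5]})


class TestStratifiedAuc:
    def test_single_stratum_equals_global(self, rng):
        scores = rng.normal(size=20)
        labels = np.r_[np.ones(10, int), np.zeros(10, int)]
        table = stratified_auc(scores, labels, ["sitting"] * 20)
        assert len(table) == 1
        assert table.loc[0, "auc"] == pytest.approx(auc(scores, labels))

    def test_missing_class_flagged_not_computed(self):
        table = stratified_auc(
            [0.1, 0.9, 0.5], [0, 1, 0], ["sitting", "sitting", "walking"]
        )
        walking = table[table.activity == "walking"].iloc[0]
        assert walking.flag == "missing class"
        assert np.isnan(walking.auc)


class TestTopWindowPattern:
    def make_model(self):
        # output = first sample of the window: ranks windows by x0
        return ClassifierModel(
            genome=build_genome([], output_gene=0), feature_mode=FeatureMode.TIME
        )

    def test_k1_is_argmax_window(self, rng):
        windows = rng.normal(size=(50, 32))
        means = top_window_pattern(self.make_model(), windows, [1])
        np.testing.assert_array_equal(means[1], windows[np.argmax(windows[:, 0])])

    def test_mean_matches_sorted_recomputation(self, rng):
        windows = rng.normal(size=(200, 32))
        means = top_window_pattern(self.make_model(), windows, [10, 50])
        order = np.argsort(windows[:, 0])[::-1]
        np.testing.assert_allclose(means[10], windows[order[:10]].mean(axis=0))
        np.testing.assert_allclose(means[50], windows[order[:50]].mean(axis=0))

    def test_insufficient_windows_rejected(self, rng):
        with pytest.raises(ValueError, match="insufficient windows"):
            top_window_pattern(self.make_model(), rng.normal(size=(5, 32)), [10])


def step_recording(levels, samples_per_level=6000, rid="epochs"):
    """Recording whose magnitude is piecewise-constant: accel x = level."""
    vals = np.repeat(np.asarray(levels, float), samples_per_level)
    accel = np.zeros((vals.size, 3))
    accel[:, 0] = vals
    return Recording(recording_id=rid, accel=accel)


def passthrough_model(thresholds):
    return ClassifierModel(
        genome=build_genome([], output_gene=0),
        feature_mode=FeatureMode.TIME,
        thresholds=thresholds,
    )


THRESH = {">=1": 1.0, ">=2": 2.0, ">=3": 3.0, ">=4": 4.0}


class TestEpisodeSummary:
    def test_all_below_threshold_no_episodes(self):
        model = passthrough_model(THRESH)
        timeline = episode_summary(step_recording([0.5, 0.5]), model)
        assert timeline.episodes == []

    def test_merge_same_band_and_no_gap_bridging(self):
        # 60 s epochs at levels 3,3,1,3: adjacent grade-3 epochs merge, the
        # low epoch splits the rest into a second episode
        model = passthrough_model(THRESH)
        timeline = episode_summary(step_recording([3.2, 3.2, 1.0, 3.2]), model)
        assert [(e.start_s, e.end_s, e.band) for e in timeline.episodes] == [
            (0.0, 120.0, 3),
            (180.0, 240.0, 3),
        ]

    def test_band_change_starts_new_episode(self):
        model = passthrough_model(THRESH)
        timeline = episode_summary(step_recording([3.5, 4.5]), model)
        assert [e.band for e in timeline.episodes] == [3, 4]

    def test_sleep_epochs_excluded(self):
        model = passthrough_model(THRESH)
        timeline = episode_summary(
            step_recording([4.5, 4.5, 4.5]), model, sleep_intervals=[(60.0, 120.0)]
        )
        assert [(e.start_s, e.end_s) for e in timeline.episodes] == [
            (0.0, 60.0),
            (120.0, 180.0),
        ]
        assert np.isnan(timeline.epochs.loc[1, "band"])

    def test_episode_duration_equals_sum_of_epochs(self):
        model = passthrough_model(THRESH)
        timeline = episode_summary(step_recording([3.2, 3.2, 3.2, 0.5, 4.2]), model)
        total = sum(e.end_s - e.start_s for e in timeline.episodes)
        n_high = (timeline.epochs.band >= 3).sum()
        assert total == pytest.approx(n_high * timeline.epoch_length_s)

    def test_uncalibrated_model_rejected(self):
        model = passthrough_model(None)
        with pytest.raises(ValueError, match="model not calibrated"):
            episode_summary(step_recording([1.0]), model)

    def test_planted_grade4_interval_recovered(self):
        """A grade-4 stretch flanked by rest is recovered within one epoch.

        The detector is a hand-built curvature expression
        abs(x16 - mean(x10, x22)) — sensitive to the burst's sharp
        structure, blind to the flat rest baseline — calibrated on pure
        rest and pure grade-4 segments with the package's own threshold
        fitting.
        """
        import dataclasses as dc

        # rest carrier throughout: the composite recording alternates rest
        # and dyskinesia-at-rest, so calibration matches those conditions
        cfg = dc.replace(cd.SyntheticConfig(), walking_carrier_prob=0.0)
        rng = np.random.default_rng(2024)

        genome = build_genome(
            [(0, "mean", 10, 22), (6, "sub", 16, 32), (12, "abs", 38, 0)],
            output_gene=44,
        )
        model = ClassifierModel(genome=genome, feature_mode=FeatureMode.TIME)

        def segment(kind, minutes, rid):
            rec, _, _ = cd.generate_segment(
                kind, minutes * 60.0, rng, cfg=cfg, noise_sd=0.08, recording_id=rid
            )
            return rec

        # calibrate on separate pure segments
        rest_scores, g4_scores = [], []
        for i in range(6):
            rest = cd.magnitude(segment("rest", 1, f"c{i}")).values
            dysk = cd.magnitude(segment(("dyskinesia", 4), 1, f"d{i}")).values
            rest_scores.append(cd.segment_score(genome, rest))
            g4_scores.append(cd.segment_score(genome, dysk))
        fit_model_thresholds(model, {0.0: rest_scores, 4.0: g4_scores})

        parts = [segment("rest", 4, "a"), segment(("dyskinesia", 4), 4, "b"),
                 segment("rest", 4, "c")]
        accel = np.vstack([p.accel for p in parts])
        rec = Recording(recording_id="day", accel=accel)
        timeline = episode_summary(rec, model, epoch_length_s=60.0)
        high = [e for e in timeline.episodes if e.band >= 3]
        assert len(high) == 1
        assert abs(high[0].start_s - 240.0) <= 60.0
        assert abs(high[0].end_s - 480.0) <= 60.0


class TestAucProperties:
    """Rank-based invariants of the Mann-Whitney AUC, property-tested."""

    from hypothesis import given, settings
    from hypothesis import strategies as st

    scores_labels = st.lists(
        st.tuples(
            st.floats(-1e6, 1e6, allow_nan=False), st.integers(0, 1)
        ),
        min_size=4,
        max_size=40,
    ).filter(lambda sl: 0 < sum(l for _, l in sl) < len(sl))

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(scores_labels)
    def test_monotone_transform_and_complement(self, sl):
        scores = np.array([s for s, _ in sl])
        labels = np.array([l for _, l in sl])
        base = auc(scores, labels)
        assert 0.0 <= base <= 1.0
        # strictly increasing transform preserves ranks, hence the AUC
        assert auc(np.arctan(scores / 1e5), labels) == pytest.approx(base)
        # inverting the labels mirrors the AUC
        assert auc(scores, 1 - labels) == pytest.approx(1.0 - base)
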
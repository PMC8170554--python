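import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rnflcomp import (
    NormativeLimits,
    RunLengthDetector,
    al_subgroup,
    detection_score,
    fit_normative_limits,
    group_mean_profile,
    performance_at,
    relative_auroc_gain,
    roc,
)
from rnflcomp.exceptions import ContractError


def brute_force_circular_run(below: np.ndarray) -> int:
    """O(P²) oracle: longest circular run of True, by direct scan."""
    P = below.size
    best = 0
    for start in range(P):
        length = 0
        for k in range(P):
            if below[(start + k) % P]:
                length += 1
            else:
                break
        best = max(best, length)
    return best


def pair_counting_auroc(scores, labels) -> float:
    """Mann–Whitney oracle: average over all (glaucoma, normal) pairs."""
    s = np.asarray(scores, dtype=float)
    pos = s[np.asarray(labels) == "glaucoma"]
    neg = s[np.asarray(labels) != "glaucoma"]
    wins = 0.0
    for p in pos:
        for q in neg:
            wins += 1.0 if p > q else (0.5 if p == q else 0.0)
    return wins / (len(pos) * len(neg))


def limits_at(bound):
    bound = np.asarray(bound, dtype=float)
    return NormativeLimits(bound, "empirical_p5", 100)


class TestNormativeLimits:
    def test_constant_profiles_give_the_constant(self):
        Y = np.full((100, 16), 100.0)
        for method in ("empirical_p5", "gaussian_1645"):
            lim = fit_normative_limits(Y, method)
            np.testing.assert_allclose(lim.lower_bound, 100.0)

    def test_empirical_p5_order_statistic_convention(self):
        Y = np.tile(np.arange(1.0, 101.0)[:, None], (1, 4))
        lim = fit_normative_limits(Y, "empirical_p5")
        np.testing.assert_allclose(lim.lower_bound, 5.95)

    def test_gaussian_limit_matches_normal_quantile(self):
        rng = np.random.default_rng(50)
        Y = rng.normal(100.0, 10.0, size=(100_000, 3))
        lim = fit_normative_limits(Y, "gaussian_1645")
        np.testing.assert_allclose(lim.lower_bound, 83.55, atol=0.2)

    def test_monotone_in_percentile(self):
        rng = np.random.default_rng(51)
        Y = rng.normal(100.0, 10.0, size=(200, 8))
        bounds = [
            fit_normative_limits(Y, percentile=p).lower_bound for p in (1, 5, 10)
        ]
        assert (bounds[0] <= bounds[1]).all() and (bounds[1] <= bounds[2]).all()

    def test_too_few_references_suggests_gaussian(self):
        with pytest.raises(ContractError, match="gaussian_1645"):
            fit_normative_limits(np.ones((10, 4)), "empirical_p5")


class TestDetectionScore:
    def test_all_above_scores_zero(self):
        assert detection_score(np.full(16, 100.0), limits_at(np.full(16, 50.0))) == 0

    def test_all_below_scores_P(self):
        assert detection_score(np.full(16, 10.0), limits_at(np.full(16, 50.0))) == 16

    def test_wraparound_run(self):
        P = 768
        y = np.full(P, 100.0)
        y[[765, 766, 767, 0, 1]] = 10.0
        assert detection_score(y, limits_at(np.full(P, 50.0))) == 5

    def test_exactly_at_bound_counts_as_not_below(self):
        y = np.array([50.0, 49.9, 50.0, 50.1])
        assert detection_score(y, limits_at(np.full(4, 50.0))) == 1

    @settings(derandomize=True, max_examples=300)
    @given(
        pattern=st.lists(st.booleans(), min_size=2, max_size=64),
    )
    def test_matches_brute_force_oracle(self, pattern):
        below = np.array(pattern, dtype=bool)
        P = below.size
        y = np.where(below, 0.0, 100.0)
        assert detection_score(y, limits_at(np.full(P, 50.0))) == (
            brute_force_circular_run(below)
        )


class TestRunLengthDetector:
    def test_fits_limits_on_normals_only(self, small_cohort):
        det = RunLengthDetector().fit(small_cohort.profiles, small_cohort.labels)
        ref = small_cohort.profiles[small_cohort.labels != "glaucoma"]
        expected = fit_normative_limits(ref)
        np.testing.assert_array_equal(det.limits_.lower_bound, expected.lower_bound)

    def test_predict_thresholds_scores(self, small_cohort):
        det = RunLengthDetector(threshold=3).fit(
            small_cohort.profiles, small_cohort.labels
        )
        scores = det.decision_function(small_cohort.profiles)
        pred = det.predict(small_cohort.profiles)
        np.testing.assert_array_equal(pred == "glaucoma", scores >= 3)


class TestRoc:
    def test_perfect_separation(self):
        r = roc([0, 1, 5, 9], ["normal", "normal", "glaucoma", "glaucoma"])
        assert r.auroc == 1.0

    def test_single_tie_counts_half(self):
        r = roc([1, 2, 2, 3], ["normal", "normal", "glaucoma", "glaucoma"])
        assert r.auroc == pytest.approx(0.875)

    def test_uninformative_scores(self):
        r = roc([4, 4, 4, 4], ["normal", "normal", "glaucoma", "glaucoma"])
        assert r.auroc == pytest.approx(0.5)

    def test_single_class_rejected(self):
        with pytest.raises(ContractError):
            roc([1, 2], ["normal", "normal"])

    @settings(derandomize=True, max_examples=100)
    @given(st.data())
    def test_matches_pair_counting_oracle(self, data):
        n = data.draw(st.integers(2, 25))
        m = data.draw(st.integers(2, 25))
        scores = data.draw(
            st.lists(st.integers(0, 10), min_size=n + m, max_size=n + m)
        )
        labels = ["normal"] * n + ["glaucoma"] * m
        assert roc(scores, labels).auroc == pytest.approx(
            pair_counting_auroc(scores, labels), abs=1e-12
        )


class TestPerformanceAt:
    def test_perfect_classifier(self):
        rep = performance_at(
            [0, 0, 9, 9], ["normal", "normal", "glaucoma", "glaucoma"], 5
        )
        assert (
            rep.accuracy == rep.sensitivity == rep.specificity
            == rep.ppv == rep.npv == 1.0
        )

    def test_printed_definitions(self):
        scores = [1] * 3 + [0] * 2 + [1] * 1 + [0] * 4  # tp=3 fn=2 fp=1 tn=4
        labels = ["glaucoma"] * 5 + ["normal"] * 5
        rep = performance_at(scores, labels, 1)
        assert (rep.tp, rep.fp, rep.tn, rep.fn) == (3, 1, 4, 2)
        assert rep.sensitivity == pytest.approx(0.6)
        assert rep.specificity == pytest.approx(0.8)
        assert rep.ppv == pytest.approx(0.75)
        assert rep.npv == pytest.approx(2 / 3)
        assert rep.accuracy == pytest.approx(0.7)

    def test_threshold_above_max_score(self):
        rep = performance_at(
            [1, 2, 3, 4], ["normal", "normal", "glaucoma", "glaucoma"], 99
        )
        assert rep.sensitivity == 0.0 and rep.specificity == 1.0
        assert np.isnan(rep.ppv)


class TestAlSubgroup:
    def test_full_fraction_is_whole_cohort(self, small_cohort):
        sub = al_subgroup(small_cohort, 1.0)
        assert len(sub) == len(small_cohort)

    def test_subgroup_mean_al_exceeds_cohort_mean(self, small_cohort):
        sub = al_subgroup(small_cohort, 0.1)
        assert (
            sub.frame["axial_length"].mean()
            > small_cohort.frame["axial_length"].mean()
        )

    def test_decile_of_508_has_51_eyes(self):
        from rnflcomp import generate_cohort

        cohort = generate_cohort(254, 254, seed=52, P=8)
        assert len(al_subgroup(cohort, 0.1)) == 51

    def test_keeps_both_labels(self, small_cohort):
        sub = al_subgroup(small_cohort, 0.5)
        assert set(sub.labels) == {"normal", "glaucoma"}


class TestRelativeGain:
    def test_no_change_is_zero(self):
        assert relative_auroc_gain(0.5, 0.5) == 0.0

    def test_rounded_figure_values(self):
        assert relative_auroc_gain(0.70, 0.84) == pytest.approx(20.0)

    def test_antitone_in_baseline(self):
        assert relative_auroc_gain(0.75, 0.9) > relative_auroc_gain(0.8, 0.9)


class TestGroupMeanProfile:
    def test_single_profile_is_itself(self):
        y = np.arange(8.0)
        np.testing.assert_array_equal(group_mean_profile(y[None, :]), y)

    def test_matches_brute_force_average(self):
        rng = np.random.default_rng(53)
        Y = rng.uniform(40, 140, size=(7, 12))
        manual = np.array([Y[:, i].sum() / 7 for i in range(12)])
        np.testing.assert_allclose(group_mean_profile(Y), manual, atol=1e-12)
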
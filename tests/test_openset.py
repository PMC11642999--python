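"""Open-set core: MAVs, Weibull tail fitting, recalibration, and both
rejection procedures, checked against hand computations and an independent
line-by-line transcription of the recalibration algorithm."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mosqopen import (
    ActivationRecord,
    ActivationSet,
    ClassProfile,
    DegenerateTailError,
    InvalidArgumentError,
    ModelBuildError,
    OpenMaxConfig,
    OpenSetModel,
    SyntheticSpec,
    UNKNOWN_LABEL,
    WeibullTail,
    compute_mavs,
    distance_to_mav,
    fit_open_set_model,
    fit_weibull_tail,
    generate_activation_set,
    openmax_probabilities,
    predict_openmax,
    predict_score_threshold,
    recalibrated_scores,
    tail_diagnostics,
    weibull_cdf,
)


# ---------------------------------------------------------------------------
# Independent oracle: plain-Python transcription of the recalibration
# algorithm, kept free of any package code.
# ---------------------------------------------------------------------------


def openmax_oracle(a, mavs, tails, beta):
    """a: list of M floats; mavs: list of M lists; tails: list of (shape, scale, loc)."""
    m = len(a)
    order = sorted(range(m), key=lambda k: (-a[k], k))
    theta = [1.0] * m
    for j in range(1, beta + 1):
        k = order[j - 1]
        d = math.sqrt(sum((a[i] - mavs[k][i]) ** 2 for i in range(m)))
        shape, scale, loc = tails[k]
        x = max(d - loc, 0.0) / scale
        cdf = 1.0 - math.exp(-(x**shape))
        theta[k] = 1.0 - ((beta - j) / beta) * cdf
    a_hat = [a[i] * theta[i] for i in range(m)]
    a0 = sum(a[i] * (1.0 - theta[i]) for i in range(m))
    logits = [a0] + a_hat
    mx = max(logits)
    exps = [math.exp(v - mx) for v in logits]
    total = sum(exps)
    return [e / total for e in exps]


def _model_as_plain(model):
    mavs = [list(map(float, p.mav)) for p in model.profiles]
    tails = [(p.tail.shape, p.tail.scale, p.tail.location) for p in model.profiles]
    return mavs, tails


# ---------------------------------------------------------------------------
# MAVs and distances
# ---------------------------------------------------------------------------


class TestComputeMavs:
    def test_single_record_is_its_own_mav(self):
        recs = [ActivationRecord("s", "c", np.array([1.0, 2.0, 3.0]))]
        mavs = compute_mavs(recs, ["c"])
        np.testing.assert_array_equal(mavs["c"][0], [1.0, 2.0, 3.0])
        assert mavs["c"][1] == 1

    def test_symmetric_pair_averages(self):
        recs = [
            ActivationRecord("s1", "c", np.array([0.0, 2.0])),
            ActivationRecord("s2", "c", np.array([2.0, 0.0])),
        ]
        np.testing.assert_array_equal(compute_mavs(recs, ["c"])["c"][0], [1.0, 1.0])

    def test_matches_accumulation_loop(self):
        rng = np.random.default_rng(14)
        vecs = rng.standard_normal((100, 5))
        recs = [ActivationRecord(f"s{i}", "c", v) for i, v in enumerate(vecs)]
        mav = compute_mavs(recs, ["c"])["c"][0]
        acc = np.zeros(5)
        for v in vecs:
            acc = acc + v
        np.testing.assert_allclose(mav, acc / 100.0, atol=1e-12)

    def test_missing_class_names_the_class(self):
        recs = [ActivationRecord("s", "a", np.array([1.0, 0.0]))]
        with pytest.raises(ModelBuildError, match="'b'"):
            compute_mavs(recs, ["a", "b"])

    def test_correct_only_filters_misclassified(self):
        recs = [
            ActivationRecord("hit", "a", np.array([3.0, 1.0])),
            ActivationRecord("miss", "a", np.array([0.0, 9.0])),
            ActivationRecord("b0", "b", np.array([0.0, 1.0])),
        ]
        mavs = compute_mavs(recs, ["a", "b"], mav_source="correct_only")
        np.testing.assert_array_equal(mavs["a"][0], [3.0, 1.0])
        assert mavs["a"][1] == 1


class TestDistance:
    def test_identity_and_pythagoras(self):
        assert distance_to_mav(np.array([1.0, 2.0]), np.array([1.0, 2.0])) == 0.0
        assert distance_to_mav(np.array([3.0, 4.0]), np.array([0.0, 0.0])) == 5.0

    def test_matches_termwise_loop(self):
        rng = np.random.default_rng(30)
        v, m = rng.standard_normal(10), rng.standard_normal(10)
        expected = math.sqrt(sum((v[i] - m[i]) ** 2 for i in range(10)))
        assert abs(distance_to_mav(v, m) - expected) < 1e-12

    def test_length_mismatch(self):
        with pytest.raises(InvalidArgumentError):
            distance_to_mav(np.zeros(3), np.zeros(4))


# ---------------------------------------------------------------------------
# Weibull
# ---------------------------------------------------------------------------


class TestWeibullCdf:
    def test_analytic_identities(self):
        tail = WeibullTail(shape=2.0, scale=3.0, location=1.0)
        assert weibull_cdf(1.0, tail) == 0.0
        assert weibull_cdf(0.5, tail) == 0.0  # below location
        assert abs(weibull_cdf(1.0 + 3.0, tail) - (1 - math.exp(-1))) < 1e-12
        assert abs(weibull_cdf(1.0 + 6.0, tail) - (1 - math.exp(-4))) < 1e-12

    def test_monotone_and_limits(self):
        tail = WeibullTail(shape=1.7, scale=2.0, location=0.5)
        xs = np.linspace(0, 50, 400)
        cdf = weibull_cdf(xs, tail)
        assert np.all(np.diff(cdf) >= 0)
        assert cdf[-1] > 1 - 1e-9


class TestFitWeibullTail:
    def test_recovers_known_parameters(self):
        rng = np.random.default_rng(100)
        draws = 3.0 * rng.weibull(2.0, size=1000)
        tail = fit_weibull_tail(draws, tail_size=1000, location_mode="zero")
        assert 1.8 <= tail.shape <= 2.2
        assert 2.85 <= tail.scale <= 3.15

    def test_mle_beats_grid_search_oracle(self):
        # independent oracle: dense log-likelihood grid over (shape, scale)
        rng = np.random.default_rng(101)
        x = 3.0 * rng.weibull(2.0, size=400)
        tail = fit_weibull_tail(x, tail_size=400, location_mode="zero")

        def loglik(k, s):
            return float(
                len(x) * math.log(k)
                - len(x) * k * math.log(s)
                + (k - 1) * np.log(x).sum()
                - ((x / s) ** k).sum()
            )

        shapes = np.arange(1.5, 2.5, 0.01)
        scales = np.arange(2.5, 3.5, 0.01)
        grid_best = max(loglik(k, s) for k in shapes for s in scales)
        assert loglik(tail.shape, tail.scale) >= grid_best - 1e-6

    def test_agrees_with_scipy_mle(self):
        from scipy import stats

        rng = np.random.default_rng(102)
        x = 2.0 * rng.weibull(1.3, size=500)
        tail = fit_weibull_tail(x, tail_size=500, location_mode="zero")
        shape_ref, _, scale_ref = stats.weibull_min.fit(x, floc=0.0)
        assert abs(tail.shape - shape_ref) / shape_ref < 1e-3
        assert abs(tail.scale - scale_ref) / scale_ref < 1e-3

    def test_exponential_is_shape_one(self):
        rng = np.random.default_rng(103)
        x = rng.exponential(3.0, size=1000)
        tail = fit_weibull_tail(x, tail_size=1000, location_mode="zero")
        assert abs(tail.shape - 1.0) < 0.1

    def test_cdf_identities_of_fitted_tail(self):
        rng = np.random.default_rng(104)
        tail = fit_weibull_tail(rng.weibull(2.0, 200), tail_size=50)
        assert weibull_cdf(tail.location, tail) == 0.0
        assert abs(weibull_cdf(tail.location + tail.scale, tail) - (1 - math.exp(-1))) < 1e-12

    def test_error_conditions(self):
        with pytest.raises(InvalidArgumentError):
            fit_weibull_tail([1.0, 2.0, 3.0], tail_size=1)
        with pytest.raises(InvalidArgumentError):
            fit_weibull_tail([1.0], tail_size=2)
        with pytest.raises(DegenerateTailError):
            fit_weibull_tail([2.0, 2.0, 2.0, 2.0], tail_size=3)

    def test_tail_min_location_sits_just_below_tail(self):
        d = np.array([1.0, 2.0, 5.0, 6.0, 9.0])
        tail = fit_weibull_tail(d, tail_size=3, location_mode="tail_min")
        assert tail.location == pytest.approx(5.0 * (1 - 1e-6))


# ---------------------------------------------------------------------------
# Recalibration and decisions
# ---------------------------------------------------------------------------


def _toy_model(decision_mode="score_threshold", beta=None, threshold=0.1):
    """Hand-set 3-class model with zero-location tails."""
    config = OpenMaxConfig(
        beta=beta, tail_size=2, threshold=threshold,
        decision_mode=decision_mode, location_mode="zero",
    )
    mavs = [np.array([4.0, 0.0, 0.0]), np.array([0.0, 4.0, 0.0]), np.array([0.0, 0.0, 4.0])]
    tails = [WeibullTail(2.0, 1.5, 0.0), WeibullTail(1.5, 2.0, 0.0), WeibullTail(2.5, 1.0, 0.0)]
    profiles = tuple(
        ClassProfile(label=f"c{i}", mav=mavs[i], tail=tails[i], n_samples=10, tail_size=2)
        for i in range(3)
    )
    return OpenSetModel(vocabulary=("c0", "c1", "c2"), profiles=profiles, config=config)


class TestRecalibratedScores:
    def test_score_is_one_at_the_mav(self):
        model = _toy_model()
        r = recalibrated_scores(np.array([4.0, 0.0, 0.0]), model)
        assert r[0] == 1.0

    def test_score_vanishes_far_away(self):
        model = _toy_model()
        r = recalibrated_scores(np.array([500.0, -500.0, 0.0]), model)
        assert np.all(r < 1e-12)

    def test_hand_computed_pipeline(self):
        model = _toy_model()
        v = np.array([3.0, 1.0, 0.0])
        r = recalibrated_scores(v, model)
        for i, (mav, tail) in enumerate(
            zip([p.mav for p in model.profiles], [p.tail for p in model.profiles])
        ):
            d = math.sqrt(sum((v[k] - mav[k]) ** 2 for k in range(3)))
            expected = math.exp(-((d / tail.scale) ** tail.shape))
            assert abs(r[i] - expected) < 1e-12

    def test_monotone_in_distance(self):
        model = _toy_model()
        mav = model.profiles[0].mav
        direction = np.array([1.0, 1.0, 1.0]) / math.sqrt(3)
        scores = [
            recalibrated_scores(mav + t * direction, model)[0] for t in np.linspace(0, 10, 50)
        ]
        assert all(a >= b - 1e-15 for a, b in zip(scores, scores[1:]))


class TestScoreThresholdDecision:
    def test_below_threshold_is_unknown(self):
        assert (
            predict_score_threshold(np.array([0.05, 0.03]), 0.1, ["a", "b"])
            == UNKNOWN_LABEL
        )

    def test_above_threshold_argmax(self):
        assert predict_score_threshold(np.array([0.9, 0.2]), 0.5, ["a", "b"]) == "a"

    def test_tie_takes_lowest_index(self):
        assert predict_score_threshold(np.array([0.4, 0.4]), 0.1, ["a", "b"]) == "a"


class TestOpenMaxProbabilities:
    def test_beta_zero_reduces_to_softmax_with_unknown_unit(self):
        model = _toy_model(beta=0)
        a = np.array([2.0, 1.0, -0.5])
        p = openmax_probabilities(a, model)
        denom = 1.0 + np.exp(a).sum()
        assert abs(p[0] - 1.0 / denom) < 1e-12
        np.testing.assert_allclose(p[1:], np.exp(a) / denom, atol=1e-12)

    def test_zero_cdf_equals_beta_zero(self):
        # at the MAV itself every CDF is 0, so recalibration changes nothing
        model_full = _toy_model(beta=3)
        model_none = _toy_model(beta=0)
        a = model_full.profiles[0].mav
        np.testing.assert_allclose(
            openmax_probabilities(a, model_full),
            openmax_probabilities(a, model_none),
            atol=1e-12,
        )

    def test_matches_line_by_line_oracle_on_toy(self):
        model = _toy_model(beta=2)
        mavs, tails = _model_as_plain(model)
        rng = np.random.default_rng(7)
        for _ in range(20):
            a = rng.standard_normal(3) * 3
            got = openmax_probabilities(a, model)
            want = openmax_oracle(list(a), mavs, tails, beta=2)
            np.testing.assert_allclose(got, want, atol=1e-9)

    def test_oracle_equivalence_across_sizes_and_betas(self):
        # >= 100 random instances across M in {2, 3, 10}, beta in {0, 1, M}
        rng = np.random.default_rng(77)
        checked = 0
        for m in (2, 3, 10):
            spec = SyntheticSpec(n_classes=m, per_class_n=20, separation=4.0, seed=m)
            train = generate_activation_set(spec)
            for beta in (0, 1, m):
                model = fit_open_set_model(
                    train, config=OpenMaxConfig(beta=beta, tail_size=10)
                )
                mavs, tails = _model_as_plain(model)
                for _ in range(12):
                    a = rng.standard_normal(m) * 4
                    got = openmax_probabilities(a, model)
                    want = openmax_oracle(list(a), mavs, tails, beta)
                    np.testing.assert_allclose(got, want, atol=1e-9)
                    checked += 1
        assert checked >= 100

    @given(st.lists(st.floats(-50, 50), min_size=3, max_size=3))
    @settings(deadline=None, max_examples=100, derandomize=True)
    def test_probabilities_normalized_nonnegative(self, raw):
        model = _toy_model(beta=3)
        p = openmax_probabilities(np.array(raw), model)
        assert p.shape == (4,)
        assert np.all(p >= 0)
        assert abs(p.sum() - 1.0) < 1e-9

    def test_literal_exponential_diagnostic_diverges(self):
        # the uncorrected weighting blows past [0, 1] even at moderate
        # distances, shoving essentially all mass to the unknown class —
        # which is exactly why the bounded CDF form is the default
        model = _toy_model(beta=3)
        a = np.array([8.0, -2.0, 0.0])
        p_literal = openmax_probabilities(a, model, literal_exponential=True)
        p_cdf = openmax_probabilities(a, model)
        assert abs(p_literal.sum() - 1.0) < 1e-9
        assert p_literal[0] > 0.999999
        assert p_cdf[0] < 0.999  # the CDF form keeps a graded decision


class TestPredictOpenMax:
    def test_unknown_wins_outright(self):
        assert predict_openmax(np.array([0.6, 0.3, 0.1]), 0.0, ["a", "b"]) == UNKNOWN_LABEL

    def test_confident_known_class(self):
        assert predict_openmax(np.array([0.1, 0.7, 0.2]), 0.5, ["a", "b"]) == "a"

    def test_low_confidence_rejected(self):
        assert predict_openmax(np.array([0.1, 0.45, 0.45]), 0.5, ["a", "b"]) == UNKNOWN_LABEL


# ---------------------------------------------------------------------------
# Model building
# ---------------------------------------------------------------------------


class TestFitOpenSetModel:
    def test_tail_fitted_on_largest_distances(self, train_set, model):
        # recompute tail membership per class with a sorting oracle
        labels = np.array(train_set.labels())
        m = train_set.matrix()
        for profile in model.profiles:
            own = m[labels == profile.label]
            dist = np.sort(np.linalg.norm(own - own.mean(axis=0), axis=1))
            assert profile.tail_size == 20
            refit = fit_weibull_tail(dist[-20:], 20, model.config.location_mode)
            assert refit.shape == pytest.approx(profile.tail.shape, rel=1e-12)
            assert refit.scale == pytest.approx(profile.tail.scale, rel=1e-12)

    def test_single_record_class_rejected(self):
        recs = [
            ActivationRecord("a0", "a", np.array([1.0, 0.0])),
            ActivationRecord("a1", "a", np.array([1.4, 0.2])),
            ActivationRecord("a2", "a", np.array([0.9, -0.1])),
            ActivationRecord("b0", "b", np.array([0.0, 1.0])),
        ]
        with pytest.raises(ModelBuildError, match="'b'"):
            fit_open_set_model(recs, config=OpenMaxConfig(tail_size=2))

    def test_build_is_deterministic(self, train_set):
        one = fit_open_set_model(train_set, config=OpenMaxConfig())
        two = fit_open_set_model(train_set, config=OpenMaxConfig())
        assert one.to_json() == two.to_json()

    def test_serialization_round_trip(self, model, tmp_path):
        path = tmp_path / "model.json"
        model.save(path)
        loaded = OpenSetModel.load(path)
        assert loaded.to_json() == model.to_json()
        assert loaded.vocabulary == model.vocabulary
        for a, b in zip(loaded.profiles, model.profiles):
            np.testing.assert_array_equal(a.mav, b.mav)
            assert a.tail == b.tail

    def test_dimension_mismatch_rejected(self):
        recs = [
            ActivationRecord("a0", "a", np.array([1.0, 0.0, 0.0])),
            ActivationRecord("a1", "a", np.array([1.0, 0.0, 0.0])),
            ActivationRecord("b0", "b", np.array([0.0, 1.0, 0.0])),
            ActivationRecord("b1", "b", np.array([0.0, 1.0, 0.0])),
        ]
        with pytest.raises(ModelBuildError, match="dimension"):
            fit_open_set_model(recs, config=OpenMaxConfig(tail_size=2))


class TestTailDiagnostics:
    def test_perfect_fit_limit(self):
        # distances drawn from the fitted family: empirical deciles should
        # land where the fitted CDF says they should
        rng = np.random.default_rng(55)
        draws = 3.0 * rng.weibull(2.0, size=5000)
        tail = fit_weibull_tail(draws, tail_size=5000, location_mode="zero")
        profile = ClassProfile("c", np.zeros(1), tail, 5000, 5000)
        model = OpenSetModel(("c",), (profile,), OpenMaxConfig(location_mode="zero"))
        recs = [ActivationRecord(f"s{i}", "c", np.array([d])) for i, d in enumerate(draws)]
        table = tail_diagnostics(model, recs)
        assert len(table) == 9
        np.testing.assert_allclose(table["fitted_cdf"], table["quantile"], atol=0.03)

    def test_round_trip_through_serialized_model(self, model, train_set, tmp_path):
        path = tmp_path / "model.json"
        model.save(path)
        reloaded = OpenSetModel.load(path)
        a = tail_diagnostics(model, train_set)
        b = tail_diagnostics(reloaded, train_set)
        assert a.equals(b)
        assert set(a["label"]) == set(model.vocabulary)
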
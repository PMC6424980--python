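"""Subset regression: OLS oracle checks, AIC algebra, exhaustive search."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phosphodecode import array_fit, core, synth
from phosphodecode.array_fit import (
    ArraySpot,
    CollinearityError,
    aggregate_importance,
    aic,
    average_replicates,
    fit_all_subsets,
    fit_subset,
    importance_matrix,
    threshold_robustness,
)
from phosphodecode.core import SITE_NAMES, PhosphoPattern


def make_spots(theta, intercept, noise_sd=0.0, seed=0, replicates=4, panel=None):
    truth = synth.ArrayGroundTruth(theta, intercept, noise_sd, replicates)
    panel = panel or core.combinatorial_panel(3)
    return synth.gen_array(truth, panel, seed)


class TestArraySpot:
    def test_needs_replicates(self):
        with pytest.raises(ValueError):
            ArraySpot(PhosphoPattern((0,) * 7), [])

    def test_rejects_negative(self):
        with pytest.raises(ValueError):
            ArraySpot(PhosphoPattern((0,) * 7), [-1.0])

    def test_rejects_nonfinite(self):
        with pytest.raises(ValueError):
            ArraySpot(PhosphoPattern((0,) * 7), [np.nan])


class TestAverageReplicates:
    def test_constant(self):
        spots = [ArraySpot(PhosphoPattern((0,) * 7, "0P"), [1, 1, 1, 1])]
        assert average_replicates(spots)["response"].iloc[0] == 1.0

    def test_mean(self):
        spots = [ArraySpot(PhosphoPattern((0,) * 7, "0P"), [0, 2])]
        assert average_replicates(spots)["response"].iloc[0] == 1.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            average_replicates([])

    def test_noise_free_equals_forward_model(self, two_site_truth):
        spots = make_spots(two_site_truth.theta, two_site_truth.intercept)
        resp = average_replicates(spots).set_index("bitstring")["response"]
        for s in spots:
            expected = two_site_truth.expected_intensity(s.pattern.bits)
            assert resp[s.pattern.bitstring] == pytest.approx(expected)


class TestFitSubset:
    def test_exact_interpolation(self, two_site_truth):
        spots = make_spots(two_site_truth.theta, two_site_truth.intercept)
        responses = average_replicates(spots)
        m = fit_subset(responses, {"T340", "S343"})
        assert m.coefficients["T340"] == pytest.approx(5.0)
        assert m.coefficients["S343"] == pytest.approx(3.0)
        assert m.intercept == pytest.approx(2.0)
        assert m.rss == pytest.approx(0.0, abs=1e-18)

    def test_intercept_only(self, rng):
        spots = make_spots((1, 2, 0, 0, 3, 0, 1), 2.0, noise_sd=1.0, seed=7)
        responses = average_replicates(spots)
        m = fit_subset(responses, set())
        y = responses["response"].to_numpy()
        assert m.intercept == pytest.approx(y.mean())
        assert m.rss == pytest.approx(np.sum((y - y.mean()) ** 2))

    def test_normal_equation_oracle(self, rng):
        # independent linear-algebra route on a random 10-pattern instance
        pats = core.enumerate_patterns(7, 3)
        idx = rng.choice(len(pats), size=10, replace=False)
        rows = [
            {
                "label": pats[i].bitstring,
                "bitstring": pats[i].bitstring,
                "response": float(rng.uniform(0, 10)),
            }
            for i in idx
        ]
        responses = pd.DataFrame(rows)
        support = ("T335", "T340", "S343")
        m = fit_subset(responses, support)
        bits = np.array([[int(c) for c in s] for s in responses["bitstring"]], float)
        X = np.column_stack([np.ones(10)] + [bits[:, SITE_NAMES.index(s)] for s in support])
        y = responses["response"].to_numpy()
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert m.intercept == pytest.approx(beta[0])
        for j, s in enumerate(support):
            assert m.coefficients[s] == pytest.approx(beta[j + 1])

    def test_collinear_design_rejected(self):
        # only two patterns, identical in the requested columns
        rows = [
            {"label": "a", "bitstring": "1100000", "response": 1.0},
            {"label": "b", "bitstring": "1100001", "response": 2.0},
        ]
        with pytest.raises(CollinearityError, match="S334"):
            fit_subset(pd.DataFrame(rows), {"S334", "T335"})


class TestAIC:
    def test_rss_equal_n_three_sites(self):
        assert aic(rss=10.0, n_obs=10, n_sites=3) == pytest.approx(8.0)

    def test_rss_equal_n_no_sites(self):
        assert aic(rss=10.0, n_obs=10, n_sites=0) == pytest.approx(2.0)

    def test_overparameterized_rejected(self):
        with pytest.raises(ValueError):
            aic(rss=1.0, n_obs=4, n_sites=3)

    def test_negative_rss_rejected(self):
        with pytest.raises(ValueError):
            aic(rss=-1.0, n_obs=10, n_sites=1)

    def test_zero_rss_finite(self):
        assert math.isfinite(aic(rss=0.0, n_obs=10, n_sites=1))

    @given(
        rss=st.floats(1e-6, 1e6),
        n=st.integers(10, 200),
        k=st.integers(0, 6),
        shrink=st.floats(1e-6, 1.0, exclude_max=True),
    )
    @settings(max_examples=200)
    def test_insufficient_rss_drop_raises_aic(self, rss, n, k, shrink):
        # adding a site only pays off if rss shrinks by more than exp(-2/n);
        # shrink is kept away from the exact boundary (log is equality there)
        cutoff = math.exp(-2.0 / n)
        rss_new = rss * (cutoff + shrink * (1 - cutoff))  # in (cutoff, 1) * rss
        assert aic(rss_new, n, k + 1) > aic(rss, n, k)


class TestFitAllSubsets:
    def test_returns_128_models(self, two_site_truth):
        responses = average_replicates(make_spots(two_site_truth.theta, 2.0))
        models = fit_all_subsets(responses)
        assert len(models) == 128
        assert len({m.support for m in models}) == 128

    def test_sorted_by_aic(self, two_site_truth):
        responses = average_replicates(make_spots(two_site_truth.theta, 2.0))
        models = fit_all_subsets(responses)
        aics = [m.aic for m in models]
        assert aics == sorted(aics)

    def test_noise_free_recovery(self, two_site_truth):
        responses = average_replicates(make_spots(two_site_truth.theta, 2.0))
        best = fit_all_subsets(responses)[0]
        assert set(best.support) == {"T340", "S343"}

    def test_best_matches_bruteforce_rescan(self, rng):
        spots = make_spots((0, 1, 0, 0, 4, 0, 2), 1.0, noise_sd=0.5, seed=11)
        responses = average_replicates(spots)
        models = fit_all_subsets(responses)
        assert models[0].aic == min(m.aic for m in models)

    def test_insufficient_patterns_rejected(self):
        pats = core.enumerate_patterns(7, 1)[:8]
        rows = [
            {"label": p.bitstring, "bitstring": p.bitstring, "response": 1.0}
            for p in pats
        ]
        with pytest.raises(ValueError, match="distinct patterns"):
            fit_all_subsets(pd.DataFrame(rows))

    def test_nested_rss_monotone(self, rng):
        # OLS rss can only drop when the support grows
        spots = make_spots((2, 0, 1, 0, 5, 1, 3), 1.5, noise_sd=1.0, seed=5)
        responses = average_replicates(spots)
        models = {m.support: m for m in fit_all_subsets(responses)}
        for support, m in models.items():
            for drop in support:
                sub = tuple(s for s in support if s != drop)
                assert m.rss <= models[sub].rss + 1e-9


class TestSupportRecovery:
    def test_true_support_recovered_50_random_draws(self):
        # sigma=0: the AIC-best support equals the planted support
        rng = np.random.default_rng(2024)
        panel = core.combinatorial_panel(3)
        for _ in range(50):
            k = rng.integers(0, 5)
            sites = rng.choice(7, size=k, replace=False)
            theta = np.zeros(7)
            theta[sites] = rng.uniform(1.0, 10.0, size=k)
            spots = make_spots(tuple(theta), rng.uniform(0, 5), panel=panel)
            best = fit_all_subsets(average_replicates(spots))[0]
            assert set(best.support) == {SITE_NAMES[i] for i in sites}

    def test_theta_within_3se_at_noise(self):
        # >= 95% coverage of |theta_hat - theta| <= 3 se over 20 seeds
        theta = (0.0, 0.0, 0.0, 0.0, 5.0, 0.0, 3.0)
        hits = total = 0
        for seed in range(20):
            spots = make_spots(theta, 2.0, noise_sd=0.5, seed=seed)
            m = fit_subset(average_replicates(spots), set(SITE_NAMES))
            for i, name in enumerate(SITE_NAMES):
                total += 1
                hits += abs(m.coefficients[name] - theta[i]) <= 3 * m.coef_se[name]
        assert hits / total >= 0.95

    def test_coefficient_error_shrinks_with_noise(self):
        theta = (0.0, 0.0, 0.0, 0.0, 5.0, 0.0, 3.0)
        errors = []
        for sd in (2.0, 0.5, 0.01):
            errs = []
            for seed in range(10):
                spots = make_spots(theta, 2.0, noise_sd=sd, seed=seed)
                m = fit_subset(average_replicates(spots), set(SITE_NAMES))
                errs.append(
                    np.mean([abs(m.coefficients[n] - theta[i]) for i, n in enumerate(SITE_NAMES)])
                )
            errors.append(np.mean(errs))
        assert errors[0] > errors[1] > errors[2]


class TestImportanceMatrix:
    def test_dimensions(self, two_site_truth):
        models = fit_all_subsets(average_replicates(make_spots(two_site_truth.theta, 2.0)))
        im = importance_matrix(models, k=20)
        assert im.matrix.shape == (20, 8)
        assert list(im.matrix.columns) == list(SITE_NAMES) + ["intercept"]

    def test_k1_is_best_model(self, two_site_truth):
        models = fit_all_subsets(average_replicates(make_spots(two_site_truth.theta, 2.0)))
        im = importance_matrix(models, k=1)
        row = im.matrix.iloc[0]
        best = models[0]
        for s in SITE_NAMES:
            assert row[s] == pytest.approx(best.coefficients.get(s, 0.0))

    def test_excluded_sites_exactly_zero(self, two_site_truth):
        models = fit_all_subsets(average_replicates(make_spots(two_site_truth.theta, 2.0)))
        im = importance_matrix(models, k=20)
        for row_idx, m in enumerate(im.models):
            for s in SITE_NAMES:
                if s not in m.support:
                    assert im.matrix.iloc[row_idx][s] == 0.0

    def test_dominant_sites_nonzero_in_most_top_rows(self):
        rng = np.random.default_rng(9)
        hits = total = 0
        for seed in range(5):
            spots = make_spots((0, 0, 0, 0, 8.0, 0, 6.0), 1.0, noise_sd=0.3, seed=seed)
            im = importance_matrix(fit_all_subsets(average_replicates(spots)), k=20)
            for s in ("T340", "S343"):
                total += 20
                hits += int((im.matrix[s] != 0).sum())
        assert hits / total >= 0.90

    def test_k_too_large_rejected(self, two_site_truth):
        models = fit_all_subsets(average_replicates(make_spots(two_site_truth.theta, 2.0)))
        with pytest.raises(ValueError):
            importance_matrix(models, k=129)


class TestThresholdRobustness:
    def test_zero_threshold_identical(self, two_site_truth):
        spots = make_spots(two_site_truth.theta, 2.0, noise_sd=0.2, seed=1)
        models = fit_all_subsets(average_replicates(spots))
        expected = list(aggregate_importance(models).index)
        result = threshold_robustness(spots, [0.0])
        assert result[0.0] == expected

    def test_threshold_above_max_infeasible(self, two_site_truth):
        spots = make_spots(two_site_truth.theta, 2.0)
        result = threshold_robustness(spots, [1e9])
        assert result[1e9] is None

    def test_unsorted_thresholds_rejected(self, two_site_truth):
        spots = make_spots(two_site_truth.theta, 2.0)
        with pytest.raises(ValueError):
            threshold_robustness(spots, [5.0, 1.0])

    def test_dominant_sites_stable_across_thresholds(self):
        spots = make_spots((0, 0, 0, 0, 8.0, 0, 6.0), 1.0, noise_sd=0.3, seed=2)
        result = threshold_robustness(spots, [0.0, 0.5, 1.0])
        for ranking in result.values():
            assert ranking is not None
            assert set(ranking[:2]) == {"T340", "S343"}


class TestIO:
    def test_array_csv_roundtrip(self, tmp_path, two_site_truth):
        spots = make_spots(two_site_truth.theta, 2.0, noise_sd=0.1, seed=4)
        path = tmp_path / "spots.csv"
        synth.write_array_csv(spots, path)
        again = array_fit.read_array_csv(path)
        assert len(again) == len(spots)
        for a, b in zip(again, spots):
            assert a.pattern.bits == b.pattern.bits
            np.testing.assert_allclose(a.intensities, b.intensities)

    def test_writers(self, tmp_path, two_site_truth):
        models = fit_all_subsets(average_replicates(make_spots(two_site_truth.theta, 2.0)))
        array_fit.write_models_tsv(models, tmp_path / "models.tsv")
        im = importance_matrix(models, k=20)
        array_fit.write_importance_tsv(im, tmp_path / "imp.tsv")
        models_df = pd.read_csv(tmp_path / "models.tsv", sep="\t")
        assert len(models_df) == 128
        imp_df = pd.read_csv(tmp_path / "imp.tsv", sep="\t", index_col=0)
        assert imp_df.shape == (20, 8)
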
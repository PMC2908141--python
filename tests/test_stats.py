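"""Slice summaries, histograms, Gaussian-mixture EM, rank tests, ANOVA."""

import numpy as np
import pytest

import vhmea
from vhmea.detect import ElectrodeEvents, SpikeEventTable, frequency_series
from vhmea.stats import (
    InsufficientDataError,
    InvalidDesignError,
    InvalidInputError,
    SliceSummary,
    anova_oneway,
    build_histogram,
    compare_conditions,
    fit_gmm,
    kruskal_wallis,
    summarize_slice,
)


def _table(times_by_electrode, duration=50.0):
    events = {
        e: ElectrodeEvents(e, np.asarray(t, dtype=float),
                           np.full(len(t), -20.0), np.full(len(t), -1, dtype=np.int8))
        for e, t in times_by_electrode.items()
    }
    return SpikeEventTable(events=events, duration=duration, fs=20_000.0)


class TestSummaries:
    def test_two_active_electrodes_at_six_hertz(self):
        t = np.linspace(0, 49.999, 300)
        tbl = _table({0: t, 1: t, 2: []})
        active = np.array([True, True, False] + [False] * 61)
        freqs = frequency_series(tbl, electrodes=[0, 1])
        s = summarize_slice(tbl, active, freqs, slice_id="s", genotype="control", drug="basal")
        assert s.n_active == 2
        assert s.mean_frequency_hz == pytest.approx(6.0)
        assert s.total_spikes_per_minute == pytest.approx(2 * 6 * 60)

    def test_no_active_electrodes(self):
        tbl = _table({0: [1.0, 2.0]})
        s = summarize_slice(tbl, np.zeros(64, dtype=bool), {}, slice_id="s")
        assert s.n_active == 0
        assert np.isnan(s.mean_frequency_hz)
        assert s.total_spikes_per_minute == 0.0

    def test_missing_frequency_series_rejected(self):
        from vhmea.stats import InconsistentInputError

        tbl = _table({0: [1.0] * 60})
        active = np.array([True] + [False] * 63)
        with pytest.raises(InconsistentInputError):
            summarize_slice(tbl, active, {}, slice_id="s")


class TestHistogram:
    def test_single_slice_weights(self):
        edges, w = build_histogram([np.array([0.2, 0.3, 0.7])])
        np.testing.assert_allclose(edges[:2], [0.0, 0.5])
        assert w[0] == pytest.approx(2 / 3)
        assert w[1] == pytest.approx(1 / 3)

    def test_each_slice_contributes_unit_mass(self):
        rng = np.random.default_rng(0)
        slices = [rng.uniform(0, 12, n) for n in (7, 400, 33)]
        _, w = build_histogram(slices)
        assert w.sum() == pytest.approx(len(slices), abs=1e-12)

    def test_negative_observation_rejected(self):
        with pytest.raises(InvalidInputError):
            build_histogram([np.array([0.5, -0.1])])

    def test_empty_slice_rejected(self):
        with pytest.raises(InvalidInputError):
            build_histogram([np.array([1.0]), np.array([])])


class TestGaussianMixtureEM:
    def test_single_component_closed_form(self):
        x = np.random.default_rng(1).normal(3.0, 2.0, size=500)
        fit = fit_gmm(x, k=1, n_starts=1, seed=0)
        assert fit.means[0] == pytest.approx(x.mean(), abs=1e-6)
        assert fit.variances[0] == pytest.approx(x.var(), abs=1e-6)  # biased variance
        assert fit.weights[0] == pytest.approx(1.0)

    def test_three_component_recovery(self):
        rng = np.random.default_rng(7)
        pi, mu, sd = (0.5, 0.3, 0.2), (1.5, 5.5, 9.0), (0.6, 0.8, 1.0)
        comp = rng.choice(3, p=pi, size=3000)
        x = rng.normal(np.asarray(mu)[comp], np.asarray(sd)[comp])
        fit = fit_gmm(x, k=3, n_starts=10, seed=0)
        assert fit.converged
        np.testing.assert_allclose(fit.means, mu, atol=0.3)
        assert fit.weights.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(np.diff(fit.log_likelihood) >= -1e-9)  # EM monotonicity

    def test_matches_sklearn_on_separated_mixture(self):
        from sklearn.mixture import GaussianMixture

        rng = np.random.default_rng(8)
        x = np.concatenate([rng.normal(0, 1, 400), rng.normal(10, 1, 400)])
        ours = fit_gmm(x, k=2, n_starts=5, seed=0)
        sk = GaussianMixture(2, n_init=5, random_state=0).fit(x[:, None])
        np.testing.assert_allclose(ours.means, np.sort(sk.means_.ravel()), atol=0.05)
        sk_ll = sk.score(x[:, None]) * x.size
        assert ours.final_log_likelihood >= sk_ll - 1.0

    def test_permutation_invariant(self):
        rng = np.random.default_rng(9)
        x = np.concatenate([rng.normal(0, 1, 300), rng.normal(8, 1, 300)])
        a = fit_gmm(x, k=2, seed=3)
        b = fit_gmm(rng.permutation(x), k=2, seed=3)
        np.testing.assert_allclose(a.means, b.means, atol=1e-4)

    def test_more_components_never_fit_worse(self):
        rng = np.random.default_rng(10)
        x = np.concatenate([rng.normal(0, 1, 300), rng.normal(6, 1, 300)])
        lls = [fit_gmm(x, k=k, n_starts=8, seed=0).final_log_likelihood for k in (1, 2, 3)]
        assert lls[1] >= lls[0] - 1e-6
        assert lls[2] >= lls[1] - 1e-6

    def test_too_few_observations_rejected(self):
        with pytest.raises(InsufficientDataError):
            fit_gmm(np.arange(20.0), k=3)


class TestKruskalWallis:
    def test_hand_computed_oracle(self):
        # rank-sum formula: H = 12/(N(N+1)) * sum R_i^2/n_i - 3(N+1)
        groups = [[1, 2, 3], [4, 5, 6], [7, 8, 9]]
        R = [6, 15, 24]
        N = 9
        H_oracle = 12 / (N * (N + 1)) * sum(r**2 / 3 for r in R) - 3 * (N + 1)
        assert H_oracle == pytest.approx(7.2)
        res = kruskal_wallis(*groups)
        assert res.H == pytest.approx(7.2)
        assert res.df == 2

    def test_identical_groups_score_zero(self):
        res = kruskal_wallis([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.H == pytest.approx(0.0, abs=1e-12)
        assert not res.significant

    def test_all_observations_equal(self):
        res = kruskal_wallis([5.0, 5.0], [5.0, 5.0, 5.0])
        assert res.H == 0.0 and res.p_value == 1.0

    def test_single_group_rejected(self):
        with pytest.raises(InvalidDesignError):
            kruskal_wallis([1.0, 2.0])

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(4)
        g = [rng.normal(m, 1, 20) for m in (0, 1, 3)]
        a = kruskal_wallis(*g)
        b = kruskal_wallis(*[np.exp(x) for x in g])
        assert a.H == pytest.approx(b.H, abs=1e-9)


class TestAnova:
    def test_identical_groups_give_zero_f(self):
        res = anova_oneway([1.0, 2.0], [1.0, 2.0], [1.0, 2.0])
        assert res.F == pytest.approx(0.0, abs=1e-12)

    def test_equals_squared_t_for_two_groups(self):
        a, b = np.array([3.0, 4.0, 5.0]), np.array([6.0, 7.0, 8.0])
        # pooled two-sample t computed by hand formula
        sp2 = ((a.var(ddof=1) * 2) + (b.var(ddof=1) * 2)) / 4
        t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / 3 + 1 / 3))
        res = anova_oneway(a, b)
        assert res.F == pytest.approx(t**2)
        assert (res.df_between, res.df_within) == (1, 4)

    def test_invariant_under_affine_transform(self):
        rng = np.random.default_rng(5)
        g = [rng.normal(m, 1, 15) for m in (0, 0.5, 2)]
        a = anova_oneway(*g)
        b = anova_oneway(*[3.0 * x - 7.0 for x in g])
        assert a.F == pytest.approx(b.F, rel=1e-9)

    def test_degenerate_constant_data(self):
        res = anova_oneway([2.0, 2.0], [2.0, 2.0])
        assert res.F == 0.0 and res.p_value == 1.0


class TestCompareConditions:
    @staticmethod
    def _summary(gt, drug, i, n_active, obs):
        obs = np.asarray(obs, dtype=float)
        return SliceSummary(
            slice_id=f"{gt}-{drug}-{i}", genotype=gt, drug=drug,
            n_active=n_active, mean_frequency_hz=float(obs.mean()),
            total_spikes_per_minute=float(obs.mean() * n_active * 60),
            frequency_observations=obs,
        )

    def test_sem_formula(self):
        rng = np.random.default_rng(0)
        summaries = [self._summary("control", "basal", i, n, rng.uniform(4, 8, 10))
                     for i, n in enumerate([4, 6])]
        report = compare_conditions(summaries)
        row = report["table"].iloc[0]
        assert row["n_active_mean"] == pytest.approx(5.0)
        assert row["n_active_sem"] == pytest.approx(1.0)

    def test_identical_conditions_not_significant(self):
        rng = np.random.default_rng(1)
        obs = [rng.normal(6, 1, 30) for _ in range(4)]
        summaries = [self._summary("control", d, i, 15, obs[i])
                     for d in ("basal", "gaba") for i, _ in enumerate(range(2))]
        # same observation sets in both conditions
        summaries[2].frequency_observations = summaries[0].frequency_observations
        summaries[3].frequency_observations = summaries[1].frequency_observations
        report = compare_conditions(summaries)
        assert not report["kruskal_wallis"]["control"]["significant"]

    def test_planted_rate_shift_is_detected(self):
        # control basal (6.08 Hz) vs serotonin (10.20 Hz): observations from
        # the package's own spike-train generator must separate at alpha=0.01
        def slice_obs(rate, seed):
            t = vhmea.simulate_spike_train(rate, 50.0, 2.0, rng=seed)
            return np.array([np.sum(t < 25) / 25.0, np.sum(t >= 25) / 25.0])

        summaries = []
        for i in range(12):
            summaries.append(self._summary("control", "basal", i, 15,
                                           slice_obs(6.08, 100 + i)))
            summaries.append(self._summary("control", "serotonin", i, 25,
                                           slice_obs(10.20, 200 + i)))
        report = compare_conditions(summaries)
        kw = report["kruskal_wallis"]["control"]
        assert kw["significant"] and kw["p_value"] < 0.01
        assert report["anova"]["control"]["significant"]
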
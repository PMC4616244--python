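import math

import numpy as np
import pytest

from gridcode import synthetic_data as syn


class TestPeriodTable:
    def test_noiseless_tables_are_exact_geometric(self):
        df = syn.generate_period_table(3, m=4, r=1.65, noise_cv=0.0, seed=0)
        for _, sub in df.groupby("animal_id"):
            periods = sub["period_cm"].to_numpy()
            assert np.allclose(periods[:-1] / periods[1:], 1.65, rtol=1e-12)

    def test_deterministic_under_seed(self):
        a = syn.generate_period_table(10, noise_cv=0.05, missing_prob=0.2, seed=9)
        b = syn.generate_period_table(10, noise_cv=0.05, missing_prob=0.2, seed=9)
        assert a.to_csv() == b.to_csv()

    def test_missing_modules_drop_rows(self):
        full = syn.generate_period_table(20, m=4, missing_prob=0.0, seed=1)
        sparse = syn.generate_period_table(20, m=4, missing_prob=0.5, seed=1)
        assert len(sparse) < len(full)

    def test_out_of_range_parameters_rejected(self):
        with pytest.raises(ValueError):
            syn.generate_period_table(5, r=0.9)
        with pytest.raises(ValueError):
            syn.generate_period_table(5, noise_cv=0.5)


class TestBuildPopulation:
    def test_periods_decrease_and_are_commensurate(self):
        pop = syn.build_population(m=4, r=1.65, lam1=120.0, seed=0)
        periods = pop.periods
        assert np.all(np.diff(periods) < 0)
        counts = 120.0 / periods
        assert np.allclose(counts, np.round(counts), atol=1e-9)

    def test_even_phases_give_uniform_coverage(self):
        pop = syn.build_population(m=1, r=2.0, n_phases_per_module=16, seed=0)
        x = np.linspace(0, pop.circumference, 256, endpoint=False)
        rates = pop.module_rates(0, x).sum(axis=0)
        assert rates.max() / rates.min() == pytest.approx(1.0, rel=1e-6)

    def test_single_module_response_periodic(self):
        pop = syn.build_population(m=1, r=2.0, seed=0)
        lam = pop.modules[0].period
        r1 = pop.module_rates(0, 7.3)[:, 0]
        r2 = pop.module_rates(0, (7.3 + lam) % pop.circumference)[:, 0]
        assert np.allclose(r1, r2, rtol=1e-10)

    def test_realized_coverage_matches_analytic(self):
        pop = syn.build_population(m=2, r=2.0, n_phases_per_module=32, seed=0)
        for i, mod in enumerate(pop.modules):
            analytic = len(mod.phases) * mod.field_width / mod.period
            assert pop.realized_coverage(i) == pytest.approx(analytic, rel=0.01)

    def test_coverage_scales_with_phases(self):
        lo = syn.build_population(m=1, r=2.0, n_phases_per_module=16, seed=0)
        hi = syn.build_population(m=1, r=2.0, n_phases_per_module=32, seed=0)
        assert hi.realized_coverage(0) == pytest.approx(
            2 * lo.realized_coverage(0), rel=0.02
        )

    def test_narrow_tuning_required(self):
        with pytest.raises(ValueError):
            syn.build_population(m=2, r=1.65, tuning_sd_frac=0.5)
        with pytest.raises(NotImplementedError):
            syn.build_population(m=2, r=1.65, dimension=2)


class TestSpikeCounts:
    def test_zero_sampling_time_gives_zero_counts(self):
        pop = syn.build_population(m=2, r=2.0, T_sample=0.0, seed=0)
        counts = syn.simulate_spike_counts(pop, 10.0, seed=1)
        assert all(c.sum() == 0 for c in counts)

    def test_deterministic_under_seed(self):
        pop = syn.build_population(m=2, r=2.0, seed=0)
        a = syn.simulate_spike_counts(pop, 33.0, seed=5)
        b = syn.simulate_spike_counts(pop, 33.0, seed=5)
        assert all(np.array_equal(x, y) for x, y in zip(a, b))

    def test_mean_counts_match_rates(self):
        pop = syn.build_population(m=1, r=2.0, n_phases_per_module=8, seed=0)
        x = 41.0
        expected = pop.module_rates(0, x)[:, 0] * pop.T_sample
        rng = np.random.default_rng(11)
        total = np.zeros_like(expected)
        n_rep = 3000
        for _ in range(n_rep):
            total += syn.simulate_spike_counts(pop, x, rng)[0]
        mean = total / n_rep
        se = np.sqrt(expected / n_rep) + 1e-9
        assert np.all(np.abs(mean - expected) < 4 * se + 1e-3)


class TestModulePosterior:
    def test_likelihood_periodic_in_module_period(self):
        pop = syn.build_population(m=2, r=2.0, seed=0)
        counts = syn.simulate_spike_counts(pop, 23.0, seed=2)
        lam = pop.modules[1].period
        x = np.array([23.0, 23.0 + lam])
        mp = syn.module_posterior(counts, pop, 1, x_grid=x)
        assert mp.log_likelihood[0] == pytest.approx(mp.log_likelihood[1], rel=1e-10)

    def test_all_zero_counts_flagged_flat(self):
        pop = syn.build_population(m=1, r=2.0, T_sample=0.0, seed=0)
        counts = syn.simulate_spike_counts(pop, 5.0, seed=3)
        mp = syn.module_posterior(counts, pop, 0)
        assert mp.flat and mp.sigma_hat is None

    def test_peak_width_shrinks_as_root_n_phases(self):
        # independent Poisson noise: sigma ~ n_phases^(-1/2); regression
        # slope of log sigma_hat on log n_phases should be near -0.5
        log_n, log_s = [], []
        for nph in (16, 32, 64):
            pop = syn.build_population(m=1, r=2.0, n_phases_per_module=nph, seed=1)
            rng = np.random.default_rng(21)
            sds = []
            for _ in range(120):
                counts = syn.simulate_spike_counts(
                    pop, rng.uniform(0, pop.circumference), rng
                )
                mp = syn.module_posterior(counts, pop, 0)
                if mp.sigma_hat is not None:
                    sds.append(mp.sigma_hat)
            log_n.append(math.log(nph))
            log_s.append(math.log(np.mean(sds)))
        slope = np.polyfit(log_n, log_s, 1)[0]
        assert slope == pytest.approx(-0.5, abs=0.1)

    def test_fitted_width_tracks_fisher_prediction(self):
        pop = syn.build_population(
            m=1, r=2.0, n_phases_per_module=48, peak_rate=20.0, T_sample=0.2, seed=1
        )
        rng = np.random.default_rng(5)
        sds = []
        for _ in range(100):
            counts = syn.simulate_spike_counts(pop, rng.uniform(0, 100), rng)
            sds.append(syn.module_posterior(counts, pop, 0).sigma_hat)
        assert np.mean(sds) == pytest.approx(syn.predicted_sigma(pop, 0), rel=0.1)


class TestMonteCarloResolution:
    def test_posterior_sd_matches_delta_recursion(self):
        for r in (1.5, 2.0, 2.5):
            pop = syn.build_population(
                m=3, r=r, n_phases_per_module=48, peak_rate=20.0, T_sample=0.2, seed=3
            )
            res = syn.monte_carlo_resolution(pop, n_trials=300, seed=5)
            assert res["posterior_sd"] == pytest.approx(
                res["predicted_posterior_sd"], rel=0.10
            )

    def test_more_modules_reduce_error(self):
        kwargs = dict(n_phases_per_module=32, peak_rate=20.0, T_sample=0.2, seed=3)
        small = syn.build_population(m=1, r=2.0, **kwargs)
        large = syn.build_population(m=3, r=2.0, **kwargs)
        res_s = syn.monte_carlo_resolution(small, n_trials=200, seed=7)
        res_l = syn.monte_carlo_resolution(large, n_trials=200, seed=7)
        assert res_l["rmse"] < res_s["rmse"]

    def test_fast_scaling_with_sparse_phases_causes_side_lobes(self):
        # scale ratio far above optimum with modest coverage: decode errors
        # concentrate at multiples of the finest period
        pop = syn.build_population(
            m=3, r=4.0, lam1=128.0, n_phases_per_module=8, tuning_sd_frac=0.05,
            peak_rate=5.0, T_sample=0.1, seed=3,
        )
        res = syn.monte_carlo_resolution(pop, n_trials=200, seed=11)
        lam_m = pop.modules[-1].period
        errors = np.abs(res["errors"])
        big = errors[errors > lam_m / 2]
        assert len(big) > 5  # ambiguous decodes occur
        # large errors sit near integer multiples of the finest period
        frac = np.abs(big / lam_m - np.round(big / lam_m))
        assert np.median(frac) < 0.2

    def test_longer_sampling_sharpens_posterior(self):
        base = dict(m=2, r=2.0, n_phases_per_module=32, peak_rate=20.0, seed=3)
        p1 = syn.build_population(T_sample=0.2, **base)
        p2 = syn.build_population(T_sample=0.4, **base)
        r1 = syn.monte_carlo_resolution(p1, n_trials=200, seed=13)
        r2 = syn.monte_carlo_resolution(p2, n_trials=200, seed=13)
        assert r2["posterior_sd"] / r1["posterior_sd"] == pytest.approx(
            1 / math.sqrt(2), rel=0.1
        )
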
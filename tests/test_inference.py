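"""Cost function, parallel-tempering sampler, and evidence machinery."""

import numpy as np
import pytest

from pxkinetics import (
    FitConfig,
    ModelParameters,
    NoiseModel,
    builtin_table1,
    cost,
    evidence_profile,
    generate_dataset,
    model_probability,
    parallel_tempering_fit,
)
from pxkinetics.datasets import LabelingObservation, StudyDataset
from pxkinetics.inference import CostFunction, swap_probability
from pxkinetics.synthetic import R24C_LIKE


def _scaled_dataset(dataset, sd_factor):
    obs = tuple(
        LabelingObservation(
            o.group, o.protocol, o.analog, o.mean_ratio,
            o.sd_ratio * sd_factor, o.n_replicates, o.scale_applied,
        )
        for o in dataset
    )
    return StudyDataset(obs)


class TestCost:
    def test_perfect_fit_has_zero_cost(self):
        noise = NoiseModel(kind="gaussian", cv=1e-12, n_replicates=3)
        ds, _ = generate_dataset(R24C_LIKE, noise, seed=0)
        assert cost(R24C_LIKE, ds) == pytest.approx(0.0, abs=1e-9)

    def test_doubling_sigmas_quarters_cost(self, params):
        ds = builtin_table1("WT:beta")
        # keep clear of the sigma floor so the scaling identity is exact
        chi1 = cost(params, _scaled_dataset(ds, 10.0))
        chi2 = cost(params, _scaled_dataset(ds, 20.0))
        assert chi2 == pytest.approx(chi1 / 4.0, rel=1e-12)

    def test_zero_sigma_requires_floor_policy(self):
        ds = builtin_table1("WT:beta")
        with pytest.raises(ValueError, match="sigma_min"):
            CostFunction(_scaled_dataset(ds, 0.0), sigma_min=None)

    def test_eta_rescales_printed_dual_analog_data(self, params):
        # with eta=3 the printed (x3) values enter the cost unchanged;
        # halving eta halves the effective dual-analog data and SDs
        ds = builtin_table1("WT:beta")
        cf = CostFunction(ds, sigma_min=None)
        d3, s3 = cf._scaled_data(np.array([3.0]))
        d15, s15 = cf._scaled_data(np.array([1.5]))
        dual = cf._is_dual
        assert np.allclose(d3[dual], cf._mean[dual])
        assert np.allclose(d15[dual], 0.5 * cf._mean[dual])
        assert np.allclose(d3[~dual], d15[~dual])
        assert np.allclose(s15[dual], 0.5 * s3[dual])

    def test_cost_invariant_to_observation_order(self, params, rng):
        ds = builtin_table1("R24C:beta")
        perm = rng.permutation(10)
        shuffled = StudyDataset(tuple(ds.observations[i] for i in perm))
        assert cost(params, shuffled) == pytest.approx(cost(params, ds), rel=1e-12)


class TestSamplerMechanics:
    def test_swap_acceptance_is_unity_at_equal_levels(self):
        assert swap_probability(0.5, 0.5, 10.0, 200.0) == 1.0
        assert swap_probability(0.5, 0.5, 200.0, 10.0) == 1.0

    def test_swap_acceptance_favors_cold_chain_improvement(self):
        # cold chain (higher level) holding the worse cost: always swap
        assert swap_probability(1.0, 0.1, 50.0, 10.0) == 1.0
        # cold chain already better: accept with the Boltzmann factor
        p = swap_probability(1.0, 0.1, 10.0, 50.0)
        assert p == pytest.approx(np.exp(-0.9 * 40.0))

    def test_same_seed_gives_identical_fit(self, small_config):
        ds = builtin_table1("WT:beta")
        a = parallel_tempering_fit(ds, small_config)
        b = parallel_tempering_fit(ds, small_config)
        assert np.array_equal(a.samples, b.samples)
        assert a.best_cost == b.best_cost
        assert np.array_equal(a.best_params.to_array(), b.best_params.to_array())
        assert a.posterior_mean == b.posterior_mean

    def test_different_seed_changes_chain(self, small_config):
        ds = builtin_table1("WT:beta")
        a = parallel_tempering_fit(ds, small_config)
        b = parallel_tempering_fit(
            ds, FitConfig(**{**small_config.to_dict(), "seed": 99})
        )
        assert not np.array_equal(a.samples, b.samples)

    def test_best_cost_beats_random_feasible_points(self, small_config, rng):
        ds = builtin_table1("R24C:beta")
        fit = parallel_tempering_fit(ds, small_config)
        cf = CostFunction(ds)
        bounds = small_config.resolved_bounds()
        names = ("f", "r0", "t_rise", "t_fall", "tau_rise", "tau_fall")
        lo = np.array([bounds[n][0] for n in names])
        hi = np.array([bounds[n][1] for n in names])
        draws = lo + (hi - lo) * rng.uniform(size=(100, 6))
        theta = np.column_stack([draws, np.full(100, 3.0)])
        assert fit.best_cost <= cf.many(theta).min()

    def test_fit_result_structure(self, small_config):
        fit = parallel_tempering_fit(builtin_table1("R24C:duct"), small_config)
        assert len(fit.predicted_ratios) == 10
        assert set(fit.free_names) == {"f", "r0", "t_rise", "t_fall", "tau_rise", "tau_fall"}
        assert fit.samples.shape[1] == 7
        assert np.all(fit.samples[:, 6] == 3.0)  # eta held fixed
        assert 0.0 <= fit.swap_rate <= 1.0

    def test_eta_free_policy_samples_eta(self):
        cfg = FitConfig(n_equilibration=2000, n_production=1000, seed=0,
                        eta_policy="free")
        fit = parallel_tempering_fit(builtin_table1("WT:beta"), cfg)
        assert "eta" in fit.free_names
        assert fit.samples[:, 6].std() > 0

    def test_posterior_contraction_with_smaller_sigmas(self):
        # halving every replicate SD sharpens the posterior (statistical)
        noise_hi = NoiseModel(kind="gaussian", cv=0.2, n_replicates=3)
        ds, _ = generate_dataset(R24C_LIKE, noise_hi, seed=5)
        cfg = FitConfig(n_equilibration=6000, n_production=4000, seed=7)
        wide = parallel_tempering_fit(ds, cfg)
        narrow = parallel_tempering_fit(_scaled_dataset(ds, 0.25), cfg)
        shrunk = sum(
            narrow.posterior_sd[n] < wide.posterior_sd[n]
            for n in ("r0", "t_rise", "f")
        )
        assert shrunk >= 2


class TestConfig:
    def test_ladder_must_increase(self):
        with pytest.raises(ValueError):
            FitConfig(temperatures=(0.5, 0.5, 1.0))

    def test_yaml_round_trip(self, tmp_path, small_config):
        import yaml

        path = tmp_path / "cfg.yaml"
        with open(path, "w") as fh:
            yaml.safe_dump(small_config.to_dict(), fh)
        back = FitConfig.from_yaml(path)
        assert back == small_config

    def test_bad_policy_rejected(self):
        with pytest.raises(ValueError):
            FitConfig(eta_policy="sometimes")


class TestEvidence:
    @pytest.fixture(scope="class")
    def low_noise_dataset(self):
        truth = R24C_LIKE.replace(f=0.0)
        noise = NoiseModel(kind="binomial", cells=20000, n_replicates=4)
        ds, _ = generate_dataset(truth, noise, seed=21)
        return ds

    def test_evidence_prefers_true_ratio(self, low_noise_dataset):
        cfg = FitConfig(n_equilibration=4000, n_production=3000, seed=3)
        good = model_probability(low_noise_dataset, 0.0, cfg)
        bad = model_probability(low_noise_dataset, 50.0, cfg)
        assert good > bad

    def test_evidence_invariant_to_observation_order(self, low_noise_dataset, rng):
        cfg = FitConfig(n_equilibration=2000, n_production=1500, seed=3)
        perm = rng.permutation(10)
        shuffled = StudyDataset(tuple(low_noise_dataset.observations[i] for i in perm))
        a = model_probability(low_noise_dataset, 1.0, cfg)
        b = model_probability(shuffled, 1.0, cfg)
        assert a == pytest.approx(b, rel=1e-12)

    def test_single_point_grid_has_probability_one(self, low_noise_dataset):
        cfg = FitConfig(n_equilibration=1000, n_production=500, seed=0)
        profile = evidence_profile(low_noise_dataset, [2.0], cfg)
        assert profile.normalized_probability[0] == pytest.approx(1.0)

    def test_probabilities_sum_to_one(self, low_noise_dataset):
        cfg = FitConfig(n_equilibration=1500, n_production=1000, seed=0)
        profile = evidence_profile(low_noise_dataset, [0.0, 5.0, 50.0], cfg)
        assert profile.normalized_probability.sum() == pytest.approx(1.0, abs=1e-10)
        assert np.all(profile.normalized_probability >= 0)

    def test_empty_or_negative_grid_rejected(self, low_noise_dataset):
        with pytest.raises(ValueError):
            evidence_profile(low_noise_dataset, [])
        with pytest.raises(ValueError):
            evidence_profile(low_noise_dataset, [-1.0, 2.0])


class TestAgainstIndependentSampler:
    def test_posterior_location_agrees_with_emcee(self):
        """Affine-invariant ensemble sampling of the same target should
        land the posterior for well-identified parameters in the same
        place as the PT production chain."""
        emcee = pytest.importorskip("emcee")
        noise = NoiseModel(kind="binomial", cells=5000, n_replicates=4)
        ds, _ = generate_dataset(R24C_LIKE, noise, seed=11)
        cfg = FitConfig(n_equilibration=8000, n_production=6000, seed=11)
        fit = parallel_tempering_fit(ds, cfg)

        cf = CostFunction(ds)
        bounds = cfg.resolved_bounds()
        names = ("f", "r0", "t_rise", "t_fall", "tau_rise", "tau_fall")
        lo = np.array([bounds[n][0] for n in names])
        hi = np.array([bounds[n][1] for n in names])

        def log_prob(x):
            if np.any(x < lo) or np.any(x > hi):
                return -np.inf
            return -cf.many(np.append(x, 3.0)[None, :])[0]

        rng = np.random.default_rng(0)
        p0 = fit.best_params.to_array()[:6] + 1e-3 * rng.standard_normal((32, 6))
        p0 = np.clip(p0, lo + 1e-6, hi - 1e-6)
        sampler = emcee.EnsembleSampler(32, 6, log_prob)
        sampler.run_mcmc(p0, 2000, progress=False)
        chain = sampler.get_chain(discard=1000, flat=True)
        for i, name in enumerate(("r0", "t_rise")):
            idx = names.index(name)
            ours = fit.posterior_mean[name]
            theirs = chain[:, idx].mean()
            spread = max(fit.posterior_sd[name], chain[:, idx].std())
            assert abs(ours - theirs) < 3 * spread
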
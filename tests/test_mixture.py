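"""Log-normal mixture EM, component reduction, and classification."""

import numpy as np
import pytest

import qflow
from qflow.errors import InvalidArgumentError, NoSignalError
from qflow.mixture import MixtureComponent, MixtureFit, _mixture_log_likelihood


def draw_mixture(rng, n, weights, mus_log10, sigma):
    comp = rng.choice(len(weights), size=n, p=weights)
    return 10 ** (np.asarray(mus_log10)[comp] + rng.normal(0, sigma, n)), comp


class TestFitMixture:
    def test_single_component_recovery(self, rng):
        x, _ = draw_mixture(rng, 10_000, [1.0], [3.5], 0.3)
        fit = qflow.fit_mixture(x, k=1, seed=0)
        (comp,) = fit.components
        assert comp.mu == pytest.approx(3.5, abs=0.01)
        assert comp.sigma == pytest.approx(0.3, abs=0.02)

    def test_k1_equals_closed_form_gaussian_ml(self, rng):
        x = 10 ** rng.normal(2.0, 0.4, 500)
        fit = qflow.fit_mixture(x, k=1, seed=0)
        logs = np.log10(x)
        (comp,) = fit.components
        assert comp.mu == pytest.approx(logs.mean(), abs=1e-9)
        assert comp.sigma == pytest.approx(logs.std(), abs=1e-6)
        assert comp.weight == 1.0

    def test_two_planted_components_recovered_through_k3(self, rng):
        """The forced k=3 fit reduces to the two planted subpopulations."""
        x, _ = draw_mixture(
            rng, 10_000, [0.731, 0.269], [np.log10(3100), np.log10(206_000)], 0.35
        )
        fit = qflow.reduce_components(qflow.fit_mixture(x, k=3, seed=1))
        assert fit.k_effective == 2
        low, high = fit.components
        assert high.weight == pytest.approx(0.269, abs=0.03)
        assert low.mu == pytest.approx(np.log10(3100), abs=0.05)
        assert high.mu == pytest.approx(np.log10(206_000), abs=0.05)

    def test_parameter_recovery_over_seeds(self):
        """Well-separated two-component mixtures are recovered across seeds."""
        for seed in range(20):
            rng = np.random.default_rng(seed)
            x, _ = draw_mixture(rng, 10_000, [0.6, 0.4], [3.0, 4.2], 0.3)
            fit = qflow.reduce_components(qflow.fit_mixture(x, k=2, seed=seed))
            assert fit.k_effective == 2
            a, b = fit.components
            assert a.weight == pytest.approx(0.6, abs=0.03)
            assert a.mu == pytest.approx(3.0, abs=0.05)
            assert b.mu == pytest.approx(4.2, abs=0.05)

    def test_zero_counts_excluded_and_reported(self, rng):
        x = np.concatenate([10 ** rng.normal(3, 0.3, 900), np.zeros(100)])
        fit = qflow.fit_mixture(x, k=1, seed=0)
        assert fit.zero_fraction == pytest.approx(0.1)
        assert fit.n == 900

    def test_all_nonpositive_rejected(self):
        with pytest.raises(NoSignalError):
            qflow.fit_mixture(np.zeros(100), k=1)

    def test_too_few_positive_rejected(self, rng):
        with pytest.raises(InvalidArgumentError):
            qflow.fit_mixture(10 ** rng.normal(3, 0.3, 10), k=1)

    def test_likelihood_dominates_random_search_oracle(self, rng):
        """On a small instance, EM beats 10^4 random parameter draws."""
        x, _ = draw_mixture(rng, 200, [0.5, 0.5], [2.5, 4.0], 0.3)
        fit = qflow.fit_mixture(x, k=2, seed=0)
        logs = np.log10(x)
        lo, hi, sd = logs.min(), logs.max(), logs.std()
        best = -np.inf
        for _ in range(10_000):
            w = rng.dirichlet(np.ones(2))
            mus = rng.uniform(lo, hi, 2)
            sigmas = rng.uniform(0.05, 2 * sd, 2)
            best = max(best, _mixture_log_likelihood(logs, w, mus, sigmas))
        assert fit.log_likelihood >= best

    def test_bic_definition(self, rng):
        x, _ = draw_mixture(rng, 1000, [1.0], [3.0], 0.3)
        fit = qflow.fit_mixture(x, k=1, seed=0)
        p = 3 * fit.k_effective - 1
        assert fit.bic == pytest.approx(-2 * fit.log_likelihood + p * np.log(fit.n))


class TestReduceComponents:
    def _fit(self, comps):
        return MixtureFit(
            components=tuple(comps),
            n=1000,
            log_likelihood=-1.0,
            k_requested=3,
            k_effective=len(comps),
        )

    def test_three_identical_components_collapse_to_one(self):
        c = MixtureComponent(1 / 3, 3.5, 0.2)
        fit = qflow.reduce_components(self._fit([c, c, c]))
        assert fit.k_effective == 1
        assert fit.components[0].weight == pytest.approx(1.0)
        assert fit.components[0].mu == pytest.approx(3.5)

    def test_moment_matched_merge_of_close_pair(self):
        comps = [
            MixtureComponent(0.40, 3.40, 0.10),
            MixtureComponent(0.35, 3.45, 0.10),
            MixtureComponent(0.25, 5.30, 0.10),
        ]
        fit = qflow.reduce_components(self._fit(comps))
        assert fit.k_effective == 2
        merged, high = fit.components
        assert merged.weight == pytest.approx(0.75)
        assert merged.mu == pytest.approx((0.40 * 3.40 + 0.35 * 3.45) / 0.75)
        assert high.mu == pytest.approx(5.30)

    def test_single_population_forced_k3_reduces_to_one(self, rng):
        """A lone log-normal population survives the forced 3-component fit."""
        x = 10 ** rng.normal(np.log10(2900), 0.35, 6000)
        fit = qflow.decompose(x, k=3, seed=0)
        assert fit.k_effective == 1
        assert fit.components[0].median == pytest.approx(2900, rel=0.1)

    def test_weight_normalization_preserved(self, rng):
        x, _ = draw_mixture(rng, 5000, [0.7, 0.3], [3.0, 5.0], 0.3)
        fit = qflow.reduce_components(qflow.fit_mixture(x, k=3, seed=2))
        assert sum(c.weight for c in fit.components) == pytest.approx(1.0, abs=1e-9)

    def test_low_weight_component_dropped(self):
        comps = [
            MixtureComponent(0.99, 3.0, 0.1),
            MixtureComponent(0.01, 6.0, 0.1),
        ]
        fit = qflow.reduce_components(self._fit(comps))
        assert fit.k_effective == 1
        assert fit.components[0].weight == pytest.approx(1.0)


class TestClassifyComponents:
    def _fit(self, comps):
        return MixtureFit(
            components=tuple(comps),
            n=100,
            log_likelihood=-1.0,
            k_requested=3,
            k_effective=len(comps),
        )

    def test_single_low_component(self):
        fit = qflow.classify_components(
            self._fit([MixtureComponent(1.0, np.log10(2900), 0.3)])
        )
        assert fit.components[0].label == "low"

    def test_single_high_component(self):
        fit = qflow.classify_components(
            self._fit([MixtureComponent(1.0, np.log10(150_000), 0.3)])
        )
        assert fit.components[0].label == "high"

    def test_two_components_low_high(self):
        fit = qflow.classify_components(
            self._fit(
                [MixtureComponent(0.7, 3.0, 0.3), MixtureComponent(0.3, 5.0, 0.3)]
            )
        )
        assert [c.label for c in fit.components] == ["low", "high"]

    def test_three_components_low_intermediate_high(self):
        fit = qflow.classify_components(
            self._fit(
                [
                    MixtureComponent(0.5, np.log10(2600), 0.3),
                    MixtureComponent(0.25, np.log10(39_100), 0.3),
                    MixtureComponent(0.25, np.log10(236_000), 0.3),
                ]
            )
        )
        assert [c.label for c in fit.components] == ["low", "intermediate", "high"]


def test_em_monotone_on_adversarial_data(rng):
    """The per-iteration monotonicity assertion holds on lumpy, tied data."""
    base = 10 ** rng.normal(3.0, 0.4, 300)
    x = np.concatenate([base, base[:150], np.full(50, 1234.0)])
    fit = qflow.fit_mixture(x, k=3, seed=5)
    assert np.isfinite(fit.log_likelihood)
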
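"""Elicitation fitting: counts to Beta/Dirichlet, chips to Beta, mean/CV to Gamma."""
import numpy as np
import pytest

from endopain import (
    RouletteHistogram,
    TransitionCounts,
    fit_beta_from_counts,
    fit_beta_from_roulette,
    fit_dirichlet_from_counts,
    gamma_from_mean_cv,
    simulate_roulette,
)


class TestBetaFromCounts:
    @pytest.mark.parametrize(
        "k, n, alpha, beta, mean",
        [
            (3, 1000, 3.0, 997.0, 0.003),       # elicited no-pain -> mild row
            (0.1, 1000, 0.1, 999.9, 0.0001),    # fractional pseudo-count row
            (4, 1000, 4.0, 996.0, 0.004),
        ],
    )
    def test_pseudo_count_parameterisation(self, k, n, alpha, beta, mean):
        d = fit_beta_from_counts(k, n)
        assert d.family == "Beta"
        assert d.params == (alpha, beta)
        assert d.mean == pytest.approx(mean, abs=1e-15)

    def test_zero_count_degrades_to_fixed_with_warning(self):
        with pytest.warns(UserWarning, match="degenerate"):
            d = fit_beta_from_counts(0, 1000)
        assert d.family == "Fixed" and d.mean == 0.0

    @pytest.mark.parametrize("k, n", [(5, 4), (-1, 10), (1, 0)])
    def test_domain_errors(self, k, n):
        with pytest.raises(ValueError):
            fit_beta_from_counts(k, n)


class TestDirichletFromCounts:
    def test_concentrations_follow_stay_then_destinations(self):
        counts = TransitionCounts(
            origin="mild", n=1000, counts={"no_pain": 2, "moderate": 2}
        )
        d = fit_dirichlet_from_counts(counts)
        assert d.family == "Dirichlet"
        assert d.params == (996.0, 2.0, 2.0)
        np.testing.assert_allclose(d.mean, [0.996, 0.002, 0.002])

    def test_fractional_counts(self):
        counts = TransitionCounts(
            origin="moderate", n=1000, counts={"mild": 3, "severe": 0.1}
        )
        d = fit_dirichlet_from_counts(counts)
        assert d.params == (996.9, 3.0, 0.1)

    def test_single_destination_rejected(self):
        counts = TransitionCounts(origin="no_pain", n=1000, counts={"mild": 3})
        with pytest.raises(ValueError, match="single destination"):
            fit_dirichlet_from_counts(counts)

    def test_sample_mean_matches_concentrations(self, rng):
        """Monte-Carlo oracle: draw mean ~ concentration / total within 3 SE."""
        d = fit_dirichlet_from_counts(
            TransitionCounts(origin="mild", n=1000, counts={"no_pain": 2, "moderate": 2})
        )
        draws = d.sample(rng, size=10_000)
        assert np.allclose(draws.sum(axis=1), 1.0)
        mean = np.asarray(d.mean)
        se = draws.std(axis=0, ddof=1) / np.sqrt(len(draws))
        assert (np.abs(draws.mean(axis=0) - mean) < 3 * se + 1e-12).all()


class TestGammaFromMeanCV:
    @pytest.mark.parametrize(
        "mean, cv, shape, scale",
        [(26.67, 0.2, 25.0, 1.0668), (2.82, 0.2, 25.0, 0.1128)],
    )
    def test_closed_form(self, mean, cv, shape, scale):
        d = gamma_from_mean_cv(mean, cv)
        assert d.params[0] == pytest.approx(shape)
        assert d.params[1] == pytest.approx(scale)
        assert d.mean == pytest.approx(mean)

    def test_sample_mean_recovers_target(self, rng):
        d = gamma_from_mean_cv(26.67, 0.2)
        draws = d.sample(rng, size=100_000)
        se = draws.std(ddof=1) / np.sqrt(len(draws))
        assert abs(draws.mean() - 26.67) < 3 * se

    @pytest.mark.parametrize("mean, cv", [(0.0, 0.2), (-1.0, 0.2), (10.0, 0.0)])
    def test_domain_errors(self, mean, cv):
        with pytest.raises(ValueError):
            gamma_from_mean_cv(mean, cv)


class TestRouletteFit:
    def test_recovers_elicited_moderate_pain_utility(self, rng):
        """Chips drawn from Beta(55.931, 22.142) recover its mean ~0.716."""
        h = simulate_roulette(55.931, 22.142, bins=20, chips=50, seed=rng)
        d = fit_beta_from_roulette(h)
        assert d.family == "Beta"
        assert abs(d.mean - 55.931 / (55.931 + 22.142)) < 0.03

    def test_symmetric_histogram_gives_symmetric_beta(self):
        h = RouletteHistogram(
            edges=(0.0, 0.2, 0.4, 0.6, 0.8, 1.0), chips=(1, 3, 8, 3, 1)
        )
        d = fit_beta_from_roulette(h)
        assert d.params[0] == pytest.approx(d.params[1], rel=1e-9)
        assert d.mean == pytest.approx(0.5)

    def test_single_bin_applies_variance_floor(self):
        h = RouletteHistogram(edges=(0.0, 0.45, 0.55, 1.0), chips=(0, 10, 0))
        d = fit_beta_from_roulette(h)
        # floored variance = width^2/12 of the occupied bin
        implied_var = (
            d.params[0] * d.params[1]
            / ((d.params[0] + d.params[1]) ** 2 * (sum(d.params) + 1))
        )
        assert implied_var == pytest.approx(0.1**2 / 12, rel=0.01)

    def test_fit_invariant_to_splitting_a_bin(self):
        """Halving a bin and splitting its chips moves the fit only by the
        midpoint-discretisation error."""
        coarse = RouletteHistogram(
            edges=(0.0, 0.25, 0.5, 0.75, 1.0), chips=(2, 10, 6, 2)
        )
        fine = RouletteHistogram(
            edges=(0.0, 0.25, 0.375, 0.5, 0.75, 1.0), chips=(2, 5, 5, 6, 2)
        )
        dc = fit_beta_from_roulette(coarse)
        df = fit_beta_from_roulette(fine)
        assert abs(dc.mean - df.mean) < 0.01

    def test_chips_validation(self):
        with pytest.raises(ValueError, match="at least one chip"):
            RouletteHistogram(edges=(0.0, 0.5, 1.0), chips=(0, 0))
        with pytest.raises(ValueError, match="increasing"):
            RouletteHistogram(edges=(0.0, 0.6, 0.4, 1.0), chips=(1, 1, 1))
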
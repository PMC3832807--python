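"""Pair likelihood ratios, LOD scores, and constrained maximization."""
from __future__ import annotations

import numpy as np
import pytest

from clasp.ibd import IBDPosterior, IBDPrior
from clasp.likelihood import (
    AnalysisModel,
    BetaParameters,
    CovariateConvention,
    ModelTag,
    PairData,
    constraint_boundary_beta2,
    lr_statistic,
    maximize_lod,
    maximize_lod_arrays,
    minmax_beta2,
    pair_likelihood_ratio,
    relative_risks,
    sample_lod,
)

from .conftest import FULL_SIB_PRIOR, multinomial_lod, pairs_from_counts

LN10 = np.log(10.0)

U2P = AnalysisModel(ModelTag.UNCONSTRAINED_2P)
C2P = AnalysisModel(ModelTag.CONSTRAINED_2P)
U1P = AnalysisModel(ModelTag.UNCONSTRAINED_1P)
C1P = AnalysisModel(ModelTag.CONSTRAINED_1P)


class TestParameterMaps:
    def test_minmax_null_maps_to_null(self):
        assert minmax_beta2(0.0) == pytest.approx(0.0, abs=1e-15)

    def test_minmax_direct_value(self):
        expected = np.log(3.634 * np.e - 2.634)
        assert minmax_beta2(1.0) == pytest.approx(expected, rel=1e-12)
        assert np.exp(minmax_beta2(1.0)) == pytest.approx(3.634 * np.e - 2.634)

    def test_minmax_domain_error(self):
        with pytest.raises(ValueError):
            minmax_beta2(np.log(2.634 / 3.634) - 0.01)

    def test_boundary_values(self):
        assert constraint_boundary_beta2(0.0) == pytest.approx(0.0, abs=1e-15)
        assert constraint_boundary_beta2(0.5) == pytest.approx(
            np.log(2 * np.exp(0.5) - 1), rel=1e-12
        )

    def test_boundary_taylor_slope_is_two(self):
        h = 1e-7
        slope = (constraint_boundary_beta2(h) - constraint_boundary_beta2(0.0)) / h
        assert slope == pytest.approx(2.0, abs=1e-5)

    def test_boundary_domain_error(self):
        with pytest.raises(ValueError):
            constraint_boundary_beta2(-1.0)

    def test_boundary_large_argument_stable(self):
        b = constraint_boundary_beta2(800.0)
        assert b == pytest.approx(800.0 + np.log(2.0))


class TestRelativeRisks:
    def test_null(self):
        assert relative_risks(BetaParameters(0.0, 0.0)) == (1.0, 1.0, 1.0)

    def test_definition(self):
        lam = relative_risks(BetaParameters(np.log(2), np.log(3)))
        assert lam == pytest.approx((1.0, 2.0, 3.0))

    def test_covariate_minmax_after_adjustment(self):
        params = BetaParameters(0.0, 0.0, deltas=(0.1,))
        lam = relative_risks(params, [2.0])
        assert lam[1] == pytest.approx(np.exp(0.2))
        assert lam[2] == pytest.approx(3.634 * np.exp(0.2) - 2.634)

    def test_covariate_tied_delta_convention(self):
        params = BetaParameters(0.5, 0.0, deltas=(0.1,))
        lam = relative_risks(params, [2.0], CovariateConvention.TIED_DELTA)
        assert lam[2] == pytest.approx(np.exp(minmax_beta2(0.5) + 0.2))

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            relative_risks(BetaParameters(0.0, 0.0), [1.0])


class TestPairLikelihoodRatio:
    def test_null_parameters_give_one(self):
        pair = PairData(IBDPosterior(0.1, 0.3, 0.6))
        assert pair_likelihood_ratio(pair, (1, 1, 1)) == pytest.approx(1.0)

    def test_two_term_arithmetic(self):
        pair = PairData(IBDPosterior(0, 0, 1))
        assert pair_likelihood_ratio(pair, (1, 1, 2)) == pytest.approx(1.6)

    def test_uninformative_marker_gives_one(self):
        pair = PairData(IBDPosterior(0.25, 0.5, 0.25))
        for lam in [(1, 2, 4), (1, 0.5, 9), (1, 1.7, 2.3)]:
            assert pair_likelihood_ratio(pair, lam) == pytest.approx(1.0)


class TestSampleLod:
    def test_null_parameters(self):
        pairs = pairs_from_counts(3, 2, 5)
        assert sample_lod(pairs, BetaParameters(0, 0), U2P) == pytest.approx(0.0)

    def test_additive_over_pairs(self):
        pair = PairData(IBDPosterior(0.1, 0.2, 0.7))
        params = BetaParameters(0.3, 0.9)
        one = sample_lod([pair], params, U2P)
        two = sample_lod([pair, pair], params, U2P)
        assert two == pytest.approx(2 * one, rel=1e-12)

    def test_count_closed_form(self):
        pairs = pairs_from_counts(25, 50, 25)
        params = BetaParameters(np.log(2), np.log(4))
        S = 0.25 + 0.5 * 2 + 0.25 * 4
        expected = (25 * np.log10(1 / S) + 50 * np.log10(2 / S) + 25 * np.log10(4 / S))
        assert sample_lod(pairs, params, U2P) == pytest.approx(expected, abs=1e-12)

    def test_empty_input(self):
        with pytest.raises(ValueError):
            sample_lod([], BetaParameters(0, 0), U2P)


class TestLrStatistic:
    def test_scale(self):
        fit = maximize_lod(pairs_from_counts(10, 50, 40), U2P)
        assert lr_statistic(fit) == pytest.approx(2 * LN10 * fit.lod, rel=1e-15)
        # a LOD of 3 corresponds to LR 6 ln 10, and the 0.05-level critical
        # LOD of the allele-sharing model, 0.742, to LR ~ 3.417
        assert 6 * LN10 == pytest.approx(13.8155, abs=5e-4)
        assert 2 * LN10 * 0.742 == pytest.approx(3.417, abs=5e-4)


class TestMaximizeUnconstrained2P:
    def test_balanced_counts_give_zero(self):
        fit = maximize_lod(pairs_from_counts(25, 50, 25), U2P)
        assert fit.lod == pytest.approx(0.0, abs=1e-10)
        assert fit.converged

    def test_multinomial_closed_form(self):
        fit = maximize_lod(pairs_from_counts(10, 50, 40), U2P)
        assert fit.lod == pytest.approx(10 * np.log10(0.4) + 40 * np.log10(1.6), abs=1e-8)
        # implied relative risks: lambda1 = z1/(2 z0), lambda2 = z2/z0
        assert np.exp(fit.params.beta1) == pytest.approx(0.5 / 0.2, abs=1e-5)
        assert np.exp(fit.params.beta2) == pytest.approx(0.4 / 0.1, abs=1e-4)

    @pytest.mark.parametrize("counts", [(5, 9, 3), (1, 1, 8), (12, 3, 4), (7, 30, 20)])
    def test_random_count_triples(self, counts):
        fit = maximize_lod(pairs_from_counts(*counts), U2P)
        assert fit.lod == pytest.approx(multinomial_lod(*counts), abs=1e-8)


class TestMaximizeConstrained2P:
    def test_deficit_sharing_is_clipped_to_null(self):
        # more IBD-0 pairs than expected: the feasible maximum is at the null
        fit = maximize_lod(pairs_from_counts(40, 50, 10), C2P)
        assert fit.lod >= 0.0
        assert fit.params.beta1 >= -1e-8
        assert fit.params.beta2 >= constraint_boundary_beta2(max(fit.params.beta1, 0)) - 1e-8

    def test_feasible_interior_matches_unconstrained(self):
        fit_u = maximize_lod(pairs_from_counts(10, 50, 40), U2P)
        fit_c = maximize_lod(pairs_from_counts(10, 50, 40), C2P)
        assert fit_c.lod == pytest.approx(fit_u.lod, abs=1e-7)

    def test_grid_search_oracle_on_counts(self, rng):
        """Constrained fits match a dense 2-D grid search within 1e-4."""
        for _ in range(25):
            counts = rng.multinomial(60, FULL_SIB_PRIOR) + 5
            fit = maximize_lod_arrays(
                np.eye(3), np.tile(FULL_SIB_PRIOR, (3, 1)), np.empty((3, 0)),
                C2P, weights=counts.astype(float),
            )
            oracle = _grid_oracle_c2p(np.eye(3), counts.astype(float))
            assert fit.lod == pytest.approx(oracle, abs=1e-4)

    def test_grid_search_oracle_on_general_posteriors(self, rng):
        checked = 0
        while checked < 10:
            n = int(rng.integers(5, 10))
            G = rng.dirichlet([6.0, 12.0, 6.0], size=n)
            w = rng.integers(2, 20, size=n).astype(float)
            fit = maximize_lod_arrays(
                G, np.tile(FULL_SIB_PRIOR, (n, 1)), np.empty((n, 0)), C2P, weights=w
            )
            s_hat = fit.params.beta2 - constraint_boundary_beta2(max(fit.params.beta1, 0.0))
            if fit.params.beta1 > 1.8 or s_hat > 1.8:
                continue  # optimum outside the oracle's grid box
            oracle = _grid_oracle_c2p(G, w)
            assert fit.lod == pytest.approx(oracle, abs=1e-4)
            checked += 1


def _grid_oracle_c2p(G: np.ndarray, w: np.ndarray) -> float:
    """Dense grid search over the constraint region (independent oracle).

    Parameterizes the feasible set by beta1 in [0, 2] and the offset
    s = beta2 - boundary(beta1) in [0, 2], step 1e-3.
    """
    b1 = np.arange(0.0, 2.0 + 1e-12, 1e-3)
    s = np.arange(0.0, 2.0 + 1e-12, 1e-3)
    B1, S = np.meshgrid(b1, s, indexing="ij")
    B2 = np.log(2.0 * np.exp(B1) - 1.0) + S
    l1, l2 = np.exp(B1), np.exp(B2)
    total = np.zeros_like(B1)
    f = FULL_SIB_PRIOR
    for gi, wi in zip(G, w):
        num = gi[0] + gi[1] * l1 + gi[2] * l2
        den = f[0] + f[1] * l1 + f[2] * l2
        total += wi * (np.log(num) - np.log(den))
    return float(total.max()) / LN10


class TestMaximizeOneParameter:
    def test_excess_sharing(self):
        fit_u = maximize_lod(pairs_from_counts(10, 50, 40), U1P)
        fit_c = maximize_lod(pairs_from_counts(10, 50, 40), C1P)
        assert fit_c.lod == pytest.approx(fit_u.lod, abs=1e-8)  # optimum has beta1 > 0
        assert fit_u.params.beta2 == pytest.approx(minmax_beta2(fit_u.params.beta1))

    def test_deficit_sharing_constrained_at_null(self):
        fit = maximize_lod(pairs_from_counts(40, 50, 10), C1P)
        assert fit.lod == pytest.approx(0.0, abs=1e-9)
        fit_u = maximize_lod(pairs_from_counts(40, 50, 10), U1P)
        assert fit_u.lod > 0.01  # the unconstrained fit moves to beta1 < 0

    def test_scalar_oracle(self, rng):
        """1-D fits match a dense grid over beta1 within 1e-4."""
        for counts in [(20, 50, 30), (30, 40, 30), (18, 55, 27)]:
            fit = maximize_lod(pairs_from_counts(*counts), C1P)
            grid = np.arange(0.0, 3.0, 1e-4)
            vals = _minmax_profile(np.array(counts, float), grid)
            assert fit.lod == pytest.approx(max(vals.max(), 0.0), abs=1e-4)


def _minmax_profile(counts: np.ndarray, grid: np.ndarray) -> np.ndarray:
    l1 = np.exp(grid)
    l2 = 3.634 * l1 - 2.634
    S = 0.25 + 0.5 * l1 + 0.25 * l2
    return (counts[1] * grid + counts[2] * np.log(l2) - counts.sum() * np.log(S)) / LN10


class TestNestingAndFeasibility:
    @pytest.mark.parametrize("seed", range(6))
    def test_nesting_of_maximized_lods(self, seed):
        """Relaxing constraints never decreases the maximized LOD."""
        r = np.random.default_rng(seed)
        n = int(r.integers(5, 40))
        G = r.dirichlet([2.0, 4.0, 2.0], size=n)
        pairs = [PairData(IBDPosterior(*g)) for g in G]
        lods = {m.value: maximize_lod(pairs, AnalysisModel(m)).lod
                for m in (ModelTag.CONSTRAINED_1P, ModelTag.UNCONSTRAINED_1P,
                          ModelTag.CONSTRAINED_2P, ModelTag.UNCONSTRAINED_2P)}
        tol = 1e-6
        assert lods["constrained-1p"] <= lods["constrained-2p"] + tol
        assert lods["constrained-2p"] <= lods["unconstrained-2p"] + tol
        assert lods["constrained-1p"] <= lods["unconstrained-1p"] + tol
        assert min(lods.values()) >= -1e-8

    @pytest.mark.parametrize("seed", range(4))
    def test_returned_parameters_feasible(self, seed):
        r = np.random.default_rng(100 + seed)
        G = r.dirichlet([2.0, 4.0, 2.0], size=20)
        pairs = [PairData(IBDPosterior(*g)) for g in G]
        fit = maximize_lod(pairs, C2P)
        assert fit.params.beta1 >= -1e-8
        assert fit.params.beta2 >= constraint_boundary_beta2(max(fit.params.beta1, 0.0)) - 1e-8
        fit1 = maximize_lod(pairs, C1P)
        assert fit1.params.beta1 >= -1e-12

    def test_lod_additive_over_datasets_at_fixed_parameters(self):
        a = pairs_from_counts(3, 6, 6)
        b = pairs_from_counts(5, 8, 2)
        params = BetaParameters(0.2, 0.6)
        assert sample_lod(a + b, params, U2P) == pytest.approx(
            sample_lod(a, params, U2P) + sample_lod(b, params, U2P), rel=1e-12
        )


class TestCovariateModels:
    @staticmethod
    def _covariate_pairs(shift: float = 0.0, seed: int = 3):
        r = np.random.default_rng(seed)
        G = np.eye(3)[r.integers(0, 3, size=60)]
        x = r.normal(size=60) + shift
        x = x - x.mean()  # mean-centering
        return [PairData(IBDPosterior(*g), covariates=(xi,)) for g, xi in zip(G, x)]

    def test_mean_centering_invariance(self):
        """Shifting the raw covariate then re-centering changes nothing."""
        model = AnalysisModel(ModelTag.UNCONSTRAINED_COVARIATE, 1)
        lod0 = maximize_lod(self._covariate_pairs(0.0), model).lod
        lod5 = maximize_lod(self._covariate_pairs(5.0), model).lod
        assert lod5 == pytest.approx(lod0, abs=1e-8)

    def test_constrained_covariate_respects_constraints(self):
        r = np.random.default_rng(5)
        G = np.eye(3)[r.integers(0, 3, size=80)]
        x = (r.random(size=80) < 0.36).astype(float) + (r.random(size=80) < 0.36)
        x = x - x.min()
        pairs = [PairData(IBDPosterior(*g), covariates=(xi,)) for g, xi in zip(G, x)]
        model = AnalysisModel(ModelTag.CONSTRAINED_COVARIATE, 1)
        fit = maximize_lod(pairs, model)
        b1, (d1,) = fit.params.beta1, fit.params.deltas
        for xv in np.unique(x[x > 0]):
            assert b1 + xv * d1 >= -1e-7
        # the constrained fit never exceeds the unconstrained-covariate fit
        fit_u = maximize_lod(pairs, AnalysisModel(ModelTag.UNCONSTRAINED_COVARIATE, 1))
        assert fit.lod <= fit_u.lod + 1e-7

    def test_covariate_dimension_checked(self):
        pairs = pairs_from_counts(2, 4, 4)
        with pytest.raises(ValueError):
            maximize_lod(pairs, AnalysisModel(ModelTag.UNCONSTRAINED_COVARIATE, 1))


class TestAnalysisModelValidation:
    def test_covariate_count_rules(self):
        with pytest.raises(ValueError):
            AnalysisModel(ModelTag.UNCONSTRAINED_COVARIATE, 0)
        with pytest.raises(ValueError):
            AnalysisModel(ModelTag.UNCONSTRAINED_2P, 1)

    def test_from_name(self):
        m = AnalysisModel.from_name("constrained-covariate")
        assert m.n_covariates == 1
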
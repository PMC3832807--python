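"""Conditional-logistic likelihood for affected relative pairs.

The model assigns relative risks lambda_i = exp(beta_i) to an individual
sharing i alleles IBD with an affected relative (lambda_0 = 1).  The
likelihood-ratio contribution of a pair with prior IBD distribution f and
marker-conditional distribution g is

    LR = (sum_i lambda_i g_i) / (sum_i lambda_i f_i),

and the sample LOD score is the sum of base-10 logs of pair LRs.  The LOD is
maximized over a feasible set that depends on the analysis model:

* unconstrained two-parameter: (beta1, beta2) free;
* constrained two-parameter:   beta1 >= 0 and beta2 >= ln(2 e^beta1 - 1)
  (the possible-triangle constraints, lambda2 >= 2 lambda1 - 1);
* one-parameter (minmax):      beta2 tied to beta1 through
  lambda2 = 3.634 lambda1 - 2.634, with beta1 free (unconstrained) or
  beta1 >= 0 (constrained);
* covariate models:            constrained one-parameter base with log-linear
  covariate effects on the relative risks.

The likelihood-ratio scale statistic is 2 ln(10) times the LOD.
"""
from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import LinearConstraint, minimize, minimize_scalar

from .ibd import IBDPosterior, IBDPrior, prior_ibd_asp

__all__ = [
    "ModelTag",
    "AnalysisModel",
    "BetaParameters",
    "PairData",
    "FitResult",
    "CovariateConvention",
    "MINMAX_PI",
    "minmax_beta2",
    "constraint_boundary_beta2",
    "relative_risks",
    "pair_likelihood_ratio",
    "sample_lod",
    "maximize_lod",
    "maximize_lod_arrays",
    "lr_statistic",
    "lod_from_lr",
]

LN10 = np.log(10.0)

#: pi of the minmax model, intermediate between recessive and dominant.
MINMAX_PI = 2.634

_BETA_BOUND = 10.0          # |beta| cap; LOD contributions saturate long before
_EXP_CLIP = 700.0           # exp() overflow guard
_MINMAX_LOWER = float(np.log(MINMAX_PI / (MINMAX_PI + 1.0)))  # lambda2 -> 0+


class ModelTag(enum.Enum):
    UNCONSTRAINED_2P = "unconstrained-2p"
    CONSTRAINED_2P = "constrained-2p"
    UNCONSTRAINED_1P = "unconstrained-1p"
    CONSTRAINED_1P = "constrained-1p"
    UNCONSTRAINED_COVARIATE = "unconstrained-covariate"
    CONSTRAINED_COVARIATE = "constrained-covariate"


_COVARIATE_TAGS = {ModelTag.UNCONSTRAINED_COVARIATE, ModelTag.CONSTRAINED_COVARIATE}
_TWO_PARAM_TAGS = {ModelTag.UNCONSTRAINED_2P, ModelTag.CONSTRAINED_2P}


@dataclass(frozen=True)
class AnalysisModel:
    """One of the six constraint regimes over which the LOD is maximized."""

    tag: ModelTag
    n_covariates: int = 0

    def __post_init__(self) -> None:
        if self.tag in _COVARIATE_TAGS and self.n_covariates < 1:
            raise ValueError("covariate models require n_covariates >= 1")
        if self.tag not in _COVARIATE_TAGS and self.n_covariates != 0:
            raise ValueError("only covariate models may carry covariates")

    @classmethod
    def from_name(cls, name: str, n_covariates: int = 0) -> "AnalysisModel":
        tag = ModelTag(name)
        if tag in _COVARIATE_TAGS and n_covariates == 0:
            n_covariates = 1
        return cls(tag, n_covariates)


class CovariateConvention(enum.Enum):
    """How covariates enter lambda2 in the one-parameter covariate models.

    ``MINMAX_AFTER_ADJUSTMENT`` (default): the minmax tie is applied to the
    covariate-adjusted lambda1, i.e. lambda2 = 3.634 lambda1 - 2.634 with
    lambda1 = exp(beta1 + sum_j delta_j x_j).  ``TIED_DELTA``: lambda2 =
    exp(minmax_beta2(beta1) + sum_j delta_j x_j), sharing delta between the
    two risks.
    """

    MINMAX_AFTER_ADJUSTMENT = "minmax-after-adjustment"
    TIED_DELTA = "tied-delta"


@dataclass(frozen=True)
class BetaParameters:
    """Log relative risks (and covariate coefficients) of the CL model."""

    beta1: float
    beta2: float
    deltas: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        vals = (self.beta1, self.beta2, *self.deltas)
        if not all(np.isfinite(v) for v in vals):
            raise ValueError("parameters must be finite")
        object.__setattr__(self, "deltas", tuple(float(d) for d in self.deltas))


@dataclass(frozen=True)
class PairData:
    """One affected relative pair: IBD posterior, prior, and covariates."""

    posterior: IBDPosterior
    prior: IBDPrior = field(default_factory=prior_ibd_asp)
    covariates: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "covariates", tuple(float(x) for x in self.covariates))


@dataclass(frozen=True)
class FitResult:
    """Maximized fit: parameter estimates, LOD, and the LR-scale statistic."""

    params: BetaParameters
    lod: float
    lr: float
    converged: bool
    n_starts_used: int


def minmax_beta2(beta1: float) -> float:
    """beta2 implied by the minmax tie lambda2 = 3.634 lambda1 - 2.634."""
    if beta1 <= _MINMAX_LOWER:
        raise ValueError(
            f"minmax relation undefined for beta1 <= {_MINMAX_LOWER:.6f} "
            "(implied lambda2 would be nonpositive)"
        )
    # ln(3.634 e^b - 2.634), written stably for large b
    if beta1 > 30.0:
        return float(beta1 + np.log((MINMAX_PI + 1.0) - MINMAX_PI * np.exp(-beta1)))
    return float(np.log((MINMAX_PI + 1.0) * np.exp(beta1) - MINMAX_PI))


def constraint_boundary_beta2(beta1: float) -> float:
    """No-dominance lower boundary beta2 = ln(2 e^beta1 - 1) of the triangle."""
    if beta1 <= -np.log(2.0):
        raise ValueError("boundary undefined for beta1 <= -ln 2 (lambda2 <= 0)")
    if beta1 > 30.0:
        return float(beta1 + np.log(2.0 - np.exp(-beta1)))
    return float(np.log(2.0 * np.exp(beta1) - 1.0))


def _lambdas_nocov(beta1: float, beta2: float) -> np.ndarray:
    b = np.clip([0.0, beta1, beta2], -_EXP_CLIP, _EXP_CLIP)
    return np.exp(b)


def relative_risks(
    params: BetaParameters,
    covariates: Sequence[float] = (),
    convention: CovariateConvention = CovariateConvention.MINMAX_AFTER_ADJUSTMENT,
) -> tuple[float, float, float]:
    """(lambda0, lambda1, lambda2) for one pair, log-linear in covariates.

    Without covariates, lambda_i = exp(beta_i).  With covariates (one-
    parameter models only), lambda1 = exp(beta1 + sum_j delta_j x_j) and
    lambda2 follows the chosen :class:`CovariateConvention`.
    """
    x = np.asarray(covariates, dtype=float)
    if len(params.deltas) != x.size:
        raise ValueError("covariate vector length must match deltas length")
    if x.size == 0:
        l0, l1, l2 = _lambdas_nocov(params.beta1, params.beta2)
        return (float(l0), float(l1), float(l2))
    shift = float(np.dot(params.deltas, x))
    arg1 = params.beta1 + shift
    if abs(arg1) > _EXP_CLIP:
        warnings.warn("exponent clipped to avoid overflow", RuntimeWarning)
        arg1 = float(np.clip(arg1, -_EXP_CLIP, _EXP_CLIP))
    l1 = float(np.exp(arg1))
    if convention is CovariateConvention.MINMAX_AFTER_ADJUSTMENT:
        l2 = (MINMAX_PI + 1.0) * l1 - MINMAX_PI
        if l2 <= 0.0:
            raise ValueError(
                "covariate-adjusted lambda1 too small: minmax lambda2 nonpositive"
            )
    else:
        arg2 = minmax_beta2(params.beta1) + shift
        l2 = float(np.exp(np.clip(arg2, -_EXP_CLIP, _EXP_CLIP)))
    return (1.0, l1, l2)


def pair_likelihood_ratio(pair: PairData, lambdas: Sequence[float]) -> float:
    """LR contribution (sum_i lambda_i g_i) / (sum_i lambda_i f_i) of a pair."""
    lam = np.asarray(lambdas, dtype=float)
    if np.any(lam <= 0.0):
        raise ValueError("relative risks must be strictly positive")
    g = pair.posterior.as_array()
    f = pair.prior.as_array()
    return float((lam @ g) / (lam @ f))


def sample_lod(
    pairs: Sequence[PairData],
    params: BetaParameters,
    model: AnalysisModel,
    convention: CovariateConvention = CovariateConvention.MINMAX_AFTER_ADJUSTMENT,
) -> float:
    """Sample LOD: sum over pairs of log10 pair likelihood ratios."""
    if len(pairs) == 0:
        raise ValueError("pair list must be nonempty")
    total = 0.0
    for pair in pairs:
        lam = relative_risks(params, pair.covariates, convention)
        total += np.log10(pair_likelihood_ratio(pair, lam))
    return float(total)


def lr_statistic(fit: FitResult) -> float:
    """CL-LR statistic 2 ln(10) * LOD."""
    return 2.0 * LN10 * fit.lod


def lod_from_lr(lr: float) -> float:
    return lr / (2.0 * LN10)


# ---------------------------------------------------------------------------
# Maximization
# ---------------------------------------------------------------------------


def _pack(pairs: Sequence[PairData]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    G = np.array([p.posterior.as_array() for p in pairs])
    F = np.array([p.prior.as_array() for p in pairs])
    X = np.array([p.covariates for p in pairs], dtype=float)
    if X.ndim == 1:
        X = X.reshape(len(pairs), -1)
    return G, F, X


def _collapse(G: np.ndarray, F: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Collapse duplicate (posterior, prior) rows into weights.

    With fully informative markers the sample reduces to the three IBD count
    classes, which makes large replicate studies cheap.
    """
    rows = np.round(np.hstack([G, F]), 12)
    uniq, inverse, counts = np.unique(rows, axis=0, return_inverse=True, return_counts=True)
    return uniq[:, :3], uniq[:, 3:], counts.astype(float)


class _Objective:
    """Weighted LOD as a function of (beta1, beta2), with analytic gradient."""

    def __init__(self, G: np.ndarray, F: np.ndarray, w: np.ndarray):
        self.G, self.F, self.w = G, F, w

    def lod(self, beta1: float, beta2: float) -> float:
        lam = _lambdas_nocov(beta1, beta2)
        num = self.G @ lam
        den = self.F @ lam
        return float(self.w @ (np.log(num) - np.log(den)) / LN10)

    def neg_lod_grad(self, beta: np.ndarray) -> tuple[float, np.ndarray]:
        lam = _lambdas_nocov(beta[0], beta[1])
        num = self.G @ lam
        den = self.F @ lam
        val = float(self.w @ (np.log(num) - np.log(den)) / LN10)
        g1 = lam[1] * float(self.w @ (self.G[:, 1] / num - self.F[:, 1] / den)) / LN10
        g2 = lam[2] * float(self.w @ (self.G[:, 2] / num - self.F[:, 2] / den)) / LN10
        return -val, -np.array([g1, g2])


def _maximize_scalar(fun, lo: float, hi: float, n_grid: int = 65) -> tuple[float, float]:
    """Maximize a scalar function on [lo, hi]: coarse grid, then Brent."""
    grid = np.linspace(lo, hi, n_grid)
    vals = np.array([fun(x) for x in grid])
    i = int(np.argmax(vals))
    a = grid[max(i - 1, 0)]
    b = grid[min(i + 1, n_grid - 1)]
    res = minimize_scalar(lambda x: -fun(x), bounds=(a, b), method="bounded",
                          options={"xatol": 1e-12})
    if -res.fun >= vals[i]:
        return float(res.x), float(-res.fun)
    return float(grid[i]), float(vals[i])


def _moment_start(G: np.ndarray, F: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Start from pooled posterior means interpreted as sharing probabilities."""
    zbar = np.clip((w @ G) / w.sum(), 1e-6, None)
    zbar = zbar / zbar.sum()
    lam1 = zbar[1] / (2.0 * zbar[0])
    lam2 = zbar[2] / zbar[0]
    return np.clip(np.log([lam1, lam2]), -5.0, 5.0)


def _fit_2p(
    G: np.ndarray, F: np.ndarray, w: np.ndarray, constrained: bool
) -> tuple[np.ndarray, float, bool, int]:
    """Two-parameter fit: adaptive multi-start plus boundary-face scans.

    Starts at the null point and a moment-based point; three jittered
    starts are added only when those two disagree or fail, which they do
    not on well-behaved likelihoods (in the allele-sharing parameterization
    the common-prior likelihood is concave, so the maximum is unique).  The
    constrained fit first tries the unconstrained optimum (feasible implies
    done), then searches the interior through the smooth reparameterization
    beta1 = u1^2, beta2 = boundary(beta1) + u2^2, and exactly scans the two
    boundary faces, on which a concave likelihood attains its constrained
    maximum whenever the unconstrained optimum is infeasible.
    """
    obj = _Objective(G, F, w)
    rng = np.random.default_rng(0)  # jitter for multi-start; fixed for determinism
    moment = _moment_start(G, F, w)

    best_beta, best_lod, converged, used = np.zeros(2), 0.0, True, 0

    def consider(beta: np.ndarray, lod: float, ok: bool) -> None:
        nonlocal best_beta, best_lod, converged
        if lod > best_lod:
            best_beta, best_lod = beta, lod
            converged = ok

    def run_free(start: np.ndarray):
        res = minimize(
            obj.neg_lod_grad, np.clip(start, -_BETA_BOUND, _BETA_BOUND), jac=True,
            method="L-BFGS-B", bounds=[(-_BETA_BOUND, _BETA_BOUND)] * 2,
            options={"ftol": 1e-14, "gtol": 1e-12, "maxiter": 500},
        )
        return res.x, -res.fun, bool(res.success)

    if not constrained:
        results = []
        for s in (np.zeros(2), moment):
            used += 1
            results.append(run_free(s))
            consider(*results[-1])
        agree = (
            all(ok for *_, ok in results)
            and abs(results[0][1] - results[1][1]) < 1e-9
        )
        if not agree:
            for _ in range(3):
                used += 1
                consider(*run_free(moment + rng.normal(scale=0.3, size=2)))
        return best_beta, max(best_lod, 0.0), converged, used

    # Feasible unconstrained optimum: the constrained maximum coincides.
    beta_u, lod_u, ok_u = run_free(moment)
    used += 1
    feasible = beta_u[0] >= -1e-9 and beta_u[1] >= constraint_boundary_beta2(
        max(beta_u[0], 0.0)
    ) - 1e-9
    if ok_u and feasible:
        beta_u = np.maximum(beta_u, [0.0, constraint_boundary_beta2(max(beta_u[0], 0.0))])
        return beta_u, max(lod_u, 0.0), True, used

    def neg_u(u: np.ndarray) -> tuple[float, np.ndarray]:
        b1 = u[0] ** 2
        bnd = constraint_boundary_beta2(b1)
        b2 = bnd + u[1] ** 2
        nval, ngrad = obj.neg_lod_grad(np.array([b1, b2]))
        dbnd = 2.0 * np.exp(b1) / (2.0 * np.exp(b1) - 1.0) if b1 < 30 else 1.0
        du1 = (ngrad[0] + ngrad[1] * dbnd) * 2.0 * u[0]
        du2 = ngrad[1] * 2.0 * u[1]
        return nval, np.array([du1, du2])

    for s in (np.zeros(2), moment):
        used += 1
        u0 = np.sqrt(np.clip(s, 0.0, _BETA_BOUND))
        res = minimize(
            neg_u, u0, jac=True, method="L-BFGS-B",
            bounds=[(0.0, np.sqrt(_BETA_BOUND))] * 2,
            options={"ftol": 1e-14, "gtol": 1e-12, "maxiter": 500},
        )
        b1 = res.x[0] ** 2
        b2 = constraint_boundary_beta2(b1) + res.x[1] ** 2
        consider(np.array([b1, b2]), -res.fun, bool(res.success))

    b1_star, lod_curve = _maximize_scalar(
        lambda b1: obj.lod(b1, constraint_boundary_beta2(b1)), 0.0, _BETA_BOUND
    )
    used += 1
    consider(np.array([b1_star, constraint_boundary_beta2(b1_star)]), lod_curve, True)
    b2_star, lod_axis = _maximize_scalar(lambda b2: obj.lod(0.0, b2), 0.0, _BETA_BOUND)
    used += 1
    consider(np.array([0.0, b2_star]), lod_axis, True)

    return best_beta, max(best_lod, 0.0), converged, used


def _fit_1p(
    G: np.ndarray, F: np.ndarray, w: np.ndarray, constrained: bool
) -> tuple[float, float, int]:
    obj = _Objective(G, F, w)

    def lod_of(b1: float) -> float:
        return obj.lod(b1, minmax_beta2(b1))

    lo = 0.0 if constrained else _MINMAX_LOWER + 1e-8
    b1_star, lod = _maximize_scalar(lod_of, lo, _BETA_BOUND, n_grid=129)
    return b1_star, max(lod, 0.0), 1


def _covariate_objective(
    G: np.ndarray, F: np.ndarray, X: np.ndarray, convention: CovariateConvention
):
    def lod(theta: np.ndarray) -> float:
        b1, delta = theta[0], theta[1:]
        shift = X @ delta
        arg1 = np.clip(b1 + shift, -_EXP_CLIP, _EXP_CLIP)
        l1 = np.exp(arg1)
        if convention is CovariateConvention.MINMAX_AFTER_ADJUSTMENT:
            l2 = np.maximum((MINMAX_PI + 1.0) * l1 - MINMAX_PI, 1e-300)
        else:
            if b1 <= _MINMAX_LOWER:
                return -np.inf
            l2 = np.exp(np.clip(minmax_beta2(b1) + shift, -_EXP_CLIP, _EXP_CLIP))
        num = G[:, 0] + G[:, 1] * l1 + G[:, 2] * l2
        den = F[:, 0] + F[:, 1] * l1 + F[:, 2] * l2
        return float(np.sum(np.log(num) - np.log(den)) / LN10)

    return lod


def _fit_covariate(
    G: np.ndarray,
    F: np.ndarray,
    X: np.ndarray,
    constrained: bool,
    convention: CovariateConvention,
) -> tuple[np.ndarray, float, bool, int]:
    K = X.shape[1]
    lod = _covariate_objective(G, F, X, convention)
    rng = np.random.default_rng(0)
    moment = np.zeros(1 + K)
    moment[0] = np.clip(_moment_start(G, F, np.ones(len(G)))[0], 0.0, 2.0)
    starts = [np.zeros(1 + K), moment]
    starts += [moment + rng.normal(scale=0.2, size=1 + K) for _ in range(3)]

    bounds = [(0.0, _BETA_BOUND)] + [(-_BETA_BOUND, _BETA_BOUND)] * K
    constraints = []
    if constrained:
        # lambda1 >= 1 at every observed covariate vector: beta1 + x.delta >= 0
        nonzero = np.unique(np.round(X, 12), axis=0)
        nonzero = nonzero[np.any(nonzero != 0.0, axis=1)]
        if len(nonzero):
            A = np.hstack([np.ones((len(nonzero), 1)), nonzero])
            constraints = [LinearConstraint(A, lb=0.0)]

    best_theta, best_lod, ok, used = np.zeros(1 + K), 0.0, True, 0
    for s in starts:
        used += 1
        s = np.clip(s, [b[0] for b in bounds], [b[1] for b in bounds])
        if constraints and np.any(constraints[0].A @ s < -1e-12):
            s = np.zeros(1 + K)
        res = minimize(
            lambda t: -lod(t), s, method="SLSQP", bounds=bounds,
            constraints=constraints, options={"ftol": 1e-12, "maxiter": 500},
        )
        if -res.fun > best_lod:
            feasible = not constraints or np.all(constraints[0].A @ res.x >= -1e-8)
            if feasible:
                best_theta, best_lod, ok = res.x, -res.fun, bool(res.success)
    return best_theta, max(best_lod, 0.0), ok, used


def maximize_lod(
    pairs: Sequence[PairData],
    model: AnalysisModel,
    convention: CovariateConvention = CovariateConvention.MINMAX_AFTER_ADJUSTMENT,
) -> FitResult:
    """Maximize the sample LOD over the model's feasible parameter set.

    The null point (all parameters zero) is feasible in every model, so the
    maximized LOD is nonnegative; values in (-1e-8, 0) produced by floating
    point are clipped to 0.  Non-convergence is flagged on the result, never
    raised.
    """
    if len(pairs) == 0:
        raise ValueError("pair list must be nonempty")
    G, F, X = _pack(pairs)
    return maximize_lod_arrays(G, F, X, model, convention=convention)


def maximize_lod_arrays(
    G: np.ndarray,
    F: np.ndarray,
    X: np.ndarray,
    model: AnalysisModel,
    convention: CovariateConvention = CovariateConvention.MINMAX_AFTER_ADJUSTMENT,
    weights: np.ndarray | None = None,
) -> FitResult:
    """Array-level entry point of :func:`maximize_lod`.

    ``G``/``F`` are (N, 3) posterior/prior arrays, ``X`` the (N, K) adjusted
    covariates.  ``weights`` replicates rows without materializing them
    (covariate-free models only), which the simulator uses to collapse
    fully informative samples to IBD counts.
    """
    if X.shape[1] != model.n_covariates:
        raise ValueError(
            f"model expects {model.n_covariates} covariates per pair, "
            f"got {X.shape[1]}"
        )

    tag = model.tag
    if tag in _COVARIATE_TAGS:
        if weights is not None:
            raise ValueError("weights are not supported for covariate models")
    else:
        if weights is None:
            Gc, Fc, w = _collapse(G, F)
        else:
            Gc, Fc, w = G, F, np.asarray(weights, dtype=float)
    if tag is ModelTag.UNCONSTRAINED_2P:
        beta, lod, ok, used = _fit_2p(Gc, Fc, w, constrained=False)
        params = BetaParameters(beta[0], beta[1])
    elif tag is ModelTag.CONSTRAINED_2P:
        beta, lod, ok, used = _fit_2p(Gc, Fc, w, constrained=True)
        params = BetaParameters(beta[0], beta[1])
    elif tag in (ModelTag.UNCONSTRAINED_1P, ModelTag.CONSTRAINED_1P):
        b1, lod, used = _fit_1p(Gc, Fc, w, constrained=tag is ModelTag.CONSTRAINED_1P)
        ok = True
        params = BetaParameters(b1, minmax_beta2(b1) if b1 > _MINMAX_LOWER else 0.0)
    else:
        theta, lod, ok, used = _fit_covariate(
            G, F, X, constrained=tag is ModelTag.CONSTRAINED_COVARIATE,
            convention=convention,
        )
        b1 = theta[0]
        params = BetaParameters(b1, minmax_beta2(max(b1, 0.0)), tuple(theta[1:]))

    lod = 0.0 if -1e-8 < lod < 0.0 else float(lod)
    return FitResult(
        params=params, lod=lod, lr=2.0 * LN10 * lod, converged=ok, n_starts_used=used
    )
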
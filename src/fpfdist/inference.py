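"""Maximum likelihood inference for the FPF distribution.

The log-likelihood depends on (alpha, theta) only through lam = alpha*theta:
the score components satisfy the exact ridge identity
``alpha * dl/dalpha = theta * dl/dtheta``, so joint 2-D maximization is a
degenerate ridge.  Estimation is therefore one-dimensional in lam; the
alpha/theta split is a presentation convenience requiring one parameter
fixed ("theta-fixed" reports alpha_hat = lam_hat/theta0 and symmetrically).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.stats import norm

from .core import FPFParams, SupportBounds

__all__ = [
    "Sample",
    "FitResult",
    "IntervalEstimate",
    "fpf_loglik",
    "fpf_score",
    "score_lambda",
    "fit_mle",
    "observed_information",
    "wald_ci",
    "bootstrap_ci",
]

_ONE_MINUS_EINV = -math.expm1(-1.0)


@dataclass(frozen=True)
class Sample:
    """A validated univariate dataset with its support convention."""

    values: np.ndarray
    bounds: SupportBounds
    bounds_rule: str = "explicit"  # explicit | zero-to-max | zero-to-inflated-max

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if vals.size < 2:
            raise ValueError("a sample needs at least 2 observations")
        if vals.min() < self.bounds.a or vals.max() > self.bounds.b:
            raise ValueError("sample values fall outside the stated support")

    @property
    def n(self) -> int:
        return int(self.values.size)

    @classmethod
    def from_values(cls, values, bounds: SupportBounds | None = None,
                    rule: str = "zero-to-max") -> "Sample":
        """Resolve support bounds from data.

        Rules: "zero-to-max" sets (0, max); "zero-to-inflated-max" sets
        (0, (1+1e-6)*max) for users worried about boundary points;
        explicit ``bounds`` always override.
        """
        vals = np.asarray(values, dtype=float)
        if bounds is not None:
            return cls(vals, bounds, "explicit")
        if rule == "zero-to-max":
            return cls(vals, SupportBounds(0.0, float(vals.max())), rule)
        if rule == "zero-to-inflated-max":
            return cls(vals, SupportBounds(0.0, float(vals.max()) * (1 + 1e-6)), rule)
        raise ValueError(f"unknown bounds rule: {rule}")


@dataclass(frozen=True)
class FitResult:
    params: FPFParams
    loglik: float
    mode: str  # lambda-only | theta-fixed | alpha-fixed
    se_lambda: float
    info_lambda: float
    converged: bool
    n_iter: int
    sample: Sample = field(repr=False)

    @property
    def lam(self) -> float:
        return self.params.lam


@dataclass(frozen=True)
class IntervalEstimate:
    point: float
    lower: float
    upper: float
    level: float
    method: str  # wald | bootstrap-percentile
    parameter: str = "lam"
    n_boot: int | None = None


def _logv(sample: Sample) -> np.ndarray:
    bd = sample.bounds
    shifted = sample.values - bd.a
    if np.any(shifted <= 0):
        raise ValueError("likelihood undefined: sample contains values <= a")
    return np.log(shifted) - math.log(bd.width)


def fpf_loglik(params: FPFParams, sample: Sample) -> float:
    """Log-likelihood; requires all observations in (a, b]."""
    logv = _logv(sample)
    lam = params.lam
    n = sample.n
    return float(
        n * math.log(lam)
        - n * math.log(sample.bounds.width)
        - n * math.log(_ONE_MINUS_EINV)
        + (lam - 1.0) * logv.sum()
        - np.exp(lam * logv).sum()
    )


def fpf_score(params: FPFParams, sample: Sample) -> tuple[float, float]:
    """Score components (dl/dalpha, dl/dtheta).

    Both equal ``(n + lam*S1 - lam*T)/parameter`` where S1 = sum log v and
    T = sum v^lam log v -- the exact ridge identity
    alpha*dl/dalpha = theta*dl/dtheta.
    """
    logv = _logv(sample)
    lam = params.lam
    n = sample.n
    common = n + lam * logv.sum() - lam * (np.exp(lam * logv) * logv).sum()
    return float(common / params.alpha), float(common / params.theta)


def score_lambda(lam: float, sample: Sample) -> float:
    """1-D score in lam: n/lam + sum log v - sum v^lam log v."""
    logv = _logv(sample)
    return float(sample.n / lam + logv.sum() - (np.exp(lam * logv) * logv).sum())


def observed_information(params: FPFParams, sample: Sample):
    """Observed information in lam and the (singular) 2x2 alpha/theta matrix.

    Returns ``(info_lam, matrix, det_diagnostic)`` where
    ``info_lam = n/lam^2 + sum v^lam (log v)^2`` and the 2x2 matrix is the
    negative Hessian in (theta, alpha); its determinant is ~0 because of
    the ridge identity, reported as the diagnostic.
    """
    logv = _logv(sample)
    lam = params.lam
    n = sample.n
    w = np.exp(lam * logv)
    s_wl2 = (w * logv**2).sum()
    info_lam = n / lam**2 + s_wl2
    alpha, theta = params.alpha, params.theta
    s1 = logv.sum()
    s_wl = (w * logv).sum()
    d2_aa = -n / alpha**2 - theta**2 * s_wl2
    d2_tt = -n / theta**2 - alpha**2 * s_wl2
    d2_at = s1 - s_wl - lam * s_wl2
    matrix = -np.array([[d2_tt, d2_at], [d2_at, d2_aa]])
    det = float(np.linalg.det(matrix))
    return float(info_lam), matrix, det


def fit_mle(
    sample: Sample,
    mode: str = "lambda-only",
    theta0: float | None = None,
    alpha0: float | None = None,
    init: float | None = None,
) -> FitResult:
    """Maximize the likelihood over lam by solving the 1-D score equation.

    The score ``n/lam + S1 - sum v^lam log v`` is strictly decreasing in
    lam (its derivative is ``-n/lam^2 - sum v^lam (log v)^2 < 0``), so the
    root is unique; it is bracketed by geometric expansion from the
    Power-Function closed form ``lam0 = -n/S1`` and solved by Brent's
    method.
    """
    logv = _logv(sample)
    n = sample.n
    s1 = logv.sum()
    if s1 >= 0:  # all values at b: score is positive everywhere
        raise RuntimeError("non-convergence: score has no root (all values at the upper bound)")

    def score(lam: float) -> float:
        return n / lam + s1 - float((np.exp(lam * logv) * logv).sum())

    lam0 = init if init is not None else -n / s1
    lam0 = min(max(lam0, 1e-6), 1e6)
    lo = hi = lam0
    n_iter = 0
    while score(lo) < 0:
        lo /= 4.0
        n_iter += 1
        if lo < 1e-6:
            raise RuntimeError("non-convergence: no sign change of the score on [1e-6, 1e6]")
    while score(hi) > 0:
        hi *= 4.0
        n_iter += 1
        if hi > 1e6:
            raise RuntimeError("non-convergence: no sign change of the score on [1e-6, 1e6]")
    lam_hat, res = brentq(score, lo, hi, xtol=1e-12, rtol=8.9e-16, full_output=True)
    n_iter += res.iterations

    if mode == "lambda-only":
        root = math.sqrt(lam_hat)
        params = FPFParams(root, root, sample.bounds)
    elif mode == "theta-fixed":
        if theta0 is None:
            raise ValueError("theta-fixed mode requires theta0")
        params = FPFParams(lam_hat / theta0, theta0, sample.bounds)
    elif mode == "alpha-fixed":
        if alpha0 is None:
            raise ValueError("alpha-fixed mode requires alpha0")
        params = FPFParams(alpha0, lam_hat / alpha0, sample.bounds)
    else:
        raise ValueError(f"unknown mode: {mode}")

    info_lam, _, _ = observed_information(params, sample)
    return FitResult(
        params=params,
        loglik=fpf_loglik(params, sample),
        mode=mode,
        se_lambda=1.0 / math.sqrt(info_lam),
        info_lambda=info_lam,
        converged=res.converged,
        n_iter=n_iter,
        sample=sample,
    )


def wald_ci(fit: FitResult, level: float = 0.95) -> IntervalEstimate:
    """Wald interval on the lam scale, transformed to the free presentation
    parameter when one parameter is fixed (the map is linear, so no delta
    correction is needed)."""
    if not fit.converged:
        raise ValueError("cannot build a Wald interval from a non-converged fit")
    if not math.isfinite(fit.se_lambda):
        raise ValueError("non-finite standard error")
    z = norm.ppf(0.5 + level / 2.0)
    lo = fit.lam - z * fit.se_lambda
    hi = fit.lam + z * fit.se_lambda
    if fit.mode == "theta-fixed":
        scale, param, point = fit.params.theta, "alpha", fit.params.alpha
    elif fit.mode == "alpha-fixed":
        scale, param, point = fit.params.alpha, "theta", fit.params.theta
    else:
        scale, param, point = 1.0, "lam", fit.lam
    return IntervalEstimate(
        point=point, lower=lo / scale, upper=hi / scale,
        level=level, method="wald", parameter=param,
    )


def bootstrap_ci(
    sample: Sample,
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int = 0,
    mode: str = "lambda-only",
    theta0: float | None = None,
    alpha0: float | None = None,
) -> IntervalEstimate:
    """Nonparametric bootstrap percentile interval for lam (or for the free
    parameter under a fixed-partner mode), with 1,000 resamples by default."""
    if sample.n < 10:
        raise ValueError("bootstrap requires at least 10 observations")
    rng = np.random.default_rng(seed)
    fit0 = fit_mle(sample, mode=mode, theta0=theta0, alpha0=alpha0)
    estimates = []
    failures = 0
    for _ in range(n_boot):
        idx = rng.integers(0, sample.n, sample.n)
        resample = Sample(sample.values[idx], sample.bounds, sample.bounds_rule)
        try:
            estimates.append(fit_mle(resample, mode=mode, theta0=theta0, alpha0=alpha0).lam)
        except (RuntimeError, ValueError):
            failures += 1
    if failures > 0.05 * n_boot:
        raise RuntimeError(f"bootstrap failed: {failures}/{n_boot} resample fits did not converge")
    est = np.sort(np.asarray(estimates))
    lo = float(np.quantile(est, 0.5 - level / 2.0))
    hi = float(np.quantile(est, 0.5 + level / 2.0))
    if mode == "theta-fixed":
        scale, param, point = theta0, "alpha", fit0.params.alpha
    elif mode == "alpha-fixed":
        scale, param, point = alpha0, "theta", fit0.params.theta
    else:
        scale, param, point = 1.0, "lam", fit0.lam
    return IntervalEstimate(
        point=point, lower=lo / scale, upper=hi / scale,
        level=level, method="bootstrap-percentile", parameter=param, n_boot=n_boot,
    )
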
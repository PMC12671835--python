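"""The seven comparison distributions for bounded-lifetime model selection.

Each model exposes ``pdf``/``cdf``/``logpdf`` and a ``fit`` classmethod
returning a fitted instance carrying ``name``, ``k`` (free-parameter count
for information criteria), ``params``, ``loglik`` and ``converged``.
Closed-form MLEs exist for the Exponential and Power Function models; the
rest use multi-start bounded quasi-Newton on log-parameters.

Two printed formulas in the source literature are degenerate: the
Kumaraswamy-PF and Weibull-PF exponents theta and alpha enter only through
their product, so the combined exponent is fitted and reported split as
theta = alpha = sqrt(exponent).  The Marshall-Olkin-PF CDF is the standard
Marshall-Olkin transform of the Power Function.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .core import SupportBounds

__all__ = [
    "FittedModel",
    "ExponentialModel",
    "PowerFunctionModel",
    "APTPowerFunctionModel",
    "WeibullPowerFunctionModel",
    "KumaraswamyPowerFunctionModel",
    "MarshallOlkinPowerFunctionModel",
    "ExponentiatedPowerFunctionModel",
    "exp_fit",
    "pf_fit",
    "aptpf_fit",
    "wpf_fit",
    "kwpf_fit",
    "mopf_fit",
    "epf_fit",
]


@dataclass
class FittedModel:
    name: str
    k: int
    params: dict
    loglik: float
    converged: bool
    n: int
    model: object = field(repr=False)

    def pdf(self, x):
        return self.model.pdf(x)

    def cdf(self, x):
        return self.model.cdf(x)

    def logpdf(self, x):
        return self.model.logpdf(x)


def _numeric_mle(neg_loglik_logspace, n_params: int, name: str):
    """Multi-start bounded quasi-Newton over log-parameters.

    Five log-spaced starting values per parameter axis (shared across
    axes); the best converged log-likelihood wins, ties broken by the
    smaller parameter norm.
    """
    starts = np.log(np.array([0.1, 0.4, 1.0, 2.5, 10.0]))
    best = None
    best_key = None
    for s in starts:
        x0 = np.full(n_params, s)
        res = minimize(neg_loglik_logspace, x0, method="L-BFGS-B",
                       bounds=[(-20.0, 20.0)] * n_params,
                       options={"ftol": 1e-12, "gtol": 1e-9, "maxiter": 1000})
        if not np.isfinite(res.fun):
            continue
        key = (round(res.fun, 9), not res.success, float(np.linalg.norm(res.x)))
        if best is None or key < best_key:
            best, best_key = res, key
    if best is None:
        raise RuntimeError(f"{name}: all optimizer starts failed")
    # derivative-free polish sharpens the optimum for gradient checks
    polish = minimize(neg_loglik_logspace, best.x, method="Nelder-Mead",
                      options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 2000})
    if np.isfinite(polish.fun) and polish.fun <= best.fun:
        polish.success = bool(best.success or polish.success)
        return polish
    return best


# ---------------------------------------------------------------------------


class ExponentialModel:
    """f(x) = lam * exp(-lam x) on x >= 0; closed-form MLE lam = 1/mean."""

    name = "exponential"
    k = 1

    def __init__(self, lam: float):
        if lam <= 0:
            raise ValueError("rate must be positive")
        self.lam = lam

    def pdf(self, x):
        x = np.asarray(x, dtype=float)
        return self.lam * np.exp(-self.lam * x)

    def logpdf(self, x):
        x = np.asarray(x, dtype=float)
        return math.log(self.lam) - self.lam * x

    def cdf(self, x):
        x = np.asarray(x, dtype=float)
        return -np.expm1(-self.lam * np.maximum(x, 0.0))

    @classmethod
    def fit(cls, values, bounds=None) -> FittedModel:
        vals = np.asarray(values, dtype=float)
        if np.any(vals <= 0):
            raise ValueError("exponential fit requires positive values")
        mean = vals.mean()
        if mean == 0:
            raise ValueError("zero mean")
        lam = 1.0 / mean
        model = cls(lam)
        ll = float(vals.size * math.log(lam) - lam * vals.sum())
        return FittedModel(cls.name, cls.k, {"lam": lam}, ll, True, vals.size, model)


class PowerFunctionModel:
    """Baseline Power Function: F = ((x-a)/(b-a))**theta on (a, b)."""

    name = "power-function"
    k = 1

    def __init__(self, theta: float, bounds: SupportBounds):
        if theta <= 0:
            raise ValueError("theta must be positive")
        self.theta = theta
        self.bounds = bounds

    def _v(self, x):
        return (np.asarray(x, dtype=float) - self.bounds.a) / self.bounds.width

    def pdf(self, x):
        v = self._v(x)
        return self.theta / self.bounds.width * v ** (self.theta - 1.0)

    def logpdf(self, x):
        v = self._v(x)
        return math.log(self.theta) - math.log(self.bounds.width) + (self.theta - 1.0) * np.log(v)

    def cdf(self, x):
        v = np.clip(self._v(x), 0.0, 1.0)
        return v**self.theta

    @classmethod
    def fit(cls, values, bounds: SupportBounds) -> FittedModel:
        vals = np.asarray(values, dtype=float)
        if np.any(vals <= bounds.a):
            raise ValueError("Power Function fit requires all values strictly above a")
        logv = np.log(vals - bounds.a) - math.log(bounds.width)
        theta = -vals.size / logv.sum()
        model = cls(theta, bounds)
        ll = float(model.logpdf(vals).sum())
        return FittedModel(cls.name, cls.k, {"theta": theta}, ll, True, vals.size, model)


class APTPowerFunctionModel:
    """Alpha-Power Transformed Power Function.

    F = (alpha**(v**theta) - 1)/(alpha - 1) with v = (x-a)/(b-a); the
    alpha -> 1 limit is the plain Power Function.
    """

    name = "apt-power-function"
    k = 2

    def __init__(self, alpha: float, theta: float, bounds: SupportBounds):
        if alpha <= 0 or theta <= 0:
            raise ValueError("alpha and theta must be positive")
        self.alpha = alpha
        self.theta = theta
        self.bounds = bounds

    def _v(self, x):
        return (np.asarray(x, dtype=float) - self.bounds.a) / self.bounds.width

    def _coef(self) -> float:
        # log(alpha)/(alpha-1), continuous through alpha = 1
        la = math.log(self.alpha)
        am1 = self.alpha - 1.0
        return 1.0 if abs(am1) < 1e-12 else la / am1

    def pdf(self, x):
        v = self._v(x)
        u = v**self.theta
        return (
            self._coef()
            * self.theta / self.bounds.width
            * v ** (self.theta - 1.0)
            * self.alpha**u
        )

    def logpdf(self, x):
        return np.log(self.pdf(x))

    def cdf(self, x):
        v = np.clip(self._v(x), 0.0, 1.0)
        u = v**self.theta
        am1 = self.alpha - 1.0
        if abs(am1) < 1e-12:
            return u
        return (self.alpha**u - 1.0) / am1

    @classmethod
    def fit(cls, values, bounds: SupportBounds) -> FittedModel:
        vals = np.asarray(values, dtype=float)

        def nll(logp):
            m = cls(math.exp(logp[0]), math.exp(logp[1]), bounds)
            with np.errstate(divide="ignore", invalid="ignore"):
                ll = m.logpdf(vals).sum()
            return -ll if np.isfinite(ll) else 1e12

        res = _numeric_mle(nll, 2, cls.name)
        alpha, theta = math.exp(res.x[0]), math.exp(res.x[1])
        model = cls(alpha, theta, bounds)
        return FittedModel(cls.name, cls.k, {"alpha": alpha, "theta": theta},
                           -res.fun, bool(res.success), vals.size, model)


class WeibullPowerFunctionModel:
    """Weibull-Power Function with the odd (ratio) construction:

    F = 1 - exp(-scale * (x/(b-x))**c) on (0, b), c = theta*alpha.

    The product reading x**theta * (b-x)**theta does not yield a valid CDF
    (it returns to 0 at b) and is exposed only through
    ``cdf_product_form`` for inspection.
    """

    name = "weibull-power-function"
    k = 3  # counted as (scale, theta, alpha) per the source convention

    def __init__(self, scale: float, exponent: float, b: float):
        if scale <= 0 or exponent <= 0 or b <= 0:
            raise ValueError("all parameters must be positive")
        self.scale = scale
        self.exponent = exponent
        self.b = b

    def _r(self, x):
        x = np.asarray(x, dtype=float)
        return x / (self.b - x)

    def cdf(self, x):
        x = np.asarray(x, dtype=float)
        out = np.where(x >= self.b, 1.0, -np.expm1(-self.scale * self._r(np.minimum(x, self.b * (1 - 1e-15))) ** self.exponent))
        return np.where(x <= 0, 0.0, out)

    def pdf(self, x):
        r = self._r(x)
        return (
            self.scale * self.exponent * r ** (self.exponent - 1.0)
            * self.b / (self.b - np.asarray(x, dtype=float)) ** 2
            * np.exp(-self.scale * r**self.exponent)
        )

    def logpdf(self, x):
        return np.log(self.pdf(x))

    @staticmethod
    def cdf_product_form(x, scale, exponent, b):
        """The literal product reading; not a CDF (returns to 0 at b)."""
        x = np.asarray(x, dtype=float)
        return -np.expm1(-scale * (x * (b - x)) ** exponent)

    @classmethod
    def fit(cls, values, bounds: SupportBounds, form: str = "ratio") -> FittedModel:
        if form != "ratio":
            raise ValueError("only the ratio (odd) form defines a fittable CDF")
        vals = np.asarray(values, dtype=float)
        b = bounds.b

        def nll(logp):
            m = cls(math.exp(logp[0]), math.exp(logp[1]), b)
            with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
                ll = m.logpdf(vals).sum()
            return -ll if np.isfinite(ll) else 1e12

        res = _numeric_mle(nll, 2, cls.name)
        scale, expo = math.exp(res.x[0]), math.exp(res.x[1])
        model = cls(scale, expo, b)
        root = math.sqrt(expo)
        return FittedModel(cls.name, cls.k,
                           {"scale": scale, "theta": root, "alpha": root, "b": b},
                           -res.fun, bool(res.success), vals.size, model)


class KumaraswamyPowerFunctionModel:
    """Kumaraswamy-Power Function: F = 1 - (1 - (x/gamma)**e)**beta on (0, gamma).

    theta and alpha enter only through the exponent e = theta*alpha.
    """

    name = "kumaraswamy-power-function"
    k = 2

    def __init__(self, exponent: float, beta: float, gamma: float):
        if exponent <= 0 or beta <= 0 or gamma <= 0:
            raise ValueError("all parameters must be positive")
        self.exponent = exponent
        self.beta = beta
        self.gamma = gamma

    def _u(self, x):
        return np.asarray(x, dtype=float) / self.gamma

    def cdf(self, x):
        u = np.clip(self._u(x), 0.0, 1.0)
        return 1.0 - (1.0 - u**self.exponent) ** self.beta

    def pdf(self, x):
        u = self._u(x)
        return (
            self.beta * self.exponent / self.gamma
            * u ** (self.exponent - 1.0)
            * (1.0 - u**self.exponent) ** (self.beta - 1.0)
        )

    def logpdf(self, x):
        u = self._u(x)
        return (
            math.log(self.beta * self.exponent / self.gamma)
            + (self.exponent - 1.0) * np.log(u)
            + (self.beta - 1.0) * np.log1p(-(u**self.exponent))
        )

    def quantile(self, q):
        q = np.asarray(q, dtype=float)
        return self.gamma * (1.0 - (1.0 - q) ** (1.0 / self.beta)) ** (1.0 / self.exponent)

    @classmethod
    def fit(cls, values, bounds: SupportBounds) -> FittedModel:
        vals = np.asarray(values, dtype=float)
        gamma = bounds.b

        def nll(logp):
            m = cls(math.exp(logp[0]), math.exp(logp[1]), gamma)
            with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
                ll = m.logpdf(vals).sum()
            return -ll if np.isfinite(ll) else 1e12

        res = _numeric_mle(nll, 2, cls.name)
        expo, beta = math.exp(res.x[0]), math.exp(res.x[1])
        model = cls(expo, beta, gamma)
        root = math.sqrt(expo)
        return FittedModel(cls.name, cls.k,
                           {"theta": root, "alpha": root, "beta": beta, "gamma": gamma},
                           -res.fun, bool(res.success), vals.size, model)


class MarshallOlkinPowerFunctionModel:
    """Marshall-Olkin transform of the Power Function:

    F = u**beta / (alpha + (1-alpha) u**beta), u = x/gamma, on (0, gamma).

    alpha = 1 reduces to the plain Power Function with exponent beta.
    """

    name = "marshall-olkin-power-function"
    k = 2

    def __init__(self, alpha: float, beta: float, gamma: float):
        if alpha <= 0 or beta <= 0 or gamma <= 0:
            raise ValueError("all parameters must be positive")
        self.alpha = alpha
        self.beta = beta
        self.gamma = gamma

    def _u(self, x):
        return np.asarray(x, dtype=float) / self.gamma

    def cdf(self, x):
        t = np.clip(self._u(x), 0.0, 1.0) ** self.beta
        return t / (self.alpha + (1.0 - self.alpha) * t)

    def pdf(self, x):
        u = self._u(x)
        t = u**self.beta
        return (
            self.alpha * self.beta * u ** (self.beta - 1.0)
            / (self.gamma * (self.alpha + (1.0 - self.alpha) * t) ** 2)
        )

    def logpdf(self, x):
        return np.log(self.pdf(x))

    @classmethod
    def fit(cls, values, bounds: SupportBounds) -> FittedModel:
        vals = np.asarray(values, dtype=float)
        gamma = bounds.b

        def nll(logp):
            m = cls(math.exp(logp[0]), math.exp(logp[1]), gamma)
            with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
                ll = m.logpdf(vals).sum()
            return -ll if np.isfinite(ll) else 1e12

        res = _numeric_mle(nll, 2, cls.name)
        alpha, beta = math.exp(res.x[0]), math.exp(res.x[1])
        model = cls(alpha, beta, gamma)
        return FittedModel(cls.name, cls.k, {"alpha": alpha, "beta": beta, "gamma": gamma},
                           -res.fun, bool(res.success), vals.size, model)


class ExponentiatedPowerFunctionModel:
    """Exponentiated Power Function: F = (1 - ((b-x)/(b-a))**theta)**alpha."""

    name = "exponentiated-power-function"
    k = 2

    def __init__(self, theta: float, alpha: float, bounds: SupportBounds):
        if theta <= 0 or alpha <= 0:
            raise ValueError("theta and alpha must be positive")
        self.theta = theta
        self.alpha = alpha
        self.bounds = bounds

    def _w(self, x):
        bd = self.bounds
        return (bd.b - np.asarray(x, dtype=float)) / bd.width

    def cdf(self, x):
        w = np.clip(self._w(x), 0.0, 1.0)
        return (1.0 - w**self.theta) ** self.alpha

    def pdf(self, x):
        w = self._w(x)
        return (
            self.alpha * self.theta / self.bounds.width
            * w ** (self.theta - 1.0)
            * (1.0 - w**self.theta) ** (self.alpha - 1.0)
        )

    def logpdf(self, x):
        w = self._w(x)
        return (
            math.log(self.alpha * self.theta / self.bounds.width)
            + (self.theta - 1.0) * np.log(w)
            + (self.alpha - 1.0) * np.log1p(-(w**self.theta))
        )

    def quantile(self, q):
        q = np.asarray(q, dtype=float)
        bd = self.bounds
        return bd.b - bd.width * (1.0 - q ** (1.0 / self.alpha)) ** (1.0 / self.theta)

    @classmethod
    def fit(cls, values, bounds: SupportBounds) -> FittedModel:
        vals = np.asarray(values, dtype=float)

        def nll(logp):
            m = cls(math.exp(logp[0]), math.exp(logp[1]), bounds)
            with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
                ll = m.logpdf(vals).sum()
            return -ll if np.isfinite(ll) else 1e12

        res = _numeric_mle(nll, 2, cls.name)
        theta, alpha = math.exp(res.x[0]), math.exp(res.x[1])
        model = cls(theta, alpha, bounds)
        return FittedModel(cls.name, cls.k, {"theta": theta, "alpha": alpha},
                           -res.fun, bool(res.success), vals.size, model)


# convenience fit functions mirroring the module's operation names

def exp_fit(values, bounds: SupportBounds | None = None) -> FittedModel:
    return ExponentialModel.fit(values)


def pf_fit(values, bounds: SupportBounds) -> FittedModel:
    return PowerFunctionModel.fit(values, bounds)


def aptpf_fit(values, bounds: SupportBounds) -> FittedModel:
    return APTPowerFunctionModel.fit(values, bounds)


def wpf_fit(values, bounds: SupportBounds, form: str = "ratio") -> FittedModel:
    return WeibullPowerFunctionModel.fit(values, bounds, form=form)


def kwpf_fit(values, bounds: SupportBounds) -> FittedModel:
    return KumaraswamyPowerFunctionModel.fit(values, bounds)


def mopf_fit(values, bounds: SupportBounds) -> FittedModel:
    return MarshallOlkinPowerFunctionModel.fit(values, bounds)


def epf_fit(values, bounds: SupportBounds) -> FittedModel:
    return ExponentiatedPowerFunctionModel.fit(values, bounds)
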
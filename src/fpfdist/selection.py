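"""Information criteria, empirical goodness-of-fit statistics, and
likelihood-ratio / Vuong model-comparison tests.

Conventions: CAIC is the small-sample corrected AIC (AICc),
``AIC + 2k(k+1)/(n-k-1)``; HQIC is ``2k log log n - 2l``.  KS p-values use
the asymptotic Kolmogorov distribution without an estimated-parameter
adjustment (the usual practice; a parametric-bootstrap adjustment is out
of scope).  The likelihood-ratio test is for nested pairs and the Vuong
test for non-nested pairs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.special import kolmogorov
from scipy.stats import chi2, norm

from .core import SupportBounds, fpf_cdf
from . import competitors as comp
from .inference import Sample, fit_mle

__all__ = [
    "GofReport",
    "PairwiseTest",
    "InformationCriteria",
    "information_criteria",
    "ks_statistic",
    "cvm_statistic",
    "ad_statistic",
    "lr_test",
    "vuong_test",
    "compare_models",
    "reports_to_frame",
]


class InformationCriteria(NamedTuple):
    aic: float
    bic: float
    caic: float
    hqic: float


@dataclass(frozen=True)
class GofReport:
    model_name: str
    k: int
    n: int
    loglik: float
    aic: float
    bic: float
    caic: float
    hqic: float
    ks_d: float
    ks_p: float
    cvm_w: float
    ad_a: float
    params: dict
    converged: bool
    error: str | None = None


@dataclass(frozen=True)
class PairwiseTest:
    kind: str  # "likelihood-ratio" | "vuong"
    model_1: str
    model_2: str
    statistic: float
    p_value: float
    better_model: str | None
    df: int | None = None
    warning: str | None = None


def information_criteria(loglik: float, k: int, n: int) -> InformationCriteria:
    """AIC, BIC, CAIC (=AICc) and HQIC from a maximized log-likelihood."""
    if n <= k + 1:
        raise ValueError("CAIC undefined: need n > k + 1")
    aic = 2 * k - 2 * loglik
    return InformationCriteria(
        aic=aic,
        bic=k * math.log(n) - 2 * loglik,
        caic=aic + 2 * k * (k + 1) / (n - k - 1),
        hqic=2 * k * math.log(math.log(n)) - 2 * loglik,
    )


def _sorted_u(values, fitted_cdf: Callable) -> np.ndarray:
    x = np.sort(np.asarray(values, dtype=float))
    return np.asarray(fitted_cdf(x), dtype=float)


def ks_statistic(values, fitted_cdf: Callable) -> tuple[float, float]:
    """One-sample Kolmogorov-Smirnov statistic and asymptotic p-value.

    D is the exact sup-distance over the order statistics; the p-value is
    from the limiting Kolmogorov distribution (no adjustment for
    parameters estimated from the same data).
    """
    u = _sorted_u(values, fitted_cdf)
    n = u.size
    i = np.arange(1, n + 1)
    d = float(np.max(np.maximum(i / n - u, u - (i - 1) / n)))
    p = float(kolmogorov(math.sqrt(n) * d))
    return d, p


def cvm_statistic(values, fitted_cdf: Callable) -> float:
    """Cramer-von Mises W = 1/(12n) + sum (u_(i) - (2i-1)/(2n))^2."""
    u = _sorted_u(values, fitted_cdf)
    n = u.size
    i = np.arange(1, n + 1)
    return float(1.0 / (12 * n) + np.sum((u - (2 * i - 1) / (2 * n)) ** 2))


def ad_statistic(values, fitted_cdf: Callable) -> float:
    """Anderson-Darling A^2 = -n - (1/n) sum (2i-1)[log u_(i) + log(1-u_(n+1-i))]."""
    u = _sorted_u(values, fitted_cdf)
    if np.any(u <= 0.0) or np.any(u >= 1.0):
        raise ValueError("Anderson-Darling undefined: fitted CDF hits 0 or 1 at a data point")
    n = u.size
    i = np.arange(1, n + 1)
    return float(-n - np.mean((2 * i - 1) * (np.log(u) + np.log(1.0 - u[::-1]))))


def lr_test(loglik_full, loglik_reduced, df: int,
            model_1: str = "full", model_2: str = "reduced") -> PairwiseTest:
    """Likelihood-ratio test for nested models: 2(l_full - l_reduced) ~ chi2(df).

    Accepts floats or objects exposing ``.loglik``.  A negative statistic
    (nesting violated) is kept, with a warning attached.
    """
    lf = getattr(loglik_full, "loglik", loglik_full)
    lr = getattr(loglik_reduced, "loglik", loglik_reduced)
    stat = 2.0 * (lf - lr)
    warning = None
    if stat < 0:
        warning = "negative LR statistic: nesting assumption violated"
    p = float(chi2.sf(max(stat, 0.0), df))
    better = model_1 if stat > 0 else (model_2 if stat < 0 else None)
    return PairwiseTest("likelihood-ratio", model_1, model_2, float(stat), p,
                        better, df=df, warning=warning)


def vuong_test(loglik_pointwise_1, loglik_pointwise_2,
               model_1: str = "model-1", model_2: str = "model-2") -> PairwiseTest:
    """Vuong closeness test for non-nested models.

    statistic = sqrt(n) * mean(m) / sd(m) with m_i the pointwise
    log-likelihood differences; two-sided normal p-value; the sign picks
    the better model.
    """
    m = np.asarray(loglik_pointwise_1, dtype=float) - np.asarray(loglik_pointwise_2, dtype=float)
    if m.shape != np.asarray(loglik_pointwise_1).shape:
        raise ValueError("pointwise log-likelihood vectors must have equal length")
    n = m.size
    sd = float(m.std(ddof=1))
    if sd == 0.0:
        return PairwiseTest("vuong", model_1, model_2, 0.0, 1.0, None,
                            warning="indistinguishable models (zero variance)")
    stat = math.sqrt(n) * float(m.mean()) / sd
    p = 2.0 * float(norm.sf(abs(stat)))
    better = model_1 if stat > 0 else (model_2 if stat < 0 else None)
    return PairwiseTest("vuong", model_1, model_2, float(stat), p, better)


# ---------------------------------------------------------------------------

# default competitor set for the application tables
_FITTERS: dict[str, Callable] = {
    "fpf": None,  # handled specially
    "exponential": lambda vals, bd: comp.exp_fit(vals),
    "power-function": comp.pf_fit,
    "apt-power-function": comp.aptpf_fit,
    "weibull-power-function": comp.wpf_fit,
    "kumaraswamy-power-function": comp.kwpf_fit,
    "marshall-olkin-power-function": comp.mopf_fit,
    "exponentiated-power-function": comp.epf_fit,
}

# pairs treated as nested with the FPF for the LR test (the paper's choice;
# strictly the Power Function is not a special case of the FPF because of
# the exp(-v^lam) tilt -- callers can reconfigure)
DEFAULT_NESTED = frozenset({"power-function"})


class _FpfAdapter:
    """Presents a fitted FPF like a competitor model for table assembly."""

    def __init__(self, fit):
        self.fit = fit
        self.name = "fpf"
        self.k = 2  # counted as (alpha, theta) following the source convention
        self.params = {"lam": fit.lam, "alpha": fit.params.alpha, "theta": fit.params.theta}
        self.loglik = fit.loglik
        self.converged = fit.converged
        self.n = fit.sample.n

    def cdf(self, x):
        return fpf_cdf(x, self.fit.params)

    def logpdf(self, x):
        from .core import fpf_logpdf
        return fpf_logpdf(x, self.fit.params)


def compare_models(
    values,
    model_set: Sequence[str] | None = None,
    bounds_rule: str = "zero-to-inflated-max",
    bounds: SupportBounds | None = None,
    nested: frozenset = DEFAULT_NESTED,
) -> tuple[list[GofReport], list[PairwiseTest]]:
    """Fit a set of models to one dataset and build the comparison table.

    Returns GofReports sorted by AIC plus pairwise tests of every other
    model against the FPF (likelihood-ratio for the configured nested set,
    Vuong otherwise).  Individual fit failures are recorded per row and
    never abort the table.  The default bounds rule inflates the upper
    bound by 1e-6 above the sample maximum so that competitors whose
    density vanishes or diverges at the boundary keep finite likelihoods.
    """
    vals = np.asarray(values, dtype=float)
    names = list(model_set) if model_set is not None else list(_FITTERS)
    if len(names) < 2:
        raise ValueError("need at least 2 models to compare")
    sample = Sample.from_values(vals, bounds=bounds, rule=bounds_rule)
    bd = sample.bounds

    fitted: dict[str, object] = {}
    reports: list[GofReport] = []
    for name in names:
        try:
            if name == "fpf":
                model = _FpfAdapter(fit_mle(sample))
            else:
                model = _FITTERS[name](vals, bd)
            ics = information_criteria(model.loglik, model.k, vals.size)
            d, p = ks_statistic(vals, model.cdf)
            w = cvm_statistic(vals, model.cdf)
            try:
                a = ad_statistic(vals, model.cdf)
            except ValueError:
                a = float("nan")
            fitted[name] = model
            reports.append(GofReport(
                model_name=name, k=model.k, n=vals.size, loglik=model.loglik,
                aic=ics.aic, bic=ics.bic, caic=ics.caic, hqic=ics.hqic,
                ks_d=d, ks_p=p, cvm_w=w, ad_a=a,
                params=dict(model.params), converged=model.converged,
            ))
        except Exception as exc:  # record the failure, keep the table going
            reports.append(GofReport(
                model_name=name, k=0, n=vals.size, loglik=float("nan"),
                aic=float("inf"), bic=float("inf"), caic=float("inf"),
                hqic=float("inf"), ks_d=float("nan"), ks_p=float("nan"),
                cvm_w=float("nan"), ad_a=float("nan"), params={},
                converged=False, error=str(exc),
            ))
    reports.sort(key=lambda r: r.aic)

    tests: list[PairwiseTest] = []
    if "fpf" in fitted:
        ref = fitted["fpf"]
        ll_ref = np.asarray(ref.logpdf(vals), dtype=float)
        for name, model in fitted.items():
            if name == "fpf":
                continue
            if name in nested:
                df = max(ref.k - model.k, 1)
                tests.append(lr_test(ref.loglik, model.loglik, df,
                                     model_1="fpf", model_2=name))
            else:
                tests.append(vuong_test(ll_ref, np.asarray(model.logpdf(vals), dtype=float),
                                        model_1="fpf", model_2=name))
    return reports, tests


def reports_to_frame(reports: Sequence[GofReport]) -> pd.DataFrame:
    """Tabular (long) form of a list of GofReports."""
    return pd.DataFrame([
        {
            "model": r.model_name, "k": r.k, "n": r.n, "loglik": r.loglik,
            "AIC": r.aic, "BIC": r.bic, "CAIC": r.caic, "HQIC": r.hqic,
            "KS_D": r.ks_d, "KS_p": r.ks_p, "W": r.cvm_w, "A": r.ad_a,
            "converged": r.converged, "error": r.error,
        }
        for r in reports
    ])
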
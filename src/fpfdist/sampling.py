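"""Random variate generation for the FPF distribution.

Two samplers: inverse transform through the closed-form quantile function
(the workhorse, used by the simulation harness) and acceptance-rejection
with a Power Function proposal on the same support.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .core import FPFParams, fpf_quantile

__all__ = ["SampleDraw", "rvs_inverse", "rvs_accept_reject"]

_ONE_MINUS_EINV = -math.expm1(-1.0)


@dataclass(frozen=True)
class SampleDraw:
    values: np.ndarray
    n: int
    seed: int
    method: str  # "inverse" | "accept-reject"
    acceptance_rate: float | None = None
    proposal_exponent: float | None = None
    bound_constant: float | None = None


def rvs_inverse(n: int, params: FPFParams, seed: int) -> SampleDraw:
    """Draw ``n`` variates by inverse transform from a seeded generator."""
    if n < 1:
        raise ValueError("n must be at least 1")
    rng = np.random.default_rng(seed)
    u = rng.random(n)
    values = fpf_quantile(u, params)
    return SampleDraw(values=np.asarray(values), n=n, seed=seed, method="inverse")


def _log_ratio_max(lam: float, p: float) -> float:
    """sup over v in (0,1) of f/g for a PF(p) proposal.

    f/g = (lam/p) * v**(lam-p) * exp(-v**lam) / (1 - e^-1).
    Unbounded at v -> 0 when p > lam (raises); analytic 1/(1-e^-1) when
    p == lam; otherwise found by bounded 1-D maximization.
    """
    if p > lam:
        raise ValueError(
            "proposal exponent exceeds lam: density ratio diverges at the lower endpoint a"
        )
    if p == lam:
        return 1.0 / _ONE_MINUS_EINV

    def neg_log_ratio(logv: float) -> float:
        v = math.exp(logv)
        return -(math.log(lam / p) + (lam - p) * logv - v**lam - math.log(_ONE_MINUS_EINV))

    res = minimize_scalar(neg_log_ratio, bounds=(-60.0, 0.0), method="bounded")
    # endpoint v=1 can carry the sup for p < lam with small lam
    cand = [math.exp(-res.fun), math.exp(-neg_log_ratio(0.0))]
    return max(cand)


def rvs_accept_reject(
    n: int,
    params: FPFParams,
    proposal_exponent: float | None = None,
    seed: int = 0,
) -> SampleDraw:
    """Acceptance-rejection with a Power Function proposal.

    The proposal PF(p) on (a, b) has density ``p v**(p-1) / (b-a)``; the
    default ``p = lam`` makes the density ratio monotone with analytic
    bound ``c = 1/(1 - e^-1)`` and acceptance probability ``1 - e^-1``
    (about 63.2%).  Two uniforms are consumed per proposal in a fixed
    order (one for the proposal draw, one for the accept test).
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    lam = params.lam
    p = lam if proposal_exponent is None else float(proposal_exponent)
    if p <= 0:
        raise ValueError("proposal_exponent must be positive")
    c = _log_ratio_max(lam, p)
    log_c = math.log(c)
    bd = params.bounds
    rng = np.random.default_rng(seed)

    accepted: list[np.ndarray] = []
    n_accept = 0
    n_total = 0
    while n_accept < n:
        m = max(int((n - n_accept) * c * 1.2) + 16, 64)
        u = rng.random((m, 2))
        v = u[:, 0] ** (1.0 / p)  # PF(p) proposal on (0,1) scale
        with np.errstate(divide="ignore"):
            logv = np.log(v)
        # log f/g - log c
        log_acc = (
            math.log(lam / p)
            + (lam - p) * logv
            - np.exp(lam * logv)
            - math.log(_ONE_MINUS_EINV)
            - log_c
        )
        keep = np.log(u[:, 1]) <= log_acc
        got = v[keep]
        if n_accept + got.size >= n:
            # count proposals only up to the one yielding the n-th acceptance
            need = n - n_accept
            idx = np.flatnonzero(keep)[need - 1]
            n_total += int(idx) + 1
            got = got[:need]
        else:
            n_total += m
        accepted.append(got)
        n_accept += got.size
    values = np.concatenate(accepted)
    rate = n / n_total
    return SampleDraw(
        values=bd.a + bd.width * values,
        n=n,
        seed=seed,
        method="accept-reject",
        acceptance_rate=rate,
        proposal_exponent=p,
        bound_constant=c,
    )
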
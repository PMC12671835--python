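"""Analytic functions of the Frechet-Power Function (FPF) distribution.

The FPF distribution arises from applying a modified Frechet generator
``u -> (exp(-u**alpha) - 1) / (exp(-1) - 1)`` to the Power Function
baseline CDF ``((x - a)/(b - a))**theta`` on a known finite support
``(a, b)``.  The resulting CDF is

    F(x) = (exp(-v**lam) - 1) / (exp(-1) - 1),   v = (x - a)/(b - a),

where the two shape parameters enter only through their product
``lam = alpha * theta``.  Internally everything is parameterized by
``lam``; ``alpha`` and ``theta`` are retained as presentation attributes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SupportBounds",
    "FPFParams",
    "HazardShape",
    "fpf_pdf",
    "fpf_logpdf",
    "fpf_cdf",
    "fpf_sf",
    "fpf_hazard",
    "fpf_quantile",
    "classify_hazard_shape",
]

# exp(-1) - 1, the normalizing constant of the Frechet generator
_EM1 = math.expm1(-1.0)  # = e^-1 - 1, negative
_ONE_MINUS_EINV = -_EM1  # = 1 - e^-1


@dataclass(frozen=True)
class SupportBounds:
    """Known finite support endpoints ``a < b``."""

    a: float
    b: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.a) and math.isfinite(self.b)):
            raise ValueError("support bounds must be finite")
        if not self.a < self.b:
            raise ValueError(f"lower bound must be strictly below upper: a={self.a}, b={self.b}")

    @property
    def width(self) -> float:
        return self.b - self.a


@dataclass(frozen=True)
class FPFParams:
    """FPF shape parameters (alpha, theta) on a support.

    The density depends on (alpha, theta) only via the product
    ``lam = alpha * theta``; two parameter objects with equal bounds and
    equal ``lam`` describe the same distribution.
    """

    alpha: float
    theta: float
    bounds: SupportBounds = field(default_factory=lambda: SupportBounds(0.0, 1.0))

    def __post_init__(self) -> None:
        if not (self.alpha > 0 and self.theta > 0):
            raise ValueError("alpha and theta must be positive")

    @property
    def lam(self) -> float:
        """Product shape parameter lambda = alpha * theta."""
        return self.alpha * self.theta

    @classmethod
    def from_lam(cls, lam: float, bounds: SupportBounds | None = None) -> "FPFParams":
        """Build parameters from the identifying product, splitting it
        symmetrically (alpha = theta = sqrt(lam))."""
        if lam <= 0:
            raise ValueError("lam must be positive")
        root = math.sqrt(lam)
        return cls(root, root, bounds or SupportBounds(0.0, 1.0))


@dataclass(frozen=True)
class HazardShape:
    """Classification of the hazard curve on an evaluation grid."""

    label: str  # increasing | decreasing | bathtub | unimodal | approximately-constant | unclassified
    grid_size: int
    rel_tolerance: float


def _v(x: np.ndarray, params: FPFParams) -> np.ndarray:
    bd = params.bounds
    return (np.asarray(x, dtype=float) - bd.a) / bd.width


def fpf_pdf(x, params: FPFParams, *, boundary: str = "limit"):
    """FPF probability density.

    ``x`` may be a scalar or array with values in the open support
    ``(a, b)``.  The endpoints are handled per ``boundary``:

    - ``"limit"`` (default): f(b) is the finite limit
      ``lam * e^-1 / ((b-a)(1-e^-1))``; f(a) is the limit 0 for lam > 1,
      ``lam / ((b-a)(1-e^-1))`` for lam == 1, and raises for lam < 1
      (the density diverges there).
    - ``"error"``: any endpoint value raises.

    Values outside the closed support always raise.
    """
    x_arr = np.asarray(x, dtype=float)
    bd = params.bounds
    if np.any(x_arr < bd.a) or np.any(x_arr > bd.b):
        raise ValueError(f"x outside support [{bd.a}, {bd.b}]")
    at_a = x_arr == bd.a
    at_b = x_arr == bd.b
    if boundary == "error" and (np.any(at_a) or np.any(at_b)):
        raise ValueError("x on the support boundary")
    lam = params.lam
    if lam < 1 and np.any(at_a):
        raise ValueError("density diverges at x = a for lam < 1")
    v = _v(x_arr, params)
    with np.errstate(divide="ignore"):
        out = lam / (bd.width * _ONE_MINUS_EINV) * v ** (lam - 1.0) * np.exp(-(v**lam))
    # v=0, lam>1 gives 0 already; lam==1 gives the finite constant already
    return out.item() if np.isscalar(x) or x_arr.ndim == 0 else out


def fpf_logpdf(x, params: FPFParams):
    """Log-density computed without forming the unlogged density.

    Stable for large ``lam`` where ``fpf_pdf`` underflows near ``a``.
    """
    x_arr = np.asarray(x, dtype=float)
    bd = params.bounds
    if np.any(x_arr <= bd.a) or np.any(x_arr > bd.b):
        raise ValueError(f"x outside half-open support ({bd.a}, {bd.b}]")
    lam = params.lam
    v = _v(x_arr, params)
    logv = np.log(v)
    out = (
        math.log(lam)
        - math.log(bd.width)
        - math.log(_ONE_MINUS_EINV)
        + (lam - 1.0) * logv
        - np.exp(lam * logv)
    )
    return out.item() if np.isscalar(x) or x_arr.ndim == 0 else out


def fpf_cdf(x, params: FPFParams):
    """FPF cumulative distribution; clamps to 0 below ``a`` and 1 above ``b``."""
    x_arr = np.asarray(x, dtype=float)
    v = np.clip(_v(x_arr, params), 0.0, 1.0)
    out = np.expm1(-(v ** params.lam)) / _EM1
    return out.item() if np.isscalar(x) or x_arr.ndim == 0 else out


def fpf_sf(x, params: FPFParams):
    """Survival function S(x) = 1 - F(x)."""
    x_arr = np.asarray(x, dtype=float)
    v = np.clip(_v(x_arr, params), 0.0, 1.0)
    # 1 - expm1(-v^lam)/expm1(-1) = (exp(-v^lam) - e^-1) / (1 - e^-1)
    out = (np.exp(-(v ** params.lam)) - math.exp(-1.0)) / _ONE_MINUS_EINV
    return out.item() if np.isscalar(x) or x_arr.ndim == 0 else out


def fpf_hazard(x, params: FPFParams):
    """Hazard rate h(x) = f(x)/S(x) on the open support.

    Raises for ``x >= b`` where survival is zero.
    """
    x_arr = np.asarray(x, dtype=float)
    bd = params.bounds
    if np.any(x_arr >= bd.b):
        raise ValueError("hazard diverges at and beyond x = b (survival is 0)")
    if np.any(x_arr <= bd.a):
        raise ValueError(f"x outside open support ({bd.a}, {bd.b})")
    out = np.exp(fpf_logpdf(x_arr, params)) / fpf_sf(x_arr, params)
    return out.item() if np.isscalar(x) or x_arr.ndim == 0 else out


def fpf_quantile(u, params: FPFParams):
    """Quantile function Q(u) = a + (b-a) * (-ln(1 + u(e^-1 - 1)))**(1/lam).

    Q(0) = a and Q(1) = b exactly; ``u`` outside [0, 1] raises.
    """
    u_arr = np.asarray(u, dtype=float)
    if np.any(u_arr < 0.0) or np.any(u_arr > 1.0):
        raise ValueError("u must lie in [0, 1]")
    bd = params.bounds
    inner = -np.log1p(u_arr * _EM1)
    out = bd.a + bd.width * inner ** (1.0 / params.lam)
    return out.item() if np.isscalar(u) or u_arr.ndim == 0 else out


def classify_hazard_shape(
    params: FPFParams,
    grid_size: int = 2001,
    rel_tolerance: float = 1e-6,
) -> HazardShape:
    """Classify the hazard curve by the sign pattern of successive differences.

    The hazard is evaluated on ``grid_size`` equispaced points on
    ``[a + 1e-4 (b-a), b - 1e-4 (b-a)]`` (avoiding boundary singularities).
    Relative changes below ``rel_tolerance`` count as flat.  Sign runs map
    to labels: all + -> increasing, all - -> decreasing, - then + ->
    bathtub, + then - -> unimodal, none -> approximately-constant.  More
    than two runs yields "unclassified" (tolerance too tight).
    """
    if grid_size < 50:
        raise ValueError("grid_size must be at least 50")
    bd = params.bounds
    eps = 1e-4 * bd.width
    grid = np.linspace(bd.a + eps, bd.b - eps, grid_size)
    h = fpf_hazard(grid, params)
    diff = np.diff(h)
    scale = np.maximum(np.abs(h[:-1]), np.abs(h[1:]))
    rel = np.where(scale > 0, np.abs(diff) / scale, 0.0)
    signs = np.sign(diff)
    signs[rel < rel_tolerance] = 0
    # compress nonzero signs into runs
    nz = signs[signs != 0]
    runs: list[int] = []
    for s in nz:
        if not runs or runs[-1] != s:
            runs.append(int(s))
    if not runs:
        label = "approximately-constant"
    elif runs == [1]:
        label = "increasing"
    elif runs == [-1]:
        label = "decreasing"
    elif runs == [-1, 1]:
        label = "bathtub"
    elif runs == [1, -1]:
        label = "unimodal"
    else:
        label = "unclassified"
    return HazardShape(label=label, grid_size=grid_size, rel_tolerance=rel_tolerance)
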
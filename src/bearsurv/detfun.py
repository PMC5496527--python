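"""Parametric detection functions for aerial line-transect surveys.

Two shapes are used:

* a half-normal ``g(x) = exp(−x²/(2σ²))`` for conventional distance sampling
  on left-truncated (monotone-declining) distances, and
* a two-piece normal with an apex at distance ``c`` from the line,
  ``g(x) = exp(−(x−c)²/(2σ₁²))`` left of the apex and the same with σ₂ to the
  right — the humped curve typical of tandem-seat aerial surveys, where the
  strip directly beneath the aircraft is poorly visible.

Both are *shapes*: g(apex) = 1 by construction, and absolute detection at the
apex is supplied separately by the double-observer mark–recapture component.
The fitting likelihood is the renormalized density g(x)/μ on [0, w], so no
vertical scaling parameter is estimated here.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Protocol, Sequence, runtime_checkable

import numpy as np
from scipy import integrate, optimize, special

__all__ = [
    "DetectionShape",
    "HalfNormalCurve",
    "TwoPieceNormalCurve",
    "eval_halfnormal",
    "eval_twopiece",
    "effective_strip_width",
    "fit_twopiece_ml",
    "TwoPieceFit",
]

_SQRT_HALF_PI = math.sqrt(math.pi / 2.0)
_SQRT2 = math.sqrt(2.0)


@runtime_checkable
class DetectionShape(Protocol):
    """A detection-probability shape g with g ∈ [0, 1] on [0, w]."""

    def evaluate(self, x): ...

    def integral(self, w: float) -> float: ...


def _hn_integral(sigma: float, w: float) -> float:
    # ∫₀ʷ exp(−x²/2σ²) dx = σ√(π/2)·erf(w/(σ√2))
    return sigma * _SQRT_HALF_PI * special.erf(w / (sigma * _SQRT2))


@dataclass(frozen=True)
class HalfNormalCurve:
    """Half-normal detection shape with scale σ in meters; g(0) = 1."""

    sigma: float

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError(f"sigma must be > 0, got {self.sigma}")

    def evaluate(self, x):
        x = np.asarray(x, dtype=float)
        out = np.exp(-(x ** 2) / (2.0 * self.sigma ** 2))
        return out if out.ndim else float(out)

    def integral(self, w: float) -> float:
        """Closed-form ∫₀ʷ g(x) dx via the error function."""
        return _hn_integral(self.sigma, w)


@dataclass(frozen=True)
class TwoPieceNormalCurve:
    """Two-piece normal detection shape: apex at c, scales σ₁ (left) / σ₂ (right)."""

    apex_c: float
    sigma_left: float
    sigma_right: float

    def __post_init__(self) -> None:
        if self.apex_c < 0:
            raise ValueError("apex_c must be ≥ 0")
        if self.sigma_left <= 0 or self.sigma_right <= 0:
            raise ValueError("sigma_left and sigma_right must be > 0")

    def evaluate(self, x):
        x = np.asarray(x, dtype=float)
        dev = x - self.apex_c
        sig = np.where(dev <= 0, self.sigma_left, self.sigma_right)
        out = np.exp(-(dev ** 2) / (2.0 * sig ** 2))
        return out if out.ndim else float(out)

    def integral(self, w: float) -> float:
        """Closed form: left piece over [0, c] plus right piece over [c, w]."""
        c = min(self.apex_c, w)
        left = self.sigma_left * _SQRT_HALF_PI * special.erf(c / (self.sigma_left * _SQRT2))
        right = 0.0
        if w > self.apex_c:
            right = _hn_integral(self.sigma_right, w - self.apex_c)
        return float(left + right)


def eval_halfnormal(x, sigma: float):
    """exp(−x²/(2σ²)); the CDS detection shape on left-truncated distances."""
    if sigma <= 0:
        raise ValueError(f"sigma must be > 0, got {sigma}")
    return HalfNormalCurve(sigma).evaluate(x)


def eval_twopiece(x, curve: TwoPieceNormalCurve):
    """Evaluate the two-piece normal shape at x (meters)."""
    return curve.evaluate(x)


def effective_strip_width(shape: DetectionShape, w: float) -> float:
    """Effective strip width μ = ∫₀ʷ g(x) dx by adaptive quadrature.

    μ is the width of a perfectly surveyed strip yielding the same expected
    number of detections as the real strip of width w.
    """
    if w <= 0:
        raise ValueError(f"w must be > 0, got {w}")
    breakpoints = None
    if isinstance(shape, TwoPieceNormalCurve) and 0 < shape.apex_c < w:
        breakpoints = [shape.apex_c]
    val, _err = integrate.quad(lambda x: float(np.asarray(shape.evaluate(x))),
                               0.0, w, points=breakpoints, epsrel=1e-10, epsabs=0.0, limit=200)
    if not math.isfinite(val):
        raise ArithmeticError("non-finite integrand in effective_strip_width")
    return float(val)


@dataclass(frozen=True)
class TwoPieceFit:
    """ML fit of the two-piece normal shape to pooled perpendicular distances."""

    curve: TwoPieceNormalCurve
    loglik: float
    w: float
    n: int

    def to_json(self) -> str:
        return json.dumps({
            "family": "two_piece_normal",
            "c": self.curve.apex_c,
            "sigma1": self.curve.sigma_left,
            "sigma2": self.curve.sigma_right,
            "w": self.w,
            "loglik": self.loglik,
        })


def _twopiece_negloglik(params: np.ndarray, x: np.ndarray, w: float) -> float:
    c, s1, s2 = params
    if s1 <= 0 or s2 <= 0:
        return np.inf
    dev = x - c
    sig = np.where(dev <= 0, s1, s2)
    logg = -(dev ** 2) / (2.0 * sig ** 2)
    mu = TwoPieceNormalCurve(max(c, 0.0), s1, s2).integral(w)
    if mu <= 0 or not math.isfinite(mu):
        return np.inf
    return float(-(logg.sum() - x.size * math.log(mu)))


def _latin_starts(w: float, c_max: float) -> np.ndarray:
    """8 deterministic starts on a Latin grid over (c, σ₁, σ₂)."""
    # stratified fractions, fixed permutations: spreads starts over the box
    frac = (np.arange(8) + 0.5) / 8.0
    c0 = c_max * frac
    s_lo, s_hi = w / 50.0, w
    s1 = s_lo + (s_hi - s_lo) * frac[[3, 6, 1, 4, 7, 0, 5, 2]]
    s2 = s_lo + (s_hi - s_lo) * frac[[5, 2, 7, 0, 3, 6, 1, 4]]
    return np.column_stack([c0, s1, s2])


def fit_twopiece_ml(
    distances: Sequence[float],
    w: float,
    c_max: float | None = None,
    starts: np.ndarray | None = None,
) -> TwoPieceFit:
    """Fit (c, σ₁, σ₂) by maximizing Π g(xᵢ)/μ over [0, w].

    Multi-start box-constrained optimization (default 8 deterministic
    Latin-grid starts); best objective wins, ties broken by smallest apex.
    ``c_max`` bounds the apex (default w/2 — an apex beyond half the strip
    leaves too little declining tail to identify σ₂).
    """
    x = np.asarray(distances, dtype=float)
    if x.size < 10:
        raise ValueError(f"need ≥ 10 distances to fit the two-piece shape, got {x.size}")
    if np.any(x < 0) or np.any(x > w):
        raise ValueError("distances must lie in [0, w]")
    if c_max is None:
        c_max = w / 2.0
    bounds = [(0.0, c_max), (w / 50.0, w), (w / 50.0, w)]
    if starts is None:
        starts = _latin_starts(w, c_max)

    results = []
    for p0 in starts:
        res = optimize.minimize(
            _twopiece_negloglik, p0, args=(x, w), method="L-BFGS-B", bounds=bounds,
        )
        if math.isfinite(res.fun):
            results.append(res)
    if not results:
        raise RuntimeError("two-piece ML fit failed to converge from any start")

    best_nll = min(r.fun for r in results)
    # ties (within 1e-6 of the best objective) resolved by smallest apex
    tied = [r for r in results if r.fun <= best_nll + 1e-6]
    best = min(tied, key=lambda r: r.x[0])
    c, s1, s2 = best.x
    curve = TwoPieceNormalCurve(apex_c=float(c), sigma_left=float(s1), sigma_right=float(s2))
    return TwoPieceFit(curve=curve, loglik=float(-best.fun), w=float(w), n=int(x.size))
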
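"""Hierarchical beta (HB) process: a stochastic process on quantile functions.

Realisations are random PPFs q̂ on [0, 1] that are monotone by
construction, non-accumulating (no preferred direction in Φ) and
self-consistent (already-sampled points never change under deeper
refinement).  The process is parametrised by a centre curve q* (the mixed
PPF), a discrepancy curve δ and a scalar sensitivity factor c ≥ 0 that
converts discrepancy into epistemic variance.

A realisation is generated by dyadic refinement: endpoints q̂(0) < q̂(1)
are drawn from Gaussians centred on q*(0), q*(1) with variance c·δ²;
then each refinement level n = 1…N splits every increment of width
2^(1−n) into two subincrements by drawing the left fraction x₁ from a
beta distribution.  The beta parameters (α, β) are chosen so that the
Aitchison centre of the split matches the corresponding split of q*
(ratio r) and the Aitchison metric variance matches c·δ² at the midpoint
(v = 2cδ²):

    ψ(α) − ψ(β) = ln r,        ψ₁(α) + ψ₁(β) = v,

with ψ, ψ₁ the digamma and trigamma functions.  Because (r, v) — and
hence (α, β) — depend only on (q*, δ, c) and the dyadic position, the
whole refinement table is deterministic and is precomputed once per
process specification.

In the c → 0 limit (or when δ ≡ 0) the process collapses onto q* exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import cached_property
from typing import List, Tuple

import numpy as np
from scipy.optimize import brentq
from scipy.special import digamma, polygamma

from .ppf_core import DiscrepancyCurve, EmpiricalPPF

DEFAULT_N_REFINEMENTS = 8  # risk integrals converge after ~8 dyadic levels
DEFAULT_MAX_ENDPOINT_REJECTIONS = 1000

# numerical guards for degenerate refinement statistics
_LN_R_CLIP = math.log(1e12)  # |ln r| cap when a q* subincrement vanishes
_V_FLOOR = 1e-12
_V_CAP = 2.0 * float(polygamma(1, 1e-8))  # keep (α, β) representable

_SOLVER_TOL = 1e-8


@dataclass(frozen=True)
class BetaParams:
    """Parameters of a Beta(α, β) increment-splitting distribution."""

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        for name, val in (("alpha", self.alpha), ("beta", self.beta)):
            if not (np.isfinite(val) and val > 0):
                raise ValueError(f"{name} must be strictly positive and finite")


def beta_centre_mvar(params: BetaParams) -> Tuple[Tuple[float, float], float]:
    """Aitchison centre and metric variance of (x₁, x₂), x₁ ~ Beta(α, β).

    centre = (e^ψ(α), e^ψ(β)) / (e^ψ(α) + e^ψ(β)) — computed through the
    logistic of ψ(α) − ψ(β) to avoid overflow — and
    mvar = ½(ψ₁(α) + ψ₁(β)).
    """
    a, b = params.alpha, params.beta
    d = float(digamma(a) - digamma(b))
    c1 = 1.0 / (1.0 + math.exp(-d))
    mvar = 0.5 * float(polygamma(1, a) + polygamma(1, b))
    return (c1, 1.0 - c1), mvar


def _inv_trigamma(y: float) -> float:
    """Solve ψ₁(z) = y for z > 0 (ψ₁ is strictly decreasing)."""
    if y <= 0:
        raise ValueError("trigamma is positive; need y > 0")
    # seed from ψ₁(z) ≈ 1/z + 1/(2z²): z ≈ (1 + √(1+2y)) / (2y)
    z = (1.0 + math.sqrt(1.0 + 2.0 * y)) / (2.0 * y)
    for _ in range(60):
        f = float(polygamma(1, z)) - y
        if abs(f) < 1e-14 * y:
            break
        step = f / float(polygamma(2, z))  # Newton (ψ₂ < 0)
        z_new = z - step
        if z_new <= 0:
            z_new = z / 2.0
        z = z_new
    return z


def _solve_beta_arrays(
    ln_r: np.ndarray, v: np.ndarray, tol: float = _SOLVER_TOL
) -> Tuple[np.ndarray, np.ndarray]:
    """Vectorised solve of ψ(α) − ψ(β) = ln r, ψ₁(α) + ψ₁(β) = v.

    Damped Newton iteration in (log α, log β) with an analytic Jacobian;
    entries that fail to converge fall back to a monotone bracketed solve.
    """
    ln_r = np.asarray(ln_r, dtype=float)
    v = np.asarray(v, dtype=float)
    r = np.exp(ln_r)

    # seeds: large-argument asymptotics ψ(z) ≈ ln z, ψ₁(z) ≈ 1/z give
    # α₀ = (1+r)/v, β₀ = (1+r)/(rv); small-argument ψ(z) ≈ −1/z,
    # ψ₁(z) ≈ 1/z² give 1/α₀ = (−ln r + √(2v − ln²r))/2.
    alpha0 = (1.0 + r) / v
    beta0 = (1.0 + r) / (r * v)
    small = (v > 20.0) & (2.0 * v > ln_r**2 * 1.0001)
    if np.any(small):
        disc = np.sqrt(np.maximum(2.0 * v - ln_r**2, 1e-30))
        inv_a = np.maximum((-ln_r + disc) / 2.0, 1e-300)
        inv_b = np.maximum(inv_a + ln_r, 1e-300)
        alpha0 = np.where(small, 1.0 / inv_a, alpha0)
        beta0 = np.where(small, 1.0 / inv_b, beta0)

    u = np.log(np.clip(alpha0, 1e-250, 1e250))
    w = np.log(np.clip(beta0, 1e-250, 1e250))

    def residuals(u, w):
        a, b = np.exp(u), np.exp(w)
        t1a, t1b = polygamma(1, a), polygamma(1, b)
        f1 = digamma(a) - digamma(b) - ln_r
        f2 = np.log(t1a + t1b) - np.log(v)
        return f1, f2, a, b, t1a, t1b

    f1, f2, a, b, t1a, t1b = residuals(u, w)
    for _ in range(100):
        active = (np.abs(f1) > tol) | (np.abs(f2) > tol)
        if not np.any(active):
            break
        # Jacobian of (f1, f2) wrt (u, w)
        j11 = a * t1a
        j12 = -b * t1b
        s = t1a + t1b
        j21 = a * polygamma(2, a) / s
        j22 = b * polygamma(2, b) / s
        det = j11 * j22 - j12 * j21
        det = np.where(np.abs(det) < 1e-300, 1e-300, det)
        du = -(j22 * f1 - j12 * f2) / det
        dw = -(-j21 * f1 + j11 * f2) / det
        # cap the step to keep the iteration in-range
        cap = 4.0
        scale = np.maximum(1.0, np.maximum(np.abs(du), np.abs(dw)) / cap)
        du, dw = du / scale, dw / scale
        norm0 = f1**2 + f2**2
        lam = np.where(active, 1.0, 0.0)
        for _ in range(10):  # backtracking line search
            f1n, f2n, an, bn, t1an, t1bn = residuals(u + lam * du, w + lam * dw)
            worse = active & (f1n**2 + f2n**2 > norm0) & (lam > 1e-3)
            if not np.any(worse):
                break
            lam = np.where(worse, lam / 2.0, lam)
        u, w = u + lam * du, w + lam * dw
        f1, f2, a, b, t1a, t1b = residuals(u, w)

    alpha, beta = np.exp(u), np.exp(w)
    bad = (np.abs(f1) > tol) | (np.abs(f2) > tol) | ~np.isfinite(alpha * beta)
    for i in np.flatnonzero(bad):
        alpha[i], beta[i] = _solve_beta_bracketed(float(ln_r[i]), float(v[i]))
    return alpha, beta


def _solve_beta_bracketed(ln_r: float, v: float) -> Tuple[float, float]:
    """Robust fallback: eliminate β via ψ₁(β) = v − ψ₁(α) and bracket α.

    f(α) = ψ(α) − ψ(β(α)) − ln r is strictly increasing on
    (ψ₁⁻¹(v), ∞), from −∞ to +∞, so a root always brackets.
    """
    alpha_min = _inv_trigamma(v)

    def f(alpha: float) -> float:
        resid = v - float(polygamma(1, alpha))
        beta = _inv_trigamma(resid)
        return float(digamma(alpha) - digamma(beta)) - ln_r

    lo = alpha_min * (1.0 + 1e-9)
    hi = max(2.0 * alpha_min, 1.0)
    for _ in range(200):
        if f(hi) > 0:
            break
        lo = hi
        hi *= 4.0
    else:
        raise RuntimeError(f"beta-parameter solver failed: r={math.exp(ln_r)}, v={v}")
    alpha = brentq(f, lo, hi, xtol=1e-300, rtol=8.9e-16, maxiter=200)
    beta = _inv_trigamma(v - float(polygamma(1, alpha)))
    return float(alpha), float(beta)


def solve_beta_params(r: float, v: float) -> BetaParams:
    """Find (α, β) with ψ(α) − ψ(β) = ln r and ψ₁(α) + ψ₁(β) = v.

    Both transformed equations are satisfied to absolute tolerance 1e−8.
    Raises ``RuntimeError`` carrying (r, v) if no solution is found.
    """
    if not (np.isfinite(r) and np.isfinite(v) and r > 0 and v > 0):
        raise ValueError("r and v must be finite and positive")
    alpha, beta = _solve_beta_arrays(np.array([math.log(r)]), np.array([v]))
    a, b = float(alpha[0]), float(beta[0])
    f1 = abs(float(digamma(a) - digamma(b)) - math.log(r))
    f2 = abs(math.log(float(polygamma(1, a) + polygamma(1, b))) - math.log(v))
    if f1 > _SOLVER_TOL or f2 > _SOLVER_TOL:
        raise RuntimeError(
            f"beta-parameter solver did not converge for r={r}, v={v}"
        )
    return BetaParams(alpha=a, beta=b)


@dataclass(frozen=True)
class HBRealisation:
    """One discretised realisation q̂ on the dyadic grid {k·2^−N}."""

    phis: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        phis = np.asarray(self.phis, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "phis", phis)
        object.__setattr__(self, "values", values)
        if phis.shape != values.shape:
            raise ValueError("phis and values must have equal length")
        if np.any(np.diff(values) < 0):
            raise ValueError("realisation must be nondecreasing")

    # alias so ppf_risk and curve IO accept realisations
    @property
    def grid(self) -> np.ndarray:
        return self.phis

    @property
    def ordinates(self) -> np.ndarray:
        return self.values

    def risk(self) -> float:
        return float(np.trapezoid(self.values, self.phis))


@dataclass(frozen=True)
class _RefinementLevel:
    """Precomputed splitting distributions for one dyadic level."""

    alphas: np.ndarray
    betas: np.ndarray
    deterministic: np.ndarray  # entries where q* is flat: split x₁ = ½


@dataclass(frozen=True)
class HBProcessSpec:
    """Full parametrisation of an HB process: (q*, δ, c, N).

    ``c`` is the dimensionless sensitivity factor converting discrepancy
    into epistemic variance; ``n_refinements`` is the dyadic depth N
    (grid of 2^N + 1 points).
    """

    mixed_ppf: EmpiricalPPF
    discrepancy: DiscrepancyCurve
    c: float
    n_refinements: int = DEFAULT_N_REFINEMENTS
    max_endpoint_rejections: int = DEFAULT_MAX_ENDPOINT_REJECTIONS

    def __post_init__(self) -> None:
        if self.c < 0:
            raise ValueError("sensitivity factor c must be nonnegative")
        if self.n_refinements < 1:
            raise ValueError("need at least one refinement level")
        if not np.array_equal(self.mixed_ppf.grid, self.discrepancy.grid):
            raise ValueError("mixed PPF and discrepancy must share a grid")

    @property
    def dyadic_grid(self) -> np.ndarray:
        n = self.n_refinements
        return np.arange(2**n + 1) / 2**n

    @cached_property
    def _q_star_dyadic(self) -> np.ndarray:
        return self.mixed_ppf(self.dyadic_grid)

    @cached_property
    def _degenerate(self) -> bool:
        return self.c == 0 or float(np.max(self.discrepancy.ordinates)) == 0.0

    @cached_property
    def _levels(self) -> List[_RefinementLevel]:
        """Beta parameters for every midpoint, level-major, left-to-right."""
        if self._degenerate:
            return []
        N = self.n_refinements
        q = self._q_star_dyadic
        levels: List[_RefinementLevel] = []
        for n in range(1, N + 1):
            step = 2 ** (N - n)  # index stride of the new midpoints
            left = np.arange(0, 2**N, 2 * step)
            mid = left + step
            right = left + 2 * step
            num = q[mid] - q[left]
            den = q[right] - q[mid]
            deterministic = (num <= 0) & (den <= 0)
            with np.errstate(divide="ignore", invalid="ignore"):
                ln_r = np.log(num) - np.log(den)
            ln_r = np.clip(np.nan_to_num(ln_r, nan=0.0), -_LN_R_CLIP, _LN_R_CLIP)
            delta_mid = self.discrepancy(mid / 2**N)
            v = np.clip(2.0 * self.c * delta_mid**2, _V_FLOOR, _V_CAP)
            free = ~deterministic
            alphas = np.ones_like(ln_r)
            betas = np.ones_like(ln_r)
            if np.any(free):
                alphas[free], betas[free] = _solve_beta_arrays(
                    ln_r[free], v[free]
                )
            levels.append(
                _RefinementLevel(
                    alphas=alphas, betas=betas, deterministic=deterministic
                )
            )
        return levels


def increment_stats(
    spec: HBProcessSpec, phi: float, half_width: float
) -> Tuple[float, float]:
    """Refinement statistics (r, v) for the increment [Φ, Φ + 2h].

    r is the ratio of the two q*-subincrements (first over second),
    clipped to keep ln r within ±ln(10¹²) when a subincrement vanishes;
    v = 2c·δ(Φ+h)², floored and capped to the representable trigamma
    range.
    """
    h = half_width
    if phi < 0 or phi + 2 * h > 1 + 1e-12:
        raise ValueError("increment must lie inside [0, 1]")
    q = spec.mixed_ppf
    num = float(q(phi + h) - q(phi))
    den = float(q(phi + 2 * h) - q(phi + h))
    if num <= 0 and den <= 0:
        ln_r = 0.0
    else:
        with np.errstate(divide="ignore"):
            ln_r = float(np.log(num) - np.log(den)) if num > 0 and den > 0 else (
                _LN_R_CLIP if den <= 0 else -_LN_R_CLIP
            )
        ln_r = float(np.clip(ln_r, -_LN_R_CLIP, _LN_R_CLIP))
    r = math.exp(ln_r)
    v = float(np.clip(2.0 * spec.c * float(spec.discrepancy(phi + h)) ** 2,
                      _V_FLOOR, _V_CAP))
    return r, v


def sample_endpoints(
    spec: HBProcessSpec, rng: np.random.Generator
) -> Tuple[float, float]:
    """Draw q̂(0) ~ N(q*(0), c·δ(0)²) and q̂(1) ~ N(q*(1), c·δ(1)²)
    independently, redrawing until q̂(0) < q̂(1)."""
    q0_mean = float(spec.mixed_ppf(0.0))
    q1_mean = float(spec.mixed_ppf(1.0))
    s0 = math.sqrt(spec.c) * float(spec.discrepancy(0.0))
    s1 = math.sqrt(spec.c) * float(spec.discrepancy(1.0))
    if s0 == 0.0 and s1 == 0.0:
        if q0_mean < q1_mean:
            return q0_mean, q1_mean
        raise RuntimeError(
            "degenerate endpoint law: q*(0) >= q*(1) with zero variance"
        )
    for _ in range(spec.max_endpoint_rejections):
        q0 = q0_mean + s0 * rng.standard_normal()
        q1 = q1_mean + s1 * rng.standard_normal()
        if q0 < q1:
            return float(q0), float(q1)
    raise RuntimeError(
        f"exceeded {spec.max_endpoint_rejections} endpoint rejections: "
        "c·δ is too large relative to q*(1) − q*(0)"
    )


def sample_realisation(
    spec: HBProcessSpec, rng: np.random.Generator
) -> HBRealisation:
    """Generate one discretised realisation of the HB process.

    Draw order is fixed — endpoints first, then refinement levels coarse
    to fine with the midpoints of each level drawn left-to-right in a
    single batch — so runs with different depths N share the coarse
    prefix of the random stream and already-sampled dyadic points are
    reproduced exactly (self-consistency).
    """
    N = spec.n_refinements
    grid = spec.dyadic_grid
    if spec._degenerate:
        return HBRealisation(phis=grid, values=spec._q_star_dyadic.copy())
    values = np.empty(2**N + 1)
    values[0], values[-1] = sample_endpoints(spec, rng)
    for n, level in enumerate(spec._levels, start=1):
        step = 2 ** (N - n)
        left = np.arange(0, 2**N, 2 * step)
        mid = left + step
        right = left + 2 * step
        x1 = np.full(left.size, 0.5)
        free = ~level.deterministic
        if np.any(free):
            x1[free] = rng.beta(level.alphas[free], level.betas[free])
        # clip away one-ulp overshoot of left + x1·Δ beyond the bracket
        values[mid] = np.clip(
            values[left] + x1 * (values[right] - values[left]),
            values[left],
            values[right],
        )
    return HBRealisation(phis=grid, values=values)
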
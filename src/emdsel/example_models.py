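"""Black-body radiation test bed: synthetic data generator and candidates.

A fictitious spectrometry experiment: the true process emits photon
counts following the Planck (or, counterfactually, the Rayleigh-Jeans)
radiance law, with Poisson counting noise of gain ``s`` and an optional
sensor bias.  The two candidate models assume the respective radiance
law with additive Gaussian noise — a deliberately (mildly) misspecified
observation model — whose standard deviation is fitted to data by
maximum likelihood.

Units: wavelengths in μm; radiances in kW·sr⁻¹·m⁻²·nm⁻¹, so that
s·B(λ;T) is a dimensionless photon count when s is expressed in
m²·nm·photons·sr·kW⁻¹.  Defaults reproduce the long-wavelength
(ambiguous) regime: T = 4000 K, s = 10⁵, λ ∈ [6, 20] μm; a "visible"
window preset covers the regime where the two laws are easily told
apart.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
import yaml

from .calibration import EpistemicDistribution

# CODATA 2018 constants (SI)
PLANCK_H = 6.62607015e-34  # J s
SPEED_OF_LIGHT = 2.99792458e8  # m / s
BOLTZMANN_K = 1.380649e-23  # J / K

# SI spectral radiance (W sr⁻¹ m⁻³) → kW sr⁻¹ m⁻² nm⁻¹
_RADIANCE_UNIT = 1e-12

DEFAULT_T = 4000.0  # K
DEFAULT_S = 1e5  # m² nm photons sr kW⁻¹ (detector gain)
LONG_WAVE_WINDOW = (6.0, 20.0)  # μm; the two laws are nearly ambiguous
VISIBLE_WINDOW = (0.4, 0.8)  # μm; Planck vs Rayleigh-Jeans is obvious
SIGMA_FLOOR = 1e-12  # radiance units; guards zero-residual MLE fits

LAWS = ("planck", "rayleigh-jeans")


def planck_radiance(lam: np.ndarray, T: float) -> np.ndarray:
    """Planck spectral radiance B(λ;T) = (2hc²/λ⁵) / (e^{hc/λk_BT} − 1).

    λ in μm, T in K, result in kW·sr⁻¹·m⁻²·nm⁻¹.  Evaluated via expm1 in
    a guarded exponent so the short-wavelength tail underflows gracefully
    to zero instead of overflowing.
    """
    lam_m = np.asarray(lam, dtype=float) * 1e-6
    if np.any(lam_m <= 0) or T <= 0:
        raise ValueError("wavelength and temperature must be positive")
    x = PLANCK_H * SPEED_OF_LIGHT / (lam_m * BOLTZMANN_K * T)
    prefac = 2.0 * PLANCK_H * SPEED_OF_LIGHT**2 / lam_m**5
    with np.errstate(over="ignore"):
        denom = np.expm1(np.minimum(x, 700.0))
    return prefac / denom * _RADIANCE_UNIT


def rayleigh_jeans_radiance(lam: np.ndarray, T: float) -> np.ndarray:
    """Rayleigh-Jeans radiance B(λ;T) = 2ck_BT/λ⁴ (same units as above)."""
    lam_m = np.asarray(lam, dtype=float) * 1e-6
    if np.any(lam_m <= 0) or T <= 0:
        raise ValueError("wavelength and temperature must be positive")
    return 2.0 * SPEED_OF_LIGHT * BOLTZMANN_K * T / lam_m**4 * _RADIANCE_UNIT


_RADIANCE_LAWS = {
    "planck": planck_radiance,
    "rayleigh-jeans": rayleigh_jeans_radiance,
}


def radiance_law(name: str):
    try:
        return _RADIANCE_LAWS[name]
    except KeyError:
        raise ValueError(f"unknown radiance law {name!r}; choose from {LAWS}")


def _uniform_grid(lam_min: float, lam_max: float, n_points: int) -> np.ndarray:
    if not lam_min < lam_max:
        raise ValueError("need lam_min < lam_max")
    if n_points < 2:
        raise ValueError("need at least 2 wavelengths")
    return np.linspace(lam_min, lam_max, n_points)


@dataclass(frozen=True)
class RadianceDataset:
    """Observed (λ, B) pairs with the generating metadata."""

    wavelengths: np.ndarray  # μm, uniform grid
    radiances: np.ndarray  # kW sr⁻¹ m⁻² nm⁻¹
    meta: Dict = None

    def __post_init__(self) -> None:
        lam = np.asarray(self.wavelengths, dtype=float)
        rad = np.asarray(self.radiances, dtype=float)
        object.__setattr__(self, "wavelengths", lam)
        object.__setattr__(self, "radiances", rad)
        object.__setattr__(self, "meta", dict(self.meta or {}))
        if lam.shape != rad.shape:
            raise ValueError("wavelengths and radiances must align")
        if lam.size >= 2:
            steps = np.diff(lam)
            if not np.allclose(steps, steps[0], rtol=1e-9, atol=0):
                raise ValueError("wavelengths must form a uniform grid")

    @property
    def xy(self) -> Tuple[np.ndarray, np.ndarray]:
        return self.wavelengths, self.radiances

    def __len__(self) -> int:
        return len(self.wavelengths)

    def to_csv(self, path) -> None:
        """Two-column (x, y) CSV; metadata goes to a YAML sidecar."""
        from .ppf_core import write_dataset

        write_dataset(self.xy, path)
        sidecar = Path(path).with_suffix(".meta.yaml")
        with open(sidecar, "w") as fh:
            yaml.safe_dump(self.meta, fh)

    @classmethod
    def from_csv(cls, path) -> "RadianceDataset":
        from .ppf_core import read_dataset

        lam, rad = read_dataset(path)
        sidecar = Path(path).with_suffix(".meta.yaml")
        meta = {}
        if sidecar.exists():
            with open(sidecar) as fh:
                meta = yaml.safe_load(fh) or {}
        return cls(wavelengths=lam, radiances=rad, meta=meta)


def generate_blackbody_data(
    lam_min: float = LONG_WAVE_WINDOW[0],
    lam_max: float = LONG_WAVE_WINDOW[1],
    n_points: int = 4096,
    T: float = DEFAULT_T,
    s: float = DEFAULT_S,
    b0: float = 0.0,
    law: str = "planck",
    rng: np.random.Generator | None = None,
    seed=None,
) -> RadianceDataset:
    """Simulate one spectrometry run: B = Poisson(s·B_law(λ;T))/s + b0 on
    a uniform wavelength grid.

    The Poisson count divided by the gain keeps B in radiance units with
    mean B_law + b0 and variance B_law/s.
    """
    if s <= 0:
        raise ValueError("gain s must be positive")
    rng = np.random.default_rng(rng if rng is not None else seed)
    lam = _uniform_grid(lam_min, lam_max, n_points)
    mean_counts = s * radiance_law(law)(lam, T)
    if np.any(mean_counts > 1e18):
        raise ValueError(
            "s·B overflow: expected counts exceed 1e18; lower the gain or "
            "restrict the wavelength window"
        )
    radiances = rng.poisson(mean_counts) / s + b0
    meta = {
        "T": float(T), "s": float(s), "b0": float(b0),
        "physical_model": law, "lam_min": float(lam_min),
        "lam_max": float(lam_max), "n_points": int(n_points),
    }
    return RadianceDataset(wavelengths=lam, radiances=radiances, meta=meta)


@dataclass(frozen=True)
class BlackBodyCandidate:
    """A radiance-law candidate with additive Gaussian observation noise.

    The loss is the Gaussian negative log likelihood
    ½log(2πσ²) + (B − B_law(λ;T))²/(2σ²) in nats.  ``sigma`` may be unset
    until fitted; the sampler reproduces the model's own assumption:
    uniform λ grid over ``window``, Gaussian noise around the law.
    """

    radiance_law: str = "planck"
    T: float = DEFAULT_T
    sigma: Optional[float] = None
    window: Tuple[float, float] = LONG_WAVE_WINDOW
    model_id: str = ""

    def __post_init__(self) -> None:
        radiance_law(self.radiance_law)  # validate name
        if self.T <= 0:
            raise ValueError("temperature must be positive")
        if self.sigma is not None and self.sigma <= 0:
            raise ValueError("sigma must be positive once set")
        if not self.model_id:
            object.__setattr__(self, "model_id", self.radiance_law)

    def curve(self, lam: np.ndarray) -> np.ndarray:
        return radiance_law(self.radiance_law)(lam, self.T)

    def _require_sigma(self) -> float:
        if self.sigma is None:
            raise ValueError(
                f"candidate {self.model_id!r} has no fitted sigma; call "
                "fit_sigma_mle or .fit first"
            )
        return self.sigma

    def loss(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        sigma = self._require_sigma()
        resid = np.asarray(y, float) - self.curve(np.asarray(x, float))
        return 0.5 * math.log(2.0 * math.pi * sigma**2) + resid**2 / (
            2.0 * sigma**2
        )

    def sample(
        self, n: int, rng: np.random.Generator
    ) -> Tuple[np.ndarray, np.ndarray]:
        sigma = self._require_sigma()
        lam = _uniform_grid(self.window[0], self.window[1], n)
        return lam, self.curve(lam) + sigma * rng.standard_normal(n)

    def fit(self, x: np.ndarray, y: np.ndarray) -> "BlackBodyCandidate":
        """Return a copy with σ set to its Gaussian MLE on (x, y)."""
        resid = np.asarray(y, float) - self.curve(np.asarray(x, float))
        sigma = float(np.sqrt(np.mean(resid**2)))
        if sigma < SIGMA_FLOOR:
            import warnings

            warnings.warn(
                "all residuals (near) zero; sigma floored", RuntimeWarning
            )
            sigma = SIGMA_FLOOR
        return replace(self, sigma=sigma)


def fit_sigma_mle(
    data: RadianceDataset, candidate: BlackBodyCandidate
) -> BlackBodyCandidate:
    """Fit the candidate's Gaussian noise SD by maximum likelihood:
    σ̂² is the mean squared residual against the candidate's radiance
    curve (law and T held fixed)."""
    return candidate.fit(data.wavelengths, data.radiances)


@dataclass(frozen=True)
class PoissonRadianceProcess:
    """A concrete data-generating process drawn from the epistemic
    distribution: one radiance law, fixed bias, Poisson counting noise."""

    law: str
    T: float = DEFAULT_T
    s: float = DEFAULT_S
    b0: float = 0.0
    window: Tuple[float, float] = LONG_WAVE_WINDOW

    def sample(
        self, n: int, rng: np.random.Generator
    ) -> Tuple[np.ndarray, np.ndarray]:
        data = generate_blackbody_data(
            lam_min=self.window[0], lam_max=self.window[1], n_points=n,
            T=self.T, s=self.s, b0=self.b0, law=self.law, rng=rng,
        )
        return data.xy


def blackbody_epistemic_dist(
    b0_range: Tuple[float, float] = (-1e-4, 1e-4),
    laws: Tuple[str, ...] = LAWS,
    T: float = DEFAULT_T,
    s: float = DEFAULT_S,
    window: Tuple[float, float] = LONG_WAVE_WINDOW,
) -> EpistemicDistribution:
    """Epistemic distribution over spectrometry experiments: each draw
    picks a radiance law uniformly from ``laws`` and a sensor bias
    uniformly from ``b0_range``; all other parameters stay fixed."""
    lo, hi = b0_range
    if not lo <= hi:
        raise ValueError("invalid b0_range")
    laws = tuple(laws)
    for law in laws:
        radiance_law(law)

    def sampler(rng: np.random.Generator) -> PoissonRadianceProcess:
        law = laws[int(rng.integers(len(laws)))]
        b0 = float(rng.uniform(lo, hi)) if hi > lo else float(lo)
        return PoissonRadianceProcess(law=law, T=T, s=s, b0=b0, window=window)

    return EpistemicDistribution(
        sampler=sampler,
        description=f"blackbody laws={laws} b0~U{b0_range} T={T} s={s:g}",
    )
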
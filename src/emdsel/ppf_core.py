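"""Empirical loss quantile functions (PPFs) and the model discrepancy δ.

The statistics of a model's pointwise loss are summarised by two quantile
functions on Φ ∈ [0, 1]:

* the *mixed* PPF ``q*``: losses evaluated with the candidate model on
  samples from the observed (true) data;
* the *synthetic* PPF ``q~``: losses evaluated with the candidate model on
  samples the candidate itself generates.

Their pointwise absolute difference, the empirical model discrepancy
``δ(Φ) = |q~(Φ) − q*(Φ)|``, measures misspecification: it vanishes
identically when the model reproduces the observations exactly.  The risk
(expected loss) is the integral of the PPF over Φ, which for an empirical
PPF recovers the sample mean of the losses.

Construction of an empirical PPF: sort the L losses ascending and place
the i-th order statistic at Φ_i = i/(L+1), then resample by linear
interpolation onto a uniform grid (default 2^10 = 1024 interior points)
with explicit endpoints at Φ = 0 and Φ = 1 carried by constant
extrapolation of the first/last ordinate.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Tuple, Union

import numpy as np
import pandas as pd

from .contract import CandidateModel

DEFAULT_N_GRID = 1024  # interior grid points of an empirical PPF
DEFAULT_L_SYNTH = 4096  # synthetic samples used for the synthetic PPF

DatasetLike = Union[Tuple[np.ndarray, np.ndarray], np.ndarray]


def _as_xy(dataset: DatasetLike) -> Tuple[np.ndarray, np.ndarray]:
    """Coerce a dataset into a pair of 1-d (x, y) arrays."""
    if hasattr(dataset, "xy"):
        x, y = dataset.xy  # e.g. RadianceDataset
    elif isinstance(dataset, tuple) and len(dataset) == 2:
        x, y = dataset
    else:
        arr = np.asarray(dataset, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise ValueError(
                "dataset must be an (x, y) pair, an N×2 array or expose .xy"
            )
        x, y = arr[:, 0], arr[:, 1]
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    return x, y


@dataclass(frozen=True)
class LossSample:
    """Per-record pointwise losses Q(x_i, y_i) for one model on one dataset.

    Values are in the units of the loss (nats for a negative log
    likelihood).  All values must be finite — an infinite loss signals a
    record to which the model assigns zero probability, which the method
    does not allow — and at least two records are required.
    """

    values: np.ndarray
    model_id: str = ""
    dataset_id: str = ""

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 1 or values.size < 2:
            raise ValueError("need at least 2 loss values")
        if not np.all(np.isfinite(values)):
            idx = int(np.flatnonzero(~np.isfinite(values))[0])
            raise ValueError(
                f"non-finite loss at record {idx}: the model assigns zero "
                "probability to this observation"
            )

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class EmpiricalPPF:
    """A monotone quantile function of the loss on a fixed Φ-grid.

    ``kind`` distinguishes mixed PPFs (losses under observed data),
    synthetic PPFs (losses under model-generated data) and realisations of
    the hierarchical beta process.
    """

    grid: np.ndarray
    ordinates: np.ndarray
    kind: str = "mixed"

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid, dtype=float)
        ordinates = np.asarray(self.ordinates, dtype=float)
        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "ordinates", ordinates)
        if grid.shape != ordinates.shape or grid.ndim != 1:
            raise ValueError("grid and ordinates must be 1-d of equal length")
        if grid.size < 2:
            raise ValueError("grid needs at least 2 points")
        if np.any(np.diff(grid) <= 0):
            raise ValueError("grid must be strictly increasing")
        if grid[0] < 0 or grid[-1] > 1:
            raise ValueError("grid must lie in [0, 1]")
        if np.any(np.diff(ordinates) < 0):
            raise ValueError("ordinates must be nondecreasing")

    def __call__(self, phi) -> np.ndarray:
        """Evaluate the PPF at Φ by linear interpolation (constant beyond
        the grid ends)."""
        return np.interp(phi, self.grid, self.ordinates)


@dataclass(frozen=True)
class DiscrepancyCurve:
    """The discrepancy δ(Φ) ≥ 0, on the same grid as its paired mixed PPF."""

    grid: np.ndarray
    ordinates: np.ndarray

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid, dtype=float)
        ordinates = np.asarray(self.ordinates, dtype=float)
        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "ordinates", ordinates)
        if grid.shape != ordinates.shape or grid.ndim != 1:
            raise ValueError("grid and ordinates must be 1-d of equal length")
        if np.any(ordinates < 0):
            raise ValueError("discrepancy must be nonnegative")

    def __call__(self, phi) -> np.ndarray:
        return np.interp(phi, self.grid, self.ordinates)


# ---------------------------------------------------------------------------
# operations


def pointwise_losses(
    dataset: DatasetLike,
    model: CandidateModel,
    dataset_id: str = "",
) -> LossSample:
    """Evaluate the model's pointwise loss on every record, order preserved.

    Raises ``ValueError`` naming the first offending record if any loss is
    non-finite (the model must assign non-vanishing probability to every
    observation).
    """
    x, y = _as_xy(dataset)
    losses = np.asarray(model.loss(x, y), dtype=float)
    if losses.shape != x.shape:
        raise ValueError("model.loss must return one loss per record")
    if not np.all(np.isfinite(losses)):
        idx = int(np.flatnonzero(~np.isfinite(losses))[0])
        raise ValueError(
            f"model assigns zero probability to record {idx} "
            f"(x={x[idx]!r}, y={y[idx]!r}): loss is non-finite"
        )
    return LossSample(
        values=losses,
        model_id=getattr(model, "model_id", ""),
        dataset_id=dataset_id,
    )


def empirical_ppf(
    losses: Union[LossSample, np.ndarray],
    n_grid: int = DEFAULT_N_GRID,
    kind: str = "mixed",
) -> EmpiricalPPF:
    """Build the empirical PPF of a loss sample.

    The L sorted losses sit at Φ_i = i/(L+1); the curve is then resampled
    by linear interpolation onto ``n_grid`` uniform interior points plus
    the endpoints Φ = 0 and Φ = 1 (constant extrapolation).
    """
    if n_grid < 2:
        raise ValueError("n_grid must be at least 2")
    values = losses.values if isinstance(losses, LossSample) else np.asarray(
        losses, dtype=float
    )
    if values.size < 2:
        raise ValueError("need at least 2 loss values")
    sorted_losses = np.sort(values, kind="stable")
    L = sorted_losses.size
    phis = np.arange(1, L + 1) / (L + 1)
    grid = np.empty(n_grid + 2)
    grid[0], grid[-1] = 0.0, 1.0
    grid[1:-1] = np.arange(1, n_grid + 1) / (n_grid + 1)
    ordinates = np.interp(grid, phis, sorted_losses)
    return EmpiricalPPF(grid=grid, ordinates=ordinates, kind=kind)


def mixed_and_synthetic_ppfs(
    model: CandidateModel,
    observed: DatasetLike,
    L_synth: int = DEFAULT_L_SYNTH,
    rng: np.random.Generator | None = None,
    n_grid: int = DEFAULT_N_GRID,
) -> Tuple[EmpiricalPPF, EmpiricalPPF]:
    """Mixed PPF (model loss on observed data) and synthetic PPF (model
    loss on ``L_synth`` model-generated samples), on a shared grid."""
    if not hasattr(model, "sample"):
        raise TypeError(
            "model lacks a sampling capability; the synthetic PPF requires it"
        )
    rng = np.random.default_rng(rng)
    mixed_losses = pointwise_losses(observed, model)
    x_s, y_s = model.sample(L_synth, rng)
    synth_losses = pointwise_losses((x_s, y_s), model)
    mixed = empirical_ppf(mixed_losses, n_grid=n_grid, kind="mixed")
    synthetic = empirical_ppf(synth_losses, n_grid=n_grid, kind="synthetic")
    return mixed, synthetic


def delta_emd(mixed: EmpiricalPPF, synthetic: EmpiricalPPF) -> DiscrepancyCurve:
    """Pointwise discrepancy |q~(Φ) − q*(Φ)| between two PPFs on one grid."""
    if mixed.grid.shape != synthetic.grid.shape or not np.array_equal(
        mixed.grid, synthetic.grid
    ):
        raise ValueError("mixed and synthetic PPFs must share the same grid")
    return DiscrepancyCurve(
        grid=mixed.grid.copy(),
        ordinates=np.abs(synthetic.ordinates - mixed.ordinates),
    )


def ppf_risk(ppf) -> float:
    """Risk functional R[q] = ∫₀¹ q(Φ) dΦ (trapezoidal rule on the grid).

    For an empirical PPF this recovers the empirical risk, i.e. the sample
    mean of the losses, up to interpolation error.
    """
    grid = np.asarray(ppf.grid, dtype=float)
    ordinates = np.asarray(
        getattr(ppf, "ordinates", getattr(ppf, "values", None)), dtype=float
    )
    return float(np.trapezoid(ordinates, grid))


# ---------------------------------------------------------------------------
# serialisation: the two-column CSV dialects

_FLOAT_FMT = "%.17g"  # lossless for IEEE doubles


def write_curve(curve, path: Union[str, Path, io.TextIOBase]) -> None:
    """Write a PPF or discrepancy curve as (phi, value) CSV, lossless to
    full double precision."""
    df = pd.DataFrame({"phi": curve.grid, "value": curve.ordinates})
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_curve(
    path: Union[str, Path, io.TextIOBase], kind: str = "mixed"
) -> EmpiricalPPF:
    df = pd.read_csv(path, float_precision="round_trip")
    return EmpiricalPPF(
        grid=df["phi"].to_numpy(), ordinates=df["value"].to_numpy(), kind=kind
    )


def read_discrepancy(path: Union[str, Path, io.TextIOBase]) -> DiscrepancyCurve:
    df = pd.read_csv(path, float_precision="round_trip")
    return DiscrepancyCurve(
        grid=df["phi"].to_numpy(), ordinates=df["value"].to_numpy()
    )


def write_dataset(
    dataset: DatasetLike, path: Union[str, Path, io.TextIOBase]
) -> None:
    """Write an (x, y) dataset as two-column CSV with a header row."""
    x, y = _as_xy(dataset)
    pd.DataFrame({"x": x, "y": y}).to_csv(
        path, index=False, float_format=_FLOAT_FMT
    )


def read_dataset(
    path: Union[str, Path, io.TextIOBase],
) -> Tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path, float_precision="round_trip")
    if df.shape[1] < 2:
        raise ValueError("dataset CSV must have two numeric columns")
    return df.iloc[:, 0].to_numpy(float), df.iloc[:, 1].to_numpy(float)
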
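"""Calibration of the sensitivity factor c against simulated replications.

The tail probability B^EMD claims to estimate P(R_A < R_B) under
replication of the experiment.  To validate it, replications are
simulated: an *epistemic distribution* Ω supplies random data-generating
processes; for each drawn process a replicate dataset is generated, the
candidates' nuisance parameters are refitted, B^EMD is computed at the
given c, and the ground-truth outcome [R_A < R_B] is recorded using true
risks evaluated by large-sample empirical risk under the drawn process.

Binning the (B^EMD, outcome) pairs by B^EMD with equal counts yields the
calibration curve B^epis(B^EMD).  A well-calibrated, conservative c keeps
the curve close to — and no steeper than — the identity:

    |B^EMD − 0.5| ≲ |B^epis − 0.5|.

Bins violating this (beyond statistical slack, or with the two deviations
on opposite sides of ½) are flagged overconfident.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .contract import CandidateModel, DataGeneratingProcess
from .ppf_core import DEFAULT_L_SYNTH, DEFAULT_N_GRID, pointwise_losses
from .risk_compare import (
    DEFAULT_M_MAX,
    DEFAULT_M_MIN,
    DEFAULT_RSE_TOL,
    compare_models,
)

logger = logging.getLogger(__name__)

DEFAULT_N_TRUE_RISK = 2**14  # samples for ground-truth risk estimates
RECOMMENDED_N_TRUE_RISK = 10**4


@dataclass(frozen=True)
class EpistemicDistribution:
    """A distribution over data-generating processes.

    ``sampler(rng)`` draws a vector of hyperparameters and returns a
    concrete process exposing ``sample(n, rng)``.  Draws are reproducible
    under a seeded generator.
    """

    sampler: Callable[[np.random.Generator], DataGeneratingProcess]
    description: str = ""


@dataclass(frozen=True)
class CalibrationRecord:
    """One simulated experiment: (B^EMD, ground-truth outcome) at given c."""

    b_emd: float
    a_beats_b: int  # Iverson bracket [R_A < R_B]
    c: float
    omega_id: int

    def __post_init__(self) -> None:
        if self.a_beats_b not in (0, 1):
            raise ValueError("a_beats_b must be a 0/1 indicator")


@dataclass(frozen=True)
class CalibrationCurve:
    """Equal-count binned calibration curve: B̄^epis against B̄^EMD."""

    bin_centres: np.ndarray  # mean B^EMD per bin
    bin_bepis: np.ndarray  # mean outcome per bin (= B^epis)
    bin_counts: np.ndarray

    def __post_init__(self) -> None:
        for name in ("bin_centres", "bin_bepis", "bin_counts"):
            object.__setattr__(self, name, np.asarray(getattr(self, name)))
        if not (
            len(self.bin_centres) == len(self.bin_bepis) == len(self.bin_counts)
        ):
            raise ValueError("bin arrays must align")
        counts = self.bin_counts
        if counts.size and counts.max() - counts.min() > 1:
            raise ValueError("bin counts must differ by at most 1")


def true_risk(
    process: DataGeneratingProcess,
    candidate: CandidateModel,
    n: int,
    rng: np.random.Generator | None = None,
) -> float:
    """Ground-truth risk of a candidate under a known process: the mean
    candidate loss over ``n`` process-generated samples.

    Below ~10⁴ samples the estimate is noisy; a warning is logged.
    """
    if n < 2:
        raise ValueError("need at least 2 samples")
    if n < RECOMMENDED_N_TRUE_RISK:
        logger.warning(
            "true_risk called with n=%d < recommended %d; estimate will be "
            "high-variance", n, RECOMMENDED_N_TRUE_RISK,
        )
    rng = np.random.default_rng(rng)
    x, y = process.sample(n, rng)
    return float(np.mean(pointwise_losses((x, y), candidate).values))


def run_calibration(
    omega: EpistemicDistribution,
    candidate_a: CandidateModel,
    candidate_b: CandidateModel,
    n_experiments: int,
    dataset_size: int,
    c: float,
    n_true_risk: int = DEFAULT_N_TRUE_RISK,
    seed: int = 0,
    L_synth: int = DEFAULT_L_SYNTH,
    n_grid: int = DEFAULT_N_GRID,
    rse_tol: float = DEFAULT_RSE_TOL,
    m_min: int = DEFAULT_M_MIN,
    m_max: int = DEFAULT_M_MAX,
) -> List[CalibrationRecord]:
    """Simulate ``n_experiments`` replications and record (B^EMD, [R_A<R_B]).

    Each experiment j runs on its own generator seeded from
    (seed, j) — SeedSequence spawn keys — so experiments are independent,
    reproducible and order-insensitive.  One replicate dataset is drawn
    per process draw.  Candidates exposing a ``fit(x, y)`` method have
    their per-replicate nuisance parameters refitted; a failing fit skips
    the experiment with a logged reason.
    """
    if n_experiments < 1:
        raise ValueError("need at least one experiment")
    records: List[CalibrationRecord] = []
    n_skipped = 0
    for j in range(n_experiments):
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=seed, spawn_key=(j,))
        )
        process = omega.sampler(rng)
        x, y = process.sample(dataset_size, rng)
        try:
            cand_a = (
                candidate_a.fit(x, y) if hasattr(candidate_a, "fit")
                else candidate_a
            )
            cand_b = (
                candidate_b.fit(x, y) if hasattr(candidate_b, "fit")
                else candidate_b
            )
        except Exception as exc:  # noqa: BLE001 — record skipped, not fatal
            n_skipped += 1
            logger.warning("experiment %d skipped: fit failed (%s)", j, exc)
            continue
        comp = compare_models(
            cand_a, cand_b, (x, y), c=c, rng=rng, L_synth=L_synth,
            n_grid=n_grid, rse_tol=rse_tol, m_min=m_min, m_max=m_max,
        )
        ra = true_risk(process, cand_a, n_true_risk, rng)
        rb = true_risk(process, cand_b, n_true_risk, rng)
        records.append(
            CalibrationRecord(
                b_emd=comp.b_emd, a_beats_b=int(ra < rb), c=c, omega_id=j
            )
        )
    if n_skipped:
        logger.warning(
            "%d of %d experiments skipped", n_skipped, n_experiments
        )
    return records


def bin_calibration(
    records: Sequence[CalibrationRecord], n_bins: int
) -> CalibrationCurve:
    """Sort records by B^EMD and split into ``n_bins`` contiguous groups of
    near-equal count (difference at most 1); per-bin means give one
    (B̄^EMD, B̄^epis) point each."""
    if n_bins < 1:
        raise ValueError("need at least one bin")
    if n_bins > len(records):
        raise ValueError("more bins than records")
    b = np.array([r.b_emd for r in records])
    outcome = np.array([r.a_beats_b for r in records], dtype=float)
    order = np.argsort(b, kind="stable")
    centres, bepis, counts = [], [], []
    for idx in np.array_split(order, n_bins):
        centres.append(b[idx].mean())
        bepis.append(outcome[idx].mean())
        counts.append(len(idx))
    return CalibrationCurve(
        bin_centres=np.array(centres),
        bin_bepis=np.array(bepis),
        bin_counts=np.array(counts),
    )


@dataclass(frozen=True)
class OverconfidenceReport:
    """Per-bin overconfidence flags with the flagged fraction."""

    flags: np.ndarray
    flagged_fraction: float


def overconfidence_check(
    curve: CalibrationCurve,
    extra_curves: Sequence[CalibrationCurve] = (),
    slack_se: float = 1.0,
) -> OverconfidenceReport:
    """Flag bins where the criterion is more confident than the simulated
    replications warrant.

    A bin is overconfident when |B̄^EMD − ½| exceeds |B̄^epis − ½| by more
    than ``slack_se`` binomial standard errors of the B^epis estimate, or
    when the two deviations point to opposite sides of ½ (wrong-side
    region).  When curves from several epistemic distributions are given,
    the minimum |B̄^epis − ½| across them is used per bin, so conclusions
    must hold under every Ω.
    """
    curves = [curve, *extra_curves]
    n_bins = len(curve.bin_centres)
    dev_emd = curve.bin_centres - 0.5
    dev_epis_abs = np.full(n_bins, np.inf)
    wrong_side = np.zeros(n_bins, dtype=bool)
    se = np.zeros(n_bins)
    for cv in curves:
        if len(cv.bin_centres) != n_bins:
            raise ValueError("curves must share the bin count")
        dev = cv.bin_bepis - 0.5
        take = np.abs(dev) < dev_epis_abs
        dev_epis_abs = np.where(take, np.abs(dev), dev_epis_abs)
        p = np.clip(cv.bin_bepis, 0.0, 1.0)
        se_cv = np.sqrt(p * (1 - p) / np.maximum(cv.bin_counts, 1))
        se = np.where(take, se_cv, se)
        wrong_side |= (dev_emd * dev < 0) & (np.abs(dev_emd) > se_cv * slack_se)
    flags = (np.abs(dev_emd) > dev_epis_abs + slack_se * se) | wrong_side
    return OverconfidenceReport(
        flags=flags, flagged_fraction=float(flags.mean())
    )


def records_to_frame(records: Sequence[CalibrationRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "omega_id": [r.omega_id for r in records],
            "b_emd": [r.b_emd for r in records],
            "a_beats_b": [r.a_beats_b for r in records],
            "c": [r.c for r in records],
        }
    )


def curve_to_frame(curve: CalibrationCurve) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "b_emd": curve.bin_centres,
            "b_epis": curve.bin_bepis,
            "count": curve.bin_counts,
        }
    )
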
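"""Risk distributions, B^EMD tail probabilities and the rejection rule.

Integrating realisations of the hierarchical beta process gives a set of
risk values per model (its R-distribution).  Two models are compared by
the tail probability

    B_AB = P(R_A < R_B) ≈ (1 / M_A M_B) Σ_i Σ_j 1[R_{A,i} < R_{B,j}],

computed by sort-and-count rather than the literal double loop (identical
result).  A model A is rejected against B only when the evidence is
strong (P(R_B < R_A) > ε, i.e. B_AB < 1 − ε) *and* A has the larger
empirical risk; otherwise both models are retained.  The comparison is
ternary: reject A, reject B, or keep both.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np

from .contract import CandidateModel
from .hb_process import HBProcessSpec, sample_realisation
from .ppf_core import (
    DEFAULT_L_SYNTH,
    DEFAULT_N_GRID,
    delta_emd,
    mixed_and_synthetic_ppfs,
    pointwise_losses,
    ppf_risk,
)

DEFAULT_RSE_TOL = 2.0**-5  # stop when the relative SE of the mean risk < 1/32
DEFAULT_M_MIN = 32
DEFAULT_M_MAX = 4096
DEFAULT_BATCH = 16

#: ε must exceed the inverse squared golden ratio for dice transitivity
GOLDEN_RATIO_SQ_INV = ((math.sqrt(5.0) - 1.0) / 2.0) ** 2  # ≈ 0.382


@dataclass(frozen=True)
class RiskSamples:
    """Risk values R[q̂_i] representing one model's R-distribution.

    ``rse`` is the achieved relative standard error of the mean risk;
    ``absolute_se_used`` flags the fallback applied when the mean risk is
    zero and a relative error is undefined.
    """

    model_id: str
    values: np.ndarray
    rse: float
    absolute_se_used: bool = False

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 1 or values.size < 1:
            raise ValueError("need at least one risk sample")
        if not np.all(np.isfinite(values)):
            raise ValueError("risk samples must be finite")

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class ComparisonResult:
    """One pairwise comparison: B_AB with the two empirical risks."""

    model_a: str
    model_b: str
    b_emd: float
    empirical_risk_a: float
    empirical_risk_b: float
    c: float


@dataclass(frozen=True)
class Decision:
    """Outcome of the rejection rule over a candidate set."""

    rejected: frozenset
    epsilon: float


def sample_risk_distribution(
    spec: HBProcessSpec,
    rng: np.random.Generator | None = None,
    rse_tol: float = DEFAULT_RSE_TOL,
    m_min: int = DEFAULT_M_MIN,
    m_max: int = DEFAULT_M_MAX,
    batch: int = DEFAULT_BATCH,
    model_id: str = "",
) -> RiskSamples:
    """Draw HB realisations and integrate each into a risk value, in
    batches, until the relative standard error of the mean risk drops
    below ``rse_tol`` (or ``m_max`` realisations are reached).

    A zero-sensitivity (or zero-discrepancy) process is a Dirac at R[q*]:
    ``m_min`` identical values are returned with rse = 0.
    """
    if not (0 < rse_tol < 1):
        raise ValueError("rse_tol must be in (0, 1)")
    rng = np.random.default_rng(rng)
    if spec._degenerate:
        r0 = float(np.trapezoid(spec._q_star_dyadic, spec.dyadic_grid))
        return RiskSamples(model_id=model_id, values=np.full(m_min, r0), rse=0.0)
    risks: List[float] = []
    absolute_se_used = False
    while True:
        risks.extend(
            sample_realisation(spec, rng).risk() for _ in range(batch)
        )
        m = len(risks)
        if m < m_min:
            continue
        arr = np.asarray(risks)
        se = float(arr.std(ddof=1)) / math.sqrt(m)
        mean = float(arr.mean())
        if mean == 0.0:
            absolute_se_used = True
            rse = se
        else:
            rse = se / abs(mean)
        if rse < rse_tol or m >= m_max:
            return RiskSamples(
                model_id=model_id,
                values=arr,
                rse=rse,
                absolute_se_used=absolute_se_used,
            )


def b_emd(a: RiskSamples, b: RiskSamples) -> float:
    """Tail probability P(R_A < R_B) from two R-sample sets.

    Equals the literal double sum over strict inequalities; ties count
    for neither direction, so with tied values the complementarity
    b(a,b) + b(b,a) = 1 degrades by exactly the tie mass.
    """
    av = a.values if isinstance(a, RiskSamples) else np.asarray(a, float)
    bv = b.values if isinstance(b, RiskSamples) else np.asarray(b, float)
    if av.size == 0 or bv.size == 0:
        raise ValueError("both sample sets must be nonempty")
    b_sorted = np.sort(bv)
    # per a_i, count of b_j strictly greater than a_i
    greater = bv.size - np.searchsorted(b_sorted, av, side="right")
    return float(greater.sum()) / (av.size * bv.size)


def compare_models(
    model_a: CandidateModel,
    model_b: CandidateModel,
    observed,
    c: float,
    rng: np.random.Generator | None = None,
    L_synth: int = DEFAULT_L_SYNTH,
    n_grid: int = DEFAULT_N_GRID,
    n_refinements: int | None = None,
    rse_tol: float = DEFAULT_RSE_TOL,
    m_min: int = DEFAULT_M_MIN,
    m_max: int = DEFAULT_M_MAX,
) -> ComparisonResult:
    """End-to-end pairwise comparison on a held-out dataset.

    Builds each model's mixed and synthetic PPFs, its discrepancy curve
    and HB process at sensitivity ``c``, samples both R-distributions and
    returns B_AB together with the two empirical risks.
    """
    rng = np.random.default_rng(rng)
    samples: Dict[str, RiskSamples] = {}
    emp_risk: Dict[str, float] = {}
    kwargs = {} if n_refinements is None else {"n_refinements": n_refinements}
    for key, model in (("a", model_a), ("b", model_b)):
        mixed, synth = mixed_and_synthetic_ppfs(
            model, observed, L_synth=L_synth, rng=rng, n_grid=n_grid
        )
        spec = HBProcessSpec(
            mixed_ppf=mixed, discrepancy=delta_emd(mixed, synth), c=c, **kwargs
        )
        samples[key] = sample_risk_distribution(
            spec, rng=rng, rse_tol=rse_tol, m_min=m_min, m_max=m_max,
            model_id=getattr(model, "model_id", key),
        )
        emp_risk[key] = float(
            np.mean(pointwise_losses(observed, model).values)
        )
    return ComparisonResult(
        model_a=samples["a"].model_id,
        model_b=samples["b"].model_id,
        b_emd=b_emd(samples["a"], samples["b"]),
        empirical_risk_a=emp_risk["a"],
        empirical_risk_b=emp_risk["b"],
        c=c,
    )


def emd_reject(
    comparisons: Iterable[ComparisonResult],
    epsilon: float,
    convention: str = "two-sided",
) -> Decision:
    """Apply the ternary rejection rule over all pairwise comparisons.

    With the default ``two-sided`` convention, model A is rejected iff
    some competitor B satisfies P(R_B < R_A) > ε — i.e. B_AB < 1 − ε —
    *and* R̂_A > R̂_B.  The ``literal`` convention instead rejects A when
    B_AB < ε (and R̂_A > R̂_B); it is provided for completeness but makes
    the rule one-sided and is not recommended.
    """
    if not (0.5 < epsilon <= 1.0):
        raise ValueError("epsilon must be in (0.5, 1]")
    if convention not in ("two-sided", "literal"):
        raise ValueError("convention must be 'two-sided' or 'literal'")
    threshold = (1.0 - epsilon) if convention == "two-sided" else epsilon
    rejected = set()
    for comp in comparisons:
        # evidence against A
        if comp.b_emd < threshold and comp.empirical_risk_a > comp.empirical_risk_b:
            rejected.add(comp.model_a)
        # evidence against B (mirror image)
        if (1.0 - comp.b_emd) < threshold and (
            comp.empirical_risk_b > comp.empirical_risk_a
        ):
            rejected.add(comp.model_b)
    return Decision(rejected=frozenset(rejected), epsilon=epsilon)


def transitivity_check(b_ab: float, b_bc: float, epsilon: float) -> bool:
    """Dice-transitivity certificate: for ε > φ⁻² (φ the golden ratio),
    B_AB > √ε and B_BC > √ε guarantee B_AC > ε without computing it.

    Returns True when the certificate applies; False makes no claim
    either way.
    """
    if epsilon <= GOLDEN_RATIO_SQ_INV:
        raise ValueError(
            f"dice transitivity requires epsilon > {GOLDEN_RATIO_SQ_INV:.6f}"
        )
    root = math.sqrt(epsilon)
    return b_ab > root and b_bc > root
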
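"""BCPNN information component: expectation, variance, credible interval.

The Bayesian Confidence Propagation Neural Network (BCPNN) information
component (IC) measures disproportionality on a 2×2 case table as the log₂
ratio of the observed joint reporting probability of a drug–event pair to
the product of its margins, shrunk toward independence by Beta/Dirichlet
priors.  With the standard hyperparameters the moments are

    E(IC) = log₂ [ (N11+γ11)(N+++α)(N+++β) / ((N+++γ)(N1++α1)(N+1+β1)) ]

    V(IC) = (1/ln 2)² [ (N++−N11+γ−γ11) / ((N11+γ11)(1+N+++γ))
                      + (N++−N1++α−α1) / ((N1++α1)(1+N+++α))
                      + (N++−N+1+β−β1) / ((N+1+β1)(1+N+++β)) ]

where the joint prior count γ is coupled to the margins,

    γ = γ11 (N+++α)(N+++β) / ((N1++α1)(N+1+β1)),

so that E(IC) = 0 exactly on an empty table.  The 95% credible interval uses
the ±2 standard-deviation convention, IC₀₂₅/IC₉₇₅ = E(IC) ∓ 2√V(IC).  A pair
is a *signal* when IC₀₂₅ > 0 and an *inverse signal* when IC₉₇₅ < 0.  The
shrinkage makes the IC stable at small counts, where the reporting odds
ratio (provided here as a comparator) is noisy or undefined.

Internals are computed with natural logs; outputs are in bits (log₂ units).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np
import pandas as pd

from .contingency import ContingencyTable

LN2 = math.log(2.0)


@dataclass(frozen=True, slots=True)
class PriorSpec:
    """BCPNN hyperparameters (dimensionless pseudo-counts).

    Defaults are the standard choice γ11=1, α1=β1=1, α=β=2.  The joint prior
    count γ is margin-coupled and therefore recomputed for every table, never
    cached across tables.
    """

    gamma11: float = 1.0
    alpha1: float = 1.0
    beta1: float = 1.0
    alpha: float = 2.0
    beta: float = 2.0

    def __post_init__(self) -> None:
        if min(self.gamma11, self.alpha1, self.beta1, self.alpha, self.beta) <= 0:
            raise ValueError("all prior hyperparameters must be positive")

    def gamma(self, n1plus: float, nplus1: float, nplusplus: float) -> float:
        """Margin-coupled joint prior count for one table."""
        return (self.gamma11 * (nplusplus + self.alpha) * (nplusplus + self.beta)
                / ((n1plus + self.alpha1) * (nplus1 + self.beta1)))


DEFAULT_PRIORS = PriorSpec()


class Classification(str, Enum):
    SIGNAL = "signal"
    INVERSE = "inverse"
    NONE = "none"


@dataclass(frozen=True, slots=True)
class ICResult:
    """IC moments (bits, bits²), credible bounds and signal classification."""

    e_ic: float
    v_ic: float
    ic025: float
    ic975: float
    classification: Classification


@dataclass(frozen=True, slots=True)
class RORResult:
    """Reporting odds ratio with its 95% CI (undefined on zero cells)."""

    ror: float
    ci_low: float | None
    ci_high: float | None


def _validate(table: ContingencyTable) -> None:
    if table.nplusplus <= 0:
        raise ValueError("the table must contain at least one case")


def expectation_ic(table: ContingencyTable,
                   priors: PriorSpec = DEFAULT_PRIORS) -> float:
    """Posterior expectation of the information component, in bits.

    Finite for every valid table, including N11 = 0: the priors bound all
    factors away from zero.
    """
    _validate(table)
    n11, n1p, np1, npp = (table.n11, table.n1plus, table.nplus1, table.nplusplus)
    g = priors.gamma(n1p, np1, npp)
    num = (math.log(n11 + priors.gamma11)
           + math.log(npp + priors.alpha) + math.log(npp + priors.beta))
    den = (math.log(npp + g)
           + math.log(n1p + priors.alpha1) + math.log(np1 + priors.beta1))
    return (num - den) / LN2


def variance_ic(table: ContingencyTable,
                priors: PriorSpec = DEFAULT_PRIORS) -> float:
    """Posterior variance of the information component, in bits²."""
    _validate(table)
    n11, n1p, np1, npp = (table.n11, table.n1plus, table.nplus1, table.nplusplus)
    g = priors.gamma(n1p, np1, npp)
    term11 = ((npp - n11 + g - priors.gamma11)
              / ((n11 + priors.gamma11) * (1 + npp + g)))
    term1p = ((npp - n1p + priors.alpha - priors.alpha1)
              / ((n1p + priors.alpha1) * (1 + npp + priors.alpha)))
    termp1 = ((npp - np1 + priors.beta - priors.beta1)
              / ((np1 + priors.beta1) * (1 + npp + priors.beta)))
    return (term11 + term1p + termp1) / LN2**2


def credible_interval(e_ic: float, v_ic: float) -> tuple[float, float]:
    """95% credible bounds (IC₀₂₅, IC₉₇₅) = E(IC) ± 2√V(IC).

    The ±2-standard-deviation convention, not ±1.96.
    """
    if v_ic < 0:
        raise ValueError("variance must be non-negative")
    half = 2.0 * math.sqrt(v_ic)
    return (e_ic - half, e_ic + half)


def classify(ic025: float, ic975: float) -> Classification:
    """Signal iff IC₀₂₅ > 0; inverse signal iff IC₉₇₅ < 0; otherwise none."""
    if ic025 > ic975:
        raise ValueError("ic025 must not exceed ic975")
    if ic025 > 0:
        return Classification.SIGNAL
    if ic975 < 0:
        return Classification.INVERSE
    return Classification.NONE


def ic_result(table: ContingencyTable,
              priors: PriorSpec = DEFAULT_PRIORS) -> ICResult:
    """Full IC scoring of one table: moments, bounds and classification."""
    e = expectation_ic(table, priors)
    v = variance_ic(table, priors)
    lo, hi = credible_interval(e, v)
    return ICResult(e_ic=e, v_ic=v, ic025=lo, ic975=hi,
                    classification=classify(lo, hi))


def ror(table: ContingencyTable) -> RORResult:
    """Reporting odds ratio (N11·N00)/(N10·N01) with a 95% Wald CI.

    The point estimate is returned where the denominator cells are positive;
    any zero cell leaves the CI (and, for zero denominators, the estimate)
    undefined.  Kept as a comparator: unlike the IC it is unstable at small
    counts.
    """
    n11, n10, n01, n00 = table.n11, table.n10, table.n01, table.n00
    if n10 == 0 or n01 == 0:
        return RORResult(ror=math.inf if n11 > 0 else math.nan,
                         ci_low=None, ci_high=None)
    point = (n11 * n00) / (n10 * n01)
    if n11 == 0 or n00 == 0:
        return RORResult(ror=point, ci_low=None, ci_high=None)
    se = math.sqrt(1 / n11 + 1 / n10 + 1 / n01 + 1 / n00)
    return RORResult(
        ror=point,
        ci_low=math.exp(math.log(point) - 1.96 * se),
        ci_high=math.exp(math.log(point) + 1.96 * se),
    )


# --------------------------------------------------------------------------
# margin calibration


def _expectation_ic_vec(n11: float, n1p: float, np1: np.ndarray, npp: float,
                        priors: PriorSpec) -> np.ndarray:
    """Vectorized E(IC) over an array of candidate N+1 margins."""
    g = (priors.gamma11 * (npp + priors.alpha) * (npp + priors.beta)
         / ((n1p + priors.alpha1) * (np1 + priors.beta1)))
    num = (np.log(n11 + priors.gamma11)
           + np.log(npp + priors.alpha) + np.log(npp + priors.beta))
    den = (np.log(npp + g)
           + np.log(n1p + priors.alpha1) + np.log(np1 + priors.beta1))
    return (num - den) / LN2


def calibrate_margin(
    rows: Sequence[tuple[int, int, float]],
    nplusplus: int,
    search_range: tuple[int, int] = (1, 50_000),
    priors: PriorSpec = DEFAULT_PRIORS,
) -> int:
    """Recover an unprinted event margin N+1 from published IC values.

    Published signal screens print N11 and N1+ per drug and the grand total
    N++, but usually not the target event's total case count N+1.  Given rows
    of (N11, N1+, published IC), this grid-searches integer N+1 over
    ``search_range`` and returns the value minimizing the sum of squared
    deviations of E(IC) from the published ICs, ties broken toward the
    smaller margin.  One margin is calibrated per database and shared by all
    of its rows.

    A minimum at either boundary of the range triggers a warning that the
    range is likely too narrow.
    """
    if not rows:
        raise ValueError("at least one calibration row is required")
    lo, hi = search_range
    if lo < 1 or hi < lo:
        raise ValueError("invalid search range")
    candidates = np.arange(lo, hi + 1, dtype=float)
    sse = np.zeros_like(candidates)
    for n11, n1p, published_ic in rows:
        sse += (_expectation_ic_vec(n11, n1p, candidates, nplusplus, priors)
                - published_ic) ** 2
    best = int(np.argmin(sse))  # argmin takes the first (smallest) on ties
    margin = int(candidates[best])
    if margin in (lo, hi):
        warnings.warn(
            f"calibrated margin {margin} lies on the search boundary "
            f"[{lo}, {hi}]; widen the range", stacklevel=2)
    return margin


# --------------------------------------------------------------------------
# batch scoring


def score_frame(counts: pd.DataFrame,
                priors: PriorSpec = DEFAULT_PRIORS) -> pd.DataFrame:
    """Score a flat table of counts.

    Input columns: ``group_name, n11, n1plus, nplus1, nplusplus``.  Output
    appends ``e_ic, v_ic, ic025, ic975, classification``.  This is the
    interchange format of the batch scorer: a tsv/csv written from it can be
    re-read and re-scored to identical classifications.
    """
    out = counts.copy()
    scored = [
        ic_result(ContingencyTable.from_margins(
            int(r.n11), int(r.n1plus), int(r.nplus1), int(r.nplusplus)), priors)
        for r in counts.itertuples(index=False)
    ]
    out["e_ic"] = [s.e_ic for s in scored]
    out["v_ic"] = [s.v_ic for s in scored]
    out["ic025"] = [s.ic025 for s in scored]
    out["ic975"] = [s.ic975 for s in scored]
    out["classification"] = [s.classification.value for s in scored]
    return out


__all__ = [
    "Classification",
    "DEFAULT_PRIORS",
    "ICResult",
    "PriorSpec",
    "RORResult",
    "calibrate_margin",
    "classify",
    "credible_interval",
    "expectation_ic",
    "ic_result",
    "ror",
    "score_frame",
    "variance_ic",
]
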
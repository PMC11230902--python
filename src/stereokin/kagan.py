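"""Closed-form kinetic-resolution (KR) relations under competing second-order kinetics.

For a racemic substrate whose enantiomers are consumed by irreversible,
first-order-in-substrate steps with rate constants k1_S (fast) and k1_R (slow),
the selectivity factor is s = k1_S / k1_R.  Dividing the two rate laws removes
time and the co-reactant concentration entirely, giving the classical (Kagan)
relations between conversion C and the enantiomeric excesses of the product
pool (ee_p) and of the recovered substrate pool (ee_s):

    s = ln[1 - C(1 + ee_p)] / ln[1 - C(1 - ee_p)]
    s = ln[(1 - C)(1 - ee_s)] / ln[(1 - C)(1 + ee_s)]

together with the mass balance ee_s (1 - C) = ee_p C.  Conversion C is defined
on the racemic substrate pool: C = 0.5 means half the racemate has reacted.

These relations hold for any co-reactant profile (they are exact for the
second-order steps used in :mod:`stereokin.network`, whose integration serves
as an independent numerical cross-check).  All e.e. values here are magnitudes
in the canonical orientation (s >= 1, fast enantiomer = S); callers wanting the
mirrored system mirror their pools explicitly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

from scipy.optimize import brentq

from .errors import DomainError, InfeasibleObservationError, UndefinedQuantityError

__all__ = [
    "KRParameters",
    "ee_product_at_conversion",
    "ee_substrate_at_conversion",
    "s_from_observation",
    "conversion_from_ees",
]

# bracket shrink and root tolerance for the monotone 1-D searches
_DELTA = 1e-12
_XTOL = 1e-10


@dataclass(frozen=True)
class KRParameters:
    """Selectivity factor and stage-1 rate constants of a kinetic resolution.

    Rate constants are stored in normalized units (k1_R = 1, k1_S = s by
    default); the closed-form relations are invariant to the common scale.
    """

    s: float
    k1_R: float = 1.0

    def __post_init__(self) -> None:
        if self.s < 1.0:
            raise DomainError(
                f"selectivity factor must be >= 1 (mirror the pools for s < 1), got {self.s}"
            )
        if self.k1_R <= 0:
            raise DomainError(f"k1_R must be positive, got {self.k1_R}")

    @property
    def k1_S(self) -> float:
        return self.s * self.k1_R


def _check_sC(s: float, C: float) -> None:
    if s < 1.0:
        raise DomainError(f"s must be >= 1 (mirror the pools first for s < 1), got {s}")
    if not 0.0 < C < 1.0:
        raise DomainError(f"conversion must lie strictly in (0, 1), got {C}")


def ee_product_at_conversion(s: float, C: float) -> float:
    """e.e. of the product pool of a KR with selectivity s at conversion C.

    Solves s = ln[1 - C(1+ee)] / ln[1 - C(1-ee)] for the unique root
    ee in [0, min(1, 1/C - 1)) by bracketed root finding; the objective is
    strictly monotone in ee, so the root is unique.
    """
    _check_sC(s, C)
    if s == 1.0:
        return 0.0

    def objective(ee: float) -> float:
        # log-difference form of the defining relation; monotone decreasing in ee
        return math.log(1.0 - C * (1.0 + ee)) - s * math.log(1.0 - C * (1.0 - ee))

    hi = min(1.0, 1.0 / C - 1.0) - _DELTA
    if objective(hi) > 0.0:  # root pinned at the bracket edge (extreme s)
        return hi
    return brentq(objective, 0.0, hi, xtol=_XTOL)


def ee_substrate_at_conversion(s: float, C: float) -> float:
    """e.e. of the recovered substrate of a KR with selectivity s at conversion C.

    Solves s = ln[(1-C)(1-ee)] / ln[(1-C)(1+ee)]; satisfies the mass balance
    ee_s (1 - C) = ee_p C with :func:`ee_product_at_conversion`.
    """
    _check_sC(s, C)
    if s == 1.0:
        return 0.0

    def objective(ee: float) -> float:
        return math.log((1.0 - C) * (1.0 - ee)) - s * math.log((1.0 - C) * (1.0 + ee))

    # (1-C)(1+ee) <= 1 requires ee <= C/(1-C)
    hi = min(1.0, C / (1.0 - C)) - _DELTA
    if objective(hi) > 0.0:
        return hi
    return brentq(objective, 0.0, hi, xtol=_XTOL)


def s_from_observation(
    C: float, ee: float, which: Literal["product", "substrate"] = "product"
) -> float:
    """Selectivity factor implied by one (conversion, e.e.) observation.

    The exact inverse of the forward relations; round-trips with them to
    better than 1e-6 relative.  Raises :class:`InfeasibleObservationError`
    naming the violated bound when the pair is not physically realizable.
    """
    if not 0.0 < C < 1.0:
        raise DomainError(f"conversion must lie strictly in (0, 1), got {C}")
    if not 0.0 <= ee < 1.0:
        raise DomainError(f"e.e. must lie in [0, 1), got {ee}")
    if which == "product":
        num_arg = 1.0 - C * (1.0 + ee)
        den_arg = 1.0 - C * (1.0 - ee)
        if num_arg <= 0.0:
            raise InfeasibleObservationError(
                f"product e.e. {ee} at conversion {C} violates C(1+ee) < 1: "
                f"the major product cannot exceed the substrate's major supply"
            )
    elif which == "substrate":
        num_arg = (1.0 - C) * (1.0 - ee)
        den_arg = (1.0 - C) * (1.0 + ee)
        if den_arg >= 1.0:
            raise InfeasibleObservationError(
                f"substrate e.e. {ee} at conversion {C} violates (1-C)(1+ee) < 1: "
                f"more major enantiomer would remain than was initially present"
            )
        if num_arg <= 0.0:  # unreachable for ee < 1, kept for symmetry
            raise InfeasibleObservationError(
                f"substrate observation (C={C}, ee={ee}) leaves a non-positive minor pool"
            )
    else:
        raise DomainError(f"which must be 'product' or 'substrate', got {which!r}")
    if ee == 0.0:
        return 1.0
    return math.log(num_arg) / math.log(den_arg)


def conversion_from_ees(ee_s: float, ee_p: float) -> float:
    """Conversion implied by the substrate and product e.e.s of one KR.

    From the mass balance ee_s (1 - C) = ee_p C: C = ee_s / (ee_s + ee_p).
    Model-free (holds for any selectivity), so it is the standard way to get C
    from two chiral-HPLC measurements.
    """
    if ee_s < 0 or ee_p < 0:
        raise DomainError("e.e. magnitudes must be nonnegative")
    if ee_s + ee_p == 0:
        raise UndefinedQuantityError(
            "conversion undefined when both e.e.s are zero (no stereochemical information)"
        )
    return ee_s / (ee_s + ee_p)
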
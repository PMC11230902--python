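"""Statistical (Horeau-type) coupling of enantiomer pools and its diagnostics.

When two enantioenriched pools are joined two-at-a-time with equal rate
constants for every configuration pairing (no asymmetric induction in the
coupling step), each pool's composition is invariant during the coupling, so
the stereoisomer distribution of the dimeric product is exactly the product of
the pools' enantiomer fractions — no kinetics, pure counting.  Writing a and b
for the e.e. magnitudes of the two pools (major convention, with the majors on
opposite configurations as a kinetic resolution delivers them), the closed
forms are

    heterochiral e.e. = (a + b) / (1 + a b)
    d.r. (hetero:homo) = (1 + a b) / (1 - a b)

— the statistical amplification of enantiopurity: the heterochiral product is
always at least as enantiopure as either pool, at the cost of a minor
homochiral fraction.  The classic symmetric-linker variant couples one pool
with itself; there the homochiral dimer is the amplified chiral product
(e.e. 2a/(1+a^2)) and the heterochiral dimer is the achiral meso byproduct.

Time-dependence and induction (k2_hetero != k2_homo) are deliberately not
modelled here; they live in :mod:`stereokin.network`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Tuple

from .errors import DomainError, UndefinedQuantityError
from .pools import EnantiomerPool, ProductDistribution

__all__ = [
    "CouplingParameters",
    "statistical_coupling",
    "hetero_ee_statistical",
    "dr_statistical",
    "horeau_homocoupling",
    "homochiral_dimer_ee",
    "meso_fraction",
    "PoolInference",
    "infer_pool_ees",
]


@dataclass(frozen=True)
class CouplingParameters:
    """Stage-2 rate constants for the coupling step.

    ``induction_ratio`` = k2_hetero / k2_homo measures asymmetric induction in
    the coupling; 1 is the statistical (no-induction) case for which the closed
    forms of this module are exact.
    """

    k2_hetero: float = 1.0
    k2_homo: float = 1.0

    def __post_init__(self) -> None:
        if self.k2_hetero <= 0 or self.k2_homo <= 0:
            raise DomainError("coupling rate constants must be positive")

    @property
    def induction_ratio(self) -> float:
        return self.k2_hetero / self.k2_homo


def hetero_ee_statistical(a: float, b: float) -> float:
    """Heterochiral-product e.e. (a+b)/(1+ab) for pool e.e. magnitudes a, b."""
    return (a + b) / (1.0 + a * b)


def dr_statistical(a: float, b: float) -> float:
    """Heterochiral:homochiral d.r. (1+ab)/(1-ab) for pool e.e. magnitudes a, b."""
    if a * b == 1.0:
        return math.inf
    return (1.0 + a * b) / (1.0 - a * b)


def statistical_coupling(
    pool1: EnantiomerPool, pool2: EnantiomerPool
) -> ProductDistribution:
    """Stereoisomer distribution from statistically coupling two pools.

    ``pool1`` is the linker-bearing intermediate, ``pool2`` the partner pool
    (e.g. recovered substrate); heterochiral means opposite absolute
    configurations joined.  The number of dimers equals the limiting pool's
    total; with equal rate constants both pools keep their composition
    throughout, so each dimer draws its two configurations independently from
    the two pools' (constant) enantiomer fractions.

    S-units and R-units are conserved exactly across the limiting amount
    consumed from each pool.
    """
    if pool1.total == 0 or pool2.total == 0:
        raise UndefinedQuantityError("cannot couple an empty pool")
    n = min(pool1.total, pool2.total)
    f1S, f1R = pool1.fraction_S, pool1.fraction_R
    f2S, f2R = pool2.fraction_S, pool2.fraction_R
    return ProductDistribution(
        hetero_SR=n * f1S * f2R,
        hetero_RS=n * f1R * f2S,
        homo_SS=n * f1S * f2S,
        homo_RR=n * f1R * f2R,
    )


def horeau_homocoupling(pool: EnantiomerPool) -> ProductDistribution:
    """Random pairwise self-coupling of one pool through a symmetric linker.

    Returns the dimer distribution (total = pool.total / 2): homochiral SS/RR
    dimers are the chiral products, the heterochiral SR dimer is meso (achiral;
    its two orientations are identical, split evenly over the two hetero
    slots).  The homochiral dimer e.e. is 2a/(1+a^2) >= a for pool e.e. a, and
    the meso fraction of all dimers is (1-a^2)/2.
    """
    if pool.total == 0:
        raise UndefinedQuantityError("cannot homocouple an empty pool")
    n = pool.total / 2.0
    p, q = pool.fraction_S, pool.fraction_R
    return ProductDistribution(
        hetero_SR=n * p * q,
        hetero_RS=n * p * q,
        homo_SS=n * p * p,
        homo_RR=n * q * q,
    )


def homochiral_dimer_ee(dist: ProductDistribution) -> float:
    """e.e. over the chiral SS/RR dimer pair of a symmetric-linker coupling."""
    return dist.homo_ee


def meso_fraction(dist: ProductDistribution) -> float:
    """Fraction of all dimers that are the achiral meso (heterochiral) isomer."""
    if dist.total == 0:
        raise UndefinedQuantityError("empty distribution")
    return dist.hetero_total / dist.total


@dataclass(frozen=True)
class PoolInference:
    """Result of inverting (d.r., d.e.) observations to pool e.e.s.

    ``feasible`` is True when some pair of pool e.e.s (a, b) in [0,1]^2 coupled
    statistically (no induction) reproduces the observation exactly; the pair
    is then in ``pool_ees`` (unordered — the summary statistics cannot say
    which pool is which).  When infeasible, ``reason`` explains the failure:
    the observation is evidence of asymmetric induction and/or more complex
    kinetics in the coupling step.
    """

    feasible: bool
    pool_ees: Optional[Tuple[float, float]]
    discriminant: float
    reason: str = ""


def infer_pool_ees(dr_observed: float, de_observed: float) -> PoolInference:
    """Invert an observed (d.r., d.e.) pair under the no-induction model.

    From the closed forms, ab = (R-1)/(R+1) with R the observed hetero:homo
    ratio, and a + b = d.e. * (1 + ab) with d.e. the excess over the
    heterochiral pair (taken as its major:minor pair; with a chiral linker the
    two heterochiral diastereomers are assumed resolved into exactly that
    pair).  a and b are then the roots of x^2 - (a+b) x + ab = 0; a negative
    discriminant, or a root outside [0, 1], certifies that NO statistical
    coupling of any two pools can produce the observation.
    """
    if dr_observed < 1.0:
        raise DomainError(
            f"d.r. must be >= 1 when written as X:1 (relabel the major diastereomer), "
            f"got {dr_observed}"
        )
    if not 0.0 <= de_observed <= 1.0:
        raise DomainError(f"d.e. must lie in [0, 1], got {de_observed}")
    prod = (dr_observed - 1.0) / (dr_observed + 1.0)  # ab
    tot = de_observed * (1.0 + prod)  # a + b
    disc = tot * tot - 4.0 * prod
    # exact-diagonal observations (a = b) have discriminant 0; rounding can
    # push the computed value a few ulp negative, which must not read as
    # model infeasibility
    noise_floor = 64.0 * 2.220446049250313e-16 * max(tot * tot, 4.0 * abs(prod), 1.0)
    if -noise_floor <= disc < 0.0:
        disc = 0.0
    if disc < 0.0:
        return PoolInference(
            feasible=False,
            pool_ees=None,
            discriminant=disc,
            reason=(
                f"discriminant (a+b)^2 - 4ab = {disc:.6g} < 0: no statistical "
                f"(no-induction) coupling of any two pools can give d.r. "
                f"{dr_observed:g}:1 with {de_observed:.0%} d.e.; the observation "
                f"implies asymmetric induction and/or more complex kinetics in "
                f"the coupling step"
            ),
        )
    root = math.sqrt(disc)
    a = (tot + root) / 2.0
    b = (tot - root) / 2.0
    if a > 1.0 + 1e-12 or b < -1e-12:
        return PoolInference(
            feasible=False,
            pool_ees=None,
            discriminant=disc,
            reason=(
                f"formal roots ({a:.6g}, {b:.6g}) fall outside [0, 1]: "
                f"no physical pool e.e. pair reproduces the observation"
            ),
        )
    return PoolInference(
        feasible=True,
        pool_ees=(min(a, 1.0), max(b, 0.0)),
        discriminant=disc,
    )
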
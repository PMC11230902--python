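"""Enantiomer bookkeeping: pools, stereoisomer distributions and e.e./d.r./d.e. algebra.

A pool is a chemically uniform collection of molecules carrying one stereocentre,
described only by the amounts of its two configurations.  The sign convention is
fixed package-wide: positive enantiomeric excess (e.e.) means S-enriched, and the
fast-reacting enantiomer of a kinetic resolution is S (so the selectivity factor
s = k1(S)/k1(R) >= 1 in the canonical orientation).  Every formula downstream
assumes this convention; the :func:`EnantiomerPool.mirrored` helper swaps it
explicitly rather than letting signs flip silently.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

from .errors import DomainError, UndefinedQuantityError

__all__ = [
    "EnantiomerPool",
    "ProductDistribution",
    "ee_of",
    "pool_from_ee",
    "dr_of",
    "format_ee_percent",
    "format_dr",
]


@dataclass(frozen=True)
class EnantiomerPool:
    """Amounts of the two configurations of one chemical pool.

    Parameters
    ----------
    amount_S, amount_R:
        Nonnegative amounts (mol, or normalized units) of the S and R
        configurations.
    label:
        Free-text identifier of the chemical pool (substrate, intermediate,
        product, ...).
    """

    amount_S: float
    amount_R: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.amount_S < 0 or self.amount_R < 0:
            raise DomainError(
                f"pool amounts must be nonnegative, got "
                f"(S={self.amount_S}, R={self.amount_R})"
            )

    @property
    def total(self) -> float:
        return self.amount_S + self.amount_R

    @property
    def ee(self) -> float:
        """Signed enantiomeric excess in [-1, 1]; positive = S-enriched."""
        return ee_of(self)

    @property
    def fraction_S(self) -> float:
        if self.total == 0:
            raise UndefinedQuantityError(f"pool {self.label!r} is empty")
        return self.amount_S / self.total

    @property
    def fraction_R(self) -> float:
        return 1.0 - self.fraction_S

    def mirrored(self) -> "EnantiomerPool":
        """The mirror-image pool (S and R amounts swapped); negates the e.e."""
        return replace(self, amount_S=self.amount_R, amount_R=self.amount_S)

    @classmethod
    def from_ee(cls, ee: float, total: float = 1.0, label: str = "") -> "EnantiomerPool":
        return pool_from_ee(ee, total, label)


def ee_of(pool: EnantiomerPool) -> float:
    """Signed enantiomeric excess (amount_S - amount_R)/total of a pool."""
    if pool.total == 0:
        raise UndefinedQuantityError(
            f"e.e. undefined for empty pool {pool.label!r} (total amount is 0)"
        )
    return (pool.amount_S - pool.amount_R) / pool.total


def pool_from_ee(ee: float, total: float, label: str = "") -> EnantiomerPool:
    """Build a pool of the given total amount and signed e.e.

    Round-trips with :func:`ee_of` to machine precision.
    """
    if not -1.0 <= ee <= 1.0:
        raise DomainError(f"|ee| must be <= 1, got {ee}")
    if total <= 0:
        raise DomainError(f"total must be positive, got {total}")
    return EnantiomerPool(
        amount_S=total * (1.0 + ee) / 2.0,
        amount_R=total * (1.0 - ee) / 2.0,
        label=label,
    )


@dataclass(frozen=True)
class ProductDistribution:
    """Amounts of the four stereoisomeric two-unit products of a coupling.

    ``hetero_SR``/``hetero_RS`` are the heterochiral (opposite-configuration)
    pairings, with the first letter naming the configuration contributed by the
    linker-bearing pool and the second the configuration from the partner pool.
    ``homo_SS``/``homo_RR`` are the homochiral pairings.
    """

    hetero_SR: float
    hetero_RS: float
    homo_SS: float
    homo_RR: float

    def __post_init__(self) -> None:
        for name in ("hetero_SR", "hetero_RS", "homo_SS", "homo_RR"):
            if getattr(self, name) < 0:
                raise DomainError(f"{name} must be nonnegative, got {getattr(self, name)}")

    @property
    def hetero_total(self) -> float:
        return self.hetero_SR + self.hetero_RS

    @property
    def homo_total(self) -> float:
        return self.homo_SS + self.homo_RR

    @property
    def total(self) -> float:
        return self.hetero_total + self.homo_total

    @property
    def hetero_ee(self) -> float:
        """Signed e.e. over the heterochiral pair, (SR - RS)/(SR + RS)."""
        if self.hetero_total == 0:
            raise UndefinedQuantityError("no heterochiral product formed; e.e. undefined")
        return (self.hetero_SR - self.hetero_RS) / self.hetero_total

    @property
    def homo_ee(self) -> float:
        """Signed e.e. over the homochiral pair, (SS - RR)/(SS + RR)."""
        if self.homo_total == 0:
            raise UndefinedQuantityError("no homochiral product formed; e.e. undefined")
        return (self.homo_SS - self.homo_RR) / self.homo_total

    @property
    def dr(self) -> float:
        return dr_of(self)

    def mirrored(self) -> "ProductDistribution":
        """Mirror image: SR<->RS and SS<->RR swapped; negates e.e.s, keeps d.r."""
        return ProductDistribution(
            hetero_SR=self.hetero_RS,
            hetero_RS=self.hetero_SR,
            homo_SS=self.homo_RR,
            homo_RR=self.homo_SS,
        )


def dr_of(dist: ProductDistribution) -> float:
    """Heterochiral:homochiral diastereomeric ratio, normalized to X:1.

    Returns ``math.inf`` when no homochiral product is present.
    """
    hetero, homo = dist.hetero_total, dist.homo_total
    if hetero == 0 and homo == 0:
        raise UndefinedQuantityError("d.r. undefined for an all-zero distribution")
    if homo == 0:
        return math.inf
    return hetero / homo


def format_ee_percent(ee: float, decimals: int = 2) -> str:
    """Render a signed-fraction e.e. as a percentage string.

    Default 2 decimal places: the near-enantiopure regime of statistically
    amplified products (e.g. 99.98% vs 99.99%) is invisible at 1 decimal.
    Python's round() is round-half-even, the assumption made for all printed
    percentages.
    """
    return f"{round(abs(ee) * 100.0, decimals):.{decimals}f}%"


def format_dr(dr: float, decimals: int = 1) -> str:
    """Render a d.r. as an 'X:1' string ('inf:1' when no minor diastereomer)."""
    if math.isinf(dr):
        return "inf:1"
    return f"{round(dr, decimals):.{decimals}f}:1"
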
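"""Synthetic KR measurement sets, selectivity-factor fitting, and experiment scenarios.

Real selectivity factors are estimated from (conversion, e.e.) pairs measured
by chiral HPLC at several stopping points of a kinetic resolution.  The
generator here emulates exactly that: noise-free e.e. values obey the
closed-form KR relations, and measurement error is additive Gaussian on the
e.e. itself (what the chromatogram integration reports), not on
concentrations.  Values falling outside [0, 1) are clipped and flagged;
fitting excludes clipped points by default since their error is no longer
Gaussian.

The scenario registry collects the package's benchmark experiments — each a
set of model inputs together with the experimentally observed stereochemical
outcome, so predictions and observations can be put side by side.  Observed
values are laboratory measurements, not model outputs: the comparison is
reported as discrepancy ratios, never asserted as equality, because induction
or more complex kinetics in the coupling step shifts the ratios away from the
statistical prediction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from types import MappingProxyType
from typing import Dict, Literal, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import minimize_scalar

from .coupling import (
    dr_statistical,
    hetero_ee_statistical,
    infer_pool_ees,
)
from .errors import DomainError, StereokinError
from .kagan import ee_product_at_conversion, ee_substrate_at_conversion

__all__ = [
    "Observation",
    "MeasurementSet",
    "generate_kr_measurements",
    "FitResult",
    "fit_s",
    "Scenario",
    "scenarios",
    "run_scenario",
]


@dataclass(frozen=True)
class Observation:
    conversion: float
    ee: float
    which: Literal["product", "substrate"] = "product"
    clipped: bool = False


@dataclass(frozen=True)
class MeasurementSet:
    """Synthetic (conversion, e.e.) observations with their generator metadata.

    ``s_true`` is the generator's ground truth, carried for parameter-recovery
    experiments; regeneration with the same seed is bit-identical.
    """

    observations: Tuple[Observation, ...]
    noise_sd: float
    s_true: float
    seed: int

    def __len__(self) -> int:
        return len(self.observations)

    @property
    def n_clipped(self) -> int:
        return sum(o.clipped for o in self.observations)


def _closed_form(s: float, C: float, which: str) -> float:
    if which == "product":
        return ee_product_at_conversion(s, C)
    return ee_substrate_at_conversion(s, C)


def generate_kr_measurements(
    s_true: float,
    conversions: Sequence[float],
    noise_sd: float = 0.0,
    seed: int = 0,
    which: Literal["product", "substrate"] = "product",
) -> MeasurementSet:
    """Draw a synthetic measurement set from the KR model.

    ee_i = closed_form(s_true, C_i) + N(0, noise_sd), clipped to [0, 1) with
    the clip recorded per observation.
    """
    conversions = list(conversions)
    if not conversions:
        raise DomainError("at least one conversion is required")
    if any(not 0.0 < C < 1.0 for C in conversions):
        raise DomainError("conversions must lie strictly in (0, 1)")
    if noise_sd < 0:
        raise DomainError("noise_sd must be nonnegative")
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, noise_sd, size=len(conversions)) if noise_sd > 0 else np.zeros(len(conversions))
    obs = []
    hi = math.nextafter(1.0, 0.0)
    for C, eps in zip(conversions, noise):
        raw = _closed_form(s_true, C, which) + eps
        clipped = not 0.0 <= raw < 1.0
        obs.append(
            Observation(
                conversion=C,
                ee=min(max(raw, 0.0), hi),
                which=which,
                clipped=clipped,
            )
        )
    return MeasurementSet(
        observations=tuple(obs), noise_sd=noise_sd, s_true=s_true, seed=seed
    )


@dataclass(frozen=True)
class FitResult:
    s_hat: float
    se: Optional[float]
    n_used: int
    rss: float


_S_LO, _S_HI = 1.0, 1e6


def fit_s(data: MeasurementSet, include_clipped: bool = False) -> FitResult:
    """Least-squares estimate of the selectivity factor from a measurement set.

    Minimizes sum_i (ee_i - closed_form(s, C_i))^2 over s in [1, 1e6]
    (searched on log s for conditioning).  The standard error comes from the
    Gauss-Newton curvature at the optimum, se^2 = sigma^2 / sum_i (df_i/ds)^2
    with sigma^2 = RSS/(n-1); it is reported only for n >= 3.
    """
    obs = [o for o in data.observations if include_clipped or not o.clipped]
    if not obs:
        raise StereokinError(
            "no usable observations (all clipped; pass include_clipped=True to force)"
        )

    def rss_of(log_s: float) -> float:
        s = math.exp(log_s)
        return sum((o.ee - _closed_form(s, o.conversion, o.which)) ** 2 for o in obs)

    res = minimize_scalar(
        rss_of,
        bounds=(math.log(_S_LO), math.log(_S_HI)),
        method="bounded",
        options={"xatol": 1e-10},
    )
    if not res.success:
        raise StereokinError(f"selectivity fit failed: {res.message}")
    s_hat = math.exp(res.x)
    rss = res.fun
    se = None
    n = len(obs)
    if n >= 3:
        h = max(1e-6 * s_hat, 1e-9)
        grad_sq = 0.0
        for o in obs:
            df = (
                _closed_form(s_hat + h, o.conversion, o.which)
                - _closed_form(max(s_hat - h, 1.0), o.conversion, o.which)
            ) / (s_hat + h - max(s_hat - h, 1.0))
            grad_sq += df * df
        sigma2 = rss / (n - 1)
        se = math.sqrt(sigma2 / grad_sq) if grad_sq > 0 else math.inf
    return FitResult(s_hat=s_hat, se=se, n_used=n, rss=rss)


# ---------------------------------------------------------------------------
# scenario registry


@dataclass(frozen=True)
class Scenario:
    """One benchmark experiment: model inputs plus observed outcomes.

    ``inputs`` parameterize the model (selectivity factor and/or measured pool
    e.e.s as signed fractions / X:1 ratios); ``observed`` holds the laboratory
    measurements of the final product, attached for comparison only.
    """

    name: str
    description: str
    inputs: Mapping[str, float]
    observed: Mapping[str, float] = field(default_factory=dict)
    notes: Mapping[str, str] = field(default_factory=dict)


def _frozen(d: dict) -> Mapping:
    return MappingProxyType(dict(d))


_SCENARIOS: Dict[str, Scenario] = {
    s.name: s
    for s in [
        Scenario(
            name="bode_amine",
            description=(
                "Acylative KR of a racemic tetrahydroisoquinoline with a "
                "chloroacetylated hydroxamic-acid reagent (s = 28), then "
                "nucleophilic-substitution coupling of the chloroacetamide "
                "with the resolved amine."
            ),
            inputs=_frozen({"s": 28.0, "conversion": 0.5}),
            observed=_frozen({}),
            notes=_frozen(
                {
                    "s": "measured selectivity factor of the acylative KR",
                    "conversion": "idealized perfect 50% conversion",
                }
            ),
        ),
        Scenario(
            name="lipase_amine",
            description=(
                "Biocatalytic (lipase) KR of a racemic primary amine with an "
                "ethyl chloroacetate linker: chloroacetamide at 96% e.e. and "
                "recovered amine at 99% e.e., coupled by nucleophilic "
                "substitution."
            ),
            inputs=_frozen({"ee_intermediate": 0.96, "ee_substrate": 0.99}),
            observed=_frozen({"ee_hetero": 0.9999, "dr": 33.0}),
            notes=_frozen(
                {
                    "ee_intermediate": "chiral-HPLC e.e. of the chloroacetamide pool",
                    "ee_substrate": "chiral-HPLC e.e. of the recovered amine pool",
                    "ee_hetero": "observed e.e. of the coupled heterochiral product",
                    "dr": "observed heterochiral:homochiral ratio, X:1",
                }
            ),
        ),
        Scenario(
            name="glutaric_alcohol",
            description=(
                "Organocatalytic acylative KR of a racemic secondary alcohol "
                "with a 2,2-dimethylglutaric-anhydride linker, then "
                "esterification of the free acid with the resolved alcohol."
            ),
            inputs=_frozen({}),
            observed=_frozen({"ee_hetero": 0.98, "dr": 5.0}),
            notes=_frozen(
                {
                    "ee_hetero": "observed e.e. of the heterochiral diester",
                    "dr": "observed heterochiral:homochiral ratio, X:1",
                }
            ),
        ),
        Scenario(
            name="chiral_linker_matched",
            description=(
                "Diastereoconvergent coupling through an enantiopure chiral "
                "linker, matched chirality combination."
            ),
            inputs=_frozen({}),
            observed=_frozen({"dr": 3.2, "de_hetero": 0.93}),
            notes=_frozen(
                {
                    "dr": "observed heterochiral:homochiral ratio, X:1",
                    "de_hetero": (
                        "observed d.e. of the heterochiral adduct, taken over "
                        "its major:minor diastereomer pair (assumption: the "
                        "chiral linker resolves exactly that pair)"
                    ),
                }
            ),
        ),
        Scenario(
            name="chiral_linker_mismatched",
            description=(
                "Diastereoconvergent coupling through an enantiopure chiral "
                "linker, mismatched chirality combination."
            ),
            inputs=_frozen({}),
            observed=_frozen({"dr": 1.4, "de_hetero": 0.66}),
            notes=_frozen(
                {
                    "dr": "observed heterochiral:homochiral ratio, X:1",
                    "de_hetero": "observed d.e. of the heterochiral adduct (as above)",
                }
            ),
        ),
    ]
}


def scenarios() -> Mapping[str, Scenario]:
    """The immutable registry of benchmark scenarios, keyed by name."""
    return MappingProxyType(_SCENARIOS)


def get_scenario(name: str) -> Scenario:
    try:
        return _SCENARIOS[name]
    except KeyError:
        raise KeyError(
            f"unknown scenario {name!r}; valid names: {sorted(_SCENARIOS)}"
        ) from None


def run_scenario(name: str) -> dict:
    """Run one scenario end-to-end and report predictions beside observations.

    The report always contains the scenario inputs and observed values; model
    predictions are added where the inputs support them (a selectivity factor
    enables the sequential KR+coupling prediction; a pair of pool e.e.s
    enables the statistical-coupling prediction; a (d.r., d.e.) observation
    enables the no-induction feasibility diagnostic).  Observed/predicted
    discrepancies are reported as ratios.
    """
    sc = get_scenario(name)
    report: dict = {
        "scenario": sc.name,
        "description": sc.description,
        "inputs": dict(sc.inputs),
        "observed": dict(sc.observed),
        "predicted": {},
        "diagnostics": {},
    }
    pred = report["predicted"]

    a = b = None
    if "s" in sc.inputs:
        C = sc.inputs.get("conversion", 0.5)
        a = ee_product_at_conversion(sc.inputs["s"], C)
        b = ee_substrate_at_conversion(sc.inputs["s"], C)
        pred["ee_intermediate"] = a
        pred["ee_substrate"] = b
    if "ee_intermediate" in sc.inputs:
        a, b = sc.inputs["ee_intermediate"], sc.inputs["ee_substrate"]
    if a is not None:
        pred["ee_hetero"] = hetero_ee_statistical(a, b)
        pred["dr"] = dr_statistical(a, b)

    if "dr" in sc.observed and "de_hetero" in sc.observed:
        inf = infer_pool_ees(sc.observed["dr"], sc.observed["de_hetero"])
        report["diagnostics"]["statistical_coupling_feasible"] = inf.feasible
        report["diagnostics"]["discriminant"] = inf.discriminant
        if inf.feasible:
            report["diagnostics"]["inferred_pool_ees"] = list(inf.pool_ees)
        else:
            report["diagnostics"]["reason"] = inf.reason

    ratios = {}
    for key, obs_val in sc.observed.items():
        if key in pred and pred[key] not in (0.0, math.inf):
            ratios[key] = obs_val / pred[key]
    if ratios:
        report["diagnostics"]["observed_over_predicted"] = ratios
    return report
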
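# Methods

## Model and assumptions

The package models a two-stage enantioconvergent process: a kinetic
resolution (KR) of a racemic substrate by a linker reagent, followed by
coupling of the linker-bearing intermediate with the resolved substrate. The
working assumptions, which the closed-form layer takes as exact, are

1. simple second-order, irreversible mass-action kinetics for every step
   (first order in each reactant; no reversibility, no catalyst species,
   no temperature dependence);
2. the coupling step is much slower than the KR (k1 ≫ k2), so the stages
   are effectively sequential;
3. no asymmetric induction in the coupling step (k2-hetero = k2-homo), so
   the coupling is statistical.

Under (1) alone the KR obeys the Kagan relations (the ratio of the two
enantiomers' rate laws eliminates both time and the co-reactant, so the
relations hold for *any* linker concentration profile). Under (3) alone the
coupling is time-independent counting: equal rate constants consume each pool
proportionally, leaving pool compositions invariant, so the stereoisomer
distribution is the outer product of the enantiomer fractions. The full
9-species network drops (2) and (3) and is the fallback whenever either is in
doubt.

Orientation is fixed package-wide: positive e.e. = S-enriched, the fast KR
enantiomer is S, hence s ≥ 1. Inputs with s < 1 are rejected rather than
silently mirrored; `EnantiomerPool.mirrored()` / `NetworkSpec.mirrored()`
perform the relabelling explicitly, and mirror-symmetry property tests guard
the convention.

## Parameters

| parameter | meaning | default | units |
|---|---|---|---|
| `s` | selectivity factor k1(S)/k1(R) of the KR | — | dimensionless |
| `C` | fraction of the racemic substrate consumed in the KR stage | 0.5 where a single number is needed | fraction |
| `k1_R` | slow-enantiomer KR rate constant | 1 | conc⁻¹ time⁻¹ (normalized) |
| `separation_factor` | k1_R / k2_homo | 1e3 | dimensionless |
| `induction_ratio` | k2_hetero / k2_homo | 1 | dimensionless |
| `A0`, `L0` | initial substrate and linker | 2 and A0/2 | normalized amount |

The timescale separation is stated in the model only as an inequality
(k1 ≫ k2); 1e3 realizes it while keeping the stiff integration cheap, and the
sequential-equivalence tests show 1e3 already reproduces the closed forms to
1e−4 in e.e. The stoichiometry L0 = A0/2 makes the KR stop at exactly 50%
conversion (linker exhaustion) and the coupling consume everything that
remains; every reported output is a dimensionless ratio, so the normalization
carries no physics.

## Numerical choices

* **KR closed forms.** The defining relation is solved in log-difference form
  by bracketed Brent root finding on ee ∈ [0, min(1, 1/C−1) − 1e−12], xtol
  1e−10; the objective is strictly monotone, so the root is unique. For
  C > 0.5 the product e.e. saturates at 1/C − 1 exponentially fast in s;
  once the bracket endpoint's objective sign shows the root is within 1e−12
  of the bound, the bound is returned. In that saturation regime forward
  values are correct but the map is flat below float resolution, so the
  inverse (`s_from_observation`) is accurate only away from C(1+ee) → 1 —
  the inverse's error messages name the violated bound.
* **Feasibility diagnostic.** `infer_pool_ees` reduces the observed
  (d.r., d.e.) to the root pair of x² − (a+b)x + ab. Exact-diagonal
  observations (a = b) have discriminant 0, and rounding can push the
  computed value a few ulp negative; discriminants within ~64 eps of the
  natural scale are therefore clamped to zero. Near the diagonal the root
  *split* is limited to ~√eps by cancellation (the root *sum* stays good to
  1e−9); genuinely infeasible observations sit at discriminants of order
  −0.1, three orders of magnitude beyond any rounding effect. The returned
  pair is unordered: d.r./d.e. summaries cannot distinguish which pool is
  which. With a chiral linker the "d.e." is taken over the heterochiral
  adduct's major:minor diastereomer pair — an assumption, flagged in the
  scenario notes.
* **Deterministic network.** Radau with rtol 1e−10 / atol 1e−12 (the
  separated regime spans ≥ 3 decades of rates, so the system is stiff by
  construction). Run-to-completion integrates geometrically growing windows
  until all reaction rates fall below 1e−10 × the initial fastest rate, with
  a window cap that warns instead of spinning. Amounts below −1e−10 are a
  solver failure; smaller negative excursions are clipped only in derived
  pool views, never in the stored trajectory.
* **Sampling "50% conversion" inside a run.** Two samplers exist:
  `state_at_substrate_amount` locates A_S + A_R = A0/2 on the dense output
  (simple, but biased by O(1/separation_factor) because the coupling also
  consumes substrate), and `state_at_kr_conversion` locates
  I_S + I_R + ΣP = C·A0, which counts exactly the substrate the KR consumed
  and stays exact when the stages overlap. The tight (1e−4) comparisons use
  the latter; at separation 1e3 the two agree to ~1e−3.
* **Stochastic oracle.** Direct-method Gillespie on integer counts
  (default 1e5 substrate molecules), volume chosen so concentrations match
  the deterministic system. The seed is a required, logged parameter; one
  `numpy` Generator per run, no global state. Same seed ⇒ bit-identical
  trajectory. Conservation is exact in counts.
* **Selectivity fit.** Least squares on the closed form, searched on log s
  over [1, 1e6] (bounded scalar minimization); the standard error comes from
  the Gauss–Newton curvature, se² = σ̂²/Σ(∂f/∂s)² with σ̂² = RSS/(n−1),
  reported for n ≥ 3.

## Synthetic data: what it emulates, what it does not

`generate_kr_measurements` emulates stopping a KR at several conversions and
measuring e.e. by chiral HPLC: noise is additive Gaussian *on the e.e.*
(HPLC reports the excess directly), absolute scale, default studies use
sd = 0.01 (1 e.e. point, routine chiral-HPLC precision) over nine conversions
spanning 0.1–0.9. Draws falling outside [0, 1) are clipped and flagged, and
fits exclude clipped points by default (their error is no longer Gaussian).
The generator inherits the model's own assumptions — exact second-order
kinetics, exactly known conversions, independent errors. Passing
parameter-recovery tests therefore shows the estimator is correct *under the
model*; it does not validate the model against real kinetics (conversion
measurement error, reversibility, catalyst deactivation are all absent).

The scenario registry stores measured pool e.e.s and observed product
outcomes for five benchmark experiments. Observed values are laboratory
measurements attached for comparison; reports put them beside predictions as
discrepancy ratios and never assert equality — stereoisomer ratios shift
whenever the coupling deviates from the statistical assumptions, which is
precisely what the feasibility diagnostic detects in the two chiral-linker
scenarios.

## Problem sizes used in tests and drivers

Closed-form checks are instantaneous. The ODE-vs-closed-form grid uses
s ∈ {2, 8, 28, 100} × C ∈ {0.1…0.9}; the stochastic-vs-ODE comparison uses
20 replicates of 1e5 molecules (≈15 s); fit recovery uses 200 seeds
(≈1 s). These sizes put every Monte-Carlo standard error well below the
asserted tolerances while keeping the full suite under a minute of compute.

## Known limitations

* No reversibility, catalyst species, or temperature dependence; no
  transition-state or electronic-structure modelling of *why* a coupling is
  hetero-selective.
* Chiral-linker (diastereoconvergent) chemistry is summarized only at the
  hetero:homo / d.e. level; the four diastereomer pools of the adduct are not
  modelled individually, and no attempt is made to predict matched vs
  mismatched selectivity factors.
* Species are abstract configuration-labelled pools — no molecular structure
  (SMILES/InChI), no chromatogram simulation.
* The inverse operations (`s_from_observation`, `infer_pool_ees`) are exact
  under the model; with real data they inherit all of the model's assumptions
  and should be read as diagnostics, not measurements.
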
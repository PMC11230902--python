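import numpy as np
import pytest

from stereokin import (
    DomainError,
    NetworkSpec,
    dr_statistical,
    ee_product_at_conversion,
    hetero_ee_statistical,
    kr_stage_ees,
    simulate_deterministic,
    simulate_stochastic,
    sweep_selectivity,
)


@pytest.fixture(scope="module")
def benchmark_run():
    """Full separated-regime run at s = 8, shared across assertions."""
    spec = NetworkSpec.from_selectivity(8, separation_factor=1e3)
    return spec, simulate_deterministic(spec)


class TestDeterministic:
    def test_final_ee_rounds_to_ninety_percent(self, benchmark_run):
        _, traj = benchmark_run
        assert round(100 * traj.product_distribution().hetero_ee) == 90

    def test_conservation_at_every_step(self, benchmark_run):
        spec, traj = benchmark_run
        traj.assert_conserved(spec.A0, spec.linker0, rtol=1e-8)

    def test_no_selectivity_means_no_stereochemical_information(self):
        traj = simulate_deterministic(NetworkSpec.from_selectivity(1.0))
        dist = traj.product_distribution()
        assert dist.hetero_ee == pytest.approx(0.0, abs=1e-9)
        assert dist.dr == pytest.approx(1.0, abs=1e-8)

    def test_intermediate_ee_at_half_conversion_matches_closed_form(self):
        spec = NetworkSpec.from_selectivity(28, separation_factor=1e3)
        traj = simulate_deterministic(spec)
        y = traj.state_at_kr_conversion(0.5, spec.A0)
        ee_I = (y[3] - y[4]) / (y[3] + y[4])
        assert ee_I == pytest.approx(ee_product_at_conversion(28, 0.5), abs=1e-4)
        # raw substrate depletion is the same point up to O(1/separation)
        y_raw = traj.state_at_substrate_amount(spec.A0 / 2.0)
        ee_raw = (y_raw[3] - y_raw[4]) / (y_raw[3] + y_raw[4])
        assert ee_raw == pytest.approx(ee_I, abs=1e-3)

    @pytest.mark.parametrize("s", [2, 8, 28, 100])
    def test_sequential_limit_equivalence(self, s):
        """Separated-regime ODE == closed-form KR-then-coupling pipeline."""
        e = ee_product_at_conversion(s, 0.5) if s > 1 else 0.0
        traj = simulate_deterministic(NetworkSpec.from_selectivity(s, 1e3))
        dist = traj.product_distribution()
        assert dist.hetero_ee == pytest.approx(hetero_ee_statistical(e, e), abs=1e-4)

    def test_mirror_symmetry_of_the_network(self):
        spec = NetworkSpec.from_selectivity(8, separation_factor=50)
        mirrored = spec.mirrored()
        y = simulate_deterministic(spec).final_state
        ym = simulate_deterministic(mirrored).final_state
        # permutation S<->R: A, I, hetero and homo slots each swap
        perm = [1, 0, 2, 4, 3, 6, 5, 8, 7]
        assert np.allclose(y, ym[perm], atol=1e-8)

    def test_breaking_the_separation_assumption_moves_the_outputs(self):
        """With k1 ~ k2 the sequential prediction no longer holds."""
        e = ee_product_at_conversion(8, 0.5)
        sequential_ee = hetero_ee_statistical(e, e)
        traj = simulate_deterministic(NetworkSpec.from_selectivity(8, separation_factor=0.1))
        assert abs(traj.product_distribution().hetero_ee - sequential_ee) > 0.01

    def test_induction_in_the_coupling_step_moves_the_dr(self):
        e = ee_product_at_conversion(8, 0.5)
        statistical_dr = dr_statistical(e, e)
        traj = simulate_deterministic(
            NetworkSpec.from_selectivity(8, separation_factor=1e3, induction_ratio=5.0)
        )
        assert abs(traj.product_distribution().dr - statistical_dr) > 0.1


class TestStageOneOracle:
    def test_matches_closed_forms_tightly(self):
        df = kr_stage_ees(8, [0.2, 0.5, 0.8])
        for _, row in df.iterrows():
            assert row.ee_product == pytest.approx(
                ee_product_at_conversion(8, row.conversion), abs=1e-8
            )
            assert row.ee_substrate == pytest.approx(
                row.ee_product * row.conversion / (1 - row.conversion), abs=1e-8
            )


class TestStochastic:
    def test_same_seed_is_bit_identical(self):
        spec = NetworkSpec.from_selectivity(8)
        t1 = simulate_stochastic(spec, n_molecules=2000, seed=42)
        t2 = simulate_stochastic(spec, n_molecules=2000, seed=42)
        assert np.array_equal(t1.times, t2.times)
        assert np.array_equal(t1.states, t2.states)

    def test_different_seed_differs(self):
        spec = NetworkSpec.from_selectivity(8)
        t1 = simulate_stochastic(spec, n_molecules=2000, seed=1)
        t2 = simulate_stochastic(spec, n_molecules=2000, seed=2)
        assert not np.array_equal(t1.states, t2.states)

    def test_enantiopure_start_cannot_make_r_products(self):
        spec = NetworkSpec.from_selectivity(8, substrate_ee0=1.0)
        traj = simulate_stochastic(spec, n_molecules=1000, seed=3)
        assert traj.species("P_RS")[-1] == 0
        assert traj.species("P_RR")[-1] == 0

    def test_exact_integer_conservation(self):
        spec = NetworkSpec.from_selectivity(8)
        traj = simulate_stochastic(spec, n_molecules=1000, seed=5)
        y = traj.states
        substrate_units = y[:, 0] + y[:, 1] + y[:, 3] + y[:, 4] + 2 * y[:, 5:9].sum(axis=1)
        linker_units = y[:, 2] + y[:, 3] + y[:, 4] + y[:, 5:9].sum(axis=1)
        assert np.all(substrate_units == 1000)
        assert np.all(linker_units == 500)

    def test_converges_to_deterministic_ee(self):
        spec = NetworkSpec.from_selectivity(8)
        det = simulate_deterministic(spec).product_distribution().hetero_ee
        ees = [
            simulate_stochastic(spec, n_molecules=20_000, seed=seed)
            .product_distribution()
            .hetero_ee
            for seed in range(6)
        ]
        se = np.std(ees, ddof=1) / np.sqrt(len(ees))
        assert abs(np.mean(ees) - det) < 3 * se + 1e-4

    def test_invalid_inputs(self):
        spec = NetworkSpec.from_selectivity(8)
        with pytest.raises(DomainError):
            simulate_stochastic(spec, n_molecules=10, seed=0)
        with pytest.raises(DomainError):
            simulate_stochastic(spec, n_molecules=1000, seed="abc")


class TestSweep:
    def test_benchmark_rows(self):
        df = sweep_selectivity([1, 8, 28])
        r1, r8, r28 = df.iloc[0], df.iloc[1], df.iloc[2]
        assert (r1.ee_intermediate_50, r1.ee_final, r1.dr_final) == (0.0, 0.0, 1.0)
        assert round(100 * r8.ee_intermediate_50) == 62
        assert round(100 * r8.ee_final) == 90
        assert r8.dr_final == pytest.approx(2.25, abs=0.05)
        assert round(100 * r28.ee_intermediate_50) == 83

    def test_strictly_monotone_in_s(self):
        df = sweep_selectivity(np.geomspace(1.01, 100, 40))
        for col in ("ee_intermediate_50", "ee_final", "dr_final"):
            assert np.all(np.diff(df[col].to_numpy()) > 0), col

    def test_bad_inputs(self):
        with pytest.raises(DomainError, match="0.5"):
            sweep_selectivity([8, 0.5])
        with pytest.raises(DomainError):
            sweep_selectivity([])
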
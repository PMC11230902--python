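import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from stereokin import (
    CouplingParameters,
    DomainError,
    EnantiomerPool,
    UndefinedQuantityError,
    dr_statistical,
    hetero_ee_statistical,
    horeau_homocoupling,
    infer_pool_ees,
    statistical_coupling,
)


def pairing_enumeration_oracle(pool1, pool2):
    """Independent oracle: explicitly enumerate the four configuration pairings.

    With equal rate constants the pools' compositions never change, so the
    dimer distribution is the outer product of the enantiomer fractions
    applied to the limiting amount.
    """
    n = min(pool1.total, pool2.total)
    counts = {}
    for (c1, f1), (c2, f2) in itertools.product(
        [("S", pool1.fraction_S), ("R", pool1.fraction_R)],
        [("S", pool2.fraction_S), ("R", pool2.fraction_R)],
    ):
        counts[c1 + c2] = n * f1 * f2
    return counts


class TestStatisticalCoupling:
    def test_matches_enumeration_oracle(self):
        pool1 = EnantiomerPool.from_ee(0.6236, 1.0)
        pool2 = EnantiomerPool.from_ee(-0.6236, 1.3)
        dist = statistical_coupling(pool1, pool2)
        oracle = pairing_enumeration_oracle(pool1, pool2)
        assert dist.hetero_SR == pytest.approx(oracle["SR"], rel=1e-12)
        assert dist.hetero_RS == pytest.approx(oracle["RS"], rel=1e-12)
        assert dist.homo_SS == pytest.approx(oracle["SS"], rel=1e-12)
        assert dist.homo_RR == pytest.approx(oracle["RR"], rel=1e-12)

    def test_amplification_of_the_low_selectivity_benchmark(self):
        """Both pools at the s=8, 50%-conversion e.e.: product rounds to 90% e.e."""
        e = 0.6233046400556052  # root of the KR relation at s=8, C=0.5
        assert round(100 * hetero_ee_statistical(e, e)) == 90

    def test_lipase_pools_prediction(self):
        """96% + 99% e.e. pools couple to 99.98% e.e. at d.r. 39.3:1."""
        dist = statistical_coupling(
            EnantiomerPool.from_ee(0.96, 1.0), EnantiomerPool.from_ee(-0.99, 1.0)
        )
        assert dist.hetero_ee == pytest.approx(0.99979, abs=5e-6)
        assert dist.dr == pytest.approx(39.3, abs=0.05)
        assert hetero_ee_statistical(0.96, 0.99) == pytest.approx(dist.hetero_ee)
        assert dr_statistical(0.96, 0.99) == pytest.approx(dist.dr)

    def test_racemic_pools_give_statistical_mixture(self):
        dist = statistical_coupling(
            EnantiomerPool.from_ee(0.0, 1.0), EnantiomerPool.from_ee(0.0, 1.0)
        )
        assert dist.hetero_ee == 0.0
        assert dist.dr == pytest.approx(1.0)

    def test_empty_pool_raises(self):
        with pytest.raises(UndefinedQuantityError):
            statistical_coupling(EnantiomerPool(0, 0), EnantiomerPool(1, 0))

    @given(
        a=st.floats(0.0, 1.0),
        b=st.floats(0.0, 1.0),
        n1=st.floats(0.1, 5.0),
        n2=st.floats(0.1, 5.0),
    )
    def test_conserves_stereounits(self, a, b, n1, n2):
        """S- and R-units drawn from the two pools are conserved exactly."""
        pool1 = EnantiomerPool.from_ee(a, n1)
        pool2 = EnantiomerPool.from_ee(-b, n2)
        dist = statistical_coupling(pool1, pool2)
        n = min(n1, n2)
        s_in = n * (pool1.fraction_S + pool2.fraction_S)
        r_in = n * (pool1.fraction_R + pool2.fraction_R)
        s_out = dist.hetero_SR + dist.hetero_RS + 2 * dist.homo_SS
        r_out = dist.hetero_SR + dist.hetero_RS + 2 * dist.homo_RR
        assert s_out == pytest.approx(s_in, rel=1e-12, abs=1e-12)
        assert r_out == pytest.approx(r_in, rel=1e-12, abs=1e-12)


class TestHoreauHomocoupling:
    @pytest.mark.parametrize(
        "a, dimer_ee, meso",
        [
            (0.62, 0.8957, 0.3078),
            (1.0, 1.0, 0.0),
            (0.0, 0.0, 0.5),
        ],
    )
    def test_symmetric_linker_amplification(self, a, dimer_ee, meso):
        dist = horeau_homocoupling(EnantiomerPool.from_ee(a, 1.0))
        if a < 1.0:
            assert dist.homo_ee == pytest.approx(dimer_ee, abs=1e-4)
        else:
            assert dist.homo_ee == 1.0
        assert dist.hetero_total / dist.total == pytest.approx(meso, abs=1e-4)

    @given(e=st.floats(0.0, 1.0))
    def test_amplification_identity(self, e):
        """2e/(1+e^2) >= e, equality only at e in {0, 1}."""
        amplified = hetero_ee_statistical(e, e)
        assert amplified >= e - 1e-15
        if 1e-6 < e < 1 - 1e-6:
            assert amplified > e

    @given(a=st.floats(-0.999, 0.999))
    def test_agrees_with_statistical_coupling_of_mirrored_copy(self, a):
        """Self-coupling == cross-coupling with the mirror pool, roles swapped.

        Coupling a pool with its own mirror image makes the opposite-
        configuration pairing the 'hetero' slot, which for a symmetric linker
        is the meso dimer; the homochiral amounts coincide directly.
        """
        pool = EnantiomerPool.from_ee(a, 1.0)
        self_dist = horeau_homocoupling(pool)
        cross = statistical_coupling(pool, pool.mirrored())
        # per-dimer fractions: self-coupling makes total/2 dimers, cross total
        assert self_dist.homo_SS / self_dist.total == pytest.approx(
            cross.hetero_SR / cross.total, abs=1e-12
        )
        assert self_dist.homo_RR / self_dist.total == pytest.approx(
            cross.hetero_RS / cross.total, abs=1e-12
        )
        assert self_dist.hetero_total / self_dist.total == pytest.approx(
            cross.homo_total / cross.total, abs=1e-12
        )


class TestInferPoolEes:
    def test_recovers_lipase_pools(self):
        inf = infer_pool_ees(39.3, 0.9998)
        assert inf.feasible
        assert sorted(inf.pool_ees) == pytest.approx([0.96, 0.99], abs=1e-3)

    @pytest.mark.parametrize("dr, de", [(3.2, 0.93), (1.4, 0.66)])
    def test_chiral_linker_observations_are_infeasible(self, dr, de):
        """The matched/mismatched chiral-linker outcomes cannot be statistical."""
        inf = infer_pool_ees(dr, de)
        assert not inf.feasible
        assert inf.discriminant < 0
        assert "induction" in inf.reason

    def test_trivial_statistical_mixture(self):
        inf = infer_pool_ees(1.0, 0.0)
        assert inf.feasible
        assert inf.pool_ees == pytest.approx((0.0, 0.0), abs=1e-12)

    def test_dr_below_one_rejected(self):
        with pytest.raises(DomainError):
            infer_pool_ees(0.8, 0.5)

    def test_round_trip_over_grid(self):
        """(d.r., d.e.) of any statistical coupling inverts back to the pools."""
        grid = np.linspace(0.0, 0.99, 12)
        for a in grid:
            for b in grid:
                inf = infer_pool_ees(dr_statistical(a, b), hetero_ee_statistical(a, b))
                assert inf.feasible
                # near a = b the quadratic's discriminant cancels
                # catastrophically, so the split of the (stable) root sum is
                # only good to ~sqrt(eps)
                tol = 1e-9 if abs(a - b) > 0.05 else 1e-7
                assert sorted(inf.pool_ees) == pytest.approx(sorted((a, b)), abs=tol)
                assert sum(inf.pool_ees) == pytest.approx(a + b, abs=1e-9)


def test_coupling_parameters_induction_ratio():
    p = CouplingParameters(k2_hetero=5e-3, k2_homo=1e-3)
    assert p.induction_ratio == pytest.approx(5.0)
    with pytest.raises(DomainError):
        CouplingParameters(k2_hetero=0.0)
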
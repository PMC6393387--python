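"""Variance propagation, mediate correlations and the heritability path."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mcmpower import (
    MCMParams,
    MediateCorrelations,
    mediate_correlations,
    params_from_correlations,
    scale_to_heritability,
    simulate_cohort,
    trait_correlations,
    variance_chain,
)

ANCHOR = MCMParams(0.25, 0.5744, 0.7183, 0.4564)


class TestVarianceChain:
    def test_genotype_variance_is_hardy_weinberg(self):
        vc = variance_chain(MCMParams(0.25, 1.0, -2.0, 0.3))
        assert vc.var_x1 == pytest.approx(0.375)

    def test_forward_propagation_at_anchor(self):
        vc = variance_chain(ANCHOR)
        assert vc.var_x2 == pytest.approx(1.12373, abs=1e-5)
        assert vc.var_x3 == pytest.approx(1.57979, abs=1e-5)
        assert vc.var_y == pytest.approx(1.32907, abs=1e-5)

    def test_null_chain_reduces_to_error_variances(self):
        vc = variance_chain(MCMParams(0.25, 0.0, 0.0, 0.0))
        assert (vc.var_x2, vc.var_x3, vc.var_y) == (1.0, 1.0, 1.0)

    @pytest.mark.parametrize("bad", [{"maf": 0.0}, {"maf": 0.6}, {"var_e3": 0.0}])
    def test_invalid_params_rejected(self, bad):
        kwargs = dict(maf=0.25, beta1=0.5, beta2=0.5, beta3=0.5)
        kwargs.update(bad)
        with pytest.raises(ValueError):
            MCMParams(**kwargs)


class TestMediateCorrelations:
    def test_anchor_reproduces_one_percent_heritability(self):
        mc = mediate_correlations(ANCHOR)
        assert mc.r1sq == pytest.approx(0.11010, abs=1e-5)
        assert mc.r2sq == pytest.approx(0.36701, abs=1e-5)
        assert mc.r3sq == pytest.approx(0.24760, abs=1e-5)
        assert mc.h2 == pytest.approx(0.0100, abs=1e-4)

    def test_broken_chain_kills_heritability(self):
        mc = mediate_correlations(MCMParams(0.25, 0.5744, 0.0, 0.4564))
        assert mc.r2sq == 0.0
        assert mc.h2 == 0.0

    def test_h2_is_product_and_lower_bound(self):
        mc = mediate_correlations(ANCHOR)
        assert mc.h2 == pytest.approx(mc.r1sq * mc.r2sq * mc.r3sq, rel=1e-12)
        assert mc.h2 <= min(mc.r1sq, mc.r2sq, mc.r3sq)

    def test_h2_matches_simulated_genotype_trait_correlation(self):
        # simulator as independent oracle at n = 1e6
        ds = simulate_cohort(ANCHOR, 1_000_000, seed=7)
        r = np.corrcoef(ds.x1, ds.y)[0, 1]
        mc = mediate_correlations(ANCHOR)
        # delta-method MC standard error of r^2
        se = 2.0 * abs(r) * (1.0 - r * r) / math.sqrt(len(ds.y))
        assert abs(r * r - mc.h2) < 3.0 * se

    def test_correlation_factorizes_along_the_chain(self):
        # closed form: cov(X1, Y) = b1 b2 b3 var(X1), so corr = r1 r2 r3
        params = MCMParams(0.3, 0.8, -0.6, 1.2, var_e2=0.5, var_e3=2.0, var_e4=1.5)
        vc = variance_chain(params)
        corr = (params.beta1 * params.beta2 * params.beta3 * vc.var_x1
                / math.sqrt(vc.var_x1 * vc.var_y))
        mc = mediate_correlations(params)
        signed = math.copysign(
            math.sqrt(mc.r1sq * mc.r2sq * mc.r3sq),
            params.beta1 * params.beta2 * params.beta3,
        )
        assert abs(corr - signed) < 1e-12


class TestTraitCorrelations:
    def test_anchor_levels(self):
        lc = trait_correlations(mediate_correlations(ANCHOR))
        assert lc.snp == pytest.approx(0.01000, abs=1e-4)
        assert lc.rna == pytest.approx(0.09087, abs=1e-4)
        assert lc.prt == pytest.approx(0.24760, abs=1e-4)

    def test_ordering_is_strict_inside_unit_cube(self):
        lc = trait_correlations(MediateCorrelations(0.1, 0.4, 0.3))
        assert lc.prt > lc.rna > lc.snp

    def test_degenerate_unit_correlations_rejected(self):
        with pytest.raises(ValueError):
            MediateCorrelations(1.0, 1.0, 1.0)


class TestInverse:
    def test_recovers_anchor_betas(self):
        target = mediate_correlations(ANCHOR)
        params = params_from_correlations(target, maf=0.25)
        assert params.betas == pytest.approx(ANCHOR.betas, abs=1e-8)

    def test_all_zero_targets_give_zero_slopes(self):
        params = params_from_correlations(MediateCorrelations(0.0, 0.0, 0.0))
        assert params.betas == (0.0, 0.0, 0.0)

    def test_rejects_unit_correlation(self):
        with pytest.raises(ValueError):
            MediateCorrelations(0.5, 1.0, 0.5)

    @given(
        maf=st.floats(0.01, 0.5),
        b1=st.floats(-2.0, 2.0),
        b2=st.floats(-2.0, 2.0),
        b3=st.floats(-2.0, 2.0),
        ve=st.tuples(*[st.floats(0.25, 4.0)] * 3),
    )
    def test_round_trip_recovers_absolute_slopes(self, maf, b1, b2, b3, ve):
        params = MCMParams(maf, b1, b2, b3, *ve)
        target = mediate_correlations(params)
        back = params_from_correlations(target, maf=maf, error_variances=ve)
        expected = tuple(abs(b) for b in (b1, b2, b3))
        assert back.betas == pytest.approx(expected, abs=1e-8)
        # forward map of the inverse reproduces the target
        mc2 = mediate_correlations(back)
        for a, b in zip((mc2.r1sq, mc2.r2sq, mc2.r3sq),
                        (target.r1sq, target.r2sq, target.r3sq)):
            assert a == pytest.approx(b, rel=1e-10, abs=1e-12)


class TestHeritabilityPath:
    def test_tenfold_reduction_scales_by_cube_root(self, anchor_mc):
        scaled = scale_to_heritability(anchor_mc, 0.001)
        assert scaled.r1sq == pytest.approx(0.05111, abs=2e-5)
        assert scaled.r2sq == pytest.approx(0.17035, abs=5e-5)
        assert scaled.r3sq == pytest.approx(0.11493, abs=5e-5)
        assert scaled.h2 == pytest.approx(0.001, rel=1e-10)

    def test_identity_and_zero_endpoints(self, anchor_mc):
        same = scale_to_heritability(anchor_mc, anchor_mc.h2)
        assert same.r1sq == pytest.approx(anchor_mc.r1sq, rel=1e-12)
        zero = scale_to_heritability(anchor_mc, 0.0)
        assert (zero.r1sq, zero.r2sq, zero.r3sq, zero.h2) == (0, 0, 0, 0)

    def test_monotone_componentwise(self, anchor_mc):
        grid = [scale_to_heritability(anchor_mc, h) for h in (0.001, 0.005, 0.02)]
        for lo, hi in zip(grid, grid[1:]):
            assert hi.r1sq > lo.r1sq
            assert hi.r2sq > lo.r2sq
            assert hi.r3sq > lo.r3sq

    def test_overflowing_scale_rejected(self, anchor_mc):
        # pushing the largest link past 1 must raise, not clip
        with pytest.raises(ValueError):
            scale_to_heritability(anchor_mc, 0.9)
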
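import itertools

import numpy as np
import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st

import swdopt as sw
from swdopt.design import Design

from oracles import individual_level_variance


def small_design_strategy(max_seq=3, max_per=4, max_m=3):
    @st.composite
    def build(draw):
        n_seq = draw(st.integers(2, max_seq))
        n_per = n_seq + 1 if n_seq + 1 <= max_per else max_per
        base = sw.make_complete_stepped_wedge(
            n_seq,
            [draw(st.integers(1, 2)) for _ in range(n_seq)],
            draw(st.integers(1, max_m)),
        )
        mask = np.array(
            [[draw(st.booleans()) for _ in range(n_per)] for _ in range(n_seq)]
        )
        if not mask.any():
            mask[0, 0] = True
        return base.with_observed(mask)

    return build()


corr_strategy = st.builds(
    sw.CorrelationSpec,
    icc=st.sampled_from([0.0, 0.01, 0.05, 0.2, 0.5]),
    cac=st.sampled_from([0.0, 0.3, 0.8, 0.95, 1.0]),
    structure=st.sampled_from(sw.variance.STRUCTURES),
)


class TestCorrelationSpec:
    @pytest.mark.parametrize("kwargs", [
        {"icc": -0.1}, {"icc": 1.0}, {"icc": 0.1, "cac": 1.5},
        {"icc": 0.1, "cac": -0.1}, {"icc": 0.1, "structure": "ar1"},
    ])
    def test_validation(self, kwargs):
        with pytest.raises(ValueError):
            sw.CorrelationSpec(**kwargs)


class TestPowerSpec:
    @pytest.mark.parametrize("kwargs", [
        {"effect_size": -1}, {"effect_size": 0.2, "alpha": 0},
        {"effect_size": 0.2, "min_power": 1.0},
    ])
    def test_validation(self, kwargs):
        with pytest.raises(ValueError):
            sw.PowerSpec(**kwargs)


class TestClusterCovariance:
    def test_decay_with_gap_widens_lag(self):
        # observed periods 1 and 3 -> lag 2 -> off-diagonal rho * r^2
        d = Design([[0, 0, 1]], [[1, 0, 1]], [1], 1)
        corr = sw.CorrelationSpec(icc=0.5, cac=0.9)
        v = sw.cluster_covariance(d, 1, corr)
        expected = np.array([[1.0, 0.5 * 0.81], [0.5 * 0.81, 1.0]])
        np.testing.assert_allclose(v, expected, rtol=1e-14)

    def test_block_exchangeable_entries(self):
        d = Design([[0, 1, 1]], [[1, 1, 1]], [1], 7)
        corr = sw.CorrelationSpec(icc=0.05, cac=0.95, structure="block_exchangeable")
        v = sw.cluster_covariance(d, 1, corr)
        assert np.allclose(np.diag(v), 0.05 + 0.95 / 7)
        off = v[~np.eye(3, dtype=bool)]
        assert np.allclose(off, 0.0475)

    def test_decay_r1_equals_exchangeable(self):
        d = Design([[0, 1, 1, 1]], [[1, 0, 1, 1]], [1], 3)
        decay = sw.cluster_covariance(d, 1, sw.CorrelationSpec(icc=0.3, cac=1.0))
        exch = sw.cluster_covariance(
            d, 1, sw.CorrelationSpec(icc=0.3, structure="exchangeable")
        )
        np.testing.assert_allclose(decay, exch, rtol=1e-15)

    def test_positive_definite(self, alliance_design, alliance_corr):
        v = sw.cluster_covariance(alliance_design, 3, alliance_corr)
        assert np.linalg.eigvalsh(v).min() > 0

    def test_empty_sequence_rejected(self):
        d = Design([[0, 1], [0, 1]], [[0, 0], [1, 1]], [1, 1], 1)
        with pytest.raises(ValueError, match="no observed periods"):
            sw.cluster_covariance(d, 1, sw.CorrelationSpec(icc=0.1))


class TestTreatmentVarianceOracle:
    def test_complete_two_sequence_design(self):
        d = sw.make_complete_stepped_wedge(2, [1, 1], 2)
        corr = sw.CorrelationSpec(icc=0.2, cac=0.8)
        expected = individual_level_variance(d, 0.2, 0.8)
        assert sw.treatment_variance(d, corr) == pytest.approx(expected, rel=1e-10)

    @pytest.mark.parametrize("structure", sw.variance.STRUCTURES)
    def test_exhaustive_two_by_three(self, structure):
        base = sw.make_complete_stepped_wedge(2, [1, 2], 3)
        corr = sw.CorrelationSpec(icc=0.15, cac=0.7, structure=structure)
        for bits in itertools.product([False, True], repeat=6):
            mask = np.array(bits).reshape(2, 3)
            if not mask.any():
                continue
            d = base.with_observed(mask)
            oracle = individual_level_variance(d, 0.15, 0.7, structure)
            if sw.is_estimable(d, corr):
                assert oracle is not None
                assert sw.treatment_variance(d, corr) == pytest.approx(
                    oracle, rel=1e-10
                )
            else:
                assert oracle is None

    @given(small_design_strategy(), corr_strategy)
    @settings(max_examples=100, deadline=None)
    def test_random_masks_match_oracle(self, design, corr):
        assume(sw.is_estimable(design, corr))
        oracle = individual_level_variance(
            design, corr.icc, corr.cac, corr.structure
        )
        assert oracle is not None
        assert sw.treatment_variance(design, corr) == pytest.approx(
            oracle, rel=1e-10
        )


class TestVarianceProperties:
    @given(small_design_strategy(), corr_strategy, st.data())
    @settings(max_examples=100, deadline=None)
    def test_adding_a_cell_never_increases_variance(self, design, corr, data):
        assume(sw.is_estimable(design, corr))
        unobserved = list(zip(*np.nonzero(~design.observed)))
        assume(unobserved)
        s, p = data.draw(st.sampled_from(unobserved))
        mask = design.observed.copy()
        mask[s, p] = True
        larger = design.with_observed(mask)
        var_small = sw.treatment_variance(design, corr)
        var_large = sw.treatment_variance(larger, corr)
        assert var_large <= var_small * (1 + 1e-9)

    def test_sequence_relabelling_invariance(self, alliance_corr):
        d = sw.make_complete_stepped_wedge(3, [2, 5, 3], 4)
        perm = [2, 0, 1]
        permuted = Design(
            d.treatment[perm],
            d.observed[perm],
            d.clusters_per_sequence[perm],
            d.cluster_period_size,
        )
        assert sw.treatment_variance(permuted, alliance_corr) == pytest.approx(
            sw.treatment_variance(d, alliance_corr), rel=1e-12
        )

    def test_structure_degenerations(self, alliance_design):
        exch = sw.treatment_variance(
            alliance_design, sw.CorrelationSpec(icc=0.1, structure="exchangeable")
        )
        decay1 = sw.treatment_variance(
            alliance_design, sw.CorrelationSpec(icc=0.1, cac=1.0)
        )
        block1 = sw.treatment_variance(
            alliance_design,
            sw.CorrelationSpec(icc=0.1, cac=1.0, structure="block_exchangeable"),
        )
        assert decay1 == pytest.approx(exch, rel=1e-12)
        assert block1 == pytest.approx(exch, rel=1e-12)

    def test_globally_unobserved_period_dropped(self):
        # period 3 unmeasured everywhere: still estimable, decay lag preserved
        base = sw.make_complete_stepped_wedge(3, [1, 1, 1], 2)
        mask = base.observed.copy()
        mask[:, 2] = False
        d = base.with_observed(mask)
        corr = sw.CorrelationSpec(icc=0.2, cac=0.8)
        expected = individual_level_variance(d, 0.2, 0.8)
        assert sw.treatment_variance(d, corr) == pytest.approx(expected, rel=1e-10)


class TestEstimability:
    def test_complete_design_estimable(self, alliance_design, alliance_corr):
        assert sw.is_estimable(alliance_design, alliance_corr)

    def test_all_control_not_estimable(self, alliance_corr):
        d = Design([[0, 0, 0], [0, 0, 0]], np.ones((2, 3), bool), [1, 1], 2)
        assert not sw.is_estimable(d, alliance_corr)

    def test_single_sequence_confounded(self, alliance_corr):
        # one control and one intervention period in different periods:
        # treatment is a linear combination of period effects
        d = Design([[0, 1]], [[1, 1]], [3], 2)
        assert not sw.is_estimable(d, alliance_corr)
        with pytest.raises(sw.NotEstimableError):
            sw.treatment_variance(d, alliance_corr)

    def test_empty_design_not_estimable(self, alliance_corr):
        d = Design([[0, 1], [0, 1]], np.zeros((2, 2), bool), [1, 1], 1)
        assert not sw.is_estimable(d, alliance_corr)


class TestPower:
    def test_zero_effect_gives_alpha_over_two(self, alliance_design, alliance_corr):
        pw = sw.PowerSpec(effect_size=0.0, alpha=0.05)
        assert sw.power(alliance_design, alliance_corr, pw) == pytest.approx(
            0.025, abs=1e-12
        )

    def test_monotone_in_effect_size(self, alliance_design, alliance_corr):
        powers = [
            sw.power(alliance_design, alliance_corr, sw.PowerSpec(effect_size=es))
            for es in (0.1, 0.2, 0.3, 0.5)
        ]
        assert powers == sorted(powers)
        assert all(0 < p < 1 for p in powers)

    def test_decreasing_in_variance(self, alliance_design, alliance_corr, power_spec):
        reduced = sw.remove_cell(alliance_design, 1, 6)
        assert sw.power(reduced, alliance_corr, power_spec) <= sw.power(
            alliance_design, alliance_corr, power_spec
        )

    def test_matches_formula(self, alliance_design, alliance_corr, power_spec):
        from scipy.stats import norm

        var = sw.treatment_variance(alliance_design, alliance_corr)
        expected = norm.cdf(0.26 / np.sqrt(var) - norm.ppf(0.975))
        assert sw.power(alliance_design, alliance_corr, power_spec) == pytest.approx(
            expected, abs=1e-15
        )
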
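"""Chemical-shift perturbations: formula, top-n summary, t-test, titrations."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as scipy_stats

from m6abind import csp
from m6abind.errors import ValidationError


def table(condition, residues, dh, dn, excluded=None):
    return csp.PeakTable(condition, np.asarray(residues), np.asarray(dh, dtype=float),
                         np.asarray(dn, dtype=float), excluded)


class TestComputeCsp:
    def test_identical_tables_give_zero(self):
        a = table("free", [1, 2, 3], [8.0, 8.5, 9.0], [110.0, 120.0, 130.0])
        profile = csp.compute_csp(a, a)
        assert np.allclose(profile.csp, 0.0)

    def test_nitrogen_weight_exposure(self):
        # a pure 1-ppm nitrogen change scores 0.15 ppm combined
        a = table("free", [1], [8.0], [110.0])
        b = table("bound", [1], [8.0], [111.0])
        assert csp.compute_csp(a, b).csp[0] == pytest.approx(0.15, rel=1e-12)

    def test_hand_evaluated_mixed_shift(self):
        # dH 0.03, dN 0.2 -> sqrt(9e-4 + 9e-4) = 0.042426 ppm
        a = table("free", [1], [8.00], [110.0])
        b = table("bound", [1], [8.03], [110.2])
        assert csp.compute_csp(a, b).csp[0] == pytest.approx(math.sqrt(0.0018), rel=1e-9)

    def test_no_shared_residues_rejected(self):
        a = table("free", [1], [8.0], [110.0])
        b = table("bound", [2], [8.0], [110.0])
        with pytest.raises(ValidationError):
            csp.compute_csp(a, b)

    def test_excluded_residues_dropped(self):
        a = table("free", [1, 2], [8.0, 9.0], [110.0, 120.0],
                  excluded=np.array([False, True]))
        b = table("bound", [1, 2], [8.1, 9.5], [110.0, 121.0])
        profile = csp.compute_csp(a, b)
        assert list(profile.residues) == [1]

    def test_symmetric_in_table_order(self):
        a = table("free", [1, 2], [8.0, 9.0], [110.0, 120.0])
        b = table("bound", [1, 2], [8.2, 8.7], [111.0, 119.0])
        assert np.allclose(csp.compute_csp(a, b).csp, csp.compute_csp(b, a).csp)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(scale=st.floats(0.01, 100.0), dh=st.floats(-1, 1), dn=st.floats(-5, 5))
    def test_linear_under_uniform_scaling(self, scale, dh, dn):
        a = table("free", [1], [8.0], [110.0])
        b = table("bound", [1], [8.0 + dh], [110.0 + dn])
        b_scaled = table("bound", [1], [8.0 + scale * dh], [110.0 + scale * dn])
        base = csp.compute_csp(a, b).csp[0]
        scaled = csp.compute_csp(a, b_scaled).csp[0]
        assert scaled == pytest.approx(scale * base, rel=1e-9, abs=1e-12)


class TestSummarizeLargest:
    def profile(self, values):
        values = np.asarray(values, dtype=float)
        return csp.CSPProfile(residues=np.arange(1, values.size + 1), csp=values)

    def test_uniform_reduces_to_plain_mean_and_population_sd(self):
        values = [0.05, 0.1, 0.2, 0.4]
        summary = csp.summarize_largest(self.profile(values), n=4, weighting="uniform")
        assert summary.center == pytest.approx(np.mean(values))
        assert summary.spread == pytest.approx(np.std(values))

    def test_magnitude_weighted_mean_hand_value(self):
        # values 0.1,0.2,0.3 self-weighted: (0.01+0.04+0.09)/0.6 = 0.2333...
        summary = csp.summarize_largest(self.profile([0.1, 0.2, 0.3]),
                                        n=3, weighting="magnitude")
        assert summary.center == pytest.approx(0.14 / 0.6, rel=1e-12)

    def test_equal_values_have_zero_spread(self):
        for weighting in ("uniform", "magnitude"):
            summary = csp.summarize_largest(self.profile([0.2] * 5), n=5,
                                            weighting=weighting)
            assert summary.spread == pytest.approx(0.0, abs=1e-15)

    def test_selects_top_n_with_residue_tiebreak(self):
        profile = csp.CSPProfile(residues=np.array([10, 20, 30, 40]),
                                 csp=np.array([0.3, 0.1, 0.3, 0.3]))
        summary = csp.summarize_largest(profile, n=2)
        assert list(summary.residues) == [10, 30]

    def test_n_bounds_enforced(self):
        with pytest.raises(ValidationError):
            csp.summarize_largest(self.profile([0.1, 0.2]), n=3)
        with pytest.raises(ValidationError):
            csp.summarize_largest(self.profile([0.1, 0.2]), n=1)


class TestCompareConditions:
    def test_identical_samples(self):
        result = csp.compare_conditions([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert result.statistic == 0.0
        assert result.p_value == 1.0
        assert result.stars == "ns"

    def test_textbook_pooled_t(self):
        # means 2 vs 5, pooled var 1 -> t = -3/sqrt(2/3) = -3.674, df = 4
        result = csp.compare_conditions([1, 2, 3], [4, 5, 6])
        assert result.statistic == pytest.approx(-3.6742346, rel=1e-6)
        assert result.df == 4

    def test_matches_scipy_on_random_pairs(self, rng):
        for _ in range(100):
            a = rng.normal(rng.uniform(-1, 1), rng.uniform(0.5, 2), size=rng.integers(3, 20))
            b = rng.normal(rng.uniform(-1, 1), rng.uniform(0.5, 2), size=rng.integers(3, 20))
            ours = csp.compare_conditions(a, b)
            ref = scipy_stats.ttest_ind(a, b, equal_var=True)
            assert ours.statistic == pytest.approx(ref.statistic, rel=1e-10)
            assert ours.p_value == pytest.approx(ref.pvalue, rel=1e-10)

    def test_star_annotation_thresholds(self):
        assert csp.compare_conditions([0, 0, 0.001], [10, 10, 10.001]).stars == "**"
        # choose samples landing between the thresholds
        mid = csp.compare_conditions([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        assert 0.005 < mid.p_value <= 0.05
        assert mid.stars == "*"

    def test_zero_variance_different_means(self):
        result = csp.compare_conditions([1.0, 1.0], [2.0, 2.0])
        assert result.p_value == 0.0

    def test_small_samples_rejected(self):
        with pytest.raises(ValidationError):
            csp.compare_conditions([1.0], [1.0, 2.0])


class TestIsotherm:
    def test_no_ligand_no_binding(self):
        assert csp.fraction_bound_isotherm(80.0, 0.0, 10.0) == 0.0

    def test_hand_evaluated_depletion_case(self):
        # P=80, L=80, KD=10: (170 - sqrt(3300)) / 160
        expected = (170.0 - math.sqrt(3300.0)) / 160.0
        assert csp.fraction_bound_isotherm(80.0, 80.0, 10.0) == pytest.approx(
            expected, rel=1e-12)

    def test_saturation_limit(self):
        assert csp.fraction_bound_isotherm(1.0, 1e7, 10.0) == pytest.approx(1.0, abs=1e-4)

    def test_dilute_protein_limit(self):
        assert csp.fraction_bound_isotherm(0.0, 5.0, 10.0) == pytest.approx(5.0 / 15.0)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(p=st.floats(0.0, 1e3), l=st.floats(0.0, 1e3), kd=st.floats(0.01, 1e3))
    def test_fraction_stays_physical(self, p, l, kd):
        f = csp.fraction_bound_isotherm(p, l, kd)
        assert 0.0 <= f <= 1.0


class TestTitration:
    DELTAS = {5: (0.12, 0.8), 9: (-0.08, 0.5), 14: (0.2, -1.1)}

    def test_ratio_zero_reproduces_free_state(self):
        series = csp.simulate_titration(1.0, 80.0, ratios=[0.0, 2.0],
                                        bound_deltas=self.DELTAS, noise_sd=0.0, seed=0)
        free = series.tables[0]
        assert np.allclose(free.delta_h, 0.0)
        assert np.allclose(free.delta_n, 0.0)

    def test_stoichiometric_limit_reaches_bound_shifts(self):
        # kd << protein: at >= 1 equivalent the protein is effectively all bound
        series = csp.simulate_titration(kd=0.001, protein_conc=80.0,
                                        ratios=[2.0], bound_deltas=self.DELTAS,
                                        noise_sd=0.0, seed=0)
        endpoint = series.tables[0]
        for i, res in enumerate(endpoint.residues):
            dh, dn = self.DELTAS[int(res)]
            assert endpoint.delta_h[i] == pytest.approx(dh, abs=1e-3)
            assert endpoint.delta_n[i] == pytest.approx(dn, abs=1e-3)

    def test_default_ratio_series(self):
        assert csp.DEFAULT_MOLAR_RATIOS == (0.5, 1.0, 2.0, 4.0, 8.0)

    def test_lower_affinity_yields_smaller_shifts_at_two_equivalents(self):
        high = csp.simulate_titration(0.5, 80.0, ratios=[2.0],
                                      bound_deltas=self.DELTAS, noise_sd=0.0, seed=0)
        low = csp.simulate_titration(200.0, 80.0, ratios=[2.0],
                                     bound_deltas=self.DELTAS, noise_sd=0.0, seed=0)
        profile_high = csp.compute_csp(high.tables[0],
                                       table("free", list(self.DELTAS), [0] * 3, [0] * 3))
        profile_low = csp.compute_csp(low.tables[0],
                                      table("free", list(self.DELTAS), [0] * 3, [0] * 3))
        assert np.all(profile_low.csp < profile_high.csp)

    def test_saturating_titration_recovers_planted_csp(self):
        noise = 0.002
        series = csp.simulate_titration(0.01, 80.0, ratios=[8.0],
                                        bound_deltas=self.DELTAS,
                                        noise_sd=noise, seed=11)
        free = table("free", list(self.DELTAS), [0.0] * 3, [0.0] * 3)
        measured = csp.compute_csp(free, series.tables[0])
        for i, res in enumerate(measured.residues):
            dh, dn = self.DELTAS[int(res)]
            expected = math.sqrt(dh ** 2 + (0.15 * dn) ** 2)
            assert measured.csp[i] == pytest.approx(expected, abs=6 * noise)
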
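"""Poisson lesion statistics, first-lesion quantiles, repair kinetics."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

import ribotraffic as rt
from ribotraffic.damage import DamageRateProfile, LESION_TYPES
from ribotraffic.locus import ConfigurationError


class TestCalibrateRate:
    @pytest.mark.parametrize(
        "fraction, length_kb, expected",
        [
            # -ln(1 - 0.873) / 2.96 and -ln(1 - 0.379) / 0.86, hand arithmetic
            (0.873, 2.96, 0.69716),
            (0.379, 0.86, 0.55403),
            (0.0, 5.0, 0.0),
        ],
    )
    def test_closed_form(self, fraction, length_kb, expected):
        assert rt.calibrate_rate(fraction, length_kb) == pytest.approx(
            expected, abs=5e-5
        )

    @pytest.mark.parametrize("bad", [1.0, 1.5, -0.1])
    def test_domain_errors(self, bad):
        with pytest.raises(ValueError):
            rt.calibrate_rate(bad, 1.0)

    @given(st.floats(0.0, 0.99), st.floats(0.1, 10.0))
    def test_roundtrip_with_zero_class(self, fraction, length_kb):
        """calibrate_rate inverts prob_at_least_one to 6 significant figures."""
        rate = rt.calibrate_rate(fraction, length_kb)
        profile = DamageRateProfile.uniform(rate, length_kb * 1000.0)
        back = rt.prob_at_least_one(profile, (0.0, length_kb * 1000.0))
        assert back == pytest.approx(fraction, rel=1e-6, abs=1e-9)


class TestZeroClass:
    def test_printed_fractions_reproduced(self):
        p1 = DamageRateProfile.uniform(0.697, 2960.0)
        assert rt.prob_at_least_one(p1, (0, 2960)) == pytest.approx(0.873, abs=1e-3)
        p2 = DamageRateProfile.uniform(0.554, 860.0)
        assert rt.prob_at_least_one(p2, (0, 860)) == pytest.approx(0.379, abs=1e-3)

    def test_piecewise_profile_matches_both_fragments(self, profile):
        assert rt.prob_at_least_one(profile, (0, 2960)) == pytest.approx(0.873, abs=1e-9)
        assert rt.prob_at_least_one(profile, (0, 860)) == pytest.approx(0.379, abs=1e-9)

    def test_empty_region_and_zero_rate(self, locus):
        zero = DamageRateProfile.uniform(0.0, locus.gene_length)
        assert rt.prob_at_least_one(zero, (0, 2960)) == 0.0
        p = DamageRateProfile.uniform(0.7, locus.gene_length)
        assert rt.prob_at_least_one(p, (500, 500)) == 0.0


class TestFirstLesionStatistics:
    def test_cdf_monotone_and_matches_numerical_integration(self, profile):
        xs = np.linspace(0, 6900, 231)
        cdf = rt.first_lesion_cdf(profile, xs)
        assert cdf[0] == 0.0
        assert np.all(np.diff(cdf) >= -1e-12)
        # independent oracle: trapezoid integration of the rate function
        grid = np.linspace(0, 6900, 69001)
        rate = np.where(grid < 860, 0.554e-3,
                        profile.segments[1][1] / 1000.0)
        mean = np.concatenate(([0.0], np.cumsum((rate[1:] + rate[:-1]) / 2
                                                * np.diff(grid))))
        oracle = 1.0 - np.exp(-np.interp(xs, grid, mean))
        assert np.allclose(cdf, oracle, atol=1e-4)

    def test_zero_class_consistency(self, profile, locus):
        total = profile.expected_lesions((0, locus.gene_length))
        tail = 1.0 - rt.first_lesion_cdf(profile, locus.gene_length)
        assert tail == pytest.approx(math.exp(-total), rel=1e-9)

    def test_quantile_roundtrip_is_2960bp(self):
        rate = rt.calibrate_rate(0.873, 2.96)
        profile = DamageRateProfile.uniform(rate, 6900.0)
        assert rt.likely_first_cpd_length(profile, 0.873) == pytest.approx(
            2960.0, abs=0.1
        )

    def test_zero_rate_returns_beyond_gene_sentinel(self, locus):
        zero = DamageRateProfile.uniform(0.0, locus.gene_length)
        assert rt.likely_first_cpd_length(zero, 0.5) == math.inf

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.2, 1.7])
    def test_threshold_domain(self, profile, bad):
        with pytest.raises(ValueError):
            rt.likely_first_cpd_length(profile, bad)


class TestSampleLesionMap:
    def test_poisson_moments(self, locus):
        profile = DamageRateProfile.uniform(0.697, locus.gene_length)
        lm = rt.sample_lesion_map(profile, locus, seed=3, n_copies=10_000)
        counts = lm.counts_in((0, locus.gene_length))
        mean = counts.mean()
        expected = 0.697 * 6.9
        se = math.sqrt(expected / 10_000)
        assert abs(mean - expected) < 3 * se
        # Poisson: variance ~ mean (index of dispersion ~ 1)
        assert counts.var() / mean == pytest.approx(1.0, abs=0.05)

    def test_zero_rate_gives_lesion_free_copies(self, locus):
        zero = DamageRateProfile.uniform(0.0, locus.gene_length)
        lm = rt.sample_lesion_map(zero, locus, seed=3, n_copies=500)
        assert len(lm) == 0

    def test_monte_carlo_matches_analytic_zero_class(self, profile, locus):
        n = 20_000
        lm = rt.sample_lesion_map(profile, locus, seed=11, n_copies=n)
        frac = (lm.counts_in((0, 2960)) > 0).mean()
        p = rt.prob_at_least_one(profile, (0, 2960))
        se = math.sqrt(p * (1 - p) / n)
        assert abs(frac - p) < 3 * se

    def test_seed_is_mandatory_and_reproducible(self, profile, locus):
        with pytest.raises(ValueError):
            rt.sample_lesion_map(profile, locus, seed=None)
        a = rt.sample_lesion_map(profile, locus, seed=42)
        b = rt.sample_lesion_map(profile, locus, seed=42)
        assert np.array_equal(a.position, b.position)
        assert np.array_equal(a.copy_id, b.copy_id)

    def test_photoproduct_mix_fractions(self, locus):
        profile = DamageRateProfile.uniform(2.0, locus.gene_length)
        lm = rt.sample_lesion_map(profile, locus, seed=5, n_copies=5000)
        frac_cpd = (lm.ltype == LESION_TYPES.index("CPD")).mean()
        assert frac_cpd == pytest.approx(0.75, abs=0.01)

    def test_tsv_roundtrip(self, profile, locus, tmp_path):
        lm = rt.sample_lesion_map(profile, locus, seed=9)
        path = tmp_path / "lesions.tsv"
        lm.to_tsv(path)
        back = rt.LesionMap.from_tsv(path, locus.n_copies, locus.gene_length)
        assert np.allclose(back.position, lm.position)
        assert np.array_equal(back.copy_id, lm.copy_id)
        assert np.array_equal(back.ltype, lm.ltype)


class TestRepairKinetics:
    def _uniform_map(self, locus, n=10_000, marked=True):
        profile = DamageRateProfile.uniform(1.0, locus.gene_length)
        lm = rt.sample_lesion_map(profile, locus, seed=21, n_copies=n)
        lm.tcr_marked[:] = marked
        return lm

    def test_tcr_half_life_gives_half_repaired_at_30min(self, locus, kinetics):
        """All-TCR repair at k = ln2/0.5 per h leaves 50% after 30 min,
        the midpoint of the measured 40-60% band."""
        lm = self._uniform_map(locus)
        rt.repair_update(lm, 0.5 * 3600, kinetics, np.random.default_rng(2))
        frac = lm.repaired.mean()
        se = math.sqrt(0.25 / len(lm))
        assert abs(frac - 0.5) < 3 * se
        assert 0.4 < frac < 0.6

    def test_mixed_channel_fraction_matches_closed_form(self, locus, kinetics):
        lm = self._uniform_map(locus, marked=False)
        lm.tcr_marked[: len(lm) // 2] = True
        rt.repair_update(lm, 3600.0, kinetics, np.random.default_rng(7))
        expect = 0.5 * (1 - math.exp(-kinetics.k_tcr)) \
            + 0.5 * (1 - math.exp(-kinetics.k_ggr))
        assert lm.repaired.mean() == pytest.approx(expect, abs=0.02)

    def test_ner_deficient_never_repairs(self, locus):
        lm = self._uniform_map(locus, n=2000)
        kin = rt.RepairKinetics(ner_active=False)
        rt.repair_update(lm, 8 * 3600, kin, np.random.default_rng(1))
        assert lm.repaired.sum() == 0

    def test_zero_dt_is_identity_and_negative_dt_rejected(self, locus, kinetics):
        lm = self._uniform_map(locus, n=1000)
        rt.repair_update(lm, 0.0, kinetics, np.random.default_rng(1))
        assert lm.repaired.sum() == 0
        with pytest.raises(ValueError):
            rt.repair_update(lm, -1.0, kinetics, np.random.default_rng(1))

    def test_repaired_count_never_decreases(self, locus, kinetics):
        lm = self._uniform_map(locus, n=2000)
        rng = np.random.default_rng(4)
        prev = 0
        for _ in range(20):
            rt.repair_update(lm, 600.0, kinetics, rng)
            now = int(lm.repaired.sum())
            assert now >= prev
            prev = now

    def test_rate_ordering_enforced(self):
        with pytest.raises(ConfigurationError):
            rt.RepairKinetics(k_tcr=0.1, k_ggr=0.5)


class TestProfileValidation:
    def test_negative_rate_rejected(self):
        with pytest.raises(ConfigurationError):
            DamageRateProfile.uniform(-0.5, 1000.0)

    def test_mix_must_sum_to_one(self):
        with pytest.raises(ConfigurationError):
            DamageRateProfile.uniform(0.5, 1000.0,
                                      photoproduct_mix={"CPD": 0.5})
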
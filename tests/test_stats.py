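"""Statistical layer against independent oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from skelemorph import phantoms, stats


def oracle_welch(a, b):
    """Hand-formula Welch t-test (independent of the implementation path)."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    t = (a.mean() - b.mean()) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
    p = 2 * sps.t.sf(abs(t), df)
    return t, df, p


class TestWelch:
    def test_hand_computed_example(self):
        t, df, p = stats.welch_t([1, 2, 3], [2, 4, 6])
        assert t == pytest.approx(-2 / np.sqrt(5 / 3), rel=1e-9)
        assert df == pytest.approx((5 / 3) ** 2 / ((1 / 3) ** 2 / 2 + (4 / 3) ** 2 / 2), rel=1e-9)

    def test_identical_samples(self):
        t, _, p = stats.welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0
        assert p == pytest.approx(1.0)

    def test_large_shift_is_highly_significant(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 1, 20)
        b = rng.normal(5, 1, 20)  # 5 sigma shift
        _, _, p = stats.welch_t(a, b)
        assert p < 0.0001

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(seed=st.integers(0, 10_000))
    def test_matches_oracle_to_1e10(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(0, 1 + rng.random(), rng.integers(3, 30))
        b = rng.normal(rng.normal(), 1 + rng.random(), rng.integers(3, 30))
        t, df, p = stats.welch_t(a, b)
        t0, df0, p0 = oracle_welch(a, b)
        assert abs(t - t0) < 1e-10
        assert abs(df - df0) < 1e-10
        assert abs(p - p0) < 1e-10

    def test_n_below_two_rejected(self):
        with pytest.raises(ValueError):
            stats.welch_t([1.0], [1.0, 2.0])


class TestHolmSidak:
    def test_two_value_example(self):
        adj = stats.holm_sidak([0.01, 0.04])
        assert adj[0] == pytest.approx(1 - 0.99**2, rel=1e-12)
        assert adj[1] == pytest.approx(0.04, rel=1e-12)

    def test_single_p_identity(self):
        assert stats.holm_sidak([0.5])[0] == pytest.approx(0.5)

    def test_all_equal_p(self):
        p = 0.03
        adj = stats.holm_sidak([p] * 4)
        assert np.allclose(adj, 1 - (1 - p) ** 4)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(seed=st.integers(0, 10_000), m=st.integers(1, 12))
    def test_matches_statsmodels_oracle(self, seed, m):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(seed)
        p = rng.uniform(0, 1, m)
        adj = stats.holm_sidak(p)
        _, adj0, _, _ = multipletests(p, method="holm-sidak")
        assert np.allclose(adj, adj0, atol=1e-10)

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(seed=st.integers(0, 10_000))
    def test_never_below_raw_and_order_preserving(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(0, 1, 8)
        adj = stats.holm_sidak(p)
        assert (adj >= p - 1e-15).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            stats.holm_sidak([0.5, 1.5])


class TestChiSquare:
    def test_birth_ratio_example(self):
        """Observed 41%/59% genotype split in 1560 births vs Mendelian 50:50."""
        chi2, df, p = stats.chi_square_gof([640, 920], [0.5, 0.5])
        assert chi2 == pytest.approx(2 * 140**2 / 780, rel=1e-12)
        assert df == 1
        assert p < 0.0001

    def test_exact_match_gives_zero(self):
        chi2, _, p = stats.chi_square_gof([50, 50], [0.5, 0.5])
        assert chi2 == 0.0
        assert p == pytest.approx(1.0)

    def test_all_in_one_cell(self):
        chi2, _, _ = stats.chi_square_gof([10, 0], [0.5, 0.5])
        assert chi2 == pytest.approx(10.0)

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(seed=st.integers(0, 10_000))
    def test_k2_equals_squared_proportion_z(self, seed):
        """With two cells, chi-square equals the square of the one-sample
        proportion z-statistic (no continuity correction)."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 1000))
        k = int(rng.integers(1, n))
        p0 = float(rng.uniform(0.1, 0.9))
        chi2, _, _ = stats.chi_square_gof([k, n - k], [p0, 1 - p0])
        z = (k / n - p0) / np.sqrt(p0 * (1 - p0) / n)
        assert abs(chi2 - z**2) < 1e-10

    def test_zero_expected_rejected(self):
        with pytest.raises(ValueError):
            stats.chi_square_gof([5, 5], [1.0, 0.0])


class TestStars:
    @pytest.mark.parametrize(
        "p,expected",
        [
            (0.049, "*"), (0.05, "ns"), (0.02, "*"),
            (0.0099, "**"), (0.01, "*"), (0.0009, "***"),
            (0.001, "**"), (0.00005, "****"), (0.0001, "***"), (0.9, "ns"),
        ],
    )
    def test_band_edges_fall_to_less_significant_band(self, p, expected):
        assert stats.significance_stars(p) == expected


class TestSummarizeGroups:
    def test_effect_pattern_detected(self):
        table = phantoms.generate_study(
            n_per_group=10, effects={"gp_volume_mm3": (-2.0, 0.0)}, seed=11
        )
        comps = {(c.measurement_name, c.age_weeks): c for c in stats.summarize_groups(table)}
        assert comps[("gp_volume_mm3", 3)].p_value < 0.05
        assert comps[("gp_volume_mm3", 3)].stars != "ns"
        # SEM definition: sd/sqrt(n)
        c = comps[("gp_volume_mm3", 3)]
        sub = table.df.query("measurement == 'gp_volume_mm3' and age_weeks == 3 and genotype == 'WT'")
        assert c.sem_wt == pytest.approx(sub["value"].std(ddof=1) / np.sqrt(len(sub)))

    def test_single_group_warns_and_returns_empty(self):
        from skelemorph.voxgrid import StudyTable

        table = StudyTable.from_records(
            [
                dict(animal_id=f"M{i}", genotype="WT", sex="M", age_weeks=3,
                     measurement="x", value=float(i))
                for i in range(5)
            ]
        )
        with pytest.warns(UserWarning):
            assert stats.summarize_groups(table) == []

    def test_null_calibration_star_rate(self):
        """With no true effects, ~5% of comparisons are starred at alpha=0.05.
        300 studies x 12 comparisons gives a tight binomial check."""
        starred = total = 0
        for seed in range(300):
            table = phantoms.generate_study(n_per_group=10, seed=seed)
            for c in stats.summarize_groups(table):
                total += 1
                starred += c.stars != "ns"
        rate = starred / total
        assert rate == pytest.approx(0.05, abs=0.015)

    def test_three_week_only_pattern_rate_matches_power_oracle(self):
        """With a -2 SD effect at 3 weeks only (n=10/group), the per-run
        probability of the joint pattern '3 wk significant AND 6 wk not' is
        power * (1 - alpha) = 0.988 * 0.95 ~= 0.94 (noncentral-t oracle);
        the observed rate over 200 runs must be consistent with that."""
        hits = 0
        n_runs = 200
        for seed in range(n_runs):
            table = phantoms.generate_study(
                n_per_group=10,
                effects={"gp_volume_mm3": (-2.0, 0.0)},
                seed=seed,
                measurements={"gp_volume_mm3": (1.2, 0.9, 0.15)},
            )
            comps = {c.age_weeks: c for c in stats.summarize_groups(table)}
            hits += (comps[3].p_value < 0.05) and (comps[6].p_value >= 0.05)
        # oracle: exact noncentral-t power at d=2, n=10/group, alpha=0.05
        df = 18
        ncp = 2.0 / np.sqrt(2 / 10)
        crit = sps.t.ppf(0.975, df)
        power = sps.nct.sf(crit, df, ncp) + sps.nct.cdf(-crit, df, ncp)
        expected = power * 0.95
        se = np.sqrt(expected * (1 - expected) / n_runs)
        assert hits / n_runs == pytest.approx(expected, abs=4 * se)


class TestTimeline:
    def test_timeline_family_adjustment_never_lowers_p(self):
        table = phantoms.generate_study(n_per_group=8, seed=3)
        comps = stats.summarize_groups(table)
        adjusted = stats.timeline_comparisons(comps)
        for raw, adj in zip(comps, adjusted):
            assert adj.p_value >= raw.p_value - 1e-15
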
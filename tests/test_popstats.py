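"""M statistic, frequency tables, and the statistical test battery.

Every closed-form test is checked against an independent textbook-formula
oracle (and the t-test additionally against a permutation test), so the
scipy-backed implementations and the hand computations must agree.
"""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as ss

import haplomig as hm


# ---------------------------------------------------------------------------
# independent oracles

def oracle_chi_square(counts):
    counts = np.asarray(counts, dtype=float)
    expected = counts.sum() / len(counts)
    stat = ((counts - expected) ** 2 / expected).sum()
    df = len(counts) - 1
    return stat, df, ss.chi2.sf(stat, df)


def oracle_pooled_t(a, b):
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
    df = na + nb - 2
    return t, df, 2 * ss.t.sf(abs(t), df)


def oracle_welch_t(a, b):
    a, b = np.asarray(a, float), np.asarray(b, float)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    t = (a.mean() - b.mean()) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va ** 2 / (len(a) - 1) + vb ** 2 / (len(b) - 1))
    return t, df, 2 * ss.t.sf(abs(t), df)


def oracle_anova(groups):
    groups = [np.asarray(g, float) for g in groups]
    allv = np.concatenate(groups)
    grand = allv.mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    k, n = len(groups), len(allv)
    f = (ssb / (k - 1)) / (ssw / (n - k))
    return f, (k - 1, n - k), ss.f.sf(f, k - 1, n - k), ssb / (ssb + ssw)


def oracle_tukey_p(groups, i, j):
    """Studentized-range p for one pair (equal-or-unequal n, Tukey-Kramer)."""
    groups = [np.asarray(g, float) for g in groups]
    n = sum(len(g) for g in groups)
    k = len(groups)
    msw = sum(((g - g.mean()) ** 2).sum() for g in groups) / (n - k)
    ni, nj = len(groups[i]), len(groups[j])
    se = np.sqrt(msw / 2 * (1 / ni + 1 / nj))
    q = abs(groups[i].mean() - groups[j].mean()) / se
    return ss.studentized_range.sf(q, k, n - k)


def permutation_t_p(a, b, n_perm, rng):
    pooled = np.concatenate([a, b])
    obs = abs(oracle_pooled_t(a, b)[0])
    hits = 0
    for _ in range(n_perm):
        rng.shuffle(pooled)
        t = oracle_pooled_t(pooled[:len(a)], pooled[len(a):])[0]
        hits += abs(t) >= obs
    return hits / n_perm


# ---------------------------------------------------------------------------

class TestMStatistic:
    def test_printed_haplotype_split(self):
        # the 71% / 26% split of the two predominant haplotypes
        assert hm.m_statistic(71, 26) == pytest.approx(45 / 97, abs=1e-12)

    def test_boundaries(self):
        assert hm.m_statistic(5, 5) == 0.0
        assert hm.m_statistic(5, 0) == 1.0
        assert hm.m_statistic(0, 5) == -1.0

    def test_both_zero_undefined(self):
        with pytest.raises(hm.UndefinedStatisticError):
            hm.m_statistic(0, 0)

    @settings(max_examples=100, derandomize=True)
    @given(a=st.integers(0, 1000), b=st.integers(0, 1000),
           k=st.integers(1, 50))
    def test_antisymmetry_scale_invariance_range(self, a, b, k):
        if a + b == 0:
            return
        m = hm.m_statistic(a, b)
        assert -1.0 <= m <= 1.0
        assert hm.m_statistic(b, a) == pytest.approx(-m)
        assert hm.m_statistic(k * a, k * b) == pytest.approx(m)


class TestFrequencyTable:
    def _frame(self, rows):
        return pd.DataFrame(rows, columns=["specimen_id", "collection_id",
                                           "state", "year", "segment",
                                           "label", "status"])

    def test_counts_one_group(self):
        rows = [(f"S{i}", "C1", "TX", 2019, "sCOIB", lab, "resolved")
                for i, lab in enumerate(["A", "A", "B", "C"])]
        ft = hm.frequency_table(self._frame(rows), grouping="collection")
        assert ft.counts.loc["C1"].to_dict() == {"A": 2, "B": 1, "C": 1}
        assert ft.n_resolved.loc["C1"] == 4

    def test_unresolved_excluded_and_empty_group_warned(self):
        rows = [("S1", "C1", "TX", 2019, "sCOIB", "A", "resolved"),
                ("S2", "C2", "LA", 2019, "sCOIB", None,
                 "unresolved_ambiguity")]
        with pytest.warns(UserWarning, match="zero resolved"):
            ft = hm.frequency_table(self._frame(rows), grouping="collection")
        assert list(ft.counts.index) == ["C1"]

    def test_state_year_grouping(self):
        rows = [("S1", "TX2019", "TX", 2019, "sCOIB", "A", "resolved"),
                ("S2", "TX2020", "TX", 2020, "sCOIB", "A", "resolved"),
                ("S3", "LA2019", "LA", 2019, "sCOIB", "B", "resolved")]
        ft = hm.frequency_table(self._frame(rows), grouping="state_year")
        assert len(ft.counts) == 3

    def test_generator_cohort_within_binomial_ci(self, refs):
        src = hm.SourcePopulation(singleton_rate=0.0)
        scn = hm.MigrationScenario(source=src, n_destinations=1,
                                   n_sampled=1000, seed=77)
        records, _ = hm.generate_records(scn, refs,
                                         segments=("sCOIB",))
        sites = hm.select_marker_sites(
            hm.discover_snps(records, "sCOIB", refs["sCOIB"]))
        calls = [hm.call_haplotype(r, "sCOIB", sites, refs["sCOIB"])
                 for r in records]
        ft = hm.frequency_table(hm.calls_to_frame(calls, records),
                                grouping="collection")
        freqs = ft.frequencies().iloc[0]
        for label, p in src.coib_freqs.items():
            half = 2.576 * np.sqrt(p * (1 - p) / 1000)
            assert abs(freqs.get(label, 0.0) - p) <= half


class TestChiSquareUniform:
    def test_uniform_counts(self):
        res = hm.chi_square_uniform([25, 25, 25, 25])
        assert res.statistic == 0.0 and res.df == 3

    def test_hand_computation(self):
        res = hm.chi_square_uniform([10, 0])
        assert res.statistic == pytest.approx(10.0)
        assert res.df == 1

    @settings(max_examples=100, derandomize=True)
    @given(seed=st.integers(0, 10_000), k=st.integers(2, 8))
    def test_matches_oracle(self, seed, k):
        rng = np.random.default_rng(seed)
        counts = rng.integers(0, 200, size=k)
        if counts.sum() == 0:
            counts[0] = 1
        res = hm.chi_square_uniform(counts)
        stat, df, p = oracle_chi_square(counts)
        assert res.statistic == pytest.approx(stat, abs=1e-10)
        assert res.df == df
        assert res.p_value == pytest.approx(p, abs=1e-10)


class TestTwoSampleT:
    def test_identical_vectors(self):
        res = hm.two_sample_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == 0.0 and res.p_value == pytest.approx(1.0)

    def test_hand_computation(self):
        res = hm.two_sample_t([1, 2, 3], [4, 5, 6], variant="pooled")
        assert res.statistic == pytest.approx(-3.674, abs=5e-4)
        assert res.df == 4

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000),
           variant=st.sampled_from(["pooled", "welch"]))
    def test_matches_formula_oracle(self, seed, variant):
        rng = np.random.default_rng(seed)
        a = rng.normal(0, 1, size=rng.integers(3, 20))
        b = rng.normal(0.5, 2, size=rng.integers(3, 20))
        res = hm.two_sample_t(a, b, variant=variant)
        oracle = oracle_pooled_t if variant == "pooled" else oracle_welch_t
        t, df, p = oracle(a, b)
        assert res.statistic == pytest.approx(t, abs=1e-10)
        assert res.df == pytest.approx(df, abs=1e-8)
        assert res.p_value == pytest.approx(p, abs=1e-10)

    def test_matches_permutation_within_mc_error(self):
        rng = np.random.default_rng(42)
        a = rng.normal(0, 1, size=12)
        b = rng.normal(0.8, 1, size=12)
        res = hm.two_sample_t(a, b)
        p_perm = permutation_t_p(a, b, 4000, rng)
        se = np.sqrt(res.p_value * (1 - res.p_value) / 4000) + 1e-4
        assert abs(p_perm - res.p_value) < 4 * se + 0.01


class TestOneWayAnova:
    def test_degenerate_constant_groups(self):
        with pytest.raises(hm.DataQualityError, match="within-group"):
            hm.one_way_anova([[1.0, 1.0], [2.0, 2.0]])

    @settings(max_examples=50, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_two_groups_f_equals_t_squared(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=8)
        b = rng.normal(1, 1, size=6)
        f = hm.one_way_anova([a, b]).statistic
        t = hm.two_sample_t(a, b, variant="pooled").statistic
        assert f == pytest.approx(t ** 2, rel=1e-10)

    @settings(max_examples=100, derandomize=True)
    @given(seed=st.integers(0, 10_000), k=st.integers(2, 6))
    def test_matches_decomposition_oracle(self, seed, k):
        rng = np.random.default_rng(seed)
        groups = [rng.normal(rng.normal(), 1, size=rng.integers(3, 12))
                  for _ in range(k)]
        res = hm.one_way_anova(groups)
        f, df, p, r2 = oracle_anova(groups)
        assert res.statistic == pytest.approx(f, abs=1e-10)
        assert res.df == df
        assert res.p_value == pytest.approx(p, abs=1e-10)
        assert res.extra["r2"] == pytest.approx(r2, abs=1e-12)


class TestTukey:
    def test_separated_groups_get_different_letters(self):
        res = hm.tukey_hsd([[0.0, 0.1, 0.05], [10.0, 10.1, 9.9]],
                           labels=["lo", "hi"])
        assert res.letters["lo"] != res.letters["hi"]

    def test_pair_count(self):
        rng = np.random.default_rng(0)
        res = hm.tukey_hsd([rng.normal(size=5) for _ in range(4)])
        assert len(res.pairwise) == 6  # k(k-1)/2

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), k=st.integers(2, 5))
    def test_pairwise_p_matches_studentized_range_oracle(self, seed, k):
        rng = np.random.default_rng(seed)
        groups = [rng.normal(rng.normal(), 1, size=rng.integers(4, 10))
                  for _ in range(k)]
        res = hm.tukey_hsd(groups)
        for row in res.pairwise.itertuples():
            i, j = int(row.group_i), int(row.group_j)
            assert row.p_value == pytest.approx(
                oracle_tukey_p(groups, i, j), abs=1e-8)

    def test_null_groups_share_letter_near_confidence_level(self):
        rng = np.random.default_rng(2024)
        same = 0
        n_sim = 200
        for _ in range(n_sim):
            groups = [rng.normal(0, 1, size=40) for _ in range(3)]
            res = hm.tukey_hsd(groups, alpha=0.05)
            same += len(set(res.letters.values())) == 1
        assert same / n_sim >= 0.90  # ~ 1 - alpha, with Monte Carlo slack


class TestRegionalCompare:
    def _m(self, state, m, i=0):
        return hm.MResult((state, 2019 + i), state, 10, 5, m)

    def test_two_sided_comparison(self):
        ms = [self._m("FL", 0.5), self._m("GA", 0.4),
              self._m("TX", -0.2), self._m("LA", -0.1)]
        res = hm.regional_compare(ms, hm.RegionScheme.east_west())
        assert res.groups["East"][0] == 2
        assert res.groups["West"][0] == 2
        assert 0 <= res.p_value <= 1

    def test_unmapped_state_raises(self):
        ms = [self._m("FL", 0.5), self._m("GA", 0.4),
              self._m("CA", 0.1), self._m("TX", 0.0)]
        with pytest.raises(hm.ValidationError, match="CA"):
            hm.regional_compare(ms, hm.RegionScheme.east_west())

    def test_excluded_state_skipped(self):
        ms = [self._m("FL", 0.5), self._m("GA", 0.4), self._m("PR", 0.9),
              self._m("TX", -0.2), self._m("LA", -0.1)]
        res = hm.regional_compare(ms, hm.RegionScheme.east_west())
        assert res.groups["East"][0] == 2  # PR not counted

    def test_single_sided_data_raises(self):
        ms = [self._m("FL", 0.5), self._m("GA", 0.4)]
        with pytest.raises(hm.DataQualityError):
            hm.regional_compare(ms, hm.RegionScheme.east_west())


def test_plot_state_pies_writes_figure(tmp_path):
    rows = [(f"S{i}", "TX2019", "TX", 2019, "sCOIB", lab, "resolved")
            for i, lab in enumerate(["A"] * 7 + ["B"] * 3)]
    rows += [(f"T{i}", "KS2019", "KS", 2019, "sCOIB", lab, "resolved")
             for i, lab in enumerate(["A"] * 2 + ["B"] * 8)]
    frame = pd.DataFrame(rows, columns=["specimen_id", "collection_id",
                                        "state", "year", "segment",
                                        "label", "status"])
    ft = hm.frequency_table(frame, grouping="state_year")
    out = tmp_path / "pies.png"
    hm.plot_state_pies(ft, out)
    assert out.stat().st_size > 0
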
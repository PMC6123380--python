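"""Cohort concordance statistics: classification, quantiles, kappa, tests."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rotorsim.concordance import (CATEGORIES, CohortFixture,
                                  RegionClassTable, UndefinedTestError,
                                  classify_regions, group_comparison, kappa,
                                  load_cohort_fixture, mann_whitney,
                                  median_iqr, quantiles, summarize_cohort,
                                  wilcoxon_signed_rank)


@pytest.fixture(scope="module")
def fixture():
    return load_cohort_fixture()


class TestClassifyRegions:
    def test_simple_membership(self):
        t = classify_regions({"p": {1}}, {"p": {1}}, {1, 2})
        cats = dict(zip(t.rows["region"], t.rows["category"]))
        assert cats == {1: "both", 2: "neither"}

    def test_patient1_reconstruction(self):
        """First cohort patient: 4 sim-harboring regions, 2 clinically
        mapped, overlap 2 -> counts (both 2, neither 3, sim_only 2,
        firm_only 0)."""
        t = classify_regions({"1": {1, 2, 3, 4}}, {"1": {1, 2}},
                             set(range(1, 8)))
        c = t.counts().loc["1"]
        assert (c["both"], c["neither"], c["sim_only"], c["firm_only"]) \
            == (2, 3, 2, 0)

    def test_empty_sets_all_neither(self):
        t = classify_regions({"p": set()}, {"p": set()}, set(range(1, 8)))
        assert set(t.rows["category"]) == {"neither"}

    def test_unknown_region_rejected(self):
        with pytest.raises(ValueError, match="unknown region"):
            classify_regions({"p": {9}}, {"p": set()}, {1, 2})


class TestFixture:
    def test_totals_row(self, fixture):
        """Pooled counts: 20 both, 35 neither, 18 latent, 4 firm-only."""
        assert fixture.table.pooled_2x2() == (20, 18, 4, 35)

    def test_outcome_split(self, fixture):
        vals = list(fixture.outcome.values())
        assert vals.count("success") == 4
        assert vals.count("failure") == 7

    def test_seven_rows_per_patient(self, fixture):
        assert (fixture.table.rows.groupby("patient").size() == 7).all()

    def test_reconstruction_identity(self, fixture):
        """Rebuilding the long table from its own per-patient counts
        reproduces the counts row by row."""
        counts = fixture.table.counts()[list(CATEGORIES)]
        rebuilt = RegionClassTable.from_counts(counts)
        assert rebuilt.counts()[list(CATEGORIES)].equals(counts)


class TestSummaries:
    def test_cohort_totals(self, fixture):
        s = summarize_cohort(fixture.table)
        t = s["totals"]
        assert t["sim"] == 38
        assert t["firm"] == 24
        assert t["agreed"] == 55
        assert t["differed"] == 22
        assert t["latent"] == 18

    def test_per_patient_medians(self, fixture):
        s = summarize_cohort(fixture.table)
        assert s["per_patient"]["sim"]["median"] == 4
        assert s["per_patient"]["sim"]["iqr"] == [3, 4]
        assert s["per_patient"]["firm"]["median"] == 2
        assert s["per_patient"]["firm"]["iqr"] == [1, 3]

    def test_all_neither_patient_zero_totals(self):
        t = classify_regions({"p": set()}, {"p": set()}, set(range(1, 8)))
        s = summarize_cohort(t)
        assert s["totals"]["sim"] == 0
        assert s["totals"]["firm"] == 0
        assert s["totals"]["differed"] == 0


class TestQuantiles:
    def test_type6_upper_quartile(self):
        assert quantiles([1, 2, 3, 4], 0.75, "type6") == pytest.approx(3.75)

    def test_conventions_disagree_on_small_samples(self):
        vals = [0, 0, 1, 2]
        assert quantiles(vals, 0.75, "type6") == pytest.approx(1.75)
        assert quantiles(vals, 0.75, "tukey_hinges") == pytest.approx(1.5)

    @pytest.mark.parametrize("method", ["type6", "type7", "tukey_hinges"])
    def test_median_agrees_across_methods(self, method):
        vals = [3, 1, 4, 1, 5, 9, 2]
        assert quantiles(vals, 0.5, method) == np.median(vals)

    def test_iqr_brackets_median(self):
        med, q1, q3 = median_iqr([5, 1, 3, 2, 4])
        assert q1 <= med <= q3

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            quantiles([], 0.5)


class TestKappa:
    def test_perfect_agreement(self):
        t = classify_regions({"p": {1, 2}}, {"p": {1, 2}}, set(range(1, 8)))
        assert kappa(t, "cohen") == pytest.approx(1.0)
        assert kappa(t, "pabak") == pytest.approx(1.0)

    def test_cohort_cohen_matches_hand_arithmetic(self, fixture):
        """p0 = 55/77, pe = (38*24 + 39*53)/77^2 -> kappa = 0.4258."""
        assert kappa(fixture.table, "cohen") == pytest.approx(0.4258,
                                                              abs=5e-4)

    def test_cohort_pabak(self, fixture):
        assert kappa(fixture.table, "pabak") == pytest.approx(0.4286,
                                                              abs=5e-4)

    def test_degenerate_marginals_undefined(self):
        t = classify_regions({"p": set()}, {"p": set()}, set(range(1, 8)))
        with pytest.raises(UndefinedTestError):
            kappa(t, "cohen")

    def test_bounds_and_independence(self):
        """All methods stay in [-1, 1]; independently generated tables
        average near zero Cohen's kappa."""
        rng = np.random.default_rng(99)
        vals = []
        for _ in range(2000):
            sim = rng.random(77) < 0.5
            firm = rng.random(77) < 0.3
            a = int((sim & firm).sum())
            b = int((sim & ~firm).sum())
            c = int((~sim & firm).sum())
            d = int((~sim & ~firm).sum())
            counts = pd.DataFrame(
                {"both": [a], "sim_only": [b], "firm_only": [c],
                 "neither": [d]}, index=["p"])
            # widen to a 77-region universe via a direct table
            rows = []
            for cat, k in zip(CATEGORIES, (a, b, c, d)):
                rows += [("p", len(rows) + i + 1, cat) for i in range(k)]
            t = RegionClassTable(pd.DataFrame(
                rows, columns=["patient", "region", "category"]))
            k_ = kappa(t, "cohen")
            assert -1.0 <= k_ <= 1.0
            vals.append(k_)
        assert abs(np.mean(vals)) < 0.02


class TestWilcoxon:
    def test_cohort_paired_counts_exact_p(self, fixture):
        """All 7 nonzero differences favor simulation: p = 2/2^7."""
        c = fixture.table.counts()
        w, p = wilcoxon_signed_rank(c["sim"], c["firm"], mode="exact")
        assert p == pytest.approx(2 / 2 ** 7)

    def test_identical_samples_undefined(self):
        with pytest.raises(UndefinedTestError):
            wilcoxon_signed_rank([1, 2, 3, 4, 5], [1, 2, 3, 4, 5])

    def test_exact_matches_monte_carlo_sign_permutation(self):
        """Exact enumeration against an independent Monte-Carlo oracle."""
        rng = np.random.default_rng(5)
        a = rng.integers(0, 6, 9).astype(float)
        b = rng.integers(0, 6, 9).astype(float)
        if np.all(a == b):
            a[0] += 1
        w, p_exact = wilcoxon_signed_rank(a, b, mode="exact")
        d = a - b
        nz = d[d != 0]
        ranks = pd.Series(np.abs(nz)).rank(method="average").to_numpy()
        mu = ranks.sum() / 2
        dev = abs(ranks[nz > 0].sum() - mu)
        n_mc = 200_000
        signs = rng.random((n_mc, ranks.size)) < 0.5
        w_mc = signs @ ranks
        p_mc = np.mean(np.abs(w_mc - mu) >= dev - 1e-12)
        assert p_exact == pytest.approx(p_mc, abs=0.005)

    def test_exact_agrees_with_enumeration_oracle_small_n(self):
        """Brute-force enumeration over sign assignments for random
        tie-free inputs up to n = 12."""
        rng = np.random.default_rng(17)
        for n in (5, 8, 12):
            a = rng.permutation(n * 3)[:n].astype(float)
            b = rng.permutation(n * 3)[:n].astype(float)
            d = a - b
            d = np.where(d == 0, 1.0, d)
            a = b + d
            w, p = wilcoxon_signed_rank(a, b, mode="exact")
            ranks = pd.Series(np.abs(d)).rank(method="average").to_numpy()
            mu = ranks.sum() / 2
            dev = abs(ranks[d > 0].sum() - mu)
            count = sum(
                abs(np.dot(s, ranks) - mu) >= dev - 1e-12
                for s in itertools.product((0.0, 1.0), repeat=n))
            assert p == pytest.approx(count / 2 ** n)


class TestMannWhitney:
    def test_cohort_latent_u_statistic(self, fixture):
        """Failure-group latent counts dominate: U = 24 of max 28."""
        c = fixture.table.counts()
        fail = [p for p, o in fixture.outcome.items() if o == "failure"]
        succ = [p for p, o in fixture.outcome.items() if o == "success"]
        u, _ = mann_whitney(c.loc[fail, "sim_only"],
                            c.loc[succ, "sim_only"],
                            mode="tie_corrected_normal")
        assert u == pytest.approx(24.0)

    def test_identical_groups_exact_p_is_one(self):
        u, p = mann_whitney([1, 2, 3], [1, 2, 3], mode="exact_permutation")
        assert p == pytest.approx(1.0)

    def test_exact_and_normal_agree_on_cohort_decision(self, fixture):
        c = fixture.table.counts()
        fail = [p for p, o in fixture.outcome.items() if o == "failure"]
        succ = [p for p, o in fixture.outcome.items() if o == "success"]
        _, p_exact = mann_whitney(c.loc[fail, "sim_only"],
                                  c.loc[succ, "sim_only"],
                                  mode="exact_permutation")
        _, p_norm = mann_whitney(c.loc[fail, "sim_only"],
                                 c.loc[succ, "sim_only"],
                                 mode="tie_corrected_normal")
        assert (p_exact < 0.05) == (p_norm < 0.05)

    def test_normal_mode_matches_scipy(self):
        """Tie-corrected normal approximation against scipy's
        implementation (no continuity correction)."""
        rng = np.random.default_rng(3)
        x = rng.integers(0, 5, 9).astype(float)
        y = rng.integers(0, 5, 6).astype(float)
        u, p = mann_whitney(x, y, mode="tie_corrected_normal")
        ref = stats.mannwhitneyu(x, y, alternative="two-sided",
                                 method="asymptotic", use_continuity=False)
        assert u == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_exact_agrees_with_enumeration_for_small_groups(self):
        rng = np.random.default_rng(23)
        x = rng.integers(0, 4, 5).astype(float)
        y = rng.integers(0, 4, 4).astype(float)
        u_obs, p = mann_whitney(x, y, mode="exact_permutation")
        pooled = np.concatenate([x, y])
        mu = x.size * y.size / 2
        dev = abs(u_obs - mu)
        count = total = 0
        for comb in itertools.combinations(range(pooled.size), x.size):
            sel = np.zeros(pooled.size, bool)
            sel[list(comb)] = True
            xs, ys = pooled[sel], pooled[~sel]
            u = (xs[:, None] > ys[None, :]).sum() \
                + 0.5 * (xs[:, None] == ys[None, :]).sum()
            total += 1
            count += abs(u - mu) >= dev - 1e-12
        assert p == pytest.approx(count / total)

    def test_empty_group_rejected(self):
        with pytest.raises(UndefinedTestError):
            mann_whitney([], [1.0])


class TestGroupComparison:
    def test_printed_group_statistics(self, fixture):
        """Latent-driver burden by outcome: failure 2 [2; 2] vs success
        0.5 [0; 1.75] (type-6) and p < 0.05."""
        gc = group_comparison(fixture)
        lat = gc["latent"]
        assert lat["failure"]["median"] == 2
        assert lat["failure"]["iqr"] == [2, 2]
        assert lat["success"]["median"] == 0.5
        assert lat["success"]["iqr"] == pytest.approx([0.0, 1.75])
        assert lat["p"] < 0.05
        assert gc["sim"]["failure"]["median"] == 4
        assert gc["sim"]["success"]["median"] == 3.5
        assert gc["sim"]["success"]["iqr"] == pytest.approx([1.5, 4.0])
        assert gc["firm"]["success"]["median"] == 2.5
        assert gc["firm"]["success"]["iqr"] == pytest.approx([1.25, 3.75])

    def test_abstract_convention_tukey_hinges(self, fixture):
        """Under fold-median hinges the success-group latent IQR upper
        bound reads 1.5 instead of 1.75."""
        gc = group_comparison(fixture, method="tukey_hinges")
        assert gc["latent"]["success"]["iqr"] == pytest.approx([0.0, 1.5])

    def test_nonsignificant_comparisons_stay_nonsignificant(self, fixture):
        gc = group_comparison(fixture)
        assert gc["sim"]["p"] > 0.05
        assert gc["firm"]["p"] > 0.05


class TestSyntheticCohortRecovery:
    def test_latent_count_mean_matches_generating_expectation(self):
        """500 synthetic cohorts through the stochastic observer: the mean
        number of latent regions matches 38*(1 - sensitivity)."""
        from rotorsim.substrate import ObserverModel, observe_regions
        fx = load_cohort_fixture()
        counts = fx.table.counts()
        all_regions = set(range(1, 8))
        model = ObserverModel()
        rng = np.random.default_rng(31)
        expect = 38 * (1 - model.sensitivity)
        totals = []
        for _ in range(500):
            latent = 0
            for patient in counts.index:
                sim = set(range(1, int(counts.loc[patient, "sim"]) + 1))
                obs = observe_regions(sim, all_regions, model, rng=rng)
                latent += len(sim - obs)
            totals.append(latent)
        assert np.mean(totals) == pytest.approx(expect, rel=0.05)
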
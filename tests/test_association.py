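"""Allele-group ANOVA, Duncan's multiple range test, favorable alleles and
pyramiding summaries."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from indelpanel.association import (
    FavorableRule,
    allele_group_anova,
    classify_alleles,
    duncan_mrt,
    pyramid_summary,
    significance_label,
)
from indelpanel.markers import HET_AB, HOM_A, HOM_B, PhenotypeTable
from indelpanel.refpanel import reference_association_results

from conftest import make_table


def panel(group_values, het_values=None):
    """One-marker genotype table + GL phenotype from per-group value lists."""
    a_vals, b_vals = group_values
    calls = [[HOM_A]] * len(a_vals) + [[HOM_B]] * len(b_vals)
    y = list(a_vals) + list(b_vals)
    if het_values is not None:
        calls += [[HET_AB]] * len(het_values)
        y += list(het_values)
    tab = make_table(calls)
    ph = PhenotypeTable(
        tab.accession_ids,
        pd.DataFrame({"GL": y}, index=tab.accession_ids),
    )
    return tab, ph


class TestAnova:
    def test_null_case_shared_letter(self):
        rng = np.random.default_rng(0)
        a = rng.normal(8, 0.5, 40)
        b = a + 0.0  # identical distribution, same values
        tab, ph = panel((a, b))
        res = allele_group_anova(tab, ph, "M1", "GL")
        assert res.f_statistic == pytest.approx(0.0, abs=1e-10)
        assert {g.letter for g in res.groups} == {"a"}

    def test_two_groups_f_equals_t_squared(self):
        rng = np.random.default_rng(1)
        a = rng.normal(7.4, 0.6, 30)
        b = rng.normal(8.4, 0.9, 50)
        tab, ph = panel((a, b))
        res = allele_group_anova(tab, ph, "M1", "GL")
        t, p = stats.ttest_ind(a, b, equal_var=True)
        assert res.f_statistic == pytest.approx(t**2)
        assert res.p_value == pytest.approx(p)

    def test_published_effect_size_detected(self):
        """Groups drawn at the published GL contrast (7.34 vs 8.41, n=60/128)
        separate at p < 0.0001 with distinct letters."""
        rng = np.random.default_rng(2)
        a = rng.normal(7.34, 0.578, 60)
        b = rng.normal(8.41, 0.890, 128)
        tab, ph = panel((a, b))
        res = allele_group_anova(tab, ph, "M1", "GL")
        assert res.p_value < 1e-4
        ga, gb = res.group("A"), res.group("B")
        assert gb.letter == "a" and ga.letter == "b"

    def test_het_group_included_only_when_large(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(8, 0.5, 30), rng.normal(8, 0.5, 30)
        tab, ph = panel((a, b), het_values=rng.normal(8, 0.5, 5))
        res = allele_group_anova(tab, ph, "M1", "GL", min_group_n=20)
        assert {g.allele for g in res.groups} == {"A", "B"}
        tab, ph = panel((a, b), het_values=rng.normal(8, 0.5, 25))
        res = allele_group_anova(tab, ph, "M1", "GL", min_group_n=20)
        assert {g.allele for g in res.groups} == {"A", "B", "AB"}

    def test_too_few_groups_rejected(self):
        tab, ph = panel(([8.0, 8.1, 8.2, 8.3], []))
        with pytest.raises(ValueError, match="fewer than 2"):
            allele_group_anova(tab, ph, "M1", "GL")

    def test_type_one_error_calibrated(self):
        """Without allele effects the 5% test rejects ~5% of the time."""
        rng = np.random.default_rng(4)
        n_rep, hits = 1000, 0
        for _ in range(n_rep):
            y = rng.normal(8, 0.9, 204)
            a, b = y[:60], y[60:]
            f, p = stats.f_oneway(a, b)
            hits += p <= 0.05
        # binomial 3-sigma band around 0.05
        band = 3 * np.sqrt(0.05 * 0.95 / n_rep)
        assert abs(hits / n_rep - 0.05) < band

    def test_power_at_published_effect(self):
        """Power at the published GW8 contrast (about 1.2 pooled SDs with
        n = 60/128) exceeds 0.99 at alpha = 0.01."""
        rng = np.random.default_rng(5)
        n_rep, hits = 300, 0
        for _ in range(n_rep):
            a = rng.normal(7.34, 0.578, 60)
            b = rng.normal(8.41, 0.890, 128)
            _, p = stats.f_oneway(a, b)
            hits += p <= 0.01
        assert hits / n_rep > 0.99


class TestDuncan:
    def test_two_close_groups_share_a_letter(self):
        letters = duncan_mrt([8.0, 8.01], [30, 30], mse=0.25, df_error=58)
        assert letters == ["a", "a"]

    def test_fully_separated_means(self):
        letters = duncan_mrt([1.0, 5.0, 9.0], [20, 20, 20], mse=1e-6, df_error=57)
        assert letters == ["c", "b", "a"]

    def test_letters_in_input_order(self):
        letters = duncan_mrt([9.0, 1.0, 5.0], [20, 20, 20], mse=1e-6, df_error=57)
        assert letters == ["a", "c", "b"]

    def test_order_consistency(self):
        """A group holding 'a' never has a smaller mean than a group without
        it, unless they share another letter."""
        rng = np.random.default_rng(6)
        for _ in range(50):
            k = rng.integers(2, 6)
            means = rng.normal(8, 1, k)
            ns = rng.integers(5, 40, k)
            letters = duncan_mrt(means, ns, mse=0.5, df_error=100)
            top = max(means[i] for i in range(k))
            for i in range(k):
                if "a" in letters[i]:
                    continue
                assert means[i] < top

    def test_agrees_with_stepwise_oracle(self):
        """Letter groupings match an independent implementation of the
        stepwise range procedure on random configurations: two groups share a
        letter exactly when the procedure declares their span homogeneous."""
        rng = np.random.default_rng(7)
        dfe = 80  # fixed error df keeps the quantile table small
        q_memo = {}

        def q(p):
            if p not in q_memo:
                alpha_p = 1 - 0.95 ** (p - 1)
                q_memo[p] = stats.studentized_range.ppf(1 - alpha_p, p, dfe)
            return q_memo[p]

        for trial in range(100):
            k = int(rng.integers(2, 6))
            means = np.round(rng.normal(8, 0.8, k), 3)
            ns = rng.integers(10, 30, k)
            mse = float(rng.uniform(0.1, 1.0))
            letters = duncan_mrt(means, ns, mse, dfe)
            # oracle: explicit recursion over spans of the sorted means
            order = np.argsort(-means)
            sm = means[order]
            n_h = k / np.sum(1.0 / ns)
            se = np.sqrt(mse / n_h)

            from functools import lru_cache

            @lru_cache(maxsize=None)
            def homogeneous(i, j):
                if i == j:
                    return True
                rp = q(j - i + 1) * se
                if sm[i] - sm[j] <= rp:
                    return True
                # protected if inside a larger homogeneous span
                return any(
                    homogeneous(a, b)
                    for a in range(0, i + 1)
                    for b in range(j, k)
                    if (a, b) != (i, j) and b - a > j - i
                )

            for x in range(k):
                for y in range(x + 1, k):
                    share = bool(set(letters[order[x]]) & set(letters[order[y]]))
                    assert share == homogeneous(x, y), (
                        trial, means.tolist(), ns.tolist(), mse, letters
                    )

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            duncan_mrt([1.0, 2.0], [5, 5], mse=0.0, df_error=8)
        with pytest.raises(ValueError):
            duncan_mrt([1.0, 2.0], [5, 5], mse=0.5, df_error=0)


class TestFavorableAlleles:
    def test_published_favorable_set(self):
        assoc = reference_association_results("GL")
        cls = classify_alleles(assoc, FavorableRule())
        fav = {(c.marker_id, c.allele) for c in cls if c.favorable}
        assert fav == {
            ("GS3-InDel", "B"),
            ("GS7-InDel", "A"),
            ("GS7-InDel", "B"),
            ("GW8-InDel", "B"),
            ("GW8-InDel1A", "B"),
            ("GW8-InDel2B", "B"),
            ("GS2-InDel1A", "B"),
            ("GS2-InDel2B", "A"),
        }

    def test_minor_allele_never_favorable(self):
        assoc = reference_association_results("GL")
        rule = FavorableRule(min_group_n=200)  # everything minor
        cls = classify_alleles(assoc, rule)
        assert not any(c.favorable for c in cls)

    def test_nonsignificant_marker_never_favorable(self):
        assoc = reference_association_results("GL")
        cls = classify_alleles(assoc, FavorableRule())
        by_key = {(c.marker_id, c.allele): c for c in cls}
        # qPE9~1 B beats the threshold with letter 'a' but p = 0.32
        assert not by_key[("qPE9~1-InDel", "B")].favorable


class TestPyramiding:
    def test_published_nonfavorable_mean(self):
        assoc = reference_association_results("GL")
        cls = classify_alleles(assoc, FavorableRule())
        rep = pyramid_summary(cls, assoc, "GL")
        nfa = sorted(round(c.mean, 2) for c in rep.non_favorable)
        assert nfa == [7.34, 7.42, 7.57, 7.64, 7.66, 7.81, 7.90]
        assert rep.nfa_mean == pytest.approx(53.34 / 7)
        assert round(rep.nfa_mean, 2) == 7.62

    def test_single_favorable_group(self):
        assoc = reference_association_results("GL")[:1]  # qPE9~1 only
        # force it favorable by lowering alpha requirement
        rule = FavorableRule(alpha=0.5)
        cls = classify_alleles(assoc, rule)
        rep = pyramid_summary(cls, assoc, "GL", alpha=0.5)
        assert len(rep.favorable) == 1
        assert rep.fa_sd == 0.0
        assert rep.fa_mean == rep.favorable[0].mean

    def test_fa_and_nfa_disjoint(self):
        assoc = reference_association_results("GL")
        cls = classify_alleles(assoc, FavorableRule())
        rep = pyramid_summary(cls, assoc, "GL")
        fa = {(c.marker_id, c.allele) for c in rep.favorable}
        nfa = {(c.marker_id, c.allele) for c in rep.non_favorable}
        assert not fa & nfa

    def test_significant_difference_between_sets(self):
        assoc = reference_association_results("GL")
        cls = classify_alleles(assoc, FavorableRule())
        rep = pyramid_summary(cls, assoc, "GL")
        assert rep.p_value < 0.01


def test_significance_labels():
    assert significance_label(0.005) == "**"
    assert significance_label(0.03) == "*"
    assert significance_label(0.08) == "+"
    assert significance_label(0.5) == ""
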
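"""Haplotype construction, Duncan's multiple range test, favorability calls."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from gmcqtl import haplotypes as hap
from gmcqtl.core_io import MISSING, TRAITS, GeneModel
from gmcqtl.haplotypes import (ALPHAS, DuncanResult, build_haplotypes,
                               classify_favorable, duncan_mrt, star_level)

from conftest import make_genotypes

GENE = GeneModel("OsTest", "1", 500, 100_000)


def pheno_frame(ids, trait_values, subset="X", trait="Zn"):
    df = pd.DataFrame({"accession_id": ids, "subset": subset})
    for t in TRAITS:
        df[t] = 1.0
    df[trait] = trait_values
    return df


class TestBuildHaplotypes:
    def test_rank_by_carrier_count(self):
        dosage = np.zeros((40, 1), dtype=np.int8)
        dosage[30:] = 2
        a = build_haplotypes(make_genotypes(dosage), GENE, "X", min_count=5)
        assert a.hap_names == ["Hap1", "Hap2"]
        assert a.hap_counts == [30, 10]
        assert a.hap_strings == ["A", "G"]    # REF first: 30 carriers

    def test_heterozygotes_excluded(self):
        dosage = np.zeros((40, 1), dtype=np.int8)
        dosage[30:] = 2
        dosage[:3] = 1
        a = build_haplotypes(make_genotypes(dosage), GENE, "X", min_count=5)
        assert a.excluded_reason[:3] == [hap.EXCLUDED_HET] * 3
        assert (a.hap_index[:3] == -1).all()
        assert a.hap_counts == [27, 10]

    def test_missing_excluded(self):
        dosage = np.zeros((20, 2), dtype=np.int8)
        dosage[10:] = 2
        dosage[0, 1] = MISSING
        a = build_haplotypes(make_genotypes(dosage), GENE, "X", min_count=2)
        assert a.excluded_reason[0] == hap.EXCLUDED_MISSING

    def test_rare_haplotypes_excluded(self):
        dosage = np.zeros((23, 1), dtype=np.int8)
        dosage[20:] = 2   # 3 carriers < min_count 5
        a = build_haplotypes(make_genotypes(dosage), GENE, "X", min_count=5)
        assert a.n_haplotypes == 1
        assert a.excluded_reason[20:] == [hap.EXCLUDED_RARE] * 3

    def test_matches_brute_force_string_grouping(self):
        rng = np.random.default_rng(14)
        dosage = rng.choice([0, 2], (40, 6)).astype(np.int8)
        G = make_genotypes(dosage)
        a = build_haplotypes(G, GENE, "X", min_count=1)
        # oracle: direct string grouping of the raw rows
        strings = ["".join("A" if d == 0 else "G" for d in row)
                   for row in dosage]
        poly = [j for j in range(6) if len({s[j] for s in strings}) > 1]
        keys = ["".join(s[j] for j in poly) for s in strings]
        for i in range(40):
            for j in range(40):
                same_oracle = keys[i] == keys[j]
                same_impl = a.hap_index[i] == a.hap_index[j]
                assert same_oracle == same_impl

    def test_carrier_counts_sum_to_subset_size(self):
        rng = np.random.default_rng(15)
        dosage = rng.choice([0, 2], (50, 4)).astype(np.int8)
        a = build_haplotypes(make_genotypes(dosage), GENE, "X", min_count=1)
        assert sum(a.hap_counts) == 50

    def test_no_polymorphic_snp_flagged_empty(self, caplog):
        with caplog.at_level("WARNING", logger="gmcqtl"):
            a = build_haplotypes(make_genotypes(np.zeros((10, 2))), GENE, "X")
        assert a.n_haplotypes == 0 and "no polymorphic" in caplog.text

    def test_identical_strings_share_haplotype_property(self):
        rng = np.random.default_rng(16)
        dosage = rng.choice([0, 1, 2, MISSING], (60, 5),
                            p=[0.45, 0.02, 0.45, 0.08]).astype(np.int8)
        a = build_haplotypes(make_genotypes(dosage), GENE, "X", min_count=1)
        seen = {}
        for i in range(60):
            if a.hap_index[i] < 0:
                continue
            key = tuple(dosage[i])
            if key in seen:
                assert a.hap_index[i] == seen[key]
            seen[key] = a.hap_index[i]


class TestDuncanMrt:
    def test_two_groups_equal_n_matches_pooled_t_rule(self):
        """With two groups, Duncan reduces to the pooled t-test exactly
        (q(2, df) = sqrt(2) * t(df)); agreement over a randomized sweep."""
        for rep in range(200):
            rng = np.random.default_rng(rep)
            n1, n2 = rng.integers(3, 25, 2)
            shift = rng.uniform(0, 1.5)
            a = rng.normal(0, 1, n1)
            b = rng.normal(shift, 1, n2)
            res = duncan_mrt({"A": a, "B": b}, alpha=0.05)
            t = stats.ttest_ind(a, b)   # pooled-variance two-sample t
            assert res.any_separation == bool(t.pvalue < 0.05), rep

    def test_identical_groups_single_letter(self):
        res = duncan_mrt({"A": [5.0, 5.0, 5.0], "B": [5.0, 5.0],
                          "C": [5.0, 5.0, 5.0]}, 0.05)
        assert res.letters == ["a", "a", "a"]
        assert not res.any_separation

    def test_null_any_separation_rate_is_duncans_full_range_level(self):
        """Under the complete null the any-separation event is the full-range
        test at the protection level 1-(1-a)^(k-1); for k=5, a=0.05 that is
        0.185 — the well-known liberal per-experiment error of Duncan's
        procedure.  Monte-Carlo with a frozen seed must reproduce it."""
        rng = np.random.default_rng(123)
        hits = 0
        n_rep = 2000
        for _ in range(n_rep):
            g = {f"H{i}": rng.normal(0, 1, 20) for i in range(5)}
            hits += duncan_mrt(g, 0.05).any_separation
        rate = hits / n_rep
        assert 0.15 <= rate <= 0.22   # theory 0.1855, MC SE ~0.009

    def test_empty_group_dropped_with_warning(self, caplog):
        with caplog.at_level("WARNING", logger="gmcqtl"):
            res = duncan_mrt({"A": [1.0, 2.0, 1.5], "B": [],
                              "C": [1.2, 1.9, 1.4]}, 0.05)
        assert res.group_names == ["A", "C"] and "dropped" in caplog.text

    def test_single_group_ns(self):
        res = duncan_mrt({"A": [1.0, 2.0]}, 0.05)
        assert not res.any_separation and res.letters == ["a"]

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(st.integers(0, 10_000))
    def test_letter_display_validity_and_monotonicity(self, seed):
        rng = np.random.default_rng(seed)
        k = int(rng.integers(2, 6))
        groups = {f"H{i}": rng.normal(rng.uniform(0, 2), 1,
                                      int(rng.integers(4, 15)))
                  for i in range(k)}
        prev_sep = None
        for alpha in ALPHAS:     # decreasing alpha = increasing stringency
            res = duncan_mrt(groups, alpha)
            # letters valid: share a letter iff not separated
            for a in range(k):
                for b in range(k):
                    share = bool(set(res.letters[a]) & set(res.letters[b]))
                    if a != b:
                        assert share == (not res.separated[a, b])
            # pairs separated at stricter alpha separated at looser alpha
            if prev_sep is not None:
                assert not (res.separated & ~prev_sep).any()
            prev_sep = res.separated.copy()


class TestStarLevel:
    def _planted(self, seed, effect=2.0, sd=0.5, n=200):
        rng = np.random.default_rng(seed)
        dosage = np.zeros((n, 1), dtype=np.int8)
        dosage[: n // 3] = 2
        G = make_genotypes(dosage)
        a = build_haplotypes(G, GENE, "X", min_count=5)
        inc = np.where(dosage[:, 0] == 2, effect, 0.0)
        y = 16.0 + inc + rng.normal(0, sd, n)
        pheno = pheno_frame(G.accession_ids, y, trait="Zn")
        return star_level(GENE, "Zn", "X", a, pheno)

    def test_planted_effect_detected_in_19_of_20(self):
        hits = sum(self._planted(seed).star != "ns" for seed in range(20))
        assert hits >= 19

    def test_strong_effect_reaches_four_stars(self):
        assert self._planted(0).star == "****"

    def test_permuted_phenotype_mostly_ns(self):
        stars = []
        for seed in range(40):
            rng = np.random.default_rng(2000 + seed)
            dosage = np.zeros((100, 1), dtype=np.int8)
            dosage[:40] = 2
            G = make_genotypes(dosage)
            a = build_haplotypes(G, GENE, "X", min_count=5)
            y = rng.normal(16.0, 1.0, 100)   # no association
            res = star_level(GENE, "Zn", "X", a,
                             pheno_frame(G.accession_ids, y, trait="Zn"))
            stars.append(res.star)
        # two-group null: any-separation rate = alpha = 5%
        assert sum(s != "ns" for s in stars) <= 7

    def test_fewer_than_two_haplotypes_ns_with_reason(self):
        G = make_genotypes(np.zeros((30, 1)))
        a = build_haplotypes(G, GENE, "X", min_count=5)
        res = star_level(GENE, "Zn", "X", a,
                         pheno_frame(G.accession_ids, np.ones(30)))
        assert res.star == "ns" and "fewer than 2" in res.reason


def _mock_result(hap_names, means, sep_pairs, trait, mse=0.1):
    """DuncanResult with a hand-built separation pattern at alpha 0.05."""
    k = len(hap_names)
    sep = np.zeros((k, k), dtype=bool)
    for a, b in sep_pairs:
        sep[a, b] = sep[b, a] = True
    mrt = hap.MrtResult(hap_names, np.full(k, 30), np.asarray(means, float),
                        np.full(k, 0.3), mse, 60, 0.05, ["?"] * k, sep)
    return DuncanResult("g", trait, "X", list(hap_names), mrt.n, mrt.means,
                        mrt.sds, mse, 60, {0.05: mrt.letters}, {0.05: mrt},
                        "*" if sep.any() else "ns")


class TestClassifyFavorable:
    def test_higher_fe_zn_cd_ns_is_favorable(self):
        """The flagship pattern: raises both micronutrients, no Cd effect."""
        haps = ["Hap1", "Hap2", "Hap3"]
        res = {
            "Fe": _mock_result(haps, [2.2, 2.3, 2.9], [(2, 0), (2, 1)], "Fe"),
            "Zn": _mock_result(haps, [15.9, 16.1, 17.2], [(2, 0), (2, 1)], "Zn"),
            "Cd": _mock_result(haps, [0.01, 0.011, 0.010], [], "Cd"),
        }
        calls = {c.haplotype: c.verdict for c in classify_favorable(res)}
        assert calls["Hap3"] == "favorable"
        assert calls["Hap1"] == "unfavorable"   # significantly lower Fe and Zn

    def test_higher_fe_lower_zn_is_conditional(self):
        """Micronutrient gain traded against a loss: second-choice haplotype."""
        haps = ["Hap1", "Hap2"]
        res = {
            "Fe": _mock_result(haps, [2.9, 2.2], [(0, 1)], "Fe"),
            "Zn": _mock_result(haps, [15.0, 16.8], [(0, 1)], "Zn"),
            "Cd": _mock_result(haps, [0.012, 0.011], [], "Cd"),
        }
        calls = {c.haplotype: c.verdict for c in classify_favorable(res)}
        assert calls["Hap1"] == "conditional"

    def test_cd_increase_without_gain_is_unfavorable(self):
        haps = ["Hap1", "Hap2"]
        res = {
            "Fe": _mock_result(haps, [2.4, 2.4], [], "Fe"),
            "Zn": _mock_result(haps, [16.0, 16.1], [], "Zn"),
            "Cd": _mock_result(haps, [0.02, 0.008], [(0, 1)], "Cd"),
        }
        calls = {c.haplotype: c.verdict for c in classify_favorable(res)}
        assert calls["Hap1"] == "unfavorable"
        # Hap2 is lower in Cd but gains no micronutrient: neutral by the rule
        assert calls["Hap2"] == "neutral"

    def test_all_ns_is_neutral(self):
        haps = ["Hap1", "Hap2"]
        res = {t: _mock_result(haps, [1.0, 1.0], [], t)
               for t in ("Fe", "Zn", "Cd")}
        assert all(c.verdict == "neutral" for c in classify_favorable(res))

    def test_missing_trait_skipped(self, caplog):
        haps = ["Hap1", "Hap2"]
        res = {"Fe": _mock_result(haps, [1.0, 1.0], [], "Fe")}
        with caplog.at_level("WARNING", logger="gmcqtl"):
            assert classify_favorable(res) == []
        assert "missing" in caplog.text


class TestParameterRecovery:
    def test_planted_effect_rank_order_recovered(self):
        """Planted per-haplotype effects recovered as the rank order of
        haplotype means (Kendall tau >= 0.8 on average)."""
        taus = []
        for rep in range(20):
            rng = np.random.default_rng(3000 + rep)
            n = 300
            hap_of = rng.integers(0, 4, n)
            # 4 haplotypes from 2 SNPs
            snp_pattern = np.array([[0, 0], [0, 2], [2, 0], [2, 2]],
                                   dtype=np.int8)
            dosage = snp_pattern[hap_of]
            G = make_genotypes(dosage)
            effects = np.array([0.0, 1.0, 2.0, 3.0])
            spread = effects.max() - effects.min()
            y = 10.0 + effects[hap_of] + rng.normal(0, spread / 2, n)
            a = build_haplotypes(G, GENE, "X", min_count=5)
            means, truth = [], []
            for h, s in enumerate(a.hap_strings):
                members = a.members(h)
                means.append(y[members].mean())
                truth.append(effects[hap_of[members[0]]])
            taus.append(stats.kendalltau(means, truth).statistic)
        assert np.mean(taus) >= 0.8


class TestPlotting:
    def test_plot_files_created_and_deterministic(self, tmp_path):
        rng = np.random.default_rng(17)
        dosage = np.zeros((60, 1), dtype=np.int8)
        dosage[25:] = 2
        G = make_genotypes(dosage)
        a = build_haplotypes(G, GENE, "X", min_count=5)
        y = 16.0 + np.where(dosage[:, 0] == 2, 1.0, 0.0) \
            + rng.normal(0, 0.5, 60)
        res = star_level(GENE, "Zn", "X", a,
                         pheno_frame(G.accession_ids, y, trait="Zn"))
        p1 = hap.plot_haplotype_traits([res], tmp_path / "a")
        p2 = hap.plot_haplotype_traits([res], tmp_path / "b")
        assert p1[0].exists() and p1[0].stat().st_size > 0
        assert p1[0].read_bytes() == p2[0].read_bytes()
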
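"""Site counting against brute-force codon enumeration, pi against the
pairwise-haplotype identity, recovery of dosed diversity, group tests."""

import itertools

import numpy as np
import pandas as pd
import pytest

from benthoscan.selection import (
    CdsFrameError,
    SelectionResult,
    codon_synonymous_fractions,
    compare_groups,
    count_sites,
    count_sites_set,
    flag_positive_candidates,
    pi_per_gene,
    summarize_pi,
)
from benthoscan.synthetic import generate_cds_set, generate_variants

from _oracles import oracle_pi_from_haplotypes, oracle_site_counts


def variants_df(rows):
    return pd.DataFrame(rows, columns=["gene", "pos", "ref", "alt", "effect",
                                       "alt_count", "n_chrom"])


class TestSiteCounts:
    def test_fourfold_third_position_codon(self):
        # GGG: third position fully synonymous, first two fully not
        assert codon_synonymous_fractions("GGG") == (0.0, 0.0, 1.0)
        sc = count_sites("GGG")
        assert sc.l_s == pytest.approx(1.0)
        assert sc.l_n == pytest.approx(2.0)

    def test_site_totals_conserve_cds_length(self):
        cds = next(iter(generate_cds_set(1, seed=3, min_codons=100,
                                         max_codons=100).values()))
        sc = count_sites(cds)
        assert sc.l_n + sc.l_s == pytest.approx(len(cds))

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_codon_enumeration(self, seed):
        cds = next(iter(generate_cds_set(1, seed=seed, min_codons=30,
                                         max_codons=60).values()))
        sc = count_sites(cds)
        l_n, l_s = oracle_site_counts(cds)
        assert sc.l_n == pytest.approx(l_n)
        assert sc.l_s == pytest.approx(l_s)

    def test_callable_mask_restricts_totals(self):
        cds = "GGGGGG"
        mask = [True] * 3 + [False] * 3
        sc = count_sites(cds, mask)
        assert sc.total == pytest.approx(3.0)
        assert sc.l_s == pytest.approx(1.0)

    @pytest.mark.parametrize("bad", ["ATGTA", "ATGTAAGGG", "ATGNNNGGG"])
    def test_frame_violations_raise(self, bad):
        with pytest.raises(CdsFrameError):
            count_sites(bad)


class TestPiEstimator:
    def test_no_variants_gives_zero_pi_and_missing_ratio(self):
        sites = pd.DataFrame({"l_n": [225.0], "l_s": [75.0]}, index=["g1"])
        res = pi_per_gene(variants_df([]), sites)
        assert res.per_gene.loc["g1", "pi_n"] == 0
        assert res.per_gene.loc["g1", "pi_s"] == 0
        assert np.isnan(res.per_gene.loc["g1", "ratio"])

    def test_single_snp_hand_arithmetic(self):
        # p = 0.5, n = 4: h = (4/3) * 2 * 0.25 = 0.6667; / L_S 75 = 0.008889
        sites = pd.DataFrame({"l_n": [225.0], "l_s": [75.0]}, index=["g1"])
        v = variants_df([("g1", 3, "A", "G", "synonymous", 2, 4)])
        res = pi_per_gene(v, sites)
        assert res.per_gene.loc["g1", "pi_s"] == pytest.approx(0.0088889, rel=1e-4)
        assert res.per_gene.loc["g1", "pi_n"] == 0

    def test_variant_for_unknown_gene_errors(self):
        sites = pd.DataFrame({"l_n": [10.0], "l_s": [5.0]}, index=["g1"])
        v = variants_df([("gX", 1, "A", "G", "synonymous", 1, 4)])
        with pytest.raises(ValueError, match="gX"):
            pi_per_gene(v, sites)

    @pytest.mark.parametrize("seed", range(8))
    def test_identity_with_average_pairwise_differences(self, seed):
        """Frequency-based pi with the n/(n-1) correction is exactly the
        mean per-pair difference count over explicit haplotypes."""
        rng = np.random.default_rng(seed)
        n, L = int(rng.integers(3, 9)), 30
        classes = [("synonymous", "nonsynonymous")[i % 2] for i in range(L)]
        hap = np.zeros((n, L), dtype=int)
        rows = []
        for pos in rng.choice(L, size=8, replace=False):
            a = int(rng.integers(1, n))
            carriers = rng.choice(n, size=a, replace=False)
            hap[carriers, pos] = 1
            rows.append(("g", pos + 1, "A", "G", classes[pos], a, n))
        l_s = classes.count("synonymous")
        l_n = classes.count("nonsynonymous")
        sites = pd.DataFrame({"l_n": [float(l_n)], "l_s": [float(l_s)]},
                             index=["g"])
        res = pi_per_gene(variants_df(rows), sites)
        o_n, o_s = oracle_pi_from_haplotypes(hap, classes, l_n, l_s)
        assert res.per_gene.loc["g", "pi_n"] == pytest.approx(o_n)
        assert res.per_gene.loc["g", "pi_s"] == pytest.approx(o_s)

    def test_multiallelic_site_heterozygosity(self):
        # alleles A/G/T at counts 2/1/1 of n=4: 1 - sum p^2 = 1 - 0.375
        # h = 4/3 * 0.625 = 0.8333
        sites = pd.DataFrame({"l_n": [0.0], "l_s": [10.0]}, index=["g"])
        v = variants_df([("g", 1, "A", "G", "synonymous", 2, 4),
                         ("g", 1, "A", "T", "synonymous", 1, 4)])
        res = pi_per_gene(v, sites)
        assert res.per_gene.loc["g", "pi_s"] == pytest.approx(0.8333 / 10, rel=1e-3)

    def test_dosed_diversity_recovered_within_15_percent(self):
        # stochastic recovery averaged over 5 seeds of 100 genes each
        est_s, est_n = [], []
        for seed in range(11, 16):
            cds = generate_cds_set(100, seed=seed, min_codons=100,
                                   max_codons=100)
            v = generate_variants(cds, 96, 0.022, 0.003, seed=seed)
            res = pi_per_gene(v, count_sites_set(cds))
            est_s.append(res.summary["mean_pi_s"])
            est_n.append(res.summary["mean_pi_n"])
        assert np.mean(est_s) == pytest.approx(0.022, rel=0.15)
        assert np.mean(est_n) == pytest.approx(0.003, rel=0.15)

    def test_zero_targets_give_empty_table(self):
        cds = generate_cds_set(5, seed=1, min_codons=50, max_codons=50)
        v = generate_variants(cds, 96, 0.0, 0.0, seed=1)
        assert len(v) == 0

    def test_single_chromosome_errors(self):
        cds = generate_cds_set(1, seed=1, min_codons=50, max_codons=50)
        with pytest.raises(ValueError, match="chromosomes"):
            generate_variants(cds, 1, 0.01, 0.01, seed=1)

    def test_internal_stop_rejected_by_generator(self):
        with pytest.raises(CdsFrameError, match="stop"):
            generate_variants({"bad": "ATGTAAGGG"}, 4, 0.01, 0.0, seed=1)

    def test_summary_ratio_convention(self):
        per_gene = pd.DataFrame(
            {"pi_n": [0.003], "pi_s": [0.022], "ratio": [0.003 / 0.022]},
            index=["g"])
        s = summarize_pi(per_gene)
        assert round(s["ratio_of_means"], 2) == 0.14


class TestGroupComparisons:
    def _result(self, ratios):
        per_gene = pd.DataFrame({
            "pi_n": 0.01, "pi_s": 0.01,
            "ratio": list(ratios)},
            index=[f"g{i}" for i in range(len(ratios))])
        return SelectionResult(per_gene, summarize_pi(per_gene))

    def test_identical_groups_are_not_distinguished(self):
        res = self._result([0.2, 0.3, 0.4, 0.2, 0.3, 0.4])
        groups = {"grp": {f"g{i}": ("A" if i < 3 else "B") for i in range(6)}}
        table = compare_groups(res, groups)
        assert table.loc[0, "median_a"] == table.loc[0, "median_b"]
        assert table.loc[0, "p_value"] > 0.9

    def test_planted_threefold_shift_detected(self):
        rng = np.random.default_rng(0)
        a = rng.lognormal(np.log(0.3), 0.4, size=200)
        b = rng.lognormal(np.log(0.1), 0.4, size=200)
        res = self._result(list(a) + list(b))
        groups = {"grp": {f"g{i}": ("A" if i < 200 else "B") for i in range(400)}}
        table = compare_groups(res, groups)
        assert table.loc[0, "median_a"] > table.loc[0, "median_b"]
        assert table.loc[0, "p_value"] < 0.05

    def test_single_gene_group_warns_and_skips(self):
        res = self._result([0.1, 0.2, 0.3])
        groups = {"grp": {"g0": "A", "g1": "A", "g2": "B"}}
        with pytest.warns(UserWarning, match="skipped"):
            table = compare_groups(res, groups)
        assert len(table) == 0


class TestPositiveCandidates:
    def _result(self, ratios):
        per_gene = pd.DataFrame(
            {"pi_n": 0.01, "pi_s": 0.01, "ratio": ratios},
            index=[f"g{i}" for i in range(len(ratios))])
        return SelectionResult(per_gene, summarize_pi(per_gene))

    def test_no_candidates_no_enrichments(self):
        res = self._result([0.1] * 10)
        de = pd.DataFrame({"gene": ["g0"], "condition": ["c"],
                           "direction": ["up"]})
        cands, table = flag_positive_candidates(res, de)
        assert cands == set() and len(table) == 0

    def test_planted_candidates_enrich_their_condition(self):
        # 20 high-ratio genes, all upregulated in "mating"; universe 200
        ratios = [2.0] * 20 + [0.1] * 180
        res = self._result(ratios)
        up = [dict(gene=f"g{i}", condition="mating", direction="up")
              for i in range(20)]
        up += [dict(gene=f"g{i}", condition="control", direction="up")
               for i in range(50, 70)]
        cands, table = flag_positive_candidates(res, pd.DataFrame(up))
        row = table.set_index("label").loc["mating"]
        assert row["enriched"]
        assert not table.set_index("label").loc["control", "enriched"]

    def test_zero_cutoff_makes_every_tested_gene_a_candidate(self):
        res = self._result([0.1] * 5)
        de = pd.DataFrame({"gene": ["g0", "g1"], "condition": ["c", "c"],
                           "direction": ["up", "up"]})
        cands, table = flag_positive_candidates(res, de, ratio_cutoff=0.0)
        assert len(cands) == 5
        assert table.loc[0, "overlap"] == 2
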
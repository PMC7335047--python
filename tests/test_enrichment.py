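"""Expression filters, hypergeometric enrichment vs exact enumeration,
pleiotropy classes and tree-based expression divergence."""

import numpy as np
import pandas as pd
import pytest

from benthoscan.enrichment import (
    ExpressionMatrix,
    apply_expression_filters,
    classify_pleiotropic,
    compute_tpm,
    divergence_by_family_size,
    expression_divergence,
    hypergeom_enrichment,
)
from benthoscan.synthetic import generate_expression

from _oracles import oracle_hypergeom_enumerate, oracle_hypergeom_upper


def expr_matrix(tpm_rows, count_rows=None, conditions=None):
    genes = [f"g{i}" for i in range(len(tpm_rows))]
    samples = [f"s{j}" for j in range(len(tpm_rows[0]))]
    tpm = pd.DataFrame(tpm_rows, index=genes, columns=samples)
    counts = pd.DataFrame(count_rows if count_rows is not None else tpm_rows,
                          index=genes, columns=samples)
    cond = pd.Series(conditions or {s: s for s in samples})
    return ExpressionMatrix(counts, tpm, cond)


class TestFilters:
    def test_tpm_exactly_two_counts_as_expressed(self):
        expr = apply_expression_filters(expr_matrix([[2.0, 0.0], [1.99, 1.99]]))
        assert expr.expressed.tolist() == [True, False]

    def test_cpm_boundary_needs_three_samples(self):
        # library sizes equal; gene0 has CPM > 1 in 2 samples, gene1 in 3
        counts = [[5000, 5000, 0, 0], [5000, 5000, 5000, 0],
                  [1_000_000, 1_000_000, 1_000_000, 1_000_000]]
        expr = apply_expression_filters(expr_matrix(counts, counts))
        assert expr.retained.tolist() == [False, True, True]

    def test_toy_matrix_flags_match_hand_computation(self):
        tpm = [[0.0, 3.0], [1.0, 1.5], [2.0, 2.0], [0.0, 0.0], [5.0, 0.1]]
        counts = [[10, 30], [1, 1], [40, 40], [0, 0], [100, 2]]
        expr = apply_expression_filters(expr_matrix(tpm, counts))
        assert expr.expressed.tolist() == [True, False, True, False, True]
        # library sizes 151 and 73; CPM > 1 means count >= 1 here, but the
        # retained rule needs >= 3 samples and there are only two
        assert expr.retained.tolist() == [False] * 5

    def test_tpm_columns_sum_to_a_million(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(rng.integers(0, 500, size=(30, 4)),
                              index=[f"g{i}" for i in range(30)])
        lengths = pd.Series(rng.integers(300, 3000, size=30),
                            index=counts.index)
        tpm = compute_tpm(counts, lengths)
        assert np.allclose(tpm.sum(axis=0), 1e6)


class TestHypergeometric:
    def test_worked_example_exact_value(self):
        # universe 20, annotation 5, target 5, overlap 4:
        # p = (C(5,4) C(15,1) + C(5,5)) / C(20,5) = 76/15504
        universe = [f"g{i}" for i in range(20)]
        ann = set(universe[:5])
        target = set(universe[:4]) | {universe[10]}
        table = hypergeom_enrichment(target, {"A": ann}, universe)
        assert table.loc[0, "overlap"] == 4
        assert table.loc[0, "p_value"] == pytest.approx(76 / 15504)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_enumeration_oracle_on_small_universes(self, seed):
        rng = np.random.default_rng(seed)
        M = int(rng.integers(8, 26))
        universe = [f"g{i}" for i in range(M)]
        K = int(rng.integers(1, M))
        N = int(rng.integers(1, min(M, 9)))
        ann = set(rng.choice(universe, size=K, replace=False))
        target = set(rng.choice(universe, size=N, replace=False))
        k = len(ann & target)
        table = hypergeom_enrichment(target, {"A": ann}, universe)
        assert table.loc[0, "p_value"] == pytest.approx(
            oracle_hypergeom_upper(M, K, N, k))
        if M <= 16:  # literal enumeration of all draws
            assert table.loc[0, "p_value"] == pytest.approx(
                oracle_hypergeom_enumerate(universe, ann, N, k))

    def test_single_hit_never_enriched_regardless_of_p(self):
        universe = [f"g{i}" for i in range(100)]
        table = hypergeom_enrichment({universe[0]}, {"A": {universe[0]}},
                                     universe)
        assert table.loc[0, "p_value"] < 0.05
        assert not table.loc[0, "enriched"]

    def test_zero_overlap_p_is_one(self):
        universe = [f"g{i}" for i in range(10)]
        table = hypergeom_enrichment(set(universe[:3]), {"A": set(universe[5:])},
                                     universe)
        assert table.loc[0, "p_value"] == pytest.approx(1.0)

    def test_bh_q_values_monotone_in_p(self):
        rng = np.random.default_rng(1)
        universe = [f"g{i}" for i in range(50)]
        target = set(rng.choice(universe, 10, replace=False))
        anns = {f"A{i}": set(rng.choice(universe, int(rng.integers(3, 20)),
                                        replace=False))
                for i in range(12)}
        table = hypergeom_enrichment(target, anns, universe).sort_values("p_value")
        assert table["q_value"].is_monotonic_increasing
        assert (table["q_value"] <= 1).all()

    def test_empty_universe_errors(self):
        with pytest.raises(ValueError, match="universe"):
            hypergeom_enrichment(set(), {"A": set()}, set())


class TestPleiotropy:
    def _table(self, family_conditions):
        rows = []
        for fam, n in family_conditions.items():
            for i in range(10):
                rows.append(dict(family=fam, condition=f"c{i}",
                                 enriched=i < n))
        return pd.DataFrame(rows)

    def test_boundary_at_seven_conditions(self):
        classes = classify_pleiotropic(self._table({"F7": 7, "F6": 6}))
        assert classes["F7"] == "pleiotropic"
        assert classes["F6"] != "pleiotropic"

    def test_one_condition_is_condition_specific(self):
        classes = classify_pleiotropic(self._table({"F1": 1, "F0": 0}))
        assert classes["F1"] == "condition-specific"
        assert classes["F0"] == "neither"

    def test_related_conditions_collapse_for_specificity(self):
        table = self._table({"F3": 3})
        related = {"c0": "sex", "c1": "sex", "c2": "sex"}
        assert classify_pleiotropic(table)["F3"] == "neither"
        assert (classify_pleiotropic(table, related_groups=related)["F3"]
                == "condition-specific")

    def test_planted_pleiotropic_family_recovered_end_to_end(self):
        expr, de_calls, _ = generate_expression(
            320, {f"c{i}": 3 for i in range(10)},
            {("F000", f"c{i}"): 2.0 for i in range(8)},
            seed=21, background_de_rate=0.02)
        fams = pd.Series({g: f"F{int(g[1:]) // 8:03d}"
                          for g in expr.counts.index})
        rows = []
        for cond, sub in de_calls[de_calls["direction"] == "up"].groupby("condition"):
            res = hypergeom_enrichment(
                set(sub["gene"]),
                {f: set(fams.index[fams == f]) for f in fams.unique()},
                set(fams.index))
            rows += [dict(family=r.label, condition=cond, enriched=r.enriched)
                     for r in res.itertuples()]
        classes = classify_pleiotropic(pd.DataFrame(rows))
        assert classes["F000"] == "pleiotropic"
        assert (classes.drop("F000") != "pleiotropic").all()

    def test_zero_replicates_rejected(self):
        with pytest.raises(ValueError, match="replicate"):
            generate_expression(10, {"c0": 0}, {}, seed=1)

    def test_no_planted_effects_gives_empty_call_table(self):
        _, de_calls, _ = generate_expression(20, {"c0": 3}, {}, seed=2)
        assert len(de_calls) == 0


class TestExpressionDivergence:
    def _expr(self, profiles, conditions=6):
        genes = sorted(profiles)
        cols = {}
        cond_map = {}
        for c in range(conditions):
            s = f"c{c}_r1"
            cond_map[s] = f"c{c}"
            cols[s] = [profiles[g][c] for g in genes]
        tpm = pd.DataFrame(cols, index=genes)
        return ExpressionMatrix(tpm.copy(), tpm, pd.Series(cond_map))

    def test_identical_profiles_zero_percent_divergent(self):
        prof = [10.0, 20.0, 5.0, 40.0, 1.0, 15.0]
        expr = self._expr({f"g{i}": prof for i in range(4)})
        tree = "((g0,g1),(g2,g3));"
        res = expression_divergence(tree, expr)
        assert res.percent_divergent == 0.0
        assert res.n_evaluable == 3

    def test_anticorrelated_clades_fully_divergent_at_root(self):
        up = [1.0, 2.0, 4.0, 8.0, 16.0, 32.0]
        down = list(reversed(up))
        expr = self._expr({"g0": up, "g1": up, "g2": down, "g3": down})
        res = expression_divergence("((g0,g1),(g2,g3));", expr)
        per = res.per_node.set_index("node")
        assert per.loc["n0", "divergent"]

    def test_small_families_are_excluded(self):
        prof = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        expr = self._expr({f"g{i}": prof for i in range(3)})
        res = expression_divergence("((g0,g1),g2);", expr)
        assert np.isnan(res.percent_divergent)

    def test_divergence_increases_with_dosed_shift(self):
        rng = np.random.default_rng(3)
        base = rng.lognormal(2, 0.2, size=6)
        pcts = []
        for shift in (0.0, 6.0):
            profiles = {
                "g0": base, "g1": base * rng.lognormal(0, 0.05, 6),
                "g2": base * 2.0 ** (shift * rng.normal(size=6)),
                "g3": base * 2.0 ** (shift * rng.normal(size=6)),
            }
            expr = self._expr({g: list(v) for g, v in profiles.items()})
            res = expression_divergence("((g0,g1),(g2,g3));", expr)
            pcts.append(res.percent_divergent)
        assert pcts[1] >= pcts[0]

    def test_size_comparison_reports_medians(self):
        prof = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        profiles = {}
        trees = {}
        for f in range(6):
            genes = [f"f{f}g{i}" for i in range(4)]
            for g in genes:
                profiles[g] = prof
            trees[f"fam{f}"] = f"(({genes[0]},{genes[1]}),({genes[2]},{genes[3]}));"
        expr = self._expr(profiles)
        profs = {f: expression_divergence(t, expr) for f, t in trees.items()}
        out = divergence_by_family_size(profs, size_threshold=4)
        assert out["n_large"] == 6 and out["n_small"] == 0
        assert np.isnan(out["p_value"])
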
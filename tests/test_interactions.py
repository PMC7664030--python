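import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from qsmart.interactions import (InteractionTerm, ancestor_closure,
                                 bh_adjust, build_drug_mutation_terms,
                                 build_ppi_terms, build_setlevel_terms,
                                 filter_terms, ftest_term, stats_table,
                                 score_terms)
from qsmart.io import FeatureMatrix


class TestDrugMutationCandidates:
    def test_cartesian_product_of_bits_and_residues(self, rng):
        n = 10
        values = pd.DataFrame({
            "Fingerprint_1": rng.binomial(1, 0.5, n).astype(float),
            "Fingerprint_2": rng.binomial(1, 0.5, n).astype(float),
            "PKA_10_CHA": rng.normal(size=n),
            "PKA_10_VOL": rng.normal(size=n),
            "PKA_20_MUT": rng.poisson(1, n).astype(float),
            "GO_1": rng.poisson(1, n).astype(float),
        })
        m = FeatureMatrix(values, {
            "Fingerprint_1": "drug", "Fingerprint_2": "drug",
            "PKA_10_CHA": "residue", "PKA_10_VOL": "residue",
            "PKA_20_MUT": "residue", "GO_1": "pathway"})
        cands = build_drug_mutation_terms(m)
        assert len(cands) == 6  # 2 bits x 3 residue features
        names = {c.name for c in cands}
        assert "PKA_10_CHA_X_Fingerprint_1" in names
        assert not any("GO_1" in n for n in names)  # no drug x high-level

    def test_zero_bit_gives_zero_term_values(self, tiny_matrix):
        m = tiny_matrix
        m.values["Fingerprint_10"] = 0.0
        m.values.loc[m.values.index[0], "Fingerprint_10"] = 0.0
        cands = build_drug_mutation_terms(m)
        term = next(c for c in cands
                    if c.name == "PKA_187_CHA_X_Fingerprint_10")
        prod = (m.values[term.components[0]]
                * m.values[term.components[1]])
        assert (prod == 0).all()


class TestPpiCandidates:
    def _matrix(self, rng, genes=("A", "B", "C")):
        values = pd.DataFrame({f"EXP_{g}": np.exp(rng.normal(0, 0.4, 8))
                               for g in genes})
        return FeatureMatrix(values,
                             {c: "gene" for c in values.columns})

    def test_score_boundary_strict(self, rng):
        m = self._matrix(rng)
        edges = pd.DataFrame({"protein1": ["A", "A"], "protein2": ["B", "C"],
                              "combined_score": [700, 701]})
        terms = build_ppi_terms(m, edges, kinase_genes={"A"})
        assert [t.name for t in terms] == ["EXP_A_X_EXP_C"]

    def test_self_edge_rejected(self, rng):
        m = self._matrix(rng)
        edges = pd.DataFrame({"protein1": ["A"], "protein2": ["A"],
                              "combined_score": [950]})
        assert build_ppi_terms(m, edges, kinase_genes={"A"}) == []

    def test_requires_kinase_endpoint_and_expression(self, rng):
        m = self._matrix(rng)
        edges = pd.DataFrame({"protein1": ["B", "A"], "protein2": ["C", "Z"],
                              "combined_score": [900, 900]})
        terms = build_ppi_terms(m, edges, kinase_genes={"A"})
        assert terms == []  # B-C has no kinase; Z lacks expression

    def test_term_value_is_expression_product(self):
        values = pd.DataFrame({"EXP_A": [2.0], "EXP_B": [3.0]})
        m = FeatureMatrix(values, {"EXP_A": "gene", "EXP_B": "gene"})
        edges = pd.DataFrame({"protein1": ["A"], "protein2": ["B"],
                              "combined_score": [900]})
        t = build_ppi_terms(m, edges, kinase_genes={"A"})[0]
        prod = m.values[t.components[0]] * m.values[t.components[1]]
        assert prod.iloc[0] == 6.0


class TestSetLevelCandidates:
    def _matrix(self, names, rng):
        values = pd.DataFrame({n: rng.poisson(1, 10).astype(float)
                               for n in names})
        return FeatureMatrix(values, {n: "pathway" for n in names})

    def test_parent_child_pair_excluded(self, rng):
        # lung cell differentiation is a child of lung development
        m = self._matrix(["GO_0060479", "GO_0030324", "GO_0048675"], rng)
        hier = pd.DataFrame({"child": ["GO_0060479"],
                             "parent": ["GO_0030324"]})
        ns = {c: "go" for c in m.feature_names}
        names = {t.name for t in build_setlevel_terms(m, ns, hier)}
        assert "GO_0030324_X_GO_0060479" not in names
        assert "GO_0030324_X_GO_0048675" in names

    def test_deep_ancestors_excluded(self, rng):
        m = self._matrix(["GO_A", "GO_B", "GO_C"], rng)
        hier = pd.DataFrame({"child": ["GO_A", "GO_B"],
                             "parent": ["GO_B", "GO_C"]})
        ns = {c: "go" for c in m.feature_names}
        names = {t.name for t in build_setlevel_terms(m, ns, hier)}
        assert names == set()  # A<B, B<C, and A<C transitively

    def test_four_unrelated_terms_give_six_pairs(self, rng):
        m = self._matrix([f"GO_{i}" for i in range(4)], rng)
        ns = {c: "go" for c in m.feature_names}
        assert len(build_setlevel_terms(m, ns, None)) == 6

    def test_cross_namespace_pairs_not_formed(self, rng):
        m = self._matrix(["GO_1", "REC_1"], rng)
        ns = {"GO_1": "go", "REC_1": "reaction"}
        assert build_setlevel_terms(m, ns, None) == []

    def test_cycle_raises(self):
        hier = pd.DataFrame({"child": ["A", "B"], "parent": ["B", "A"]})
        with pytest.raises(ValueError, match="cycl"):
            ancestor_closure(hier)


class TestFTest:
    def test_perfect_interaction_is_overwhelming(self, rng):
        n = 20
        a = rng.normal(size=n)
        b = rng.normal(size=n)
        y = a * b
        _, p = ftest_term(y, a * b, a, b)
        assert p < 1e-10

    def test_matches_statsmodels_nested_anova(self, rng):
        n = 40
        a = rng.normal(size=n)
        b = rng.normal(size=n)
        y = 0.5 * a - b + 0.8 * a * b + rng.normal(size=n)
        f, p = ftest_term(y, a * b, a, b)
        ones = np.ones(n)
        full = sm.OLS(y, np.column_stack([ones, a, b, a * b])).fit()
        red = sm.OLS(y, np.column_stack([ones, a, b])).fit()
        cmp = sm.stats.anova_lm(red, full)
        assert f == pytest.approx(cmp["F"].iloc[1], rel=1e-10)
        assert p == pytest.approx(cmp["Pr(>F)"].iloc[1], rel=1e-10)

    def test_five_point_manual_oracle(self):
        a = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        b = np.array([1.0, 0.0, 1.0, 0.0, 1.0])
        y = np.array([0.5, 1.0, 2.5, 2.0, 5.0])
        term = a * b
        ones = np.ones(5)

        def rss(cols):
            x = np.column_stack(cols)
            beta, *_ = np.linalg.lstsq(x, y, rcond=None)
            return float(np.sum((y - x @ beta) ** 2))

        rss_red = rss([ones, a, b])
        rss_full = rss([ones, a, b, term])
        expected_f = (rss_red - rss_full) / (rss_full / (5 - 4))
        f, _ = ftest_term(y, term, a, b)
        assert f == pytest.approx(expected_f, rel=1e-10)

    def test_zero_variance_term_rejected(self):
        n = 10
        a = np.zeros(n)
        b = np.arange(n, dtype=float)
        with pytest.raises(ValueError, match="zero-variance"):
            ftest_term(b, a * b, a, b)


class TestBhAdjustment:
    def test_hand_computed_three_values(self):
        q = bh_adjust(np.array([0.01, 0.02, 0.04]))
        assert np.allclose(q, [0.03, 0.03, 0.04])

    def test_properties_monotone_bounded(self, rng):
        p = rng.uniform(0, 1, 200)
        q = bh_adjust(p)
        assert (q >= p - 1e-12).all() and (q <= 1).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()


class TestFilterTerms:
    def _term(self, name, p, nonzero):
        t = InteractionTerm(name, "ppi", ("a", "b"))
        t.p_value, t.nonzero_count = p, nonzero
        return t

    def test_support_boundary_29_vs_30(self):
        terms = [self._term("t29", 0.001, 29), self._term("t30", 0.001, 30)]
        kept = filter_terms(terms)
        assert [t.name for t in kept] == ["t30"]

    def test_fdr_boundary(self):
        terms = [self._term("sig", 1e-6, 50), self._term("null", 0.9, 50)]
        kept = filter_terms(terms)
        assert [t.name for t in kept] == ["sig"]

    def test_all_null_retention_near_zero(self, rng):
        n = 200
        kept_total = 0
        for _ in range(5):
            values = pd.DataFrame(
                {f"x{i}": rng.normal(size=n) for i in range(20)})
            m = FeatureMatrix(values, {c: "gene" for c in values.columns})
            y = rng.normal(size=n)
            cands = [InteractionTerm(f"x{i}_X_x{j}", "ppi",
                                     (f"x{i}", f"x{j}"))
                     for i in range(20) for j in range(i + 1, 20)]
            _, tested = score_terms(m, cands, y, min_nonzero=30)
            kept_total += len(filter_terms(tested))
        assert kept_total <= 2  # BH under the global null

    def test_term_values_match_naive_product_loop(self, tiny_matrix, rng):
        y = rng.normal(size=len(tiny_matrix.values))
        cands = build_drug_mutation_terms(tiny_matrix)
        values, tested = score_terms(tiny_matrix, cands, y, min_nonzero=1)
        for t in tested:
            a = tiny_matrix.values[t.components[0]].to_numpy()
            b = tiny_matrix.values[t.components[1]].to_numpy()
            naive = np.array([ai * bi for ai, bi in zip(a, b)])
            assert np.array_equal(values[t.name].to_numpy(), naive)

    def test_stats_table_columns(self):
        t = self._term("t", 0.5, 10)
        tab = stats_table([t])
        assert set(tab.columns) >= {"term", "type", "f_stat", "p_value",
                                    "fdr_q", "nonzero_count"}
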
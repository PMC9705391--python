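"""Wilcoxon DE against a permutation oracle; GO classic/elim enrichment."""

import itertools

import anndata as ad
import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from scipy.special import comb
from scipy.stats import hypergeom, rankdata

from organovasc import cluster, markers_go
from organovasc.ontology import GODag


def _adata(X, genes=None):
    X = np.asarray(X, dtype=float)
    genes = genes or [f"g{i}" for i in range(X.shape[1])]
    return ad.AnnData(
        X=X,
        obs=pd.DataFrame(index=[f"c{i}" for i in range(X.shape[0])]),
        var=pd.DataFrame(index=pd.Index(genes, name="gene")),
    )


def _perm_p(x, y):
    """Exact two-sided rank-sum p by enumeration of all assignments."""
    allv = np.concatenate([x, y])
    r = rankdata(allv)
    obs = r[: len(x)].sum()
    tot = le = ge = 0
    for combo in itertools.combinations(range(len(allv)), len(x)):
        w = r[list(combo)].sum()
        tot += 1
        le += w <= obs + 1e-12
        ge += w >= obs - 1e-12
    return min(1.0, 2 * min(le, ge) / tot)


class TestDegWilcoxon:
    def test_constant_gene_p_one_lfc_zero(self):
        X = np.column_stack([np.full(10, 3.0), np.arange(10, dtype=float)])
        table = markers_go.deg_wilcoxon(_adata(X), np.array([1] * 5 + [0] * 5), 1)
        row = table.set_index("gene").loc["g0"]
        assert row.p == 1.0
        assert row.log2fc == 0.0

    def test_matches_exact_permutation_oracle(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(12, 5))  # tie-free
        labels = np.array([1] * 6 + [0] * 6)
        table = markers_go.deg_wilcoxon(_adata(X), labels, 1).set_index("gene")
        for gi in range(5):
            expected = _perm_p(X[:6, gi], X[6:, gi])
            assert table.loc[f"g{gi}", "p"] == pytest.approx(expected, abs=1e-10)

    def test_small_cluster_rejected(self):
        X = np.random.default_rng(0).normal(size=(6, 3))
        with pytest.raises(ValueError, match="too small"):
            markers_go.deg_wilcoxon(_adata(X), np.array([1, 1, 0, 0, 0, 0]), 1)

    def test_bh_adjustment_is_monotone(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(30, 40))
        X[:15, :10] += 1.5
        labels = np.array([1] * 15 + [0] * 15)
        table = markers_go.deg_wilcoxon(_adata(X), labels, 1)
        by_p = table.sort_values(["p", "gene"]).gene.tolist()
        by_padj = table.sort_values(["p_adj", "p", "gene"]).gene.tolist()
        assert by_p == by_padj
        assert (table.p_adj >= table.p - 1e-15).all()

    def test_planted_marker_in_top_degs(self, small_filtered):
        filtered, truth = small_filtered
        tc = truth.true_class.to_numpy()
        keep = np.isin(tc, ["EC-2", "EC-1", "EC-3"])
        sub = cluster.normalize_log1p(filtered[keep].copy())
        labels = (tc[keep] == "EC-2").astype(int)
        table = markers_go.deg_wilcoxon(sub, labels, 1)
        top10 = set(table.gene.head(10))
        planted = set(sub.var_names[sub.var.marker_of == "EC-2"])
        assert top10 & planted


def _toy_dag():
    # root <- A <- C ; root <- B ; A and B siblings, C leaf under A
    return GODag.from_edges(
        [("GO:A", "GO:ROOT"), ("GO:B", "GO:ROOT"), ("GO:C", "GO:A")]
    )


class TestAnnotateUniverse:
    def test_leaf_annotation_counted_at_root(self):
        dag = _toy_dag()
        tg = markers_go.annotate_universe(dag, {"g1": {"GO:C"}}, ["g1"])
        assert "g1" in tg["GO:ROOT"] and "g1" in tg["GO:A"] and "g1" in tg["GO:C"]
        assert "g1" not in tg["GO:B"]

    def test_empty_annotations_give_empty_sets(self):
        tg = markers_go.annotate_universe(_toy_dag(), {}, ["g1", "g2"])
        assert all(len(v) == 0 for v in tg.values())

    def test_genes_outside_universe_dropped(self):
        tg = markers_go.annotate_universe(_toy_dag(), {"gX": {"GO:C"}}, ["g1"])
        assert all(len(v) == 0 for v in tg.values())

    def test_matches_transitive_closure_oracle(self):
        rng = np.random.default_rng(6)
        import networkx as nx

        dag, ann, uni, _ = __import__("organovasc.simulate", fromlist=["x"]).simulate_go_fixture(
            n_terms=25, depth=4, seed=6
        )
        tg = markers_go.annotate_universe(dag, ann, uni)
        # oracle: per gene, walk the graph upward collecting every ancestor
        expected = {t: set() for t in dag.terms}
        for g, terms in ann.items():
            for t in terms:
                for anc in {t} | nx.descendants(dag.graph, t):
                    expected[anc].add(g)
        assert tg == expected


class TestFisherClassic:
    def test_saturated_table_p_one(self):
        uni = [f"g{i}" for i in range(10)]
        tg = {"GO:T": set(uni)}
        p = markers_go.fisher_classic(tg, set(uni), uni)
        assert p["GO:T"] == pytest.approx(1.0)

    def test_closed_form_extreme_table(self):
        # 5 significant genes all inside a 5-gene term, universe 10
        uni = [f"g{i}" for i in range(10)]
        tg = {"GO:T": set(uni[:5])}
        p = markers_go.fisher_classic(tg, set(uni[:5]), uni)
        assert p["GO:T"] == pytest.approx(1 / comb(10, 5), rel=1e-12)

    def test_monotone_in_overlap(self):
        uni = [f"g{i}" for i in range(40)]
        sig = set(uni[:10])
        ps = []
        for k in range(0, 11):
            term = set(uni[:k]) | set(uni[30 : 40 - k])  # size-10 term, overlap k
            ps.append(markers_go.fisher_classic({"T": term}, sig, uni)["T"])
        assert all(a >= b - 1e-12 for a, b in zip(ps, ps[1:]))


class TestFisherElim:
    def _nested_fixture(self):
        """All signal in the child C; parent A is enriched only by inheritance."""
        dag = _toy_dag()
        uni = [f"g{i}" for i in range(60)]
        ann = {g: {"GO:C"} for g in uni[:10]}
        ann.update({g: {"GO:A"} for g in uni[10:20]})
        ann.update({g: {"GO:B"} for g in uni[20:40]})
        sig = set(uni[:10])
        return dag, markers_go.annotate_universe(dag, ann, uni), sig, uni

    def test_cutoff_zero_equals_classic(self):
        dag, tg, sig, uni = self._nested_fixture()
        enr = markers_go.fisher_elim(dag, tg, sig, uni, elim_cutoff=0.0)
        for e in enr:
            assert e.p_elim == pytest.approx(e.p_classic, abs=1e-15)

    def test_parent_deflated_child_unchanged(self):
        dag, tg, sig, uni = self._nested_fixture()
        enr = {e.term: e for e in markers_go.fisher_elim(dag, tg, sig, uni, 0.01)}
        assert enr["GO:C"].p_elim == pytest.approx(enr["GO:C"].p_classic, abs=1e-15)
        assert enr["GO:A"].p_elim > enr["GO:A"].p_classic
        assert enr["GO:A"].p_classic < 0.01  # inherited significance under classic

    def test_elim_validated_against_brute_force(self):
        dag, tg, sig, uni = self._nested_fixture()
        enr = {e.term: e for e in markers_go.fisher_elim(dag, tg, sig, uni, 0.01)}
        n_u, n_s = len(uni), len(sig)

        def tail(genes):
            return hypergeom.sf(len(genes & sig) - 1, n_u, len(genes), n_s)

        # brute-force elim: child first; C significant -> remove its genes
        # from A and ROOT before testing them
        assert enr["GO:C"].p_elim == pytest.approx(tail(tg["GO:C"]), abs=1e-15)
        assert tail(tg["GO:C"]) < 0.01
        reduced_a = tg["GO:A"] - tg["GO:C"]
        reduced_root = tg["GO:ROOT"] - tg["GO:C"]
        assert enr["GO:A"].p_elim == pytest.approx(tail(reduced_a), abs=1e-15)
        assert enr["GO:ROOT"].p_elim == pytest.approx(tail(reduced_root), abs=1e-15)
        for t in ("GO:A", "GO:B", "GO:C", "GO:ROOT"):
            assert enr[t].p_classic == pytest.approx(tail(tg[t]), abs=1e-15)

    def test_flat_dag_elim_touches_only_root(self):
        dag = GODag.from_edges([("GO:X", "GO:ROOT"), ("GO:Y", "GO:ROOT")])
        uni = [f"g{i}" for i in range(30)]
        ann = {g: {"GO:X"} for g in uni[:8]}
        ann.update({g: {"GO:Y"} for g in uni[8:16]})
        sig = set(uni[:8])
        tg = markers_go.annotate_universe(dag, ann, uni)
        enr = {e.term: e for e in markers_go.fisher_elim(dag, tg, sig, uni, 0.05)}
        assert enr["GO:X"].p_elim == pytest.approx(enr["GO:X"].p_classic, abs=1e-15)
        assert enr["GO:Y"].p_elim == pytest.approx(enr["GO:Y"].p_classic, abs=1e-15)
        assert enr["GO:ROOT"].p_elim >= enr["GO:ROOT"].p_classic

    def test_margins_reconcile_with_universe(self):
        dag, tg, sig, uni = self._nested_fixture()
        for e in markers_go.fisher_elim(dag, tg, sig, uni, 0.01):
            assert e.sig_in_term <= e.annotated_in_term
            assert e.sig_in_term <= e.sig_total
            assert e.annotated_in_term <= e.universe_total
            assert e.universe_total == len(uni)


class TestRankGo:
    def test_top_k_saturation(self):
        dag, tg, sig, uni = TestFisherElim()._nested_fixture()
        enr = markers_go.fisher_elim(dag, tg, sig, uni, 0.01)
        assert len(markers_go.rank_go(enr, top_k=100)) == len(enr)

    def test_ties_break_by_term_id(self):
        recs = [
            markers_go.GOEnrichment("GO:B", "b", 0.5, 0.5, 1, 2, 3, 10),
            markers_go.GOEnrichment("GO:A", "a", 0.5, 0.5, 1, 2, 3, 10),
        ]
        table = markers_go.rank_go(recs)
        assert table.term.tolist() == ["GO:A", "GO:B"]

    def test_sorted_by_neg_log10_descending(self):
        dag, tg, sig, uni = TestFisherElim()._nested_fixture()
        table = markers_go.rank_go(markers_go.fisher_elim(dag, tg, sig, uni, 0.01))
        assert (np.diff(table.neg_log10_p.to_numpy()) <= 1e-12).all()
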
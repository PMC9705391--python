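"""Per-cluster marker genes and GO biological-process over-representation.

Differential expression uses the two-sided Wilcoxon rank-sum test of one
cluster against all remaining cells on log-normalized values (exact null
distribution for small tie-free groups, normal approximation with tie
correction otherwise), Benjamini–Hochberg adjusted across genes.  Fold
changes are ``log2((mean expm1 in + 1) / (mean expm1 out + 1))``.

GO enrichment tests each term's annotated gene set against a significant
gene list by the one-sided hypergeometric (Fisher) tail, either classically
or with the *elim* algorithm: terms are visited children before parents, and
whenever a term's p-value passes the elimination cutoff its annotated genes
are removed from all ancestor terms before those are tested.  This
suppresses the inheritance artifact where a parent looks enriched only
because of one significant child.
"""

from __future__ import annotations

from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ConfigurationError
from .ontology import GODag

__all__ = [
    "deg_wilcoxon",
    "annotate_universe",
    "fisher_classic",
    "fisher_elim",
    "rank_go",
    "GOEnrichment",
]


# ---------------------------------------------------------------------------
# differential expression
# ---------------------------------------------------------------------------

def deg_wilcoxon(
    norm: ad.AnnData, cluster_labels: np.ndarray, cluster: int
) -> pd.DataFrame:
    """Markers of ``cluster`` vs all other cells by Wilcoxon rank-sum.

    Returns a DataFrame (gene, cluster, log2fc, p, p_adj, pct_in, pct_out)
    sorted by p then descending \\|log2fc\\|.  Clusters of fewer than 3 cells
    are rejected.
    """
    cluster_labels = np.asarray(cluster_labels)
    in_mask = cluster_labels == cluster
    n_in, n_out = int(in_mask.sum()), int((~in_mask).sum())
    if n_in < 3 or n_out < 3:
        raise ValueError(f"cluster {cluster} too small for DE ({n_in} vs {n_out} cells)")
    X = norm.X
    dense = np.asarray(X.todense()) if sp.issparse(X) else np.asarray(X, dtype=float)
    x_in, x_out = dense[in_mask], dense[~in_mask]

    res = stats.mannwhitneyu(x_in, x_out, axis=0, alternative="two-sided", method="auto")
    p = np.asarray(res.pvalue, dtype=float)

    expm1_in = np.expm1(x_in).mean(axis=0)
    expm1_out = np.expm1(x_out).mean(axis=0)
    log2fc = np.log2((expm1_in + 1.0) / (expm1_out + 1.0))
    # constant genes (all values tied) carry no information; pin p to 1
    allsame = np.all(dense == dense[0:1], axis=0)
    p[allsame | ~np.isfinite(p)] = 1.0
    p = np.clip(p, 0.0, 1.0)
    p_adj = multipletests(p, method="fdr_bh")[1]

    table = pd.DataFrame(
        {
            "gene": norm.var_names,
            "cluster": cluster,
            "log2fc": log2fc,
            "p": p,
            "p_adj": p_adj,
            "pct_in": (x_in > 0).mean(axis=0),
            "pct_out": (x_out > 0).mean(axis=0),
        }
    )
    table["abs_lfc"] = table["log2fc"].abs()
    table = table.sort_values(["p", "abs_lfc"], ascending=[True, False], kind="stable")
    return table.drop(columns="abs_lfc").reset_index(drop=True)


# ---------------------------------------------------------------------------
# GO enrichment
# ---------------------------------------------------------------------------

@dataclass
class GOEnrichment:
    """Per-term enrichment record (elim and classic p, 2x2 table counts)."""

    term: str
    name: str
    p_elim: float
    p_classic: float
    sig_in_term: int
    annotated_in_term: int
    sig_total: int
    universe_total: int

    @property
    def neg_log10_p(self) -> float:
        return -np.log10(self.p_elim)


def annotate_universe(
    dag: GODag, annotations: dict[str, set[str]], universe: list[str] | set[str]
) -> dict[str, set[str]]:
    """Propagate direct gene annotations to all ancestor terms.

    Genes outside ``universe`` and terms outside the DAG are dropped.
    Returns term -> gene-set (every DAG term present, possibly empty).
    """
    universe = set(universe)
    term_genes: dict[str, set[str]] = {t: set() for t in dag.terms}
    for gene, terms in annotations.items():
        if gene not in universe:
            continue
        for t in terms:
            if t not in dag:
                continue
            term_genes[t].add(gene)
            for anc in dag.ancestors(t):
                term_genes[anc].add(gene)
    return term_genes


def _hypergeom_tail(sig_in: int, n_annotated: int, n_sig: int, n_universe: int) -> float:
    """One-sided over-representation p: P(X >= sig_in)."""
    return float(stats.hypergeom.sf(sig_in - 1, n_universe, n_annotated, n_sig))


def fisher_classic(
    term_genes: dict[str, set[str]],
    significant: set[str],
    universe: list[str] | set[str],
) -> dict[str, float]:
    """Classic one-sided Fisher (hypergeometric tail) p per term."""
    universe = set(universe)
    significant = set(significant) & universe
    n_u, n_s = len(universe), len(significant)
    return {
        t: _hypergeom_tail(len(genes & significant), len(genes), n_s, n_u)
        for t, genes in term_genes.items()
    }


def fisher_elim(
    dag: GODag,
    term_genes: dict[str, set[str]],
    significant: set[str],
    universe: list[str] | set[str],
    elim_cutoff: float = 0.01,
) -> list[GOEnrichment]:
    """Fisher enrichment with the elim algorithm.

    Terms are processed children before parents.  When a term's elim p-value
    falls below ``elim_cutoff``, its annotated genes are removed from every
    ancestor's working gene set before those ancestors are tested.  With
    ``elim_cutoff=0`` no elimination happens and ``p_elim == p_classic``.
    """
    universe = set(universe)
    significant = set(significant) & universe
    n_u, n_s = len(universe), len(significant)
    classic = fisher_classic(term_genes, significant, universe)
    working = {t: set(g) for t, g in term_genes.items()}

    out: dict[str, GOEnrichment] = {}
    for term in dag.topological_children_first():
        genes = working.get(term, set())
        p = _hypergeom_tail(len(genes & significant), len(genes), n_s, n_u)
        out[term] = GOEnrichment(
            term=term,
            name=dag.name(term),
            p_elim=p,
            p_classic=classic.get(term, 1.0),
            sig_in_term=len(genes & significant),
            annotated_in_term=len(genes),
            sig_total=n_s,
            universe_total=n_u,
        )
        if p < elim_cutoff:
            removed = term_genes.get(term, set())
            for anc in dag.ancestors(term):
                if anc in working:
                    working[anc] -= removed
    return [out[t] for t in dag.terms]


def rank_go(enrichments: list[GOEnrichment], top_k: int | None = None) -> pd.DataFrame:
    """Rank terms by descending -log10(p_elim); ties break by term id."""
    rows = [
        {
            "term": e.term,
            "name": e.name,
            "p_elim": e.p_elim,
            "p_classic": e.p_classic,
            "neg_log10_p": e.neg_log10_p,
            "sig_in_term": e.sig_in_term,
            "annotated_in_term": e.annotated_in_term,
            "sig_total": e.sig_total,
            "universe_total": e.universe_total,
        }
        for e in enrichments
    ]
    table = pd.DataFrame(rows)
    table = table.sort_values(
        ["neg_log10_p", "term"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    if top_k is not None:
        table = table.head(top_k)
    return table


def go_enrichment_for_cluster(
    degs: pd.DataFrame,
    dag: GODag,
    annotations: dict[str, set[str]],
    universe: list[str],
    top_degs: int = 20,
    elim_cutoff: float = 0.01,
    top_k: int | None = None,
) -> pd.DataFrame:
    """Convenience: elim enrichment of a cluster's top DEGs, ranked.

    The significant set is the top ``top_degs`` markers by the DE ordering;
    the universe is the expressed-gene list handed in by the caller.
    """
    if degs.empty:
        raise ConfigurationError("empty DEG table")
    sig = set(degs["gene"].head(top_degs))
    term_genes = annotate_universe(dag, annotations, universe)
    enr = fisher_elim(dag, term_genes, sig, universe, elim_cutoff=elim_cutoff)
    return rank_go(enr, top_k=top_k)
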
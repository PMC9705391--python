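"""The normalized in-vivo similarity score for endothelial cells.

Three endothelial groups — a 2D monolayer reference, 3D microvessel-network
cells, and organ-matched in-vivo cells — are placed on a common axis:

1. the monolayer is subsampled to 300 or 600 cells, whichever is closer to
   the 3D group size (ties go to 300);
2. the top 20 markers of the in-vivo group (Wilcoxon vs the rest) define an
   in-vivo gene program;
3. every cell receives a module score for that program — mean expression of
   the program genes minus the mean of expression-bin-matched control genes
   (the binned-control scheme of Tirosh et al.);
4. scores are affinely rescaled so the 2D group mean maps to 0 and the
   in-vivo group mean to 100.  The 3D group mean then reads directly as a
   position on the monolayer -> in-vivo axis.

Groups are compared by one-way ANOVA.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats

from .cluster import normalize_log1p, pca_embed, select_hvg
from .errors import ConfigurationError, DegenerateNormalizationError
from .markers_go import deg_wilcoxon

__all__ = [
    "MONO_2D",
    "NETWORK_3D",
    "IN_VIVO",
    "subsample_monolayer",
    "joint_embed",
    "invivo_degs",
    "module_score",
    "normalize_score",
    "anova_oneway",
    "invivo_similarity",
    "InVivoScoreResult",
]

MONO_2D = "MONO_2D"
NETWORK_3D = "NETWORK_3D"
IN_VIVO = "IN_VIVO"
GROUPS = (MONO_2D, NETWORK_3D, IN_VIVO)


@dataclass
class InVivoScoreResult:
    """Per-cell scores plus group summaries and the ANOVA comparison."""

    scores: pd.DataFrame  # columns: raw_score, normalized_score, group
    program_genes: list[str]
    group_means: pd.Series
    group_sds: pd.Series
    anova_F: float
    anova_p: float


def subsample_monolayer(
    adata: ad.AnnData, n_network: int, seed: int = 0
) -> ad.AnnData:
    """Subsample the 2D monolayer to 300 or 600 cells matching the 3D count.

    The target is the member of {300, 600} closest to ``n_network`` (tie ->
    300), drawn uniformly without replacement.  If fewer cells are available
    all are kept with a warning.
    """
    target = 300 if abs(n_network - 300) <= abs(n_network - 600) else 600
    if adata.n_obs <= target:
        if adata.n_obs < target:
            warnings.warn(
                f"monolayer has {adata.n_obs} cells < target {target}; using all"
            )
        return adata.copy()
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(adata.n_obs, size=target, replace=False))
    return adata[idx].copy()


def joint_embed(
    groups: ad.AnnData, n_comps: int = 30, n_hvg: int = 2000, group_key: str = "group"
) -> np.ndarray:
    """Joint PCA of the groups on intersected per-group HVGs.

    Each group's genes are centered and unit-scaled within the group before
    the joint decomposition, a light-weight stand-in for anchor-based
    integration that removes per-group location/scale differences.
    """
    norm = normalize_log1p(groups)
    labels = norm.obs[group_key].to_numpy()
    hvg_sets = []
    for g in np.unique(labels):
        sub = norm[labels == g]
        if sub.n_obs < 2:
            raise ConfigurationError(f"group {g} has fewer than 2 cells")
        hvg_sets.append(set(select_hvg(sub, n_hvg).tolist()))
    shared = sorted(set.intersection(*hvg_sets))
    if not shared:
        raise ConfigurationError("groups share no highly variable genes")
    X = norm.X[:, shared]
    dense = np.asarray(X.todense()) if sp.issparse(X) else np.asarray(X, dtype=float)
    for g in np.unique(labels):
        m = labels == g
        mu = dense[m].mean(axis=0)
        sd = dense[m].std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        dense[m] = np.clip((dense[m] - mu) / sd, -10, 10)
    sub_ad = ad.AnnData(X=dense, obs=norm.obs.copy())
    emb, _ = pca_embed(sub_ad, hvg=None, n_comps=n_comps)
    return emb


def invivo_degs(
    norm: ad.AnnData, top_n: int = 20, group_key: str = "group"
) -> list[str]:
    """Top markers of the in-vivo group vs all other cells."""
    labels = (norm.obs[group_key] == IN_VIVO).to_numpy().astype(int)
    table = deg_wilcoxon(norm, labels, cluster=1)
    up = table[table["log2fc"] > 0]
    return up["gene"].head(top_n).tolist()


def module_score(
    norm: ad.AnnData,
    gene_set: list[str],
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
) -> np.ndarray:
    """Binned-control module score per cell.

    Genes are split into ``n_bins`` bins of average expression; for each
    gene-set gene, ``n_ctrl`` control genes are drawn from its bin (without
    replacement, capped at the bin size).  The score is the mean expression
    of the gene set minus the mean expression of the pooled controls.
    """
    genes_present = [g for g in gene_set if g in norm.var_names]
    if not genes_present:
        raise ConfigurationError("gene_set shares no genes with the matrix")
    rng = np.random.default_rng(seed)
    X = sp.csc_matrix(norm.X, dtype=float)
    avg = np.asarray(X.mean(axis=0)).ravel()
    order = np.argsort(avg, kind="stable")
    bins = np.array_split(order, min(n_bins, len(order)))
    bin_of = np.empty(len(avg), dtype=int)
    for b, members in enumerate(bins):
        bin_of[members] = b

    set_idx = np.array([norm.var_names.get_loc(g) for g in genes_present])
    ctrl_idx: list[int] = []
    for gi in set_idx:
        pool = bins[bin_of[gi]]
        take = min(n_ctrl, len(pool))
        ctrl_idx.extend(rng.choice(pool, size=take, replace=False).tolist())
    ctrl_idx = np.array(ctrl_idx)

    set_mean = np.asarray(X[:, set_idx].mean(axis=1)).ravel()
    ctrl_mean = np.asarray(X[:, ctrl_idx].mean(axis=1)).ravel()
    return set_mean - ctrl_mean


def normalize_score(
    raw_scores: np.ndarray, groups: np.ndarray | pd.Series
) -> pd.DataFrame:
    """Affine rescaling pinning the 2D mean at 0 and the in-vivo mean at 100.

    ``normalized = 100 * (raw - mean_2D) / (mean_invivo - mean_2D)``; the
    group means of the normalized scores are asserted to be exactly 0 and
    100.  Coincident anchor means are a degenerate configuration.
    """
    groups = np.asarray(groups)
    raw = np.asarray(raw_scores, dtype=float)
    m2d = raw[groups == MONO_2D].mean()
    miv = raw[groups == IN_VIVO].mean()
    if not np.isfinite(m2d) or not np.isfinite(miv) or m2d == miv:
        raise DegenerateNormalizationError(
            "2D and in-vivo anchor means coincide; score axis undefined"
        )
    normalized = 100.0 * (raw - m2d) / (miv - m2d)
    out = pd.DataFrame(
        {"raw_score": raw, "normalized_score": normalized, "group": groups}
    )
    assert abs(out.loc[out.group == MONO_2D, "normalized_score"].mean()) < 1e-8
    assert abs(out.loc[out.group == IN_VIVO, "normalized_score"].mean() - 100) < 1e-8
    return out


def anova_oneway(*groups: np.ndarray) -> tuple[float, float]:
    """One-way ANOVA F statistic and p-value (between/within decomposition)."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2 or any(len(a) < 2 for a in arrays):
        raise ValueError("need at least two groups with at least two values each")
    all_vals = np.concatenate(arrays)
    grand = all_vals.mean()
    k = len(arrays)
    n = len(all_vals)
    ss_between = sum(len(a) * (a.mean() - grand) ** 2 for a in arrays)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    df_b, df_w = k - 1, n - k
    if ss_within == 0:
        if ss_between == 0:
            return 0.0, 1.0
        return float("inf"), 0.0
    F = (ss_between / df_b) / (ss_within / df_w)
    p = float(stats.f.sf(F, df_b, df_w))
    return float(F), p


def invivo_similarity(
    groups: ad.AnnData,
    top_n_degs: int = 20,
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
    group_key: str = "group",
) -> InVivoScoreResult:
    """Full similarity-score pipeline on a three-group cell set.

    ``groups`` holds raw counts with ``obs[group_key]`` in
    {MONO_2D, NETWORK_3D, IN_VIVO}.  The monolayer is subsampled to match
    the 3D group, data are depth-normalized jointly, the in-vivo program is
    learned, scored with binned controls, and anchor-normalized.
    """
    labels = groups.obs[group_key]
    missing = set(GROUPS) - set(labels.unique())
    if missing:
        raise ConfigurationError(f"missing groups: {sorted(missing)}")
    n_network = int((labels == NETWORK_3D).sum())
    mono = subsample_monolayer(groups[(labels == MONO_2D).to_numpy()], n_network, seed=seed)
    rest = groups[(labels != MONO_2D).to_numpy()]
    combined = ad.concat([mono, rest], join="inner", merge="same")
    combined.obs_names_make_unique()

    norm = normalize_log1p(combined)
    program = invivo_degs(norm, top_n=top_n_degs, group_key=group_key)
    raw = module_score(norm, program, n_bins=n_bins, n_ctrl=n_ctrl, seed=seed)
    scores = normalize_score(raw, norm.obs[group_key].to_numpy())
    scores.index = norm.obs_names

    means = scores.groupby("group")["normalized_score"].mean()
    sds = scores.groupby("group")["normalized_score"].std()
    F, p = anova_oneway(
        *(scores.loc[scores.group == g, "normalized_score"].to_numpy() for g in GROUPS)
    )
    return InVivoScoreResult(
        scores=scores,
        program_genes=program,
        group_means=means,
        group_sds=sds,
        anova_F=F,
        anova_p=p,
    )
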
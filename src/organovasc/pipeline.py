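"""End-to-end pipeline: simulate -> QC -> cluster -> classify -> markers/GO
-> in-vivo score -> morphometry, driven by one validated configuration.

Every stage writes its outputs once into ``<out_dir>/<stage>/`` and records
parameters and SHA-256 hashes of its output files in a run manifest, so a
re-run with the same configuration reproduces identical hashes for all
deterministic stages.  A failing stage halts downstream stages; the partial
manifest is still written.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml
from pydantic import BaseModel, ConfigDict, model_validator

from . import classify as classify_mod
from . import cluster as cluster_mod
from . import invivo as invivo_mod
from . import io as io_mod
from . import markers_go as mgo
from . import morphometry as morpho_mod
from . import qc as qc_mod
from . import simulate as sim_mod
from .errors import PipelineError

__all__ = ["RunConfig", "run_pipeline", "load_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SimulateConfig(_Strict):
    n_conditions: int = 6
    n_genes: int = 5000
    marker_baseline: float = 0.05
    ec_count_range: tuple[int, int] = (75, 688)
    osc_count_range: tuple[int, int] = (1065, 5220)
    marker_log2fc: float = 4.0
    nb_dispersion: float = 0.25
    lowq_cell_fraction: float = 0.05
    images_per_condition: int = 3
    vessel_segments: list[int] | None = None  # per condition; default ramp
    vessel_noise_sd: float = 0.05
    image_shape: tuple[int, int] = (256, 256)
    go_n_terms: int = 30
    go_depth: int = 3


class QCConfig(_Strict):
    min_genes: int = 200
    max_genes: int = 7500
    max_pct_mito: float = 10.0
    min_cells_per_gene: int = 3


class ClusterConfig(_Strict):
    resolution: float = 1.0
    ec_resolution: float = 0.3
    scale_factor: float = 1e4
    n_hvg: int = 2000
    n_comps: int = 30
    k_neighbors: int = 20
    compute_silhouette: bool = False


class ClassifyConfig(_Strict):
    tau_pos: float = 0.5
    tau_neg: float = 0.2


class MarkersGOConfig(_Strict):
    top_degs: int = 20
    elim_cutoff: float = 0.01
    top_k: int = 6


class ScoreConfig(_Strict):
    organs: list[str] = ["skin", "heart"]
    top_n_degs: int = 20
    n_bins: int = 24
    n_ctrl: int = 100


class MorphoConfig(_Strict):
    pixel_size: float = 1.0
    threshold: float = 0.5
    min_object_px: int = 10
    merge_radius_px: int = 2


class RunConfig(_Strict):
    """Validated configuration for a full pipeline run."""

    out_dir: str
    seed: int = 0
    simulate: SimulateConfig = SimulateConfig()
    qc: QCConfig = QCConfig()
    cluster: ClusterConfig = ClusterConfig()
    classify: ClassifyConfig = ClassifyConfig()
    markers_go: MarkersGOConfig = MarkersGOConfig()
    score: ScoreConfig = ScoreConfig()
    morphometry: MorphoConfig = MorphoConfig()

    @model_validator(mode="after")
    def _check(self):
        # surfaces inconsistencies before any stage executes
        qc_mod.QCThresholds(
            min_genes=self.qc.min_genes,
            max_genes=self.qc.max_genes,
            max_pct_mito=self.qc.max_pct_mito,
            min_cells_per_gene=self.qc.min_cells_per_gene,
        )
        if not self.classify.tau_pos > self.classify.tau_neg:
            raise ValueError("classify.tau_pos must exceed classify.tau_neg")
        return self


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        return RunConfig(**yaml.safe_load(fh))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _stage_seed(master: int, idx: int) -> int:
    return int((master * 1000003 + idx * 7919) % (2**31 - 1))


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages in dependency order; return the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, dict] = {}
    state: dict[str, object] = {}

    stages = [
        ("simulate", _stage_simulate),
        ("qc", _stage_qc),
        ("cluster", _stage_cluster),
        ("classify", _stage_classify),
        ("markers_go", _stage_markers_go),
        ("score", _stage_score),
        ("morphometry", _stage_morphometry),
    ]
    for idx, (name, fn) in enumerate(stages):
        stage_dir = out / name
        stage_dir.mkdir(exist_ok=True)
        seed = _stage_seed(config.seed, idx)
        try:
            params = fn(config, stage_dir, seed, state)
        except Exception as exc:  # halt downstream, keep partial manifest
            manifest[name] = {"status": "failed", "error": str(exc)}
            (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        outputs = {
            str(p.relative_to(out)): _sha256(p)
            for p in sorted(stage_dir.rglob("*"))
            if p.is_file()
        }
        manifest[name] = {"status": "ok", "seed": seed, "params": params, "outputs": outputs}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _stage_simulate(config: RunConfig, stage_dir: Path, seed: int, state: dict) -> dict:
    sc = config.simulate
    spec = sim_mod.SimulationSpec(
        n_conditions=sc.n_conditions,
        n_genes=sc.n_genes,
        ec_count_range=sc.ec_count_range,
        osc_count_range=sc.osc_count_range,
        marker_log2fc=sc.marker_log2fc,
        marker_baseline=sc.marker_baseline,
        nb_dispersion=sc.nb_dispersion,
        lowq_cell_fraction=sc.lowq_cell_fraction,
        seed=seed,
    )
    adata, truth = sim_mod.simulate_counts(spec)
    io_mod.write_10x_mtx(adata, stage_dir / "counts")
    state["counts"] = adata
    state["truth"] = truth

    segments = sc.vessel_segments or [
        8 + 4 * i for i in range(sc.n_conditions)
    ]
    conditions = list(dict.fromkeys(adata.obs["condition"]))
    rows = []
    img_dir = stage_dir / "images"
    img_dir.mkdir(exist_ok=True)
    state["images"] = {}
    for ci, cond in enumerate(conditions):
        n_seg = segments[ci % len(segments)]
        for rep in range(sc.images_per_condition):
            img, vtruth = sim_mod.simulate_vessel_image(
                n_segments=n_seg,
                noise_sd=sc.vessel_noise_sd,
                seed=_stage_seed(seed, 100 + ci * 10 + rep),
                shape=sc.image_shape,
            )
            fname = f"{cond}_{rep}.tiff"
            tifffile.imwrite(img_dir / fname, img.pixels.astype(np.float32))
            state["images"][fname] = (cond, img, vtruth)
            rows.append(
                {
                    "image": fname,
                    "condition": cond,
                    "true_length_px": vtruth.length_px,
                    "true_junctions": vtruth.n_junctions,
                }
            )
    pd.DataFrame(rows).to_csv(stage_dir / "image_truth.csv", index=False)

    dag, ann, universe, significant = sim_mod.simulate_go_fixture(
        n_terms=sc.go_n_terms,
        depth=sc.go_depth,
        seed=seed,
        universe=list(adata.var_names),
        planted_term=None,
        planted_genes=list(
            truth.genes.index[truth.genes["marker_of"] == "EC-1"]
        ),
    )
    dag.to_obo(stage_dir / "go.obo")
    pd.DataFrame(
        [(g, t) for g, ts in ann.items() for t in sorted(ts)],
        columns=["gene", "term"],
    ).to_csv(stage_dir / "annotations.tsv", sep="\t", index=False)
    state["go"] = (dag, ann)
    return {"n_cells": int(adata.n_obs), "n_genes": int(adata.n_vars)}


def _stage_qc(config: RunConfig, stage_dir: Path, seed: int, state: dict) -> dict:
    thresholds = qc_mod.QCThresholds(
        min_genes=config.qc.min_genes,
        max_genes=config.qc.max_genes,
        max_pct_mito=config.qc.max_pct_mito,
        min_cells_per_gene=config.qc.min_cells_per_gene,
    )
    adata = state["counts"]
    metrics = qc_mod.compute_qc_metrics(adata)
    filtered, log = qc_mod.qc_filter(adata, metrics, thresholds)
    metrics.to_csv(stage_dir / "qc_metrics.csv")
    log.to_csv(stage_dir / "removal_log.csv", index=False)
    io_mod.write_10x_mtx(filtered, stage_dir / "filtered")
    state["filtered"] = filtered
    return {
        "cells_in": int(adata.n_obs),
        "cells_kept": int(filtered.n_obs),
        "genes_kept": int(filtered.n_vars),
    }


def _stage_cluster(config: RunConfig, stage_dir: Path, seed: int, state: dict) -> dict:
    cc = config.cluster
    norm = cluster_mod.normalize_log1p(state["filtered"], scale_factor=cc.scale_factor)
    hvg = cluster_mod.select_hvg(norm, n_hvg=cc.n_hvg)
    emb, _ = cluster_mod.pca_embed(norm, hvg, n_comps=cc.n_comps)
    result = cluster_mod.cluster_graph(
        emb, k_neighbors=cc.k_neighbors, resolution=cc.resolution, seed=seed
    )
    if cc.compute_silhouette:
        result.silhouette_per_cluster = cluster_mod.silhouette_by_cluster(
            emb, result.labels
        )
    df = pd.DataFrame(
        {"barcode": norm.obs_names, "cluster": result.labels}
    )
    df.to_csv(stage_dir / "clusters.csv", index=False)
    np.savetxt(stage_dir / "embedding.csv", emb, delimiter=",")
    state["norm"] = norm
    state["embedding"] = emb
    state["clusters"] = result
    return {"n_clusters": int(result.n_clusters), "resolution": cc.resolution}


def _stage_classify(config: RunConfig, stage_dir: Path, seed: int, state: dict) -> dict:
    norm = state["norm"]
    labels = state["clusters"].labels
    ec_f = classify_mod.panel_detection_fraction(norm, labels, classify_mod.MarkerPanel().ec_genes)
    st_f = classify_mod.panel_detection_fraction(
        norm, labels, classify_mod.MarkerPanel().stromal_genes
    )
    classes = classify_mod.classify_clusters(
        ec_f, st_f, tau_pos=config.classify.tau_pos, tau_neg=config.classify.tau_neg
    )
    classes = classify_mod.exclude_lymphatic(
        norm, labels, classes, tau_pos=config.classify.tau_pos
    )
    classes.evidence.to_csv(stage_dir / "cluster_classes.csv")
    per_cell = pd.DataFrame(
        {"barcode": norm.obs_names, "cluster": labels, "class": classes.cells(labels)}
    )
    per_cell.to_csv(stage_dir / "cell_classes.csv", index=False)
    state["classes"] = classes
    counts = per_cell["class"].value_counts().to_dict()
    return {"class_counts": {k: int(v) for k, v in counts.items()}}


def _stage_markers_go(config: RunConfig, stage_dir: Path, seed: int, state: dict) -> dict:
    mc = config.markers_go
    cc = config.cluster
    norm = state["norm"]
    labels = state["clusters"].labels
    classes = state["classes"]
    cell_class = classes.cells(labels)
    ec_mask = cell_class == classify_mod.EC
    if ec_mask.sum() <= cc.k_neighbors + 1:
        raise PipelineError("too few endothelial cells to re-cluster")
    # re-normalize the endothelial subset and re-cluster at the EC resolution
    ec_counts = state["filtered"][ec_mask].copy()
    ec_norm = cluster_mod.normalize_log1p(ec_counts, scale_factor=cc.scale_factor)
    ec_hvg = cluster_mod.select_hvg(ec_norm, n_hvg=cc.n_hvg)
    ec_emb, _ = cluster_mod.pca_embed(ec_norm, ec_hvg, n_comps=cc.n_comps)
    ec_clusters = cluster_mod.cluster_graph(
        ec_emb, k_neighbors=cc.k_neighbors, resolution=cc.ec_resolution, seed=seed
    )
    pd.DataFrame(
        {"barcode": ec_norm.obs_names, "ec_cluster": ec_clusters.labels}
    ).to_csv(stage_dir / "ec_clusters.csv", index=False)
    state["ec_norm"] = ec_norm
    state["ec_clusters"] = ec_clusters

    dag, ann = state["go"]
    universe = list(ec_norm.var_names)
    deg_tables, go_tables = [], []
    for cluster_id in range(ec_clusters.n_clusters):
        if (ec_clusters.labels == cluster_id).sum() < 3:
            continue
        degs = mgo.deg_wilcoxon(ec_norm, ec_clusters.labels, cluster_id)
        deg_tables.append(degs.head(mc.top_degs))
        go_table = mgo.go_enrichment_for_cluster(
            degs,
            dag,
            ann,
            universe,
            top_degs=mc.top_degs,
            elim_cutoff=mc.elim_cutoff,
            top_k=mc.top_k,
        )
        go_table.insert(0, "cluster", cluster_id)
        go_tables.append(go_table)
    pd.concat(deg_tables).to_csv(stage_dir / "top_degs.csv", index=False)
    pd.concat(go_tables).to_csv(stage_dir / "go_enrichment.csv", index=False)
    return {"n_ec_clusters": int(ec_clusters.n_clusters)}


def _stage_score(config: RunConfig, stage_dir: Path, seed: int, state: dict) -> dict:
    rows = []
    for i, organ in enumerate(config.score.organs):
        groups = sim_mod.simulate_ec_groups(organ=organ, seed=_stage_seed(seed, i))
        res = invivo_mod.invivo_similarity(
            groups,
            top_n_degs=config.score.top_n_degs,
            n_bins=config.score.n_bins,
            n_ctrl=config.score.n_ctrl,
            seed=_stage_seed(seed, 50 + i),
        )
        res.scores.to_csv(stage_dir / f"scores_{organ}.csv")
        for grp in invivo_mod.GROUPS:
            rows.append(
                {
                    "organ": organ,
                    "group": grp,
                    "mean": res.group_means[grp],
                    "sd": res.group_sds[grp],
                    "anova_F": res.anova_F,
                    "anova_p": res.anova_p,
                }
            )
    pd.DataFrame(rows).to_csv(stage_dir / "score_summary.csv", index=False)
    return {"organs": list(config.score.organs)}


def _stage_morphometry(config: RunConfig, stage_dir: Path, seed: int, state: dict) -> dict:
    mc = config.morphometry
    rows = []
    for fname, (cond, img, vtruth) in state["images"].items():
        res = morpho_mod.analyze_image(
            img.pixels,
            pixel_size=mc.pixel_size,
            threshold=mc.threshold,
            min_object_px=mc.min_object_px,
            merge_radius_px=mc.merge_radius_px,
        )
        rows.append(
            {
                "image": fname,
                "condition": cond,
                "total_length_per_area": res.total_length_per_area,
                "junctions_per_area": res.junctions_per_area,
                "total_length": res.total_length,
                "n_junctions": res.n_junctions,
                "true_length_px": vtruth.length_px,
                "true_junctions": vtruth.n_junctions,
            }
        )
    per_image = pd.DataFrame(rows)
    per_image.to_csv(stage_dir / "per_image.csv", index=False)
    anova = morpho_mod.condition_stats(per_image)
    anova.to_csv(stage_dir / "condition_anova.csv", index=False)

    # correlate EC sub-cluster composition with mean vessel length
    ec_clusters = state.get("ec_clusters")
    summary: dict = {}
    if ec_clusters is not None and ec_clusters.n_clusters >= 2:
        ec_norm = state["ec_norm"]
        comp = (
            pd.DataFrame(
                {
                    "condition": ec_norm.obs["condition"].to_numpy(),
                    "cluster": ec_clusters.labels,
                }
            )
            .groupby("condition")["cluster"]
            .apply(lambda s: (s == 1).mean() * 100)
        )
        lengths = per_image.groupby("condition")["total_length_per_area"].mean()
        common = comp.index.intersection(lengths.index)
        if len(common) >= 3:
            r, p = morpho_mod.correlate_composition(
                comp[common].to_numpy(), lengths[common].to_numpy()
            )
            pd.DataFrame(
                {"condition": common, "ec_cluster1_pct": comp[common], "mean_length": lengths[common]}
            ).to_csv(stage_dir / "composition_vs_length.csv", index=False)
            summary = {"pearson_r": float(r), "pearson_p": float(p)}
    return summary
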
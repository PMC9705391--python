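"""Cluster-level endothelial / stromal classification by marker panels.

Each cluster is scored by the detection fraction of a positive endothelial
panel (CDH5, CLDN5, ICAM2, MCAM, PECAM1) and a stromal panel (COL1A1,
COL1A2, PDGFRA, PDGFRB, TAGLN): the mean over panel genes of the fraction of
cells with a nonzero count.  A cluster is endothelial when the EC fraction
clears ``tau_pos`` while the stromal fraction stays below ``tau_neg`` (and
vice versa); anything else is labeled by the larger fraction and flagged
ambiguous.  Endothelial clusters that also detect the lymphatic panel
(FLT4, LYVE1, PDPN, PROX1) are relabeled for exclusion, mirroring the
removal of lymphatic endothelium from downstream references.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

from .simulate import EC_PANEL, LYMPHATIC_PANEL, STROMAL_PANEL

__all__ = [
    "MarkerPanel",
    "ClassLabel",
    "panel_detection_fraction",
    "classify_clusters",
    "exclude_lymphatic",
]

EC = "EC"
OSC = "OSC"
LYMPHATIC_EXCLUDED = "LYMPHATIC_EXCLUDED"


@dataclass(frozen=True)
class MarkerPanel:
    """Named marker gene lists driving classification."""

    ec_genes: tuple[str, ...] = EC_PANEL
    stromal_genes: tuple[str, ...] = STROMAL_PANEL
    lymphatic_genes: tuple[str, ...] = LYMPHATIC_PANEL

    def __post_init__(self):
        sets = [set(self.ec_genes), set(self.stromal_genes), set(self.lymphatic_genes)]
        if sets[0] & sets[1] or sets[0] & sets[2] or sets[1] & sets[2]:
            raise ValueError("marker panels must be disjoint")


@dataclass
class ClassLabel:
    """Cluster -> class assignment with the per-panel evidence table."""

    labels: dict[int, str]
    evidence: pd.DataFrame

    def cells(self, cluster_labels: np.ndarray) -> np.ndarray:
        """Broadcast cluster classes onto per-cell labels."""
        return np.array([self.labels[int(c)] for c in cluster_labels])


def panel_detection_fraction(
    adata: ad.AnnData, cluster_labels: np.ndarray, panel: tuple[str, ...] | list[str]
) -> pd.Series:
    """Per-cluster mean detection fraction over the panel genes.

    Panel genes absent from the matrix contribute 0 to the mean and are
    reported with a warning.
    """
    cluster_labels = np.asarray(cluster_labels)
    present = [g for g in panel if g in adata.var_names]
    missing = sorted(set(panel) - set(present))
    if missing:
        warnings.warn(f"panel genes absent from matrix (contribute 0): {missing}")
    X = sp.csc_matrix(adata.X)
    uniq = np.unique(cluster_labels)
    out = {}
    for c in uniq:
        mask = cluster_labels == c
        if present:
            sub = X[np.where(mask)[0]][:, [adata.var_names.get_loc(g) for g in present]]
            det = sub.getnnz(axis=0) / mask.sum()
            out[int(c)] = float(det.sum() / len(panel))
        else:
            out[int(c)] = 0.0
    return pd.Series(out, name="detection_fraction")


def classify_clusters(
    ec_fraction: pd.Series,
    stromal_fraction: pd.Series,
    tau_pos: float = 0.5,
    tau_neg: float = 0.2,
) -> ClassLabel:
    """Assign EC/OSC per cluster from the two panel detection fractions."""
    if not tau_pos > tau_neg:
        raise ValueError("tau_pos must exceed tau_neg")
    labels, rows = {}, []
    for c in ec_fraction.index:
        ec_f, st_f = float(ec_fraction[c]), float(stromal_fraction[c])
        ambiguous = False
        if ec_f >= tau_pos and st_f <= tau_neg:
            lab = EC
        elif st_f >= tau_pos and ec_f <= tau_neg:
            lab = OSC
        else:
            lab = EC if ec_f > st_f else OSC
            ambiguous = True
        labels[int(c)] = lab
        rows.append((int(c), ec_f, st_f, lab, ambiguous))
    evidence = pd.DataFrame(
        rows, columns=["cluster", "ec_fraction", "stromal_fraction", "label", "ambiguous"]
    ).set_index("cluster")
    return ClassLabel(labels=labels, evidence=evidence)


def exclude_lymphatic(
    adata: ad.AnnData,
    cluster_labels: np.ndarray,
    classes: ClassLabel,
    panel: tuple[str, ...] | list[str] = LYMPHATIC_PANEL,
    tau_pos: float = 0.5,
) -> ClassLabel:
    """Relabel EC clusters with high lymphatic-panel detection for exclusion.

    Only EC clusters are eligible; stromal clusters are never relabeled.
    Returns an updated :class:`ClassLabel` (the input is not mutated).
    """
    lymph = panel_detection_fraction(adata, cluster_labels, panel)
    labels = dict(classes.labels)
    evidence = classes.evidence.copy()
    evidence["lymphatic_fraction"] = lymph.reindex(evidence.index).fillna(0.0)
    for c, lab in labels.items():
        if lab == EC and evidence.loc[c, "lymphatic_fraction"] >= tau_pos:
            labels[c] = LYMPHATIC_EXCLUDED
    evidence["label"] = [labels[c] for c in evidence.index]
    return ClassLabel(labels=labels, evidence=evidence)
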
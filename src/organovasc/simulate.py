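"""Synthetic study-data generators with planted ground truth.

Three generators back the analysis pipeline:

* :func:`simulate_counts` — negative-binomial UMI count matrices emulating a
  six-condition endothelial/stromal co-culture experiment (~2:1
  stromal:endothelial seeding; endothelial cells 75–688 and stromal cells
  1065–5220 per condition), with planted endothelial subtypes, per-condition
  unique plus shared stromal populations, an optional lymphatic endothelial
  population, mitochondrial and ribosomal gene content, and deliberately
  QC-failing cells.
* :func:`simulate_vessel_image` — random planar vessel networks rasterized to
  tube-width images, with the centerline length and junction count recorded
  exactly at rasterization.
* :func:`simulate_go_fixture` — small GO DAGs with annotation maps and a
  planted enriched term.
* :func:`simulate_ec_groups` — three endothelial populations (2D monolayer,
  3D network, in vivo) sharing one gene space, with an organ-specific
  "in vivo program" expressed fully in vivo and partially in the 3D group.

Every generator draws all randomness from a single integer seed through
spawned :class:`numpy.random.Generator` streams, so fixtures are reproducible
byte for byte.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from skimage.draw import line as draw_line
from skimage.morphology import dilation, disk

from .errors import ConfigurationError
from .ontology import GODag

__all__ = [
    "EC_PANEL",
    "STROMAL_PANEL",
    "LYMPHATIC_PANEL",
    "SimulationSpec",
    "GroundTruth",
    "VesselImage",
    "VesselTruth",
    "simulate_counts",
    "simulate_vessel_image",
    "simulate_go_fixture",
    "simulate_ec_groups",
    "ORGAN_PRESETS",
]

# Marker panels used both for planting signal and for downstream
# classification (endothelial-positive, stromal-positive, lymphatic).
EC_PANEL = ("CDH5", "CLDN5", "ICAM2", "MCAM", "PECAM1")
STROMAL_PANEL = ("COL1A1", "COL1A2", "PDGFRA", "PDGFRB", "TAGLN")
LYMPHATIC_PANEL = ("FLT4", "LYVE1", "PDPN", "PROX1")

MITO_GENES = (
    "MT-ND1", "MT-ND2", "MT-CO1", "MT-CO2", "MT-ATP8", "MT-ATP6", "MT-CO3",
    "MT-ND3", "MT-ND4L", "MT-ND4", "MT-ND5", "MT-ND6", "MT-CYB",
)
RIBO_GENES = (
    "RPS2", "RPS3", "RPS4X", "RPS5", "RPS6", "RPS7", "RPS8", "RPS9",
    "RPS10", "RPS11", "RPS12", "RPS15A",
    "RPL3", "RPL4", "RPL5", "RPL6", "RPL7", "RPL8", "RPL9", "RPL10",
    "RPL11", "RPL13", "RPL15", "RPL23A",
)

CONDITION_NAMES = ("Skin", "Heart", "Lung", "Marrow", "nPancreas", "cPancreas")

# Per-condition endothelial subtype mixes (5 subtypes). Subtype 1 dominates,
# subtype 2 varies most between conditions and subtype 5 stays smallest,
# mimicking the composition gradients seen in organotypic co-cultures.
_DEFAULT_EC_PROPORTIONS = np.array(
    [
        [0.50, 0.10, 0.18, 0.14, 0.08],
        [0.48, 0.16, 0.15, 0.13, 0.08],
        [0.52, 0.14, 0.14, 0.12, 0.08],
        [0.46, 0.24, 0.12, 0.11, 0.07],
        [0.50, 0.20, 0.12, 0.11, 0.07],
        [0.44, 0.28, 0.11, 0.10, 0.07],
    ]
)

_N_EC_SUBTYPES = 5
# stromal split within a condition: unique population, then two shared ones
_OSC_SPLIT = (0.50, 0.35, 0.15)


@dataclass
class SimulationSpec:
    """Parameters of the co-culture count simulation.

    The defaults encode the study conditions being emulated: six co-culture
    conditions, endothelial cell counts drawn in 75–688 and stromal counts in
    1065–5220 per condition (~2:1 stromal:EC seeding), five endothelial
    subtypes, one condition-unique plus two shared stromal populations, and a
    16-fold (log2FC 4) planted marker effect.
    """

    n_conditions: int = 6
    ec_count_range: tuple[int, int] = (75, 688)
    osc_count_range: tuple[int, int] = (1065, 5220)
    n_genes: int = 5000
    ec_subtype_proportions: np.ndarray | None = None
    marker_log2fc: float = 4.0
    nb_dispersion: float = 0.25
    pct_mito_distribution: tuple[float, float] = (0.04, 0.015)
    lowq_cell_fraction: float = 0.05
    seed: int = 0
    # secondary knobs (not part of the headline study description)
    depth_mean: float = 2500.0
    library_sd: float = 0.3
    n_marker_genes: int = 16
    marker_baseline: float = 0.05
    include_lymphatic: bool = True
    lymphatic_fraction: float = 0.08

    def __post_init__(self):
        if self.n_conditions < 1:
            raise ConfigurationError("n_conditions must be >= 1")
        for name in ("ec_count_range", "osc_count_range"):
            lo, hi = getattr(self, name)
            if lo <= 0 or hi < lo:
                raise ConfigurationError(f"{name} must be positive and ordered")
        if not (0 <= self.lowq_cell_fraction < 1):
            raise ConfigurationError("lowq_cell_fraction must lie in [0, 1)")
        if self.marker_log2fc <= 0:
            raise ConfigurationError("marker_log2fc must be positive")
        if self.nb_dispersion < 0:
            raise ConfigurationError("nb_dispersion must be non-negative")
        if self.ec_subtype_proportions is None:
            reps = -(-self.n_conditions // len(_DEFAULT_EC_PROPORTIONS))
            self.ec_subtype_proportions = np.tile(_DEFAULT_EC_PROPORTIONS, (reps, 1))[
                : self.n_conditions
            ]
        self.ec_subtype_proportions = np.asarray(self.ec_subtype_proportions, dtype=float)
        if self.ec_subtype_proportions.ndim == 1:
            self.ec_subtype_proportions = np.tile(
                self.ec_subtype_proportions, (self.n_conditions, 1)
            )
        if self.ec_subtype_proportions.shape != (self.n_conditions, _N_EC_SUBTYPES):
            raise ConfigurationError(
                "ec_subtype_proportions must have shape "
                f"({self.n_conditions}, {_N_EC_SUBTYPES})"
            )
        sums = self.ec_subtype_proportions.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-12):
            raise ConfigurationError("ec_subtype_proportions rows must sum to 1")
        n_marker_blocks = _N_EC_SUBTYPES + self.n_conditions + 2 + int(self.include_lymphatic)
        reserved = (
            len(EC_PANEL)
            + len(STROMAL_PANEL)
            + len(LYMPHATIC_PANEL)
            + len(MITO_GENES)
            + len(RIBO_GENES)
            + n_marker_blocks * self.n_marker_genes
        )
        if self.n_genes < reserved + 10:
            raise ConfigurationError(
                f"n_genes={self.n_genes} too small to host all marker panels "
                f"(need at least {reserved + 10})"
            )


@dataclass
class GroundTruth:
    """Planted truth for a simulated dataset.

    ``cells`` is indexed by barcode with columns ``condition``,
    ``true_class`` (e.g. ``EC-1``, ``OSC-S2``, ``low-quality``) and
    ``lowq_mechanism``; ``genes`` is indexed by symbol with a ``marker_of``
    column naming the population or panel a gene is planted for.
    """

    cells: pd.DataFrame
    genes: pd.DataFrame

    @property
    def true_class(self) -> pd.Series:
        return self.cells["true_class"]


@dataclass
class VesselImage:
    """Grayscale vessel-network image with acquisition metadata."""

    pixels: np.ndarray
    pixel_size: float = 1.0
    threshold: float = 0.5


@dataclass
class VesselTruth:
    """Centerline truth recorded while rasterizing a vessel network."""

    length_px: float
    n_junctions: int
    centerline: np.ndarray
    segments: list | None = None


# ---------------------------------------------------------------------------
# count-matrix simulation
# ---------------------------------------------------------------------------

def _population_table(spec: SimulationSpec) -> tuple[list[dict], pd.DataFrame]:
    """Define gene symbols and population -> boosted-gene-set mapping."""
    marker_blocks: dict[str, list[str]] = {}
    for k in range(1, _N_EC_SUBTYPES + 1):
        marker_blocks[f"EC-{k}"] = [f"ECS{k}M{j:02d}" for j in range(spec.n_marker_genes)]
    if spec.include_lymphatic:
        extra = [f"LECM{j:02d}" for j in range(spec.n_marker_genes - len(LYMPHATIC_PANEL))]
        marker_blocks["EC-LYM"] = list(LYMPHATIC_PANEL) + extra
    for i in range(spec.n_conditions):
        marker_blocks[f"OSC-U{i + 1}"] = [
            f"OSCU{i + 1}M{j:02d}" for j in range(spec.n_marker_genes)
        ]
    for s in (1, 2):
        marker_blocks[f"OSC-S{s}"] = [f"OSCS{s}M{j:02d}" for j in range(spec.n_marker_genes)]

    named = (
        list(EC_PANEL)
        + list(STROMAL_PANEL)
        + list(LYMPHATIC_PANEL)
        + list(MITO_GENES)
        + list(RIBO_GENES)
        + [g for block in marker_blocks.values() for g in block if g not in LYMPHATIC_PANEL]
    )
    n_filler = spec.n_genes - len(named)
    genes = named + [f"GENE{i:04d}" for i in range(n_filler)]

    marker_of = pd.Series("background", index=pd.Index(genes, name="gene"))
    marker_of[list(EC_PANEL)] = "panel:EC"
    marker_of[list(STROMAL_PANEL)] = "panel:stromal"
    marker_of[list(LYMPHATIC_PANEL)] = "panel:lymphatic"
    marker_of[list(MITO_GENES)] = "mito"
    marker_of[list(RIBO_GENES)] = "ribo"
    for pop, block in marker_blocks.items():
        for g in block:
            if g not in LYMPHATIC_PANEL:
                marker_of[g] = pop

    populations = []
    for k in range(1, _N_EC_SUBTYPES + 1):
        populations.append(
            dict(name=f"EC-{k}", kind="EC", boosted=list(EC_PANEL) + marker_blocks[f"EC-{k}"])
        )
    if spec.include_lymphatic:
        populations.append(
            dict(
                name="EC-LYM",
                kind="EC",
                boosted=list(EC_PANEL) + marker_blocks["EC-LYM"],
            )
        )
    for i in range(spec.n_conditions):
        populations.append(
            dict(
                name=f"OSC-U{i + 1}",
                kind="OSC",
                boosted=list(STROMAL_PANEL) + marker_blocks[f"OSC-U{i + 1}"],
            )
        )
    for s in (1, 2):
        populations.append(
            dict(
                name=f"OSC-S{s}",
                kind="OSC",
                boosted=list(STROMAL_PANEL) + marker_blocks[f"OSC-S{s}"],
            )
        )
    gene_truth = pd.DataFrame({"marker_of": marker_of})
    return populations, gene_truth


def _nb_sample(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial draws, mean ``mu``, variance ``mu + dispersion*mu**2``."""
    if dispersion <= 1e-12:
        return rng.poisson(mu)
    r = 1.0 / dispersion
    p = r / (r + mu)
    return rng.negative_binomial(r, p)


def simulate_counts(spec: SimulationSpec) -> tuple[ad.AnnData, GroundTruth]:
    """Simulate a multi-condition UMI count matrix with planted structure.

    Returns a cells-x-genes :class:`AnnData` with raw integer counts in
    ``X``, per-cell ``condition``/``true_class`` in ``obs``, planted marker
    membership in ``var`` — and the same truth bundled as a
    :class:`GroundTruth`.
    """
    root = np.random.SeedSequence(spec.seed)
    rng_sizes, rng_means, rng_cells, rng_counts = (
        np.random.default_rng(s) for s in root.spawn(4)
    )

    populations, gene_truth = _population_table(spec)
    genes = list(gene_truth.index)
    gene_idx = {g: i for i, g in enumerate(genes)}
    n_genes = len(genes)

    # Per-gene baseline means (arbitrary library-fraction units, normalized
    # per cell later). Ribosomal genes are given high expression so that the
    # RPS/RPL content metric has realistic weight.
    base = np.zeros(n_genes)
    is_bg = (gene_truth["marker_of"] == "background").to_numpy()
    base[is_bg] = np.clip(rng_means.lognormal(np.log(0.08), 1.0, is_bg.sum()), 1e-4, 3.0)
    for g in RIBO_GENES:
        base[gene_idx[g]] = rng_means.uniform(2.0, 4.0)
    marker_like = ~is_bg & ~gene_truth["marker_of"].isin(["mito", "ribo"]).to_numpy()
    base[marker_like] = spec.marker_baseline
    mito_ix = np.array([gene_idx[g] for g in MITO_GENES])
    mito_profile = rng_means.lognormal(0.0, 0.5, len(mito_ix))
    mito_profile /= mito_profile.sum()

    boost = 2.0 ** spec.marker_log2fc
    pop_profiles = {}
    for pop in populations:
        mean = base.copy()
        for g in pop["boosted"]:
            mean[gene_idx[g]] *= boost
        mean[mito_ix] = 0.0
        pop_profiles[pop["name"]] = mean / mean.sum()

    mito_mean, mito_sd = spec.pct_mito_distribution
    conditions = [
        CONDITION_NAMES[i] if i < len(CONDITION_NAMES) else f"Cond{i + 1}"
        for i in range(spec.n_conditions)
    ]

    blocks: list[sp.csr_matrix] = []
    obs_rows: list[tuple[str, str, str]] = []
    ambient_possible = spec.n_genes >= 8000
    lowq_mechs = ["low_depth", "high_mito"] + (["ambient"] if ambient_possible else [])

    for ci, cond in enumerate(conditions):
        n_ec = int(rng_sizes.integers(spec.ec_count_range[0], spec.ec_count_range[1] + 1))
        n_osc = int(rng_sizes.integers(spec.osc_count_range[0], spec.osc_count_range[1] + 1))

        pop_sizes: list[tuple[str, int]] = []
        props = spec.ec_subtype_proportions[ci]
        if spec.include_lymphatic:
            n_lym = int(round(spec.lymphatic_fraction * n_ec))
            pop_sizes.append(("EC-LYM", n_lym))
        else:
            n_lym = 0
        ec_rest = n_ec - n_lym
        sub_sizes = np.floor(props * ec_rest).astype(int)
        sub_sizes[0] += ec_rest - sub_sizes.sum()
        for k in range(_N_EC_SUBTYPES):
            pop_sizes.append((f"EC-{k + 1}", int(sub_sizes[k])))
        osc_sizes = np.floor(np.array(_OSC_SPLIT) * n_osc).astype(int)
        osc_sizes[0] += n_osc - osc_sizes.sum()
        for name, size in zip((f"OSC-U{ci + 1}", "OSC-S1", "OSC-S2"), osc_sizes):
            pop_sizes.append((name, int(size)))

        for pop_name, size in pop_sizes:
            if size == 0:
                continue
            profile = pop_profiles[pop_name]
            lowq = rng_cells.random(size) < spec.lowq_cell_fraction
            mech = np.where(
                lowq,
                rng_cells.choice(lowq_mechs, size=size),
                "",
            )
            depth = spec.depth_mean * rng_cells.lognormal(0.0, spec.library_sd, size)
            m = np.clip(rng_cells.normal(mito_mean, mito_sd, size), 0.001, 0.09)
            # dedicated QC violators
            depth[mech == "low_depth"] = rng_cells.uniform(30, 90, (mech == "low_depth").sum())
            m[mech == "high_mito"] = rng_cells.uniform(0.25, 0.55, (mech == "high_mito").sum())
            mu = depth[:, None] * profile[None, :]  # profile is zero on MT genes
            counts = _nb_sample(rng_counts, mu, spec.nb_dispersion)
            # mitochondrial content is pinned to the per-cell target fraction:
            # counts are allocated multinomially so clean cells cannot drift
            # across the QC boundary through sampling noise
            nonmito_tot = counts.sum(axis=1)
            mito_tot = np.round(nonmito_tot * m / (1 - m)).astype(np.int64)
            counts[:, mito_ix] = rng_counts.multinomial(mito_tot, mito_profile)
            if ambient_possible and (mech == "ambient").any():
                amb = mech == "ambient"
                flat_mu = np.full(n_genes, 4.0)
                counts[amb] = _nb_sample(
                    rng_counts, np.tile(flat_mu, (amb.sum(), 1)), spec.nb_dispersion
                )
            blocks.append(sp.csr_matrix(counts.astype(np.int32)))
            for j in range(size):
                cls = "low-quality" if lowq[j] else pop_name
                obs_rows.append((cond, cls, mech[j]))

    X = sp.vstack(blocks, format="csr")
    barcodes = [f"BC{i:06d}" for i in range(X.shape[0])]
    obs = pd.DataFrame(
        obs_rows,
        columns=["condition", "true_class", "lowq_mechanism"],
        index=pd.Index(barcodes, name="barcode"),
    )
    adata = ad.AnnData(X=X, obs=obs, var=gene_truth.copy())
    adata.uns["simulation"] = {
        "seed": spec.seed,
        "n_conditions": spec.n_conditions,
        "marker_log2fc": spec.marker_log2fc,
        "nb_dispersion": spec.nb_dispersion,
        "lowq_cell_fraction": spec.lowq_cell_fraction,
    }
    truth = GroundTruth(cells=obs.copy(), genes=gene_truth.copy())
    return adata, truth


# ---------------------------------------------------------------------------
# vessel-image simulation
# ---------------------------------------------------------------------------

def _centerline_metrics(mask: np.ndarray, merge_radius_px: int = 2) -> tuple[float, int]:
    """Length (orthogonal 1 / diagonal sqrt(2) steps) and junction count of a
    1-px centerline mask; recorded at rasterization time."""
    from .morphometry import count_junctions, total_length

    return float(total_length(mask, 1.0)), int(count_junctions(mask, merge_radius_px))


def simulate_vessel_image(
    n_segments: int,
    width_px: int = 5,
    noise_sd: float = 0.05,
    seed: int = 0,
    shape: tuple[int, int] = (256, 256),
    branch_prob: float = 0.6,
    segments: Sequence[tuple[tuple[int, int], tuple[int, int]]] | None = None,
) -> tuple[VesselImage, VesselTruth]:
    """Draw a random planar line network and dilate it to tube width.

    A first segment is placed at random; each further segment either branches
    from a random interior pixel of the existing network (probability
    ``branch_prob``, producing a degree-3 junction) or starts at a fresh
    location.  Candidate segments that would cross or shadow the existing
    network away from their attachment point are rejected and redrawn, so
    the recorded truth (centerline length with orthogonal step 1 and diagonal
    step sqrt(2); junctions = merged clusters of centerline pixels with
    >= 3 neighbors) is exact.

    Explicit ``segments`` (list of ((r0, c0), (r1, c1)) endpoints) bypass the
    random placement; a segment fully outside the canvas is an error.
    """
    if n_segments < 1 and segments is None:
        raise ConfigurationError("n_segments must be >= 1")
    if width_px < 1 or width_px % 2 == 0:
        raise ConfigurationError("width_px must be odd and >= 1")
    rng = np.random.default_rng(seed)
    h, w = shape
    mask = np.zeros(shape, dtype=bool)
    margin = max(width_px, 6)

    def rasterize(p0, p1):
        rr, cc = draw_line(int(p0[0]), int(p0[1]), int(p1[0]), int(p1[1]))
        keep = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
        return rr[keep], cc[keep]

    if segments is not None:
        for p0, p1 in segments:
            rr, cc = rasterize(p0, p1)
            if rr.size == 0:
                raise ConfigurationError(f"segment {p0}->{p1} lies fully outside the canvas")
            mask[rr, cc] = True
    else:
        seg_pixels: list[np.ndarray] = []

        clear = width_px + 2  # min centerline separation preventing tube merges
        reach = 3 * width_px  # chain steps a branch may spend leaving its host

        def try_place(near, start=None, host_dir=None, host_zone=None):
            for _ in range(60):
                if start is None:
                    p0 = rng.integers(margin, [h - margin, w - margin])
                else:
                    p0 = start
                ang = rng.uniform(0, 2 * np.pi)
                if host_dir is not None:
                    # shallow branches smear the junction under dilation and
                    # re-thinning; demand a clear angle to the host segment
                    diff = abs(((ang - host_dir) + np.pi / 2) % np.pi - np.pi / 2)
                    if diff < np.deg2rad(40):
                        continue
                length = rng.uniform(60, 130)
                p1 = np.clip(
                    np.round(p0 + length * np.array([np.sin(ang), np.cos(ang)])),
                    margin,
                    [h - margin - 1, w - margin - 1],
                ).astype(int)
                rr, cc = rasterize(p0, p1)
                if rr.size < 15:
                    continue
                # Only a branch's first few chain pixels may come near the
                # existing network, and only inside its own host's vicinity
                # (leaving the host tube). Anywhere else, proximity would
                # merge the dilated tubes and plant an unrecorded junction.
                if start is not None and host_zone is not None:
                    allowed = (np.arange(rr.size) <= reach) & host_zone[rr, cc]
                else:
                    allowed = np.zeros(rr.size, dtype=bool)
                if np.any(near[rr, cc] & ~allowed):
                    continue
                return rr, cc
            return None

        junction_points: list[np.ndarray] = []
        min_junction_sep = 3 * width_px  # keeps anatomical junctions resolvable
        placed = 0
        misses = 0
        while placed < n_segments:
            near = dilation(mask, disk(clear))
            branch = placed > 0 and rng.random() < branch_prob
            res = None
            start = None
            if branch:
                host_dir = host_zone = None
                end_gap = 12  # attachments near a host end form V apexes
                for _ in range(30):
                    host = seg_pixels[rng.integers(len(seg_pixels))]
                    n_host = len(host[0])
                    if n_host < 2 * end_gap + 3:
                        continue
                    k = int(rng.integers(end_gap, n_host - end_gap))
                    cand = np.array([host[0][k], host[1][k]])
                    if all(
                        np.hypot(*(cand - jp)) >= min_junction_sep
                        for jp in junction_points
                    ):
                        start = cand
                        lo, hi = max(0, k - 8), min(n_host - 1, k + 8)
                        host_dir = np.arctan2(
                            host[0][hi] - host[0][lo], host[1][hi] - host[1][lo]
                        )
                        zone = np.zeros(shape, dtype=bool)
                        s0, s1 = max(0, k - reach), min(n_host, k + reach)
                        zone[host[0][s0:s1], host[1][s0:s1]] = True
                        host_zone = dilation(zone, disk(clear))
                        break
                if start is not None:
                    res = try_place(near, start, host_dir, host_zone)
            if res is None:
                start = None
                res = try_place(near)
            if res is None:
                misses += 1
                if misses >= 5:
                    # canvas saturated for this width; stop adding segments
                    warnings.warn("vessel canvas saturated before reaching n_segments")
                    break
                continue
            if branch and start is not None:
                junction_points.append(start)
            rr, cc = res
            mask[rr, cc] = True
            seg_pixels.append((rr, cc))
            placed += 1

    length_px, n_junctions = _centerline_metrics(mask)
    img = dilation(mask, disk(width_px // 2)).astype(float)
    if noise_sd > 0:
        img = np.clip(img + rng.normal(0.0, noise_sd, img.shape), 0.0, 1.0)
    return (
        VesselImage(pixels=img, pixel_size=1.0, threshold=0.5),
        VesselTruth(
            length_px=length_px,
            n_junctions=n_junctions,
            centerline=mask,
            segments=None if segments is not None else seg_pixels,
        ),
    )


# ---------------------------------------------------------------------------
# GO fixture simulation
# ---------------------------------------------------------------------------

def simulate_go_fixture(
    n_terms: int = 30,
    depth: int = 3,
    planted_term: str | Sequence[str] | None = None,
    seed: int = 0,
    n_genes: int = 200,
    genes_per_planted: int = 12,
    universe: Sequence[str] | None = None,
    planted_genes: Sequence[str] | None = None,
):
    """Build a small random GO DAG plus annotations with a planted signal.

    ``depth`` counts levels including the root (``depth=1`` is a root-only
    ontology).  Each planted term receives ``genes_per_planted`` dedicated
    genes, most of which are placed into the significant set, so the term is
    genuinely over-represented.

    A caller may supply its own gene ``universe`` (e.g. the symbols of a
    simulated count matrix) and, for a single planted term, the explicit
    ``planted_genes`` to annotate to it.

    Returns ``(dag, annotations, universe, significant)`` where
    ``annotations`` maps gene -> set of *directly* annotated term ids.
    """
    if depth < 1 or n_terms < 1:
        raise ConfigurationError("depth and n_terms must be >= 1")
    rng = np.random.default_rng(seed)
    root = "GO:0000001"
    if depth == 1:
        import networkx as nx

        g = nx.DiGraph()
        g.add_node(root, name="biological_process", namespace="biological_process")
        dag = GODag(g)
        non_root: list[str] = []
    else:
        n_rest = n_terms - 1
        ids = [f"GO:{i + 2:07d}" for i in range(n_rest)]
        levels = np.sort(rng.integers(1, depth, n_rest))
        by_level: dict[int, list[str]] = {0: [root]}
        for t, lvl in zip(ids, levels):
            by_level.setdefault(int(lvl), []).append(t)
        edges = []
        for lvl in sorted(by_level):
            if lvl == 0:
                continue
            parents_pool = by_level.get(lvl - 1) or [root]
            for t in by_level[lvl]:
                n_par = 1 + int(rng.random() < 0.3 and len(parents_pool) > 1)
                chosen = rng.choice(len(parents_pool), size=n_par, replace=False)
                for c in chosen:
                    edges.append((t, parents_pool[c]))
        dag = GODag.from_edges(edges)
        non_root = ids

    if planted_term is None:
        planted = [non_root[-1]] if non_root else [root]
    elif isinstance(planted_term, str):
        planted = [planted_term]
    else:
        planted = list(planted_term)
    for t in planted:
        if t not in dag:
            raise ConfigurationError(f"planted term {t} not in the generated DAG")

    if universe is None:
        universe = [f"G{i:04d}" for i in range(n_genes)]
    else:
        universe = list(universe)
    annotations: dict[str, set[str]] = {g: set() for g in universe}
    assigned: dict[str, list[str]] = {}
    if planted_genes is not None:
        if len(planted) != 1:
            raise ConfigurationError("explicit planted_genes needs a single planted term")
        block = [g for g in planted_genes if g in annotations]
        if not block:
            raise ConfigurationError("planted_genes not found in the universe")
        assigned[planted[0]] = block
        cursor = 0
    else:
        cursor = 0
        for t in planted:
            block = universe[cursor : cursor + genes_per_planted]
            cursor += genes_per_planted
            assigned[t] = block
    for t, block in assigned.items():
        for g in block:
            annotations[g].add(t)
    planted_set = {g for block in assigned.values() for g in block}
    pool = non_root if non_root else [root]
    for g in universe[cursor:]:
        if g in planted_set:
            continue
        k = int(rng.integers(1, 4))
        for c in rng.choice(len(pool), size=min(k, len(pool)), replace=False):
            annotations[g].add(pool[c])

    significant: set[str] = set()
    for t in planted:
        block = assigned[t]
        keep = max(1, int(0.85 * len(block)))
        significant.update(block[:keep])
    bg = [g for g in universe if g not in significant]
    n_bg = min(5, len(bg))
    for c in rng.choice(len(bg), size=n_bg, replace=False):
        significant.add(bg[c])
    return dag, annotations, universe, significant


# ---------------------------------------------------------------------------
# three-group endothelial sets for the in-vivo similarity score
# ---------------------------------------------------------------------------

# Organ presets: how far along the 2D -> in-vivo axis (in log-fold-change
# units of the in-vivo program) the 3D network group sits, emulating the
# qualitative ordering seen across organs (skin far along; heart, lung and
# pancreas closer to the monolayer).
ORGAN_PRESETS = {
    "skin": 0.74,
    "heart": 0.09,
    "lung": 0.07,
    "npancreas": 0.06,
}


def simulate_ec_groups(
    organ: str = "skin",
    seed: int = 0,
    n_genes: int = 600,
    n_invivo: int = 800,
    n_network: int = 450,
    n_mono: int = 2000,
    n_program_genes: int = 30,
    program_log2fc: float = 3.0,
    network_position: float | None = None,
    nb_dispersion: float = 0.25,
    depth_mean: float = 2000.0,
    library_sd: float = 0.3,
) -> ad.AnnData:
    """Simulate 2D-monolayer, 3D-network and in-vivo endothelial groups.

    All groups share one gene space. An organ-specific in-vivo program of
    ``n_program_genes`` genes is overexpressed by ``program_log2fc`` in the
    in-vivo group and by ``network_position * program_log2fc`` in the 3D
    group (``network_position`` defaults to the organ preset), leaving the
    monolayer at baseline.  Returns cells x genes counts with ``obs.group``
    in {MONO_2D, NETWORK_3D, IN_VIVO} and ``var.in_program``.
    """
    if network_position is None:
        if organ not in ORGAN_PRESETS:
            raise ConfigurationError(
                f"unknown organ {organ!r}; pass network_position explicitly"
            )
        network_position = ORGAN_PRESETS[organ]
    if not 0 <= network_position <= 1:
        raise ConfigurationError("network_position must lie in [0, 1]")
    if n_program_genes >= n_genes:
        raise ConfigurationError("n_program_genes must be smaller than n_genes")
    root = np.random.SeedSequence(seed)
    rng_means, rng_cells, rng_counts = (np.random.default_rng(s) for s in root.spawn(3))

    prog = [f"{organ.upper()}IVP{j:02d}" for j in range(n_program_genes)]
    genes = prog + [f"GENE{i:04d}" for i in range(n_genes - n_program_genes)]
    base = np.clip(rng_means.lognormal(np.log(0.2), 1.0, n_genes), 1e-4, 5.0)
    base[:n_program_genes] = np.clip(base[:n_program_genes], 0.05, None)

    group_sizes = {"MONO_2D": n_mono, "NETWORK_3D": n_network, "IN_VIVO": n_invivo}
    group_boost = {
        "MONO_2D": 1.0,
        "NETWORK_3D": 2.0 ** (network_position * program_log2fc),
        "IN_VIVO": 2.0 ** program_log2fc,
    }
    blocks, obs_rows = [], []
    for grp, size in group_sizes.items():
        mean = base.copy()
        mean[:n_program_genes] *= group_boost[grp]
        profile = mean / mean.sum()
        depth = depth_mean * rng_cells.lognormal(0.0, library_sd, size)
        mu = depth[:, None] * profile[None, :]
        counts = _nb_sample(rng_counts, mu, nb_dispersion)
        blocks.append(sp.csr_matrix(counts.astype(np.int32)))
        obs_rows += [(grp, organ)] * size
    X = sp.vstack(blocks, format="csr")
    obs = pd.DataFrame(
        obs_rows,
        columns=["group", "organ"],
        index=pd.Index([f"EC{i:06d}" for i in range(X.shape[0])], name="barcode"),
    )
    var = pd.DataFrame(
        {"in_program": [g in set(prog) for g in genes]},
        index=pd.Index(genes, name="gene"),
    )
    adata = ad.AnnData(X=X, obs=obs, var=var)
    adata.uns["organ"] = organ
    adata.uns["network_position"] = float(network_position)
    return adata
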
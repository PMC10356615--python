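"""Synthetic decidua datasets with known ground truth.

The generator emulates the statistical and geometric structure the
analysis assumes — staged artery rasters with concentric smooth-muscle and
endothelium rings, clustered cell placements with GA/stage-dependent
composition and marker positivity, and ROI count matrices with quadratic
expression trajectories, planted coordinated pathways and lognormal
negative-probe background — so that every pipeline stage can be tested
against planted parameters without any external download.

Artery outlines are ellipses with a sinusoidal boundary perturbation
(controllable jaggedness); remodelling stage 1 arteries are small with
near-complete smooth-muscle and endothelial rings, stage 5 arteries are
large, smooth-muscle-depleted and EVT-lined. Counts use lognormal noise
(the normalization operates on continuous scaled counts); a negative
binomial option is available via ``count_noise``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .model import FeatureMasks, ImageMeta, PathwaySet, RoiExpression


@dataclass
class StageGeometry:
    """Artery geometry for one manual remodelling stage."""

    lumen_radius: float
    wall_thickness: float
    sma_coverage: float        # angular fraction of intact smooth muscle
    endo_coverage: float       # angular fraction of intact endothelium
    n_intravascular_evt: int
    n_perivascular_evt: int
    wobble_amp: float = 0.04   # sinusoidal boundary perturbation amplitude
    ellipticity: float = 1.1


#: Default stage morphology: progressive dilation, smooth-muscle loss,
#: endothelial disruption and EVT infiltration from stage 1 to 5.
DEFAULT_STAGE_GEOMETRY: dict[int, StageGeometry] = {
    1: StageGeometry(18, 14, 0.95, 0.95, 0, 0, wobble_amp=0.03),
    2: StageGeometry(24, 13, 0.80, 0.85, 0, 2, wobble_amp=0.05),
    3: StageGeometry(32, 12, 0.55, 0.60, 3, 6, wobble_amp=0.07),
    4: StageGeometry(42, 10, 0.30, 0.35, 8, 10, wobble_amp=0.09),
    5: StageGeometry(54, 8, 0.05, 0.10, 15, 12, wobble_amp=0.11),
}

#: Manual-stage frequencies matching a first-half-of-pregnancy cohort
#: (unremodelled arteries dominate).
DEFAULT_STAGE_WEIGHTS = {1: 186, 2: 300, 3: 43, 4: 34, 5: 25}

DEFAULT_LINEAGES = (
    "NK1", "NK2", "Mac1a", "Mac2a", "T", "CD4T", "fibroblast",
    "myofibroblast", "endothelial", "glandular", "muscle",
    "EVT1a", "EVT1b", "other",
)

IMMUNE_LINEAGES = ("NK1", "NK2", "Mac1a", "Mac2a", "T", "CD4T")

DEFAULT_MARKERS = (
    "CD3", "CD4", "CD14", "CD11c", "CD56", "CD57", "CK7", "FOXP3",
    "HLAG", "Ki67", "PDL1", "tryptase",
)


@dataclass
class SimulationSpec:
    """Study conditions for a synthetic cohort.

    Defaults mirror the study design: 66 subjects sampled across 6-20
    weeks of gestation, a handful of images per subject, artery stages
    correlated with GA (``stage_ga_correlation``), and composition/marker
    trends of realistic effect size (a lymphoid-to-myeloid shift along GA,
    EVT enrichment along remodelling).
    """

    n_subjects: int = 66
    images_per_subject: int = 2
    ga_range: tuple[int, int] = (42, 140)
    arteries_per_image: tuple[int, int] = (1, 3)
    fov_size: int = 400
    cells_per_image: int = 500
    stage_ga_correlation: float = 0.5
    stage_geometry: dict[int, StageGeometry] = field(
        default_factory=lambda: dict(DEFAULT_STAGE_GEOMETRY)
    )
    stage_weights: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_STAGE_WEIGHTS)
    )
    lineages: tuple[str, ...] = DEFAULT_LINEAGES
    markers: tuple[str, ...] = DEFAULT_MARKERS
    base_fractions: dict[str, float] = field(
        default_factory=lambda: {
            "NK1": 0.14, "NK2": 0.06, "Mac1a": 0.10, "Mac2a": 0.06,
            "T": 0.05, "CD4T": 0.03, "fibroblast": 0.30,
            "myofibroblast": 0.12, "endothelial": 0.04, "glandular": 0.03,
            "muscle": 0.02, "EVT1a": 0.02, "EVT1b": 0.01, "other": 0.02,
        }
    )
    #: lineage -> (axis, fraction at axis minimum, fraction at axis max);
    #: axis is "ga" or "stage". The published cohort shows a GA-driven
    #: lymphoid-to-myeloid shift and SAR-driven EVT accumulation.
    composition_trends: dict[str, tuple[str, float, float]] = field(
        default_factory=lambda: {
            "Mac1a": ("ga", 0.05, 0.22),
            "NK1": ("ga", 0.22, 0.08),
            "T": ("ga", 0.08, 0.03),
            "EVT1a": ("stage", 0.01, 0.10),
            "NK2": ("stage", 0.03, 0.10),
        }
    )
    #: (lineage, marker) -> baseline positive fraction.
    marker_positivity: dict[tuple[str, str], float] = field(
        default_factory=lambda: {
            ("T", "CD3"): 0.95, ("CD4T", "CD3"): 0.95, ("CD4T", "CD4"): 0.9,
            ("NK1", "CD56"): 0.9, ("NK2", "CD56"): 0.85, ("NK2", "CD57"): 0.85,
            ("Mac1a", "CD14"): 0.9, ("Mac2a", "CD14"): 0.9,
            ("Mac2a", "CD11c"): 0.7, ("EVT1a", "HLAG"): 0.9,
            ("EVT1a", "CK7"): 0.9, ("EVT1b", "HLAG"): 0.85,
            ("EVT1b", "CK7"): 0.85, ("glandular", "CK7"): 0.9,
        }
    )
    #: (lineage, marker) -> (axis, fraction lo, fraction hi) positivity trend.
    positivity_trends: dict[tuple[str, str], tuple[str, float, float]] = field(
        default_factory=lambda: {
            ("Mac1a", "PDL1"): ("ga", 0.1, 0.6),
            ("EVT1a", "Ki67"): ("stage", 0.4, 0.05),
        }
    )
    #: lineage pairs placed around shared cluster parents (planted spatial
    #: enrichment); None disables clustering for all lineages.
    clustered_pairs: tuple[tuple[str, str], ...] = (("NK2", "Mac2a"),)
    cluster_sd: float = 40.0
    clusters_per_image: int = 6
    cell_area_mean: float = 150.0
    # gene model
    n_genes: int = 400
    n_trending_delta: int = 60
    n_trending_ga: int = 30
    gene_fold_change: float = 4.0
    gene_noise_sigma: float = 0.15
    background_level: float = 4.0
    background_sigma: float = 0.4
    n_neg_probes: int = 100
    count_scale: float = 200.0
    count_noise: str = "lognormal"  # or "nb"
    nb_dispersion: float = 10.0
    #: name -> (n genes, target COM on the delta axis in [1,5], COM spread)
    planted_pathways: dict[str, tuple[int, float, float]] = field(
        default_factory=lambda: {"PLANTED_EARLY": (12, 2.0, 0.1)}
    )
    #: gene -> log2 shift in intravascular vs interstitial EVT ROIs
    de_genes: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        for g in self.stage_geometry.values():
            if not (0 <= g.sma_coverage <= 1 and 0 <= g.endo_coverage <= 1):
                raise ValueError("angular coverages must be in [0, 1]")
        outer = max(
            (g.lumen_radius + g.wall_thickness) * g.ellipticity * (1 + g.wobble_amp)
            for g in self.stage_geometry.values()
        )
        if 2 * outer >= self.fov_size:
            raise ValueError("stage geometry does not fit inside the image")
        n_pathway_genes = sum(n for n, _, _ in self.planted_pathways.values())
        if n_pathway_genes > self.n_genes:
            raise ValueError("planted pathway genes exceed n_genes")


def simulate_artery_mask(
    stage: int,
    geometry: StageGeometry,
    rng: np.random.Generator,
    canvas: int | None = None,
) -> tuple[np.ndarray, tuple[float, float], dict[str, np.ndarray], dict]:
    """Rasterize one artery and its wall-marker channels on a local canvas.

    Returns (mask, centre, marker rasters, truth). The mask covers the
    whole vessel (wall + lumen); SMA fills the wall ring over a contiguous
    arc of the stage's angular coverage, CD31 a thin ring at the lumen
    boundary over its own arc, HLA-G/CK7 blobs mark intravascular EVTs,
    and VIM/H3 fill the tissue. Truth records the planted coverages and
    EVT counts.
    """
    r_out_base = geometry.lumen_radius + geometry.wall_thickness
    r_max = r_out_base * geometry.ellipticity * (1 + geometry.wobble_amp) + 2
    size = canvas or int(np.ceil(2 * r_max + 8))
    if 2 * r_max >= size:
        raise ValueError("artery geometry overflows the canvas")
    c = size / 2.0
    yy, xx = np.mgrid[0:size, 0:size]
    dx = (xx - c) / geometry.ellipticity
    dy = yy - c
    r = np.hypot(dx, dy)
    theta = np.mod(np.arctan2(-dy, dx), 2 * np.pi)
    phase = rng.uniform(0, 2 * np.pi)
    wobble = 1 + geometry.wobble_amp * np.sin(3 * theta + phase)
    r_outer = r_out_base * wobble
    r_lumen = geometry.lumen_radius * wobble
    mask = r <= r_outer
    wall = mask & (r >= r_lumen)
    endo_ring = np.abs(r - r_lumen) <= 3.0

    def arc(fraction: float) -> np.ndarray:
        if fraction >= 1:
            return np.ones_like(theta, dtype=bool)
        if fraction <= 0:
            return np.zeros_like(theta, dtype=bool)
        start = rng.uniform(0, 2 * np.pi)
        width = 2 * np.pi * fraction
        return np.mod(theta - start, 2 * np.pi) <= width

    sma_arc = arc(geometry.sma_coverage)
    endo_arc = arc(geometry.endo_coverage)

    def noisy(region: np.ndarray, mean: float, sigma: float = 0.25) -> np.ndarray:
        out = rng.lognormal(np.log(0.02), 0.5, size=(size, size))
        vals = rng.lognormal(np.log(mean), sigma, size=int(region.sum()))
        out[region] = vals
        return out

    rasters = {
        "SMA": noisy(wall & sma_arc, 1.0),
        "CD31": noisy(endo_ring & endo_arc & mask, 1.0),
        "VIM": noisy(mask, 0.6),
        "H3": noisy(mask, 0.5),
    }
    hlag = rng.lognormal(np.log(0.02), 0.5, size=(size, size))
    ck7 = rng.lognormal(np.log(0.02), 0.5, size=(size, size))
    evt_xy = []
    for _ in range(geometry.n_intravascular_evt):
        ang = rng.uniform(0, 2 * np.pi)
        rad = rng.uniform(0, max(geometry.lumen_radius - 5, 1))
        ex = c + rad * np.cos(ang) * geometry.ellipticity
        ey = c - rad * np.sin(ang)
        blob = (xx - ex) ** 2 + (yy - ey) ** 2 <= 16
        hlag[blob] = rng.lognormal(np.log(1.2), 0.2, size=int(blob.sum()))
        ck7[blob] = rng.lognormal(np.log(1.0), 0.2, size=int(blob.sum()))
        evt_xy.append((float(ex), float(ey)))
    rasters["HLAG"] = hlag
    rasters["CK7"] = ck7
    truth = {
        "stage": stage,
        "sma_coverage": geometry.sma_coverage,
        "endo_coverage": geometry.endo_coverage,
        "n_intravascular_evt": geometry.n_intravascular_evt,
        "intravascular_evt_xy": evt_xy,
        "lumen_radius": geometry.lumen_radius,
        "wall_thickness": geometry.wall_thickness,
    }
    return mask, (c, c), rasters, truth


def _interp_geometry(spec: SimulationSpec, t: float) -> StageGeometry:
    """Continuous morphology along the latent remodelling coordinate t in
    [1, 5], linearly interpolated between adjacent stage geometries."""
    t = float(np.clip(t, 1, 5))
    lo = int(np.floor(t))
    hi = min(lo + 1, 5)
    w = t - lo
    a, b = spec.stage_geometry[lo], spec.stage_geometry[hi]
    mix = lambda u, v: (1 - w) * u + w * v
    return StageGeometry(
        lumen_radius=mix(a.lumen_radius, b.lumen_radius),
        wall_thickness=mix(a.wall_thickness, b.wall_thickness),
        sma_coverage=mix(a.sma_coverage, b.sma_coverage),
        endo_coverage=mix(a.endo_coverage, b.endo_coverage),
        n_intravascular_evt=int(round(mix(a.n_intravascular_evt, b.n_intravascular_evt))),
        n_perivascular_evt=int(round(mix(a.n_perivascular_evt, b.n_perivascular_evt))),
        wobble_amp=mix(a.wobble_amp, b.wobble_amp),
        ellipticity=mix(a.ellipticity, b.ellipticity),
    )


def _composition(spec: SimulationSpec, ga_norm: float, stage_norm: float) -> np.ndarray:
    """Lineage probabilities for one image given normalized GA/stage."""
    probs = {}
    trended_mass = 0.0
    for lin, (axis, lo, hi) in spec.composition_trends.items():
        x = ga_norm if axis == "ga" else stage_norm
        probs[lin] = lo + (hi - lo) * x
        trended_mass += probs[lin]
    rest = {
        lin: spec.base_fractions.get(lin, 0.0)
        for lin in spec.lineages
        if lin not in probs
    }
    rest_total = sum(rest.values())
    remaining = max(1.0 - trended_mass, 0.0)
    for lin, w in rest.items():
        probs[lin] = remaining * w / rest_total if rest_total else 0.0
    p = np.array([probs.get(lin, 0.0) for lin in spec.lineages])
    return p / p.sum()


def _positivity_fraction(
    spec: SimulationSpec, lineage: str, marker: str, ga_norm: float, stage_norm: float
) -> float:
    if (lineage, marker) in spec.positivity_trends:
        axis, lo, hi = spec.positivity_trends[(lineage, marker)]
        x = ga_norm if axis == "ga" else stage_norm
        return float(np.clip(lo + (hi - lo) * x, 0, 1))
    return spec.marker_positivity.get((lineage, marker), 0.03)


#: Per-pixel signal-density laws for positive and negative cells; raw
#: marker totals are density x area so area normalization recovers them.
_POS_LOGMEAN, _POS_SIGMA = np.log(1.0), 0.3
_NEG_LOGMEAN, _NEG_SIGMA = np.log(0.05), 0.5
#: Raw-density threshold separating the two modes (geometric midpoint).
RAW_DENSITY_THRESHOLD = float(np.exp((_POS_LOGMEAN + _NEG_LOGMEAN) / 2))


def simulate_cells(
    spec: SimulationSpec,
    image: ImageMeta,
    masks: FeatureMasks,
    stage_norm: float,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Place one image's cells and draw their raw marker totals.

    Lineage proportions follow the simulation spec's GA/stage trends;
    lineages in
    ``clustered_pairs`` share Gaussian cluster parents (planted spatial
    enrichment), everything else lands uniformly on decidua pixels.
    Marker totals are per-pixel densities (bimodal lognormal, mode chosen
    by the configured positivity fraction) times cell area, except Ki67
    which is a pure density (nuclear signal). Raises if more cells are
    requested than decidua pixels can hold.
    """
    ga_lo, ga_hi = spec.ga_range
    ga_norm = (image.ga_days - ga_lo) / max(ga_hi - ga_lo, 1)
    decidua = masks.decidua & (masks.artery == 0) & ~masks.gland & ~masks.vessel & ~masks.cell_column
    free_rows, free_cols = np.nonzero(decidua)
    n = spec.cells_per_image
    if n > len(free_rows):
        raise ValueError("requested cell density exceeds available decidua pixels")
    p = _composition(spec, ga_norm, stage_norm)
    lineage_idx = rng.choice(len(spec.lineages), size=n, p=p)
    lineages = np.array(spec.lineages)[lineage_idx]

    xs = np.empty(n)
    ys = np.empty(n)
    clustered = {lin for pair in spec.clustered_pairs for lin in pair}
    parents = rng.integers(0, len(free_rows), size=spec.clusters_per_image)
    parent_xy = np.column_stack([free_cols[parents], free_rows[parents]]).astype(float)
    h, w = masks.shape
    for i, lin in enumerate(lineages):
        if lin in clustered and len(parent_xy):
            px, py = parent_xy[rng.integers(0, len(parent_xy))]
            xs[i] = np.clip(px + rng.normal(0, spec.cluster_sd), 0, w - 1)
            ys[i] = np.clip(py + rng.normal(0, spec.cluster_sd), 0, h - 1)
        else:
            j = rng.integers(0, len(free_rows))
            xs[i] = free_cols[j] + rng.uniform(-0.5, 0.5)
            ys[i] = free_rows[j] + rng.uniform(-0.5, 0.5)

    areas = np.clip(
        rng.lognormal(np.log(spec.cell_area_mean), 0.3, size=n), 30, 1000
    )
    table = {
        "cell_id": np.arange(1, n + 1),
        "image_id": image.image_id,
        "x": xs,
        "y": ys,
        "area": areas,
        "lineage": lineages,
        "nucleated": rng.random(n) < 0.9,
    }
    for marker in spec.markers:
        dens = np.empty(n)
        for lin in np.unique(lineages):
            sel = lineages == lin
            f = _positivity_fraction(spec, lin, marker, ga_norm, stage_norm)
            pos = rng.random(int(sel.sum())) < f
            d = np.where(
                pos,
                rng.lognormal(_POS_LOGMEAN, _POS_SIGMA, size=pos.size),
                rng.lognormal(_NEG_LOGMEAN, _NEG_SIGMA, size=pos.size),
            )
            dens[sel] = d
        table[marker] = dens if marker == "Ki67" else dens * areas
    return pd.DataFrame(table)


def _quadratic_trajectory(
    t: np.ndarray, baseline: float, amplitude: float, peak: float, t_range: tuple[float, float]
) -> np.ndarray:
    """Quadratic bump peaking at ``peak`` with half-width equal to half
    the axis range, clipped to ``baseline`` outside; the full
    amplitude-to-baseline fold change is realized within the observed
    range wherever the peak sits."""
    lo, hi = t_range
    halfwidth = (hi - lo) / 2.0
    q = 1 - ((t - peak) / halfwidth) ** 2
    return baseline + (amplitude - baseline) * np.clip(q, 0, None)


@dataclass
class GeneModel:
    gene: str
    baseline: float
    amplitude: float
    peak: float
    axis: str | None   # "delta", "ga" or None (flat)


def build_gene_models(spec: SimulationSpec, rng: np.random.Generator) -> list[GeneModel]:
    """Assign each synthetic gene a trajectory: pathway genes first (COMs
    tight around their pathway's target), then the remaining delta- and
    GA-trending genes, then flat genes."""
    genes = [f"G{i:05d}" for i in range(spec.n_genes)]
    models: list[GeneModel] = []
    i = 0
    for name, (npw, target_com, spread) in spec.planted_pathways.items():
        for _ in range(npw):
            peak = rng.normal(target_com, spread)
            models.append(
                GeneModel(genes[i], 1.0, spec.gene_fold_change, float(np.clip(peak, 1, 5)), "delta")
            )
            i += 1
    n_extra_delta = min(max(spec.n_trending_delta - i, 0), spec.n_genes - i)
    for _ in range(n_extra_delta):
        models.append(
            GeneModel(genes[i], 1.0, spec.gene_fold_change, rng.uniform(1, 5), "delta")
        )
        i += 1
    ga_lo, ga_hi = spec.ga_range
    for _ in range(min(spec.n_trending_ga, spec.n_genes - i)):
        models.append(
            GeneModel(genes[i], 1.0, spec.gene_fold_change, rng.uniform(ga_lo, ga_hi), "ga")
        )
        i += 1
    while i < spec.n_genes:
        models.append(GeneModel(genes[i], 1.0, 1.0, 0.0, None))
        i += 1
    return models


def simulate_roi_counts(
    spec: SimulationSpec,
    models: list[GeneModel],
    roi_id: str,
    roi_type: str,
    delta: float | None,
    ga_days: float,
    rng: np.random.Generator,
    linked: list | None = None,
) -> RoiExpression:
    """Draw one ROI's gene and negative-probe counts.

    Counts are the scaled mean trajectory (quadratic in the gene's axis)
    times multiplicative lognormal noise plus a lognormal background; the
    100 negative probes are drawn from the background law alone. EVT-type
    ROIs additionally apply the planted log2 shifts of ``de_genes`` in the
    intravascular group.
    """
    counts = {}
    for m in models:
        if m.axis == "delta" and delta is not None:
            mean = _quadratic_trajectory(
                np.array([delta]), m.baseline, m.amplitude, m.peak, (1, 5)
            )[0]
        elif m.axis == "ga":
            mean = _quadratic_trajectory(
                np.array([ga_days]), m.baseline, m.amplitude, m.peak,
                (spec.ga_range[0], spec.ga_range[1]),
            )[0]
        else:
            mean = m.baseline
        level = spec.count_scale * mean
        if roi_type == "intravascular_evt" and m.gene in spec.de_genes:
            level *= 2.0 ** spec.de_genes[m.gene]
        if spec.count_noise == "nb":
            mu = level + spec.background_level
            r = spec.nb_dispersion
            val = rng.negative_binomial(r, r / (r + mu))
        else:
            val = level * rng.lognormal(0, spec.gene_noise_sigma) + rng.lognormal(
                np.log(spec.background_level), spec.background_sigma
            )
        counts[m.gene] = float(np.round(val))
    neg = np.round(
        rng.lognormal(np.log(spec.background_level), spec.background_sigma, spec.n_neg_probes)
    )
    return RoiExpression(
        roi_id=roi_id,
        roi_type=roi_type,
        raw_counts=counts,
        neg_probe_counts=neg,
        ga_days=float(ga_days),
        delta=delta,
        linked_artery_ids=linked or [],
    )


@dataclass
class SyntheticDataset:
    spec: SimulationSpec
    images: list[ImageMeta]
    masks: dict[str, FeatureMasks]
    artery_crops: dict[tuple[str, int], dict]
    arteries: pd.DataFrame
    cells: pd.DataFrame
    rois: list[RoiExpression]
    pathways: list[PathwaySet]
    gene_models: list[GeneModel]
    truth: dict


def simulate_dataset(spec: SimulationSpec, seed: int | None = None) -> SyntheticDataset:
    """Generate a full synthetic cohort.

    Per subject: a GA drawn uniformly over ``ga_range`` and a few images;
    per image: arteries whose manual stage follows a latent remodelling
    coordinate correlated with GA (``stage_ga_correlation``), pasted into
    an instance-labeled artery raster along with simple gland / vessel /
    cell-column features and a decidua background; cells per image; and a
    handful of transcriptome ROIs (artery ROIs linked to sampled arteries
    plus interstitial/intravascular EVT ROIs). Identical seeds give
    byte-identical outputs.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    ga_lo, ga_hi = spec.ga_range
    stage_vals = sorted(spec.stage_weights)
    stage_p = np.array([spec.stage_weights[s] for s in stage_vals], dtype=float)
    stage_p /= stage_p.sum()

    images: list[ImageMeta] = []
    masks: dict[str, FeatureMasks] = {}
    artery_crops: dict[tuple[str, int], dict] = {}
    artery_rows = []
    cell_frames = []
    rois: list[RoiExpression] = []
    gene_models = build_gene_models(spec, rng)
    rho = spec.stage_ga_correlation

    for s in range(spec.n_subjects):
        subject = f"S{s:03d}"
        ga = int(rng.integers(ga_lo, ga_hi + 1))
        ga_norm = (ga - ga_lo) / max(ga_hi - ga_lo, 1)
        for im in range(spec.images_per_subject):
            image_id = f"{subject}_img{im}"
            size = spec.fov_size
            artery_raster = np.zeros((size, size), dtype=np.int32)
            centres: dict[int, tuple[float, float]] = {}
            n_art = int(rng.integers(spec.arteries_per_image[0], spec.arteries_per_image[1] + 1))
            # latent stage: blend of GA rank and cohort stage prior noise
            stage_list = []
            for a in range(1, n_art + 1):
                u = rng.random()
                prior_stage = float(rng.choice(stage_vals, p=stage_p))
                latent = rho * (1 + 4 * ga_norm) + (1 - rho) * (
                    prior_stage + rng.uniform(-0.5, 0.5)
                )
                t_true = float(np.clip(latent + rng.normal(0, 0.3), 1, 5))
                stage = int(np.clip(round(t_true), 1, 5))
                geom = _interp_geometry(spec, t_true)
                mask, centre, rasters, truth = simulate_artery_mask(stage, geom, rng)
                ch = mask.shape[0]
                # place without overlap on a coarse grid
                placed = False
                for _try in range(30):
                    oy = int(rng.integers(0, size - ch))
                    ox = int(rng.integers(0, size - ch))
                    region = artery_raster[oy : oy + ch, ox : ox + ch]
                    if (region[mask] == 0).all():
                        region[mask] = a
                        placed = True
                        break
                if not placed:
                    continue
                cx, cy = centre[0] + ox, centre[1] + oy
                centres[a] = (cx, cy)
                artery_crops[(image_id, a)] = {
                    "mask": mask,
                    "centre": centre,
                    "rasters": rasters,
                    "truth": truth,
                    "t_true": t_true,
                    "offset": (ox, oy),
                }
                stage_list.append(t_true)
                artery_rows.append(
                    {
                        "image_id": image_id,
                        "artery_id": a,
                        "subject_id": subject,
                        "ga_days": ga,
                        "manual_stage": stage,
                        "t_true": t_true,
                        "sma_coverage": geom.sma_coverage,
                        "endo_coverage": geom.endo_coverage,
                        "n_intravascular_evt_true": geom.n_intravascular_evt,
                    }
                )
            gland = np.zeros((size, size), dtype=bool)
            vessel = np.zeros((size, size), dtype=bool)
            cell_column = np.zeros((size, size), dtype=bool)
            yy, xx = np.mgrid[0:size, 0:size]
            for arr, radius in ((gland, 25), (vessel, 12), (cell_column, 30)):
                for _ in range(2):
                    gx, gy = rng.integers(0, size, 2)
                    cand = (xx - gx) ** 2 + (yy - gy) ** 2 <= radius**2
                    if not (artery_raster[cand] > 0).any():
                        arr |= cand
            decidua = np.ones((size, size), dtype=bool)
            fm = FeatureMasks(
                image_id=image_id,
                artery=artery_raster,
                gland=gland,
                vessel=vessel,
                cell_column=cell_column,
                decidua=decidua,
                artery_centres=centres,
            )
            meta = ImageMeta(image_id, subject, ga, size)
            images.append(meta)
            masks[image_id] = fm
            stage_norm = (
                (float(np.mean(stage_list)) - 1) / 4 if stage_list else ga_norm
            )
            cell_frames.append(simulate_cells(spec, meta, fm, stage_norm, rng))

    arteries = pd.DataFrame(artery_rows)
    cells = pd.concat(cell_frames, ignore_index=True)

    # transcriptome ROIs: artery ROIs across the remodelling range plus
    # EVT ROIs for differential expression (study scale: 13 artery, 5
    # interstitial, 3 intravascular)
    if len(arteries):
        order = arteries.sort_values("t_true")
        pick = order.iloc[
            np.linspace(0, len(order) - 1, min(13, len(order))).astype(int)
        ]
        for j, row in enumerate(pick.itertuples()):
            rois.append(
                simulate_roi_counts(
                    spec, gene_models, f"roi_art{j}", "artery",
                    float(row.t_true), float(row.ga_days), rng,
                    linked=[(row.image_id, int(row.artery_id))],
                )
            )
    ga_mid = float(np.mean(spec.ga_range))
    for j in range(5):
        rois.append(
            simulate_roi_counts(
                spec, gene_models, f"roi_int{j}", "interstitial_evt",
                None, ga_mid, rng,
            )
        )
    for j in range(3):
        rois.append(
            simulate_roi_counts(
                spec, gene_models, f"roi_intra{j}", "intravascular_evt",
                None, ga_mid, rng,
            )
        )

    # pathway membership follows gene-model construction order
    pathways = []
    offset = 0
    for name, (npw, com, spread) in spec.planted_pathways.items():
        pathways.append(
            PathwaySet(
                name=name,
                genes=frozenset(m.gene for m in gene_models[offset : offset + npw]),
            )
        )
        offset += npw

    truth = {
        "composition_trends": {
            k: list(v) for k, v in spec.composition_trends.items()
        },
        "positivity_trends": {
            f"{l}|{m}": list(v) for (l, m), v in spec.positivity_trends.items()
        },
        "clustered_pairs": [list(p) for p in spec.clustered_pairs],
        "raw_density_threshold": RAW_DENSITY_THRESHOLD,
        "planted_pathways": {
            k: {"n_genes": n, "target_com": c, "spread": s}
            for k, (n, c, s) in spec.planted_pathways.items()
        },
        "trending_delta_genes": [m.gene for m in gene_models if m.axis == "delta"],
        "trending_ga_genes": [m.gene for m in gene_models if m.axis == "ga"],
        "de_genes": dict(spec.de_genes),
    }
    return SyntheticDataset(
        spec=spec,
        images=images,
        masks=masks,
        artery_crops=artery_crops,
        arteries=arteries,
        cells=cells,
        rois=rois,
        pathways=pathways,
        gene_models=gene_models,
        truth=truth,
    )


def write_dataset(ds: SyntheticDataset, out_dir: str | Path) -> None:
    """Write a dataset directory: cells.csv, images.csv, arteries.csv,
    masks/, roi count/meta/negprobe CSVs, pathways.gmt and truth.json."""
    from . import io as _io

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ds.cells.to_csv(out / "cells.csv", index=False)
    _io.write_image_table(ds.images, out / "images.csv")
    ds.arteries.to_csv(out / "arteries.csv", index=False)
    for fm in ds.masks.values():
        _io.write_masks(fm, out / "masks")
    # image-level wall-marker rasters assembled from the per-artery crops
    import tifffile

    for image_id, fm in ds.masks.items():
        size = fm.shape[0]
        channels = {
            m: np.zeros((size, size), dtype=np.float32)
            for m in ("SMA", "CD31", "VIM", "H3", "HLAG", "CK7")
        }
        for (img, aid), crop in ds.artery_crops.items():
            if img != image_id:
                continue
            ox, oy = crop["offset"]
            ch = crop["mask"].shape[0]
            for m, arr in crop["rasters"].items():
                region = channels[m][oy : oy + ch, ox : ox + ch]
                np.maximum(region, arr.astype(np.float32), out=region)
        for m, arr in channels.items():
            tifffile.imwrite(out / "masks" / image_id / f"marker_{m}.tif", arr)
    if ds.rois:
        _io.write_rois(
            ds.rois, out / "roi_counts.csv", out / "roi_meta.csv", out / "roi_negprobes.csv"
        )
    _io.write_pathways(ds.pathways, out / "pathways.gmt")
    (out / "truth.json").write_text(json.dumps(ds.truth, indent=1))
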
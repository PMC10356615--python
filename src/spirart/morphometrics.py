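"""Artery morphometry via the concentric "onion" partition.

Each artery mask is digitized by overlaying a disc centred on the
user-defined artery centre, sliced into I concentric layers of thickness
``n`` pixels and ``k`` equal angular sectors. Every in-mask pixel falls in
exactly one layer x sector segment; wall-protein rasters (SMA, CD31, ...)
are then summarized per segment to yield, per marker: a pixel-weighted
average signal, per-sector wall thickness (mean and SD over sectors), and
radial coverage (the fraction of sectors whose mean signal clears a
threshold). Geometry is summarized by inscribed radius, traced perimeter
and pixel area, plus an outline-jaggedness ratio from the medial-axis
skeleton. Cohort-relative SMA/endothelium loss scores are derived from the
SMA average signal and CD31 radial coverage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure
from skimage.morphology import medial_axis

from .model import MORPHOMETRY_MARKERS

#: Canonical order of the per-artery morphometric feature vector:
#: three geometric features, one outline jaggedness, and four wall-protein
#: statistics for each morphology marker.
FEATURE_NAMES: tuple[str, ...] = (
    "radius",
    "perimeter",
    "area",
    "jaggedness",
    *(
        f"{marker}_{stat}"
        for marker in MORPHOMETRY_MARKERS
        for stat in ("average_signal", "thickness_mean", "thickness_sd", "radial_coverage")
    ),
)


@dataclass
class OnionStructure:
    """Layer x sector partition of an artery disc.

    ``layer_idx``/``sector_idx`` give, per member pixel (parallel to
    ``rows``/``cols``), its concentric layer (0 innermost) and angular
    sector (0 starting east, counter-clockwise).
    """

    centre: tuple[float, float]
    outer_radius: int
    layer_px: int
    n_layers: int
    n_sectors: int
    rows: np.ndarray
    cols: np.ndarray
    layer_idx: np.ndarray
    sector_idx: np.ndarray
    degenerate: bool = False

    @property
    def segment_labels(self) -> np.ndarray:
        """Flat segment id per member pixel (layer * k + sector)."""
        return self.layer_idx * self.n_sectors + self.sector_idx

    def segment_counts(self) -> np.ndarray:
        """Pixel count per segment, shape (I, k)."""
        counts = np.bincount(
            self.segment_labels, minlength=self.n_layers * self.n_sectors
        )
        return counts.reshape(self.n_layers, self.n_sectors)

    def trapezoid_vertices(self, layer: int, sector: int) -> np.ndarray:
        """Corner coordinates (x, y) of a segment's trapezoid.

        Arcs are replaced by their secants, so each segment is the
        quadrilateral spanned by the sector's two boundary angles at the
        layer's inner and outer radii. Recorded for visualization; all
        statistics use pixel membership.
        """
        cx, cy = self.centre
        t0 = 2 * np.pi * sector / self.n_sectors
        t1 = 2 * np.pi * (sector + 1) / self.n_sectors
        r0 = layer * self.layer_px
        r1 = (layer + 1) * self.layer_px
        pts = []
        for r, t in ((r0, t0), (r1, t0), (r1, t1), (r0, t1)):
            # y grows downward; sectors advance counter-clockwise on screen
            pts.append((cx + r * np.cos(t), cy - r * np.sin(t)))
        return np.array(pts)


def build_onion(
    mask: np.ndarray, centre: tuple[float, float], n: int = 10, k: int = 100
) -> OnionStructure:
    """Construct the onion partition of a single artery mask.

    The outer radius is the maximum distance from the centre to the mask
    edge, rounded up to the nearest multiple of ``n``. Pixels exactly on a
    sector boundary go to the lower-index sector; pixels at a radius that
    is an exact multiple of ``n`` go to the outer adjacent layer.
    """
    if n < 1 or k < 1:
        raise ValueError("n and k must be >= 1")
    mask = np.asarray(mask, dtype=bool)
    cx, cy = float(centre[0]), float(centre[1])
    ix, iy = int(round(cx)), int(round(cy))
    if not (
        0 <= iy < mask.shape[0] and 0 <= ix < mask.shape[1] and mask[iy, ix]
    ):
        raise ValueError(f"centre {centre} is not inside the mask")

    edge = mask & ~ndimage.binary_erosion(mask, border_value=0)
    er, ec = np.nonzero(edge)
    max_dist = np.sqrt((ec - cx) ** 2 + (er - cy) ** 2).max()
    n_layers = max(1, int(np.ceil(max_dist / n)))
    outer_radius = n_layers * n

    rows, cols = np.nonzero(mask)
    dx = cols - cx
    dy = rows - cy
    r = np.hypot(dx, dy)
    inside = r <= outer_radius
    rows, cols, r, dx, dy = rows[inside], cols[inside], r[inside], dx[inside], dy[inside]

    layer = np.minimum((r // n).astype(int), n_layers - 1)
    # screen counter-clockwise from east with y pointing down
    theta = np.mod(np.arctan2(-dy, dx), 2 * np.pi)
    sector = np.minimum((theta * k / (2 * np.pi)).astype(int), k - 1)

    degenerate = mask.sum() < k
    if degenerate:
        warnings.warn("degenerate mask (area < k); features will be missing", stacklevel=2)
    return OnionStructure(
        centre=(cx, cy),
        outer_radius=outer_radius,
        layer_px=n,
        n_layers=n_layers,
        n_sectors=k,
        rows=rows,
        cols=cols,
        layer_idx=layer,
        sector_idx=sector,
        degenerate=degenerate,
    )


def geometric_features(mask: np.ndarray) -> dict[str, float]:
    """Inscribed radius (max of the interior distance transform), traced
    perimeter (unit steps for 4-neighbours, sqrt(2) for diagonals) and
    pixel area of the mask."""
    mask = np.asarray(mask, dtype=bool)
    area = float(mask.sum())
    if area == 0:
        return {"radius": 0.0, "perimeter": 0.0, "area": 0.0}
    radius = float(ndimage.distance_transform_edt(mask).max())
    perimeter = float(measure.perimeter(mask, neighborhood=4))
    return {"radius": radius, "perimeter": perimeter, "area": area}


def protein_features(
    onion: OnionStructure,
    raster: np.ndarray,
    segment_threshold: float,
    sector_threshold: float,
) -> dict[str, float]:
    """Wall-protein morphology statistics for one marker raster.

    A segment is positive when the mean signal over its member pixels
    reaches ``segment_threshold``; per sector, thickness d spans the
    inclusive layer range from innermost to outermost positive segment
    (a single positive layer has d = n). A sector is positive when the
    mean over all its member pixels reaches ``sector_threshold``; radial
    coverage is the positive fraction of the k sectors.
    """
    if onion.degenerate:
        return {
            "average_signal": np.nan,
            "thickness_mean": np.nan,
            "thickness_sd": np.nan,
            "radial_coverage": np.nan,
        }
    vals = np.asarray(raster, dtype=float)[onion.rows, onion.cols]
    I, k = onion.n_layers, onion.n_sectors
    labels = onion.segment_labels
    counts = np.bincount(labels, minlength=I * k)
    sums = np.bincount(labels, weights=vals, minlength=I * k)
    with np.errstate(invalid="ignore"):
        seg_mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    seg_mean = seg_mean.reshape(I, k)
    counts2 = counts.reshape(I, k)

    total = counts.sum()
    average_signal = float(sums.sum() / total) if total else np.nan

    positive = (counts2 > 0) & (seg_mean >= segment_threshold)
    thickness = np.zeros(k)
    for s in range(k):
        idx = np.nonzero(positive[:, s])[0]
        if idx.size:
            thickness[s] = onion.layer_px * (idx[-1] - idx[0] + 1)
    sector_counts = counts2.sum(axis=0)
    sector_sums = sums.reshape(I, k).sum(axis=0)
    with np.errstate(invalid="ignore"):
        sector_mean = np.where(sector_counts > 0, sector_sums / np.maximum(sector_counts, 1), -np.inf)
    radial_coverage = float(np.mean((sector_counts > 0) & (sector_mean >= sector_threshold)))

    return {
        "average_signal": average_signal,
        "thickness_mean": float(thickness.mean()),
        "thickness_sd": float(thickness.std()),
        "radial_coverage": radial_coverage,
    }


def jaggedness(mask: np.ndarray, high_thr: float = 60, low_thr: float = 5) -> float:
    """Outline jaggedness from the valued medial-axis skeleton.

    The medial axis carries, per skeleton pixel, its distance to the mask
    boundary. Pixels with value >= ``high_thr`` form the deep "core"
    (non-branch) skeleton; pixels >= ``low_thr`` additionally include the
    shallow branches that jagged outlines spawn. Jaggedness is the branch
    count over the core count (0 when the core is empty), so smooth
    compact shapes score near 1 and irregular outlines score higher.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return 0.0
    skel, dist = medial_axis(mask, return_distance=True)
    vals = dist[skel]
    core = int((vals >= high_thr).sum())
    if core == 0:
        return 0.0
    return float((vals >= low_thr).sum()) / core


def default_thresholds(value: float = 0.25) -> dict[str, float]:
    """Per-marker segment/sector positivity thresholds, placed between
    background and signal levels. CD31 is a thin endothelial ring whose
    signal is diluted when averaged over a whole sector wedge, so its
    threshold sits much lower."""
    thr = {m: value for m in MORPHOMETRY_MARKERS}
    thr["CD31"] = min(value, 0.06)
    return thr


def artery_features(
    mask: np.ndarray,
    centre: tuple[float, float],
    marker_rasters: dict[str, np.ndarray],
    n: int = 10,
    k: int = 100,
    segment_thresholds: dict[str, float] | None = None,
    sector_thresholds: dict[str, float] | None = None,
    jaggedness_high: float = 60,
    jaggedness_low: float = 5,
) -> dict[str, float]:
    """Full morphometric vector for one artery (see :data:`FEATURE_NAMES`)."""
    segment_thresholds = segment_thresholds or {}
    sector_thresholds = sector_thresholds or {}
    onion = build_onion(mask, centre, n=n, k=k)
    out = geometric_features(mask)
    out["jaggedness"] = jaggedness(mask, jaggedness_high, jaggedness_low)
    for marker in MORPHOMETRY_MARKERS:
        if marker not in marker_rasters:
            raise ValueError(f"missing marker raster {marker!r}")
        if marker not in segment_thresholds or marker not in sector_thresholds:
            raise ValueError(f"missing segment/sector threshold for {marker!r}")
        stats = protein_features(
            onion,
            marker_rasters[marker],
            segment_thresholds[marker],
            sector_thresholds[marker],
        )
        for stat, v in stats.items():
            out[f"{marker}_{stat}"] = v
    return out


def loss_scores(feature_table: "np.ndarray | object") -> "object":
    """Cohort-relative SMA and endothelium loss per artery.

    Input: DataFrame with columns ``SMA_average_signal`` and
    ``CD31_radial_coverage`` (one row per artery). For each of the two
    features: divide by the cohort maximum, subtract from 1, then min-max
    rescale the losses to [0, 1]. Returns a DataFrame with ``sma_loss`` and
    ``endo_loss`` aligned to the input index.
    """
    import pandas as pd

    df = feature_table
    if len(df) < 2:
        raise ValueError("loss scores need at least 2 arteries")
    out = pd.DataFrame(index=df.index)
    for col, name in (
        ("SMA_average_signal", "sma_loss"),
        ("CD31_radial_coverage", "endo_loss"),
    ):
        f = df[col].to_numpy(dtype=float)
        fmax = np.nanmax(f)
        loss = 1.0 - (f / fmax if fmax > 0 else np.ones_like(f))
        lo, hi = np.nanmin(loss), np.nanmax(loss)
        out[name] = (loss - lo) / (hi - lo) if hi > lo else np.zeros_like(loss)
    return out
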
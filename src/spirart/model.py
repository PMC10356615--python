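"""Shared data model for the decidua spatial-analysis pipeline.

The pipeline quantifies two temporal axes of the first-half-of-pregnancy
decidua: gestational age (GA, days) and spiral artery remodelling (SAR),
the latter summarized per artery by a continuous score ``delta`` in [1, 5].
These containers carry the segmented single-cell table, per-image feature
masks, per-artery morphometry, and targeted spatial-transcriptomics ROIs
between pipeline stages.

Conventions: coordinates are 0-based pixel indices with y increasing
downward (raster order); all distances are Euclidean in pixels. Conversion
to micrometres is display-only and governed by :class:`RunConfig`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

#: Compartments a cell can primarily occupy. ``perivascular`` is a flag on
#: decidua cells (within the perivascular band of an artery), not a primary
#: compartment of its own.
COMPARTMENTS = ("decidua", "artery", "gland", "vessel", "cell_column", "none")

#: Feature-mask classes stored per image. ``artery`` is an instance-labeled
#: raster (0 = background, i = artery i); the rest are binary.
MASK_CLASSES = ("artery", "gland", "vessel", "cell_column", "decidua")

#: Markers used for artery wall protein morphology.
MORPHOMETRY_MARKERS = ("CD31", "CK7", "H3", "HLAG", "SMA", "VIM")

#: Markers used for the one-dimensional EVT compartment discriminant.
EVT_LDA_MARKERS = ("CD56", "CD57", "HLAG", "CK7", "PDL1", "Ki67")

ROI_TYPES = ("artery", "decidua", "interstitial_evt", "intravascular_evt")


@dataclass
class CellRecord:
    """One segmented cell."""

    cell_id: int
    image_id: str
    x: float
    y: float
    area: float
    lineage: str
    markers: dict[str, float] = field(default_factory=dict)
    positivity: dict[str, bool] = field(default_factory=dict)
    compartment: str = "none"
    perivascular: bool = False

    def __post_init__(self) -> None:
        if self.area <= 0:
            raise ValueError(f"cell {self.cell_id}: area must be > 0")


@dataclass
class ImageMeta:
    """Per-image (field-of-view) metadata."""

    image_id: str
    subject_id: str
    ga_days: int
    fov_size: int

    def __post_init__(self) -> None:
        if self.ga_days < 0:
            raise ValueError("ga_days must be >= 0")


@dataclass
class FeatureMasks:
    """Feature-class rasters for one image.

    ``artery`` is integer-labeled by artery instance; the other classes are
    boolean. ``artery_centres`` maps artery id to its user-defined centre
    (x, y) in pixel coordinates.
    """

    image_id: str
    artery: np.ndarray
    gland: np.ndarray
    vessel: np.ndarray
    cell_column: np.ndarray
    decidua: np.ndarray
    artery_centres: dict[int, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        shape = self.artery.shape
        for name in ("gland", "vessel", "cell_column", "decidua"):
            arr = getattr(self, name)
            if arr.shape != shape:
                raise ValueError(
                    f"mask '{name}' shape {arr.shape} != artery shape {shape}"
                )
        labels = set(np.unique(self.artery)) - {0}
        for aid, (cx, cy) in self.artery_centres.items():
            if aid not in labels:
                raise ValueError(f"centre listed for artery {aid} absent from raster")
            rows, cols = np.nonzero(self.artery == aid)
            if not (
                cols.min() <= cx <= cols.max() and rows.min() <= cy <= rows.max()
            ):
                raise ValueError(
                    f"centre {(cx, cy)} outside bounding box of artery {aid}"
                )

    @property
    def shape(self) -> tuple[int, int]:
        return self.artery.shape

    def artery_ids(self) -> list[int]:
        return sorted(int(i) for i in np.unique(self.artery) if i != 0)


@dataclass
class ArteryRecord:
    """One artery instance with its morphometry and remodelling scores."""

    artery_id: int
    image_id: str
    manual_stage: int
    features: dict[str, float] = field(default_factory=dict)
    lda_coords: np.ndarray | None = None
    delta: float | None = None
    sma_loss: float | None = None
    endo_loss: float | None = None
    n_perivascular_evt: int = 0
    n_intravascular_evt: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.manual_stage <= 5:
            raise ValueError("manual_stage must be in 1..5")


@dataclass
class RoiExpression:
    """One spatial-transcriptomics region of interest.

    ``raw_counts`` are probe counts per gene; ``neg_probe_counts`` holds the
    negative-control probes whose geometric mean estimates the nonspecific
    background; ``norm_counts`` is filled by the normalization stage.
    """

    roi_id: str
    roi_type: str
    raw_counts: dict[str, float]
    neg_probe_counts: np.ndarray
    ga_days: float
    delta: float | None = None
    norm_counts: dict[str, float] | None = None
    linked_artery_ids: list[tuple[str, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.roi_type not in ROI_TYPES:
            raise ValueError(f"unknown roi_type {self.roi_type!r}")
        self.neg_probe_counts = np.asarray(self.neg_probe_counts, dtype=float)


@dataclass
class PathwaySet:
    """A named gene set (e.g. one GO Biological Process term)."""

    name: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"pathway {self.name!r} is empty")


def cells_to_frame(cells: Sequence[CellRecord]) -> "pd.DataFrame":
    """Flatten CellRecords into a DataFrame (markers/positivity as columns)."""
    import pandas as pd

    rows = []
    for c in cells:
        row: dict = {
            "cell_id": c.cell_id,
            "image_id": c.image_id,
            "x": c.x,
            "y": c.y,
            "area": c.area,
            "lineage": c.lineage,
            "compartment": c.compartment,
            "perivascular": c.perivascular,
        }
        row.update(c.markers)
        for m, v in c.positivity.items():
            row[f"pos_{m}"] = bool(v)
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_cells(frame: "pd.DataFrame") -> list[CellRecord]:
    """Inverse of :func:`cells_to_frame`."""
    reserved = {
        "cell_id", "image_id", "x", "y", "area", "lineage",
        "compartment", "perivascular",
    }
    marker_cols = [
        c for c in frame.columns if c not in reserved and not c.startswith("pos_")
    ]
    pos_cols = [c for c in frame.columns if c.startswith("pos_")]
    cells = []
    for d in frame.to_dict("records"):
        cells.append(
            CellRecord(
                cell_id=int(d["cell_id"]),
                image_id=str(d["image_id"]),
                x=float(d["x"]),
                y=float(d["y"]),
                area=float(d["area"]),
                lineage=str(d["lineage"]),
                markers={m: float(d[m]) for m in marker_cols},
                positivity={c[4:]: bool(d[c]) for c in pos_cols},
                compartment=str(d.get("compartment", "none")),
                perivascular=bool(d.get("perivascular", False)),
            )
        )
    return cells
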
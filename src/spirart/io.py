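"""Readers and writers for the pipeline's on-disk formats.

Cell tables, image metadata, artery sidecars and ROI count matrices are
plain CSV; feature masks are one TIFF per feature class per image; pathway
sets use the tab-separated GMT convention (name, description, genes...).
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import tifffile

from .model import (
    MASK_CLASSES,
    CellRecord,
    FeatureMasks,
    ImageMeta,
    PathwaySet,
    RoiExpression,
    cells_to_frame,
    frame_to_cells,
)

_CELL_REQUIRED = ("cell_id", "image_id", "x", "y", "area", "lineage")


class FormatError(ValueError):
    """A file does not conform to the expected format."""


def read_cell_table(
    path: str | Path, known_lineages: Iterable[str] | None = None
) -> list[CellRecord]:
    """Read a per-cell CSV.

    Marker columns are inferred from the header (anything not reserved and
    not prefixed ``pos_``). If ``known_lineages`` is given, labels outside
    the vocabulary are mapped to ``"other"`` with a warning.
    """
    frame = pd.read_csv(path)
    missing = [c for c in _CELL_REQUIRED if c not in frame.columns]
    if missing:
        raise FormatError(f"cell table missing required column(s): {missing}")
    dup = frame.duplicated(subset=["image_id", "cell_id"])
    if dup.any():
        raise FormatError(
            f"duplicated cell_id within an image: "
            f"{frame.loc[dup, ['image_id', 'cell_id']].values[:5].tolist()}"
        )
    if known_lineages is not None:
        vocab = set(known_lineages) | {"other"}
        unknown = ~frame["lineage"].isin(vocab)
        if unknown.any():
            warnings.warn(
                f"{int(unknown.sum())} cells with unknown lineage mapped to 'other'",
                stacklevel=2,
            )
            frame.loc[unknown, "lineage"] = "other"
    return frame_to_cells(frame)


def write_cell_table(cells: Sequence[CellRecord], path: str | Path) -> None:
    cells_to_frame(cells).to_csv(path, index=False)


def read_image_table(path: str | Path) -> list[ImageMeta]:
    frame = pd.read_csv(path)
    required = {"image_id", "subject_id", "ga_days", "fov_size"}
    missing = required - set(frame.columns)
    if missing:
        raise FormatError(f"image table missing column(s): {sorted(missing)}")
    return [
        ImageMeta(str(r.image_id), str(r.subject_id), int(r.ga_days), int(r.fov_size))
        for r in frame.itertuples()
    ]


def write_image_table(images: Sequence[ImageMeta], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "image_id": im.image_id,
                "subject_id": im.subject_id,
                "ga_days": im.ga_days,
                "fov_size": im.fov_size,
            }
            for im in images
        ]
    ).to_csv(path, index=False)


def read_masks(mask_dir: str | Path, image_id: str) -> FeatureMasks:
    """Load the feature-class rasters and artery-centre sidecar of one image.

    Expects ``<mask_dir>/<image_id>/<class>.tif`` for every class in
    :data:`~spirart.model.MASK_CLASSES` plus ``centres.csv`` with columns
    artery_id, x, y. Validation (shape agreement, centres inside their
    artery's bounding box) happens in :class:`FeatureMasks`.
    """
    base = Path(mask_dir) / image_id
    rasters = {}
    for name in MASK_CLASSES:
        f = base / f"{name}.tif"
        if not f.exists():
            raise FormatError(f"missing mask raster: {f}")
        arr = tifffile.imread(f)
        rasters[name] = (
            arr.astype(np.int32) if name == "artery" else arr.astype(bool)
        )
    centres: dict[int, tuple[float, float]] = {}
    centre_file = base / "centres.csv"
    if centre_file.exists():
        cf = pd.read_csv(centre_file)
        centres = {
            int(r.artery_id): (float(r.x), float(r.y)) for r in cf.itertuples()
        }
    return FeatureMasks(image_id=image_id, artery_centres=centres, **rasters)


def write_masks(masks: FeatureMasks, mask_dir: str | Path) -> None:
    base = Path(mask_dir) / masks.image_id
    base.mkdir(parents=True, exist_ok=True)
    for name in MASK_CLASSES:
        arr = getattr(masks, name)
        dtype = np.int32 if name == "artery" else np.uint8
        tifffile.imwrite(base / f"{name}.tif", arr.astype(dtype))
    pd.DataFrame(
        [
            {"artery_id": aid, "x": x, "y": y}
            for aid, (x, y) in sorted(masks.artery_centres.items())
        ]
    ).to_csv(base / "centres.csv", index=False)


def read_pathways(path: str | Path) -> list[PathwaySet]:
    """Read a GMT file: ``name<TAB>description<TAB>gene1<TAB>gene2...``.

    Gene symbols are upper-cased and de-duplicated; lines without any gene
    are skipped with a warning. Intersection-size filtering happens in the
    coordination stage, not here.
    """
    sets: list[PathwaySet] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        genes = {g.strip().upper() for g in parts[2:] if g.strip()}
        if not genes:
            warnings.warn(f"GMT line {lineno} has no genes; skipped", stacklevel=2)
            continue
        sets.append(PathwaySet(name=parts[0], genes=frozenset(genes)))
    return sets


def write_pathways(pathways: Sequence[PathwaySet], path: str | Path) -> None:
    lines = [
        "\t".join([p.name, "na", *sorted(p.genes)]) for p in pathways
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_rois(
    counts_path: str | Path,
    meta_path: str | Path,
    negprobes_path: str | Path,
) -> list[RoiExpression]:
    """Assemble ROIs from a genes x ROIs count CSV plus metadata sidecars.

    ``counts``: first column ``gene``, one column per roi_id. ``meta``:
    roi_id, roi_type, ga_days, delta (blank allowed), linked_arteries
    (semicolon-separated ``image:artery`` tokens, optional). ``negprobes``:
    first column ``probe``, one column per roi_id.
    """
    counts = pd.read_csv(counts_path).set_index("gene")
    neg = pd.read_csv(negprobes_path).set_index("probe")
    meta = pd.read_csv(meta_path)
    required = {"roi_id", "roi_type", "ga_days"}
    if required - set(meta.columns):
        raise FormatError(f"roi meta missing column(s): {sorted(required - set(meta.columns))}")
    rois = []
    for r in meta.itertuples():
        rid = str(r.roi_id)
        if rid not in counts.columns:
            raise FormatError(f"roi {rid} absent from count matrix")
        linked = []
        raw_link = getattr(r, "linked_arteries", "")
        if isinstance(raw_link, str) and raw_link:
            for tok in raw_link.split(";"):
                img, aid = tok.rsplit(":", 1)
                linked.append((img, int(aid)))
        delta = getattr(r, "delta", np.nan)
        rois.append(
            RoiExpression(
                roi_id=rid,
                roi_type=str(r.roi_type),
                raw_counts=counts[rid].to_dict(),
                neg_probe_counts=neg[rid].to_numpy(dtype=float),
                ga_days=float(r.ga_days),
                delta=None if pd.isna(delta) else float(delta),
                linked_artery_ids=linked,
            )
        )
    return rois


def write_rois(
    rois: Sequence[RoiExpression],
    counts_path: str | Path,
    meta_path: str | Path,
    negprobes_path: str | Path,
) -> None:
    genes = sorted(rois[0].raw_counts)
    counts = pd.DataFrame(
        {r.roi_id: [r.raw_counts[g] for g in genes] for r in rois},
        index=pd.Index(genes, name="gene"),
    )
    counts.to_csv(counts_path)
    neg = pd.DataFrame(
        {r.roi_id: r.neg_probe_counts for r in rois},
        index=pd.Index(
            [f"neg_{i}" for i in range(len(rois[0].neg_probe_counts))], name="probe"
        ),
    )
    neg.to_csv(negprobes_path)
    pd.DataFrame(
        [
            {
                "roi_id": r.roi_id,
                "roi_type": r.roi_type,
                "ga_days": r.ga_days,
                "delta": np.nan if r.delta is None else r.delta,
                "linked_arteries": ";".join(
                    f"{img}:{aid}" for img, aid in r.linked_artery_ids
                ),
            }
            for r in rois
        ]
    ).to_csv(meta_path, index=False)


def read_artery_table(path: str | Path) -> pd.DataFrame:
    """Per-artery sidecar: image_id, artery_id, manual_stage (+extras)."""
    frame = pd.read_csv(path)
    required = {"image_id", "artery_id", "manual_stage"}
    if required - set(frame.columns):
        raise FormatError(
            f"artery table missing column(s): {sorted(required - set(frame.columns))}"
        )
    return frame
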
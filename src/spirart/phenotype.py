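"""Single-cell normalization, marker positivity, lineage refinement and
spatial compartment assignment.

Raw per-cell marker totals are area-normalized, linearly scaled (x100),
ArcSinh-transformed (cofactor 5) and divided by the per-marker 99th
percentile over the dataset. Functional positivity is a per-marker
threshold on the normalized value (inclusive); Ki67 is special-cased:
nuclear signal is not diluted by cell size, so it skips area
normalization, and positivity is defined only for nucleated cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage


@dataclass
class NormalizationParams:
    scale_factor: float = 100.0
    arcsinh_cofactor: float = 5.0
    percentile: float = 99.0
    #: markers whose signal is confined to the nucleus and therefore not
    #: divided by cell area
    no_area_markers: tuple[str, ...] = ("Ki67",)

    def __post_init__(self) -> None:
        if self.arcsinh_cofactor <= 0:
            raise ValueError("cofactor must be > 0")
        if not 0 < self.percentile <= 100:
            raise ValueError("percentile must be in (0, 100]")


def normalize_expression(
    cells: pd.DataFrame,
    marker_cols: list[str],
    params: NormalizationParams | None = None,
) -> pd.DataFrame:
    """Three-step normalization of raw marker totals.

    Per cell and marker: v1 = v / area (skipped for nuclear markers),
    v2 = asinh(scale * v1 / cofactor), v3 = v2 / P99(v2) computed per
    marker over all cells. Markers whose percentile divisor is zero are
    left at 0. Returns a copy with marker columns replaced.
    """
    params = params or NormalizationParams()
    out = cells.copy()
    area = out["area"].to_numpy(dtype=float)
    if (area <= 0).any():
        raise ValueError("all cell areas must be > 0")
    for m in marker_cols:
        v = out[m].to_numpy(dtype=float)
        if (v < 0).any():
            raise ValueError(f"negative raw expression in marker {m!r}")
        v1 = v if m in params.no_area_markers else v / area
        v2 = np.arcsinh(params.scale_factor * v1 / params.arcsinh_cofactor)
        q = np.percentile(v2, params.percentile)
        out[m] = v2 / q if q > 0 else np.zeros_like(v2)
    return out


def apply_positivity(
    cells: pd.DataFrame,
    thresholds: dict[str, float],
    nucleated_col: str | None = "nucleated",
) -> pd.DataFrame:
    """Flag cells positive for each thresholded functional marker.

    Positivity is inclusive (value >= threshold). Ki67 positivity is
    defined only for nucleated cells (False elsewhere) when a nucleation
    column is present.
    """
    missing = [m for m in thresholds if m not in cells.columns]
    if missing:
        raise ValueError(f"markers missing from the table: {missing}")
    out = cells.copy()
    for m, thr in thresholds.items():
        pos = out[m].to_numpy(dtype=float) >= thr
        if m == "Ki67" and nucleated_col and nucleated_col in out.columns:
            pos &= out[nucleated_col].to_numpy(dtype=bool)
        out[f"pos_{m}"] = pos
    return out


#: (rule name, target lineage) in application order; first match wins.
REFINEMENT_ORDER = ("treg", "mast", "mac2b", "hofbauer", "ck7")


def refine_lineages(
    cells: pd.DataFrame,
    t_cell_labels: tuple[str, ...] = ("T",),
    cd4_label: str = "CD4T",
    macrophage_labels: tuple[str, ...] = ("Mac1a", "Mac1b", "Mac2a", "Mac2c"),
    ck7_dominant_labels: tuple[str, ...] = ("CK7_dominant",),
    foxp3_thr: float = 0.5,
    tryptase_thr: float = 0.9,
    cd11c_thr: float = 0.5,
    cd14_thr: float = 0.5,
) -> pd.DataFrame:
    """Rule-based lineage reassignments on normalized expression.

    In order: (1) T cells with CD3 >= the mean CD3 of CD4+ T cells and
    FOXP3 > 0.5 become Treg; (2) any cell with tryptase > 0.9 becomes
    mast; (3) macrophages with CD11c > 0.5 become Mac2b; (4) CD14 > 0.5
    cells inside the cell column become Hofbauer; (5) CK7-dominant
    clusters become EVT2 inside the cell column, glandular otherwise.
    A cell undergoes at most one terminal reassignment (first match wins);
    the rules are idempotent.
    """
    needed = {"CD3", "FOXP3", "tryptase", "CD11c", "CD14"}
    missing = needed - set(cells.columns)
    if missing:
        raise ValueError(f"refinement rules need markers: {sorted(missing)}")
    out = cells.copy()
    lineage = out["lineage"].astype(str).to_numpy()
    in_cc = (
        out["compartment"].to_numpy() == "cell_column"
        if "compartment" in out.columns
        else np.zeros(len(out), dtype=bool)
    )
    claimed = np.zeros(len(out), dtype=bool)

    cd4 = out.loc[out["lineage"] == cd4_label, "CD3"]
    cd3_ref = float(cd4.mean()) if len(cd4) else float(out["CD3"].mean())
    rule_treg = (
        np.isin(lineage, t_cell_labels + (cd4_label,))
        & (out["CD3"].to_numpy() >= cd3_ref)
        & (out["FOXP3"].to_numpy() > foxp3_thr)
    )
    lineage[rule_treg & ~claimed] = "Treg"
    claimed |= rule_treg

    rule_mast = out["tryptase"].to_numpy() > tryptase_thr
    lineage[rule_mast & ~claimed] = "mast"
    claimed |= rule_mast

    rule_mac2b = np.isin(lineage, macrophage_labels) & (
        out["CD11c"].to_numpy() > cd11c_thr
    )
    lineage[rule_mac2b & ~claimed] = "Mac2b"
    claimed |= rule_mac2b

    rule_hof = (out["CD14"].to_numpy() > cd14_thr) & in_cc
    lineage[rule_hof & ~claimed] = "Hofbauer"
    claimed |= rule_hof

    rule_ck7 = np.isin(lineage, ck7_dominant_labels)
    lineage[rule_ck7 & ~claimed & in_cc] = "EVT2"
    lineage[rule_ck7 & ~claimed & ~in_cc] = "glandular"

    out["lineage"] = lineage
    return out


def distance_to_artery(masks: "FeatureMasks") -> np.ndarray:
    """Euclidean distance transform to the nearest artery pixel."""
    return ndimage.distance_transform_edt(masks.artery == 0)


def assign_compartments(
    cells: pd.DataFrame,
    masks: "FeatureMasks",
    band_width: float = 50.0,
) -> pd.DataFrame:
    """Assign each cell a primary compartment and a perivascular flag.

    Primary compartment by centroid mask membership with precedence
    artery > cell_column > gland > vessel > decidua; centroids outside all
    masks get "none". Decidua cells whose centroid lies within
    ``band_width`` pixels (inclusive) of an artery boundary are flagged
    perivascular. Cells of other images must be filtered out beforehand.
    """
    out = cells.copy()
    h, w = masks.shape
    rr = np.clip(out["y"].round().astype(int), 0, h - 1).to_numpy()
    cc = np.clip(out["x"].round().astype(int), 0, w - 1).to_numpy()

    comp = np.full(len(out), "none", dtype=object)
    comp[masks.decidua[rr, cc]] = "decidua"
    comp[masks.vessel[rr, cc]] = "vessel"
    comp[masks.gland[rr, cc]] = "gland"
    comp[masks.cell_column[rr, cc]] = "cell_column"
    comp[masks.artery[rr, cc] > 0] = "artery"
    out["compartment"] = comp

    dist = distance_to_artery(masks)
    out["perivascular"] = (comp == "decidua") & (dist[rr, cc] <= band_width)
    # nearest artery instance (for per-artery EVT bookkeeping)
    if (masks.artery > 0).any():
        _, (ir, ic) = ndimage.distance_transform_edt(
            masks.artery == 0, return_indices=True
        )
        out["nearest_artery"] = masks.artery[ir[rr, cc], ic[rr, cc]]
        out["artery_distance"] = dist[rr, cc]
    else:
        out["nearest_artery"] = 0
        out["artery_distance"] = np.inf
    return out
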
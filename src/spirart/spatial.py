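"""Bootstrap spatial enrichment, microenvironments and per-artery EVT
bookkeeping.

Enrichment of cell type A around type B in one image counts ordered pairs
closer than a distance threshold (100 px by default), then re-places the
A cells uniformly (without replacement) over the observed cell positions
100 times; the Z-score of the observed count within the pool of
{bootstraps + observed} is the enrichment. Keeping the candidate
positions fixed to real cell locations preserves tissue architecture in
the null. Cells outside the decidua compartment are excluded throughout.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial import cKDTree
from sklearn.cluster import KMeans


def _decidua_positions(cells: pd.DataFrame) -> pd.DataFrame:
    if "compartment" in cells.columns:
        return cells[cells["compartment"] == "decidua"]
    return cells


def close_interactions(
    cells: pd.DataFrame,
    type_a: str,
    type_b: str,
    threshold: float = 100.0,
) -> int:
    """Ordered (a, b) pairs of decidua cells with distance strictly below
    the threshold; a cell never pairs with itself."""
    dec = _decidua_positions(cells)
    a = dec[dec["lineage"] == type_a]
    b = dec[dec["lineage"] == type_b]
    if a.empty or b.empty:
        return 0
    ta = cKDTree(a[["x", "y"]].to_numpy(dtype=float))
    tb = cKDTree(b[["x", "y"]].to_numpy(dtype=float))
    # count_neighbors with strict inequality via a tiny epsilon shrink is
    # fragile; query pairs explicitly instead.
    pairs = ta.query_ball_tree(tb, r=threshold)
    bx = b[["x", "y"]].to_numpy(dtype=float)
    ax = a[["x", "y"]].to_numpy(dtype=float)
    a_ids = a["cell_id"].to_numpy()
    b_ids = b["cell_id"].to_numpy()
    count = 0
    for i, neigh in enumerate(pairs):
        for j in neigh:
            if a_ids[i] == b_ids[j]:
                continue
            if np.hypot(*(ax[i] - bx[j])) < threshold:
                count += 1
    return count


def _neighbour_counts(
    positions: np.ndarray, b_positions: np.ndarray, threshold: float
) -> np.ndarray:
    """For every candidate position, the number of B cells strictly closer
    than the threshold."""
    if len(b_positions) == 0:
        return np.zeros(len(positions), dtype=int)
    tree = cKDTree(b_positions)
    counts = np.zeros(len(positions), dtype=int)
    for i, neigh in enumerate(tree.query_ball_point(positions, r=threshold)):
        d = np.hypot(*(b_positions[neigh] - positions[i]).T) if neigh else np.array([])
        counts[i] = int((d < threshold).sum())
    return counts


def enrichment_z(
    cells: pd.DataFrame,
    type_a: str,
    type_b: str,
    threshold: float = 100.0,
    n_boot: int = 100,
    rng: np.random.Generator | None = None,
) -> float:
    """Bootstrap enrichment Z of type A around type B in one image.

    Each bootstrap reassigns the A label to |A| cells drawn without
    replacement from all decidua cells (any type; B stays fixed) and
    recounts A-B close interactions; a cell never pairs with itself, so
    a resampled A that is also a B contributes no distance-zero self
    pair. Z = (observed - mean(pool)) / sd(pool) with pool = bootstraps
    + {observed} and population sd; NaN when the pool is degenerate.
    """
    rng = rng or np.random.default_rng()
    dec = _decidua_positions(cells)
    a_mask = (dec["lineage"] == type_a).to_numpy()
    b_mask = (dec["lineage"] == type_b).to_numpy()
    n_a = int(a_mask.sum())
    if n_a == 0 or not b_mask.any():
        return np.nan
    pos = dec[["x", "y"]].to_numpy(dtype=float)
    # B cells within the threshold of each candidate cell, excluding the
    # candidate itself (a B cell is within distance 0 of itself)
    per_cell = _neighbour_counts(pos, pos[b_mask], threshold) - b_mask.astype(int)

    observed = int(per_cell[a_mask].sum())
    boots = np.empty(n_boot)
    for it in range(n_boot):
        idx = rng.choice(len(pos), size=n_a, replace=False)
        boots[it] = per_cell[idx].sum()
    pool = np.concatenate([boots, [observed]])
    sd = pool.std()
    if sd == 0:
        return np.nan
    return float((observed - pool.mean()) / sd)


def artery_proximity(
    cells: pd.DataFrame, artery_distance: np.ndarray, threshold: float = 100.0
) -> np.ndarray:
    """Boolean proximity of each cell to the nearest artery (strict)."""
    return np.asarray(artery_distance) < threshold


def artery_enrichment_z(
    cells: pd.DataFrame,
    type_a: str,
    threshold: float = 100.0,
    n_boot: int = 100,
    rng: np.random.Generator | None = None,
) -> float:
    """Bootstrap enrichment Z of type A around the image's arteries.

    Requires an ``artery_distance`` column (from compartment assignment).
    A cell is artery-proximal when its distance to the nearest artery
    boundary is strictly below the threshold; the same position-resampling
    null as cell-cell enrichment applies.
    """
    rng = rng or np.random.default_rng()
    dec = _decidua_positions(cells)
    if "artery_distance" not in dec.columns or not np.isfinite(
        dec["artery_distance"].to_numpy(dtype=float)
    ).any():
        return np.nan
    a_mask = (dec["lineage"] == type_a).to_numpy()
    n_a = int(a_mask.sum())
    if n_a == 0:
        return np.nan
    proximal = dec["artery_distance"].to_numpy(dtype=float) < threshold
    observed = int(proximal[a_mask].sum())
    boots = np.empty(n_boot)
    for it in range(n_boot):
        idx = rng.choice(len(dec), size=n_a, replace=False)
        boots[it] = proximal[idx].sum()
    pool = np.concatenate([boots, [observed]])
    sd = pool.std()
    if sd == 0:
        return np.nan
    return float((observed - pool.mean()) / sd)


def enrichment_matrix(
    cells: pd.DataFrame,
    populations: list[str],
    threshold: float = 100.0,
    n_boot: int = 100,
    rng: np.random.Generator | None = None,
    include_artery: bool = True,
) -> pd.DataFrame:
    """All ordered pairwise enrichments for one image (rows: A, cols: B).

    Entries where either type is absent are NaN ("missing", not zero).
    An extra ``artery`` column holds the cell-artery enrichment.
    """
    rng = rng or np.random.default_rng()
    cols = list(populations) + (["artery"] if include_artery else [])
    out = pd.DataFrame(np.nan, index=populations, columns=cols)
    for a in populations:
        for b in populations:
            out.loc[a, b] = enrichment_z(cells, a, b, threshold, n_boot, rng)
        if include_artery:
            out.loc[a, "artery"] = artery_enrichment_z(cells, a, threshold, n_boot, rng)
    return out


def neighbourhood_compositions(
    cells: pd.DataFrame,
    populations: list[str],
    nn: int = 25,
) -> pd.DataFrame:
    """Per decidua cell: composition of its ``nn`` nearest decidua
    neighbours over the population vocabulary (rows sum to 1).

    Neighbourhoods never cross image boundaries; images with fewer than
    nn + 1 decidua cells contribute no rows. k-NN ties resolve by cell id
    order (the KD-tree query is deterministic for fixed input order).
    """
    rows = []
    index = []
    for image_id, grp in cells.groupby("image_id", sort=True):
        dec = _decidua_positions(grp).sort_values("cell_id")
        if len(dec) < nn + 1:
            continue
        pos = dec[["x", "y"]].to_numpy(dtype=float)
        lin = dec["lineage"].to_numpy()
        tree = cKDTree(pos)
        _, idx = tree.query(pos, k=nn + 1)
        for i, cid in enumerate(dec["cell_id"].to_numpy()):
            neigh = [j for j in idx[i] if j != i][:nn]
            counts = pd.Series(lin[neigh]).value_counts()
            rows.append([counts.get(p, 0) / nn for p in populations])
            index.append((image_id, cid))
    return pd.DataFrame(
        rows,
        index=pd.MultiIndex.from_tuples(index, names=["image_id", "cell_id"]),
        columns=populations,
    )


def microenvironments(
    cells: pd.DataFrame,
    populations: list[str],
    nn: int = 25,
    k: int = 20,
    merge_threshold: float = 0.5,
    seed: int = 0,
) -> tuple[pd.Series, pd.DataFrame]:
    """Discover recurring cellular neighbourhoods (microenvironments).

    Neighbourhood composition vectors are k-means clustered (k centroids,
    seeded), then centroids are merged by complete-linkage hierarchical
    clustering cut at ``merge_threshold`` Euclidean distance. Returns the
    per-cell environment labels and the mean composition per environment.
    """
    comp = neighbourhood_compositions(cells, populations, nn)
    if comp.empty:
        return pd.Series(dtype=int), pd.DataFrame(columns=populations)
    k_eff = min(k, len(comp))
    km = KMeans(n_clusters=k_eff, n_init=10, random_state=seed)
    raw_labels = km.fit_predict(comp.to_numpy())
    centroids = km.cluster_centers_
    if len(centroids) > 1:
        merge_map = fcluster(
            linkage(centroids, method="complete"),
            t=merge_threshold,
            criterion="distance",
        )
    else:
        merge_map = np.array([1])
    labels = pd.Series(merge_map[raw_labels], index=comp.index, name="environment")
    profiles = comp.groupby(labels).mean()
    return labels, profiles


def artery_evt_summary(
    cells: pd.DataFrame,
    evt_lineages: tuple[str, ...],
    min_evt: int = 5,
    inclusive: bool = True,
) -> pd.DataFrame:
    """Per-artery EVT counts, presence flags and compartment ratio.

    Intravascular EVTs sit inside the artery mask; perivascular EVTs are
    decidua EVTs flagged within the perivascular band, attributed to their
    nearest artery. Presence requires at least ``min_evt`` EVTs in the
    compartment (``inclusive=False`` switches to strictly more, matching
    the alternative published phrasing). The intravascular/perivascular
    ratio is defined only when both counts are positive.
    """
    evt = cells[cells["lineage"].isin(evt_lineages)]
    rows = {}
    for (image_id, aid), grp in evt.groupby(["image_id", "nearest_artery"]):
        if aid == 0:
            continue
        intra = int(((grp["compartment"] == "artery")).sum())
        peri = int((grp.get("perivascular", pd.Series(False, index=grp.index))).sum())
        rows[(image_id, int(aid))] = (intra, peri)
    out = []
    cmp_fn = (lambda c: c >= min_evt) if inclusive else (lambda c: c > min_evt)
    for (image_id, aid), (intra, peri) in sorted(rows.items()):
        out.append(
            {
                "image_id": image_id,
                "artery_id": aid,
                "n_intravascular_evt": intra,
                "n_perivascular_evt": peri,
                "intravascular_present": cmp_fn(intra),
                "perivascular_present": cmp_fn(peri),
                "intra_peri_ratio": intra / peri if intra > 0 and peri > 0 else np.nan,
            }
        )
    return pd.DataFrame(out)
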
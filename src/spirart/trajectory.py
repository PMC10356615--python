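"""Continuous spiral-artery-remodelling score (delta) and EVT discriminant.

Manual remodelling stages 1-5 are ordinal and coarse; to obtain a
continuous per-artery pseudotime, morphometric feature vectors are
standardized and projected by a supervised linear discriminant analysis
using the manual stages as class labels. A polynomial curve (degree chosen
in 1..6 by minimizing the Kruskal-Wallis p value for separating the score
by manual stage) is fitted through the arteries in the plane of the first
two discriminants; delta is the arc length along that curve from its
origin to the point nearest each artery, min-max rescaled to [1, 5] over
the cohort and oriented so that delta increases with manual stage.

The published cohort model is exposed as :func:`reference_trajectory`.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

#: Coefficients (highest degree first) of the published cohort trajectory
#: polynomial in discriminant space, f(x) = 0.0005 x^4 - 0.01227 x^3
#: + 0.1363 x^2 - 0.4354 x - 0.7425.
REFERENCE_TRAJECTORY_COEFFS: tuple[float, ...] = (
    0.0005, -0.01227, 0.1363, -0.4354, -0.7425
)


def reference_trajectory() -> np.poly1d:
    """The published quartic trajectory polynomial f(x) in LDA space."""
    return np.poly1d(REFERENCE_TRAJECTORY_COEFFS)


def standardize(
    X: np.ndarray, mean: np.ndarray | None = None, sd: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Column-standardize with median imputation of missing entries.

    Zero-variance columns are left centred (divisor 1) so constant
    features carry no discriminative weight rather than blowing up.
    """
    X = np.asarray(X, dtype=float).copy()
    for j in range(X.shape[1]):
        col = X[:, j]
        bad = ~np.isfinite(col)
        if bad.any():
            med = np.nanmedian(np.where(np.isfinite(col), col, np.nan))
            X[bad, j] = 0.0 if not np.isfinite(med) else med
    if mean is None:
        mean = X.mean(axis=0)
        sd = X.std(axis=0)
    sd_safe = np.where(sd > 0, sd, 1.0)
    return (X - mean) / sd_safe, mean, sd


def fit_lda(
    X: np.ndarray, stages: np.ndarray, n_components: int = 2
) -> tuple[np.ndarray, "LinearDiscriminantAnalysis", np.ndarray, np.ndarray]:
    """Standardize features and project onto class-separating axes.

    Uses the eigen solver with Ledoit-Wolf shrinkage of the within-class
    scatter toward a scaled identity, which keeps the projection defined
    when features are collinear or classes are small.

    Returns (coords, fitted estimator, mean, sd); ``coords`` has up to
    ``n_components`` columns (capped at #classes - 1).
    """
    stages = np.asarray(stages)
    if len(np.unique(stages)) < 2:
        raise ValueError("need >= 2 manual stages to fit the discriminant")
    Z, mean, sd = standardize(X)
    n_comp = min(n_components, len(np.unique(stages)) - 1, Z.shape[1])
    lda = LinearDiscriminantAnalysis(
        solver="eigen", shrinkage="auto", n_components=n_comp
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        coords = lda.fit(Z, stages).transform(Z)
    return coords, lda, mean, sd


def separation_ratio(coords: np.ndarray, stages: np.ndarray) -> float:
    """Between/within variance ratio of the first discriminant coordinate."""
    x = coords[:, 0]
    groups = [x[stages == s] for s in np.unique(stages)]
    grand = x.mean()
    between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups) / len(x)
    within = sum(((g - g.mean()) ** 2).sum() for g in groups) / len(x)
    return float(between / within) if within > 0 else np.inf


@dataclass
class TrajectoryModel:
    """Fitted trajectory through discriminant space, frozen for reuse."""

    degree: int
    coeffs: np.ndarray              # highest degree first, y = f(x)
    grid_x: np.ndarray              # dense interpolation grid (10^4 points)
    grid_y: np.ndarray
    arc_length: np.ndarray          # cumulative arc length from grid[0]
    origin_at_start: bool = True    # delta measured from grid[0] if True
    rescale_bounds: tuple[float, float] | None = None

    @classmethod
    def fit(
        cls,
        coords: np.ndarray,
        degree: int,
        grid_points: int = 10_000,
    ) -> "TrajectoryModel":
        x, y = coords[:, 0], coords[:, 1]
        coeffs = np.polyfit(x, y, degree)
        gx = np.linspace(x.min(), x.max(), grid_points)
        gy = np.polyval(coeffs, gx)
        seg = np.hypot(np.diff(gx), np.diff(gy))
        arc = np.concatenate([[0.0], np.cumsum(seg)])
        return cls(degree=degree, coeffs=coeffs, grid_x=gx, grid_y=gy, arc_length=arc)

    def raw_arc_positions(self, coords: np.ndarray) -> np.ndarray:
        """Arc length from the origin endpoint to the nearest grid point.

        Nearest-point ties resolve to the lower arc-length grid point.
        """
        arc_from_origin = (
            self.arc_length
            if self.origin_at_start
            else self.arc_length[-1] - self.arc_length
        )
        pos = np.empty(len(coords))
        for i, (px, py) in enumerate(coords[:, :2]):
            d2 = (self.grid_x - px) ** 2 + (self.grid_y - py) ** 2
            best = d2.min()
            ties = np.nonzero(d2 == best)[0]
            pos[i] = arc_from_origin[ties].min()
        return pos

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "degree": self.degree,
                    "coeffs": self.coeffs.tolist(),
                    "grid_x": [float(self.grid_x[0]), float(self.grid_x[-1]), len(self.grid_x)],
                    "origin_at_start": self.origin_at_start,
                    "rescale_bounds": self.rescale_bounds,
                }
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "TrajectoryModel":
        d = json.loads(Path(path).read_text())
        x0, x1, npts = d["grid_x"]
        gx = np.linspace(x0, x1, int(npts))
        coeffs = np.asarray(d["coeffs"])
        gy = np.polyval(coeffs, gx)
        seg = np.hypot(np.diff(gx), np.diff(gy))
        arc = np.concatenate([[0.0], np.cumsum(seg)])
        return cls(
            degree=int(d["degree"]),
            coeffs=coeffs,
            grid_x=gx,
            grid_y=gy,
            arc_length=arc,
            origin_at_start=bool(d["origin_at_start"]),
            rescale_bounds=tuple(d["rescale_bounds"]) if d["rescale_bounds"] else None,
        )


def _stage_separation_p(delta: np.ndarray, stages: np.ndarray) -> float:
    groups = [delta[stages == s] for s in np.unique(stages)]
    groups = [g for g in groups if len(g) > 0]
    if len(groups) < 2:
        return 1.0
    try:
        return float(stats.kruskal(*groups).pvalue)
    except ValueError:  # all values identical
        return 1.0


def select_degree(
    coords: np.ndarray,
    stages: np.ndarray,
    degrees: range = range(1, 7),
    grid_points: int = 10_000,
    tie_factor: float = 10.0,
) -> tuple[int, dict[int, float]]:
    """Pick the polynomial degree whose delta best separates manual stages.

    For every candidate degree a curve is fitted, delta computed for all
    arteries, and a Kruskal-Wallis test of delta across stages scored; the
    degree with the smallest p wins. Nested higher-degree fits produce
    near-identical p values, so ties are resolved toward parsimony: the
    lowest degree whose p is within ``tie_factor`` of the minimum.
    """
    stages = np.asarray(stages)
    counts = pd.Series(stages).value_counts()
    if (counts < 3).any():
        warnings.warn(
            "fewer than 3 arteries in some stages; degree selection may be unstable",
            stacklevel=2,
        )
    pvals: dict[int, float] = {}
    for deg in degrees:
        model = TrajectoryModel.fit(coords, deg, grid_points)
        delta = compute_delta(coords, model, stages)
        pvals[deg] = _stage_separation_p(delta, stages)
    p_min = min(pvals.values())
    best = min(d for d, p in pvals.items() if p <= tie_factor * p_min)
    return best, pvals


def compute_delta(
    coords: np.ndarray,
    model: TrajectoryModel,
    stages: np.ndarray | None = None,
) -> np.ndarray:
    """Arc-length score per artery, rescaled to [1, 5] over the cohort.

    When ``stages`` is given, the curve orientation is chosen so that the
    score increases (on average) with manual stage, and the rescale bounds
    are refreshed from this cohort; otherwise the model's stored
    orientation and bounds are reused (frozen-model scoring).
    """
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    if stages is not None:
        stages = np.asarray(stages, dtype=float)
        raw = model.raw_arc_positions(coords)
        r = np.corrcoef(raw, stages)[0, 1] if np.std(raw) > 0 else 0.0
        if r < 0:
            model.origin_at_start = not model.origin_at_start
            raw = model.raw_arc_positions(coords)
        model.rescale_bounds = (float(raw.min()), float(raw.max()))
    else:
        raw = model.raw_arc_positions(coords)
    lo, hi = model.rescale_bounds
    if hi > lo:
        return 1.0 + 4.0 * (np.clip(raw, lo, hi) - lo) / (hi - lo)
    return np.full(len(coords), 1.0)


def fit_sar_trajectory(
    features: pd.DataFrame,
    stages: np.ndarray,
    grid_points: int = 10_000,
) -> tuple[np.ndarray, TrajectoryModel, dict]:
    """End-to-end: features + manual stages -> delta per artery.

    Returns (delta, trajectory model, audit dict with LDA loadings, the
    selected degree and per-degree separation p values).
    """
    stages = np.asarray(stages)
    coords, lda, mean, sd = fit_lda(features.to_numpy(dtype=float), stages)
    if coords.shape[1] < 2:
        coords = np.column_stack([coords[:, 0], np.zeros(len(coords))])
    degree, pvals = select_degree(coords, stages, grid_points=grid_points)
    model = TrajectoryModel.fit(coords, degree, grid_points)
    delta = compute_delta(coords, model, stages)
    audit = {
        "degree": degree,
        "degree_pvalues": pvals,
        "loadings": lda.scalings_[:, :2].tolist(),
        "feature_names": list(features.columns),
        "coords": coords,
    }
    return delta, model, audit


def evt_compartment_lda(
    markers: pd.DataFrame,
    compartments: np.ndarray,
    train_labels: tuple[str, ...] = ("cell_column", "interstitial", "intravascular"),
) -> np.ndarray:
    """One-dimensional discriminant (LD1) over EVT functional markers.

    Standardizes marker expression over all EVTs, trains on the cell
    column / interstitial / intravascular compartments, and scores every
    EVT — including compartments withheld from training (perivascular),
    whose LD1 placement relative to the training classes is the readout.
    """
    compartments = np.asarray(compartments)
    Z, _, _ = standardize(markers.to_numpy(dtype=float))
    train = np.isin(compartments, train_labels)
    if train.sum() < 3:
        raise ValueError("too few training EVTs")
    lda = LinearDiscriminantAnalysis(solver="eigen", shrinkage="auto", n_components=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        lda.fit(Z[train], compartments[train])
    return lda.transform(Z)[:, 0]
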
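"""Per-image features and temporal trend classification along GA and SAR.

Every per-image feature (cell-type frequency, marker positivity fraction,
pairwise enrichment) is regressed linearly against the two temporal axes:
gestational age and the image's mean artery remodelling score (delta).
The ratio of the two R-squared values classifies the trend as GA-driven,
SAR-driven or synchronized; trend size measures the fitted change over
the observed axis range (in units of the mean for frequency-like
features). A ridge regression predicting GA from immune composition
quantifies how tightly the immune compartment tracks gestational age.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import Ridge, RidgeCV
from sklearn.preprocessing import MinMaxScaler


@dataclass
class TrendFit:
    slope: float
    intercept: float
    r2: float
    p: float
    trend_size: float
    n: int


def linear_trend(
    values: np.ndarray,
    axis: np.ndarray,
    normalize_trend_size: bool = True,
    raw_endpoints: bool = False,
) -> TrendFit:
    """OLS of a per-image feature against a temporal axis.

    Trend size is the change over the observed axis range: by default the
    fitted values at max(X) and min(X) are differenced and, for
    frequency-like features, divided by the mean; ``raw_endpoints`` uses
    the raw observations at the extreme axis values instead.
    """
    v = np.asarray(values, dtype=float)
    x = np.asarray(axis, dtype=float)
    ok = np.isfinite(v) & np.isfinite(x)
    v, x = v[ok], x[ok]
    if len(v) < 3:
        raise ValueError("need >= 3 finite points")
    if np.ptp(x) == 0:
        raise ValueError("constant axis: trend undefined")
    res = stats.linregress(x, v)
    fitted_hi = res.intercept + res.slope * x.max()
    fitted_lo = res.intercept + res.slope * x.min()
    if raw_endpoints:
        hi = v[np.argmax(x)]
        lo = v[np.argmin(x)]
    else:
        hi, lo = fitted_hi, fitted_lo
    size = hi - lo
    if normalize_trend_size:
        mean_v = v.mean()
        size = size / mean_v if mean_v != 0 else 0.0
    return TrendFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue**2),
        p=float(res.pvalue),
        trend_size=float(size),
        n=len(v),
    )


def classify_axis(
    r2_ga: float,
    p_ga: float,
    r2_delta: float,
    p_delta: float,
    rule: str = "volcano",
    r2_min: float = 0.05,
    p_max: float = 0.05,
) -> tuple[str, float]:
    """Classify a feature's temporal trend between the GA and SAR axes.

    ``volcano`` (cell/marker features): the axis with the larger R-squared
    wins, reported with log2(R2_delta / R2_GA); features whose better
    model has R-squared < ``r2_min`` or p > ``p_max`` are "none".
    ``gene``: SAR-driven iff log2 ratio >= 1 with R2_delta >= 0.05;
    GA-driven iff log2 ratio <= -1 with R2_GA >= 0.05; otherwise
    synchronized. Returns (class, log2 ratio).
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        if r2_ga == 0 and r2_delta == 0:
            ratio = 0.0
        elif r2_ga == 0:
            ratio = np.inf
        elif r2_delta == 0:
            ratio = -np.inf
        else:
            # difference of logs: stable for extreme R-squared ratios
            ratio = float(np.log2(r2_delta) - np.log2(r2_ga))
    if rule == "volcano":
        if r2_delta >= r2_ga:
            best_r2, best_p, label = r2_delta, p_delta, "SAR-driven"
        else:
            best_r2, best_p, label = r2_ga, p_ga, "GA-driven"
        if best_r2 < r2_min or best_p > p_max:
            return "none", ratio
        return label, ratio
    if rule == "gene":
        if ratio >= 1 and r2_delta >= r2_min:
            return "SAR-driven", ratio
        if ratio <= -1 and r2_ga >= r2_min:
            return "GA-driven", ratio
        return "synchronized", ratio
    raise ValueError(f"unknown rule {rule!r}")


#: Lineages excluded from decidua composition denominators: unassigned
#: cells plus populations that spill out of their own feature masks.
EXCLUDED_LINEAGES = ("other", "muscle", "glandular")


def image_features(
    cells: pd.DataFrame,
    images: pd.DataFrame,
    arteries: pd.DataFrame | None = None,
    positivity_pairs: list[tuple[str, str]] | None = None,
    excluded_lineages: tuple[str, ...] = EXCLUDED_LINEAGES,
) -> pd.DataFrame:
    """Per-image feature table: lineage frequencies, positivity fractions,
    GA and mean artery delta.

    Frequencies are proportions among decidua-compartment cells after
    dropping unassigned ("other"), muscle and glandular cells. Positivity
    fractions for a (lineage, marker) pair use all cells of the lineage
    outside the cell column (glandular cells restricted to the gland
    mask). Images without arteries carry a missing mean delta and are
    excluded from delta-axis regressions downstream.
    """
    feats = {}
    for image_id, grp in cells.groupby("image_id"):
        dec = grp[
            (grp["compartment"] == "decidua")
            & ~grp["lineage"].isin(excluded_lineages)
        ]
        if dec.empty:
            warnings.warn(f"image {image_id}: no eligible decidua cells; dropped", stacklevel=2)
            continue
        row = {}
        freq = dec["lineage"].value_counts(normalize=True)
        for lin, f in freq.items():
            row[f"freq_{lin}"] = f
        if positivity_pairs:
            for lin, marker in positivity_pairs:
                sub = grp[grp["lineage"] == lin]
                sub = sub[
                    sub["compartment"] == "gland"
                ] if lin == "glandular" else sub[sub["compartment"] != "cell_column"]
                col = f"pos_{marker}"
                if len(sub) and col in sub.columns:
                    row[f"posfrac_{lin}_{marker}"] = float(sub[col].mean())
        feats[image_id] = row
    table = pd.DataFrame.from_dict(feats, orient="index")
    freq_cols = [c for c in table.columns if c.startswith("freq_")]
    table[freq_cols] = table[freq_cols].fillna(0.0)
    meta = images.set_index("image_id")
    table["ga_days"] = meta["ga_days"].reindex(table.index)
    if arteries is not None and "delta" in arteries.columns:
        mean_delta = arteries.groupby("image_id")["delta"].mean()
        table["mean_delta"] = mean_delta.reindex(table.index)
    else:
        table["mean_delta"] = np.nan
    table.index.name = "image_id"
    return table


def trend_table(
    features: pd.DataFrame,
    feature_cols: list[str] | None = None,
    rule: str = "volcano",
    normalize_trend_size: bool = True,
) -> pd.DataFrame:
    """Fit GA- and delta-axis regressions for every feature column and
    classify each trend. Adds a Benjamini-Hochberg column per axis for
    reference; classification uses raw p values as published."""
    from statsmodels.stats.multitest import multipletests

    feature_cols = feature_cols or [
        c for c in features.columns if c not in ("ga_days", "mean_delta")
    ]
    rows = []
    for col in feature_cols:
        try:
            ga = linear_trend(features[col], features["ga_days"], normalize_trend_size)
            de = linear_trend(features[col], features["mean_delta"], normalize_trend_size)
        except ValueError:
            continue
        label, ratio = classify_axis(ga.r2, ga.p, de.r2, de.p, rule=rule)
        best = de if de.r2 >= ga.r2 else ga
        rows.append(
            {
                "feature": col,
                "slope_ga": ga.slope, "r2_ga": ga.r2, "p_ga": ga.p,
                "slope_delta": de.slope, "r2_delta": de.r2, "p_delta": de.p,
                "log2_r2_ratio": ratio,
                "class": label,
                "trend_size": best.trend_size,
                "p_best": best.p,
            }
        )
    out = pd.DataFrame(rows)
    if not out.empty:
        for ax in ("ga", "delta"):
            out[f"q_{ax}"] = multipletests(out[f"p_{ax}"], method="fdr_bh")[1]
    return out


def cohort_summary(images: pd.DataFrame, arteries: pd.DataFrame) -> dict:
    """Cohort bookkeeping: subject count, mean GA in weeks (per subject),
    artery count and manual-stage breakdown."""
    per_subject = images.groupby("subject_id")["ga_days"].mean()
    stage_counts = arteries["manual_stage"].value_counts().sort_index()
    return {
        "n_subjects": int(per_subject.size),
        "mean_ga_weeks": float(per_subject.mean() / 7.0),
        "n_images": int(images["image_id"].nunique()),
        "n_arteries": int(len(arteries)),
        "stage_counts": {int(s): int(c) for s, c in stage_counts.items()},
    }


@dataclass
class RidgeResult:
    r2: float
    rmse: float
    alpha: float
    coefficients: pd.Series
    predictions: pd.DataFrame
    split_report: dict


def ga_ridge(
    features: pd.DataFrame,
    ga_days: pd.Series,
    immune_counts: pd.Series | None = None,
    min_immune: int = 10,
    test_fraction: float = 0.3,
    alphas: np.ndarray | None = None,
    seed: int = 0,
) -> RidgeResult:
    """Predict GA from per-image immune composition with ridge regression.

    Features are min-max scaled to [0, 1]; images with fewer than
    ``min_immune`` immune cells are dropped; a 70/30 train/test split
    stratified over GA quantile bins is drawn; the ridge penalty is chosen
    by leave-one-out cross-validation on the training set.
    """
    X = features.copy()
    y = ga_days.reindex(X.index).astype(float)
    if immune_counts is not None:
        keep = immune_counts.reindex(X.index) >= min_immune
        X, y = X[keep], y[keep]
    ok = y.notna() & np.isfinite(X).all(axis=1)
    X, y = X[ok], y[ok]
    if len(X) < 10:
        raise ValueError("fewer than 10 usable images")
    Xs = pd.DataFrame(
        MinMaxScaler().fit_transform(X), index=X.index, columns=X.columns
    )
    rng = np.random.default_rng(seed)
    bins = pd.qcut(y, q=min(4, max(2, len(y) // 8)), labels=False, duplicates="drop")
    test_idx = []
    for b in np.unique(bins):
        members = np.array(X.index[bins == b])
        n_test = max(1, int(round(test_fraction * len(members))))
        test_idx.extend(rng.choice(members, size=n_test, replace=False))
    is_test = Xs.index.isin(test_idx)
    Xtr, ytr = Xs[~is_test], y[~is_test]
    Xte, yte = Xs[is_test], y[is_test]

    alphas = alphas if alphas is not None else np.logspace(-3, 3, 61)
    cv = RidgeCV(alphas=alphas)  # efficient leave-one-out by default
    cv.fit(Xtr, ytr)
    model = Ridge(alpha=cv.alpha_).fit(Xtr, ytr)
    pred = model.predict(Xte)
    ss_res = float(((yte - pred) ** 2).sum())
    ss_tot = float(((yte - yte.mean()) ** 2).sum())
    r2 = 1 - ss_res / ss_tot if ss_tot > 0 else 0.0
    rmse = float(np.sqrt(np.mean((yte - pred) ** 2)))
    split_report = {
        "n_train": int(len(ytr)),
        "n_test": int(len(yte)),
        "ga_mean_train": float(ytr.mean()),
        "ga_mean_test": float(yte.mean()),
    }
    return RidgeResult(
        r2=float(r2),
        rmse=rmse,
        alpha=float(cv.alpha_),
        coefficients=pd.Series(model.coef_, index=Xs.columns),
        predictions=pd.DataFrame({"ga_days": yte, "predicted": pred}),
        split_report=split_report,
    )
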
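"""Targeted spatial-transcriptomics processing.

ROI count matrices carry, per region of interest, probe counts for ~18k
genes plus 100 negative-control probes whose geometric mean estimates the
nonspecific-binding background. Normalization follows the third-quartile
convention for this platform: optional per-ROI background subtraction
(used for artery/decidua ROIs, where ROI size tracks remodelling stage
and background would otherwise confound trends), division by the per-ROI
75th percentile, and multiplication by the geometric mean of all 75th
percentiles so the scale is comparable across ROIs.

Downstream: per-gene quadratic trend detection along GA and delta with an
expression-weighted centre of mass (COM); a pathway temporal-coordination
statistic comparing the COM dispersal of a pathway's genes against random
draws from the genes of interest; and a moderated-t differential
expression test between EVT compartments with empirical-Bayes variance
shrinkage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .model import PathwaySet, RoiExpression


def _geomean(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    x = x[x > 0]
    return float(np.exp(np.mean(np.log(x)))) if x.size else 0.0


def normalize_counts(
    rois: list[RoiExpression], background_subtract: bool
) -> list[RoiExpression]:
    """Q75 normalization with optional negative-probe background
    subtraction, applied jointly to the given group of ROIs.

    With subtraction (artery/decidua ROIs): counts <- max(counts -
    geomean(negative probes), 0) per ROI. Then each ROI's counts are
    divided by its 75th percentile and multiplied by the geometric mean of
    all ROIs' 75th percentiles. ROIs with a zero 75th percentile are
    flagged unusable (norm_counts left None).
    """
    corrected = []
    for roi in rois:
        vals = np.array(list(roi.raw_counts.values()), dtype=float)
        if background_subtract:
            bg = _geomean(roi.neg_probe_counts)
            vals = np.maximum(vals - bg, 0.0)
        corrected.append(vals)
    q75 = np.array([np.percentile(v, 75) for v in corrected])
    scale = _geomean(q75[q75 > 0])
    genes = list(rois[0].raw_counts)
    for roi, vals, q in zip(rois, corrected, q75):
        if q <= 0:
            roi.norm_counts = None
            continue
        roi.norm_counts = dict(zip(genes, vals / q * scale))
    return rois


def expression_matrix(rois: list[RoiExpression]) -> pd.DataFrame:
    """Genes x ROIs matrix of normalized counts (usable ROIs only)."""
    usable = [r for r in rois if r.norm_counts is not None]
    return pd.DataFrame({r.roi_id: r.norm_counts for r in usable})


def expressed_filter(
    rois: list[RoiExpression], min_count: float = 10, min_rois: int = 2
) -> list[str]:
    """Genes with normalized counts >= ``min_count`` in at least
    ``min_rois`` of the given ROIs."""
    mat = expression_matrix(rois)
    keep = (mat >= min_count).sum(axis=1) >= min_rois
    return sorted(mat.index[keep])


def attach_delta(rois: list[RoiExpression], artery_delta: dict) -> list[RoiExpression]:
    """Assign each ROI the mean delta of its linked arteries."""
    for roi in rois:
        ds = [
            artery_delta[key] for key in roi.linked_artery_ids if key in artery_delta
        ]
        if ds:
            roi.delta = float(np.mean(ds))
    return rois


@dataclass
class GeneTrend:
    gene: str
    coeffs_ga: np.ndarray
    r2_ga: float
    p_ga: float
    fc_ga: float
    com_ga: float
    coeffs_delta: np.ndarray
    r2_delta: float
    p_delta: float
    fc_delta: float
    com_delta: float
    trending: bool
    label: str
    log2_r2_ratio: float


def quadratic_fit(t: np.ndarray, e: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Quadratic OLS e ~ 1 + t + t^2; returns (coeffs high-first, R2,
    overall F-test p)."""
    t = np.asarray(t, dtype=float)
    e = np.asarray(e, dtype=float)
    n = len(t)
    X = np.column_stack([t**2, t, np.ones(n)])
    beta, *_ = np.linalg.lstsq(X, e, rcond=None)
    fitted = X @ beta
    ss_res = float(((e - fitted) ** 2).sum())
    ss_tot = float(((e - e.mean()) ** 2).sum())
    r2 = 1 - ss_res / ss_tot if ss_tot > 0 else 0.0
    df_model, df_resid = 2, n - 3
    if df_resid <= 0 or ss_res <= 0 or ss_tot <= ss_res:
        p = 1.0 if r2 <= 0 else 0.0
    else:
        f = (ss_tot - ss_res) / df_model / (ss_res / df_resid)
        p = float(stats.f.sf(f, df_model, df_resid))
    return beta, r2, p


def centre_of_mass(t: np.ndarray, e: np.ndarray) -> float:
    """Expression-weighted mean of the temporal coordinate."""
    t = np.asarray(t, dtype=float)
    e = np.asarray(e, dtype=float)
    total = e.sum()
    return float((t * e).sum() / total) if total > 0 else float(np.mean(t))


def fold_change(e: np.ndarray) -> float:
    """Max/min of raw expression with the minimum floored at half the
    smallest positive value (so zero minima give a finite ratio)."""
    e = np.asarray(e, dtype=float)
    pos = e[e > 0]
    if pos.size == 0:
        return 1.0
    floor = pos.min() / 2
    return float(e.max() / max(e.min(), floor))


def gene_trends(
    rois: list[RoiExpression],
    genes: list[str],
    p_max: float = 0.05,
    fc_min: float = 2.0,
    r2_min: float = 0.05,
) -> pd.DataFrame:
    """Quadratic temporal trends per gene along GA and delta.

    A gene is trending when either axis' regression has p <= 0.05 and the
    raw expression fold change is >= 2; trending genes are classified
    SAR-driven / GA-driven / synchronized by the log2 R-squared ratio rule.
    """
    from .trends import classify_axis

    usable = [r for r in rois if r.norm_counts is not None and r.delta is not None]
    if len(usable) < 5:
        raise ValueError("need >= 5 usable ROIs with delta")
    ga = np.array([r.ga_days for r in usable], dtype=float)
    de = np.array([r.delta for r in usable], dtype=float)
    rows = []
    for g in genes:
        e = np.array([r.norm_counts[g] for r in usable], dtype=float)
        cg, r2g, pg = quadratic_fit(ga, e)
        cd, r2d, pd_ = quadratic_fit(de, e)
        fc = fold_change(e)
        trending_delta = fc >= fc_min and pd_ <= p_max
        trending_ga = fc >= fc_min and pg <= p_max
        trending = trending_delta or trending_ga
        if trending:
            label, ratio = classify_axis(r2g, pg, r2d, pd_, rule="gene", r2_min=r2_min)
        else:
            _, ratio = classify_axis(r2g, pg, r2d, pd_, rule="gene", r2_min=r2_min)
            label = "none"
        rows.append(
            {
                "gene": g,
                "r2_ga": r2g, "p_ga": pg,
                "r2_delta": r2d, "p_delta": pd_,
                "fold_change": fc,
                "com_ga": centre_of_mass(ga, e),
                "com_delta": centre_of_mass(de, e),
                "trending": trending,
                "trending_delta": trending_delta,
                "trending_ga": trending_ga,
                "class": label,
                "log2_r2_ratio": ratio,
                "coeffs_ga": cg.tolist(),
                "coeffs_delta": cd.tolist(),
            }
        )
    return pd.DataFrame(rows).set_index("gene")


def _cd(coms: np.ndarray) -> float:
    """COM dispersal: median absolute deviation from the median COM."""
    med = np.median(coms)
    return float(np.median(np.abs(coms - med)))


def coordination_test(
    interest_coms: pd.Series,
    pathways: list[PathwaySet],
    n_rand: int = 100_000,
    score_cutoff: float = 1.5,
    p_max: float = 0.05,
    min_intersection: int = 10,
    score_cap: float = 10.0,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Temporal coordination of pathway gene sets among genes of interest.

    For each pathway whose intersection with the interest set has >= 10
    genes: CD_group is the median absolute deviation of the member COMs
    from their median; the null draws N genes without replacement from the
    interest set ``n_rand`` times; CD_rand is the median null CD; the
    score is log2(CD_rand / CD_group) and p is the fraction of null CDs
    below CD_group with a 1/R pseudocount. q values are Benjamini-Hochberg
    over all tested pathways; coordinated means score >= 1.5 and p <= 0.05.
    Degenerate CD_group = 0 gets the capped score and the floor p.
    """
    rng = rng or np.random.default_rng()
    coms = interest_coms.dropna()
    universe = coms.index.to_numpy()
    values = coms.to_numpy(dtype=float)
    rows = []
    null_cache: dict[int, np.ndarray] = {}
    for pw in pathways:
        members = np.array(sorted(set(pw.genes) & set(universe)))
        n = len(members)
        if n < min_intersection:
            continue
        cd_group = _cd(coms.loc[members].to_numpy(dtype=float))
        if n not in null_cache:
            draws = np.array(
                [rng.choice(len(values), size=n, replace=False) for _ in range(n_rand)]
            )
            sample = values[draws]
            med = np.median(sample, axis=1, keepdims=True)
            null_cache[n] = np.median(np.abs(sample - med), axis=1)
        null = null_cache[n]
        cd_rand = float(np.median(null))
        if cd_group > 0:
            score = float(np.log2(cd_rand / cd_group)) if cd_rand > 0 else 0.0
            score = min(score, score_cap)
            p = float((null < cd_group).sum()) / n_rand + 1.0 / n_rand
        else:
            score = score_cap
            p = 1.0 / n_rand
        rows.append(
            {
                "pathway": pw.name,
                "n_genes": n,
                "com_med": float(np.median(coms.loc[members])),
                "cd_group": cd_group,
                "cd_rand": cd_rand,
                "score": score,
                "p": p,
            }
        )
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    out["coordinated"] = (out["score"] >= score_cutoff) & (out["p"] <= p_max)
    return out.set_index("pathway")


def _fit_f_dist(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match a scaled F prior to the observed gene variances.

    Returns (prior df d0, prior variance s0^2); d0 = inf when the
    empirical spread of log variances is no wider than expected from the
    residual chi-squared alone.
    """
    s2 = np.asarray(s2, dtype=float)
    s2 = np.where(s2 > 0, s2, s2[s2 > 0].min() if (s2 > 0).any() else 1e-8)
    z = np.log(s2)
    e = z - special.digamma(df / 2) + np.log(df / 2)
    e_mean = float(np.mean(e))
    e_var = float(np.var(e, ddof=1)) - float(special.polygamma(1, df / 2))
    if e_var <= 0:
        return np.inf, float(np.exp(e_mean))
    # invert trigamma(d0/2) = e_var by Newton iteration
    y = 0.5 + 1.0 / e_var
    for _ in range(50):
        tri = special.polygamma(1, y)
        delta = tri * (1 - tri / e_var) / special.polygamma(2, y)
        y += delta
        if abs(delta) < 1e-10 * y:
            break
    d0 = 2 * float(y)
    s02 = float(np.exp(e_mean + special.digamma(y) - np.log(y)))
    return d0, s02


def moderated_de(
    expr: pd.DataFrame,
    groups: pd.Series,
    group_a: str = "interstitial_evt",
    group_b: str = "intravascular_evt",
    fdr: float = 0.1,
    lfc_min: float = 2.0,
    prior_df: float | None = None,
) -> pd.DataFrame:
    """Two-group moderated-t differential expression on log2(norm + 1).

    Per-gene residual variances are shrunk toward a common prior fitted by
    moment-matching the log-variance distribution (empirical Bayes); the
    moderated t uses the augmented degrees of freedom. logFC is group_b
    minus group_a (positive = up in group_b). DEGs satisfy BH-adjusted
    p <= ``fdr`` and |logFC| >= ``lfc_min``. ``prior_df`` overrides the
    fitted prior df (0 recovers the ordinary t-test).
    """
    cols_a = groups.index[groups == group_a]
    cols_b = groups.index[groups == group_b]
    n1, n2 = len(cols_a), len(cols_b)
    if n1 < 2 or n2 < 2:
        raise ValueError("need >= 2 ROIs per group")
    df_resid = n1 + n2 - 2
    if df_resid <= 0:
        raise ValueError("zero residual degrees of freedom")
    la = np.log2(expr[cols_a].to_numpy(dtype=float) + 1)
    lb = np.log2(expr[cols_b].to_numpy(dtype=float) + 1)
    mean_a, mean_b = la.mean(axis=1), lb.mean(axis=1)
    lfc = mean_b - mean_a
    ss = ((la - mean_a[:, None]) ** 2).sum(axis=1) + (
        (lb - mean_b[:, None]) ** 2
    ).sum(axis=1)
    s2 = ss / df_resid

    if prior_df is None:
        d0, s02 = _fit_f_dist(s2, df_resid)
    elif prior_df == 0:
        d0, s02 = 0.0, 0.0
    else:
        d0 = float(prior_df)
        s02 = float(np.median(s2))
    if np.isinf(d0):
        s2_post = np.full_like(s2, s02)
        df_total = np.inf
    else:
        s2_post = (d0 * s02 + df_resid * s2) / (d0 + df_resid)
        df_total = df_resid + d0
    s2_post = np.maximum(s2_post, 1e-12)
    se = np.sqrt(s2_post * (1 / n1 + 1 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(se > 0, lfc / se, 0.0)
    if np.isinf(df_total):
        p = 2 * stats.norm.sf(np.abs(tstat))
    else:
        p = 2 * stats.t.sf(np.abs(tstat), df_total)
    q = multipletests(p, method="fdr_bh")[1]
    out = pd.DataFrame(
        {
            "logFC": lfc,
            "t": tstat,
            "p": p,
            "q": q,
            "s2": s2,
            "s2_post": s2_post,
        },
        index=expr.index,
    )
    out["significant"] = (out["q"] <= fdr) & (out["logFC"].abs() >= lfc_min)
    out["direction"] = np.where(out["logFC"] > 0, "up", "down")
    out.attrs["prior_df"] = d0
    out.attrs["prior_var"] = s02
    return out
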
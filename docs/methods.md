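# Methods

`spirart` re-implements, as a tested library, the quantitative machinery of
a spatiotemporal analysis of the human maternal–fetal interface: the first
half of pregnancy is described along two partially coupled temporal axes —
gestational age (GA, days) and spiral artery remodelling (SAR), the
transformation of maternal uterine arteries into dilated, smooth-muscle-
depleted, trophoblast-lined vessels. This note documents the models, their
assumptions, the parameters that matter, and the choices made where the
design was genuinely open.

## Single-cell phenotyping

Raw per-cell marker totals from multiplexed imaging are normalized in three
steps: division by cell area (pixels), linear scaling by 100 and ArcSinh
transform with cofactor 5, then division by the per-marker 99th percentile
over the dataset. Ki67 is nuclear, so its signal is not diluted by cell
size: it skips area normalization, and its positivity is defined only for
nucleated cells. Functional positivity is an inclusive threshold
(value ≥ threshold) on the normalized scale; thresholds are config values
because in the original workflow they were set by inspection per marker.

Rule-based lineage refinements run in a fixed order with first-match-wins
semantics (Treg, mast, CD11c⁺ macrophage, Hofbauer, CK7-dominant
reassignment); the rules are idempotent. Whether the rule thresholds apply
to percentile-normalized or pre-percentile values is not fixed by the
source description; percentile-normalized is the default here.

Compartments are assigned from feature masks by centroid membership with
precedence artery > cell column > gland > vessel > decidua. Perivascular is
a flag on decidua cells whose centroid lies within 50 px (inclusive) of an
artery boundary, computed from the Euclidean distance transform of the
artery raster's complement. When only centroids and areas are available
(the released-table situation), membership is by centroid rather than the
≥70 %-area-overlap rule.

## Artery morphometry (the onion)

Each artery mask is partitioned by a disc centred on the user-defined
artery centre: the outer radius is the maximum centre-to-edge distance
rounded **up** to a multiple of the layer thickness n (default 10 px), cut
into I concentric layers and k = 100 equal angular sectors (3.6° each,
starting east, counter-clockwise). Deterministic tie-breaks: pixels on a
sector boundary go to the lower-index sector; pixels at an exact layer
radius go to the outer adjacent layer. Trapezoid vertices (arcs replaced by
secants) are recorded for visualization; every statistic is computed from
pixel membership, which is conserved exactly (each in-mask, in-circle pixel
belongs to one segment).

Per marker (CD31, CK7, H3, HLA-G, SMA, VIM): average signal is the
pixel-count-weighted mean over segments (equal to the in-circle mask mean);
a segment is positive when its mean reaches the per-marker segment
threshold; sector thickness d spans the inclusive layer range from the
innermost to the outermost positive segment (a single positive layer has
d = n — a one-layer ring has physical thickness ≈ n, not 0); radial
coverage is the fraction of sectors whose whole-sector mean reaches the
sector threshold. Because a thin endothelial ring is diluted in
whole-sector means, the default CD31 sector threshold is much lower (0.06
vs 0.25 on the generator's intensity scale) — per-marker thresholds are the
intended usage.

Geometry: inscribed radius = max of the interior Euclidean distance
transform; perimeter by weighted boundary steps (1 orthogonal, √2
diagonal); area = pixel count. Jaggedness is computed from the valued
medial-axis skeleton: pixels with distance ≥ 60 px form the deep core,
pixels ≥ 5 px include shallow branches; the ratio branch-inclusive/core
increases with outline irregularity (≈1 for smooth compact shapes, 0 when
the core is empty). The direction of this ratio is ambiguous in the source
description; this orientation is the one under which the statistic
increases with jaggedness, verified by a star-vs-disc ordering test.

SMA/endothelium loss: per artery, 1 − feature/max(feature) using the SMA
average signal and the CD31 radial coverage respectively, then min-max
rescaled to [0, 1] across the cohort. Loss scores are cohort-relative.

## Continuous remodelling score δ

Features are median-imputed, standardized, and projected by a supervised
LDA on the manual stages (eigen solver with Ledoit–Wolf shrinkage of the
within-class scatter — 28 features against few late-stage arteries make
shrinkage necessary; it also keeps collinear features harmless). A
polynomial y = f(x) is fitted through the arteries in the plane of the
first two discriminants. The degree is chosen in 1..6 by minimizing the
Kruskal–Wallis p value for separating δ across manual stages; because
nested higher degrees give near-identical fits, ties are broken toward
parsimony (lowest degree with p within 10× of the minimum). The curve is
interpolated on a dense 10⁴-point grid; δ_raw is the cumulative arc length
(trapezoidal) from the curve origin to the grid point nearest the artery
(ties to the lower arc position); orientation is chosen so δ increases
with mean manual stage; δ is min-max rescaled to [1, 5] over the cohort.
Grid refinement to 10⁵ points moves δ by < 0.01.

δ is therefore comparable only within a cohort; `TrajectoryModel`
serializes the fitted curve, orientation and rescale bounds so new
arteries can be scored against a frozen trajectory. The published cohort's
quartic f(x) = 0.0005x⁴ − 0.01227x³ + 0.1363x² − 0.4354x − 0.7425 is
exposed as `reference_trajectory()` for worked examples and audits.

A one-dimensional variant (`evt_compartment_lda`) characterizes EVT
similarity across spatial compartments: standardized CD56/CD57/HLA-G/CK7/
PD-L1/Ki67 expression, trained on cell-column/interstitial/intravascular
EVTs with perivascular cells withheld and scored afterwards; on planted
monotone gradients the perivascular median falls between the interstitial
and intravascular medians.

## Spatial statistics

Close interactions are ordered cell pairs strictly closer than 100 px
(~39 µm at the study's nominal scale), among decidua-compartment cells
only. Enrichment of A around B in an image: 100 bootstrap iterations
reassign the A label to |A| cells drawn without replacement from all
decidua cells (B fixed); Z-scores the observed count within the pool of
bootstraps plus the observed value (population SD; missing when the pool
is degenerate). The randomization is a label permutation over cells, so a
resampled A that coincides with a B cell contributes no distance-zero self
pair — counting such self pairs would bias the null by roughly −1.3 Z
under complete spatial randomness. Cell–artery enrichment thresholds the
distance-transform distance to the nearest artery at the same 100 px and
uses the same null. Enrichment is asymmetric; both directions are
reported. Cohort-level enriched pairs use |mean Z| ≥ 2.

Microenvironments: per decidua cell, the lineage composition of its 25
nearest decidua neighbours (per image); k-means with k = 20 (seeded);
complete-linkage merge of centroids cut at Euclidean distance 0.5.
Raising the merge threshold can only reduce the environment count.

Per-artery EVT bookkeeping counts intravascular (inside the artery label)
and perivascular (flagged band cells attributed to their nearest artery)
EVTs; presence defaults to count ≥ 5 (the stricter "> 5" reading is
available via `inclusive=False`), and the intravascular/perivascular ratio
is defined only when both counts are positive.

## Trend classification and GA prediction

Per-image features (lineage frequencies among decidua cells excluding
"other"/muscle/glandular; positivity fractions excluding the cell column,
glandular restricted to glands; pairwise enrichments) are regressed
linearly on GA and on the image's mean δ. Classification: the axis with
the larger R² wins, reported with log₂(R²_δ/R²_GA) and the better model's
p; features whose best model has R² < 0.05 or p > 0.05 are unclassified.
Gene-level rule: SAR-driven iff log₂ ratio ≥ 1 and R²_δ ≥ 0.05, GA-driven
iff log₂ ratio ≤ −1 and R²_GA ≥ 0.05, else synchronized. Trend size uses
the fitted values at the axis extremes (normalized by the mean for
frequency-like features); a raw-endpoint mode matches the frequency
formula written on the data. Volcano outputs report raw p values;
Benjamini–Hochberg columns are emitted for reference but do not drive
classification.

GA ridge regression: features min-max scaled to [0, 1]; images with fewer
than 10 immune cells dropped; a 70/30 split stratified over GA quantile
bins (the split report verifies balance); the penalty chosen by
leave-one-out cross-validation on the training set; test R², RMSE and
coefficient loadings reported.

## Transcriptomics

Normalization is applied jointly per ROI group: optional background
subtraction (geometric mean of the 100 negative probes, clipped at zero) —
used for artery/decidua ROIs where ROI size tracks remodelling stage, and
skipped for EVT ROIs — then division by the per-ROI 75th percentile and
multiplication by the geometric mean of all 75th percentiles. ROIs with a
zero Q75 are flagged unusable. The expressed-gene gate keeps genes with
normalized counts ≥ 10 in ≥ 2 artery ROIs.

Per gene, quadratic regressions (overall F-test p) run against GA and
against δ (δ of an ROI = mean δ of its linked arteries); fold change is
the raw max/min with the minimum floored at half the smallest positive
value; the COM is the expression-weighted mean of the temporal coordinate.
Trending requires p ≤ 0.05 on an axis and FC ≥ 2; the genes of interest
for coordination are those trending on the δ axis.

Pathway coordination: for pathways intersecting the interest set in ≥ 10
genes, CD_group is the median absolute deviation of member COMs from their
median; the null redraws N genes from the interest set 10⁵ times; CD_rand
is the median null CD; score = log₂(CD_rand/CD_group) (capped at 10 when
CD_group = 0); p counts null CDs below CD_group with a 1/R pseudocount; BH
q values run over all tested pathways; coordinated means score ≥ 1.5 and
p ≤ 0.05. The score is invariant to affine transforms of the time axis.

Differential expression between interstitial and intravascular EVT ROIs
uses a hand-written moderated t on log₂(norm + 1): per-gene residual
variances are shrunk toward a prior fitted by moment-matching the
log-variance distribution (trigamma inversion by Newton iteration), the
moderated t uses the augmented degrees of freedom, and DEGs satisfy BH
p ≤ 0.1 and |logFC| ≥ 2. Setting the prior df to 0 recovers the ordinary
t-test exactly; the implementation is cross-checked in the test suite
against the Bioconductor reference on a small matrix.

## Synthetic data

The generator defines the study conditions the tests run under. Per
subject (66 by default), a GA is drawn uniformly over 42–140 days; per
image, arteries receive a latent remodelling coordinate that blends the
GA rank with a cohort stage prior (186/300/43/34/25 across stages 1–5) at
correlation 0.5 — stages visibly spread within GA, as in the motivating
cohort. Artery outlines are ellipses with sinusoidal boundary perturbation
(outline irregularity is visible in the source material but unquantified;
the amplitude is a parameter); stage geometry progresses from small
vessels with ≈95 % smooth-muscle/endothelial angular coverage to large,
SMA-depleted, EVT-lined ones. Wall-marker rasters place lognormal signal
in the planted arcs over a low lognormal background.

Cells are placed uniformly on decidua pixels, except lineage pairs planted
for enrichment tests, which share Gaussian cluster parents (SD 40 px).
Composition follows per-lineage linear trends in GA or stage (defaults: a
lymphoid-to-myeloid shift along GA, EVT and NK2 accumulation along
remodelling); marker values are bimodal lognormal per-pixel densities
times area (Ki67: density alone), so positivity fractions survive the
monotone normalization chain exactly.

ROI counts are a quadratic bump along the gene's axis — peak amplitude =
fold change 4 × baseline, half-width equal to half the axis range so the
planted fold change is realized inside the sampled range wherever the
peak sits — times lognormal noise (σ = 0.15; the planted-effect condition
is a strong trend with low noise) plus lognormal background; the 100
negative probes are drawn from the background law alone. Planted pathways
concentrate member peaks near a target COM; planted DE genes receive log₂
shifts in intravascular ROIs. Identical seeds give identical outputs.

What the generator does **not** emulate: segmentation errors, marker
spillover, image-boundary truncation of arteries, batch effects across
tissue arrays, negative-binomial overdispersion (available via
`count_noise="nb"` but not the default), and anatomically realistic
vessel branching. Passing tests therefore demonstrate correctness of the
statistical machinery under the stated generative assumptions, not
robustness to those real-data artefacts.

## Problem sizes and numerics

The test suite and the acceptance script run the full pipeline on
desk-scale cohorts (tens of subjects, 300–500 cells per image, hundreds of
genes, 10⁴–10⁵ randomizations), chosen so the whole suite completes in a
few minutes on one CPU while every calibration retains power; the
acceptance script uses 40 subjects × 2 images and 600 genes. Tolerances:
round-trips and regression oracles at 1e-9; raster-derived features at 2 %
under rotation; Monte-Carlo calibrations at the conventional levels
(type-I ≤ 10 % for enrichment, ≤ 7 % for coordination at nominal 5 %).
Degenerate inputs (masks smaller than the sector count, all-equal loss
features, constant axes, zero dispersal) return missing values, zeros or
capped scores as documented per function rather than raising mid-pipeline.
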
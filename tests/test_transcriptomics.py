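import numpy as np
import pandas as pd
import pytest

from spirart.model import PathwaySet, RoiExpression
from spirart.transcriptomics import (
    centre_of_mass,
    coordination_test,
    expressed_filter,
    expression_matrix,
    fold_change,
    gene_trends,
    moderated_de,
    normalize_counts,
    quadratic_fit,
)


def _roi(roi_id, counts, neg=None, ga=80.0, delta=2.0, roi_type="artery"):
    return RoiExpression(
        roi_id=roi_id,
        roi_type=roi_type,
        raw_counts=counts,
        neg_probe_counts=np.full(100, 4.0) if neg is None else neg,
        ga_days=ga,
        delta=delta,
    )


class TestNormalization:
    def test_identical_rois_identical_output(self):
        counts = {"A": 100.0, "B": 40.0, "C": 10.0, "D": 5.0}
        rois = [_roi("r1", dict(counts)), _roi("r2", dict(counts))]
        normalize_counts(rois, background_subtract=False)
        assert rois[0].norm_counts == pytest.approx(rois[1].norm_counts)

    def test_scaling_a_roi_cancels(self):
        counts = {"A": 100.0, "B": 40.0, "C": 10.0, "D": 5.0}
        doubled = {g: 2 * v for g, v in counts.items()}
        rois = [_roi("r1", counts), _roi("r2", doubled)]
        normalize_counts(rois, background_subtract=False)
        assert rois[0].norm_counts == pytest.approx(rois[1].norm_counts)

    def test_matches_hand_computed_oracle(self):
        """Background subtraction + Q75 scaling against a spreadsheet-style
        recomputation to 1e-9."""
        c1 = {"A": 20.0, "B": 12.0, "C": 8.0, "D": 4.0}
        c2 = {"A": 40.0, "B": 20.0, "C": 10.0, "D": 6.0}
        neg1 = np.full(100, 2.0)
        neg2 = np.full(100, 4.0)
        rois = [_roi("r1", c1, neg1), _roi("r2", c2, neg2)]
        normalize_counts(rois, background_subtract=True)
        # oracle
        s1 = np.maximum(np.array([20, 12, 8, 4.0]) - 2.0, 0)
        s2 = np.maximum(np.array([40, 20, 10, 6.0]) - 4.0, 0)
        q1, q2 = np.percentile(s1, 75), np.percentile(s2, 75)
        scale = np.sqrt(q1 * q2)
        np.testing.assert_allclose(
            [rois[0].norm_counts[g] for g in "ABCD"], s1 / q1 * scale, atol=1e-9
        )
        np.testing.assert_allclose(
            [rois[1].norm_counts[g] for g in "ABCD"], s2 / q2 * scale, atol=1e-9
        )

    def test_idempotent_up_to_global_scale(self):
        rng = np.random.default_rng(0)
        rois = [
            _roi(f"r{i}", {f"G{j}": float(rng.integers(1, 500)) for j in range(50)})
            for i in range(4)
        ]
        normalize_counts(rois, background_subtract=False)
        first = {r.roi_id: dict(r.norm_counts) for r in rois}
        rois2 = [
            _roi(r.roi_id, dict(first[r.roi_id])) for r in rois
        ]
        normalize_counts(rois2, background_subtract=False)
        for r in rois2:
            ratios = [
                r.norm_counts[g] / first[r.roi_id][g]
                for g in r.norm_counts
                if first[r.roi_id][g] > 0
            ]
            np.testing.assert_allclose(ratios, ratios[0], rtol=1e-9)

    def test_zero_q75_flagged_unusable(self):
        rois = [
            _roi("r1", {"A": 0.0, "B": 0.0}),
            _roi("r2", {"A": 10.0, "B": 20.0}),
        ]
        normalize_counts(rois, background_subtract=False)
        assert rois[0].norm_counts is None
        assert rois[1].norm_counts is not None


class TestExpressedFilter:
    def test_gates(self):
        rois = [
            _roi("r1", {"A": 12.0, "B": 12.0, "C": 1.0}),
            _roi("r2", {"A": 11.0, "B": 1.0, "C": 1.0}),
            _roi("r3", {"A": 1.0, "B": 1.0, "C": 1.0}),
        ]
        for r in rois:  # skip normalization scaling: inject directly
            r.norm_counts = dict(r.raw_counts)
        kept = expressed_filter(rois, min_count=10, min_rois=2)
        assert kept == ["A"]  # B reaches 10 in only one ROI


class TestGeneTrends:
    def test_com_weighting(self):
        t = np.array([1.0, 2, 3, 4, 5])
        assert centre_of_mass(t, t) > 3.0  # monotone weights pull late
        sym = np.array([1.0, 2, 3, 2, 1])
        assert centre_of_mass(t, sym) == pytest.approx(3.0)

    def test_fold_change_floor(self):
        assert fold_change(np.array([0.0, 1.0, 8.0])) == pytest.approx(16.0)
        assert fold_change(np.array([2.0, 4.0])) == pytest.approx(2.0)

    def test_quadratic_recovery_within_two_se(self):
        """Planted quadratic + noise: fitted coefficients sit within 2
        standard errors of truth in the vast majority of replicates."""
        rng = np.random.default_rng(1)
        true = np.array([0.5, -2.0, 3.0])  # a t^2 + b t + c
        hits = 0
        reps = 60
        for _ in range(reps):
            t = rng.uniform(0, 5, 30)
            e = np.polyval(true, t) + rng.normal(0, 0.5, 30)
            beta, r2, p = quadratic_fit(t, e)
            X = np.column_stack([t**2, t, np.ones(30)])
            resid = e - X @ beta
            s2 = (resid**2).sum() / (30 - 3)
            cov = s2 * np.linalg.inv(X.T @ X)
            se = np.sqrt(np.diag(cov))
            hits += bool(np.all(np.abs(beta - true) <= 2 * se))
        assert hits / reps >= 0.8

    def test_classifies_and_gates(self, small_dataset):
        ds = small_dataset
        art = [r for r in ds.rois if r.roi_type == "artery"]
        normalize_counts(art, background_subtract=True)
        tr = gene_trends(art, expressed_filter(art))
        assert set(tr.loc[tr.trending, "class"]) <= {
            "SAR-driven", "GA-driven", "synchronized"
        }
        td = set(ds.truth["trending_delta_genes"]) & set(tr.index)
        assert tr.loc[sorted(td), "trending_delta"].mean() >= 0.8


class TestCoordination:
    def _interest(self, n=200, seed=0):
        rng = np.random.default_rng(seed)
        return pd.Series(
            rng.uniform(1, 5, n), index=[f"G{i:04d}" for i in range(n)]
        )

    def test_null_type_one_error_controlled(self):
        """Pathways drawn at random from the interest set are flagged at
        no more than 7% at nominal p <= 0.05 (reduced randomization
        count)."""
        rng = np.random.default_rng(2)
        coms = self._interest()
        pathways = [
            PathwaySet(
                name=f"NULL{i}",
                genes=frozenset(rng.choice(coms.index, size=15, replace=False)),
            )
            for i in range(200)
        ]
        out = coordination_test(coms, pathways, n_rand=10_000, rng=rng)
        assert (out["p"] <= 0.05).mean() <= 0.07

    def test_degenerate_zero_dispersal_capped(self):
        coms = self._interest()
        coms.iloc[:12] = 2.5  # identical COMs
        pw = PathwaySet(name="TIGHT", genes=frozenset(coms.index[:12]))
        out = coordination_test(coms, [pw], n_rand=1000, rng=np.random.default_rng(3))
        assert out.loc["TIGHT", "score"] == 10.0
        assert out.loc["TIGHT", "p"] == pytest.approx(1 / 1000)

    def test_planted_tight_pathway_flagged(self):
        rng = np.random.default_rng(4)
        flags = 0
        for rep in range(10):
            coms = self._interest(seed=rep + 10)
            members = coms.index[:10]
            coms.loc[members] = 3.0 + rng.normal(0, 0.1, 10)  # 2.5% of range
            pw = PathwaySet(name="P", genes=frozenset(members))
            out = coordination_test(coms, [pw], n_rand=5000, rng=rng)
            flags += bool(out.loc["P", "coordinated"])
        assert flags >= 9

    def test_small_intersection_skipped(self):
        coms = self._interest()
        pw = PathwaySet(name="TINY", genes=frozenset(coms.index[:5]))
        out = coordination_test(coms, [pw], n_rand=100, rng=np.random.default_rng(0))
        assert out.empty

    def test_score_invariant_to_affine_time_axis(self):
        rng = np.random.default_rng(5)
        coms = self._interest(seed=6)
        pw = PathwaySet(name="P", genes=frozenset(coms.index[:15]))
        out1 = coordination_test(coms, [pw], n_rand=3000, rng=np.random.default_rng(9))
        out2 = coordination_test(
            coms * 7.0 + 3.0, [pw], n_rand=3000, rng=np.random.default_rng(9)
        )
        assert out1.loc["P", "score"] == pytest.approx(out2.loc["P", "score"], abs=1e-9)


def _de_matrix(n_genes=200, shift_genes=20, shift=3.0, n=4, seed=0):
    rng = np.random.default_rng(seed)
    base = rng.uniform(3, 9, n_genes)
    a = base[:, None] + rng.normal(0, 0.3, (n_genes, n))
    b = base[:, None] + rng.normal(0, 0.3, (n_genes, n))
    b[:shift_genes] += shift
    expr = pd.DataFrame(
        np.exp2(np.hstack([a, b])) - 1,
        index=[f"G{i:04d}" for i in range(n_genes)],
        columns=[f"int{i}" for i in range(n)] + [f"intra{i}" for i in range(n)],
    ).clip(lower=0)
    groups = pd.Series(
        ["interstitial_evt"] * n + ["intravascular_evt"] * n, index=expr.columns
    )
    return expr, groups


class TestModeratedDe:
    def test_identical_groups_no_degs(self):
        expr, groups = _de_matrix(shift_genes=0)
        out = moderated_de(expr, groups)
        assert int(out["significant"].sum()) == 0

    def test_planted_shift_detected(self):
        detected_total, fp_total = 0, 0
        for seed in range(3):
            expr, groups = _de_matrix(seed=seed)
            out = moderated_de(expr, groups)
            detected_total += int(out["significant"].iloc[:20].sum())
            fp_total += int(out["significant"].iloc[20:].sum())
        assert detected_total >= 3 * 18
        assert fp_total <= 3 * 2

    def test_zero_prior_df_equals_ordinary_t(self):
        from scipy import stats

        expr, groups = _de_matrix(seed=1)
        out = moderated_de(expr, groups, prior_df=0)
        la = np.log2(expr[groups.index[groups == "interstitial_evt"]] + 1)
        lb = np.log2(expr[groups.index[groups == "intravascular_evt"]] + 1)
        t, p = stats.ttest_ind(lb, la, axis=1)
        np.testing.assert_allclose(out["t"], t, atol=1e-9)
        np.testing.assert_allclose(out["p"], p, atol=1e-9)

    def test_bh_matches_step_up_oracle(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(0, 1, 100)
        from statsmodels.stats.multitest import multipletests

        q = multipletests(p, method="fdr_bh")[1]
        # independent step-up oracle
        order = np.argsort(p)
        n = len(p)
        adj = p[order] * n / (np.arange(n) + 1)
        adj = np.minimum.accumulate(adj[::-1])[::-1]
        oracle = np.empty(n)
        oracle[order] = np.minimum(adj, 1)
        np.testing.assert_allclose(q, oracle, atol=1e-12)
        # monotone in raw p
        assert (np.diff(q[np.argsort(p)]) >= -1e-12).all()

    def test_agrees_with_limma_reference(self, tmp_path):
        """Moderated statistics track the reference empirical-Bayes
        implementation on a small matrix (logFC exact; moderated t close
        after variance-prior fitting)."""
        import subprocess

        expr, groups = _de_matrix(n_genes=60, shift_genes=6, seed=3)
        log_expr = np.log2(expr + 1)
        mat = tmp_path / "m.csv"
        log_expr.to_csv(mat)
        script = tmp_path / "limma.R"
        script.write_text(
            """
            suppressMessages(library(limma))
            args <- commandArgs(trailingOnly=TRUE)
            m <- as.matrix(read.csv(args[1], row.names=1))
            design <- cbind(1, c(rep(0,4), rep(1,4)))
            fit <- eBayes(lmFit(m, design))
            out <- data.frame(logFC=fit$coefficients[,2], t=fit$t[,2], p=fit$p.value[,2])
            write.csv(out, args[2])
            """
        )
        out_csv = tmp_path / "out.csv"
        subprocess.run(
            ["Rscript", str(script), str(mat), str(out_csv)],
            check=True, capture_output=True,
        )
        ref = pd.read_csv(out_csv, index_col=0)
        ours = moderated_de(expr, groups)
        np.testing.assert_allclose(ours["logFC"], ref["logFC"], atol=1e-6)
        np.testing.assert_allclose(ours["t"], ref["t"], rtol=0.05, atol=0.1)
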
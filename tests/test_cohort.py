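"""ROI aggregation, age models, correlation grids and factor analysis."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dmriage.atlas import jhu_labels, jhu_pairing, merged_roi_names
from dmriage.cohort import (
    FactorModel,
    factor_scores,
    fit_age_polynomial,
    match_factors,
    merge_homologous,
    pca_metrics,
    remove_outlier_participants,
    roi_average,
    run_full_analysis,
    select_components,
    subgroup_correlations,
    to_long,
    to_wide,
    tucker_congruence,
    varimax,
    zscore_table,
)
from dmriage.synthetic import CohortSpec, generate_cohort


class TestRoiAverage:
    def _make(self, fiso):
        n = len(fiso)
        maps = pd.DataFrame({"FA": np.linspace(0.2, 0.8, n)})
        labels = np.array(["roiA"] * n)
        return maps, labels, np.asarray(fiso)

    def test_no_filtering_is_plain_mean(self):
        maps, labels, fiso = self._make([0.0] * 5)
        means, diag = roi_average(maps, labels, fiso)
        assert means.loc["roiA", "FA"] == pytest.approx(maps["FA"].mean())
        assert diag.loc["roiA", "excluded_fraction"] == 0.0

    def test_cutoff_is_strict(self):
        """Fiso=0.91 is excluded, exactly 0.90 is kept."""
        maps, labels, fiso = self._make([0.0, 0.91, 0.90])
        means, diag = roi_average(maps, labels, fiso, cutoff=0.9)
        kept = maps.loc[[0, 2], "FA"].mean()
        assert means.loc["roiA", "FA"] == pytest.approx(kept)
        assert diag.loc["roiA", "excluded_fraction"] == pytest.approx(1 / 3)

    def test_fully_excluded_roi_flagged_missing(self):
        maps, labels, fiso = self._make([0.95, 0.99])
        means, diag = roi_average(maps, labels, fiso)
        assert np.isnan(means.loc["roiA", "FA"])
        assert bool(diag.loc["roiA", "empty"])


class TestMergeHomologous:
    def _table(self, labels, values):
        return pd.DataFrame({"participant_id": 1, "roi": labels,
                             "metric": "FA", "value": values})

    def test_jhu_48_to_27(self):
        labels = jhu_labels()
        table = self._table(labels, np.arange(len(labels), dtype=float))
        merged = merge_homologous(table, jhu_pairing())
        assert merged["roi"].nunique() == 27
        assert set(merged["roi"]) == set(merged_roi_names())

    def test_pair_is_unweighted_mean(self):
        pairing = pd.DataFrame({"label": ["X L", "X R"],
                                "merged_name": ["X", "X"],
                                "hemisphere": ["L", "R"]})
        merged = merge_homologous(self._table(["X L", "X R"], [0.4, 0.6]), pairing)
        assert merged["value"].iloc[0] == pytest.approx(0.5)

    def test_unpaired_labels_pass_through(self):
        pairing = pd.DataFrame({"label": ["A", "B"], "merged_name": ["A", "B"],
                                "hemisphere": ["M", "M"]})
        merged = merge_homologous(self._table(["A", "B"], [1.0, 2.0]), pairing)
        assert merged["roi"].nunique() == 2

    def test_missing_label_is_named_in_error(self):
        pairing = jhu_pairing()
        with pytest.raises(KeyError, match="Mystery tract"):
            merge_homologous(self._table(["Mystery tract"], [1.0]), pairing)


class TestZscore:
    def _long(self, values):
        return pd.DataFrame({"participant_id": np.arange(len(values)),
                             "roi": "r", "metric": "m", "value": values})

    def test_mean_zero_unit_sd(self, rng):
        z, flags = zscore_table(self._long(rng.normal(2.0, 3.0, 50)))
        assert z["value"].mean() == pytest.approx(0.0, abs=1e-12)
        assert z["value"].std(ddof=1) == pytest.approx(1.0, rel=1e-12)
        assert flags == []

    def test_constant_column_flagged_zero(self):
        z, flags = zscore_table(self._long(np.full(10, 3.3)))
        assert (z["value"] == 0).all()
        assert flags == [("r", "m")]

    def test_idempotent(self, rng):
        z1, _ = zscore_table(self._long(rng.normal(size=40)))
        z2, _ = zscore_table(z1)
        np.testing.assert_allclose(z1["value"], z2["value"], atol=1e-12)


class TestOutlierRemoval:
    def test_clean_gaussian_removes_nobody(self, rng):
        """P(|z| > 5) ≈ 5.7e-7 per cell: a clean n=636 cohort loses nobody."""
        long = pd.DataFrame({
            "participant_id": np.repeat(np.arange(636), 6),
            "roi": "r", "metric": np.tile(list("abcdef"), 636),
            "value": rng.normal(size=636 * 6)})
        z, _ = zscore_table(long)
        _, removed, _ = remove_outlier_participants(z, mode="value", k=5.0)
        assert removed == []

    def test_injected_outlier_removed_in_residual_mode(self, rng):
        n = 200
        age = rng.uniform(18, 88, n)
        table = pd.DataFrame({
            "participant_id": np.arange(n), "age": age,
            "sex": rng.choice(["M", "F"], n),
            "FA": 0.45 - 0.001 * age + rng.normal(0, 0.01, n)})
        table.loc[17, "FA"] += 0.12  # ~12 residual SDs
        reduced, removed, refits = remove_outlier_participants(
            table, mode="residual", k=5.0, metrics=["FA"])
        assert removed == [17]
        assert refits["FA"].n_used == n - 1

    def test_infinite_k_keeps_everything(self, rng):
        long = pd.DataFrame({"participant_id": range(20), "roi": "r",
                             "metric": "m", "value": rng.normal(size=20)})
        out, removed, _ = remove_outlier_participants(long, mode="value",
                                                      k=np.inf)
        assert removed == [] and len(out) == 20

    def test_invalid_k(self):
        with pytest.raises(ValueError):
            remove_outlier_participants(pd.DataFrame(), mode="value", k=0.0)


class TestAgePolynomial:
    def test_exactly_linear(self, rng):
        age = rng.uniform(18, 88, 100)
        res = fit_age_polynomial(2.0 + 0.03 * age, age, include_sex=False)
        assert res.r2_linear == pytest.approx(1.0, abs=1e-10)
        assert res.dr2_quadratic == pytest.approx(0.0, abs=1e-10)

    def test_constant_outcome(self, rng):
        age = rng.uniform(18, 88, 50)
        res = fit_age_polynomial(np.full(50, 1.5), age, include_sex=False)
        assert res.r2_linear == 0.0 and res.dr2_quadratic == 0.0

    def test_affine_invariance(self, rng):
        """R² increments are unchanged by affine rescaling of age and y."""
        age = rng.uniform(18, 88, 300)
        y = 0.5 * age - 0.004 * age**2 + rng.normal(0, 2.0, 300)
        r1 = fit_age_polynomial(y, age, include_sex=False)
        r2 = fit_age_polynomial(3.0 * y - 7.0, 0.1 * age + 4.0,
                                include_sex=False)
        assert r1.r2_linear == pytest.approx(r2.r2_linear, abs=1e-10)
        assert r1.dr2_quadratic == pytest.approx(r2.dr2_quadratic, abs=1e-10)

    def test_planted_partition_recovered(self):
        """Generator + regression algebra: planted (0.41, 0.13) on MSD is
        recovered within ±0.05 on average over seeded replicates."""
        r2l, dr2q = [], []
        for seed in range(20):
            spec = CohortSpec(metrics=("MSD",), rois=("global",),
                              roi_age_scale_range=(1.0, 1.0))
            _, glob, _ = generate_cohort(spec, seed=seed)
            res = fit_age_polynomial(glob["MSD"].to_numpy(),
                                     glob["age"].to_numpy(),
                                     glob["sex"].to_numpy())
            r2l.append(res.r2_linear)
            dr2q.append(res.dr2_quadratic)
        assert np.mean(r2l) == pytest.approx(0.41, abs=0.05)
        assert np.mean(dr2q) == pytest.approx(0.13, abs=0.05)

    def test_too_few_observations(self):
        with pytest.raises(ValueError):
            fit_age_polynomial(np.ones(5), np.arange(5), include_sex=False)


def _cohort_long(n=300, seed=0, n_rois=27, n_metrics=6, planted=None):
    rng = np.random.default_rng(seed)
    age = rng.uniform(18, 88, n)
    rows = []
    metrics = [f"m{j}" for j in range(n_metrics)]
    for r in range(n_rois):
        for m in metrics:
            v = rng.normal(size=n)
            if planted and (r, m) in planted:
                v = planted[(r, m)] * (age - age.mean()) / age.std() \
                    + np.sqrt(1 - planted[(r, m)] ** 2) * v
            rows.append(pd.DataFrame({"participant_id": np.arange(n),
                                      "age": age, "roi": f"r{r}",
                                      "metric": m, "value": v}))
    return pd.concat(rows, ignore_index=True)


class TestSubgroupCorrelations:
    def test_grid_size_is_486(self):
        grid = subgroup_correlations(_cohort_long(n=400, seed=1))
        assert grid.n_tests == 3 * 6 * 27 == 486

    def test_inclusive_bounds(self):
        long = _cohort_long(n=200, seed=2, n_rois=1, n_metrics=1)
        long["age"] = np.linspace(28, 47, len(long))
        grid = subgroup_correlations(long, subgroups=((28, 47),))
        assert grid.table["n"].iloc[0] == long["participant_id"].nunique()

    def test_planted_effect_survives_fdr(self):
        """r=0.5 within one subgroup's cell at n≈200: essentially always
        detected after joint FDR (the Pearson test has power ≈ 1 there)."""
        long = _cohort_long(n=650, seed=3)
        in_grp = (long["age"] >= 28) & (long["age"] <= 47)
        cell = in_grp & (long["roi"] == "r0") & (long["metric"] == "m0")
        a = long.loc[cell, "age"]
        z = (a - a.mean()) / a.std()
        rng = np.random.default_rng(99)
        long.loc[cell, "value"] = 0.5 * z + np.sqrt(0.75) * rng.normal(size=z.size)
        grid = subgroup_correlations(long)
        hit = grid.table[(grid.table["roi"] == "r0")
                         & (grid.table["metric"] == "m0")
                         & (grid.table["subgroup"] == "28-47")]
        assert bool(hit["significant"].iloc[0])

    def test_p_values_match_scipy(self):
        from scipy.stats import pearsonr

        long = _cohort_long(n=120, seed=4, n_rois=2, n_metrics=2)
        grid = subgroup_correlations(long, subgroups=((18, 88),))
        pivot = long.pivot_table(index="participant_id",
                                 columns=["metric", "roi"], values="value")
        ages = long.drop_duplicates("participant_id").set_index(
            "participant_id")["age"].loc[pivot.index]
        for _, row in grid.table.iterrows():
            r, p = pearsonr(pivot[(row["metric"], row["roi"])], ages)
            assert row["r"] == pytest.approx(r, abs=1e-12)
            assert row["p"] == pytest.approx(p, rel=1e-9)

    def test_empty_subgroup_errors(self):
        long = _cohort_long(n=50, seed=5, n_rois=1, n_metrics=1)
        with pytest.raises(ValueError, match="subgroup"):
            subgroup_correlations(long, subgroups=((120, 130),))


class TestPCAAndRetention:
    def test_identity_correlation(self):
        res = pca_metrics(correlation=np.eye(6))
        np.testing.assert_allclose(res.eigenvalues, 1.0)
        np.testing.assert_allclose(res.variance_fractions, 1 / 6)

    def test_rank_one_data(self, rng):
        base = rng.normal(size=500)
        X = np.column_stack([base * c for c in (1.0, -2.0, 0.5)])
        res = pca_metrics(X)
        assert res.variance_fractions[0] == pytest.approx(1.0, abs=1e-10)

    def test_fractions_sum_to_one(self, rng):
        X = rng.normal(size=(200, 5)) @ rng.normal(size=(5, 5))
        res = pca_metrics(X)
        assert res.variance_fractions.sum() == pytest.approx(1.0, abs=1e-10)

    def test_missing_values_rejected(self):
        X = np.ones((10, 3))
        X[0, 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            pca_metrics(X)

    @pytest.mark.parametrize(
        "ev, rule, threshold, expected",
        [
            ([1.0] * 6, "kaiser", None, 0),        # strict inequality
            ([3, 2, 0.5, 0.3, 0.1, 0.1], "kaiser", None, 2),
            ([3, 1.8, 1.2, 0, 0, 0], "cumvar", 0.95, 3),
        ],
    )
    def test_select_components(self, ev, rule, threshold, expected):
        kwargs = {} if threshold is None else {"threshold": threshold}
        assert select_components(np.array(ev, float), rule=rule, **kwargs) == expected


def _pairwise_varimax_oracle(L, n_iter=2000, tol=1e-12):
    """Independent classical pairwise-rotation varimax (Kaiser's algorithm
    without row normalization)."""
    L = L.copy()
    p, k = L.shape
    R = np.eye(k)
    def criterion(M):
        return np.sum(np.var(M**2, axis=0))
    last = criterion(L)
    for _ in range(n_iter):
        for i in range(k):
            for j in range(i + 1, k):
                x, y = L[:, i], L[:, j]
                u = x**2 - y**2
                v = 2 * x * y
                num = 2 * (p * u @ v - u.sum() * v.sum())
                den = p * (u @ u - v @ v) - (u.sum()**2 - v.sum()**2)
                phi = 0.25 * np.arctan2(num, den)
                c, s = np.cos(phi), np.sin(phi)
                rot = np.eye(k)
                rot[[i, i, j, j], [i, j, i, j]] = [c, -s, s, c]
                L = L @ rot
                R = R @ rot
        now = criterion(L)
        if abs(now - last) < tol:
            break
        last = now
    return L, R


class TestVarimax:
    def test_communalities_preserved(self, rng):
        L = rng.normal(size=(8, 3))
        rotated, R = varimax(L)
        np.testing.assert_allclose(R @ R.T, np.eye(3), atol=1e-10)
        np.testing.assert_allclose((rotated**2).sum(axis=1),
                                   (L**2).sum(axis=1), atol=1e-10)

    def test_simple_structure_is_fixed_point(self):
        L = np.array([[0.9, 0, 0], [0.8, 0, 0], [0, 0.7, 0],
                      [0, 0.9, 0], [0, 0, 0.8], [0, 0, 0.6]])
        rotated, _ = varimax(L)
        cong = match_factors(rotated, L)
        np.testing.assert_allclose(cong, 1.0, atol=1e-8)

    def test_matches_independent_pairwise_oracle(self, rng):
        L = rng.normal(size=(10, 3)) @ np.diag([1.5, 1.0, 0.7])
        ours, _ = varimax(L)
        oracle, _ = _pairwise_varimax_oracle(L)
        cong = match_factors(ours, oracle)
        np.testing.assert_allclose(cong, 1.0, atol=1e-6)

    def test_sign_convention(self, rng):
        rotated, _ = varimax(rng.normal(size=(7, 3)))
        for j in range(3):
            assert rotated[np.argmax(np.abs(rotated[:, j])), j] > 0

    def test_single_factor_identity_up_to_sign(self):
        L = np.array([[0.5], [-0.9], [0.2]])
        rotated, R = varimax(L)
        np.testing.assert_allclose(np.abs(R), np.eye(1))
        np.testing.assert_allclose(rotated, L @ R)
        assert rotated[1, 0] > 0  # sign convention applied


class TestFactorScores:
    def test_zero_row_gives_zero_score(self, rng):
        L = rng.normal(size=(6, 3))
        X = np.zeros((4, 6))
        out = factor_scores(L, pd.DataFrame(X))
        np.testing.assert_allclose(out["scores"], 0.0)

    def test_roi_permutation_invariance(self, rng):
        L = rng.normal(size=(6, 2))
        X = rng.normal(size=(30, 6))
        pids = np.repeat(np.arange(10), 3)
        a = factor_scores(L, pd.DataFrame(X), participant_ids=pids)
        perm = rng.permutation(30)
        b = factor_scores(L, pd.DataFrame(X[perm]), participant_ids=pids[perm])
        np.testing.assert_allclose(a["participant_scores"].to_numpy(),
                                   b["participant_scores"].to_numpy(),
                                   atol=1e-12)

    def test_dimension_mismatch(self, rng):
        with pytest.raises(ValueError, match="columns"):
            factor_scores(rng.normal(size=(6, 2)),
                          pd.DataFrame(rng.normal(size=(5, 4))))

    def test_planted_scores_recovered(self):
        """Regression scores of the fitted model correlate r > 0.9 with the
        generator's true factor scores."""
        spec = CohortSpec()
        roi, glob, gt = generate_cohort(spec, seed=31)
        long = to_long(roi, list(spec.metrics))
        z, _ = zscore_table(long)
        pivot = z.pivot_table(index=["participant_id", "roi"],
                              columns="metric", values="value")[list(spec.metrics)]
        model = FactorModel.from_matrix(pivot)
        pids = pivot.index.get_level_values("participant_id").to_numpy()
        out = factor_scores(model, pivot, participant_ids=pids)
        est = out["participant_scores"].to_numpy()
        true = gt["factor_scores"][:, :3]
        # match each true factor to its best estimated counterpart
        corr = np.abs(np.corrcoef(est.T, true.T)[:3, 3:])
        assert corr.max(axis=0).min() > 0.9


class TestRunFullAnalysis:
    def test_smoke_and_reproducibility(self, tmp_path):
        spec = CohortSpec(n_participants=120)
        roi, glob, _ = generate_cohort(spec, seed=9)
        out1 = run_full_analysis(roi, glob, out_dir=tmp_path / "a", seed=9)
        run_full_analysis(roi, glob, out_dir=tmp_path / "b", seed=9)
        assert out1["correlation_grid"].n_tests == 486
        assert out1["factor_analyses"]["6"]["model"].n_retained >= 1
        for name in ("correlation_grid.csv", "factor_loadings_6.csv",
                     "manifest.yaml"):
            assert (tmp_path / "a" / name).read_bytes() \
                == (tmp_path / "b" / name).read_bytes()

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            run_full_analysis(pd.DataFrame({"participant_id": [1]}),
                              pd.DataFrame({"participant_id": [1], "age": [50],
                                            "sex": ["M"]}))

    def test_long_wide_round_trip(self):
        spec = CohortSpec(n_participants=25)
        roi, _, _ = generate_cohort(spec, seed=13)
        long = to_long(roi, list(spec.metrics))
        wide = to_wide(long)
        assert wide.shape[0] == 25
        col = f"{spec.rois[0]}_{spec.metrics[0]}"
        np.testing.assert_allclose(np.sort(wide[col]), np.sort(roi[col]))
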
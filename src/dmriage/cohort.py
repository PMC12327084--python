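"""Cohort statistics: ROI aggregation, age models, correlation grids, factors.

The pipeline mirrors a regional white-matter ageing analysis:

1. voxel → ROI means with free-water filtering (Fiso > 0.9 voxels removed);
2. merging of hemisphere-homologous ROIs (48 atlas labels → 27 regions);
3. global quadratic age models with sex covariates and 5-SD residual outlier
   removal (single pass, then one refit);
4. per-ROI z-scoring, 5-SD value outlier removal, per-ROI age-R² ranking;
5. Pearson age correlations in three age subgroups with Benjamini-Hochberg
   FDR over the full metric × ROI × subgroup grid;
6. PCA of the participant×ROI-by-metric matrix, Kaiser retention, varimax
   rotation, regression factor scores and their age profiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "AgeModelResult",
    "CorrelationGrid",
    "PCAResult",
    "FactorModel",
    "roi_average",
    "merge_homologous",
    "to_long",
    "to_wide",
    "zscore_table",
    "remove_outlier_participants",
    "fit_age_polynomial",
    "subgroup_correlations",
    "pca_metrics",
    "select_components",
    "varimax",
    "factor_scores",
    "tucker_congruence",
    "match_factors",
    "run_full_analysis",
    "DEFAULT_SUBGROUPS",
]

DEFAULT_SUBGROUPS: tuple[tuple[float, float], ...] = ((28, 47), (48, 67), (68, 87))


# --------------------------------------------------------------------------
# ROI aggregation
# --------------------------------------------------------------------------

def roi_average(
    metric_maps: pd.DataFrame,
    roi_labels: np.ndarray,
    fiso_map: np.ndarray,
    cutoff: float = 0.9,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-ROI means of voxelwise metrics after free-water filtering.

    Voxels with Fiso strictly greater than ``cutoff`` are excluded before
    averaging (a voxel at exactly the cutoff is kept).  Returns the per-ROI
    mean table (NaN rows where every voxel was excluded) and a diagnostics
    table with the excluded-voxel fraction per ROI.
    """
    labels = np.asarray(roi_labels)
    fiso = np.asarray(fiso_map, dtype=float)
    if not (len(labels) == len(metric_maps) == len(fiso)):
        raise ValueError("metric_maps, roi_labels and fiso_map must align")
    keep = fiso <= cutoff
    rois = pd.unique(labels)
    rows, diags = [], []
    for roi in rois:
        in_roi = labels == roi
        surviving = in_roi & keep
        frac_excluded = 1.0 - surviving.sum() / in_roi.sum()
        diags.append({"roi": roi, "n_voxels": int(in_roi.sum()),
                      "excluded_fraction": frac_excluded,
                      "empty": not surviving.any()})
        if surviving.any():
            rows.append(metric_maps.loc[surviving].mean())
        else:
            rows.append(pd.Series(np.nan, index=metric_maps.columns))
    means = pd.DataFrame(rows, index=pd.Index(rois, name="roi"))
    return means, pd.DataFrame(diags).set_index("roi")


def merge_homologous(
    roi_table: pd.DataFrame, pairing: pd.DataFrame
) -> pd.DataFrame:
    """Average metric values across hemisphere-homologous ROI pairs.

    ``roi_table`` is long format with columns participant_id, roi, metric,
    value; ``pairing`` maps each label to a merged name (columns label,
    merged_name).  Merged value = unweighted mean of the pair members;
    midline labels map to themselves.  A label absent from the pairing table
    is an error naming it.
    """
    mapping = dict(zip(pairing["label"], pairing["merged_name"]))
    unknown = set(roi_table["roi"]) - set(mapping)
    if unknown:
        raise KeyError(f"ROI labels missing from pairing table: {sorted(unknown)}")
    out = roi_table.copy()
    out["roi"] = out["roi"].map(mapping)
    return (out.groupby(["participant_id", "roi", "metric"], sort=False,
                        as_index=False)["value"].mean())


def to_long(wide: pd.DataFrame, metrics: list[str]) -> pd.DataFrame:
    """Wide ROI table (columns ``{roi}_{metric}``) → long format."""
    id_cols = [c for c in ("participant_id", "age", "sex") if c in wide.columns]
    records = []
    for col in wide.columns:
        if col in id_cols:
            continue
        for m in metrics:
            if col.endswith("_" + m):
                roi = col[: -(len(m) + 1)]
                rec = wide[id_cols].copy()
                rec["roi"] = roi
                rec["metric"] = m
                rec["value"] = wide[col].to_numpy()
                records.append(rec)
                break
    return pd.concat(records, ignore_index=True)


def to_wide(long: pd.DataFrame) -> pd.DataFrame:
    """Long format → wide ROI table with ``{roi}_{metric}`` columns."""
    id_cols = [c for c in ("age", "sex") if c in long.columns]
    wide = long.pivot_table(index="participant_id", columns=["roi", "metric"],
                            values="value", sort=False)
    wide.columns = [f"{r}_{m}" for r, m in wide.columns]
    if id_cols:
        meta = long.drop_duplicates("participant_id").set_index("participant_id")[id_cols]
        wide = meta.join(wide)
    return wide.reset_index()


def zscore_table(long: pd.DataFrame) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Z-score values across participants within each (ROI, metric) column.

    Uses the sample standard deviation (n−1).  Zero-spread columns are left
    as zeros and reported in the returned flag list.
    """
    out = long.copy()
    flagged: list[tuple[str, str]] = []
    for (roi, metric), idx in out.groupby(["roi", "metric"]).groups.items():
        v = out.loc[idx, "value"]
        sd = v.std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            out.loc[idx, "value"] = 0.0
            flagged.append((roi, metric))
        else:
            out.loc[idx, "value"] = (v - v.mean()) / sd
    return out, flagged


# --------------------------------------------------------------------------
# age models and outlier removal
# --------------------------------------------------------------------------

@dataclass
class AgeModelResult:
    """Hierarchical variance partition of a quadratic age model."""

    r2_linear: float
    dr2_quadratic: float
    dr2_sex: float | None
    dr2_age_by_sex: float | None
    coefficients: np.ndarray
    n_used: int
    removed_ids: list = field(default_factory=list)

    @property
    def r2_full(self) -> float:
        total = self.r2_linear + self.dr2_quadratic
        for inc in (self.dr2_sex, self.dr2_age_by_sex):
            if inc is not None:
                total += inc
        return total


def _ols_r2(X: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss == 0:
        return 0.0, beta
    return 1.0 - float(np.sum(resid**2)) / tss, beta


def fit_age_polynomial(
    y: np.ndarray,
    age: np.ndarray,
    sex: np.ndarray | None = None,
    include_sex: bool = True,
) -> AgeModelResult:
    """Hierarchical R² partition of a second-order age polynomial.

    Age is centered and scaled before expansion (R² increments are invariant
    to this).  Increments: R²_linear from the age-only linear model;
    ΔR²_quadratic from adding age²; then, if sex is given, ΔR² for the sex
    main effect (coded ±0.5) and for the sex × age interactions.
    """
    y = np.asarray(y, dtype=float)
    age = np.asarray(age, dtype=float)
    if y.size < 10:
        raise ValueError("need at least 10 observations")
    if np.ptp(age) == 0:
        raise ValueError("age must not be constant")
    a = (age - age.mean()) / age.std()
    X1 = np.column_stack([np.ones_like(a), a])
    X2 = np.column_stack([X1, a**2])
    r2_1, _ = _ols_r2(X1, y)
    r2_2, beta2 = _ols_r2(X2, y)
    dr2_sex = dr2_int = None
    beta = beta2
    n_params = 3
    if include_sex and sex is not None:
        x = np.where(np.asarray(sex) == np.asarray(sex)[0], 0.5, -0.5)
        if np.unique(np.asarray(sex)).size == 2:
            X3 = np.column_stack([X2, x])
            X4 = np.column_stack([X3, x * a, x * a**2])
            if np.linalg.matrix_rank(X4) < X4.shape[1]:
                raise ValueError("collinear design (age/sex)")
            r2_3, _ = _ols_r2(X3, y)
            r2_4, beta = _ols_r2(X4, y)
            dr2_sex = max(r2_3 - r2_2, 0.0)
            dr2_int = max(r2_4 - r2_3, 0.0)
            n_params = 6
    return AgeModelResult(
        r2_linear=r2_1,
        dr2_quadratic=max(r2_2 - r2_1, 0.0),
        dr2_sex=dr2_sex,
        dr2_age_by_sex=dr2_int,
        coefficients=np.asarray(beta)[:n_params],
        n_used=int(y.size),
    )


def remove_outlier_participants(
    table: pd.DataFrame,
    mode: str = "residual",
    k: float = 5.0,
    metrics: list[str] | None = None,
) -> tuple[pd.DataFrame, list, dict]:
    """Single-pass participant-level outlier removal.

    mode="residual": ``table`` is a global table (one row per participant,
    metric columns); per metric, fit the quadratic age + sex model, remove
    participants whose standardized residual exceeds ``k`` in absolute value
    for any metric, then refit once.  Returns the reduced table, removed
    participant ids, and the refitted AgeModelResult per metric.

    mode="value": ``table`` is a long z-scored table; participants with any
    |z| > k in any (ROI, metric) cell are removed.  Exactly one pass.
    """
    if not k > 0:
        raise ValueError("k must be positive")
    if mode == "residual":
        if metrics is None:
            metrics = [c for c in table.columns
                       if c not in ("participant_id", "age", "sex")]
        bad: set = set()
        for m in metrics:
            res = fit_age_polynomial(table[m].to_numpy(), table["age"].to_numpy(),
                                     table["sex"].to_numpy())
            age_arr = table["age"].to_numpy()
            a = (age_arr - age_arr.mean()) / age_arr.std()  # matches the fit's scaling
            x = np.where(table["sex"] == table["sex"].iloc[0], 0.5, -0.5)
            X = np.column_stack([np.ones(len(table)), a, a**2, x, x * a, x * a**2])
            X = X[:, : res.coefficients.size]
            resid = table[m].to_numpy() - X @ res.coefficients
            z = (resid - resid.mean()) / resid.std(ddof=1)
            bad |= set(table.loc[np.abs(z) > k, "participant_id"])
        reduced = table[~table["participant_id"].isin(bad)].reset_index(drop=True)
        refits = {
            m: fit_age_polynomial(reduced[m].to_numpy(), reduced["age"].to_numpy(),
                                  reduced["sex"].to_numpy())
            for m in metrics
        }
        return reduced, sorted(bad), refits
    if mode == "value":
        bad = set(table.loc[table["value"].abs() > k, "participant_id"])
        reduced = table[~table["participant_id"].isin(bad)].reset_index(drop=True)
        return reduced, sorted(bad), {}
    raise ValueError(f"unknown mode {mode!r}")


# --------------------------------------------------------------------------
# subgroup correlations with FDR
# --------------------------------------------------------------------------

@dataclass
class CorrelationGrid:
    """Pearson age correlations per (subgroup, metric, ROI) with a joint
    Benjamini-Hochberg FDR mask."""

    table: pd.DataFrame          # subgroup, metric, roi, n, r, p, significant
    q: float
    n_tests: int

    @property
    def n_significant(self) -> int:
        return int(self.table["significant"].sum())


def _pearson_grid(values: np.ndarray, age: np.ndarray):
    """Vectorized Pearson r (columns of ``values`` vs age) with exact
    two-sided p-values from the t distribution."""
    n = age.size
    vc = values - values.mean(axis=0)
    ac = age - age.mean()
    denom = np.sqrt((vc**2).sum(axis=0) * (ac**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (vc.T @ ac) / denom
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.abs(r) >= 1.0, 0.0, p)
    return r, p


def subgroup_correlations(
    long: pd.DataFrame,
    subgroups: tuple[tuple[float, float], ...] = DEFAULT_SUBGROUPS,
    q: float = 0.05,
    method: str = "bh",
) -> CorrelationGrid:
    """Metric-age Pearson correlations per ROI within age subgroups.

    Subgroup bounds are inclusive on both ends.  FDR (Benjamini-Hochberg by
    default; ``method="by"`` for Benjamini-Yekutieli) is applied jointly
    across all subgroup × metric × ROI tests.
    """
    rows = []
    for lo, hi in subgroups:
        sub = long[(long["age"] >= lo) & (long["age"] <= hi)]
        if sub["participant_id"].nunique() < 3:
            raise ValueError(f"empty or too-small age subgroup [{lo}, {hi}]")
        pivot = sub.pivot_table(index="participant_id", columns=["metric", "roi"],
                                values="value", sort=False)
        ages = sub.drop_duplicates("participant_id").set_index("participant_id")["age"]
        ages = ages.loc[pivot.index].to_numpy()
        r, p = _pearson_grid(pivot.to_numpy(), ages)
        for (metric, roi), ri, pi in zip(pivot.columns, r, p):
            rows.append({"subgroup": f"{lo:g}-{hi:g}", "metric": metric,
                         "roi": roi, "n": len(ages), "r": ri, "p": pi})
    table = pd.DataFrame(rows)
    mt_method = {"bh": "fdr_bh", "by": "fdr_by"}[method]
    reject, *_ = multipletests(table["p"].to_numpy(), alpha=q, method=mt_method)
    table["significant"] = reject
    return CorrelationGrid(table=table, q=q, n_tests=len(table))


# --------------------------------------------------------------------------
# PCA, component retention, varimax, factor scores
# --------------------------------------------------------------------------

@dataclass
class PCAResult:
    eigenvalues: np.ndarray        # descending, correlation scale
    variance_fractions: np.ndarray
    loadings: np.ndarray           # eigenvector * sqrt(eigenvalue), all comps
    columns: list[str] | None = None


def pca_metrics(
    matrix: pd.DataFrame | np.ndarray | None = None,
    correlation: np.ndarray | None = None,
) -> PCAResult:
    """PCA of the column correlation matrix of an observations × metrics
    matrix (participant×ROI rows concatenated), or of a supplied correlation
    matrix.  Missing values are an error: filter rows first."""
    columns = None
    if correlation is None:
        if matrix is None:
            raise ValueError("provide a matrix or a correlation matrix")
        if isinstance(matrix, pd.DataFrame):
            columns = list(matrix.columns)
            matrix = matrix.to_numpy(dtype=float)
        if np.isnan(matrix).any():
            raise ValueError("matrix contains missing values; drop those rows first")
        if matrix.shape[0] < matrix.shape[1] + 1:
            raise ValueError("need more observations than metrics")
        correlation = np.corrcoef(matrix, rowvar=False)
    ev, evec = np.linalg.eigh(correlation)
    order = np.argsort(ev)[::-1]
    ev, evec = np.clip(ev[order], 0, None), evec[:, order]
    loadings = evec * np.sqrt(ev)[None, :]
    return PCAResult(
        eigenvalues=ev,
        variance_fractions=ev / correlation.shape[0],
        loadings=loadings,
        columns=columns,
    )


def select_components(
    eigenvalues: np.ndarray, rule: str = "kaiser", threshold: float = 0.95
) -> int:
    """Component retention count.

    ``kaiser``: number of correlation-scale eigenvalues strictly greater
    than 1.  ``cumvar``: smallest count whose cumulative variance fraction
    exceeds ``threshold``.
    """
    ev = np.asarray(eigenvalues, dtype=float)
    if np.any(np.diff(ev) > 1e-10):
        raise ValueError("eigenvalues must be sorted descending")
    if rule == "kaiser":
        return int((ev > 1.0).sum())
    if rule == "cumvar":
        frac = np.cumsum(ev) / ev.sum()
        return int(np.searchsorted(frac, threshold) + 1)
    raise ValueError(f"unknown rule {rule!r}")


def varimax(loadings: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Varimax rotation (no Kaiser row-normalization) with sign convention.

    Returns ``(rotated, rotation)`` with ``rotated = loadings @ rotation``,
    rotation orthogonal, and each factor's largest-|loading| entry positive.
    k = 1 returns the sign-fixed input with the identity rotation.
    """
    L = np.asarray(loadings, dtype=float)
    if L.ndim != 2:
        raise ValueError("loadings must be 2-D")
    k = L.shape[1]
    if k == 1:
        R = np.eye(1)
        rotated = L.copy()
    else:
        from statsmodels.multivariate.factor_rotation import rotate_factors

        # statsmodels GPA varimax operates on the raw loadings (no Kaiser
        # row-normalization), which is the convention pinned here; errstate
        # silences a harmless log10(0) in its iteration log
        with np.errstate(divide="ignore"):
            rotated, R = rotate_factors(L, "varimax", tol=1e-10, max_tries=500)
    for j in range(rotated.shape[1]):
        if rotated[np.argmax(np.abs(rotated[:, j])), j] < 0:
            rotated[:, j] = -rotated[:, j]
            R[:, j] = -R[:, j]
    return rotated, R


@dataclass
class FactorModel:
    """Retained, varimax-rotated principal-component factor solution."""

    eigenvalues: np.ndarray
    variance_fractions: np.ndarray
    n_retained: int
    retention_rule: str
    loadings: np.ndarray            # rotated, metrics × factors
    rotation: np.ndarray
    communalities: np.ndarray
    columns: list[str] | None = None

    @classmethod
    def from_matrix(
        cls, matrix: pd.DataFrame | np.ndarray, rule: str = "kaiser",
        threshold: float = 0.95, n_retained: int | None = None,
    ) -> "FactorModel":
        pca = pca_metrics(matrix)
        if n_retained is None:
            n_retained = select_components(pca.eigenvalues, rule=rule,
                                           threshold=threshold)
            n_retained = max(n_retained, 1)
        raw = pca.loadings[:, :n_retained]
        rotated, R = varimax(raw)
        return cls(
            eigenvalues=pca.eigenvalues,
            variance_fractions=pca.variance_fractions,
            n_retained=n_retained,
            retention_rule=rule,
            loadings=rotated,
            rotation=R,
            communalities=(rotated**2).sum(axis=1),
            columns=pca.columns,
        )


def factor_scores(
    model: FactorModel | np.ndarray,
    matrix: pd.DataFrame,
    participant_ids: np.ndarray | None = None,
    age: np.ndarray | None = None,
) -> dict:
    """Regression-method factor scores, per-participant averages, age profiles.

    ``matrix`` holds z-scored observations (participant×ROI rows) whose
    columns match the model loadings.  Scores are least squares on the
    rotated loadings: F = X L (LᵀL)⁻¹.  With ``participant_ids`` the per-row
    scores are averaged per participant; with ``age`` as well, each averaged
    factor score gets a quadratic age-profile fit.
    """
    L = model.loadings if isinstance(model, FactorModel) else np.asarray(model)
    X = matrix.to_numpy(dtype=float) if isinstance(matrix, pd.DataFrame) else np.asarray(matrix)
    if X.shape[1] != L.shape[0]:
        raise ValueError(f"matrix has {X.shape[1]} columns, loadings expect {L.shape[0]}")
    scores = X @ L @ np.linalg.inv(L.T @ L)
    out: dict = {"scores": scores}
    if participant_ids is not None:
        df = pd.DataFrame(scores, columns=[f"factor_{j+1}" for j in range(L.shape[1])])
        df["participant_id"] = np.asarray(participant_ids)
        per_part = df.groupby("participant_id", sort=True).mean()
        out["participant_scores"] = per_part
        if age is not None:
            ages = pd.Series(np.asarray(age), index=np.asarray(participant_ids))
            ages = ages.groupby(level=0).first().loc[per_part.index]
            out["age_profiles"] = {
                col: fit_age_polynomial(per_part[col].to_numpy(),
                                        ages.to_numpy(), include_sex=False)
                for col in per_part.columns
            }
    return out


def tucker_congruence(a: np.ndarray, b: np.ndarray) -> float:
    """Tucker congruence |aᵀb| / (‖a‖‖b‖) between two loading columns."""
    return float(np.abs(a @ b) / (np.linalg.norm(a) * np.linalg.norm(b)))


def match_factors(estimated: np.ndarray, truth: np.ndarray) -> np.ndarray:
    """Congruence of each true factor with its best-matching estimated factor
    under a one-to-one assignment (sign-invariant).  Returns one congruence
    per true column."""
    from scipy.optimize import linear_sum_assignment

    k = truth.shape[1]
    C = np.zeros((k, estimated.shape[1]))
    for i in range(k):
        for j in range(estimated.shape[1]):
            C[i, j] = tucker_congruence(truth[:, i], estimated[:, j])
    row, col = linear_sum_assignment(-C)
    out = np.zeros(k)
    out[row] = C[row, col]
    return out


# --------------------------------------------------------------------------
# full pipeline
# --------------------------------------------------------------------------

def run_full_analysis(
    roi_table: pd.DataFrame,
    global_table: pd.DataFrame,
    metrics: list[str] | None = None,
    metric_sets: dict[str, list[str]] | None = None,
    subgroups=DEFAULT_SUBGROUPS,
    q: float = 0.05,
    k_outlier: float = 5.0,
    out_dir: str | Path | None = None,
    seed: int | None = None,
    config: dict | None = None,
) -> dict:
    """Run the cohort statistics end to end on (already ROI-level) tables.

    Stages: global age models with residual-outlier removal and refit →
    z-scoring and value-outlier removal → per-ROI age-R² ranking → subgroup
    correlation grid with joint FDR → PCA/Kaiser/varimax factor models for
    the configured metric sets (sex is dropped after the global stage) →
    factor scores and their age profiles.  Returns a results dict; with
    ``out_dir`` every stage's table is also written as CSV plus a YAML run
    manifest.
    """
    if metrics is None:
        metrics = [c for c in global_table.columns
                   if c not in ("participant_id", "age", "sex")]
    if len(metrics) == 0 or roi_table.shape[1] <= 3:
        raise ValueError("analysis stage: no metrics/ROIs in input tables")
    if global_table["participant_id"].duplicated().any():
        raise ValueError("duplicated participant ids")
    if metric_sets is None:
        metric_sets = {"6": list(metrics)}
        if all(m in metrics for m in ("MD", "RD", "AD")):
            base6 = [m for m in metrics if m in ("FA", "MSD", "MSK", "NDI", "ODI", "Fiso")]
            metric_sets = {
                "6": base6,
                "9": base6 + ["MD", "RD", "AD"],
            }
            if all(m in metrics for m in ("MK", "RK", "AK")):
                metric_sets["12"] = base6 + ["MD", "RD", "AD", "MK", "RK", "AK"]

    results: dict = {"config": config or {}, "seed": seed}

    # --- global stage: residual outliers + refit ---
    reduced_global, removed_resid, global_models = remove_outlier_participants(
        global_table, mode="residual", k=k_outlier, metrics=metrics)
    results["global_models"] = global_models
    results["removed_residual_outliers"] = removed_resid

    # --- ROI stage: z-score, value outliers ---
    long = to_long(roi_table, metrics)
    long = long[~long["participant_id"].isin(removed_resid)]
    z, zero_flags = zscore_table(long)
    z, removed_value, _ = remove_outlier_participants(z, mode="value", k=k_outlier)
    if removed_value:  # re-standardize the surviving participants
        z, _ = zscore_table(z)
    results["removed_value_outliers"] = removed_value
    results["zero_spread_columns"] = zero_flags
    results["n_participants_final"] = int(z["participant_id"].nunique())

    # --- per-ROI age-R² ranking (age-only models after the global stage) ---
    ranking_rows = []
    ages_by_pid = z.drop_duplicates("participant_id").set_index("participant_id")["age"]
    for (roi, metric), grp in z.groupby(["roi", "metric"], sort=False):
        res = fit_age_polynomial(grp["value"].to_numpy(), grp["age"].to_numpy(),
                                 include_sex=False)
        ranking_rows.append({"roi": roi, "metric": metric,
                             "r2_age": res.r2_linear + res.dr2_quadratic})
    ranking = pd.DataFrame(ranking_rows)
    ranking["rank"] = ranking.groupby("metric")["r2_age"].rank(ascending=False)
    results["roi_r2_ranking"] = ranking

    # --- subgroup correlations + FDR ---
    results["correlation_grid"] = subgroup_correlations(z, subgroups=subgroups, q=q)

    # --- factor analyses per metric set ---
    factor_results: dict = {}
    for name, mset in metric_sets.items():
        zz = z[z["metric"].isin(mset)]
        pivot = zz.pivot_table(index=["participant_id", "roi"], columns="metric",
                               values="value", sort=False)[mset]
        n_dropped = int(pivot.isna().any(axis=1).sum())
        pivot = pivot.dropna()
        model = FactorModel.from_matrix(pivot)
        pids = pivot.index.get_level_values("participant_id").to_numpy()
        scores = factor_scores(model, pivot, participant_ids=pids,
                               age=ages_by_pid.loc[pids].to_numpy())
        factor_results[name] = {
            "model": model,
            "n_observations": int(pivot.shape[0]),
            "n_dropped_rows": n_dropped,
            "n_cumvar95": select_components(model.eigenvalues, rule="cumvar",
                                            threshold=0.95),
            "scores": scores,
        }
    results["factor_analyses"] = factor_results

    if out_dir is not None:
        _write_results(Path(out_dir), results, z)
    return results


def _write_results(out_dir: Path, results: dict, z: pd.DataFrame) -> None:
    import yaml

    out_dir.mkdir(parents=True, exist_ok=True)
    z.to_csv(out_dir / "zscored_long.csv", index=False)
    results["roi_r2_ranking"].to_csv(out_dir / "roi_r2_ranking.csv", index=False)
    results["correlation_grid"].table.to_csv(out_dir / "correlation_grid.csv",
                                             index=False)
    for name, fr in results["factor_analyses"].items():
        model: FactorModel = fr["model"]
        pd.DataFrame(model.loadings,
                     index=model.columns,
                     columns=[f"factor_{j+1}" for j in range(model.n_retained)]
                     ).to_csv(out_dir / f"factor_loadings_{name}.csv")
        fr["scores"]["participant_scores"].to_csv(
            out_dir / f"factor_scores_{name}.csv")
    global_rows = []
    for m, res in results["global_models"].items():
        global_rows.append({"metric": m, "r2_linear": res.r2_linear,
                            "dr2_quadratic": res.dr2_quadratic,
                            "dr2_sex": res.dr2_sex,
                            "dr2_age_by_sex": res.dr2_age_by_sex,
                            "n_used": res.n_used})
    pd.DataFrame(global_rows).to_csv(out_dir / "global_age_models.csv", index=False)
    manifest = {
        "seed": results.get("seed"),
        "config": results.get("config"),
        "removed_residual_outliers": [int(i) for i in results["removed_residual_outliers"]],
        "removed_value_outliers": [int(i) for i in results["removed_value_outliers"]],
        "n_participants_final": results["n_participants_final"],
        "n_correlation_tests": results["correlation_grid"].n_tests,
        "factor_sets": {name: {"n_retained": fr["model"].n_retained,
                               "n_cumvar95": fr["n_cumvar95"],
                               "n_observations": fr["n_observations"]}
                        for name, fr in results["factor_analyses"].items()},
    }
    with open(out_dir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
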
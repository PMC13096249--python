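"""Statistical spine of the profiling pipeline.

The analysis path from a single-cell feature table to condition-level
conclusions:

1. per-plate z-scoring of every feature, then concatenation of plates;
2. maximum-likelihood factor analysis, keeping the smallest number of
   factors whose common part explains a target share (default 80%) of the
   total feature variance;
3. regression-method factor scores per cell, averaged to one profile per
   well (wells with too few cells are dropped), then rescaled to zero mean
   and unit variance per factor across wells;
4. linear discriminant analysis fitted only on the albumin-free conditions
   and used to score every well, including albumin-supplemented arms;
5. Welch t-tests on discriminant scores between conditions, paired Wilcoxon
   signed-rank tests per factor across albumin arms with Benjamini-Hochberg
   FDR control, and a loading-based attribution of each factor to the
   cellular compartment that dominates it;
6. an analogous PCA train/score path with a permutation test on condition
   centroid shifts, used for titration experiments.

Estimation is delegated to scikit-learn (FactorAnalysis, LDA, PCA) and
scipy/statsmodels (tests, FDR); this module owns the selection rules,
aggregation conventions, sign conventions and pairing logic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA, FactorAnalysis
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from statsmodels.stats.multitest import multipletests

from .clinical_stats import TestResult
from .synthetic.tables import METADATA_COLUMNS

WELL_KEYS = ["plate_id", "well_id"]
WELL_META = ["plate_id", "well_id", "group", "albumin_arm", "sample_id"]


def feature_columns(table: pd.DataFrame) -> list[str]:
    """All columns of a feature table that are not well/cell metadata."""
    meta = set(METADATA_COLUMNS)
    return [c for c in table.columns if c not in meta]


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Normalisation


def zscore_per_plate(
    table: pd.DataFrame, feature_cols: list[str] | None = None
) -> tuple[pd.DataFrame, list[str]]:
    """Z-score each feature within each plate, then recombine plates.

    Features with zero variance on any plate cannot be standardised there
    and are dropped from the combined table; the dropped names are returned
    for logging. Raises if any plate has fewer than two cells.
    """
    feature_cols = feature_cols or feature_columns(table)
    counts = table.groupby("plate_id").size()
    if (counts < 2).any():
        bad = counts[counts < 2].index.tolist()
        raise ValueError(f"plates with <2 cells cannot be z-scored: {bad}")
    out = table.copy()
    dropped: set[str] = set()
    for _, idx in table.groupby("plate_id").groups.items():
        block = table.loc[idx, feature_cols]
        sd = block.std(ddof=0)
        dropped |= set(sd.index[sd == 0])
        out.loc[idx, feature_cols] = (block - block.mean()) / sd.replace(0, np.nan)
    dropped_list = sorted(dropped)
    if dropped_list:
        out = out.drop(columns=dropped_list)
    return out, dropped_list


# ---------------------------------------------------------------------------
# Factor analysis


@dataclass
class FactorModel:
    """Fitted maximum-likelihood factor model.

    ``loadings`` is features x factors, columns ordered by explained
    variance; ``explained_variance_ratio`` is each factor's share of the
    *total* sample variance (sum of squared loadings / total variance), so
    ``cumulative_variance`` is the share of total variance carried by the
    common factors together.
    """

    n_factors: int
    loadings: np.ndarray
    noise_variance: np.ndarray
    mean: np.ndarray
    feature_names: list
    explained_variance_ratio: np.ndarray
    cumulative_variance: float
    variance_target: float
    rotation: str | None = None
    reached_target: bool = True
    warnings: list = field(default_factory=list)

    def score_weights(self) -> np.ndarray:
        """Regression (Thomson) score weight matrix, features x factors."""
        lam = self.loadings
        psi_inv = 1.0 / self.noise_variance
        a = lam * psi_inv[:, None]  # Psi^-1 Lambda
        m = np.eye(self.n_factors) + lam.T @ a
        return a @ np.linalg.inv(m)


def _varimax(loadings: np.ndarray) -> np.ndarray:
    from statsmodels.multivariate.factor_rotation import rotate_factors

    rotated, _ = rotate_factors(loadings, "varimax")
    return rotated


def fit_factor_analysis(
    table: pd.DataFrame,
    feature_cols: list[str] | None = None,
    variance_target: float = 0.80,
    n_max: int | None = None,
    rotation: str | None = None,
    max_iter: int = 1000,
) -> FactorModel:
    """ML factor analysis with variance-targeted factor-count selection.

    Fits models with increasing factor count and keeps the smallest count
    whose common factors explain at least ``variance_target`` of the total
    sample variance. If the target is unreachable by ``n_max`` factors
    (e.g., near-isotropic noise), the ``n_max`` model is returned with
    ``reached_target=False`` and a warning recorded.
    """
    feature_cols = feature_cols or feature_columns(table)
    x = table[feature_cols].to_numpy(dtype=float)
    n, p = x.shape
    n_max = n_max or min(p, 30)
    total_var = float(x.var(axis=0, ddof=0).sum())
    if total_var <= 0:
        raise ValueError("feature table has zero total variance")

    model = None
    for k in range(1, n_max + 1):
        if n < 10 * k:
            warnings.warn(
                f"only {n} cells for {k} candidate factors; "
                "recommend >= 10 cells per factor",
                stacklevel=2,
            )
        fa = FactorAnalysis(n_components=k, max_iter=max_iter)
        fa.fit(x)
        if fa.n_iter_ >= max_iter:
            warnings.warn(f"factor analysis EM hit max_iter at k={k}", stacklevel=2)
        lam = fa.components_.T  # p x k
        evr = (lam**2).sum(axis=0) / total_var
        order = np.argsort(evr)[::-1]
        lam, evr = lam[:, order], evr[order]
        cum = float(evr.sum())
        model = FactorModel(
            n_factors=k,
            loadings=lam,
            noise_variance=fa.noise_variance_,
            mean=fa.mean_,
            feature_names=list(feature_cols),
            explained_variance_ratio=evr,
            cumulative_variance=cum,
            variance_target=variance_target,
        )
        if cum >= variance_target:
            break
    assert model is not None
    if model.cumulative_variance < variance_target:
        model.reached_target = False
        model.warnings.append(
            f"cumulative explained variance {model.cumulative_variance:.3f} "
            f"below target {variance_target} at n_max={n_max}"
        )
    if rotation == "varimax":
        model.loadings = _varimax(model.loadings)
        model.rotation = "varimax"
    elif rotation is not None:
        raise ValueError(f"unknown rotation {rotation!r}")
    return model


def score_factors(model: FactorModel, table: pd.DataFrame) -> pd.DataFrame:
    """Regression-method factor scores per cell, with metadata carried."""
    x = table[model.feature_names].to_numpy(dtype=float)
    scores = (x - model.mean) @ model.score_weights()
    cols = [f"factor_{k + 1:02d}" for k in range(model.n_factors)]
    meta_cols = [c for c in METADATA_COLUMNS if c in table.columns]
    out = table[meta_cols].reset_index(drop=True)
    return pd.concat([out, pd.DataFrame(scores, columns=cols)], axis=1)


def factor_score_columns(df: pd.DataFrame) -> list[str]:
    return [c for c in df.columns if c.startswith("factor_")]


# ---------------------------------------------------------------------------
# Well profiles


def aggregate_wells(
    scores: pd.DataFrame, min_cells: int = 50, rescale: bool = True
) -> tuple[pd.DataFrame, list[str]]:
    """Average cell factor scores per well; rescale factors across wells.

    Wells with fewer than ``min_cells`` cells are excluded (their ids are
    returned for logging). With ``rescale=True`` every factor column of the
    resulting well-profile table is scaled to zero mean, unit variance
    across the retained wells.
    """
    fcols = factor_score_columns(scores)
    keys = [k for k in WELL_META if k in scores.columns]
    grouped = scores.groupby(keys, sort=True, observed=True)
    profiles = grouped[fcols].mean().reset_index()
    profiles["n_cells"] = grouped.size().to_numpy()
    low = profiles["n_cells"] < min_cells
    dropped = profiles.loc[low, "well_id"].tolist()
    profiles = profiles.loc[~low].reset_index(drop=True)
    if rescale and len(profiles):
        block = profiles[fcols]
        sd = block.std(ddof=0).replace(0, np.nan)
        profiles[fcols] = (block - block.mean()) / sd
    return profiles, dropped


# ---------------------------------------------------------------------------
# Linear discriminant scoring


@dataclass
class LDAModel:
    """LDA fitted on a filtered subset of well profiles.

    ``orientation`` holds the per-component sign applied after projection;
    the convention is that LD1 increases from healthy (HC) towards
    decompensated (DC) class means.
    """

    estimator: LinearDiscriminantAnalysis
    factor_cols: list
    orientation: np.ndarray
    training_filter: str
    class_means: pd.DataFrame
    warnings: list = field(default_factory=list)

    @property
    def classes(self):
        return list(self.estimator.classes_)


def fit_lda(
    profiles: pd.DataFrame,
    label: str = "group",
    training_filter: str = "albumin_arm == 'none'",
    n_components: int = 2,
    shrinkage: str | float | None = "auto",
) -> LDAModel:
    """Fit LDA on the training subset of well profiles.

    ``training_filter`` is a pandas query string selecting the training
    wells (default: albumin-free conditions). Shrinkage (Ledoit-Wolf
    ``"auto"``) stabilises the within-class scatter when wells are few
    relative to factors; pass ``None`` for plain LDA.
    """
    if n_components not in (1, 2):
        raise ValueError("n_components must be 1 or 2")
    train = profiles.query(training_filter)
    fcols = factor_score_columns(profiles)
    y = train[label].to_numpy()
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("need >= 2 classes in the training subset")
    n_components = min(n_components, len(classes) - 1)
    model_warnings = []
    counts = pd.Series(y).value_counts()
    if (counts < len(fcols) / 2).any():
        model_warnings.append(
            "fewer than n_factors/2 training wells in some class; "
            "shrinkage strongly recommended"
        )
    lda = LinearDiscriminantAnalysis(
        solver="eigen", shrinkage=shrinkage, n_components=n_components
    )
    try:
        lda.fit(train[fcols].to_numpy(), y)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "singular within-class scatter; refit with shrinkage='auto'"
        ) from err

    proj = lda.transform(train[fcols].to_numpy())[:, :n_components]
    orientation = np.ones(n_components)
    if "HC" in classes and "DC" in classes:
        m_hc = proj[y == "HC", 0].mean()
        m_dc = proj[y == "DC", 0].mean()
        if m_hc > m_dc:
            orientation[0] = -1.0
    proj = proj * orientation
    means = (
        pd.DataFrame(proj, columns=[f"LD{i + 1}" for i in range(n_components)])
        .assign(**{label: y})
        .groupby(label)
        .mean()
    )
    return LDAModel(
        estimator=lda,
        factor_cols=fcols,
        orientation=orientation,
        training_filter=training_filter,
        class_means=means,
        warnings=model_warnings,
    )


def score_lda(model: LDAModel, profiles: pd.DataFrame) -> pd.DataFrame:
    """Project well profiles onto the fitted discriminant axes (no refit)."""
    proj = model.estimator.transform(profiles[model.factor_cols].to_numpy())
    proj = proj[:, : len(model.orientation)] * model.orientation
    out = profiles.drop(columns=model.factor_cols).copy()
    for i in range(proj.shape[1]):
        out[f"LD{i + 1}"] = proj[:, i]
    return out


def _select_condition(scores: pd.DataFrame, cond: dict) -> pd.DataFrame:
    sel = np.ones(len(scores), dtype=bool)
    for k, v in cond.items():
        sel &= (scores[k] == v).to_numpy()
    return scores.loc[sel]


def compare_lda_scores(
    scores: pd.DataFrame, cond_a: dict, cond_b: dict, value: str = "LD1"
) -> TestResult:
    """Welch independent t-test on a discriminant axis between conditions.

    Conditions are given as metadata filters, e.g. ``{"group": "DC",
    "albumin_arm": "none"}``.
    """
    a = _select_condition(scores, cond_a)[value].to_numpy()
    b = _select_condition(scores, cond_b)[value].to_numpy()
    t, p = stats.ttest_ind(a, b, equal_var=False)
    if np.isnan(p):  # zero variance in both, identical means
        t, p = 0.0, 1.0
    return TestResult(
        statistic=float(t), p_value=float(p), method="welch_t", n=(len(a), len(b))
    )


def arm_shift(
    lda_scores: pd.DataFrame,
    group: str,
    arm_a: str,
    arm_b: str,
    value: str = "LD1",
) -> tuple[float, float]:
    """Albumin-arm shift on a discriminant axis, in pooled-SD units.

    The shift is the mean over plasma samples of the paired per-sample
    difference (arm_b − arm_a of within-sample well means) — arms are
    paired within sample and plate by the study design, so this is the
    minimum-variance estimate of the arm effect. Returns ``(shift,
    pooled_sd)`` where ``pooled_sd`` is the pooled within-condition SD of
    the two arms.
    """
    sub = lda_scores[lda_scores["group"] == group]
    per = sub.groupby(["sample_id", "albumin_arm"], observed=True)[value].mean().unstack()
    if arm_a not in per.columns or arm_b not in per.columns:
        raise ValueError(f"arms {arm_a!r}/{arm_b!r} not present for group {group!r}")
    shift = float((per[arm_b] - per[arm_a]).dropna().mean())
    pooled_sd = float(
        np.sqrt(sub.groupby("albumin_arm", observed=True)[value].var().mean())
    )
    return shift, pooled_sd


# ---------------------------------------------------------------------------
# Per-factor paired tests


def wilcoxon_signed_rank(differences) -> TestResult:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Zero differences are discarded (Wilcoxon's convention); the exact null
    distribution is used for up to 25 non-zero pairs without ties in
    |difference|, the normal approximation with continuity correction
    otherwise. An all-zero difference vector is degenerate: statistic 0,
    p = 1 by convention.
    """
    d = np.asarray(differences, dtype=float)
    d = d[d != 0]
    if d.size == 0:
        return TestResult(statistic=0.0, p_value=1.0, method="wilcoxon_degenerate")
    ties = len(np.unique(np.abs(d))) < d.size
    method = "exact" if (d.size <= 25 and not ties) else "approx"
    res = stats.wilcoxon(
        d,
        zero_method="wilcox",
        correction=(method == "approx"),
        method=method,
        alternative="two-sided",
    )
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        method=f"wilcoxon_{method}",
        n=(d.size,),
    )


def per_factor_tests(
    profiles: pd.DataFrame,
    group: str,
    arm_a: str = "none",
    arm_b: str = "physiological",
    pairing: str = "sample_id",
    min_pairs: int = 6,
) -> pd.DataFrame:
    """Paired Wilcoxon signed-rank test per factor between albumin arms.

    Wells are first averaged to one profile per (sample, arm) — replicate
    wells of one plasma sample are technical replicates — and pairs are
    formed by ``pairing`` (the plasma sample) across the two arms.
    Benjamini-Hochberg q-values are computed across factors.
    """
    fcols = factor_score_columns(profiles)
    sub = profiles[profiles["group"] == group]
    sub = sub[sub["albumin_arm"].isin([arm_a, arm_b])]
    per_sample = (
        sub.groupby([pairing, "albumin_arm"], observed=True)[fcols].mean().reset_index()
    )
    a = per_sample[per_sample["albumin_arm"] == arm_a].set_index(pairing)
    b = per_sample[per_sample["albumin_arm"] == arm_b].set_index(pairing)
    common = a.index.intersection(b.index)
    missing = sorted(set(a.index).symmetric_difference(b.index))
    if missing:
        raise ValueError(f"unpaired samples across arms: {missing}")
    if len(common) < min_pairs:
        raise ValueError(f"need >= {min_pairs} complete pairs, got {len(common)}")
    rows = []
    for col in fcols:
        res = wilcoxon_signed_rank(a.loc[common, col] - b.loc[common, col])
        rows.append(
            {
                "factor": col,
                "statistic": res.statistic,
                "p_value": res.p_value,
                "n_pairs": len(common),
                "method": res.method,
            }
        )
    out = pd.DataFrame(rows)
    out["q_value"] = bh_adjust(out["p_value"].to_numpy())
    return out


# ---------------------------------------------------------------------------
# Factor -> compartment attribution


def factor_component_map(model: FactorModel, tags_map: dict) -> pd.DataFrame:
    """Attribute each factor to cellular compartments by loading weight.

    For every factor the absolute loadings are summed per compartment tag
    and normalised to 1; the dominant compartment is reported, with exact
    ties broken alphabetically and flagged.
    """
    tags = pd.Series([tags_map[f] for f in model.feature_names])
    all_tags = sorted(tags.unique())
    rows = []
    for k in range(model.n_factors):
        w = pd.Series(np.abs(model.loadings[:, k])).groupby(tags).sum()
        w = w.reindex(all_tags, fill_value=0.0)
        total = w.sum()
        w = w / total if total > 0 else w
        top = w.max()
        winners = sorted(w.index[w == top])
        row = {"factor": f"factor_{k + 1:02d}", "dominant": winners[0],
               "tie": len(winners) > 1}
        row.update({f"weight_{t}": w[t] for t in all_tags})
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# PCA train/score path (titration experiments)


@dataclass
class ProfilingResult:
    """Everything the profiling spine produces for one cohort."""

    zscored: pd.DataFrame
    dropped_features: list
    factor_model: FactorModel
    cell_scores: pd.DataFrame
    well_profiles: pd.DataFrame
    dropped_wells: list
    lda_model: LDAModel
    lda_scores: pd.DataFrame

    def median_ld1(self) -> pd.Series:
        return self.lda_scores.groupby(["group", "albumin_arm"])["LD1"].median()


def profile_cohort(
    feature_table: pd.DataFrame,
    variance_target: float = 0.80,
    min_cells: int = 50,
    n_components: int = 2,
    n_max: int | None = None,
    training_filter: str = "albumin_arm == 'none'",
) -> ProfilingResult:
    """Run the full profiling spine on a single-cell feature table.

    Per-plate z-scoring, factor analysis at ``variance_target``, per-cell
    factor scores, well aggregation with rescaling, LDA fitted on the
    ``training_filter`` wells and used to score every well.
    """
    zt, dropped_features = zscore_per_plate(feature_table)
    model = fit_factor_analysis(zt, variance_target=variance_target, n_max=n_max)
    scores = score_factors(model, zt)
    profiles, dropped_wells = aggregate_wells(scores, min_cells=min_cells)
    lda = fit_lda(profiles, training_filter=training_filter,
                  n_components=n_components)
    lda_scores = score_lda(lda, profiles)
    return ProfilingResult(
        zscored=zt,
        dropped_features=dropped_features,
        factor_model=model,
        cell_scores=scores,
        well_profiles=profiles,
        dropped_wells=dropped_wells,
        lda_model=lda,
        lda_scores=lda_scores,
    )


@dataclass
class PCAModel:
    estimator: PCA
    factor_cols: list
    training_filter: str


def fit_pca(
    profiles: pd.DataFrame,
    training_filter: str = "albumin_arm == 'none'",
    n_components: int = 2,
) -> PCAModel:
    """PCA fitted on the training wells of an (already unit-scaled) profile table."""
    train = profiles.query(training_filter)
    fcols = factor_score_columns(profiles)
    pca = PCA(n_components=min(n_components, len(fcols)))
    pca.fit(train[fcols].to_numpy())
    return PCAModel(estimator=pca, factor_cols=fcols, training_filter=training_filter)


def score_pca(model: PCAModel, profiles: pd.DataFrame) -> pd.DataFrame:
    proj = model.estimator.transform(profiles[model.factor_cols].to_numpy())
    out = profiles.drop(columns=model.factor_cols).copy()
    for i in range(proj.shape[1]):
        out[f"PC{i + 1}"] = proj[:, i]
    return out


def pca_shift_test(
    scores: pd.DataFrame,
    cond_a: dict,
    cond_b: dict,
    n_permutations: int = 1000,
    seed: int = 0,
) -> TestResult:
    """Permutation test on the centroid shift between two conditions.

    The statistic is the Euclidean distance between condition centroids in
    PC space; the null is generated by permuting condition membership among
    the pooled wells.
    """
    pc_cols = [c for c in scores.columns if c.startswith("PC")]
    a = _select_condition(scores, cond_a)[pc_cols].to_numpy()
    b = _select_condition(scores, cond_b)[pc_cols].to_numpy()
    if len(a) == 0 or len(b) == 0:
        raise ValueError("empty condition in shift test")
    observed = float(np.linalg.norm(a.mean(axis=0) - b.mean(axis=0)))
    pooled = np.vstack([a, b])
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(len(pooled))
        pa, pb = pooled[perm[: len(a)]], pooled[perm[len(a) :]]
        if np.linalg.norm(pa.mean(axis=0) - pb.mean(axis=0)) >= observed:
            count += 1
    p = (count + 1) / (n_permutations + 1)
    return TestResult(
        statistic=observed, p_value=p, method="pca_centroid_permutation",
        n=(len(a), len(b)),
    )
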
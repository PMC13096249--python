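"""Profiling spine: normalisation, factor selection, scoring, LDA/PCA and
paired tests — with brute-force oracles for the exact Wilcoxon path."""

from __future__ import annotations

import warnings
from itertools import product

import numpy as np
import pandas as pd
import pytest

from ecmorph.profiles import (
    aggregate_wells,
    bh_adjust,
    compare_lda_scores,
    factor_component_map,
    fit_factor_analysis,
    fit_lda,
    fit_pca,
    pca_shift_test,
    per_factor_tests,
    score_factors,
    score_lda,
    score_pca,
    wilcoxon_signed_rank,
    zscore_per_plate,
)
from ecmorph.synthetic import (
    LayoutConfig,
    default_latent_spec,
    generate_feature_table,
    generate_plate_layout,
)


def wilcoxon_oracle(d) -> float:
    """Exact two-sided signed-rank p by enumerating all sign assignments."""
    d = np.asarray(d, float)
    d = d[d != 0]
    n = len(d)
    ranks = pd.Series(np.abs(d)).rank().to_numpy()
    w_obs = ranks[d > 0].sum()
    ws = []
    for signs in product([0, 1], repeat=n):
        ws.append(sum(r for r, s in zip(ranks, signs) if s))
    ws = np.array(ws)
    cdf = (ws <= w_obs).mean()
    sf = (ws >= w_obs).mean()
    return min(1.0, 2 * min(cdf, sf))


@pytest.fixture(scope="module")
def plain_table():
    layout = generate_plate_layout(LayoutConfig(3, 3, 3, replicates=1), seed=1)
    spec = default_latent_spec(n_factors=4, n_features=24, seed=0,
                               group_effects=False)
    table = generate_feature_table(spec, cells_per_well=80, layout=layout, seed=2)
    return table, spec


# ---------------------------------------------------------------------------
# z-scoring


def test_zscore_centres_each_plate(plain_table):
    table, spec = plain_table
    zt, dropped = zscore_per_plate(table)
    assert not dropped
    for _, block in zt.groupby("plate_id"):
        means = block[spec.feature_names].mean()
        sds = block[spec.feature_names].std(ddof=0)
        np.testing.assert_allclose(means, 0.0, atol=1e-9)
        np.testing.assert_allclose(sds, 1.0, atol=1e-9)


def test_zscore_drops_plate_constant_feature(plain_table):
    table, spec = plain_table
    bad = table.copy()
    bad["stuck_feature"] = 3.14
    zt, dropped = zscore_per_plate(bad)
    assert dropped == ["stuck_feature"]
    assert "stuck_feature" not in zt.columns


def test_zscore_removes_plate_batch_offsets():
    """Two plates generated with different batch offsets become
    distributionally identical after per-plate z-scoring."""
    spec = default_latent_spec(n_factors=3, n_features=12, seed=0,
                               group_effects=False)
    layout = generate_plate_layout(
        LayoutConfig(2, 2, 2, replicates=1,
                     group_arms={g: ("none",) for g in ("HC", "CC", "DC")}),
        seed=0,
    )
    t1 = generate_feature_table(spec, 200, layout, seed=1, plate_offset_sd=0.0)
    t2 = generate_feature_table(spec, 200, layout, seed=1, plate_offset_sd=0.0)
    t2[spec.feature_names] += 5.0  # pure batch offset
    t2["plate_id"] = "P2"
    combined = pd.concat([t1, t2], ignore_index=True)
    zt, _ = zscore_per_plate(combined)
    a = zt[zt.plate_id == "P1"][spec.feature_names].to_numpy()
    b = zt[zt.plate_id == "P2"][spec.feature_names].to_numpy()
    np.testing.assert_allclose(a, b, atol=1e-9)


def test_zscore_rejects_single_cell_plate(plain_table):
    table, _ = plain_table
    with pytest.raises(ValueError):
        zscore_per_plate(table.iloc[:1])


# ---------------------------------------------------------------------------
# factor analysis


def test_factor_count_recovery_from_generative_model(plain_table):
    table, _ = plain_table
    zt, _ = zscore_per_plate(table)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = fit_factor_analysis(zt, variance_target=0.80, n_max=10)
    assert model.n_factors == 4
    assert model.reached_target
    assert 0.80 <= model.cumulative_variance <= 0.95


def test_isotropic_noise_cannot_reach_target():
    rng = np.random.default_rng(0)
    table = pd.DataFrame(rng.normal(size=(400, 12)),
                         columns=[f"f{i}" for i in range(12)])
    table["plate_id"] = "P1"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = fit_factor_analysis(table, variance_target=0.80, n_max=5)
    assert not model.reached_target
    assert model.n_factors == 5
    assert model.warnings


def test_variance_target_one_exhausts_n_max(plain_table):
    table, _ = plain_table
    zt, _ = zscore_per_plate(table)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = fit_factor_analysis(zt, variance_target=1.0, n_max=6)
    assert model.n_factors == 6


def test_score_factors_centred_and_idempotent(plain_table):
    table, _ = plain_table
    zt, _ = zscore_per_plate(table)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = fit_factor_analysis(zt, n_max=6)
    s1 = score_factors(model, zt)
    s2 = score_factors(model, zt)
    fcols = [c for c in s1.columns if c.startswith("factor_")]
    # scoring the training data and averaging equals the model-implied
    # (centred) score means
    np.testing.assert_allclose(s1[fcols].mean(), 0.0, atol=1e-6)
    pd.testing.assert_frame_equal(s1, s2)
    # the mean feature vector maps to the zero score vector
    mean_row = zt.iloc[:1].copy()
    mean_row[model.feature_names] = model.mean
    np.testing.assert_allclose(
        score_factors(model, mean_row)[fcols].to_numpy(), 0.0, atol=1e-9
    )


# ---------------------------------------------------------------------------
# well aggregation


def test_aggregate_wells_scaling_and_min_cells(plain_table):
    table, _ = plain_table
    zt, _ = zscore_per_plate(table)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = fit_factor_analysis(zt, n_max=6)
    scores = score_factors(model, zt)
    profiles, dropped = aggregate_wells(scores, min_cells=50)
    fcols = [c for c in profiles.columns if c.startswith("factor_")]
    assert not dropped
    np.testing.assert_allclose(profiles[fcols].mean(), 0.0, atol=1e-9)
    np.testing.assert_allclose(profiles[fcols].std(ddof=0), 1.0, atol=1e-9)
    # raising min_cells above the well size drops every well
    _, dropped_all = aggregate_wells(scores, min_cells=10_000)
    assert len(dropped_all) == scores.groupby(["plate_id", "well_id"]).ngroups


def test_single_well_profile_equals_cell_mean():
    scores = pd.DataFrame(
        {
            "plate_id": "P1",
            "well_id": "A01",
            "group": "HC",
            "albumin_arm": "none",
            "sample_id": "HC001",
            "factor_01": [2.0, 2.0, 2.0],
        }
    )
    profiles, _ = aggregate_wells(scores, min_cells=1, rescale=False)
    assert profiles.loc[0, "factor_01"] == pytest.approx(2.0)
    assert profiles.loc[0, "n_cells"] == 3


# ---------------------------------------------------------------------------
# LDA


def _gaussian_profiles(rng, n_per_class=20, delta=5.0, n_factors=4):
    rows = []
    for grp, mu in (("HC", 0.0), ("DC", delta)):
        for i in range(n_per_class):
            rows.append(
                {
                    "plate_id": "P1",
                    "well_id": f"{grp}{i}",
                    "group": grp,
                    "albumin_arm": "none",
                    "sample_id": f"{grp}{i}",
                    **{f"factor_{k + 1:02d}": rng.normal(mu if k == 0 else 0.0, 1.0)
                       for k in range(n_factors)},
                }
            )
    return pd.DataFrame(rows)


def test_separated_classes_classified_perfectly_and_oriented():
    rng = np.random.default_rng(0)
    profiles = _gaussian_profiles(rng)
    model = fit_lda(profiles, n_components=1)
    scores = score_lda(model, profiles)
    med = scores.groupby("group").LD1.median()
    assert med["HC"] < med["DC"]  # sign convention
    fcols = model.factor_cols
    acc = (model.estimator.predict(profiles[fcols].to_numpy())
           == profiles.group.to_numpy()).mean()
    assert acc == 1.0


def test_label_permutation_destroys_separation():
    """Fitting on permuted class labels yields axes with no generalisable
    separation: scored on held-out wells, the Welch t-test is null."""
    rng = np.random.default_rng(1)
    nonsig = 0
    for _ in range(100):
        train = _gaussian_profiles(rng, delta=0.0)
        train["group"] = rng.permutation(train["group"].to_numpy())
        held_out = _gaussian_profiles(rng, delta=0.0)
        model = fit_lda(train, n_components=1)
        scores = score_lda(model, held_out)
        res = compare_lda_scores(scores, {"group": "HC"}, {"group": "DC"})
        if res.p_value > 0.05:
            nonsig += 1
    assert nonsig >= 90


def test_lda_power_on_two_sd_shift():
    rng = np.random.default_rng(2)
    sig = 0
    for _ in range(100):
        profiles = _gaussian_profiles(rng, n_per_class=20, delta=2.0)
        model = fit_lda(profiles, n_components=1)
        scores = score_lda(model, profiles)
        res = compare_lda_scores(scores, {"group": "DC"}, {"group": "HC"})
        if res.p_value < 0.01:
            sig += 1
    assert sig >= 95


def test_scoring_training_wells_reproduces_fit_scores():
    rng = np.random.default_rng(3)
    profiles = _gaussian_profiles(rng)
    model = fit_lda(profiles, n_components=1)
    scores = score_lda(model, profiles)
    med = scores.groupby("group").LD1.mean()
    np.testing.assert_allclose(
        med.sort_index().to_numpy(),
        model.class_means["LD1"].sort_index().to_numpy(),
        atol=1e-9,
    )


def test_lda_projection_is_affine():
    rng = np.random.default_rng(4)
    profiles = _gaussian_profiles(rng)
    model = fit_lda(profiles, n_components=1)
    fcols = model.factor_cols
    base = score_lda(model, profiles).LD1.to_numpy()
    shifted = profiles.copy()
    shifted[fcols] = shifted[fcols] + 2.0
    s = score_lda(model, shifted).LD1.to_numpy()
    np.testing.assert_allclose(np.diff(s - base), 0.0, atol=1e-9)


def test_welch_t_symmetry():
    rng = np.random.default_rng(5)
    profiles = _gaussian_profiles(rng, delta=1.0)
    model = fit_lda(profiles, n_components=1)
    scores = score_lda(model, profiles)
    ab = compare_lda_scores(scores, {"group": "HC"}, {"group": "DC"})
    ba = compare_lda_scores(scores, {"group": "DC"}, {"group": "HC"})
    assert ab.statistic == pytest.approx(-ba.statistic)
    assert ab.p_value == pytest.approx(ba.p_value)


def test_identical_conditions_give_t_zero():
    rng = np.random.default_rng(6)
    profiles = _gaussian_profiles(rng)
    model = fit_lda(profiles, n_components=1)
    scores = score_lda(model, profiles)
    res = compare_lda_scores(scores, {"group": "HC"}, {"group": "HC"})
    assert res.statistic == pytest.approx(0.0)
    assert res.p_value == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# Wilcoxon and BH


def test_wilcoxon_all_positive_closed_form():
    res = wilcoxon_signed_rank([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
    assert res.p_value == pytest.approx(2 / 2**6)
    assert res.method == "wilcoxon_exact"


def test_wilcoxon_degenerate_zero_differences():
    res = wilcoxon_signed_rank([0.0, 0.0, 0.0])
    assert res.statistic == 0.0 and res.p_value == 1.0


@pytest.mark.parametrize("seed", [0, 1, 2, 3])
def test_wilcoxon_matches_enumeration_oracle(seed):
    rng = np.random.default_rng(seed)
    for n in (6, 8, 10):
        d = rng.normal(0.4, 1.0, n)
        assert wilcoxon_signed_rank(d).p_value == pytest.approx(
            wilcoxon_oracle(d), abs=1e-12
        )


def test_bh_adjustment_arithmetic_and_monotonicity():
    q = bh_adjust([0.01, 0.02, 0.20])
    np.testing.assert_allclose(q, [0.03, 0.03, 0.20])
    p = np.array([0.001, 0.01, 0.02, 0.5, 0.9])
    q = bh_adjust(p)
    assert (np.diff(q[np.argsort(p)]) >= -1e-12).all()
    assert q[np.argmax(p)] >= p.max() - 1e-12


def test_per_factor_tests_pairing_validation(small_cohort_run):
    result, _ = small_cohort_run
    out = per_factor_tests(result.well_profiles, group="DC")
    assert len(out) == result.factor_model.n_factors
    assert (out.q_value >= out.p_value - 1e-12).all()
    broken = result.well_profiles[
        ~((result.well_profiles.sample_id == "DC001")
          & (result.well_profiles.albumin_arm == "physiological"))
    ]
    with pytest.raises(ValueError, match="DC001"):
        per_factor_tests(broken, group="DC")


# ---------------------------------------------------------------------------
# factor -> compartment attribution


def test_component_map_pure_and_uniform_loadings():
    from ecmorph.profiles import FactorModel

    loadings = np.zeros((6, 2))
    loadings[:3, 0] = 0.9   # mito block
    loadings[:, 1] = 0.5    # uniform
    model = FactorModel(
        n_factors=2, loadings=loadings, noise_variance=np.ones(6),
        mean=np.zeros(6), feature_names=[f"f{i}" for i in range(6)],
        explained_variance_ratio=np.array([0.5, 0.3]), cumulative_variance=0.8,
        variance_target=0.8,
    )
    tags = {f"f{i}": ("mitochondria" if i < 3 else "actin") for i in range(6)}
    cm = factor_component_map(model, tags).set_index("factor")
    assert cm.loc["factor_01", "weight_mitochondria"] == pytest.approx(1.0)
    assert cm.loc["factor_01", "dominant"] == "mitochondria"
    # uniform loadings: weights proportional to tag counts (3 vs 3)
    assert cm.loc["factor_02", "weight_mitochondria"] == pytest.approx(0.5)
    assert cm.loc["factor_02", "tie"]
    assert cm.loc["factor_02", "dominant"] == "actin"  # alphabetical tie-break


# ---------------------------------------------------------------------------
# PCA path


def test_pca_training_scores_centred_and_null_shift():
    rng = np.random.default_rng(7)
    profiles = _gaussian_profiles(rng, delta=0.0)
    # mark half of each class as a held-out "albumin" arm drawn identically
    profiles.loc[profiles.index % 2 == 1, "albumin_arm"] = "physiological"
    model = fit_pca(profiles)
    scores = score_pca(model, profiles)
    train = scores.query("albumin_arm == 'none'")
    np.testing.assert_allclose(train[["PC1", "PC2"]].mean(), 0.0, atol=1e-9)
    nonsig = 0
    for seed in range(20):
        res = pca_shift_test(
            scores, {"albumin_arm": "none"}, {"albumin_arm": "physiological"},
            n_permutations=300, seed=seed,
        )
        if res.p_value > 0.05:
            nonsig += 1
    assert nonsig >= 18  # identically generated arm shows no shift


def test_duplicating_a_held_out_well_preserves_centroid():
    rng = np.random.default_rng(8)
    profiles = _gaussian_profiles(rng)
    model = fit_pca(profiles)
    scores = score_pca(model, profiles)
    dup = pd.concat([profiles, profiles.iloc[[0]]], ignore_index=True)
    dup_scores = score_pca(model, dup)
    np.testing.assert_allclose(
        dup_scores.iloc[0][["PC1", "PC2"]].astype(float),
        dup_scores.iloc[-1][["PC1", "PC2"]].astype(float),
    )
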
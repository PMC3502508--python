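import numpy as np
import pandas as pd
import pytest
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

import bhlhkit as bk
from bhlhkit.discriminant import SingularMatrixError


def anova_wilks_oracle(x, y):
    """Direct one-way ANOVA sums of squares: SSE_within / SSE_total."""
    x = np.asarray(x, dtype=float)
    grand = x.mean()
    sse_tot = ((x - grand) ** 2).sum()
    sse_within = 0.0
    for g in np.unique(y):
        xg = x[y == g]
        sse_within += ((xg - xg.mean()) ** 2).sum()
    return sse_within / sse_tot


def brute_force_eigs(X, y):
    """Dense eigen-solve of W^-1 B, independent of the fitted path."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    grand = X.mean(axis=0)
    p = X.shape[1]
    W = np.zeros((p, p))
    B = np.zeros((p, p))
    for g in np.unique(y):
        Xg = X[y == g]
        C = Xg - Xg.mean(axis=0)
        W += C.T @ C
        d = (Xg.mean(axis=0) - grand)[:, None]
        B += len(Xg) * d @ d.T
    evals = np.linalg.eigvals(np.linalg.solve(W, B))
    return np.sort(np.real(evals))[::-1]


# ---------------------------------------------------------------------------
# Wilks' lambda


def test_wilks_equals_anova_identity_for_one_variable_two_groups():
    rng = np.random.default_rng(1)
    x = rng.normal(size=80)
    x[:40] += 1.5
    y = np.repeat(["a", "b"], 40)
    got = bk.wilks_lambda(x[:, None], y)
    assert got == pytest.approx(anova_wilks_oracle(x, y), rel=1e-12)


def test_wilks_near_one_without_separation_and_tiny_with():
    rng = np.random.default_rng(2)
    y = np.repeat(["a", "b", "c"], 400)
    X_null = rng.normal(size=(1200, 3))
    assert bk.wilks_lambda(X_null, y) > 0.98
    # two widely separated groups (means +-10, sd 1): population
    # lambda = 1 / (1 + 10^2) < 0.01; large n keeps sampling noise tiny
    y2 = np.repeat(["a", "b"], 10_000)
    X_sep = rng.normal(size=(20_000, 1))
    X_sep[y2 == "a"] -= 10
    X_sep[y2 == "b"] += 10
    assert bk.wilks_lambda(X_sep, y2) < 0.01


def test_wilks_diagnoses_collinear_variables():
    rng = np.random.default_rng(3)
    x = rng.normal(size=60)
    X = np.column_stack([x, 2 * x])
    y = np.repeat(["a", "b"], 30)
    with pytest.raises(SingularMatrixError):
        bk.wilks_lambda(X, y)


# ---------------------------------------------------------------------------
# ASCC


def test_ascc_near_zero_without_separation():
    rng = np.random.default_rng(4)
    y = np.repeat(["a", "b", "c"], 500)
    assert bk.ascc(rng.normal(size=(1500, 4)), y) < 0.01


def test_ascc_two_groups_one_variable_equals_one_minus_lambda():
    """With G=2 and p=1 there is a single canonical correlation and
    rho^2 = 1 - Wilks' lambda exactly."""
    rng = np.random.default_rng(5)
    x = rng.normal(size=100)
    x[:50] += 2.0
    y = np.repeat(["a", "b"], 50)
    assert bk.ascc(x[:, None], y) == pytest.approx(
        1 - bk.wilks_lambda(x[:, None], y), rel=1e-10
    )


def test_ascc_equals_mean_squared_canonical_correlation(gaussian_3group):
    X, y = gaussian_3group
    model = bk.fit_cva(X, y)
    assert bk.ascc(X, y) == pytest.approx(
        model.canonical_corr_sq_.mean(), rel=1e-10
    )


# ---------------------------------------------------------------------------
# CVA


def test_cva_eigenvalues_match_brute_force_solve(gaussian_3group):
    X, y = gaussian_3group
    model = bk.fit_cva(X, y)
    oracle = brute_force_eigs(X, y)[:2]
    assert np.allclose(model.eigenvalues_, oracle, rtol=1e-8)
    assert model.proportions_.sum() == pytest.approx(1.0)
    assert np.all(np.diff(model.eigenvalues_) <= 1e-12)
    assert np.all((model.canonical_corr_sq_ >= 0) & (model.canonical_corr_sq_ < 1))


def test_canonical_scores_have_unit_pooled_within_variance(gaussian_3group):
    X, y = gaussian_3group
    model = bk.fit_cva(X, y)
    scores = model.transform(X)
    G = len(model.classes_)
    pooled = np.zeros(scores.shape[1])
    for g in model.classes_:
        s = scores[(y == g).to_numpy()]
        pooled += ((s - s.mean(axis=0)) ** 2).sum(axis=0)
    pooled /= len(X) - G
    assert np.allclose(pooled, 1.0, atol=1e-8)


def test_degenerate_geometry_first_cv_aligns_with_separating_axis():
    rng = np.random.default_rng(6)
    n = 200
    X = rng.normal(size=(3 * n, 2))
    X[:n, 0] -= 6
    X[2 * n :, 0] += 6
    y = np.repeat(["a", "b", "c"], n)
    model = bk.fit_cva(X, y)
    v = model.coef_[:, 0] / np.linalg.norm(model.coef_[:, 0])
    assert abs(v[0]) > 0.99  # collinear with axis 1
    assert model.proportions_[1] < 0.02


def test_fewer_than_two_groups_is_domain_error():
    X = np.random.default_rng(0).normal(size=(20, 2))
    with pytest.raises(ValueError, match="2 groups"):
        bk.fit_cva(X, ["only"] * 20)


def test_predictions_agree_with_sklearn_lda(gaussian_3group):
    """Independent cross-check: with proportional priors, the Mahalanobis
    posterior rule coincides with Fisher/Gaussian LDA."""
    X, y = gaussian_3group
    ours = bk.fit_cva(X, y, priors="proportional").predict(X)
    lda = LinearDiscriminantAnalysis(solver="svd").fit(X, y).predict(X)
    agreement = (ours == lda).mean()
    assert agreement > 0.995


# ---------------------------------------------------------------------------
# Mahalanobis distances and classification


def test_mahalanobis_between_identity_symmetry_and_canonical_equivalence(gaussian_3group):
    X, y = gaussian_3group
    model = bk.fit_cva(X, y)
    assert model.mahalanobis_between("Plant", "Plant") == 0.0
    d_ab = model.mahalanobis_between("Animal", "Fungal")
    assert d_ab == pytest.approx(model.mahalanobis_between("Fungal", "Animal"))
    # equals Euclidean distance between centroids in full canonical space
    ca = model.centroids_[list(model.classes_).index("Animal")]
    cf = model.centroids_[list(model.classes_).index("Fungal")]
    assert d_ab == pytest.approx(float(np.linalg.norm(ca - cf)), rel=1e-8)


def test_centroid_distances_form_a_metric(gaussian_3group):
    X, y = gaussian_3group
    model = bk.fit_cva(X, y)
    D = model.pairwise_distances().to_numpy()
    assert np.allclose(D, D.T)
    assert (D[~np.eye(3, dtype=bool)] > 0).all()
    for i in range(3):
        for j in range(3):
            for k in range(3):
                assert D[i, j] <= D[i, k] + D[k, j] + 1e-12


def test_classifying_group_means_recovers_each_group(gaussian_3group):
    X, y = gaussian_3group
    model = bk.fit_cva(X, y)
    pred = model.predict(model.means_)
    assert list(pred) == list(model.classes_)
    d = model.mahalanobis(model.means_)
    assert np.allclose(np.diag(d.to_numpy()), 0.0, atol=1e-8)


def test_any_missing_model_variable_means_unclassified(gaussian_3group):
    X, y = gaussian_3group
    model = bk.fit_cva(X, y)
    row = X.iloc[[0]].copy()
    row.iloc[0, 2] = np.nan
    assert model.predict(row)[0] == bk.UNCLASSIFIED
    assert np.isnan(model.predict_proba(row)).all()


def test_equidistant_point_gets_equal_posteriors():
    # two groups symmetric about 0: the midpoint is equidistant
    rng = np.random.default_rng(7)
    X = rng.normal(size=(200, 2))
    X[:100, 0] -= 2
    X[100:, 0] += 2
    y = np.repeat(["a", "b"], 100)
    model = bk.fit_cva(X, y)
    mid = (model.means_.loc["a"] + model.means_.loc["b"]) / 2
    proba = model.predict_proba(mid.to_frame().T)
    assert np.allclose(proba, 0.5, atol=1e-10)


def test_posteriors_sum_to_one_when_classified(gaussian_3group):
    X, y = gaussian_3group
    proba = bk.fit_cva(X, y).predict_proba(X)
    assert np.allclose(proba.sum(axis=1), 1.0)


def test_model_json_round_trip(gaussian_3group, tmp_path):
    X, y = gaussian_3group
    model = bk.fit_cva(X, y)
    path = tmp_path / "cva.json"
    model.save(path)
    back = bk.CanonicalVariateClassifier.load(path)
    assert np.allclose(back.coef_, model.coef_)
    assert (back.predict(X) == model.predict(X)).all()
    assert np.allclose(back.mahalanobis(X).to_numpy(), model.mahalanobis(X).to_numpy())


# ---------------------------------------------------------------------------
# SWDA


def planted_dataset(seed=8, n=300, noise_vars=20):
    """One informative variable (group means -2/0/+2, sd 1) + pure noise."""
    rng = np.random.default_rng(seed)
    y = np.repeat(["a", "b", "c"], n // 3)
    info = rng.normal(size=n) + np.repeat([-2.0, 0.0, 2.0], n // 3)
    noise = rng.normal(size=(n, noise_vars))
    X = pd.DataFrame(np.column_stack([info, noise]))
    X.columns = ["info"] + [f"noise{i}" for i in range(noise_vars)]
    return X, pd.Series(y)


def test_swda_enters_the_planted_informative_variable_first():
    X, y = planted_dataset()
    sel = bk.fit_swda(X, y, ascc_target=0.70)
    assert sel.steps_.at[0, "variable"] == "info"


def test_swda_lambda_strictly_decreases_and_ascc_never_decreases():
    X, y = planted_dataset(seed=9)
    sel = bk.fit_swda(X, y, ascc_target=0.99, max_steps=8, entry_alpha=0.9)
    lam = sel.steps_["wilks_lambda"].to_numpy()
    a = sel.steps_["ascc"].to_numpy()
    assert (np.diff(lam) < 0).all()
    assert (np.diff(a) >= -1e-12).all()
    assert ((sel.steps_["partial_r2"] >= 0) & (sel.steps_["partial_r2"] <= 1)).all()


def test_duplicate_of_entered_variable_contributes_nothing():
    X, y = planted_dataset(seed=10, noise_vars=5)
    X["info_copy"] = X["info"] + np.random.default_rng(11).normal(
        scale=1e-6, size=len(X)
    )
    sel = bk.fit_swda(X, y, ascc_target=0.99, max_steps=6, entry_alpha=0.99)
    steps = sel.steps_.set_index("variable")
    assert steps.index[0] == "info"
    if "info_copy" in steps.index:
        assert steps.at["info_copy", "partial_r2"] < 1e-3


def test_permuted_labels_stop_at_entry_threshold_with_tiny_ascc():
    X, y = planted_dataset(seed=12)
    y_perm = pd.Series(
        np.random.default_rng(13).permutation(y.to_numpy()), index=y.index
    )
    sel = bk.fit_swda(X, y_perm, ascc_target=0.70, entry_alpha=0.05)
    assert sel.stopping_reason_ == "entry_threshold"
    if len(sel.steps_):
        assert sel.steps_["ascc"].iloc[-1] < 0.1


def test_swda_ascc_matches_direct_recomputation_on_selected_set():
    X, y = planted_dataset(seed=14)
    sel = bk.fit_swda(X, y, ascc_target=0.99, max_steps=5, entry_alpha=0.9)
    recomputed = bk.ascc(X[sel.selected_], y)
    assert sel.steps_["ascc"].iloc[-1] == pytest.approx(recomputed, rel=1e-10)


def test_swda_classifier_tolerates_gaps_at_unselected_sites():
    X, y = planted_dataset(seed=15)
    sel = bk.fit_swda(X, y, ascc_target=0.70)
    model = bk.swda_to_classifier(X, y, sel)
    row = X.iloc[[0]].copy()
    unselected = [c for c in X.columns if c not in sel.selected_]
    row[unselected] = np.nan
    assert model.predict(row[sel.selected_])[0] != bk.UNCLASSIFIED
    # training accuracy near the generating model's separability
    acc = (model.predict(X[sel.selected_]) == y.to_numpy()).mean()
    assert acc > 0.75


def test_restricting_to_selected_variables_never_lowers_lambda():
    X, y = planted_dataset(seed=16, noise_vars=6)
    sel = bk.fit_swda(X, y, ascc_target=0.99, max_steps=3, entry_alpha=0.9)
    lam_subset = bk.wilks_lambda(X[sel.selected_], y)
    lam_full = bk.wilks_lambda(X, y)
    assert lam_subset >= lam_full - 1e-12


def test_discerning_sites_threshold_semantics():
    X, y = planted_dataset(seed=17)
    sel = bk.fit_swda(X, y, ascc_target=0.99, max_steps=5, entry_alpha=0.9)
    assert bk.discerning_sites(sel, r2_threshold=0.20) == ["info"]
    assert set(bk.discerning_sites(sel, r2_threshold=0.0)) == set(
        sel.steps_["variable"]
    )
    assert bk.discerning_sites(sel, r2_threshold=1.0) == []


def test_cv_top_sites_threshold_is_on_raw_coefficients():
    """Scaling a variable's inputs by 10 scales its canonical coefficient
    by 1/10 — the magnitude threshold is on raw coefficients."""
    rng = np.random.default_rng(18)
    n = 300
    # within-group sd 0.5 puts the separating variable's raw canonical
    # coefficient (unit pooled within-group variance scale) near 2
    X = pd.DataFrame(rng.normal(scale=0.5, size=(n, 3)), columns=["u", "v", "w"])
    y = pd.Series(np.repeat(["a", "b", "c"], n // 3))
    X["u"] += np.repeat([-2.0, 0.0, 2.0], n // 3)
    m1 = bk.fit_cva(X, y)
    X10 = X.copy()
    X10["u"] = X10["u"] * 10
    m2 = bk.fit_cva(X10, y)
    i = list(X.columns).index("u")
    assert m2.coef_[i, 0] == pytest.approx(m1.coef_[i, 0] / 10, rel=1e-8)
    assert "u" in bk.cv_top_sites(m1, magnitude_threshold=1.0)[1]
    assert bk.cv_top_sites(m1, magnitude_threshold=1e6) == {1: [], 2: []}
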
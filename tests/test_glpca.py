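import numpy as np
import pandas as pd
import pytest

from neuroreserve import (
    component_correlations,
    fit_glpca,
    laplacian,
    normalize_to_tiv,
    standardize,
)
from neuroreserve.glpca import StandardizedMatrix
from neuroreserve.graph import RegionGraph


def random_standardized(n, p, seed=0, columns=None):
    rng = np.random.default_rng(seed)
    cols = columns or [f"m{j}" for j in range(p)]
    df = pd.DataFrame(rng.normal(size=(n, p)), columns=cols)
    return standardize(df, cols)


def path_laplacian(p):
    W = np.zeros((p, p))
    for j in range(p - 1):
        W[j, j + 1] = W[j + 1, j] = 1.0
    return laplacian(RegionGraph(tuple(f"m{j}" for j in range(p)), W))


def test_standardize_two_subject_column_and_round_trip():
    df = pd.DataFrame({"a": [4.0, 6.0], "b": [1.0, 3.0]})
    out = standardize(df, ["a", "b"])
    # sample-sd (n-1) convention: {4, 6} has mean 5 and sd sqrt(2)
    assert np.allclose(out.X[:, 0], [-1 / np.sqrt(2), 1 / np.sqrt(2)])
    pd.testing.assert_frame_equal(out.destandardize(), df)


def test_standardized_columns_have_zero_mean_unit_sd():
    data = random_standardized(100, 8, seed=1)
    assert np.all(np.abs(data.X.mean(axis=0)) < 1e-10)
    assert np.allclose(data.X.std(axis=0, ddof=1), 1.0, atol=1e-8)


def test_standardize_rejects_constant_column():
    df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "flat": [7.0, 7.0, 7.0]})
    with pytest.raises(ValueError, match="flat"):
        standardize(df, ["a", "flat"])


def test_beta_zero_recovers_classical_pca():
    data = random_standardized(60, 6, seed=2)
    model = fit_glpca(data, np.zeros((6, 6)), k=2, beta=0.0)
    _, _, Vt = np.linalg.svd(data.X, full_matrices=False)
    for j in range(2):
        assert abs(np.dot(model.Q[:, j], Vt[j])) == pytest.approx(1.0, abs=1e-8)
    # scores are the same projections up to the sign orientation
    for j in range(2):
        sign = np.sign(np.dot(model.Q[:, j], Vt[j]))
        assert np.allclose(model.U[:, j], sign * data.X @ Vt[j], atol=1e-8)


def test_beta_one_gives_constant_loading_on_connected_graph():
    p = 5
    data = random_standardized(40, p, seed=3)
    model = fit_glpca(data, path_laplacian(p), k=1, beta=1.0)
    assert np.allclose(model.Q[:, 0], np.full(p, 1 / np.sqrt(p)), atol=1e-8)
    assert np.allclose(model.U[:, 0], data.X.sum(axis=1) / np.sqrt(p), atol=1e-8)


def test_three_measure_example_matches_dense_eigendecomposition():
    """Brute-force oracle: eigendecompose the composite operator built from
    its definition and compare loadings and objective to 1e-10."""
    rng = np.random.default_rng(4)
    df = pd.DataFrame(rng.normal(size=(4, 3)) @ np.diag([3.0, 1.5, 1.0]), columns=list("abc"))
    data = standardize(df, list("abc"))
    L = np.array([[1, -1, 0], [-1, 2, -1], [0, -1, 1]], dtype=float)
    beta = 0.5
    model = fit_glpca(data, L, k=1, beta=beta)

    X = data.X
    lam_d = np.linalg.eigvalsh(X.T @ X)[-1]
    lam_g = np.linalg.eigvalsh(L)[-1]
    G = (1 - beta) * (np.eye(3) - X.T @ X / lam_d) + beta * L / lam_g
    w, V = np.linalg.eigh(G)
    q_oracle = V[:, 0] if V[:, 0].sum() >= 0 else -V[:, 0]
    assert np.allclose(model.Q[:, 0], q_oracle, atol=1e-10)
    assert model.eigenvalues[0] == pytest.approx(w[0], abs=1e-10)
    assert model.lambda_data == pytest.approx(lam_d, rel=1e-12)


def test_loadings_are_orthonormal_and_scores_centered(template_graph, scheme):
    rng = np.random.default_rng(5)
    df = pd.DataFrame(rng.normal(size=(80, 27)), columns=scheme.names)
    data = standardize(df, scheme.names)
    model = fit_glpca(data, laplacian(template_graph), k=3, beta=0.5)
    assert np.allclose(model.Q.T @ model.Q, np.eye(3), atol=1e-8)
    assert np.all(np.abs(model.U.mean(axis=0)) < 1e-10)
    assert np.all(model.Q.sum(axis=0) >= 0)


def test_returned_loading_minimizes_penalized_objective():
    """Among 200 random unit vectors, none attains a lower value of
    ||X - Xqq'||_F^2 + alpha q'Lq than the fitted loading."""
    data = random_standardized(50, 6, seed=6)
    L = path_laplacian(6)
    beta = 0.5
    model = fit_glpca(data, L, k=1, beta=beta)
    alpha = beta * model.lambda_data / ((1 - beta) * model.lambda_graph)
    X = data.X

    def objective(q):
        return np.linalg.norm(X - np.outer(X @ q, q)) ** 2 + alpha * q @ L @ q

    best = objective(model.Q[:, 0])
    rng = np.random.default_rng(7)
    for _ in range(200):
        q = rng.normal(size=6)
        q /= np.linalg.norm(q)
        assert objective(q) >= best - 1e-8


def test_pc1_direction_is_continuous_in_beta():
    data = random_standardized(100, 6, seed=8)
    L = path_laplacian(6)
    q0 = fit_glpca(data, L, k=1, beta=0.0).Q[:, 0]
    q_eps = fit_glpca(data, L, k=1, beta=0.01).Q[:, 0]
    angle = np.degrees(np.arccos(np.clip(abs(np.dot(q0, q_eps)), -1, 1)))
    assert angle < 10.0


def test_fit_rejects_invalid_arguments():
    data = random_standardized(20, 4, seed=9)
    L = path_laplacian(4)
    with pytest.raises(ValueError, match="beta"):
        fit_glpca(data, L, k=1, beta=1.5)
    with pytest.raises(ValueError, match="k"):
        fit_glpca(data, L, k=4, beta=0.5)
    with pytest.raises(ValueError, match="symmetric"):
        fit_glpca(data, np.triu(np.ones((4, 4)), 1), k=1, beta=0.5)
    with pytest.raises(ValueError, match="empty graph"):
        fit_glpca(data, np.zeros((4, 4)), k=1, beta=0.5)


def test_component_correlations_match_direct_pearson():
    data = random_standardized(60, 5, seed=10)
    model = fit_glpca(data, path_laplacian(5), k=2, beta=0.3)
    table = component_correlations(model, data)
    for _, row in table.iterrows():
        j = list(data.columns).index(row["measure"])
        expected = np.corrcoef(data.X[:, j], model.U[:, int(row["component"]) - 1])[0, 1]
        assert row["r"] == pytest.approx(expected, abs=1e-12)


def test_rank_one_noiseless_data_has_unit_correlations():
    rng = np.random.default_rng(11)
    scores = rng.normal(size=30)
    loadings = np.array([1.0, -2.0, 0.5])
    df = pd.DataFrame(np.outer(scores, loadings), columns=list("abc"))
    data = standardize(df, list("abc"))
    model = fit_glpca(data, np.zeros((3, 3)), k=1, beta=0.0)
    table = component_correlations(model, data)
    assert np.allclose(table["r"].abs(), 1.0, atol=1e-10)


def test_high_loading_lobes_dominate_pc1(scheme, template_graph, cohort_with_outcome):
    """With frontal/parietal/temporal generative weights 3x the rest, those
    lobes must occupy the top |r| ranks against PC1."""
    frame, volumes, _ = cohort_with_outcome
    normalized = normalize_to_tiv(volumes, scheme)
    data = standardize(normalized, scheme.names)
    model = fit_glpca(data, laplacian(template_graph), k=1, beta=0.5)
    table = component_correlations(model, data)
    top6 = table.nsmallest(6, "abs_rank")["measure"]
    top_structures = {scheme[m].structure for m in top6}
    assert top_structures <= {"frontal", "parietal", "temporal"}


def test_destandardize_inverts_standardize(scheme, small_volume_table):
    normalized = normalize_to_tiv(small_volume_table, scheme)
    data = standardize(normalized, scheme.names)
    assert isinstance(data, StandardizedMatrix)
    pd.testing.assert_frame_equal(
        data.destandardize(), normalized[scheme.names], check_names=False
    )
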
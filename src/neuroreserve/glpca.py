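"""Graph-Laplacian principal component analysis (gLPCA).

Classical PCA of z-scored regional volumes ignores that grey-matter measures
are spatially organised and strongly left-right correlated. gLPCA adds a
Laplacian smoothness penalty on the loadings: minimise

    || X - U Q' ||_F^2  +  alpha * tr(Q' L Q),    U = X Q,  Q'Q = I_k,

which has a closed-form solution. With the mixing weight ``beta`` in [0, 1]
define the normalised composite operator

    G_beta = (1 - beta) * (I_p - X'X / lambda_data) + beta * (L / lambda_graph)

where ``lambda_data`` and ``lambda_graph`` are the largest eigenvalues of
X'X and L. The loadings Q are the eigenvectors of ``G_beta`` for its k
smallest eigenvalues; ``beta = 0`` recovers classical PCA and ``beta = 1``
uses the graph alone. The implied penalty weight is
``alpha = beta * lambda_data / ((1 - beta) * lambda_graph)``.

The first component score (PC1) is the grey-matter composite used as the
outcome of the mixed-effects interaction model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import eigh

__all__ = ["StandardizedMatrix", "GLPCAModel", "standardize", "fit_glpca", "component_correlations"]

EIGEN_TIE_TOL = 1e-10


@dataclass(frozen=True)
class StandardizedMatrix:
    """Column z-scored data with the statistics needed to invert the transform."""

    X: np.ndarray = field(repr=False)
    columns: tuple[str, ...]
    means: np.ndarray = field(repr=False)
    sds: np.ndarray = field(repr=False)
    subject_ids: tuple = field(repr=False, default=())

    def destandardize(self) -> pd.DataFrame:
        raw = self.X * self.sds + self.means
        return pd.DataFrame(raw, columns=list(self.columns))


@dataclass(frozen=True)
class GLPCAModel:
    """Fitted gLPCA: orthonormal loadings ``Q`` (p x k), scores ``U = X Q`` (n x k)."""

    beta: float
    Q: np.ndarray = field(repr=False)
    U: np.ndarray = field(repr=False)
    eigenvalues: np.ndarray = field(repr=False)
    lambda_data: float
    lambda_graph: float
    columns: tuple[str, ...]
    subject_ids: tuple = field(repr=False, default=())

    @property
    def k(self) -> int:
        return self.Q.shape[1]

    def scores_frame(self) -> pd.DataFrame:
        cols = {f"pc{i + 1}": self.U[:, i] for i in range(self.k)}
        df = pd.DataFrame(cols)
        if self.subject_ids:
            df.insert(0, "subject_id", list(self.subject_ids))
        return df

    def to_dict(self) -> dict:
        return {
            "beta": self.beta,
            "lambda_data": self.lambda_data,
            "lambda_graph": self.lambda_graph,
            "eigenvalues": [float(v) for v in self.eigenvalues],
            "loadings": {
                name: [float(v) for v in self.Q[j]] for j, name in enumerate(self.columns)
            },
        }


def standardize(normalized: pd.DataFrame, columns: list[str]) -> StandardizedMatrix:
    """z-score each measure column (ddof=1); errors on constant columns."""
    if len(normalized) < 2:
        raise ValueError("standardization needs at least 2 subjects")
    X = normalized[columns].to_numpy(dtype=float)
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    constant = [c for c, s in zip(columns, sds) if s == 0]
    if constant:
        raise ValueError(f"constant measure column(s): {', '.join(constant)}")
    ids = tuple(normalized["subject_id"]) if "subject_id" in normalized.columns else ()
    return StandardizedMatrix((X - means) / sds, tuple(columns), means, sds, ids)


def _orient_sign(Q: np.ndarray) -> np.ndarray:
    """Flip each column so its coefficient sum is >= 0 (first nonzero entry
    positive on an exact tie), making larger PC1 read as more grey matter."""
    Q = Q.copy()
    for j in range(Q.shape[1]):
        s = Q[:, j].sum()
        if s < 0:
            Q[:, j] = -Q[:, j]
        elif s == 0:
            nz = np.nonzero(Q[:, j])[0]
            if nz.size and Q[nz[0], j] < 0:
                Q[:, j] = -Q[:, j]
    return Q


def fit_glpca(data: StandardizedMatrix, L: np.ndarray, k: int = 1, beta: float = 0.5) -> GLPCAModel:
    """Closed-form gLPCA fit.

    Parameters
    ----------
    data
        Standardized n x p matrix.
    L
        p x p symmetric positive semi-definite graph Laplacian.
    k
        Number of components, ``1 <= k < p``.
    beta
        Graph mixing weight in [0, 1].
    """
    X = data.X
    p = X.shape[1]
    if not 0 <= beta <= 1:
        raise ValueError(f"beta must be in [0, 1], got {beta}")
    if not 1 <= k < p:
        raise ValueError(f"k must satisfy 1 <= k < p={p}, got {k}")
    L = np.asarray(L, dtype=float)
    if L.shape != (p, p):
        raise ValueError(f"Laplacian shape {L.shape} does not match p={p}")
    if not np.allclose(L, L.T):
        raise ValueError("Laplacian must be symmetric")

    XtX = X.T @ X
    lambda_data = float(eigh(XtX, eigvals_only=True, subset_by_index=[p - 1, p - 1])[0])
    lambda_graph = float(eigh(L, eigvals_only=True, subset_by_index=[p - 1, p - 1])[0])
    if beta > 0 and lambda_graph <= 0:
        raise ValueError("empty graph (lambda_graph = 0): beta > 0 is undefined")

    G = (1 - beta) * (np.eye(p) - XtX / lambda_data)
    if beta > 0:
        G = G + beta * (L / lambda_graph)
    eigenvalues, vectors = eigh(G)  # ascending, deterministic
    if eigenvalues[k] - eigenvalues[k - 1] < EIGEN_TIE_TOL:
        warnings.warn(
            f"eigenvalue tie at component cut k={k}; keeping deterministic index order",
            RuntimeWarning,
            stacklevel=2,
        )
    Q = _orient_sign(vectors[:, :k])
    return GLPCAModel(
        beta=float(beta),
        Q=Q,
        U=X @ Q,
        eigenvalues=eigenvalues[:k],
        lambda_data=lambda_data,
        lambda_graph=lambda_graph,
        columns=data.columns,
        subject_ids=data.subject_ids,
    )


def component_correlations(model: GLPCAModel, data: StandardizedMatrix) -> pd.DataFrame:
    """Pearson correlation of every measure with every component score.

    Returns a tidy frame (measure, component, r, abs_rank) where ``abs_rank``
    ranks measures by |r| within each component (1 = strongest). Components
    with zero score variance yield missing correlations.
    """
    rows = []
    for comp in range(model.k):
        u = model.U[:, comp]
        su = u.std(ddof=1)
        for j, name in enumerate(model.columns):
            x = data.X[:, j]
            if su == 0 or x.std(ddof=1) == 0:
                r = np.nan
            else:
                r = float(np.corrcoef(x, u)[0, 1])
            rows.append({"measure": name, "component": comp + 1, "r": r})
    out = pd.DataFrame(rows)
    out["abs_rank"] = (
        out.assign(abs_r=out["r"].abs())
        .groupby("component")["abs_r"]
        .rank(ascending=False, method="first")
        .astype("Int64")
    )
    return out
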
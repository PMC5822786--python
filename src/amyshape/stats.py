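"""Vertex-wise and cluster-level statistics for radial shape analysis.

Implements the full inferential battery: a per-point ordinary least squares
GLM of radius on a behavioural score with age and eTIV covariates,
Benjamini-Hochberg FDR over the surface, cluster-extent filtering on the
spherical adjacency of the sampling directions, cluster-level regression on
adjusted mean radii, volume regressions, Pearson correlations with pairwise
deletion, the Mann-Whitney U test, and the balanced baseline/follow-up
random-intercept comparison (equivalent to, and computed as, the paired t).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import sparse, stats as sps
from scipy.spatial import ConvexHull
from statsmodels.stats.multitest import multipletests

__all__ = [
    "VertexStats",
    "ClusterResult",
    "build_adjacency",
    "vertexwise_glm",
    "fdr_correct",
    "find_clusters",
    "cluster_adjusted_regression",
    "volume_regression",
    "pearson_matrix",
    "mann_whitney_u",
    "paired_mixed_model",
]


@dataclass
class VertexStats:
    """Per-point GLM output for one scale and hemisphere."""

    beta: np.ndarray  # mm per score unit
    t: np.ndarray
    p: np.ndarray  # two-sided
    scale: str = ""
    covariates: Tuple[str, ...] = ("age", "etiv")
    n: int = 0
    q: Optional[np.ndarray] = None  # BH-adjusted p
    significant: Optional[np.ndarray] = None
    alpha: float = 0.05

    def apply_fdr(self, alpha: float = 0.05) -> "VertexStats":
        self.q, self.significant = fdr_correct(self.p, alpha)
        self.alpha = alpha
        return self

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "direction_index": np.arange(len(self.beta)),
                "beta": self.beta,
                "t": self.t,
                "p": self.p,
            }
        )
        if self.q is not None:
            df["q"] = self.q
            df["significant"] = self.significant
        return df


@dataclass
class ClusterResult:
    """A surviving surface cluster and its cluster-level regression."""

    indices: np.ndarray
    size: int
    dominant_subregion: str = ""
    subregion_fraction: float = float("nan")
    adjusted_mean_radii: Optional[np.ndarray] = None  # per subject, mm
    beta: float = float("nan")
    t: float = float("nan")
    p: float = float("nan")


def _hull_faces(directions: np.ndarray) -> np.ndarray:
    """Triangles of the spherical Delaunay triangulation (convex hull)."""
    return ConvexHull(np.asarray(directions, dtype=float)).simplices


def build_adjacency(directions) -> sparse.csr_matrix:
    """Symmetric point adjacency from the convex hull of the unit directions."""
    d = getattr(directions, "directions", directions)
    faces = _hull_faces(d)
    rows = np.concatenate([faces[:, 0], faces[:, 1], faces[:, 2]])
    cols = np.concatenate([faces[:, 1], faces[:, 2], faces[:, 0]])
    n = len(d)
    A = sparse.csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    A = ((A + A.T) > 0).astype(np.int8)
    return A


def _design(score, age, etiv) -> np.ndarray:
    X = np.column_stack(
        [np.ones(len(score)), np.asarray(score, float),
         np.asarray(age, float), np.asarray(etiv, float)]
    )
    names = ["intercept", "score", "age", "etiv"]
    for j in range(1, X.shape[1]):
        if np.ptp(X[:, j]) == 0:
            raise ValueError(f"design matrix is rank deficient: predictor "
                             f"{names[j]!r} is constant")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient (collinear predictors)")
    return X


def _ols(X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """OLS of each column of Y on X; returns betas, t and p for column 1 of X."""
    n, k = X.shape
    if n <= k:
        raise ValueError(f"need more than {k} subjects for a {k}-predictor model")
    if np.any(np.ptp(Y, axis=0) == 0):
        raise ValueError("zero residual variance: response is constant across subjects")
    XtX_inv = np.linalg.inv(X.T @ X)
    B = XtX_inv @ X.T @ Y  # (k, m)
    resid = Y - X @ B
    dof = n - k
    sigma2 = (resid**2).sum(axis=0) / dof
    scale = max(1.0, float(np.abs(Y).max()))
    if np.any(sigma2 <= (1e-9 * scale) ** 2):
        raise ValueError("zero residual variance: response is an exact linear "
                         "function of the predictors at some point")
    se = np.sqrt(sigma2 * XtX_inv[1, 1])
    t = B[1] / se
    p = 2.0 * sps.t.sf(np.abs(t), dof)
    return B, t, p, dof


def vertexwise_glm(
    radii_matrix: np.ndarray,
    score: Sequence[float],
    age: Sequence[float],
    etiv: Sequence[float],
    scale: str = "",
) -> VertexStats:
    """Per-point Gaussian-identity GLM: radius ~ intercept + score + age + eTIV.

    ``radii_matrix`` is subjects x points (mm).  Returns the score term's
    beta, t and two-sided p at every point.
    """
    Y = np.asarray(radii_matrix, dtype=float)
    if np.any(~np.isfinite(Y)):
        raise ValueError("radii matrix contains missing values")
    X = _design(score, age, etiv)
    if len(Y) != len(X):
        raise ValueError("radii matrix and predictors disagree on subject count")
    B, t, p, _ = _ols(X, Y)
    return VertexStats(beta=B[1], t=t, p=p, scale=scale, n=len(X))


def fdr_correct(pvals: np.ndarray, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up FDR: returns (q values, rejection flags)."""
    p = np.asarray(pvals, dtype=float)
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, q, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return q, reject


def find_clusters(
    flags: np.ndarray,
    adjacency: sparse.spmatrix,
    extent_min: int = 15,
) -> List[ClusterResult]:
    """Connected components of the significant subgraph, extent-filtered.

    Components with fewer than ``extent_min`` points are eliminated; a
    component of exactly ``extent_min`` points survives.
    """
    flags = np.asarray(flags, dtype=bool)
    idx = np.flatnonzero(flags)
    if len(idx) == 0:
        return []
    sub = adjacency[np.ix_(idx, idx)]
    n_comp, labels = sparse.csgraph.connected_components(sub, directed=False)
    clusters = []
    for c in range(n_comp):
        members = idx[labels == c]
        if len(members) >= extent_min:
            clusters.append(ClusterResult(indices=members, size=len(members)))
    clusters.sort(key=lambda c: -c.size)
    return clusters


def cluster_adjusted_regression(
    cluster: ClusterResult,
    radii_matrix: np.ndarray,
    score: Sequence[float],
    age: Sequence[float],
    etiv: Sequence[float],
) -> ClusterResult:
    """Cluster-level regression of per-subject mean radius on the score.

    Fits mean_radius ~ intercept + score + age + eTIV and stores the score
    term.  The adjusted mean radius reported per subject is the grand mean
    plus the residual of mean_radius ~ age + eTIV (for effect displays).
    """
    if cluster.size == 0:
        raise ValueError("empty cluster")
    Y = np.asarray(radii_matrix, float)[:, cluster.indices].mean(axis=1)
    X = _design(score, age, etiv)
    try:
        B, t, p, _ = _ols(X, Y[:, None])
        cluster.beta = float(B[1, 0])
        cluster.t = float(t[0])
        cluster.p = float(p[0])
    except ValueError as err:
        if "exact linear" not in str(err):
            raise
        # perfect fit: the coefficient is determined, inference degenerates
        warnings.warn("cluster mean radius is an exact linear function of the "
                      "predictors")
        B = np.linalg.lstsq(X, Y[:, None], rcond=None)[0]
        cluster.beta = float(B[1, 0])
        cluster.t = float("inf")
        cluster.p = 0.0
    Xc = X[:, [0, 2, 3]]  # intercept + covariates only
    resid = Y - Xc @ np.linalg.lstsq(Xc, Y, rcond=None)[0]
    cluster.adjusted_mean_radii = Y.mean() + resid
    return cluster


def volume_regression(
    volumes: Sequence[float],
    score: Sequence[float],
    age: Sequence[float],
    etiv: Sequence[float],
) -> Tuple[float, float, float]:
    """Linear regression of structure volume (mm^3) on a score with covariates."""
    Y = np.asarray(volumes, dtype=float)
    if np.ptp(Y) == 0:
        raise ValueError("volumes have zero variance")
    X = _design(score, age, etiv)
    try:
        B, t, p, _ = _ols(X, Y[:, None])
    except ValueError as err:
        if "zero residual" in str(err):
            # exact linear fit: coefficient is determined, p degenerates to 0
            B = np.linalg.lstsq(X, Y[:, None], rcond=None)[0]
            warnings.warn("volume is an exact linear function of the predictors")
            return float(B[1, 0]), float("inf"), 0.0
        raise
    return float(B[1, 0]), float(t[0]), float(p[0])


def pearson_matrix(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson correlations with two-sided p and per-pair n.

    Missing values are dropped pairwise.  A zero-variance column yields NaN
    against everything, with a warning.
    """
    cols = list(table.columns)
    k = len(cols)
    r = np.full((k, k), np.nan)
    p = np.full((k, k), np.nan)
    n = np.zeros((k, k), dtype=int)
    for i in range(k):
        for j in range(i, k):
            xy = table[[cols[i], cols[j]]].dropna()
            n[i, j] = n[j, i] = len(xy)
            if len(xy) < 3:
                continue
            x = xy.iloc[:, 0].to_numpy(float)
            y = xy.iloc[:, 1].to_numpy(float) if i != j else x
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                warnings.warn(
                    f"zero variance in {cols[i] if np.ptp(x) == 0 else cols[j]!r}: "
                    "correlation undefined"
                )
                continue
            res = sps.pearsonr(x, y)
            r[i, j] = r[j, i] = res.statistic
            p[i, j] = p[j, i] = res.pvalue
    as_df = lambda a: pd.DataFrame(a, index=cols, columns=cols)
    return as_df(r), as_df(p), as_df(n)


def mann_whitney_u(
    group_a: Sequence[float], group_b: Sequence[float]
) -> Tuple[float, float]:
    """Mann-Whitney U with midrank ties.

    Exact two-sided p by enumeration when n_a + n_b <= 20 with no ties,
    otherwise the normal approximation with tie and continuity corrections.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(pooled) <= 20 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def paired_mixed_model(
    baseline: Sequence[float], followup: Sequence[float]
) -> Tuple[float, float, float]:
    """Baseline vs follow-up period effect from a random-intercept model.

    On complete balanced pairs with one two-level fixed factor, the
    random-intercept mixed model's period inference coincides with the paired
    t-test, which is what is computed: effect = mean(followup - baseline),
    t and two-sided p on n-1 degrees of freedom.
    """
    x = np.asarray(baseline, dtype=float)
    y = np.asarray(followup, dtype=float)
    if len(x) != len(y):
        raise ValueError("baseline and follow-up must be paired")
    if len(x) < 2:
        raise ValueError("need at least 2 complete pairs")
    d = y - x
    effect = float(d.mean())
    sd = d.std(ddof=1)
    if sd == 0:
        warnings.warn("zero residual variance in paired comparison")
        if effect == 0:
            return 0.0, 0.0, 1.0
        return effect, float("inf"), 0.0
    t = effect / (sd / np.sqrt(len(d)))
    p = 2.0 * sps.t.sf(abs(t), len(d) - 1)
    return effect, float(t), float(p)
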
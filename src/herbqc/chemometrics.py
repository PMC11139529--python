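"""Batch discrimination: clustering, PCA composite scoring, OPLS-DA, t-tests.

The workflow mirrors the SPSS/SIMCA conventions common in herbal
quality-evaluation studies:

* hierarchical clustering with squared Euclidean distances and
  between-groups (average) linkage;
* PCA on the correlation matrix, retaining components with eigenvalue > 1,
  and a composite score per sample as the contribution-weighted mean of its
  component scores;
* OPLS-DA with one predictive component, orthogonal components added while
  the 7-fold cross-validated Q2 improves, a permutation test, and VIP;
* pooled-variance two-sample t-tests on per-group contents.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

__all__ = [
    "DataMatrix",
    "ClusterTree",
    "PCAModel",
    "OPLSModel",
    "TTestResult",
    "autoscale",
    "hcluster",
    "pca",
    "composite_score",
    "oplsda",
    "permutation_test",
    "vip",
    "ttest",
]


@dataclass
class DataMatrix:
    """Samples-by-variables matrix with row and column labels."""

    sample_ids: list[str]
    variable_names: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")
        if self.values.shape != (len(self.sample_ids), len(self.variable_names)):
            raise ValueError("label lengths do not match the value matrix")
        if np.isnan(self.values).any():
            raise ValueError("missing values are not supported")

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, id_column: str = "batch_id") -> "DataMatrix":
        if id_column in frame.columns:
            frame = frame.set_index(id_column)
        return cls(
            sample_ids=[str(i) for i in frame.index],
            variable_names=[str(c) for c in frame.columns],
            values=frame.to_numpy(dtype=float),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.sample_ids, columns=self.variable_names
        )

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_variables(self) -> int:
        return self.values.shape[1]


def autoscale(m: DataMatrix) -> DataMatrix:
    """Center each column to mean 0 and scale to unit sample SD (n-1)."""
    sd = m.values.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = [v for v, s in zip(m.variable_names, sd) if s == 0]
        raise ValueError(f"constant columns cannot be autoscaled: {bad}")
    scaled = (m.values - m.values.mean(axis=0)) / sd
    return DataMatrix(list(m.sample_ids), list(m.variable_names), scaled)


@dataclass
class ClusterTree:
    """Agglomerative merge history with a cut-to-k-groups accessor."""

    linkage: np.ndarray  # scipy linkage matrix
    sample_ids: list[str]

    def cut(self, k: int) -> dict[str, int]:
        """Group label (1..k) per sample at the k-cluster cut."""
        if not 1 <= k <= len(self.sample_ids):
            raise ValueError("k out of range")
        labels = hierarchy.fcluster(self.linkage, t=k, criterion="maxclust")
        return dict(zip(self.sample_ids, (int(l) for l in labels)))

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def merge_history(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.linkage,
            columns=["cluster_a", "cluster_b", "height", "size"],
        )


def hcluster(m: DataMatrix) -> ClusterTree:
    """Average ("between-groups") linkage on squared Euclidean distances."""
    if m.n_samples < 2:
        raise ValueError("clustering needs at least two samples")
    dists = pdist(m.values, metric="sqeuclidean")
    linkage = hierarchy.linkage(dists, method="average")
    return ClusterTree(linkage=linkage, sample_ids=list(m.sample_ids))


@dataclass
class PCAModel:
    """Correlation-matrix PCA with composite quality scoring.

    ``eigenvalues`` covers all (non-degenerate) components; loadings,
    score coefficients, scores, composite scores and ranks cover only the
    retained components (eigenvalue > 1).
    """

    variable_names: list[str]
    sample_ids: list[str]
    eigenvalues: np.ndarray
    contribution_pct: np.ndarray
    cumulative_pct: np.ndarray
    retained: int
    loadings: np.ndarray  # variables x retained
    score_coefficients: np.ndarray  # variables x retained
    scores: np.ndarray  # samples x retained
    composite_scores: np.ndarray
    ranks: np.ndarray

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "eigenvalue": self.eigenvalues,
                "contribution_pct": self.contribution_pct,
                "cumulative_pct": self.cumulative_pct,
            },
            index=pd.Index(
                range(1, len(self.eigenvalues) + 1), name="component"
            ),
        )

    def score_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            self.scores,
            index=self.sample_ids,
            columns=[f"PC{i + 1}" for i in range(self.retained)],
        )
        frame["composite_score"] = self.composite_scores
        frame["rank"] = self.ranks
        return frame


def pca(m: DataMatrix) -> PCAModel:
    """Eigendecomposition of the correlation matrix of ``m``.

    Loadings are eigenvectors scaled by sqrt(eigenvalue); score
    coefficients are loadings divided by the eigenvalue; scores are the
    autoscaled data projected through the coefficients.  Component signs
    are fixed so the largest-magnitude loading of each component is
    positive.  Eigenvalues numerically at zero (rank deficiency) are
    dropped.
    """
    if m.n_samples < 3 or m.n_variables < 2:
        raise ValueError("PCA needs at least 3 samples and 2 variables")
    z = autoscale(m)
    corr = np.corrcoef(m.values, rowvar=False)
    eigvals, eigvecs = np.linalg.eigh(corr)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    keep = eigvals > 1e-10
    eigvals, eigvecs = eigvals[keep], eigvecs[:, keep]
    p = m.n_variables
    contribution = 100.0 * eigvals / p
    retained = max(int(np.sum(eigvals > 1.0)), 1)
    lam = eigvals[:retained]
    vecs = eigvecs[:, :retained]
    loadings = vecs * np.sqrt(lam)
    # sign convention: dominant loading of each component positive
    flips = np.sign(loadings[np.abs(loadings).argmax(axis=0), np.arange(retained)])
    flips[flips == 0] = 1.0
    loadings = loadings * flips
    coeffs = loadings / lam
    scores = z.values @ coeffs
    composite, ranks = composite_score(scores, contribution[:retained])
    return PCAModel(
        variable_names=list(m.variable_names),
        sample_ids=list(m.sample_ids),
        eigenvalues=eigvals,
        contribution_pct=contribution,
        cumulative_pct=np.cumsum(contribution),
        retained=retained,
        loadings=loadings,
        score_coefficients=coeffs,
        scores=scores,
        composite_scores=composite,
        ranks=ranks,
    )


def composite_score(
    scores: np.ndarray | Sequence[Sequence[float]],
    contributions: Sequence[float],
) -> tuple[np.ndarray, np.ndarray]:
    """Contribution-weighted mean of component scores, with descending ranks.

    F = sum_i(w_i * t_i) / sum_i(w_i).  Ties receive the average rank.
    """
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    weights = np.asarray(contributions, dtype=float)
    if np.any(weights <= 0):
        raise ValueError("contributions must be positive")
    if scores.shape[1] != weights.size:
        raise ValueError("scores and contributions disagree on component count")
    composite = scores @ weights / weights.sum()
    ranks = stats.rankdata(-composite, method="average")
    return composite, ranks


@dataclass
class OPLSModel:
    """One-predictive-component OPLS-DA fit."""

    variable_names: list[str]
    sample_ids: list[str]
    weights: np.ndarray  # predictive weight vector w (unit norm)
    scores_pred: np.ndarray  # predictive scores t
    loadings_pred: np.ndarray  # predictive loadings p
    c: float  # y-loading
    ortho_weights: np.ndarray  # n_ortho x p
    ortho_scores: np.ndarray  # n x n_ortho
    ortho_loadings: np.ndarray  # n_ortho x p
    r2x: float
    r2y: float
    q2: float
    y: np.ndarray  # centered class code used in the fit
    y_mean: float
    n_ortho: int
    cv_folds: int
    cv_seed: int

    def predict(self, x_new: np.ndarray) -> np.ndarray:
        """Predicted (centered-code scale) response for autoscaled rows."""
        x = np.atleast_2d(np.asarray(x_new, dtype=float)).copy()
        for i in range(self.n_ortho):
            t_o = x @ self.ortho_weights[i]
            x -= np.outer(t_o, self.ortho_loadings[i])
        return (x @ self.weights) * self.c

    def predict_class(self, x_new: np.ndarray) -> np.ndarray:
        """Class label (+1/-1) from the sign of the decentered prediction."""
        return np.where(self.predict(x_new) + self.y_mean >= 0, 1, -1)


def _code_labels(groups: Sequence) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(groups)
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError("OPLS-DA needs exactly two classes")
    coded = np.where(labels == classes[0], -1.0, 1.0)
    return coded, classes


def _opls_fit_raw(
    x: np.ndarray, y: np.ndarray, n_ortho: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float, list, list, list]:
    """Trygg-Wold orthogonal signal correction with a single predictive LV."""
    w = x.T @ y
    norm = np.linalg.norm(w)
    if norm == 0:
        raise ValueError("response carries no covariance with the data")
    w = w / norm
    xd = x.copy()
    w_os, t_os, p_os = [], [], []
    for _ in range(n_ortho):
        t = xd @ w
        p = xd.T @ t / (t @ t)
        w_o = p - (w @ p) * w
        n_o = np.linalg.norm(w_o)
        if n_o < 1e-12:
            break
        w_o /= n_o
        t_o = xd @ w_o
        p_o = xd.T @ t_o / (t_o @ t_o)
        xd = xd - np.outer(t_o, p_o)
        w_os.append(w_o)
        t_os.append(t_o)
        p_os.append(p_o)
    t = xd @ w
    p = xd.T @ t / (t @ t)
    c = float(y @ t / (t @ t))
    return w, t, p, c, w_os, t_os, p_os


def _cv_folds(n: int, n_folds: int, seed: int) -> list[np.ndarray]:
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    return [order[i::n_folds] for i in range(n_folds)]


def _predict_raw(
    x: np.ndarray, w: np.ndarray, c: float, w_os: list, p_os: list
) -> np.ndarray:
    xd = np.atleast_2d(x).copy()
    for w_o, p_o in zip(w_os, p_os):
        t_o = xd @ w_o
        xd -= np.outer(t_o, p_o)
    return (xd @ w) * c


def _q2(x: np.ndarray, y: np.ndarray, n_ortho: int, n_folds: int, seed: int) -> float:
    n = len(y)
    folds = [f for f in _cv_folds(n, min(n_folds, n), seed) if f.size]
    press = 0.0
    for fold in folds:
        train = np.setdiff1d(np.arange(n), fold)
        w, _, _, c, w_os, _, p_os = _opls_fit_raw(x[train], y[train], n_ortho)
        pred = _predict_raw(x[fold], w, c, w_os, p_os)
        press += float(np.sum((y[fold] - pred) ** 2))
    return 1.0 - press / float(y @ y)


def oplsda(
    m: DataMatrix,
    groups: Sequence,
    n_folds: int = 7,
    seed: int = 1,
    max_ortho: int = 5,
    q2_tol: float = 0.01,
) -> OPLSModel:
    """Fit an OPLS-DA model discriminating two groups.

    The class vector is coded +/-1 and centered; X must already be
    autoscaled.  Orthogonal components are added one at a time while the
    cross-validated Q2 improves by more than ``q2_tol`` (at most
    ``max_ortho``); Q2 uses ``n_folds``-fold cross-validation with folds
    assigned by a seeded shuffle of the sample order.
    """
    x = np.asarray(m.values, dtype=float)
    coded, _ = _code_labels(groups)
    if len(coded) != m.n_samples:
        raise ValueError("group labels do not match the sample count")
    y_mean = float(coded.mean())
    y = coded - y_mean
    best_n = 0
    best_q2 = _q2(x, y, 0, n_folds, seed)
    for n_o in range(1, max_ortho + 1):
        q2_candidate = _q2(x, y, n_o, n_folds, seed)
        if q2_candidate > best_q2 + q2_tol:
            best_q2, best_n = q2_candidate, n_o
        else:
            break
    w, t, p, c, w_os, t_os, p_os = _opls_fit_raw(x, y, best_n)
    ss_x = float(np.sum(x**2))
    explained = float(np.sum(np.outer(t, p) ** 2))
    for t_o, p_o in zip(t_os, p_os):
        explained += float(np.sum(np.outer(t_o, p_o) ** 2))
    resid_y = y - t * c
    return OPLSModel(
        variable_names=list(m.variable_names),
        sample_ids=list(m.sample_ids),
        weights=w,
        scores_pred=t,
        loadings_pred=p,
        c=c,
        ortho_weights=np.array(w_os) if w_os else np.empty((0, x.shape[1])),
        ortho_scores=np.column_stack(t_os) if t_os else np.empty((len(y), 0)),
        ortho_loadings=np.array(p_os) if p_os else np.empty((0, x.shape[1])),
        r2x=explained / ss_x,
        r2y=1.0 - float(resid_y @ resid_y) / float(y @ y),
        q2=best_q2,
        y=y,
        y_mean=y_mean,
        n_ortho=best_n,
        cv_folds=n_folds,
        cv_seed=seed,
    )


def permutation_test(
    m: DataMatrix,
    groups: Sequence,
    n_perm: int = 200,
    seed: int = 1,
    n_folds: int = 7,
) -> dict:
    """Label-permutation validation of an OPLS-DA model.

    Refits the model for ``n_perm`` permuted class vectors, recording the
    absolute correlation of each permuted vector with the original, R2Y and
    Q2.  Intercepts are the values at correlation 0 of least-squares lines
    through the permuted points plus the original model at correlation 1.
    """
    if n_perm < 20:
        raise ValueError("need at least 20 permutations")
    model = oplsda(m, groups, n_folds=n_folds, seed=seed)
    x = np.asarray(m.values, dtype=float)
    coded, _ = _code_labels(groups)
    y0 = coded - coded.mean()
    rng = np.random.default_rng(seed)
    corrs, r2ys, q2s = [1.0], [model.r2y], [model.q2]
    for _ in range(n_perm):
        perm = rng.permutation(len(coded))
        yp_coded = coded[perm]
        yp = yp_coded - yp_coded.mean()
        denom = np.linalg.norm(yp) * np.linalg.norm(y0)
        corrs.append(abs(float(yp @ y0)) / denom if denom else 0.0)
        _, t, _, c, _, _, _ = _opls_fit_raw(x, yp, model.n_ortho)
        resid = yp - t * c
        r2ys.append(1.0 - float(resid @ resid) / float(yp @ yp))
        q2s.append(_q2(x, yp, model.n_ortho, n_folds, seed))
    corrs_arr = np.asarray(corrs)
    r2_line = np.polyfit(corrs_arr, np.asarray(r2ys), 1)
    q2_line = np.polyfit(corrs_arr, np.asarray(q2s), 1)
    perm_r2 = np.asarray(r2ys[1:])
    perm_q2 = np.asarray(q2s[1:])
    return {
        "r2y_intercept": float(r2_line[1]),
        "q2_intercept": float(q2_line[1]),
        "r2y_original": model.r2y,
        "q2_original": model.q2,
        "correlations": corrs_arr[1:],
        "permuted_r2y": perm_r2,
        "permuted_q2": perm_q2,
        "n_exceeding_r2y": int(np.sum(perm_r2 >= model.r2y)),
        "n_exceeding_q2": int(np.sum(perm_q2 >= model.q2)),
        "valid": bool(
            model.r2y > perm_r2.max()
            and model.q2 > perm_q2.max()
            and float(q2_line[1]) < 0
        ),
    }


def vip(model: OPLSModel) -> pd.Series:
    """Variable importance in projection over the predictive component(s).

    VIP_j = sqrt(p * sum_a(SSY_a * w_ja^2) / sum_a(SSY_a)); with a single
    predictive component this reduces to sqrt(p) * |w_j|, so the squared
    VIPs always sum to the variable count.
    """
    w = np.asarray(model.weights, dtype=float)
    p = w.size
    ssy = float(model.c**2 * (model.scores_pred @ model.scores_pred))
    values = np.sqrt(p * (ssy * w**2) / ssy)
    return pd.Series(values, index=model.variable_names, name="VIP")


@dataclass(frozen=True)
class TTestResult:
    statistic: float
    df: float
    pvalue: float


def ttest(group_a: Sequence[float], group_b: Sequence[float]) -> TTestResult:
    """Two-sample Student's t-test with pooled variance, two-sided."""
    a = np.asarray(list(group_a), dtype=float)
    b = np.asarray(list(group_b), dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two observations")
    res = stats.ttest_ind(a, b, equal_var=True)
    return TTestResult(
        statistic=float(res.statistic),
        df=float(a.size + b.size - 2),
        pvalue=float(res.pvalue),
    )
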
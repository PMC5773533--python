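"""Strain discrimination: pairwise clustering, classification, PCA ellipsoids.

Three complementary views of how separable strains are in feature space:

* **Pairwise clustering** — unsupervised K-means (K = 2) on mouse-day
  vectors of two strains, scored by a symmetric clustering accuracy score
  ``S`` (0.5 ~ chance, 1 = perfect separation).
* **Full strain classification** — one-vs-rest L2-regularised logistic
  regression over all strains, cross-validated over per-mouse half
  splits, at the mouse-day level and at the mouse level (classifying each
  animal's held-out average vector).
* **PCA ellipsoids** — mouse-average vectors projected onto the top three
  variance-normalised principal components; each strain summarised by an
  axis-aligned ellipsoid (mean center, per-component sd semi-axes) and
  pairwise overlap estimated by Monte Carlo sampling.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.linear_model import LogisticRegression
from sklearn.multiclass import OneVsRestClassifier


# ---------------------------------------------------------------------------
# Clustering accuracy score
# ---------------------------------------------------------------------------

def clustering_score(true_labels: Sequence[int], pred_labels: Sequence[int]) -> dict[str, float]:
    """Two-group clustering accuracy score S = (S_in + S_out) / 2.

    ``S_in`` rates how well common membership is detected: within each
    true group, count the most common predicted label (I1, I2) and set
    S_in = (I1 + I2) / t.  ``S_out`` rates discriminability: within each
    predicted group, count the most common true label (O1, O2) and set
    S_out = (O1 + O2) / t.  An empty predicted group contributes 0.  The
    score is symmetric under simultaneous relabeling of the two groups
    and lies in [0, 1]; identical labelings score 1, random guessing
    approaches 0.5 for large balanced inputs.
    """
    T = np.asarray(true_labels)
    L = np.asarray(pred_labels)
    if T.shape != L.shape or T.ndim != 1:
        raise ValueError("true and predicted label vectors must have equal length")
    t = len(T)
    if t == 0:
        raise ValueError("empty label vectors")
    groups_t = np.unique(T)
    groups_l = np.unique(L)
    if len(groups_t) > 2 or len(groups_l) > 2:
        raise ValueError("clustering_score is defined for two-group labelings")

    def _most_common_count(v: np.ndarray) -> int:
        if len(v) == 0:
            return 0
        _, counts = np.unique(v, return_counts=True)
        return int(counts.max())

    s_in = sum(_most_common_count(L[T == g]) for g in (1, 2)) / t
    s_out = sum(_most_common_count(T[L == g]) for g in (1, 2)) / t
    return {"S": (s_in + s_out) / 2, "S_in": s_in, "S_out": s_out}


def _per_mouse_split(
    mouse_ids: np.ndarray, rng: np.random.Generator, train_fraction: float = 0.5
) -> np.ndarray:
    """Boolean train mask: a stratified fraction of each mouse's days."""
    train = np.zeros(len(mouse_ids), dtype=bool)
    for m in np.unique(mouse_ids):
        idx = np.flatnonzero(mouse_ids == m)
        k = max(1, int(np.floor(len(idx) * train_fraction)))
        if k >= len(idx):
            raise ValueError(f"mouse {m!r} has too few days for train_fraction={train_fraction}")
        train[rng.choice(idx, size=k, replace=False)] = True
    return train


@dataclass
class PairwiseClusterResult:
    strain_a: str
    strain_b: str
    train_mean: float
    train_sd: float
    test_mean: float
    test_sd: float


def pairwise_cluster_accuracy(
    X: np.ndarray,
    strain_labels: np.ndarray,
    mouse_ids: np.ndarray,
    trials: int = 20,
    seed: int = 0,
) -> PairwiseClusterResult:
    """Cross-validated K-means (K=2) separability of two strains.

    Per trial, half of each animal's days form the train set; K-means
    fits two centroids on the train vectors; every day (train and test)
    is assigned to its nearest centroid and scored against the true
    strain labels with :func:`clustering_score`.
    """
    X = np.asarray(X, dtype=float)
    strain_labels = np.asarray(strain_labels)
    mouse_ids = np.asarray(mouse_ids)
    strains = sorted(np.unique(strain_labels))
    if len(strains) != 2:
        raise ValueError("pairwise_cluster_accuracy needs exactly two strains")
    T = np.where(strain_labels == strains[0], 1, 2)
    rng = np.random.default_rng(seed)
    tr_scores, te_scores = [], []
    for _ in range(trials):
        train = _per_mouse_split(mouse_ids, rng)
        mu = X[train].mean(axis=0)
        sd = X[train].std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        Z = (X - mu) / sd
        km = KMeans(n_clusters=2, n_init=10, random_state=int(rng.integers(2**31 - 1)))
        km.fit(Z[train])
        L = km.predict(Z) + 1
        tr_scores.append(clustering_score(T[train], L[train])["S"])
        te_scores.append(clustering_score(T[~train], L[~train])["S"])
    return PairwiseClusterResult(
        str(strains[0]), str(strains[1]),
        float(np.mean(tr_scores)), float(np.std(tr_scores, ddof=0)),
        float(np.mean(te_scores)), float(np.std(te_scores, ddof=0)),
    )


def all_pairwise_scores(
    X: np.ndarray,
    strain_labels: np.ndarray,
    mouse_ids: np.ndarray,
    trials: int = 20,
    seed: int = 0,
) -> pd.DataFrame:
    """Clustering scores for every strain pair (120 pairs for 16 strains)."""
    strain_labels = np.asarray(strain_labels)
    mouse_ids = np.asarray(mouse_ids)
    rows = []
    for i, (a, b) in enumerate(combinations(sorted(np.unique(strain_labels)), 2)):
        sel = np.isin(strain_labels, [a, b])
        res = pairwise_cluster_accuracy(
            X[sel], strain_labels[sel], mouse_ids[sel], trials=trials, seed=seed + i
        )
        rows.append(res.__dict__)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Full strain classifier
# ---------------------------------------------------------------------------

@dataclass
class ClassifierResult:
    md_mean: float
    md_sd: float
    mouse_mean: float
    mouse_sd: float
    trials: int


def strain_classifier(
    X: np.ndarray,
    strain_labels: np.ndarray,
    mouse_ids: np.ndarray,
    train_fraction: float = 0.5,
    trials: int = 20,
    seed: int = 0,
    C: float = 1.0,
) -> ClassifierResult:
    """Cross-validated one-vs-rest logistic-regression strain classification.

    Features are standardised on train-set statistics (needed for the
    mixed-unit 99-D concatenation).  Mouse-day accuracy scores held-out
    days; mouse accuracy classifies each animal's held-out average
    vector.  ``C`` is the inverse regularisation strength.
    """
    X = np.asarray(X, dtype=float)
    strain_labels = np.asarray(strain_labels)
    mouse_ids = np.asarray(mouse_ids)
    if len(np.unique(strain_labels)) < 2:
        raise ValueError("need at least two strains")
    rng = np.random.default_rng(seed)
    md_accs, mouse_accs = [], []
    for _ in range(trials):
        train = _per_mouse_split(mouse_ids, rng, train_fraction)
        if len(np.unique(strain_labels[train])) < 2:
            raise ValueError("degenerate training fold with a single class")
        mu = X[train].mean(axis=0)
        sd = X[train].std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        Z = (X - mu) / sd
        clf = OneVsRestClassifier(
            LogisticRegression(C=C, max_iter=2000, solver="lbfgs")
        )
        clf.fit(Z[train], strain_labels[train])
        pred = clf.predict(Z[~train])
        md_accs.append(float(np.mean(pred == strain_labels[~train])))
        test_idx = np.flatnonzero(~train)
        mouse_rows, mouse_true = [], []
        for m in np.unique(mouse_ids):
            sel = test_idx[mouse_ids[test_idx] == m]
            if len(sel) == 0:
                continue
            mouse_rows.append(Z[sel].mean(axis=0))
            mouse_true.append(strain_labels[sel[0]])
        pred_m = clf.predict(np.asarray(mouse_rows))
        mouse_accs.append(float(np.mean(pred_m == np.asarray(mouse_true))))
    return ClassifierResult(
        float(np.mean(md_accs)), float(np.std(md_accs, ddof=0)),
        float(np.mean(mouse_accs)), float(np.std(mouse_accs, ddof=0)),
        trials,
    )


# ---------------------------------------------------------------------------
# PCA projection and strain ellipsoids
# ---------------------------------------------------------------------------

@dataclass
class ProjectionModel:
    """Variance-normalised PCA of mouse-average feature vectors.

    With M the column-centered data (one mouse per row), C = (1/n) M^T M,
    C = V D V^T, the projected coordinates are N = M V D^{-1/2}; every
    retained column of N has unit variance.  ``projected`` holds the first
    three columns.
    """

    mean_: np.ndarray
    eigenvectors: np.ndarray  # columns, descending eigenvalue order
    eigenvalues: np.ndarray
    projected: np.ndarray  # (n_mice, 3)
    explained_fraction: float
    kept_features: np.ndarray

    def full_projection(self, M_centered: Optional[np.ndarray] = None) -> np.ndarray:
        lam = self.eigenvalues
        if M_centered is None:
            raise ValueError("pass the centered data matrix")
        return M_centered @ self.eigenvectors @ np.diag(1.0 / np.sqrt(lam))


def pca_projection(mouse_averages: np.ndarray, n_components: int = 3) -> ProjectionModel:
    """Project mouse-average vectors onto variance-normalised components.

    Zero-variance features are dropped (with a warning) before the
    eigendecomposition; the model errors if fewer than ``n_components``
    positive eigenvalues remain.
    """
    M = np.asarray(mouse_averages, dtype=float)
    if M.ndim != 2 or M.shape[0] < 4:
        raise ValueError("need at least 4 mice")
    var = M.var(axis=0)
    kept = np.flatnonzero(var > 0)
    if len(kept) < M.shape[1]:
        import warnings

        warnings.warn(f"dropping {M.shape[1] - len(kept)} zero-variance feature(s)")
    if len(kept) < n_components:
        raise ValueError("not enough varying features")
    M = M[:, kept]
    mean = M.mean(axis=0)
    Mc = M - mean
    n = Mc.shape[0]
    C = (Mc.T @ Mc) / n
    lam, V = np.linalg.eigh(C)
    order = np.argsort(lam)[::-1]
    lam, V = lam[order], V[:, order]
    if lam[n_components - 1] <= 1e-12 * max(lam[0], 1e-300):
        raise ValueError("covariance rank below the requested number of components")
    pos = lam > 1e-12 * lam[0]
    lam, V = lam[pos], V[:, pos]
    N = Mc @ V @ np.diag(1.0 / np.sqrt(lam))
    return ProjectionModel(
        mean_=mean,
        eigenvectors=V,
        eigenvalues=lam,
        projected=N[:, :n_components],
        explained_fraction=float(lam[:n_components].sum() / np.trace(C)),
        kept_features=kept,
    )


@dataclass(frozen=True)
class StrainEllipsoid:
    """Axis-aligned 3-D summary of a strain in projected coordinates."""

    label: str
    center: tuple[float, float, float]
    semi_axes: tuple[float, float, float]

    def __post_init__(self) -> None:
        if any(a <= 0 for a in self.semi_axes):
            raise ValueError(f"strain {self.label!r}: semi-axes must be positive")

    @property
    def volume(self) -> float:
        return 4.0 / 3.0 * np.pi * float(np.prod(self.semi_axes))

    def contains(self, points: np.ndarray) -> np.ndarray:
        z = (np.asarray(points, float) - np.asarray(self.center)) / np.asarray(self.semi_axes)
        return np.sum(z**2, axis=-1) <= 1.0


def strain_ellipsoids(
    model: ProjectionModel, strain_labels: Sequence[str]
) -> list[StrainEllipsoid]:
    """Per-strain mean center and per-component sd semi-axes."""
    labels = np.asarray(strain_labels)
    if len(labels) != model.projected.shape[0]:
        raise ValueError("labels not aligned with projected rows")
    out = []
    for st in sorted(np.unique(labels)):
        pts = model.projected[labels == st]
        if len(pts) < 2:
            raise ValueError(f"strain {st!r} has fewer than 2 mice")
        out.append(
            StrainEllipsoid(
                str(st),
                tuple(pts.mean(axis=0)),
                tuple(pts.std(axis=0, ddof=0)),
            )
        )
    return out


def ellipsoid_overlap(
    e1: StrainEllipsoid,
    e2: StrainEllipsoid,
    n_points: int = 10000,
    seed: int = 0,
) -> float:
    """Monte Carlo overlap: fraction of the smaller ellipsoid inside the larger.

    Points are sampled uniformly in the smaller ellipsoid's bounding box;
    the overlap is (#points in both) / (#points in the smaller).  Volume
    ties are broken lexicographically by label.  If no sampled point
    lands inside the smaller ellipsoid (vanishingly unlikely for an
    axis-aligned box), sampling is repeated with a larger n.
    """
    va, vb = np.prod(e1.semi_axes), np.prod(e2.semi_axes)
    if va > vb or (va == vb and e1.label <= e2.label):
        big, small = e1, e2
    else:
        big, small = e2, e1
    rng = np.random.default_rng(seed)
    n = int(n_points)
    for _ in range(6):
        lo = np.asarray(small.center) - np.asarray(small.semi_axes)
        hi = np.asarray(small.center) + np.asarray(small.semi_axes)
        pts = rng.uniform(lo, hi, size=(n, 3))
        in_small = small.contains(pts)
        hits = int(in_small.sum())
        if hits > 0:
            in_both = int((in_small & big.contains(pts)).sum())
            return in_both / hits
        n *= 4
    raise RuntimeError("no Monte Carlo point landed inside the smaller ellipsoid")


def overlap_matrix(
    ellipsoids: Sequence[StrainEllipsoid], n_points: int = 10000, seed: int = 0
) -> pd.DataFrame:
    """Symmetric table of pairwise overlap numbers."""
    labels = [e.label for e in ellipsoids]
    out = pd.DataFrame(np.eye(len(labels)), index=labels, columns=labels)
    for i, j in combinations(range(len(labels)), 2):
        ov = ellipsoid_overlap(ellipsoids[i], ellipsoids[j], n_points, seed + 31 * i + j)
        out.iloc[i, j] = out.iloc[j, i] = ov
    return out
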
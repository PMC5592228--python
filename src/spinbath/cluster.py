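"""Patient stratification: Gustafson-Kessel fuzzy clustering with PCA view.

Gustafson-Kessel (GK) clustering generalizes fuzzy c-means by giving every
cluster its own determinant-constrained covariance norm, so clusters may be
hyperellipsoids of different orientation and elongation.  Clustering runs
in the full standardized feature space; a two-component PCA then provides
the planar representation and the factor loadings used to read off which
features drive the separation.  Clusters are finally ranked by the mean
disease burden of their members.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.decomposition import PCA

from .features import FeatureMatrix

__all__ = [
    "GustafsonKessel",
    "hard_assign",
    "pca_2d",
    "PCAResult",
    "factor_loading_table",
    "cluster_db_report",
    "ClusterReport",
]


def _as_array(X) -> np.ndarray:
    if isinstance(X, FeatureMatrix):
        return X.values
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D (subjects x features)")
    if not np.all(np.isfinite(X)):
        raise ValueError("X contains non-finite values")
    return X


class GustafsonKessel(ClusterMixin, BaseEstimator):
    """Fuzzy clustering with per-cluster adaptive Mahalanobis norms.

    Alternating optimization of the fuzzy objective
    ``J = sum_ik u_ik^m d2_ik`` where ``d2_ik = (x_k - v_i)' A_i (x_k - v_i)``
    and ``A_i = (rho det(S_i))^(1/p) S_i^{-1}`` with the fuzzy covariance
    ``S_i`` and volume constraint ``rho = 1``.  With ``norm="identity"`` the
    algorithm reduces exactly to fuzzy c-means.

    Parameters
    ----------
    n_clusters:
        Number of clusters ``c``; clusters may come out empty under hard
        assignment and are reported, not pruned.
    fuzzifier:
        Membership softness exponent ``m`` (> 1); 2 is the community default.
    tol:
        Convergence threshold on the maximum membership change.
    max_iter:
        Iteration cap per restart.
    n_init:
        Random restarts; the run with the lowest final objective is kept.
    norm:
        ``"adaptive"`` (GK) or ``"identity"`` (fuzzy c-means reduction).
    cov_blend:
        Shrinkage of each fuzzy covariance toward the global data
        covariance, ``S_i <- (1-g) S_i + g S_data`` (as in regularized
        discriminant analysis).  The pure determinant-constrained norm
        (``cov_blend=0``) makes every cluster unit-volume in its own
        metric, so a compact group gains nothing from staying together and
        gets fragmented when ``c`` exceeds the true structure; shrinking
        toward the data covariance anchors cluster volume at the data
        scale while preserving anisotropy shared with the data.
    eig_floor:
        Covariance eigenvalues are floored at ``max_eig * eig_floor`` before
        inversion (small-n conditioning).
    ridge:
        Ridge added to the fuzzy covariance before eigendecomposition.
    random_state:
        Seed of the restart stream.

    Attributes
    ----------
    cluster_centers_ : (c, p) array
    covariances_ : (c, p, p) conditioned fuzzy covariances
    norm_matrices_ : (c, p, p) norm-inducing matrices ``A_i``
    memberships_ : (n, c) fuzzy partition; rows sum to 1
    labels_ : hard assignment (argmax membership, ties to lowest index)
    empty_clusters_ : clusters with no hard members
    objective_trace_ : per-iteration objective of the winning restart
    objective_ : final objective value
    n_iter_ : iterations of the winning restart
    """

    def __init__(
        self,
        n_clusters: int = 6,
        fuzzifier: float = 2.0,
        tol: float = 1e-6,
        max_iter: int = 500,
        n_init: int = 16,
        norm: str = "adaptive",
        cov_blend: float = 0.5,
        eig_floor: float = 1e-5,
        ridge: float = 1e-9,
        random_state: int | None = None,
    ):
        self.n_clusters = n_clusters
        self.fuzzifier = fuzzifier
        self.tol = tol
        self.max_iter = max_iter
        self.n_init = n_init
        self.norm = norm
        self.cov_blend = cov_blend
        self.eig_floor = eig_floor
        self.ridge = ridge
        self.random_state = random_state

    # -- internals ---------------------------------------------------------

    def _check_params(self, X: np.ndarray) -> None:
        n = X.shape[0]
        if not self.n_clusters >= 1:
            raise ValueError("n_clusters must be >= 1")
        if n < self.n_clusters:
            raise ValueError(f"n_clusters={self.n_clusters} exceeds n_samples={n}")
        if not self.fuzzifier > 1:
            raise ValueError("fuzzifier must exceed 1")
        if self.norm not in ("adaptive", "identity"):
            raise ValueError("norm must be 'adaptive' or 'identity'")
        if not 0.0 <= self.cov_blend <= 1.0:
            raise ValueError("cov_blend must be in [0, 1]")

    def _norm_matrices(self, X, centers, um, data_cov):
        c, p = centers.shape
        a_mats = np.empty((c, p, p))
        covs = np.empty((c, p, p))
        eye = np.eye(p)
        for i in range(c):
            if self.norm == "identity":
                covs[i] = eye
                a_mats[i] = eye
                continue
            diff = X - centers[i]
            w = um[:, i]
            cov = (diff * w[:, None]).T @ diff / w.sum()
            if self.cov_blend > 0.0:
                cov = (1.0 - self.cov_blend) * cov + self.cov_blend * data_cov
            cov = cov + self.ridge * eye
            evals, evecs = np.linalg.eigh(cov)
            evals = np.maximum(evals, evals[-1] * self.eig_floor)
            covs[i] = (evecs * evals) @ evecs.T
            # volume-normalized inverse: A = (det S)^(1/p) S^-1
            det_root = float(np.exp(np.mean(np.log(evals))))
            a_mats[i] = det_root * ((evecs / evals) @ evecs.T)
        return covs, a_mats

    @staticmethod
    def _distances(X, centers, a_mats):
        c = centers.shape[0]
        d2 = np.empty((X.shape[0], c))
        for i in range(c):
            diff = X - centers[i]
            d2[:, i] = np.einsum("nj,jk,nk->n", diff, a_mats[i], diff)
        return np.maximum(d2, 0.0)

    def _memberships(self, d2: np.ndarray) -> np.ndarray:
        n, c = d2.shape
        u = np.zeros((n, c))
        zero = d2 <= 0.0
        any_zero = zero.any(axis=1)
        if any_zero.any():
            rows = np.where(any_zero)[0]
            u[rows] = zero[rows] / zero[rows].sum(axis=1, keepdims=True)
        ok = ~any_zero
        if ok.any():
            expo = -1.0 / (self.fuzzifier - 1.0)
            w = d2[ok] ** expo
            u[ok] = w / w.sum(axis=1, keepdims=True)
        return u

    def _single_run(self, X: np.ndarray, rng: np.random.Generator):
        n, p = X.shape
        c, m = self.n_clusters, self.fuzzifier
        u = rng.random((n, c)) + 1e-3
        u /= u.sum(axis=1, keepdims=True)
        if self.norm == "adaptive" and self.cov_blend > 0.0:
            data_cov = np.atleast_2d(np.cov(X, rowvar=False)) + self.ridge * np.eye(p)
        else:
            data_cov = np.eye(p)
        trace: list[float] = []
        for it in range(1, self.max_iter + 1):
            um = u**m
            centers = (um.T @ X) / um.sum(axis=0)[:, None]
            covs, a_mats = self._norm_matrices(X, centers, um, data_cov)
            d2 = self._distances(X, centers, a_mats)
            u_new = self._memberships(d2)
            trace.append(float(np.sum(u_new**m * d2)))
            delta = float(np.max(np.abs(u_new - u)))
            u = u_new
            if delta < self.tol:
                break
        return {
            "memberships": u, "centers": centers, "covariances": covs,
            "norm_matrices": a_mats, "trace": trace, "n_iter": it,
        }

    # -- sklearn API -------------------------------------------------------

    def fit(self, X, y=None):
        X = _as_array(X)
        self._check_params(X)
        root = np.random.default_rng(self.random_state)
        seeds = root.integers(0, 2**31 - 1, size=self.n_init)
        best = None
        for s in seeds:
            run = self._single_run(X, np.random.default_rng(int(s)))
            if best is None or run["trace"][-1] < best["trace"][-1]:
                best = run
        self.cluster_centers_ = best["centers"]
        self.covariances_ = best["covariances"]
        self.norm_matrices_ = best["norm_matrices"]
        self.memberships_ = best["memberships"]
        self.objective_trace_ = tuple(best["trace"])
        self.objective_ = best["trace"][-1]
        self.n_iter_ = best["n_iter"]
        self.labels_, self.empty_clusters_ = hard_assign(self.memberships_)
        self.n_features_in_ = X.shape[1]
        return self

    def soft_predict(self, X) -> np.ndarray:
        """Membership matrix of new points under the fitted norms."""
        X = _as_array(X)
        d2 = self._distances(X, self.cluster_centers_, self.norm_matrices_)
        return self._memberships(d2)

    def predict(self, X) -> np.ndarray:
        labels, _ = hard_assign(self.soft_predict(X))
        return labels

    def fit_predict(self, X, y=None) -> np.ndarray:
        return self.fit(X).labels_


def hard_assign(memberships: np.ndarray) -> tuple[np.ndarray, list[int]]:
    """Argmax hard assignment; ties break to the lowest cluster index.

    Returns the label vector and the list of clusters that received no
    members (reported, not dropped).
    """
    memberships = np.asarray(memberships, dtype=float)
    labels = np.argmax(memberships, axis=1)
    c = memberships.shape[1]
    empty = [i for i in range(c) if not np.any(labels == i)]
    return labels, empty


@dataclass(frozen=True)
class PCAResult:
    """Top-two principal components of the (standardized) feature matrix."""

    loadings: np.ndarray  # (2, p) orthonormal rows
    scores: np.ndarray  # (n, 2)
    explained_variance_ratio: tuple[float, float]
    full_spectrum: tuple[float, ...]  # all eigenvalues, nonincreasing
    feature_names: tuple[str, ...] | None = None


def pca_2d(X) -> PCAResult:
    """Two-component PCA of the sample covariance.

    Sign convention: in each component the largest-magnitude loading entry
    is made positive, so projections are reproducible across runs.
    """
    names = tuple(X.data.columns) if isinstance(X, FeatureMatrix) else None
    X = _as_array(X)
    n, p = X.shape
    if n < 3 or p < 2:
        raise ValueError("PCA requires at least 3 samples and 2 features")
    if np.allclose(X, X[0]):
        raise ValueError("rank-0 data: all samples identical")
    pca = PCA(n_components=min(n, p), svd_solver="full")
    scores = pca.fit_transform(X)[:, :2]
    loadings = pca.components_[:2].copy()
    for k in range(2):
        j = int(np.argmax(np.abs(loadings[k])))
        if loadings[k, j] < 0:
            loadings[k] *= -1.0
            scores[:, k] *= -1.0
    ratio = pca.explained_variance_ratio_
    return PCAResult(
        loadings=loadings,
        scores=scores,
        explained_variance_ratio=(float(ratio[0]), float(ratio[1]) if len(ratio) > 1 else 0.0),
        full_spectrum=tuple(float(v) for v in pca.explained_variance_),
        feature_names=names,
    )


def factor_loading_table(pca: PCAResult, feature_names: Sequence[str]) -> pd.DataFrame:
    """Per-feature loadings and squared-loading shares on components 1 and 2.

    Shares sum to 1 within each component (loadings are unit vectors), so
    they read directly as relative contributions.
    """
    p = pca.loadings.shape[1]
    if len(feature_names) != p:
        raise ValueError(f"expected {p} feature names, got {len(feature_names)}")
    out = pd.DataFrame(index=pd.Index(feature_names, name="feature"))
    for k in (0, 1):
        load = pca.loadings[k]
        out[f"loading_pc{k + 1}"] = load
        out[f"share_pc{k + 1}"] = load**2 / np.sum(load**2)
    return out


@dataclass
class ClusterReport:
    """Cluster composition ordered by the members' mean disease burden.

    Controls carry no disease burden score; they enter the ranking with a
    sentinel of 0 and each affected cluster is flagged.  Transition clusters
    are the nonempty clusters strictly between the top- and bottom-ranked
    ones.
    """

    n_clusters: int
    clusters: list[dict]
    dbs_rank: list[int]  # nonempty clusters, descending mean DBS
    empty_clusters: list[int]
    transition_clusters: list[int]

    @property
    def top_cluster(self) -> int:
        return self.dbs_rank[0]

    @property
    def bottom_cluster(self) -> int:
        return self.dbs_rank[-1]

    def to_dict(self) -> dict:
        return {
            "n_clusters": self.n_clusters,
            "clusters": self.clusters,
            "dbs_rank": self.dbs_rank,
            "empty_clusters": self.empty_clusters,
            "transition_clusters": self.transition_clusters,
        }

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n")


def cluster_db_report(
    labels: np.ndarray, cohort: pd.DataFrame, n_clusters: int | None = None
) -> ClusterReport:
    """Summarize clusters against the cohort's disease burden scores."""
    labels = np.asarray(labels)
    if len(labels) != len(cohort):
        raise ValueError("labels and cohort length mismatch")
    c = int(n_clusters if n_clusters is not None else labels.max() + 1)
    dbs_sentinel = pd.to_numeric(cohort["dbs"], errors="coerce").fillna(0.0).to_numpy()
    dbs_raw = pd.to_numeric(cohort["dbs"], errors="coerce").to_numpy()
    groups = cohort["group"].to_numpy()
    ids = cohort["subject_id"].to_numpy()

    clusters = []
    for i in range(c):
        sel = labels == i
        size = int(sel.sum())
        entry: dict = {"cluster": i, "size": size, "member_ids": [str(s) for s in ids[sel]]}
        if size:
            comp = pd.Series(groups[sel]).value_counts().to_dict()
            entry["group_composition"] = {str(k): int(v) for k, v in sorted(comp.items())}
            entry["contains_controls"] = bool((groups[sel] == "control").any())
            entry["mean_dbs_for_ranking"] = float(dbs_sentinel[sel].mean())
            carrier_dbs = dbs_raw[sel]
            carrier_dbs = carrier_dbs[np.isfinite(carrier_dbs)]
            if carrier_dbs.size:
                entry["dbs_min"] = float(carrier_dbs.min())
                entry["dbs_mean"] = float(carrier_dbs.mean())
                entry["dbs_max"] = float(carrier_dbs.max())
        clusters.append(entry)

    nonempty = [e["cluster"] for e in clusters if e["size"] > 0]
    if len(nonempty) == 1:
        warnings.warn("degenerate clustering: all subjects in one cluster", stacklevel=2)
    rank = sorted(nonempty, key=lambda i: (-clusters[i]["mean_dbs_for_ranking"], i))
    empty = [e["cluster"] for e in clusters if e["size"] == 0]
    transition = rank[1:-1] if len(rank) > 2 else []
    return ClusterReport(
        n_clusters=c,
        clusters=clusters,
        dbs_rank=rank,
        empty_clusters=empty,
        transition_clusters=transition,
    )
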
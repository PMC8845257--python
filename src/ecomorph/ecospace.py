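"""Microhabitat clustering: Jaccard distances, PCoA, BIC-based cluster
count selection, k-means, and descriptor-to-cluster affiliation."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata
from sklearn.cluster import KMeans
from sklearn.mixture import GaussianMixture

from ecomorph.io_formats import MicrohabitatMatrix

__all__ = [
    "DistanceMatrix",
    "Ordination",
    "BICCurve",
    "ClusterModel",
    "AffiliationTable",
    "jaccard_distance",
    "pcoa",
    "gmm_bic_curve",
    "select_k_plateau",
    "kmeans_cluster",
    "trait_axis_correlation",
    "cluster_trait_affiliation",
    "name_clusters",
]

GMM_MODELS = ("spherical", "diag", "full")


@dataclass
class DistanceMatrix:
    values: np.ndarray
    species_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.species_ids)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.abs(np.diag(self.values)) > 1e-12):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(self.values < -1e-12) or np.any(self.values > 1 + 1e-12):
            raise ValueError("Jaccard distances must lie in [0, 1]")

    def to_csv(self, path) -> None:
        pd.DataFrame(
            self.values, index=self.species_ids, columns=self.species_ids
        ).to_csv(path, index_label="species")


@dataclass
class Ordination:
    """PCoA axes: ``scores`` (n x A), positive ``eigenvalues`` sorted
    decreasing, and the proportion of positive-eigenvalue variance per axis."""

    scores: np.ndarray
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray
    species_ids: list[str]

    @property
    def n_axes(self) -> int:
        return self.scores.shape[1]

    def to_csv(self, path) -> None:
        cols = [f"axis_{i + 1}" for i in range(self.n_axes)]
        pd.DataFrame(self.scores, index=self.species_ids, columns=cols).to_csv(
            path, index_label="species"
        )


@dataclass
class BICCurve:
    """Best BIC per candidate k (convention 2*logLik - params*log(n);
    higher is better) and the winning covariance-model name."""

    ks: list[int]
    bic: np.ndarray
    model_names: list[str]

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"k": self.ks, "bic": self.bic, "model": self.model_names}
        ).to_csv(path, index=False)


@dataclass
class ClusterModel:
    k: int
    assignments: np.ndarray  # labels in 1..k
    centers: np.ndarray  # k x A, ordination space
    inertia: float
    species_ids: list[str]

    def __post_init__(self) -> None:
        self.assignments = np.asarray(self.assignments, dtype=int)
        counts = np.bincount(self.assignments, minlength=self.k + 1)[1:]
        if np.any(counts == 0):
            raise ValueError("cluster model contains an empty cluster")

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"species": self.species_ids, "cluster": self.assignments}
        ).to_csv(path, index=False)


@dataclass
class AffiliationTable:
    """Descriptor-by-cluster correlation table (Pearson or Spearman)."""

    values: np.ndarray  # m x k
    descriptor_names: list[str]
    cluster_ids: list[int]
    method: str

    def __post_init__(self) -> None:
        if np.any(np.abs(self.values) > 1 + 1e-9):
            raise ValueError("affiliations must lie in [-1, 1]")

    def to_csv(self, path) -> None:
        pd.DataFrame(
            self.values,
            index=self.descriptor_names,
            columns=[f"cluster_{c}" for c in self.cluster_ids],
        ).to_csv(path, index_label="descriptor")


def jaccard_distance(M: MicrohabitatMatrix) -> DistanceMatrix:
    """Pairwise binary Jaccard distances: 1 - |shared 1s| / |union of 1s|."""
    D = squareform(pdist(M.values.astype(bool), metric="jaccard"))
    return DistanceMatrix(D, list(M.species_ids))


def pcoa(D: DistanceMatrix, tol: float = 1e-8) -> Ordination:
    """Principal coordinates via Gower double-centering.

    B = -0.5 * J D^2 J with J the centering projector; axes with
    eigenvalue > tol * max eigenvalue are retained and scaled by the
    square root of their eigenvalue.
    """
    d2 = D.values**2
    n = d2.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ d2 @ J
    eigval, eigvec = np.linalg.eigh((B + B.T) / 2)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    if eigval[0] <= tol:
        raise ValueError("no positive eigenvalues: degenerate distance matrix")
    keep = eigval > tol * eigval[0]
    eigval, eigvec = eigval[keep], eigvec[:, keep]
    scores = eigvec * np.sqrt(eigval)
    return Ordination(scores, eigval, eigval / eigval.sum(), list(D.species_ids))


def gmm_bic_curve(
    X: np.ndarray,
    kmax: int,
    models: tuple[str, ...] = GMM_MODELS,
    seed: int | None = None,
    n_init: int = 5,
) -> BICCurve:
    """Best Gaussian-mixture BIC per cluster count k = 1..kmax.

    Each k is fitted by EM under every covariance model with multiple
    restarts; the best (highest) BIC over models is recorded.  A k at
    which every model fails is marked NaN with a warning.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if kmax < 2:
        raise ValueError("kmax must be >= 2")
    if n < kmax:
        raise ValueError("fewer rows than kmax")
    ks = list(range(1, kmax + 1))
    best = np.full(len(ks), np.nan)
    names = [""] * len(ks)
    for i, k in enumerate(ks):
        for model in models:
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    gm = GaussianMixture(
                        n_components=k,
                        covariance_type=model,
                        n_init=n_init,
                        random_state=seed,
                        reg_covar=1e-6,
                    ).fit(X)
                bic = -gm.bic(X)  # sklearn reports lower-is-better
            except Exception:
                continue
            if np.isfinite(bic) and (np.isnan(best[i]) or bic > best[i]):
                best[i] = bic
                names[i] = model
        if np.isnan(best[i]):
            warnings.warn(f"all mixture models failed at k={k}", stacklevel=2)
    return BICCurve(ks, best, names)


def select_k_plateau(b: BICCurve, eps: float = 0.05) -> int:
    """Smallest k before the BIC curve flattens.

    Returns the first k whose step to k+1 gains less than ``eps`` times
    the BIC range; falls back to the argmax of the curve if the gain
    never drops below the threshold.
    """
    if len(b.ks) < 3:
        raise ValueError("BIC curve needs at least 3 entries")
    if not 0 < eps < 1:
        raise ValueError("eps must be in (0, 1)")
    vals = np.asarray(b.bic, dtype=float)
    finite = np.isfinite(vals)
    if not finite.any():
        raise ValueError("BIC curve has no finite values")
    rng = np.nanmax(vals) - np.nanmin(vals)
    threshold = eps * rng
    for i in range(len(vals) - 1):
        if not (np.isfinite(vals[i]) and np.isfinite(vals[i + 1])):
            continue
        if vals[i + 1] - vals[i] < threshold:
            return b.ks[i]
    return b.ks[int(np.nanargmax(vals))]


def kmeans_cluster(
    X: np.ndarray,
    k: int,
    restarts: int = 100,
    seed: int | None = None,
    species_ids: list[str] | None = None,
) -> ClusterModel:
    """Lloyd k-means with k-means++ starts; best of ``restarts`` by inertia."""
    X = np.asarray(X, dtype=float)
    if k < 1:
        raise ValueError("k must be >= 1")
    if restarts < 1:
        raise ValueError("restarts must be >= 1")
    km = KMeans(
        n_clusters=k,
        n_init=restarts,
        random_state=seed,
        algorithm="lloyd",
        init="k-means++",
    ).fit(X)
    if species_ids is None:
        species_ids = [f"s{i + 1}" for i in range(X.shape[0])]
    return ClusterModel(
        k=k,
        assignments=km.labels_ + 1,
        centers=km.cluster_centers_,
        inertia=float(km.inertia_),
        species_ids=list(species_ids),
    )


def _corr_columns(a: np.ndarray, b: np.ndarray, method: str) -> np.ndarray:
    """Correlation of every column of ``a`` with every column of ``b``."""
    if method == "spearman":
        a = np.apply_along_axis(rankdata, 0, a)
        b = np.apply_along_axis(rankdata, 0, b)
    elif method != "pearson":
        raise ValueError(f"unknown method {method!r}")
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    sa = np.sqrt((ac**2).sum(axis=0))
    sb = np.sqrt((bc**2).sum(axis=0))
    out = np.zeros((a.shape[1], b.shape[1]))
    ok_a = sa > 0
    ok_b = sb > 0
    if not ok_a.all() or not ok_b.all():
        warnings.warn("constant column: correlation set to 0", stacklevel=3)
    num = ac.T @ bc
    denom = np.outer(np.where(ok_a, sa, 1.0), np.where(ok_b, sb, 1.0))
    out = num / denom
    out[~ok_a, :] = 0.0
    out[:, ~ok_b] = 0.0
    return np.clip(out, -1.0, 1.0)


def trait_axis_correlation(
    M: MicrohabitatMatrix, ordination: Ordination, method: str = "pearson"
) -> np.ndarray:
    """Descriptor-by-axis correlation matrix across species (m x A)."""
    if M.species_ids != ordination.species_ids:
        raise ValueError("species order mismatch; run align_species first")
    return _corr_columns(M.values.astype(float), ordination.scores, method)


def cluster_trait_affiliation(
    TA: np.ndarray,
    model: ClusterModel,
    method: str = "pearson",
    descriptor_names: list[str] | None = None,
) -> AffiliationTable:
    """Correlate descriptor axis-profiles with k-means cluster centers.

    Entry (j, c) is the correlation over the A ordination axes between
    descriptor j's axis-correlation profile and cluster c's center.
    """
    TA = np.asarray(TA, dtype=float)
    A = TA.shape[1]
    if A < 3:
        raise ValueError("need at least 3 ordination axes for affiliation")
    if model.centers.shape[1] != A:
        raise ValueError("cluster centers not in the same ordination space")
    vals = _corr_columns(TA.T, model.centers.T, method)
    if descriptor_names is None:
        descriptor_names = [f"d{j + 1}" for j in range(TA.shape[0])]
    return AffiliationTable(
        vals, list(descriptor_names), list(range(1, model.k + 1)), method
    )


def name_clusters(A: AffiliationTable, top_n: int | None = None) -> dict[int, list[str]]:
    """Rank descriptors per cluster by descending affiliation."""
    out: dict[int, list[str]] = {}
    for c, cid in enumerate(A.cluster_ids):
        col = A.values[:, c]
        if np.allclose(col, 0):
            warnings.warn(
                f"cluster {cid}: all-zero affiliation, ranking arbitrary",
                stacklevel=2,
            )
        order = np.argsort(-col, kind="stable")
        ranked = [A.descriptor_names[j] for j in order]
        out[cid] = ranked[:top_n] if top_n is not None else ranked
    return out
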
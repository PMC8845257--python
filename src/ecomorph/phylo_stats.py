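"""Phylogenetically informed inference.

Implements generalized-least-squares building blocks on a Brownian-motion
covariance matrix C, a phylogenetic two-block partial least squares with
permutation test, the Kappa-statistic phylogenetic signal (univariate and
multivariate), a GLS MANOVA with randomized residual permutation, and
pairwise group-mean distance tests sharing the MANOVA's null stream.

Permutation p-values use the +1 convention: p = (#{stat* >= stat} + 1) /
(n_perm + 1), so the smallest attainable p is 1/(n_perm + 1).  Effect
sizes are (observed - null mean) / null SD on the raw statistic scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PLSResult",
    "KResult",
    "ManovaResult",
    "PairwiseResult",
    "GroupMeansPCA",
    "phylo_gls_mean",
    "phylo_transform",
    "inv_sqrt",
    "phylo_pls",
    "eco_project",
    "physignal",
    "rrpp_manova",
    "pairwise_group_tests",
    "group_means_pca",
]

_PERM_CHUNK = 2000


# ---------------------------------------------------------------------------
# GLS building blocks


def _as_matrix(Y) -> np.ndarray:
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    return Y


def inv_sqrt(C: np.ndarray, ridge: float = 1e-8) -> np.ndarray:
    """Symmetric inverse square root of C via eigendecomposition.

    Near-singular C (smallest eigenvalue < 1e-10) gets a ridge of
    ``ridge`` on the diagonal, with a warning.
    """
    C = np.asarray(C, dtype=float)
    eigval, eigvec = np.linalg.eigh((C + C.T) / 2)
    if eigval.min() < 1e-10:
        warnings.warn(
            f"C nearly singular (min eigenvalue {eigval.min():.3g}); "
            f"adding ridge {ridge}",
            stacklevel=2,
        )
        eigval, eigvec = np.linalg.eigh((C + C.T) / 2 + ridge * np.eye(C.shape[0]))
    return (eigvec / np.sqrt(eigval)) @ eigvec.T


def phylo_gls_mean(Y, C: np.ndarray) -> np.ndarray:
    """GLS estimate of the root state: (1'C^-1 1)^-1 1'C^-1 Y."""
    Y = _as_matrix(Y)
    w = np.linalg.solve(C, np.ones(C.shape[0]))
    return (w @ Y) / w.sum()


def phylo_transform(Y, C: np.ndarray, center: bool = True) -> np.ndarray:
    """Whiten Y by C^(-1/2), optionally after removing the GLS mean.

    Rows of the output have identity error covariance under Brownian
    motion on the tree that produced C.
    """
    Y = _as_matrix(Y)
    P = inv_sqrt(C)
    if center:
        Y = Y - phylo_gls_mean(Y, C)
    return P @ Y


def _perm_indices(rng: np.random.Generator, n: int, n_perm: int) -> np.ndarray:
    return np.array([rng.permutation(n) for _ in range(n_perm)])


# ---------------------------------------------------------------------------
# two-block phylogenetic PLS


@dataclass
class PLSResult:
    r: float
    z: float
    p: float
    x_loadings: np.ndarray
    y_loadings: np.ndarray
    x_scores: np.ndarray
    y_scores: np.ndarray
    n_perm: int
    singular_values: np.ndarray = field(default=None, repr=False)
    x_rotation: np.ndarray = field(default=None, repr=False)
    y_rotation: np.ndarray = field(default=None, repr=False)


def _pls_first_pair(Xt: np.ndarray, Yt: np.ndarray):
    """First singular pair of the cross-covariance of whitened blocks."""
    R12 = Xt.T @ Yt / (Xt.shape[0] - 1)
    U, d, Vt = np.linalg.svd(R12, full_matrices=False)
    return U, d, Vt.T


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    return float(a @ b / np.sqrt((a @ a) * (b @ b)))


def phylo_pls(
    X,
    Y,
    C: np.ndarray,
    n_perm: int = 10000,
    seed: int | None = None,
) -> PLSResult:
    """Phylogenetic two-block PLS between blocks X (n x p) and Y (n x q).

    Both blocks are GLS-centered and whitened by C^(-1/2); the first
    singular pair of their cross-covariance gives loadings, scores, and
    the score correlation r.  The null distribution permutes whole rows
    of the whitened Y block.  ``n_perm=0`` skips the test (z and p NaN).
    """
    X, Y = _as_matrix(X), _as_matrix(Y)
    n = X.shape[0]
    if Y.shape[0] != n or C.shape != (n, n):
        raise ValueError("X, Y and C must share the species dimension")
    if n <= 2:
        raise ValueError("need more than 2 species")
    P = inv_sqrt(C)
    Xt = P @ (X - phylo_gls_mean(X, C))
    Yt = P @ (Y - phylo_gls_mean(Y, C))
    U, d, V = _pls_first_pair(Xt, Yt)
    u1, v1 = U[:, 0], V[:, 0]
    xs, ys = Xt @ u1, Yt @ v1
    r_obs = _pearson(xs, ys)

    if n_perm <= 0:
        return PLSResult(r_obs, np.nan, np.nan, u1, v1, xs, ys, 0, d, U, V)

    rng = np.random.default_rng(seed)
    r_perm = np.empty(n_perm)
    scale = 1.0 / (n - 1)
    done = 0
    while done < n_perm:
        B = min(_PERM_CHUNK, n_perm - done)
        idx = _perm_indices(rng, n, B)
        Ytp = Yt[idx]  # B x n x q
        R12 = np.einsum("np,bnq->bpq", Xt, Ytp) * scale
        Ub, _, Vtb = np.linalg.svd(R12, full_matrices=False)
        xsp = Xt @ Ub[:, :, 0].T  # n x B
        ysp = np.einsum("bnq,bq->nb", Ytp, Vtb[:, 0, :])
        xc = xsp - xsp.mean(axis=0)
        yc = ysp - ysp.mean(axis=0)
        r_perm[done : done + B] = (xc * yc).sum(axis=0) / np.sqrt(
            (xc**2).sum(axis=0) * (yc**2).sum(axis=0)
        )
        done += B
    p = (np.count_nonzero(r_perm >= r_obs) + 1) / (n_perm + 1)
    z = (r_obs - r_perm.mean()) / r_perm.std(ddof=1)
    return PLSResult(r_obs, float(z), float(p), u1, v1, xs, ys, n_perm, d, U, V)


def eco_project(Y, C: np.ndarray, pls: PLSResult, mode: str = "axes") -> np.ndarray:
    """Rotate morphology into the PLS frame that maximizes eco-covariance.

    ``mode="axes"`` projects the GLS-centered Y block onto all right
    singular vectors of the PLS cross-covariance; ``mode="scores"``
    returns the first-pair score vector only.
    """
    Y = _as_matrix(Y)
    Yc = Y - phylo_gls_mean(Y, C)
    if mode == "axes":
        return Yc @ pls.y_rotation
    if mode == "scores":
        return (Yc @ pls.y_loadings)[:, None]
    raise ValueError(f"unknown eco-projection mode {mode!r}")


# ---------------------------------------------------------------------------
# phylogenetic signal (Kappa statistic)


@dataclass
class KResult:
    K: float
    p: float
    n_perm: int
    scope: str


def _is_star(C: np.ndarray) -> bool:
    off = C - np.diag(np.diag(C))
    return bool(np.all(np.abs(off) < 1e-12))


def physignal(
    y,
    C: np.ndarray,
    n_perm: int = 999,
    seed: int | None = None,
) -> KResult:
    """Kappa-statistic phylogenetic signal, univariate or multivariate.

    K is the ratio of observed to GLS-weighted trait dispersion, scaled
    by its Brownian-motion expectation, so K has expectation ~1 when the
    data evolved by Brownian motion on the tree behind C.  The null
    distribution shuffles tip rows.
    """
    Y = _as_matrix(y)
    n, q = Y.shape
    if C.shape != (n, n):
        raise ValueError("C does not match the trait matrix")
    if _is_star(C):
        raise ValueError("K is undefined on a star phylogeny")
    Cinv = np.linalg.inv(C)
    w = Cinv @ np.ones(n)
    wsum = w.sum()
    expected = (np.trace(C) - n / wsum) / (n - 1)

    def _K(Yb: np.ndarray) -> np.ndarray:
        # Yb: B x n x q
        a = np.einsum("n,bnq->bq", w, Yb) / wsum
        Yc = Yb - a[:, None, :]
        num = np.einsum("bnq,bnq->b", Yc, Yc)
        den = np.einsum("bnq,nm,bmq->b", Yc, Cinv, Yc)
        return (num / den) / expected

    K_obs = float(_K(Y[None])[0])
    if n_perm <= 0:
        return KResult(K_obs, np.nan, 0, "univariate" if q == 1 else "multivariate")
    rng = np.random.default_rng(seed)
    K_perm = np.empty(n_perm)
    done = 0
    while done < n_perm:
        B = min(_PERM_CHUNK, n_perm - done)
        idx = _perm_indices(rng, n, B)
        K_perm[done : done + B] = _K(Y[idx])
        done += B
    p = (np.count_nonzero(K_perm >= K_obs) + 1) / (n_perm + 1)
    return KResult(K_obs, float(p), n_perm, "univariate" if q == 1 else "multivariate")


# ---------------------------------------------------------------------------
# GLS MANOVA with randomized residual permutation


@dataclass
class ManovaResult:
    df_term: int
    ss_term: float
    ms_term: float
    rsq: float
    f: float
    z: float
    p: float
    df_resid: int
    ss_resid: float
    ms_resid: float
    df_total: int
    ss_total: float
    n_perm: int
    group_levels: list = field(default=None, repr=False)
    _context: dict = field(default=None, repr=False)

    def table(self) -> dict:
        return {
            "term": {
                "Df": self.df_term,
                "SS": self.ss_term,
                "MS": self.ms_term,
                "Rsq": self.rsq,
                "F": self.f,
                "Z": self.z,
                "p": self.p,
            },
            "residuals": {
                "Df": self.df_resid,
                "SS": self.ss_resid,
                "MS": self.ms_resid,
            },
            "total": {"Df": self.df_total, "SS": self.ss_total},
            "n_perm": self.n_perm,
        }


def _design(groups) -> tuple[np.ndarray, list]:
    groups = np.asarray(groups)
    levels = sorted(set(groups.tolist()))
    k = len(levels)
    if k < 2:
        raise ValueError("need at least 2 group levels")
    for lev in levels:
        if np.count_nonzero(groups == lev) < 2:
            raise ValueError(f"group level {lev!r} has fewer than 2 members")
    n = groups.shape[0]
    X = np.ones((n, k))
    for j, lev in enumerate(levels[1:], start=1):
        X[:, j] = (groups == lev).astype(float)
    return X, levels


def rrpp_manova(
    Y,
    groups,
    C: np.ndarray,
    n_perm: int = 10000,
    seed: int | None = None,
) -> ManovaResult:
    """GLS one-factor MANOVA with randomized-residual permutation.

    Y and the design are whitened by C^(-1/2) and fitted by OLS; sums of
    squares are traces of residual cross-products.  The null shuffles
    reduced-model (intercept-only) residual rows and refits.
    """
    Y = _as_matrix(Y)
    n, q = Y.shape
    X, levels = _design(groups)
    if C.shape != (n, n):
        raise ValueError("C does not match Y")
    k = len(levels)
    P = inv_sqrt(C)
    Yt = P @ Y
    Xt = P @ X
    Xr = P @ np.ones((n, 1))
    H_full = Xt @ np.linalg.pinv(Xt)
    H_red = Xr @ np.linalg.pinv(Xr)
    Q_full = np.eye(n) - H_full
    Q_red = np.eye(n) - H_red

    rss_full = float(np.sum((Q_full @ Yt) ** 2))
    rss_red = float(np.sum((Q_red @ Yt) ** 2))
    ss_term = rss_red - rss_full
    df_term, df_resid = k - 1, n - k
    ms_term, ms_resid = ss_term / df_term, rss_full / df_resid
    f_obs = ms_term / ms_resid
    rsq = ss_term / rss_red

    fitted_red = H_red @ Yt
    resid_red = Q_red @ Yt

    rng = np.random.default_rng(seed)
    f_perm = np.empty(max(n_perm, 0))
    perm_idx = np.empty((max(n_perm, 0), n), dtype=np.intp)
    done = 0
    while done < n_perm:
        B = min(_PERM_CHUNK, n_perm - done)
        idx = _perm_indices(rng, n, B)
        perm_idx[done : done + B] = idx
        Ystar = fitted_red + resid_red[idx]  # B x n x q
        rf = np.einsum("bnq,bnq->b", np.matmul(Q_full, Ystar), Ystar)
        rr = np.einsum("bnq,bnq->b", np.matmul(Q_red, Ystar), Ystar)
        f_perm[done : done + B] = ((rr - rf) / df_term) / (rf / df_resid)
        done += B
    if n_perm > 0:
        p = (np.count_nonzero(f_perm >= f_obs) + 1) / (n_perm + 1)
        z = (f_obs - f_perm.mean()) / f_perm.std(ddof=1)
    else:
        p = z = np.nan

    res = ManovaResult(
        df_term=df_term,
        ss_term=ss_term,
        ms_term=ms_term,
        rsq=rsq,
        f=float(f_obs),
        z=float(z),
        p=float(p),
        df_resid=df_resid,
        ss_resid=rss_full,
        ms_resid=ms_resid,
        df_total=n - 1,
        ss_total=rss_red,
        n_perm=n_perm,
        group_levels=levels,
        _context={
            "Yt": Yt,
            "Xt": Xt,
            "fitted_red": fitted_red,
            "resid_red": resid_red,
            "perm_idx": perm_idx,
            "levels": levels,
        },
    )
    assert abs(res.ss_term + res.ss_resid - res.ss_total) <= 1e-8 * max(
        1.0, abs(res.ss_total)
    )
    assert res.df_term + res.df_resid == res.df_total
    return res


@dataclass
class PairwiseResult:
    pairs: list[tuple]
    distances: np.ndarray
    p_values: np.ndarray
    effect_sizes: np.ndarray

    def rows(self) -> list[dict]:
        return [
            {
                "group_a": a,
                "group_b": b,
                "distance": float(d),
                "p": float(p),
                "z": float(z),
            }
            for (a, b), d, p, z in zip(
                self.pairs, self.distances, self.p_values, self.effect_sizes
            )
        ]


def _ls_means(Xt: np.ndarray, Y: np.ndarray, k: int) -> np.ndarray:
    """GLS least-squares group means in original trait space (k x q)."""
    beta = np.linalg.pinv(Xt) @ Y
    L = np.ones((k, Xt.shape[1]))
    L[:, 1:] = np.eye(k)[:, 1:]
    return L @ beta


def pairwise_group_tests(fit: ManovaResult) -> PairwiseResult:
    """Distances between GLS LS means, tested against the MANOVA's own
    reduced-model residual permutations."""
    ctx = fit._context
    if ctx is None:
        raise ValueError("ManovaResult carries no fit context")
    Xt, Yt = ctx["Xt"], ctx["Yt"]
    levels = ctx["levels"]
    k = len(levels)
    pinvX = np.linalg.pinv(Xt)
    L = np.ones((k, Xt.shape[1]))
    L[:, 1:] = np.eye(k)[:, 1:]
    means = L @ (pinvX @ Yt)
    pairs = [(levels[a], levels[b]) for a in range(k) for b in range(a + 1, k)]
    pair_idx = [(a, b) for a in range(k) for b in range(a + 1, k)]
    d_obs = np.array(
        [np.linalg.norm(means[a] - means[b]) for a, b in pair_idx]
    )
    perm_idx = ctx["perm_idx"]
    n_perm = perm_idx.shape[0]
    d_perm = np.empty((n_perm, len(pairs)))
    done = 0
    while done < n_perm:
        B = min(_PERM_CHUNK, n_perm - done)
        idx = perm_idx[done : done + B]
        Ystar = ctx["fitted_red"] + ctx["resid_red"][idx]
        means_b = np.einsum("kn,bnq->bkq", L @ pinvX, Ystar)
        for j, (a, b) in enumerate(pair_idx):
            d_perm[done : done + B, j] = np.linalg.norm(
                means_b[:, a] - means_b[:, b], axis=1
            )
        done += B
    p = (np.count_nonzero(d_perm >= d_obs, axis=0) + 1) / (n_perm + 1)
    z = (d_obs - d_perm.mean(axis=0)) / d_perm.std(axis=0, ddof=1)
    return PairwiseResult(pairs, d_obs, p, z)


# ---------------------------------------------------------------------------
# group means in principal-component rotation


@dataclass
class GroupMeansPCA:
    group_levels: list
    rotated_means: np.ndarray  # k x r
    rotation: np.ndarray  # q x r
    group_covariances: list  # per group, r x r score covariance


def group_means_pca(Y, groups, C: np.ndarray) -> GroupMeansPCA:
    """Rotate GLS LS means to their principal components.

    Also returns each group's covariance of member scores around its
    rotated mean, for downstream confidence-ellipse drawing.
    """
    Y = _as_matrix(Y)
    X, levels = _design(groups)
    P = inv_sqrt(C)
    means = _ls_means(P @ X, P @ Y, len(levels))
    centered = means - means.mean(axis=0)
    _, _, Vt = np.linalg.svd(centered, full_matrices=False)
    rot = Vt.T
    rotated = centered @ rot
    groups = np.asarray(groups)
    covs = []
    Yc = Y - means.mean(axis=0)
    scores = Yc @ rot
    for lev in levels:
        block = scores[groups == lev]
        covs.append(np.cov(block, rowvar=False))
    return GroupMeansPCA(levels, rotated, rot, covs)
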
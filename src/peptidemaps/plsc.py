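"""Partial least squares correlation (PLSC) and profile PCA.

PLSC column-standardizes two regional data blocks X (regions x p) and
Y (regions x q) and takes the singular value decomposition of their
cross-covariance X'Y. Each latent variable (LV) pairs an x-weight and a
y-weight vector; the share of squared singular value mass is the covariance
explained; loadings are Pearson correlations of the original columns with
their side's LV score. Inference uses permutation nulls on singular values
(with orthogonal alignment of permuted LVs to the empirical basis),
bootstrap percentile intervals on loadings, and train/test split
cross-validation of LV1 score correlations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .atlas import DistanceMatrix, RegionalMatrix, ValidationError
from .nulls import SurrogateGenerator, matched_gene_nulls


def _block(x, what: str) -> np.ndarray:
    v = x.require_complete(what) if isinstance(x, RegionalMatrix) else np.asarray(x, float)
    if v.ndim != 2:
        raise ValidationError(f"{what}: expected a 2-D block")
    return v


def _standardize(v: np.ndarray, mean=None, sd=None):
    mean = v.mean(axis=0) if mean is None else mean
    sd = v.std(axis=0) if sd is None else sd
    if np.any(sd == 0):
        j = int(np.flatnonzero(sd == 0)[0])
        raise ValidationError(f"zero-variance column at index {j}")
    return (v - mean) / sd, mean, sd


def _fix_signs(u: np.ndarray, v: np.ndarray):
    """Deterministic sign convention: the largest-|weight| entry per LV > 0."""
    for k in range(u.shape[1]):
        joint = np.concatenate([u[:, k], v[:, k]])
        if joint[np.argmax(np.abs(joint))] < 0:
            u[:, k] *= -1
            v[:, k] *= -1
    return u, v


def _loadings(data: np.ndarray, scores: np.ndarray) -> np.ndarray:
    """Pearson correlation of each data column with each score column."""
    dz = (data - data.mean(axis=0)) / data.std(axis=0)
    sz = (scores - scores.mean(axis=0)) / scores.std(axis=0)
    return dz.T @ sz / data.shape[0]


@dataclass
class PLSCResult:
    singular_values: np.ndarray
    covariance_explained: np.ndarray  # percent per LV
    x_weights: np.ndarray
    y_weights: np.ndarray
    x_scores: np.ndarray
    y_scores: np.ndarray
    x_loadings: np.ndarray
    y_loadings: np.ndarray
    perm_p: np.ndarray | None = None
    bootstrap_ci: dict | None = None
    cv_correlations: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.any(np.diff(self.singular_values) > 1e-10):
            raise ValidationError("singular values must be non-increasing")
        if not np.isclose(self.covariance_explained.sum(), 100.0, atol=1e-6):
            raise ValidationError("covariance explained must sum to 100%")
        for w in (self.x_weights, self.y_weights):
            if not np.allclose(w.T @ w, np.eye(w.shape[1]), atol=1e-8):
                raise ValidationError("weights must be orthonormal")
        for ld in (self.x_loadings, self.y_loadings):
            if np.any(np.abs(ld) > 1 + 1e-9):
                raise ValidationError("loadings must lie in [-1, 1]")

    @property
    def n_lv(self) -> int:
        return len(self.singular_values)


def plsc_fit(X, Y) -> PLSCResult:
    """Column-standardized SVD of the cross-covariance of two blocks."""
    xv = _block(X, "plsc_fit X")
    yv = _block(Y, "plsc_fit Y")
    if xv.shape[0] != yv.shape[0]:
        raise ValidationError("blocks must share observations (regions)")
    n = xv.shape[0]
    xz, _, _ = _standardize(xv)
    yz, _, _ = _standardize(yv)
    c = xz.T @ yz / (n - 1)
    u, s, vt = np.linalg.svd(c, full_matrices=False)
    v = vt.T
    u, v = _fix_signs(u, v)
    cov_exp = 100 * s**2 / np.sum(s**2)
    xs, ys = xz @ u, yz @ v
    return PLSCResult(
        singular_values=s,
        covariance_explained=cov_exp,
        x_weights=u,
        y_weights=v,
        x_scores=xs,
        y_scores=ys,
        x_loadings=_loadings(xv, xs),
        y_loadings=_loadings(yv, ys),
        meta={"n": n},
    )


def _aligned_singvals(c_perm: np.ndarray, ref_u: np.ndarray, align: bool) -> np.ndarray:
    u_p, s_p, _ = np.linalg.svd(c_perm, full_matrices=False)
    if not align:
        return np.sort(s_p)[::-1]
    # orthogonal (Procrustes) rotation of the permuted LV basis onto the
    # empirical basis before reading off per-LV singular values
    a, _, bt = np.linalg.svd(u_p.T @ ref_u)
    rot = a @ bt
    return np.sqrt(((s_p[:, None] * rot) ** 2).sum(axis=0))


def plsc_permutation(
    X,
    Y,
    null_kind: str = "surrogate_maps",
    n_perm: int = 1000,
    seed: int = 0,
    dist: DistanceMatrix | None = None,
    pool: RegionalMatrix | None = None,
    align: bool = False,
    fit: PLSCResult | None = None,
    candidates_per_draw: int = 100,
    **null_kwargs,
) -> np.ndarray:
    """Per-LV permutation p-values from spatially informed nulls of Y.

    ``surrogate_maps`` rebuilds each Y column as a variogram-matched
    surrogate per permutation (requires ``dist``); ``matched_genes``
    replaces each Y column with an independently matched null gene drawn
    from ``pool``. P-values use the greater tail on singular values; by
    default null singular values are compared rank-for-rank (sorted), which
    is calibrated for LV1 under a global null. ``align=True`` instead
    rotates each permuted LV basis onto the empirical basis
    (Procrustes-style) before reading off per-LV values, which tracks
    specific LVs but is anticonservative for LV1 under the null.
    """
    if n_perm < 100:
        raise ValidationError("need n_perm >= 100")
    xv = _block(X, "plsc_permutation X")
    yv = _block(Y, "plsc_permutation Y")
    n, q = yv.shape
    emp = fit or plsc_fit(xv, yv)
    xz, _, _ = _standardize(xv)
    rng = np.random.default_rng(seed)

    if null_kind == "surrogate_maps":
        if dist is None:
            raise ValidationError("surrogate_maps null requires dist")
        gens = [SurrogateGenerator(yv[:, j], dist, **null_kwargs) for j in range(q)]

        def draw_block(m):
            block = np.empty((m, n, q))
            for j, g in enumerate(gens):
                block[:, :, j] = g.sample(m, rng).T
            return block

    elif null_kind == "matched_genes":
        if pool is None:
            raise ValidationError("matched_genes null requires a gene pool")
        if dist is None:
            raise ValidationError("matched_genes null requires dist")
        y_cols = list(Y.columns) if isinstance(Y, RegionalMatrix) else [None] * q
        ensembles = []
        for j in range(q):
            target = y_cols[j] if y_cols[j] in pool.columns else yv[:, j]
            ens = matched_gene_nulls(
                target,
                pool,
                dist,
                n_draws=n_perm,
                candidates_per_draw=candidates_per_draw,
                seed=int(rng.integers(2**31)),
                **null_kwargs,
            )
            ensembles.append([pool.column(g) for g in ens.members])

        consumed = [0]

        def draw_block(m):
            start = consumed[0]
            block = np.empty((m, n, q))
            for j in range(q):
                for b in range(m):
                    block[b, :, j] = ensembles[j][start + b]
            consumed[0] += m
            return block

    else:
        raise ValidationError(f"unknown null_kind {null_kind!r}")

    null_sv = np.empty((n_perm, emp.n_lv))
    done = 0
    while done < n_perm:
        m = min(64, n_perm - done)
        block = draw_block(m)
        for b in range(m):
            yp, _, _ = _standardize(block[b])
            c = xz.T @ yp / (n - 1)
            null_sv[done + b] = _aligned_singvals(c, emp.x_weights, align)
        done += m
    exceed = (null_sv >= emp.singular_values[None, :]).sum(axis=0)
    return (exceed + 1) / (n_perm + 1)


def plsc_bootstrap(X, Y, n_boot: int = 1000, seed: int = 0, fit: PLSCResult | None = None) -> dict:
    """Percentile 95% CIs for loadings from region resampling.

    Bootstrap LVs are sign-aligned to the empirical LVs; degenerate
    resamples (a zero-variance column) are redrawn and counted.
    """
    if n_boot < 100:
        raise ValidationError("need n_boot >= 100")
    xv = _block(X, "plsc_bootstrap X")
    yv = _block(Y, "plsc_bootstrap Y")
    emp = fit or plsc_fit(xv, yv)
    n = xv.shape[0]
    rng = np.random.default_rng(seed)
    xl = np.empty((n_boot,) + emp.x_loadings.shape)
    yl = np.empty((n_boot,) + emp.y_loadings.shape)
    redrawn = 0
    b = 0
    while b < n_boot:
        idx = rng.integers(0, n, size=n)
        xb, yb = xv[idx], yv[idx]
        if np.any(xb.std(axis=0) == 0) or np.any(yb.std(axis=0) == 0):
            redrawn += 1
            continue
        xz, _, _ = _standardize(xb)
        yz, _, _ = _standardize(yb)
        u, s, vt = np.linalg.svd(xz.T @ yz / (n - 1), full_matrices=False)
        v = vt.T
        # sign-align each bootstrap LV to the empirical one
        signs = np.sign(
            np.einsum("ij,ij->j", u, emp.x_weights) + np.einsum("ij,ij->j", v, emp.y_weights)
        )
        signs[signs == 0] = 1
        u *= signs
        v *= signs
        xl[b] = _loadings(xb, xz @ u)
        yl[b] = _loadings(yb, yz @ v)
        b += 1
    lo, hi = 2.5, 97.5
    return {
        "x_loadings_ci": np.stack(
            [np.percentile(xl, lo, axis=0), np.percentile(xl, hi, axis=0)], axis=-1
        ),
        "y_loadings_ci": np.stack(
            [np.percentile(yl, lo, axis=0), np.percentile(yl, hi, axis=0)], axis=-1
        ),
        "n_redrawn": redrawn,
    }


def plsc_crossval(
    X, Y, train_frac: float = 0.7, n_splits: int = 1000, seed: int = 0
) -> np.ndarray:
    """Out-of-sample LV1 score correlations over random train/test splits.

    Standardization parameters and weights are learned on the training
    regions only; test regions are projected with them. Returns the
    per-split Pearson correlations of the test-side LV1 scores.
    """
    if not 0 < train_frac < 1:
        raise ValidationError("train_frac must be in (0, 1)")
    if n_splits < 1:
        raise ValidationError("need n_splits >= 1")
    xv = _block(X, "plsc_crossval X")
    yv = _block(Y, "plsc_crossval Y")
    n = xv.shape[0]
    n_train = int(np.floor(train_frac * n))
    if n - n_train < 3:
        raise ValidationError("test set smaller than 3 regions")
    rng = np.random.default_rng(seed)
    out = np.empty(n_splits)
    for split in range(n_splits):
        perm = rng.permutation(n)
        tr, te = perm[:n_train], perm[n_train:]
        xz, xm, xs = _standardize(xv[tr])
        yz, ym, ys = _standardize(yv[tr])
        u, _, vt = np.linalg.svd(xz.T @ yz / (n_train - 1), full_matrices=False)
        xt = (xv[te] - xm) / xs @ u[:, 0]
        yt = (yv[te] - ym) / ys @ vt[0]
        out[split] = stats.pearsonr(xt, yt).statistic
    return out


# ---------------------------------------------------------------------------
# PCA of observation profiles
# ---------------------------------------------------------------------------

@dataclass
class PCAResult:
    scores: np.ndarray  # observations x components
    loadings: np.ndarray  # variables x components
    variance_explained: np.ndarray  # percent, non-increasing

    def __post_init__(self) -> None:
        if np.any(np.diff(self.variance_explained) > 1e-10):
            raise ValidationError("variance explained must be non-increasing")
        if not np.isclose(self.variance_explained.sum(), 100.0, atol=1e-6):
            raise ValidationError("variance explained must sum to 100%")


def pca_profile(matrix) -> PCAResult:
    """Column-centered PCA (via SVD) of an observations x variables table."""
    x = _block(matrix, "pca_profile") if not isinstance(matrix, np.ndarray) else matrix
    x = np.asarray(x, float)
    if x.shape[0] < 2:
        raise ValidationError("need at least 2 observations")
    xc = x - x.mean(axis=0)
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    rank = min(x.shape[0] - 1, x.shape[1])
    u, s, vt = u[:, :rank], s[:rank], vt[:rank]
    var = s**2
    return PCAResult(
        scores=u * s,
        loadings=vt.T,
        variance_explained=100 * var / var.sum(),
    )
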
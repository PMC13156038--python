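"""Synthetic regional data with controlled spatial and latent structure.

Every generator is a pure function of its parameters and seed. Regional
fields are drawn from zero-mean Gaussian random fields with an exponential
covariance kernel

    C(d) = sill * [(1 - nugget) * exp(-d / corr_range) + nugget * 1{d = 0}],

which gives a single interpretable autocorrelation range in millimetres.
The generators emulate the statistical structure of parcellated brain data:
spatially autocorrelated receptor/term maps, gene pools with heterogeneous
autocorrelation, paired map sets sharing a planted latent dimension,
regression designs with known predictor contributions, and multi-donor
expression stacks with known inter-donor reliability.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .atlas import (
    DistanceMatrix,
    RegionAtlas,
    RegionalMatrix,
    ValidationError,
    pairwise_distances,
)

CORTICAL_NETWORKS = (
    "visual",
    "somatomotor",
    "dorsal_attention",
    "ventral_attention",
    "frontoparietal",
    "default_mode",
    "limbic",
)
SUBCORTICAL_STRUCTURES = (
    "amygdala",
    "caudate",
    "globus_pallidus",
    "hippocampus",
    "nucleus_accumbens",
    "putamen",
    "thalamus",
)
HYPOTHALAMIC_NUCLEI = (
    "lateral_hypothalamus",
    "ventromedial_nucleus",
    "dorsomedial_nucleus",
    "perifornical_nucleus",
    "posterior_hypothalamus",
    "medial_mammillary",
    "lateral_mammillary",
    "tuberomammillary",
)

_JITTER = 1e-10


@dataclass(frozen=True)
class SAParams:
    """Exponential-covariance field parameters (range in mm)."""

    corr_range: float
    nugget: float = 0.0
    sill: float = 1.0

    def __post_init__(self) -> None:
        if self.corr_range < 0:
            raise ValidationError("corr_range must be >= 0")
        if not 0 <= self.nugget <= 1:
            raise ValidationError("nugget must be in [0, 1]")
        if self.sill <= 0:
            raise ValidationError("sill must be > 0")


@dataclass(frozen=True)
class PlantedLatentTruth:
    """Ground truth for a planted cross-block latent dimension."""

    x_weights: np.ndarray
    y_weights: np.ndarray
    latent_share: float
    noise_sd: float = 1.0

    def __post_init__(self) -> None:
        for name in ("x_weights", "y_weights"):
            w = np.asarray(getattr(self, name), float)
            norm = np.linalg.norm(w)
            if norm == 0:
                raise ValidationError(f"{name} must be nonzero")
            object.__setattr__(self, name, w / norm)
        if not 0 <= self.latent_share <= 1:
            raise ValidationError("latent_share must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")


def make_atlas(
    n_cortex: int,
    n_subcortex: int,
    include_hypothalamus: bool = True,
    seed: int = 0,
) -> RegionAtlas:
    """Sample a synthetic region atlas with disjoint spatial blocks.

    Cortical centroids lie on a spherical shell (55-75 mm from the origin),
    subcortical centroids in a central ball (radius <= 25 mm), and the
    optional single hypothalamus region sits near the origin, so that
    cortex-subcortex contrasts are geometrically meaningful.
    """
    if n_cortex < 0 or n_subcortex < 0:
        raise ValidationError("counts must be >= 0")
    n_total = n_cortex + n_subcortex + int(include_hypothalamus)
    if n_total == 0:
        raise ValidationError("atlas must contain at least one region")
    rng = np.random.default_rng(seed)
    rows = []
    rid = 1
    for i in range(n_cortex):
        direction = rng.standard_normal(3)
        direction /= np.linalg.norm(direction)
        radius = rng.uniform(55.0, 75.0)
        x, y, z = direction * radius
        stratum = CORTICAL_NETWORKS[i % len(CORTICAL_NETWORKS)]
        hemi = "L" if x < 0 else "R"
        rows.append((rid, f"ctx_{stratum}_{i}", "cortex", stratum, hemi, x, y, z))
        rid += 1
    for i in range(n_subcortex):
        while True:
            p = rng.standard_normal(3) * 12.0
            if np.linalg.norm(p) <= 25.0:
                break
        stratum = SUBCORTICAL_STRUCTURES[i % len(SUBCORTICAL_STRUCTURES)]
        hemi = "L" if p[0] < 0 else "R"
        rows.append((rid, f"sub_{stratum}_{i}", "subcortex", stratum, hemi, *p))
        rid += 1
    if include_hypothalamus:
        rows.append((rid, "hypothalamus", "hypothalamus", "hypothalamus", "M", 0.0, 2.0, -12.0))
    table = pd.DataFrame(
        rows, columns=["region_id", "name", "structure", "stratum", "hemisphere", "x", "y", "z"]
    )
    return RegionAtlas(table)


def exponential_covariance(dist: np.ndarray, params: SAParams) -> np.ndarray:
    d = np.asarray(dist, float)
    if params.corr_range == 0:
        c = np.where(d == 0, params.sill, 0.0)
    else:
        c = params.sill * (1 - params.nugget) * np.exp(-d / params.corr_range)
        c[d == 0] += params.sill * params.nugget
    return c


class GRFSampler:
    """Factorizes an exponential covariance once and draws many fields."""

    def __init__(self, dist: DistanceMatrix | np.ndarray, params: SAParams):
        d = dist.values if isinstance(dist, DistanceMatrix) else np.asarray(dist, float)
        cov = exponential_covariance(d, params)
        cov = cov + np.eye(len(d)) * (_JITTER * params.sill)
        try:
            self._factor = np.linalg.cholesky(cov)
        except np.linalg.LinAlgError as err:  # pragma: no cover
            raise ValidationError("covariance not positive definite after jitter") from err
        self.params = params

    def sample(self, rng: np.random.Generator, n_draws: int = 1) -> np.ndarray:
        """Draw ``n_draws`` fields; returns (n_regions, n_draws)."""
        return self._factor @ rng.standard_normal((self._factor.shape[0], n_draws))


def sample_sa_map(
    atlas: RegionAtlas, params: SAParams, seed: int = 0, name: str = "map"
) -> RegionalMatrix:
    """One draw from the exponential-covariance Gaussian random field."""
    dist = pairwise_distances(atlas)
    rng = np.random.default_rng(seed)
    values = GRFSampler(dist, params).sample(rng, 1)
    return RegionalMatrix(atlas, [name], values)


def atlas_diameter(atlas: RegionAtlas) -> float:
    return float(pairwise_distances(atlas).values.max())


def make_gene_pool(
    atlas: RegionAtlas,
    n_genes: int,
    range_low: float,
    range_high: float,
    seed: int = 0,
    nugget: float = 0.0,
) -> tuple[RegionalMatrix, np.ndarray]:
    """Independent fields with per-gene autocorrelation ranges.

    Each column is a GRF whose correlation range is drawn uniformly in
    ``[range_low, range_high]``; the drawn ranges are returned alongside the
    matrix as the per-column ground truth.
    """
    if n_genes < 1:
        raise ValidationError("n_genes must be >= 1")
    if range_low > range_high or range_low < 0:
        raise ValidationError("need 0 <= range_low <= range_high")
    rng = np.random.default_rng(seed)
    dist = pairwise_distances(atlas)
    ranges = rng.uniform(range_low, range_high, size=n_genes)
    values = np.empty((atlas.n_regions, n_genes))
    for j, rho in enumerate(ranges):
        sampler = GRFSampler(dist, SAParams(corr_range=float(rho), nugget=nugget))
        values[:, j] = sampler.sample(rng, 1)[:, 0]
    names = [f"gene_{j:04d}" for j in range(n_genes)]
    return RegionalMatrix(atlas, names, values), ranges


def _standardize(x: np.ndarray) -> np.ndarray:
    return (x - x.mean()) / x.std()


def _lv1_share(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    s = np.linalg.svd(xc.T @ yc, compute_uv=False)
    return float(s[0] ** 2 / np.sum(s**2))


def make_planted_latent(
    atlas: RegionAtlas,
    n_x: int,
    n_y: int,
    truth: PlantedLatentTruth,
    seed: int = 0,
) -> tuple[RegionalMatrix, RegionalMatrix, PlantedLatentTruth]:
    """Two blocks sharing one spatially smooth latent dimension.

    The latent score is itself a smooth field (range = atlas diameter / 4)
    so that spatial-autocorrelation-preserving nulls are a meaningful
    challenge. Independent noise is rescaled (by a solver on the realized
    cross-covariance) so the first singular value carries approximately
    ``truth.latent_share`` of the squared-singular-value mass.
    """
    if n_x < 2 or n_y < 2:
        raise ValidationError("need at least 2 variables per block")
    a = np.asarray(truth.x_weights, float)
    b = np.asarray(truth.y_weights, float)
    if len(a) != n_x or len(b) != n_y:
        raise ValidationError("weight lengths must match n_x / n_y")
    if truth.latent_share == 0 and truth.noise_sd == 0:
        raise ValidationError("latent_share=0 with noise_sd=0 is degenerate")
    rng = np.random.default_rng(seed)
    n = atlas.n_regions
    dist = pairwise_distances(atlas)
    z = GRFSampler(dist, SAParams(corr_range=atlas_diameter(atlas) / 4)).sample(rng, 1)[:, 0]
    z = _standardize(z)
    sd = truth.noise_sd if truth.noise_sd > 0 else 1.0
    ex = rng.standard_normal((n, n_x)) * sd
    ey = rng.standard_normal((n, n_y)) * sd
    signal_x = np.outer(z, a)
    signal_y = np.outer(z, b)

    if truth.latent_share == 0:
        x, y = ex, ey
    elif truth.noise_sd == 0:
        x, y = signal_x, signal_y
    else:
        def gap(lam: float) -> float:
            return _lv1_share(signal_x + lam * ex, signal_y + lam * ey) - truth.latent_share

        hi = 1.0
        while gap(hi) > 0 and hi < 1e6:
            hi *= 2.0
        if gap(hi) > 0:
            raise ValidationError(
                "latent_share below the noise floor achievable for this block size"
            )
        lam = brentq(gap, 0.0, hi, xtol=1e-10)
        x = signal_x + lam * ex
        y = signal_y + lam * ey

    xm = RegionalMatrix(atlas, [f"x_{j:03d}" for j in range(n_x)], x)
    ym = RegionalMatrix(atlas, [f"y_{j:03d}" for j in range(n_y)], y)
    return xm, ym, truth


def make_dominance_design(
    atlas: RegionAtlas,
    contributions: np.ndarray,
    noise_sd: float | None = None,
    orthogonal: bool = True,
    seed: int = 0,
) -> tuple[RegionalMatrix, RegionalMatrix, dict]:
    """Regression design with planted per-predictor R-squared shares.

    With ``orthogonal=True``, raw smooth fields are orthonormalized (QR)
    before mixing, so predictor k's population R-squared share equals
    ``contributions[k]`` and the full-model R-squared equals their sum.
    ``noise_sd`` defaults to ``sqrt(1 - sum(contributions))``, the value at
    which the planted shares are exact in population.
    """
    c = np.asarray(contributions, float)
    if np.any(c < 0):
        raise ValidationError("contributions must be nonnegative")
    if c.sum() > 1 + 1e-12:
        raise ValidationError("contributions must sum to <= 1")
    if noise_sd is None:
        noise_sd = float(np.sqrt(max(0.0, 1.0 - c.sum())))
    rng = np.random.default_rng(seed)
    n, p = atlas.n_regions, len(c)
    dist = pairwise_distances(atlas)
    sampler = GRFSampler(dist, SAParams(corr_range=atlas_diameter(atlas) / 6))
    fields = sampler.sample(rng, p)
    fields = fields - fields.mean(axis=0)
    if orthogonal:
        q, _ = np.linalg.qr(fields)
        x = q * np.sqrt(n)  # unit-variance orthogonal columns
    else:
        x = fields / fields.std(axis=0)
    y = x @ np.sqrt(c) + noise_sd * rng.standard_normal(n)
    xm = RegionalMatrix(atlas, [f"pred_{j:02d}" for j in range(p)], x)
    ym = RegionalMatrix(atlas, ["target"], y)
    total = c.sum()
    truth = {
        "contributions": c,
        "noise_sd": noise_sd,
        "relative_contribution_pct": (100 * c / total if total > 0 else np.zeros(p)),
        "full_r2": total / (total + noise_sd**2) if (total + noise_sd**2) > 0 else 0.0,
    }
    return xm, ym, truth


def make_donor_stack(
    atlas: RegionAtlas,
    n_donors: int,
    n_genes: int,
    reliability: float,
    seed: int = 0,
    corr_range: float | None = None,
) -> list[RegionalMatrix]:
    """Donor expression matrices sharing a per-gene signal of given reliability.

    Each donor's profile for gene g is sqrt(r) * s_g + sqrt(1-r) * noise, so
    the expected inter-donor correlation of each gene equals ``reliability``.
    """
    if n_donors < 2:
        raise ValidationError("need at least 2 donors")
    if not 0 <= reliability <= 1:
        raise ValidationError("reliability must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n = atlas.n_regions
    dist = pairwise_distances(atlas)
    rho = corr_range if corr_range is not None else atlas_diameter(atlas) / 6
    shared = GRFSampler(dist, SAParams(corr_range=rho)).sample(rng, n_genes)
    shared = (shared - shared.mean(axis=0)) / shared.std(axis=0)
    names = [f"gene_{j:04d}" for j in range(n_genes)]
    donors = []
    for _ in range(n_donors):
        noise = rng.standard_normal((n, n_genes))
        vals = np.sqrt(reliability) * shared + np.sqrt(1 - reliability) * noise
        donors.append(RegionalMatrix(atlas, list(names), vals))
    return donors
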
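"""Dominance analysis and null-calibrated colocalization of regional maps.

Dominance analysis decomposes the R-squared of a multiple regression into
per-predictor "total dominance": the average, over all submodels not
containing a predictor, of the R-squared increment from adding it, averaged
first within each submodel size and then across sizes. The totals sum to
the full-model R-squared (this is the Shapley decomposition of R-squared),
so each predictor's share can be expressed as a percentage relative
contribution.

All 2^p - 1 submodel R-squared values are computed from a single
cross-product matrix of the centered data (no refitting from raw data),
which keeps dozens of targets at p = 16 predictors tractable.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .atlas import DistanceMatrix, RegionalMatrix, ValidationError, as_map
from .nulls import SurrogateGenerator, empirical_pvalue

MAX_PREDICTORS = 20


@dataclass
class DominanceResult:
    """Per-predictor dominance decomposition of one regression."""

    predictors: list[str]
    total_dominance: np.ndarray
    relative_contribution: np.ndarray  # percent of full R^2
    full_r2: float
    adjusted_r2: float
    n_submodels: int

    def __post_init__(self) -> None:
        if not np.isclose(self.total_dominance.sum(), self.full_r2, atol=1e-8):
            raise ValidationError("total dominances must sum to the full R^2")
        if self.full_r2 > 0 and not np.isclose(
            self.relative_contribution.sum(), 100.0, atol=1e-6
        ):
            raise ValidationError("relative contributions must sum to 100%")


class _SubsetSweep:
    """Reusable all-subsets R^2 engine for a fixed predictor count."""

    def __init__(self, p: int):
        self.p = p
        self._by_size = []
        for size in range(1, p + 1):
            idx = np.array(list(combinations(range(p), size)), dtype=np.intp)
            masks = (1 << idx).sum(axis=1)
            self._by_size.append((idx, masks))
        bits = np.arange(2**p, dtype=np.uint64)
        self._sizes = np.bitwise_count(bits).astype(np.intp)

    def r2_all(self, sxx: np.ndarray, sxy: np.ndarray, syy: float) -> np.ndarray:
        """R^2 for every predictor-subset bitmask (index = mask)."""
        r2 = np.zeros(2**self.p)
        for idx, masks in self._by_size:
            a = sxx[idx[:, :, None], idx[:, None, :]]
            b = sxy[idx]
            sol = np.linalg.solve(a, b[..., None])[..., 0]
            r2[masks] = np.einsum("ij,ij->i", b, sol) / syy
        return r2

    def total_dominance(self, r2: np.ndarray) -> np.ndarray:
        """Average R^2 increment of each predictor over sizes, from r2_all."""
        p = self.p
        bits = np.arange(2**p, dtype=np.intp)
        totals = np.empty(p)
        for k in range(p):
            without = bits[(bits >> k) & 1 == 0]
            inc = r2[without | (1 << k)] - r2[without]
            size = self._sizes[without]
            mean_by_size = np.bincount(size, weights=inc, minlength=p) / np.bincount(
                size, minlength=p
            )
            totals[k] = mean_by_size.mean()
        return totals


def _cross_products(x: np.ndarray, y: np.ndarray):
    xc = x - x.mean(axis=0)
    yc = y - y.mean()
    return xc.T @ xc, xc.T @ yc, float(yc @ yc)


def dominance_analysis(
    X: RegionalMatrix | np.ndarray,
    y: RegionalMatrix | np.ndarray,
    predictors: list[str] | None = None,
    max_predictors: int = MAX_PREDICTORS,
    _sweep: _SubsetSweep | None = None,
) -> DominanceResult:
    """Exhaustive dominance decomposition of an OLS regression."""
    if isinstance(X, RegionalMatrix):
        predictors = predictors or list(X.columns)
        X = X.require_complete("dominance_analysis")
    yv = as_map(y) if isinstance(y, RegionalMatrix) else np.asarray(y, float)
    X = np.asarray(X, float)
    n, p = X.shape
    predictors = predictors or [f"x{k}" for k in range(p)]
    if p > max_predictors:
        raise ValidationError(
            f"{p} predictors exceeds the exhaustive-enumeration bound "
            f"({max_predictors}); raise max_predictors explicitly to proceed"
        )
    if n <= p + 1:
        raise ValidationError("need n > p + 1 observations")
    sxx, sxy, syy = _cross_products(X, yv)
    if np.linalg.matrix_rank(sxx) < p:
        raise ValidationError("rank-deficient design matrix")
    if syy == 0:
        raise ValidationError("constant response")
    sweep = _sweep or _SubsetSweep(p)
    r2 = sweep.r2_all(sxx, sxy, syy)
    totals = sweep.total_dominance(r2)
    full_r2 = float(r2[-1])
    rel = 100 * totals / full_r2 if full_r2 > 0 else np.zeros(p)
    adj = 1 - (1 - full_r2) * (n - 1) / (n - p - 1)
    return DominanceResult(
        predictors=list(predictors),
        total_dominance=totals,
        relative_contribution=rel,
        full_r2=full_r2,
        adjusted_r2=float(adj),
        n_submodels=2**p - 1,
    )


@dataclass
class ColocalizationTable:
    """Per-target dominance results against a shared predictor set."""

    table: pd.DataFrame  # targets x (per-predictor % contribution, R^2 columns)
    results: dict[str, DominanceResult]

    @property
    def mean_adjusted_r2(self) -> float:
        return float(self.table["adjusted_r2"].mean())

    @property
    def median_adjusted_r2(self) -> float:
        return float(self.table["adjusted_r2"].median())


def colocalization_table(
    predictor_maps: RegionalMatrix,
    target_maps: RegionalMatrix,
    max_predictors: int = MAX_PREDICTORS,
) -> ColocalizationTable:
    """One dominance analysis per target column, predictors shared.

    Rows are sorted by adjusted R-squared descending. The subset-sweep
    structures and the predictor cross-product matrix are computed once and
    reused across targets.
    """
    if predictor_maps.atlas.n_regions != target_maps.atlas.n_regions:
        raise ValidationError("predictor and target maps must share an atlas")
    X = predictor_maps.require_complete("colocalization_table")
    Y = target_maps.require_complete("colocalization_table")
    p = X.shape[1]
    sweep = _SubsetSweep(p)
    results: dict[str, DominanceResult] = {}
    rows = []
    for j, name in enumerate(target_maps.columns):
        try:
            res = dominance_analysis(
                X,
                Y[:, j],
                predictors=list(predictor_maps.columns),
                max_predictors=max_predictors,
                _sweep=sweep,
            )
        except ValidationError as err:
            raise ValidationError(f"target {name!r}: {err}") from err
        results[name] = res
        rows.append(
            {
                "target": name,
                **dict(zip(res.predictors, res.relative_contribution)),
                "full_r2": res.full_r2,
                "adjusted_r2": res.adjusted_r2,
            }
        )
    table = (
        pd.DataFrame(rows)
        .set_index("target")
        .sort_values("adjusted_r2", ascending=False)
    )
    return ColocalizationTable(table, results)


def class_contrast(
    table: ColocalizationTable,
    labels: pd.Series | dict,
    paired: bool = False,
    welch: bool = False,
) -> tuple[float, int, float]:
    """Ionotropic-vs-metabotropic contrast of average relative contributions.

    Per target, the relative contributions are averaged within each receptor
    class; the two per-target vectors are compared with a two-tailed t-test
    (unpaired pooled-variance by default, df = 2k - 2).
    """
    labels = pd.Series(labels)
    classes = set(labels.unique())
    if classes != {"ionotropic", "metabotropic"}:
        raise ValidationError(f"labels must cover both classes, got {sorted(classes)}")
    some = next(iter(table.results.values()))
    unlabeled = [pr for pr in some.predictors if pr not in labels.index]
    if unlabeled:
        raise ValidationError(f"unlabeled predictors: {unlabeled}")
    iono = [pr for pr in some.predictors if labels[pr] == "ionotropic"]
    metab = [pr for pr in some.predictors if labels[pr] == "metabotropic"]
    if not iono or not metab:
        raise ValidationError("each class needs at least one predictor")
    tab = table.table
    if len(tab) < 2:
        raise ValidationError("need at least 2 targets")
    iono_means = tab[iono].mean(axis=1).to_numpy()
    metab_means = tab[metab].mean(axis=1).to_numpy()
    k = len(tab)
    if paired:
        t, p = stats.ttest_rel(iono_means, metab_means)
        df = k - 1
    else:
        t, p = stats.ttest_ind(iono_means, metab_means, equal_var=not welch)
        df = 2 * k - 2 if not welch else None
    return float(t), df, float(p)


def corr_with_null(
    map_a,
    map_b,
    dist: DistanceMatrix,
    n_surrogates: int = 1000,
    seed: int = 0,
    tail: str = "two_sided",
    **surrogate_kwargs,
) -> tuple[float, float]:
    """Spearman correlation with a variogram-surrogate p-value.

    The null distribution correlates ``map_b`` with surrogates of ``map_a``
    that preserve its value distribution and spatial autocorrelation.
    """
    a = as_map(map_a) if isinstance(map_a, RegionalMatrix) else np.asarray(map_a, float)
    b = as_map(map_b) if isinstance(map_b, RegionalMatrix) else np.asarray(map_b, float)
    rho = float(stats.spearmanr(a, b).statistic)
    gen = SurrogateGenerator(a, dist, **surrogate_kwargs)
    surr = gen.sample(n_surrogates, np.random.default_rng(seed))
    rb = stats.rankdata(b)
    rs = np.apply_along_axis(stats.rankdata, 0, surr)
    null_rho = np.corrcoef(rb, rs.T)[0, 1:]
    return rho, empirical_pvalue(rho, null_rho, tail=tail)
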
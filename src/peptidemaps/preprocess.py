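"""Expression QC, normalization, donor aggregation and stratified summaries.

The regional pipeline mirrors standard parcellated-transcriptome practice:
genes are retained when mean probe intensity, correlation with RNA-seq and
differential stability all clear their thresholds; expression is rescaled
with a robust sigmoid (median / IQR logistic) followed by min-max
normalization; donor matrices are mean-averaged; and maps are summarized per
anatomical stratum. Differential stability is the mean pairwise Pearson
correlation of a gene's regional profile across donors.

Probe-level steps (background filtering, probe selection against an RNA-seq
reference) act on probe x sample tables and are provided as a documented
pass-through contract; they are not part of the regional pipeline proper.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.stats import pearsonr, spearmanr

from .atlas import RegionAtlas, RegionalMatrix, ReceptorAnnotation, ValidationError


@dataclass(frozen=True)
class QCThresholds:
    """Gene-inclusion thresholds; ``inclusive`` keeps metrics equal to the cut.

    The defaults correspond to the standard rule set: mean intensity > 0.2,
    RNA-seq correlation > 0.2, differential stability > 0.1, compared
    inclusively because published tables print metrics rounded to the same
    precision as the cuts.
    """

    min_intensity: float = 0.2
    min_rnaseq_corr: float = 0.2
    min_diff_stability: float = 0.1
    inclusive: bool = True

    def __post_init__(self) -> None:
        for v in (self.min_intensity, self.min_rnaseq_corr, self.min_diff_stability):
            if not 0 <= v <= 1:
                raise ValidationError("thresholds must lie in [0, 1]")


def qc_filter(annotation: ReceptorAnnotation, thresholds: QCThresholds | None = None) -> list[str]:
    """Genes whose three QC metrics all clear the thresholds, order preserved."""
    thresholds = thresholds or QCThresholds()
    t = annotation.table
    metrics = ["mean_intensity", "rnaseq_correlation", "differential_stability"]
    for m in metrics:
        bad = t.loc[t[m].isna(), "gene"]
        if len(bad):
            raise ValidationError(f"missing metric {m!r} for gene {bad.iloc[0]!r}")
    cuts = [thresholds.min_intensity, thresholds.min_rnaseq_corr, thresholds.min_diff_stability]
    keep = np.ones(len(t), bool)
    for m, cut in zip(metrics, cuts):
        vals = t[m].to_numpy(float)
        keep &= (vals >= cut) if thresholds.inclusive else (vals > cut)
    return list(t.loc[keep, "gene"])


def robust_sigmoid_normalize(
    matrix: RegionalMatrix,
    axis: str = "within_gene",
    zero_iqr: str = "error",
) -> RegionalMatrix:
    """Robust sigmoid plus min-max rescaling, per column or per row.

    Each slice x is mapped through 1 / (1 + exp(-(x - median) / (IQR/1.35)))
    — the 1.35 divisor makes the scale consistent with the standard
    deviation under normality — and then min-max rescaled to [0, 1].
    ``axis='within_gene'`` normalizes each column across regions;
    ``'within_region'`` each row across variables. A zero-IQR slice either
    raises (default) or maps to a constant 0.5 (``zero_iqr='constant'``).
    """
    if axis not in ("within_gene", "within_region"):
        raise ValidationError(f"unknown axis {axis!r}")
    if zero_iqr not in ("error", "constant"):
        raise ValidationError(f"unknown zero_iqr policy {zero_iqr!r}")
    x = matrix.require_complete("robust_sigmoid_normalize")
    work = x.copy() if axis == "within_gene" else x.T.copy()
    out = np.empty_like(work)
    for j in range(work.shape[1]):
        col = work[:, j]
        q75, q25 = np.percentile(col, [75, 25])
        iqr = q75 - q25
        if iqr == 0:
            if zero_iqr == "error":
                raise ValidationError(f"zero IQR in slice {j}")
            out[:, j] = 0.5
            continue
        sig = 1.0 / (1.0 + np.exp(-(col - np.median(col)) / (iqr / 1.35)))
        out[:, j] = (sig - sig.min()) / (sig.max() - sig.min())
    values = out if axis == "within_gene" else out.T
    return RegionalMatrix(matrix.atlas, list(matrix.columns), values)


def _check_shared(donors: list[RegionalMatrix]) -> None:
    first = donors[0]
    for d in donors[1:]:
        if d.atlas is not first.atlas and not np.array_equal(
            d.atlas.region_ids, first.atlas.region_ids
        ):
            raise ValidationError("donor matrices must share an atlas")
        if d.columns != first.columns:
            raise ValidationError("donor matrices must share gene columns")


def differential_stability(
    donors: list[RegionalMatrix], method: str = "pearson"
) -> pd.Series:
    """Per-gene mean pairwise inter-donor correlation of regional profiles.

    Donor pairs where either profile has zero variance are skipped with a
    warning; a gene with no usable pair gets NaN.
    """
    if len(donors) < 2:
        raise ValidationError("need at least 2 donors")
    _check_shared(donors)
    corr = {"pearson": pearsonr, "spearman": spearmanr}[method]
    genes = donors[0].columns
    values = np.empty(len(genes))
    for j, gene in enumerate(genes):
        pair_r = []
        for a, b in combinations(donors, 2):
            xa, xb = a.values[:, j], b.values[:, j]
            if xa.std() == 0 or xb.std() == 0:
                warnings.warn(f"zero-variance donor profile for {gene}; pair skipped")
                continue
            pair_r.append(corr(xa, xb)[0])
        values[j] = np.mean(pair_r) if pair_r else np.nan
    return pd.Series(values, index=genes, name="differential_stability")


def aggregate_donors(donors: list[RegionalMatrix]) -> RegionalMatrix:
    """Elementwise mean across donors, ignoring explicitly missing cells."""
    if not donors:
        raise ValidationError("no donor matrices")
    _check_shared(donors)
    stack = np.stack([d.values for d in donors])
    masks = np.stack([d.mask for d in donors])
    counts = masks.sum(axis=0)
    with np.errstate(invalid="ignore"):
        mean = np.where(counts > 0, np.nansum(np.where(masks, stack, 0.0), axis=0), np.nan)
        mean = np.divide(mean, counts, out=np.full(counts.shape, np.nan), where=counts > 0)
    return RegionalMatrix(donors[0].atlas, list(donors[0].columns), mean, mask=counts > 0)


@dataclass
class StratifiedSummary:
    """Per-stratum means, per-structure medians and a clustering order."""

    stratum_means: pd.DataFrame  # strata x variables
    structure_medians: pd.DataFrame  # structure class x variables
    ordering: list[str]  # dendrogram leaf order over variables


def stratified_summary(matrix: RegionalMatrix, atlas: RegionAtlas | None = None) -> StratifiedSummary:
    """Summarize each map within anatomical strata and structure classes.

    Variables (columns) are ordered by average-linkage hierarchical
    clustering of their standardized regional profiles, the order used to
    sort receptors in expression heatmaps.
    """
    atlas = atlas or matrix.atlas
    x = matrix.require_complete("stratified_summary")
    df = pd.DataFrame(x, columns=matrix.columns)
    strata = atlas.strata.to_numpy()
    structures = atlas.structures.to_numpy()
    stratum_means = df.groupby(strata).mean()
    stratum_means.index.name = "stratum"
    structure_medians = df.groupby(structures).median()
    structure_medians.index.name = "structure"
    if len(matrix.columns) > 2:
        profiles = (x - x.mean(axis=0)) / np.where(x.std(axis=0) == 0, 1, x.std(axis=0))
        order_idx = leaves_list(linkage(profiles.T, method="average"))
        ordering = [matrix.columns[i] for i in order_idx]
    else:
        ordering = list(matrix.columns)
    return StratifiedSummary(stratum_means, structure_medians, ordering)


# ---------------------------------------------------------------------------
# probe-level pass-through contract
# ---------------------------------------------------------------------------

def filter_probes_by_background(
    intensity: pd.DataFrame,
    above_background: pd.DataFrame,
    fraction: float = 0.2,
    literal: bool = False,
) -> pd.DataFrame:
    """Drop probes by how often they fall below background noise.

    With ``literal=False`` (default) a probe is dropped when it is below
    background in MORE than ``fraction`` of samples — the reading under
    which the filter removes unreliable probes. ``literal=True`` applies the
    opposite comparison (drop when below background in LESS than
    ``fraction`` of samples); both are exposed because the source wording
    of this rule is self-contradictory and neither reading is asserted.
    """
    if intensity.shape != above_background.shape:
        raise ValidationError("intensity and background mask shapes differ")
    frac_below = 1.0 - above_background.to_numpy(bool).mean(axis=1)
    drop = (frac_below < fraction) if literal else (frac_below > fraction)
    return intensity.loc[~drop]


def select_probes_by_rnaseq(
    probe_expr: pd.DataFrame,
    probe_to_gene: pd.Series,
    rnaseq: pd.DataFrame,
) -> pd.Series:
    """Per gene, keep the probe maximally Pearson-correlated with RNA-seq.

    ``probe_expr`` is probes x samples, ``rnaseq`` genes x samples on the
    same sample columns; returns a gene -> probe mapping. A gene with no
    RNA-seq reference keeps its highest-mean-intensity probe.
    """
    if list(probe_expr.columns) != list(rnaseq.columns):
        raise ValidationError("probe and RNA-seq tables must share sample columns")
    chosen: dict[str, str] = {}
    for gene, probes in probe_to_gene.groupby(probe_to_gene):
        probe_ids = list(probes.index)
        if gene in rnaseq.index:
            ref = rnaseq.loc[gene].to_numpy(float)
            rs = [pearsonr(probe_expr.loc[p].to_numpy(float), ref)[0] for p in probe_ids]
            chosen[gene] = probe_ids[int(np.argmax(rs))]
        else:
            means = probe_expr.loc[probe_ids].mean(axis=1)
            chosen[gene] = means.idxmax()
    return pd.Series(chosen, name="probe")
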
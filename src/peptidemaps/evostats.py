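"""Sequence-similarity and concordance statistics for receptor evolution.

Inputs are consumed as upstream outputs: an aligned amino-acid FASTA for
percent identity, and a complete branches x signaling-category table of
substitution rates (dn/ds) for the Friedman test with Kendall's W effect
size (W = chi2 / (n * (k - 1))).
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import AlignIO
from scipy.stats import chi2 as chi2_dist
from scipy.stats import rankdata

from .atlas import ValidationError

GAP_CHARS = frozenset("-.")


def percent_identity(aligned) -> pd.DataFrame:
    """Pairwise percent identity over columns where both sequences are ungapped.

    ``aligned`` is a path to an aligned FASTA or a Biopython alignment.
    Columns where either sequence has a gap are excluded pairwise; a pair
    with no comparable columns gets NaN with a warning. The diagonal is 100.
    """
    if isinstance(aligned, (str, Path)):
        aligned = AlignIO.read(str(aligned), "fasta")
    names = [rec.id for rec in aligned]
    seqs = [str(rec.seq).upper() for rec in aligned]
    lengths = {len(s) for s in seqs}
    if len(lengths) > 1:
        raise ValidationError(f"sequences have unequal lengths: {sorted(lengths)}")
    arr = np.array([list(s) for s in seqs])
    is_gap = np.isin(arr, list(GAP_CHARS))
    n = len(seqs)
    out = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            comparable = ~is_gap[i] & ~is_gap[j]
            total = comparable.sum()
            if total == 0:
                warnings.warn(f"no comparable columns between {names[i]} and {names[j]}")
                out[i, j] = out[j, i] = np.nan
                continue
            matches = (arr[i, comparable] == arr[j, comparable]).sum()
            out[i, j] = out[j, i] = 100.0 * matches / total
    return pd.DataFrame(out, index=names, columns=names)


def kendalls_w_from_chi2(chi2: float, n: int, k: int) -> float:
    """Concordance effect size implied by a Friedman chi-squared statistic."""
    return chi2 / (n * (k - 1))


def friedman_kendall(
    table: pd.DataFrame | np.ndarray, tie_correction: bool = False
) -> tuple[float, float, float]:
    """Friedman test across columns with rows as repeated measures.

    Within-row mid-ranks; chi2 = 12/(n k (k+1)) * sum_j R_j^2 - 3 n (k+1)
    on k - 1 degrees of freedom, with an optional tie-correction divisor.
    Returns (chi2, p, Kendall's W).
    """
    x = np.asarray(table, float)
    if x.ndim != 2:
        raise ValidationError("expected a 2-D block table")
    n, k = x.shape
    if n < 2 or k < 2:
        raise ValidationError("need at least 2 rows and 2 columns")
    if not np.isfinite(x).all():
        raise ValidationError("the Friedman test requires a complete table")
    ranks = np.apply_along_axis(rankdata, 1, x)
    rj = ranks.sum(axis=0)
    chi2 = 12.0 / (n * k * (k + 1)) * np.sum(rj**2) - 3.0 * n * (k + 1)
    if tie_correction:
        ties = 0.0
        for row in x:
            _, counts = np.unique(row, return_counts=True)
            ties += np.sum(counts**3 - counts)
        denom = 1.0 - ties / (n * k * (k**2 - 1))
        if denom <= 0:
            raise ValidationError("all values tied in every row")
        chi2 /= denom
    p = float(chi2_dist.sf(chi2, k - 1))
    return float(chi2), p, kendalls_w_from_chi2(float(chi2), n, k)


def load_rate_table(path: str | Path) -> pd.DataFrame:
    """Branches x categories substitution-rate table (TSV, first column = branch)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    vals = df.to_numpy(float)
    if not np.isfinite(vals).all():
        raise ValidationError("rate table has missing cells")
    if np.any(vals <= 0):
        raise ValidationError("substitution rates must be positive before log transform")
    return df
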
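"""Count matrices, normalization, log fold changes and distribution diagnostics.

The central summary statistic of a negative-selection screen is the log2
fold change of a gRNA's (pseudocounted) abundance after versus before the
proliferation phase, LFC = log2((n_after + 1)/(n_ref + 1)), computed after
scaling every treatment column to the total read count of the reference
sample. The diagnostics implemented here quantify the pathologies this
package is about: the 90/10-percentile width of an abundance distribution,
the asymmetry of the LFC tails (fractions below -1 / above +1, overall and
per reference-abundance quintile), and between-replicate correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .exceptions import (
    DegenerateSampleError,
    InvalidParameterError,
    UndefinedWidthError,
)

__all__ = [
    "CountMatrix",
    "LFCMatrix",
    "size_normalize",
    "lfc",
    "lfc_matrix",
    "library_width",
    "tail_fractions",
    "replicate_correlation",
]


@dataclass
class CountMatrix:
    """gRNA x sample count table with sample roles.

    ``counts`` is indexed by guide id with one column per sample; ``genes``
    maps each guide to its gene. ``reference`` names the before-screen
    sample (plasmid library or T0); ``treatments`` the after-screen
    replicate columns.
    """

    counts: pd.DataFrame
    genes: pd.Series
    reference: str | None = None
    treatments: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise InvalidParameterError("counts must be non-negative")
        if self.counts.index.has_duplicates:
            raise InvalidParameterError("duplicate guide ids in count matrix")
        if not self.genes.index.equals(self.counts.index):
            self.genes = self.genes.reindex(self.counts.index)
            if self.genes.isna().any():
                raise InvalidParameterError("gene annotation missing for some guides")
        if self.reference is not None:
            if self.reference not in self.counts.columns:
                raise InvalidParameterError(
                    f"reference sample {self.reference!r} not in columns"
                )
            if self.counts[self.reference].sum() <= 0:
                raise DegenerateSampleError("reference column total is zero")
        missing = [t for t in self.treatments if t not in self.counts.columns]
        if missing:
            raise InvalidParameterError(f"treatment column(s) missing: {missing}")

    @property
    def n_guides(self) -> int:
        return len(self.counts)


@dataclass
class LFCMatrix:
    """Per-guide, per-treatment-replicate log2 fold changes.

    ``ref_abundance`` keeps the (raw) reference counts used for
    stratification and quintile diagnostics; ``strata`` is filled in by the
    null-model fitting step.
    """

    lfc: pd.DataFrame  # guides x treatment replicates, finite
    ref_abundance: pd.Series
    genes: pd.Series
    strata: pd.Series | None = None

    @property
    def n_replicates(self) -> int:
        return self.lfc.shape[1]


def size_normalize(cm: CountMatrix) -> CountMatrix:
    """Scale every treatment column to the reference sample's total count.

    The reference column is left unchanged; each treatment column is
    multiplied by (reference total)/(column total), yielding real-valued
    "counts" with equal column sums.
    """
    if cm.reference is None:
        raise InvalidParameterError("count matrix has no reference sample")
    ref_total = cm.counts[cm.reference].sum()
    out = cm.counts.astype(float).copy()
    for col in cm.treatments:
        col_total = out[col].sum()
        if col_total <= 0:
            raise DegenerateSampleError(f"treatment column {col!r} total is zero")
        out[col] *= ref_total / col_total
    return CountMatrix(out, cm.genes, cm.reference, list(cm.treatments))


def lfc(n_treat, n_ref):
    """Pseudocounted log2 fold change: log2((n_treat + 1)/(n_ref + 1)).

    Accepts scalars or arrays; counts must be non-negative (real-valued
    counts from size normalization are fine).
    """
    n_treat = np.asarray(n_treat, dtype=float)
    n_ref = np.asarray(n_ref, dtype=float)
    if (n_treat < 0).any() or (n_ref < 0).any():
        raise InvalidParameterError("counts must be non-negative")
    out = np.log2((n_treat + 1.0) / (n_ref + 1.0))
    return float(out) if out.ndim == 0 else out


def lfc_matrix(cm: CountMatrix, normalize: bool = True) -> LFCMatrix:
    """Compute the LFC of every treatment replicate against the reference.

    Size normalization (on by default) is applied first; the pseudocount of
    1 is added to the *normalized* counts.
    """
    if cm.reference is None or not cm.treatments:
        raise InvalidParameterError("need a reference and >=1 treatment column")
    ref_raw = cm.counts[cm.reference].copy()
    work = size_normalize(cm) if normalize else cm
    ref = work.counts[work.reference]
    lfcs = pd.DataFrame(
        {col: lfc(work.counts[col], ref) for col in work.treatments},
        index=work.counts.index,
    )
    return LFCMatrix(lfc=lfcs, ref_abundance=ref_raw, genes=cm.genes)


def library_width(abundances) -> float:
    """90/10-percentile ratio of an abundance distribution.

    Uses linear interpolation between order statistics (the common
    statistical-package default quantile convention).
    """
    x = np.asarray(abundances, dtype=float)
    if x.size < 10:
        raise InvalidParameterError("need at least 10 abundances for a width")
    p10, p90 = np.percentile(x, [10, 90])
    if p10 <= 0:
        raise UndefinedWidthError(
            f"10th percentile is {p10}; width is undefined (p10 = 0)"
        )
    return float(p90 / p10)


@dataclass
class TailFractions:
    """LFC tail asymmetry summary (fractions averaged over replicates)."""

    frac_below: float  # fraction with LFC < -1
    frac_above: float  # fraction with LFC > +1
    per_quintile: pd.DataFrame  # index 1..5, columns frac_below / frac_above


def tail_fractions(lfcs: LFCMatrix, mask=None) -> TailFractions:
    """Fractions of guides with LFC < -1 and LFC > +1.

    Computed per treatment replicate then averaged; the per-quintile
    breakdown assigns guides to quintiles of the reference abundance
    (quintile 1 = least abundant), with ties kept in stable guide order.
    Empty quintiles are reported as NaN.
    """
    if mask is None:
        mask = np.ones(len(lfcs.lfc), dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise InvalidParameterError("mask selects no guides")
    sub = lfcs.lfc.loc[mask]
    ref = lfcs.ref_abundance.loc[mask]

    below = (sub < -1).mean(axis=0)  # per replicate
    above = (sub > 1).mean(axis=0)

    # stable-order quintiles of reference abundance
    order = np.argsort(ref.to_numpy(), kind="stable")
    q = np.empty(len(ref), dtype=int)
    q[order] = np.minimum((np.arange(len(ref)) * 5) // len(ref), 4) + 1
    rows = []
    for quint in range(1, 6):
        in_q = q == quint
        if not in_q.any():
            rows.append((np.nan, np.nan))
            continue
        rows.append(
            (
                float((sub.iloc[in_q] < -1).mean(axis=0).mean()),
                float((sub.iloc[in_q] > 1).mean(axis=0).mean()),
            )
        )
    per_quintile = pd.DataFrame(
        rows, index=pd.RangeIndex(1, 6, name="quintile"),
        columns=["frac_below", "frac_above"],
    )
    return TailFractions(
        frac_below=float(below.mean()),
        frac_above=float(above.mean()),
        per_quintile=per_quintile,
    )


def replicate_correlation(lfcs: LFCMatrix) -> float:
    """Mean pairwise Pearson correlation of per-guide LFCs across replicates.

    Returns NaN (with a warning from numpy suppressed into NaN) when a
    replicate column is constant, in which case the correlation is
    undefined.
    """
    if lfcs.n_replicates < 2:
        raise InvalidParameterError("need >= 2 replicates for a correlation")
    cols = lfcs.lfc.columns
    rs = []
    for a, b in combinations(cols, 2):
        x = lfcs.lfc[a].to_numpy()
        y = lfcs.lfc[b].to_numpy()
        if np.std(x) == 0 or np.std(y) == 0:
            rs.append(np.nan)
        else:
            rs.append(float(np.corrcoef(x, y)[0, 1]))
    return float(np.nanmean(rs)) if not all(np.isnan(rs)) else float("nan")
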
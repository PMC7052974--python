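"""Gene-level aggregation of gRNA ranks by alpha-robust rank aggregation.

For one tail (depletion or enrichment) the p-values of all guides and all
replicates are pooled into a single ranked list; each guide/replicate entry
gets a normalized rank r in (0, 1]. A gene with n such entries is scored by

    rho = min_{k = 1..j} BetaCDF(r_(k); k, n - k + 1)

over its j "selected" entries (those with p below the alpha cutoff; rho = 1
when none is selected): under the null the k-th smallest of n uniform ranks
is Beta(k, n-k+1), so rho measures how surprisingly small the gene's best
ranks are while ignoring its non-significant guides. Significance of rho is
calibrated by permutation: pseudo-genes of n uniform ranks, subjected to
the same selection rule (a rank is selected iff it falls below the
alpha-quantile threshold of the pooled observed list), yield the null
distribution of rho.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .exceptions import InvalidParameterError
from .null_model import GuideResults

__all__ = [
    "normalized_ranks",
    "rho_statistic",
    "permutation_pvalues",
    "bh_fdr",
    "rank_genes",
    "aggregate_genes",
]


def normalized_ranks(
    guide_results: GuideResults, tail: str = "depletion"
) -> pd.DataFrame:
    """Pool all replicates of one tail into a single normalized rank list.

    Returns a tidy frame with one row per (guide, replicate): columns
    ``gene``, ``p``, ``norm_rank`` where norm_rank = pooled rank /
    (N_guides * N_replicates). Ranking is ascending in p with ties broken
    by the more extreme LFC, then stable order.
    """
    if tail not in ("depletion", "enrichment"):
        raise InvalidParameterError("tail must be 'depletion' or 'enrichment'")
    pvals = (
        guide_results.p_depletion if tail == "depletion" else guide_results.p_enrichment
    )
    sign = 1.0 if tail == "depletion" else -1.0
    frames = []
    for rep in pvals.columns:
        frames.append(
            pd.DataFrame(
                {
                    "guide": pvals.index,
                    "replicate": rep,
                    "gene": guide_results.genes.to_numpy(),
                    "p": pvals[rep].to_numpy(),
                    "tiebreak": sign * guide_results.lfc[rep].to_numpy(),
                }
            )
        )
    pooled = pd.concat(frames, ignore_index=True)
    order = np.lexsort(
        (np.arange(len(pooled)), pooled["tiebreak"].to_numpy(), pooled["p"].to_numpy())
    )
    ranks = np.empty(len(pooled), dtype=np.int64)
    ranks[order] = np.arange(1, len(pooled) + 1)
    pooled["norm_rank"] = ranks / len(pooled)
    return pooled.drop(columns="tiebreak")


def rho_statistic(norm_ranks, alpha: float = 0.05, selected=None) -> float:
    """Beta order-statistic score of one gene's normalized ranks.

    ``selected`` marks the ranks that passed the alpha cutoff (all, if
    omitted). With the j selected ranks sorted ascending, rho is the
    minimum over k of BetaCDF(r_(k); k, n - k + 1) where n is the total
    number of ranks (selected or not); rho = 1 when nothing is selected.
    """
    r = np.asarray(norm_ranks, dtype=float)
    n = r.size
    if n == 0:
        raise InvalidParameterError("gene has no ranks")
    if np.any(r <= 0) or np.any(r > 1):
        raise InvalidParameterError("normalized ranks must lie in (0, 1]")
    if selected is None:
        selected = np.ones(n, dtype=bool)
    selected = np.asarray(selected, dtype=bool)
    sel = np.sort(r[selected])
    j = sel.size
    if j == 0:
        return 1.0
    k = np.arange(1, j + 1)
    return float(np.min(stats.beta.cdf(sel, k, n - k + 1)))


def _rho_matrix(sorted_ranks: np.ndarray, n_selected: np.ndarray) -> np.ndarray:
    """Vectorized rho for many pseudo-genes.

    ``sorted_ranks`` is (m, n) with rows ascending; ``n_selected`` gives j
    per row (selected ranks are a prefix of the sorted row).
    """
    m, n = sorted_ranks.shape
    k = np.arange(1, n + 1)
    betas = stats.beta.cdf(sorted_ranks, k, n - k + 1)
    mask = k[None, :] > n_selected[:, None]
    betas = np.where(mask, np.inf, betas)
    rho = betas.min(axis=1)
    rho[n_selected == 0] = 1.0
    return rho


def permutation_pvalues(
    rho_obs: pd.Series,
    n_ranks_per_gene: pd.Series,
    threshold: float,
    n_perm: int = 1000,
    rng: np.random.Generator | int | None = None,
    rank_sampler=None,
) -> pd.Series:
    """Permutation p-value per gene: pseudo-genes of n uniform ranks.

    For every distinct rank count n, ``n_perm`` pseudo-genes of n i.i.d.
    uniform ranks are drawn; a pseudo-rank is selected iff it falls below
    ``threshold`` (the alpha-quantile of the pooled observed rank list),
    mirroring the selection applied to real genes. The p-value uses add-one
    smoothing: p = (1 + #{rho_perm <= rho_obs}) / (1 + n_perm).

    ``rank_sampler(rng, size)`` may replace the uniform sampler (used by
    tests to compare against exact enumeration on a discrete grid).
    """
    if n_perm < 100:
        raise InvalidParameterError("n_perm must be >= 100")
    rng = np.random.default_rng(rng)
    sampler = rank_sampler or (lambda r, size: r.uniform(size=size))
    out = pd.Series(index=rho_obs.index, dtype=float)
    for n in sorted(n_ranks_per_gene.unique()):
        n = int(n)
        u = np.sort(sampler(rng, (n_perm, n)), axis=1)
        j = (u < threshold).sum(axis=1)
        rho_null = _rho_matrix(u, j)
        genes_n = n_ranks_per_gene.index[n_ranks_per_gene == n]
        obs = rho_obs.loc[genes_n].to_numpy()
        counts = (rho_null[None, :] <= obs[:, None]).sum(axis=1)
        out.loc[genes_n] = (1.0 + counts) / (1.0 + n_perm)
    return out


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise InvalidParameterError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def aggregate_genes(
    guide_results: GuideResults,
    tail: str = "depletion",
    alpha: float = 0.05,
    n_perm: int = 1000,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Full alpha-RRA for one tail: rho, permutation p, BH FDR per gene.

    Returns a frame indexed by gene with columns rho, p_perm, fdr,
    n_ranks, n_selected.
    """
    pooled = normalized_ranks(guide_results, tail)
    pooled["selected"] = pooled["p"].to_numpy() < alpha
    threshold = float(pooled["selected"].mean())  # alpha-quantile of the rank list

    by_gene = pooled.groupby("gene", sort=True)
    rho_obs = by_gene.apply(
        lambda g: rho_statistic(
            g["norm_rank"].to_numpy(), alpha, g["selected"].to_numpy()
        ),
        include_groups=False,
    ).rename("rho")
    n_ranks = by_gene.size().rename("n_ranks")
    p_perm = permutation_pvalues(rho_obs, n_ranks, threshold, n_perm, rng)
    result = pd.DataFrame(
        {
            "rho": rho_obs,
            "p_perm": p_perm,
            "fdr": bh_fdr(p_perm.to_numpy()),
            "n_ranks": n_ranks,
            "n_selected": by_gene["selected"].sum(),
        }
    )
    result.index.name = "gene"
    return result


def rank_genes(
    gene_table: pd.DataFrame,
    p_col: str = "p_perm",
    lfc_col: str = "gene_lfc",
    tail: str = "depletion",
) -> pd.DataFrame:
    """Total ordering of genes: ascending p, ties by mean LFC, then gene id.

    In the depletion tail a more negative gene LFC wins ties; in the
    enrichment tail a more positive one. The returned frame carries a
    ``rank`` column (1 = most significant) and is sorted by it.
    """
    if tail not in ("depletion", "enrichment"):
        raise InvalidParameterError("tail must be 'depletion' or 'enrichment'")
    sign = 1.0 if tail == "depletion" else -1.0
    df = gene_table.copy()
    order = np.lexsort(
        (
            df.index.to_numpy(),
            sign * df[lfc_col].to_numpy(),
            df[p_col].to_numpy(),
        )
    )
    ranks = np.empty(len(df), dtype=np.int64)
    ranks[order] = np.arange(1, len(df) + 1)
    df["rank"] = ranks
    return df.sort_values("rank")
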
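"""Generative simulation of a pooled CRISPR knockout screen.

The simulator tracks the integer abundance of every gRNA from the plasmid
library through viral transduction, growth to T0, repeated cell-splitting
bottlenecks with exponential growth, and finally PCR/sequencing of the
library, T0 and T1 pools. Every stochastic step is a draw from the
multivariate hypergeometric distribution (sampling cells or molecules
without replacement from the current integer pool); when the requested
number of draws exceeds the pool total — which happens for transduction and
sequencing of small lognormal libraries — the draw falls back to a
multinomial with the pool frequencies, mimicking amplification with
replacement, and a warning is emitted.

Growth is deterministic per gRNA: over one splitting interval the abundance
is multiplied by e^beta_g and truncated to the integer part, where beta_g is
the baseline growth factor beta = (delta_t / tau) * ln 2 scaled by the
gRNA's fitness effect (beta for neutral, beta*(1+eps) for growth-promoting
knockouts, beta*(1-eps) for growth-suppressing knockouts, with eps drawn per
gene from the grid {0, 0.01, ..., 0.2}).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .counts import CountMatrix
from .exceptions import InvalidParameterError, SimulationCollapseError
from .params import SimParams

__all__ = [
    "GuideLibrary",
    "PoolState",
    "SimulationResult",
    "sigma_for_width",
    "generate_library",
    "assign_fitness",
    "growth_factor",
    "grow",
    "subsample",
    "run_screen",
    "coverage_for_p10",
]

#: log-mean of the plasmid-library lognormal; chosen so that simulated
#: libraries resemble experimentally observed count distributions.
LIB_LOG_MEAN = 5.0

#: grid of fitness-effect magnitudes eps available to non-neutral genes
EPSILON_GRID = np.round(np.arange(0, 0.201, 0.01), 2)

_Z_SPREAD = stats.norm.ppf(0.9) - stats.norm.ppf(0.1)  # = 2.5631...


@dataclass
class GuideLibrary:
    """gRNA identities, plasmid abundances and ground-truth fitness effects."""

    guide_id: np.ndarray  # str array, length N_tot
    gene_id: np.ndarray  # str array, length N_tot
    plasmid_abundance: np.ndarray  # non-negative int64
    fitness_class: np.ndarray  # 'neutral' | 'negative' | 'positive' per guide
    epsilon: np.ndarray  # effect magnitude per guide (0 for neutral)
    growth_factor: np.ndarray  # beta_g per splitting interval

    @property
    def n_guides(self) -> int:
        return len(self.guide_id)

    @property
    def neutral_mask(self) -> np.ndarray:
        return self.fitness_class == "neutral"

    def gene_truth(self) -> pd.Series:
        """Ground-truth fitness class per gene (genes share one class)."""
        s = pd.Series(self.fitness_class, index=self.gene_id)
        return s.groupby(level=0, sort=False).first().rename("fitness_class")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sgRNA": self.guide_id,
                "gene": self.gene_id,
                "plasmid_abundance": self.plasmid_abundance,
                "fitness_class": self.fitness_class,
                "epsilon": self.epsilon,
                "growth_factor": self.growth_factor,
            }
        )


@dataclass
class PoolState:
    """Integer gRNA abundances of a cell or molecule pool at one stage."""

    abundances: np.ndarray
    stage: str

    @property
    def total(self) -> int:
        return int(self.abundances.sum())


@dataclass
class SimulationResult:
    """All sequenced count matrices plus the ground truth of one screen."""

    library_counts: CountMatrix
    t0_counts: CountMatrix
    t1_counts: CountMatrix
    truth: pd.Series  # gene_id -> fitness_class
    params: SimParams
    library: GuideLibrary
    #: per biological replicate: list of pool abundance vectors recorded
    #: after each splitting round's growth step (only if requested)
    trajectories: list[list[np.ndarray]] | None = field(default=None, repr=False)

    def combined_counts(self, reference: str | None = None) -> CountMatrix:
        """All samples in one matrix; reference defaults to the first
        library sequencing replicate (the recommended reference)."""
        counts = pd.concat(
            [
                self.library_counts.counts,
                self.t0_counts.counts,
                self.t1_counts.counts,
            ],
            axis=1,
        )
        if reference is None:
            reference = self.library_counts.counts.columns[0]
        treatments = [c for c in self.t1_counts.counts.columns]
        return CountMatrix(
            counts=counts,
            genes=self.library_counts.genes,
            reference=reference,
            treatments=treatments,
        )

    def analysis_counts(self, aggregate_technical: bool = False) -> CountMatrix:
        """Reference (first library replicate) + T1 treatment columns.

        With ``aggregate_technical`` the technical sequencing replicates of
        each biological replicate are summed into one column per biological
        replicate (they measure the same pool, so treating them as
        independent replicates in the analysis would be pseudo-replication).
        """
        cm = self.combined_counts()
        if not aggregate_technical:
            keep = [cm.reference] + cm.treatments
            return CountMatrix(
                counts=cm.counts[keep],
                genes=cm.genes,
                reference=cm.reference,
                treatments=cm.treatments,
            )
        t1 = self.t1_counts.counts
        bios = sorted({c.rsplit("_", 1)[0] for c in t1.columns})
        agg = pd.DataFrame(
            {b: t1[[c for c in t1.columns if c.startswith(b + "_")]].sum(axis=1)
             for b in bios}
        )
        counts = pd.concat([cm.counts[[cm.reference]], agg], axis=1)
        return CountMatrix(
            counts=counts, genes=cm.genes, reference=cm.reference, treatments=bios
        )


def sigma_for_width(lib_width: float) -> float:
    """Log-scale standard deviation giving a lognormal the requested
    90/10-percentile ratio.

    For LN(mu, sigma) the 90/10 quantile ratio is exp(sigma*(z90 - z10)),
    independent of mu, so sigma = ln(L) / (z90 - z10).
    """
    if lib_width < 1:
        raise InvalidParameterError("library width must be >= 1")
    return float(np.log(lib_width) / _Z_SPREAD)


def growth_factor(delta_t: float, tau: float) -> float:
    """Baseline growth factor per splitting interval: beta = (delta_t/tau)*ln 2.

    e^beta is then the fold-expansion of a neutral clone over one interval;
    delta_t == tau gives beta = ln 2, i.e. exactly one doubling.
    """
    if delta_t <= 0 or tau <= 0:
        raise InvalidParameterError("delta_t and tau must be strictly positive")
    return float((delta_t / tau) * np.log(2.0))


def assign_fitness(
    params: SimParams, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Assign fitness classes and effect sizes at the gene level.

    round(freq_negfc * n_genes) genes become negative, round(freq_posfc *
    n_genes) positive, the rest neutral; gene order is randomized so classes
    are not correlated with gene index. All guides of a gene share the class
    and a single eps drawn uniformly from {0, 0.01, ..., 0.2}.

    Returns (fitness_class, epsilon, growth_factor) arrays per *guide*.
    """
    n_genes = params.n_genes
    n_neg = int(round(params.freq_negfc * n_genes))
    n_pos = int(round(params.freq_posfc * n_genes))
    if n_neg + n_pos > n_genes:
        raise InvalidParameterError("fitness-effect fractions exceed gene count")

    gene_class = np.array(["neutral"] * n_genes, dtype=object)
    order = rng.permutation(n_genes)
    gene_class[order[:n_neg]] = "negative"
    gene_class[order[n_neg : n_neg + n_pos]] = "positive"

    gene_eps = np.zeros(n_genes)
    affected = gene_class != "neutral"
    gene_eps[affected] = rng.choice(EPSILON_GRID, size=int(affected.sum()))

    beta = growth_factor(params.split_interval, params.dupl_time)
    sign = np.where(
        gene_class == "negative", -1.0, np.where(gene_class == "positive", 1.0, 0.0)
    )
    gene_beta = beta * (1.0 + sign * gene_eps)

    k = params.n_sgrnas_per_gene
    return (
        np.repeat(gene_class, k).astype(object),
        np.repeat(gene_eps, k),
        np.repeat(gene_beta, k),
    )


def generate_library(
    params: SimParams, rng: np.random.Generator | int | None = None
) -> tuple[GuideLibrary, PoolState]:
    """Draw plasmid abundances and ground-truth fitness effects.

    Abundances are i.i.d. LN(5, sigma_for_width(L)) rounded to the nearest
    integer (guides rounded to 0 are kept at abundance 0).
    """
    rng = np.random.default_rng(rng)
    sigma = sigma_for_width(params.lib_width)
    draws = rng.lognormal(LIB_LOG_MEAN, sigma, params.n_sgrnas)
    abundances = np.round(draws).astype(np.int64)

    n_genes = params.n_genes
    gene_ids = np.repeat(
        np.array([f"gene_{i:05d}" for i in range(n_genes)], dtype=object),
        params.n_sgrnas_per_gene,
    )
    guide_ids = np.array(
        [f"{g}_sg{j % params.n_sgrnas_per_gene + 1}" for j, g in enumerate(gene_ids)],
        dtype=object,
    )
    fitness_class, epsilon, beta_g = assign_fitness(params, rng)
    lib = GuideLibrary(
        guide_id=guide_ids,
        gene_id=gene_ids,
        plasmid_abundance=abundances,
        fitness_class=fitness_class,
        epsilon=epsilon,
        growth_factor=beta_g,
    )
    return lib, PoolState(abundances.copy(), "library")


def grow(pool: PoolState, library: GuideLibrary, stage: str | None = None) -> PoolState:
    """One deterministic growth interval: n_g -> floor(e^{beta_g} * n_g).

    Zeros stay zero — extinction of a guide is absorbing.
    """
    if np.any(pool.abundances < 0):
        raise InvalidParameterError("pool abundances must be non-negative")
    grown = np.floor(np.exp(library.growth_factor) * pool.abundances).astype(np.int64)
    return PoolState(grown, stage or f"{pool.stage}_grown")


def subsample(
    pool: PoolState,
    n_draws: int,
    rng: np.random.Generator | int | None = None,
    stage: str | None = None,
) -> PoolState:
    """Draw ``n_draws`` cells/molecules without replacement from the pool.

    The draw is multivariate hypergeometric on the integer abundances. If
    n_draws exceeds the pool total the draw switches to a multinomial with
    the pool frequencies (amplification with replacement) and warns.
    """
    if n_draws < 0:
        raise InvalidParameterError("n_draws must be >= 0")
    stage = stage or f"{pool.stage}_sampled"
    total = pool.total
    if total == 0:
        raise SimulationCollapseError(stage)
    if n_draws == 0:
        return PoolState(np.zeros_like(pool.abundances), stage)
    rng = np.random.default_rng(rng)
    if n_draws > total:
        warnings.warn(
            f"requested {n_draws} draws from a pool of {total} at stage "
            f"'{stage}'; falling back to multinomial sampling",
            stacklevel=2,
        )
        probs = pool.abundances / total
        out = rng.multinomial(n_draws, probs).astype(np.int64)
    else:
        out = rng.multivariate_hypergeometric(
            pool.abundances, n_draws, method="marginals"
        ).astype(np.int64)
    return PoolState(out, stage)


def _sequence(
    pool: PoolState,
    params: SimParams,
    rng_streams: list[np.random.Generator],
    names: list[str],
) -> pd.DataFrame:
    """Sequence a pool: C_PCR * N_tot draws, one column per technical replicate."""
    n_draws = int(round(params.cov_pcr * params.n_sgrnas))
    cols = {}
    for name, stream in zip(names, rng_streams):
        cols[name] = subsample(pool, n_draws, stream, stage=f"seq_{name}").abundances
    return pd.DataFrame(cols)


def run_screen(
    params: SimParams,
    record_trajectories: bool = False,
) -> SimulationResult:
    """Simulate a complete screen and return all sequenced counts + truth.

    Stages: plasmid library -> library sequencing (n_repl_lib_pcr technical
    replicates); transduction (C_virus*N_tot draws); one growth interval to
    T0; T0 sequencing (n_repl_pcr technical replicates); then n_repl_sel
    independent biological replicates each running n_splittings rounds of
    (C_cells*N_tot-draw bottleneck, growth) from the shared T0 pool,
    followed by T1 sequencing (n_repl_pcr technical replicates each).
    """
    root = np.random.SeedSequence(params.rng_seed)
    ss_lib, ss_libseq, ss_trans, ss_t0seq, ss_bio = root.spawn(5)

    # the library (abundances + fitness truth) has its own child stream so
    # that e.g. changing n_repl_sel does not change the library itself
    library, lib_pool = generate_library(params, np.random.default_rng(ss_lib))
    if lib_pool.total == 0:
        raise SimulationCollapseError("library")

    guide_index = pd.Index(library.guide_id, name="sgRNA")
    genes = pd.Series(library.gene_id, index=guide_index, name="gene")

    # --- library sequencing ---------------------------------------------
    lib_names = [f"library_R1_{t + 1}" for t in range(params.n_repl_lib_pcr)]
    lib_streams = [np.random.default_rng(s) for s in ss_libseq.spawn(len(lib_names))]
    lib_df = _sequence(lib_pool, params, lib_streams, lib_names)
    lib_df.index = guide_index

    # --- transduction and growth to T0 ----------------------------------
    n_trans = int(round(params.cov_virus * params.n_sgrnas))
    trans_pool = subsample(
        lib_pool, n_trans, np.random.default_rng(ss_trans), stage="transduced"
    )
    t0_pool = grow(trans_pool, library, stage="t0")
    if t0_pool.total == 0:
        raise SimulationCollapseError("t0")

    t0_names = [f"t0_R1_{t + 1}" for t in range(params.n_repl_pcr)]
    t0_streams = [np.random.default_rng(s) for s in ss_t0seq.spawn(len(t0_names))]
    t0_df = _sequence(t0_pool, params, t0_streams, t0_names)
    t0_df.index = guide_index

    # --- proliferation phase: biological replicates ----------------------
    n_split_draws = int(round(params.cov_cells * params.n_sgrnas))
    bio_seeds = ss_bio.spawn(params.n_repl_sel)
    t1_cols: dict[str, np.ndarray] = {}
    trajectories: list[list[np.ndarray]] | None = [] if record_trajectories else None
    for b, bio_ss in enumerate(bio_seeds, start=1):
        split_seeds = bio_ss.spawn(params.n_splittings + 1)
        pool = t0_pool
        track: list[np.ndarray] = []
        for i in range(params.n_splittings):
            pool = subsample(
                pool,
                n_split_draws,
                np.random.default_rng(split_seeds[i]),
                stage=f"split_{i + 1}_R{b}",
            )
            pool = grow(pool, library, stage=f"grown_{i + 1}_R{b}")
            if pool.total == 0:
                raise SimulationCollapseError(pool.stage)
            if record_trajectories:
                track.append(pool.abundances.copy())
        if record_trajectories:
            trajectories.append(track)
        seq_streams = [
            np.random.default_rng(s)
            for s in split_seeds[params.n_splittings].spawn(params.n_repl_pcr)
        ]
        names = [f"t1_R{b}_{t + 1}" for t in range(params.n_repl_pcr)]
        df = _sequence(pool, params, seq_streams, names)
        for name in names:
            t1_cols[name] = df[name].to_numpy()

    t1_df = pd.DataFrame(t1_cols, index=guide_index)

    lib_cm = CountMatrix(lib_df, genes, reference=lib_names[0], treatments=[])
    t0_cm = CountMatrix(t0_df, genes, reference=None, treatments=list(t0_df.columns))
    t1_cm = CountMatrix(t1_df, genes, reference=None, treatments=list(t1_df.columns))

    return SimulationResult(
        library_counts=lib_cm,
        t0_counts=t0_cm,
        t1_counts=t1_cm,
        truth=library.gene_truth(),
        params=params,
        library=library,
        trajectories=trajectories,
    )


def coverage_for_p10(abundances: np.ndarray, target_p10_coverage: float = 100.0) -> float:
    """Coverage C such that the 10th-percentile guide is sampled ~target-fold.

    Solves C = target * (pool total) / (N_tot * p10 abundance): with
    C*N_tot total draws, a guide at the 10th abundance percentile expects
    C*N_tot*p10/total draws, which equals ``target_p10_coverage``.
    """
    abundances = np.asarray(abundances)
    p10 = np.percentile(abundances, 10)
    if p10 <= 0:
        raise InvalidParameterError("10th-percentile abundance is zero")
    return float(target_p10_coverage * abundances.sum() / (len(abundances) * p10))
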
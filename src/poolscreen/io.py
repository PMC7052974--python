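"""Reading and writing count tables, truth tables and result tables.

Count tables follow the de-facto screen-count dialect: a tab-separated
header ``sgRNA<TAB>gene<TAB><sample>...`` with one integer column per
sample. Simulator output names its samples ``<stage>_R<bio>_<tech>``
(stages: library, t0, t1). Output files written by this package carry a
header comment line with the config hash and seed for provenance.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .counts import CountMatrix
from .exceptions import CountTableParseError
from .simulate import SimulationResult

__all__ = [
    "read_counts",
    "write_counts",
    "write_simulation",
    "read_truth",
    "write_table",
]

logger = logging.getLogger(__name__)


def _pick_reference(columns: list[str]) -> str:
    """Default reference: a library column when present, else T0, else first.

    The plasmid library is the preferred reference because gRNAs targeting
    essential genes are already depleted by T0.
    """
    lib = [c for c in columns if c.lower().startswith(("lib", "plasmid"))]
    if lib:
        return lib[0]
    t0 = [c for c in columns if c.lower().startswith("t0")]
    if t0:
        logger.info("no library column found; using T0 column %r as reference", t0[0])
        return t0[0]
    logger.info("no library/T0 column found; using first column %r as reference",
                columns[0])
    return columns[0]


def read_counts(
    path: str,
    reference: str | None = None,
    treatments: list[str] | None = None,
) -> CountMatrix:
    """Parse a tab-separated count table into a :class:`CountMatrix`.

    Lines starting with ``#`` are ignored. Errors name the offending line
    number. Without an explicit ``reference``, a library column is
    preferred, then T0, then the first sample column; ``treatments``
    default to all non-reference columns.
    """
    with open(path) as fh:
        lines = fh.readlines()
    rows = [
        (i + 1, line.rstrip("\n").split("\t"))
        for i, line in enumerate(lines)
        if line.strip() and not line.startswith("#")
    ]
    if not rows:
        raise CountTableParseError(f"{path}: empty count table")
    header_no, header = rows[0]
    if len(header) < 3 or header[0] not in ("sgRNA", "guide", "sgrna"):
        raise CountTableParseError(
            f"{path}:{header_no}: expected header 'sgRNA\\tgene\\t<samples...>', "
            f"got {header[:3]!r}"
        )
    samples = header[2:]
    guides, genes, data = [], [], []
    seen: set[str] = set()
    for line_no, fields in rows[1:]:
        if len(fields) != len(header):
            raise CountTableParseError(
                f"{path}:{line_no}: expected {len(header)} fields, got {len(fields)}"
            )
        gid = fields[0]
        if gid in seen:
            raise CountTableParseError(f"{path}:{line_no}: duplicate guide id {gid!r}")
        seen.add(gid)
        vals = []
        for col, raw in zip(samples, fields[2:]):
            try:
                v = int(raw)
            except ValueError:
                raise CountTableParseError(
                    f"{path}:{line_no}: non-integer count {raw!r} in column {col!r}"
                ) from None
            if v < 0:
                raise CountTableParseError(
                    f"{path}:{line_no}: negative count {v} in column {col!r}"
                )
            vals.append(v)
        guides.append(gid)
        genes.append(fields[1])
        data.append(vals)
    index = pd.Index(guides, name="sgRNA")
    counts = pd.DataFrame(np.asarray(data, dtype=np.int64), index=index, columns=samples)
    genes_s = pd.Series(genes, index=index, name="gene")
    ref = reference or _pick_reference(samples)
    if ref not in samples:
        raise CountTableParseError(f"{path}: reference column {ref!r} not found")
    treat = treatments if treatments is not None else [s for s in samples if s != ref]
    return CountMatrix(counts=counts, genes=genes_s, reference=ref, treatments=treat)


def _provenance(meta: dict | None) -> str:
    if not meta:
        return ""
    parts = " ".join(f"{k}={v}" for k, v in meta.items())
    return f"# {parts}\n"


def write_counts(cm: CountMatrix, path: str, meta: dict | None = None) -> None:
    """Write a count matrix in the sgRNA/gene dialect (with provenance)."""
    with open(path, "w") as fh:
        fh.write(_provenance(meta))
        cols = list(cm.counts.columns)
        fh.write("sgRNA\tgene\t" + "\t".join(cols) + "\n")
        gene_arr = cm.genes.to_numpy()
        mat = cm.counts.to_numpy()
        for i, gid in enumerate(cm.counts.index):
            vals = "\t".join(str(int(v)) for v in mat[i])
            fh.write(f"{gid}\t{gene_arr[i]}\t{vals}\n")


def write_simulation(sim: SimulationResult, counts_path: str, truth_path: str) -> None:
    """Write a simulation's combined counts and its gene-level truth table."""
    meta = {"config_hash": sim.params.config_hash(), "seed": sim.params.rng_seed}
    write_counts(sim.combined_counts(), counts_path, meta=meta)
    with open(truth_path, "w") as fh:
        fh.write(_provenance(meta))
        fh.write("gene\tfitness_class\n")
        for gene, cls in sim.truth.items():
            fh.write(f"{gene}\t{cls}\n")


def read_truth(path: str) -> pd.Series:
    """Read a two-column gene -> fitness_class table."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if df.shape[1] < 2:
        raise CountTableParseError(f"{path}: expected two columns (gene, class)")
    return pd.Series(df.iloc[:, 1].to_numpy(), index=df.iloc[:, 0], name="fitness_class")


def write_table(df: pd.DataFrame, path: str, meta: dict | None = None) -> None:
    """Write any result table as TSV with a provenance header comment."""
    with open(path, "w") as fh:
        fh.write(_provenance(meta))
        df.to_csv(fh, sep="\t", index=df.index.name is not None)
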
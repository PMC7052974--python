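"""Simulation parameters for pooled CRISPR knockout screens.

The parameter set mirrors the standard experiment-design quantities of a
negative-selection screen: per-step gRNA coverages (viral transduction,
cell splitting, PCR/sequencing), the 90/10-percentile width of the plasmid
library, cell doubling time, the fractions of genes with negative/positive
fitness effects, library geometry (number of gRNAs, gRNAs per gene) and the
replication structure (library sequencing replicates, biological replicates,
sequencing replicates per biological replicate, number of cell splittings).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from typing import Any

import yaml

from .exceptions import InvalidParameterError

__all__ = ["SimParams", "load_params", "save_params"]


@dataclass(frozen=True)
class SimParams:
    """Complete parameter set of a simulated pooled CRISPR-KO screen.

    Attributes
    ----------
    cov_virus:
        Mean draws per gRNA during viral transduction (C_virus).
    cov_cells:
        Mean draws per gRNA at each cell splitting (C_cells). This is the
        coverage that controls the bottleneck during the proliferation phase.
    cov_pcr:
        Mean draws per gRNA during PCR amplification / sequencing (C_PCR).
    lib_width:
        Target 90/10-percentile ratio of the plasmid-library abundance
        distribution (dimensionless, >= 1).
    dupl_time:
        Cell doubling time tau in hours.
    freq_negfc:
        Fraction of genes whose knockout decreases fitness.
    freq_posfc:
        Fraction of genes whose knockout increases fitness.
    n_sgrnas:
        Total number of gRNAs in the library (N_tot).
    n_sgrnas_per_gene:
        gRNAs per gene; n_sgrnas must be divisible by this.
    n_repl_lib_pcr:
        Technical sequencing replicates of the plasmid library.
    n_repl_sel:
        Independent biological replicates of the proliferation phase.
    n_repl_pcr:
        Technical sequencing replicates per biological replicate.
    n_splittings:
        Number of cell splitting rounds during the proliferation phase.
    split_interval:
        Time between two splittings in hours (delta-t).
    rng_seed:
        Master seed; every stage derives its own child stream from it.
    """

    cov_virus: float = 400
    cov_cells: float = 400
    cov_pcr: float = 400
    lib_width: float = 7.5
    dupl_time: float = 30.0
    freq_negfc: float = 0.1
    freq_posfc: float = 0.01
    n_sgrnas: int = 50_000
    n_sgrnas_per_gene: int = 4
    n_repl_lib_pcr: int = 2
    n_repl_sel: int = 10
    n_repl_pcr: int = 3
    n_splittings: int = 7
    split_interval: float = 72.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "cov_virus",
            "cov_cells",
            "cov_pcr",
            "dupl_time",
            "split_interval",
        ):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be strictly positive")
        for name in (
            "n_sgrnas",
            "n_sgrnas_per_gene",
            "n_repl_lib_pcr",
            "n_repl_sel",
            "n_repl_pcr",
        ):
            if getattr(self, name) < 1:
                raise InvalidParameterError(f"{name} must be a positive integer")
        if self.n_splittings < 0:
            raise InvalidParameterError("n_splittings must be >= 0")
        if self.lib_width < 1:
            raise InvalidParameterError("lib_width must be >= 1")
        if not (0 <= self.freq_negfc <= 1 and 0 <= self.freq_posfc <= 1):
            raise InvalidParameterError("fitness-effect fractions must be in [0, 1]")
        if self.freq_negfc + self.freq_posfc > 1:
            raise InvalidParameterError("freq_negfc + freq_posfc must be <= 1")
        if self.n_sgrnas % self.n_sgrnas_per_gene != 0:
            raise InvalidParameterError(
                "n_sgrnas must be divisible by n_sgrnas_per_gene"
            )

    @property
    def n_genes(self) -> int:
        return self.n_sgrnas // self.n_sgrnas_per_gene

    def replace(self, **changes: Any) -> "SimParams":
        """Return a copy with the given fields replaced (validated)."""
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        """Short stable hash of the full parameter set, for output headers."""
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


def load_params(path: str) -> SimParams:
    """Read a flat key/value YAML parameter file into a :class:`SimParams`.

    Unknown keys raise; missing keys fall back to the defaults.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise InvalidParameterError(f"parameter file {path!r} is not a mapping")
    valid = {f.name for f in dataclasses.fields(SimParams)}
    unknown = set(raw) - valid
    if unknown:
        raise InvalidParameterError(
            f"unknown parameter(s) in {path!r}: {', '.join(sorted(unknown))}"
        )
    return SimParams(**raw)


def save_params(params: SimParams, path: str) -> None:
    """Write a :class:`SimParams` as a flat YAML key/value file."""
    with open(path, "w") as fh:
        yaml.safe_dump(params.to_dict(), fh, sort_keys=False)
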
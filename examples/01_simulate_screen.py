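"""Simulate a pooled CRISPR knockout screen and write its count tables.

A screen is simulated end to end — lognormal plasmid library, viral
transduction, growth to T0, seven cell-splitting bottlenecks with
exponential growth, and PCR/sequencing of every pool — at a reduced scale
(10,000 gRNAs) so the script runs in seconds. The printed numbers show the
realized library width (the 90/10-percentile abundance ratio the library
was generated to hit) and how the sequenced samples are laid out.
"""

import warnings

import poolscreen as ps
from poolscreen import io

warnings.simplefilter("ignore")  # library sequencing uses the amplification regime

params = ps.SimParams(n_sgrnas=10_000, n_repl_sel=3, rng_seed=1)
sim = ps.run_screen(params)

width = ps.library_width(sim.library.plasmid_abundance)
print(f"simulated {params.n_sgrnas} gRNAs targeting {params.n_genes} genes")
print(f"realized library width: {width:.2f} (target {params.lib_width})")
print(f"library samples:  {list(sim.library_counts.counts.columns)}")
print(f"T0 samples:       {list(sim.t0_counts.counts.columns)}")
print(f"T1 samples:       {list(sim.t1_counts.counts.columns)}")
print(f"ground truth:     {sim.truth.value_counts().to_dict()}")

io.write_simulation(sim, "counts.tsv", "truth.tsv")
print("wrote counts.tsv and truth.tsv "
      "(tab-separated, sgRNA/gene + one integer column per sample)")
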
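"""Benchmark essential-gene recovery against the simulated ground truth.

Recall at 99% precision — the largest fraction of truly essential genes
recovered by any ranking prefix that stays at least 99% pure — is the
headline benchmark metric. This script scores the pipeline on one screen
and compares it with its own symmetric-null ablation (identical pipeline,
skew frozen at 1), isolating what modelling the asymmetry contributes.
Run at a reduced scale (10,000 gRNAs) to finish in about a minute.
"""

import warnings

import poolscreen as ps

warnings.simplefilter("ignore")

params = ps.SimParams(n_sgrnas=10_000, cov_cells=300, n_repl_sel=3, rng_seed=3)
sim = ps.run_screen(params)
counts = sim.analysis_counts(aggregate_technical=True)

for label, fix_skew in (("skew-normal null", None), ("symmetric ablation", 1.0)):
    result = ps.analyze_screen(counts, n_perm=1000, seed=0, fix_skew=fix_skew)
    ranked = result.ranked("depletion").index
    curve = ps.precision_recall(ranked, sim.truth, "negative")
    r99 = ps.recall_at_precision(curve, 0.99)
    r95 = ps.recall_at_precision(curve, 0.95)
    print(f"{label:>20}: recall@99% = {r99:.3f}   recall@95% = {r95:.3f}")

print("\nnote: ~1/21 of 'essential' genes carry effect size 0 and are")
print("undetectable in principle, capping attainable recall near 0.95")
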
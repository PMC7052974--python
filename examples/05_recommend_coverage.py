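"""Derive a screening-coverage recommendation for a given library width.

Given the 90/10-percentile width of a plasmid library, the minimal
cell-splitting coverage that still meets a target recall at fixed precision
is found by simulating screens along an ascending coverage grid. Here the
search runs at a reduced scale (5,000 gRNAs, 2 repeats per grid point, a
relaxed target) so it completes in a few minutes; a real experiment-design
run would use the full library size and >= 5 repeats per point.
"""

import warnings

import poolscreen as ps

warnings.simplefilter("ignore")

base = ps.SimParams(n_sgrnas=5_000, n_repl_sel=3)
rec = ps.recommend_coverage(
    lib_width=7.5,
    coverage_grid=(100, 200, 300, 400),
    target_recall=0.85,
    precision_level=0.99,
    base_params=base,
    n_repeats=2,
    seed=0,
    n_perm=300,
)

print("mean recall@99% precision by cell-splitting coverage (width 7.5):")
print(rec.profile.groupby("cov_cells")["recall"].mean().round(3).to_string())
if rec.recommended is None:
    print(f"\ntarget recall {rec.target_recall} not reached on this grid "
          f"(max {rec.max_recall:.3f})")
else:
    print(f"\nsmallest coverage meeting recall >= {rec.target_recall}: "
          f"{rec.recommended}")
    n_cells = ps.cells_required(base.n_sgrnas, rec.recommended)
    print(f"cells to culture at that coverage: {n_cells:,} "
          f"({base.n_sgrnas:,} gRNAs x {rec.recommended})")
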
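"""Shared fixtures: small simulated screens generated at test time."""

import warnings

import pytest

import poolscreen as ps


@pytest.fixture(scope="session")
def tiny_params():
    """A fast, fully in-regime parameter set (no sampling fallbacks)."""
    return ps.SimParams(
        n_sgrnas=2000,
        n_sgrnas_per_gene=4,
        cov_virus=50,
        cov_cells=50,
        cov_pcr=50,
        n_repl_sel=2,
        n_repl_pcr=2,
        n_repl_lib_pcr=2,
        rng_seed=42,
    )


@pytest.fixture(scope="session")
def tiny_sim(tiny_params):
    return ps.run_screen(tiny_params)


@pytest.fixture(scope="session")
def small_sim():
    """Mid-size screen with fitness effects, for pipeline-level tests."""
    params = ps.SimParams(n_sgrnas=5000, n_repl_sel=3, rng_seed=11)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return ps.run_screen(params)


@pytest.fixture(scope="session")
def small_analysis(small_sim):
    return ps.analyze_screen(
        small_sim.analysis_counts(aggregate_technical=True),
        n_perm=300,
        seed=5,
    )
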
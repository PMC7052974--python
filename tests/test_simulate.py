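"""Unit and property tests for the screen simulator."""

import numpy as np
import pytest

import poolscreen as ps
from poolscreen.exceptions import InvalidParameterError, SimulationCollapseError
from poolscreen.simulate import PoolState, coverage_for_p10


class TestSigmaForWidth:
    def test_degenerate_width_one_gives_zero_sigma(self):
        assert ps.sigma_for_width(1.0) == 0.0

    def test_closed_form_values(self):
        # ln(7.5) / (z90 - z10) with z90 - z10 = 2.5631031311
        assert ps.sigma_for_width(7.5) == pytest.approx(0.7861185904, abs=1e-9)
        assert ps.sigma_for_width(np.exp(2.5631031311)) == pytest.approx(1.0, abs=1e-9)

    def test_monte_carlo_width_matches_target(self):
        rng = np.random.default_rng(0)
        draws = rng.lognormal(5.0, ps.sigma_for_width(7.5), 10**6)
        assert ps.library_width(draws) == pytest.approx(7.5, rel=0.01)

    def test_invalid_width_rejected(self):
        with pytest.raises(InvalidParameterError):
            ps.sigma_for_width(0.5)


class TestGrowthFactor:
    def test_one_doubling_per_interval(self):
        assert ps.growth_factor(30.0, 30.0) == pytest.approx(np.log(2))

    @pytest.mark.parametrize(
        "delta_t,tau,expected",
        [(72, 30, 1.6635532333), (72, 90, 0.5545177444)],
    )
    def test_closed_form(self, delta_t, tau, expected):
        assert ps.growth_factor(delta_t, tau) == pytest.approx(expected, abs=1e-9)

    def test_slower_growth_smaller_beta(self):
        assert ps.growth_factor(72, 90) < ps.growth_factor(72, 20)

    @pytest.mark.parametrize("delta_t,tau", [(0, 30), (72, 0), (-1, 30)])
    def test_nonpositive_inputs_rejected(self, delta_t, tau):
        with pytest.raises(InvalidParameterError):
            ps.growth_factor(delta_t, tau)


def _neutral_library(n, beta):
    return ps.GuideLibrary(
        guide_id=np.array([f"g{i}" for i in range(n)], dtype=object),
        gene_id=np.array([f"G{i // 4}" for i in range(n)], dtype=object),
        plasmid_abundance=np.ones(n, dtype=np.int64),
        fitness_class=np.array(["neutral"] * n, dtype=object),
        epsilon=np.zeros(n),
        growth_factor=np.full(n, beta),
    )


class TestGrow:
    def test_extinction_absorbing_and_exact_doubling(self):
        lib = _neutral_library(3, np.log(2))
        pool = PoolState(np.array([0, 100, 7]), "t0")
        out = ps.grow(pool, lib)
        assert list(out.abundances) == [0, 200, 14]

    def test_truncation_to_integer_part(self):
        # 148 * e^1.6635532 = 148 * 2^2.4 = 781.148... -> 781
        lib = _neutral_library(1, 1.6635532333)
        out = ps.grow(PoolState(np.array([148]), "t0"), lib)
        assert out.abundances[0] == 781

    def test_never_decreases_for_nonnegative_beta(self):
        rng = np.random.default_rng(1)
        n = 500
        lib = _neutral_library(n, 0.0)
        lib.growth_factor = rng.uniform(0, 2, n)
        pool = PoolState(rng.integers(0, 1000, n), "t0")
        out = ps.grow(pool, lib)
        assert np.all(out.abundances >= pool.abundances)


class TestGenerateLibrary:
    def test_zero_variance_library_is_constant(self):
        params = ps.SimParams(lib_width=1.0, n_sgrnas=1000, n_sgrnas_per_gene=4)
        lib, pool = ps.generate_library(params, rng=0)
        assert np.all(lib.plasmid_abundance == 148)  # round(e^5)

    def test_realized_width_and_mean(self):
        params = ps.SimParams(rng_seed=0)
        lib, _ = ps.generate_library(params, rng=0)
        width = ps.library_width(lib.plasmid_abundance)
        assert 6.75 <= width <= 8.25  # within 10% of the target 7.5
        sigma = ps.sigma_for_width(7.5)
        expected_mean = np.exp(5 + sigma**2 / 2)
        assert lib.plasmid_abundance.mean() == pytest.approx(expected_mean, rel=0.02)

    def test_guides_per_gene(self):
        params = ps.SimParams(n_sgrnas=2000, rng_seed=0)
        lib, _ = ps.generate_library(params, rng=0)
        _, counts = np.unique(lib.gene_id, return_counts=True)
        assert np.all(counts == params.n_sgrnas_per_gene)


class TestAssignFitness:
    def test_default_fractions_give_expected_counts(self):
        params = ps.SimParams()  # 12,500 genes, 10% negative, 1% positive
        cls, eps, beta = ps.assign_fitness(params, np.random.default_rng(0))
        assert (cls == "negative").sum() == 5000  # 1,250 genes * 4 guides
        assert (cls == "positive").sum() == 500

    def test_all_neutral_when_fractions_zero(self):
        params = ps.SimParams(freq_negfc=0.0, freq_posfc=0.0, n_sgrnas=1000)
        cls, eps, beta = ps.assign_fitness(params, np.random.default_rng(0))
        assert np.all(cls == "neutral")
        assert len(np.unique(beta)) == 1

    def test_gene_level_coherence_and_epsilon_grid(self):
        params = ps.SimParams(n_sgrnas=4000, rng_seed=0)
        lib, _ = ps.generate_library(params, rng=3)
        for gene in np.unique(lib.gene_id):
            in_g = lib.gene_id == gene
            assert len(set(lib.fitness_class[in_g])) == 1
            assert len(set(lib.epsilon[in_g])) == 1
        affected = lib.fitness_class != "neutral"
        grid = np.round(np.arange(0, 0.201, 0.01), 2)
        assert set(np.round(lib.epsilon[affected], 2)) <= set(grid)
        assert np.all(lib.epsilon[~affected] == 0)
        # an epsilon of 0 leaves the growth factor at baseline
        beta = ps.growth_factor(params.split_interval, params.dupl_time)
        zero_eps = affected & (lib.epsilon == 0)
        assert np.allclose(lib.growth_factor[zero_eps], beta)

    def test_overfull_fractions_rejected(self):
        with pytest.raises(InvalidParameterError):
            ps.SimParams(freq_negfc=0.7, freq_posfc=0.5)


class TestSubsample:
    def test_exhaustive_draw_returns_pool(self):
        pool = PoolState(np.array([5, 10, 0, 3]), "t0")
        out = ps.subsample(pool, 18, rng=0)
        assert np.array_equal(out.abundances, pool.abundances)

    def test_zero_draws(self):
        out = ps.subsample(PoolState(np.array([5, 10]), "t0"), 0, rng=0)
        assert np.all(out.abundances == 0)

    def test_never_exceeds_input(self):
        rng = np.random.default_rng(2)
        pool = PoolState(rng.integers(0, 50, 100), "t0")
        out = ps.subsample(pool, int(pool.total // 2), rng=3)
        assert np.all(out.abundances <= pool.abundances)
        assert out.total == pool.total // 2

    def test_empty_pool_raises_with_stage(self):
        with pytest.raises(SimulationCollapseError) as err:
            ps.subsample(PoolState(np.zeros(3, dtype=int), "split_4"), 10, rng=0)
        assert "split_4" in str(err.value)

    def test_hypergeometric_moments(self):
        # two-guide pool (60, 40), 50 draws: mean 30,
        # variance 50 * 0.6 * 0.4 * (50/99) = 6.0606
        rng = np.random.default_rng(7)
        pool = np.array([60, 40])
        draws = rng.multivariate_hypergeometric(
            pool, 50, size=100_000, method="count"
        )[:, 0]
        assert draws.mean() == pytest.approx(30.0, abs=0.05)
        assert draws.var() == pytest.approx(50 * 0.6 * 0.4 * (50 / 99), rel=0.03)
        # and the subsample wrapper agrees on its marginal expectation
        ours = np.array(
            [
                ps.subsample(PoolState(pool, "t0"), 50, rng=s).abundances[0]
                for s in range(3000)
            ]
        )
        assert ours.mean() == pytest.approx(30.0, abs=0.35)

    def test_multinomial_fallback_warns(self):
        pool = PoolState(np.array([60, 40]), "lib")
        with pytest.warns(UserWarning, match="multinomial"):
            out = ps.subsample(pool, 500, rng=0)
        assert out.total == 500


class TestRunScreen:
    def test_determinism(self, tiny_params, tiny_sim):
        again = ps.run_screen(tiny_params)
        assert tiny_sim.t1_counts.counts.equals(again.t1_counts.counts)
        assert tiny_sim.library_counts.counts.equals(again.library_counts.counts)

    def test_sequencing_depth_exact(self, tiny_params, tiny_sim):
        depth = round(tiny_params.cov_pcr * tiny_params.n_sgrnas)
        for cm in (tiny_sim.library_counts, tiny_sim.t0_counts, tiny_sim.t1_counts):
            assert (cm.counts.sum(axis=0) == depth).all()

    def test_replicate_structure(self, tiny_params, tiny_sim):
        assert tiny_sim.library_counts.counts.shape[1] == tiny_params.n_repl_lib_pcr
        assert tiny_sim.t0_counts.counts.shape[1] == tiny_params.n_repl_pcr
        assert (
            tiny_sim.t1_counts.counts.shape[1]
            == tiny_params.n_repl_sel * tiny_params.n_repl_pcr
        )
        assert set(tiny_sim.truth.unique()) <= {"neutral", "negative", "positive"}
        assert len(tiny_sim.truth) == tiny_params.n_genes

    def test_no_splittings_means_t1_tracks_t0(self, tiny_params):
        sim = ps.run_screen(tiny_params.replace(n_splittings=0))
        t0 = sim.t0_counts.counts.iloc[:, 0]
        t1 = sim.t1_counts.counts.iloc[:, 0]
        assert np.corrcoef(t0, t1)[0, 1] > 0.95

    def test_aggregated_analysis_counts(self, tiny_params, tiny_sim):
        cm = tiny_sim.analysis_counts(aggregate_technical=True)
        assert len(cm.treatments) == tiny_params.n_repl_sel
        total = round(tiny_params.cov_pcr * tiny_params.n_sgrnas)
        assert (cm.counts[cm.treatments].sum(axis=0) == total * tiny_params.n_repl_pcr).all()


class TestScreenProperties:
    def test_width_broadens_with_splitting_round(self):
        params = ps.SimParams(
            cov_cells=100, n_repl_sel=1, freq_negfc=0, freq_posfc=0, rng_seed=5
        )
        sim = ps.run_screen(params, record_trajectories=True)
        widths = [ps.library_width(pool) for pool in sim.trajectories[0]]
        assert all(b >= a for a, b in zip(widths, widths[1:]))
        assert widths[-1] > widths[0]

    def test_depletion_visible_already_at_t0_and_grows_with_fast_division(self):
        gaps = {}
        for tau in (20, 60):
            params = ps.SimParams(rng_seed=5, dupl_time=tau, n_repl_sel=1)
            sim = ps.run_screen(params)
            cm = sim.combined_counts()
            t0_cols = list(sim.t0_counts.counts.columns)
            cm0 = ps.CountMatrix(
                cm.counts[[cm.reference] + t0_cols], cm.genes, cm.reference, t0_cols
            )
            lf = ps.lfc_matrix(cm0)
            m_neg = lf.lfc.loc[sim.library.fitness_class == "negative"].mean().mean()
            m_neu = lf.lfc.loc[sim.library.neutral_mask].mean().mean()
            gaps[tau] = m_neu - m_neg
        assert gaps[20] > 0 and gaps[60] > 0
        assert gaps[20] > gaps[60]

    def test_pcr_and_transduction_noise_secondary_to_splitting(self):
        # reducing C_cells inflates the depleted tail far more than reducing
        # C_PCR or C_virus by the same amount
        def frac_below(**kw):
            params = ps.SimParams(rng_seed=3, n_repl_sel=2, **kw)
            sim = ps.run_screen(params)
            lf = ps.lfc_matrix(sim.analysis_counts())
            return ps.tail_fractions(lf, mask=sim.library.neutral_mask).frac_below

        f_cells = frac_below(cov_cells=100)
        f_pcr = frac_below(cov_pcr=100)
        f_virus = frac_below(cov_virus=100)
        assert f_cells > 3 * f_pcr
        assert f_cells > 3 * f_virus


def test_coverage_for_p10_solves_the_100fold_rule():
    abundances = np.full(1000, 200)
    abundances[:150] = 50  # p10 = 50 (inside the low block)
    cov = coverage_for_p10(abundances, 100.0)
    # expected p10 draws = cov * N * (50/total) = 100
    assert cov * 1000 * 50 / abundances.sum() == pytest.approx(100.0)
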
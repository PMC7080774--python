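"""Harmonic-mean Ne, model expansion, folded SFS, genotype PCA, grid fit."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from founderdrift import (
    DemographicModel,
    FoldedSFS,
    NeTrajectory,
    SimConfig,
    expand_model_to_trajectory,
    fit_bottleneck_grid,
    folded_sfs,
    genotype_pca,
    harmonic_mean_ne,
    sample_genotypes,
    simulate_dataset,
    to_variant_table,
)
from conftest import make_table


class TestHarmonicMean:
    def test_constant_trajectory_returns_the_constant(self):
        assert harmonic_mean_ne(NeTrajectory.constant(50, 7)) == pytest.approx(50.0)

    def test_bottleneck_dominates(self):
        sizes = np.concatenate([np.full(16, 2.0), np.full(16, 1e6)])
        expected = 32 / (16 / 2 + 16 / 1e6)
        assert harmonic_mean_ne(NeTrajectory(sizes)) == pytest.approx(expected)
        assert expected == pytest.approx(4.0, abs=1e-3)

    @settings(deadline=None, max_examples=50)
    @given(
        st.lists(st.floats(min_value=1.0, max_value=1e6), min_size=1, max_size=64),
        st.randoms(use_true_random=False),
    )
    def test_order_invariant_and_below_arithmetic_mean(self, sizes, rnd):
        traj = NeTrajectory(np.array(sizes))
        shuffled = list(sizes)
        rnd.shuffle(shuffled)
        hm = harmonic_mean_ne(traj)
        assert hm == pytest.approx(harmonic_mean_ne(NeTrajectory(np.array(shuffled))))
        assert hm <= np.mean(sizes) * (1 + 1e-12)
        assert hm >= min(sizes) * (1 - 1e-12)


class TestModelExpansion:
    def test_segment_lengths(self):
        traj = expand_model_to_trajectory(
            DemographicModel(),
            {"N_intro": 5, "t_exp": 22, "N_contemporary": 1e6},
        )
        assert traj.n_generations == 32
        assert np.all(traj.sizes[:10] == 5)
        assert np.all(traj.sizes[10:] == 1e6)

    def test_single_founding_generation_boundary(self):
        traj = expand_model_to_trajectory(
            DemographicModel(),
            {"N_intro": 5, "t_exp": 26, "N_contemporary": 1e6},
        )
        # t_exp at its bound leaves t_intro - t_exp = 6 founder generations
        assert np.sum(traj.sizes == 5) == 6

    def test_harmonic_mean_dominant_term(self):
        point = {"N_intro": 5, "t_exp": 22, "N_contemporary": 1e7}
        traj = expand_model_to_trajectory(DemographicModel(), point)
        approx = 32 * 5 / (32 - 22)
        assert harmonic_mean_ne(traj) == pytest.approx(approx, rel=0.01)

    def test_out_of_bounds_names_the_parameter(self):
        with pytest.raises(ValueError, match="N_intro"):
            expand_model_to_trajectory(
                DemographicModel(),
                {"N_intro": 1, "t_exp": 22, "N_contemporary": 1e6},
            )

    def test_island_split_trajectory(self):
        model = DemographicModel(model_kind="three-population")
        point = {
            "N_intro": 5,
            "t_exp": 22,
            "N_contemporary": 1e6,
            "t_col": 13,
            "N_col": 400,
            "t_change": 5,
            "N_island": 10,
        }
        traj = expand_model_to_trajectory(model, point, population="island")
        assert np.all(traj.sizes[:10] == 5)
        assert np.all(traj.sizes[10:19] == 1e6)
        assert np.all(traj.sizes[19:27] == 400)
        assert np.all(traj.sizes[27:] == 10)


class TestFoldedSfs:
    def test_singleton_site_lands_in_first_bin(self):
        sfs = folded_sfs(make_table([[1, 0]]))
        assert sfs.counts[0] == 1 and sfs.n_polymorphic == 1

    def test_monomorphic_site_excluded(self):
        sfs = folded_sfs(make_table([[2, 2], [0, 0], [1, 0]]))
        assert sfs.n_polymorphic == 1

    def test_folding_merges_complementary_counts(self):
        # alt count 1 and alt count n-1 = 3 are the same minor count
        sfs = folded_sfs(make_table([[1, 0], [2, 1]]))
        assert sfs.counts[0] == 2

    def test_missing_genotypes_rejected(self):
        with pytest.raises(ValueError, match="complete"):
            folded_sfs(make_table([[1, -1]]))

    def test_total_equals_polymorphic_site_count(self, small_sim):
        vt = to_variant_table(small_sim)
        complete = vt.take_sites(np.flatnonzero((vt.genotypes >= 0).all(axis=1)))
        sfs = folded_sfs(complete)
        alt = complete.genotypes.sum(axis=1)
        n_poly = int(((alt > 0) & (alt < 2 * complete.n_individuals)).sum())
        assert sfs.n_polymorphic == n_poly

    def test_spectrum_matches_binomial_mixture_oracle(self):
        # Frequencies drawn from the neutral density (proportional to
        # 1/(p(1-p)), realised as a logistic transform of a uniform), then
        # Hardy-Weinberg sampling of 10 diploids: the folded spectrum must
        # match the closed-form binomial-mixture expectation over the same
        # frequency draws.
        from scipy.stats import binom

        rng = np.random.default_rng(0)
        n_ind, n_loci = 10, 5000
        lo, hi = np.log(0.01 / 0.99), np.log(0.99 / 0.01)
        p = 1.0 / (1.0 + np.exp(-rng.uniform(lo, hi, n_loci)))
        vt = make_table(sample_genotypes(p, n_ind, seed=1))
        sfs = folded_sfs(vt)
        n = 2 * n_ind
        pmf = binom.pmf(np.arange(n + 1)[:, None], n, p[None, :]).sum(axis=1)
        expect = np.array(
            [pmf[i] + (pmf[n - i] if i != n - i else 0) for i in range(1, n // 2 + 1)]
        )
        expect /= expect.sum()
        observed = sfs.counts / sfs.n_polymorphic
        assert np.abs(observed - expect).max() < 0.02


class TestGenotypePca:
    def test_two_drifted_populations_separate_on_pc1(self, small_sim):
        vt = to_variant_table(small_sim)
        res = genotype_pca(vt, n_components=2)
        n_src = small_sim.config.n_source_sample
        src, der = res.scores[:n_src, 0], res.scores[n_src:, 0]
        assert src.max() < der.min() or der.max() < src.min()

    def test_duplicated_individual_gets_identical_scores(self):
        rng = np.random.default_rng(1)
        g = rng.binomial(2, 0.5, size=(50, 10)).astype(np.int8)
        g = np.concatenate([g, g[:, :1]], axis=1)  # copy individual 0
        res = genotype_pca(make_table(g), n_components=3)
        assert np.allclose(res.scores[0], res.scores[-1])

    def test_variance_fractions_non_increasing_and_bounded(self, small_sim):
        res = genotype_pca(to_variant_table(small_sim), n_components=5)
        assert np.all(np.diff(res.variance_fractions) <= 1e-12)
        assert res.variance_fractions.sum() <= 1.0 + 1e-9

    def test_monomorphic_matrix_rejected(self):
        with pytest.raises(ValueError):
            genotype_pca(make_table([[1, 1, 1], [2, 2, 2]]))


@pytest.fixture(scope="module")
def observed():
    model = DemographicModel()
    truth = {"N_intro": 5.0, "t_exp": 22, "N_contemporary": 1e6}
    traj = expand_model_to_trajectory(model, truth)
    cfg = SimConfig(n_loci=5000, seed=17, trajectory=traj, n_derived_sample=30)
    res = simulate_dataset(cfg)
    vt = make_table(res.derived_genotypes, pos=res.positions)
    return folded_sfs(vt), model


class TestGridFit:

    def test_recovery_within_one_grid_step(self, observed):
        obs, model = observed
        grid = {"N_intro": [2.0, 5.0, 10.0, 20.0], "bottleneck_duration": [6, 10, 13]}
        fit = fit_bottleneck_grid(obs, model, grid, reps_per_point=20,
                                  n_loci=2000, seed=3)
        n_idx = grid["N_intro"].index(fit.best_point["N_intro"])
        assert abs(n_idx - grid["N_intro"].index(5.0)) <= 1
        d_idx = [6, 10, 13].index(32 - fit.best_point["t_exp"])
        assert abs(d_idx - 1) <= 1  # truth duration 10 is index 1

    def test_self_consistent_point_maximizes_score(self):
        from founderdrift.structure import expected_folded_sfs

        model = DemographicModel()
        grid_points = [
            {"N_intro": 2.0, "t_exp": 22},
            {"N_intro": 20.0, "t_exp": 22},
        ]
        target = {**grid_points[1], "N_contemporary": 1e6}
        exp = expected_folded_sfs(model, target, 40, 4000, 20, seed=5)
        obs = FoldedSFS(exp * 10_000, 40)
        fit = fit_bottleneck_grid(
            obs, model, {"N_intro": [2.0, 20.0], "t_exp": [22]},
            reps_per_point=20, n_loci=2000, seed=6,
        )
        assert fit.best_point["N_intro"] == 20.0

    def test_surface_invariant_to_obs_scaling(self, observed):
        obs, model = observed
        grid = {"N_intro": [2.0, 20.0], "t_exp": [22]}
        fit1 = fit_bottleneck_grid(obs, model, grid, reps_per_point=5,
                                   n_loci=500, seed=7)
        scaled = FoldedSFS(obs.counts * 3, obs.n)
        fit2 = fit_bottleneck_grid(scaled, model, grid, reps_per_point=5,
                                   n_loci=500, seed=7)
        assert np.allclose(
            fit1.surface["loglik"] * 3, fit2.surface["loglik"]
        )

    def test_empty_grid_rejected(self, observed):
        obs, model = observed
        with pytest.raises(ValueError, match="empty"):
            fit_bottleneck_grid(obs, model, {"N_intro": []}, seed=0)
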
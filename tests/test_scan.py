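"""Selection scan: z-scores, Mahalanobis D2, inflation, FDR, proximity."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from founderdrift import (
    NeTrajectory,
    ScanConfig,
    bh_fdr,
    candidate_proximity,
    inflation_correct,
    mahalanobis_stats,
    planted_sweep_dataset,
    read_intervals,
    sample_genotypes,
    scan,
    snp_zscores,
)
from conftest import make_table

BENCH_TRAJ = NeTrajectory(np.concatenate([np.full(10, 50.0), np.full(22, 1e4)]))


def _panmictic_table(n_loci, n_ind, seed):
    rng = np.random.default_rng(seed)
    freqs = rng.uniform(0.05, 0.95, n_loci)
    return make_table(sample_genotypes(freqs, n_ind, seed=seed + 1))


class TestZScores:
    def test_structured_snp_loads_on_pc1(self):
        # two clusters differing at many loci; a SNP matching the cluster
        # split must get a large first-component z-score
        rng = np.random.default_rng(0)
        g1 = rng.binomial(2, 0.1, size=(200, 30))
        g2 = rng.binomial(2, 0.9, size=(200, 30))
        g = np.concatenate([g1, g2], axis=1).astype(np.int8)
        z = snp_zscores(make_table(g), k=2)
        assert np.median(np.abs(z[:, 0])) > np.median(np.abs(z[:, 1]))

    def test_null_zscores_centered_gaussian(self):
        # Pure-noise SNPs give centered Gaussian z-scores.  The scale is
        # mildly inflated because the score vectors are eigenvectors of the
        # same matrix; the scan absorbs that through the Mahalanobis
        # covariance and the inflation factor, so shape is what matters here.
        vt = _panmictic_table(3000, 60, seed=2)
        z = snp_zscores(vt, k=2)
        assert abs(z.mean()) < 0.05
        zs = z / z.std(axis=0)
        assert stats.kstest(zs.ravel(), "norm").statistic < 0.03

    def test_too_few_individuals_rejected(self):
        with pytest.raises(ValueError):
            snp_zscores(_panmictic_table(50, 3, seed=3), k=2)


class TestMahalanobis:
    def test_euclidean_case(self):
        rng = np.random.default_rng(4)
        z = rng.standard_normal((5000, 2))
        z = np.vstack([z, [3.0, 4.0]])
        d2 = mahalanobis_stats(z)
        # with near-identity covariance and near-zero center, D2 ~ 25
        assert d2[-1] == pytest.approx(25.0, rel=0.1)

    def test_affine_invariance(self):
        rng = np.random.default_rng(5)
        z = rng.standard_normal((500, 2))
        a = np.array([[2.0, 0.5], [-1.0, 3.0]])
        d2 = mahalanobis_stats(z)
        d2t = mahalanobis_stats(z @ a.T + [5.0, -7.0])
        assert np.allclose(d2, d2t)

    def test_null_distribution_is_chi2(self):
        rng = np.random.default_rng(6)
        z = rng.standard_normal((5000, 2))
        d2 = mahalanobis_stats(z)
        assert stats.kstest(d2, stats.chi2(df=2).cdf).statistic < 0.03

    def test_singular_covariance_rejected(self):
        z = np.ones((10, 2))
        z[:, 1] = 2 * z[:, 0]
        with pytest.raises(ValueError):
            mahalanobis_stats(z)


class TestInflation:
    def test_lambda_near_one_for_chi2_draws(self):
        d2 = stats.chi2(df=2).rvs(10_000, random_state=7)
        lam, _ = inflation_correct(d2, k=2)
        assert lam == pytest.approx(1.0, abs=0.05)

    def test_scale_equivariance(self):
        d2 = stats.chi2(df=2).rvs(1000, random_state=8)
        lam1, p1 = inflation_correct(d2, k=2)
        lam3, p3 = inflation_correct(3 * d2, k=2)
        assert lam3 == pytest.approx(3 * lam1)
        assert np.allclose(p1, p3)

    def test_extreme_statistic_gets_smallest_p(self):
        d2 = np.concatenate([stats.chi2(df=2).rvs(500, random_state=9), [400.0]])
        _, p = inflation_correct(d2, k=2)
        assert p.argmin() == 500


class TestBhFdr:
    def test_step_up_by_hand(self):
        q, flags = bh_fdr(np.array([0.001, 0.02, 0.9]), q=0.05)
        assert list(flags) == [True, True, False]
        assert np.allclose(q, [0.003, 0.03, 0.9])

    def test_all_ones_flag_nothing(self):
        _, flags = bh_fdr(np.ones(10), q=0.05)
        assert not flags.any()

    def test_qvalues_monotone_in_sorted_p(self):
        rng = np.random.default_rng(10)
        p = np.sort(rng.uniform(size=100))
        q, _ = bh_fdr(p, q=0.1)
        assert np.all(np.diff(q) >= -1e-12)


class TestScan:
    def test_panmictic_null_calibrated(self):
        vt = _panmictic_table(5000, 70, seed=11)
        out = scan(vt)
        p = out["p"].dropna().to_numpy()
        assert stats.kstest(p, "uniform").statistic < 0.03
        assert out["outlier"].sum() <= 2 * 0.01 * p.size

    def test_planted_sweeps_detected(self):
        vt, causal = planted_sweep_dataset(BENCH_TRAJ, seed=11)
        out = scan(vt)
        flagged = set(np.flatnonzero(out["outlier"].to_numpy()))
        assert len(flagged & set(causal.tolist())) / causal.size >= 0.5

    def test_duplicating_individuals_preserves_flags(self):
        vt, _ = planted_sweep_dataset(BENCH_TRAJ, n_loci=500, seed=12)
        doubled = vt.take_individuals(
            np.concatenate([np.arange(vt.n_individuals)] * 2)
        )
        f1 = scan(vt)["outlier"].to_numpy()
        f2 = scan(doubled)["outlier"].to_numpy()
        assert np.array_equal(f1, f2)

    def test_population_pair_selection(self):
        vt, _ = planted_sweep_dataset(BENCH_TRAJ, n_loci=300, seed=13)
        labels = {s: s.split("_")[0] for s in vt.samples}
        out = scan(vt, populations=("SRC", "DER"), pop_labels=labels)
        assert len(out) == 300


class TestProximity:
    def _outliers(self, positions, chrom="1"):
        return pd.DataFrame(
            {
                "chrom": [chrom] * len(positions),
                "pos": positions,
                "outlier": [True] * len(positions),
            }
        )

    def test_snp_inside_interval_hits_at_zero(self):
        ann = pd.DataFrame(
            {"chrom": ["1"], "start": [100], "end": [199], "name": ["g"]}
        )
        hits = candidate_proximity(self._outliers([150]), ann, 10_000)
        assert len(hits) == 1 and hits["distance"].iloc[0] == 0

    def test_window_boundary_arithmetic(self):
        # interval covering 100..199: position 10,199 is exactly 10 kb past
        # the end, 10,201 is beyond the window
        ann = pd.DataFrame(
            {"chrom": ["1"], "start": [100], "end": [199], "name": ["g"]}
        )
        hits = candidate_proximity(self._outliers([10_199, 10_201]), ann, 10_000)
        assert list(hits["pos"]) == [10_199]
        assert hits["distance"].iloc[0] == 10_000

    def test_upstream_distance_is_negative(self):
        ann = pd.DataFrame(
            {"chrom": ["1"], "start": [5000], "end": [6000], "name": ["g"]}
        )
        hits = candidate_proximity(self._outliers([4000]), ann, 10_000)
        assert hits["distance"].iloc[0] == -1000

    def test_empty_annotations_no_hits_no_error(self):
        ann = pd.DataFrame(columns=["chrom", "start", "end", "name"])
        hits = candidate_proximity(self._outliers([100]), ann, 10_000)
        assert len(hits) == 0

    def test_bed_and_gff_readers(self, tmp_path):
        bed = tmp_path / "a.bed"
        bed.write_text("1\t99\t200\tgeneA\n2\t0\t50\tgeneB\n")
        iv = read_intervals(bed)
        assert iv.loc[0, "start"] == 100 and iv.loc[0, "end"] == 200
        gff = tmp_path / "a.gff3"
        gff.write_text(
            "##gff-version 3\n"
            "1\tsrc\tgene\t100\t200\t.\t+\t.\tID=geneA;biotype=x\n"
            "1\tsrc\texon\t100\t150\t.\t+\t.\tID=e1\n"
        )
        iv2 = read_intervals(gff)
        assert len(iv2) == 1
        assert iv2.loc[0, "start"] == 100 and iv2.loc[0, "end"] == 200

    def test_malformed_interval_rejected(self, tmp_path):
        bed = tmp_path / "bad.bed"
        bed.write_text("1\t500\t100\tg\n")
        with pytest.raises(ValueError):
            read_intervals(bed)
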
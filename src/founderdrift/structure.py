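"""Population structure: genotype PCA, folded SFS, and a grid bottleneck fit.

The folded site-frequency spectrum (minor-allele counts across polymorphic
sites) carries the bottleneck signal used for demographic inference; without
an outgroup the unfolded spectrum is unavailable, so everything here is
folded.  The demographic fit is a documented grid search: candidate
founder-model parameter points are expanded to size trajectories, pushed
through the Wright-Fisher simulator to get an expected folded spectrum, and
scored against the observed spectrum with a multinomial composite
log-likelihood on normalized spectra (shape only — no absolute-rate / theta
estimation).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from pathlib import Path

import numpy as np
import pandas as pd

from .demography import DemographicModel, NeTrajectory, expand_model_to_trajectory
from .variants import MISSING, VariantTable

__all__ = ["FoldedSFS", "folded_sfs", "genotype_pca", "fit_bottleneck_grid",
           "expected_folded_sfs", "PCAResult", "GridFit"]


@dataclass(frozen=True)
class FoldedSFS:
    """Counts of polymorphic sites by minor-allele count 1..floor(n/2),
    over n sampled haploid alleles.  Monomorphic sites are excluded."""

    counts: np.ndarray
    n: int

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        if counts.size != self.n // 2:
            raise ValueError("need one bin per minor-allele count 1..n//2")
        if np.any(counts < 0):
            raise ValueError("bin counts must be non-negative")
        object.__setattr__(self, "counts", counts)

    @property
    def n_polymorphic(self) -> float:
        return float(self.counts.sum())

    def normalized(self) -> np.ndarray:
        total = self.counts.sum()
        if total == 0:
            raise ValueError("empty spectrum")
        return self.counts / total

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"minor_count": np.arange(1, self.counts.size + 1),
             "sites": self.counts}
        ).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "FoldedSFS":
        df = pd.read_csv(path, sep="\t")
        # bins run 1..n//2; n recovered as twice the top bin (even-n convention)
        return cls(df["sites"].to_numpy(float), int(2 * df["minor_count"].max()))


def folded_sfs(vt: VariantTable) -> FoldedSFS:
    """Tally minor-allele counts into the folded spectrum.

    Requires complete genotypes (no missing calls) so every site is counted
    over the same number of alleles — filter first.  Counts of i and n-i
    fold into the same bin; exact n/2 goes once into the top bin.
    """
    if np.any(vt.genotypes == MISSING):
        raise ValueError(
            "folded SFS requires complete genotypes; filter to sites called "
            "in all individuals first"
        )
    n = 2 * vt.n_individuals
    alt = vt.genotypes.sum(axis=1, dtype=np.int64)
    minor = np.minimum(alt, n - alt)
    poly = minor > 0
    counts = np.bincount(minor[poly], minlength=n // 2 + 1)[1 : n // 2 + 1]
    return FoldedSFS(counts.astype(float), n)


@dataclass(frozen=True)
class PCAResult:
    scores: np.ndarray  # (n_individuals, k)
    loadings: np.ndarray  # (n_sites, k)
    variance_fractions: np.ndarray


def genotype_pca(vt: VariantTable, n_components: int = 10) -> PCAResult:
    """PCA of the genotype matrix with allele-frequency scaling.

    Each site is centered by twice its allele frequency and scaled by the
    binomial SD sqrt(2 p (1-p)); missing calls are mean-imputed before the
    decomposition.  Component signs are fixed so the largest-magnitude
    loading is positive.
    """
    if vt.n_individuals < 2 or vt.n_sites < 2:
        raise ValueError("PCA needs at least 2 individuals and 2 sites")
    g = vt.genotypes.astype(float).T  # individuals x sites
    miss = vt.genotypes.T == MISSING
    g[miss] = np.nan
    p = np.nanmean(g, axis=0) / 2.0
    scale = np.sqrt(2.0 * p * (1.0 - p))
    keep = scale > 0
    if not keep.any():
        raise ValueError("all sites monomorphic: zero-variance matrix")
    x = (g[:, keep] - 2.0 * p[keep]) / scale[keep]
    x = np.where(np.isnan(x), 0.0, x)  # mean imputation in scaled units
    k = min(n_components, min(x.shape))
    u, s, vh = np.linalg.svd(x, full_matrices=False)
    total_var = float(np.sum(x * x))
    if total_var == 0:
        raise ValueError("zero-variance matrix")
    scores = u[:, :k] * s[:k]
    load_kept = vh[:k].T
    # re-inflate loadings to the full site set (zero at excluded sites)
    loadings = np.zeros((vt.n_sites, k))
    loadings[np.flatnonzero(keep)] = load_kept
    sign = np.sign(load_kept[np.argmax(np.abs(load_kept), axis=0), np.arange(k)])
    sign[sign == 0] = 1.0
    return PCAResult(
        scores=scores * sign,
        loadings=loadings * sign,
        variance_fractions=(s[:k] ** 2) / total_var,
    )


def expected_folded_sfs(
    model: DemographicModel,
    point: dict,
    n_haploid: int,
    n_loci: int,
    reps: int,
    seed: int | np.random.SeedSequence,
    source_freq_dist: tuple = ("uniform", 0.05, 0.95),
) -> np.ndarray:
    """Average normalized folded spectrum under a founder-model point.

    Simulates ``reps`` Wright-Fisher passes of ``n_loci`` source loci through
    the point's trajectory, samples n_haploid alleles, and averages the
    folded spectra.  Pooling replicates before normalizing keeps points with
    heavy allele loss comparable.
    """
    from .simulate import SimConfig, draw_source_frequencies, simulate_wf_trajectory

    traj = expand_model_to_trajectory(model, point)
    ss = np.random.SeedSequence(seed) if isinstance(seed, int) else seed
    pooled = np.zeros(n_haploid // 2)
    for i, sub in enumerate(ss.spawn(reps)):
        freq_seed, wf_seed, samp_seed = sub.spawn(3)
        cfg = SimConfig(
            n_loci=n_loci,
            source_freq_dist=source_freq_dist,
            seed=int(freq_seed.generate_state(1)[0] % (2**31)),
        )
        freqs = draw_source_frequencies(cfg)
        final, _ = simulate_wf_trajectory(freqs, traj, wf_seed)
        rng = np.random.default_rng(samp_seed)
        alt = rng.binomial(n_haploid, final)
        minor = np.minimum(alt, n_haploid - alt)
        minor = minor[minor > 0]
        pooled += np.bincount(minor, minlength=n_haploid // 2 + 1)[1:]
    total = pooled.sum()
    if total == 0:
        raise ValueError("no polymorphic sites simulated; increase n_loci/reps")
    return pooled / total


@dataclass(frozen=True)
class GridFit:
    best_point: dict
    surface: pd.DataFrame  # one row per grid point with log-likelihood


def fit_bottleneck_grid(
    obs: FoldedSFS,
    model: DemographicModel,
    grid: dict[str, list],
    reps_per_point: int = 20,
    n_loci: int = 2000,
    seed: int = 0,
    n_contemporary: float = 1e6,
    source_freq_dist: tuple = ("uniform", 0.05, 0.95),
) -> GridFit:
    """Grid-search fit of founder parameters to an observed folded spectrum.

    ``grid`` maps parameter names (typically N_intro and t_exp, the recovery
    time in generations ago) to candidate values; unlisted parameters are
    fixed (N_contemporary defaults to 1e6).  Each point is scored by the
    multinomial composite log-likelihood sum_i obs_i * log(expected_i), which
    is invariant to scaling the observed counts.
    """
    names = sorted(grid)
    points = [dict(zip(names, combo)) for combo in product(*(grid[n] for n in names))]
    if not points:
        raise ValueError("empty grid")
    ss = np.random.SeedSequence(seed)
    rows = []
    best = None
    for point, sub in zip(points, ss.spawn(len(points))):
        full = {"N_contemporary": n_contemporary, **point}
        if "bottleneck_duration" in full:
            # convenience axis: duration d <=> recovery t_exp = t_intro - d ago
            full["t_exp"] = model.t_intro - int(full.pop("bottleneck_duration"))
        exp = expected_folded_sfs(
            model, full, obs.n, n_loci, reps_per_point, sub,
            source_freq_dist=source_freq_dist,
        )
        exp = np.clip(exp, 1e-12, None)
        ll = float(np.sum(obs.counts * np.log(exp)))
        rows.append({**point, "loglik": ll})
        if best is None or ll > best[0]:
            best = (ll, full)
    return GridFit(best_point=best[1], surface=pd.DataFrame(rows))
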
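"""Synthetic founder-event datasets: genotypes, phenotypes, and trait drift.

The generator emulates the study design the analysis assumes: a large source
population, a derived population founded by very few individuals roughly 32
generations ago with delayed recovery, and a heritable additive trait whose
mean may shift by drift alone or by drift plus directional selection.

The genetic model is a pure Wright-Fisher chain over unlinked biallelic
loci: each generation g the allele frequency is binomially resampled with
2*N_g trials.  Founder sampling IS the first trajectory generation (size
N_intro) — the founder effect is realised as a one-generation extreme
bottleneck.  Mutation is off (32 generations at ~5e-9 per site is
negligible for every quantity tested); directional selection, when enabled,
applies the deterministic update p' = p(1+s)/(1+ps) before each binomial
draw.

Phenotypes are additive: trait = sum of dosage x effect over causal loci
plus Gaussian noise whose variance is set so that additive/total variance
equals the target narrow-sense heritability in the generating population.

A single master seed spawns independent substreams for every stochastic
operation, so partial re-runs are replicable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .demography import NeTrajectory
from .variants import MISSING, VariantTable, write_vcf

__all__ = [
    "SimConfig",
    "SimResult",
    "PhenotypeSim",
    "draw_source_frequencies",
    "simulate_wf_trajectory",
    "sample_genotypes",
    "simulate_phenotypes",
    "simulate_trait_drift",
    "simulate_dataset",
    "planted_sweep_dataset",
    "to_variant_table",
    "write_fixture",
]

#: generation time (years) used to convert the 80-year history to 32 generations
GENERATION_YEARS = 2.5

#: per-site per-generation mutation rate (collared-flycatcher estimate); kept
#: in the config for SFS scaling, not used by the drift chain itself
DEFAULT_MU = 4.6e-9

TRAIT_NAMES = ("wing", "tail", "tarsus", "bill_length", "bill_depth", "bill_width")

# Baseline adult measurements (mm) for a small passerine, used when the
# simulated heritable size factor is expressed as six morphometric traits.
_TRAIT_BASELINE_MM = {
    "wing": 60.0,
    "tail": 42.0,
    "tarsus": 17.0,
    "bill_length": 11.0,
    "bill_depth": 3.4,
    "bill_width": 2.9,
}
_TRAIT_GENETIC_LOADING = 0.05  # log-scale loading of the shared size factor
_TRAIT_NOISE_SD = 0.02  # per-trait log-scale measurement/environment noise


def _default_trajectory() -> NeTrajectory:
    # 10 founder-bottleneck generations at N=5, then recovery to a large
    # contemporary size: the "few founders, delayed recovery" history.
    return NeTrajectory(np.concatenate([np.full(10, 5.0), np.full(22, 1e4)]))


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one synthetic founder-event dataset."""

    n_loci: int = 1000
    source_freq_dist: tuple = ("uniform", 0.05, 0.95)
    n_source_sample: int = 20
    trajectory: NeTrajectory = field(default_factory=_default_trajectory)
    n_derived_sample: int = 50
    n_causal: int = 20
    h2_target: float = 0.4
    selection_coeffs: float | np.ndarray = 0.0
    missing_rate: float = 0.0
    mu: float = DEFAULT_MU
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_causal > self.n_loci:
            raise ValueError("n_causal must be <= n_loci")
        if not 0.0 < self.h2_target <= 1.0:
            raise ValueError("h2_target must be in (0, 1]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")


@dataclass(frozen=True)
class PhenotypeSim:
    values: np.ndarray
    realized_h2: float
    noise_sd: float
    genetic_values: np.ndarray


@dataclass(frozen=True)
class SimResult:
    """Everything one simulation run produced, including ground truth."""

    config: SimConfig
    source_genotypes: np.ndarray  # (n_loci, n_source) dosage 0/1/2, -1 missing
    derived_genotypes: np.ndarray
    source_trait: np.ndarray
    derived_trait: np.ndarray
    true_freq_paths: np.ndarray  # (n_generations + 1, n_loci), row 0 = source
    causal_effects: np.ndarray  # per-locus additive effects (0 off-causal)
    causal_loci: np.ndarray
    realized_h2: float
    positions: np.ndarray
    chrom: np.ndarray


def _check_dist(dist: tuple) -> tuple:
    kind = dist[0]
    if kind == "uniform":
        _, lo, hi = dist
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError(f"uniform bounds must satisfy 0 <= lo <= hi <= 1: {dist}")
    elif kind == "beta":
        _, a, b = dist
        if a <= 0 or b <= 0:
            raise ValueError(f"beta parameters must be positive: {dist}")
    else:
        raise ValueError(f"unknown frequency distribution: {kind!r}")
    return dist


def draw_source_frequencies(config: SimConfig) -> np.ndarray:
    """Draw source-population allele frequencies from the configured spec.

    Frequencies are clipped away from exact 0/1 so every locus starts
    segregating (the chain can still absorb later).
    """
    if config.n_loci < 1:
        raise ValueError("n_loci must be >= 1")
    kind, a, b = _check_dist(config.source_freq_dist)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    if kind == "uniform":
        f = rng.uniform(a, b, size=config.n_loci)
    else:
        f = rng.beta(a, b, size=config.n_loci)
    eps = 1e-9
    return np.clip(f, eps, 1.0 - eps)


def simulate_wf_trajectory(
    freqs: np.ndarray,
    trajectory: NeTrajectory,
    seed: int | np.random.SeedSequence,
    selection: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Propagate allele frequencies through a Wright-Fisher size trajectory.

    Each generation g (size N_g) the frequency becomes a Binomial(2*N_g, p)
    draw divided by 2*N_g.  ``selection`` optionally gives a per-locus
    coefficient s applied deterministically, p' = p(1+s)/(1+ps), before the
    draw.  Returns (final frequencies, paths) where paths has one row per
    generation plus the initial state.
    """
    p = np.asarray(freqs, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("frequencies must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    paths = np.empty((trajectory.n_generations + 1, p.size))
    paths[0] = p
    for g, n in enumerate(trajectory.sizes, start=1):
        if selection is not None:
            p = p * (1.0 + selection) / (1.0 + p * selection)
        n2 = int(round(2 * n))
        p = rng.binomial(n2, p) / n2
        paths[g] = p
    return p, paths


def sample_genotypes(
    freqs: np.ndarray,
    n_ind: int,
    missing_rate: float = 0.0,
    seed: int | np.random.SeedSequence = 0,
) -> np.ndarray:
    """Hardy-Weinberg genotype sampling: 2 independent allele copies per
    individual per locus, with independent missingness."""
    if n_ind < 1:
        raise ValueError("n_ind must be >= 1")
    rng = np.random.default_rng(seed)
    p = np.asarray(freqs, dtype=float)
    g = rng.binomial(2, p[:, None], size=(p.size, n_ind)).astype(np.int8)
    if missing_rate > 0:
        g[rng.random(g.shape) < missing_rate] = MISSING
    return g


def simulate_phenotypes(
    genotypes: np.ndarray,
    effects: np.ndarray,
    h2_target: float,
    seed: int | np.random.SeedSequence = 0,
    noise_sd: float | None = None,
) -> PhenotypeSim:
    """Additive trait values with environmental noise calibrated to h2.

    The noise SD is solved from the sample additive variance of the provided
    genotypes so that Va / (Va + Ve) = h2_target in this (generating)
    population; pass ``noise_sd`` to reuse a source-calibrated value for a
    second population.  Raises when the additive variance is zero (all
    effects zero or all causal loci fixed) — heritability is then undefined.
    """
    if effects.shape[0] != genotypes.shape[0]:
        raise ValueError("effects length must equal locus count")
    if not 0.0 < h2_target <= 1.0:
        raise ValueError("h2_target must be in (0, 1]")
    if np.any(genotypes < 0):
        raise ValueError("phenotype simulation requires complete genotypes")
    g_values = effects @ genotypes.astype(float)
    va = float(np.var(g_values, ddof=1))
    if noise_sd is None:
        if va == 0.0:
            raise ValueError(
                "zero additive variance: all effects zero or all causal loci "
                "fixed — heritability is undefined"
            )
        noise_sd = float(np.sqrt(va * (1.0 - h2_target) / h2_target))
    rng = np.random.default_rng(seed)
    values = g_values + rng.normal(0.0, noise_sd, size=g_values.size)
    vp = float(np.var(values, ddof=1))
    realized = va / vp if vp > 0 else float("nan")
    return PhenotypeSim(values, realized, noise_sd, g_values)


def simulate_trait_drift(
    h2: float,
    sigma_p: float,
    trajectory: NeTrajectory,
    n_reps: int,
    seed: int | np.random.SeedSequence = 0,
) -> np.ndarray:
    """Replicate trait-mean shifts (in units of sigma) under pure drift.

    The Brownian null: each generation the trait mean moves by a Gaussian
    increment of variance h2 * sigma^2 / N_g, so over the whole trajectory
    Var(z / sigma) = h2 * sum_g 1/N_g = h2 * t / Ne(h).  This is the null
    model the Lande rate test inverts.
    """
    if not 0.0 < h2 <= 1.0:
        raise ValueError("h2 must be in (0, 1]")
    rng = np.random.default_rng(seed)
    step_sd = np.sqrt(h2 / trajectory.sizes)  # in sigma units
    increments = rng.standard_normal((n_reps, trajectory.n_generations)) * step_sd
    return increments.sum(axis=1)


def simulate_dataset(config: SimConfig) -> SimResult:
    """Run the full generator: source sample, founder WF chain, derived
    sample, and the additive trait in both populations."""
    ss = np.random.SeedSequence(config.seed)
    (s_freq, s_wf, s_src, s_der, s_eff, s_phs, s_phd, s_miss) = ss.spawn(8)

    freqs = draw_source_frequencies(config)
    rng_eff = np.random.default_rng(s_eff)
    causal = np.sort(rng_eff.choice(config.n_loci, size=config.n_causal, replace=False))
    effects = np.zeros(config.n_loci)
    effects[causal] = rng_eff.normal(0.0, 1.0, size=config.n_causal)

    sel = np.asarray(config.selection_coeffs, dtype=float)
    selection = None
    if np.any(sel != 0.0):
        selection = np.zeros(config.n_loci)
        selection[causal] = sel if sel.ndim else np.full(config.n_causal, float(sel))

    src_geno = sample_genotypes(freqs, config.n_source_sample, 0.0, s_src)
    final, paths = simulate_wf_trajectory(freqs, config.trajectory, s_wf, selection)
    der_geno = sample_genotypes(final, config.n_derived_sample, 0.0, s_der)

    src_ph = simulate_phenotypes(src_geno, effects, config.h2_target, s_phs)
    der_ph = simulate_phenotypes(
        der_geno, effects, config.h2_target, s_phd, noise_sd=src_ph.noise_sd
    )

    if config.missing_rate > 0:
        rng_m = np.random.default_rng(s_miss)
        src_geno = src_geno.copy()
        der_geno = der_geno.copy()
        src_geno[rng_m.random(src_geno.shape) < config.missing_rate] = MISSING
        der_geno[rng_m.random(der_geno.shape) < config.missing_rate] = MISSING

    return SimResult(
        config=config,
        source_genotypes=src_geno,
        derived_genotypes=der_geno,
        source_trait=src_ph.values,
        derived_trait=der_ph.values,
        true_freq_paths=paths,
        causal_effects=effects,
        causal_loci=causal,
        realized_h2=src_ph.realized_h2,
        positions=np.arange(1, config.n_loci + 1, dtype=np.int64) * 1000,
        chrom=np.full(config.n_loci, "1", dtype=object),
    )


def planted_sweep_dataset(
    trajectory: NeTrajectory,
    n_loci: int = 5000,
    n_causal: int = 20,
    s: float = 0.5,
    n_source: int = 20,
    n_derived: int = 50,
    seed: int = 0,
    source_freq_dist: tuple = ("uniform", 0.05, 0.95),
) -> tuple[VariantTable, np.ndarray]:
    """Founder dataset with directional sweeps planted at known loci.

    Selection of magnitude ``s`` is oriented toward each causal locus's
    minor allele in the source population (sign flipped where the favoured
    allele is already the major one), the standard design for a
    planted-outlier power benchmark: sweeps act on standing variation and
    the swept locus stays polymorphic in the pooled sample.  Returns the
    combined source+derived VariantTable and the causal site indices.
    """
    ss = np.random.SeedSequence(seed)
    s_causal, s_wf, s_src, s_der = ss.spawn(4)
    cfg = SimConfig(
        n_loci=n_loci, source_freq_dist=source_freq_dist, trajectory=trajectory,
        seed=seed,
    )
    freqs = draw_source_frequencies(cfg)
    rng = np.random.default_rng(s_causal)
    causal = np.sort(rng.choice(n_loci, size=n_causal, replace=False))
    selection = np.zeros(n_loci)
    selection[causal] = np.where(freqs[causal] < 0.5, s, -s)
    final, _ = simulate_wf_trajectory(freqs, trajectory, s_wf, selection)
    geno = np.concatenate(
        [
            sample_genotypes(freqs, n_source, 0.0, s_src),
            sample_genotypes(final, n_derived, 0.0, s_der),
        ],
        axis=1,
    )
    samples = tuple(f"SRC_{i + 1}" for i in range(n_source)) + tuple(
        f"DER_{i + 1}" for i in range(n_derived)
    )
    vt = VariantTable(
        chrom=np.full(n_loci, "1", dtype=object),
        pos=np.arange(1, n_loci + 1, dtype=np.int64) * 1000,
        ref=np.full(n_loci, "A", dtype=object),
        alt=np.full(n_loci, "T", dtype=object),
        genotypes=geno,
        samples=samples,
    )
    return vt, causal


def to_variant_table(result: SimResult) -> VariantTable:
    """Combine source + derived genotypes into one VariantTable (samples
    SRC_1.. then DER_1..)."""
    geno = np.concatenate([result.source_genotypes, result.derived_genotypes], axis=1)
    samples = tuple(
        f"SRC_{i + 1}" for i in range(result.source_genotypes.shape[1])
    ) + tuple(f"DER_{i + 1}" for i in range(result.derived_genotypes.shape[1]))
    n = result.config.n_loci
    return VariantTable(
        chrom=result.chrom,
        pos=result.positions,
        ref=np.full(n, "A", dtype=object),
        alt=np.full(n, "T", dtype=object),
        genotypes=geno,
        samples=samples,
    )


def trait_table_from_result(result: SimResult, seed: int | None = None) -> pd.DataFrame:
    """Express the simulated heritable size factor as six morphometric traits.

    Each measurement is baseline_mm * exp(loading * z + noise) where z is the
    individual's standardized simulated trait value — a one-factor body-size
    model with independent per-trait log-scale noise.  Condition flags are 0.
    """
    ss = np.random.SeedSequence(
        [result.config.seed, 1001] if seed is None else [seed, 1001]
    )
    rng = np.random.default_rng(ss)
    values = np.concatenate([result.source_trait, result.derived_trait])
    z = (values - values.mean()) / values.std(ddof=1)
    pops = ["SRC"] * result.source_trait.size + ["DER"] * result.derived_trait.size
    ids = [f"SRC_{i + 1}" for i in range(result.source_trait.size)] + [
        f"DER_{i + 1}" for i in range(result.derived_trait.size)
    ]
    data = {"individual": ids, "population": pops}
    for name in TRAIT_NAMES:
        noise = rng.normal(0.0, _TRAIT_NOISE_SD, size=z.size)
        data[name] = _TRAIT_BASELINE_MM[name] * np.exp(
            _TRAIT_GENETIC_LOADING * z + noise
        )
    data["moulting"] = np.zeros(z.size, dtype=int)
    data["bill_damaged"] = np.zeros(z.size, dtype=int)
    return pd.DataFrame(data)


def write_fixture(result: SimResult, out_dir: str | Path) -> dict[str, Path]:
    """Write VCF + trait CSV + trajectory JSON; round-trips through the
    package's readers without loss."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": out / "genotypes.vcf",
        "traits": out / "traits.csv",
        "trajectory": out / "trajectory.json",
    }
    write_vcf(to_variant_table(result), paths["vcf"])
    trait_table_from_result(result).to_csv(paths["traits"], index=False)
    result.config.trajectory.to_json(paths["trajectory"])
    return paths
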
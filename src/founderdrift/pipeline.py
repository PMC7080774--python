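"""End-to-end pipeline: simulate -> filter -> structure -> morphology ->
rate test -> selection scan, driven by one JSON/YAML config with a master
seed, writing every stage output plus a reproducibility manifest."""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .demography import NeTrajectory, harmonic_mean_ne
from .morphology import read_trait_table, shift_table
from .rate_test import LandeParams, rate_test_report
from .scan import ScanConfig, scan
from .simulate import SimConfig, simulate_dataset, write_fixture
from .structure import folded_sfs, genotype_pca
from .variants import FilterConfig, filter_variants, read_vcf, write_vcf

logger = logging.getLogger("founderdrift")

__all__ = ["PipelineConfig", "validate_config", "run_pipeline", "load_config"]


@dataclass
class PipelineConfig:
    out_dir: str = "founderdrift_run"
    seed: int = 0
    vcf_path: str | None = None  # None => simulate
    traits_path: str | None = None
    trajectory_path: str | None = None
    source_pop: str = "SRC"
    derived_pop: str = "DER"
    sim: dict = field(default_factory=dict)
    filter: dict = field(default_factory=dict)
    lande: dict = field(default_factory=dict)
    scan: dict = field(default_factory=dict)
    sigma: str = "colonised"
    log_level: str = "INFO"


def load_config(path: str | Path) -> PipelineConfig:
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        import yaml

        data = yaml.safe_load(text)
    else:
        data = json.loads(text)
    return PipelineConfig(**data)


def validate_config(config: PipelineConfig) -> list[str]:
    """Check every bound; returns a human-readable violation list."""
    violations: list[str] = []
    sim = config.sim
    if "h2_target" in sim and not 0.0 < sim["h2_target"] <= 1.0:
        violations.append(f"h2_target={sim['h2_target']} outside (0, 1]")
    if "missing_rate" in sim and not 0.0 <= sim["missing_rate"] < 1.0:
        violations.append(f"missing_rate={sim['missing_rate']} outside [0, 1)")
    if "n_intro" in sim and not 2 <= sim["n_intro"] <= 100:
        violations.append(f"N_intro={sim['n_intro']} below bound 2 or above 100"
                          if sim["n_intro"] < 2
                          else f"N_intro={sim['n_intro']} above bound 100")
    for name in ("h2_low", "h2_high"):
        if name in config.lande and not 0.0 < config.lande[name] <= 1.0:
            violations.append(f"{name}={config.lande[name]} outside (0, 1]")
    for name in ("gen_years_low", "gen_years_high", "elapsed_years"):
        if name in config.lande and config.lande[name] <= 0:
            violations.append(f"{name} must be positive")
    try:
        ScanConfig(**config.scan)
    except (ValueError, TypeError) as e:
        violations.append(f"scan config: {e}")
    try:
        FilterConfig(**config.filter)
    except (ValueError, TypeError) as e:
        violations.append(f"filter config: {e}")
    if config.vcf_path is not None and not Path(config.vcf_path).exists():
        violations.append(f"vcf_path does not exist: {config.vcf_path}")
    if config.sigma not in ("colonised", "pooled"):
        violations.append(f"sigma must be colonised|pooled, got {config.sigma!r}")
    return violations


def run_pipeline(config: PipelineConfig) -> Path:
    """Run all six stages; returns the run directory.

    Outputs are deterministic functions of (config, seed).  A failed stage
    aborts with the stage name in the exception; outputs of earlier stages
    are retained in the run directory.
    """
    violations = validate_config(config)
    if violations:
        raise ValueError("invalid config: " + "; ".join(violations))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    logger.addHandler(handler)
    logger.setLevel(config.log_level)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": asdict(config),
        "stages": [],
    }
    stage = "simulate"
    try:
        if config.vcf_path is None:
            sim_kwargs = dict(config.sim)
            sim_kwargs.pop("n_intro", None)
            if config.trajectory_path:
                sim_kwargs["trajectory"] = NeTrajectory.from_json(
                    config.trajectory_path
                )
            cfg = SimConfig(seed=config.seed, **sim_kwargs)
            result = simulate_dataset(cfg)
            paths = write_fixture(result, out / "simulated")
            vcf_path, traits_path = paths["vcf"], paths["traits"]
            traj = cfg.trajectory
            logger.info("simulated %d loci", cfg.n_loci)
        else:
            vcf_path = Path(config.vcf_path)
            traits_path = Path(config.traits_path) if config.traits_path else None
            traj = (
                NeTrajectory.from_json(config.trajectory_path)
                if config.trajectory_path
                else None
            )
        manifest["stages"].append(stage)

        stage = "filter"
        vt = read_vcf(vcf_path)
        fcfg = FilterConfig(**config.filter)
        filtered, counts = filter_variants(vt, fcfg)
        write_vcf(filtered, out / "filtered.vcf")
        pd.DataFrame(
            [{"rule": k, "removed": v} for k, v in counts.items()]
        ).to_csv(out / "filter_counts.tsv", sep="\t", index=False)
        logger.info("filter retained %d/%d sites", filtered.n_sites, vt.n_sites)
        manifest["stages"].append(stage)

        stage = "structure"
        pca = genotype_pca(filtered, n_components=min(10, filtered.n_individuals))
        pd.DataFrame(
            pca.scores,
            columns=[f"PC{i + 1}" for i in range(pca.scores.shape[1])],
        ).assign(individual=list(filtered.samples)).to_csv(
            out / "genotype_pca.csv", index=False
        )
        complete = filtered.take_sites(
            np.flatnonzero((filtered.genotypes >= 0).all(axis=1))
        )
        sfs = folded_sfs(complete)
        sfs.to_tsv(out / "folded_sfs.tsv")
        ne_h = harmonic_mean_ne(traj) if traj is not None else None
        manifest["ne_h"] = ne_h
        manifest["stages"].append(stage)

        stage = "morphology"
        shifts = []
        if traits_path is not None:
            tt = read_trait_table(traits_path)
            shifts = shift_table(tt, config.source_pop, config.derived_pop)
            pd.DataFrame(
                [
                    {
                        "trait": s.trait,
                        "z": s.z,
                        "sigma_pooled": s.sigma_pooled,
                        "sigma_colonised": s.sigma_colonised,
                        "z_over_sigma": s.z_over_sigma(config.sigma),
                    }
                    for s in shifts
                ]
            ).to_csv(out / "shifts.tsv", sep="\t", index=False)
        manifest["stages"].append(stage)

        stage = "rate_test"
        if shifts and ne_h is not None:
            report = rate_test_report(
                shifts, LandeParams(**config.lande), ne_h=ne_h, sigma=config.sigma
            )
            report.to_csv(out / "rate_test.tsv", sep="\t", index=False)
        manifest["stages"].append(stage)

        stage = "scan"
        labels = {s: ("SRC" if s.startswith("SRC") else "DER")
                  for s in filtered.samples}
        outliers = scan(
            filtered,
            ScanConfig(**config.scan),
            populations=(config.source_pop, config.derived_pop)
            if config.vcf_path is None
            else None,
            pop_labels=labels if config.vcf_path is None else None,
        )
        outliers.to_csv(out / "outliers.tsv", sep="\t", index=False)
        manifest["lambda"] = outliers.attrs.get("lambda")
        manifest["stages"].append(stage)
    except Exception as e:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {e}") from e
    finally:
        logger.removeHandler(handler)
        handler.close()

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return out
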
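"""SNP genotype tables: VCF reading/writing, quality filtering, LD pruning.

Genotypes are diploid alt-allele dosages coded 0/1/2 with -1 for missing,
stored as a sites x individuals int8 matrix.  Reading goes through cyvcf2;
writing emits the minimal VCF v4.2 dialect used throughout the package
(REF/ALT single bases, unphased GT, "./." for missing).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from cyvcf2 import VCF

MISSING = -1

__all__ = [
    "MISSING",
    "VariantTable",
    "FilterConfig",
    "read_vcf",
    "write_vcf",
    "filter_variants",
    "compute_maf",
    "prune_ld",
]


@dataclass(frozen=True)
class VariantTable:
    """Biallelic SNP sites with per-individual genotype dosages.

    ``genotypes`` has shape (n_sites, n_individuals); ``gq`` and ``dp`` are
    optional same-shape per-call quality/depth arrays.
    """

    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    genotypes: np.ndarray
    samples: tuple[str, ...]
    gq: np.ndarray | None = None
    dp: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.genotypes.ndim != 2:
            raise ValueError("genotypes must be 2-D (sites x individuals)")
        if self.genotypes.shape[0] != self.pos.size:
            raise ValueError("site metadata and genotype rows disagree")
        if self.genotypes.shape[1] != len(self.samples):
            raise ValueError("sample names and genotype columns disagree")
        bad = ~np.isin(self.genotypes, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("genotype codes must be 0/1/2 or missing")
        for c in np.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if p.size > 1 and np.any(np.diff(p) <= 0):
                raise ValueError(f"positions not strictly increasing on {c}")

    @property
    def n_sites(self) -> int:
        return int(self.pos.size)

    @property
    def n_individuals(self) -> int:
        return len(self.samples)

    def take_sites(self, idx: np.ndarray) -> "VariantTable":
        return replace(
            self,
            chrom=self.chrom[idx],
            pos=self.pos[idx],
            ref=self.ref[idx],
            alt=self.alt[idx],
            genotypes=self.genotypes[idx],
            gq=None if self.gq is None else self.gq[idx],
            dp=None if self.dp is None else self.dp[idx],
        )

    def take_individuals(self, idx: np.ndarray) -> "VariantTable":
        samples = tuple(np.asarray(self.samples)[idx])
        return replace(
            self,
            genotypes=self.genotypes[:, idx],
            samples=samples,
            gq=None if self.gq is None else self.gq[:, idx],
            dp=None if self.dp is None else self.dp[:, idx],
        )


def read_vcf(path: str | Path, snps_only: bool = True) -> VariantTable:
    """Load a VCF v4.x file into a VariantTable.

    Indels and multi-allelic records are dropped when ``snps_only`` (the
    default); GQ/DP arrays are attached when the FORMAT declares them.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    vcf = VCF(str(path))
    samples = tuple(vcf.samples)
    chrom, pos, ref, alt, rows, gqs, dps = [], [], [], [], [], [], []
    has_gq = has_dp = False
    for i, rec in enumerate(vcf):
        if snps_only:
            if len(rec.ALT) != 1:
                continue
            if len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
                continue  # indel
        elif len(rec.ALT) != 1:
            raise ValueError(
                f"multi-allelic record at {rec.CHROM}:{rec.POS} "
                "(record {i}); enable snps_only to drop it"
            )
        chrom.append(rec.CHROM)
        pos.append(rec.POS)
        ref.append(rec.REF)
        alt.append(rec.ALT[0])
        row = np.empty(len(samples), dtype=np.int8)
        for j, g in enumerate(rec.genotypes):
            a, b = g[0], g[1]
            row[j] = MISSING if (a < 0 or b < 0) else a + b
        rows.append(row)
        try:
            gq = rec.format("GQ")
        except KeyError:
            gq = None
        try:
            dp = rec.format("DP")
        except KeyError:
            dp = None
        if gq is not None:
            has_gq = True
        if dp is not None:
            has_dp = True
        gqs.append(None if gq is None else gq.reshape(-1).astype(float))
        dps.append(None if dp is None else dp.reshape(-1).astype(float))
    n = len(samples)
    fill = np.full(n, np.nan)
    return VariantTable(
        chrom=np.array(chrom, dtype=object),
        pos=np.array(pos, dtype=np.int64),
        ref=np.array(ref, dtype=object),
        alt=np.array(alt, dtype=object),
        genotypes=np.array(rows, dtype=np.int8).reshape(len(rows), n),
        samples=samples,
        gq=np.array([g if g is not None else fill for g in gqs]) if has_gq else None,
        dp=np.array([d if d is not None else fill for d in dps]) if has_dp else None,
    )


_GT_STR = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(vt: VariantTable, path: str | Path) -> None:
    """Write the minimal VCF v4.2 dialect; inverse of read_vcf."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in dict.fromkeys(vt.chrom):  # preserves order
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(vt.samples)
            + "\n"
        )
        for i in range(vt.n_sites):
            gts = "\t".join(_GT_STR[int(g)] for g in vt.genotypes[i])
            fh.write(
                f"{vt.chrom[i]}\t{vt.pos[i]}\t.\t{vt.ref[i]}\t{vt.alt[i]}"
                f"\t.\tPASS\t.\tGT\t{gts}\n"
            )


@dataclass(frozen=True)
class FilterConfig:
    """Quality thresholds applied genotype-level, then site-level, then
    individual-level: calls failing GQ/DP are set missing; sites must be
    biallelic SNPs with enough calls and minor-allele support; individuals
    with too much missing data are dropped."""

    biallelic_only: bool = True
    min_maf: float = 0.01
    min_mac: int | None = None  # alternative minor-allele-count criterion
    min_gq: float | None = 30.0
    min_dp: float | None = 8.0
    min_site_call_rate: float = 0.5
    max_individual_missingness: float = 0.3

    def __post_init__(self) -> None:
        for name in ("min_maf", "min_site_call_rate", "max_individual_missingness"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


def compute_maf(vt: VariantTable) -> np.ndarray:
    """Per-site minor allele frequency over called genotypes; NaN where no calls."""
    g = vt.genotypes.astype(float)
    called = g >= 0
    n_alleles = 2.0 * called.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(called, g, 0.0).sum(axis=1) / n_alleles
    maf = np.minimum(p, 1.0 - p)
    maf[n_alleles == 0] = np.nan
    return maf


def filter_variants(
    vt: VariantTable, cfg: FilterConfig
) -> tuple[VariantTable, dict[str, int]]:
    """Apply the filter cascade; returns the table and per-rule removal counts.

    Order: (1) genotype calls failing GQ/DP thresholds set to missing;
    (2) site filters — biallelic SNP, call rate, MAF (or MAC) on remaining
    calls; (3) individuals above the missingness cut dropped.  An empty
    result is returned as-is, never raised.
    """
    counts = {"genotypes_masked": 0, "triallelic": 0, "call_rate": 0, "maf": 0,
              "individuals": 0}
    g = vt.genotypes.copy()
    mask = np.zeros(g.shape, dtype=bool)
    if cfg.min_gq is not None and vt.gq is not None:
        mask |= ~(vt.gq >= cfg.min_gq)  # NaN fails
    if cfg.min_dp is not None and vt.dp is not None:
        mask |= ~(vt.dp >= cfg.min_dp)
    mask &= g != MISSING
    counts["genotypes_masked"] = int(mask.sum())
    g[mask] = MISSING
    vt = replace(vt, genotypes=g)

    keep = np.ones(vt.n_sites, dtype=bool)
    if cfg.biallelic_only:
        # multi-allelic records were flagged at read time by dropping; here a
        # site is "triallelic" if REF/ALT are not single distinct bases
        bad = np.array(
            [len(r) != 1 or len(a) != 1 or r == a for r, a in zip(vt.ref, vt.alt)]
        )
        counts["triallelic"] = int(bad.sum())
        keep &= ~bad
    called = (vt.genotypes >= 0).mean(axis=1)
    low_cr = keep & (called < cfg.min_site_call_rate)
    counts["call_rate"] = int(low_cr.sum())
    keep &= ~low_cr
    maf = compute_maf(vt)
    if cfg.min_mac is not None:
        gg = vt.genotypes.astype(float)
        alt = np.where(gg >= 0, gg, 0.0).sum(axis=1)
        tot = 2.0 * (gg >= 0).sum(axis=1)
        mac = np.minimum(alt, tot - alt)
        low = keep & ~(mac >= cfg.min_mac)
    else:
        low = keep & ~(maf > cfg.min_maf)
    counts["maf"] = int(low.sum())
    keep &= ~low
    vt = vt.take_sites(np.flatnonzero(keep))

    if vt.n_sites > 0:
        miss = (vt.genotypes == MISSING).mean(axis=0)
        ind_keep = miss < cfg.max_individual_missingness
        counts["individuals"] = int((~ind_keep).sum())
        vt = vt.take_individuals(np.flatnonzero(ind_keep))
    return vt, counts


def _pairwise_r2(a: np.ndarray, b: np.ndarray) -> float:
    """Squared Pearson correlation of dosages over jointly called individuals."""
    ok = (a >= 0) & (b >= 0)
    if ok.sum() < 2:
        return 0.0
    x = a[ok].astype(float)
    y = b[ok].astype(float)
    sx, sy = x.std(), y.std()
    if sx == 0.0 or sy == 0.0:
        return 0.0
    r = np.corrcoef(x, y)[0, 1]
    if abs(r) < 1e-12:  # "r^2 > 0" is numerically unusable verbatim
        return 0.0
    return float(r * r)


def prune_ld(
    vt: VariantTable, window_bp: int = 100_000, r2_threshold: float = 0.0
) -> VariantTable:
    """Greedy left-to-right LD pruning: within ``window_bp`` on a chromosome,
    the later SNP of any pair with dosage r^2 > threshold is removed."""
    keep: list[int] = []
    for i in range(vt.n_sites):
        ok = True
        for j in reversed(keep):
            if vt.chrom[j] != vt.chrom[i]:
                break
            if vt.pos[i] - vt.pos[j] > window_bp:
                break
            if _pairwise_r2(vt.genotypes[i], vt.genotypes[j]) > r2_threshold:
                ok = False
                break
        if ok:
            keep.append(i)
    return vt.take_sites(np.array(keep, dtype=int))
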
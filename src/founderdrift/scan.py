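"""PC-based selection scan: Mahalanobis outlier statistic with inflation
and FDR control, plus interval-proximity candidate annotation.

Pipeline per scan: MAF filter -> genotype PCA (K components) -> per-SNP
association z-scores against the K score vectors -> Mahalanobis D^2 across
SNPs -> genomic-inflation correction (median-based lambda against chi^2_K)
-> Benjamini-Hochberg q-values and outlier flags.  Defaults follow common
scan practice for a two-group founder contrast: K = 2, MinMAF = 0.1,
FDR q = 0.01, and a 10 kb annotation window.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .structure import genotype_pca
from .variants import MISSING, VariantTable, compute_maf

__all__ = [
    "ScanConfig",
    "snp_zscores",
    "mahalanobis_stats",
    "inflation_correct",
    "bh_fdr",
    "scan",
    "read_intervals",
    "candidate_proximity",
]


@dataclass(frozen=True)
class ScanConfig:
    k: int = 2
    min_maf: float = 0.1
    fdr_q: float = 0.01
    proximity_bp: int = 10_000

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if not 0.0 <= self.min_maf < 0.5:
            raise ValueError("min_maf must be in [0, 0.5)")
        if not 0.0 < self.fdr_q < 1.0:
            raise ValueError("fdr_q must be in (0, 1)")


def snp_zscores(vt: VariantTable, k: int = 2) -> np.ndarray:
    """Per-SNP association z-scores against the first k genotype PCs.

    Each SNP's standardized dosage is regressed (with intercept) on the k
    score vectors; the z-score is coefficient / standard error per
    component.  Returns an (n_sites, k) array.
    """
    if vt.n_individuals < k + 2:
        raise ValueError("need at least k + 2 individuals")
    pca = genotype_pca(vt, n_components=k)
    scores = pca.scores[:, :k]
    if np.linalg.matrix_rank(scores) < k:
        raise ValueError("rank-deficient score matrix")
    n = vt.n_individuals
    g = vt.genotypes.astype(float).T  # individuals x sites
    g[vt.genotypes.T == MISSING] = np.nan
    mean = np.nanmean(g, axis=0)
    sd = np.nanstd(g, axis=0, ddof=1)
    sd[sd == 0] = 1.0
    y = (np.where(np.isnan(g), mean, g) - mean) / sd

    x = np.column_stack([np.ones(n), scores])
    xtx_inv = np.linalg.inv(x.T @ x)
    beta = xtx_inv @ (x.T @ y)  # (k+1, n_sites)
    resid = y - x @ beta
    dof = n - (k + 1)
    sigma2 = (resid**2).sum(axis=0) / dof
    se = np.sqrt(np.outer(np.diag(xtx_inv), sigma2))
    with np.errstate(invalid="ignore", divide="ignore"):
        z = beta / se
    return z[1:].T  # drop intercept


def mahalanobis_stats(z: np.ndarray) -> np.ndarray:
    """D^2_j = (z_j - center)' Sigma^{-1} (z_j - center), center and Sigma
    estimated across SNPs; invariant to any affine transform of z."""
    z = np.atleast_2d(np.asarray(z, dtype=float))
    n, k = z.shape
    if n < k + 1:
        raise ValueError("need at least k + 1 SNPs")
    center = z.mean(axis=0)
    cov = np.cov(z, rowvar=False).reshape(k, k)
    try:
        prec = np.linalg.inv(cov)
    except np.linalg.LinAlgError as e:
        raise ValueError("singular covariance of z-scores") from e
    d = z - center
    return np.einsum("ij,jk,ik->i", d, prec, d)


def inflation_correct(d2: np.ndarray, k: int) -> tuple[float, np.ndarray]:
    """Median-based genomic inflation factor and corrected p-values.

    lambda = median(D^2) / median(chi^2_k); p_j = upper tail of chi^2_k at
    D^2_j / lambda.  Rescaling all D^2 by a constant scales lambda and
    leaves the p-values unchanged.
    """
    d2 = np.asarray(d2, dtype=float)
    if d2.size == 0:
        raise ValueError("empty statistic vector")
    lam = float(np.median(d2) / stats.chi2.median(df=k))
    p = stats.chi2.sf(d2 / lam, df=k)
    return lam, p


def bh_fdr(p: np.ndarray, q: float) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (q-values, flags with q-value <= q)."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    _, qvals, _, _ = multipletests(p, method="fdr_bh")
    return qvals, qvals <= q


def scan(
    vt: VariantTable,
    cfg: ScanConfig = ScanConfig(),
    populations: tuple[str, str] | None = None,
    pop_labels: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Full outlier scan; returns the per-SNP OutlierTable DataFrame.

    ``populations`` with ``pop_labels`` (sample -> label) restricts the scan
    to a chosen pair of population labels, mirroring per-island vs source
    contrasts.  Stages run in fixed order (MAF filter, PCA, z-scores, D^2,
    inflation-corrected p, BH flags), so output is deterministic given the
    input.  Rows for MAF-excluded SNPs carry NaN statistics and False flags.
    """
    if populations is not None:
        if pop_labels is None:
            raise ValueError("populations requires pop_labels")
        wanted = [i for i, s in enumerate(vt.samples)
                  if pop_labels.get(s) in populations]
        vt = vt.take_individuals(np.array(wanted, dtype=int))
    maf = compute_maf(vt)
    keep = maf >= cfg.min_maf
    sub = vt.take_sites(np.flatnonzero(keep))
    z = snp_zscores(sub, cfg.k)
    d2 = mahalanobis_stats(z)
    lam, p = inflation_correct(d2, cfg.k)
    qvals, flags = bh_fdr(p, cfg.fdr_q)

    out = pd.DataFrame(
        {
            "chrom": vt.chrom,
            "pos": vt.pos,
            "maf": maf,
            "d2": np.nan,
            "p": np.nan,
            "q": np.nan,
            "outlier": False,
        }
    )
    idx = np.flatnonzero(keep)
    out.loc[idx, "d2"] = d2
    out.loc[idx, "p"] = p
    out.loc[idx, "q"] = qvals
    out.loc[idx, "outlier"] = flags
    out.attrs["lambda"] = lam
    return out


def read_intervals(path: str | Path) -> pd.DataFrame:
    """Read annotation intervals from BED (0-based half-open) or GFF3 (gene
    lines, 1-based inclusive) into 1-based inclusive (chrom, start, end,
    name) records."""
    path = Path(path)
    rows = []
    if path.suffix.lower() in (".gff", ".gff3"):
        for line in path.read_text().splitlines():
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 9 or f[2] != "gene":
                continue
            name = "."
            for kv in f[8].split(";"):
                if kv.startswith(("ID=", "Name=")):
                    name = kv.split("=", 1)[1]
                    break
            rows.append((f[0], int(f[3]), int(f[4]), name))
    else:  # BED
        for line in path.read_text().splitlines():
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            start, end = int(f[1]), int(f[2])
            rows.append((f[0], start + 1, end, f[3] if len(f) > 3 else "."))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])
    if len(df) and np.any(df["end"] < df["start"]):
        raise ValueError("malformed interval: end < start")
    return df.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)


def candidate_proximity(
    outliers: pd.DataFrame, annotations: pd.DataFrame, window_bp: int = 10_000
) -> pd.DataFrame:
    """List annotation intervals within ``window_bp`` of each outlier SNP.

    Distance is 0 inside an interval, negative when the SNP lies left of the
    interval start, positive when right of the end (strand-agnostic).  Only
    rows flagged as outliers are annotated.
    """
    hits = []
    flagged = outliers[outliers["outlier"].fillna(False).astype(bool)]
    for _, snp in flagged.iterrows():
        ann = annotations[annotations["chrom"] == snp["chrom"]]
        for _, iv in ann.iterrows():
            if snp["pos"] < iv["start"]:
                dist = int(snp["pos"] - iv["start"])  # negative: SNP upstream
            elif snp["pos"] > iv["end"]:
                dist = int(snp["pos"] - iv["end"])
            else:
                dist = 0
            if abs(dist) <= window_bp:
                hits.append(
                    {
                        "chrom": snp["chrom"],
                        "pos": int(snp["pos"]),
                        "name": iv["name"],
                        "distance": dist,
                    }
                )
    return pd.DataFrame(hits, columns=["chrom", "pos", "name", "distance"])
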
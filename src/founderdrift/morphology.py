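"""Morphometric trait tables: exclusions, standardized shifts, PCA, tests.

Trait tables are pandas DataFrames with columns
``individual, population, wing, tail, tarsus, bill_length, bill_depth,
bill_width, moulting, bill_damaged`` — six linear measurements in mm plus
two condition flags.  Measurement-condition exclusions (moulting voids wing
and tail, a damaged mandible voids bill length) are applied before any
statistics.

Divergence between populations is expressed on the natural-log scale in
standard-deviation units, which makes the shift estimate invariant to a
change of measurement units and feeds directly into the drift rate test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

TRAIT_COLUMNS = ("wing", "tail", "tarsus", "bill_length", "bill_depth", "bill_width")
FLAG_COLUMNS = ("moulting", "bill_damaged")

__all__ = [
    "TRAIT_COLUMNS",
    "ShiftEstimate",
    "read_trait_table",
    "apply_exclusions",
    "standardized_shift",
    "shift_table",
    "morph_pca",
    "rank_sum_test",
    "anova_oneway",
]


def read_trait_table(path: str | Path) -> pd.DataFrame:
    tt = pd.read_csv(path)
    missing = [c for c in ("individual", "population", *TRAIT_COLUMNS) if c not in tt]
    if missing:
        raise ValueError(f"trait table missing columns: {missing}")
    return tt


def apply_exclusions(tt: pd.DataFrame) -> pd.DataFrame:
    """Void measurements whose condition flags invalidate them.

    Moulting individuals lose wing and tail (feather wear/regrowth biases
    length); individuals with a damaged mandible lose bill length.  All
    other traits are untouched.  Returns a copy.
    """
    out = tt.copy()
    if "moulting" in out:
        flag = out["moulting"].fillna(0).astype(bool)
        out.loc[flag, ["wing", "tail"]] = np.nan
    if "bill_damaged" in out:
        flag = out["bill_damaged"].fillna(0).astype(bool)
        out.loc[flag, "bill_length"] = np.nan
    return out


@dataclass(frozen=True)
class ShiftEstimate:
    """Standardized log-scale shift of one trait between two populations.

    ``z`` is the absolute difference of log-scale population means;
    ``sign`` is +1 when the colonised mean exceeds the source mean.  Both the
    pooled SD and the colonised-population SD are carried because the rate
    test can standardize by either.
    """

    trait: str
    z: float
    sign: int
    sigma_pooled: float
    sigma_colonised: float
    n_source: int
    n_colonised: int

    def z_over_sigma(self, sigma: str = "colonised") -> float:
        sd = self.sigma_colonised if sigma == "colonised" else self.sigma_pooled
        return self.z / sd


def standardized_shift(
    source: np.ndarray,
    colonised: np.ndarray,
    trait: str = "",
    pre_logged: bool = False,
) -> ShiftEstimate:
    """Natural-log shift between populations in SD units.

    Requires >= 2 non-missing positive values per population.  Pooled SD is
    sqrt(((n1-1)s1^2 + (n2-1)s2^2) / (n1+n2-2)).
    """
    a = np.asarray(source, dtype=float)
    b = np.asarray(colonised, dtype=float)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if a.size < 2 or b.size < 2:
        raise ValueError(f"need >= 2 values per population for {trait or 'trait'}")
    if not pre_logged:
        if np.any(a <= 0) or np.any(b <= 0):
            raise ValueError("measurements must be positive for log transform")
        a, b = np.log(a), np.log(b)
    s1, s2 = a.std(ddof=1), b.std(ddof=1)
    if s1 == 0.0 or s2 == 0.0:
        raise ValueError("zero variance in a population")
    diff = b.mean() - a.mean()
    pooled = math.sqrt(
        ((a.size - 1) * s1**2 + (b.size - 1) * s2**2) / (a.size + b.size - 2)
    )
    return ShiftEstimate(
        trait=trait,
        z=abs(diff),
        sign=1 if diff >= 0 else -1,
        sigma_pooled=pooled,
        sigma_colonised=float(s2),
        n_source=int(a.size),
        n_colonised=int(b.size),
    )


def shift_table(
    tt: pd.DataFrame, source_pop: str, colonised_pop: str
) -> list[ShiftEstimate]:
    """Per-trait standardized shifts after exclusions; traits with
    insufficient data are skipped."""
    tt = apply_exclusions(tt)
    shifts = []
    for trait in TRAIT_COLUMNS:
        a = tt.loc[tt["population"] == source_pop, trait].to_numpy(float)
        b = tt.loc[tt["population"] == colonised_pop, trait].to_numpy(float)
        try:
            shifts.append(standardized_shift(a, b, trait=trait))
        except ValueError:
            continue
    return shifts


def morph_pca(tt: pd.DataFrame, traits: tuple[str, ...] = TRAIT_COLUMNS):
    """PCA on centered natural-log traits, complete rows only.

    Returns (scores DataFrame indexed like the retained rows, loadings,
    variance fractions, size_axis flag).  The size_axis flag is True when all
    first-component loadings share a sign — the classic single "body size"
    factor.
    """
    tt = apply_exclusions(tt)
    x = tt.loc[:, list(traits)].to_numpy(float)
    complete = ~np.isnan(x).any(axis=1)
    if complete.sum() < 2:
        raise ValueError("fewer than 2 complete rows after exclusions")
    logx = np.log(x[complete])
    centered = logx - logx.mean(axis=0)
    u, s, vh = np.linalg.svd(centered, full_matrices=False)
    var_frac = s**2 / np.sum(s**2)
    loadings = vh.T
    sign = np.sign(loadings[np.argmax(np.abs(loadings), axis=0), np.arange(s.size)])
    sign[sign == 0] = 1.0
    scores = pd.DataFrame(
        (u * s) * sign,
        index=tt.index[complete],
        columns=[f"PC{i + 1}" for i in range(s.size)],
    )
    size_axis = bool(np.all(loadings[:, 0] * sign[0] > 0))
    return scores, loadings * sign, var_frac, size_axis


def rank_sum_test(a, b) -> tuple[float, float]:
    """Wilcoxon rank-sum (Mann-Whitney) test with midrank ties.

    Exact p by enumeration for small tie-free samples (n_a + n_b <= 12),
    normal approximation with continuity correction otherwise.  Returns
    (W, two-sided p) with W the Mann-Whitney statistic of the first sample,
    matching R's ``wilcox.test``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (a.size + b.size <= 12 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def anova_oneway(groups) -> tuple[float, float]:
    """One-way ANOVA F test across >= 2 groups of >= 2 values each."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 values each")
    if all(np.ptp(g) == 0 for g in groups):
        raise ValueError("zero within-group variance overall")
    res = stats.f_oneway(*groups)
    return float(res.statistic), float(res.pvalue)
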
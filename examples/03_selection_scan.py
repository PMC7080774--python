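"""PC-based selection scan with planted sweeps and gene annotation.

Plants 20 directional sweeps (s = 0.5 toward the minor allele) in a
founder simulation, scans all 5,000 SNPs with the Mahalanobis outlier
statistic (K = 2, MinMAF = 0.1, FDR q = 0.01), and annotates outliers
against a small interval set within a 10 kb window.
"""

import numpy as np
import pandas as pd

from founderdrift import (
    NeTrajectory,
    candidate_proximity,
    planted_sweep_dataset,
    scan,
)

traj = NeTrajectory(np.concatenate([np.full(10, 50.0), np.full(22, 1e4)]))
vt, causal = planted_sweep_dataset(traj, n_loci=5000, n_causal=20, s=0.5, seed=11)

out = scan(vt)
flagged = np.flatnonzero(out["outlier"].to_numpy())
hits = set(flagged) & set(causal.tolist())
print(f"genomic inflation factor lambda = {out.attrs['lambda']:.3f}")
print(f"flagged {flagged.size} outliers at q <= 0.01; "
      f"{len(hits)}/20 planted sweeps recovered "
      f"({100 * len(hits) / 20:.0f}% power)")

# annotate the strongest outlier against toy gene intervals
genes = pd.DataFrame(
    {
        "chrom": ["1", "1"],
        "start": [out.loc[flagged[0], "pos"] - 3000] * 2,
        "end": [out.loc[flagged[0], "pos"] - 2000,
                out.loc[flagged[0], "pos"] + 500],
        "name": ["geneA", "geneB"],
    }
)
prox = candidate_proximity(out, genes, window_bp=10_000)
print("\nannotation hits (distance 0 = SNP inside the interval):")
print(prox.head(10).to_string(index=False))
print("\nmissed sweeps are typically loci whose favoured allele swept the")
print("pooled minor-allele frequency below the scan's MinMAF filter.")
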
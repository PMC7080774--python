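import numpy as np
import pytest

from founderdrift import SimConfig, VariantTable, simulate_dataset


def make_table(genotypes, pos=None, chrom=None, ref=None, alt=None, **kw):
    """Build a VariantTable from a plain (sites x individuals) list/array."""
    g = np.asarray(genotypes, dtype=np.int8)
    n_sites, n_ind = g.shape
    return VariantTable(
        chrom=np.asarray(chrom if chrom is not None else ["1"] * n_sites, dtype=object),
        pos=np.asarray(
            pos if pos is not None else (np.arange(n_sites) + 1) * 100, dtype=np.int64
        ),
        ref=np.asarray(ref if ref is not None else ["A"] * n_sites, dtype=object),
        alt=np.asarray(alt if alt is not None else ["T"] * n_sites, dtype=object),
        genotypes=g,
        samples=tuple(f"I{i}" for i in range(n_ind)),
        **kw,
    )


@pytest.fixture(scope="session")
def small_sim():
    """A 300-locus founder dataset with 5% missingness, shared across tests."""
    return simulate_dataset(SimConfig(n_loci=300, seed=42, missing_rate=0.05))


@pytest.fixture(scope="session")
def fixture_dir(small_sim, tmp_path_factory):
    from founderdrift import write_fixture

    out = tmp_path_factory.mktemp("fixture")
    return write_fixture(small_sim, out)
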
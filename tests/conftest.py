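import numpy as np
import pytest

from gmcqtl import core_io, simulate
from gmcqtl.core_io import GenotypeMatrix, Snp


def make_genotypes(dosage, chrom="1", start=1000, step=1000,
                   subset=None, prefix="A"):
    """GenotypeMatrix from a raw dosage array with evenly spaced SNPs."""
    dosage = np.asarray(dosage, dtype=np.int8)
    n, m = dosage.shape
    snps = [Snp(chrom, start + j * step, "A", "G", f"s{j}") for j in range(m)]
    ids = [f"{prefix}{i:03d}" for i in range(n)]
    sub = subset if subset is not None else ["X"] * n
    return GenotypeMatrix(ids, list(sub), snps, dosage)


@pytest.fixture(scope="session")
def structured_panel():
    """A null two-subset panel with population structure, reused widely."""
    cfg = simulate.null_config(n_X=120, n_G=120, n_chrom=4,
                               snps_per_chrom=500, fst=0.15, seed=11)
    return simulate.simulate_panel(cfg)


@pytest.fixture(scope="session")
def published_table():
    return core_io.load_published_qtl_table()
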
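import numpy as np
import pandas as pd
import pytest

from rohkit.genotype_io import GenotypeMatrix, MarkerMap


def make_map(n_snps, spacing_bp=100_000, chrom="1", start_bp=None,
             prefix="snp"):
    """Evenly spaced single-chromosome marker map."""
    start = start_bp if start_bp is not None else spacing_bp
    pos = start + spacing_bp * np.arange(n_snps)
    return MarkerMap(pd.DataFrame({
        "snp_id": [f"{prefix}{chrom}_{i}" for i in range(n_snps)],
        "chrom": chrom,
        "cm": pos / 1e6,
        "pos_bp": pos,
    }))


def make_genotypes(rows, samples=None):
    rows = np.asarray(rows, dtype=np.int8)
    if rows.ndim == 1:
        rows = rows[None, :]
    if samples is None:
        samples = [f"S{i:03d}" for i in range(rows.shape[0])]
    return GenotypeMatrix(list(samples), rows)


@pytest.fixture
def single_chrom_map():
    return make_map(60, spacing_bp=100_000)
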
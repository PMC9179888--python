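import numpy as np
import pandas as pd
import pytest

from selsig.io import MISSING, GenotypePanel


def random_panel(rng: np.random.Generator, n_samples=8, n_snps=40, n_chrom=2,
                 missing_rate=0.05, population="pop") -> GenotypePanel:
    """Random panel with sorted markers, random alleles and missingness."""
    chrom = np.sort(rng.integers(1, n_chrom + 1, n_snps))
    pos = np.zeros(n_snps, dtype=int)
    for c in np.unique(chrom):
        sel = chrom == c
        pos[sel] = np.sort(rng.choice(np.arange(1, 10_000_000, 100),
                                      sel.sum(), replace=False))
    pairs = [("A", "C"), ("A", "G"), ("C", "T"), ("G", "T")]
    a1a2 = [pairs[k] for k in rng.integers(0, len(pairs), n_snps)]
    markers = pd.DataFrame({
        "snp_id": [f"rs{k}" for k in range(n_snps)],
        "chrom": chrom, "pos_bp": pos,
        "a1": [p[0] for p in a1a2], "a2": [p[1] for p in a1a2]})
    dosage = rng.integers(0, 3, (n_samples, n_snps)).astype(np.int8)
    dosage[rng.random(dosage.shape) < missing_rate] = MISSING
    samples = pd.DataFrame({
        "sample_id": [f"ind{i}" for i in range(n_samples)],
        "sex": rng.integers(1, 3, n_samples),
        "population": population})
    return GenotypePanel(markers=markers, samples=samples, dosage=dosage)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
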
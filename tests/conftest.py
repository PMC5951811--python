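import numpy as np
import pandas as pd
import pytest

from polydiff.genotype_io import PopulationPanel


def build_panel(genotypes, pops, chrom=None, pos=None, ref="A", alt="G",
                snp_ids=None):
    """Hand-build a small panel from a dosage matrix and population labels."""
    genotypes = np.asarray(genotypes, dtype=np.int8)
    n, m = genotypes.shape
    snps = pd.DataFrame({
        "snp": snp_ids or [f"s{j}" for j in range(m)],
        "chrom": chrom if chrom is not None else ["1"] * m,
        "pos": pos if pos is not None else [(j + 1) * 1000 for j in range(m)],
        "ref": ref, "alt": alt,
    })
    samples = [f"i{k}" for k in range(n)]
    panel = PopulationPanel(genotypes, samples, np.asarray(pops, dtype=object),
                            snps)
    panel.validate()
    return panel


def random_panel(rng, n_per_pop=30, n_snps=50, pops=("P1", "P2"),
                 n_chrom=2, spacing=2000, missing_rate=0.0):
    """Random polymorphic panel for oracle comparisons."""
    per_chrom = int(np.ceil(n_snps / n_chrom))
    chrom = [str(j // per_chrom + 1) for j in range(n_snps)]
    pos = [(j % per_chrom + 1) * spacing for j in range(n_snps)]
    freqs = rng.uniform(0.1, 0.9, size=(len(pops), n_snps))
    blocks = []
    labels = []
    for i, p in enumerate(pops):
        blocks.append(rng.binomial(2, freqs[i], size=(n_per_pop, n_snps)))
        labels += [p] * n_per_pop
    g = np.vstack(blocks).astype(np.int8)
    if missing_rate:
        mask = rng.random(g.shape) < missing_rate
        g[mask] = -1
    return build_panel(g, labels, chrom=chrom, pos=pos)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def drift_panel():
    """Shared mid-size drift panel (2 pops) for statistics tests."""
    from polydiff.synthetic_data import DriftPanelSpec, make_drift_panel
    spec = DriftPanelSpec(n_pops=2, pop_labels=("EUR", "AFR"), n_per_pop=200,
                          n_snps=3000, n_chrom=5, seed=99)
    return make_drift_panel(spec)
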
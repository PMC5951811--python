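"""Synthetic multi-population genotype panels and GWAS-summary fixtures.

Drift panels follow the Balding-Nichols model: each SNP has an ancestral
frequency p drawn from a spectrum (uniform on [0.01, 0.5] by default), and
each population's frequency is Beta(p(1-F)/F, (1-p)(1-F)/F), so F directly
parameterizes the expected differentiation the enrichment test must not
confound.  Local LD is produced by a block latent-haplotype model: within a
block of B consecutive SNPs, each haplotype's alleles share a latent
Gaussian factor with loading sqrt(rho) (a Gaussian copula), giving
analytically controllable within-block correlation at O(n*m) cost.

Defaults mirror the harmonized real-data design this package emulates:
three populations (EUR/AFR/EAS-like) of 1,099 diploids each.

Selection alternatives are injected by shifting targeted SNPs' population
frequencies on the logit scale and redrawing those genotypes; a GWAS cohort
can be drawn from any population's frequencies so that cohort and panel
share SNP identifiers, as a real GWAS shares its SNP panel with the
reference populations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .genotype_io import PopulationPanel

logger = logging.getLogger(__name__)


@dataclass
class DriftPanelSpec:
    """Balding-Nichols drift panel configuration."""

    n_pops: int = 3
    pop_labels: tuple[str, ...] = ("EUR", "AFR", "EAS")
    n_per_pop: int = 1099
    n_snps: int = 20_000
    fst: float = 0.15                      # Balding-Nichols concentration F
    ancestral_law: str = "uniform"         # uniform | beta
    ancestral_low: float = 0.01
    ancestral_high: float = 0.5
    ancestral_beta: tuple[float, float] = (0.5, 0.5)
    n_chrom: int = 20
    snp_spacing_bp: int = 5_000
    block_size: int = 10                   # SNPs per LD block
    block_rho: float = 0.7                 # latent haplotype correlation
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.fst < 1):
            raise ValueError("F must be in (0, 1)")
        if not (0 <= self.block_rho < 1):
            raise ValueError("rho must be in [0, 1)")
        if len(self.pop_labels) < self.n_pops:
            self.pop_labels = tuple(
                f"POP{i}" for i in range(self.n_pops))
        else:
            self.pop_labels = tuple(self.pop_labels[: self.n_pops])


def _snp_table(spec: DriftPanelSpec) -> pd.DataFrame:
    per_chrom = int(np.ceil(spec.n_snps / spec.n_chrom))
    chroms, positions = [], []
    for j in range(spec.n_snps):
        c, k = divmod(j, per_chrom)
        chroms.append(str(c + 1))
        positions.append((k + 1) * spec.snp_spacing_bp)
    return pd.DataFrame({
        "snp": [f"rs{j + 1}" for j in range(spec.n_snps)],
        "chrom": chroms, "pos": positions, "ref": "A", "alt": "G"})


def drift_frequencies(spec: DriftPanelSpec,
                      rng: np.random.Generator | None = None):
    """Draw the SNP table, ancestral frequencies and per-population
    Balding-Nichols frequencies; returns (snps, ancestral, freqs[pop, snp])."""
    rng = rng or np.random.default_rng(spec.seed)
    snps = _snp_table(spec)
    if spec.ancestral_law == "uniform":
        anc = rng.uniform(spec.ancestral_low, spec.ancestral_high, spec.n_snps)
    elif spec.ancestral_law == "beta":
        a, b = spec.ancestral_beta
        anc = rng.beta(a, b, spec.n_snps)
        anc = np.clip(anc, spec.ancestral_low, 1 - spec.ancestral_low)
    else:
        raise ValueError(f"unknown ancestral law {spec.ancestral_law!r}")
    conc = (1.0 - spec.fst) / spec.fst
    freqs = rng.beta(anc * conc, (1.0 - anc) * conc,
                     size=(spec.n_pops, spec.n_snps))
    freqs = np.clip(freqs, 1e-4, 1 - 1e-4)
    return snps, anc, freqs


def _block_ids(n_snps: int, chroms: np.ndarray, block_size: int) -> np.ndarray:
    """Consecutive-SNP block labels that never span a chromosome break."""
    ids = np.zeros(n_snps, dtype=np.int64)
    bid, k, prev = 0, 0, None
    for j in range(n_snps):
        if chroms[j] != prev or k >= block_size:
            if prev is not None:
                bid += 1
            k, prev = 0, chroms[j]
        ids[j] = bid
        k += 1
    return ids


def genotypes_from_freqs(freqs: np.ndarray, n_ind: int, snps: pd.DataFrame,
                         block_size: int, block_rho: float,
                         rng: np.random.Generator) -> np.ndarray:
    """Diploid dosages for one population via the Gaussian-copula block
    model: haplotype allele = 1 when a correlated latent normal falls below
    the frequency quantile."""
    m = len(freqs)
    thresh = sps.norm.ppf(freqs).astype(np.float32)
    blocks = _block_ids(m, snps["chrom"].to_numpy(), block_size)
    n_blocks = blocks[-1] + 1
    geno = np.zeros((n_ind, m), dtype=np.int8)
    sr = np.float32(np.sqrt(block_rho))
    se = np.float32(np.sqrt(1.0 - block_rho))
    chunk = max(1, min(n_ind, int(250e6 // max(m, 1))))  # cap float32 temps
    for _ in range(2):  # two haplotypes per individual
        for lo in range(0, n_ind, chunk):
            hi = min(lo + chunk, n_ind)
            z_block = rng.standard_normal((hi - lo, n_blocks)).astype(np.float32)
            eps = rng.standard_normal((hi - lo, m)).astype(np.float32)
            latent = sr * z_block[:, blocks] + se * eps
            geno[lo:hi] += (latent < thresh[None, :]).astype(np.int8)
    return geno


def make_drift_panel(spec: DriftPanelSpec, return_freqs: bool = False):
    """Generate a multi-population drift panel (seeded, reproducible).

    With ``return_freqs=True`` also returns the latent population
    frequencies (pop x snp) so a GWAS cohort can be drawn from the same
    generative frequencies (see :func:`make_cohort`).
    """
    rng = np.random.default_rng(spec.seed)
    snps, _, freqs = drift_frequencies(spec, rng)
    blocks_geno, samples, pops = [], [], []
    for i, pop in enumerate(spec.pop_labels):
        g = genotypes_from_freqs(freqs[i], spec.n_per_pop, snps,
                                 spec.block_size, spec.block_rho, rng)
        blocks_geno.append(g)
        samples.extend(f"{pop}_{k}" for k in range(spec.n_per_pop))
        pops.extend([pop] * spec.n_per_pop)
    panel = PopulationPanel(np.vstack(blocks_geno), samples,
                            np.array(pops, dtype=object), snps)
    panel.validate()
    if return_freqs:
        return panel, freqs
    return panel


def make_cohort(spec: DriftPanelSpec, freqs_row: np.ndarray, n_ind: int,
                seed: int, pop_label: str = "COHORT") -> PopulationPanel:
    """Draw a GWAS cohort from one population's latent frequencies, sharing
    the panel's SNP table (ids, positions, alleles and LD block layout)."""
    rng = np.random.default_rng(seed)
    snps = _snp_table(spec)
    g = genotypes_from_freqs(freqs_row, n_ind, snps, spec.block_size,
                             spec.block_rho, rng)
    samples = [f"{pop_label}_{k}" for k in range(n_ind)]
    return PopulationPanel(g, samples,
                           np.array([pop_label] * n_ind, dtype=object), snps)


# ---------------------------------------------------------------------------
# Selection injection
# ---------------------------------------------------------------------------


@dataclass
class SelectionInjection:
    """Logit-scale frequency shifts at target SNPs.

    ``shifts`` maps population label -> shift added to the logit of the
    shifted allele's frequency.  By default the alternate allele is shifted;
    ``trait_increasing`` (snp -> +1/-1, the sign of the SNP's trait effect)
    couples the shift direction to a trait so the trait-increasing allele is
    the favored one.
    """

    targets: np.ndarray
    shifts: dict[str, float]
    trait_increasing: dict[str, int] | None = None


def inject_selection(panel: PopulationPanel, injection: SelectionInjection,
                     seed: int) -> PopulationPanel:
    """Return a panel with targeted SNPs' frequencies shifted on the logit
    scale and their genotypes redrawn (binomially) in the shifted
    populations; all other SNPs untouched."""
    targets = np.asarray(injection.targets)
    indexer = panel.snp_indexer()
    missing = [t for t in targets if t not in indexer.index]
    if missing:
        raise KeyError(f"unknown target SNPs, e.g. {missing[:3]}")
    cols = indexer.loc[targets].to_numpy()
    rng = np.random.default_rng(seed)
    geno = panel.genotypes.copy()
    sign = np.ones(len(targets))
    if injection.trait_increasing is not None:
        sign = np.array([injection.trait_increasing.get(t, 1)
                         for t in targets], dtype=float)
    for pop, delta in injection.shifts.items():
        rows = np.flatnonzero(panel.pop_mask(pop))
        f = np.clip(panel.freqs(pop)[cols], 0.001, 0.999)
        logit = np.log(f / (1 - f)) + delta * sign
        f_new = np.clip(1.0 / (1.0 + np.exp(-logit)), 0.001, 0.999)
        draws = rng.binomial(2, f_new, size=(len(rows), len(cols)))
        geno[np.ix_(rows, cols)] = draws.astype(np.int8)
    return PopulationPanel(geno, list(panel.samples), panel.populations.copy(),
                           panel.snps.copy())


# ---------------------------------------------------------------------------
# Summary fixtures
# ---------------------------------------------------------------------------


def make_summary_fixture(panel: PopulationPanel, effects: pd.Series,
                         mode: str = "analytic", n: int = 10_000,
                         se: float = 0.01,
                         cohort: PopulationPanel | None = None,
                         phenotype: np.ndarray | None = None,
                         n_pcs: int = 0) -> pd.DataFrame:
    """Build a GWAS summary frame aligned to the panel's alleles.

    ``analytic`` mode writes the given effects verbatim with the stated
    standard error; ``scan`` mode runs a PC-adjusted regression of the given
    phenotype on the cohort and reports the estimated effects.  The result
    round-trips through :func:`polydiff.genotype_io.write_gwas_summary`.
    """
    if mode == "analytic":
        idx = panel.snp_indexer().loc[effects.index].to_numpy()
        b = effects.to_numpy(dtype=float)
        z = b / se
        p = np.clip(2 * sps.norm.sf(np.abs(z)), np.finfo(float).tiny, 1.0)
        return pd.DataFrame({
            "snp": effects.index.to_numpy(),
            "a1": panel.snps["alt"].to_numpy()[idx],
            "a2": panel.snps["ref"].to_numpy()[idx],
            "freq": panel.freqs()[idx],
            "b": b, "se": se, "p": p, "n": n})
    if mode == "scan":
        if cohort is None or phenotype is None:
            raise ValueError("scan mode needs a cohort and a phenotype")
        from .gwas_sim import gwas_scan
        tbl = gwas_scan(cohort, phenotype, n_pcs=n_pcs).summary()
        return tbl[tbl["snp"].isin(effects.index)].reset_index(drop=True)
    raise ValueError(f"unknown mode {mode!r}")
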
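"""Genotype panels, GWAS summary statistics, and quality control.

The central container is :class:`PopulationPanel`: a diploid dosage matrix
(individuals x SNPs, 0/1/2 counts of the alternate allele, -1 for missing)
with population labels and positionally aligned SNP metadata.  Panels are
read from VCF (via cyvcf2) or PLINK-1 bed/bim/fam triplets, and GWAS summary
statistics from whitespace-delimited ".ma" files (``SNP A1 A2 freq b se p N``,
``freq`` optional).

QC follows the common human-genetics recipe: per-population MAF and
Hardy-Weinberg filters, an overall SNP call-rate filter, GRM-based
relatedness pruning, and PCA outlier removal of target samples against a
reference population.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = -1

#: strand-ambiguous allele pairs dropped during harmonization
_AMBIGUOUS = {frozenset(("A", "T")), frozenset(("C", "G"))}


def chrom_rank(chroms) -> np.ndarray:
    """Natural chromosome ordering: numeric labels first in numeric order,
    then the rest lexicographically ("2" before "10" before "X")."""
    def key(c: str):
        return (0, int(c), "") if c.isdigit() else (1, 0, c)

    uniq = sorted({str(c) for c in chroms}, key=key)
    rank = {c: i for i, c in enumerate(uniq)}
    return np.array([rank[str(c)] for c in chroms], dtype=np.int64)


@dataclass
class QCThresholds:
    """Filter thresholds applied by :func:`qc_filter`."""

    maf_min: float = 0.01
    hwe_p_min: float = 1e-6
    call_rate_min: float = 0.98
    relatedness_max: float = 0.05
    pca_sd: float = 3.0

    def __post_init__(self) -> None:
        if not (0 <= self.maf_min < 0.5):
            raise ValueError("maf_min must be in [0, 0.5)")
        if not (0 < self.hwe_p_min <= 1):
            raise ValueError("hwe_p_min must be in (0, 1]")
        if not (0 < self.call_rate_min <= 1):
            raise ValueError("call_rate_min must be in (0, 1]")


@dataclass
class PopulationPanel:
    """Diploid genotype panel with population labels.

    Parameters
    ----------
    genotypes
        int8 array of shape (n_individuals, n_snps); entries in {0, 1, 2}
        count the alternate allele, -1 marks a missing call.
    samples
        Sample identifiers, one per row.
    populations
        Population label per sample (same length as ``samples``).
    snps
        DataFrame with columns ``snp, chrom, pos, ref, alt`` aligned to the
        genotype columns; sorted by (chrom, pos) with unique SNP ids.
    """

    genotypes: np.ndarray
    samples: list[str]
    populations: np.ndarray
    snps: pd.DataFrame

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.populations = np.asarray(self.populations, dtype=object)
        self.snps = self.snps.reset_index(drop=True)
        # panels are treated as immutable once built; derived quantities
        # (frequencies, the id->column indexer) are cached lazily
        self._freq_cache: dict = {}
        self._indexer = None

    # -- basic structure ---------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    @property
    def pop_labels(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.populations:
            seen.setdefault(p, None)
        return list(seen)

    def pop_mask(self, pop: str) -> np.ndarray:
        mask = self.populations == pop
        if not mask.any():
            raise KeyError(f"unknown population {pop!r}")
        return mask

    def validate(self) -> None:
        g = self.genotypes
        if g.ndim != 2:
            raise ValueError("genotypes must be 2-D")
        bad = ~np.isin(g, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("dosages must be in {0, 1, 2, missing}")
        if len(self.samples) != g.shape[0] or len(self.populations) != g.shape[0]:
            raise ValueError("sample/population length mismatch")
        if len(self.snps) != g.shape[1]:
            raise ValueError("snp table length mismatch")
        if self.snps["snp"].duplicated().any():
            raise ValueError("duplicate SNP ids")
        order = np.lexsort((self.snps["pos"].to_numpy(),
                            chrom_rank(self.snps["chrom"])))
        if not (order == np.arange(len(order))).all():
            raise ValueError("SNPs must be sorted by (chrom, pos)")
        if (self.snps["ref"] == self.snps["alt"]).any():
            raise ValueError("ref and alt alleles must differ")

    # -- frequencies -------------------------------------------------------
    def freqs(self, pop: str | None = None) -> np.ndarray:
        """Alternate-allele frequency over non-missing genotypes (cached)."""
        if pop in self._freq_cache:
            return self._freq_cache[pop]
        g = self.genotypes if pop is None else self.genotypes[self.pop_mask(pop)]
        if not (g == MISSING).any():
            out = g.sum(axis=0, dtype=np.int64) / (2.0 * g.shape[0])
        else:
            obs = g != MISSING
            n = obs.sum(axis=0)
            tot = np.where(obs, g, 0).sum(axis=0)
            with np.errstate(invalid="ignore"):
                out = np.where(n > 0, tot / (2.0 * n), np.nan)
        self._freq_cache[pop] = out
        return out

    def maf(self, pop: str | None = None) -> np.ndarray:
        f = self.freqs(pop)
        return np.minimum(f, 1.0 - f)

    def per_pop_freq(self) -> pd.DataFrame:
        """Per-population alternate-allele frequencies, SNPs as rows."""
        return pd.DataFrame(
            {pop: self.freqs(pop) for pop in self.pop_labels},
            index=self.snps["snp"],
        )

    def call_rate(self) -> np.ndarray:
        return (self.genotypes != MISSING).mean(axis=0)

    # -- subsetting --------------------------------------------------------
    def subset_snps(self, index: np.ndarray) -> "PopulationPanel":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return PopulationPanel(
            self.genotypes[:, index],
            list(self.samples),
            self.populations.copy(),
            self.snps.iloc[index].reset_index(drop=True),
        )

    def subset_individuals(self, index: np.ndarray) -> "PopulationPanel":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return PopulationPanel(
            self.genotypes[index],
            [self.samples[i] for i in index],
            self.populations[index],
            self.snps.copy(),
        )

    def snp_indexer(self) -> pd.Series:
        """Map SNP id -> column index (cached)."""
        if self._indexer is None:
            self._indexer = pd.Series(np.arange(self.n_snps),
                                      index=self.snps["snp"])
        return self._indexer

    def dosages(self, snp_ids) -> np.ndarray:
        """Dosage sub-matrix (individuals x requested SNPs)."""
        idx = self.snp_indexer().loc[list(snp_ids)].to_numpy()
        return self.genotypes[:, idx]


# ---------------------------------------------------------------------------
# Reading / writing panels
# ---------------------------------------------------------------------------


def read_pop_map(path) -> pd.Series:
    """Two-column TSV (sample, population) -> Series sample -> population."""
    df = pd.read_csv(path, sep=r"\s+", header=None, names=["sample", "population"],
                     dtype=str, comment="#")
    return df.set_index("sample")["population"]


def _finish_panel(genotypes, samples, pop_map, snp_rows) -> PopulationPanel:
    pops = []
    for s in samples:
        if s not in pop_map.index:
            raise ValueError(f"sample {s!r} missing from population map")
        pops.append(pop_map.loc[s])
    snps = pd.DataFrame(snp_rows, columns=["snp", "chrom", "pos", "ref", "alt"])
    snps["pos"] = snps["pos"].astype(np.int64)
    order = np.lexsort((snps["pos"].to_numpy(), chrom_rank(snps["chrom"])))
    panel = PopulationPanel(
        np.asarray(genotypes, dtype=np.int8)[:, order],
        list(samples),
        np.asarray(pops, dtype=object),
        snps.iloc[order].reset_index(drop=True),
    )
    panel.validate()
    return panel


def read_vcf(path, pop_map: pd.Series) -> PopulationPanel:
    """Read a (possibly gzipped) VCF 4.x into a panel.

    Multi-allelic sites and indels are dropped with a logged count; hard
    genotype calls only.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    rows, cols, n_dropped = [], [], 0
    for var in vcf:
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            n_dropped += 1
            continue
        g = np.asarray(var.gt_types, dtype=np.int8)
        g[g == 3] = MISSING
        cols.append(g)
        rows.append((var.ID or f"{var.CHROM}:{var.POS}", str(var.CHROM),
                     int(var.POS), var.REF, var.ALT[0]))
    if n_dropped:
        logger.info("read_vcf: dropped %d non-biallelic-SNP records", n_dropped)
    if not rows:
        raise ValueError(f"no biallelic SNPs found in {path}")
    return _finish_panel(np.column_stack(cols), samples, pop_map, rows)


def write_vcf(panel: PopulationPanel, path) -> None:
    """Write the panel as an uncompressed VCF 4.2 with hard GT calls."""
    gt_strings = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=polydiff\n")
        for chrom in dict.fromkeys(panel.snps["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(panel.samples) + "\n")
        g = panel.genotypes
        for j, rec in panel.snps.iterrows():
            calls = "\t".join(gt_strings[int(x)] for x in g[:, j])
            fh.write(f"{rec.chrom}\t{rec.pos}\t{rec.snp}\t{rec.ref}\t{rec.alt}"
                     f"\t.\t.\t.\tGT\t{calls}\n")


def write_pop_map(panel: PopulationPanel, path) -> None:
    with open(path, "w") as fh:
        for s, p in zip(panel.samples, panel.populations):
            fh.write(f"{s}\t{p}\n")


# PLINK-1 .bed stores genotypes SNP-major, 2 bits per sample:
# 00 = hom A1, 10 = het, 11 = hom A2, 01 = missing.  A1 is treated as the
# alternate allele, so the dosage counts copies of A1.
_BED_CODE_TO_DOSAGE = np.array([2, MISSING, 1, 0], dtype=np.int8)


def read_plink(prefix, pop_map: pd.Series) -> PopulationPanel:
    """Read a PLINK-1 bed/bim/fam triplet (no external reader required)."""
    fam = pd.read_csv(f"{prefix}.fam", sep=r"\s+", header=None,
                      usecols=[1], names=["iid"], dtype=str)
    bim = pd.read_csv(f"{prefix}.bim", sep=r"\s+", header=None,
                      names=["chrom", "snp", "cm", "pos", "a1", "a2"],
                      dtype={"chrom": str, "snp": str, "a1": str, "a2": str})
    n, m = len(fam), len(bim)
    raw = np.fromfile(f"{prefix}.bed", dtype=np.uint8)
    if raw[:3].tolist() != [0x6C, 0x1B, 0x01]:
        raise ValueError(f"{prefix}.bed is not a SNP-major PLINK-1 file")
    bytes_per_snp = (n + 3) // 4
    body = raw[3:].reshape(m, bytes_per_snp)
    codes = np.stack([(body >> shift) & 0b11 for shift in (0, 2, 4, 6)], axis=2)
    codes = codes.reshape(m, -1)[:, :n]  # SNP-major -> (m, n)
    geno = _BED_CODE_TO_DOSAGE[codes].T
    keep = (bim.a1.str.len() == 1) & (bim.a2.str.len() == 1) & (bim.a1 != bim.a2)
    if (~keep).any():
        logger.info("read_plink: dropped %d non-SNP records", int((~keep).sum()))
    rows = [(r.snp, r.chrom, int(r.pos), r.a2, r.a1)
            for r in bim[keep.to_numpy()].itertuples()]
    return _finish_panel(geno[:, keep.to_numpy()], fam["iid"].tolist(), pop_map, rows)


def read_panel(path, format: str = "vcf", pop_map=None) -> PopulationPanel:
    """Read a genotype panel; ``format`` is ``"vcf"`` or ``"plink-bed"``."""
    if pop_map is None:
        raise ValueError("a sample -> population map is required")
    if not isinstance(pop_map, pd.Series):
        pop_map = read_pop_map(pop_map)
    if format == "vcf":
        return read_vcf(path, pop_map)
    if format == "plink-bed":
        return read_plink(path, pop_map)
    raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# GWAS summary statistics (".ma" dialect)
# ---------------------------------------------------------------------------

#: canonical column order of a GWAS summary frame
SUMMARY_COLUMNS = ["snp", "a1", "a2", "freq", "b", "se", "p", "n"]


def read_gwas_summary(path) -> pd.DataFrame:
    """Read whitespace-delimited summary statistics with header
    ``SNP A1 A2 [freq] b se p N`` into a normalized frame."""
    df = pd.read_csv(path, sep=r"\s+")
    df.columns = [c.lower() for c in df.columns]
    if "freq" not in df.columns:
        df["freq"] = np.nan
    missing = [c for c in SUMMARY_COLUMNS if c != "freq" and c not in df.columns]
    if missing:
        raise ValueError(f"summary file missing columns {missing}")
    df = df[SUMMARY_COLUMNS].copy()
    df["snp"] = df["snp"].astype(str)
    for c in ("a1", "a2"):
        df[c] = df[c].astype(str).str.upper()
    if ((df["p"] <= 0) | (df["p"] > 1)).any():
        raise ValueError("P-values must be in (0, 1]")
    return df


def write_gwas_summary(summary: pd.DataFrame, path) -> None:
    out = summary.copy()
    out.columns = ["SNP", "A1", "A2", "freq", "b", "se", "p", "N"]
    if out["freq"].isna().all():
        out = out.drop(columns="freq")
    out.to_csv(path, sep="\t", index=False, na_rep="NA")


def harmonize(summary: pd.DataFrame, panel: PopulationPanel) -> pd.DataFrame:
    """Align summary effect alleles to the panel's alternate alleles.

    Betas (and freq, if present) are flipped where the effect allele matches
    the panel ref allele; SNPs absent from the panel, with mismatched allele
    sets, or strand-ambiguous (A/T, C/G) are dropped with logged counts.
    Idempotent: re-running on its output changes nothing.
    """
    snps = panel.snps.set_index("snp")
    df = summary[summary["snp"].isin(snps.index)].copy()
    n_absent = len(summary) - len(df)
    ref = snps.loc[df["snp"], "ref"].to_numpy()
    alt = snps.loc[df["snp"], "alt"].to_numpy()
    ambiguous = np.array(
        [frozenset((x, y)) in _AMBIGUOUS for x, y in zip(df["a1"], df["a2"])],
        dtype=bool)
    match_fwd = (df["a1"].to_numpy() == alt) & (df["a2"].to_numpy() == ref)
    match_rev = (df["a1"].to_numpy() == ref) & (df["a2"].to_numpy() == alt)
    keep = (match_fwd | match_rev) & ~ambiguous
    n_mismatch = int((~(match_fwd | match_rev)).sum())
    n_ambiguous = int((ambiguous & (match_fwd | match_rev)).sum())
    if n_absent or n_mismatch or n_ambiguous:
        logger.info("harmonize: dropped %d absent, %d allele-mismatched, "
                    "%d strand-ambiguous SNPs", n_absent, n_mismatch, n_ambiguous)
    df = df[keep].copy()
    if df.empty:
        raise ValueError("no SNPs overlap between summary and panel")
    flip = match_rev[keep]
    df.loc[flip, "b"] = -df.loc[flip, "b"]
    df.loc[flip, "freq"] = 1.0 - df.loc[flip, "freq"]
    a1 = df["a1"].to_numpy().copy()
    a2 = df["a2"].to_numpy().copy()
    df.loc[:, "a1"] = np.where(flip, a2, a1)
    df.loc[:, "a2"] = np.where(flip, a1, a2)
    return df.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------


def hwe_exact_p(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact two-sided Hardy-Weinberg test P-value.

    Sums the probabilities of all heterozygote counts no more likely than
    the observed one, conditional on the allele counts (the classic exact
    conditional test).  Monomorphic sites return 1.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("at least one genotype required")
    n_rare = 2 * min(n_AA, n_aa) + n_Aa
    if n_rare == 0 or n_rare == 2 * n:
        return 1.0
    # unnormalized probabilities over all het counts with the parity of n_rare
    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    probs = np.empty(len(hets), dtype=float)
    # recurrence: P(h+2)/P(h) = 4*nA(h)*na(h) / ((h+2)*(h+1)),
    # where nA(h), na(h) are the implied homozygote counts at het count h
    mid_i = len(hets) // 2
    probs[mid_i] = 1.0
    for i in range(mid_i, len(hets) - 1):
        h = hets[i]
        hom_r = (n_rare - h) // 2
        hom_c = n - h - hom_r
        probs[i + 1] = probs[i] * 4.0 * hom_r * hom_c / ((h + 2.0) * (h + 1.0))
    for i in range(mid_i, 0, -1):
        h = hets[i]
        hom_r = (n_rare - h) // 2
        hom_c = n - h - hom_r
        probs[i - 1] = probs[i] * h * (h - 1.0) / (4.0 * (hom_r + 1.0) * (hom_c + 1.0))
    probs /= probs.sum()
    p_obs = probs[np.searchsorted(hets, n_Aa)]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


def _hwe_p_per_snp(g: np.ndarray) -> np.ndarray:
    out = np.ones(g.shape[1])
    for j in range(g.shape[1]):
        col = g[:, j]
        col = col[col != MISSING]
        out[j] = hwe_exact_p(int((col == 0).sum()), int((col == 1).sum()),
                             int((col == 2).sum()))
    return out


# ---------------------------------------------------------------------------
# QC filters
# ---------------------------------------------------------------------------


def qc_filter(panel: PopulationPanel,
              thresholds: QCThresholds | None = None) -> PopulationPanel:
    """SNP-level QC: keep SNPs passing MAF and HWE in *every* population
    separately and the call-rate filter overall."""
    thr = thresholds or QCThresholds()
    if not panel.pop_labels:
        raise ValueError("panel has no populations")
    keep = panel.call_rate() >= thr.call_rate_min
    for pop in panel.pop_labels:
        mask = panel.pop_mask(pop)
        maf = panel.maf(pop)
        keep &= np.nan_to_num(maf, nan=-1.0) >= thr.maf_min
        hwe = _hwe_p_per_snp(panel.genotypes[mask])
        keep &= hwe >= thr.hwe_p_min
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("qc_filter: removed %d of %d SNPs", n_drop, panel.n_snps)
    if not keep.any():
        raise ValueError("QC removed all SNPs")
    return panel.subset_snps(keep)


def compute_grm(panel: PopulationPanel, pop: str) -> np.ndarray:
    """Genetic relationship matrix within one population.

    Entry (j, k) is the average over SNPs of
    ``(x_j - 2p)(x_k - 2p) / (2p(1-p))`` using the within-population allele
    frequency p.  Monomorphic SNPs are skipped; missing genotypes are handled
    pairwise-complete.
    """
    mask = panel.pop_mask(pop)
    if mask.sum() < 2:
        raise ValueError("GRM needs at least 2 individuals")
    g = panel.genotypes[mask].astype(float)
    obs = g != MISSING
    p = panel.freqs(pop)
    poly = (p > 0) & (p < 1) & ~np.isnan(p)
    g, obs, p = g[:, poly], obs[:, poly], p[poly]
    z = np.where(obs, (g - 2 * p) / np.sqrt(2 * p * (1 - p)), 0.0)
    counts = obs.astype(float) @ obs.T.astype(float)
    with np.errstate(invalid="ignore"):
        grm = (z @ z.T) / counts
    return grm


def prune_related(panel: PopulationPanel, pop: str,
                  threshold: float = 0.05) -> PopulationPanel:
    """Remove individuals until no within-population pair exceeds the
    relatedness threshold.

    Greedy: repeatedly drop the individual with the most over-threshold
    partners, breaking ties by sample-id order, so runs are reproducible.
    """
    mask = panel.pop_mask(pop)
    idx = np.flatnonzero(mask)
    grm = compute_grm(panel, pop)
    over = np.nan_to_num(grm) > threshold
    np.fill_diagonal(over, False)
    alive = np.ones(len(idx), dtype=bool)
    ids = [panel.samples[i] for i in idx]
    while True:
        deg = (over & alive[None, :] & alive[:, None]).sum(axis=1)
        deg[~alive] = 0
        if deg.max() == 0:
            break
        worst = np.flatnonzero(deg == deg.max())
        drop = worst[np.argsort([ids[w] for w in worst], kind="stable")[0]]
        alive[drop] = False
    removed = idx[~alive]
    if len(removed) == 0:
        return panel
    logger.info("prune_related: removed %d of %d %s individuals",
                len(removed), len(idx), pop)
    keep = np.ones(panel.n_individuals, dtype=bool)
    keep[removed] = False
    return panel.subset_individuals(keep)


def _standardized_genotypes(g: np.ndarray) -> np.ndarray:
    """Column-standardize dosages (missing -> mean), dropping nothing."""
    g = g.astype(float)
    g[g == MISSING] = np.nan
    mu = np.nanmean(g, axis=0)
    sd = np.nanstd(g, axis=0)
    sd[sd == 0] = 1.0
    z = (g - mu) / sd
    return np.nan_to_num(z, nan=0.0)


def pca(genotypes: np.ndarray, n_pcs: int) -> np.ndarray:
    """Principal components of standardized genotypes (rows = individuals)."""
    z = _standardized_genotypes(genotypes)
    if n_pcs > min(z.shape) - 1:
        raise ValueError(f"n_pcs={n_pcs} exceeds matrix rank")
    if min(z.shape) <= 2000 and z.shape[1] <= 50000:
        u, s, _ = np.linalg.svd(z, full_matrices=False)
    else:
        from scipy.sparse.linalg import svds
        u, s, _ = svds(z.astype(np.float32), k=n_pcs)
        order = np.argsort(s)[::-1]
        u, s = u[:, order], s[order]
    return u[:, :n_pcs] * s[:n_pcs]


def pca_outlier_filter(panel: PopulationPanel, reference_pop: str,
                       target_samples: list[str], n_pcs: int = 10,
                       sd_limit: float = 3.0) -> list[str]:
    """Retain target samples within ``sd_limit`` reference s.d. of the
    reference-population mean on each of the first ``n_pcs`` PCs."""
    ref_idx = np.flatnonzero(panel.pop_mask(reference_pop))
    sample_pos = {s: i for i, s in enumerate(panel.samples)}
    tgt_idx = np.array([sample_pos[s] for s in target_samples])
    combined = np.concatenate([ref_idx, tgt_idx])
    pcs = pca(panel.genotypes[combined], n_pcs)
    ref_pcs = pcs[: len(ref_idx)]
    tgt_pcs = pcs[len(ref_idx):]
    mu = ref_pcs.mean(axis=0)
    sd = ref_pcs.std(axis=0, ddof=1)
    ok = (np.abs(tgt_pcs - mu) <= sd_limit * sd).all(axis=1)
    return [s for s, keep in zip(target_samples, ok) if keep]


def downsample(panel: PopulationPanel, n: int, seed: int) -> PopulationPanel:
    """Harmonize sample sizes by randomly keeping ``n`` individuals per
    population (populations already at or below ``n`` are kept whole)."""
    rng = np.random.default_rng(seed)
    keep: list[int] = []
    for pop in panel.pop_labels:
        idx = np.flatnonzero(panel.pop_mask(pop))
        if len(idx) > n:
            idx = np.sort(rng.choice(idx, size=n, replace=False))
        keep.extend(idx.tolist())
    return panel.subset_individuals(np.array(sorted(keep)))
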
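"""Simulation study machinery: polygenic traits, PC-adjusted GWAS scans,
and the end-to-end null/alternative calibration of the enrichment test.

Traits follow the standard additive model ``y = g + e = sum_i w_i u_i + e``
with ``w_i`` the standardized genotype of causal variant i, effect
``u_i ~ N(0, 1)``, and residual ``e ~ N(0, var(g) (1/h^2 - 1))`` so the
realized heritability is h^2.  Causal variants are sampled at random (the
drift null), from the top half of the F_ST distribution (the selection
alternative), skewed toward low MAF, or clustered in 1-Mb neighbourhoods
(confound scenarios).

The scan regresses the phenotype on each SNP's dosage with the leading
principal components of the genotype matrix as covariates; clumped hits
then feed the matched-control enrichment test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import clumping, enrichment, popgen_stats
from .genotype_io import MISSING, PopulationPanel

logger = logging.getLogger(__name__)


@dataclass
class TraitSimSpec:
    """Configuration of one simulated polygenic trait."""

    m: int = 1000                       # number of (primary) causal variants
    h2: float = 0.5                     # heritability
    causal_mode: str = "random"         # random | top_fst | maf_skew | clustered
    top_fraction: float = 0.5           # top-F_ST fraction for mode 'top_fst'
    maf_skew_extra: int = 500           # extra low-MAF causals for 'maf_skew'
    maf_skew_maf_max: float = 0.1
    cluster_extra: int = 2              # extra causals per primary, 'clustered'
    cluster_window_bp: int = 1_000_000
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (0 < self.h2 <= 1):
            raise ValueError("h2 must be in (0, 1]")
        if self.m < 1:
            raise ValueError("m must be >= 1")


@dataclass
class ScanResult:
    """Per-SNP association scan output."""

    table: pd.DataFrame       # columns: snp, a1, a2, freq, b, se, p, n
    n_pcs: int

    def summary(self) -> pd.DataFrame:
        """The scan as a GWAS summary frame (effect allele = panel alt)."""
        return self.table


def sample_causals(panel: PopulationPanel, spec: TraitSimSpec,
                   fst_reference: np.ndarray | None = None,
                   rng: np.random.Generator | None = None) -> np.ndarray:
    """Seeded sampling of causal variant ids under the spec's mode.

    Only SNPs polymorphic in the panel are eligible (a monomorphic variant
    has no standardized genotype, so it cannot carry a trait effect)."""
    rng = rng or np.random.default_rng(spec.seed)
    maf = panel.maf()
    poly = np.nan_to_num(maf, nan=0.0) > 0
    ids = panel.snps["snp"].to_numpy()[poly]
    if spec.causal_mode == "top_fst" and fst_reference is not None:
        fst_reference = np.asarray(fst_reference, dtype=float)[poly]
    if spec.causal_mode == "random":
        pool = ids
        if len(pool) < spec.m:
            raise ValueError("not enough SNPs to sample causals")
        return rng.choice(pool, size=spec.m, replace=False)
    if spec.causal_mode == "top_fst":
        if fst_reference is None:
            raise ValueError("mode 'top_fst' requires F_ST values")
        fst = np.asarray(fst_reference, dtype=float)
        cutoff = np.nanquantile(fst, 1.0 - spec.top_fraction)
        pool = ids[np.nan_to_num(fst, nan=-np.inf) >= cutoff]
        if len(pool) < spec.m:
            raise ValueError("not enough high-F_ST SNPs to sample causals")
        return rng.choice(pool, size=spec.m, replace=False)
    if spec.causal_mode == "maf_skew":
        primary = rng.choice(ids, size=spec.m, replace=False)
        low = ids[(maf[poly] < spec.maf_skew_maf_max) & ~np.isin(ids, primary)]
        if len(low) < spec.maf_skew_extra:
            raise ValueError("not enough low-MAF SNPs for the skew scenario")
        extra = rng.choice(low, size=spec.maf_skew_extra, replace=False)
        return np.concatenate([primary, extra])
    if spec.causal_mode == "clustered":
        primary = rng.choice(ids, size=spec.m, replace=False)
        chrom = panel.snps.set_index("snp")["chrom"]
        pos = panel.snps.set_index("snp")["pos"]
        chosen = list(primary)
        chosen_set = set(primary)
        for snp in primary:
            near = panel.snps[
                (panel.snps["chrom"] == chrom[snp])
                & (np.abs(panel.snps["pos"] - pos[snp]) <= spec.cluster_window_bp)
                & ~panel.snps["snp"].isin(chosen_set)]["snp"].to_numpy()
            if len(near) < spec.cluster_extra:
                raise ValueError(
                    f"not enough SNPs within 1 Mb of {snp} for clustered causals")
            extra = rng.choice(near, size=spec.cluster_extra, replace=False)
            chosen.extend(extra)
            chosen_set.update(extra)
        return np.asarray(chosen)
    raise ValueError(f"unknown causal mode {spec.causal_mode!r}")


def simulate_trait(cohort: PopulationPanel, causal_ids, h2: float,
                   rng: np.random.Generator):
    """Phenotypes under the additive model; returns (y, effects-by-snp).

    The genetic value g sums standardized causal genotypes times N(0,1)
    effects; the residual variance is var(g)(1/h^2 - 1), so h^2 = 1 gives
    y = g exactly.
    """
    if not (0 < h2 <= 1):
        raise ValueError("h2 must be in (0, 1]")
    causal_ids = np.asarray(causal_ids)
    x = cohort.dosages(causal_ids).astype(np.float32)
    if (x == MISSING).any():
        x[x == MISSING] = np.nan
        mu = np.nanmean(x, axis=0)
        sd = np.nanstd(x, axis=0)
    else:
        mu = x.mean(axis=0)
        sd = x.std(axis=0)
    if (sd == 0).any():
        raise ValueError("causal SNPs must be polymorphic in the cohort")
    w = np.nan_to_num((x - mu) / sd, nan=0.0)
    u = rng.standard_normal(len(causal_ids))
    g = (w @ u.astype(np.float32)).astype(np.float64)
    var_g = g.var()
    e = (np.zeros_like(g) if h2 == 1.0
         else rng.normal(0.0, np.sqrt(var_g * (1.0 / h2 - 1.0)), size=len(g)))
    return g + e, pd.Series(u, index=causal_ids)


class ScanEngine:
    """PC-adjusted single-SNP regression engine.

    Precomputes the cohort's leading PCs and the PC-residualized dosage
    matrix once, so repeated traits on the same cohort only cost one
    matrix-vector product each.  Effects are per alternate-allele copy.
    """

    def __init__(self, cohort: PopulationPanel, n_pcs: int = 10,
                 n_pca_snps: int | None = None):
        n = cohort.n_individuals
        if n < n_pcs + 2:
            raise ValueError("need at least n_pcs + 2 individuals")
        self.cohort = cohort
        self.n_pcs = n_pcs
        g = cohort.genotypes.astype(np.float32)
        g[g == MISSING] = np.nan
        col_mu = np.nanmean(g, axis=0)
        g = np.where(np.isnan(g), col_mu, g)
        # PCs from the standardized matrix; covariate basis Q = [1, PCs].
        # n_pca_snps bounds the SNPs entering the PCA (a random thinning,
        # the usual trick on large cohorts) to cap memory.
        cols = np.arange(g.shape[1])
        if n_pca_snps is not None and n_pca_snps < g.shape[1]:
            cols = np.sort(np.random.default_rng(0).choice(
                g.shape[1], size=n_pca_snps, replace=False))
        sub = g[:, cols]
        sd = sub.std(axis=0)
        z = (sub - col_mu[cols]) / np.where(sd == 0, 1.0, sd)
        if n_pcs > 0:
            from scipy.sparse.linalg import svds
            rng = np.random.default_rng(0)  # deterministic svds start vector
            u, s, _ = svds(z, k=n_pcs, v0=rng.standard_normal(min(z.shape)))
            pcs = u[:, np.argsort(s)[::-1]]
            cov = np.column_stack([np.ones(n, dtype=np.float32), pcs])
        else:
            cov = np.ones((n, 1), dtype=np.float32)
        self.q, _ = np.linalg.qr(cov.astype(np.float32))
        del z
        g -= self.q @ (self.q.T @ g)
        self._g_resid = g
        self._g2 = (g ** 2).sum(axis=0).astype(np.float64)
        self._df = n - self.q.shape[1] - 1

    def scan(self, y: np.ndarray) -> ScanResult:
        y = np.asarray(y, dtype=np.float64)
        y = y - self.q @ (self.q.T @ y)
        yy = float(y @ y)
        num = self._g_resid.T @ y.astype(np.float32)
        num = num.astype(np.float64)
        g2 = self._g2
        poly = g2 > 1e-8
        with np.errstate(invalid="ignore", divide="ignore"):
            beta = np.where(poly, num / g2, np.nan)
            rss = np.maximum(yy - num ** 2 / np.where(poly, g2, 1.0), 0.0)
            se = np.sqrt(rss / (self._df * np.where(poly, g2, np.nan)))
            t = beta / se
        p = 2.0 * sps.t.sf(np.abs(t), self._df)
        p = np.clip(p, np.finfo(float).tiny, 1.0)
        p[~poly] = np.nan
        tbl = pd.DataFrame({
            "snp": self.cohort.snps["snp"],
            "a1": self.cohort.snps["alt"],
            "a2": self.cohort.snps["ref"],
            "freq": self.cohort.freqs(),
            "b": beta, "se": se, "p": p,
            "n": self.cohort.n_individuals,
        })
        return ScanResult(tbl, self.n_pcs)


def gwas_scan(cohort: PopulationPanel, phenotype: np.ndarray,
              n_pcs: int = 10) -> ScanResult:
    """One-shot PC-adjusted scan (build the engine yourself for many traits)."""
    return ScanEngine(cohort, n_pcs).scan(phenotype)


# ---------------------------------------------------------------------------
# End-to-end study
# ---------------------------------------------------------------------------


@dataclass
class StudyConfig:
    """Replicate-trait study: simulate -> scan -> clump -> enrichment."""

    spec: TraitSimSpec
    n_traits: int = 100
    thresholds: tuple[float, ...] = (5e-8, 5e-6)
    n_control_sets: int = 200
    matching_mode: str = "maf_and_ld"
    stat: str = "fst"                 # fst | ldcv
    summary_stat: str = "mean"        # mean | variance
    n_pcs: int = 10
    clump_r2: float = clumping.DEFAULT_CLUMP_R2
    clump_window_bp: int = clumping.DEFAULT_CLUMP_WINDOW_BP
    mask_causals: bool = False
    reference_pop: str | None = None  # pop supplying MAF/LD/clump reference
    seed: int = 0


def run_study(panel: PopulationPanel, cohort: PopulationPanel,
              config: StudyConfig,
              fst: np.ndarray | None = None,
              ld_scores_by_pop: dict[str, np.ndarray] | None = None,
              engine: ScanEngine | None = None) -> pd.DataFrame:
    """Run the replicate-trait study and return one row per
    (trait, clumping threshold).

    The panel supplies F_ST (and LD scores for matching); the cohort is the
    GWAS sample.  Cohort SNPs must be a superset of the panel SNPs (the
    synthetic generators guarantee this by construction).
    """
    rng = np.random.default_rng(config.seed)
    ref_pop = config.reference_pop or panel.pop_labels[0]
    if fst is None:
        fst = popgen_stats.fst_per_snp(panel)
    fst_s = pd.Series(fst, index=panel.snps["snp"])
    maf = panel.maf(ref_pop)
    if config.matching_mode == "maf_only":
        ld = None
    else:
        ld_pop = (panel.pop_labels[1] if config.matching_mode == "maf_and_afr_ld"
                  and len(panel.pop_labels) > 1 else ref_pop)
        if ld_scores_by_pop and ld_pop in ld_scores_by_pop:
            ld = ld_scores_by_pop[ld_pop]
        else:
            ld = popgen_stats.ld_scores(panel, ld_pop)
    if config.stat == "ldcv":
        if not ld_scores_by_pop:
            ld_scores_by_pop = {p: popgen_stats.ld_scores(panel, p)
                                for p in panel.pop_labels}
        stat_s = pd.Series(popgen_stats.ldcv(ld_scores_by_pop),
                           index=panel.snps["snp"])
    else:
        stat_s = fst_s
    bins = enrichment.build_bins(panel.snps["snp"], maf, ld,
                                 matching_mode=config.matching_mode)
    engine = engine or ScanEngine(cohort, config.n_pcs)

    rows = []
    for trait_i in range(config.n_traits):
        causals = sample_causals(cohort, config.spec,
                                 fst_reference=fst_s.reindex(
                                     cohort.snps["snp"]).to_numpy(),
                                 rng=rng)
        y, _ = simulate_trait(cohort, causals, config.spec.h2, rng)
        scan = engine.scan(y)
        summary = scan.summary().dropna(subset=["p"])
        if config.mask_causals:
            summary = summary[~summary["snp"].isin(set(causals))]
        for thr in config.thresholds:
            cs = clumping.clump(summary, panel, ref_pop, thr,
                                config.clump_r2, config.clump_window_bp)
            hits = [s for s in cs.index_snps if s in bins.assignment.index]
            row = {"trait": trait_i, "threshold": thr, "n_hits": len(hits)}
            if len(hits) == 0:
                row.update(observed=np.nan, null_mu=np.nan, null_sd=np.nan,
                           z=np.nan, p=np.nan, n_snps=0)
            else:
                sets = enrichment.sample_controls(
                    bins, hits, config.n_control_sets, rng)
                res = enrichment.enrichment_test(
                    stat_s, hits, sets, config.summary_stat, config.stat)
                row.update(observed=res.observed, null_mu=res.null_mu,
                           null_sd=res.null_sd, z=res.z, p=res.p_two_tailed,
                           n_snps=res.n_snps)
            rows.append(row)
    return pd.DataFrame(rows)


def rejection_rate(study: pd.DataFrame, threshold: float,
                   alpha: float = 0.05) -> float:
    """Fraction of traits (at one clumping threshold) rejected at alpha,
    among traits that produced at least one associated SNP."""
    sub = study[(study["threshold"] == threshold) & study["p"].notna()]
    if sub.empty:
        return np.nan
    return float((sub["p"] < alpha).mean())


def qq_data(pvalues: np.ndarray) -> pd.DataFrame:
    """Expected vs observed -log10 P for a QQ plot."""
    p = np.sort(np.asarray(pvalues)[~np.isnan(pvalues)])
    n = len(p)
    exp = (np.arange(1, n + 1) - 0.5) / n
    return pd.DataFrame({"EXPECTED": -np.log10(exp), "OBSERVED": -np.log10(p)})
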
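"""Per-SNP population differentiation statistics: F_ST, windowed LD scores,
and the cross-population LD coefficient of variation (LDCV).

F_ST defaults to the Weir-Cockerham (1984) multi-population theta-hat per
SNP, computed from genotype counts (allele frequencies plus observed
heterozygosity); Nei's G_ST and the Hudson estimator are selectable.
Negative estimates are retained as-is.

The LD score of a focal SNP is the sum of squared dosage correlations (r^2)
with all SNPs on the same chromosome within a physical window (default
10 Mb), self term included; pairs with r^2 below ``r2_min`` (default 0.01)
are excluded to avoid accumulating chance correlations.  LDCV is the ratio
of the standard deviation (n-1 denominator) to the mean of a SNP's LD scores
across populations.
"""

from __future__ import annotations

import logging
from itertools import combinations

import numpy as np
import pandas as pd

from .genotype_io import MISSING, PopulationPanel

logger = logging.getLogger(__name__)

DEFAULT_LD_WINDOW_BP = 10_000_000
DEFAULT_R2_MIN = 0.01


def _pop_counts(panel: PopulationPanel, pops: list[str]):
    """Per-population (n, p, h) arrays: sample size, alt frequency and
    observed heterozygote proportion per SNP."""
    ns, ps, hs = [], [], []
    for pop in pops:
        g = panel.genotypes[panel.pop_mask(pop)]
        obs = g != MISSING
        n = obs.sum(axis=0).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(obs, g, 0).sum(axis=0) / (2.0 * n)
            h = (g == 1).sum(axis=0) / n
        ns.append(n)
        ps.append(p)
        hs.append(h)
    return np.array(ns), np.array(ps), np.array(hs)


def _wc_components(n, p, h):
    """Weir & Cockerham (1984) per-SNP variance components (a, b, c):
    among-population, among-individual and within-individual."""
    r = n.shape[0]
    nbar = n.mean(axis=0)
    nc = (n.sum(axis=0) - (n ** 2).sum(axis=0) / n.sum(axis=0)) / (r - 1)
    pbar = (n * p).sum(axis=0) / (r * nbar)
    s2 = (n * (p - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
    hbar = (n * h).sum(axis=0) / (r * nbar)
    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1))
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar)
    c = hbar / 2
    return a, b, c


def _fst_wc(n, p, h):
    """Weir & Cockerham (1984) theta-hat per SNP for r populations."""
    a, b, c = _wc_components(n, p, h)
    denom = a + b + c
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(denom != 0, a / denom, np.nan)


def _fst_nei(n, p, h):
    """Nei's G_ST with unweighted population means: 1 - Hs/Ht."""
    pbar = p.mean(axis=0)
    hs = (2 * p * (1 - p)).mean(axis=0)
    ht = 2 * pbar * (1 - pbar)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(ht > 0, 1 - hs / ht, np.nan)


def _fst_hudson(n, p, h):
    """Hudson estimator, averaged (ratio of sums) over population pairs.

    Allele counts are 2n; within-population diversity uses the unbiased
    p(1-p)·2n/(2n-1) form via the (p1-p2)^2 numerator correction.
    """
    num = np.zeros(p.shape[1])
    den = np.zeros(p.shape[1])
    for i, j in combinations(range(p.shape[0]), 2):
        a1, a2 = 2 * n[i], 2 * n[j]
        p1, p2 = p[i], p[j]
        num += (p1 - p2) ** 2 - p1 * (1 - p1) / (a1 - 1) - p2 * (1 - p2) / (a2 - 1)
        den += p1 * (1 - p2) + p2 * (1 - p1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(den > 0, num / den, np.nan)


_ESTIMATORS = {"wc": _fst_wc, "nei": _fst_nei, "hudson": _fst_hudson}


def fst_per_snp(panel: PopulationPanel, pops: list[str] | None = None,
                estimator: str = "wc") -> np.ndarray:
    """Per-SNP F_ST across the given populations (default: all).

    SNPs monomorphic in every population (or with fewer than two called
    diploids in any population) are returned as NaN.
    """
    pops = pops or panel.pop_labels
    if len(pops) < 2:
        raise ValueError("F_ST requires at least two populations")
    if estimator not in _ESTIMATORS:
        raise ValueError(f"unknown estimator {estimator!r}")
    n, p, h = _pop_counts(panel, pops)
    out = _ESTIMATORS[estimator](n, p, h)
    # undefined only when the pooled sample is monomorphic (differentially
    # fixed SNPs are the F_ST -> 1 limit, not missing)
    mono = (np.all((p == 0.0) | np.isnan(p), axis=0)
            | np.all((p == 1.0) | np.isnan(p), axis=0))
    too_few = (n < 2).any(axis=0)
    out = np.asarray(out, dtype=float)
    out[mono | too_few] = np.nan
    return out


def fst_overall(panel: PopulationPanel, pops: list[str] | None = None):
    """Multi-locus Weir-Cockerham estimate: ratio of summed variance
    components across SNPs, ``sum(a) / sum(a+b+c)``.

    Unlike the mean of per-SNP ratios (which is biased toward zero with few
    populations because each SNP's among-population variance is noisy), the
    ratio-of-averages form is consistent for the generating F and is the
    form Weir & Cockerham recommend for combining loci.  Returns
    ``(theta, se)`` with a leave-one-SNP-out jackknife standard error.
    """
    pops = pops or panel.pop_labels
    n, p, h = _pop_counts(panel, pops)
    a, b, c = _wc_components(n, p, h)
    tot = a + b + c
    ok = np.isfinite(a) & np.isfinite(tot)
    a, tot = a[ok], tot[ok]
    sa, st = a.sum(), tot.sum()
    theta = sa / st
    # delete-one jackknife over SNPs
    loo = (sa - a) / (st - tot)
    m = len(a)
    se = np.sqrt((m - 1) / m * ((loo - loo.mean()) ** 2).sum())
    return float(theta), float(se)


# ---------------------------------------------------------------------------
# LD
# ---------------------------------------------------------------------------


def ld_r2(panel: PopulationPanel, pop: str, snp_a: str, snp_b: str) -> float:
    """Squared Pearson correlation of two SNPs' dosages within a population,
    over pairwise-complete individuals (composite LD)."""
    idx = panel.snp_indexer()
    g = panel.genotypes[panel.pop_mask(pop)][:, [idx[snp_a], idx[snp_b]]]
    ok = (g != MISSING).all(axis=1)
    x, y = g[ok, 0].astype(float), g[ok, 1].astype(float)
    if x.std() == 0 or y.std() == 0:
        return np.nan
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def ld_scores(panel: PopulationPanel, pop: str,
              window_bp: int = DEFAULT_LD_WINDOW_BP,
              r2_min: float = DEFAULT_R2_MIN,
              max_block: int = 4000) -> np.ndarray:
    """Windowed LD scores within one population.

    For SNP j: ``l_j = sum of r^2(j, k)`` over SNPs k on the same chromosome
    with |pos_k - pos_j| <= window_bp and r^2 >= r2_min, including k = j.
    Monomorphic SNPs get NaN.  Missing dosages are mean-imputed for the
    correlation (panels should be QC'd for call rate first).
    """
    g_all = panel.genotypes[panel.pop_mask(pop)]
    out = np.full(panel.n_snps, np.nan)
    chroms = panel.snps["chrom"].to_numpy()
    positions = panel.snps["pos"].to_numpy()
    for chrom in pd.unique(chroms):
        cols = np.flatnonzero(chroms == chrom)
        pos = positions[cols]
        z = g_all[:, cols].astype(float)
        z[z == MISSING] = np.nan
        mu = np.nanmean(z, axis=0)
        z = np.nan_to_num(z - mu, nan=0.0)
        norm = np.sqrt((z ** 2).sum(axis=0))
        poly = norm > 0
        zn = np.where(poly, z / np.where(norm == 0, 1.0, norm), 0.0)
        scores = np.full(len(cols), np.nan)
        # process in column blocks to bound memory on long chromosomes
        for start in range(0, len(cols), max_block):
            stop = min(start + max_block, len(cols))
            lo = np.searchsorted(pos, pos[start:stop] - window_bp, side="left")
            hi = np.searchsorted(pos, pos[start:stop] + window_bp, side="right")
            nlo, nhi = lo.min(), hi.max()
            r = zn[:, start:stop].T @ zn[:, nlo:nhi]
            r2 = r * r
            # mask outside-window pairs and sub-threshold correlations
            col_pos = pos[nlo:nhi]
            in_win = np.abs(col_pos[None, :] - pos[start:stop, None]) <= window_bp
            r2 = np.where(in_win & (r2 >= r2_min), r2, 0.0)
            scores[start:stop] = r2.sum(axis=1)
        scores[~poly] = np.nan
        out[cols] = scores
    return out


def ldcv(ld_scores_by_pop: dict[str, np.ndarray]) -> np.ndarray:
    """Coefficient of variation (sd/mean, n-1 denominator) of per-SNP LD
    scores across populations; NaN where any population's score is missing."""
    if len(ld_scores_by_pop) < 2:
        raise ValueError("LDCV requires LD scores from at least 2 populations")
    mat = np.vstack(list(ld_scores_by_pop.values()))
    with np.errstate(invalid="ignore"):
        return mat.std(axis=0, ddof=1) / mat.mean(axis=0)


def stats_table(panel: PopulationPanel, fst: np.ndarray,
                ld_scores_by_pop: dict[str, np.ndarray] | None = None) -> pd.DataFrame:
    """Per-SNP stats frame: ``SNP CHR BP FST [LD_<pop>...] [LDCV]``."""
    df = pd.DataFrame({
        "SNP": panel.snps["snp"],
        "CHR": panel.snps["chrom"],
        "BP": panel.snps["pos"],
        "FST": fst,
    })
    if ld_scores_by_pop:
        for pop, sc in ld_scores_by_pop.items():
            df[f"LD_{pop}"] = sc
        df["LDCV"] = ldcv(ld_scores_by_pop)
    return df
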
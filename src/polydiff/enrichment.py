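"""Matched-control resampling enrichment test.

The core test of the package: is the mean (or variance) of a per-SNP
statistic (F_ST or LDCV) over trait-associated SNPs larger than expected
under drift?  The null is built by resampling control SNPs that match the
associated SNPs' minor-allele-frequency and LD-score bin occupancy, cell by
cell, many times (default 10,000); a two-tailed P-value is computed against
a normal fit to the resampled null means, with an empirical rank P-value
reported alongside.

Binning: 20 MAF bins over (0, 0.5] of width 0.025 (SNPs with MAF < 0.01
excluded); each MAF bin is further cut into 20 LD-score quantile bins.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

N_MAF_BINS = 20
N_LD_BINS = 20
MAF_BIN_WIDTH = 0.025
MAF_MIN = 0.01
DEFAULT_N_SETS = 10_000

MATCHING_MODES = ("maf_and_ld", "maf_only", "maf_and_afr_ld")


@dataclass
class BinIndex:
    """Deterministic SNP -> (MAF bin, LD bin) assignment used for matching."""

    assignment: pd.Series          # snp id -> cell code (maf_bin * n_ld + ld_bin)
    maf_bin: pd.Series
    ld_bin: pd.Series
    matching_mode: str
    n_maf_bins: int
    n_ld_bins: int

    def cells(self) -> pd.Series:
        return self.assignment


@dataclass
class EnrichmentResult:
    """Observed statistic vs the matched-control resampling null."""

    observed: float
    null_means: np.ndarray
    null_mu: float
    null_sd: float
    z: float
    p_two_tailed: float
    p_empirical: float
    statistic_name: str = "fst"
    summary_stat: str = "mean"
    n_snps: int = 0

    def to_row(self, trait: str = "trait") -> dict:
        return {"TRAIT": trait, "N_SNPS": self.n_snps, "OBS_MEAN": self.observed,
                "NULL_MEAN": self.null_mu, "NULL_SD": self.null_sd,
                "Z": self.z, "P": self.p_two_tailed}


def maf_bin_index(maf: np.ndarray, n_bins: int = N_MAF_BINS,
                  width: float = MAF_BIN_WIDTH) -> np.ndarray:
    """Half-open MAF bins [lo, hi) of the given width; the last bin is
    closed at 0.5.  Caller is responsible for excluding MAF < 0.01."""
    idx = np.floor(np.asarray(maf) / width).astype(int)
    return np.minimum(idx, n_bins - 1)


def build_bins(snp_ids, maf, ld_score=None, matching_mode: str = "maf_and_ld",
               n_maf_bins: int = N_MAF_BINS, n_ld_bins: int = N_LD_BINS) -> BinIndex:
    """Assign every eligible SNP (MAF >= 0.01) to a MAF x LD-score cell.

    LD quantile boundaries are computed per MAF bin from all eligible SNPs;
    SNPs tied at a boundary go to the lower bin.  A MAF bin with fewer SNPs
    than LD bins collapses to a single LD bin (logged, never fatal).
    In ``maf_only`` mode the LD dimension is a single bin.
    """
    if matching_mode not in MATCHING_MODES:
        raise ValueError(f"unknown matching mode {matching_mode!r}")
    snp_ids = np.asarray(snp_ids)
    maf = np.asarray(maf, dtype=float)
    eligible = (maf >= MAF_MIN) & (maf <= 0.5) & ~np.isnan(maf)
    use_ld = matching_mode != "maf_only"
    if use_ld:
        if ld_score is None:
            raise ValueError("LD scores required unless matching_mode='maf_only'")
        ld_score = np.asarray(ld_score, dtype=float)
        eligible &= ~np.isnan(ld_score)
    n_excl = int((~eligible).sum())
    if n_excl:
        logger.info("build_bins: excluded %d SNPs (MAF < %.2f or missing stats)",
                    n_excl, MAF_MIN)
    snp_ids, maf = snp_ids[eligible], maf[eligible]
    mbin = maf_bin_index(maf, n_maf_bins)
    lbin = np.zeros(len(snp_ids), dtype=int)
    if use_ld:
        ld = ld_score[eligible]
        for b in np.unique(mbin):
            sel = mbin == b
            vals = ld[sel]
            if len(vals) < n_ld_bins:
                logger.info("build_bins: MAF bin %d has %d SNPs; collapsing "
                            "LD bins", b, len(vals))
                continue
            edges = np.quantile(vals, np.arange(1, n_ld_bins) / n_ld_bins)
            # side='left': values equal to a boundary fall in the lower bin
            lbin[sel] = np.searchsorted(edges, vals, side="left")
    cell = mbin * n_ld_bins + lbin
    idx = pd.Index(snp_ids, name="snp")
    return BinIndex(pd.Series(cell, index=idx),
                    pd.Series(mbin, index=idx),
                    pd.Series(lbin, index=idx),
                    matching_mode, n_maf_bins, n_ld_bins)


def sample_controls(bins: BinIndex, associated, n_sets: int = DEFAULT_N_SETS,
                    seed: int | np.random.Generator = 0,
                    pool=None, exclude_associated: bool = True) -> list[np.ndarray]:
    """Draw ``n_sets`` control SNP sets matching the associated SNPs' cell
    occupancy exactly.

    Within a set, sampling is without replacement; sets are independent.
    ``pool`` optionally restricts the control candidates.  If a cell's pool
    is smaller than required, that cell is sampled with replacement (warned).
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    associated = np.asarray(associated)
    cells = bins.assignment
    missing = [s for s in associated if s not in cells.index]
    if missing:
        raise ValueError(f"{len(missing)} associated SNPs not assigned to bins "
                         f"(e.g. {missing[:3]})")
    assoc_cells = cells.loc[associated]
    pool_ids = cells.index.to_numpy() if pool is None else np.asarray(pool)
    if exclude_associated:
        pool_ids = pool_ids[~np.isin(pool_ids, associated)]
    pool_cells = cells.loc[pool_ids]

    sets = [[] for _ in range(n_sets)]
    pool_by_cell = {c: g.index.to_numpy() for c, g in pool_cells.groupby(pool_cells)}
    pool_maf_bins = pool_cells // bins.n_ld_bins
    pool_by_maf = {b: g.index.to_numpy() for b, g in
                   pool_cells.groupby(pool_maf_bins)}
    for cell, count in assoc_cells.value_counts().items():
        cell_pool = pool_by_cell.get(cell, np.array([], dtype=object))
        if len(cell_pool) == 0:
            # sparse pools: fall back to the cell's whole MAF bin
            cell_pool = pool_by_maf.get(cell // bins.n_ld_bins,
                                        np.array([], dtype=object))
            logger.warning("sample_controls: cell %d pool empty; matching on "
                           "MAF bin only (%d candidates)", cell,
                           len(cell_pool))
            if len(cell_pool) == 0:
                raise ValueError(
                    f"no control SNPs available for cell {cell}'s MAF bin")
        if len(cell_pool) < count:
            logger.warning("sample_controls: cell %d pool (%d) smaller than "
                           "needed (%d); sampling with replacement",
                           cell, len(cell_pool), count)
            draws = rng.choice(cell_pool, size=(n_sets, count), replace=True)
        else:
            # top-`count` of random keys per row = without-replacement draw
            keys = rng.random((n_sets, len(cell_pool)))
            draws = cell_pool[np.argpartition(keys, count - 1, axis=1)[:, :count]]
        for i in range(n_sets):
            sets[i].append(draws[i])
    return [np.concatenate(parts) for parts in sets]


def enrichment_test(stat: pd.Series, associated, control_sets,
                    summary_stat: str = "mean",
                    statistic_name: str = "fst") -> EnrichmentResult:
    """Two-tailed test of the associated SNPs' mean (or variance) of a
    per-SNP statistic against the resampled matched-control null.

    SNPs with a missing statistic are dropped symmetrically from the
    associated set and from every control set (logged).  The primary P-value
    assumes normality of the null means; an empirical rank P-value
    ``(1 + #{|null - mu| >= |obs - mu|}) / (n_sets + 1)`` is also reported.
    """
    if len(control_sets) < 2:
        raise ValueError("need at least 2 control sets")
    if summary_stat not in ("mean", "variance"):
        raise ValueError("summary_stat must be 'mean' or 'variance'")
    stat = stat.dropna()

    def _value(ids) -> float:
        vals = stat.reindex(ids).dropna().to_numpy()
        if len(vals) == 0:
            return np.nan
        return float(vals.mean() if summary_stat == "mean"
                     else vals.var(ddof=1))

    associated = np.asarray(associated)
    n_defined = int(stat.index.isin(associated).sum())
    if n_defined < len(associated):
        logger.info("enrichment_test: %d associated SNPs lack the statistic; "
                    "dropped symmetrically", len(associated) - n_defined)
    observed = _value(associated)
    null_means = np.array([_value(s) for s in control_sets])
    null_means = null_means[~np.isnan(null_means)]
    null_mu = float(null_means.mean())
    null_sd = float(null_means.std(ddof=1))
    if null_sd == 0:
        z = 0.0 if observed == null_mu else np.inf * np.sign(observed - null_mu)
    else:
        z = (observed - null_mu) / null_sd
    p = float(2 * sps.norm.sf(abs(z)))
    d = abs(observed - null_mu)
    p_emp = float((1 + (np.abs(null_means - null_mu) >= d - 1e-300).sum())
                  / (len(null_means) + 1))
    return EnrichmentResult(observed=observed, null_means=null_means,
                            null_mu=null_mu, null_sd=null_sd, z=float(z),
                            p_two_tailed=min(1.0, p), p_empirical=min(1.0, p_emp),
                            statistic_name=statistic_name,
                            summary_stat=summary_stat, n_snps=n_defined)
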
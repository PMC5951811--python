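"""Direction of genetic differentiation: polygenic-score deviations and
trait-increasing-allele frequency (fTIA) contrasts.

A polygenic risk score ``g_hat_i = sum_l x_il * b_hat_l`` is computed per
individual from harmonized per-allele effects, standardized over the
combined sample, and decomposed as ``g_hat_i = mu + v_j + e_i`` where
``v_j`` is the deviation of population j's mean score from the grand mean
(in s.d. units of the standardized score).  Under drift v_j is centred on
zero; its drift variability is drawn as a 95% band from matched control SNP
sets.  No significance test is attached to the direction itself — the
enrichment test carries the significance; the band only displays drift
variability.

The fTIA analysis compares, between two populations, the mean frequency of
the allele with positive estimated effect; its drift expectation is 0.5 per
population and 0 for the between-population difference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype_io import MISSING, PopulationPanel

logger = logging.getLogger(__name__)


@dataclass
class PRSDeviation:
    """Population deviations of the standardized polygenic score."""

    mu: float
    v: dict[str, float]
    se: dict[str, float]
    n: dict[str, int]
    control_band: dict[str, tuple[float, float]] | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for pop in self.v:
            lo, hi = (self.control_band or {}).get(pop, (np.nan, np.nan))
            rows.append({"POP": pop, "V_J": self.v[pop], "SE": self.se[pop],
                         "BAND_LO": lo, "BAND_HI": hi})
        return pd.DataFrame(rows)


@dataclass
class DirectionResult:
    """fTIA contrast between two populations."""

    pop_a: str
    pop_b: str
    ftia_mean: dict[str, float]
    delta: float
    per_snp: pd.DataFrame = field(repr=False, default=None)
    control_deltas: np.ndarray | None = field(repr=False, default=None)

    def to_row(self) -> dict:
        ctrl = self.control_deltas
        return {"POP_A": self.pop_a, "POP_B": self.pop_b,
                "DELTA_FTIA": self.delta,
                "NULL_MEAN": np.nan if ctrl is None else float(np.mean(ctrl)),
                "NULL_LO": np.nan if ctrl is None else float(np.quantile(ctrl, 0.025)),
                "NULL_HI": np.nan if ctrl is None else float(np.quantile(ctrl, 0.975))}


def _dosage_matrix(panel: PopulationPanel, snp_ids) -> np.ndarray:
    """Float dosages with missing calls imputed as 2x the individual's own
    population allele frequency."""
    x = panel.dosages(snp_ids).astype(float)
    if (x == MISSING).any():
        idx = panel.snp_indexer().loc[list(snp_ids)].to_numpy()
        for pop in panel.pop_labels:
            rows = panel.pop_mask(pop)
            fill = 2.0 * panel.freqs(pop)[idx]
            block = x[rows]
            miss = block == MISSING
            block[miss] = np.broadcast_to(fill, block.shape)[miss]
            x[rows] = block
    return x


def prs(panel: PopulationPanel, summary: pd.DataFrame, snps=None) -> np.ndarray:
    """Standardized polygenic score per individual.

    ``summary`` must already be harmonized to the panel (betas aligned to
    the alternate allele).  The raw score sum(dosage * beta) is standardized
    to mean 0, s.d. 1 over the combined sample.
    """
    use = summary if snps is None else summary[summary["snp"].isin(set(snps))]
    use = use[use["snp"].isin(panel.snps["snp"])]
    if use.empty:
        raise ValueError("no usable SNPs for the polygenic score")
    x = _dosage_matrix(panel, use["snp"].to_numpy())
    raw = x @ use["b"].to_numpy()
    sd = raw.std()
    if sd == 0:
        raise ValueError("polygenic score has zero variance; cannot standardize")
    return (raw - raw.mean()) / sd


def prs_deviation(scores: np.ndarray, pops: np.ndarray) -> PRSDeviation:
    """Per-population deviation of the mean score from the grand mean.

    The least-squares solution under the population-size weighting:
    ``v_j = mean_j(score) - mu`` with ``mu`` the grand mean, so the
    size-weighted deviations sum to zero exactly.  Standard errors use the
    pooled within-population residual s.d.
    """
    scores = np.asarray(scores, dtype=float)
    pops = np.asarray(pops)
    labels = [p for p in dict.fromkeys(pops) if (pops == p).sum() > 0]
    if len(labels) < 2:
        raise ValueError("need at least two non-empty populations")
    mu = float(scores.mean())
    v, se, n = {}, {}, {}
    rss, df = 0.0, 0
    for pop in labels:
        vals = scores[pops == pop]
        v[pop] = float(vals.mean() - mu)
        n[pop] = len(vals)
        rss += float(((vals - vals.mean()) ** 2).sum())
        df += len(vals) - 1
    s_e = np.sqrt(rss / df) if df > 0 else np.nan
    for pop in labels:
        se[pop] = float(s_e / np.sqrt(n[pop]))
    return PRSDeviation(mu=mu, v=v, se=se, n=n)


def control_band(panel: PopulationPanel, summary: pd.DataFrame, control_sets,
                 quantiles: tuple[float, float] = (0.025, 0.975)):
    """Drift band for v_j: run the PRS + deviation on each control SNP set
    and return per-population (lo, hi) quantiles plus the full draws.

    Equivalent to calling :func:`prs` + :func:`prs_deviation` per set, but
    gathers the dosages of the union of control SNPs once so thousands of
    sets stay cheap.
    """
    beta = summary.drop_duplicates("snp").set_index("snp")["b"]
    union = pd.unique(np.concatenate([np.asarray(s) for s in control_sets]))
    union = pd.Index(union).intersection(beta.index).intersection(
        panel.snps["snp"])
    x_all = _dosage_matrix(panel, union.to_numpy())
    col = pd.Series(np.arange(len(union)), index=union)
    pops = panel.pop_labels
    masks = {p: panel.pop_mask(p) for p in pops}
    draws: dict[str, list[float]] = {p: [] for p in pops}
    for ids in control_sets:
        use = col.reindex(np.asarray(ids)).dropna()
        if use.empty:
            raise ValueError("no usable SNPs for the polygenic score")
        cols = use.to_numpy(dtype=np.intp)
        raw = x_all[:, cols] @ beta.loc[use.index].to_numpy()
        sd = raw.std()
        if sd == 0:
            raise ValueError("polygenic score has zero variance")
        scores = (raw - raw.mean()) / sd
        mu = scores.mean()
        for p in pops:
            draws[p].append(float(scores[masks[p]].mean() - mu))
    band = {pop: (float(np.quantile(vals, quantiles[0])),
                  float(np.quantile(vals, quantiles[1])))
            for pop, vals in draws.items()}
    return band, {pop: np.asarray(vals) for pop, vals in draws.items()}


def ftia(summary: pd.DataFrame, panel: PopulationPanel, snps,
         pops: list[str] | None = None) -> pd.DataFrame:
    """Per-SNP trait-increasing-allele frequency in each population.

    The TIA is the allele with positive harmonized beta (beta = 0 SNPs are
    dropped, logged); for a positive beta it is the panel alternate allele,
    so fTIA = alt frequency, else 1 - alt frequency.
    """
    use = summary[summary["snp"].isin(set(snps))]
    use = use[use["snp"].isin(panel.snps["snp"])]
    if use.empty:
        raise ValueError("no usable SNPs for fTIA")
    zero = use["b"] == 0
    if zero.any():
        logger.info("ftia: dropped %d SNPs with beta = 0 (no defined TIA)",
                    int(zero.sum()))
        use = use[~zero]
    pops = pops or panel.pop_labels
    idx = panel.snp_indexer().loc[use["snp"]].to_numpy()
    pos_beta = (use["b"] > 0).to_numpy()
    out = pd.DataFrame({"snp": use["snp"].to_numpy()})
    for pop in pops:
        f_alt = panel.freqs(pop)[idx]
        out[pop] = np.where(pos_beta, f_alt, 1.0 - f_alt)
    return out


def ftia_contrast(summary: pd.DataFrame, panel: PopulationPanel, snps,
                  pop_a: str, pop_b: str,
                  control_sets=None) -> DirectionResult:
    """Mean fTIA difference between two populations, with the control-set
    null distribution of the difference if control sets are given."""
    tbl = ftia(summary, panel, snps, [pop_a, pop_b])
    means = {pop_a: float(tbl[pop_a].mean()), pop_b: float(tbl[pop_b].mean())}
    delta = means[pop_a] - means[pop_b]
    ctrl = None
    if control_sets is not None:
        ctrl = np.array([
            (lambda t: t[pop_a].mean() - t[pop_b].mean())(
                ftia(summary, panel, ids, [pop_a, pop_b]))
            for ids in control_sets])
    return DirectionResult(pop_a=pop_a, pop_b=pop_b, ftia_mean=means,
                           delta=float(delta), per_snp=tbl, control_deltas=ctrl)
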
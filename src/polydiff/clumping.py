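"""LD-based clumping of GWAS summary statistics.

Greedy index-SNP selection in the PLINK style: candidates below the P-value
threshold are visited in order of ascending P (ties broken by genomic
position); each index SNP absorbs all remaining candidates within the
physical window whose LD r^2 with it (in the reference panel) reaches the
threshold.  The surviving index SNPs are nearly independent: every
within-window pair has r^2 below the threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype_io import MISSING, PopulationPanel

logger = logging.getLogger(__name__)

DEFAULT_CLUMP_R2 = 0.01
DEFAULT_CLUMP_WINDOW_BP = 1_000_000


@dataclass
class ClumpSet:
    """Result of LD clumping: ordered index SNPs, their clump members and
    the parameters used."""

    index_snps: list[str]
    members: dict[str, list[str]]
    params: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.index_snps)

    def to_frame(self, summary: pd.DataFrame | None = None,
                 snps: pd.DataFrame | None = None) -> pd.DataFrame:
        """Report table ``INDEX_SNP [CHR BP] [P] N_MEMBERS MEMBERS``;
        positions come from ``snps`` (a panel's SNP frame) when given."""
        rows = []
        info = (summary.set_index("snp") if summary is not None else None)
        pos = (snps.set_index("snp") if snps is not None else None)
        for snp in self.index_snps:
            row = {"INDEX_SNP": snp}
            if pos is not None and snp in pos.index:
                row["CHR"] = pos.loc[snp, "chrom"]
                row["BP"] = pos.loc[snp, "pos"]
            if info is not None and snp in info.index:
                row["P"] = info.loc[snp, "p"]
            row["N_MEMBERS"] = len(self.members[snp])
            row["MEMBERS"] = ",".join(self.members[snp]) or "."
            rows.append(row)
        return pd.DataFrame(rows)


def clump(summary: pd.DataFrame, reference: PopulationPanel, pop: str,
          p_threshold: float, r2_threshold: float = DEFAULT_CLUMP_R2,
          window_bp: int = DEFAULT_CLUMP_WINDOW_BP) -> ClumpSet:
    """Greedy LD clumping of ``summary`` against a reference panel.

    Parameters
    ----------
    summary
        Harmonized GWAS summary frame (columns ``snp, p`` used here).
    reference, pop
        Panel and population label supplying LD r^2 between candidates.
    p_threshold
        Only SNPs with P below this enter the clumping.
    r2_threshold, window_bp
        A candidate joins an index SNP's clump if it lies within
        ``window_bp`` base pairs (index-to-candidate distance) and its
        dosage r^2 with the index reaches ``r2_threshold``.
    """
    params = dict(p_threshold=p_threshold, r2_threshold=r2_threshold,
                  window_bp=window_bp, reference_pop=pop)
    cand = summary[summary["p"] < p_threshold]
    snp_info = reference.snps.set_index("snp")
    cand = cand[cand["snp"].isin(snp_info.index)]
    if cand.empty:
        logger.warning("clump: no SNPs pass P < %g", p_threshold)
        return ClumpSet([], {}, params)

    ids = cand["snp"].to_numpy()
    chrom = snp_info.loc[ids, "chrom"].to_numpy()
    pos = snp_info.loc[ids, "pos"].to_numpy()
    order = np.lexsort((pos, chrom, cand["p"].to_numpy()))

    # dosages of all candidates in the reference population, mean-centered
    g = reference.dosages(ids)[reference.pop_mask(pop)].astype(float)
    g[g == MISSING] = np.nan
    g = np.nan_to_num(g - np.nanmean(g, axis=0), nan=0.0)
    norm = np.sqrt((g ** 2).sum(axis=0))
    poly = norm > 0
    if not poly.all():
        logger.info("clump: %d candidates monomorphic in reference, kept "
                    "as their own indices", int((~poly).sum()))
    gn = g / np.where(norm == 0, 1.0, norm)

    unassigned = np.ones(len(ids), dtype=bool)
    index_snps: list[str] = []
    members: dict[str, list[str]] = {}
    for k in order:
        if not unassigned[k]:
            continue
        unassigned[k] = False
        index_snps.append(ids[k])
        near = unassigned & (chrom == chrom[k]) & (np.abs(pos - pos[k]) <= window_bp)
        clumped: list[str] = []
        if near.any() and poly[k]:
            r = gn[:, near].T @ gn[:, k]
            hit = np.flatnonzero(near)[(r * r) >= r2_threshold]
            unassigned[hit] = False
            clumped = [ids[i] for i in hit]
        members[ids[k]] = clumped
    return ClumpSet(index_snps, members, params)
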
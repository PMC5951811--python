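"""Canonical study configurations: bundled panel + cohort assets and the
replicate-trait direction study used for calibration and validation runs.

The full-scale design this package emulates ran GWAS on ~54,000 individuals
with 1,000 causal variants (per-causal non-centrality n*h^2/m ~ 27).  The
bundled desk-scale configuration keeps that per-variant signal by scaling
the cohort to 5,000 and the causal count to 100 (non-centrality ~ 25), so
power and calibration behave like the full design at a fraction of the
cost; the full-size trait model (m = 1000) is available by passing a larger
cohort.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import clumping, direction, enrichment, gwas_sim, popgen_stats
from .genotype_io import PopulationPanel, harmonize
from .synthetic_data import DriftPanelSpec, make_cohort, make_drift_panel

logger = logging.getLogger(__name__)


@dataclass
class StudyAssets:
    """Everything repeated trait replicates share: the reference panel with
    its differentiation statistics, the GWAS cohort and the scan engine."""

    panel: PopulationPanel
    cohort: PopulationPanel
    engine: gwas_sim.ScanEngine
    fst: pd.Series
    bins: enrichment.BinIndex
    reference_pop: str


def build_drift_assets(seed: int, n_pops: int = 3,
                       pop_labels: tuple[str, ...] = ("EUR", "AFR", "EAS"),
                       n_per_pop: int = 500, n_snps: int = 20_000,
                       cohort_n: int = 5_000, n_pcs: int = 10,
                       n_pca_snps: int | None = 4_000,
                       matching_mode: str = "maf_and_ld") -> StudyAssets:
    """Generate the drift panel, a GWAS cohort drawn from the first
    population's frequencies, the PC-adjusted scan engine, per-SNP F_ST and
    the MAF/LD matching bins."""
    spec = DriftPanelSpec(n_pops=n_pops, pop_labels=pop_labels,
                          n_per_pop=n_per_pop, n_snps=n_snps, seed=seed)
    panel, freqs = make_drift_panel(spec, return_freqs=True)
    cohort = make_cohort(spec, freqs[0], cohort_n, seed=seed + 1)
    engine = gwas_sim.ScanEngine(cohort, n_pcs=n_pcs, n_pca_snps=n_pca_snps)
    ref = pop_labels[0]
    fst = pd.Series(popgen_stats.fst_per_snp(panel), index=panel.snps["snp"])
    ld = (None if matching_mode == "maf_only"
          else popgen_stats.ld_scores(panel, ref))
    bins = enrichment.build_bins(panel.snps["snp"], panel.maf(ref), ld,
                                 matching_mode=matching_mode)
    return StudyAssets(panel=panel, cohort=cohort, engine=engine, fst=fst,
                       bins=bins, reference_pop=ref)


def direction_drift_study(assets: StudyAssets, n_traits: int = 100,
                          m: int = 100, h2: float = 0.5,
                          p_threshold: float = 5e-6,
                          n_control_sets: int = 200,
                          pop_a: str | None = None, pop_b: str | None = None,
                          seed: int = 0) -> pd.DataFrame:
    """Replicate drift traits through scan -> clump -> direction analyses.

    Per replicate: simulate a polygenic trait on the cohort, run the
    PC-adjusted scan, clump the hits against the reference panel, harmonize,
    and record the mean fTIA difference between two populations plus
    whether each population's polygenic-score deviation v_j falls inside
    its 95% matched-control band.  Under drift the fTIA difference is
    centred on zero and the band should cover ~95% of replicates.
    """
    pops = assets.panel.pop_labels
    pop_a = pop_a or pops[0]
    pop_b = pop_b or pops[1]
    rng = np.random.default_rng(seed)
    spec = gwas_sim.TraitSimSpec(m=m, h2=h2)
    rows = []
    for rep in range(n_traits):
        causals = gwas_sim.sample_causals(assets.cohort, spec, rng=rng)
        y, _ = gwas_sim.simulate_trait(assets.cohort, causals, h2, rng)
        summary = assets.engine.scan(y).summary().dropna(subset=["p"])
        cs = clumping.clump(summary, assets.panel, assets.reference_pop,
                            p_threshold)
        hits = [s for s in cs.index_snps if s in assets.bins.assignment.index]
        row = {"trait": rep, "n_hits": len(hits)}
        if len(hits) >= 2:
            hsum = harmonize(summary, assets.panel)
            res = direction.ftia_contrast(hsum, assets.panel, hits,
                                          pop_a, pop_b)
            row["delta_ftia"] = res.delta
            sets = enrichment.sample_controls(assets.bins, hits,
                                              n_control_sets, rng)
            dev = direction.prs_deviation(
                direction.prs(assets.panel, hsum, hits),
                assets.panel.populations)
            band, _ = direction.control_band(assets.panel, hsum, sets)
            for pop in dev.v:
                row[f"v_{pop}"] = dev.v[pop]
                lo, hi = band[pop]
                row[f"v_in_band_{pop}"] = bool(lo <= dev.v[pop] <= hi)
        rows.append(row)
    return pd.DataFrame(rows)


def direction_summary(study: pd.DataFrame, pops) -> dict:
    """Aggregate a direction study: mean fTIA difference (with its
    Monte-Carlo standard error) and the band coverage of v_j."""
    ok = study.dropna(subset=["delta_ftia"])
    deltas = ok["delta_ftia"].to_numpy()
    cover_cols = [f"v_in_band_{p}" for p in pops
                  if f"v_in_band_{p}" in study.columns]
    coverage = float(ok[cover_cols].to_numpy(dtype=float).mean())
    return {
        "n_replicates": int(len(ok)),
        "mean_delta_ftia": float(deltas.mean()),
        "se_delta_ftia": float(deltas.std(ddof=1) / np.sqrt(len(deltas))),
        "mean_n_hits": float(ok["n_hits"].mean()),
        "v_band_coverage": coverage,
    }
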
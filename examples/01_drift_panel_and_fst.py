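"""Generate a three-population drift panel and measure its differentiation.

Builds a Balding-Nichols panel (the drift null the enrichment test is
calibrated against), applies QC, and prints per-SNP and multi-locus F_ST.
"""

import numpy as np

from polydiff import DriftPanelSpec, fst_per_snp, make_drift_panel, qc_filter
from polydiff.popgen_stats import fst_overall

spec = DriftPanelSpec(n_per_pop=300, n_snps=5000, fst=0.15, seed=1)
panel = make_drift_panel(spec)
panel = qc_filter(panel)
print(f"panel: {panel.n_individuals} individuals x {panel.n_snps} SNPs, "
      f"populations {panel.pop_labels}")

fst = fst_per_snp(panel)
theta, se = fst_overall(panel)
print(f"per-SNP Weir-Cockerham F_ST: median {np.nanmedian(fst):.3f}, "
      f"90% range [{np.nanquantile(fst, 0.05):.3f}, "
      f"{np.nanquantile(fst, 0.95):.3f}]")
print(f"multi-locus estimate: {theta:.4f} +/- {se:.4f}")
# The multi-locus ratio-of-averages recovers the generating F = 0.15;
# individual SNPs scatter widely around it, which is exactly why the
# enrichment test works with matched resampling rather than point values.
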
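"""Independent brute-force oracles used by the test suite.

Each function re-derives a statistic along a different computational route
than the package (scalar loops, exact rational arithmetic, exhaustive
enumeration) so agreement is evidence of correctness, not shared bugs.
"""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np


def hwe_exact_enumeration(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact HWE P by full enumeration with rational arithmetic.

    P(h hets | allele counts) ∝ C(n, h) C(n-h, (nA-h)/2) 2^h over the
    multinomial; summed exactly with Fractions, then the two-sided tail.
    """
    n = n_AA + n_Aa + n_aa
    n_a = 2 * n_AA + n_Aa  # copies of the rarer-or-not allele A
    n_b = 2 * n - n_a
    n_rare = min(n_a, n_b)
    if n_rare == 0:
        return 1.0
    weights = {}
    for h in range(n_rare % 2, n_rare + 1, 2):
        hom_r = (n_rare - h) // 2
        hom_c = n - h - hom_r
        # multinomial coefficient x 2^h (genotype orderings within het)
        w = Fraction(math.factorial(n) * 2 ** h,
                     math.factorial(hom_r) * math.factorial(h)
                     * math.factorial(hom_c))
        weights[h] = w
    total = sum(weights.values())
    p_obs = weights[n_Aa] / total
    tail = sum(w for w in weights.values() if Fraction(w, total) <= p_obs)
    return float(Fraction(tail, total))


def wc_fst_scalar(pop_genotypes: list[np.ndarray]) -> float:
    """Weir & Cockerham (1984) theta-hat for one SNP, written as direct
    scalar transcription of the published equations (r samples, diploid)."""
    r = len(pop_genotypes)
    n_i, p_i, h_i = [], [], []
    for g in pop_genotypes:
        g = np.asarray(g)
        g = g[g >= 0]
        n_i.append(len(g))
        p_i.append(np.mean(g) / 2.0)
        h_i.append(np.mean(g == 1))
    n_i, p_i, h_i = map(np.asarray, (n_i, p_i, h_i))
    nbar = n_i.mean()
    nc = (r * nbar - (n_i ** 2).sum() / (r * nbar)) / (r - 1)
    pbar = (n_i * p_i).sum() / (r * nbar)
    s2 = (n_i * (p_i - pbar) ** 2).sum() / ((r - 1) * nbar)
    hbar = (n_i * h_i).sum() / (r * nbar)
    a = nbar / nc * (s2 - 1 / (nbar - 1)
                     * (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4))
    b = nbar / (nbar - 1) * (pbar * (1 - pbar) - (r - 1) / r * s2
                             - (2 * nbar - 1) / (4 * nbar) * hbar)
    c = hbar / 2
    if a + b + c == 0:
        return float("nan")
    return float(a / (a + b + c))


def grm_brute(genotypes: np.ndarray) -> np.ndarray:
    """GRM by explicit double loop over individual pairs and SNPs."""
    g = np.asarray(genotypes, dtype=float)
    g[g < 0] = np.nan
    n, m = g.shape
    p = np.nanmean(g, axis=0) / 2.0
    out = np.zeros((n, n))
    for j in range(n):
        for k in range(n):
            acc, cnt = 0.0, 0
            for snp in range(m):
                pj = p[snp]
                if pj <= 0 or pj >= 1:
                    continue
                xj, xk = g[j, snp], g[k, snp]
                if np.isnan(xj) or np.isnan(xk):
                    continue
                acc += (xj - 2 * pj) * (xk - 2 * pj) / (2 * pj * (1 - pj))
                cnt += 1
            out[j, k] = acc / cnt if cnt else np.nan
    return out


def r2_brute(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation from the raw covariance formula."""
    ok = (x >= 0) & (y >= 0)
    x, y = x[ok].astype(float), y[ok].astype(float)
    cov = np.mean(x * y) - np.mean(x) * np.mean(y)
    vx = np.mean(x * x) - np.mean(x) ** 2
    vy = np.mean(y * y) - np.mean(y) ** 2
    if vx == 0 or vy == 0:
        return float("nan")
    return float(cov * cov / (vx * vy))


def ld_scores_brute(panel, pop: str, window_bp: int,
                    r2_min: float) -> np.ndarray:
    """O(m^2) double-loop LD scores: all pairs, then window/threshold
    filtering applied afterwards."""
    g = panel.genotypes[panel.pop_mask(pop)]
    m = panel.n_snps
    chrom = panel.snps["chrom"].to_numpy()
    pos = panel.snps["pos"].to_numpy()
    out = np.full(m, np.nan)
    for j in range(m):
        if len(np.unique(g[g[:, j] >= 0, j])) < 2:
            continue
        total = 0.0
        for k in range(m):
            if chrom[k] != chrom[j] or abs(int(pos[k]) - int(pos[j])) > window_bp:
                continue
            r2 = 1.0 if k == j else r2_brute(g[:, j], g[:, k])
            if not np.isnan(r2) and r2 >= r2_min:
                total += r2
        out[j] = total
    return out


def clump_brute(cand: "pd.DataFrame", r2_lookup, r2_threshold: float,
                window_bp: int) -> list[str]:
    """Greedy clumping re-implemented with explicit sets and scalar r^2
    lookups; ``cand`` needs columns snp, p, chrom, pos."""
    import pandas as pd  # noqa: F401  (kept local; oracle-only dependency)

    rows = cand.sort_values(["p", "chrom", "pos"]).to_dict("records")
    unassigned = {r["snp"] for r in rows}
    index = []
    for r in rows:
        if r["snp"] not in unassigned:
            continue
        unassigned.discard(r["snp"])
        index.append(r["snp"])
        for other in rows:
            if other["snp"] not in unassigned:
                continue
            if other["chrom"] != r["chrom"]:
                continue
            if abs(int(other["pos"]) - int(r["pos"])) > window_bp:
                continue
            if r2_lookup(r["snp"], other["snp"]) >= r2_threshold:
                unassigned.discard(other["snp"])
    return index
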
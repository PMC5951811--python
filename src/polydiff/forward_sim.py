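"""Forward Wright-Fisher simulation of background selection in a two-deme
Out-of-Africa-style demography.

Two independent segments are simulated: on segment 1 a fraction of new
mutations (default 5%) is deleterious with selection coefficient s = -0.01
(additive dominance h = 0.5, multiplicative fitness across loci); segment 2
is fully neutral.  The demographic schedule follows the standard
Out-of-Africa model: an ancestral population of 7,310 diploids, African
expansion to 14,474, a European founding bottleneck with subsequent
exponential growth to 34,039 at generation 58,000, with symmetric migration
between the demes.

A rescaling factor ``lambda >= 1`` divides population sizes and times and
multiplies mutation, recombination, selection and migration rates, keeping
theta = 4*N*mu (and the strength of selection relative to drift, N*s)
invariant, so desk-scale runs preserve the expected diversity and the
direction of the background-selection contrast.

The end-point contrast compares mean F_ST (or LDCV) of the fully neutral
segment-2 variants against MAF/LD-matched *non-deleterious* segment-1
variants, some of which are linked to deleterious mutations: background
selection inflates differentiation on segment 1.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import enrichment, popgen_stats
from .genotype_io import PopulationPanel

logger = logging.getLogger(__name__)

# Out-of-Africa model constants (diploid sizes; times in generations before
# the end of a 58,000-generation run; migration per gamete per generation)
N_ANCESTRAL = 7_310
N_AFR = 14_474
N_OOA_BOTTLENECK = 1_861
N_EUR_FOUNDING = 1_032
N_EUR_FINAL = 34_039
T_TOTAL = 58_000
T_AFR_EXPAND_BEFORE_END = 5_920
T_SPLIT_BEFORE_END = 2_040
T_EUR_GROWTH_BEFORE_END = 920
M_AFR_OOA = 15e-5
M_AFR_EUR = 2.5e-5


@dataclass
class DemographySchedule:
    """Scaled two-deme demographic schedule (deme 0 = AFR, deme 1 = EUR)."""

    lam: float
    n_generations: int
    t_afr_expand: int
    t_split: int
    t_eur_growth: int
    n_ancestral: int
    n_afr: int
    n_bottleneck: int
    n_eur0: int
    n_eur_final: int
    m_split: float
    m_growth: float

    @property
    def growth_rate(self) -> float:
        span = self.n_generations - self.t_eur_growth
        return math.log(self.n_eur_final / self.n_eur0) / span

    def deme_sizes(self, gen: int) -> tuple[int, int | None]:
        """Diploid sizes (AFR, EUR-or-None) of the generation born at
        ``gen`` (1-based; gen == n_generations is the final one)."""
        n0 = self.n_ancestral if gen < self.t_afr_expand else self.n_afr
        if gen < self.t_split:
            return n0, None
        if gen < self.t_eur_growth:
            return n0, self.n_bottleneck
        t = gen - self.t_eur_growth
        return n0, int(round(self.n_eur0 * math.exp(self.growth_rate * t)))

    def migration(self, gen: int) -> float:
        if gen < self.t_split:
            return 0.0
        if gen < self.t_eur_growth:
            return self.m_split
        return self.m_growth

    @property
    def terminal_sizes(self) -> dict[str, int]:
        n0, n1 = self.deme_sizes(self.n_generations)
        return {"AFR": n0, "EUR": n1}


def build_schedule(lam: float = 1.0) -> DemographySchedule:
    """Build the Out-of-Africa schedule rescaled by ``lam``.

    Sizes and times are divided by lam (rounded); migration is multiplied.
    Mutation/recombination/selection scaling is applied by the simulator
    (which reads ``schedule.lam``).
    """
    if lam < 1:
        raise ValueError("lambda must be >= 1")

    def size(x: int) -> int:
        v = int(round(x / lam))
        if v < 2:
            raise ValueError(f"lambda={lam} scales deme size {x} below 2")
        return v

    n_gen = int(round(T_TOTAL / lam))
    return DemographySchedule(
        lam=lam,
        n_generations=n_gen,
        t_afr_expand=n_gen - int(round(T_AFR_EXPAND_BEFORE_END / lam)),
        t_split=n_gen - int(round(T_SPLIT_BEFORE_END / lam)),
        t_eur_growth=n_gen - int(round(T_EUR_GROWTH_BEFORE_END / lam)),
        n_ancestral=size(N_ANCESTRAL),
        n_afr=size(N_AFR),
        n_bottleneck=size(N_OOA_BOTTLENECK),
        n_eur0=size(N_EUR_FOUNDING),
        n_eur_final=size(N_EUR_FINAL),
        m_split=min(1.0, M_AFR_OOA * lam),
        m_growth=min(1.0, M_AFR_EUR * lam),
    )


@dataclass
class ForwardSimSpec:
    """Mutation/selection/recombination configuration (unscaled rates;
    the schedule's lambda rescales them inside the simulator)."""

    segment_lengths: tuple[int, int] = (100_000, 100_000)
    mutation_rate: float = 2.36e-8       # per bp per generation
    deleterious_fraction: float = 0.05   # of new segment-1 mutations
    s: float = -0.01                     # selection coefficient, deleterious
    dominance: float = 0.5               # additive
    recombination_rate: float = 1e-8     # per bp per generation
    sample_per_deme: int = 500

    def __post_init__(self) -> None:
        if self.s > 0:
            raise ValueError("deleterious class needs s <= 0")
        if not (0 <= self.deleterious_fraction <= 1):
            raise ValueError("deleterious fraction must be a probability")


class _State:
    """Per-segment haplotype matrices plus per-site annotations.

    The two segments are unlinked, so each lives in its own contiguous
    (2N x S_seg) uint8 matrix — row gathers during reproduction then avoid
    slow mixed row/column fancy indexing.  ``deleterious`` annotates
    segment-1 sites only (segment 2 is fully neutral).
    """

    __slots__ = ("haps", "positions", "deleterious", "deme_sizes")

    def __init__(self, n0: int):
        self.haps = [np.zeros((2 * n0, 0), dtype=np.uint8) for _ in range(2)]
        self.positions = [np.zeros(0) for _ in range(2)]
        self.deleterious = np.zeros(0, dtype=bool)
        self.deme_sizes = [n0, 0]


def _fitness(state: _State, s: float, h: float) -> np.ndarray:
    if not state.deleterious.any():
        return np.ones(state.haps[0].shape[0] // 2)
    hap = state.haps[0][:, state.deleterious]
    g = hap[0::2].astype(np.int16) + hap[1::2]
    log_w = ((g == 1).sum(axis=1) * math.log1p(h * s)
             + (g == 2).sum(axis=1) * math.log1p(s))
    return np.exp(log_w)


def run_forward(spec: ForwardSimSpec, schedule: DemographySchedule,
                seed: int):
    """Run the forward simulation; returns (panel, variant classes).

    The panel holds ``sample_per_deme`` diploids per deme (populations
    "AFR" and "EUR", segments on chromosomes "1" and "2"); the classes
    frame records each variant's segment, mutation class and selection
    coefficient.
    """
    rng = np.random.default_rng(seed)
    lam = schedule.lam
    mu = spec.mutation_rate * lam
    rr = spec.recombination_rate * lam
    s_scaled = spec.s * lam
    if s_scaled <= -1:
        raise ValueError("scaled selection coefficient reaches -1; reduce lambda")
    l1, l2 = spec.segment_lengths
    l_tot = l1 + l2

    state = _State(schedule.deme_sizes(0)[0])
    for gen in range(1, schedule.n_generations + 1):
        state = _advance(state, schedule, gen, rng, mu, rr, s_scaled,
                         spec.dominance, spec.deleterious_fraction, l1, l_tot)
    return _sample_panel(state, spec, s_scaled, l1, rng)


def _advance(state: _State, schedule: DemographySchedule, gen: int,
             rng: np.random.Generator, mu: float, rr: float, s: float,
             h: float, del_fraction: float, l1: int, l_tot: int) -> _State:
    n0_new, n1_new = schedule.deme_sizes(gen)
    n1_new = n1_new or 0
    n_off = n0_new + n1_new
    mig = schedule.migration(gen)

    w = _fitness(state, s, h)
    cur0, cur1 = state.deme_sizes
    probs = []
    for lo, hi in ((0, cur0), (cur0, cur0 + cur1)):
        wd = w[lo:hi]
        tot = wd.sum()
        if hi > lo and tot == 0:
            raise RuntimeError(
                f"population extinct under selection load at generation {gen}")
        probs.append(wd / tot if hi > lo else None)

    # two gametes per offspring; migrant gametes take a parent from the
    # other deme (deme 1 exists only after the split)
    parent = np.empty(2 * n_off, dtype=np.int64)
    slot_deme = np.repeat([0, 1], [2 * n0_new, 2 * n1_new])
    both = cur1 > 0
    for d in (0, 1):
        slots = np.flatnonzero(slot_deme == d)
        if len(slots) == 0:
            continue
        src = np.full(len(slots), d if (d == 0 or both) else 0)
        if both and mig > 0:
            flip = rng.random(len(slots)) < mig
            src[flip] = 1 - src[flip]
        for sd in (0, 1):
            take = slots[src == sd]
            if len(take) == 0:
                continue
            base = 0 if sd == 0 else cur0
            parent[take] = base + rng.choice(
                len(probs[sd]), size=len(take), p=probs[sd])

    # each segment assorts independently: per-gamete haplotype choice,
    # contiguous row gathers, then the (rare) within-segment crossovers
    out = _State.__new__(_State)
    out.haps, out.positions = [None, None], [None, None]
    out.deme_sizes = [n0_new, n1_new]
    seg_lengths = (float(l1), float(l_tot - l1))
    count_dtype = np.uint16 if 2 * n_off < 60000 else np.int64
    for si in (0, 1):
        hap = state.haps[si]
        pos = state.positions[si]
        hsel = rng.integers(0, 2, size=2 * n_off, dtype=np.int64)
        child = hap[2 * parent + hsel]
        n_co = rng.poisson(rr * seg_lengths[si], size=2 * n_off)
        for g in np.flatnonzero(n_co):
            breaks = np.sort(rng.uniform(0.0, seg_lengths[si], size=n_co[g]))
            swap = (np.searchsorted(breaks, pos) % 2) == 1
            other = hap[2 * parent[g] + 1 - hsel[g]]
            child[g, swap] = other[swap]

        # prune fixed/lost variants and append new mutations in one pass
        # (a fixed deleterious variant scales all fitnesses equally, so
        # dropping it is exact; new mutations are singletons, always kept)
        counts = child.sum(axis=0, dtype=count_dtype)
        keep = (counts > 0) & (counts < 2 * n_off)
        nk = int(keep.sum())
        k = rng.poisson(2 * n_off * mu * seg_lengths[si])
        merged = np.zeros((2 * n_off, nk + k), dtype=np.uint8)
        np.compress(keep, child, axis=1, out=merged[:, :nk])
        pos_kept = pos[keep]
        if k:
            rows = rng.integers(0, 2 * n_off, size=k)
            merged[rows, nk + np.arange(k)] = 1
            pos_kept = np.concatenate(
                [pos_kept, rng.uniform(0.0, seg_lengths[si], size=k)])
        out.haps[si] = merged
        out.positions[si] = pos_kept
        if si == 0:
            dele = state.deleterious[keep]
            if k:
                dele = np.concatenate([dele, rng.random(k) < del_fraction])
            out.deleterious = dele
    return out


def _sample_panel(state: _State, spec: ForwardSimSpec, s_scaled: float,
                  l1: int, rng: np.random.Generator):
    n0, n1 = state.deme_sizes
    take0 = np.sort(rng.choice(n0, size=min(spec.sample_per_deme, n0),
                               replace=False))
    take1 = n0 + np.sort(rng.choice(n1, size=min(spec.sample_per_deme, n1),
                                    replace=False))
    idx = np.concatenate([take0, take1])
    hap = np.concatenate(state.haps, axis=1)
    geno = (hap[2 * idx].astype(np.int8) + hap[2 * idx + 1])
    pops = np.array(["AFR"] * len(take0) + ["EUR"] * len(take1), dtype=object)
    samples = [f"{p}_{i}" for i, p in enumerate(pops)]

    s1 = state.haps[0].shape[1]
    seg = np.repeat([1, 2], [s1, state.haps[1].shape[1]])
    bp = np.concatenate(state.positions).astype(np.int64) + 1
    dele = np.concatenate([state.deleterious,
                           np.zeros(state.haps[1].shape[1], dtype=bool)])
    order = np.lexsort((bp, seg))
    seg, bp = seg[order], bp[order]
    geno = geno[:, order]
    dele = dele[order]
    # drop bp collisions from the continuous-coordinate discretization
    dup = np.zeros(len(bp), dtype=bool)
    dup[1:] = (seg[1:] == seg[:-1]) & (bp[1:] == bp[:-1])
    seg, bp, geno, dele = seg[~dup], bp[~dup], geno[:, ~dup], dele[~dup]

    snps = pd.DataFrame({
        "snp": [f"v{i:06d}" for i in range(len(bp))],
        "chrom": seg.astype(str), "pos": bp,
        "ref": "A", "alt": "G"})
    panel = PopulationPanel(geno, samples, pops, snps)
    classes = pd.DataFrame({
        "snp": snps["snp"], "segment": seg,
        "cls": np.where(dele, "deleterious", "neutral"),
        "s": np.where(dele, s_scaled, 0.0)})
    return panel, classes


@dataclass
class BGSContrast:
    """Replicate-level neutral-vs-linked comparison."""

    mean_fst_neutral: float
    mean_fst_linked: float
    mean_ldcv_neutral: float
    mean_ldcv_linked: float
    n_neutral: int
    n_pool: int

    @property
    def fst_diff(self) -> float:
        return self.mean_fst_linked - self.mean_fst_neutral

    @property
    def ldcv_diff(self) -> float:
        return self.mean_ldcv_linked - self.mean_ldcv_neutral


def bgs_contrast(panel: PopulationPanel, classes: pd.DataFrame,
                 n_sets: int = 200, seed: int = 0,
                 matching_pop: str = "AFR",
                 maf_min: float = 0.01) -> BGSContrast:
    """Compare segment-2 neutral variants with MAF/LD-matched non-deleterious
    segment-1 variants on mean F_ST and mean LDCV.

    Matching reuses the enrichment binning (MAF x LD-score cells, taken from
    ``matching_pop``); bins are coarsened automatically until every
    segment-2 cell has segment-1 candidates.  Common variants only
    (MAF > ``maf_min`` in each deme's sample).
    """
    common = np.ones(panel.n_snps, dtype=bool)
    for pop in panel.pop_labels:
        common &= panel.maf(pop) > maf_min
    cls = classes.set_index("snp")
    ids = panel.snps["snp"].to_numpy()
    seg = cls.loc[ids, "segment"].to_numpy()
    kind = cls.loc[ids, "cls"].to_numpy()
    neutral2 = common & (seg == 2)
    pool1 = common & (seg == 1) & (kind == "neutral")
    if neutral2.sum() < 2 or pool1.sum() < 2:
        raise ValueError("too few common variants for the contrast")

    fst = pd.Series(popgen_stats.fst_per_snp(panel), index=ids)
    lds = {pop: popgen_stats.ld_scores(panel, pop) for pop in panel.pop_labels}
    ldcv = pd.Series(popgen_stats.ldcv(lds), index=ids)
    maf = panel.maf(matching_pop)
    ld_match = lds[matching_pop]

    use = neutral2 | pool1
    targets = ids[neutral2]
    pool_ids = ids[pool1]
    rng = np.random.default_rng(seed)
    for nm, nl in ((10, 4), (5, 2), (2, 1), (1, 1)):
        bins = enrichment.build_bins(ids[use], maf[use], ld_match[use],
                                     n_maf_bins=nm, n_ld_bins=nl)
        tgt = [t for t in targets if t in bins.assignment.index]
        pl = [p for p in pool_ids if p in bins.assignment.index]
        t_cells = set(bins.assignment.loc[tgt])
        p_cells = set(bins.assignment.loc[pl])
        if t_cells <= p_cells:
            break
        logger.warning("bgs_contrast: empty matched cells at %dx%d bins; "
                       "widening", nm, nl)
    sets = enrichment.sample_controls(
        bins, tgt, n_sets=n_sets, seed=rng, pool=np.asarray(pl))
    linked_fst = float(np.mean([fst.reindex(s).mean() for s in sets]))
    linked_ldcv = float(np.mean([ldcv.reindex(s).mean() for s in sets]))
    return BGSContrast(
        mean_fst_neutral=float(fst.reindex(tgt).mean()),
        mean_fst_linked=linked_fst,
        mean_ldcv_neutral=float(ldcv.reindex(tgt).mean()),
        mean_ldcv_linked=linked_ldcv,
        n_neutral=len(tgt), n_pool=len(pl))


def run_forward_study(spec: ForwardSimSpec, schedule: DemographySchedule,
                      n_replicates: int, seed: int) -> pd.DataFrame:
    """Replicated forward simulations plus the neutral-vs-linked contrast;
    one row per replicate."""
    rows = []
    for rep in range(n_replicates):
        panel, classes = run_forward(spec, schedule, seed=seed + rep)
        c = bgs_contrast(panel, classes, seed=seed + rep)
        rows.append({"replicate": rep,
                     "fst_neutral": c.mean_fst_neutral,
                     "fst_linked": c.mean_fst_linked,
                     "fst_diff": c.fst_diff,
                     "ldcv_neutral": c.mean_ldcv_neutral,
                     "ldcv_linked": c.mean_ldcv_linked,
                     "ldcv_diff": c.ldcv_diff,
                     "n_neutral": c.n_neutral, "n_pool": c.n_pool})
    return pd.DataFrame(rows)
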
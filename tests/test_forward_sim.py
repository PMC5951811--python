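"""Wright-Fisher forward simulator: demographic schedule, neutral
expectations, selection effects and determinism."""

import numpy as np
import pytest

from polydiff import forward_sim as fs
from polydiff import popgen_stats


def constant_schedule(n: int, n_gen: int, split_at: int | None = None,
                      n1: int | None = None, mig: float = 0.0):
    """Minimal schedule for controlled experiments: one deme of size n,
    optionally splitting into a second deme of size n1."""
    far = n_gen + 1
    return fs.DemographySchedule(
        lam=1.0, n_generations=n_gen, t_afr_expand=far,
        t_split=split_at if split_at is not None else far,
        t_eur_growth=far, n_ancestral=n, n_afr=n,
        n_bottleneck=n1 or n, n_eur0=n1 or n, n_eur_final=n1 or n,
        m_split=mig, m_growth=mig)


class TestSchedule:
    def test_printed_sizes_at_lambda_one(self):
        s = fs.build_schedule(1.0)
        assert s.terminal_sizes == {"AFR": 14474, "EUR": 34039}
        assert s.deme_sizes(0) == (7310, None)
        assert s.n_generations == 58000

    def test_lambda_scaling_identity(self):
        s = fs.build_schedule(10.0)
        assert s.n_generations == 5800
        assert s.terminal_sizes == {"AFR": 1447, "EUR": 3404}
        assert s.deme_sizes(0) == (731, None)
        # theta = 4 N mu is preserved: sizes / 10, rates * 10 in run_forward
        assert s.m_split == pytest.approx(15e-5 * 10)

    def test_overscaled_errors(self):
        with pytest.raises(ValueError):
            fs.build_schedule(1000.0)
        with pytest.raises(ValueError):
            fs.build_schedule(0.5)


class TestNeutralExpectations:
    def test_pairwise_diversity_matches_theta(self):
        """Constant-size neutral run: mean pairwise diversity per site
        approaches theta = 4 N mu."""
        n, mu, length = 100, 5e-7, 40_000
        spec = fs.ForwardSimSpec(segment_lengths=(length, length),
                                 mutation_rate=mu, deleterious_fraction=0.0,
                                 s=0.0, recombination_rate=1e-8,
                                 sample_per_deme=50)
        sched = constant_schedule(n, 900)
        pis = []
        for seed in range(6):
            panel, _ = fs.run_forward(spec, sched, seed=seed)
            g = panel.genotypes[panel.pop_mask("AFR")]
            nh = 2 * g.shape[0]
            p = g.sum(axis=0) / nh
            pi = (2 * p * (1 - p) * nh / (nh - 1)).sum() / (2 * length)
            pis.append(pi)
        theta = 4 * n * mu
        mean, se = np.mean(pis), np.std(pis, ddof=1) / np.sqrt(len(pis))
        assert abs(mean - theta) < 3 * max(se, 0.05 * theta)

    def test_post_split_fst_grows_like_drift(self):
        """Two demes without migration: E[F_ST] ~ 1 - exp(-t/2N)."""
        n, t_split, t_end = 150, 200, 500
        spec = fs.ForwardSimSpec(segment_lengths=(30_000, 30_000),
                                 mutation_rate=1e-6, deleterious_fraction=0.0,
                                 s=0.0, sample_per_deme=100)
        sched = constant_schedule(n, t_end, split_at=t_split, n1=n, mig=0.0)
        vals = []
        for seed in range(4):
            panel, _ = fs.run_forward(spec, sched, seed=100 + seed)
            common = panel.maf() > 0.05
            theta, _ = popgen_stats.fst_overall(panel.subset_snps(common))
            vals.append(theta)
        expected = 1 - np.exp(-(t_end - t_split) / (2 * n))
        assert np.mean(vals) == pytest.approx(expected, abs=0.2)

    def test_fixed_seed_identical_output(self):
        spec = fs.ForwardSimSpec(segment_lengths=(20_000, 20_000),
                                 mutation_rate=1e-6, s=-0.01,
                                 sample_per_deme=30)
        sched = constant_schedule(80, 300)
        p1, c1 = fs.run_forward(spec, sched, seed=42)
        p2, c2 = fs.run_forward(spec, sched, seed=42)
        np.testing.assert_array_equal(p1.genotypes, p2.genotypes)
        assert c1.equals(c2)


class TestSelection:
    def test_deleterious_spectrum_shifted_rare(self):
        """Deleterious variants should segregate at lower frequencies than
        neutral ones in the same runs."""
        spec = fs.ForwardSimSpec(segment_lengths=(60_000, 60_000),
                                 mutation_rate=1e-6,
                                 deleterious_fraction=0.3, s=-0.08,
                                 sample_per_deme=100)
        sched = constant_schedule(150, 700)
        del_maf, neu_maf = [], []
        for seed in range(4):
            panel, classes = fs.run_forward(spec, sched, seed=seed)
            maf = panel.maf()
            dele = classes.set_index("snp").loc[panel.snps["snp"], "cls"]
            dele = (dele == "deleterious").to_numpy()
            del_maf.extend(maf[dele])
            neu_maf.extend(maf[~dele])
        assert np.mean(del_maf) < np.mean(neu_maf)

    def test_frequencies_bounded(self):
        spec = fs.ForwardSimSpec(segment_lengths=(20_000, 20_000),
                                 mutation_rate=2e-6, deleterious_fraction=0.2,
                                 s=-0.05, sample_per_deme=50)
        panel, _ = fs.run_forward(spec, constant_schedule(60, 250), seed=7)
        f = panel.freqs()
        assert ((f >= 0) & (f <= 1)).all()
        # fixed/lost variants pruned: the population itself is polymorphic,
        # though a finite sample may still be monomorphic at some sites
        assert panel.n_snps > 0


class TestBackgroundSelectionMechanism:
    def test_linked_neutral_diversity_reduced(self):
        """Where the deleterious load is non-negligible (U_del/s ~ 0.36),
        purifying selection depresses nucleotide diversity at *neutral*
        variants on the selected segment relative to the fully neutral
        segment — the background-selection mechanism itself."""
        spec = fs.ForwardSimSpec(segment_lengths=(60_000, 60_000),
                                 mutation_rate=1e-6,
                                 deleterious_fraction=0.3, s=-0.05,
                                 recombination_rate=1e-6,
                                 sample_per_deme=100)
        sched = constant_schedule(200, 900)
        ratios = []
        for seed in range(4):
            panel, classes = fs.run_forward(spec, sched, seed=600 + seed)
            cls = classes.set_index("snp")
            seg = cls.loc[panel.snps["snp"], "segment"].to_numpy()
            kind = cls.loc[panel.snps["snp"], "cls"].to_numpy()
            f = panel.freqs()
            pi = 2 * f * (1 - f)
            pi1 = pi[(seg == 1) & (kind == "neutral")].sum()
            pi2 = pi[seg == 2].sum()
            ratios.append(pi1 / pi2)
        assert np.mean(ratios) < 0.85


class TestBgsContrast:
    def test_neutral_segments_no_systematic_difference(self):
        """With s = 0 both segments are exchangeable; the matched contrast
        should be centred on zero."""
        spec = fs.ForwardSimSpec(segment_lengths=(40_000, 40_000),
                                 mutation_rate=2e-6, deleterious_fraction=0.05,
                                 s=0.0, sample_per_deme=100)
        # shallow split with migration keeps polymorphism shared, so both
        # segments retain enough common variants for the matched contrast
        sched = constant_schedule(150, 500, split_at=420, n1=150, mig=0.01)
        diffs = []
        for seed in range(5):
            panel, classes = fs.run_forward(spec, sched, seed=200 + seed)
            c = fs.bgs_contrast(panel, classes, n_sets=100, seed=seed)
            diffs.append(c.fst_diff)
        spread = np.std(diffs, ddof=1)
        assert abs(np.mean(diffs)) < max(3 * spread / np.sqrt(len(diffs)),
                                         0.01)
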
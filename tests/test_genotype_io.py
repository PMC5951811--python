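"""Panel I/O, QC filters, relatedness and harmonization."""

import numpy as np
import pandas as pd
import pytest

from polydiff import genotype_io as gio
from conftest import build_panel, random_panel
from oracles import grm_brute, hwe_exact_enumeration

VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3\n")


def _pop_map(samples, pop="EUR"):
    return pd.Series([pop] * len(samples), index=samples)


class TestVCF:
    def test_read_basic_freq_and_triallelic_drop(self, tmp_path):
        vcf = tmp_path / "t.vcf"
        vcf.write_text(
            VCF_HEADER
            + "1\t100\tsnp1\tA\tG\t.\t.\t.\tGT\t0/0\t0/1\t1/1\n"
            + "1\t200\tsnp2\tA\tC,T\t.\t.\t.\tGT\t0/0\t0/1\t1/1\n"
            + "1\t300\tsnp3\tA\tT\t.\t.\t.\tGT\t./.\t0/1\t1/1\n")
        panel = gio.read_vcf(vcf, _pop_map(["S1", "S2", "S3"]))
        assert panel.snps["snp"].tolist() == ["snp1", "snp3"]  # triallelic out
        assert panel.freqs()[0] == pytest.approx(0.5)
        np.testing.assert_array_equal(panel.genotypes[:, 1], [-1, 1, 2])
        assert panel.freqs()[1] == pytest.approx(0.75)  # non-missing only

    def test_unknown_sample_errors(self, tmp_path):
        vcf = tmp_path / "t.vcf"
        vcf.write_text(VCF_HEADER + "1\t100\tsnp1\tA\tG\t.\t.\t.\tGT\t0/0\t0/1\t1/1\n")
        with pytest.raises(ValueError, match="missing from population map"):
            gio.read_vcf(vcf, pd.Series({"S1": "EUR", "S2": "EUR"}))

    def test_roundtrip_random_panel(self, tmp_path, rng):
        panel = random_panel(rng, n_per_pop=25, n_snps=200, missing_rate=0.03)
        gio.write_vcf(panel, tmp_path / "rt.vcf")
        gio.write_pop_map(panel, tmp_path / "rt.pop")
        back = gio.read_panel(tmp_path / "rt.vcf", "vcf", tmp_path / "rt.pop")
        np.testing.assert_array_equal(back.genotypes, panel.genotypes)
        assert back.snps["snp"].tolist() == panel.snps["snp"].tolist()
        assert list(back.populations) == list(panel.populations)


class TestPlink:
    @staticmethod
    def _write_plink(panel, prefix):
        """Independent PLINK-1 writer (A1 = alt): encodes each dosage with
        the published 2-bit codes, acting as an oracle for the reader."""
        code = {2: 0b00, -1: 0b01, 1: 0b10, 0: 0b11}
        n, m = panel.n_individuals, panel.n_snps
        with open(f"{prefix}.fam", "w") as fh:
            for s in panel.samples:
                fh.write(f"F {s} 0 0 0 -9\n")
        with open(f"{prefix}.bim", "w") as fh:
            for r in panel.snps.itertuples():
                fh.write(f"{r.chrom} {r.snp} 0 {r.pos} {r.alt} {r.ref}\n")
        body = bytearray([0x6C, 0x1B, 0x01])
        for j in range(m):
            for byte_start in range(0, n, 4):
                b = 0
                for k, i in enumerate(range(byte_start, min(byte_start + 4, n))):
                    b |= code[int(panel.genotypes[i, j])] << (2 * k)
                body.append(b)
        with open(f"{prefix}.bed", "wb") as fh:
            fh.write(bytes(body))

    def test_bed_roundtrip(self, tmp_path, rng):
        panel = random_panel(rng, n_per_pop=11, n_snps=30, missing_rate=0.05)
        self._write_plink(panel, tmp_path / "p")
        pm = pd.Series(list(panel.populations), index=panel.samples)
        back = gio.read_plink(str(tmp_path / "p"), pm)
        np.testing.assert_array_equal(back.genotypes, panel.genotypes)
        assert back.snps["snp"].tolist() == panel.snps["snp"].tolist()


class TestHWE:
    @pytest.mark.parametrize("counts", [
        (0, 100, 0), (25, 50, 25), (50, 0, 50), (3, 14, 17), (1, 1, 1),
        (40, 20, 40), (0, 1, 30), (7, 0, 2)])
    def test_matches_exact_enumeration(self, counts):
        assert gio.hwe_exact_p(*counts) == pytest.approx(
            hwe_exact_enumeration(*counts), rel=1e-9)

    def test_extreme_and_degenerate(self):
        assert gio.hwe_exact_p(0, 100, 0) < 1e-6
        assert gio.hwe_exact_p(25, 50, 25) > 0.8   # modal configuration
        assert gio.hwe_exact_p(10, 0, 0) == 1.0    # monomorphic
        with pytest.raises(ValueError):
            gio.hwe_exact_p(0, 0, 0)


class TestQCFilter:
    def test_per_population_maf_rule(self):
        # SNP 0: alt freq 0.005 in P1 (1 het in 100) but common in P2;
        # SNP 1 is HWE-consistent and common everywhere
        hwe_ok = np.array([0, 1, 2, 1] * 25, dtype=np.int8)
        g1 = np.zeros((100, 2), dtype=np.int8)
        g1[0, 0] = 1
        g1[:, 1] = hwe_ok
        g2 = np.column_stack([hwe_ok, hwe_ok])
        panel = build_panel(np.vstack([g1, g2]), ["P1"] * 100 + ["P2"] * 100)
        out = gio.qc_filter(panel)
        assert out.snps["snp"].tolist() == ["s1"]

    def test_hwe_violation_removed(self):
        # (AA=50, Aa=0, aa=50) is an extreme heterozygote deficit
        bad = np.array([0] * 50 + [2] * 50, dtype=np.int8)
        ok = np.array(([0, 1, 2, 1] * 25), dtype=np.int8)
        panel = build_panel(np.column_stack([bad, ok]), ["P1"] * 100)
        assert gio.hwe_exact_p(50, 0, 50) < 1e-6
        out = gio.qc_filter(panel)
        assert out.snps["snp"].tolist() == ["s1"]

    def test_identity_and_idempotence(self, rng):
        panel = random_panel(rng, n_per_pop=120, n_snps=40)
        once = gio.qc_filter(panel)
        twice = gio.qc_filter(once)
        np.testing.assert_array_equal(once.genotypes, twice.genotypes)

    def test_all_removed_errors(self):
        g = np.zeros((60, 1), dtype=np.int8)
        g[0, 0] = 1  # MAF < 0.01
        panel = build_panel(g, ["P1"] * 60)
        with pytest.raises(ValueError, match="removed all SNPs"):
            gio.qc_filter(panel)


class TestGRM:
    def test_single_snp_forced_value(self):
        panel = build_panel([[0], [2]], ["P1", "P1"])
        grm = gio.compute_grm(panel, "P1")
        assert grm[0, 1] == pytest.approx(-2.0)

    def test_matches_brute_force(self, rng):
        panel = random_panel(rng, n_per_pop=5, n_snps=20, pops=("P1",),
                             missing_rate=0.05)
        grm = gio.compute_grm(panel, "P1")
        ref = grm_brute(panel.genotypes)
        np.testing.assert_allclose(grm, ref, atol=1e-10)

    def test_identical_twins(self, rng):
        g = rng.binomial(2, 0.4, size=(1, 25)).astype(np.int8)
        panel = build_panel(np.vstack([g, g, rng.binomial(2, 0.4, (3, 25))]),
                            ["P1"] * 5)
        grm = gio.compute_grm(panel, "P1")
        assert grm[0, 1] == pytest.approx(grm[0, 0])


class TestPruneRelated:
    def test_unrelated_unchanged(self, rng):
        panel = random_panel(rng, n_per_pop=40, n_snps=500, pops=("P1",))
        out = gio.prune_related(panel, "P1", threshold=0.5)
        assert out.n_individuals == panel.n_individuals

    def test_duplicate_removed_and_clique(self, rng):
        base = rng.binomial(2, rng.uniform(0.2, 0.8, 300),
                            size=(8, 300)).astype(np.int8)
        dup = np.vstack([base, base[:1]])  # individual 8 duplicates 0
        panel = build_panel(dup, ["P1"] * 9)
        out = gio.prune_related(panel, "P1", threshold=0.5)
        assert out.n_individuals == 8
        grm = gio.compute_grm(out, "P1")
        off = grm[~np.eye(out.n_individuals, dtype=bool)]
        assert (off <= 0.5).all()  # exhaustive post-hoc pair scan

    def test_triplet_clique_minimal_removal(self, rng):
        base = rng.binomial(2, rng.uniform(0.2, 0.8, 400),
                            size=(6, 400)).astype(np.int8)
        trip = np.vstack([base, base[:1], base[:1]])  # 0, 6, 7 identical
        panel = build_panel(trip, ["P1"] * 8)
        out = gio.prune_related(panel, "P1", threshold=0.5)
        assert out.n_individuals == 6  # 2 of the 3-clique removed
        grm = gio.compute_grm(out, "P1")
        off = grm[~np.eye(out.n_individuals, dtype=bool)]
        assert (off <= 0.5).all()


class TestPCAOutlier:
    def test_divergent_targets_removed(self, rng):
        m = 400
        anc = rng.uniform(0.2, 0.8, m)
        ref = rng.binomial(2, anc, size=(80, m)).astype(np.int8)
        same = rng.binomial(2, anc, size=(30, m)).astype(np.int8)
        # strongly diverged frequencies for the outlier group
        div = np.clip(anc + rng.choice([-0.35, 0.35], m), 0.02, 0.98)
        other = rng.binomial(2, div, size=(5, m)).astype(np.int8)
        panel = build_panel(np.vstack([ref, same, other]),
                            ["REF"] * 80 + ["T"] * 35,
                            chrom=["1"] * m, pos=list(range(1000, 1000 + m)))
        targets = [f"i{k}" for k in range(80, 115)]
        kept = gio.pca_outlier_filter(panel, "REF", targets, n_pcs=2)
        outliers = set(targets[30:])
        assert not outliers & set(kept)
        assert len(set(targets[:30]) & set(kept)) >= 27  # most same-pop kept

    def test_infinite_limit_keeps_all(self, rng):
        panel = random_panel(rng, n_per_pop=30, n_snps=100, pops=("REF", "T"))
        targets = [s for s, p in zip(panel.samples, panel.populations)
                   if p == "T"]
        kept = gio.pca_outlier_filter(panel, "REF", targets, n_pcs=2,
                                      sd_limit=np.inf)
        assert kept == targets


class TestHarmonize:
    @pytest.fixture
    def panel(self):
        return build_panel([[0, 1, 2], [1, 2, 0], [2, 0, 1]], ["P1"] * 3,
                           ref="A", alt="G")

    def test_flip_and_keep(self, panel):
        summary = pd.DataFrame({
            "snp": ["s0", "s1"], "a1": ["G", "A"], "a2": ["A", "G"],
            "freq": [0.5, 0.3], "b": [0.2, 0.3], "se": 0.1, "p": 0.5, "n": 100})
        out = gio.harmonize(summary, panel)
        assert out.loc[out.snp == "s0", "b"].item() == pytest.approx(0.2)
        assert out.loc[out.snp == "s1", "b"].item() == pytest.approx(-0.3)
        assert out.loc[out.snp == "s1", "freq"].item() == pytest.approx(0.7)
        assert (out["a1"] == "G").all()

    def test_ambiguous_and_mismatch_dropped(self, panel):
        panel.snps.loc[0, ["ref", "alt"]] = ["A", "T"]
        summary = pd.DataFrame({
            "snp": ["s0", "s1", "s2"], "a1": ["A", "C", "G"],
            "a2": ["T", "T", "A"], "freq": np.nan, "b": [0.1, 0.2, 0.3],
            "se": 0.1, "p": 0.5, "n": 100})
        out = gio.harmonize(summary, panel)
        assert out["snp"].tolist() == ["s2"]  # A/T ambiguous, C/T mismatched

    def test_idempotent(self, panel):
        summary = pd.DataFrame({
            "snp": ["s0", "s1"], "a1": ["A", "G"], "a2": ["G", "A"],
            "freq": [0.4, 0.6], "b": [0.5, -0.5], "se": 0.1, "p": 0.5, "n": 9})
        once = gio.harmonize(summary, panel)
        twice = gio.harmonize(once, panel)
        pd.testing.assert_frame_equal(once, twice)

    def test_no_overlap_errors(self, panel):
        summary = pd.DataFrame({
            "snp": ["nope"], "a1": ["A"], "a2": ["G"], "freq": np.nan,
            "b": [0.1], "se": 0.1, "p": 0.5, "n": 10})
        with pytest.raises(ValueError, match="no SNPs overlap"):
            gio.harmonize(summary, panel)


class TestSummaryIO:
    def test_ma_roundtrip_and_optional_freq(self, tmp_path):
        df = pd.DataFrame({
            "snp": ["rs1", "rs2"], "a1": ["A", "G"], "a2": ["G", "A"],
            "freq": [np.nan, np.nan], "b": [0.1, -0.2], "se": [0.01, 0.02],
            "p": [1e-8, 0.5], "n": [1000, 1000]})
        gio.write_gwas_summary(df, tmp_path / "x.ma")
        back = gio.read_gwas_summary(tmp_path / "x.ma")
        pd.testing.assert_frame_equal(
            back.drop(columns="freq"), df.drop(columns="freq"),
            check_dtype=False)

    def test_invalid_p_rejected(self, tmp_path):
        (tmp_path / "bad.ma").write_text(
            "SNP A1 A2 b se p N\nrs1 A G 0.1 0.1 0 100\n")
        with pytest.raises(ValueError, match="P-values"):
            gio.read_gwas_summary(tmp_path / "bad.ma")


def test_downsample_seeded(rng):
    panel = random_panel(rng, n_per_pop=50, n_snps=20, pops=("P1", "P2"))
    a = gio.downsample(panel, 20, seed=5)
    b = gio.downsample(panel, 20, seed=5)
    assert a.samples == b.samples
    assert all((a.populations == p).sum() == 20 for p in ("P1", "P2"))
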
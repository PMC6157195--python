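"""QC filters, SNP-CpG pairing and gene/set assembly."""

import numpy as np
import pytest
from scipy import stats

from methgene.datatypes import (
    MISSING_GENOTYPE,
    GeneDefinition,
    GenotypeMatrix,
    MethylationMatrix,
    QCThresholds,
)
from methgene.preprocess import assemble_gene_sets, hwe_test, pair_snps_to_cpgs, qc_filter


def _geno(columns, positions=None, chrom=None, ids=None):
    v = np.array(columns, dtype=np.int8).T
    s = v.shape[1]
    return GenotypeMatrix(
        values=v,
        snp_ids=np.array(ids if ids is not None else [f"s{j}" for j in range(s)]),
        positions=np.array(positions if positions is not None else np.arange(1, s + 1) * 100),
        chromosomes=np.array(chrom if chrom is not None else ["1"] * s),
    )


def _meth(n, positions, chrom=None, ids=None):
    c = len(positions)
    return MethylationMatrix(
        values=np.full((n, c), 0.5),
        cpg_ids=np.array(ids if ids is not None else [f"c{j}" for j in range(c)]),
        positions=np.array(positions),
        chromosomes=np.array(chrom if chrom is not None else ["1"] * c),
    )


class TestHWE:
    def test_exact_equilibrium_gives_p_one(self):
        assert hwe_test(25, 50, 25) == pytest.approx(1.0)

    def test_hand_computed_chi_square(self):
        # expected counts 25/50/25 at p_hat=0.5 -> chi2 = 1 + 2 + 1 = 4
        expected = float(stats.chi2.sf(4.0, 1))
        assert hwe_test(30, 40, 30) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(0.0455, abs=5e-5)

    def test_monomorphic_convention(self):
        assert hwe_test(100, 0, 0) == 1.0
        assert hwe_test(0, 0, 77) == 1.0

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            hwe_test(0, 0, 0)
        with pytest.raises(ValueError):
            hwe_test(-1, 5, 5)


class TestQCFilter:
    def test_low_maf_dropped(self, rng):
        n = 1000
        rare = rng.binomial(2, 0.009, n)  # maf ~0.9%
        common = rng.binomial(2, 0.3, n)
        keep = qc_filter(_geno([rare, common]))
        assert not keep[0] and keep[1]

    def test_missingness_dropped(self, rng):
        n = 500
        good = rng.binomial(2, 0.3, n)
        bad = good.copy()
        bad[: int(0.06 * n)] = MISSING_GENOTYPE
        keep = qc_filter(_geno([good, bad]))
        assert keep[0] and not keep[1]

    def test_hwe_violation_dropped(self):
        # gross heterozygote deficit: only homozygotes at 50/50
        v = np.array([0] * 250 + [2] * 250)
        keep = qc_filter(_geno([v]))
        assert not keep[0]

    def test_extreme_thresholds_identity_filter(self, rng):
        cols = [rng.binomial(2, f, 200) for f in (0.02, 0.2, 0.5)]
        thr = QCThresholds(hwe_p_min=0.0, maf_min=0.0, missing_max=1.0)
        keep = qc_filter(_geno(cols), thr)
        # monomorphic columns would still pass: maf>0 fails only at exactly 0
        assert keep.all() or (~keep).sum() == sum(np.std(c) == 0 for c in cols)

    def test_filter_monotone_in_thresholds(self, rng):
        cols = [rng.binomial(2, f, 300) for f in np.linspace(0.01, 0.5, 12)]
        for c in cols[:4]:
            c[rng.integers(0, 300, 10)] = MISSING_GENOTYPE
        g = _geno(cols)
        strict = qc_filter(g, QCThresholds(1e-4, 0.05, 0.02))
        loose = qc_filter(g, QCThresholds(1e-8, 0.01, 0.10))
        assert (loose | ~strict).all()  # strict kept => loose kept


class TestPairing:
    def test_nearest_cpg_wins(self):
        g = _geno([[0, 1, 2] * 5], positions=[100])
        m = _meth(15, positions=[90, 120])
        pm = pair_snps_to_cpgs(g, m)
        assert pm.cpg_ids[0] == "c0"

    def test_tie_broken_to_lower_coordinate(self):
        g = _geno([[0, 1, 2] * 5], positions=[100])
        m = _meth(15, positions=[90, 110])
        pm = pair_snps_to_cpgs(g, m)
        assert int(m.positions[pm.cpg_index[0]]) == 90

    def test_override_wins_and_far_override_warns(self):
        g = _geno([[0, 1, 2] * 5], positions=[100], ids=["snp_x"])
        m = _meth(15, positions=[110, 90_000], ids=["near", "causal"])
        with pytest.warns(UserWarning, match="spans"):
            pm = pair_snps_to_cpgs(g, m, overrides={"snp_x": "causal"})
        assert pm.cpg_ids[0] == "causal"

    def test_chromosome_without_cpgs_errors(self):
        g = _geno([[0, 1, 2] * 5], positions=[100], chrom=["2"])
        m = _meth(15, positions=[110], chrom=["1"])
        with pytest.raises(ValueError, match="no CpG"):
            pair_snps_to_cpgs(g, m)

    def test_pairing_total_and_deterministic(self, rng):
        s = 30
        cols = [rng.binomial(2, 0.3, 50) for _ in range(s)]
        g = _geno(cols, positions=np.sort(rng.choice(10_000, s, replace=False)) + 1)
        m = _meth(50, positions=np.sort(rng.choice(10_000, 10, replace=False)) + 1)
        pm1 = pair_snps_to_cpgs(g, m)
        pm2 = pair_snps_to_cpgs(g, m)
        assert pm1.n_pairs == s  # every kept SNP in exactly one pair
        assert len(np.unique(pm1.snp_index)) == s
        np.testing.assert_array_equal(pm1.cpg_index, pm2.cpg_index)


class TestGeneAssembly:
    def _setup(self, snp_positions, ids=None):
        cols = [[0, 1, 2] * 5 for _ in snp_positions]
        g = _geno(cols, positions=snp_positions, ids=ids)
        m = _meth(15, positions=[p + 7 for p in snp_positions])
        pm = pair_snps_to_cpgs(g, m)
        return g, pm

    def test_inclusive_interval_bounds(self):
        g, pm = self._setup([999, 1000, 2000, 2001])
        genes = [GeneDefinition("G", "1", 1000, 2000)]
        out = assemble_gene_sets(pm, g, genes)
        assert set(out.gene_assignments["G"]) == {1, 2}

    def test_orphan_major_snp_within_50kb_appended(self):
        g, pm = self._setup([1000, 2000, 32_000], ids=["a", "b", "major"])
        genes = [GeneDefinition("G", "1", 500, 2500, "major_causal")]
        out = assemble_gene_sets(pm, g, genes, major_snp_ids=("major",))
        assert 2 in out.gene_assignments["G"]
        assert out.m("G") == 3

    def test_orphan_beyond_50kb_gets_synthetic_gene(self):
        g, pm = self._setup([1000, 70_000, 100_000, 200_000], ids=["a", "near", "major", "far"])
        genes = [GeneDefinition("G", "1", 500, 1500)]
        out = assemble_gene_sets(pm, g, genes, major_snp_ids=("major",))
        # synthetic gene spans +/- 50 kb around the major SNP at 100 kb
        assert set(out.gene_assignments["SYNTH_major"]) == {1, 2}
        assert out.gene_categories["SYNTH_major"] == "major_causal"

    def test_union_and_spiked_sets(self):
        g, pm = self._setup([100, 200, 5000, 6000])
        genes = [
            GeneDefinition("G1", "1", 50, 300),
            GeneDefinition("G2", "1", 4500, 6500),
        ]
        out = assemble_gene_sets(
            pm,
            g,
            genes,
            union_sets={"U": ["G1", "G2"]},
            spiked_sets={"S": np.array([0, 3])},
        )
        assert out.m("U") == 4
        assert set(out.gene_assignments["S"]) == {0, 3}

    def test_empty_gene_excluded(self):
        g, pm = self._setup([100, 200])
        genes = [GeneDefinition("EMPTY", "1", 50_000, 60_000)]
        out = assemble_gene_sets(pm, g, genes)
        assert "EMPTY" not in out.gene_assignments
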
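"""Pedigree, kinship, genotype/methylation simulation and calibration."""

import numpy as np
import pandas as pd
import pytest

from methgene.datatypes import Pedigree, SimScenario
from methgene.synthetic import (
    build_pedigree,
    calibrate_effect_size,
    kinship_from_pedigree,
    simulate_cohort,
    simulate_genotypes,
    simulate_methylation,
)


class TestPedigree:
    def test_single_individual_is_founder(self):
        ped = build_pedigree(1, seed=0)
        assert ped.n == 1 and ped.is_founder.all()

    def test_cohort_size_and_parentage(self):
        ped = build_pedigree(670, sibship_sizes=(2, 3, 4), seed=1)
        assert ped.n == 670
        kids = ~ped.is_founder
        assert (ped.father[kids] >= 0).all() and (ped.mother[kids] >= 0).all()
        # both parents belong to the same family as the child
        assert (ped.family_id[ped.father[kids]] == ped.family_id[kids]).all()

    def test_same_seed_identical(self):
        a = build_pedigree(100, seed=7)
        b = build_pedigree(100, seed=7)
        np.testing.assert_array_equal(a.father, b.father)
        np.testing.assert_array_equal(a.individual_id, b.individual_id)

    def test_nonpositive_n_rejected(self):
        with pytest.raises(ValueError):
            build_pedigree(0)

    def test_child_before_parent_rejected(self):
        with pytest.raises(ValueError, match="precede"):
            Pedigree(
                individual_id=np.array(["kid", "dad", "mum"]),
                family_id=np.array(["F", "F", "F"]),
                father=np.array([1, -1, -1]),
                mother=np.array([2, -1, -1]),
                sex=np.array([1, 1, 2]),
            )


def _three_generation_toy():
    """Founders 0-3; 4 and 5 are full sibs (parents 0, 1); 6 = child of
    (4, 2); 7 = child of (6, 3): three generations deep."""
    return Pedigree(
        individual_id=np.array([f"i{k}" for k in range(8)]),
        family_id=np.array(["F"] * 8),
        father=np.array([-1, -1, -1, -1, 0, 0, 4, 6]),
        mother=np.array([-1, -1, -1, -1, 1, 1, 2, 3]),
        sex=np.array([1, 2, 2, 2, 1, 1, 1, 1]),
    )


class TestKinship:
    def test_founders_only(self):
        ped = build_pedigree(2, sibship_sizes=(2,), seed=0)
        ped_founders = Pedigree(
            individual_id=ped.individual_id[:2],
            family_id=ped.family_id[:2],
            father=np.array([-1, -1]),
            mother=np.array([-1, -1]),
            sex=ped.sex[:2],
        )
        phi = kinship_from_pedigree(ped_founders).values
        np.testing.assert_allclose(phi, 0.5 * np.eye(2))

    def test_textbook_coefficients(self):
        ped = _three_generation_toy()
        phi = kinship_from_pedigree(ped).values
        assert phi[0, 4] == pytest.approx(0.25)  # parent-offspring
        assert phi[4, 5] == pytest.approx(0.25)  # full sibs
        assert phi[0, 6] == pytest.approx(0.125)  # grandparent
        assert phi[5, 6] == pytest.approx(0.125)  # avuncular

    def test_gene_dropping_oracle(self):
        """Kinship = P(two alleles drawn at random, one from each
        individual, are IBD), estimated by dropping founder alleles through
        the three-generation toy pedigree."""
        ped = _three_generation_toy()
        phi = kinship_from_pedigree(ped).values
        rng = np.random.default_rng(99)
        n_drops = 120_000
        n = ped.n
        alleles = np.empty((n, n_drops, 2), dtype=np.int32)
        lab = np.arange(2 * n, dtype=np.int32).reshape(n, 2)
        for i in range(n):
            f, m = ped.father[i], ped.mother[i]
            if f < 0:
                alleles[i] = lab[i][None, :]
            else:
                pf = rng.integers(0, 2, n_drops)
                pm = rng.integers(0, 2, n_drops)
                alleles[i, :, 0] = alleles[f, np.arange(n_drops), pf]
                alleles[i, :, 1] = alleles[m, np.arange(n_drops), pm]
        for i, j in [(0, 4), (4, 5), (0, 6), (5, 6), (6, 7)]:
            pick_i = alleles[i, np.arange(n_drops), rng.integers(0, 2, n_drops)]
            pick_j = alleles[j, np.arange(n_drops), rng.integers(0, 2, n_drops)]
            est = (pick_i == pick_j).mean()
            se = np.sqrt(est * (1 - est) / n_drops)
            assert abs(est - phi[i, j]) < 3 * max(se, 1e-4), (i, j)

    def test_generated_pedigree_kinship_psd(self, small_kinship):
        evals = np.linalg.eigvalsh(small_kinship.additive_relationship())
        assert evals.min() > -1e-10


class TestGenotypes:
    def test_founder_hwe_frequencies(self):
        ped = build_pedigree(4000, sibship_sizes=(1,), seed=2)
        founders = ped.is_founder
        g = simulate_genotypes(ped, mafs=[0.5], positions=[100], seed=3)
        v = g.values[founders, 0]
        n = founders.sum()
        for k, expect in [(0, 0.25), (1, 0.5), (2, 0.25)]:
            se = np.sqrt(expect * (1 - expect) / n)
            assert abs((v == k).mean() - expect) < 3 * se

    def test_tiny_maf_all_reference(self):
        ped = build_pedigree(100, seed=1)
        g = simulate_genotypes(ped, mafs=[1e-7], positions=[100], seed=4)
        assert (g.values == 0).all()

    def test_sib_genotype_correlation(self):
        """Full sibs share alleles with E[IBD]/2 = kinship 0.25, so the
        genotype correlation approaches 2*phi = 0.5."""
        corrs = []
        for seed in range(4):
            ped = build_pedigree(3000, sibship_sizes=(2,), seed=seed)
            g = simulate_genotypes(ped, mafs=[0.3], positions=[100], seed=100 + seed)
            sib1 = np.flatnonzero(~ped.is_founder)[::2]
            corrs.append(np.corrcoef(g.values[sib1, 0], g.values[sib1 + 1, 0])[0, 1])
        assert np.mean(corrs) == pytest.approx(0.5, abs=0.04)

    def test_invalid_maf(self, small_pedigree):
        with pytest.raises(ValueError):
            simulate_genotypes(small_pedigree, mafs=[0.7], positions=[1])

    def test_missingness_applied(self, small_pedigree):
        g = simulate_genotypes(
            small_pedigree, mafs=[0.3], positions=[1], missing_rate=0.2, seed=8
        )
        assert 0.05 < (g.values == -1).mean() < 0.4


class TestMethylation:
    def test_uniform_case_moments(self):
        m = simulate_methylation(5000, [100], beta_params=(1.0, 1.0), seed=9)
        assert m.values.min() >= 0 and m.values.max() <= 1
        assert m.values.mean() == pytest.approx(0.5, abs=0.02)

    def test_beta22_moments(self):
        m = simulate_methylation(10_000, [100], beta_params=(2.0, 2.0), seed=10)
        assert m.values.mean() == pytest.approx(0.5, abs=0.01)
        assert m.values.var() == pytest.approx(0.05, abs=0.005)

    def test_point_mass_option(self):
        m = simulate_methylation(50, [100], beta_params=(0.0, 0.0), seed=1)
        assert (m.values == 0).all()

    def test_negative_params_rejected(self):
        with pytest.raises(ValueError):
            simulate_methylation(10, [100], beta_params=(-1.0, 2.0))


class TestEffectCalibration:
    def test_zero_heritability(self):
        assert calibrate_effect_size(0.0, 0.3) == 0.0

    def test_unmoderated_closed_form(self):
        # CPG identically 0 -> W = 1 -> beta = sqrt(h2 / Var(SNP))
        beta = calibrate_effect_size(0.125, 0.11, meth_beta=(0.0, 0.0))
        assert beta == pytest.approx(np.sqrt(0.125 / (2 * 0.11 * 0.89)), rel=1e-12)

    def test_monte_carlo_variance_share(self, rng):
        h2, maf = 0.10, 0.19
        beta = calibrate_effect_size(h2, maf, meth_beta=(2.0, 2.0))
        snp = rng.binomial(2, maf, 1_000_000)
        cpg = rng.beta(2.0, 2.0, 1_000_000)
        var = np.var(beta * snp * (1 - cpg))
        assert var == pytest.approx(h2, rel=0.01)

    def test_h2_bounds(self):
        with pytest.raises(ValueError):
            calibrate_effect_size(1.0, 0.2)


def _one_snp_scenario(h2, n=400, sigma2_g=0.0):
    snps = pd.DataFrame(
        {"snp_id": ["s0"], "chrom": "1", "pos": [1000], "maf": [0.3], "h2": [h2], "cpg_id": ["c0"]}
    )
    cpgs = pd.DataFrame({"cpg_id": ["c0"], "chrom": "1", "pos": [1100]})
    return SimScenario(n_individuals=n, snps=snps, cpgs=cpgs, sigma2_g=sigma2_g)


class TestPhenotype:
    def test_same_seed_bit_identical_cohort(self):
        sc = _one_snp_scenario(0.1)
        a = simulate_cohort(sc, seed=21)
        b = simulate_cohort(sc, seed=21)
        np.testing.assert_array_equal(a.genotypes.values, b.genotypes.values)
        np.testing.assert_array_equal(a.methylation.values, b.methylation.values)
        pd.testing.assert_frame_equal(a.phenotypes, b.phenotypes)

    def test_causal_variance_share_recovered(self):
        """Squared correlation of the causal term with the latent change
        approaches the target heritability over replicates."""
        shares = []
        for rep in range(30):
            c = simulate_cohort(_one_snp_scenario(0.125, n=500), seed=100 + rep)
            delta = c.phenotypes.attrs["latent_change"]
            causal = c.phenotypes.attrs["causal_term"]
            shares.append(np.corrcoef(causal, delta)[0, 1] ** 2)
        assert np.mean(shares) == pytest.approx(0.125, abs=0.02)

    def test_sib_intraclass_correlation_under_polygenic_model(self):
        """With sigma2_g and no causal effects, cov(sib change scores) =
        2 * 0.25 * sigma2_g."""
        sc = _one_snp_scenario(0.0, n=2000, sigma2_g=0.4)
        covs = []
        for rep in range(10):
            c = simulate_cohort(sc, seed=300 + rep)
            delta = c.phenotypes.attrs["latent_change"] - c.phenotypes.attrs["causal_term"]
            ped = c.pedigree
            sibs_first = np.flatnonzero(~ped.is_founder)
            pairs = [
                (i, j)
                for i in sibs_first
                for j in sibs_first
                if i < j and ped.family_id[i] == ped.family_id[j]
            ]
            i, j = np.array(pairs).T
            covs.append(np.cov(delta[i], delta[j])[0, 1])
        assert np.mean(covs) == pytest.approx(0.5 * 0.4, abs=0.04)

    def test_tg_measurements_strictly_positive(self, null_cohort):
        cols = ["tg_baseline_1", "tg_baseline_2", "tg_followup_1", "tg_followup_2"]
        vals = null_cohort.phenotypes[cols].to_numpy()
        assert np.nanmin(vals) > 0
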
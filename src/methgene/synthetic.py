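"""Synthetic family cohorts with methylation-moderated SNP effects.

Emulates the structure of a family-based lipid study: ~670 related
individuals in nuclear families, seven covariates, a change-in-ln-TG
phenotype, and causal SNPs whose effects are attenuated by methylation of
an assigned CpG site (effect term ``beta * SNP * (1 - CPG)``).

The phenotypic variance of the latent change score is normalised to 1, so a
causal SNP's target heritability is directly the variance share of its
interaction term; :func:`calibrate_effect_size` converts that share into a
regression coefficient analytically from the first two moments of the
genotype and methylation distributions.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import (
    MISSING_GENOTYPE,
    CohortData,
    GenotypeMatrix,
    KinshipMatrix,
    MethylationMatrix,
    Pedigree,
    SimScenario,
)

__all__ = [
    "build_pedigree",
    "kinship_from_pedigree",
    "simulate_genotypes",
    "simulate_methylation",
    "calibrate_effect_size",
    "simulate_phenotype",
    "simulate_cohort",
]


def build_pedigree(
    n_individuals: int,
    sibship_sizes: tuple[int, ...] = (2, 3, 4),
    seed: int | np.random.Generator = 0,
) -> Pedigree:
    """Nuclear-family pedigree (two founders + sibs) covering exactly
    ``n_individuals``.

    Families are appended until the target is reached; the last family is
    truncated, so the tail may be a founder couple or a lone founder.
    """
    if n_individuals < 1:
        raise ValueError("n_individuals must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    fam, iid, fat, mot, sex = [], [], [], [], []
    fam_no = 0
    while len(iid) < n_individuals:
        fam_no += 1
        fid = f"F{fam_no:04d}"
        remaining = n_individuals - len(iid)
        n_sibs = int(rng.choice(sibship_sizes))
        # two founders
        father_row = mother_row = -1
        for parent_sex in (1, 2):
            if remaining == 0:
                break
            row = len(iid)
            fam.append(fid)
            iid.append(f"{fid}_{parent_sex:02d}")
            fat.append(-1)
            mot.append(-1)
            sex.append(parent_sex)
            if parent_sex == 1:
                father_row = row
            else:
                mother_row = row
            remaining -= 1
        if remaining == 0 or mother_row < 0:
            break
        for s in range(min(n_sibs, remaining)):
            fam.append(fid)
            iid.append(f"{fid}_{s + 3:02d}")
            fat.append(father_row)
            mot.append(mother_row)
            sex.append(int(rng.integers(1, 3)))
    return Pedigree(
        individual_id=np.array(iid),
        family_id=np.array(fam),
        father=np.array(fat, dtype=int),
        mother=np.array(mot, dtype=int),
        sex=np.array(sex, dtype=int),
    )


def kinship_from_pedigree(ped: Pedigree) -> KinshipMatrix:
    """Expected kinship coefficients by the recursive tabular method.

    Founders are mutually unrelated and non-inbred.  Requires (and the
    :class:`~methgene.datatypes.Pedigree` constructor enforces) that parents
    precede their children, which also rules out ancestry cycles.
    """
    n = ped.n
    phi = np.zeros((n, n))
    for i in range(n):
        f, m = ped.father[i], ped.mother[i]
        if f < 0:
            phi[i, i] = 0.5
        else:
            phi[i, :i] = 0.5 * (phi[f, :i] + phi[m, :i])
            phi[:i, i] = phi[i, :i]
            phi[i, i] = 0.5 + 0.5 * phi[f, m]
    return KinshipMatrix(values=phi, individual_id=ped.individual_id)


def simulate_genotypes(
    ped: Pedigree,
    mafs: np.ndarray,
    positions: np.ndarray,
    chromosomes: np.ndarray | None = None,
    snp_ids: np.ndarray | None = None,
    missing_rate: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> GenotypeMatrix:
    """Gene-dropping genotype simulation.

    Founder alleles are independent Bernoulli(maf); each offspring receives
    one uniformly chosen allele from each parent (Mendelian transmission).
    SNPs are unlinked.  An optional uniform missing-call rate masks entries
    after dropping.
    """
    mafs = np.asarray(mafs, dtype=float)
    if ((mafs <= 0) | (mafs > 0.5)).any():
        raise ValueError("MAFs must lie in (0, 0.5]")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n, s = ped.n, len(mafs)
    alleles = np.empty((n, s, 2), dtype=np.int8)
    for i in range(n):
        f, m = ped.father[i], ped.mother[i]
        if f < 0:
            alleles[i] = rng.random((s, 2)) < mafs[:, None]
        else:
            pick_f = rng.integers(0, 2, size=s)
            pick_m = rng.integers(0, 2, size=s)
            alleles[i, :, 0] = alleles[f, np.arange(s), pick_f]
            alleles[i, :, 1] = alleles[m, np.arange(s), pick_m]
    geno = alleles.sum(axis=2).astype(np.int8)
    if missing_rate > 0:
        mask = rng.random(geno.shape) < missing_rate
        geno[mask] = MISSING_GENOTYPE
    positions = np.asarray(positions)
    if chromosomes is None:
        chromosomes = np.full(s, "1")
    if snp_ids is None:
        snp_ids = np.array([f"snp{j}" for j in range(s)])
    return GenotypeMatrix(
        values=geno,
        snp_ids=np.asarray(snp_ids),
        positions=positions,
        chromosomes=np.asarray(chromosomes),
    )


def simulate_methylation(
    n: int,
    cpg_positions: np.ndarray,
    beta_params: tuple[float, float] = (2.0, 2.0),
    chromosomes: np.ndarray | None = None,
    cpg_ids: np.ndarray | None = None,
    seed: int | np.random.Generator = 0,
) -> MethylationMatrix:
    """Independent beta-distributed methylation proportions.

    ``beta_params == (0, 0)`` is the degenerate point-mass-at-zero option in
    which downstream SNP effects are unmoderated.
    """
    a, b = beta_params
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    c = len(cpg_positions)
    if a == 0 and b == 0:
        values = np.zeros((n, c))
    elif a <= 0 or b <= 0:
        raise ValueError("beta parameters must be positive")
    else:
        values = rng.beta(a, b, size=(n, c))
    if chromosomes is None:
        chromosomes = np.full(c, "1")
    if cpg_ids is None:
        cpg_ids = np.array([f"cpg{j}" for j in range(c)])
    return MethylationMatrix(
        values=values,
        cpg_ids=np.asarray(cpg_ids),
        positions=np.asarray(cpg_positions),
        chromosomes=np.asarray(chromosomes),
    )


def _moderator_moments(beta_a: float, beta_b: float, moderation: str) -> tuple[float, float]:
    """Mean and variance of the moderation weight W applied to the SNP."""
    if moderation == "none" or (beta_a == 0 and beta_b == 0):
        return 1.0, 0.0
    mu_c = beta_a / (beta_a + beta_b)
    var_c = beta_a * beta_b / ((beta_a + beta_b) ** 2 * (beta_a + beta_b + 1))
    if moderation == "attenuation":  # W = 1 - CPG
        return 1.0 - mu_c, var_c
    raise ValueError(f"unknown moderation {moderation!r}")


def calibrate_effect_size(
    h2_target: float,
    maf: float,
    meth_beta: tuple[float, float] = (2.0, 2.0),
    moderation: str = "attenuation",
) -> float:
    """Coefficient beta with Var(beta * SNP * W) equal to ``h2_target``.

    SNP ~ Binomial(2, maf) and the moderation weight W (1 - CPG under the
    attenuation model) are independent, so
    Var(SNP*W) = E[SNP^2] E[W^2] - (E[SNP] E[W])^2, evaluated from closed-form
    moments.  Total phenotypic variance is 1 by convention, hence the variance
    of the term equals its heritability share.
    """
    if not 0.0 <= h2_target < 1.0:
        raise ValueError("h2_target must lie in [0, 1)")
    if not 0.0 < maf <= 0.5:
        raise ValueError("maf must lie in (0, 0.5]")
    if h2_target == 0.0:
        return 0.0
    mu_s = 2.0 * maf
    var_s = 2.0 * maf * (1.0 - maf)
    mu_w, var_w = _moderator_moments(*meth_beta, moderation)
    var_sw = (var_s + mu_s**2) * (var_w + mu_w**2) - (mu_s * mu_w) ** 2
    return float(np.sqrt(h2_target / var_sw))


def _draw_covariates(n: int, rng: np.random.Generator) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "age": rng.normal(50.0, 10.0, n),
            "center": rng.integers(0, 2, n),
            "smoking": (rng.random(n) < 0.25).astype(int),
            "msdx_score": rng.normal(0.0, 1.0, n),
            "fasting_time": rng.normal(9.0, 2.0, n),
        }
    )


def simulate_phenotype(
    scenario: SimScenario,
    geno: GenotypeMatrix,
    meth: MethylationMatrix,
    ped: Pedigree,
    kinship: KinshipMatrix,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Phenotype/covariate table with duplicate visit measurements.

    The latent change score is

        delta = X gamma + sum_causal beta_j SNP_j (1 - CPG_j) + g + e,

    with g ~ N(0, 2 Phi sigma2_g) and e iid N(0, sigma2_e).  Baseline ln-TG
    is drawn independently and follow-up TG is constructed so that
    ln(followup) - ln(baseline) equals the latent change; each visit-level
    measurement adds small ln-scale Gaussian noise, and second measurements
    are present with ``second_measurement_prob``.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n = ped.n
    if geno.n_individuals != n or meth.values.shape[0] != n:
        raise ValueError("genotype/methylation dimensions do not match pedigree")

    cov = _draw_covariates(n, rng)
    ln_hdl_true = rng.normal(3.9, 0.25, n)
    ln_tg_true = rng.normal(5.0, 0.45, n)

    # causal interaction terms
    causal_term = np.zeros(n)
    if scenario.snps is not None:
        snp_pos = {sid: j for j, sid in enumerate(geno.snp_ids)}
        cpg_pos = {cid: j for j, cid in enumerate(meth.cpg_ids)}
        for _, row in scenario.snps.iterrows():
            if row["h2"] <= 0:
                continue
            beta = calibrate_effect_size(
                float(row["h2"]),
                float(row["maf"]),
                (scenario.meth_beta_a, scenario.meth_beta_b),
                scenario.moderation,
            )
            g = geno.values[:, snp_pos[row["snp_id"]]].astype(float)
            g[g == MISSING_GENOTYPE] = np.nan
            g = np.nan_to_num(g, nan=2.0 * float(row["maf"]))  # mean-impute for simulation
            c = meth.values[:, cpg_pos[row["cpg_id"]]]
            w = (1.0 - c) if scenario.moderation == "attenuation" else np.ones(n)
            causal_term += beta * g * w

    # polygenic effect via eigendecomposition of 2*Phi
    if scenario.sigma2_g > 0:
        k2 = kinship.additive_relationship()
        evals, evecs = np.linalg.eigh(k2)
        evals = np.clip(evals, 0.0, None)
        g_poly = evecs @ (np.sqrt(scenario.sigma2_g * evals) * rng.standard_normal(n))
    else:
        g_poly = np.zeros(n)

    noise = rng.normal(0.0, np.sqrt(scenario.sigma2_e), n)

    eff = scenario.covariate_effects
    z = lambda x: (x - np.mean(x)) / (np.std(x) if np.std(x) > 0 else 1.0)
    fixed = (
        eff.get("age", 0.0) * z(cov["age"].to_numpy())
        + eff.get("center", 0.0) * cov["center"].to_numpy()
        + eff.get("smoking", 0.0) * cov["smoking"].to_numpy()
        + eff.get("msdx_score", 0.0) * z(cov["msdx_score"].to_numpy())
        + eff.get("fasting_time", 0.0) * z(cov["fasting_time"].to_numpy())
        + eff.get("ln_hdl_base", 0.0) * z(ln_hdl_true)
        + eff.get("ln_tg_base", 0.0) * z(ln_tg_true)
    )

    delta = fixed + causal_term + g_poly + noise
    ln_tg_follow_true = ln_tg_true + delta

    sd = scenario.measurement_noise_sd
    p2 = scenario.second_measurement_prob

    def visits(ln_true: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        m1 = np.exp(ln_true + rng.normal(0.0, sd, n))
        m2 = np.exp(ln_true + rng.normal(0.0, sd, n))
        m2 = np.where(rng.random(n) < p2, m2, np.nan)
        return m1, m2

    tg_b1, tg_b2 = visits(ln_tg_true)
    tg_f1, tg_f2 = visits(ln_tg_follow_true)
    hdl_1, hdl_2 = visits(ln_hdl_true)

    out = cov.copy()
    out.insert(0, "individual_id", ped.individual_id)
    out["hdl_1"], out["hdl_2"] = hdl_1, hdl_2
    out["tg_baseline_1"], out["tg_baseline_2"] = tg_b1, tg_b2
    out["tg_followup_1"], out["tg_followup_2"] = tg_f1, tg_f2
    # latent pieces kept for simulation-level diagnostics only
    out.attrs["latent_change"] = delta
    out.attrs["causal_term"] = causal_term
    out.attrs["polygenic"] = g_poly
    return out


def simulate_cohort(scenario: SimScenario, seed: int) -> CohortData:
    """One fully specified cohort: pedigree, kinship, omics and phenotypes.

    All randomness flows from a single seeded generator, so the same
    (scenario, seed) yields a bit-identical cohort.
    """
    rng = np.random.default_rng(seed)
    ped = build_pedigree(scenario.n_individuals, scenario.sibship_sizes, rng)
    kin = kinship_from_pedigree(ped)
    if scenario.snps is None or scenario.cpgs is None:
        raise ValueError("scenario must define snps and cpgs tables")
    snps = scenario.snps
    cpgs = scenario.cpgs
    geno = simulate_genotypes(
        ped,
        mafs=snps["maf"].to_numpy(),
        positions=snps["pos"].to_numpy(),
        chromosomes=snps["chrom"].to_numpy().astype(str),
        snp_ids=snps["snp_id"].to_numpy(),
        missing_rate=scenario.genotype_missing_rate,
        seed=rng,
    )
    meth = simulate_methylation(
        ped.n,
        cpg_positions=cpgs["pos"].to_numpy(),
        beta_params=(scenario.meth_beta_a, scenario.meth_beta_b),
        chromosomes=cpgs["chrom"].to_numpy().astype(str),
        cpg_ids=cpgs["cpg_id"].to_numpy(),
        seed=rng,
    )
    pheno = simulate_phenotype(scenario, geno, meth, ped, kin, seed=rng)
    return CohortData(pedigree=ped, kinship=kin, genotypes=geno, methylation=meth, phenotypes=pheno)
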
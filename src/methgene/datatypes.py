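"""Core containers shared across the pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Sentinel for a missing genotype call in integer-coded matrices.
MISSING_GENOTYPE: int = -1


@dataclass
class Pedigree:
    """A family sample in parent-before-child order.

    ``father`` / ``mother`` hold row indices into the pedigree itself, or -1
    for founders.  Both parents are either present or absent; half-known
    parentage is not modelled.
    """

    individual_id: np.ndarray  # str array, shape (n,)
    family_id: np.ndarray  # str array, shape (n,)
    father: np.ndarray  # int array, -1 for founders
    mother: np.ndarray  # int array, -1 for founders
    sex: np.ndarray  # int array, 1=male 2=female

    def __post_init__(self) -> None:
        n = len(self.individual_id)
        for name in ("family_id", "father", "mother", "sex"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"pedigree field {name!r} has inconsistent length")
        founders = (self.father < 0) != (self.mother < 0)
        if founders.any():
            raise ValueError("individuals must have both parents known or neither")
        idx = np.arange(n)
        if ((self.father >= idx) & (self.father >= 0)).any() or (
            (self.mother >= idx) & (self.mother >= 0)
        ).any():
            raise ValueError("parents must precede children in pedigree order")

    @property
    def n(self) -> int:
        return len(self.individual_id)

    @property
    def is_founder(self) -> np.ndarray:
        return self.father < 0

    def to_frame(self) -> pd.DataFrame:
        pat = np.where(self.father >= 0, self.individual_id[np.clip(self.father, 0, None)], "0")
        mat = np.where(self.mother >= 0, self.individual_id[np.clip(self.mother, 0, None)], "0")
        return pd.DataFrame(
            {
                "family_id": self.family_id,
                "individual_id": self.individual_id,
                "father_id": pat,
                "mother_id": mat,
                "sex": self.sex,
            }
        )


@dataclass
class KinshipMatrix:
    """Expected kinship coefficients Phi for a set of individuals.

    Diagonal entries are 0.5 for non-inbred individuals; 2*Phi is the
    additive relationship matrix used as the polygenic covariance kernel.
    """

    values: np.ndarray
    individual_id: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("kinship matrix must be square")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("kinship matrix must be symmetric")
        self.values = v

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def additive_relationship(self) -> np.ndarray:
        """2*Phi, the covariance kernel of the additive polygenic effect."""
        return 2.0 * self.values


@dataclass
class GenotypeMatrix:
    """Minor-allele count matrix, individuals x SNPs.

    Entries are 0/1/2 or :data:`MISSING_GENOTYPE`.  Positions are 1-based
    basepairs, strictly increasing within each chromosome.
    """

    values: np.ndarray  # int8, (n, S)
    snp_ids: np.ndarray
    positions: np.ndarray
    chromosomes: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        ok = np.isin(self.values, [0, 1, 2, MISSING_GENOTYPE])
        if not ok.all():
            raise ValueError("genotype codes must be 0/1/2 or missing")
        for chrom in np.unique(self.chromosomes):
            pos = self.positions[self.chromosomes == chrom]
            if not (np.diff(pos) > 0).all():
                raise ValueError(f"positions not strictly increasing on {chrom}")

    @property
    def n_individuals(self) -> int:
        return self.values.shape[0]

    @property
    def n_snps(self) -> int:
        return self.values.shape[1]


@dataclass
class MethylationMatrix:
    """Methylation proportions in [0, 1], individuals x CpG sites."""

    values: np.ndarray  # float, (n, C)
    cpg_ids: np.ndarray
    positions: np.ndarray
    chromosomes: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.size and (v.min() < 0 or v.max() > 1):
            raise ValueError("methylation values must lie in [0, 1]")
        self.values = v

    @property
    def n_cpgs(self) -> int:
        return self.values.shape[1]


@dataclass
class QCThresholds:
    """Standard GWAS per-SNP quality-control cutoffs.

    A SNP is kept iff HWE p > ``hwe_p_min``, MAF > ``maf_min`` and
    missing-call rate < ``missing_max`` (all inequalities strict).
    """

    hwe_p_min: float = 1e-6
    maf_min: float = 0.01
    missing_max: float = 0.05

    def __post_init__(self) -> None:
        for name in ("hwe_p_min", "maf_min", "missing_max"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass
class GeneDefinition:
    """A gene (or synthetic set) interval, 1-based inclusive coordinates."""

    gene_id: str
    chromosome: str
    start: int
    stop: int
    category: str = "noncausal"  # major_causal | minor_causal | noncausal | synthetic_set

    def __post_init__(self) -> None:
        if self.start > self.stop:
            raise ValueError(f"gene {self.gene_id}: start > stop")


@dataclass
class PairMap:
    """SNP->CpG assignments and their grouping into genes/sets.

    ``snp_index`` / ``cpg_index`` are parallel arrays over pairs (one pair
    per kept SNP; a CpG may serve several SNPs).  ``gene_assignments`` maps
    gene/set id to the array of pair indices it contains; ``m`` per gene is
    the length of that array.
    """

    snp_ids: np.ndarray
    cpg_ids: np.ndarray
    snp_index: np.ndarray
    cpg_index: np.ndarray
    gene_assignments: dict[str, np.ndarray] = field(default_factory=dict)
    gene_categories: dict[str, str] = field(default_factory=dict)

    @property
    def n_pairs(self) -> int:
        return len(self.snp_index)

    def m(self, gene_id: str) -> int:
        return len(self.gene_assignments[gene_id])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"snp_id": self.snp_ids, "cpg_id": self.cpg_ids})


@dataclass
class SimScenario:
    """Generative parameters for one synthetic cohort.

    Variance accounting: the phenotypic variance of the latent change score
    (causal interaction terms + polygenic + residual noise) is normalised to
    1; covariate fixed effects add variance on top and are removed again in
    stage 1.  Each causal SNP's ``h2`` is the variance share of its
    beta * SNP * (1 - CPG) term.
    """

    n_individuals: int = 670
    sibship_sizes: tuple[int, ...] = (2, 3, 4)
    snps: pd.DataFrame | None = None  # columns: snp_id, chrom, pos, maf, h2, cpg_id
    cpgs: pd.DataFrame | None = None  # columns: cpg_id, chrom, pos
    meth_beta_a: float = 2.0
    meth_beta_b: float = 2.0
    sigma2_g: float = 0.2
    moderation: str = "attenuation"  # 'attenuation' (1-CPG) or 'none'
    covariate_effects: dict[str, float] = field(
        default_factory=lambda: {
            "age": 0.10,
            "center": 0.10,
            "smoking": 0.15,
            "msdx_score": 0.10,
            "fasting_time": 0.05,
            "ln_hdl_base": -0.15,
            "ln_tg_base": -0.20,
        }
    )
    measurement_noise_sd: float = 0.05
    second_measurement_prob: float = 0.7
    genotype_missing_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.snps is not None:
            h2 = np.asarray(self.snps["h2"], dtype=float)
            if ((h2 < 0) | (h2 >= 1)).any():
                raise ValueError("per-SNP h2 must lie in [0, 1)")
            mafs = np.asarray(self.snps["maf"], dtype=float)
            if ((mafs <= 0) | (mafs > 0.5)).any():
                raise ValueError("MAFs must lie in (0, 0.5]")
            total = float(h2.sum()) + self.sigma2_g
            if total >= 1.0:
                raise ValueError(
                    "causal heritabilities plus polygenic variance must be < 1 "
                    f"(got {total:.3f})"
                )

    @property
    def sigma2_e(self) -> float:
        """Residual variance implied by unit total phenotypic variance."""
        h2_total = 0.0 if self.snps is None else float(self.snps["h2"].sum())
        return 1.0 - h2_total - self.sigma2_g


@dataclass
class CohortData:
    """Everything the pipeline consumes for one cohort."""

    pedigree: Pedigree
    kinship: KinshipMatrix
    genotypes: GenotypeMatrix
    methylation: MethylationMatrix
    phenotypes: pd.DataFrame
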
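"""End-to-end experiment runner: replicate cohorts -> rejection proportions.

Builds a gene catalogue (major-effect genes with one causal SNP-CpG pair
each, minor-effect genes at h2 = 0.001, noncausal genes, and the five named
variant sets), simulates replicate cohorts, runs QC -> pairing -> stage-1
residualisation -> stage-2 pair fits -> gene statistics -> permutation
significance, and tabulates per-gene and category-pooled rejection
proportions.

Because noise SNPs are simulated independently (no linkage
disequilibrium), per-gene power values are not expected to match a real
cohort's; the structural behaviours — null rejection near alpha, an
all-causal positive-control set near power 1, and the robustness ordering
of the combiners in noise-dominated sets — are what the runner is for.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import GeneDefinition, PairMap, QCThresholds, SimScenario
from .gene_stats import METHODS
from .permutation import run_gene_tests
from .preprocess import assemble_gene_sets, pair_snps_to_cpgs, qc_filter
from .stage1 import derive_phenotype, fit_stage1
from .synthetic import simulate_cohort

__all__ = [
    "GeneSpec",
    "ExperimentConfig",
    "build_catalogue",
    "default_major_genes",
    "build_set_catalogue",
    "build_null_catalogue",
    "run_replicate",
    "run_experiment",
    "pooled_by_category",
    "report",
]

ALL_METHODS = (*METHODS, "single_marker")


@dataclass
class GeneSpec:
    """One gene in the catalogue: size, category and (optional) causal pair."""

    gene_id: str
    n_pairs: int
    category: str = "noncausal"  # major_causal | minor_causal | noncausal
    h2: float = 0.0
    causal_maf: float = 0.2


def default_major_genes() -> list[GeneSpec]:
    """Five major-effect genes: sizes, heritabilities and causal-variant
    MAFs matching the study design this package emulates."""
    rows = [
        ("MAJ1", 141, 0.125, 0.11),
        ("MAJ2", 23, 0.100, 0.19),
        ("MAJ3", 63, 0.075, 0.10),
        ("MAJ4", 29, 0.050, 0.41),
        ("MAJ5", 32, 0.025, 0.14),
    ]
    return [GeneSpec(g, m, "major_causal", h2, maf) for g, m, h2, maf in rows]


@dataclass
class Catalogue:
    snps: pd.DataFrame
    cpgs: pd.DataFrame
    genes: list[GeneDefinition]
    overrides: dict[str, str]
    set_specs: dict[str, dict]
    causal_snp_ids: list[str]


def build_catalogue(
    gene_specs: list[GeneSpec],
    noise_maf_range: tuple[float, float] = (0.05, 0.5),
    seed: int = 0,
    snp_spacing_bp: int = 1000,
    cpg_offset_bp: int = 137,
    set_specs: dict[str, dict] | None = None,
) -> Catalogue:
    """Lay out genes on one synthetic chromosome.

    Each gene gets ``n_pairs`` SNPs spaced ``snp_spacing_bp`` apart with a
    CpG site ``cpg_offset_bp`` downstream of each SNP (so nearest-CpG
    pairing is unambiguous and yields exactly one pair per SNP).  The
    causal SNP of a causal gene sits mid-gene and is explicitly overridden
    to its own CpG, exercising the designated-CpG path.  Noise-SNP MAFs are
    drawn once from ``noise_maf_range`` and are part of the catalogue, not
    of the per-replicate randomness.
    """
    rng = np.random.default_rng(seed)
    snp_rows, cpg_rows, genes = [], [], []
    overrides: dict[str, str] = {}
    causal_snp_ids: list[str] = []
    cursor = 10_000
    for spec in gene_specs:
        causal_idx = spec.n_pairs // 2 if spec.h2 > 0 else -1
        start = cursor
        for j in range(spec.n_pairs):
            pos = cursor + j * snp_spacing_bp
            sid = f"{spec.gene_id}_s{j}"
            cid = f"{spec.gene_id}_c{j}"
            causal = j == causal_idx
            maf = spec.causal_maf if causal else float(rng.uniform(*noise_maf_range))
            snp_rows.append(
                {
                    "snp_id": sid,
                    "chrom": "1",
                    "pos": pos,
                    "maf": maf,
                    "h2": spec.h2 if causal else 0.0,
                    "cpg_id": cid,
                }
            )
            cpg_rows.append({"cpg_id": cid, "chrom": "1", "pos": pos + cpg_offset_bp})
            if causal:
                overrides[sid] = cid
                causal_snp_ids.append(sid)
        stop = cursor + (spec.n_pairs - 1) * snp_spacing_bp + snp_spacing_bp // 2
        genes.append(GeneDefinition(spec.gene_id, "1", start - snp_spacing_bp // 2, stop, spec.category))
        cursor = stop + 100_000  # intergenic gap
    return Catalogue(
        snps=pd.DataFrame(snp_rows),
        cpgs=pd.DataFrame(cpg_rows),
        genes=genes,
        overrides=overrides,
        set_specs=set_specs or {},
        causal_snp_ids=causal_snp_ids,
    )


def build_set_catalogue(
    n_minor: int = 0,
    minor_pairs: int = 10,
    n_noncausal: int = 10,
    noncausal_pairs: int = 30,
    seed: int = 0,
) -> Catalogue:
    """Catalogue with the five major genes plus the five named variant sets.

    CAUSAL5 holds only the 5 causal pairs (positive control); UNION5 and
    UNION2 are unions of gene pair-lists (288 and 92 pairs, 5 and 2 causal);
    NOISE5 and NOISE2 keep the same causal pairs but replace the in-gene
    neighbours with unrelated noncausal filler pairs (again 288 and 92
    pairs total).  Minor/noncausal genes supply the fillers.
    """
    specs = default_major_genes()
    for i in range(n_minor):
        specs.append(GeneSpec(f"MIN{i + 1}", minor_pairs, "minor_causal", 0.001, 0.2))
    filler_needed = 283 + 90
    n_noncausal = max(n_noncausal, int(np.ceil(filler_needed / noncausal_pairs)))
    for i in range(n_noncausal):
        specs.append(GeneSpec(f"NC{i + 1}", noncausal_pairs, "noncausal"))
    cat = build_catalogue(specs, seed=seed)
    major_ids = [s.gene_id for s in specs if s.category == "major_causal"]
    causal5 = cat.causal_snp_ids[:5]
    causal2 = [cat.causal_snp_ids[2], cat.causal_snp_ids[3]]  # MAJ3 + MAJ4 analogues
    filler_pool = [
        r["snp_id"]
        for r in cat.snps.to_dict("records")
        if r["h2"] == 0.0 and r["snp_id"].startswith(("NC", "MIN"))
    ]
    cat.set_specs = {
        "CAUSAL5": {"snps": causal5, "category": "synthetic_set"},
        "UNION5": {"union": major_ids, "category": "synthetic_set"},
        "UNION2": {"union": ["MAJ3", "MAJ4"], "category": "synthetic_set"},
        "NOISE5": {"snps": causal5 + filler_pool[:283], "category": "synthetic_set"},
        "NOISE2": {"snps": causal2 + filler_pool[283 : 283 + 90], "category": "synthetic_set"},
    }
    return cat


def build_null_catalogue(
    n_genes: int = 39,
    sizes: tuple[int, ...] = (5, 8, 10, 12, 15, 18, 20, 22, 25, 28, 30),
    seed: int = 0,
) -> Catalogue:
    """Catalogue of noncausal genes only, for type-I-error experiments.

    Gene sizes cycle through ``sizes`` (kept modest, m <= 30, since null
    calibration is a per-gene property, not a function of gene length).
    """
    specs = [
        GeneSpec(f"NC{i + 1}", sizes[i % len(sizes)], "noncausal") for i in range(n_genes)
    ]
    return build_catalogue(specs, seed=seed)


@dataclass
class ExperimentConfig:
    """A full simulation experiment: scenario x catalogue x testing plan."""

    catalogue: Catalogue
    n_individuals: int = 670
    sibship_sizes: tuple[int, ...] = (2, 3, 4)
    sigma2_g: float = 0.2
    meth_beta: tuple[float, float] = (2.0, 2.0)
    n_replicates: int = 200
    b_permutations: int = 1000
    alpha: float = 0.05
    master_seed: int = 0
    qc: QCThresholds = field(default_factory=QCThresholds)
    residual_type: str = "conditional"

    def scenario(self) -> SimScenario:
        return SimScenario(
            n_individuals=self.n_individuals,
            sibship_sizes=self.sibship_sizes,
            snps=self.catalogue.snps,
            cpgs=self.catalogue.cpgs,
            sigma2_g=self.sigma2_g,
            meth_beta_a=self.meth_beta[0],
            meth_beta_b=self.meth_beta[1],
        )


def _replicate_seeds(master_seed: int, rep: int) -> tuple[int, int]:
    """Deterministic, stream-separated cohort and permutation seeds."""
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(rep,))
    s_cohort, s_perm = ss.generate_state(2)
    return int(s_cohort & 0x7FFFFFFF), int(s_perm & 0x7FFFFFFF)


def _resolve_sets(
    pairs: PairMap, set_specs: dict[str, dict]
) -> tuple[dict[str, list[str]], dict[str, np.ndarray]]:
    """Translate catalogue set specs into union lists / pair-index arrays."""
    union_sets, spiked_sets = {}, {}
    snp_to_pair = {sid: k for k, sid in enumerate(pairs.snp_ids)}
    for set_id, spec in set_specs.items():
        if "union" in spec:
            union_sets[set_id] = spec["union"]
        else:
            idx = [snp_to_pair[s] for s in spec["snps"] if s in snp_to_pair]
            spiked_sets[set_id] = np.asarray(idx, dtype=int)
    return union_sets, spiked_sets


def run_replicate(cfg: ExperimentConfig, rep: int) -> pd.DataFrame:
    """One replicate: simulate -> QC -> pair -> stage 1 -> stage 2 ->
    statistics -> permutation -> decisions."""
    s_cohort, s_perm = _replicate_seeds(cfg.master_seed, rep)
    cohort = simulate_cohort(cfg.scenario(), seed=s_cohort)

    keep = qc_filter(cohort.genotypes, cfg.qc)
    pairs = pair_snps_to_cpgs(
        cohort.genotypes, cohort.methylation, keep, overrides=cfg.catalogue.overrides
    )
    union_sets, spiked_sets = _resolve_sets(pairs, cfg.catalogue.set_specs)
    pairs = assemble_gene_sets(
        pairs,
        cohort.genotypes,
        cfg.catalogue.genes,
        major_snp_ids=tuple(cfg.catalogue.causal_snp_ids),
        union_sets=union_sets,
        spiked_sets=spiked_sets,
    )

    y, cov = derive_phenotype(cohort.phenotypes)
    if len(y) < cohort.kinship.n:
        raise RuntimeError("individuals excluded at phenotype derivation in a synthetic cohort")
    fit = fit_stage1(y.to_numpy(), cov, cohort.kinship, residual_type=cfg.residual_type)

    res = run_gene_tests(
        fit.residuals,
        cohort.genotypes,
        cohort.methylation,
        pairs,
        b=cfg.b_permutations,
        seed=s_perm,
        alpha=cfg.alpha,
    )
    res.insert(0, "replicate", rep)
    return res


def run_experiment(cfg: ExperimentConfig, progress: bool = False) -> pd.DataFrame:
    """Rejection proportions per gene/set and method over all replicates.

    Returns the PowerTable: columns gene_id, category, method,
    rejection_proportion, n_replicates.  Failed replicates are logged and
    excluded from the denominators.
    """
    import logging

    logger = logging.getLogger(__name__)
    all_rows = []
    for rep in range(cfg.n_replicates):
        try:
            all_rows.append(run_replicate(cfg, rep))
        except Exception as exc:  # noqa: BLE001 - a replicate may fail without killing the run
            logger.warning("replicate %d failed: %s", rep, exc)
        if progress and (rep + 1) % 10 == 0:
            logger.info("completed %d/%d replicates", rep + 1, cfg.n_replicates)
    if not all_rows:
        return pd.DataFrame(
            columns=["gene_id", "category", "method", "rejection_proportion", "n_replicates"]
        )
    detail = pd.concat(all_rows, ignore_index=True)
    table = (
        detail.groupby(["gene_id", "category", "method"], sort=False)["significant"]
        .agg(rejection_proportion="mean", n_replicates="size")
        .reset_index()
    )
    table.attrs["detail"] = detail
    return table


def pooled_by_category(table: pd.DataFrame) -> pd.DataFrame:
    """Category-pooled rejection proportions (every gene x replicate
    weighted equally)."""
    detail = table.attrs.get("detail")
    if detail is None:
        raise ValueError("table has no replicate-level detail attached")
    return (
        detail.groupby(["category", "method"], sort=False)["significant"]
        .agg(rejection_proportion="mean", n_gene_replicates="size")
        .reset_index()
    )


def report(table: pd.DataFrame, out_dir: str | Path, fmt: str = "tsv") -> list[Path]:
    """Write the PowerTable (and pooled summary when available) to disk."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    path = out_dir / "power_table.tsv"
    table.to_csv(path, sep="\t", index=False)
    written.append(path)
    try:
        pooled = pooled_by_category(table)
    except ValueError:
        pooled = None
    if pooled is not None:
        path = out_dir / "power_by_category.tsv"
        pooled.to_csv(path, sep="\t", index=False)
        written.append(path)
    return written
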
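"""SNP quality control and assembly of SNP-CpG pairs into genes and sets.

QC keeps a SNP iff HWE p > 1e-6, MAF > 1% and missing-call rate < 5%
(strict inequalities, defaults of :class:`~methgene.datatypes.QCThresholds`).
Each kept SNP is then paired to its nearest CpG site on the same chromosome
(point-to-point distance, ties broken toward the lower coordinate), unless
an explicit override assigns it to a designated CpG.  Genes collect all
pairs whose SNP lies within the gene's start-stop interval; major-effect
SNPs falling outside every gene are rescued by a 50-kb orphan rule.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import (
    MISSING_GENOTYPE,
    GeneDefinition,
    GenotypeMatrix,
    MethylationMatrix,
    PairMap,
    QCThresholds,
)

logger = logging.getLogger(__name__)

__all__ = [
    "hwe_test",
    "genotype_counts",
    "qc_filter",
    "pair_snps_to_cpgs",
    "assemble_gene_sets",
]

#: Maximum SNP-to-CpG distance an override may span without a warning.
OVERRIDE_WARN_BP = 12_500


def hwe_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Hardy-Weinberg goodness-of-fit p-value (1-df chi-square, no
    continuity correction).

    Monomorphic SNPs (sample allele frequency 0 or 1) return 1 by
    convention: there is nothing to test.
    """
    counts = np.array([n_AA, n_Aa, n_aa], dtype=float)
    if (counts < 0).any():
        raise ValueError("genotype counts must be nonnegative")
    n = counts.sum()
    if n == 0:
        raise ValueError("all genotype counts are zero")
    p_hat = (2 * n_aa + n_Aa) / (2 * n)
    if p_hat in (0.0, 1.0):
        return 1.0
    expected = n * np.array([(1 - p_hat) ** 2, 2 * p_hat * (1 - p_hat), p_hat**2])
    chi2 = float(((counts - expected) ** 2 / expected).sum())
    return float(stats.chi2.sf(chi2, df=1))


def genotype_counts(geno: GenotypeMatrix) -> pd.DataFrame:
    """Per-SNP genotype counts, MAF (folded to <= 0.5) and missing rate."""
    v = geno.values
    miss = v == MISSING_GENOTYPE
    n0 = ((v == 0) & ~miss).sum(axis=0)
    n1 = (v == 1).sum(axis=0)
    n2 = (v == 2).sum(axis=0)
    n_called = n0 + n1 + n2
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(n_called > 0, (2 * n2 + n1) / (2 * n_called), np.nan)
    maf = np.minimum(freq, 1 - freq)
    return pd.DataFrame(
        {
            "snp_id": geno.snp_ids,
            "n_AA": n0,
            "n_Aa": n1,
            "n_aa": n2,
            "n_called": n_called,
            "maf": maf,
            "missing_rate": miss.mean(axis=0),
        }
    )


def qc_filter(geno: GenotypeMatrix, thr: QCThresholds | None = None) -> np.ndarray:
    """Boolean keep-mask over SNPs under the three strict QC inequalities.

    MAF is computed on non-missing calls and folded.  SNPs with zero
    non-missing calls are dropped and logged.
    """
    thr = thr or QCThresholds()
    tab = genotype_counts(geno)
    hwe_p = np.ones(len(tab))
    for i, row in enumerate(tab.itertuples(index=False)):
        if row.n_called > 0:
            hwe_p[i] = hwe_test(row.n_AA, row.n_Aa, row.n_aa)
    no_calls = tab["n_called"].to_numpy() == 0
    if no_calls.any():
        logger.warning("%d SNP(s) with zero non-missing calls dropped", no_calls.sum())
    maf = np.nan_to_num(tab["maf"].to_numpy(), nan=0.0)
    keep = (
        ~no_calls
        & (hwe_p > thr.hwe_p_min)
        & (maf > thr.maf_min)
        & (tab["missing_rate"].to_numpy() < thr.missing_max)
    )
    return keep


def pair_snps_to_cpgs(
    geno: GenotypeMatrix,
    meth: MethylationMatrix,
    keep_mask: np.ndarray | None = None,
    overrides: dict[str, str] | None = None,
) -> PairMap:
    """Assign every kept SNP to exactly one CpG site.

    Default rule: the minimum-|distance| CpG on the same chromosome, ties
    broken toward the lower coordinate.  ``overrides`` (snp_id -> cpg_id)
    wins over the nearest rule; an override spanning more than 12,500 bp
    triggers a warning but is honoured.
    """
    if keep_mask is None:
        keep_mask = np.ones(geno.n_snps, dtype=bool)
    overrides = overrides or {}
    cpg_lookup = {cid: j for j, cid in enumerate(meth.cpg_ids)}

    snp_idx_out: list[int] = []
    cpg_idx_out: list[int] = []
    kept = np.flatnonzero(keep_mask)
    for chrom in pd.unique(geno.chromosomes[kept]):
        snp_sel = kept[geno.chromosomes[kept] == chrom]
        cpg_sel = np.flatnonzero(meth.chromosomes == chrom)
        if len(cpg_sel) == 0:
            raise ValueError(f"chromosome {chrom} has SNPs but no CpG sites")
        cpg_pos = meth.positions[cpg_sel]
        order = np.argsort(cpg_pos, kind="stable")
        cpg_sel, cpg_pos = cpg_sel[order], cpg_pos[order]
        for si in snp_sel:
            sid = geno.snp_ids[si]
            if sid in overrides:
                cj = cpg_lookup[overrides[sid]]
                dist = abs(int(meth.positions[cj]) - int(geno.positions[si]))
                if dist > OVERRIDE_WARN_BP:
                    warnings.warn(
                        f"override pairing {sid}->{overrides[sid]} spans {dist} bp "
                        f"(> {OVERRIDE_WARN_BP})",
                        stacklevel=2,
                    )
                snp_idx_out.append(si)
                cpg_idx_out.append(cj)
                continue
            pos = geno.positions[si]
            k = int(np.searchsorted(cpg_pos, pos))
            best = None
            for cand in (k - 1, k):
                if 0 <= cand < len(cpg_pos):
                    d = abs(int(cpg_pos[cand]) - int(pos))
                    # strict < keeps the lower-coordinate CpG on ties
                    if best is None or d < best[0]:
                        best = (d, cand)
            snp_idx_out.append(si)
            cpg_idx_out.append(int(cpg_sel[best[1]]))

    order = np.argsort(snp_idx_out, kind="stable")
    snp_index = np.asarray(snp_idx_out, dtype=int)[order]
    cpg_index = np.asarray(cpg_idx_out, dtype=int)[order]
    return PairMap(
        snp_ids=geno.snp_ids[snp_index],
        cpg_ids=meth.cpg_ids[cpg_index],
        snp_index=snp_index,
        cpg_index=cpg_index,
    )


def assemble_gene_sets(
    pairs: PairMap,
    geno: GenotypeMatrix,
    genes: list[GeneDefinition],
    major_snp_ids: tuple[str, ...] = (),
    orphan_rule_bp: int = 50_000,
    union_sets: dict[str, list[str]] | None = None,
    spiked_sets: dict[str, np.ndarray] | None = None,
) -> PairMap:
    """Group pairs into genes and optional union/spiked sets.

    A pair belongs to gene ``k`` iff its SNP position satisfies
    ``start <= pos <= stop`` on the gene's chromosome (1-based inclusive).
    A *major* SNP caught by no gene is appended to the nearest gene within
    ``orphan_rule_bp``; failing that, a synthetic gene spanning +/-
    ``orphan_rule_bp`` around the SNP is created.  ``union_sets`` maps a set
    id to gene ids whose pairs are unioned; ``spiked_sets`` maps a set id to
    an explicit pair-index array (causal pairs plus listed fillers).  Genes
    left empty after assembly are excluded and logged.
    """
    pos = geno.positions[pairs.snp_index]
    chrom = geno.chromosomes[pairs.snp_index]
    sid = pairs.snp_ids

    assignments: dict[str, np.ndarray] = {}
    categories: dict[str, str] = {}
    genes = list(genes)

    claimed = np.zeros(pairs.n_pairs, dtype=bool)
    for g in genes:
        in_gene = (chrom == g.chromosome) & (pos >= g.start) & (pos <= g.stop)
        assignments[g.gene_id] = np.flatnonzero(in_gene)
        categories[g.gene_id] = g.category
        claimed |= in_gene

    for major in major_snp_ids:
        hit = np.flatnonzero(sid == major)
        if len(hit) == 0 or claimed[hit[0]]:
            continue
        j = hit[0]
        # distance to nearest gene interval on the same chromosome
        best_gene, best_dist = None, None
        for g in genes:
            if g.chromosome != chrom[j]:
                continue
            d = max(g.start - pos[j], pos[j] - g.stop, 0)
            if best_dist is None or d < best_dist:
                best_gene, best_dist = g, d
        if best_gene is not None and best_dist <= orphan_rule_bp:
            assignments[best_gene.gene_id] = np.append(assignments[best_gene.gene_id], j)
            claimed[j] = True
        else:
            synth_id = f"SYNTH_{major}"
            lo, hi = pos[j] - orphan_rule_bp, pos[j] + orphan_rule_bp
            members = np.flatnonzero((chrom == chrom[j]) & (pos >= lo) & (pos <= hi))
            assignments[synth_id] = members
            categories[synth_id] = "major_causal"
            claimed[members] = True

    for set_id, gene_ids in (union_sets or {}).items():
        member = np.unique(np.concatenate([assignments[g] for g in gene_ids]))
        assignments[set_id] = member
        categories[set_id] = "synthetic_set"
    for set_id, idx in (spiked_sets or {}).items():
        assignments[set_id] = np.asarray(idx, dtype=int)
        categories[set_id] = "synthetic_set"

    empty = [k for k, v in assignments.items() if len(v) == 0]
    for k in empty:
        logger.warning("gene/set %s is empty after assembly; excluded", k)
        del assignments[k]
        del categories[k]

    return PairMap(
        snp_ids=pairs.snp_ids,
        cpg_ids=pairs.cpg_ids,
        snp_index=pairs.snp_index,
        cpg_index=pairs.cpg_index,
        gene_assignments=assignments,
        gene_categories=categories,
    )
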
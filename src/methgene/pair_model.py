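"""Stage 2: per-pair regression of residuals on SNP, CpG and interaction.

For each SNP-CpG pair the stage-1 residual vector r is regressed on
{SNP, CPG, SNP*CPG} (an intercept is included by default; the literal
no-intercept form is available) and the overall-model F test of the slope
coefficients gives the pair p-value p_j.

Rank-deficient designs are reduced rather than discarded: the F test spans
whatever slope directions remain identifiable (e.g. with a point-mass CpG
the model collapses to a single-SNP regression with a 1-df numerator) and
the ``degenerate`` flag records that the full three-term model was not
estimable.  Only when no slope direction varies at all — a monomorphic SNP
*and* constant CpG — is p = 1 returned.  p-values are clamped to
[1e-300, 1] so ln p stays finite downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .datatypes import MISSING_GENOTYPE, GenotypeMatrix, MethylationMatrix, PairMap

__all__ = ["PairFit", "P_FLOOR", "MIN_EXTRA_OBS", "fit_pair", "fit_all_pairs", "PairDesigns"]

#: Lower clamp for p-values; keeps ln(p) finite for the combiners.
P_FLOOR = 1e-300

#: Required excess of observations over fitted parameters.
MIN_EXTRA_OBS = 10

_RANK_TOL = 1e-9


@dataclass
class PairFit:
    beta_s: float
    beta_c: float
    beta_sc: float
    f_stat: float
    df: tuple[int, int]
    p_value: float
    n_used: int
    degenerate: bool = False


def _orthobasis(x: np.ndarray) -> tuple[np.ndarray, int]:
    """Orthonormal basis of the column space of x and its rank."""
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    rank = int((s > _RANK_TOL * s[0]).sum()) if s.size and s[0] > 0 else 0
    return u[:, :rank], rank


def _f_p(ssm: float, sse: float, q: int, df2: int) -> tuple[float, float]:
    if q == 0:
        return 0.0, 1.0
    if sse <= 0.0:
        return np.inf, P_FLOOR
    f = (ssm / q) / (sse / df2)
    return f, float(np.clip(stats.f.sf(f, q, df2), P_FLOOR, 1.0))


def fit_pair(
    r: np.ndarray,
    snp: np.ndarray,
    cpg: np.ndarray,
    include_intercept: bool = True,
) -> PairFit:
    """Least-squares fit of r on {1, SNP, CPG, SNP*CPG} with the joint
    F test of the slope terms.

    Individuals with a missing genotype call are dropped pairwise.  With
    ``include_intercept=False`` the literal three-term model is fitted and
    the F test compares it against the zero model (uncentred total sum of
    squares).
    """
    r = np.asarray(r, dtype=float)
    snp = np.asarray(snp, dtype=float)
    cpg = np.asarray(cpg, dtype=float)
    keep = snp != MISSING_GENOTYPE
    r, snp, cpg = r[keep], snp[keep], cpg[keep]
    if not (np.isfinite(r).all() and np.isfinite(snp).all() and np.isfinite(cpg).all()):
        raise ValueError("non-finite values in pair-model inputs")

    cols = [snp, cpg, snp * cpg]
    if include_intercept:
        x = np.column_stack([np.ones(len(r)), *cols])
    else:
        x = np.column_stack(cols)
    n, p_full = x.shape
    if n - p_full < MIN_EXTRA_OBS:
        raise ValueError(f"need at least {MIN_EXTRA_OBS} more observations than parameters")

    q_basis, rank = _orthobasis(x)
    degenerate = rank < p_full
    beta = np.full(p_full, np.nan)
    if not degenerate:
        beta, _, _, _ = np.linalg.lstsq(x, r, rcond=None)

    coef = q_basis.T @ r
    fit_ss = float(coef @ coef)
    tot_ss = float(r @ r)
    sse = max(tot_ss - fit_ss, 0.0)
    if include_intercept:
        sst = tot_ss - n * float(r.mean()) ** 2
        q = rank - 1 if rank >= 1 else 0
    else:
        sst = tot_ss
        q = rank
    ssm = max(sst - sse, 0.0)
    df2 = n - rank
    f, pval = _f_p(ssm, sse, q, df2)
    b = beta[1:] if include_intercept else beta
    return PairFit(
        float(b[0]), float(b[1]), float(b[2]), f, (q, df2), pval, n, degenerate=degenerate
    )


class PairDesigns:
    """Precomputed orthonormal pair designs for fast repeated response fits.

    For each pair, the design X = [1, SNP, CPG, SNP*CPG] (rows restricted
    to non-missing genotypes) is reduced to an orthonormal basis Q of its
    column space.  For any response y, SSE = ||y||^2 - ||Q'y||^2 and the
    centred model sum of squares is (||y||^2 - n ybar^2) - SSE, so
    refitting under a new response — a permuted residual vector — costs one
    small matrix product instead of a full regression.  This is what makes
    shuffle-sharing permutation sweeps O(B) vector products per pair.
    """

    def __init__(self, geno: GenotypeMatrix, meth: MethylationMatrix, pairs: PairMap):
        n = geno.n_individuals
        self.n_pairs = pairs.n_pairs
        self.n = n
        self.q_blocks: list[np.ndarray | None] = []
        self.row_subsets: list[np.ndarray | None] = []
        self.q_num = np.zeros(pairs.n_pairs, dtype=int)  # numerator df of the F test
        self.df2 = np.empty(pairs.n_pairs, dtype=int)
        self.degenerate = np.zeros(pairs.n_pairs, dtype=bool)
        for k in range(pairs.n_pairs):
            snp = geno.values[:, pairs.snp_index[k]].astype(float)
            cpg = meth.values[:, pairs.cpg_index[k]]
            keep = snp != MISSING_GENOTYPE
            snp_k, cpg_k = snp[keep], cpg[keep]
            x = np.column_stack([np.ones(keep.sum()), snp_k, cpg_k, snp_k * cpg_k])
            if x.shape[0] - 4 < MIN_EXTRA_OBS:
                raise ValueError("too few non-missing observations for pair model")
            q_basis, rank = _orthobasis(x)
            self.degenerate[k] = rank < 4
            self.q_num[k] = max(rank - 1, 0)
            self.df2[k] = x.shape[0] - rank
            self.q_blocks.append(q_basis if rank > 1 else None)
            self.row_subsets.append(None if keep.all() else np.flatnonzero(keep))
        # full-row pairs with full rank are stacked for one BLAS product
        self._full = [
            k
            for k in range(self.n_pairs)
            if self.q_num[k] == 3 and self.row_subsets[k] is None
        ]
        self._qstack = (
            np.concatenate([self.q_blocks[k].T for k in self._full], axis=0)
            if self._full
            else np.zeros((0, n))
        )

    def p_values(self, responses: np.ndarray) -> np.ndarray:
        """Pair F-test p-values for each response column.

        ``responses`` is (n, B); returns (n_pairs, B) clamped p-values.
        Pairs with nothing to test yield p = 1 in every column.
        """
        resp = np.asarray(responses, dtype=float)
        if resp.ndim == 1:
            resp = resp[:, None]
        b = resp.shape[1]
        out = np.ones((self.n_pairs, b))
        tot_ss = (resp**2).sum(axis=0)
        sst_c = tot_ss - self.n * resp.mean(axis=0) ** 2

        if self._full:
            a = self._qstack @ resp  # (4*n_full, B)
            fit_ss = (a**2).reshape(len(self._full), 4, b).sum(axis=1)
            sse = np.maximum(tot_ss[None, :] - fit_ss, 0.0)
            ssm = np.maximum(sst_c[None, :] - sse, 0.0)
            df2 = self.df2[self._full][:, None]
            with np.errstate(divide="ignore", invalid="ignore"):
                f = (ssm / 3.0) / (sse / df2)
            p = stats.f.sf(f, 3, df2)
            p[~np.isfinite(f)] = 0.0  # perfect fit underflows to the clamp
            out[self._full, :] = np.clip(p, P_FLOOR, 1.0)

        for k in range(self.n_pairs):
            if k in self._full or self.q_num[k] == 0:
                continue
            sub = self.row_subsets[k]
            rsub = resp if sub is None else resp[sub, :]
            tot = (rsub**2).sum(axis=0)
            sst = tot - rsub.shape[0] * rsub.mean(axis=0) ** 2
            fit_ss = ((self.q_blocks[k].T @ rsub) ** 2).sum(axis=0)
            sse = np.maximum(tot - fit_ss, 0.0)
            ssm = np.maximum(sst - sse, 0.0)
            with np.errstate(divide="ignore", invalid="ignore"):
                f = (ssm / self.q_num[k]) / (sse / self.df2[k])
            p = stats.f.sf(f, self.q_num[k], self.df2[k])
            p[~np.isfinite(f)] = 0.0
            out[k, :] = np.clip(p, P_FLOOR, 1.0)
        return out


def fit_all_pairs(
    r: np.ndarray,
    geno: GenotypeMatrix,
    meth: MethylationMatrix,
    pairs: PairMap,
) -> np.ndarray:
    """Observed p_j for every pair, order-aligned with the PairMap."""
    if pairs.n_pairs == 0:
        return np.empty(0)
    designs = PairDesigns(geno, meth, pairs)
    return designs.p_values(np.asarray(r, dtype=float))[:, 0]
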
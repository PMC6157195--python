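"""Gene-level statistics combining per-pair p-values.

Six combiners, all oriented so that a *smaller* statistic is more extreme:

========================  =====================================================
sum_ln_p                  Fisher-style burden analogue, sum_j ln p_j
sum_neg_sq_ln_p           variance-components analogue, sum_j -(ln p_j)^2
min_p                     minimum p_j
pt_0.01 / pt_0.05 / pt_0.10  truncated threshold statistics: a pair
                          contributes -(ln(p_j/T))^2 when p_j <= T and 0
                          otherwise, so pairs non-significant at T add
                          nothing ("noise" pairs are zeroed out)
========================  =====================================================

The threshold statistic is continuous at p = T (both branches vanish) and
at T = 1 it coincides with sum_neg_sq_ln_p.  Significance for all six is by
permutation only; the single-marker comparator applies a per-gene
Bonferroni rule (min p < alpha / m).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "METHODS",
    "sum_ln_p",
    "sum_neg_sq_ln_p",
    "min_p",
    "threshold_stat",
    "compute_all",
    "single_marker_decision",
]

#: Canonical method order used in result tables.
METHODS = ("sum_ln_p", "sum_neg_sq_ln_p", "min_p", "pt_0.10", "pt_0.05", "pt_0.01")


def _check(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.shape[0] == 0:
        raise ValueError("empty p-value vector")
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1] (clamp upstream)")
    return p


def sum_ln_p(p: np.ndarray) -> float | np.ndarray:
    """Sum of natural-log-transformed p-values (axis 0 for matrices)."""
    return np.log(_check(p)).sum(axis=0)


def sum_neg_sq_ln_p(p: np.ndarray) -> float | np.ndarray:
    """Sum of negative squared log-transformed p-values."""
    return (-np.log(_check(p)) ** 2).sum(axis=0)


def min_p(p: np.ndarray) -> float | np.ndarray:
    """Minimum p-value over the gene's pairs."""
    return _check(p).min(axis=0)


def threshold_stat(p: np.ndarray, threshold: float) -> float | np.ndarray:
    """Truncated combiner: sum of -(ln(p_j/T))^2 over pairs with p_j <= T."""
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must lie in (0, 1]")
    p = _check(p)
    term = np.where(p <= threshold, -np.log(p / threshold) ** 2, 0.0)
    return term.sum(axis=0)


def compute_all(p: np.ndarray) -> dict[str, float | np.ndarray]:
    """All six statistics; for a (m, B) matrix, each value is length B."""
    return {
        "sum_ln_p": sum_ln_p(p),
        "sum_neg_sq_ln_p": sum_neg_sq_ln_p(p),
        "min_p": min_p(p),
        "pt_0.10": threshold_stat(p, 0.10),
        "pt_0.05": threshold_stat(p, 0.05),
        "pt_0.01": threshold_stat(p, 0.01),
    }


def single_marker_decision(p: np.ndarray, alpha: float = 0.05) -> bool:
    """Bonferroni single-marker rule: any p_j < alpha / m."""
    p = _check(p)
    return bool(p.min() < alpha / p.shape[0])
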
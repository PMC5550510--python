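"""Exact small-sample nonparametric tests.

Matched-pair comparisons between array datasets (e.g. a panel of ECM
genes measured under albumin vs. albumin plus TGFbeta-receptor
blockers) involve sample sizes far too small for asymptotic p-values:
with n = 8 pairs the smallest attainable two-sided signed-rank p is
2^(1-8) = 0.0078125.  Both tests here therefore enumerate the full
exact null distribution -- all 2^n sign assignments for the signed-rank
test, all C(nx+ny, nx) group labelings for the Mann-Whitney test --
and report the two-sided p as twice the smaller tail, capped at 1.
"""

from __future__ import annotations

from itertools import combinations
from typing import Iterable, NamedTuple

import numpy as np
from scipy.stats import rankdata

__all__ = [
    "WilcoxonResult",
    "MannWhitneyResult",
    "wilcoxon_signed_rank_exact",
    "mann_whitney_exact",
    "signed_rank_null_distribution",
]

MAX_EXACT_PAIRS = 20
MAX_EXACT_POOLED = 12


class WilcoxonResult(NamedTuple):
    w: float  # sum of ranks of positive differences
    p_two_sided: float
    n: int  # nonzero pairs used


class MannWhitneyResult(NamedTuple):
    u: float  # pairs with x > y plus half the ties
    p_two_sided: float
    method: str  # "exact" or "normal"


def signed_rank_null_distribution(ranks: Iterable[float]) -> dict[float, int]:
    """Null distribution of W (sum of positive-sign ranks) conditional
    on the observed midranks: counts over all 2^n sign assignments.

    Computed by polynomial convolution over doubled (integer) ranks, so
    midranks of the form k/2 are handled exactly.
    """
    doubled = [int(round(2 * r)) for r in ranks]
    if any(abs(2 * r - d) > 1e-9 for r, d in zip(ranks, doubled)):
        raise ValueError("ranks must be multiples of 1/2 (midranks)")
    total = sum(doubled)
    counts = np.zeros(total + 1, dtype=object)
    counts[0] = 1
    for d in doubled:
        shifted = np.zeros_like(counts)
        shifted[d:] = counts[: total + 1 - d]
        counts = counts + shifted
    return {i / 2.0: int(c) for i, c in enumerate(counts) if c}


def wilcoxon_signed_rank_exact(diffs: Iterable[float]) -> WilcoxonResult:
    """Exact two-sided Wilcoxon signed-rank test on paired differences.

    Zero differences are dropped; tied magnitudes receive midranks; the
    null distribution conditions on the observed midranks and is
    enumerated over all 2^n equally likely sign assignments.  The
    two-sided p doubles the smaller of P(W <= w_obs) and P(W >= w_obs),
    capped at 1.

    Raises for an empty nonzero sample and for n > 20 pairs (callers
    wanting an approximation must opt in to one explicitly).
    """
    d = np.asarray(list(diffs), dtype=float)
    if d.size == 0:
        raise ValueError("no paired differences supplied")
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise ValueError("all paired differences are zero")
    if n > MAX_EXACT_PAIRS:
        raise ValueError(
            f"{n} nonzero pairs exceeds the exact enumeration range ({MAX_EXACT_PAIRS}); "
            "use an explicit large-sample approximation instead"
        )
    ranks = rankdata(np.abs(d))
    w_obs = float(ranks[d > 0].sum())
    dist = signed_rank_null_distribution(ranks)
    total = float(2**n)
    eps = 1e-9
    p_le = sum(c for w, c in dist.items() if w <= w_obs + eps) / total
    p_ge = sum(c for w, c in dist.items() if w >= w_obs - eps) / total
    p = min(1.0, 2.0 * min(p_le, p_ge))
    return WilcoxonResult(w=w_obs, p_two_sided=p, n=n)


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    gt = (x[:, None] > y[None, :]).sum()
    eq = (x[:, None] == y[None, :]).sum()
    return float(gt) + 0.5 * float(eq)


def mann_whitney_exact(x: Iterable[float], y: Iterable[float]) -> MannWhitneyResult:
    """Two-sided Mann-Whitney test; exact by enumeration when the pooled
    sample has <= 12 observations, else a tie-corrected normal
    approximation with continuity correction (method reported).
    """
    xa = np.asarray(list(x), dtype=float)
    ya = np.asarray(list(y), dtype=float)
    if xa.size == 0 or ya.size == 0:
        raise ValueError("both samples must be nonempty")
    nx, ny = xa.size, ya.size
    u_obs = _u_statistic(xa, ya)
    pooled = np.concatenate([xa, ya])
    if nx + ny <= MAX_EXACT_POOLED:
        idx = range(nx + ny)
        us = []
        for x_pos in combinations(idx, nx):
            mask = np.zeros(nx + ny, dtype=bool)
            mask[list(x_pos)] = True
            us.append(_u_statistic(pooled[mask], pooled[~mask]))
        us = np.asarray(us)
        eps = 1e-9
        p_le = float((us <= u_obs + eps).sum()) / us.size
        p_ge = float((us >= u_obs - eps).sum()) / us.size
        p = min(1.0, 2.0 * min(p_le, p_ge))
        return MannWhitneyResult(u=u_obs, p_two_sided=p, method="exact")
    # tie-corrected normal approximation
    n = nx + ny
    mu = nx * ny / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3) - tie_counts).sum())
    sigma2 = nx * ny / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if sigma2 <= 0:
        return MannWhitneyResult(u=u_obs, p_two_sided=1.0, method="normal")
    from scipy.stats import norm

    z = (abs(u_obs - mu) - 0.5) / np.sqrt(sigma2)
    p = min(1.0, 2.0 * float(norm.sf(max(z, 0.0))))
    return MannWhitneyResult(u=u_obs, p_two_sided=p, method="normal")
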
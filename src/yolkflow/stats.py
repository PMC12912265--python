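"""Hypothesis tests applied to per-embryo summaries.

Welch's unequal-variance *t*-test, the Mann–Whitney U test (exact by
enumeration for small untied samples, tie-corrected normal
approximation with continuity correction otherwise) and the χ²
goodness-of-fit test on quadrant counts (re-exported from the PIV
module). Tails are always explicit and recorded verbatim in the result;
p-values are never truncated.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
from scipy import stats as _stats

from .piv import TestResult, compare_quadrants  # noqa: F401  (re-export)

__all__ = ["welch_t", "mann_whitney", "compare_quadrants", "TestResult"]


def welch_t(a, b, tails: str = "two") -> TestResult:
    """Welch's t-test for unequal variances.

    ``t = (x̄_a − x̄_b)/√(s²_a/n_a + s²_b/n_b)`` with Welch–Satterthwaite
    degrees of freedom. One-tailed p is for the alternative mean(a) >
    mean(b).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs n >= 2")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            return TestResult("welch_t", 0.0, 1.0, tails, df=float(a.size + b.size - 2),
                              group_sizes=(a.size, b.size))
        raise ValueError("both samples have zero variance with different means")
    sa, sb = va / a.size, vb / b.size
    t = (a.mean() - b.mean()) / np.sqrt(sa + sb)
    df = (sa + sb) ** 2 / (sa**2 / (a.size - 1) + sb**2 / (b.size - 1))
    if tails == "two":
        p = 2.0 * _stats.t.sf(abs(t), df)
    elif tails == "one":
        p = _stats.t.sf(t, df)
    else:
        raise ValueError(f"tails must be 'one' or 'two', got {tails!r}")
    return TestResult(
        name="welch_t",
        statistic=float(t),
        p_value=float(min(p, 1.0)),
        tails=tails,
        df=float(df),
        group_sizes=(a.size, b.size),
    )


def _u_from_ranks(a: np.ndarray, b: np.ndarray) -> float:
    """U statistic for sample a, midranks for ties."""
    pooled = np.concatenate([a, b])
    ranks = _stats.rankdata(pooled)
    ra = ranks[: a.size].sum()
    return float(ra - a.size * (a.size + 1) / 2.0)


def mann_whitney(a, b, tails: str = "two") -> TestResult:
    """Mann–Whitney U test.

    Exact p by enumerating all label assignments when ``n_a + n_b ≤ 12``
    and there are no ties; otherwise a normal approximation with
    tie-corrected variance and continuity correction. One-tailed p is
    for the alternative that ``a`` is stochastically larger.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("samples must be non-empty")
    if tails not in ("one", "two"):
        raise ValueError(f"tails must be 'one' or 'two', got {tails!r}")
    na, nb = a.size, b.size
    u_a = _u_from_ranks(a, b)
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    if na + nb <= 12 and not has_ties:
        # enumerate every labelling; without ties the pooled ranks are
        # exactly 1..n, so U = (sum of selected ranks) - na(na+1)/2
        all_u = np.asarray(
            [sum(combo) - na * (na + 1) / 2.0
             for combo in combinations(range(1, na + nb + 1), na)]
        )
        if tails == "two":
            mu = na * nb / 2.0
            p = float(np.mean(np.abs(all_u - mu) >= abs(u_a - mu) - 1e-12))
        else:
            p = float(np.mean(all_u >= u_a - 1e-12))
        method = "exact"
    else:
        mu = na * nb / 2.0
        n = na + nb
        _, counts = np.unique(pooled, return_counts=True)
        tie_term = np.sum(counts**3 - counts) / (n * (n - 1))
        sigma2 = na * nb / 12.0 * (n + 1 - tie_term)
        sigma = np.sqrt(sigma2)
        if sigma == 0:
            p = 1.0
        else:
            z = (abs(u_a - mu) - 0.5) / sigma  # continuity correction
            z = max(z, 0.0)
            p = 2.0 * _stats.norm.sf(z) if tails == "two" else float(
                _stats.norm.sf((u_a - mu - 0.5) / sigma)
            )
        method = "normal"
    return TestResult(
        name=f"mann_whitney_{method}",
        statistic=float(u_a),
        p_value=float(min(p, 1.0)),
        tails=tails,
        df=None,
        group_sizes=(na, nb),
    )
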
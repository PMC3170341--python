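"""Exact and resampling statistics shared by every analysis stage.

The hypergeometric upper tail is the workhorse: it scores the overlap
between a miRNA's target set and a protein complex against random draws
from the combined target/complex universe.  Around it sit the Fisher
one-sided test (the same tail on a 2x2 table), Holm/Bonferroni family-wise
correction with an explicit family size, a one-sided two-sample
Kolmogorov-Smirnov test with the asymptotic tail p, the Wilcoxon signed-rank
test, an add-one permutation p-value and the Pearson product-moment
coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Sequence, Tuple

import numpy as np
from scipy import stats as sps
from scipy.special import logsumexp

from .types import DomainError, UndefinedCorrelationError


@dataclass
class TestResult:
    statistic: float
    p_value: float
    alternative: str
    method: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise DomainError(f"p-value {self.p_value} outside [0, 1]")


# ---------------------------------------------------------------------------
# Hypergeometric tail and Fisher's exact test
# ---------------------------------------------------------------------------

def hypergeom_tail_geq(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), summed in log space.

    Drawing ``n`` items without replacement from a universe of ``N``
    containing ``K`` successes, the probability of at least ``k``
    successes.  This is the association p-value for observing ``k``
    unit targets inside a complex of size ``K`` given ``n`` unit targets
    in a universe of ``N`` proteins.
    """
    k, K, n, N = int(k), int(K), int(n), int(N)
    if min(k, K, n, N) < 0:
        raise DomainError("counts must be non-negative")
    if k > min(n, K):
        raise DomainError(f"k={k} exceeds min(n={n}, K={K})")
    if K > N or n > N:
        raise DomainError(f"K={K} and n={n} must not exceed N={N}")
    if k == 0:
        return 1.0
    support = np.arange(k, min(n, K) + 1)
    log_terms = sps.hypergeom.logpmf(support, N, K, n)
    p = float(np.exp(logsumexp(log_terms)))
    return min(p, 1.0)


def fisher_exact_greater(a: int, b: int, c: int, d: int) -> TestResult:
    """One-sided (greater) Fisher's exact test on the 2x2 table [[a,b],[c,d]].

    The p-value is the hypergeometric upper tail
    ``hypergeom_tail_geq(a, a+b, a+c, a+b+c+d)``; the statistic is the
    sample odds ratio.
    """
    for name, x in (("a", a), ("b", b), ("c", c), ("d", d)):
        if x < 0:
            raise DomainError(f"negative count {name}={x}")
    p = hypergeom_tail_geq(a, a + b, a + c, a + b + c + d)
    odds = (a * d) / (b * c) if b * c > 0 else float("inf") if a * d > 0 else float("nan")
    return TestResult(odds, p, "greater", "fisher_exact")


# ---------------------------------------------------------------------------
# Multiple-testing correction
# ---------------------------------------------------------------------------

def adjust_pvalues(
    p: Sequence[float], method: str = "holm", m: int | None = None
) -> List[float]:
    """Family-wise adjusted p-values with an explicit family size.

    ``m`` may exceed ``len(p)``: tests that were never materialised (e.g.
    miRNAs with no overlap anywhere) still count toward the family.
    Holm is the step-down procedure with a running maximum; Bonferroni is
    ``min(1, m*p)``.  Holm-adjusted values never exceed Bonferroni's.
    """
    p_arr = np.asarray(list(p), dtype=float)
    if p_arr.size and (np.any(p_arr < 0) or np.any(p_arr > 1)):
        raise DomainError("p-values must lie in [0, 1]")
    if m is None:
        m = p_arr.size
    if m < p_arr.size:
        raise DomainError(f"family size m={m} smaller than number of tests {p_arr.size}")
    if p_arr.size == 0:
        return []
    if method == "bonferroni":
        return list(np.minimum(1.0, m * p_arr))
    if method != "holm":
        raise DomainError(f"unknown correction method {method!r}")
    order = np.argsort(p_arr, kind="stable")
    multipliers = m - np.arange(p_arr.size)
    stepped = np.maximum.accumulate(p_arr[order] * multipliers)
    adjusted = np.empty_like(p_arr)
    adjusted[order] = np.minimum(1.0, stepped)
    return list(adjusted)


# ---------------------------------------------------------------------------
# One-sided two-sample Kolmogorov-Smirnov
# ---------------------------------------------------------------------------

def ks_one_sided(
    sample_a: Sequence[float], sample_b: Sequence[float], alternative: str
) -> TestResult:
    """One-sided two-sample KS test with the asymptotic tail p-value.

    ``alternative="a_less"`` tests whether sample_a is stochastically
    smaller than sample_b (its ECDF lies above), with statistic
    D+ = sup_x [F_a(x) - F_b(x)]; ``"a_greater"`` is the mirror image.
    The p-value is ``exp(-2 m n D^2 / (m + n))`` clipped to [0, 1].
    """
    a = np.sort(np.asarray(sample_a, dtype=float))
    b = np.sort(np.asarray(sample_b, dtype=float))
    if a.size == 0 or b.size == 0:
        raise DomainError("both samples must be non-empty")
    if alternative not in ("a_less", "a_greater"):
        raise DomainError(f"unknown alternative {alternative!r}")
    grid = np.concatenate([a, b])
    f_a = np.searchsorted(a, grid, side="right") / a.size
    f_b = np.searchsorted(b, grid, side="right") / b.size
    diff = f_a - f_b if alternative == "a_less" else f_b - f_a
    d = float(diff.max())
    m, n = a.size, b.size
    p = float(np.exp(-2.0 * m * n * d * d / (m + n))) if d > 0 else 1.0
    return TestResult(d, min(max(p, 0.0), 1.0), alternative, "ks_one_sided_asymp")


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank
# ---------------------------------------------------------------------------

def wilcoxon_signed_rank(
    pairs: Iterable[Tuple[float, float]], alternative: str = "greater"
) -> TestResult:
    """Wilcoxon signed-rank test of observed vs reference pairs.

    Zero differences are dropped; |differences| are ranked with average
    ranks for ties.  The exact null distribution is used for n <= 25
    when the |differences| are tie-free, otherwise the normal
    approximation with tie-corrected variance.  Requires >= 6 non-zero
    differences.
    """
    if alternative not in ("greater", "less", "two-sided"):
        raise DomainError(f"unknown alternative {alternative!r}")
    obs, ref = zip(*pairs) if pairs else ((), ())
    d = np.asarray(obs, dtype=float) - np.asarray(ref, dtype=float)
    d = d[d != 0.0]
    if d.size == 0:
        raise DomainError("all differences are zero")
    if d.size < 6:
        raise DomainError(f"need >= 6 non-zero differences, got {d.size}")
    abs_d = np.abs(d)
    tie_free = np.unique(abs_d).size == abs_d.size
    method = "exact" if (d.size <= 25 and tie_free) else "approx"
    res = sps.wilcoxon(
        d, alternative=alternative, method=method, correction=False
    )
    return TestResult(
        float(res.statistic), float(res.pvalue), alternative, f"wilcoxon_{method}"
    )


# ---------------------------------------------------------------------------
# Permutation p-value and Pearson correlation
# ---------------------------------------------------------------------------

def permutation_pvalue(
    observed: float, null_samples: Sequence[float], alternative: str = "greater"
) -> float:
    """Add-one permutation p-value: (1 + #{null >= observed}) / (1 + R).

    The add-one correction counts the observed statistic as one more
    draw from the null, so the p-value can never be zero — with R
    resamples its floor is 1/(R+1).
    """
    nulls = np.asarray(list(null_samples), dtype=float)
    if nulls.size == 0:
        raise DomainError("empty null sample")
    if alternative != "greater":
        raise DomainError(f"unsupported alternative {alternative!r}")
    return float((1 + np.count_nonzero(nulls >= observed)) / (1 + nulls.size))


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation; errors on zero variance (caller skips)."""
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if xv.size != yv.size:
        raise DomainError("samples must have equal length")
    if xv.size < 3:
        raise DomainError("need at least 3 observations")
    if np.ptp(xv) == 0.0 or np.ptp(yv) == 0.0:
        raise UndefinedCorrelationError("zero-variance profile")
    xc = xv - xv.mean()
    yc = yv - yv.mean()
    r = float((xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc)))
    return max(-1.0, min(1.0, r))
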
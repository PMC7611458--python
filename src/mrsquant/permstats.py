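"""Exact permutation inference for small-cohort metabolite comparisons.

One-sample (sign-flip) and unpaired two-sample permutation t-tests with
full enumeration when feasible — 2^n sign patterns or C(n1+n2, n1) label
assignments — and a seeded Monte-Carlo fallback above ``max_exhaustive``.
The identity shuffling is always counted, so exhaustive p-values are exact
multiples of 1/n_shufflings and never fall below it (for n = 4 paired
differences the smallest attainable p is 1/16 = 0.0625).

Families of tests sharing one shuffling scheme are corrected for
family-wise error with the single-step max-statistic (Westfall-Young)
method; Bonferroni is available as an alternative.  Effect sizes are
Cohen's d under the convention that reproduces the t <-> d identities
t = d*sqrt(n) (one-sample) and t = d*sqrt(n1*n2/(n1+n2)) (two-sample).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
from scipy import stats

_EPS = 1e-12


class DegenerateDataError(ValueError):
    pass


@dataclass
class StatTestResult:
    """Permutation test outcome with its enumerated null distribution."""

    statistic: float
    df: int
    n_shufflings: int
    p_uncorrected_onetailed: float
    p_twotailed: float
    cohens_d: float
    tail: str
    exhaustive: bool
    scheme: tuple  # (kind, sample sizes); must match across a FWER batch
    p_fwer: float | None = None
    perm_stats: np.ndarray = field(default=None, repr=False)

    @property
    def p_bidirectional(self) -> float:
        """Doubled one-tailed p (capped at 1); equals the two-tailed p for a
        symmetric enumerated distribution."""
        opposite = _tail_p(self.perm_stats, self.statistic, _flip(self.tail))
        return bidirectional_correction(self.p_uncorrected_onetailed, opposite)

    def summary(self) -> str:
        return (
            f"t({self.df}) = {self.statistic:.3f}, d = {self.cohens_d:.3f}, "
            f"{self.n_shufflings} shufflings"
            f"{' (exhaustive)' if self.exhaustive else ' (Monte Carlo)'}, "
            f"one-tailed p = {self.p_uncorrected_onetailed:.4f}, "
            f"two-tailed p = {self.p_twotailed:.4f}"
            + (f", FWER p = {self.p_fwer:.4f}" if self.p_fwer is not None else "")
        )


@dataclass
class CorrelationResult:
    """Pearson correlation with its t-based two-tailed p."""

    r: float
    t_statistic: float
    df: int
    p_twotailed: float

    @property
    def r_squared(self) -> float:
        return self.r**2

    def summary(self) -> str:
        return (
            f"r({self.df}) = {self.r:.3f} (R^2 = {self.r_squared:.3f}), "
            f"p = {self.p_twotailed:.4f}"
        )


def _flip(tail: str) -> str:
    return {"greater": "less", "less": "greater"}[tail]


def _tail_p(perm: np.ndarray, observed: float, tail: str) -> float:
    if tail == "greater":
        return float(np.mean(perm >= observed - _EPS))
    if tail == "less":
        return float(np.mean(perm <= observed + _EPS))
    raise ValueError(f"tail must be 'greater' or 'less', got {tail!r}")


def _one_sample_t(x: np.ndarray) -> float:
    n = len(x)
    sd = x.std(ddof=1)
    if sd == 0:
        m = x.mean()
        return 0.0 if m == 0 else np.sign(m) * np.inf
    return x.mean() / (sd / np.sqrt(n))


def _one_sample_t_rows(x: np.ndarray) -> np.ndarray:
    """Row-wise one-sample t for a matrix of sign-flipped replicates."""
    n = x.shape[1]
    m = x.mean(axis=1)
    sd = x.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = m / (sd / np.sqrt(n))
    t[np.isnan(t)] = 0.0  # 0/0: flat all-zero rows
    return t


def sign_flip_test(
    diffs: np.ndarray,
    tail: str = "greater",
    max_exhaustive: int = 2**20,
    seed: int | None = None,
) -> StatTestResult:
    """Exact one-sample permutation t-test by sign flipping.

    Enumerates all 2^n sign patterns when that count does not exceed
    ``max_exhaustive``; otherwise draws that many seeded random patterns
    with the identity included.
    """
    d = np.asarray(diffs, dtype=float)
    n = len(d)
    if n < 2:
        raise DegenerateDataError("need at least 2 paired differences")
    if np.all(d == 0):
        raise DegenerateDataError("all paired differences are zero")
    t_obs = _one_sample_t(d)
    n_total = 2**n
    if n_total <= max_exhaustive:
        signs = _all_sign_patterns(n)
        exhaustive = True
    else:
        rng = np.random.default_rng(seed)
        signs = rng.choice([-1.0, 1.0], size=(max_exhaustive, n))
        signs[0] = 1.0  # identity shuffling always counted
        exhaustive = False
    perm = _one_sample_t_rows(signs * d)
    return StatTestResult(
        statistic=float(t_obs),
        df=n - 1,
        n_shufflings=len(signs),
        p_uncorrected_onetailed=_tail_p(perm, t_obs, tail),
        p_twotailed=float(np.mean(np.abs(perm) >= abs(t_obs) - _EPS)),
        cohens_d=cohens_d(d),
        tail=tail,
        exhaustive=exhaustive,
        scheme=("sign_flip", n),
        perm_stats=perm,
    )


def _all_sign_patterns(n: int) -> np.ndarray:
    codes = np.arange(2**n, dtype=np.int64)
    bits = (codes[:, None] >> np.arange(n)) & 1
    return bits * 2.0 - 1.0


def _pooled_t(x: np.ndarray, y: np.ndarray) -> float:
    n1, n2 = len(x), len(y)
    sp2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / (n1 + n2 - 2)
    if sp2 == 0:
        diff = x.mean() - y.mean()
        return 0.0 if diff == 0 else np.sign(diff) * np.inf
    return (x.mean() - y.mean()) / np.sqrt(sp2 * (1 / n1 + 1 / n2))


def permutation_two_sample(
    x: np.ndarray,
    y: np.ndarray,
    tail: str = "greater",
    max_exhaustive: int = 2**20,
    seed: int | None = None,
) -> StatTestResult:
    """Exact unpaired two-sample permutation t-test (pooled variance).

    Enumerates all C(n1+n2, n1) group-label assignments when feasible.
    ``tail='greater'`` tests mean(x) > mean(y).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 < 2 or n2 < 2:
        raise DegenerateDataError("need at least 2 observations per group")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        raise DegenerateDataError("zero pooled variance")
    t_obs = _pooled_t(x, y)
    n_total = comb(n1 + n2, n1)
    if n_total <= max_exhaustive:
        idx_sets = combinations(range(n1 + n2), n1)
        perm = np.empty(n_total)
        mask = np.zeros(n1 + n2, dtype=bool)
        for i, idx in enumerate(idx_sets):
            mask[:] = False
            mask[list(idx)] = True
            perm[i] = _pooled_t(pooled[mask], pooled[~mask])
        exhaustive = True
        n_shuff = n_total
    else:
        rng = np.random.default_rng(seed)
        n_shuff = max_exhaustive
        perm = np.empty(n_shuff)
        perm[0] = t_obs  # identity
        for i in range(1, n_shuff):
            p = rng.permutation(pooled)
            perm[i] = _pooled_t(p[:n1], p[n1:])
        exhaustive = False
    return StatTestResult(
        statistic=float(t_obs),
        df=n1 + n2 - 2,
        n_shufflings=n_shuff,
        p_uncorrected_onetailed=_tail_p(perm, t_obs, tail),
        p_twotailed=float(np.mean(np.abs(perm) >= abs(t_obs) - _EPS)),
        cohens_d=cohens_d(x, y),
        tail=tail,
        exhaustive=exhaustive,
        scheme=("two_sample", n1, n2),
        perm_stats=perm,
    )


def cohens_d(values: np.ndarray, other: np.ndarray | None = None) -> float:
    """Cohen's d: mean/sd for one sample, pooled-SD difference for two.

    Satisfies t = d*sqrt(n) (one-sample) and t = d*sqrt(n1*n2/(n1+n2))
    (two-sample) against the pooled-variance t statistic.
    """
    x = np.asarray(values, dtype=float)
    if other is None:
        sd = x.std(ddof=1)
        if sd == 0:
            raise DegenerateDataError("zero standard deviation: d undefined")
        return float(x.mean() / sd)
    y = np.asarray(other, dtype=float)
    n1, n2 = len(x), len(y)
    sp2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / (n1 + n2 - 2)
    if sp2 == 0:
        raise DegenerateDataError("zero pooled standard deviation: d undefined")
    return float((x.mean() - y.mean()) / np.sqrt(sp2))


def fwer_correct_batch(
    results: list[StatTestResult], method: str = "max_stat"
) -> list[float]:
    """Family-wise error correction across tests sharing one shuffling scheme.

    ``max_stat``: single-step Westfall-Young — corrected p of test m is the
    proportion of shufflings whose maximum |t| across the family reaches
    |t_m|.  Requires every result to carry the same exhaustively-or-seeded
    enumerated scheme so shufflings align across tests.  ``bonferroni``
    multiplies the two-tailed p by the family size.  Corrected p-values are
    never below the uncorrected two-tailed ones; results are updated in
    place (``p_fwer``) and returned.
    """
    if not results:
        return []
    schemes = {r.scheme for r in results}
    counts = {r.n_shufflings for r in results}
    if len(schemes) != 1 or len(counts) != 1:
        raise ValueError(
            "FWER batch requires a single shared shuffling scheme; got "
            f"schemes {schemes} with counts {counts}"
        )
    if method == "bonferroni":
        corrected = [min(1.0, r.p_twotailed * len(results)) for r in results]
    elif method == "max_stat":
        mat = np.vstack([np.abs(r.perm_stats) for r in results])
        max_dist = mat.max(axis=0)
        corrected = [
            float(np.mean(max_dist >= abs(r.statistic) - _EPS)) for r in results
        ]
    else:
        raise ValueError(f"unknown FWER method {method!r}")
    for r, p in zip(results, corrected):
        r.p_fwer = max(p, r.p_twotailed) if method == "max_stat" else p
    return [r.p_fwer for r in results]


def bidirectional_correction(p_expected_tail: float, p_opposite_tail: float) -> float:
    """Correct a one-tailed test run in both directions: 2*min(p), capped at 1.

    For a symmetric exhaustively enumerated null this equals the two-tailed
    p-value.
    """
    return min(1.0, 2.0 * min(p_expected_tail, p_opposite_tail))


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Per-test significance threshold alpha/m."""
    if m < 1:
        raise ValueError("number of tests must be at least 1")
    return alpha / m


def pearson_with_p(x: np.ndarray, y: np.ndarray) -> CorrelationResult:
    """Pearson r with its exact t-based two-tailed p (df = n - 2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 3:
        raise DegenerateDataError("need at least 3 pairs")
    if x.std() == 0 or y.std() == 0:
        raise DegenerateDataError("constant input: correlation undefined")
    r, p = stats.pearsonr(x, y)
    r = float(r)
    if abs(r) >= 1.0:
        t = np.sign(r) * np.inf
        p = 0.0
    else:
        t = r * np.sqrt((n - 2) / (1 - r**2))
        p = 2.0 * stats.t.sf(abs(t), n - 2)
    return CorrelationResult(r=r, t_statistic=float(t), df=n - 2, p_twotailed=float(p))


def chi_square_yates(table: np.ndarray) -> tuple[float, float]:
    """Yates-corrected chi-square test of a 2x2 count table (df = 1)."""
    tab = np.asarray(table)
    if tab.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(tab < 0) or not np.issubdtype(tab.dtype, np.integer):
        tab = tab.astype(float)
        if np.any(tab < 0) or np.any(tab != np.round(tab)):
            raise ValueError("counts must be non-negative integers")
    if np.any(tab.sum(axis=0) == 0) or np.any(tab.sum(axis=1) == 0):
        raise DegenerateDataError("zero margin in contingency table")
    res = stats.chi2_contingency(tab, correction=True)
    return float(res.statistic), float(res.pvalue)
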
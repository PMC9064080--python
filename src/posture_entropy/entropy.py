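"""Sample entropy (SampEn) of a time series.

SampEn(m, r, N) = -log(A / B), where B counts ordered pairs of distinct
length-m templates lying within a Chebyshev distance of r*SD of each other,
and A counts the subset of those pairs that remain within tolerance when
extended to length m+1.  Self-matches are excluded.  Templates are taken at
start indices 0..N-m-1 for both counts, so every length-m template has a
length-(m+1) extension and A <= B holds by construction.

Conventions (documented because the literature varies):

* distance: Chebyshev (max norm), the Richman-Moorman convention;
* similarity: inclusive (<= radius), so a constant series — radius 0, all
  distances 0 — gives A = B and SampEn = 0, the "perfectly repeatable"
  limit;
* tolerance radius: r times the population SD (divisor N) of the analyzed
  series itself;
* logarithm: natural, so values are in nats.

A = 0 with B > 0 yields the +inf sentinel (no (m+1)-matches observed) with
a warning; downstream statistics must treat it as missing.  The optimized
counting loop is JIT-compiled; :func:`sample_entropy_oracle` is a literal
all-pairs recount kept deliberately independent for verification.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from numba import njit

from .errors import LengthError, UndefinedEntropyError


@dataclass(frozen=True)
class SampEnParams:
    """Template length ``m`` and tolerance fraction ``r`` (of the series SD)."""

    m: int = 3
    r: float = 0.2

    def __post_init__(self):
        if self.m < 1 or int(self.m) != self.m:
            raise ValueError(f"m must be a positive integer, got {self.m}")
        if not self.r > 0:
            raise ValueError(f"r must be positive, got {self.r}")


@dataclass(frozen=True)
class SampEnResult:
    """SampEn value (nats; +inf sentinel allowed) with the raw match counts.

    ``a_count`` and ``b_count`` are ordered-pair counts (i != j both ways),
    as in the original formulation; the ratio A/B is unaffected by the
    ordered/unordered choice.
    """

    value: float
    a_count: int
    b_count: int
    n: int
    params: SampEnParams

    def __post_init__(self):
        if self.a_count > self.b_count:
            raise ValueError("a_count cannot exceed b_count")

    @property
    def is_finite(self) -> bool:
        return math.isfinite(self.value)


@njit(cache=True)
def _count_pairs(x, m, radius):  # pragma: no cover - exercised via sample_entropy
    n = x.shape[0]
    nt = n - m  # templates with an (m+1) extension
    a = 0
    b = 0
    for i in range(nt - 1):
        for j in range(i + 1, nt):
            similar = True
            for k in range(m):
                if abs(x[i + k] - x[j + k]) > radius:
                    similar = False
                    break
            if similar:
                b += 1
                if abs(x[i + m] - x[j + m]) <= radius:
                    a += 1
    return a, b


def _finish(a: int, b: int, n: int, params: SampEnParams) -> SampEnResult:
    # counts are reported as ordered pairs
    a, b = 2 * a, 2 * b
    if b == 0:
        raise UndefinedEntropyError(
            f"no template matches at m={params.m}: SampEn is undefined for this series"
        )
    if a == 0:
        warnings.warn(
            "no template matches at m+1: SampEn is +inf (treated as missing downstream)",
            RuntimeWarning,
            stacklevel=3,
        )
        return SampEnResult(math.inf, 0, b, n, params)
    # max() also normalizes -0.0 (a == b) to exactly 0.0
    return SampEnResult(max(0.0, -math.log(a / b)), a, b, n, params)


def _prepare(series, params: SampEnParams) -> tuple[np.ndarray, float]:
    x = np.ascontiguousarray(series, dtype=float)
    if x.ndim != 1:
        raise ValueError("series must be one-dimensional")
    n = len(x)
    if n <= params.m + 1:
        raise LengthError(f"series length {n} must exceed m+1 = {params.m + 1}")
    radius = params.r * float(np.std(x))  # population SD
    return x, radius


def sample_entropy(series, params: SampEnParams = SampEnParams()) -> SampEnResult:
    """Compute SampEn of a series with the conventions documented above."""
    x, radius = _prepare(series, params)
    a, b = _count_pairs(x, params.m, radius)
    return _finish(int(a), int(b), len(x), params)


#: Guard on the quadratic-memory oracle.
ORACLE_N_MAX = 5000


def sample_entropy_oracle(series, params: SampEnParams = SampEnParams()) -> SampEnResult:
    """Brute-force SampEn: explicit pairwise Chebyshev distances between all
    templates, via numpy broadcasting.  Verification twin of
    :func:`sample_entropy`; quadratic in memory, guarded at N <= 5000.
    """
    x, radius = _prepare(series, params)
    n = len(x)
    if n > ORACLE_N_MAX:
        raise LengthError(f"oracle restricted to N <= {ORACLE_N_MAX}, got {n}")
    m = params.m
    nt = n - m
    # Chebyshev distance between all template pairs, built one lag at a time.
    dist_m = np.zeros((nt, nt))
    for k in range(m):
        col = x[k : k + nt]
        np.maximum(dist_m, np.abs(col[:, None] - col[None, :]), out=dist_m)
    sim_m = dist_m <= radius
    ext = x[m : m + nt]
    sim_m1 = sim_m & (np.abs(ext[:, None] - ext[None, :]) <= radius)
    off_diag = nt * nt - nt
    b = int(sim_m.sum()) - nt  # remove self-matches (diagonal), ordered count
    a = int(sim_m1.sum()) - nt
    assert 0 <= a <= b <= off_diag
    return _finish(a // 2, b // 2, n, params)


def sampen_sensitivity(
    series,
    m_values=(2, 3),
    r_values=(0.15, 0.2, 0.25),
):
    """SampEn over an m x r parameter grid, as a tidy DataFrame.

    Supports the usual robustness check that conclusions do not hinge on the
    (m, r) choice; SampEn is non-increasing in r for fixed m.
    """
    import pandas as pd

    rows = []
    for m in m_values:
        for r in r_values:
            res = sample_entropy(series, SampEnParams(m=m, r=r))
            rows.append(
                {
                    "m": m,
                    "r": r,
                    "sampen": res.value,
                    "a_count": res.a_count,
                    "b_count": res.b_count,
                    "n": res.n,
                }
            )
    return pd.DataFrame(rows)
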
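"""Sample-coverage estimation and coverage-based rarefaction/extrapolation.

Species richness observed on a single trap night depends heavily on how many
individuals were caught.  Rather than comparing raw richness across nights
with unequal catch sizes, richness is standardized to a common *sample
coverage* — the estimated fraction of individuals in the community that
belong to species present in the sample (Chao–Jost).  Nights whose coverage
exceeds the target are rarefied (interpolated); nights below it are
extrapolated, capped at twice the observed sample size.

All binomial-coefficient ratios are evaluated in log space via ``gammaln``
so that nights with thousands of individuals remain overflow-safe.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.special import gammaln


@dataclass(frozen=True)
class AbundanceVector:
    """Per-night species abundances with the summaries the coverage
    estimator needs: total catch ``n``, observed richness ``S_obs``, and the
    singleton/doubleton counts ``f1``/``f2``."""

    night_id: object
    counts: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self):
        for sp, c in self.counts.items():
            if c < 1 or c != int(c):
                raise ValueError(
                    f"stored counts must be positive integers; {sp!r} has {c}"
                )

    @property
    def abundances(self) -> np.ndarray:
        return np.asarray(sorted(self.counts.values(), reverse=True), dtype=int)

    @property
    def n(self) -> int:
        return int(sum(self.counts.values()))

    @property
    def s_obs(self) -> int:
        return len(self.counts)

    @property
    def f1(self) -> int:
        return sum(1 for c in self.counts.values() if c == 1)

    @property
    def f2(self) -> int:
        return sum(1 for c in self.counts.values() if c == 2)


def sample_coverage(av: AbundanceVector) -> float:
    """Chao–Jost estimated sample coverage.

    ``C_hat = 1 - (f1/n) * [(n-1)f1 / ((n-1)f1 + 2 f2)]``; a single
    individual gives coverage 0, an empty night is undefined (NaN).
    """
    n = av.n
    if n == 0:
        warnings.warn("empty night: coverage undefined", stacklevel=2)
        return float("nan")
    if n == 1:
        return 0.0
    f1, f2 = av.f1, av.f2
    if f1 == 0:
        return 1.0
    a = (n - 1) * f1
    return 1.0 - (f1 / n) * (a / (a + 2.0 * f2))


def _log_choose(n, k):
    n = np.asarray(n, dtype=float)
    k = np.asarray(k, dtype=float)
    return gammaln(n + 1.0) - gammaln(k + 1.0) - gammaln(n - k + 1.0)


def rarefied_richness(av: AbundanceVector, m: int) -> float:
    """Expected richness of a random subsample of ``m`` individuals
    (without replacement), ``S(m) = sum_s [1 - C(n - x_s, m) / C(n, m)]``."""
    n = av.n
    if not (0 <= m <= n):
        raise ValueError(f"m must lie in [0, n={n}], got {m}")
    if m == 0:
        return 0.0
    x = av.abundances
    keep = (n - x) >= m
    miss = np.zeros(len(x))
    if np.any(keep):
        miss[keep] = np.exp(_log_choose(n - x[keep], m) - _log_choose(n, m))
    return float(np.sum(1.0 - miss))


def rarefied_coverage(av: AbundanceVector, m: int) -> float:
    """Expected coverage of a subsample of size ``m < n``:
    ``C(m) = 1 - sum_s (x_s/n) * C(n - x_s, m) / C(n-1, m)``."""
    n = av.n
    if not (1 <= m <= n):
        raise ValueError("m must lie in [1, n]")
    if m == n:
        return sample_coverage(av)
    x = av.abundances
    term = np.zeros(len(x))
    ok = (n - x) >= m
    if np.any(ok):
        term[ok] = (x[ok] / n) * np.exp(_log_choose(n - x[ok], m) - _log_choose(n - 1, m))
    return float(1.0 - np.sum(term))


def _f0_hat(n: int, f1: int, f2: int) -> float:
    """Chao1 estimate of the number of undetected species."""
    if f1 == 0:
        return 0.0
    if f2 > 0:
        return ((n - 1) / n) * f1 * f1 / (2.0 * f2)
    return ((n - 1) / n) * f1 * (f1 - 1) / 2.0


def extrapolated_richness(av: AbundanceVector, m: float) -> float:
    """Expected richness at sample size ``m > n``:
    ``S(n) + f0_hat * [1 - (1 - f1/(n f0_hat + f1))**(m-n)]``."""
    n = av.n
    if m <= n:
        raise ValueError("extrapolation requires m > n")
    f1 = av.f1
    f0 = _f0_hat(n, f1, av.f2)
    if f0 == 0.0 or f1 == 0:
        return float(av.s_obs)
    rate = f1 / (n * f0 + f1)
    return float(av.s_obs + f0 * (1.0 - (1.0 - rate) ** (m - n)))


def extrapolated_coverage(av: AbundanceVector, m: float) -> float:
    """Expected coverage at ``m >= n``:
    ``1 - (f1/n) * [(n-1)f1 / ((n-1)f1 + 2 f2)]**(m - n + 1)``."""
    n = av.n
    f1, f2 = av.f1, av.f2
    if f1 == 0:
        return 1.0
    a = (n - 1) * f1
    r = a / (a + 2.0 * f2) if (a + 2.0 * f2) > 0 else 1.0
    return float(1.0 - (f1 / n) * r ** (m - n + 1.0))


def coverage_corrected_richness(av: AbundanceVector, target_coverage: float) -> float:
    """Species richness standardized to a common sample coverage.

    The effective sample size ``m`` with expected coverage equal to
    ``target_coverage`` is located; richness is interpolated (``m <= n``) via
    the combinatorial expectation or extrapolated (``m > n``) via the Chao1
    asymptotic form, with extrapolation capped at ``m = 2n``.  Nights whose
    coverage at ``2n`` still falls short of the target return the capped
    value with a warning.  An empty night has richness 0.
    """
    if not (0.0 < target_coverage < 1.0):
        raise ValueError("target coverage must lie strictly between 0 and 1")
    n = av.n
    if n == 0:
        return 0.0
    c_n = sample_coverage(av)
    if c_n >= target_coverage:
        # smallest m whose expected coverage reaches the target
        lo, hi = 1, n
        while lo < hi:
            mid = (lo + hi) // 2
            if rarefied_coverage(av, mid) >= target_coverage:
                hi = mid
            else:
                lo = mid + 1
        return rarefied_richness(av, lo)
    # extrapolate: solve closed form for m, cap at 2n
    f1, f2 = av.f1, av.f2
    if f1 == 0:  # coverage already 1, cannot be below target
        return float(av.s_obs)
    a = (n - 1) * f1
    r = a / (a + 2.0 * f2) if (a + 2.0 * f2) > 0 else 1.0
    if r >= 1.0:  # f2 == 0: extrapolated coverage never reaches the target
        m_star = np.inf
    else:
        # (f1/n) r**(m-n+1) = 1 - C*  =>  m = n - 1 + log(n(1-C*)/f1)/log(r)
        m_star = n - 1.0 + np.log(n * (1.0 - target_coverage) / f1) / np.log(r)
    if m_star > 2 * n:
        warnings.warn(
            f"night {av.night_id!r}: coverage {extrapolated_coverage(av, 2 * n):.3f} "
            f"at m=2n below target {target_coverage}; using capped extrapolation",
            stacklevel=2,
        )
        m_star = float(2 * n)
    if m_star <= n:
        return float(av.s_obs)
    return extrapolated_richness(av, m_star)
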
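"""Repeatability metric and noninferiority machinery.

Repeatability at a measurement point is the median of the absolute
pairwise width differences across replicate samples — the Rousseeuw–Croux
Sn family of robust scale statistics (outlier-resistant, valid for
asymmetric distributions).  Group comparison uses a one-sided
Mann–Whitney U noninferiority test with a 1 mm margin implemented as a
location shift: the configurable group's values minus the margin are
tested against the standard group's.  The shift effect Δ is the
Hodges–Lehmann median of pairwise differences and the one-sided 95 %
upper confidence bound comes from inverting the U test.  A Monte-Carlo
sample-size search reproduces the study's simulation-based power
analysis, and an OLS regression relates repeatability to probe speed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats as sps

from .profiles import ValidationError

__all__ = [
    "RepeatabilitySet",
    "NoninferiorityResult",
    "SearchLimitError",
    "repeatability_at_point",
    "mann_whitney_noninferiority",
    "hodges_lehmann",
    "sample_size_search",
    "speed_regression",
]


class SearchLimitError(RuntimeError):
    """Raised when the sample-size search hits its upper bound."""


@dataclass
class RepeatabilitySet:
    """Per-measurement-point repeatability values for one shape group.

    ``values[i]`` is the repeatability (mm) at measurement point i;
    ``point_z`` and ``speed`` carry the axial position and the commanded
    probe speed at that point, aligned with ``values``; ``shape_label``
    likewise (one entry per value) when points come from several shapes.
    """

    values: np.ndarray
    group: str
    shape_label: Sequence[str] | str | None = None
    point_z: np.ndarray | None = None
    speed: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.group not in ("standard", "configurable"):
            raise ValidationError("group must be 'standard' or 'configurable'")
        if np.any(self.values < 0):
            raise ValidationError("repeatability values must be >= 0")
        for name in ("point_z", "speed"):
            v = getattr(self, name)
            if v is not None:
                setattr(self, name, np.asarray(v, dtype=float))


@dataclass
class NoninferiorityResult:
    """Outcome of the one-sided Mann–Whitney noninferiority test."""

    p_value: float
    delta: float  # Hodges–Lehmann estimate of median(conf) − median(std), mm
    ci_upper: float  # one-sided (1 − alpha) upper bound for the shift, mm
    margin: float
    alpha: float
    n_conf: int
    n_std: int

    @property
    def noninferior(self) -> bool:
        return self.p_value < self.alpha


def repeatability_at_point(widths: Sequence[float]) -> float:
    """Median of |wᵢ − wⱼ| over all unordered pairs of sample widths (mm).

    Translation-invariant and absolutely scale-equivariant; requires at
    least two widths.
    """
    w = np.asarray(widths, dtype=float)
    if w.size < 2:
        raise ValidationError("repeatability needs at least 2 widths")
    i, j = np.triu_indices(w.size, k=1)
    return float(np.median(np.abs(w[i] - w[j])))


def hodges_lehmann(x: np.ndarray, y: np.ndarray) -> float:
    """Hodges–Lehmann shift estimate: median over all xᵢ − yⱼ."""
    return float(np.median(np.subtract.outer(np.asarray(x, float), np.asarray(y, float))))


def _exact_u_cdf(m: int, n: int) -> np.ndarray:
    """Null CDF of the Mann–Whitney U statistic (no ties), P(U ≤ u).

    The null counts are the coefficients of the Gaussian (q-)binomial
    coefficient [m+n, m]_q, built by the q-Pascal recursion
    C(i, j) = C(i−1, j)·q^j + C(i, j−1).  Sizes here stay small.
    """
    prev = [np.array([1.0]) for _ in range(n + 1)]  # row i = 0
    for i in range(1, m + 1):
        cur = [np.array([1.0])]
        for j in range(1, n + 1):
            a = np.zeros(i * j + 1)
            p_shift = prev[j]
            a[j : j + p_shift.size] += p_shift
            p_same = cur[j - 1]
            a[: p_same.size] += p_same
            cur.append(a)
        prev = cur
    cdf = np.cumsum(prev[n])
    return cdf / cdf[-1]


def _u_critical(m: int, n: int, alpha: float) -> int:
    """Largest k with P(U ≤ k) ≤ alpha under the null (−1 if none)."""
    if m * n <= 400:
        cdf = _exact_u_cdf(m, n)
        ks = np.nonzero(cdf <= alpha + 1e-12)[0]
        return int(ks[-1]) if ks.size else -1
    mu = m * n / 2.0
    sd = np.sqrt(m * n * (m + n + 1) / 12.0)
    return int(np.floor(mu + sps.norm.ppf(alpha) * sd - 0.5))


def mann_whitney_noninferiority(
    conf: "RepeatabilitySet | Sequence[float]",
    std: "RepeatabilitySet | Sequence[float]",
    margin: float = 1.0,
    alpha: float = 0.05,
) -> NoninferiorityResult:
    """One-sided Mann–Whitney U test of noninferiority with a shift margin.

    H₀: median(conf) − median(std) ≥ margin (configurable worse by at
    least the margin) against H₁: the excess is below the margin.  The
    test shifts the configurable values down by the margin and applies a
    one-sided U test; an exact null distribution is used when both
    groups have ≤ 12 values and no ties, otherwise the tie-corrected
    normal approximation.  Δ is the Hodges–Lehmann estimate of the
    unshifted difference and ``ci_upper`` its one-sided (1 − α) upper
    bound by test inversion.
    """
    x = np.asarray(conf.values if isinstance(conf, RepeatabilitySet) else conf, float)
    y = np.asarray(std.values if isinstance(std, RepeatabilitySet) else std, float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("both groups must be nonempty")
    if margin < 0:
        raise ValidationError("margin must be >= 0")
    shifted = x - margin
    no_ties = np.unique(np.concatenate([shifted, y])).size == x.size + y.size
    method = "exact" if (x.size <= 12 and y.size <= 12 and no_ties) else "asymptotic"
    res = sps.mannwhitneyu(shifted, y, alternative="less", method=method)
    delta = hodges_lehmann(x, y)
    diffs = np.sort(np.subtract.outer(x, y).ravel())
    k = _u_critical(x.size, y.size, alpha)
    idx = diffs.size - 1 - max(k, 0) if k >= 0 else diffs.size - 1
    # upper bound of the one-sided CI for the shift by inverting the U test
    ci_upper = float(diffs[min(max(idx, 0), diffs.size - 1)])
    return NoninferiorityResult(
        p_value=float(res.pvalue),
        delta=delta,
        ci_upper=ci_upper,
        margin=margin,
        alpha=alpha,
        n_conf=int(x.size),
        n_std=int(y.size),
    )


def sample_size_search(
    sd_std: float,
    sd_conf: float,
    margin: float = 1.0,
    ratio: float = 0.5,
    alpha: float = 0.05,
    power_target: float | None = None,
    reps: int = 500,
    seed: int = 0,
    n_max: int = 1000,
) -> tuple[int, int]:
    """Simulation-based noninferiority sample-size calculation.

    Both groups are drawn normal with a common (arbitrary) mean and the
    given standard deviations — the study's generative model — and
    tested for noninferiority at the margin.  The search returns the
    smallest ``(n_std, n_conf)`` with ``n_std = ratio × n_conf`` whose
    Monte-Carlo rejection rate reaches ``power_target`` (default
    ``1 − 1/reps``, the finite-sample reading of "100 % probability of
    significance").  Common random numbers (a fixed stream per
    replicate) make power monotone in n for a fixed seed batch.
    """
    if sd_std <= 0 or sd_conf <= 0:
        raise ValidationError("standard deviations must be positive")
    if not 0 < ratio <= 1:
        raise ValidationError("ratio must be in (0, 1]")
    if reps < 100:
        raise ValidationError("reps must be >= 100")
    if power_target is None:
        power_target = 1.0 - 1.0 / reps
    for n_conf in range(4, n_max + 1):
        n_std = max(2, int(round(ratio * n_conf)))
        rate = estimated_power(
            n_std, n_conf, sd_std, sd_conf, margin=margin, shift=0.0,
            alpha=alpha, reps=reps, seed=seed,
        )
        if rate >= power_target:
            return n_std, n_conf
    raise SearchLimitError(
        f"target power {power_target} not reached within n_conf <= {n_max}"
    )


def estimated_power(
    n_std: int,
    n_conf: int,
    sd_std: float,
    sd_conf: float,
    margin: float = 1.0,
    shift: float = 0.0,
    alpha: float = 0.05,
    reps: int = 500,
    seed: int = 0,
) -> float:
    """Monte-Carlo rejection rate of the noninferiority test.

    ``shift`` is the true median excess of the configurable group
    (0 under identity, ``margin`` at the noninferiority boundary).
    Replicate r uses the stream ``SeedSequence([seed, r])`` and draws the
    configurable sample first, so the first draws coincide across
    different n — common random numbers.
    """
    hits = 0
    for r in range(reps):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), r]))
        x = rng.normal(shift, sd_conf, n_conf)
        y = rng.normal(0.0, sd_std, n_std)
        p = sps.mannwhitneyu(x - margin, y, alternative="less", method="asymptotic").pvalue
        hits += p < alpha
    return hits / reps


def speed_regression(
    repeatability: "RepeatabilitySet | Sequence[float]",
    speeds: Sequence[float] | None = None,
    alpha: float = 0.05,
) -> dict:
    """OLS of repeatability on probe speed with a slope CI and R².

    Returns {slope, intercept, slope_ci (two-sided 1 − α), r_squared,
    p_value}.  Requires ≥ 3 points with non-constant speed.
    """
    if isinstance(repeatability, RepeatabilitySet):
        y = repeatability.values
        x = repeatability.speed if speeds is None else np.asarray(speeds, float)
    else:
        y = np.asarray(repeatability, dtype=float)
        x = np.asarray(speeds, dtype=float) if speeds is not None else None
    if x is None:
        raise ValidationError("speeds are required")
    if y.size < 3:
        raise ValidationError("regression needs at least 3 points")
    if np.ptp(x) == 0:
        raise ValidationError("degenerate design: speeds are constant")
    X = sm.add_constant(np.asarray(x, float))
    fit = sm.OLS(np.asarray(y, float), X).fit()
    lo, hi = fit.conf_int(alpha=alpha)[1]
    return {
        "slope": float(fit.params[1]),
        "intercept": float(fit.params[0]),
        "slope_ci": (float(lo), float(hi)),
        "r_squared": float(fit.rsquared),
        "p_value": float(fit.pvalues[1]),
    }
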
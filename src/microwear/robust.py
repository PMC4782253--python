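"""Robust heteroscedastic group comparison for surface texture parameters.

Texture parameters of worn enamel are typically non-normal and
heteroscedastic across habitat groups, so inference is built on trimmed
means throughout:

* a Welch-type heteroscedastic omnibus F-test on γ-trimmed means
  (Welch–Yuen), with γ = 0.15 by default;
* unadjusted pairwise two-sample trimmed-means tests with Welch-type
  degrees of freedom (the "Lincon" battery, analogous to Dunnett's T3;
  family-wise studentized-maximum-modulus adjustment available as an
  opt-in);
* Cliff's rank-based dominance statistic δ with its asymmetric
  distribution-free confidence interval as a confirmation test;
* a two-test consensus rule: a pair differs only if the trimmed-means
  p-value and Cliff's interval agree.

The omnibus result does not gate the pairwise battery: consensus is
defined purely pairwise.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .exceptions import DegeneracyError, ValidationError

__all__ = [
    "StatsConfig",
    "OmnibusResult",
    "PairwiseResult",
    "CliffResult",
    "trimmed_mean",
    "winsorized_variance",
    "yuen_two_sample",
    "welch_yuen_omnibus",
    "lincon_pairwise",
    "cliff_delta",
    "consensus",
]


@dataclass(frozen=True)
class StatsConfig:
    """Trimming fraction γ per tail and two-sided significance level α."""

    gamma: float = 0.15
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 <= self.gamma < 0.5:
            raise ValidationError(f"gamma must lie in [0, 0.5), got {self.gamma}")
        if not 0.0 < self.alpha < 1.0:
            raise ValidationError(f"alpha must lie in (0, 1), got {self.alpha}")


@dataclass
class OmnibusResult:
    """Welch–Yuen omnibus test result for one parameter."""

    Ft: float
    nu1: int
    nu2: float
    P: float
    parameter: str = ""


@dataclass
class CliffResult:
    """Cliff's delta with its asymmetric confidence interval."""

    delta: float
    ci_low: float
    ci_high: float
    significant: bool


@dataclass
class PairwiseResult:
    """One group pair: trimmed-means test, Cliff's method, consensus flag."""

    pair: Tuple[str, str]
    t: float
    df: float
    P: float
    delta: float = math.nan
    ci_low: float = math.nan
    ci_high: float = math.nan
    cliff_significant: bool = False
    consensus: bool = False
    parameter: str = ""


# ---------------------------------------------------------------------------
# trimmed-mean building blocks


def _check_sample(x: np.ndarray, gamma: float, min_n: int = 1) -> Tuple[np.ndarray, int]:
    x = np.asarray(x, dtype=float).ravel()
    n = x.size
    if n < min_n:
        raise ValidationError(f"sample size {n} below minimum {min_n}")
    g = int(math.floor(gamma * n))
    if n - 2 * g < 1:
        raise DegeneracyError(
            f"trimming {gamma} removes all {n} observations (g={g})"
        )
    return np.sort(x), g


def trimmed_mean(x: Sequence[float], gamma: float) -> float:
    """Mean after removing the ⌊γ·n⌋ smallest and largest observations."""
    xs, g = _check_sample(np.asarray(x), gamma)
    return float(xs[g: xs.size - g].mean())


def winsorized_variance(x: Sequence[float], gamma: float) -> float:
    """Sample variance (n−1 denominator) of the γ-winsorized sample.

    The g smallest values are replaced by the (g+1)-th order statistic and
    the g largest by the (n−g)-th before taking the ordinary variance.
    """
    xs, g = _check_sample(np.asarray(x), gamma, min_n=2)
    n = xs.size
    w = xs.copy()
    w[:g] = xs[g]
    w[n - g:] = xs[n - g - 1]
    return float(w.var(ddof=1))


def _yuen_d(x: np.ndarray, gamma: float) -> Tuple[float, float, int]:
    """Squared standard error d, trimmed mean, and effective size h."""
    x = np.asarray(x, dtype=float).ravel()
    n = x.size
    g = int(math.floor(gamma * n))
    h = n - 2 * g
    if h < 2:
        raise DegeneracyError(
            f"group of size {n} leaves h={h} < 2 observations after trimming"
        )
    sw2 = winsorized_variance(x, gamma)
    d = (n - 1) * sw2 / (h * (h - 1))
    return d, trimmed_mean(x, gamma), h


# ---------------------------------------------------------------------------
# omnibus test


def welch_yuen_omnibus(
    groups: Sequence[Sequence[float]],
    cfg: StatsConfig = StatsConfig(),
    labels: Optional[Sequence[str]] = None,
) -> OmnibusResult:
    """Heteroscedastic omnibus F-test on γ-trimmed means across J groups.

    With per-group squared standard errors d_j = (n_j−1)·s²_wj/(h_j(h_j−1)),
    weights w_j = 1/d_j, U = Σw_j and weighted grand mean X̃:

        A  = Σ w_j (x̄_tj − X̃)² / (J−1)
        B  = 2(J−2)/(J²−1) · Σ (1 − w_j/U)²/(h_j−1)
        Ft = A / (1 + B),   ν1 = J−1,
        ν2 = [ 3/(J²−1) · Σ (1 − w_j/U)²/(h_j−1) ]⁻¹

    and the p-value comes from the F(ν1, ν2) distribution.  With J = 2 and
    γ = 0 this reduces to the square of Welch's two-sample t statistic.
    """
    J = len(groups)
    if J < 2:
        raise ValidationError(f"need at least 2 groups, got {J}")
    if labels is None:
        labels = [f"group{j}" for j in range(J)]
    d = np.empty(J)
    xt = np.empty(J)
    hh = np.empty(J)
    for j, x in enumerate(groups):
        dj, mj, hj = _yuen_d(np.asarray(x), cfg.gamma)
        if dj == 0.0:
            raise DegeneracyError(
                f"group {labels[j]!r} has zero winsorized variance"
            )
        d[j], xt[j], hh[j] = dj, mj, hj
    w = 1.0 / d
    U = w.sum()
    grand = (w * xt).sum() / U
    A = (w * (xt - grand) ** 2).sum() / (J - 1)
    C = ((1.0 - w / U) ** 2 / (hh - 1.0)).sum()
    B = 2.0 * (J - 2) / (J**2 - 1.0) * C
    Ft = A / (1.0 + B)
    nu2 = (J**2 - 1.0) / (3.0 * C)
    P = float(stats.f.sf(Ft, J - 1, nu2))
    return OmnibusResult(Ft=float(Ft), nu1=J - 1, nu2=float(nu2), P=P)


# ---------------------------------------------------------------------------
# pairwise trimmed-means tests


def yuen_two_sample(
    x: Sequence[float], y: Sequence[float], cfg: StatsConfig = StatsConfig()
) -> Tuple[float, float, float]:
    """Two-sample trimmed-means test; returns (t, df, two-sided P).

    t = |x̄_t − ȳ_t| / √(d_x + d_y) with Welch-type degrees of freedom
    df = (d_x + d_y)² / (d_x²/(h_x−1) + d_y²/(h_y−1)).
    """
    dx, mx, hx = _yuen_d(np.asarray(x), cfg.gamma)
    dy, my, hy = _yuen_d(np.asarray(y), cfg.gamma)
    if dx + dy == 0.0:
        raise DegeneracyError("both samples have zero winsorized variance")
    t = abs(mx - my) / math.sqrt(dx + dy)
    df = (dx + dy) ** 2 / (dx**2 / (hx - 1) + dy**2 / (hy - 1))
    P = float(2.0 * stats.t.sf(t, df))
    return float(t), float(df), P


def lincon_pairwise(
    groups: Dict[str, Sequence[float]],
    cfg: StatsConfig = StatsConfig(),
    adjust: bool = False,
) -> List[PairwiseResult]:
    """All J(J−1)/2 pairwise trimmed-means comparisons.

    P-values are per-pair (unadjusted) by default, flagged against
    ``cfg.alpha`` downstream.  With ``adjust=True`` each p-value is
    Šidák-corrected for the number of pairs, a conservative stand-in for
    the studentized-maximum-modulus family-wise critical values used by
    some implementations.
    """
    labels = list(groups)
    if len(labels) < 2:
        raise ValidationError(f"need at least 2 groups, got {len(labels)}")
    m = len(labels) * (len(labels) - 1) // 2
    out = []
    for a, b in itertools.combinations(labels, 2):
        t, df, P = yuen_two_sample(groups[a], groups[b], cfg)
        if adjust:
            P = float(1.0 - (1.0 - P) ** m)
        out.append(PairwiseResult(pair=(a, b), t=t, df=df, P=P))
    return out


# ---------------------------------------------------------------------------
# Cliff's rank-based method


def cliff_delta(
    x: Sequence[float], y: Sequence[float], cfg: StatsConfig = StatsConfig()
) -> CliffResult:
    """Cliff's dominance statistic δ = P(X>Y) − P(X<Y) with its CI.

    δ is the mean of sign(xᵢ − yⱼ) over all n_x·n_y pairs (ties count 0).
    Its sampling variance uses Cliff's consistent estimator combining the
    variances of the row dominances, column dominances and the individual
    pair signs; the confidence interval is Cliff's asymmetric interval at
    level 1−α, clipped to [−1, 1], and the pair is significant when the
    interval excludes 0.  Complete separation (|δ| = 1) has a degenerate
    variance estimate; the interval is then computed as if one of the
    n_x·n_y comparisons were tied, which keeps the bound inside (−1, 1).
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size < 2 or y.size < 2:
        raise ValidationError(
            f"Cliff's method needs at least 2 observations per sample, "
            f"got {x.size} and {y.size}"
        )
    nx, ny = x.size, y.size
    dm = np.sign(x[:, None] - y[None, :])
    delta = float(dm.mean())
    npairs = nx * ny
    if np.all(dm == dm.flat[0]) and dm.flat[0] == 0.0:
        # all observations tied: no evidence of dominance either way
        return CliffResult(delta=0.0, ci_low=0.0, ci_high=0.0, significant=False)

    if abs(delta) == 1.0:
        d_eff = delta * (npairs - 1) / npairs
        s2 = (1.0 - d_eff**2) / (npairs - 1)
    else:
        d_eff = delta
        di = dm.mean(axis=1)
        dj = dm.mean(axis=0)
        s2 = (
            ny**2 * np.sum((di - delta) ** 2)
            + nx**2 * np.sum((dj - delta) ** 2)
            - np.sum((dm - delta) ** 2)
        ) / (nx * ny * (nx - 1) * (ny - 1))
        s2 = max(float(s2), (1.0 - delta**2) / (npairs - 1))
    z = float(stats.norm.ppf(1.0 - cfg.alpha / 2.0))
    den = 1.0 - d_eff**2 + z**2 * s2
    half = z * math.sqrt(s2) * math.sqrt((1.0 - d_eff**2) ** 2 + z**2 * s2)
    lo = (d_eff - d_eff**3 - half) / den
    hi = (d_eff - d_eff**3 + half) / den
    # the interval always contains the point estimate, also in the
    # complete-separation case where it is computed around the shrunk d_eff
    lo, hi = max(-1.0, min(lo, delta)), min(1.0, max(hi, delta))
    return CliffResult(
        delta=delta, ci_low=lo, ci_high=hi, significant=bool(lo > 0.0 or hi < 0.0)
    )


# ---------------------------------------------------------------------------
# consensus rule


def consensus(
    lincon: Sequence[PairwiseResult],
    cliff: Dict[Tuple[str, str], CliffResult],
    cfg: StatsConfig = StatsConfig(),
) -> Tuple[List[PairwiseResult], bool]:
    """Merge the trimmed-means and Cliff results pair by pair.

    A pair is consensus-significant iff its trimmed-means P ≤ α AND
    Cliff's interval excludes 0.  Returns the merged pairwise results and
    the parameter-level flag (any pair consensus-significant).
    """
    if set(r.pair for r in lincon) != set(cliff):
        raise ValidationError("lincon and Cliff results cover different pairs")
    merged = []
    any_sig = False
    for r in lincon:
        c = cliff[r.pair]
        flag = bool(r.P <= cfg.alpha and c.significant)
        any_sig = any_sig or flag
        merged.append(
            PairwiseResult(
                pair=r.pair, t=r.t, df=r.df, P=r.P,
                delta=c.delta, ci_low=c.ci_low, ci_high=c.ci_high,
                cliff_significant=c.significant, consensus=flag,
                parameter=r.parameter,
            )
        )
    return merged, any_sig
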
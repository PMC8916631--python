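"""Single change-point analysis (CPA) with split-cost criteria.

A series ``x`` contains a change point if it can be split into two segments
``x1``, ``x2`` such that ``C(x1) + C(x2) < C(x)`` for a cost function ``C``.
Three cost kinds are supported:

``mean``
    ``C(x) = N * var(x)`` with the *sample* variance (denominator ``N - 1``).
    Sensitive to level shifts.  Length-1 and constant segments cost 0.
``variance``
    ``C(x) = N * log(var(x) + eps)``, the Gaussian scale cost.  Sensitive to
    changes of dispersion.
``linear_trend``
    Sum of squared residuals around the OLS line on ``(t, x)``.  Sensitive to
    slope breaks.

The search is exhaustive over all admissible split positions, the detected
position is the 1-based index of the first point of the *second* segment, and
at most one change point is reported.

Because any continuous-valued series admits some split that lowers the raw
cost, the bare inequality alone would flag a change in essentially every
series.  Detection therefore additionally applies the Schwarz-criterion
single-change-point test (Chen & Gupta): the likelihood-ratio gain of the
best split must exceed ``p * log(n)``, where ``p`` is the number of extra
parameters the split introduces (2 for a mean or variance change, 3 for a
trend break).  ``penalty="none"`` restores the bare inequality.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np

__all__ = ["CostKind", "CpaResult", "segment_cost", "find_change_point"]

CostKind = Literal["mean", "variance", "linear_trend"]

#: Floor added inside the log of the variance cost to keep it finite for
#: (near-)constant segments.
EPS_VAR = 1e-12

#: Minimal admissible segment length per cost kind.
MIN_SEG = {"mean": 1, "variance": 2, "linear_trend": 2}

#: Extra free parameters a single change point introduces, per cost kind
#: (split location + new mean / new variance / new slope and intercept).
SIC_PARAMS = {"mean": 2, "variance": 2, "linear_trend": 3}


@dataclass(frozen=True)
class CpaResult:
    """Outcome of a single change-point scan.

    ``position`` is the 1-based index of the first point of the new regime,
    or ``None`` when no split strictly beats the unsplit cost.  ``cost_gain``
    is ``C(x) - [C(x1) + C(x2)]`` at the best split (possibly <= 0).
    """

    position: Optional[int]
    cost_gain: float


def _check_kind(kind: str) -> None:
    if kind not in MIN_SEG:
        raise ValueError(f"unknown cost kind {kind!r}; expected one of {sorted(MIN_SEG)}")


def segment_cost(segment: np.ndarray, kind: CostKind = "mean") -> float:
    """Cost of a single segment under the given cost kind."""
    _check_kind(kind)
    x = np.asarray(segment, dtype=float)
    if x.ndim != 1:
        raise ValueError("segment must be one-dimensional")
    n = x.size
    if n == 0:
        raise ValueError("empty segment has no cost")
    if kind == "mean":
        if n < 2:
            return 0.0
        return float(n * np.var(x, ddof=1))
    if kind == "variance":
        v = float(np.var(x, ddof=1)) if n >= 2 else 0.0
        return float(n * np.log(v + EPS_VAR))
    # linear_trend: SSR of the OLS line on (t, x); any <=2-point fit is exact
    if n <= 2:
        return 0.0
    t = np.arange(1.0, n + 1.0)
    slope, intercept = np.polyfit(t, x, 1)
    resid = x - (slope * t + intercept)
    return float(resid @ resid)


def _mean_costs(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vector of left/right mean-kind costs for every split ``k`` (left length)."""
    n = x.size
    s1 = np.cumsum(x)
    s2 = np.cumsum(x * x)
    k = np.arange(1, n, dtype=float)            # left lengths 1 .. n-1
    ss_l = s2[:-1] - s1[:-1] ** 2 / k
    ss_r = (s2[-1] - s2[:-1]) - (s1[-1] - s1[:-1]) ** 2 / (n - k)
    ss_l = np.maximum(ss_l, 0.0)
    ss_r = np.maximum(ss_r, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        c_l = np.where(k > 1, k * ss_l / np.maximum(k - 1, 1), 0.0)
        c_r = np.where(n - k > 1, (n - k) * ss_r / np.maximum(n - k - 1, 1), 0.0)
    return c_l, c_r


def _segment_stats(x: np.ndarray):
    """Prefix machinery shared by the variance and linear-trend scans."""
    n = x.size
    t = np.arange(1.0, n + 1.0)
    s1 = np.cumsum(x)
    s2 = np.cumsum(x * x)
    st = np.cumsum(t)
    stt = np.cumsum(t * t)
    stx = np.cumsum(t * x)
    return n, t, s1, s2, st, stt, stx


def _ssr_all_splits(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """OLS sum of squared residuals for all prefixes/suffixes (left length k)."""
    n, t, s1, s2, st, stt, stx = _segment_stats(x)
    k = np.arange(1, n, dtype=float)

    def ssr(sum1, sum2, sumt, sumtt, sumtx, m):
        syy = sum2 - sum1 ** 2 / m
        sty = sumtx - sumt * sum1 / m
        s_tt = sumtt - sumt ** 2 / m
        with np.errstate(divide="ignore", invalid="ignore"):
            out = syy - np.where(s_tt > 0, sty ** 2 / np.maximum(s_tt, 1e-300), 0.0)
        return np.maximum(out, 0.0)

    ssr_l = ssr(s1[:-1], s2[:-1], st[:-1], stt[:-1], stx[:-1], k)
    ssr_r = ssr(s1[-1] - s1[:-1], s2[-1] - s2[:-1], st[-1] - st[:-1],
                stt[-1] - stt[:-1], stx[-1] - stx[:-1], n - k)
    # segments of length <= 2 are fitted exactly
    ssr_l[k <= 2] = 0.0
    ssr_r[(n - k) <= 2] = 0.0
    return ssr_l, ssr_r


def _variance_costs(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n = x.size
    s1 = np.cumsum(x)
    s2 = np.cumsum(x * x)
    k = np.arange(1, n, dtype=float)
    ss_l = np.maximum(s2[:-1] - s1[:-1] ** 2 / k, 0.0)
    ss_r = np.maximum((s2[-1] - s2[:-1]) - (s1[-1] - s1[:-1]) ** 2 / (n - k), 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        v_l = np.where(k > 1, ss_l / np.maximum(k - 1, 1), 0.0)
        v_r = np.where(n - k > 1, ss_r / np.maximum(n - k - 1, 1), 0.0)
    return k * np.log(v_l + EPS_VAR), (n - k) * np.log(v_r + EPS_VAR)


def _plain_ss_splits(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Within-segment sums of squares (no inflation) for every split."""
    n = x.size
    s1 = np.cumsum(x)
    s2 = np.cumsum(x * x)
    k = np.arange(1, n, dtype=float)
    ss_l = np.maximum(s2[:-1] - s1[:-1] ** 2 / k, 0.0)
    ss_r = np.maximum((s2[-1] - s2[:-1]) - (s1[-1] - s1[:-1]) ** 2 / (n - k), 0.0)
    return ss_l, ss_r


def find_change_point(series: np.ndarray, kind: CostKind = "mean",
                      penalty: str = "sic") -> CpaResult:
    """Exhaustive single change-point scan under the split-cost criterion.

    Returns the split minimising ``C(x1) + C(x2)`` over all splits whose
    segments both have at least the kind's minimal length (ties broken in
    favour of the earliest split).  With ``penalty="sic"`` (default) the
    position is reported only when the likelihood-ratio gain of that split
    beats the Schwarz threshold ``p * log(n)``; with ``penalty="none"`` the
    bare inequality ``C(x1) + C(x2) < C(x)`` decides.
    """
    _check_kind(kind)
    if penalty not in ("sic", "none"):
        raise ValueError("penalty must be 'sic' or 'none'")
    x = np.asarray(series, dtype=float).ravel()
    n = x.size
    if not np.all(np.isfinite(x)):
        raise ValueError("series contains non-finite values")
    if n < 4:
        warnings.warn("series too short for change-point analysis (length < 4)",
                      stacklevel=2)
        return CpaResult(None, 0.0)

    if kind == "mean":
        c_l, c_r = _mean_costs(x)
    elif kind == "variance":
        c_l, c_r = _variance_costs(x)
    else:
        c_l, c_r = _ssr_all_splits(x)

    total = c_l + c_r
    mseg = MIN_SEG[kind]
    k = np.arange(1, n)                       # left lengths
    admissible = (k >= mseg) & (n - k >= mseg)
    total = np.where(admissible, total, np.inf)
    best = int(np.argmin(total))              # earliest argmin by np.argmin
    whole = segment_cost(x, kind)
    gain = whole - float(total[best])
    # numerical floor: round-off from least-squares fits must not count as gain
    tol = n * (1e-12 * float(np.var(x)) + 1e-18 * float(np.mean(x * x)))
    if not np.isfinite(gain) or gain <= tol:
        return CpaResult(None, float(gain) if np.isfinite(gain) else 0.0)
    if penalty == "sic" and not _passes_sic(x, kind, best, gain):
        return CpaResult(None, gain)
    return CpaResult(best + 2, gain)          # left length k -> position k+1 (1-based)


def _split_residuals(x: np.ndarray, kind: str, k: int) -> np.ndarray:
    """Residuals of the fitted two-segment model with left length ``k``."""
    left, right = x[:k], x[k:]
    if kind == "linear_trend":
        def res(seg):
            n = seg.size
            if n <= 2:
                return np.zeros(n)
            t = np.arange(1.0, n + 1.0)
            slope, intercept = np.polyfit(t, seg, 1)
            return seg - (slope * t + intercept)
        return np.concatenate([res(left), res(right)])
    return np.concatenate([left - left.mean(), right - right.mean()])


def _effective_n(resid: np.ndarray) -> float:
    """Sample size corrected for lag-1 residual dependence (Bartlett).

    Positively autocorrelated residuals (e.g. rows of sliding-window
    representations, which are smooth by construction) carry far fewer
    independent observations than points; the classical first-order
    correction is ``n (1 - rho) / (1 + rho)``.
    """
    n = resid.size
    denom = float(resid @ resid)
    if denom <= 0.0:
        return float(n)
    rho = float(resid[:-1] @ resid[1:]) / denom
    rho = min(max(rho, -0.95), 0.95)
    n_eff = n * (1.0 - rho) / (1.0 + rho)
    return float(min(max(n_eff, 8.0), 3.0 * n))


def _passes_sic(x: np.ndarray, kind: str, best: int, gain: float) -> bool:
    """Schwarz-criterion gate at the chosen split, on effective observations."""
    n = x.size
    k = best + 1                              # left segment length
    n_eff = _effective_n(_split_residuals(x, kind, k))
    threshold = SIC_PARAMS[kind] * np.log(n_eff)
    if kind == "variance":
        return gain * (n_eff / n) > threshold  # cost is already on the log scale
    if kind == "mean":
        ss_l, ss_r = _plain_ss_splits(x)
        fit0 = float(np.var(x) * n)           # total sum of squares (ML)
        fit1 = float(ss_l[best] + ss_r[best])
    else:
        ssr_l, ssr_r = _ssr_all_splits(x)
        fit0 = segment_cost(x, "linear_trend")
        fit1 = float(ssr_l[best] + ssr_r[best])
    if fit0 <= 0.0:
        return False
    if fit1 <= 0.0:
        return True                           # exact fit after the split
    return n_eff * np.log(fit0 / fit1) > threshold
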
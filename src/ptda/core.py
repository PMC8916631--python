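"""The Pattern Transition Detection Algorithm (PTDA).

The detector aggregates convergent evidence from several views of a series:

1. outliers are deleted (generalized extreme Studentized deviate test) and
   an index map keeps every later result on the original time axis;
2. change-point analysis (CPA) runs on the raw series (mean, variance and
   linear-trend costs) and, with the mean cost, on the Dynamic Complexity
   series and on every row of the recurrence and time-frequency matrices —
   the two matrices are each condensed to one change point by a histogram
   vote over their row-wise change points;
3. change points in the first or last 10% of the series are discarded
   (edge filter);
4. the clustering of the surviving change points is tested against chance:
   their interquartile range must fall below the lower bound of the
   uniform-resampling distribution of IQRs (100 replicates);
5. if significant, the overall transition point (TP) is the rounded median
   of the surviving change points, and a probability band (sum of unit-height
   Gaussian kernels, variance 5, one per change point) visualises their
   convergence.

In *whole-system* mode the change points of all variables of a multivariate
recording are pooled before steps 3-5.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .changepoint import find_change_point
from .config import PtdaConfig
from .secondary import distance_matrix, dynamic_complexity, embed, stockwell_tfd

__all__ = [
    "ChangePoint", "TransitionResult", "remove_outliers", "matrix_change_point",
    "collect_cps", "edge_filter", "significance_test", "derive_tp",
    "probability_band", "run_ptda",
]

logger = logging.getLogger(__name__)

#: Method tags in reporting order.
METHODS = ("raw_mean", "raw_variance", "raw_linear", "dc_mean", "rp_hist", "tfd_hist")


@dataclass(frozen=True)
class ChangePoint:
    """A single-method change point on the original (1-based) time axis."""

    position: int
    method: str
    series_id: int = 0


@dataclass
class TransitionResult:
    """Aggregate outcome of the detector for one (multi)variate recording."""

    tp: Optional[int]
    significant: bool
    cps: List[ChangePoint]            # all collected change points
    surviving: List[ChangePoint]      # after the edge filter
    real_iqr: Optional[float]
    random_iqr_mean: Optional[float]
    random_iqr_lower: Optional[float]
    band: np.ndarray
    length: int = 0


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


# ---------------------------------------------------------------------------
# Outlier deletion (generalized extreme Studentized deviate)
# ---------------------------------------------------------------------------

def remove_outliers(series: np.ndarray, alpha: float = 0.05,
                    max_frac: float = 0.1) -> Tuple[np.ndarray, np.ndarray]:
    """Iterative GESD outlier deletion.

    Returns the cleaned series and an index map: ``index_map[i]`` is the
    original 1-based index of clean position ``i+1``.  At most
    ``ceil(max_frac * L)`` points are removed; a constant series is returned
    untouched (the test statistic is undefined at zero spread).
    """
    x = np.asarray(series, dtype=float).ravel()
    n = x.size
    if n < 15:
        raise ValueError("GESD outlier screening needs at least 15 points")
    r_max = int(math.ceil(max_frac * n))
    work = x.copy()
    idx = np.arange(n)
    stats_r = []          # (test statistic, critical value, candidate index)
    for i in range(1, r_max + 1):
        sd = work.std(ddof=1)
        if sd == 0 or work.size < 3:
            break
        dev = np.abs(work - work.mean())
        j = int(np.argmax(dev))
        R = dev[j] / sd
        m = work.size
        p = 1.0 - alpha / (2.0 * m)
        tcrit = stats.t.ppf(p, m - 2)
        lam = (m - 1) * tcrit / math.sqrt((m - 2 + tcrit ** 2) * m)
        stats_r.append((R, lam, idx[j]))
        work = np.delete(work, j)
        idx = np.delete(idx, j)
    n_out = 0
    for i, (R, lam, _) in enumerate(stats_r, start=1):
        if R > lam:
            n_out = i
    if n_out > 0.5 * n:
        raise ValueError("more than half of the series flagged as outliers")
    drop = {stats_r[i][2] for i in range(n_out)}
    keep = np.array([i for i in range(n) if i not in drop], dtype=int)
    return x[keep], keep + 1


# ---------------------------------------------------------------------------
# Matrix condensation: row-wise CPA + histogram vote
# ---------------------------------------------------------------------------

def matrix_change_point(matrix: np.ndarray, bin_frac: float = 0.2,
                        edge_frac: float = 0.1) -> Optional[int]:
    """Condense a (rows x time) matrix to one change point.

    Mean-cost CPA runs on every non-constant row; the detected positions are
    binned with bin width ``round(bin_frac * L)`` (edges anchored at t = 1)
    and the rounded middle of the votes inside the modal bin (their median)
    is returned — the bin selects the consensus region, the in-bin median
    keeps the resolution the rows agree on.  Row-level change points inside
    the ``edge_frac`` end zones are edge artifacts of the row-wise scans and
    are excluded from the vote.  ``None`` if no row yields a change point.
    """
    mat = np.atleast_2d(np.asarray(matrix, dtype=float))
    if mat.size == 0:
        raise ValueError("empty matrix")
    L = mat.shape[1]
    lo, hi = math.ceil(edge_frac * L), math.floor((1.0 - edge_frac) * L)
    positions = []
    for row in mat:
        if np.ptp(row) == 0.0:
            continue
        res = find_change_point(row, "mean")
        if res.position is not None and lo < res.position <= hi:
            positions.append(res.position)
    if not positions:
        return None
    bw = max(1, _round_half_up(bin_frac * L))
    edges = np.arange(1, L + bw + 1, bw)      # bin j covers [edges[j], edges[j+1]-1]
    counts, _ = np.histogram(positions, bins=edges)
    j = int(np.argmax(counts))                # earliest modal bin on ties
    lo_b, hi_b = int(edges[j]), int(edges[j + 1]) - 1
    in_bin = [p for p in positions if lo_b <= p <= hi_b]
    return _round_half_up(float(np.median(in_bin)))


# ---------------------------------------------------------------------------
# Per-series change-point collection
# ---------------------------------------------------------------------------

def collect_cps(series: np.ndarray, config: PtdaConfig,
                index_map: Optional[np.ndarray] = None,
                series_id: int = 0,
                scale_range: Optional[Tuple[float, float]] = None,
                ) -> List[ChangePoint]:
    """All single-method change points of one (outlier-cleaned) series.

    Up to six change points are produced: mean-, variance- and trend-cost CPA
    on the raw series, mean-cost CPA on the Dynamic Complexity series, and
    the histogram vote over the recurrence and time-frequency matrices.
    Positions from shortened representations are mapped back to the original
    axis via the representation's start index and the outlier index map.
    """
    x = np.asarray(series, dtype=float).ravel()
    L = x.size
    if index_map is None:
        index_map = np.arange(1, L + 1)

    def to_original(clean_pos: int) -> int:
        return int(index_map[min(clean_pos, L) - 1])

    cps: List[ChangePoint] = []
    if np.ptp(x) == 0.0:
        return cps

    for kind, tag in (("mean", "raw_mean"), ("variance", "raw_variance"),
                      ("linear_trend", "raw_linear")):
        res = find_change_point(x, kind)
        if res.position is not None:
            cps.append(ChangePoint(to_original(res.position), tag, series_id))

    sr = scale_range or config.scale_range or (float(x.min()), float(x.max()))
    # measurement noise can push observations past the nominal rating bounds;
    # widen to the observed hull so the DC stays defined
    sr = (min(sr[0], float(x.min())), max(sr[1], float(x.max())))
    if sr[1] > sr[0] and L >= config.w + 3:
        dc = dynamic_complexity(x, w=config.w, scale_range=sr)
        res = find_change_point(dc.values, "mean") if np.ptp(dc.values) else None
        if res is not None and res.position is not None:
            # DC value sits at its window's last point: offset w - 1
            cps.append(ChangePoint(to_original(res.position + config.w - 1),
                                   "dc_mean", series_id))

    n_emb = L - (config.m - 1) * config.tau
    if n_emb >= 4:
        rp = distance_matrix(embed(x, config.m, config.tau), config.m, config.tau)
        pos = matrix_change_point(rp.distances, config.bin_frac)
        if pos is not None:
            cps.append(ChangePoint(to_original(pos), "rp_hist", series_id))

    if L >= 8:
        tfd = stockwell_tfd(x)
        pos = matrix_change_point(tfd.amplitudes, config.bin_frac)
        if pos is not None:
            cps.append(ChangePoint(to_original(pos), "tfd_hist", series_id))
    return cps


# ---------------------------------------------------------------------------
# Aggregation steps
# ---------------------------------------------------------------------------

def edge_filter(cps: Sequence[ChangePoint], L: int,
                edge_frac: float = 0.1) -> List[ChangePoint]:
    """Drop change points in the first or last ``edge_frac`` of the series."""
    lo = math.ceil(edge_frac * L)
    hi = math.floor((1.0 - edge_frac) * L)
    return [cp for cp in cps if lo < cp.position <= hi]


def significance_test(cps: Sequence[ChangePoint], L: int, n_rep: int = 100,
                      seed: Optional[int] = None, min_cps: int = 3,
                      ci_method: str = "percentile",
                      ) -> Tuple[bool, Optional[float], Optional[float], Optional[float]]:
    """Dispersion test of change-point clustering against a uniform null.

    The IQR of the observed positions is compared with the IQRs of ``n_rep``
    draws of equally many positions uniform on ``[1, L]``; the verdict is
    significant when the observed IQR lies strictly below the lower bound of
    the null's central 95% interval (2.5th percentile, or mean - 1.96 SD with
    ``ci_method="normal"``).  Fewer than ``min_cps`` change points yield a
    negative verdict.
    """
    k = len(cps)
    if k < min_cps:
        return False, None, None, None
    pos = np.array([cp.position for cp in cps], dtype=float)
    real_iqr = float(np.percentile(pos, 75) - np.percentile(pos, 25))
    rng = np.random.default_rng(seed)
    draws = rng.integers(1, L + 1, size=(n_rep, k))
    q75, q25 = np.percentile(draws, [75, 25], axis=1)
    iqrs = q75 - q25
    mean = float(iqrs.mean())
    if ci_method == "normal":
        lower = mean - 1.96 * float(iqrs.std(ddof=1))
    else:
        lower = float(np.percentile(iqrs, 2.5))
    return bool(real_iqr < lower), real_iqr, mean, lower


def derive_tp(cps: Sequence[ChangePoint]) -> int:
    """Overall transition point: rounded (half-up) median of the positions."""
    pos = np.array([cp.position for cp in cps], dtype=float)
    return _round_half_up(float(np.median(pos)))


def probability_band(cps: Sequence[ChangePoint], L: int,
                     var: float = 5.0) -> np.ndarray:
    """Sum of unit-height Gaussian kernels, one per change point.

    ``band[t-1] = sum_p exp(-(t - p)^2 / (2 var))`` for ``t = 1 .. L``; a
    narrow bright ridge in this band marks strong convergence of methods.
    """
    t = np.arange(1, L + 1, dtype=float)
    band = np.zeros(L)
    for cp in cps:
        band += np.exp(-((t - cp.position) ** 2) / (2.0 * var))
    return band


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------

def run_ptda(series_list: Sequence[np.ndarray],
             config: Optional[PtdaConfig] = None,
             scale_ranges: Optional[Sequence[Tuple[float, float]]] = None,
             ) -> TransitionResult:
    """Run the detector on one series (single mode) or several (whole-system).

    All series must share one length.  Change points from every series and
    method are pooled, edge-filtered, and tested for clustering; a transition
    point is reported only on a significant verdict.
    """
    cfg = config or PtdaConfig()
    if len(series_list) == 0:
        raise ValueError("need at least one series")
    arrays = [np.asarray(s, dtype=float).ravel() for s in series_list]
    L = arrays[0].size
    if any(a.size != L for a in arrays):
        raise ValueError("all series must have the same length")
    if scale_ranges is not None and len(scale_ranges) != len(arrays):
        raise ValueError("one scale_range per series required")

    all_cps: List[ChangePoint] = []
    for sid, x in enumerate(arrays):
        if L >= 15:
            clean, index_map = remove_outliers(x, cfg.alpha, cfg.max_outlier_frac)
        else:
            clean, index_map = x, np.arange(1, L + 1)
        sr = scale_ranges[sid] if scale_ranges is not None else None
        all_cps.extend(collect_cps(clean, cfg, index_map, sid, sr))

    surviving = edge_filter(all_cps, L, cfg.edge_frac)
    significant, real_iqr, rnd_mean, rnd_lower = significance_test(
        surviving, L, cfg.n_rep, cfg.seed, cfg.min_cps, cfg.ci_method)
    tp = derive_tp(surviving) if significant else None
    band = probability_band(surviving, L, cfg.band_var)

    if logger.isEnabledFor(logging.INFO):
        table = ", ".join(f"{cp.method}[{cp.series_id}]={cp.position}"
                          for cp in all_cps) or "none"
        logger.info("change points: %s", table)
        logger.info("TP=%s significant=%s IQR=%s null_lower=%s",
                    tp, significant, real_iqr, rnd_lower)

    return TransitionResult(tp=tp, significant=significant, cps=all_cps,
                            surviving=surviving, real_iqr=real_iqr,
                            random_iqr_mean=rnd_mean, random_iqr_lower=rnd_lower,
                            band=band, length=L)
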
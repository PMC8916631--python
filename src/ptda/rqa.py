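"""Sliding-window recurrence quantification: Determinism and Recurrence Time
Entropy.

Both quantifiers operate on thresholded recurrence plots (``R_ij = 1`` iff
the Euclidean distance between embedded states i and j is at most ``eps``,
on *raw*, unnormalised distances) restricted to square windows along the
main diagonal:

* ``DET`` — the fraction of recurrence points lying on diagonal lines of
  length at least ``l_min`` (main diagonal excluded); close to 1 for regular,
  rhythmic dynamics, small for uncorrelated ones.
* ``RTE`` — the Shannon entropy (natural log) of the distribution of
  recurrence times, read off as the lengths of *white* vertical gaps between
  successive recurrence points in each column.  A single recurrence time
  (strict periodicity) gives 0.  The entropy of the black vertical line
  lengths is available as an alternative reading (``vertical="black"``).

Windows advance one sample at a time and each value is assigned to the
window's last index, so rising complexity registers at, not after, the
transition.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import List, Sequence, Tuple

import numpy as np

from .secondary import RecurrenceMatrix, distance_matrix, embed

__all__ = ["RqaConfig", "threshold_rp", "det_windowed", "rte_windowed",
           "det_of_window", "recurrence_times"]


@dataclass(frozen=True)
class RqaConfig:
    m: int = 3
    tau: int = 1
    eps: float = 0.1
    l_min: int = 2
    window_widths: Tuple[int, ...] = (25, 45, 65)
    vertical: str = "white"        # recurrence-time reading: "white" | "black"

    def __post_init__(self):
        if self.eps <= 0:
            raise ValueError("eps must be > 0")
        if self.l_min < 2:
            raise ValueError("l_min must be >= 2")


def threshold_rp(dist: RecurrenceMatrix | np.ndarray, eps: float) -> np.ndarray:
    """Binary recurrence matrix: 1 where distance <= eps."""
    d = dist.distances if isinstance(dist, RecurrenceMatrix) else np.asarray(dist)
    if eps <= 0:
        raise ValueError("eps must be > 0")
    return (d <= eps).astype(np.int8)


def _diagonal_line_lengths(window: np.ndarray) -> List[Tuple[int, bool]]:
    """Maximal diagonal runs of 1s, main diagonal excluded.

    Returns ``(length, censored)`` pairs; a run is censored when it touches
    the window border, i.e. it is the visible part of a possibly longer line.
    """
    n = window.shape[0]
    runs: List[Tuple[int, bool]] = []
    for off in range(-(n - 1), n):
        if off == 0:
            continue
        diag = np.diagonal(window, offset=off)
        m = diag.size
        run = 0
        for i, v in enumerate(diag):
            if v:
                run += 1
            elif run:
                runs.append((run, i == run))          # touched the start?
                run = 0
        if run:
            runs.append((run, True))                  # touches the end
    return runs


def det_of_window(window: np.ndarray, l_min: int = 2) -> float:
    """DET of one thresholded RP window (main diagonal excluded).

    Runs cut by the window border are censored observations of longer lines
    and count as deterministic at their truncated length; interior runs must
    reach ``l_min``.  Without this, a strictly periodic signal could not
    attain DET = 1 in any finite window.
    """
    runs = _diagonal_line_lengths(window)
    total = sum(l for l, _ in runs)
    if total == 0:
        warnings.warn("RP window holds no recurrence points; DET set to 0",
                      stacklevel=2)
        return 0.0
    kept = sum(l for l, censored in runs if censored or l >= l_min)
    return kept / total


def recurrence_times(window: np.ndarray, vertical: str = "white") -> List[int]:
    """Vertical-structure lengths of a thresholded RP window.

    ``"white"``: gaps between successive recurrence points in each column
    (the recurrence times proper).  ``"black"``: lengths of contiguous
    vertical runs of recurrence points.
    """
    out: List[int] = []
    for j in range(window.shape[1]):
        col = window[:, j]
        ones = np.flatnonzero(col)
        if vertical == "white":
            if ones.size >= 2:
                out.extend(np.diff(ones).tolist())
        else:
            run = 0
            for v in col:
                if v:
                    run += 1
                elif run:
                    out.append(run)
                    run = 0
            if run:
                out.append(run)
    return out


def _entropy(values: Sequence[int]) -> float:
    if not values:
        return 0.0
    counts = np.array(list(Counter(values).values()), dtype=float)
    p = counts / counts.sum()
    return float(-(p * np.log(p)).sum())


def _windows(series: np.ndarray, cfg: RqaConfig, width: int):
    emb = embed(series, cfg.m, cfg.tau)
    if width > emb.shape[0]:
        raise ValueError("window width exceeds the embedded series length")
    rp = threshold_rp(distance_matrix(emb, cfg.m, cfg.tau), cfg.eps)
    for s in range(rp.shape[0] - width + 1):
        yield s + width, rp[s: s + width, s: s + width]


def det_windowed(series: np.ndarray, cfg: RqaConfig | None = None,
                 width: int | None = None) -> Tuple[np.ndarray, np.ndarray]:
    """Sliding-window DET profile.

    Returns ``(positions, values)`` where each value belongs to the embedded
    window ending at that (1-based) position.
    """
    cfg = cfg or RqaConfig()
    width = width or cfg.window_widths[0]
    pos, vals = [], []
    for end, win in _windows(series, cfg, width):
        pos.append(end)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            vals.append(det_of_window(win, cfg.l_min))
    return np.array(pos), np.array(vals)


def rte_windowed(series: np.ndarray, cfg: RqaConfig | None = None,
                 width: int | None = None) -> Tuple[np.ndarray, np.ndarray]:
    """Sliding-window Recurrence Time Entropy profile (natural log)."""
    cfg = cfg or RqaConfig()
    width = width or cfg.window_widths[0]
    pos, vals = [], []
    for end, win in _windows(series, cfg, width):
        pos.append(end)
        vals.append(_entropy(recurrence_times(win, cfg.vertical)))
    return np.array(pos), np.array(vals)
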
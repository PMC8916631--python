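"""Second-level representations of a time series.

Three transforms feed the transition detector beyond the raw series:

* **Dynamic Complexity (DC)** — a sliding-window product ``F * D`` of a
  fluctuation measure (amplitude and reversal frequency of monotone runs,
  normalised so that min/max alternation at every step scores 1) and a
  distribution measure (how evenly the window covers the admissible rating
  range; 1 = uniform coverage, 0 = degenerate).  Designed for short, bounded,
  coarse-grained daily-rating series.
* **Recurrence distance matrix** — pairwise Euclidean distances between
  delay-embedded state vectors (default embedding dimension m = 3, delay
  tau = 1).  Left unthresholded: each row is itself a time series to which
  change-point analysis can be applied.
* **Stockwell time-frequency distribution (TFD)** — amplitude of the discrete
  S-transform, a Fourier decomposition with a frequency-dependent Gaussian
  window that keeps absolutely-referenced phase.  Each frequency row is again
  a time series.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "DcSeries", "RecurrenceMatrix", "TfdMatrix", "fluctuation_measure",
    "distribution_measure", "dynamic_complexity", "embed", "distance_matrix",
    "stockwell_tfd",
]


@dataclass
class DcSeries:
    """Dynamic-complexity values, one per sliding window (aligned to the
    window's *last* time point; the first value belongs to time ``w``)."""

    values: np.ndarray
    window_width: int
    scale_range: Tuple[float, float]


@dataclass
class RecurrenceMatrix:
    """Unthresholded recurrence (distance) matrix over embedded vectors."""

    distances: np.ndarray
    m: int
    tau: int


@dataclass
class TfdMatrix:
    """S-transform amplitudes; row k is frequency k cycles per series length."""

    amplitudes: np.ndarray    # shape (L // 2, L)


# ---------------------------------------------------------------------------
# Dynamic Complexity
# ---------------------------------------------------------------------------

def fluctuation_measure(window: np.ndarray, scale_range: Tuple[float, float]) -> float:
    """Fluctuation ``F`` of one window.

    The window is split into maximal monotone runs (strictly rising or
    falling; flat steps separate runs and contribute nothing).  Each run
    contributes its amplitude divided by its duration, and the sum is
    normalised by the largest value attainable on the rating scale — a full
    min/max alternation at every step — so that ``F`` lies in ``[0, 1]``.
    """
    x = np.asarray(window, dtype=float)
    lo, hi = scale_range
    rng = hi - lo
    d = np.diff(x)
    total = 0.0
    i = 0
    n = d.size
    while i < n:
        s = np.sign(d[i])
        if s == 0:
            i += 1
            continue
        j = i
        while j < n and np.sign(d[j]) == s:
            j += 1
        amp = abs(x[j] - x[i])          # run covers points i .. j
        total += amp / (j - i)
        i = j
    return float(total / (rng * (x.size - 1)))


def distribution_measure(window: np.ndarray, scale_range: Tuple[float, float]) -> float:
    """Distribution ``D`` of one window: evenness of coverage of the scale.

    The sorted window values are compared against a perfectly even spread of
    the same number of points over the full rating range.  For every pair of
    sorted values the shortfall of their actual spacing below the even-spread
    spacing is accumulated; ``D`` is one minus the normalised shortfall, so a
    perfectly even spread scores 1 and a constant window scores 0.
    """
    y = np.sort(np.asarray(window, dtype=float))
    lo, hi = scale_range
    n = y.size
    g = (hi - lo) / (n - 1)             # even-spread gap
    idx = np.arange(n)
    span = idx[None, :] - idx[:, None]          # b - a for all pairs
    actual = y[None, :] - y[:, None]
    mask = span > 0
    ideal = span[mask] * g
    shortfall = np.clip(ideal - actual[mask], 0.0, None)
    return float(1.0 - shortfall.sum() / ideal.sum())


def dynamic_complexity(series: np.ndarray, w: int = 7,
                       scale_range: Optional[Tuple[float, float]] = None) -> DcSeries:
    """Sliding-window Dynamic Complexity ``DC = F * D``.

    ``scale_range`` is the theoretical range of the rating scale; it must be
    non-degenerate and contain every observation.  The output has
    ``L - w + 1`` values, the i-th belonging to the window ending at time
    ``w + i`` (1-based).
    """
    x = np.asarray(series, dtype=float).ravel()
    if w < 3:
        raise ValueError("window width must be >= 3")
    if x.size < w:
        raise ValueError("series shorter than the window width")
    if scale_range is None:
        raise ValueError("scale_range is required for Dynamic Complexity")
    lo, hi = scale_range
    if not hi > lo:
        raise ValueError("scale_range must be non-degenerate")
    if x.min() < lo - 1e-9 or x.max() > hi + 1e-9:
        raise ValueError("series values fall outside scale_range")
    vals = np.empty(x.size - w + 1)
    for i in range(vals.size):
        win = x[i: i + w]
        vals[i] = fluctuation_measure(win, scale_range) * \
            distribution_measure(win, scale_range)
    return DcSeries(values=vals, window_width=w, scale_range=(lo, hi))


# ---------------------------------------------------------------------------
# Delay embedding and recurrence distances
# ---------------------------------------------------------------------------

def embed(series: np.ndarray, m: int = 3, tau: int = 1) -> np.ndarray:
    """Time-delay embedding: vector ``i`` is ``(x_i, x_{i+tau}, ..., x_{i+(m-1)tau})``."""
    x = np.asarray(series, dtype=float).ravel()
    if m < 1 or tau < 1:
        raise ValueError("m and tau must be >= 1")
    n = x.size - (m - 1) * tau
    if n < 1:
        raise ValueError("series too short for the requested embedding")
    return np.column_stack([x[j * tau: j * tau + n] for j in range(m)])


def distance_matrix(vectors: np.ndarray, m: int = 3, tau: int = 1) -> RecurrenceMatrix:
    """Euclidean distance matrix between embedded state vectors."""
    v = np.atleast_2d(np.asarray(vectors, dtype=float))
    if v.shape[0] < 2:
        raise ValueError("need at least two vectors")
    d = squareform(pdist(v, metric="euclidean"))
    return RecurrenceMatrix(distances=d, m=m, tau=tau)


# ---------------------------------------------------------------------------
# Stockwell transform
# ---------------------------------------------------------------------------

def stockwell_tfd(series: np.ndarray) -> TfdMatrix:
    """Discrete S-transform amplitude matrix via the FFT algorithm.

    For frequency row ``n`` (cycles per record) the transform is the inverse
    FFT of the shifted spectrum ``H[m + n]`` windowed by the Gaussian voice
    ``exp(-2 pi^2 m^2 / n^2)`` — the standard frequency-domain formulation of
    the S-transform with window width proportional to wavelength.  The
    zero-frequency row (the local mean) is excluded; rows ``1 .. L // 2`` are
    returned.
    """
    x = np.asarray(series, dtype=float).ravel()
    L = x.size
    if L < 8:
        raise ValueError("series too short for a time-frequency distribution")
    if not np.all(np.isfinite(x)):
        raise ValueError("series contains non-finite values")
    H = np.fft.fft(x)
    Hcat = np.concatenate([H, H])             # cheap circular indexing
    mfreq = np.fft.fftfreq(L, d=1.0 / L)      # signed integer frequencies
    nmax = L // 2
    amps = np.empty((nmax, L))
    for n in range(1, nmax + 1):
        gauss = np.exp(-2.0 * np.pi ** 2 * mfreq ** 2 / n ** 2)
        voice = np.fft.ifft(Hcat[n: n + L] * gauss)
        amps[n - 1] = np.abs(voice)
    return TfdMatrix(amplitudes=amps)
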
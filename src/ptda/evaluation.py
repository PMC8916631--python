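"""Validation harness: performance metrics and the simulation experiments.

The experiments regenerate the validation protocol — 60 complexity-filtered
simulation runs, 5 series each — and score three detectors on it: the
whole-system detector (one verdict per run, pooling all five variables),
the single-series detector (one verdict per series) and bare mean-cost CPA.
Five performance measures are reported per condition: the mean and SD of the
detected transition points, the precision (share of detected TPs within +/-5
time points of the induced shift), the false-negative rate (transition-bearing
series with no verdict) and the false-positive rate (shift-free windows with a
verdict).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence

import numpy as np

from .changepoint import find_change_point
from .config import PtdaConfig
from .core import run_ptda
from .sim_model import VARIABLES, STATE_RANGES, ValidationWindow, make_validation_set

__all__ = ["PerformanceReport", "performance_metrics", "run_table_experiment",
           "detect_windows"]

#: Per-variable rating ranges handed to the Dynamic Complexity measure.
SIM_SCALE_RANGES = tuple(STATE_RANGES[v] for v in VARIABLES)


@dataclass
class PerformanceReport:
    mean_tp: Optional[float]
    sd_tp: Optional[float]
    precision_pct: Optional[float]
    fn_pct: Optional[float]
    fp_pct: Optional[float]
    n: int
    condition: Dict = field(default_factory=dict)

    def as_dict(self) -> Dict:
        return asdict(self)


def performance_metrics(detected: Sequence[Optional[int]],
                        truths: Sequence[Optional[int]],
                        tol: int = 5, condition: Optional[Dict] = None,
                        ) -> PerformanceReport:
    """Score detections against ground truth.

    Precision counts only series where a TP was detected *and* a true TP
    exists (detected-only denominator); the false-negative rate is computed
    on truth-bearing series, the false-positive rate on truth-free ones —
    disjoint denominators.
    """
    if len(detected) != len(truths):
        raise ValueError("detected and truths must have the same length")
    if len(detected) == 0:
        raise ValueError("empty input")
    hits = [(d, t) for d, t in zip(detected, truths) if t is not None and d is not None]
    pos = [d for d, t in zip(detected, truths) if t is not None]
    neg = [d for d, t in zip(detected, truths) if t is None]

    mean_tp = sd_tp = precision = fn = fp = None
    if hits:
        vals = np.array([d for d, _ in hits], dtype=float)
        mean_tp = float(vals.mean())
        sd_tp = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
        precision = 100.0 * sum(abs(d - t) <= tol for d, t in hits) / len(hits)
    if pos:
        fn = 100.0 * sum(d is None for d in pos) / len(pos)
    if neg:
        fp = 100.0 * sum(d is not None for d in neg) / len(neg)
    return PerformanceReport(mean_tp, sd_tp, precision, fn, fp,
                             n=len(detected), condition=condition or {})


def detect_windows(windows: Sequence[ValidationWindow], mode: str,
                   config: Optional[PtdaConfig] = None,
                   ) -> List[Optional[int]]:
    """Run a detector over validation windows.

    ``mode="whole"`` yields one verdict per window (all 5 variables pooled),
    ``"single"`` one verdict per variable series (5 per window), and
    ``"cpa"`` applies bare mean-cost CPA per variable series.
    """
    cfg = config or PtdaConfig()
    out: List[Optional[int]] = []
    for wi, win in enumerate(windows):
        cols = [win.data[:, j] for j in range(win.data.shape[1])]
        seed = None if cfg.seed is None else cfg.seed + 1000 * wi
        wcfg = cfg.with_(seed=seed)
        if mode == "whole":
            res = run_ptda(cols, wcfg, scale_ranges=SIM_SCALE_RANGES)
            out.append(res.tp)
        elif mode == "single":
            for j, col in enumerate(cols):
                res = run_ptda([col], wcfg.with_(seed=None if seed is None
                                                 else seed + j),
                               scale_ranges=[SIM_SCALE_RANGES[j]])
                out.append(res.tp)
        elif mode == "cpa":
            for col in cols:
                out.append(find_change_point(col, "mean").position)
        else:
            raise ValueError(f"unknown mode {mode!r}")
    return out


def _truths(windows: Sequence[ValidationWindow], per_series: bool) -> List[Optional[int]]:
    reps = 5 if per_series else 1
    out: List[Optional[int]] = []
    for w in windows:
        out.extend([w.true_tp] * reps)
    return out


def run_table_experiment(table: int, condition: Optional[Dict] = None,
                         seed: int = 0, n_runs: int = 60,
                         config: Optional[PtdaConfig] = None,
                         ) -> Dict[str, PerformanceReport]:
    """Replicate one validation experiment.

    ``table=1``: baseline (shift at position 50, no noise, instantaneous) for
    all three detectors, with shift-free windows for the false-positive
    rates.  ``table=2``: one real-world condition, ``condition`` holding one
    of ``{"noise": pct}``, ``{"position": p}``, ``{"ramp": n}``.  ``table=3``:
    shortened series, ``condition={"length": n}`` with the shift mid-window.
    """
    cond = dict(condition or {})
    cfg = (config or PtdaConfig()).with_(seed=seed)
    noise = float(cond.get("noise", 0.0))
    ramp = int(cond.get("ramp", 0))
    position = int(cond.get("position", 50))
    length = 100

    if table == 3:
        length = int(cond["length"])
        position = length // 2

    trans = make_validation_set(n_runs, tp_position=position, noise_pct=noise,
                                ramp_length=ramp, seed=seed, length=length)
    null = make_validation_set(n_runs, tp_position=None, noise_pct=noise,
                               ramp_length=ramp, seed=seed + 1, length=length)

    reports: Dict[str, PerformanceReport] = {}
    for mode in ("whole", "single", "cpa"):
        per_series = mode != "whole"
        detected = detect_windows(trans, mode, cfg) + detect_windows(null, mode, cfg)
        truths = _truths(trans, per_series) + _truths(null, per_series)
        reports[mode] = performance_metrics(
            detected, truths, tol=5,
            condition={**cond, "table": table, "mode": mode, "n_runs": n_runs,
                       "length": length, "position": position})
    return reports
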
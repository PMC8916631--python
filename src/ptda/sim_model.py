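"""Simulation model of psychotherapeutic change and the validation protocol.

This module is the package's synthetic-data generator.  It implements a
*synthetic* five-variable nonlinear difference-equation model of
psychotherapeutic change: five order parameters — emotions ``E``, problem
severity ``P``, motivation for change ``M``, insight ``I`` and therapeutic
success ``S`` — coupled through nonlinear functions whose shapes are
modulated by four slow control parameters (client traits): working alliance
``a``, cognitive competencies ``c``, trait motivation / hopefulness ``m`` and
resources / behavioural skills ``r``.  The map reproduces the qualitative
phenomenology required of such models: depending on the traits the dynamics
settle on a fixed point, a limit cycle or a chaotic attractor, and a shift of
the traits triggers a pattern transition of the fast variables.

The concrete coupling functions are this package's own construction
(synthetic stand-in); they were designed once for regime diversity and for a
networked (not master-slave) topology in which different variables can
express different patterns.  Internally the map is a unidirectional
coupled-logistic ring on unit-interval coordinates ``u_E, u_P, u_M, u_I,
u_S`` with the logistic kernel ``f(u; mu) = mu u (1 - u)``:

.. math::

    u_E' &= 0.9\\, f(u_E; \\mu_E) + 0.1\\, f(u_P; \\mu_P) \\\\
    u_P' &= 0.9\\, f(u_P; \\mu_P) + 0.1\\, f(u_M; \\mu_M) \\\\
    u_M' &= 0.9\\, f(u_M; \\mu_M) + 0.1\\, f(u_S; \\mu_S) \\\\
    u_I' &= (1-\\kappa)\\, u_I + \\kappa\\,(u_M + u_E)/2, \\qquad \\kappa = 0.1 + 0.3c \\\\
    u_S' &= 0.8\\, f(u_S; \\mu_S) + 0.2\\,(u_I + u_M)/2

and trait-dependent growth rates

.. math::

    \\mu_E = 2.6 + 1.4(0.6a + 0.4r), \\quad
    \\mu_P = 2.6 + 1.4(0.6c + 0.4m), \\quad
    \\mu_M = 2.6 + 1.4(0.6m + 0.4r), \\quad
    \\mu_S = 2.6 + 1.4(0.5a + 0.5m).

Each trait vector places the four cores somewhere on the period-doubling
route; chaos in any core spreads aperiodicity along the ring (complete
synchronisation is impossible for distinct growth rates) while the
variables keep distinct amplitudes and frequencies.  The observed variables
add a trait-dependent *level* on top of the internal regime,

.. math::

    x_V = (1 - \\beta)\\, u_V + \\beta\\, g_V(a, c, m, r), \\qquad \\beta = 0.35,

with per-variable level mixes ``g_E = 0.7a + 0.3c``,
``g_P = 0.6(1-m) + 0.4(1-r)``, ``g_M = 0.6m + 0.4a``,
``g_I = 0.5c + 0.5a``, ``g_S = 0.5r + 0.5m``; ``E, P, S`` are then mapped
to ``2x - 1``.  A trait shift therefore moves both the dynamic pattern (via
the growth rates) and, usually but not always, the observed level — so most
transitions are visible to mean-based change-point analysis while a
minority express themselves only in variance, frequency or complexity.
``E, P, S`` live in ``[-1, 1]`` and ``I, M`` in ``[0, 1]`` by construction.

The validation protocol mirrors a short daily-rating study: runs of ``T=400``
iterations from random initial conditions, an instantaneous (or linearly
ramped) shift of all four traits at iteration 250 with a minimum magnitude of
0.05 per trait, a 100-point transient discard, a complexity filter keeping
only runs whose pre-shift series are highly periodic (period >= 16) or
chaotic, and extraction of 100-point analysis windows that place the induced
transition at a chosen in-window position.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np

__all__ = [
    "VARIABLES", "STATE_RANGES", "ModelParams", "ModelState", "ShiftProtocol",
    "SimulationRun", "ValidationWindow", "DynamicsLabel", "step_model",
    "simulate_run", "classify_dynamics", "make_validation_set", "add_noise",
    "write_run_csv",
]

#: Column order used throughout the package (and in CSV exports).
VARIABLES: Tuple[str, ...] = ("E", "P", "M", "I", "S")

#: Admissible range per state variable.
STATE_RANGES = {"E": (-1.0, 1.0), "P": (-1.0, 1.0), "M": (0.0, 1.0),
                "I": (0.0, 1.0), "S": (-1.0, 1.0)}

TRANSIENT = 100          # discarded leading iterations (saturation effects)
DEFAULT_T = 400          # iterations per simulation run
DEFAULT_SHIFT_TIME = 250  # iteration at which the trait shift is induced
WINDOW_LEN = 100          # length of an extracted analysis window


@dataclass(frozen=True)
class ModelParams:
    """Trait (control) parameters, each in [0, 1]."""

    a: float  # working alliance / ability to bond
    c: float  # cognitive competencies
    m: float  # motivation to cope / hopefulness
    r: float  # resources / behavioural skills

    def __post_init__(self):
        for name, v in asdict(self).items():
            if not np.isfinite(v) or not 0.0 <= v <= 1.0:
                raise ValueError(f"parameter {name}={v} outside [0, 1]")

    def as_array(self) -> np.ndarray:
        return np.array([self.a, self.c, self.m, self.r])


@dataclass(frozen=True)
class ModelState:
    """State (order-parameter) vector of the map."""

    E: float
    P: float
    M: float
    I: float
    S: float

    def __post_init__(self):
        for name, v in asdict(self).items():
            lo, hi = STATE_RANGES[name]
            if not np.isfinite(v):
                raise ValueError(f"state variable {name} is not finite")
            if not lo - 1e-12 <= v <= hi + 1e-12:
                raise ValueError(f"state variable {name}={v} outside [{lo}, {hi}]")

    def as_array(self) -> np.ndarray:
        return np.array([self.E, self.P, self.M, self.I, self.S])


@dataclass(frozen=True)
class ShiftProtocol:
    """How and when the control parameters are shifted within a run.

    ``direction="increase"`` raises every trait by a random amount (a trait
    already within ``min_abs_delta`` of the upper bound is lowered instead,
    so the minimum-change rule always holds after clipping);
    ``direction="signed"`` draws an independent random sign per trait.
    """

    shift_time: int = DEFAULT_SHIFT_TIME
    ramp_length: int = 0          # 0 = instantaneous
    min_abs_delta: float = 0.05   # minimal |change| per parameter
    direction: str = "increase"   # "increase" | "signed"
    rng_seed: int = 0

    def __post_init__(self):
        if self.shift_time <= TRANSIENT:
            raise ValueError("shift_time must exceed the transient length")
        if self.ramp_length < 0:
            raise ValueError("ramp_length must be >= 0")
        if self.direction not in ("increase", "signed"):
            raise ValueError("direction must be 'increase' or 'signed'")


@dataclass
class SimulationRun:
    """One full simulation: trajectories plus ground-truth shift metadata."""

    trajectories: np.ndarray          # (T, 5) in VARIABLES order
    params_before: ModelParams
    params_after: ModelParams
    protocol: ShiftProtocol
    param_path: np.ndarray            # (T, 4) parameter value used at each step

    @property
    def adjusted(self) -> np.ndarray:
        """Trajectories with the transient discarded (time re-zeroed)."""
        return self.trajectories[TRANSIENT:]


@dataclass
class ValidationWindow:
    """A 100-point (or shorter) analysis window cut from a simulation run."""

    data: np.ndarray                  # (length, 5)
    true_tp: Optional[int]            # in-window 1-based position of the shift
    run_seed: int
    params_before: ModelParams
    params_after: ModelParams
    noise_pct: float = 0.0


@dataclass(frozen=True)
class DynamicsLabel:
    """Regime classification of a stationary tail: fixed / periodic(p) / chaotic."""

    kind: str                          # "fixed" | "periodic" | "chaotic"
    period: Optional[int] = None

    @property
    def is_complex(self) -> bool:
        """True for the regimes kept by the validation filter."""
        return self.kind == "chaotic" or (self.kind == "periodic"
                                          and (self.period or 0) >= 16)


#: Weight of the trait-dependent level component in the observed variables.
LEVEL_BETA = 0.35


def _core_step(u: np.ndarray, params: np.ndarray) -> np.ndarray:
    """One iteration of the internal coupled-logistic ring (unit coordinates).

    Broadcasts over trailing ensemble axes.
    """
    uE, uP, uM, uI, uS = u
    a, c, m, r = params
    muE = 2.6 + 1.4 * (0.6 * a + 0.4 * r)
    muP = 2.6 + 1.4 * (0.6 * c + 0.4 * m)
    muM = 2.6 + 1.4 * (0.6 * m + 0.4 * r)
    muS = 2.6 + 1.4 * (0.5 * a + 0.5 * m)
    fE = muE * uE * (1.0 - uE)
    fP = muP * uP * (1.0 - uP)
    fM = muM * uM * (1.0 - uM)
    fS = muS * uS * (1.0 - uS)
    kappa = 0.1 + 0.3 * c
    return np.stack([
        0.9 * fE + 0.1 * fP,
        0.9 * fP + 0.1 * fM,
        0.9 * fM + 0.1 * fS,
        (1.0 - kappa) * uI + kappa * 0.5 * (uM + uE),
        0.8 * fS + 0.2 * 0.5 * (uI + uM),
    ])


def _level_mix(params: np.ndarray) -> np.ndarray:
    """Trait-dependent level ``g_V`` per variable (unit scale)."""
    a, c, m, r = params
    return np.stack([
        0.7 * a + 0.3 * c,
        0.6 * (1.0 - m) + 0.4 * (1.0 - r),
        0.6 * m + 0.4 * a,
        0.5 * c + 0.5 * a,
        0.5 * r + 0.5 * m,
    ])


def _bipolar_mask(ndim: int) -> np.ndarray:
    """Which of (E,P,M,I,S) live on [-1, 1], shaped to broadcast on axis 0."""
    mask = np.array([True, True, False, False, True])
    return mask.reshape((5,) + (1,) * (ndim - 1))


def _observe(u: np.ndarray, params: np.ndarray) -> np.ndarray:
    """Map internal unit coordinates to the observed (E,P,M,I,S) scales."""
    g = _level_mix(params).reshape((5,) + (1,) * (u.ndim - 1))
    x = (1.0 - LEVEL_BETA) * u + LEVEL_BETA * g
    return np.where(_bipolar_mask(x.ndim), 2.0 * x - 1.0, x)


def _invert_observation(state: np.ndarray, params: np.ndarray) -> np.ndarray:
    """Recover internal unit coordinates from observed values (clipped)."""
    g = _level_mix(params).reshape((5,) + (1,) * (state.ndim - 1))
    x = np.where(_bipolar_mask(state.ndim), (state + 1.0) / 2.0, state)
    u = (x - LEVEL_BETA * g) / (1.0 - LEVEL_BETA)
    return np.clip(u, 0.0, 1.0)


def _step_arrays(state: np.ndarray, params: np.ndarray) -> np.ndarray:
    """One map iteration on observed-scale arrays."""
    u = _invert_observation(state, params)
    return _observe(_core_step(u, params), params)


def step_model(state: ModelState, params: ModelParams) -> ModelState:
    """Apply the map once.  Pure and deterministic; output is range-clipped."""
    nxt = _step_arrays(state.as_array(), params.as_array())
    lo = np.array([STATE_RANGES[v][0] for v in VARIABLES])
    hi = np.array([STATE_RANGES[v][1] for v in VARIABLES])
    nxt = np.clip(nxt, lo, hi)
    return ModelState(*[float(v) for v in nxt])


def _draw_shifted_params(before: np.ndarray, rng: np.random.Generator,
                         min_abs_delta: float, direction: str) -> np.ndarray:
    """Random shift per trait; redrawn until |after - before| >= delta."""
    after = np.empty_like(before)
    for i, p in enumerate(before):
        if direction == "increase":
            sign = 1.0 if p <= 1.0 - min_abs_delta else -1.0
        while True:
            if direction == "signed":
                sign = rng.choice((-1.0, 1.0))
            cand = float(np.clip(p + sign * rng.uniform(0.0, 1.0), 0.0, 1.0))
            if abs(cand - p) >= min_abs_delta:
                after[i] = cand
                break
    return after


def _param_at(t: int, protocol: ShiftProtocol, before: np.ndarray,
              after: np.ndarray) -> np.ndarray:
    """Parameter vector in force when generating sample ``t`` (1-based)."""
    s, ramp = protocol.shift_time, protocol.ramp_length
    if t <= s:
        return before
    if ramp == 0 or t > s + ramp:
        return after
    return before + (t - s) / ramp * (after - before)


def simulate_run(initial_seed: int, protocol: ShiftProtocol,
                 T: int = DEFAULT_T) -> SimulationRun:
    """Simulate one run with a trait shift at ``protocol.shift_time``.

    Initial (internal) state values and traits are drawn uniformly from
    [0, 1]; at the shift time every trait changes by a random amount of at
    least ``min_abs_delta`` (after clipping to [0, 1]), by default upward.
    With ``ramp_length > 0`` the traits drift linearly to their new values
    over that many iterations.
    """
    rng = np.random.default_rng(initial_seed)
    u = rng.uniform(0.0, 1.0, 5)          # internal unit coordinates
    before = rng.uniform(0.0, 1.0, 4)
    after = _draw_shifted_params(before, rng, protocol.min_abs_delta,
                                 protocol.direction)

    traj = np.empty((T, 5))
    path = np.empty((T, 4))
    for t in range(1, T + 1):
        p = _param_at(t, protocol, before, after)
        u = _core_step(u, p)
        traj[t - 1] = _observe(u, p)
        path[t - 1] = p
    return SimulationRun(
        trajectories=traj,
        params_before=ModelParams(*before),
        params_after=ModelParams(*after),
        protocol=protocol,
        param_path=path,
    )


def classify_dynamics(series: np.ndarray, tol: float = 1e-6,
                      max_period: int = 32, tail: int = 64) -> DynamicsLabel:
    """Classify the stationary tail of a deterministic series.

    ``periodic(p)`` iff ``x[t+p] == x[t]`` within ``tol`` for all tail points
    and ``p`` is minimal; ``fixed`` is the ``p = 1`` case; anything that is
    not periodic for any ``p <= max_period`` is labelled chaotic.
    """
    x = np.asarray(series, dtype=float).ravel()
    if x.size < tail:
        raise ValueError(f"series too short to classify (need >= {tail} points)")
    seg = x[-tail:]
    for p in range(1, max_period + 1):
        if np.all(np.abs(seg[p:] - seg[:-p]) <= tol):
            if p == 1:
                return DynamicsLabel("fixed")
            return DynamicsLabel("periodic", p)
    return DynamicsLabel("chaotic")


def run_is_complex(run: SimulationRun) -> bool:
    """Validation filter: all five pre-shift series periodic(>=16) or chaotic."""
    pre = run.adjusted[: run.protocol.shift_time - TRANSIENT - 1]
    return all(classify_dynamics(pre[:, j]).is_complex for j in range(pre.shape[1]))


def add_noise(series: np.ndarray, noise_pct: float,
              seed: Union[int, np.random.Generator, None] = None) -> np.ndarray:
    """Add Gaussian noise with variance ``noise_pct/100`` of the sample variance.

    Works column-wise on 2-D input.  ``noise_pct = 0`` returns the input
    unchanged.
    """
    if noise_pct < 0:
        raise ValueError("noise_pct must be >= 0")
    x = np.asarray(series, dtype=float)
    if noise_pct == 0:
        return x.copy()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    var = np.var(x, axis=0, ddof=1)
    sd = np.sqrt(noise_pct / 100.0 * var)
    return x + rng.standard_normal(x.shape) * sd


def make_validation_set(n_runs: int, tp_position: Optional[int] = 50,
                        noise_pct: float = 0.0, ramp_length: int = 0,
                        seed: int = 0, length: int = WINDOW_LEN,
                        ) -> List[ValidationWindow]:
    """Generate ``n_runs`` complexity-filtered runs and cut analysis windows.

    Each accepted run contributes one :class:`ValidationWindow` holding all
    five variables; single-series analyses iterate over its columns, so
    ``n_runs`` runs yield ``5 * n_runs`` univariate series.  The window is
    placed so that the induced shift sits at in-window position
    ``tp_position`` (e.g. 50 -> the post-transient interval [100, 200]); with
    ``tp_position=None`` the window lies entirely inside the pre-shift
    stationary regime and carries no transition.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    adj_shift = DEFAULT_SHIFT_TIME - TRANSIENT      # shift position on adjusted axis
    if tp_position is None:
        offset = 0
    else:
        offset = adj_shift - tp_position
        if not 0 < tp_position <= length:
            raise ValueError("tp_position must lie inside the window")
        if offset < 0:
            raise ValueError("window would start before the transient ends")
    if offset + length > DEFAULT_T - TRANSIENT:
        raise ValueError("window extends past the end of the run")

    ss = np.random.SeedSequence(seed)
    windows: List[ValidationWindow] = []
    while len(windows) < n_runs:
        (child,) = ss.spawn(1)
        run_seed = int(child.generate_state(1)[0] % (2 ** 31))
        protocol = ShiftProtocol(ramp_length=ramp_length, rng_seed=run_seed)
        run = simulate_run(run_seed, protocol)
        if not run_is_complex(run):
            continue
        data = run.adjusted[offset: offset + length].copy()
        if noise_pct > 0:
            noise_rng = np.random.default_rng(child.generate_state(2)[1] % (2 ** 31))
            data = add_noise(data, noise_pct, noise_rng)
        windows.append(ValidationWindow(
            data=data,
            true_tp=tp_position,
            run_seed=run_seed,
            params_before=run.params_before,
            params_after=run.params_after,
            noise_pct=noise_pct,
        ))
    return windows


def write_run_csv(run: SimulationRun, path: Union[str, Path],
                  true_tp: Optional[int] = None) -> None:
    """Export a run as CSV (columns E,P,M,I,S) with a JSON metadata sidecar."""
    path = Path(path)
    header = ",".join(VARIABLES)
    np.savetxt(path, run.trajectories, delimiter=",", header=header,
               comments="", fmt="%.17g")
    meta = {
        "seed": run.protocol.rng_seed,
        "shift_time": run.protocol.shift_time,
        "ramp_length": run.protocol.ramp_length,
        "true_tp": true_tp,
        "params_before": asdict(run.params_before),
        "params_after": asdict(run.params_after),
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))
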
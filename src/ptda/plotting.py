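"""Overview figure: raw series, secondary representations and the result."""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Tuple, Union

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt
import numpy as np

from .config import PtdaConfig
from .core import TransitionResult
from .secondary import distance_matrix, dynamic_complexity, embed, stockwell_tfd

__all__ = ["plot_overview"]

_MARKERS = {"raw_mean": "tab:blue", "raw_variance": "tab:green",
            "raw_linear": "tab:red", "dc_mean": "tab:purple",
            "rp_hist": "tab:orange", "tfd_hist": "tab:brown"}


def plot_overview(series: np.ndarray, result: TransitionResult,
                  path: Union[str, Path], config: Optional[PtdaConfig] = None,
                  scale_range: Optional[Tuple[float, float]] = None) -> None:
    """Stacked panels: series with change points, DC, RP, TFD, probability band.

    Rendering is best effort: panels whose representation cannot be computed
    (e.g. a constant series) are simply left empty.
    """
    cfg = config or PtdaConfig()
    x = np.asarray(series, dtype=float).ravel()
    t = np.arange(1, x.size + 1)
    fig, axes = plt.subplots(
        5, 1, figsize=(8, 10), sharex=True,
        gridspec_kw={"height_ratios": [2, 1.2, 2, 2, 0.4]})

    ax = axes[0]
    ax.plot(t, x, lw=0.9, color="k")
    for cp in result.cps:
        ax.plot(cp.position, x[min(cp.position, x.size) - 1], "o",
                color=_MARKERS.get(cp.method, "grey"), ms=6, mfc="none",
                label=cp.method)
    if result.tp is not None:
        for a in axes[:4]:
            a.axvline(result.tp, color="k", lw=1.2)
    ax.set_ylabel("series")

    try:
        sr = scale_range or cfg.scale_range or (float(x.min()), float(x.max()))
        dc = dynamic_complexity(x, cfg.w, sr)
        axes[1].plot(t[cfg.w - 1:], dc.values, lw=0.9, color="tab:purple")
    except ValueError:
        pass
    axes[1].set_ylabel("DC")

    try:
        rp = distance_matrix(embed(x, cfg.m, cfg.tau))
        axes[2].imshow(rp.distances, origin="lower", aspect="auto",
                       cmap="jet", extent=(1, rp.distances.shape[1],
                                           1, rp.distances.shape[0]))
    except ValueError:
        pass
    axes[2].set_ylabel("RP")

    try:
        tfd = stockwell_tfd(x)
        axes[3].imshow(tfd.amplitudes, origin="lower", aspect="auto",
                       cmap="viridis", extent=(1, x.size, 1,
                                               tfd.amplitudes.shape[0]))
    except ValueError:
        pass
    axes[3].set_ylabel("TFD")

    band = result.band if result.band.size else np.zeros(x.size)
    axes[4].imshow(band[None, :], aspect="auto", cmap="viridis",
                   extent=(1, x.size, 0, 1))
    axes[4].set_yticks([])
    axes[4].set_ylabel("band")
    axes[4].set_xlabel("time")

    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
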
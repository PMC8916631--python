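"""Runtime configuration for the transition detector."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Tuple, Union

__all__ = ["PtdaConfig", "load_config"]


@dataclass(frozen=True)
class PtdaConfig:
    """Tunable parameters of the detection pipeline.

    Defaults follow daily-rating practice: a one-week complexity window,
    a small embedding (m=3, tau=1) that preserves most state vectors of a
    short series, histogram bins of one fifth of the series length, a 10%
    edge-exclusion zone, and 100 uniform-resampling replicates for the
    dispersion significance test.
    """

    w: int = 7                     # DC sliding-window width (one week)
    m: int = 3                     # embedding dimension
    tau: int = 1                   # embedding delay
    bin_frac: float = 0.2          # histogram bin width as fraction of length
    edge_frac: float = 0.1         # excluded fraction at either end
    n_rep: int = 100               # uniform-null replicates
    min_cps: int = 3               # minimum change points for a verdict
    alpha: float = 0.05            # GESD outlier significance level
    max_outlier_frac: float = 0.1  # cap on the fraction of removable outliers
    band_var: float = 5.0          # variance of each probability-band kernel
    ci_method: str = "percentile"  # "percentile" | "normal" lower bound
    seed: Optional[int] = None     # seed for the significance-test resampling
    scale_range: Optional[Tuple[float, float]] = None  # DC rating-scale bounds

    def with_(self, **kw) -> "PtdaConfig":
        return replace(self, **kw)


def load_config(path: Union[str, Path]) -> PtdaConfig:
    """Read a config from a TOML (or simple ``key = value``) file."""
    import tomllib

    raw = Path(path).read_bytes()
    data = tomllib.loads(raw.decode())
    if "scale_range" in data and data["scale_range"] is not None:
        data["scale_range"] = tuple(data["scale_range"])
    return PtdaConfig(**data)
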
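"""Reading rating-series files and serialising detector results."""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .core import ChangePoint, TransitionResult

__all__ = ["Dataset", "read_timeseries_csv", "write_result_json",
           "result_to_dict", "result_from_dict"]

logger = logging.getLogger(__name__)


@dataclass
class Dataset:
    """A rectangular time x variables recording with known rating ranges."""

    values: np.ndarray
    names: List[str]
    scale_ranges: List[Tuple[float, float]]
    source: Optional[str] = None

    @property
    def n_vars(self) -> int:
        return self.values.shape[1]

    def columns(self) -> List[np.ndarray]:
        return [self.values[:, j] for j in range(self.n_vars)]


def _looks_like_header(fields: Sequence[str]) -> bool:
    for f in fields:
        try:
            float(f)
        except ValueError:
            return True
    return False


def read_timeseries_csv(path: Union[str, Path], interpolate: bool = False,
                        scale_ranges: Optional[Sequence[Tuple[float, float]]] = None,
                        ) -> Dataset:
    """Load a CSV/TSV/semicolon file, one column per variable, rows = time.

    The delimiter is auto-detected among comma, semicolon and tab, and a
    header row is detected by non-numeric first-line cells.  Missing cells
    are rejected unless ``interpolate=True`` (linear interpolation between
    neighbours).  Without explicit ``scale_ranges`` the observed min/max per
    column is used, with a warning — Dynamic Complexity needs the theoretical
    rating bounds to be meaningful.
    """
    path = Path(path)
    first = path.read_text().lstrip().splitlines()[0]
    sep = max(",;\t", key=first.count)
    header = 0 if _looks_like_header(first.split(sep)) else None
    try:
        df = pd.read_csv(path, sep=sep, header=header)
    except pd.errors.ParserError as e:
        raise ValueError(f"malformed delimited file {path}: {e}") from e
    try:
        df = df.astype(float)
    except (ValueError, TypeError) as e:
        raise ValueError(f"non-numeric cells in {path}: {e}") from e
    if df.isna().any().any():
        if not interpolate:
            raise ValueError(f"missing cells in {path}; pass interpolate=True "
                             "to fill them linearly")
        df = df.interpolate(method="linear", limit_direction="both")
    values = df.to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError(f"non-finite values remain in {path}")
    names = [str(c) for c in df.columns] if header == 0 else \
        [f"var{j + 1}" for j in range(values.shape[1])]
    if scale_ranges is None:
        scale_ranges = [(float(values[:, j].min()), float(values[:, j].max()))
                        for j in range(values.shape[1])]
        warnings.warn("no scale ranges supplied; using observed min/max per "
                      "column for the Dynamic Complexity measure", stacklevel=2)
    return Dataset(values=values, names=names,
                   scale_ranges=[tuple(r) for r in scale_ranges],
                   source=str(path))


def _cp_to_dict(cp: ChangePoint) -> Dict:
    return {"position": cp.position, "method": cp.method,
            "series_id": cp.series_id}


def result_to_dict(result: TransitionResult) -> Dict:
    return {
        "tp": result.tp,
        "significant": result.significant,
        "cps": [_cp_to_dict(cp) for cp in result.cps],
        "surviving": [_cp_to_dict(cp) for cp in result.surviving],
        "real_iqr": result.real_iqr,
        "random_iqr_mean": result.random_iqr_mean,
        "random_iqr_lower": result.random_iqr_lower,
        "band": [float(v) for v in result.band],
        "length": result.length,
    }


def result_from_dict(data: Dict) -> TransitionResult:
    return TransitionResult(
        tp=data["tp"],
        significant=data["significant"],
        cps=[ChangePoint(**cp) for cp in data["cps"]],
        surviving=[ChangePoint(**cp) for cp in data["surviving"]],
        real_iqr=data["real_iqr"],
        random_iqr_mean=data["random_iqr_mean"],
        random_iqr_lower=data["random_iqr_lower"],
        band=np.array(data["band"], dtype=float),
        length=data["length"],
    )


def write_result_json(result: TransitionResult, path: Union[str, Path]) -> None:
    """Serialise a result losslessly; ``tp=None`` becomes an explicit null."""
    Path(path).write_text(json.dumps(result_to_dict(result), indent=2))
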
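"""Tabular output: tab-separated tables plus a metadata sidecar.

Every writer emits plain TSV (readable by pandas/R) and, alongside the
main table, a ``<name>.meta.json`` sidecar recording the full
configuration, the master seed and the package version, so any table
can be regenerated exactly.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from . import __version__
from .params import ModelParams, SimSpec, StimulusSpec
from .spectra import PowerSpectrum

__all__ = [
    "write_table",
    "write_metadata",
    "lfp_table",
    "spectrum_table",
    "peaks_table",
]


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)
    return path


def write_metadata(
    path: str | Path,
    params: ModelParams | None = None,
    stim: StimulusSpec | None = None,
    sim: SimSpec | None = None,
    extra: Mapping[str, Any] | None = None,
) -> Path:
    """Write the run-metadata sidecar next to a table."""
    path = Path(path)
    meta: dict[str, Any] = {"version": __version__}
    for key, obj in (("model", params), ("stimulus", stim), ("simulation", sim)):
        if obj is not None:
            meta[key] = dataclasses.asdict(obj)
    if extra:
        meta.update(extra)
    side = path.with_suffix(path.suffix + ".meta.json") if path.suffix != ".json" \
        else path
    side.parent.mkdir(parents=True, exist_ok=True)
    side.write_text(json.dumps(meta, indent=2, default=_jsonable) + "\n")
    return side


def _jsonable(obj: Any):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def lfp_table(lfp: np.ndarray, times: np.ndarray) -> pd.DataFrame:
    """Long-format LFP table: repeat, time_s, value."""
    lfp = np.atleast_2d(lfp)
    n_rep, n_t = lfp.shape
    return pd.DataFrame(
        {
            "repeat": np.repeat(np.arange(n_rep), n_t),
            "time_s": np.tile(times[:n_t], n_rep),
            "value": lfp.ravel(),
        }
    )


def read_lfp_table(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Inverse of :func:`lfp_table`: returns (lfp[reps, t], times)."""
    df = pd.read_csv(path, sep="\t")
    reps = np.sort(df["repeat"].unique())
    times = np.sort(df[df["repeat"] == reps[0]]["time_s"].to_numpy())
    lfp = np.stack(
        [
            df[df["repeat"] == r].sort_values("time_s")["value"].to_numpy()
            for r in reps
        ]
    )
    return lfp, times


def spectrum_table(spec: PowerSpectrum) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "condition": spec.condition or "default",
            "freq_hz": spec.freqs,
            "power": spec.power,
        }
    )


def peaks_table(peaks: Mapping[str, Any], condition: str = "") -> pd.DataFrame:
    rows = []
    for name, pk in peaks.items():
        rows.append(
            {
                "condition": condition or "default",
                "band": name,
                "f_lo": pk.band.f_lo,
                "f_hi": pk.band.f_hi,
                "present": pk.present,
                "peak_freq_hz": pk.peak_freq,
                "peak_power": pk.peak_power,
            }
        )
    return pd.DataFrame(rows)
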
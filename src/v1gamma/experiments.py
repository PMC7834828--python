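"""Experiment orchestration: single conditions, parameter sweeps,
size tuning and cross-band summaries.

Every experiment composes the same pipeline: simulate -> average
periodograms of the central-unit LFP -> detect the slow and fast gamma
peaks.  Sweeps vary coupling weights on a grid and tabulate presence,
peak frequency and peak power per band; size tuning varies the
stimulus radius and adds the suppression index (SI) and frequency
change (FC) statistics per band.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .network import extract_lfp, simulate, Trajectory
from .params import ModelParams, ParameterError, SimSpec, StimulusSpec
from .spectra import (
    DEFAULT_BANDS,
    GammaBand,
    GammaPeak,
    GammaUndefined,
    PowerSpectrum,
    detect_gamma_peak,
    frequency_change,
    power_spectrum,
    suppression_index,
)

__all__ = [
    "ConditionResult",
    "SweepSpec",
    "SizeTuningResult",
    "run_condition",
    "sweep_hc",
    "sweep_fb",
    "size_tuning",
    "scatter_summary",
    "sustained_onset",
]


@dataclass
class ConditionResult:
    """Spectrum and per-band peaks of one simulated condition."""

    spectrum: PowerSpectrum
    peaks: dict[str, GammaPeak]
    trajectory: Trajectory

    @property
    def gamma_count(self) -> int:
        return sum(p.present for p in self.peaks.values())

    @property
    def unstable(self) -> bool:
        return self.trajectory.any_unstable


@dataclass(frozen=True)
class SweepSpec:
    """A grid sweep over ModelParams fields.

    ``grids`` maps parameter names (ModelParams fields) to value
    arrays; the sweep is their Cartesian product evaluated on top of
    ``base``.
    """

    grids: Mapping[str, Sequence[float]]
    base: ModelParams
    stim: StimulusSpec
    sim: SimSpec
    bands: tuple[GammaBand, ...] = DEFAULT_BANDS

    def __post_init__(self) -> None:
        if not self.grids:
            raise ParameterError("sweep needs at least one parameter grid")
        model_fields = set(ModelParams.__dataclass_fields__)
        for name, grid in self.grids.items():
            if name not in model_fields:
                raise ParameterError(f"{name!r} is not a ModelParams field")
            if len(grid) == 0:
                raise ParameterError(f"grid for {name!r} is empty")

    def points(self):
        names = list(self.grids)
        mesh = np.meshgrid(*[np.asarray(self.grids[n]) for n in names], indexing="ij")
        for values in zip(*[m.ravel() for m in mesh]):
            yield dict(zip(names, (float(v) for v in values)))


def run_condition(
    params: ModelParams,
    stim: StimulusSpec,
    sim: SimSpec,
    bands: Sequence[GammaBand] = DEFAULT_BANDS,
    condition: str = "",
) -> ConditionResult:
    """Simulate one condition and detect gamma peaks per band."""
    traj = simulate(params, stim, sim)
    spec = power_spectrum(extract_lfp(traj), sim, condition=condition)
    peaks = {band.name or f"{band.f_lo}-{band.f_hi}": detect_gamma_peak(spec, band)
             for band in bands}
    return ConditionResult(spectrum=spec, peaks=peaks, trajectory=traj)


def _peak_columns(peaks: Mapping[str, GammaPeak]) -> dict[str, float | bool]:
    row: dict[str, float | bool] = {}
    for name, pk in peaks.items():
        row[f"{name}_present"] = bool(pk.present)
        row[f"{name}_freq"] = pk.peak_freq
        row[f"{name}_power"] = pk.peak_power
    return row


def _run_sweep(spec: SweepSpec) -> pd.DataFrame:
    rows = []
    for point in spec.points():
        params = spec.base.replace(**point)
        res = run_condition(params, spec.stim, spec.sim, spec.bands)
        row = dict(point)
        row["gamma_count"] = res.gamma_count
        row["unstable"] = res.unstable
        row.update(_peak_columns(res.peaks))
        rows.append(row)
    return pd.DataFrame(rows)


def sweep_hc(spec: SweepSpec) -> pd.DataFrame:
    """Horizontal-connection sweep (feedback must be off in the base).

    One row per grid point with gamma count and per-band peak
    statistics — the phase-diagram table.
    """
    if spec.base.w_eg != 0.0 or spec.base.w_ig != 0.0:
        raise ParameterError("sweep_hc expects feedback couplings zero in base")
    return _run_sweep(spec)


def sweep_fb(spec: SweepSpec) -> pd.DataFrame:
    """Feedback sweep over (w_eg, w_ig) at a fixed HC setting."""
    return _run_sweep(spec)


@dataclass
class SizeTuningResult:
    """Per-band tuning curves over stimulus radius, with SI and FC."""

    radii: np.ndarray
    table: pd.DataFrame
    si: dict[str, Optional[float]]
    fc: dict[str, Optional[float]]
    band_names: tuple[str, ...] = field(default=())


def size_tuning(
    params: ModelParams,
    radii: Sequence[float],
    sim: SimSpec,
    bands: Sequence[GammaBand] = DEFAULT_BANDS,
    stim: StimulusSpec | None = None,
) -> SizeTuningResult:
    """Stimulus-size tuning of the gamma peaks.

    Runs one condition per radius (holding every other stimulus field
    of ``stim`` fixed) and derives per-band SI and FC.  Radii must be
    ascending.  A band whose SI or FC is undefined (peak present at
    fewer than two sizes, or absent at the largest size) gets ``None``.
    """
    radii = np.asarray(list(radii), dtype=float)
    if radii.size < 1 or np.any(np.diff(radii) <= 0):
        raise ParameterError("radii must be non-empty and strictly increasing")
    base_stim = stim if stim is not None else StimulusSpec()
    names = [b.name or f"{b.f_lo}-{b.f_hi}" for b in bands]
    rows = []
    for radius in radii:
        res = run_condition(
            params, replace(base_stim, radius=float(radius)), sim, bands
        )
        row: dict[str, float | bool] = {"radius": float(radius)}
        row["gamma_count"] = res.gamma_count
        row["unstable"] = res.unstable
        row.update(_peak_columns(res.peaks))
        rows.append(row)
    table = pd.DataFrame(rows)
    si: dict[str, Optional[float]] = {}
    fc: dict[str, Optional[float]] = {}
    for name in names:
        # restrict to the sustained run of detections (see
        # sustained_onset): isolated noise-level detections at odd radii
        # would otherwise anchor the frequency-change reference size
        present = [bool(row[f"{name}_present"]) for row in rows]
        run = _longest_run(present)
        in_run = [run is not None and run[0] <= i < run[1]
                  for i in range(len(rows))]
        powers = [
            row[f"{name}_power"] if keep else None
            for keep, row in zip(in_run, rows)
        ]
        freqs = [
            row[f"{name}_freq"] if keep else None
            for keep, row in zip(in_run, rows)
        ]
        try:
            si[name] = suppression_index(powers)
        except GammaUndefined:
            si[name] = None
        try:
            fc[name] = frequency_change(freqs)
        except GammaUndefined:
            fc[name] = None
    return SizeTuningResult(
        radii=radii, table=table, si=si, fc=fc, band_names=tuple(names)
    )


def scatter_summary(
    table: pd.DataFrame,
    x_column: str,
    y_column: str,
) -> tuple[pd.DataFrame, int]:
    """Paired cross-band statistic table and its rank-correlation sign.

    Collects rows of ``table`` where both columns are defined (finite)
    and returns them with the sign (+1, -1 or 0) of the Spearman rank
    correlation between them.  Needs at least three valid pairs.
    """
    pairs = table[[x_column, y_column]].apply(pd.to_numeric, errors="coerce").dropna()
    pairs = pairs[np.isfinite(pairs).all(axis=1)]
    if len(pairs) < 3:
        raise GammaUndefined(
            "rank correlation needs at least 3 grid points with both "
            "statistics defined"
        )
    rho = spearmanr(pairs[x_column], pairs[y_column]).statistic
    if np.isnan(rho):
        sign = 0
    else:
        sign = int(np.sign(rho))
    return pairs.reset_index(drop=True), sign


def _longest_run(present: Sequence[bool]) -> Optional[tuple[int, int]]:
    """(start, stop) of the longest consecutive run of ``True``;
    earliest run on ties, ``None`` when all ``False``."""
    best = None
    best_len = 0
    start = None
    for i, flag in enumerate(list(present) + [False]):
        if flag:
            if start is None:
                start = i
        elif start is not None:
            if i - start > best_len:
                best, best_len = (start, i), i - start
            start = None
    return best


def sustained_onset(present: Sequence[bool]) -> Optional[int]:
    """Index where the longest consecutive run of ``True`` begins.

    Detection on noisy averaged spectra occasionally flags isolated
    grid points; the onset of a rhythm along a swept axis (stimulus
    radius, coupling strength) is therefore read as the start of the
    longest unbroken stretch of detections, which is robust to such
    blips.  Ties resolve to the earliest run; all-``False`` gives
    ``None``.
    """
    run = _longest_run(present)
    return None if run is None else run[0]
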
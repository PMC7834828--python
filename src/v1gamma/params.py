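"""Parameter containers for the V1 gamma network.

Three frozen dataclasses describe a run: :class:`ModelParams` (coupling
weights, time constants, lattice geometry), :class:`StimulusSpec` (the
LGN drive induced by a grating of a given size) and :class:`SimSpec`
(integration protocol).  Defaults reproduce the reference parameter set
of the model: a 15 x 15 sheet of excitatory-inhibitory (E-I) units with
local recurrent couplings, Gaussian-decaying horizontal connections and
a single global feedback node.

Sign conventions: inhibitory couplings carry their sign in the weight
(``w_ei_rc`` and ``w_ii_rc`` are negative).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping

import yaml

__all__ = [
    "ModelParams",
    "StimulusSpec",
    "SimSpec",
    "ParameterError",
    "load_config",
    "dump_config",
]


class ParameterError(ValueError):
    """Raised when a parameter set violates its invariants."""


@dataclass(frozen=True)
class ModelParams:
    """All couplings and geometry of the network.

    Attributes
    ----------
    tau_e, tau_i, tau_g:
        Time constants (seconds) of the local excitatory, local
        inhibitory and global feedback populations.
    w_ee_rc, w_ei_rc, w_ie_rc, w_ii_rc:
        Local recurrent couplings within an E-I unit (dimensionless;
        the I-source weights are negative).
    w_el, w_il:
        Feed-forward LGN couplings onto E and I.
    w_ee_hc, w_ie_hc:
        Amplitudes of the long-range horizontal connections from E
        onto E and onto I of other units.
    w_eg, w_ig:
        Feedback couplings from the global node G onto E and I.
    w_ge:
        Feed-forward coupling from each V1 E component onto G.
    sigma_hc:
        Width (lattice units) of the Gaussian horizontal-connection
        kernel.
    grid_rows, grid_cols:
        Lattice dimensions; the number of E-I units is their product.
    overflow:
        Instability guard: a repeat whose state magnitude exceeds this
        bound is flagged unstable.
    """

    tau_e: float = 0.006
    tau_i: float = 0.012
    tau_g: float = 0.019
    w_ee_rc: float = 1.5
    w_ei_rc: float = -3.25
    w_ie_rc: float = 3.5
    w_ii_rc: float = -2.5
    w_el: float = 1.75
    w_il: float = 1.25
    w_ee_hc: float = 0.0
    w_ie_hc: float = 0.0
    w_eg: float = 0.0
    w_ig: float = 0.0
    w_ge: float = 0.1
    sigma_hc: float = 4.0
    grid_rows: int = 15
    grid_cols: int = 15
    overflow: float = 1e6

    def __post_init__(self) -> None:
        for name in ("tau_e", "tau_i", "tau_g"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")
        if self.w_ei_rc > 0 or self.w_ii_rc > 0:
            raise ParameterError(
                "inhibitory couplings w_ei_rc and w_ii_rc must be <= 0 "
                "(the sign is carried in the weight)"
            )
        if self.sigma_hc <= 0:
            raise ParameterError("sigma_hc must be positive")
        if self.grid_rows < 1 or self.grid_cols < 1:
            raise ParameterError("grid dimensions must be >= 1")
        if self.overflow <= 0:
            raise ParameterError("overflow bound must be positive")

    @property
    def n_units(self) -> int:
        return self.grid_rows * self.grid_cols

    def replace(self, **kwargs: Any) -> "ModelParams":
        """Return a copy with the given fields replaced."""
        return dataclasses.replace(self, **kwargs)


@dataclass(frozen=True)
class StimulusSpec:
    """LGN drive induced by a grating of a given size.

    Units whose lattice distance from the grid centre is at most
    ``radius`` receive Gaussian samples with mean ``rate_in`` (Hz);
    units outside receive mean ``rate_out``.  ``noise_sd`` is the
    per-step standard deviation of the drive.  ``radius = 0`` drives
    only the central unit; a blank (zero-contrast) stimulus is
    expressed by ``rate_in == rate_out == 0`` (see :meth:`blank`).
    """

    radius: float = 30.0
    rate_in: float = 40.0
    rate_out: float = 0.0
    noise_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.radius < 0:
            raise ParameterError("radius must be >= 0")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")

    @classmethod
    def full_field(cls, rate_in: float = 40.0, noise_sd: float = 1.0) -> "StimulusSpec":
        """A stimulus large enough to drive every unit of any grid."""
        return cls(radius=1e9, rate_in=rate_in, noise_sd=noise_sd)

    @classmethod
    def blank(cls, noise_sd: float = 1.0) -> "StimulusSpec":
        """Zero-contrast stimulus: every unit at the background rate."""
        return cls(radius=0.0, rate_in=0.0, rate_out=0.0, noise_sd=noise_sd)

    def replace(self, **kwargs: Any) -> "StimulusSpec":
        return dataclasses.replace(self, **kwargs)


@dataclass(frozen=True)
class SimSpec:
    """Integration protocol: forward Euler at ``dt`` for ``duration``
    seconds, ``repeats`` independent repeats, analysis restricted to
    the window after ``discard`` seconds."""

    dt: float = 0.001
    duration: float = 1.3
    discard: float = 0.3
    repeats: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ParameterError("dt must be positive")
        if not 0 <= self.discard < self.duration:
            raise ParameterError("discard must satisfy 0 <= discard < duration")
        if self.repeats < 1:
            raise ParameterError("repeats must be >= 1")

    @property
    def n_steps(self) -> int:
        return int(round(self.duration / self.dt))

    @property
    def n_discard(self) -> int:
        return int(round(self.discard / self.dt))

    @property
    def analysis_duration(self) -> float:
        return self.duration - self.discard

    def replace(self, **kwargs: Any) -> "SimSpec":
        return dataclasses.replace(self, **kwargs)


_SECTIONS = {
    "model": ModelParams,
    "stimulus": StimulusSpec,
    "simulation": SimSpec,
}


def load_config(path: str | Path | None = None, data: Mapping[str, Any] | None = None):
    """Load ``(ModelParams, StimulusSpec, SimSpec)`` from a YAML file.

    The file has up to three sections, ``model``, ``stimulus`` and
    ``simulation``, whose keys map 1:1 onto the dataclass fields.
    Missing sections or keys fall back to the built-in defaults.
    """
    if (path is None) == (data is None):
        raise ParameterError("pass exactly one of path or data")
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    if not isinstance(data, Mapping):
        raise ParameterError("config root must be a mapping")
    unknown = set(data) - set(_SECTIONS)
    if unknown:
        raise ParameterError(f"unknown config sections: {sorted(unknown)}")
    out = []
    for section, cls in _SECTIONS.items():
        kwargs = dict(data.get(section) or {})
        fields = {f.name for f in dataclasses.fields(cls)}
        bad = set(kwargs) - fields
        if bad:
            raise ParameterError(f"unknown keys in [{section}]: {sorted(bad)}")
        try:
            out.append(cls(**kwargs))
        except TypeError as exc:  # pragma: no cover - defensive
            raise ParameterError(str(exc)) from exc
    return tuple(out)


def dump_config(params: ModelParams, stim: StimulusSpec, sim: SimSpec) -> str:
    """Serialize a run configuration back to YAML."""
    doc = {
        "model": dataclasses.asdict(params),
        "stimulus": dataclasses.asdict(stim),
        "simulation": dataclasses.asdict(sim),
    }
    return yaml.safe_dump(doc, sort_keys=False)
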
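"""Analytic linear reductions of the network.

Two collective-coordinate compressions of the linearized system
(rectification replaced by the identity, noise dropped) serve as
oracles for what the full simulation can and cannot do:

* feedback-only network -> 3-D system in (E, I, G), where E and I are
  the summed excitatory and inhibitory activities.  A real 3x3 matrix
  has at most one conjugate eigenvalue pair, so feedback alone can
  never support two distinct oscillation frequencies.
* horizontal-only network -> 4-D system in (E_RC, I_RC, E_HC, I_HC),
  where the HC coordinates are the Gaussian-kernel-weighted activities
  feeding a unit.  The closure of the kernel-kernel convolution gives
  the cross-coupling factor 4 sigma^2 (W_EE^HC)^2 pi^2 (the squared
  continuous kernel mass (2 pi sigma W)^2), with alpha =
  W_EE^HC / W_IE^HC relating E-targeting to I-targeting amplitudes.
  Two conjugate pairs here mean two distinct oscillations.

The matrices are assembled in mutually consistent coordinates: the
collective-coordinate couplings appear once, not once per unit.  (A
naive compression is easy to over-count by the unit number N — the
coupling *products*, which the eigenvalues depend on, must equal
n W_EG W_GE / (tau_E tau_G) for the E-G loop and
4 sigma^2 W^2 pi^2 / (tau_E^2) etc. for the RC-HC loop.)

An eigenvalue pair lambda = a +/- b i oscillates at frequency
|b| / (2 pi) Hz.  The reduction assumes the kernel width sigma is
large; its quantitative accuracy degrades for narrow kernels and for
operating points where rectification is active.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import ModelParams, ParameterError

__all__ = [
    "ReducedSystem",
    "reduce_fb_matrix",
    "reduce_hc_matrix",
    "predicted_frequencies",
]

_PAIR_TOL = 1e-9  # |imag| above this counts as complex
_DEDUP_REL = 1e-6  # relative tolerance for merging duplicate pair frequencies


@dataclass
class ReducedSystem:
    """A reduced linear system and its oscillation classification."""

    kind: str  # "FB" or "HC"
    matrix: np.ndarray
    n_units: int
    alpha: float
    eigenvalues: np.ndarray = field(init=False)
    oscillation_count: int = field(init=False)
    predicted_freqs: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.eigenvalues = np.linalg.eigvals(self.matrix)
        freqs = _pair_frequencies(self.eigenvalues)
        self.predicted_freqs = np.array(freqs)
        self.oscillation_count = len(freqs)


def _pair_frequencies(eigenvalues: np.ndarray) -> list[float]:
    """Distinct conjugate-pair frequencies |b|/(2 pi), ascending."""
    b = np.abs(eigenvalues.imag)
    b = np.sort(b[b > _PAIR_TOL])
    freqs: list[float] = []
    for bi in b[::2]:  # conjugate partners are adjacent after sorting
        f = bi / (2.0 * np.pi)
        if freqs and abs(f - freqs[-1]) <= _DEDUP_REL * max(abs(f), 1.0):
            continue
        freqs.append(float(f))
    return freqs


def _rc_block(p: ModelParams) -> np.ndarray:
    return np.array(
        [
            [(p.w_ee_rc - 1.0) / p.tau_e, p.w_ei_rc / p.tau_e],
            [p.w_ie_rc / p.tau_i, (p.w_ii_rc - 1.0) / p.tau_i],
        ]
    )


def reduce_fb_matrix(params: ModelParams) -> ReducedSystem:
    """3x3 reduction of the feedback-only network (HC must be off).

    Coordinates (E, I, G) with E = sum_i E_i, I = sum_i I_i.  The G
    column carries n W_EG / tau_E and n W_IG / tau_I (every unit
    receives the feedback); the G row carries W_GE / tau_G (G sums the
    collective E once).
    """
    if params.w_ee_hc != 0.0 or params.w_ie_hc != 0.0:
        raise ParameterError(
            "reduce_fb_matrix applies to the FB-only regime: horizontal "
            "amplitudes must be zero"
        )
    n = params.n_units
    a = _rc_block(params)
    m = np.zeros((3, 3))
    m[:2, :2] = a
    m[0, 2] = n * params.w_eg / params.tau_e
    m[1, 2] = n * params.w_ig / params.tau_i
    m[2, 0] = params.w_ge / params.tau_g
    m[2, 2] = -1.0 / params.tau_g
    return ReducedSystem(kind="FB", matrix=m, n_units=n, alpha=float("nan"))


def reduce_hc_matrix(params: ModelParams) -> ReducedSystem:
    """4x4 reduction of the horizontal-only network (FB must be off).

    Coordinates (E_RC, I_RC, E_HC, I_HC).  The RC rows receive the HC
    coordinates with weights N/tau (alpha N/tau for the I row); the HC
    rows couple back to E_RC through the convolution closure
    4 sigma^2 (W_EE^HC)^2 pi^2 / N (alpha times that for I_HC).  When
    W_IE^HC = 0 the alpha ratio is bypassed and the I-row horizontal
    terms are simply zero (no E->I horizontal pathway exists).
    """
    if params.w_eg != 0.0 or params.w_ig != 0.0:
        raise ParameterError(
            "reduce_hc_matrix applies to the HC-only regime: feedback "
            "couplings must be zero"
        )
    n = params.n_units
    a = _rc_block(params)
    if params.w_ie_hc != 0.0:
        alpha = params.w_ee_hc / params.w_ie_hc
    else:
        alpha = 0.0  # alpha bypassed: no E->I horizontal pathway
    c = 4.0 * params.sigma_hc**2 * params.w_ee_hc**2 * np.pi**2 / n
    m = np.zeros((4, 4))
    m[:2, :2] = a
    m[2:, 2:] = a
    m[0, 2] = n / params.tau_e
    m[1, 2] = alpha * n / params.tau_i
    m[2, 0] = c / params.tau_e
    m[3, 0] = alpha * c / params.tau_i
    return ReducedSystem(kind="HC", matrix=m, n_units=n, alpha=float(alpha))


def predicted_frequencies(rs: ReducedSystem) -> np.ndarray:
    """Oscillation frequencies (Hz) of a reduced system, ascending;
    empty when every eigenvalue is real."""
    return rs.predicted_freqs.copy()
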
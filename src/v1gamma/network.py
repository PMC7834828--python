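"""Network construction and integration.

The model is a sheet of E-I rate units (one per lattice node) with four
connection classes:

* feed-forward LGN drive (Gaussian noise around a stimulus-dependent
  mean rate, drawn independently per step for E and I),
* local recurrent couplings within a unit,
* long-range horizontal connections from E onto E and I of other
  units, decaying as a Gaussian of lattice distance,
* global feedback: a single excitatory node G integrates all rectified
  E activities and projects back onto every E and I.

Dynamics (forward Euler, rectification H(x)=max(x,0) applied inside
every interaction term)::

    tau_E dE_i/dt = -E_i + W_EE^RC H(E_i) + W_EI^RC H(I_i) + W_EG H(G)
                    + sum_j K_E(i,j) H(E_j) + W_EL R_i^E(t)
    tau_I dI_i/dt = -I_i + W_IE^RC H(E_i) + W_II^RC H(I_i) + W_IG H(G)
                    + sum_j K_I(i,j) H(E_j) + W_IL R_i^I(t)
    tau_G dG/dt   = -G + W_GE sum_i H(E_i)

with K_R(i,j) = W_RE^HC exp(-d_ij^2 / 2 sigma^2) / sigma for j != i.
The lattice is open (no periodic wrap); edge units simply receive less
total horizontal input.  The LFP is the unrectified E of the central
unit; multiunit activity is the time-averaged rectified activity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .params import ModelParams, ParameterError, SimSpec, StimulusSpec

__all__ = [
    "rectify",
    "grid_coordinates",
    "center_index",
    "build_hc_kernel",
    "lgn_drive",
    "simulate",
    "Trajectory",
    "extract_lfp",
    "compute_mua",
]

# repeats integrated together in one vectorized block; results do not
# depend on this number because every repeat has its own noise stream
_CHUNK = 25


def rectify(x):
    """Half-wave rectification H(x): x for x > 0, else 0 (elementwise)."""
    return np.maximum(x, 0.0)


def grid_coordinates(params: ModelParams) -> np.ndarray:
    """(n_units, 2) array of integer lattice coordinates, row-major."""
    r, c = np.meshgrid(
        np.arange(params.grid_rows), np.arange(params.grid_cols), indexing="ij"
    )
    return np.stack([r.ravel(), c.ravel()], axis=1).astype(float)


def center_index(params: ModelParams) -> int:
    """Flat index of the central unit.

    For odd grids this is the unique centre; for even grids the
    convention is floor((n+1)/2) along each axis (1-based), i.e. the
    lower-left of the four central nodes.
    """
    r = (params.grid_rows - 1) // 2
    c = (params.grid_cols - 1) // 2
    return r * params.grid_cols + c


def build_hc_kernel(params: ModelParams, target: str) -> np.ndarray:
    """Unit-by-unit horizontal-connection weight matrix.

    Entry (i, j) is ``W_tE^HC * exp(-d_ij^2 / (2 sigma^2)) / sigma``
    for j != i and 0 on the diagonal (a unit does not project onto
    itself horizontally).  ``target`` selects the receiving population,
    ``"E"`` or ``"I"``.  Distances are Euclidean on the integer
    lattice; boundaries are open.
    """
    if target == "E":
        amplitude = params.w_ee_hc
    elif target == "I":
        amplitude = params.w_ie_hc
    else:
        raise ValueError(f"target must be 'E' or 'I', got {target!r}")
    if params.sigma_hc <= 0:  # unreachable through ModelParams, kept for raw use
        raise ParameterError("sigma_hc must be positive")
    coords = grid_coordinates(params)
    d2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(axis=-1)
    kernel = amplitude * np.exp(-d2 / (2.0 * params.sigma_hc**2)) / params.sigma_hc
    np.fill_diagonal(kernel, 0.0)
    return kernel


def activation_mask(params: ModelParams, stim: StimulusSpec) -> np.ndarray:
    """Boolean mask of units inside the stimulus activation zone."""
    coords = grid_coordinates(params)
    centre = coords[center_index(params)]
    dist = np.sqrt(((coords - centre) ** 2).sum(axis=1))
    return dist <= stim.radius


def _repeat_rng(master_seed: int, repeat: int) -> np.random.Generator:
    """Child generator for one repeat, derived from the master seed."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=master_seed, spawn_key=(repeat,))
    )


def lgn_drive(
    stim: StimulusSpec,
    params: ModelParams,
    sim: SimSpec,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Raw LGN rate samples for one repeat.

    Returns two (n_steps, n_units) arrays: the streams feeding E and I.
    Each entry is an independent Gaussian sample with mean ``rate_in``
    (inside the activation zone) or ``rate_out`` and SD ``noise_sd``.
    The feed-forward weights w_el / w_il are applied by the integrator,
    not here.
    """
    mean = np.where(activation_mask(params, stim), stim.rate_in, stim.rate_out)
    shape = (sim.n_steps, params.n_units)
    r_e = mean + stim.noise_sd * rng.standard_normal(shape)
    r_i = mean + stim.noise_sd * rng.standard_normal(shape)
    return r_e, r_i


@dataclass
class Trajectory:
    """Result of :func:`simulate`.

    ``lfp`` holds the full, undiscarded central-E series of every
    repeat; :func:`extract_lfp` restricts it to the analysis window.
    ``mua_e`` / ``mua_g`` are the analysis-window means of H(E)
    (averaged over units) and H(G), per repeat.  ``unstable`` flags
    repeats whose state exceeded the overflow bound; their series are
    frozen at the moment the bound was crossed.
    """

    times: np.ndarray
    lfp: np.ndarray  # (repeats, n_steps)
    g: np.ndarray  # (repeats, n_steps)
    mua_e: np.ndarray  # (repeats,)
    mua_g: np.ndarray  # (repeats,)
    unstable: np.ndarray  # (repeats,) bool
    params: ModelParams
    stim: StimulusSpec
    sim: SimSpec
    full_state: Optional[np.ndarray] = field(default=None, repr=False)
    # full_state: (repeats, n_steps, 2, n_units) when recorded

    @property
    def any_unstable(self) -> bool:
        return bool(self.unstable.any())


def simulate(
    params: ModelParams,
    stim: StimulusSpec,
    sim: SimSpec,
    record_full: bool = False,
    init: tuple[float | np.ndarray, float | np.ndarray, float] | None = None,
) -> Trajectory:
    """Integrate the network with forward Euler.

    All repeats start from the all-zero state unless ``init`` supplies
    (E0, I0, G0) values (scalars or per-unit arrays, shared across
    repeats); repeat ``r`` draws its
    noise from a child stream of ``sim.seed`` indexed by ``r``, so runs
    are reproducible and repeats independent.  Noise is one Gaussian
    draw per step per component, injected as a rate input (no sqrt(dt)
    scaling): the spectra therefore refer to the stated dt.

    A repeat whose state magnitude exceeds ``params.overflow`` is
    flagged unstable and frozen rather than allowed to overflow.
    """
    n = params.n_units
    n_steps = sim.n_steps
    dt = sim.dt
    k_e = build_hc_kernel(params, "E")
    k_i = build_hc_kernel(params, "I")
    mean = np.where(activation_mask(params, stim), stim.rate_in, stim.rate_out)

    lfp = np.empty((sim.repeats, n_steps))
    g_series = np.empty((sim.repeats, n_steps))
    mua_e = np.empty(sim.repeats)
    mua_g = np.empty(sim.repeats)
    unstable = np.zeros(sim.repeats, dtype=bool)
    full = (
        np.empty((sim.repeats, n_steps, 2, n)) if record_full else None
    )
    centre = center_index(params)
    i0 = sim.n_discard
    check_every = 50

    for start in range(0, sim.repeats, _CHUNK):
        stop = min(start + _CHUNK, sim.repeats)
        rows = slice(start, stop)
        m = stop - start
        noise_e = np.empty((m, n_steps, n))
        noise_i = np.empty((m, n_steps, n))
        for k, r in enumerate(range(start, stop)):
            rng = _repeat_rng(sim.seed, r)
            noise_e[k] = rng.standard_normal((n_steps, n))
            noise_i[k] = rng.standard_normal((n_steps, n))

        if init is None:
            e = np.zeros((m, n))
            i_ = np.zeros((m, n))
            g = np.zeros(m)
        else:
            e = np.broadcast_to(np.asarray(init[0], dtype=float), (m, n)).copy()
            i_ = np.broadcast_to(np.asarray(init[1], dtype=float), (m, n)).copy()
            g = np.full(m, float(init[2]))
        alive = np.ones(m, dtype=bool)
        acc_e = np.zeros(m)
        acc_g = np.zeros(m)
        for t in range(n_steps):
            h_e = rectify(e)
            h_i = rectify(i_)
            h_g = rectify(g)
            r_e = mean + stim.noise_sd * noise_e[:, t, :]
            r_i = mean + stim.noise_sd * noise_i[:, t, :]
            de = (
                -e
                + params.w_ee_rc * h_e
                + params.w_ei_rc * h_i
                + params.w_eg * h_g[:, None]
                + h_e @ k_e
                + params.w_el * r_e
            ) / params.tau_e
            di = (
                -i_
                + params.w_ie_rc * h_e
                + params.w_ii_rc * h_i
                + params.w_ig * h_g[:, None]
                + h_e @ k_i
                + params.w_il * r_i
            ) / params.tau_i
            dg = (-g + params.w_ge * h_e.sum(axis=1)) / params.tau_g
            step = dt * alive[:, None]
            e = e + step * de
            i_ = i_ + step * di
            g = g + dt * alive * dg
            if (t + 1) % check_every == 0 or t == n_steps - 1:
                bad = alive & (
                    (np.abs(e).max(axis=1) > params.overflow)
                    | (np.abs(i_).max(axis=1) > params.overflow)
                    | (np.abs(g) > params.overflow)
                    | ~np.isfinite(e).all(axis=1)
                    | ~np.isfinite(i_).all(axis=1)
                )
                if bad.any():
                    alive &= ~bad
                    e[bad] = np.nan_to_num(e[bad], posinf=0.0, neginf=0.0)
                    i_[bad] = np.nan_to_num(i_[bad], posinf=0.0, neginf=0.0)
            lfp[rows, t] = e[:, centre]
            g_series[rows, t] = g
            if full is not None:
                full[rows, t, 0, :] = e
                full[rows, t, 1, :] = i_
            if t >= i0:
                acc_e += rectify(e).mean(axis=1)
                acc_g += rectify(g)
        n_window = n_steps - i0
        mua_e[rows] = acc_e / n_window
        mua_g[rows] = acc_g / n_window
        unstable[rows] = ~alive

    times = np.arange(n_steps) * dt
    return Trajectory(
        times=times,
        lfp=lfp,
        g=g_series,
        mua_e=mua_e,
        mua_g=mua_g,
        unstable=unstable,
        params=params,
        stim=stim,
        sim=sim,
        full_state=full,
    )


def extract_lfp(traj: Trajectory, analysis: bool = True) -> np.ndarray:
    """Central-unit unrectified E series, (repeats, n_samples).

    With ``analysis=True`` (default) the first ``discard`` seconds are
    dropped, leaving the stationary window the spectra are computed on.
    """
    if analysis:
        return traj.lfp[:, traj.sim.n_discard :]
    return traj.lfp


def compute_mua(traj: Trajectory) -> tuple[float, float]:
    """Mean firing-rate proxies: time-averaged H(E) and H(G).

    Averages over the analysis window, all units and all repeats;
    both values are nonnegative by construction.
    """
    return float(traj.mua_e.mean()), float(traj.mua_g.mean())
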
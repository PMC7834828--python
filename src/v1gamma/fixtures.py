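"""Synthetic power spectra for exercising the detection statistics
without running simulations."""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .spectra import PowerSpectrum

__all__ = ["fixture_spectrum"]


def fixture_spectrum(
    kind: str,
    centers: Sequence[float] = (),
    heights: Sequence[float] = (),
    widths: Sequence[float] = (),
    background: float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    freqs: np.ndarray | None = None,
    n_repeats: int = 100,
) -> PowerSpectrum:
    """Construct a flat, single-bump or double-bump power spectrum.

    ``kind`` is ``"flat"``, ``"bump"`` (one Gaussian bump; pass one
    center/height/width) or ``"bumps"`` (one per entry).  Optional
    multiplicative noise with relative SD ``noise_sd`` emulates the
    residual fluctuation of an averaged periodogram; ``n_repeats`` is
    recorded on the result so the detector's significance criterion
    scales as it would for a simulated spectrum of that many repeats.
    """
    if freqs is None:
        freqs = np.arange(0.0, 501.0)
    freqs = np.asarray(freqs, dtype=float)
    power = np.full(freqs.shape, float(background))
    if kind == "flat":
        if centers or heights or widths:
            raise ValueError("flat spectrum takes no bump parameters")
    elif kind in ("bump", "bumps"):
        if not (len(centers) == len(heights) == len(widths)):
            raise ValueError("centers, heights and widths must have equal length")
        if kind == "bump" and len(centers) != 1:
            raise ValueError("kind='bump' takes exactly one bump")
        if not centers:
            raise ValueError(f"kind={kind!r} needs at least one bump")
        for c, h, w in zip(centers, heights, widths):
            if w <= 0:
                raise ValueError("bump width must be positive")
            power = power + h * np.exp(-((freqs - c) ** 2) / (2.0 * w**2))
    else:
        raise ValueError(f"unknown fixture kind {kind!r}")
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        power = power * np.clip(
            1.0 + noise_sd * rng.standard_normal(freqs.shape), 1e-12, None
        )
    return PowerSpectrum(
        freqs=freqs, power=power, n_repeats=n_repeats, condition=f"fixture:{kind}"
    )
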
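"""Minimal static figures for spectra and order profiles."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .profiles import OrderProfile
from .spectra import Spectrum


def plot_spectrum(spectrum: Spectrum, half_width_khz: float = 250.0, ax=None,
                  **kwargs):
    """Plot a powder spectrum cropped to the display window."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    s = spectrum.crop(half_width_khz)
    ax.plot(s.frequencies, s.intensities, lw=0.8, **kwargs)
    ax.set_xlabel("frequency (kHz)")
    ax.set_ylabel("intensity (a.u.)")
    ax.set_xlim(-half_width_khz, half_width_khz)
    return ax


def plot_profile(profile: OrderProfile, ax=None, **kwargs):
    """Plot |S_CD| against carbon index."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    ax.plot(profile.carbons, profile.magnitudes, "o-", **kwargs)
    ax.set_xlabel("carbon index")
    ax.set_ylabel("|S$_{CD}$|")
    ax.set_ylim(bottom=0)
    return ax
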
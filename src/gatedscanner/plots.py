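"""Static figure export for traces, profiles and fitted curves."""

from __future__ import annotations

import numpy as np


def _ax(ax):
    if ax is not None:
        return ax
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    _, ax = plt.subplots()
    return ax


def plot_trace(trace, ax=None, chi_window=None):
    """Position-vs-time trace; the Chi window is marked when given."""
    ax = _ax(ax)
    ax.plot(trace.time_s, trace.position_bp, lw=0.8)
    if chi_window is not None:
        ax.axhspan(*chi_window, color="green", alpha=0.15)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("position (bp)")
    return ax


def plot_velocity_profile(profile_df, ax=None):
    """Binned mean velocity vs position (output of mean_velocity_profile)."""
    ax = _ax(ax)
    centers = 0.5 * (profile_df["bin_start_bp"] + profile_df["bin_end_bp"])
    ax.plot(centers, profile_df["mean_velocity"], drawstyle="steps-mid")
    ax.set_xlabel("position (bp)")
    ax.set_ylabel("mean velocity (bp/s)")
    return ax


def plot_chase(series, fit=None, ax=None):
    """Chase survival points with the fitted exponential decay."""
    ax = _ax(ax)
    ax.plot(series.time_min, series.fragment_fraction, "o")
    if fit is not None:
        t = np.linspace(series.time_min[0], series.time_min[-1], 200)
        ax.plot(t, fit.f0 * np.exp(-fit.k * t), "-")
    ax.set_xlabel("time after chase (min)")
    ax.set_ylabel("Chi fragment fraction")
    return ax


def plot_triplex(curve, fit=None, ax=None):
    """Normalized triplex transient with the fitted biphasic curve."""
    ax = _ax(ax)
    ax.plot(curve.time_s, curve.signal, lw=0.8)
    if fit is not None:
        from .kinetics import _biphasic_model

        t = np.asarray(curve.time_s)
        ax.plot(t, _biphasic_model(t, fit.a1, fit.k1, fit.d1, fit.a2, fit.k2, fit.d2),
                "--")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("normalized fluorescence")
    return ax
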
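"""Optional figure helpers (profiles, measurement series, force curves)."""

from __future__ import annotations

import numpy as np


def plot_profiles(profiles, tether_level=None, ax=None):
    """Overlay intensity profiles with the I_2x / I_4x reference lines.

    ``profiles`` is an iterable of :class:`~loopblock.quantify.IntensityProfile`;
    when ``tether_level`` is given, dashed lines mark 2x and 4x that level —
    the single- and double-loop expectations.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for p in profiles:
        label = p.stage_label or (f"frame {p.frame_index}" if p.frame_index is not None else None)
        ax.plot(p.arc_position_um, p.intensity, label=label)
    if tether_level is not None:
        ax.axhline(2 * tether_level, ls="--", c="gray", label="I_2x")
        ax.axhline(4 * tether_level, ls="--", c="black", label="I_4x")
    ax.set_xlabel("position along contour (µm)")
    ax.set_ylabel("intensity (counts)")
    ax.legend(fontsize="small")
    return ax


def plot_series(series, encounter_frame=None, axes=None):
    """Loop size and roadblock-stem distance versus time for one event."""
    import matplotlib.pyplot as plt

    if axes is None:
        _, axes = plt.subplots(2, 1, sharex=True)
    t = series["time_s"]
    axes[0].plot(t, series["loop_kb"], c="green")
    axes[0].set_ylabel("loop size (kb)")
    axes[1].plot(t, series["roadblock_distance_um"], c="red")
    axes[1].set_ylabel("roadblock–stem\ndistance (µm)")
    axes[1].set_xlabel("time (s)")
    if encounter_frame is not None:
        t_enc = float(np.asarray(t)[int(encounter_frame)])
        for ax in axes:
            ax.axvline(t_enc, ls="--", c="gray")
    return axes


def plot_force_table(table, ax=None):
    """Drag force versus particle size / loop size (log-log)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for kind, color in (("particle", "red"), ("loop", "blue")):
        sub = table[table["kind"] == kind]
        if len(sub):
            ax.plot(sub["size"], sub["force_pn"], c=color, label=kind)
    ax.set_xlabel("size (nm diameter / kb)")
    ax.set_ylabel("drag force (pN)")
    ax.set_yscale("log")
    ax.legend()
    return ax
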
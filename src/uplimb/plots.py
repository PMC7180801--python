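"""Figure helpers: waveform overlays and Bland-Altman panels."""

from __future__ import annotations

import os

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .datamodel import CHANNELS
from .evaluate import bland_altman


def plot_waveform_overlay(reference, raw, refined, path, title=""):
    """One panel per channel: gold standard vs raw vs refined waveforms.

    Inputs are (T, 4) arrays in degrees on a common 0-100% time base.
    """
    pct = np.linspace(0, 100, len(reference))
    fig, axes = plt.subplots(2, 2, figsize=(9, 6), sharex=True)
    for ci, (ax, ch) in enumerate(zip(axes.ravel(), CHANNELS)):
        ax.plot(pct, reference[:, ci], color="tab:orange", label="gold standard")
        ax.plot(pct, raw[:, ci], color="tab:blue", label="depth sensor")
        ax.plot(pct, refined[:, ci], "--", color="tab:green", label="refined")
        ax.set_title(ch)
        ax.set_ylabel("angle (deg)")
    axes[1, 0].set_xlabel("movement (%)")
    axes[1, 1].set_xlabel("movement (%)")
    axes[0, 0].legend(fontsize=8)
    fig.suptitle(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return str(path)


def plot_bland_altman(x, y, path, title="", param="parameter (deg)"):
    """Bland-Altman panel: per-pair mean vs difference with mean and LoA lines."""
    ba = bland_altman(x, y)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(ba["means"], ba["diffs"], s=18, color="tab:blue")
    ax.axhline(ba["mean_diff"], color="red")
    for loa in (ba["loa_lower"], ba["loa_upper"]):
        ax.axhline(loa, color="gray", linestyle="--")
    ax.set_xlabel(f"mean of systems: {param}")
    ax.set_ylabel("difference (deg)")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return str(path)


def render_fold_plots(folds, out_dir):
    """Waveform overlays per held-out subject plus PTA/ROM BA panels."""
    from .evaluate import pta, rom

    os.makedirs(out_dir, exist_ok=True)
    written = []
    for f in folds:
        if not f.refined:
            continue
        written.append(plot_waveform_overlay(
            f.targets[0].values, f.inputs[0].values, f.refined[0].values,
            os.path.join(out_dir, f"waveforms_{f.subject_id}.png"),
            title=f"{f.task} - held-out {f.subject_id}"))
    for name, fn in (("pta", pta), ("rom", rom)):
        for ci, ch in enumerate(CHANNELS):
            hat = np.array([np.mean([fn(w.values[:, ci]) for w in f.refined])
                            for f in folds])
            ref = np.array([np.mean([fn(g.values[:, ci]) for g in f.targets])
                            for f in folds])
            if len(hat) < 2:
                continue
            written.append(plot_bland_altman(
                hat, ref,
                os.path.join(out_dir, f"ba_{name}_{ch}.png"),
                title=f"{folds[0].task} {ch} {name.upper()} (refined vs gold)",
                param=f"{ch} {name.upper()} (deg)"))
    return written
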
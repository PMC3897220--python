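"""Minimal static plots: CH scatter, disorder track, composition bars."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .disorder import CHPoint, CompositionProfile, ScoreTrack


def plot_ch_plane(points: dict[str, CHPoint], path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(5, 4))
    for name, p in points.items():
        ax.scatter(p.h, p.q, label=f"{name} ({p.label})")
    if points:
        slope = next(iter(points.values())).boundary_slope
        intercept = next(iter(points.values())).boundary_intercept
        h = np.linspace(0.3, 0.8, 50)
        ax.plot(h, slope * h + intercept, "k-", lw=1, label="boundary")
    ax.set_xlabel("mean normalized hydropathy ⟨H⟩")
    ax.set_ylabel("mean net charge ⟨q⟩")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_disorder_track(track: ScoreTrack, path: str | Path, threshold: float = 0.5) -> None:
    fig, ax = plt.subplots(figsize=(7, 2.5))
    ax.plot(np.arange(1, len(track) + 1), track.scores, lw=0.8)
    ax.axhline(threshold, color="r", ls="--", lw=0.8)
    ax.set_xlabel("residue")
    ax.set_ylabel("disorder score")
    ax.set_ylim(0, 1)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_composition_bars(profile: CompositionProfile, path: str | Path) -> None:
    table = profile.table
    fig, ax = plt.subplots(figsize=(7, 3))
    x = np.arange(len(table))
    d = table["d"].to_numpy()
    err = np.vstack([d - table["ci_low"], table["ci_high"] - d])
    ax.bar(x, d, yerr=np.abs(err), color="gray", capsize=2)
    ax.axhline(0, color="k", lw=0.8)
    ax.set_xticks(x, table.index)
    ax.set_ylabel("(C_X − C_order) / C_order")
    ax.set_xlabel("rigid → flexible")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
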
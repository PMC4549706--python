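"""Diagnostic plots: progress-curve overlays, double-reciprocal panels,
and kobs/A/B panels."""

from __future__ import annotations

from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .models import KobsRegression, ProgressCurve
from .progress import SlowBindingCurveFit
from .steady_state import ReciprocalDiagnostics


def plot_progress_overlay(curves: Sequence[ProgressCurve],
                          fits: Sequence[SlowBindingCurveFit] | None,
                          path) -> None:
    """Raw traces as dots with fitted curves overlaid as lines."""
    fig, ax = plt.subplots(figsize=(6, 4))
    for idx, c in enumerate(curves):
        dots = ax.plot(c.times, c.signal, ".", ms=3,
                       label=f"I={c.I*1e9:.3g} nM")[0]
        if fits is not None:
            f = fits[idx]
            t = np.linspace(c.times[0], c.times[-1], 200)
            y = f.v0 * t if not f.slow_binding else (
                f.vs * t + (f.v0 - f.vs) * (-np.expm1(-f.kobs * t)) / f.kobs)
            ax.plot(t, y, "-", color=dots.get_color(), lw=1)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("product signal")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_reciprocal_panel(diag: ReciprocalDiagnostics, path) -> None:
    """Lineweaver-Burk lines, one per inhibitor level."""
    fig, ax = plt.subplots(figsize=(5, 4))
    for _, row in diag.lines.iterrows():
        x = np.linspace(0, 1, 50)
        ax.plot(x, row["intercept"] + row["slope"] * x,
                label=f"I={row['I']*1e9:.3g} nM")
    ax.set_xlabel("1/[S] (1/M)")
    ax.set_ylabel("1/v")
    ax.set_title(f"pattern: {diag.classification}")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_kobs_panel(regressions: Mapping[float, KobsRegression], path) -> None:
    """kobs-vs-[I] lines per substrate level plus the A(S) and B(S) trends."""
    fig, axes = plt.subplots(1, 3, figsize=(11, 3.5))
    S = np.array(sorted(regressions))
    for s in S:
        r = regressions[s]
        x = np.linspace(0, 1.2e-7, 50)
        axes[0].plot(x * 1e9, r.B + r.A * x, label=f"S={s*1e6:.3g} uM")
    axes[0].set_xlabel("[I] (nM)")
    axes[0].set_ylabel("kobs (1/s)")
    axes[0].legend(fontsize=7)
    A = [regressions[s].A * 1e-9 for s in S]
    B = [regressions[s].B for s in S]
    axes[1].plot(S * 1e6, A, "o-")
    axes[1].set_xlabel("[S] (uM)")
    axes[1].set_ylabel("A (1/s/nM)")
    axes[2].plot(S * 1e6, B, "o-")
    axes[2].set_xlabel("[S] (uM)")
    axes[2].set_ylabel("B (1/s)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
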
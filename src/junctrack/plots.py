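"""Figure-style outputs: heatmaps, box plots, CDFs and streamline fields."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .kinematics import RateField
from .rotation import PhasePortrait
from .stats import BoxSummary, significance_stars


def plot_heatmap(field: RateField, path: str | Path,
                 title: str | None = None) -> None:
    """Render a (time/length, angle) binned field as an image."""
    fig, ax = plt.subplots(figsize=(6, 4))
    im = ax.pcolormesh(field.angle_edges, field.x_edges, field.mean,
                       shading="flat", cmap="RdBu_r")
    fig.colorbar(im, ax=ax, label=field.statistic)
    ax.set_xlabel("orientation angle θ (°)")
    ax.set_ylabel(field.x_name)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(str(path))
    plt.close(fig)


def plot_boxes(summaries: list[BoxSummary], path: str | Path,
               ylabel: str = "", p_value: float | None = None) -> None:
    """Box plot from precomputed summaries (paper whisker convention)."""
    fig, ax = plt.subplots(figsize=(1.2 + 0.9 * len(summaries), 4))
    stats = [{
        "label": s.label, "med": s.median, "q1": s.q1, "q3": s.q3,
        "whislo": s.whisker_lo, "whishi": s.whisker_hi,
        "fliers": s.outliers,
    } for s in summaries]
    ax.bxp(stats, showfliers=True)
    ax.set_ylabel(ylabel)
    if p_value is not None:
        ax.set_title(significance_stars(p_value))
    fig.tight_layout()
    fig.savefig(str(path))
    plt.close(fig)


def plot_cdfs(groups: dict[str, np.ndarray], path: str | Path,
              xlabel: str = "") -> None:
    """Empirical cumulative distribution per group."""
    fig, ax = plt.subplots(figsize=(5, 4))
    for label, vals in groups.items():
        v = np.sort(np.asarray(vals, dtype=float))
        v = v[np.isfinite(v)]
        if v.size == 0:
            continue
        ax.step(v, np.arange(1, v.size + 1) / v.size, where="post",
                label=str(label))
    ax.set_xlabel(xlabel)
    ax.set_ylabel("cumulative fraction")
    ax.legend()
    fig.tight_layout()
    fig.savefig(str(path))
    plt.close(fig)


def plot_phase_portrait(portrait: PhasePortrait, path: str | Path,
                        streamlines: list[np.ndarray] | None = None) -> None:
    """Quiver of the (l, θ) flow field with optional streamlines overlaid."""
    fig, ax = plt.subplots(figsize=(6, 4))
    tt, ll = np.meshgrid(portrait.theta_centers, portrait.l_centers)
    ax.quiver(tt, ll, portrait.dtheta_dt, portrait.dl_dt, angles="xy",
              color="gray")
    for traj in (streamlines or portrait.streamlines):
        ax.plot(traj[:, 1], traj[:, 0], lw=1.5)
    ax.set_xlabel("orientation angle θ (°)")
    ax.set_ylabel("interface length l (µm)")
    fig.tight_layout()
    fig.savefig(str(path))
    plt.close(fig)
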
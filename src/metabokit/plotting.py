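"""Static figure export (PNG/SVG) for the main analysis outputs."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.patches as mpatches  # noqa: E402
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402

from .multivariate import HeatmapSpec, ScoresLoadings, confidence_ellipse


def plot_scores(sl: ScoresLoadings, group, path, level: float = 0.95) -> None:
    """2D scores plot with per-group confidence ellipses."""
    fig, ax = plt.subplots(figsize=(6, 6))
    scores2 = sl.scores.iloc[:, :2]
    for g in sorted(group.unique()):
        pts = scores2.loc[group[group == g].index]
        ax.scatter(pts.iloc[:, 0], pts.iloc[:, 1], label=str(g), alpha=0.8)
    try:
        for ell in confidence_ellipse(scores2, group, level=level):
            width, height = 2 * ell.axes
            ax.add_patch(mpatches.Ellipse(
                ell.center, width, height, angle=np.degrees(ell.angle),
                fill=True, alpha=0.15))
    except Exception:
        pass  # tiny groups: plot points only
    ax.set_xlabel(f"{scores2.columns[0]} ({100 * sl.explained[0]:.1f}%)")
    ax.set_ylabel(f"{scores2.columns[1]} ({100 * sl.explained[1]:.1f}%)")
    ax.legend()
    fig.savefig(path, bbox_inches="tight")
    plt.close(fig)


def plot_heatmap(values, spec: HeatmapSpec, path, dpi: int = 72) -> None:
    """Render a clustered heatmap at the size the spec prescribes."""
    data = values.loc[spec.row_order, spec.col_order].to_numpy(dtype=float).T
    figsize = (spec.image_width / dpi, spec.image_height / dpi)
    fig, ax = plt.subplots(figsize=figsize)
    ax.imshow(data, aspect="auto", cmap=spec.color_scale.get("cmap", "RdBu_r"),
              vmin=spec.color_scale.get("vmin"),
              vmax=spec.color_scale.get("vmax"), interpolation="nearest")
    ax.set_xticks(range(len(spec.row_order)))
    ax.set_xticklabels([str(s) for s in spec.row_order], rotation=90,
                       fontsize=6)
    if len(spec.col_order) <= 2000:
        ax.set_yticks(range(len(spec.col_order)))
        ax.set_yticklabels([str(f) for f in spec.col_order], fontsize=6)
    fig.savefig(path, dpi=dpi, bbox_inches="tight")
    plt.close(fig)


def plot_volcano(coords, selected, path) -> None:
    sel = coords["feature"].isin(set(selected))
    fig, ax = plt.subplots(figsize=(6, 5))
    ax.scatter(coords.loc[~sel, "log2_fc"], coords.loc[~sel, "neg_log10_p"],
               c="grey", s=12, alpha=0.6)
    ax.scatter(coords.loc[sel, "log2_fc"], coords.loc[sel, "neg_log10_p"],
               c="crimson", s=16)
    ax.set_xlabel("log2 fold change")
    ax.set_ylabel("-log10 p")
    fig.savefig(path, bbox_inches="tight")
    plt.close(fig)


def plot_roc(curve, path, label: str | None = None) -> None:
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.plot(curve.one_minus_specificity, curve.sensitivity,
            label=label or f"AUC = {curve.auc:.3f}")
    ax.plot([0, 1], [0, 1], "--", c="grey", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend(loc="lower right")
    fig.savefig(path, bbox_inches="tight")
    plt.close(fig)


def plot_power_curve(pc, path, target: float | None = 0.8) -> None:
    fig, ax = plt.subplots(figsize=(6, 4.5))
    ax.plot(pc.sample_sizes, pc.avg_power, marker="o", ms=3)
    if target is not None:
        ax.axhline(target, ls="--", c="grey", lw=0.8)
    ax.set_xscale("log")
    ax.set_xlabel("sample size per group")
    ax.set_ylabel("predicted average power")
    ax.set_ylim(0, 1.02)
    fig.savefig(path, bbox_inches="tight")
    plt.close(fig)
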
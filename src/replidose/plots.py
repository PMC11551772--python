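"""Optional matplotlib figures (the analysis itself runs headless)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .mfa import MFAProfile, ReplicationFit, rebin
from .phenomics import PMComparison

__all__ = ["plot_mfa_profile", "plot_pm_comparison"]


def plot_mfa_profile(profile: MFAProfile, fit: ReplicationFit, path) -> None:
    """Ori-centred dosage profile: per-window points plus 10x coarser
    means, one colour pair per replicon, log2 y-axis."""
    fig, ax = plt.subplots(figsize=(8, 4.5))
    colors = plt.rcParams["axes.prop_cycle"].by_key()["color"]
    for i, (name, sub) in enumerate(profile.df.groupby("replicon", sort=False)):
        inc = sub["included"] & (sub["frequency"] > 0)
        x = sub.loc[inc, "ori_distance"] / 1e6
        y = np.log2(sub.loc[inc, "frequency"])
        ax.plot(x, y, ".", ms=2, alpha=0.35, color=colors[i % len(colors)], label=name)
        # coarse means
        order = np.argsort(x.to_numpy())
        xs, ys = x.to_numpy()[order], y.to_numpy()[order]
        k = max(1, len(xs) // 100)
        xm = [xs[j : j + k].mean() for j in range(0, len(xs), k)]
        ym = [ys[j : j + k].mean() for j in range(0, len(ys), k)]
        ax.plot(xm, ym, "s", ms=3, color=colors[(i + 2) % len(colors)])
    ax.set_xlabel("position relative to ori (Mb)")
    ax.set_ylabel("log2 normalized frequency")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_pm_comparison(comparisons: list[PMComparison], path, error_bar: str = "sd") -> None:
    """Mean AUC of mutant vs WT with error bars and the bisector."""
    fig, ax = plt.subplots(figsize=(5, 5))
    xs = [c.mean_auc_wt for c in comparisons]
    ys = [c.mean_auc_mut for c in comparisons]
    ex = [c.sd_wt if error_bar == "sd" else c.se_wt for c in comparisons]
    ey = [c.sd_mut if error_bar == "sd" else c.se_mut for c in comparisons]
    flagged = [c.flagged for c in comparisons]
    ax.errorbar(xs, ys, xerr=ex, yerr=ey, fmt="o", ms=3, alpha=0.5, lw=0.5)
    if any(flagged):
        fx = [x for x, f in zip(xs, flagged) if f]
        fy = [y for y, f in zip(ys, flagged) if f]
        ax.plot(fx, fy, "r*", ms=10, label="flagged")
        ax.legend(frameon=False)
    lim = max(max(xs, default=1), max(ys, default=1)) * 1.05
    ax.plot([0, lim], [0, lim], "k--", lw=1)
    ax.set_xlabel("mean AUC, WT (OD·min)")
    ax.set_ylabel("mean AUC, mutant (OD·min)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
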
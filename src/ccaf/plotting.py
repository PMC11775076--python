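"""Optional matplotlib views of choice data and fitted curves."""

from __future__ import annotations

import numpy as np

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402


def plot_group_curves(summary, fits, ax=None):
    """Observed percent alcohol choice per level with fitted curves.

    ``fits`` maps group label -> PsychometricResults.
    """
    if ax is None:
        fig, ax = plt.subplots(figsize=(5, 4))
    else:
        fig = ax.figure
    xs = np.linspace(-2.5, 2.5, 200)
    colors = {"HD": "tab:red", "LD": "tab:blue"}
    for grp, res in sorted(fits.items()):
        color = colors.get(grp, None)
        ax.plot(xs, 100 * res.predict(xs), label=f"{grp} fit", color=color)
        sub = summary[summary["group"] == grp]
        obs = sub.groupby("relative_point_level").apply(
            lambda d: 100 * d["k"].sum() / d["n"].sum(), include_groups=False)
        ax.scatter(obs.index, obs.values, color=color, zorder=3)
        ax.axvline(res.alpha, color=color, ls=":", lw=1)
    ax.axhline(50, color="grey", lw=0.5)
    ax.set_xlabel("relative point level (alcohol - snack)")
    ax.set_ylabel("% alcohol choice")
    ax.set_xticks([-2, 0, 2])
    ax.legend(frameon=False)
    fig.tight_layout()
    return fig


def plot_subject_curves(summary, subject_fits, ncols=6):
    """Small-multiple per-subject curves (one panel per subject)."""
    sids = sorted(summary["subject_id"].unique())
    nrows = int(np.ceil(len(sids) / ncols))
    fig, axes = plt.subplots(nrows, ncols, figsize=(2 * ncols, 1.8 * nrows),
                             sharex=True, sharey=True)
    xs = np.linspace(-2.5, 2.5, 100)
    for ax, sid in zip(np.ravel(axes), sids):
        res = subject_fits[sid]
        sub = summary[summary["subject_id"] == sid]
        ax.plot(xs, 100 * res.predict(xs), lw=1)
        ax.scatter(sub["relative_point_level"], sub["pct"], s=8)
        ax.set_title(sid, fontsize=7)
    for ax in np.ravel(axes)[len(sids):]:
        ax.axis("off")
    fig.tight_layout()
    return fig
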
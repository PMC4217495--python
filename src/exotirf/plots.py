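"""Optional matplotlib figures: trace galleries, half-life dot plots,
kymographs and the probability-vs-N curve of the null model."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd


def _plt():
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    return plt


def plot_trace_gallery(traces, path: str | Path, max_traces: int = 12):
    plt = _plt()
    traces = list(traces)[:max_traces]
    n = max(1, len(traces))
    fig, axes = plt.subplots(n, 1, figsize=(6, 1.6 * n), sharex=True, squeeze=False)
    for ax, tr in zip(axes[:, 0], traces):
        ax.plot(tr.times_s, tr.spot, lw=0.8, label="spot")
        ax.plot(tr.times_s, tr.surround, lw=0.8, color="r", label="surround")
        ax.axhline(2 * tr.background_B, ls="--", color="k", lw=0.6)
        ax.set_ylabel(f"ev {tr.event_id}")
    axes[-1, 0].set_xlabel("time (s)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_halflife_dotplot(events: pd.DataFrame, path: str | Path):
    """Dot plot of per-event half-lives by class with mean +/- SD bars."""
    plt = _plt()
    fig, ax = plt.subplots(figsize=(4, 4))
    labels = [l for l in events["label"].unique() if events["label"].eq(l).any()]
    rng = np.random.default_rng(0)
    for i, label in enumerate(labels):
        vals = events.loc[
            events["label"].eq(label) & events["converged"], "half_life_s"
        ].dropna()
        x = i + rng.uniform(-0.12, 0.12, len(vals))
        ax.plot(x, vals, "o", ms=3, alpha=0.6)
        if len(vals):
            ax.errorbar(
                [i], [vals.mean()],
                yerr=[vals.std(ddof=1) if len(vals) > 1 else 0.0],
                fmt="_", color="k", capsize=4, ms=16,
            )
    ax.set_xticks(range(len(labels)), labels, rotation=20)
    ax.set_ylabel("half-life (s)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_kymograph(kymo: np.ndarray, frame_rate_hz: float, path: str | Path):
    plt = _plt()
    fig, ax = plt.subplots(figsize=(6, 3))
    extent = (0, kymo.shape[1] / frame_rate_hz, kymo.shape[0], 0)
    ax.imshow(kymo, aspect="auto", cmap="gray", extent=extent)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("position along path (px)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_probability_curve(curve: pd.DataFrame, path: str | Path):
    plt = _plt()
    fig, ax = plt.subplots(figsize=(4, 3))
    ax.plot(curve["N"], curve["p_hat"], "o-")
    ax.set_xlabel("total events N")
    ax.set_ylabel("P(>=1 consecutive pair)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
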
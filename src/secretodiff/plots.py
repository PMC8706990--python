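"""Optional SVG plots (requires the ``plot`` extra: matplotlib)."""

from __future__ import annotations

import pandas as pd


def _pyplot():
    try:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
    except ImportError as exc:  # pragma: no cover
        raise ImportError("plotting needs matplotlib (install the 'plot' extra)") from exc
    return plt


def km_plot(result, path) -> None:
    """Step plot of the per-arm survival curves of a SurvivalResult."""
    plt = _pyplot()
    fig, ax = plt.subplots(figsize=(5, 4))
    for arm, curve in result.km_curves.items():
        ax.step(curve["time"], curve["survival"], where="post", label=arm)
    ax.set_xlabel("time")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.05)
    ax.legend(
        title=f"HR={result.hazard_ratio:.2f} "
        f"[{result.hr_ci[0]:.2f},{result.hr_ci[1]:.2f}], p={result.logrank_p:.2g}"
    )
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def volcano_plot(volcano: pd.DataFrame, path) -> None:
    """Scatter of log2 ratio vs -log10 p, selected proteins highlighted."""
    plt = _pyplot()
    fig, ax = plt.subplots(figsize=(5, 4))
    sel = volcano["selected"].astype(bool)
    ax.scatter(volcano.loc[~sel, "log2_ratio"], volcano.loc[~sel, "neg_log10_p"],
               s=6, c="grey", alpha=0.5, label="not selected")
    ax.scatter(volcano.loc[sel, "log2_ratio"], volcano.loc[sel, "neg_log10_p"],
               s=8, c="crimson", label="selected")
    ax.set_xlabel("log2 abundance ratio (treated / control)")
    ax.set_ylabel("-log10 p")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
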
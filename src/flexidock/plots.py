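"""Plotting helpers (matplotlib imported lazily; optional dependency)."""

from __future__ import annotations

from pathlib import Path


def funnel_plot(
    scores,
    rmsds,
    path: str | Path,
    xlabel: str = "CA RMSD (A)",
    ylabel: str = "score",
    highlight=None,
    title: str | None = None,
) -> None:
    """Score-vs-RMSD scatter ("funnel") written to ``path``.

    ``highlight`` is an optional boolean mask marking near-native points.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(rmsds, scores, s=10, c="0.5", label="candidates")
    if highlight is not None:
        hx = [r for r, h in zip(rmsds, highlight) if h]
        hy = [s for s, h in zip(scores, highlight) if h]
        ax.scatter(hx, hy, s=14, c="tab:blue", label="near-native")
        ax.legend(frameon=False)
    ax.set_xlabel(xlabel)
    ax.set_ylabel(ylabel)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def exchange_diagnostics_plot(diagnostics: dict, path: str | Path) -> None:
    """Bar chart of per-pair exchange acceptance rates."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    rates = diagnostics.get("exchange_acceptance", {})
    fig, ax = plt.subplots(figsize=(4, 3))
    ax.bar(list(rates), list(rates.values()), color="tab:green")
    ax.set_ylim(0, 1)
    ax.set_xlabel("replica pair")
    ax.set_ylabel("exchange acceptance")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
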
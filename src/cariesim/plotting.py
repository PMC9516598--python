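"""Optional figure rendering (requires matplotlib); off by default —
nothing in the pipeline imports this module unless asked to plot."""

from __future__ import annotations

from pathlib import Path


def plot_ce_plane(psa, reference: str, comparator: str, path) -> Path:
    """Scatter of incremental (effect, cost) pairs per PSA draw."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    i_ref = psa.strategy_index(reference)
    i_cmp = psa.strategy_index(comparator)
    de = psa.effects[:, i_cmp] - psa.effects[:, i_ref]
    dc = psa.costs[:, i_cmp] - psa.costs[:, i_ref]
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(de, dc, s=8, alpha=0.4)
    ax.axhline(0, color="k", lw=0.8)
    ax.axvline(0, color="k", lw=0.8)
    ax.set_xlabel("incremental retention (years)")
    ax.set_ylabel("incremental cost (euros)")
    ax.set_title(f"{comparator} vs {reference}")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def plot_ceac(curve, path) -> Path:
    """Acceptability per strategy over the willingness-to-pay grid."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for label, probs in curve.acceptability.items():
        ax.plot(curve.lambda_grid, probs, label=label)
    ax.set_xlabel("willingness to pay (euros / retention year)")
    ax.set_ylabel("probability cost-effective")
    ax.set_ylim(-0.02, 1.02)
    ax.legend()
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
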
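"""Sociogram export (convenience, not part of the tested analysis surface)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import networkx as nx

_MARKERS = ("s", "o", "^", "D")


def plot_sociogram(net: nx.Graph, path: str | Path, seed: int = 0) -> None:
    """Spring-layout sociogram: node shape by species, size by degree,
    edge width by SRI weight."""
    pos = nx.spring_layout(net, weight="weight", seed=seed)
    species = sorted({d.get("species", "?") for _, d in net.nodes(data=True)})
    fig, ax = plt.subplots(figsize=(7, 7))
    for marker, sp in zip(_MARKERS, species):
        nodes = [n for n, d in net.nodes(data=True) if d.get("species", "?") == sp]
        sizes = [60 + 25 * net.degree(n) for n in nodes]
        nx.draw_networkx_nodes(
            net, pos, nodelist=nodes, node_shape=marker, node_size=sizes,
            label=sp, ax=ax,
        )
    widths = [4 * d["weight"] for _, _, d in net.edges(data=True)]
    nx.draw_networkx_edges(net, pos, width=widths, alpha=0.4, ax=ax)
    ax.legend(loc="best")
    ax.set_axis_off()
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
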
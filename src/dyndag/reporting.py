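"""Result artefacts: the effect-distribution grid and the consensus DAG.

The consensus graph condenses edge posteriors into a displayable summary:
a within-slice pair is shown when the posterior mass of either orientation
totals at least the inclusion threshold, drawn single-headed toward the
dominant direction when that direction carries a large enough share of
the mass and double-headed otherwise (the data cannot resolve the
direction, typically because both orientations are Markov-equivalent).
Between-slice connections are always directed forward in time and drawn
dashed; line weight grows with the connection's posterior strength.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import networkx as nx
import numpy as np
import pandas as pd

from .effects import EffectDistribution
from .panel_io import ConfigurationError
from .sampler import EdgePosteriors


@dataclass(frozen=True)
class Connection:
    source: int
    target: int
    kind: str        # "directed" | "double" | "between"
    strength: float  # total posterior of the connection
    p_forward: float
    p_backward: float = 0.0


@dataclass
class ConsensusGraph:
    nodes: list[str]
    connections: list[Connection]
    include_threshold: float
    direction_ratio: float

    def within(self) -> list[Connection]:
        return [c for c in self.connections if c.kind != "between"]

    def between(self) -> list[Connection]:
        return [c for c in self.connections if c.kind == "between"]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.connections:
            rows.append({
                "source": self.nodes[c.source], "target": self.nodes[c.target],
                "kind": c.kind, "strength": c.strength,
                "p_forward": c.p_forward, "p_backward": c.p_backward,
            })
        return pd.DataFrame(rows, columns=["source", "target", "kind",
                                           "strength", "p_forward", "p_backward"])

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        for k, name in enumerate(self.nodes):
            g.add_node(name, index=k)
        for c in self.connections:
            g.add_edge(self.nodes[c.source], self.nodes[c.target],
                       kind=c.kind, strength=round(c.strength, 6),
                       p_forward=round(c.p_forward, 6),
                       p_backward=round(c.p_backward, 6))
        return g

    def to_graphml(self, path) -> None:
        nx.write_graphml(self.to_networkx(), path)

    def to_dot(self, path=None) -> str:
        lines = ["digraph consensus {"]
        for name in self.nodes:
            lines.append(f'  "{name}";')
        for c in self.connections:
            style = "dashed" if c.kind == "between" else "solid"
            dir_ = "both" if c.kind == "double" else "forward"
            lines.append(
                f'  "{self.nodes[c.source]}" -> "{self.nodes[c.target]}" '
                f'[style={style}, dir={dir_}, penwidth={0.5 + 4 * c.strength:.3f}, '
                f'label="{c.strength:.2f}"];'
            )
        lines.append("}")
        text = "\n".join(lines) + "\n"
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def build_consensus(posteriors: EdgePosteriors, names: list[str] | None = None,
                    include_threshold: float = 0.5,
                    direction_ratio: float = 0.8) -> ConsensusGraph:
    """Threshold edge posteriors into a consensus graph.

    Within-slice pair {i, j}: included when p(i->j) + p(j->i) >=
    ``include_threshold``; single-headed toward the dominant direction
    when max / total >= ``direction_ratio``, else double-headed.
    Between-slice edge i -> j: included when its posterior passes the
    threshold.
    """
    if not (0.0 <= include_threshold <= 1.0 and 0.0 <= direction_ratio <= 1.0):
        raise ConfigurationError("thresholds must be in [0, 1]")
    n = posteriors.within.shape[0]
    names = list(names) if names else [f"V{k + 1}" for k in range(n)]
    conns: list[Connection] = []
    for i in range(n):
        for j in range(i + 1, n):
            pij = float(posteriors.within[i, j])
            pji = float(posteriors.within[j, i])
            total = pij + pji
            if total < include_threshold or total == 0.0:
                continue
            if max(pij, pji) / total >= direction_ratio:
                a, b = (i, j) if pij >= pji else (j, i)
                conns.append(Connection(a, b, "directed", total,
                                        max(pij, pji), min(pij, pji)))
            else:
                a, b = (i, j) if pij >= pji else (j, i)
                conns.append(Connection(a, b, "double", total,
                                        max(pij, pji), min(pij, pji)))
    for i in range(n):
        for j in range(n):
            p = float(posteriors.between[i, j])
            if p >= include_threshold and p > 0.0:
                conns.append(Connection(i, j, "between", p, p))
    return ConsensusGraph(nodes=names, connections=conns,
                          include_threshold=include_threshold,
                          direction_ratio=direction_ratio)


def plot_effect_grid(effects: EffectDistribution, path,
                     display_range: tuple[float, float] = (-0.1, 0.5)) -> None:
    """n x n grid of per-pair effect densities.

    Rows are sources (prior slice), columns targets (subsequent slice);
    each cell sketches the draw distribution truncated to
    ``display_range``, marks zero with a red line, is shaded when the
    credible interval excludes zero, and is annotated with the posterior
    mean — the same number exported by ``EffectDistribution.to_frame``.
    """
    if effects.draws.size == 0:
        raise ValueError("empty effect distribution")
    ns, nt = len(effects.sources), len(effects.targets)
    lo, hi = display_range
    fig, axes = plt.subplots(ns, nt, figsize=(1.1 * nt + 1.2, 1.1 * ns + 1.2),
                             squeeze=False)
    grid = np.linspace(lo, hi, 41)
    for a in range(ns):
        for b in range(nt):
            ax = axes[a][b]
            d = np.clip(effects.draws[:, a, b], lo, hi)
            if np.ptp(d) < 1e-12:
                ax.axvline(float(d[0]), color="k", lw=1.2)
            else:
                ax.hist(d, bins=grid, density=True, histtype="stepfilled",
                        color="0.55", edgecolor="none")
            if effects.significant[a, b]:
                ax.set_facecolor("#fde8c8")
            ax.axvline(0.0, color="red", lw=0.8)
            ax.set_xlim(lo, hi)
            ax.set_yticks([])
            ax.set_xticks([])
            ax.text(0.97, 0.92, f"{effects.mean[a, b]:.2f}", ha="right",
                    va="top", transform=ax.transAxes, fontsize=6)
            if b == 0:
                ax.set_ylabel(effects.sources[a], fontsize=6, rotation=0,
                              ha="right", va="center")
            if a == 0:
                ax.set_title(effects.targets[b], fontsize=6)
    fig.suptitle("Causal effects of row variable (t) on column variable (t+1)",
                 fontsize=9)
    fig.tight_layout(rect=(0, 0, 1, 0.97))
    fig.savefig(path)
    plt.close(fig)


def plot_consensus_dag(graph: ConsensusGraph, path) -> None:
    """Two-column drawing of the consensus DBN.

    Slice t on the left, slice t + 1 on the right; within-slice
    connections are drawn solid inside each column (double-headed when
    the direction is unresolved), between-slice connections dashed across
    columns, with line width increasing monotonically in connection
    strength.
    """
    n = len(graph.nodes)
    fig, ax = plt.subplots(figsize=(8, 0.6 * max(n, 4) + 1.5))
    ys = np.linspace(1, 0, n)
    pos = {}
    for k, name in enumerate(graph.nodes):
        pos[("t", k)] = (0.12, ys[k])
        pos[("t1", k)] = (0.88, ys[k])

    def lw(strength):
        return 0.6 + 3.4 * strength

    for c in graph.within():
        for col in ("t", "t1"):
            x1, y1 = pos[(col, c.source)]
            x2, y2 = pos[(col, c.target)]
            bend = 0.18 if col == "t" else -0.18
            style = "<|-|>" if c.kind == "double" else "-|>"
            ax.annotate("", xy=(x2, y2), xytext=(x1, y1),
                        arrowprops=dict(arrowstyle=style, lw=lw(c.strength),
                                        color="0.2",
                                        connectionstyle=f"arc3,rad={bend}",
                                        shrinkA=14, shrinkB=14))
    for c in graph.between():
        x1, y1 = pos[("t", c.source)]
        x2, y2 = pos[("t1", c.target)]
        ax.annotate("", xy=(x2, y2), xytext=(x1, y1),
                    arrowprops=dict(arrowstyle="-|>", lw=lw(c.strength),
                                    color="0.35", linestyle="--",
                                    shrinkA=14, shrinkB=14))
    for (col, k), (x, y) in pos.items():
        ax.text(x, y, graph.nodes[k], ha="center", va="center", fontsize=8,
                bbox=dict(boxstyle="round,pad=0.25", fc="white", ec="0.4"))
    ax.text(0.12, 1.08, "slice t", ha="center", fontsize=10)
    ax.text(0.88, 1.08, "slice t+1", ha="center", fontsize=10)
    ax.set_xlim(-0.05, 1.05)
    ax.set_ylim(-0.08, 1.14)
    ax.axis("off")
    fig.savefig(path, bbox_inches="tight")
    plt.close(fig)
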
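"""Parallel-track genome plots: homology lines and paralogy arcs.

Two or three genomes are drawn as horizontal tracks of equidistant
vertices, one per gene occurrence.  Green lines connect homologous genes
(same name) in adjacent tracks, paired copy-to-copy by the gene-level
alignment so that duplicated genes connect consistently; red arcs link
duplicated copies of a gene within one track.  The plot spec is a plain
JSON-serialisable structure, rendered to SVG (deterministic text output)
or PNG with matplotlib.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
from matplotlib.patches import FancyArrowPatch

from .alignment import align_gene_orders
from .genomes_io import GeneOrder

__all__ = ["PlotSpec", "build_plot_spec", "render_plot"]


@dataclass
class PlotSpec:
    """Everything needed to draw 2-3 genomes as parallel tracks."""

    tracks: list[dict]  # {"organism_id", "occurrences": [{"position","name","strand"}]}
    homology_edges: list[tuple[int, int, int]] = field(default_factory=list)
    # (upper track index, position in upper, position in lower=index+1)
    paralogy_arcs: list[tuple[int, int, int]] = field(default_factory=list)
    # (track index, position, position)
    window: tuple[int, int] | None = None

    def to_json(self) -> str:
        return json.dumps(
            {
                "tracks": self.tracks,
                "homology_edges": [list(e) for e in self.homology_edges],
                "paralogy_arcs": [list(a) for a in self.paralogy_arcs],
                "window": list(self.window) if self.window else None,
            },
            indent=2,
            sort_keys=True,
        )


def build_plot_spec(
    genomes: Sequence[GeneOrder], window: tuple[int, int] | None = None
) -> PlotSpec:
    """Build the parallel-track spec for 2 or 3 genomes.

    Homology edges come from the match columns (same base name) of the
    pairwise alignment of adjacent tracks; paralogy arcs enumerate all
    same-name pairs within each track.  ``window`` is a half-open position
    range applied to every track; an occurrence with no partner inside the
    window simply has no edge.
    """
    if not 2 <= len(genomes) <= 3:
        raise ValueError("build_plot_spec takes 2 or 3 genomes")

    def inside(pos: int) -> bool:
        return window is None or window[0] <= pos < window[1]

    tracks = []
    for g in genomes:
        occs = [
            {"position": o.position, "name": o.display_name, "strand": o.strand}
            for o in g.occurrences
            if inside(o.position)
        ]
        tracks.append({"organism_id": g.organism_id, "occurrences": occs})
    if all(not t["occurrences"] for t in tracks):
        raise ValueError("window is empty for every track")

    edges: list[tuple[int, int, int]] = []
    for t in range(len(genomes) - 1):
        upper, lower = genomes[t], genomes[t + 1]
        aln = align_gene_orders(upper, lower, include_strand=False)
        up_syms, lo_syms = upper.symbols(), lower.symbols()
        for ai, bj in aln.columns:
            if ai is None or bj is None:
                continue
            if up_syms[ai][0] == lo_syms[bj][0] and inside(ai) and inside(bj):
                edges.append((t, ai, bj))

    arcs: list[tuple[int, int, int]] = []
    for t, g in enumerate(genomes):
        by_name: dict[str, list[int]] = {}
        for o in g.occurrences:
            if inside(o.position):
                by_name.setdefault(o.base_name, []).append(o.position)
        for positions in by_name.values():
            for p1, p2 in combinations(positions, 2):
                arcs.append((t, p1, p2))
    arcs.sort()
    return PlotSpec(tracks=tracks, homology_edges=edges, paralogy_arcs=arcs, window=window)


def render_plot(spec: PlotSpec, path: str, fmt: str = "svg") -> None:
    """Render a plot spec to SVG (default, deterministic) or PNG."""
    with plt.rc_context({"svg.hashsalt": "ancorder"}):
        n_tracks = len(spec.tracks)
        fig, ax = plt.subplots(figsize=(11, 1.8 * n_tracks + 1))
        ys = {t: n_tracks - 1 - t for t in range(n_tracks)}
        for t, track in enumerate(spec.tracks):
            y = ys[t]
            xs = [o["position"] for o in track["occurrences"]]
            if xs:
                ax.hlines(y, min(xs), max(xs), color="0.6", lw=0.8, zorder=1)
                ax.plot(xs, [y] * len(xs), "o", ms=3, color="black", zorder=3)
            ax.text(
                (min(xs) if xs else 0) - 0.6,
                y,
                track["organism_id"],
                ha="right",
                va="center",
                fontsize=9,
            )
        for t, pa, pb in spec.homology_edges:
            ax.plot([pa, pb], [ys[t], ys[t + 1]], color="green", lw=0.7, zorder=2)
        for t, p1, p2 in spec.paralogy_arcs:
            arc = FancyArrowPatch(
                (p1, ys[t]),
                (p2, ys[t]),
                connectionstyle="arc3,rad=0.35",
                color="red",
                lw=0.7,
                arrowstyle="-",
                zorder=2,
            )
            ax.add_patch(arc)
        ax.set_ylim(-0.8, n_tracks - 0.2)
        ax.set_yticks([])
        ax.set_xlabel("gene position")
        ax.spines[["left", "top", "right"]].set_visible(False)
        fig.tight_layout()
        fig.savefig(path, format=fmt, metadata={"Date": None} if fmt == "svg" else None)
        plt.close(fig)
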
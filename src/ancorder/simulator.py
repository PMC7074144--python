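"""Forward simulation of gene-order evolution along a tree, and scoring.

The generator emulates the situation in small organellar genomes: an
ancestral gene order of ~160 genes (chloroplast scale) evolves along a
rooted binary tree under four gene-level operations — insertion, deletion,
duplication and inversion of one gene or a block.  Event counts per branch
are Poisson-distributed (or fixed for scripted scenarios); positions are
uniform.  The full operation log is recorded per branch so that a history
can be replayed exactly, giving ground truth for recovery tests.

``score_reconstruction`` compares two node→gene-order maps (truth vs
prediction, or two tools' outputs) on gene content, copy numbers and
order.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .alignment import gestalt_ratio
from .genomes_io import GeneOrder, Phylogeny
from .inversions import InversionRegion
from .reconstruction import BranchEvents

__all__ = [
    "EvolutionConfig",
    "SimulatedHistory",
    "ComparisonReport",
    "simulate",
    "replay_branch",
    "score_reconstruction",
    "default_gene_pool",
]


def default_gene_pool(size: int = 400) -> tuple[str, ...]:
    """A pool of synthetic gene symbols (G001, G002, ...)."""
    return tuple(f"G{i:03d}" for i in range(1, size + 1))


@dataclass(frozen=True)
class EvolutionConfig:
    """Study conditions for the forward simulator.

    Defaults mirror a quiet organellar history: a 160-gene root (typical
    chloroplast gene count) with a handful of duplicated genes, and well
    under one event per branch and type, so most variation between close
    genomes is in copy numbers — the regime observed in Apiales-like data.
    """

    root_length: int = 160
    gene_name_pool: tuple[str, ...] = field(default_factory=default_gene_pool)
    insertion_mean: float = 0.2
    deletion_mean: float = 0.2
    duplication_mean: float = 0.5
    inversion_mean: float = 0.1
    inversion_len_range: tuple[int, int] = (2, 6)
    duplication_mode: str = "tandem"  # or "dispersed"
    seed: int = 0
    count_mode: str = "poisson"  # or "fixed" (counts = round(mean))
    max_events_per_branch: int | None = None
    deletion_targets: str = "any"  # or "duplicated" (copy-number-only regime)
    insertion_names: str = "novel"  # or "existing" (Fig-4-style hard cases)
    root_duplicates: int = 0  # genes of the root made two-copy up front

    def __post_init__(self) -> None:
        if self.root_length < 1:
            raise ValueError("root_length must be >= 1")
        if not self.gene_name_pool:
            raise ValueError("empty gene name pool")
        if self.inversion_len_range[1] < self.inversion_len_range[0]:
            raise ValueError("inversion length range: max < min")
        if self.root_length + self.root_duplicates > len(self.gene_name_pool) and (
            self.insertion_names == "novel"
        ):
            pass  # insertions will fall back to existing names when exhausted


@dataclass
class SimulatedHistory:
    tree: Phylogeny
    true_orders: dict[str, GeneOrder]
    true_events: list[BranchEvents]
    config: EvolutionConfig


def _apply_op(symbols: list, op: tuple) -> None:
    kind = op[0]
    if kind == "ins":
        _, pos, name, strand = op
        symbols.insert(pos, (name, strand))
    elif kind == "del":
        symbols.pop(op[1])
    elif kind == "dup":
        _, src, dst = op
        symbols.insert(dst, symbols[src])
    elif kind == "inv":
        _, start, end = op
        symbols[start:end] = [(n, -s) for n, s in reversed(symbols[start:end])]
    else:  # pragma: no cover
        raise ValueError(f"unknown operation {kind!r}")


def replay_branch(parent: GeneOrder, events: BranchEvents, child_id: str) -> GeneOrder:
    """Apply a branch's raw operation log to the parent gene order."""
    symbols = list(parent.symbols())
    for op in events.operations:
        _apply_op(symbols, op)
    return GeneOrder.from_symbols(child_id, symbols)


def _draw_counts(rng: np.random.Generator, config: EvolutionConfig) -> dict[str, int]:
    means = {
        "ins": config.insertion_mean,
        "del": config.deletion_mean,
        "dup": config.duplication_mean,
        "inv": config.inversion_mean,
    }
    if config.count_mode == "fixed":
        counts = {k: int(round(v)) for k, v in means.items()}
    else:
        counts = {k: int(rng.poisson(v)) for k, v in means.items()}
    cap = config.max_events_per_branch
    if cap is not None:
        total = sum(counts.values())
        while total > cap:
            nonzero = [k for k, v in counts.items() if v > 0]
            victim = nonzero[int(rng.integers(len(nonzero)))]
            counts[victim] -= 1
            total -= 1
    return counts


def simulate(config: EvolutionConfig, tree: Phylogeny) -> SimulatedHistory:
    """Evolve gene orders down a labeled tree; fully reproducible from the seed.

    Within a branch, events apply in the fixed order
    insertion → deletion → duplication → inversion.  Deletions never empty
    a genome; with ``deletion_targets="duplicated"`` they only hit genes
    currently in >= 2 copies (pure copy-number evolution).  Inserted genes
    draw novel names from the pool's unused suffix by default, so that
    insertions are recognisable in the truth.
    """
    from .genomes_io import label_internal_nodes

    if any(n.label is None for n in tree.internal_nodes()):
        label_internal_nodes(tree)
    rng = np.random.default_rng(config.seed)

    root_syms = [(name, 1) for name in config.gene_name_pool[: config.root_length]]
    used = set(config.gene_name_pool[: config.root_length])
    if config.root_duplicates:
        dup_idx = rng.choice(
            config.root_length, size=min(config.root_duplicates, config.root_length),
            replace=False,
        )
        for idx in sorted(dup_idx, reverse=True):
            root_syms.insert(int(idx) + 1, root_syms[int(idx)])
    unused = [n for n in config.gene_name_pool if n not in used]

    true_orders: dict[str, GeneOrder] = {}
    true_events: list[BranchEvents] = []
    root = tree.root
    true_orders[root.node_id] = GeneOrder.from_symbols(root.node_id, root_syms)

    def name_for_insertion(symbols) -> str:
        if config.insertion_names == "novel" and unused:
            return unused.pop(0)
        present = sorted({n for n, _ in symbols})
        return present[int(rng.integers(len(present)))]

    for node in tree.preorder():
        for child in node.children:
            parent_order = true_orders[node.node_id]
            symbols = list(parent_order.symbols())
            ops: list[tuple] = []
            led_deletions: list[tuple[str, int]] = []
            counts = _draw_counts(rng, config)
            for _ in range(counts["ins"]):
                pos = int(rng.integers(len(symbols) + 1))
                strand = 1 if rng.random() < 0.5 else -1
                op = ("ins", pos, name_for_insertion(symbols), strand)
                _apply_op(symbols, op)
                ops.append(op)
            for _ in range(counts["del"]):
                if len(symbols) <= 1:
                    break
                if config.deletion_targets == "duplicated":
                    cnt = Counter(n for n, _ in symbols)
                    cand = [i for i, (n, _) in enumerate(symbols) if cnt[n] >= 2]
                    if not cand:
                        continue
                    pos = cand[int(rng.integers(len(cand)))]
                else:
                    pos = int(rng.integers(len(symbols)))
                deleted_name = symbols[pos][0]
                op = ("del", pos)
                _apply_op(symbols, op)
                ops.append(op)
                led_deletions.append((deleted_name, pos))
            for _ in range(counts["dup"]):
                src = int(rng.integers(len(symbols)))
                if config.duplication_mode == "tandem":
                    dst = src + 1
                else:
                    dst = int(rng.integers(len(symbols) + 1))
                op = ("dup", src, dst)
                _apply_op(symbols, op)
                ops.append(op)
            for _ in range(counts["inv"]):
                lo, hi = config.inversion_len_range
                if len(symbols) < lo:
                    continue
                length = int(rng.integers(lo, min(hi, len(symbols)) + 1))
                start = int(rng.integers(len(symbols) - length + 1))
                op = ("inv", start, start + length)
                _apply_op(symbols, op)
                ops.append(op)

            child_order = GeneOrder.from_symbols(child.node_id, symbols)
            true_orders[child.node_id] = child_order
            led = BranchEvents(branch=(node.node_id, child.node_id), operations=ops)
            led.deletions.extend(led_deletions)
            for op in ops:
                if op[0] == "ins":
                    led.insertions.append((op[2], op[1]))
                elif op[0] == "inv":
                    led.inversions.append(
                        InversionRegion(op[1], op[2], op[1], op[2])
                    )
            pc, cc = parent_order.base_counts(), child_order.base_counts()
            for base in sorted(set(pc) | set(cc)):
                if pc[base] != cc[base]:
                    led.copy_number_changes.append((base, pc[base], cc[base]))
            true_events.append(led)

    return SimulatedHistory(
        tree=tree, true_orders=true_orders, true_events=true_events, config=config
    )


# ---------------------------------------------------------------------------
# Scoring two reconstructions against each other
# ---------------------------------------------------------------------------


@dataclass
class ComparisonReport:
    """Per-node agreement between two node→gene-order maps."""

    content_jaccard: dict[str, float]
    copy_number_match: dict[str, float]
    order_similarity: dict[str, float]
    disagreements: list[tuple[str, str, int, int]]  # (node, gene, count_a, count_b)

    def to_dict(self) -> dict:
        return {
            "content_jaccard": self.content_jaccard,
            "copy_number_match": self.copy_number_match,
            "order_similarity": self.order_similarity,
            "disagreements": [list(d) for d in self.disagreements],
        }


def _multiset_jaccard(a: Counter, b: Counter) -> float:
    union = sum((a | b).values())
    if union == 0:
        return 1.0
    return sum((a & b).values()) / union


def score_reconstruction(
    reference: dict[str, GeneOrder], predicted: dict[str, GeneOrder]
) -> ComparisonReport:
    """Compare two reconstructions node by node on shared node labels.

    Metrics per node: multiset Jaccard of gene contents, fraction of genes
    with exactly matching copy number, and the Gestalt order-similarity
    ratio.  Disagreements list every (node, gene, count_ref, count_pred)
    with differing counts, sorted by node then gene.
    """
    shared = sorted(set(reference) & set(predicted))
    if not shared:
        raise ValueError("no shared node labels between the two reconstructions")
    jac: dict[str, float] = {}
    cn: dict[str, float] = {}
    sim: dict[str, float] = {}
    disagreements: list[tuple[str, str, int, int]] = []
    for node in shared:
        a, b = reference[node], predicted[node]
        ca, cb = a.base_counts(), b.base_counts()
        jac[node] = _multiset_jaccard(ca, cb)
        genes = sorted(set(ca) | set(cb))
        cn[node] = (
            sum(1 for g in genes if ca[g] == cb[g]) / len(genes) if genes else 1.0
        )
        sim[node] = gestalt_ratio(a, b)
        for g in genes:
            if ca[g] != cb[g]:
                disagreements.append((node, g, ca[g], cb[g]))
    disagreements.sort()
    return ComparisonReport(jac, cn, sim, disagreements)
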
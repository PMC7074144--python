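"""Gene-order tables and phylogenetic trees: parsing, validation, labeling.

A genome is abstracted as its *gene order*: the ordered list of annotated
gene names, each with a strand, allowing duplicated names (the situation in
chloroplasts, where the inverted repeat carries multiple copies of genes
such as YCF68).  Duplicate copies are distinguished by a left-to-right
``occurrence_index``, mirroring the ``YCF68`` / ``YCF68_1`` display
convention used by annotation pipelines.

Trees are read from Newick (via dendropy) into a light-weight rooted node
structure whose internal nodes are labeled alphabetically in post-order
(``a``, ``b``, ... then ``aa``, ``ab``, ...), children before parents.
"""

from __future__ import annotations

import io
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import dendropy
import pandas as pd

__all__ = [
    "GeneOccurrence",
    "GeneOrder",
    "PhyloNode",
    "Phylogeny",
    "GeneOrderError",
    "TreeError",
    "parse_gene_orders",
    "write_gene_orders",
    "parse_newick",
    "label_internal_nodes",
]

STRAND_TOKENS = {"+": 1, "-": -1}
STRAND_SYMBOLS = {1: "+", -1: "-"}


class GeneOrderError(ValueError):
    """Raised on malformed gene-order input."""


class TreeError(ValueError):
    """Raised on malformed tree input."""


@dataclass(frozen=True)
class GeneOccurrence:
    """One positioned, strand-annotated copy of a named gene in a genome."""

    base_name: str
    occurrence_index: int
    strand: int  # +1 or -1
    position: int  # 0-based rank in the genome's gene list

    def __post_init__(self) -> None:
        if self.strand not in (1, -1):
            raise GeneOrderError(f"strand must be +1 or -1, got {self.strand!r}")
        if self.occurrence_index < 0 or self.position < 0:
            raise GeneOrderError("occurrence_index and position must be >= 0")

    @property
    def display_name(self) -> str:
        """``YCF68`` for the first copy, ``YCF68_1`` for the second, ..."""
        if self.occurrence_index == 0:
            return self.base_name
        return f"{self.base_name}_{self.occurrence_index}"

    def key(self, include_strand: bool = True):
        """Matching key: copy identity is deliberately not part of it."""
        return (self.base_name, self.strand) if include_strand else self.base_name


@dataclass(frozen=True)
class GeneOrder:
    """An organism's ordered list of gene occurrences.

    Invariants (checked on construction): positions are exactly ``0..n-1``
    and each ``occurrence_index`` equals the number of earlier occurrences
    of the same ``base_name``.
    """

    organism_id: str
    occurrences: tuple[GeneOccurrence, ...]

    def __post_init__(self) -> None:
        if not self.occurrences:
            raise GeneOrderError(f"empty genome for organism {self.organism_id!r}")
        counts: Counter[str] = Counter()
        for pos, occ in enumerate(self.occurrences):
            if occ.position != pos:
                raise GeneOrderError(
                    f"{self.organism_id}: position {occ.position} at rank {pos}; "
                    "positions must be 0..n-1 without gaps"
                )
            if occ.occurrence_index != counts[occ.base_name]:
                raise GeneOrderError(
                    f"{self.organism_id}: bad occurrence_index for {occ.base_name} "
                    f"at position {pos}"
                )
            counts[occ.base_name] += 1

    @classmethod
    def from_symbols(
        cls, organism_id: str, symbols: Iterable[tuple[str, int]]
    ) -> "GeneOrder":
        """Build from ``(base_name, strand)`` pairs, deriving indices/positions."""
        counts: Counter[str] = Counter()
        occs = []
        for pos, (name, strand) in enumerate(symbols):
            occs.append(GeneOccurrence(name, counts[name], strand, pos))
            counts[name] += 1
        return cls(organism_id, tuple(occs))

    def __len__(self) -> int:
        return len(self.occurrences)

    def __iter__(self) -> Iterator[GeneOccurrence]:
        return iter(self.occurrences)

    def keys(self, include_strand: bool = True) -> tuple:
        return tuple(o.key(include_strand) for o in self.occurrences)

    def symbols(self) -> tuple[tuple[str, int], ...]:
        return tuple((o.base_name, o.strand) for o in self.occurrences)

    def copy_count(self, base_name: str) -> int:
        return sum(1 for o in self.occurrences if o.base_name == base_name)

    def base_counts(self) -> Counter:
        return Counter(o.base_name for o in self.occurrences)

    def rename(self, organism_id: str) -> "GeneOrder":
        return GeneOrder.from_symbols(organism_id, self.symbols())


# ---------------------------------------------------------------------------
# Gene-order TSV dialect: columns organism_id, position, gene, strand;
# '#' comments; strand tokens '+' / '-'.
# ---------------------------------------------------------------------------

_COLUMNS = ["organism_id", "position", "gene", "strand"]


def parse_gene_orders(source) -> list[GeneOrder]:
    """Read gene-order TSV from a path, file object, or string of text.

    Gene names are uppercased on ingest.  The ``position`` column is
    optional; when present it defines the within-organism ordering (and is
    normalised to ``0..n-1``), otherwise file order is used.
    """
    if isinstance(source, str) and "\n" in source:
        source = io.StringIO(source)
    df = pd.read_csv(source, sep="\t", comment="#", dtype=str)
    missing = {"organism_id", "gene", "strand"} - set(df.columns)
    if missing:
        raise GeneOrderError(f"missing required columns: {sorted(missing)}")
    orders: list[GeneOrder] = []
    for organism_id, grp in df.groupby("organism_id", sort=False):
        if "position" in grp.columns and grp["position"].notna().all():
            pos = grp["position"].astype(int)
            if pos.duplicated().any():
                dup = int(pos[pos.duplicated()].iloc[0])
                raise GeneOrderError(
                    f"{organism_id}: duplicate position {dup}"
                )
            grp = grp.assign(_pos=pos.to_numpy()).sort_values("_pos", kind="stable")
        symbols = []
        for row in grp.itertuples(index=True):
            strand_tok = row.strand
            if strand_tok not in STRAND_TOKENS:
                raise GeneOrderError(
                    f"{organism_id}: unknown strand symbol {strand_tok!r} "
                    f"in row {row.Index}"
                )
            if not isinstance(row.gene, str) or not row.gene:
                raise GeneOrderError(f"{organism_id}: empty gene name in row {row.Index}")
            symbols.append((row.gene.upper(), STRAND_TOKENS[strand_tok]))
        if not symbols:
            raise GeneOrderError(f"empty genome for organism {organism_id!r}")
        orders.append(GeneOrder.from_symbols(str(organism_id), symbols))
    return orders


def write_gene_orders(genomes: Sequence[GeneOrder], sink=None) -> str:
    """Write gene orders as TSV; returns the text (and writes to *sink* if given).

    Round-trip safe: ``parse_gene_orders(write_gene_orders(X)) == X``.
    """
    rows = [
        (g.organism_id, o.position, o.base_name, STRAND_SYMBOLS[o.strand])
        for g in genomes
        for o in g.occurrences
    ]
    df = pd.DataFrame(rows, columns=_COLUMNS)
    text = df.to_csv(sep="\t", index=False)
    if sink is not None:
        if hasattr(sink, "write"):
            sink.write(text)
        else:
            with open(sink, "w", encoding="utf-8") as fh:
                fh.write(text)
    return text


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------


@dataclass
class PhyloNode:
    """A node of a rooted phylogeny.

    Leaves carry ``organism_id``; internal nodes get an alphabetical
    ``label`` from :func:`label_internal_nodes`.  ``node_id`` is the
    organism id for leaves and the label for internal nodes.
    """

    organism_id: str | None = None
    label: str | None = None
    children: list["PhyloNode"] = field(default_factory=list)
    parent: "PhyloNode | None" = field(default=None, repr=False)
    edge_length: float | None = None
    support: float | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    @property
    def node_id(self) -> str | None:
        return self.organism_id if self.is_leaf else self.label


@dataclass
class Phylogeny:
    """Rooted tree with a leaf <-> organism mapping and labeled ancestors."""

    root: PhyloNode

    def postorder(self) -> Iterator[PhyloNode]:
        def walk(node: PhyloNode) -> Iterator[PhyloNode]:
            for child in node.children:
                yield from walk(child)
            yield node

        return walk(self.root)

    def preorder(self) -> Iterator[PhyloNode]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def leaves(self) -> list[PhyloNode]:
        return [n for n in self.postorder() if n.is_leaf]

    def internal_nodes(self) -> list[PhyloNode]:
        return [n for n in self.postorder() if not n.is_leaf]

    def is_binary(self) -> bool:
        return all(len(n.children) == 2 for n in self.internal_nodes())

    def find(self, node_id: str) -> PhyloNode:
        for n in self.postorder():
            if n.node_id == node_id:
                return n
        raise KeyError(node_id)

    def path_edge_count(self, a: PhyloNode, b: PhyloNode) -> int:
        """Number of edges on the path between two nodes."""
        depth = {}
        n: PhyloNode | None = a
        d = 0
        while n is not None:
            depth[id(n)] = d
            n, d = n.parent, d + 1
        n, d = b, 0
        while n is not None:
            if id(n) in depth:
                return depth[id(n)] + d
            n, d = n.parent, d + 1
        raise TreeError("nodes are not in the same tree")

    def resolve_polytomies(self) -> None:
        """Arbitrarily resolve polytomies into a left-leaning caterpillar."""
        for node in list(self.postorder()):
            while len(node.children) > 2:
                left, second = node.children[0], node.children[1]
                merged = PhyloNode(children=[left, second], parent=node)
                left.parent = second.parent = merged
                node.children = [merged] + node.children[2:]

    def to_newick(self) -> str:
        def fmt(node: PhyloNode) -> str:
            if node.is_leaf:
                core = node.organism_id or ""
            else:
                inner = ",".join(fmt(c) for c in node.children)
                core = f"({inner}){node.label or ''}"
            if node.edge_length is not None:
                core += f":{node.edge_length:g}"
            return core

        return fmt(self.root) + ";"


def parse_newick(text: str) -> Phylogeny:
    """Parse a Newick string (or path to one) into a rooted :class:`Phylogeny`.

    Numeric internal-node labels are interpreted as bootstrap supports.
    """
    if "(" not in text:
        with open(text, encoding="utf-8") as fh:
            text = fh.read()
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises its own hierarchy
        raise TreeError(f"malformed Newick: {exc}") from exc

    def convert(dnode) -> PhyloNode:
        node = PhyloNode(edge_length=dnode.edge.length)
        if dnode.is_leaf():
            node.organism_id = (
                dnode.taxon.label if dnode.taxon is not None else dnode.label
            )
            if not node.organism_id:
                raise TreeError("leaf without a name")
        else:
            raw = dnode.label
            if raw:
                try:
                    node.support = float(raw)
                except ValueError:
                    node.label = raw
            for child in dnode.child_nodes():
                cnode = convert(child)
                cnode.parent = node
                node.children.append(cnode)
        return node

    root = convert(dtree.seed_node)
    tree = Phylogeny(root)
    names = [leaf.organism_id for leaf in tree.leaves()]
    dup = [n for n, c in Counter(names).items() if c > 1]
    if dup:
        raise TreeError(f"duplicate leaf names: {dup}")
    return tree


def _label_sequence() -> Iterator[str]:
    """a, b, ..., z, aa, ab, ... (bijective base-26, lowercase)."""
    i = 0
    while True:
        i += 1
        n, out = i, ""
        while n:
            n, r = divmod(n - 1, 26)
            out = chr(ord("a") + r) + out
        yield out


def label_internal_nodes(tree: Phylogeny) -> Phylogeny:
    """Label internal nodes alphabetically, bottom-up (post-order).

    Children are visited in the order written in the Newick source, so the
    labeling is deterministic and idempotent for a fixed tree.
    """
    labels = _label_sequence()
    for node in tree.postorder():
        if not node.is_leaf:
            node.label = next(labels)
    return tree
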
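"""Bottom-up ancestral gene-order inference with sister/cousin voting.

The procedure walks a rooted binary tree from the leaves to the root:

1.  Among the *cherries* (internal nodes whose two children are already
    resolved), pick the pair of sisters with the smallest gene-level
    edit distance.
2.  Order every other currently resolved lineage as a *cousin* list, by
    topological proximity to the cherry, breaking ties with the edit
    distance and then lexicographically.
3.  Align the two sisters gene-by-gene.  Matched columns go straight into
    the ancestor γ.  Each conflict column is put to a vote: cousins are
    consulted in order, and the first cousin agreeing with one sister
    decides.  A gene supported by no cousin is excluded from γ and called
    an insertion on the branch that carries it.
4.  Per-gene copy numbers of γ are reconciled by the same cousin vote on
    counts (``resolve_copy_number``), reproducing the YCF1/YCF68/ORF56
    style of decision.
5.  The cherry is replaced by its ancestor and the loop repeats until the
    root is reconstructed.  Every parent→child branch gets an event ledger
    (insertions, deletions, copy-number changes, inversions) satisfying
    ``|child| = |parent| + insertions - deletions`` in gene copies.

Inverted regions between the two sisters are detected first and oriented
by the first informative cousin; the disagreeing sister is rewritten into
the ancestral orientation before column voting, and the inversion event is
charged to its branch.
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

from .alignment import (
    Scoring,
    UNIT_SCORING,
    align_gene_orders,
    gene_order_distance,
)
from .genomes_io import GeneOrder, PhyloNode, Phylogeny
from .inversions import InversionRegion, detect_inversions, flip_slice, _block_support

__all__ = [
    "AncestorState",
    "BranchEvents",
    "ReconstructionResult",
    "ReconstructionParams",
    "select_sister_pair",
    "order_cousins",
    "resolve_copy_number",
    "infer_pair_ancestor",
    "reconstruct_all",
    "event_ledger",
]

logger = logging.getLogger(__name__)


@dataclass
class ReconstructionParams:
    """Tunables of the voting procedure."""

    scoring: Scoring = UNIT_SCORING
    max_cousins: int | None = None  # None: consult all cousins in order
    min_inversion_len: int = 2

    def to_dict(self) -> dict:
        return {
            "scoring": {
                "match": self.scoring.match,
                "mismatch": self.scoring.mismatch,
                "gap": self.scoring.gap,
            },
            "max_cousins": self.max_cousins,
            "min_inversion_len": self.min_inversion_len,
        }


@dataclass
class AncestorState:
    """Inferred gene order γ at one internal node, with per-gene provenance."""

    node_label: str
    gene_order: GeneOrder
    provenance: dict[int, str] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)


@dataclass
class BranchEvents:
    """Ledger of rearrangement events on one parent→child branch."""

    branch: tuple[str, str]  # (parent_label, child_id)
    insertions: list[tuple[str, int]] = field(default_factory=list)
    deletions: list[tuple[str, int]] = field(default_factory=list)
    copy_number_changes: list[tuple[str, int, int]] = field(default_factory=list)
    inversions: list[InversionRegion] = field(default_factory=list)
    # Ordered raw operation log (used by the simulator for exact replay).
    operations: list[tuple] = field(default_factory=list)

    @property
    def n_insertions(self) -> int:
        return len(self.insertions)

    @property
    def n_deletions(self) -> int:
        return len(self.deletions)


@dataclass
class ReconstructionResult:
    tree: Phylogeny
    states: dict[str, AncestorState]
    ledgers: list[BranchEvents]
    order_of_resolution: list[str]
    params: ReconstructionParams = field(default_factory=ReconstructionParams)

    def ancestor_orders(self) -> dict[str, GeneOrder]:
        return {label: st.gene_order for label, st in self.states.items()}

    def events_table(self) -> str:
        """Events TSV: ``branch type gene parent_pos child_pos detail``."""
        lines = ["branch\ttype\tgene\tparent_pos\tchild_pos\tdetail"]
        for led in self.ledgers:
            branch = f"{led.branch[0]}->{led.branch[1]}"
            for name, pos in led.insertions:
                lines.append(f"{branch}\tinsertion\t{name}\t-\t{pos}\t")
            for name, pos in led.deletions:
                lines.append(f"{branch}\tdeletion\t{name}\t{pos}\t-\t")
            for name, pc, cc in led.copy_number_changes:
                lines.append(f"{branch}\tcopy_number\t{name}\t-\t-\t{pc}->{cc}")
            for reg in led.inversions:
                lines.append(
                    f"{branch}\tinversion\t-\t{reg.a_start}\t{reg.b_start}\t"
                    f"len={reg.length}"
                )
        return "\n".join(lines) + "\n"

    def manifest(self) -> str:
        return json.dumps(
            {
                "params": self.params.to_dict(),
                "order_of_resolution": self.order_of_resolution,
            },
            indent=2,
            sort_keys=True,
        )


# ---------------------------------------------------------------------------
# Step 2: genome selection
# ---------------------------------------------------------------------------


def _cherries(tree: Phylogeny, states: dict[str, GeneOrder]) -> list[PhyloNode]:
    out = []
    for node in tree.postorder():
        if node.is_leaf or node.node_id in states:
            continue
        if all(c.node_id in states for c in node.children):
            out.append(node)
    return out


def select_sister_pair(
    tree: Phylogeny, states: dict[str, GeneOrder]
) -> tuple[PhyloNode, PhyloNode]:
    """The cherry whose two resolved children minimise the gene edit distance.

    Ties are broken lexicographically on the sorted pair of child ids.
    """
    best = None
    for cherry in _cherries(tree, states):
        c1, c2 = cherry.children[0], cherry.children[1]
        d = gene_order_distance(states[c1.node_id], states[c2.node_id])
        key = (d, tuple(sorted((c1.node_id, c2.node_id))))
        if best is None or key < best[0]:
            best = (key, (c1, c2))
    if best is None:
        raise ValueError("no cherry with two resolved children")
    return best[1]


def order_cousins(
    tree: Phylogeny,
    cherry: PhyloNode,
    states: dict[str, GeneOrder],
) -> list[PhyloNode]:
    """Resolved non-sister lineages ordered by proximity to the cherry.

    Sort key: number of tree edges to the cherry node, then the smaller
    edit distance to either sister, then node id.
    """
    sisters = {c.node_id for c in cherry.children}
    sister_orders = [states[c.node_id] for c in cherry.children]
    active = []
    for node in tree.postorder():
        nid = node.node_id
        if nid in states and nid not in sisters:
            # active = resolved but not absorbed into a resolved parent
            if node.parent is None or node.parent.node_id not in states:
                active.append(node)
    def key(node: PhyloNode):
        topo = tree.path_edge_count(node, cherry)
        d = min(gene_order_distance(states[node.node_id], s) for s in sister_orders)
        return (topo, d, node.node_id)

    return sorted(active, key=key)


# ---------------------------------------------------------------------------
# Copy-number voting (the YCF1 / YCF68 / ORF56 rule)
# ---------------------------------------------------------------------------


def resolve_copy_number(c1: int, c2: int, cousin_counts: Sequence[int]) -> int:
    """Ancestral copy count of one gene given sister counts and cousin votes.

    * Sisters agree → that count, no cousin consulted.
    * Otherwise walk cousins in order; the first cousin whose count equals
      one sister's count settles the vote.
    * No exact agreement, but the gene is present in the first cousin and
      in exactly one sister → presence wins and the ancestral count is
      taken from the sister carrying the gene.
    * Cousins exhausted → ``min(c1, c2)`` (parsimony: do not posit copies
      no relative supports).
    """
    if c1 == c2:
        return c1
    for c3 in cousin_counts:
        if c3 == c1 or c3 == c2:
            return c3
    if cousin_counts and cousin_counts[0] > 0 and (c1 > 0) != (c2 > 0):
        return c1 if c1 > 0 else c2
    return min(c1, c2)


# ---------------------------------------------------------------------------
# Step 3: gene investigation
# ---------------------------------------------------------------------------


def _vote_gap(carrier_idx, carrier_syms, cousin_syms_list, aln_cache, max_cousins):
    """Vote on a gene present in only one sister.

    Each cousin is aligned to the carrier sister; a cousin matching the
    disputed gene at the homologous column supports presence, a gap there
    supports absence, and a different gene is a third pattern that passes
    the vote to the next cousin.  Returns True (keep), False (drop) or
    None (undecided).
    """
    consult = cousin_syms_list if max_cousins is None else cousin_syms_list[:max_cousins]
    for k, csym in enumerate(consult):
        key = ("carrier", id(carrier_syms), k)
        if key not in aln_cache:
            aln_cache[key] = align_gene_orders(carrier_syms, csym)
        aln = aln_cache[key]
        for ai, cj in aln.columns:
            if ai == carrier_idx:
                if cj is None:
                    return False
                if csym[cj] == carrier_syms[carrier_idx]:
                    return True
                break  # third pattern: ask the next cousin
    return None


def infer_pair_ancestor(
    U1: GeneOrder,
    U2: GeneOrder,
    cousins: Sequence[GeneOrder],
    params: ReconstructionParams | None = None,
    node_label: str = "ancestor",
) -> tuple[AncestorState, BranchEvents, BranchEvents]:
    """Infer the ancestor γ of two sister gene orders by cousin voting.

    Returns the ancestral state and one event ledger per sister branch.
    The ledgers satisfy ``|child| = |γ| + insertions - deletions``.
    """
    params = params or ReconstructionParams()
    u1 = list(U1.symbols())
    u2 = list(U2.symbols())
    cousin_syms = [list(c.symbols()) for c in cousins]
    warnings: list[str] = []

    # --- inversion normalisation -------------------------------------------------
    inv_u1: list[InversionRegion] = []
    inv_u2: list[InversionRegion] = []
    for reg in detect_inversions(u1, u2, params.min_inversion_len):
        a_slice = u1[reg.a_start : reg.a_end]
        b_slice = u2[reg.b_start : reg.b_end]
        orientation = "A"
        informative = False
        for csym in cousin_syms:
            sa = _block_support(a_slice, csym)
            sb = _block_support(b_slice, csym)
            if sa != sb:
                orientation = "A" if sa > sb else "B"
                informative = True
                break
        if not informative and cousins:
            warnings.append(
                f"inversion at U1[{reg.a_start}:{reg.a_end}]: no informative "
                "cousin; kept the first sister's orientation"
            )
        if orientation == "A":
            u2[reg.b_start : reg.b_end] = flip_slice(b_slice)
            inv_u2.append(reg)
        else:
            u1[reg.a_start : reg.a_end] = flip_slice(a_slice)
            inv_u1.append(reg)

    # --- column voting -----------------------------------------------------------
    aln = align_gene_orders(u1, u2, params.scoring)
    reference_is_u1 = len(u1) >= len(u2)
    aln_cache: dict = {}
    gamma: list[tuple[int, int, tuple[str, int], str]] = []  # (col, side, sym, prov)
    excluded: list[tuple[int, int, tuple[str, int]]] = []  # (col, side, sym)
    if not cousins and any(
        ai is None or bj is None or u1[ai] != u2[bj] for ai, bj in aln.columns
    ):
        warnings.append("conflicts with no cousins: treated as insertions")

    for col, (ai, bj) in enumerate(aln.columns):
        if ai is not None and bj is not None and u1[ai] == u2[bj]:
            gamma.append((col, 0, u1[ai], "matched"))
            continue
        if ai is not None and bj is None:
            verdict = _vote_gap(ai, u1, cousin_syms, aln_cache, params.max_cousins)
            if verdict:
                gamma.append((col, 0, u1[ai], "cousin_vote"))
            else:
                excluded.append((col, 0, u1[ai]))
        elif bj is not None and ai is None:
            verdict = _vote_gap(bj, u2, cousin_syms, aln_cache, params.max_cousins)
            if verdict:
                gamma.append((col, 1, u2[bj], "cousin_vote"))
            else:
                excluded.append((col, 1, u2[bj]))
        else:  # mismatch column: reference-brother lookup
            ref_idx, ref_syms, ref_side = (ai, u1, 0) if reference_is_u1 else (bj, u2, 1)
            other_sym, other_side = (u2[bj], 1) if reference_is_u1 else (u1[ai], 0)
            decided = False
            consult = (
                cousin_syms
                if params.max_cousins is None
                else cousin_syms[: params.max_cousins]
            )
            for k, csym in enumerate(consult):
                key = ("carrier", id(ref_syms), k)
                if key not in aln_cache:
                    aln_cache[key] = align_gene_orders(ref_syms, csym)
                caln = aln_cache[key]
                hit = next(
                    (cj for ri, cj in caln.columns if ri == ref_idx), None
                )
                if hit is None:
                    continue
                if csym[hit] == ref_syms[ref_idx]:
                    gamma.append((col, ref_side, ref_syms[ref_idx], "cousin_vote"))
                    excluded.append((col, other_side, other_sym))
                    decided = True
                    break
                if csym[hit] == other_sym:
                    gamma.append((col, other_side, other_sym, "cousin_vote"))
                    excluded.append((col, ref_side, ref_syms[ref_idx]))
                    decided = True
                    break
            if not decided:  # exhausted: exclude both disputed genes
                excluded.append((col, ref_side, ref_syms[ref_idx]))
                excluded.append((col, other_side, other_sym))

    # --- copy-number reconciliation ----------------------------------------------
    n1 = Counter(name for name, _ in u1)
    n2 = Counter(name for name, _ in u2)
    for base in sorted(set(n1) | set(n2)):
        c1, c2 = n1[base], n2[base]
        if c1 == c2:
            continue
        target = resolve_copy_number(
            c1, c2, [sum(1 for nm, _ in cs if nm == base) for cs in cousin_syms]
        )
        current = sum(1 for _, _, (nm, _s), _p in gamma if nm == base)
        if current < target:
            donor_side = 0 if c1 >= c2 else 1
            pool = sorted(
                (e for e in excluded if e[2][0] == base and e[1] == donor_side),
                key=lambda e: e[0],
            )
            for entry in pool[: target - current]:
                gamma.append((entry[0], entry[1], entry[2], "copy_number"))
                excluded.remove(entry)
        elif current > target:
            removable = sorted(
                (g for g in gamma if g[2][0] == base),
                key=lambda g: (g[3] == "matched", g[0]),  # drop voted copies first
            )
            for entry in removable[: current - target]:
                gamma.remove(entry)
                excluded.append((entry[0], entry[1], entry[2]))

    gamma.sort(key=lambda g: (g[0], g[1]))
    state = AncestorState(
        node_label=node_label,
        gene_order=GeneOrder.from_symbols(node_label, [g[2] for g in gamma]),
        provenance={pos: g[3] for pos, g in enumerate(gamma)},
        warnings=warnings,
    )

    ev1 = event_ledger(state.gene_order, GeneOrder.from_symbols(U1.organism_id, u1))
    ev2 = event_ledger(state.gene_order, GeneOrder.from_symbols(U2.organism_id, u2))
    ev1.branch = (node_label, U1.organism_id)
    ev2.branch = (node_label, U2.organism_id)
    ev1.inversions.extend(inv_u1)
    ev2.inversions.extend(inv_u2)
    return state, ev1, ev2


def event_ledger(
    parent: GeneOrder, child: GeneOrder, scoring: Scoring = UNIT_SCORING
) -> BranchEvents:
    """Events separating a parent gene order from a child gene order.

    Computed from the global alignment: gap-in-parent columns are
    insertions, gap-in-child columns deletions, and a mismatch column is a
    paired deletion+insertion; copy-number changes are per-gene count
    differences.  The identity ``|child| = |parent| + ins - del`` holds by
    construction.
    """
    aln = align_gene_orders(parent, child, scoring)
    p, c = parent.symbols(), child.symbols()
    led = BranchEvents(branch=(parent.organism_id, child.organism_id))
    for pi, ci in aln.columns:
        if pi is None:
            led.insertions.append((c[ci][0], ci))
        elif ci is None:
            led.deletions.append((p[pi][0], pi))
        elif p[pi] != c[ci]:
            led.deletions.append((p[pi][0], pi))
            led.insertions.append((c[ci][0], ci))
    pc, cc = parent.base_counts(), child.base_counts()
    for base in sorted(set(pc) | set(cc)):
        if pc[base] != cc[base]:
            led.copy_number_changes.append((base, pc[base], cc[base]))
    return led


# ---------------------------------------------------------------------------
# Steps 1-5: the full bottom-up loop
# ---------------------------------------------------------------------------


def reconstruct_all(
    tree: Phylogeny,
    leaves: Sequence[GeneOrder],
    params: ReconstructionParams | None = None,
    resolve_polytomies: bool = False,
) -> ReconstructionResult:
    """Reconstruct the gene order at every internal node of a rooted tree.

    ``leaves`` must supply one gene order per leaf organism.  The tree must
    be binary (or ``resolve_polytomies=True`` to caterpillar-resolve it).
    Deterministic: two runs on the same inputs give identical results.
    """
    from .genomes_io import label_internal_nodes

    params = params or ReconstructionParams()
    if resolve_polytomies and not tree.is_binary():
        tree.resolve_polytomies()
    if not tree.is_binary():
        raise ValueError("tree is not binary (pass resolve_polytomies=True)")
    label_internal_nodes(tree)

    by_id = {g.organism_id: g for g in leaves}
    states: dict[str, GeneOrder] = {}
    for leaf in tree.leaves():
        if leaf.organism_id not in by_id:
            raise ValueError(f"no gene order for leaf {leaf.organism_id!r}")
        states[leaf.organism_id] = by_id[leaf.organism_id]

    anc_states: dict[str, AncestorState] = {}
    ledgers: list[BranchEvents] = []
    order_of_resolution: list[str] = []
    n_internal = len(tree.internal_nodes())
    while len(order_of_resolution) < n_internal:
        c1, c2 = select_sister_pair(tree, states)
        cherry = c1.parent
        label = cherry.label
        cousins = order_cousins(tree, cherry, states)
        logger.info(
            "resolving %s = ancestor(%s, %s); cousins: %s",
            label,
            c1.node_id,
            c2.node_id,
            [n.node_id for n in cousins],
        )
        state, ev1, ev2 = infer_pair_ancestor(
            states[c1.node_id],
            states[c2.node_id],
            [states[n.node_id] for n in cousins],
            params,
            node_label=label,
        )
        anc_states[label] = state
        ledgers.extend([ev1, ev2])
        states[label] = state.gene_order
        order_of_resolution.append(label)
    return ReconstructionResult(
        tree=tree,
        states=anc_states,
        ledgers=ledgers,
        order_of_resolution=order_of_resolution,
        params=params,
    )
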
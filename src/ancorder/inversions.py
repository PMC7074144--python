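"""Detection and resolution of inverted regions between two gene orders.

An inversion (reversal) is a contiguous block of genes whose order is
reversed and whose strands are flipped relative to the other genome.
Detection finds maximal such regions; resolution decides which orientation
the ancestor keeps by consulting cousins, assigning the inversion event to
the branch of the disagreeing sister.
"""

from __future__ import annotations

from dataclasses import dataclass

from .alignment import align_gene_orders, gestalt_matching_blocks
from .genomes_io import GeneOrder

__all__ = [
    "InversionRegion",
    "detect_inversions",
    "resolve_inverted_region",
    "flip_slice",
]


@dataclass(frozen=True)
class InversionRegion:
    """Half-open region on A and on B related by reversal + strand flip."""

    a_start: int
    a_end: int
    b_start: int
    b_end: int

    @property
    def length(self) -> int:
        return self.a_end - self.a_start


def _symbols(genome):
    if isinstance(genome, GeneOrder):
        return list(genome.symbols())
    return list(genome)


def flip_slice(symbols):
    """Reverse a run of ``(name, strand)`` symbols and flip every strand."""
    return [(name, -strand) for name, strand in reversed(symbols)]


def detect_inversions(A, B, min_len: int = 2) -> list[InversionRegion]:
    """Maximal non-overlapping inverted regions between A and B.

    A cell ``(i, j)`` participates when ``A[i]`` equals ``B[j]`` with the
    strand flipped; runs extend along anti-diagonals (A forward, B
    backward).  Regions shorter than ``min_len`` are suppressed: a
    single-gene "inversion" is indistinguishable from a strand-annotation
    flip.  Overlapping candidates keep the longer region (tie: smaller
    ``a_start``); output is sorted by ``a_start``.
    """
    if min_len < 2:
        raise ValueError("min_len must be >= 2")
    a, b = _symbols(A), _symbols(B)
    n, m = len(a), len(b)
    flipped_b = [(name, -strand) for name, strand in b]
    # L[i][j]: length of the inverted run whose A part starts at i and whose
    # B part ends at j (inclusive); extends to (i+1, j-1).
    L = [[0] * m for _ in range(n)]
    candidates = []
    for i in range(n - 1, -1, -1):
        for j in range(m):
            if a[i] == flipped_b[j]:
                run = 1 + (L[i + 1][j - 1] if i + 1 < n and j - 1 >= 0 else 0)
                L[i][j] = run
                # maximal iff it cannot be extended to (i-1, j+1)
                extendable = (
                    i - 1 >= 0
                    and j + 1 < m
                    and a[i - 1] == flipped_b[j + 1]
                )
                if run >= min_len and not extendable:
                    candidates.append(
                        InversionRegion(i, i + run, j - run + 1, j + 1)
                    )
    # greedy maximality: longer first, tie smaller a_start, then b_start
    candidates.sort(key=lambda r: (-r.length, r.a_start, r.b_start))
    chosen: list[InversionRegion] = []
    for reg in candidates:
        clash = any(
            not (reg.a_end <= c.a_start or c.a_end <= reg.a_start)
            or not (reg.b_end <= c.b_start or c.b_end <= reg.b_start)
            for c in chosen
        )
        if not clash:
            chosen.append(reg)
    chosen.sort(key=lambda r: r.a_start)
    return chosen


def _block_support(slice_symbols, cousin_symbols) -> int:
    """Total matched symbols between a candidate slice and a cousin genome."""
    if not slice_symbols:
        return 0
    return sum(
        blk.length for blk in gestalt_matching_blocks(slice_symbols, cousin_symbols)
    )


@dataclass(frozen=True)
class ResolvedInversion:
    """Outcome of the reference-brother resolution of one inverted region."""

    block: tuple[tuple[str, int], ...]  # oriented ancestor block
    assigned_branch: str  # "A" or "B": the sister that underwent the inversion
    confidence: str  # "cousin" or "low" (no informative cousin)
    insertions: tuple[tuple[str, str], ...]  # (branch, gene) inside the region
    deletions: tuple[tuple[str, str], ...]


def resolve_inverted_region(
    A, B, region: InversionRegion, cousins
) -> ResolvedInversion:
    """Orient one inverted region by the first informative cousin.

    One brother acts as reference; each cousin is scored against the
    region in A's frame and in B's frame (total matched genes), and the
    first cousin preferring one frame decides the ancestral orientation.
    The inversion event is assigned to the branch of the disagreeing
    sister.  With no informative cousin, A's orientation is kept and the
    result is flagged low-confidence.

    Gene-content conflicts inside the region (indels within the inversion
    zone) are voted per gene in the region's coordinate frame: the
    non-reference slice is rewritten into the reference frame (reversed,
    strands flipped) before aligning, and a disputed gene is kept only if
    the deciding cousin carries a copy of it.
    """
    a, b = _symbols(A), _symbols(B)
    a_slice = a[region.a_start : region.a_end]
    b_slice = b[region.b_start : region.b_end]
    cousin_syms = [_symbols(c) for c in cousins]

    orientation = "A"
    confidence = "low"
    decider = None
    for csym in cousin_syms:
        support_a = _block_support(a_slice, csym)
        support_b = _block_support(b_slice, csym)
        if support_a > support_b:
            orientation, confidence, decider = "A", "cousin", csym
            break
        if support_b > support_a:
            orientation, confidence, decider = "B", "cousin", csym
            break

    if orientation == "A":
        ref_slice, other_slice = a_slice, flip_slice(b_slice)
        ref_branch, other_branch = "A", "B"
    else:
        ref_slice, other_slice = b_slice, flip_slice(a_slice)
        ref_branch, other_branch = "B", "A"

    aln = align_gene_orders(ref_slice, other_slice)
    block: list[tuple[str, int]] = []
    insertions: list[tuple[str, str]] = []
    deletions: list[tuple[str, str]] = []
    decider_names = {name for name, _ in decider} if decider else set()
    for ri, oi in aln.columns:
        if ri is not None and oi is not None and ref_slice[ri] == other_slice[oi]:
            block.append(ref_slice[ri])
            continue
        for idx, branch in ((ri, ref_branch), (oi, other_branch)):
            if idx is None:
                continue
            sym = ref_slice[idx] if branch == ref_branch else other_slice[idx]
            if decider is not None and sym[0] in decider_names:
                block.append(sym)
                deletions.append((other_branch if branch == ref_branch else ref_branch, sym[0]))
            else:
                insertions.append((branch, sym[0]))
    return ResolvedInversion(
        block=tuple(block),
        assigned_branch=other_branch,
        confidence=confidence,
        insertions=tuple(insertions),
        deletions=tuple(deletions),
    )
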
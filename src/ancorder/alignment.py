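"""Gene-level sequence comparison.

Two complementary primitives operate on gene orders, treating each
occurrence as a symbol ``(base_name, strand)``:

* **Gestalt pattern matching** (Ratcliff/Obershelp, the algorithm behind
  :class:`difflib.SequenceMatcher`): recursively takes the longest common
  contiguous block, recurses left and right of it, and summarises the
  result as the similarity ratio ``2*M / (|A| + |B|)`` where ``M`` is the
  total number of matched symbols.
* **Needleman-Wunsch global alignment** over gene symbols, with a
  deterministic traceback.  ``gene_order_distance`` is the number of
  non-match columns of the optimal alignment under unit costs
  (match 0, mismatch -1, gap -1), i.e. the Levenshtein edit distance over
  gene symbols, which is a metric.

Copy identity is deliberately *not* part of the matching key: two copies of
YCF68 match each other, and which copy pairs with which is resolved
positionally by the alignment.
"""

from __future__ import annotations

from dataclasses import dataclass
from difflib import SequenceMatcher

from .genomes_io import GeneOrder

__all__ = [
    "MatchBlock",
    "GeneAlignment",
    "Scoring",
    "DEFAULT_SCORING",
    "UNIT_SCORING",
    "gestalt_matching_blocks",
    "gestalt_ratio",
    "align_gene_orders",
    "gene_order_distance",
    "dump_alignment",
]

GAP = None  # sentinel used in alignment columns


@dataclass(frozen=True)
class MatchBlock:
    """A maximal run of identical symbols: A[a_start:a_start+length] == B[b_start:...]."""

    a_start: int
    b_start: int
    length: int


@dataclass(frozen=True)
class Scoring:
    match: float = 1.0
    mismatch: float = -1.0
    gap: float = -1.0

    def __post_init__(self) -> None:
        if not (self.match > self.mismatch and self.match > self.gap):
            raise ValueError("scoring requires match > mismatch and match > gap")


#: General-purpose default (favors matched columns).
DEFAULT_SCORING = Scoring(1.0, -1.0, -1.0)
#: Unit-cost scoring: the optimal score is minus the edit distance.
UNIT_SCORING = Scoring(0.0, -1.0, -1.0)


@dataclass(frozen=True)
class GeneAlignment:
    """A global alignment of two gene orders.

    ``columns`` pair indices into A and B (``None`` for a gap); every index
    of each sequence appears exactly once and in increasing order.
    ``edit_distance`` counts the non-match columns; ``ratio`` is
    ``2 * matches / (|A| + |B|)``.
    """

    columns: tuple[tuple[int | None, int | None], ...]
    score: float
    edit_distance: int
    ratio: float


def _keys(genome, include_strand: bool = True):
    if isinstance(genome, GeneOrder):
        return list(genome.keys(include_strand))
    return list(genome)


def gestalt_matching_blocks(A, B, include_strand: bool = True) -> list[MatchBlock]:
    """Non-crossing matching blocks from the recursive longest-block decomposition.

    Ties among equally long longest blocks go to the smallest ``a_start``,
    then the smallest ``b_start``; no junk heuristic is applied.
    """
    a, b = _keys(A, include_strand), _keys(B, include_strand)
    if not a or not b:
        return []
    sm = SequenceMatcher(None, a, b, autojunk=False)
    return [
        MatchBlock(m.a, m.b, m.size)
        for m in sm.get_matching_blocks()
        if m.size > 0
    ]


def gestalt_ratio(A, B, include_strand: bool = True) -> float:
    """Similarity ratio ``2*M / (|A| + |B|)`` in [0, 1]; 1 iff identical."""
    a, b = _keys(A, include_strand), _keys(B, include_strand)
    if not a and not b:
        raise ValueError("gestalt_ratio undefined for two empty sequences")
    m = sum(blk.length for blk in gestalt_matching_blocks(a, b))
    return 2.0 * m / (len(a) + len(b))


def align_gene_orders(
    A,
    B,
    scoring: Scoring = DEFAULT_SCORING,
    include_strand: bool = True,
) -> GeneAlignment:
    """Global Needleman-Wunsch alignment of two gene orders.

    Traceback ties are broken diagonal (match/mismatch) over up (gap in B)
    over left (gap in A), making the alignment deterministic.
    """
    a, b = _keys(A, include_strand), _keys(B, include_strand)
    n, m = len(a), len(b)
    match, mis, gap = scoring.match, scoring.mismatch, scoring.gap
    prev = [j * gap for j in range(m + 1)]
    rows = [prev]
    for i in range(1, n + 1):
        ai = a[i - 1]
        cur = [i * gap] + [0.0] * m
        prow = rows[i - 1]
        for j in range(1, m + 1):
            d = prow[j - 1] + (match if ai == b[j - 1] else mis)
            u = prow[j] + gap
            left = cur[j - 1] + gap
            cur[j] = d if d >= u and d >= left else (u if u >= left else left)
        rows.append(cur)
    # traceback, diag > up > left
    cols: list[tuple[int | None, int | None]] = []
    i, j = n, m
    while i > 0 or j > 0:
        here = rows[i][j]
        if (
            i > 0
            and j > 0
            and here == rows[i - 1][j - 1] + (match if a[i - 1] == b[j - 1] else mis)
        ):
            cols.append((i - 1, j - 1))
            i, j = i - 1, j - 1
        elif i > 0 and here == rows[i - 1][j] + gap:
            cols.append((i - 1, None))
            i -= 1
        else:
            cols.append((None, j - 1))
            j -= 1
    cols.reverse()
    n_match = sum(
        1 for ai, bj in cols if ai is not None and bj is not None and a[ai] == b[bj]
    )
    edit = len(cols) - n_match
    ratio = 2.0 * n_match / (n + m) if n + m else 1.0
    return GeneAlignment(tuple(cols), rows[n][m], edit, ratio)


def gene_order_distance(A, B, include_strand: bool = True) -> int:
    """Edit distance over gene symbols (unit costs); symmetric, zero iff identical."""
    return align_gene_orders(A, B, UNIT_SCORING, include_strand).edit_distance


def dump_alignment(A, B, alignment: GeneAlignment) -> str:
    """One column per line: ``a_pos  b_pos  status`` with '-' for a gap."""
    a, b = _keys(A), _keys(B)
    lines = ["a_pos\tb_pos\tstatus"]
    for ai, bj in alignment.columns:
        if ai is None or bj is None:
            status = "gap"
        elif a[ai] == b[bj]:
            status = "match"
        else:
            status = "mismatch"
        lines.append(
            f"{'-' if ai is None else ai}\t{'-' if bj is None else bj}\t{status}"
        )
    return "\n".join(lines) + "\n"
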
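"""Shared fixtures: small genomes and the in-literature worked scenarios."""

from __future__ import annotations

import pytest

from ancorder import GeneOrder, parse_newick


def go(organism_id: str, names, strands=None) -> GeneOrder:
    """Build a gene order from bare names (all forward unless given)."""
    if strands is None:
        strands = [1] * len(names)
    return GeneOrder.from_symbols(organism_id, list(zip(names, strands)))


def chloroplast_like(organism_id: str, copy_counts: dict[str, int]) -> GeneOrder:
    """A small plastid-style genome: a conserved backbone with the requested
    multi-copy genes interleaved (copies dispersed, mimicking inverted-repeat
    duplications)."""
    backbone = [
        "PSBA", "MATK", "RPS16", "PSBK", "ATPA", "ATPF", "RPOC2", "RPOB",
        "PETN", "PSBM", "PSBD", "PSBC", "RPS14", "PSAB", "PSAA", "YCF3",
        "RPS4", "NDHJ", "ATPB", "RBCL",
    ]
    symbols = [(g, 1) for g in backbone]
    # copies go to count-independent anchor slots, so genomes differing only
    # in copy count share the locations of the copies they have in common
    for name, count in sorted(copy_counts.items()):
        for k in range(count):
            symbols.insert(min(3 + 4 * k, len(symbols)), (name, 1 if k % 2 == 0 else -1))
    return GeneOrder.from_symbols(organism_id, symbols)


@pytest.fixture
def fig_toy():
    """Three-leaf configuration of the gene-investigation toy: sisters
    [A,B,D] and [A,B,C,D,E] with a cousin [A,B,C,D]."""
    return {
        "tree": parse_newick("((AB_D,ABCDE),COUSIN);"),
        "AB_D": go("AB_D", ["A", "B", "D"]),
        "ABCDE": go("ABCDE", ["A", "B", "C", "D", "E"]),
        "COUSIN": go("COUSIN", ["A", "B", "C", "D"]),
    }
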
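"""Turn a fragment design into orderable oligo sets and an assembly plan.

Two assembly strategies are supported:

* **Method A** — every fragment is ordered as its sense strand. Assembly
  PCR is linear: the antisense gene primer copies the last fragment, each
  further cycle bridges one more fragment leftward, so a full-length copy
  needs about as many cycles as there are fragments.
* **Method B** — fragments alternate sense/antisense (odd indices sense,
  even antisense). Neighboring fragments can then prime each other
  directly, so disjoint pairs merge in parallel and the number of merge
  rounds grows logarithmically in the fragment count.

For genes with many fragments the plan is hierarchical ("divide and
conquer"): consecutive fragments are grouped into blocks of at most
``max_block_size``, each block is PCR-assembled and amplified on its own
with block primers, and the purified blocks are finally assembled into the
full gene with the gene primers. Block primers are not designed anew: the
forward primer of a block is the sense junction overlap entering it (the
gene's 5' primer for the first block) and the reverse primer is the
reverse complement of the junction leaving it (the gene's 3' primer for
the last block) — so neighboring blocks share exactly one junction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

from .design import DesignError, DesignResult, Fragment
from .sequences import melting_temperature, reverse_complement

__all__ = [
    "OrderedOligo",
    "BlockPrimerPair",
    "BlockPlan",
    "to_method_a",
    "to_method_b",
    "plan_blocks",
    "make_block_plan",
    "derive_block_primers",
    "minimal_cycles",
]

Strand = Literal["sense", "antisense"]
Method = Literal["A", "B"]


@dataclass(frozen=True)
class OrderedOligo:
    """One vendor-orderable oligo: a fragment on its ordering strand."""

    index: int
    seq: str
    strand: Strand
    method: Method


@dataclass(frozen=True)
class BlockPrimerPair:
    forward: str
    reverse: str
    tm_forward: float
    tm_reverse: float


@dataclass
class BlockPlan:
    """Partition of the fragment series into consecutive assembly blocks.

    ``block_ranges`` holds 1-based inclusive (first_fragment,
    last_fragment) index pairs; ``primer_pairs`` is filled by
    :func:`derive_block_primers`.
    """

    block_sizes: list[int]
    block_ranges: list[tuple[int, int]]
    primer_pairs: list[BlockPrimerPair] = field(default_factory=list)

    @property
    def n_blocks(self) -> int:
        return len(self.block_sizes)


def to_method_a(fragments: list[Fragment]) -> list[OrderedOligo]:
    """All-sense oligo set (method A)."""
    if not fragments:
        raise DesignError("empty design")
    return [OrderedOligo(index=f.index, seq=f.seq_sense,
                         strand="sense", method="A")
            for f in fragments]


def to_method_b(fragments: list[Fragment]) -> list[OrderedOligo]:
    """Alternating-strand oligo set (method B).

    Odd fragment indices stay sense, even indices are ordered as the
    reverse complement. Junction metadata elsewhere keeps reporting
    overlaps on the sense strand regardless.
    """
    if not fragments:
        raise DesignError("empty design")
    out = []
    for f in fragments:
        if f.index % 2 == 1:
            out.append(OrderedOligo(index=f.index, seq=f.seq_sense,
                                    strand="sense", method="B"))
        else:
            out.append(OrderedOligo(index=f.index,
                                    seq=reverse_complement(f.seq_sense),
                                    strand="antisense", method="B"))
    return out


def plan_blocks(n_fragments: int, max_block_size: int) -> list[int]:
    """Balanced block sizes: as few blocks as allowed, sizes differing by
    at most one, smaller blocks first.

    E.g. 20 fragments with at most 7 per block -> [6, 7, 7]; 22 -> [5, 5,
    6, 6]; 27 with at most 9 -> [9, 9, 9].
    """
    if n_fragments < 1 or max_block_size < 1:
        raise DesignError("n_fragments and max_block_size must be >= 1")
    n_blocks = math.ceil(n_fragments / max_block_size)
    base, extra = divmod(n_fragments, n_blocks)
    return [base] * (n_blocks - extra) + [base + 1] * extra


def make_block_plan(design: DesignResult,
                    max_block_size: int | None = None) -> BlockPlan:
    """Block plan (sizes and fragment ranges) for a design."""
    cap = max_block_size or design.params.max_block_size
    sizes = plan_blocks(design.n_fragments, cap)
    ranges, first = [], 1
    for size in sizes:
        ranges.append((first, first + size - 1))
        first += size
    return BlockPlan(block_sizes=sizes, block_ranges=ranges)


def derive_block_primers(design: DesignResult, plan: BlockPlan) -> BlockPlan:
    """Fill in the primer pair of every block.

    Forward primer: the sense gene primer for block 1, else the sense
    junction overlap entering the block. Reverse primer: the antisense
    gene primer for the last block, else the reverse complement of the
    junction overlap leaving the block. Hence
    ``reverse_complement(block k reverse) == block k+1 forward``.
    """
    if sum(plan.block_sizes) != design.n_fragments:
        raise DesignError(
            f"plan covers {sum(plan.block_sizes)} fragments, design has "
            f"{design.n_fragments}")
    if design.primers is None:
        raise DesignError("design has no gene primers")
    fragments = design.fragments
    pairs: list[BlockPrimerPair] = []
    for k, (first, last) in enumerate(plan.block_ranges):
        if k == 0:
            forward = design.primers.sense_primer
        else:
            entering = fragments[first - 2].right_overlap
            assert entering is not None
            forward = entering.seq_sense
        if k == plan.n_blocks - 1:
            reverse = design.primers.antisense_primer
        else:
            leaving = fragments[last - 1].right_overlap
            assert leaving is not None
            reverse = reverse_complement(leaving.seq_sense)
        pairs.append(BlockPrimerPair(
            forward=forward, reverse=reverse,
            tm_forward=melting_temperature(forward),
            tm_reverse=melting_temperature(reverse)))
    plan.primer_pairs = pairs
    return plan


def minimal_cycles(n_fragments: int, method: Method) -> int:
    """Minimal PCR cycles to reach one full-length copy.

    Method A joins one fragment per cycle after an initial cycle in which
    the antisense gene primer copies the last fragment: ``n`` cycles for
    ``n`` fragments. Method B merges disjoint neighbor pairs each cycle:
    ``ceil(log2 n)`` cycles. A single fragment is already full length (0).
    """
    if n_fragments < 1:
        raise DesignError("n_fragments must be >= 1")
    if n_fragments == 1:
        return 0
    if method == "A":
        return n_fragments
    if method == "B":
        return math.ceil(math.log2(n_fragments))
    raise DesignError(f"unknown method {method!r}")
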
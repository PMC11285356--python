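"""In-silico overlap-extension assembly: the design verification oracle.

Given the ordered oligo set as it would go into the assembly PCR (any mix
of strands — during PCR either strand of a fragment takes part, so every
oligo may be flipped without changing the outcome) plus the gene primers,
the simulator checks that the fragments chain into exactly one full-length
product:

* every oligo is first canonicalized onto a common strand by walking the
  chain and orienting each oligo so that it shares an exact 3'/5' overlap
  of at least ``min_overlap`` nt with its predecessor;
* an ambiguity scan then looks for overlaps between *non*-neighboring
  oligos — a junction sequence that could bridge two different partners
  predicts mis-assembly in the tube and is reported as failure;
* finally neighbors are merged: ``linear`` mode models all-sense assembly
  (one fragment joined per round, right to left, after an initial round in
  which the antisense primer copies the last fragment), ``pairwise`` mode
  models alternating-strand assembly (all disjoint neighbor pairs merge in
  each round).

Only exact overlap matches count; hybridization thermodynamics and
polymerase errors are out of scope — the question answered is "is the
design self-consistent?", not "how efficient is the reaction?".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

from .assembly import OrderedOligo
from .design import GenePrimerPair
from .sequences import reverse_complement

__all__ = ["AssemblyOutcome", "simulate_assembly"]

Mode = Literal["linear", "pairwise"]


@dataclass
class AssemblyOutcome:
    """Result of a simulated assembly; failure is an outcome, not an error."""

    success: bool
    assembled_seq: str | None = None
    rounds_used: int = 0
    junction_log: list[tuple[int, int, int]] = field(default_factory=list)
    reason: str | None = None


def _suffix_prefix_overlap(left: str, right: str, min_overlap: int) -> int:
    """Longest exact overlap (suffix of ``left`` == prefix of ``right``)
    of at least ``min_overlap`` nt; 0 if none."""
    for k in range(min(len(left), len(right)), min_overlap - 1, -1):
        if left[-k:] == right[:k]:
            return k
    return 0


def _canonicalize(seqs: list[str], min_overlap: int
                  ) -> tuple[list[str], list[int]] | None:
    """Orient every oligo onto one strand so consecutive oligos overlap.

    Tries both orientations of the first oligo; each later oligo takes
    whichever orientation chains (preferring the longer overlap if, in a
    degenerate sequence, both do). Returns (oriented seqs, overlap
    lengths) or None if the chain breaks.
    """
    for first in (seqs[0], reverse_complement(seqs[0])):
        oriented = [first]
        overlaps: list[int] = []
        ok = True
        for nxt in seqs[1:]:
            flipped = reverse_complement(nxt)
            ov_fwd = _suffix_prefix_overlap(oriented[-1], nxt, min_overlap)
            ov_rev = _suffix_prefix_overlap(oriented[-1], flipped, min_overlap)
            if ov_fwd == 0 and ov_rev == 0:
                ok = False
                break
            if ov_fwd >= ov_rev:
                oriented.append(nxt)
                overlaps.append(ov_fwd)
            else:
                oriented.append(flipped)
                overlaps.append(ov_rev)
        if ok:
            return oriented, overlaps
    return None


def _primers_flank(seq: str, primers: GenePrimerPair) -> bool:
    fwd, rev = primers.sense_primer, primers.antisense_primer
    if seq.startswith(fwd) and seq.endswith(reverse_complement(rev)):
        return True
    flipped = reverse_complement(seq)
    return flipped.startswith(fwd) and flipped.endswith(
        reverse_complement(rev))


def simulate_assembly(oligos: Sequence[OrderedOligo],
                      primers: GenePrimerPair,
                      mode: Mode = "pairwise",
                      min_overlap: int = 15) -> AssemblyOutcome:
    """Simulate overlap-extension assembly of an ordered oligo set.

    Succeeds iff the oligos chain unambiguously into one sequence whose
    ends the gene primers flank (on either strand). ``min_overlap`` should
    be the design's ``overlap_min`` so that spurious short matches do not
    count as junctions.
    """
    if not oligos:
        return AssemblyOutcome(success=False, reason="no oligos supplied")
    seqs = [o.seq for o in oligos]
    if len(seqs) == 1:
        seq = seqs[0]
        if _primers_flank(seq, primers):
            return AssemblyOutcome(success=True, assembled_seq=seq,
                                   rounds_used=0)
        return AssemblyOutcome(
            success=False, reason="gene primers do not flank the oligo")

    chained = _canonicalize(seqs, min_overlap)
    if chained is None:
        return AssemblyOutcome(
            success=False,
            reason=f"chain broken: some neighboring oligos share no exact "
                   f"overlap of >= {min_overlap} nt in either orientation")
    oriented, overlaps = chained

    # ambiguity scan: a 3' end that could bridge a non-neighbor predicts
    # mis-assembly — unless the alternative join would produce exactly the
    # designed product anyway. That benign case is real: when the terminal
    # fragment absorbs borrowed bases from its predecessor, its 5' region
    # can legitimately share sequence with the fragment two back, and any
    # bridge there reads through to the same gene slice.
    def _chain_segment(i: int, j: int) -> str:
        seg = oriented[i]
        for t in range(i + 1, j + 1):
            seg += oriented[t][overlaps[t - 1]:]
        return seg

    for i, left in enumerate(oriented):
        for j, right in enumerate(oriented):
            if j in (i, i + 1):
                continue
            k = _suffix_prefix_overlap(left, right, min_overlap)
            if not k:
                continue
            if j > i and left + right[k:] == _chain_segment(i, j):
                continue  # redundant but product-consistent bridge
            return AssemblyOutcome(
                success=False,
                reason=f"ambiguous bridging: oligo {i + 1} can also "
                       f"anneal to oligo {j + 1}")

    # merge rounds
    units = list(range(len(oriented)))  # indices of surviving chain heads
    junction_log = [(i + 1, i + 2, overlaps[i]) for i in range(len(overlaps))]
    if mode == "linear":
        # one priming round, then one junction joined per round
        rounds = 1 + len(overlaps)
    elif mode == "pairwise":
        rounds = 0
        remaining = len(oriented)
        while remaining > 1:
            remaining = (remaining + 1) // 2
            rounds += 1
    else:
        return AssemblyOutcome(success=False, reason=f"unknown mode {mode!r}")

    assembled = oriented[0]
    for seq, ov in zip(oriented[1:], overlaps):
        assembled += seq[ov:]

    if not _primers_flank(assembled, primers):
        return AssemblyOutcome(
            success=False, assembled_seq=assembled, rounds_used=rounds,
            junction_log=junction_log,
            reason="assembled product is not flanked by the gene primers")
    return AssemblyOutcome(success=True, assembled_seq=assembled,
                           rounds_used=rounds, junction_log=junction_log)
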
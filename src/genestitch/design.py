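"""Fragment partitioning with Tm-matched junction overlaps.

The design problem: split a (codon-optimized) gene into fragments of a
fixed, vendor-friendly length such that every pair of consecutive fragments
shares an overlap whose melting temperature is as close as possible to a
single annealing temperature. During overlap-extension PCR those junctions
prime each other, so a tight Tm cluster is what makes one annealing step
work for every junction at once.

Algorithm (per gene, for one candidate annealing temperature ``tm_set``):

1. The first fragment is the 5' ``fragment_len`` nt of the gene.
2. The junction into the next fragment is the suffix of the current
   fragment (length searched over ``[overlap_min, overlap_max]``) whose Tm
   is closest to ``tm_set``; the next fragment is that overlap plus the
   following unconsumed sequence, again ``fragment_len`` nt.
3. When overlap + unconsumed remainder no longer fills a whole fragment,
   the last fragment is simply overlap + remainder — unless the remainder
   is shorter than ``remainder_min`` (20 nt), in which case 20 nt are
   borrowed from the 3' end of the previous fragment (which itself stays
   unchanged), the overlap is re-selected on the context preceding the
   borrowed stretch, and the final fragment becomes
   overlap + borrowed 20 nt + remainder.

``screen_tm_settings`` repeats this for every integer ``tm_set`` in the
screening range and keeps the design whose worst junction deviation from
the design's mean junction Tm is smallest; full-length gene primers are
then tuned to that winning mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from statistics import fmean

from .sequences import (
    MIN_DUPLEX_LEN,
    GeneSequence,
    melting_temperature,
    reverse_complement,
)

__all__ = [
    "DesignError",
    "DesignParameters",
    "OverlapJunction",
    "Fragment",
    "GenePrimerPair",
    "DesignResult",
    "select_overlap",
    "partition_gene",
    "design_gene_primers",
    "screen_tm_settings",
    "design_at",
]


class DesignError(ValueError):
    """Inconsistent parameters or a gene the algorithm cannot partition."""


@dataclass(frozen=True)
class DesignParameters:
    """Tunable knobs of the partitioning algorithm.

    fragment_len
        Uniform synthesis length of the fragments, nt. 59 trades vendor
        base price against fragment count.
    tm_screen_min, tm_screen_max
        Half-open integer range of candidate annealing temperatures
        screened, deg C (54..68 inclusive by default).
    remainder_min
        If the terminal remainder falls below this (20 nt), bases are
        borrowed from the previous fragment so the last fragment is not
        degenerately short.
    overlap_min, overlap_max
        Search bounds for junction overlap length, nt. 15 is a practical
        floor for specific annealing near 54 deg C; 35 keeps the overlap
        well inside a 59-nt fragment.
    max_block_size
        Fragments per assembly block cap (nine were joined per block in
        the validating experiments).
    """

    fragment_len: int = 59
    tm_screen_min: int = 54
    tm_screen_max: int = 69
    remainder_min: int = 20
    overlap_min: int = 15
    overlap_max: int = 35
    max_block_size: int = 9

    def __post_init__(self) -> None:
        if self.overlap_min < MIN_DUPLEX_LEN:
            raise DesignError(
                f"overlap_min {self.overlap_min} below minimum duplex "
                f"length {MIN_DUPLEX_LEN}")
        if self.overlap_min > self.overlap_max:
            raise DesignError("overlap_min must be <= overlap_max")
        if self.overlap_max >= self.fragment_len:
            raise DesignError(
                f"overlap_max {self.overlap_max} must be smaller than "
                f"fragment_len {self.fragment_len}")
        if self.tm_screen_min >= self.tm_screen_max:
            raise DesignError("tm_screen_min must be < tm_screen_max")
        if self.fragment_len <= self.remainder_min:
            raise DesignError("fragment_len must exceed remainder_min")
        if self.max_block_size < 1:
            raise DesignError("max_block_size must be >= 1")

    @property
    def tm_screen_range(self) -> range:
        return range(self.tm_screen_min, self.tm_screen_max)


@dataclass
class OverlapJunction:
    """The Tm-selected annealing sequence joining two consecutive fragments.

    ``seq_sense`` is reported on the sense strand; it is always a prefix of
    the right-hand fragment. For every junction except a borrowed terminal
    one it is also a suffix of the left-hand fragment; when the terminal
    borrowing rule fired, ``borrowed`` > 0 and the annealing sequence ends
    that many nt before the left fragment's 3' end (the physical overlap of
    the two fragments is then ``length + borrowed`` nt).

    ``tm_deviation`` (Tm - design Tm_mean) is filled once the whole design
    is known.
    """

    seq_sense: str
    tm: float
    tm_deviation: float = 0.0
    borrowed: int = 0

    @property
    def length(self) -> int:
        return len(self.seq_sense)


@dataclass
class Fragment:
    """One designed synthesis piece, stored on the sense strand.

    Coordinates are 1-based inclusive on the gene. ``right_overlap`` is the
    junction into the next fragment; ``None`` only for the last fragment.
    """

    index: int
    seq_sense: str
    start_pos: int
    end_pos: int
    right_overlap: OverlapJunction | None = None

    @property
    def length(self) -> int:
        return self.end_pos - self.start_pos + 1


@dataclass
class GenePrimerPair:
    """Terminal primers (gene_5 / gene_3) amplifying the full-length gene."""

    sense_primer: str
    antisense_primer: str
    tm_sense: float
    tm_antisense: float
    tm_deviation_sense: float = 0.0
    tm_deviation_antisense: float = 0.0

    @property
    def tm_deviation_max(self) -> float:
        return max(abs(self.tm_deviation_sense),
                   abs(self.tm_deviation_antisense))


@dataclass
class DesignResult:
    """A complete design for one chosen annealing temperature."""

    gene: GeneSequence
    params: DesignParameters
    tm_set_chosen: int
    fragments: list[Fragment]
    primers: GenePrimerPair | None
    tm_mean: float
    tm_dev_max: float

    @property
    def junctions(self) -> list[OverlapJunction]:
        return [f.right_overlap for f in self.fragments
                if f.right_overlap is not None]

    @property
    def n_fragments(self) -> int:
        return len(self.fragments)


def select_overlap(left_context: str, tm_target: float,
                   params: DesignParameters) -> OverlapJunction:
    """Pick the 3'-suffix of ``left_context`` with Tm closest to target.

    Every suffix length in ``[overlap_min, overlap_max]`` is evaluated;
    ties break toward the shorter suffix (same Tm fit, cheaper primer).
    """
    if len(left_context) < params.overlap_max:
        raise DesignError(
            f"context of {len(left_context)} nt shorter than overlap_max "
            f"{params.overlap_max}")
    best: OverlapJunction | None = None
    best_dev = float("inf")
    for k in range(params.overlap_min, params.overlap_max + 1):
        suffix = left_context[-k:]
        dev = abs(melting_temperature(suffix) - tm_target)
        if dev < best_dev:
            best = OverlapJunction(seq_sense=suffix,
                                   tm=melting_temperature(suffix))
            best_dev = dev
    assert best is not None
    return best


def partition_gene(gene: GeneSequence, tm_set: float,
                   params: DesignParameters | None = None) -> list[Fragment]:
    """Partition ``gene`` into overlapping fragments for one ``tm_set``.

    Returns fragments in 5'->3' order; every fragment except possibly the
    last has length ``params.fragment_len``. Genes no longer than one
    fragment yield a single fragment spanning the whole gene.
    """
    params = params or DesignParameters()
    seq = gene.seq
    n = len(seq)
    if n <= params.fragment_len:
        return [Fragment(index=1, seq_sense=seq, start_pos=1, end_pos=n)]
    if n < 2 * params.overlap_max:
        raise DesignError(
            f"gene of {n} nt too short to design junctions with "
            f"overlap_max {params.overlap_max}")

    flen = params.fragment_len
    fragments = [Fragment(index=1, seq_sense=seq[:flen],
                          start_pos=1, end_pos=flen)]
    consumed = flen  # 0-based end of the last fragment on the gene
    while consumed < n:
        prev = fragments[-1]
        remainder = n - consumed
        junction = select_overlap(prev.seq_sense, tm_set, params)
        if junction.length + remainder >= flen:
            start0 = consumed - junction.length  # 0-based
            end0 = start0 + flen
            nxt = Fragment(index=prev.index + 1,
                           seq_sense=seq[start0:end0],
                           start_pos=start0 + 1, end_pos=end0)
            consumed = end0
        else:
            # terminal fragment: overlap + remainder no longer fills a
            # whole fragment
            if remainder < params.remainder_min:
                borrow = params.remainder_min
                context = prev.seq_sense[:-borrow]
                if len(context) < params.overlap_max:
                    raise DesignError(
                        f"cannot borrow {borrow} nt from a {prev.length}-nt "
                        f"fragment and still search overlaps up to "
                        f"{params.overlap_max} nt; reduce overlap_max or "
                        f"remainder_min")
                junction = select_overlap(context, tm_set, params)
                junction.borrowed = borrow
                start0 = consumed - borrow - junction.length
            else:
                start0 = consumed - junction.length
            nxt = Fragment(index=prev.index + 1,
                           seq_sense=seq[start0:],
                           start_pos=start0 + 1, end_pos=n)
            consumed = n
        prev.right_overlap = junction
        fragments.append(nxt)
    return fragments


def _argmin_terminal(candidates: list[str], tm_target: float) -> str:
    """Shortest candidate whose Tm is closest to target (shared by both
    gene primers)."""
    best, best_dev = None, float("inf")
    for cand in candidates:
        dev = abs(melting_temperature(cand) - tm_target)
        if dev < best_dev:
            best, best_dev = cand, dev
    assert best is not None
    return best


def design_gene_primers(gene: GeneSequence, tm_target: float,
                        params: DesignParameters | None = None
                        ) -> GenePrimerPair:
    """Terminal primers for exponential amplification of the full gene.

    The sense primer is the gene prefix, and the antisense primer the
    reverse complement of the gene suffix, whose lengths (searched over
    the overlap bounds) bring each Tm closest to ``tm_target``.
    """
    params = params or DesignParameters()
    if gene.length < 2 * params.overlap_max:
        raise DesignError(
            f"gene of {gene.length} nt too short for two non-overlapping "
            f"terminal primers up to {params.overlap_max} nt")
    lengths = range(params.overlap_min, params.overlap_max + 1)
    sense = _argmin_terminal([gene.seq[:k] for k in lengths], tm_target)
    suffix = _argmin_terminal([gene.seq[-k:] for k in lengths], tm_target)
    return GenePrimerPair(
        sense_primer=sense,
        antisense_primer=reverse_complement(suffix),
        tm_sense=melting_temperature(sense),
        tm_antisense=melting_temperature(suffix),
    )


def design_at(gene: GeneSequence, tm_set: int,
              params: DesignParameters | None = None,
              with_primers: bool = True) -> DesignResult:
    """Full design (fragments + statistics + primers) for one ``tm_set``."""
    params = params or DesignParameters()
    fragments = partition_gene(gene, tm_set, params)
    junctions = [f.right_overlap for f in fragments if f.right_overlap]
    if junctions:
        tm_mean = fmean(j.tm for j in junctions)
        tm_dev_max = max(abs(j.tm - tm_mean) for j in junctions)
    else:
        # single-fragment design: no junctions to average, so primers are
        # targeted at the candidate annealing temperature itself
        tm_mean = float(tm_set)
        tm_dev_max = 0.0
    for j in junctions:
        j.tm_deviation = j.tm - tm_mean
    primers = None
    if with_primers:
        primers = design_gene_primers(gene, tm_mean, params)
        primers.tm_deviation_sense = primers.tm_sense - tm_mean
        primers.tm_deviation_antisense = primers.tm_antisense - tm_mean
    return DesignResult(gene=gene, params=params, tm_set_chosen=tm_set,
                        fragments=fragments, primers=primers,
                        tm_mean=tm_mean, tm_dev_max=tm_dev_max)


def screen_tm_settings(gene: GeneSequence,
                       params: DesignParameters | None = None
                       ) -> DesignResult:
    """Screen every integer annealing temperature and keep the tightest
    design.

    The winner minimizes the maximum absolute junction deviation from the
    design's own mean junction Tm (ties break toward the lower candidate
    temperature); gene primers are then tuned to the winner's Tm_mean.
    """
    params = params or DesignParameters()
    if gene.length < 100:
        warnings.warn(
            f"gene of {gene.length} nt: genes under ~100 nt are usually "
            f"cheaper to synthesize directly as two annealed strands",
            stacklevel=2)
    best: DesignResult | None = None
    for tm_set in params.tm_screen_range:
        candidate = design_at(gene, tm_set, params, with_primers=False)
        if best is None or candidate.tm_dev_max < best.tm_dev_max:
            best = candidate
    assert best is not None
    # re-run the winner with primers targeted at its Tm_mean
    return design_at(gene, best.tm_set_chosen, params, with_primers=True)


def reconstruct(fragments: list[Fragment]) -> str:
    """Stitch fragments back into the gene via their declared overlaps.

    Used as the lossless-partition check: the result must equal the input
    gene byte-for-byte.
    """
    if not fragments:
        raise DesignError("no fragments to reconstruct")
    out = fragments[0].seq_sense
    for prev, frag in zip(fragments, fragments[1:]):
        assert prev.right_overlap is not None
        drop = prev.right_overlap.length + prev.right_overlap.borrowed
        out += frag.seq_sense[drop:]
    return out
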
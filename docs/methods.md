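# Methods

## The design problem

Overlap-extension assembly builds a gene from synthetic fragments whose
junctions prime each other. The whole reaction runs at one annealing
temperature, so the quality of a design is the spread of junction melting
temperatures: the statistic optimized and reported throughout is
`max_i |Tm_i − Tm_mean|`, the worst junction's deviation from the
design's mean junction Tm.

## Melting temperature model

Tm is computed by nearest-neighbor thermodynamics via
`Bio.SeqUtils.MeltingTemp.Tm_NN` at its defaults: the Allawi & SantaLucia
(1997) unified ΔH/ΔS table, duplex initiation and terminal A·T penalties,
the SantaLucia (1998) entropy salt correction at 50 mM Na⁺, and 25 nM per
strand. The parameterization is frozen in
`genestitch.sequences.DEFAULT_TM_CONFIG`; passing a `config` override to
`melting_temperature` swaps in alternatives (different tables, salt,
concentrations) for sensitivity checks. The unit tests reproduce the
default model with an independent hand summation of the published table,
so the library call is verified rather than trusted.

Two consequences matter downstream. Tm is strand-symmetric (both strands
describe one duplex), which is why the same junction Tm serves the
all-sense and the alternating-strand oligo sets. And nearest-neighbor
values are unreliable for very short duplexes, so sequences under 8 nt
are rejected outright rather than approximated with another formula.
Absolute Tm values shift by ~0.1–1 °C under other salt/concentration
assumptions; deviations from a design's own mean are much more stable.

## Partitioning algorithm

Parameters (all user-settable; defaults in parentheses):

| parameter | default | meaning |
|---|---|---|
| `fragment_len` | 59 nt | uniform synthesis length; trades vendor base price against fragment count |
| `tm_screen_min/max` | 54, 69 °C | half-open integer screen of candidate annealing temperatures (54…68) |
| `overlap_min/max` | 15, 35 nt | junction length search bounds; 15 nt is a practical floor for specific annealing near 54 °C, 35 keeps the overlap well inside a fragment |
| `remainder_min` | 20 nt | terminal remainder below which bases are borrowed from the previous fragment |
| `max_block_size` | 9 | fragments per assembly block |

For one candidate `tm_set`: the first fragment is the 5′ `fragment_len`
nt; each junction is the suffix of the current fragment, length searched
exhaustively over `[overlap_min, overlap_max]`, minimizing
`|Tm − tm_set|` (ties to the shorter suffix — same fit, cheaper oligo);
the next fragment starts at that overlap and again spans `fragment_len`
nt. When overlap + unconsumed remainder no longer fills a fragment, the
last fragment is overlap + remainder — unless the remainder is under
`remainder_min`, in which case 20 nt are borrowed from the 3′ end of the
previous fragment (which itself is left unchanged), the junction is
re-selected on the context preceding the borrowed stretch, and the final
fragment becomes junction + borrowed 20 nt + remainder. The final
fragment may therefore be shorter *or* somewhat longer than
`fragment_len`; every other fragment is exact.

A junction object always stores the Tm-selected annealing sequence on the
sense strand — that sequence is what gets plotted, what enters the Tm
statistics, and what becomes a block primer. In the borrowed terminal
case the *physical* overlap between the last two fragments is the
annealing sequence plus the borrowed 20 nt (`length + borrowed`), which
is what the coordinate bookkeeping and the reconstruction check use.

The screen runs every integer `tm_set` in the range and keeps the design
minimizing the worst junction deviation, ties to the lower temperature.
Minimizing the maximum (rather than variance) directly optimizes the
quantity reported to the bench, and empirically screened ~1 kb designs
end with a worst deviation around 1 °C. Gene primers (a gene prefix and
the reverse complement of a gene suffix, lengths searched like overlaps)
are tuned to the *winning design's Tm_mean*, not to `tm_set`, and are
excluded from the mean itself: the mean characterizes junctions, and the
primers should match the temperature at which the junctions actually
anneal. Single-fragment designs have no junctions; their primers target
the chosen `tm_set` and a warning notes that genes under ~100 nt are
cheaper to synthesize directly as two annealed strands.

## Assembly planning

Method A orders every fragment sense; method B flips even-indexed
fragments to the antisense strand so that neighbors can prime each other
directly. Minimal PCR cycle accounting follows the mechanism: method A
needs one cycle for the antisense gene primer to copy the last fragment
plus one cycle per remaining junction (`n` cycles for `n ≥ 2` fragments);
method B merges disjoint neighbor pairs each cycle (`⌈log₂ n⌉`). One
fragment needs 0 cycles. Whether method A's initial priming cycle counts
is a convention; it is included here, and the simulator counts rounds the
same way, so the formulas are validated against the mechanism rather
than asserted.

Blocks: `⌈n / max_block_size⌉` consecutive blocks, sizes as equal as
possible, smaller blocks first (20 fragments, cap 7 → 6+7+7; 22 → 5+5+6+6;
27, cap 9 → 9+9+9). Block primers are not re-optimized: the forward
primer of a block is the sense junction overlap entering it (the gene_5
primer for block 1) and the reverse primer is the reverse complement of
the junction leaving it (gene_3 for the last block). Hence
`revcomp(reverse_k) == forward_{k+1}` and neighboring block amplicons
share exactly one junction.

## In-silico assembly verification

The simulator answers "is this design self-consistent?", standing in for
wet-lab validation. It models hybridization as *exact* string overlap of
at least `overlap_min` nt — no mismatches, no kinetics, no concentration
effects — because the failure modes it must catch (broken chains, wrong
coordinates, strand bookkeeping errors, duplicated junctions) are all
exact-sequence properties. What a passing simulation does **not** show:
that the PCR will be efficient, that secondary structure will not
interfere, or that near-exact off-target priming cannot occur; those are
delegated upstream to codon optimization and to the bench.

Each oligo may arrive on either strand (in PCR both strands participate),
so the simulator first orients every oligo onto a common strand by
walking the chain (both orientations of the first oligo are tried). It
then scans all non-neighbor pairs for possible bridges: a 3′ end that
could anneal to a second partner predicts mis-assembly and fails the
design with a diagnostic — *unless* the alternative join would read
through to exactly the designed product. That benign case genuinely
occurs: the terminal borrowing rule can leave the last fragment's 5′
region sharing ≥ `overlap_min` nt with the fragment two back, and a
bridge there yields the same gene slice. Finally neighbors are merged —
`linear` mode one junction per round right-to-left after a priming round,
`pairwise` mode all disjoint neighbor pairs per round — and the run
succeeds iff a single product remains whose ends the gene primers flank
(on either strand; flipping every oligo is still a success).

## Synthetic data

Test and example genes come from `random_gene`: i.i.d. bases with
P(G)=P(C)=gc/2. This reproduces the *scale* of real design inputs
(length, GC, Tm spread along the sequence) but not codon structure,
repeats, or low-complexity regions of natural genes — so passing the
randomized suites demonstrates algorithmic correctness, not that every
real gene yields a tight design; a gene with a pathological region can
legitimately end with a larger worst deviation. The acceptance script
uses a 1,050-nt, GC 0.5 gene: the scale of the experimentally validated
~1 kb example that partitions into 27–31 fragments of 59 nt. Empirically
(frozen as a regression bound), at least 90% of random 1-kb genes screen
to a worst junction deviation below 1.5 °C.

## Numerical choices and degenerate inputs

* Overlap and primer searches are exhaustive over the length bounds —
  21 Tm evaluations per junction — with Tm values cached, so screening
  15 temperatures over a 3-kb gene stays well under a second of unique
  thermodynamics work.
* Ties (equal |Tm − target|) always resolve to the shorter sequence;
  equal worst deviations across the screen resolve to the lower
  temperature. Both make the design a pure function of its inputs.
* Genes not longer than `fragment_len` yield a single fragment; genes
  shorter than `2 × overlap_max` cannot carry two terminal primers and
  are rejected with a clear error.
* Coordinates are 1-based inclusive in every report (`start_pos-end_pos`
  columns); temperatures are printed to two decimals.

## Known limitations

* No secondary-structure, hairpin or primer-dimer screening; the input
  is assumed codon-optimized with such regions already smoothed.
* Exact-match assembly simulation (see above): thermodynamic
  cross-hybridization is out of scope.
* The Tm parameterization is fixed to one widely used default; designs
  compared across tools should compare deviations, not absolute Tm.
* Block boundaries are balanced by fragment count only, not re-optimized
  by junction Tm or GC.
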
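"""Plan hierarchical assembly: blocks, block primers and PCR cycles.

With many fragments, joining everything in one PCR is unreliable, so
consecutive fragments are grouped into blocks (at most nine per block
here), each block is assembled and amplified with its own primer pair,
and the blocks are then joined into the full gene. Block primers cost
nothing extra: they are the junction overlaps already designed, so
neighboring blocks share exactly one junction.
"""

from genestitch import (
    derive_block_primers,
    make_block_plan,
    minimal_cycles,
    random_gene,
    screen_tm_settings,
)

gene = random_gene(1000, gc_fraction=0.5, seed=42, id="demo_gene")
design = screen_tm_settings(gene)
plan = derive_block_primers(design, make_block_plan(design))

print(f"{design.n_fragments} fragments -> {plan.n_blocks} blocks "
      f"of sizes {plan.block_sizes}")
for k, ((first, last), pair) in enumerate(
        zip(plan.block_ranges, plan.primer_pairs), start=1):
    print(f"\nblock {k}: fragments {first}-{last}")
    print(f"  forward ({len(pair.forward)} nt, Tm {pair.tm_forward:.2f}): "
          f"{pair.forward}")
    print(f"  reverse ({len(pair.reverse)} nt, Tm {pair.tm_reverse:.2f}): "
          f"{pair.reverse}")

n = design.n_fragments
print(f"\nminimal PCR cycles to one full-length copy: "
      f"method A (all sense, one join per cycle) = {minimal_cycles(n, 'A')}, "
      f"method B (alternating strands, pairwise joins) = "
      f"{minimal_cycles(n, 'B')}")
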
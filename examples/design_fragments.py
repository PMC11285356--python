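"""Design Tm-matched fragments for a gene.

Builds a random 1 kb "codon-optimized" gene, screens every candidate
annealing temperature from 54 to 68 degC, and prints the winning
fragment set. Each junction overlap's Tm should sit within about 1 degC
of the design mean — that tight cluster is what lets a single PCR
annealing temperature serve every junction during assembly.
"""

from genestitch import random_gene, screen_tm_settings

gene = random_gene(1000, gc_fraction=0.5, seed=42, id="demo_gene")
design = screen_tm_settings(gene)

print(f"gene {gene.id}: {gene.length} nt")
print(f"chosen Tm_set: {design.tm_set_chosen} degC   "
      f"Tm_mean: {design.tm_mean:.2f} degC   "
      f"max |Tm - Tm_mean|: {design.tm_dev_max:.2f} degC")
print(f"{design.n_fragments} fragments "
      f"(all {design.params.fragment_len} nt except possibly the last)\n")

print(f"{'idx':>3} {'pos':>12} {'len':>4} {'ov_len':>6} "
      f"{'ov_Tm':>7} {'dev':>6}")
for frag in design.fragments:
    j = frag.right_overlap
    pos = f"{frag.start_pos}-{frag.end_pos}"
    if j is not None:
        print(f"{frag.index:>3} {pos:>12} {frag.length:>4} "
              f"{j.length:>6} {j.tm:>7.2f} {j.tm_deviation:>+6.2f}")
    else:
        print(f"{frag.index:>3} {pos:>12} {frag.length:>4} "
              f"{'-':>6} {'-':>7} {'-':>6}")

p = design.primers
print(f"\ngene_5 primer ({len(p.sense_primer)} nt)  Tm {p.tm_sense:.2f}  "
      f"dev {p.tm_deviation_sense:+.2f}")
print(f"gene_3 primer ({len(p.antisense_primer)} nt)  "
      f"Tm {p.tm_antisense:.2f}  dev {p.tm_deviation_antisense:+.2f}")
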
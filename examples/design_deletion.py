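"""Design a complete deletion-primer set for one gene.

Builds a small seeded genome with a planted 900-nt gene plus a synthetic
1400-nt marker cassette, runs the design pipeline, and prints the nine
primers (four flank primers, five check primers) with their anchors, GC
and Tm, followed by the fused-construct arithmetic.
"""

from delkit.design import design_gene_deletion
from delkit.synthetic import FixtureSpec, GeneSpec, generate_genome, synthetic_cassette

genome, genes, _ = generate_genome(FixtureSpec(seed=1, genes=(GeneSpec(length=900),)))
cassette = synthetic_cassette(seed=1)
design = design_gene_deletion(genome, genes[0], cassette)

print(f"gene {design.gene.gene_id}: {design.gene.chromosome}:"
      f"{design.gene.start}-{design.gene.end}({design.gene.strand})")
print(f"{'primer':8s} {'len':>3s} {'tail':>4s} {'GC%':>5s} {'Tm':>5s}  anchor")
for name, p in design.primers.items():
    anchor = p.anchor or p.cassette_anchor
    loc = f"{anchor[0]}:{anchor[1]}-{anchor[2]}({anchor[3]})"
    print(f"{name:8s} {len(p.oligo):3d} {p.tail_len:4d} {100*p.gc_fraction:5.1f} "
          f"{p.tm_C:5.1f}  {loc}")
print(f"\nflanks: {design.flank5_len} bp + cassette {cassette.length} bp + "
      f"{design.flank3_len} bp = construct {design.construct_len} nt (~2 kb)")

# The 47-nt inner primers carry 23-nt cassette homology tails; the outer and
# check primers are plain genomic 24-35-mers with >= 30% GC.  The construct
# length is the sum of both homology arms and the cassette.
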
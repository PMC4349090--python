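"""Predict the diagnostic colony-PCR band patterns for each genotype.

Designs a deletion, edits the genome in silico, then runs the left
(5chk x kanRchk), right (kanFchk x 3chk) and ORF (5chk x ORFchk) check
reactions on wild-type, deletant and mixed colonies, printing the expected
band sizes and the verdict for each.
"""

from delkit.design import design_gene_deletion
from delkit.pcr import apply_deletion, predict_check_bands
from delkit.synthetic import FixtureSpec, GeneSpec, generate_genome, synthetic_cassette

genome, genes, _ = generate_genome(FixtureSpec(seed=2, genes=(GeneSpec(length=900),)))
cassette = synthetic_cassette(seed=2)
design = design_gene_deletion(genome, genes[0], cassette)
deletant = apply_deletion(genome, design, cassette)
report = predict_check_bands(design, genome, deletant)

for genotype in ("wild_type", "deletant", "mixed"):
    bands = report.bands[genotype]
    sizes = {rxn: (lengths or "no band") for rxn, lengths in bands.items()}
    print(f"{genotype:10s} left={sizes['left']} right={sizes['right']} "
          f"orf={sizes['orf']} -> {report.verdicts[genotype]}")
print(f"wild-type ORF control band: {report.wt_control_bands}")

# A correct deletant shows left+right bands and no ORF band; a colony with
# bands in all three reactions is a mixed population (part of the colony
# still carries the targeted ORF).  The wild-type control band rules out a
# technical failure of the ORF reaction.
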
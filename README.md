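# delkit

Design, verify and phenotype PCR-based gene deletions in fission yeast.

`delkit` implements the two-step fusion-PCR strategy used to build haploid
deletion collections in *Schizosaccharomyces pombe*: each targeted open
reading frame (ORF) is replaced by a dominant selection cassette (kanMX-style,
conferring G418 resistance) flanked by ~300-bp homology arms. The package
covers the complete in-silico side of that workflow:

* **Primer design** — flank primers 5F/5R/3F/3R at the canonical windows
  (5F at −324..−301 and 5R at −24..−1 upstream of the ATG; 3F at +1..+24 and
  3R at +301..+324 downstream of the stop codon), with 23-nt cassette homology
  tails on the inner primers. Primers must be 24–35 nt with ≥ 30 % GC; failing
  outer primers are re-selected by exhaustive search keeping the flank within
  200–500 bp, and the position-fixed inner primers are extended up to 35 nt.
  Five check primers (5′chk, 3′chk, ORF chk on the genome; kanR chk, kanF chk
  on the cassette) are placed at the published offsets.
* **Construct assembly** — the fusion product flank5–cassette–flank3
  (324 + 1400 + 324 = 2048 nt with the default geometry, i.e. ~2 kb), with the
  23-nt junction overlaps verified.
* **In-silico verification** — genome editing (`apply_deletion`), primer-site
  search and PCR simulation, and the three diagnostic colony reactions
  (left = 5′chk × kanR chk, right = kanF chk × 3′chk, ORF = 5′chk × ORF chk,
  plus a wild-type ORF control). Verdicts: `correct_deletion`,
  `no_integration`, `mixed_population` (bands in all three reactions — a
  colony whose cells are a mixture of deletant and ORF-retaining genotypes),
  or `ambiguous` when the control fails.
* **Stress-screen phenotyping** — spot-assay scoring against wild type on the
  16-condition stress panel (13 compounds, 19°/36°, minimal medium) into the
  ordinal calls very sensitive / sensitive / not sensitive / resistant,
  encoded 2/1/0/−1; multi-stress counting; drug-set queries; complete-linkage
  hierarchical clustering; CDT/GTR export readable by Java TreeView.
* **Synthetic fixtures** — seeded genomes with planted GC pathologies, a
  synthetic marker cassette, colony templates and a synthetic 281-strain call
  table, so everything runs with no downloads.

## Worked example

```python
from delkit.design import design_gene_deletion
from delkit.pcr import apply_deletion, predict_check_bands
from delkit.synthetic import FixtureSpec, GeneSpec, generate_genome, synthetic_cassette

genome, genes, _ = generate_genome(FixtureSpec(seed=2, genes=(GeneSpec(length=900),)))
cassette = synthetic_cassette(seed=2)
design = design_gene_deletion(genome, genes[0], cassette)
report = predict_check_bands(design, genome, apply_deletion(genome, design, cassette))
```

Printing the per-genotype reactions (`examples/verify_colony.py`) gives:

```
wild_type  left=no band right=no band orf=[422] -> no_integration
deletant   left=[641] right=[485] orf=no band -> correct_deletion
mixed      left=[641] right=[485] orf=[422] -> mixed_population
wild-type ORF control band: [422]
```

The deletant shows the two junction bands (641 and 485 nt here) and no ORF
band; the mixed colony shows all three, and the 422-nt wild-type control band
confirms the ORF reaction works. `design.construct_len` is 2048 nt:
324-bp arm + 1400-nt cassette + 324-bp arm.

More narrative examples live in `examples/` (one script per capability);
the same operations are available from the shell via the `delkit` command
(`design`, `apply`, `verify`, `screen score|cluster|summarize`, `simulate`).

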
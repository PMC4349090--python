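# Methods

## The deletion strategy being modelled

A gene is deleted by replacing its whole annotated genomic span — ATG through
stop codon inclusive, introns included — with a dominant selection cassette.
Two PCRs produce the transforming fragment: the first amplifies ~300-bp
homology arms on either side of the ORF with primer pairs 5F/5R and 3F/3R,
where the inner primers carry 23-nt tails complementary to the cassette
termini; the second uses those arm products as primers on the cassette
template, fusing arm–cassette–arm into a single linear fragment that directs
homologous recombination. Integration is diagnosed by three colony-PCR
reactions spanning the two junctions and probing for the (now absent) ORF.

## Coordinate conventions

User-facing coordinates are 1-based inclusive (GFF3); internally strings are
indexed 0-based half-open, and the conversion layer is exercised by
round-trip tests. Gene-relative offsets follow transcription orientation:
−1 is the base immediately 5′ of the ATG, +1 the base immediately 3′ of the
gene span (the stop codon is part of the deleted span, so +1 is the first
base *after* the stop codon; `DesignConfig.stop_included_in_orf` records the
convention). For minus-strand genes the upstream window sits at higher
genomic coordinates and all returned sequences are reverse-complemented into
transcription orientation.

The published primer windows are quoted as 25-position ranges (−324 to −300)
for 24-nt primers. We resolve the off-by-one by fixing 5F at −324..−301 and
3R at +301..+324, making each default homology arm exactly 324 bp — the
"approximately 300 bp" of the protocol. This choice is applied consistently
everywhere (flank arithmetic, construct length, tests).

## Design rules and their parameters

| parameter | default | meaning |
|---|---|---|
| `flank_target` | 300 bp | targeted arm length; default windows give 324 bp arms |
| `flank_min..flank_max` | 200–500 bp | allowed arm band when re-selection moves an outer primer |
| `primer_min..primer_max` | 24–35 nt | anchored primer length band |
| `min_gc` | 0.30 | GC floor on the anchored portion of outer and check primers |
| `tail_len` | 23 nt | cassette homology tail on 5R/3F |
| `chk_window` | 500 bp | 5′chk/3′chk placed within this distance outside the arm |
| `orf_chk_window` | 100 bp | ORF chk anchored within the first 100 bp of the ORF |
| `kanr_chk_offset` | 20 bp | kanR chk 3′ end downstream of the marker ATG |
| `kanf_chk_offset` | 113 bp | kanF chk 3′ end upstream of the cassette 3′ end |
| `tm_target` | 60 °C | secondary objective during searches |

GC is computed on the anchored (genomic or cassette) portion only; tails
never count. N in a primer window is treated as a failure, like low GC:
oligos must be concrete, and any ambiguity code other than N in the genome is
a hard error.

**Outer re-selection.** The published workflow delegates relocation of
low-GC outer primers to an external primer-optimization program whose
objective is not specified. We implement an equivalent, dependency-free
exhaustive search over all (flank, length) pairs in the allowed bands,
choosing the candidate minimizing |flank − 300|, then |Tm − 60 °C|, then
(flank, length) as the deterministic tie-break. The tie-break is expressed in
gene-relative terms rather than genomic coordinates so that the design is
strand-symmetric: designing against a reverse-complemented genome yields
byte-identical oligos (a tested invariant). The search is validated against
an independently written brute-force argmin in the tests.

**Inner extension.** 5R and 3F cannot move (their ORF-adjacent ends define
the junction), so a low-GC inner primer is extended away from the ORF one
base at a time up to 35 nt. If the floor is still unmet at 35 nt the 35-mer
is kept with a warning note — extension beyond that is not allowed even when
it would eventually help, and extension proceeds even through bases that
temporarily lower GC.

**Check primers.** 5′chk/3′chk must lie strictly outside the homology arm
(so they cannot prime on the transforming fragment itself) and within 500 bp
of the arm's outer edge; among feasible sites the one closest to the arm
wins, keeping diagnostic products short — appropriate for whole-cell PCR.
The cassette-anchored primers are computed from the cassette record (marker
ATG offset, 3′-end offset), not hard-coded, so any marker cassette works.

**Tm model.** The Wallace rule 2(A+T) + 4(G+C) is the default: it is
deterministic and monotone under extension, which is all the extension rule
needs. A nearest-neighbor estimate (Biopython) is selectable via
`DesignConfig.tm_model="nn"`.

## PCR simulation

Priming requires a perfect match of the anchored portion on either strand
(a mismatch allowance exists; the 3′-terminal 3 nt must always match, since
3′ mismatches abolish extension). Every convergent plus/minus site pair whose
3′ ends do not cross yields a product, including pairs where one primer
supplies both sites; tails are excluded from matching and included in the
product. Products above `max_product` (default 5000 nt, generous for
whole-cell check PCR) are suppressed. There is no yield or efficiency model:
a band is "present" iff an amplicon exists.

The mixed-colony genotype is modelled as the union of wild-type and deletant
chromosome sets — a colony in which recombination occurred in only a
subpopulation of cells. An alternative "episomal" fixture mode retains the
linear construct beside an unedited genome; note that only the subpopulation
scenario produces bands in all three check reactions, because the construct
itself carries neither the 5′chk/3′chk sites (outside the arms) nor the ORF.

## Screen scoring and clustering

Spot-assay readouts are integer dilution depths (count of 10-fold dilution
spots showing growth) for mutant and wild type on the same plate. Calls:
very sensitive iff the mutant shows no growth while wild type grows;
sensitive iff it grows ≥ 2 dilution factors shallower ("approximately two or
more" is implemented as exactly ≥ 2 on integer depths); resistant iff it
grows deeper than wild type; not sensitive otherwise. A wild-type depth of 0
is an uninformative plate and an error. Repeated measurements of a cell keep
the most extreme confirmed call, with sensitivity winning ties against
resistance. The encoding 2/1/0/−1 is fixed.

Multi-stress counting supports two modes, because "affected by a stress" can
mean any nonzero call (sensitivity or resistance) or positive calls only;
both are reported in summaries. Percentages default to a denominator of 281,
the size of the deletion collection the workflow was built for.

Clustering is agglomerative complete linkage (scipy), Euclidean on the
ordinal codes by default; uncentered correlation — the historical default of
the clustering program commonly paired with TreeView — is selectable but
undefined on all-zero profiles (error suggests Euclidean). Because ordinal
profiles produce many tied distances, two correct complete-linkage
implementations may merge in different orders and report genuinely different
height multisets; the oracle test therefore audits each merge of the produced
dendrogram (height = max pairwise distance between the merged clusters, and
no closer active pair exists) rather than comparing height lists, which is
exact even under ties. Export follows the clustered-data-table conventions:
a CDT with rows in leaf order plus GTR (and ATR when columns are clustered)
join-tree files; the join-value column holds the merge distance.

## Synthetic data: what it does and does not emulate

Genomes are i.i.d. bases at 36 % GC (fission-yeast-like) with planted ORFs
(ATG…TAA) spaced ≥ 1100 bp so arms and check windows never collide. GC
pathology classes rewrite specific primer windows: `low_gc_5prime` /
`low_gc_3prime` plant a 5/24-GC outer window (20.8 %, below the floor), and
`low_gc_inner` plants a failing 5R window next to a GC-rich run so the
extension rule succeeds within the cap. The truth table records which rule
must fire, and the pipeline tests assert it fires exactly then. The cassette
is a random 45 %-GC sequence with a planted marker ATG — a synthetic
stand-in; only its geometry matters to the arithmetic.

Growth readouts are built by inverting the classifier (noise-free), so
scoring recovers the intended call matrix exactly. The synthetic 281-strain
call table reproduces the collection's aggregate structure — 77 strains
affected by ≥ 1 stress, 35 by ≥ 3 (both counting modes agree by
construction), 10 in the DNA-metabolism drug set and 10 in the latrunculin A
set — while which strains/conditions carry the calls is seeded-random. The
counts are generator contracts; what the tests demonstrate is that the
counting machinery recovers them from the matrix, not that real screen data
were reproduced.

None of the fixtures model real genome composition (repeats, introns, local
GC structure), plate noise, transformation efficiency or colony passaging;
conclusions about real data require real inputs through the same interfaces
(FASTA/GFF3/TSV).

## Problem sizes

The test suite and the acceptance script use 200 designed genes for the
rule-conformance sweep, 8 genes for end-to-end verification, 50 random
templates up to 20 kb for the PCR oracle, and 8×16 matrices for the
clustering audit — sizes at which the brute-force oracles remain exact and
fast while covering all GC classes and strands.

## Known limitations

* No primer-dimer/hairpin thermodynamics, multiplexing or plate layout.
* No PCR yield/efficiency model; band presence is purely combinatorial.
* Annotation handling is single-isoform, intron-unaware by design (the
  deletion removes the genomic block, so transcript structure is irrelevant).
* The re-selection objective is a documented stand-in for the unpublished
  objective of the original primer-optimization step; positions may differ
  from historical designs while satisfying the same constraints.
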
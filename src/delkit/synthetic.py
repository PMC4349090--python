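"""Synthetic fixtures: genomes with planted genes and GC pathologies, a
synthetic selection cassette, colony genotype templates, growth readouts and
a synthetic strain-collection phenotype table.

Everything is generated from a seed, so every module of the package can be
built and tested without downloading a real genome or supplementary data.
The background base composition defaults to 36% GC (fission-yeast-like);
planted AT-rich windows exercise the primer re-selection and extension
rules, and the truth table records which rule must fire for each gene.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from delkit.design import Cassette, DeletionDesign
from delkit.genome_io import (
    GeneModel,
    Genome,
    reverse_complement,
    write_annotation,
    write_genome,
)
from delkit.pcr import apply_deletion
from delkit.screen import PhenotypeMatrix, SensitivityCall, StressPanel

GC_CLASSES = ("normal", "low_gc_5prime", "low_gc_3prime", "low_gc_inner")

# room on both sides of each gene for flanks (<=500 bp) + check primers (<=500+35)
GENE_SPACING = 1100


class FixtureError(ValueError):
    """Raised on infeasible fixture specifications."""


@dataclass(frozen=True)
class GeneSpec:
    length: int = 900
    strand: str = "+"
    gc_class: str = "normal"

    def __post_init__(self) -> None:
        if self.gc_class not in GC_CLASSES:
            raise FixtureError(f"unknown gc_class {self.gc_class!r}")
        if self.length < 6:
            raise FixtureError("gene length must be >= 6")


@dataclass(frozen=True)
class FixtureSpec:
    seed: int = 1
    chromosome_name: str = "chrI"
    chromosome_length: int | None = None  # None: computed from gene packing
    genes: tuple[GeneSpec, ...] = (GeneSpec(),)
    background_gc: float = 0.36
    cassette_length: int = 1400
    marker_orf_start: int = 250


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return rng.choice(np.array(list("ACGT")), size=n, p=p)


def _window_with_gc(
    rng: np.random.Generator, length: int, n_gc: int
) -> str:
    """A random window with exactly n_gc G/C bases."""
    bases = [str(rng.choice(["G", "C"])) for _ in range(n_gc)]
    bases += [str(rng.choice(["A", "T"])) for _ in range(length - n_gc)]
    order = rng.permutation(length)
    return "".join(bases[i] for i in order)


def _write_gene_window(
    chrom: list[str], gene: GeneModel, rel_start: int, rel_end: int, seq: str
) -> None:
    """Write `seq` (gene transcription orientation) at a gene-relative window."""
    assert len(seq) == rel_end - rel_start + 1
    if gene.strand == "+":
        if rel_end < 0:
            g_start = gene.start + rel_start
        else:
            g_start = gene.end + rel_start
        chrom[g_start - 1 : g_start - 1 + len(seq)] = list(seq)
    else:
        if rel_end < 0:
            g_start = gene.end - rel_end
        else:
            g_start = gene.start - rel_end
        chrom[g_start - 1 : g_start - 1 + len(seq)] = list(reverse_complement(seq))


def synthetic_cassette(
    seed: int = 1, length: int = 1400, marker_orf_start: int = 250,
    name: str = "synthetic_marker_cassette",
) -> Cassette:
    """A synthetic dominant-marker cassette (random 45% GC, planted marker ATG).

    A stand-in for a real kanMX-style module: the true cassette sequence is
    not shipped, only its geometry (length, marker ATG offset) matters to the
    design and verification arithmetic.
    """
    rng = np.random.default_rng(seed + 977)
    seq = _random_bases(rng, length, 0.45)
    m = marker_orf_start
    seq[m - 1 : m + 2] = list("ATG")
    return Cassette(name=name, sequence="".join(seq), marker_orf_start=m)


def generate_genome(spec: FixtureSpec) -> tuple[Genome, list[GeneModel], dict]:
    """Generate a seeded genome with planted genes and GC pathologies.

    Returns the genome, the gene models and a truth table recording the
    planted GC class of every gene and the design rule it must trigger.
    The same spec always regenerates byte-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    n = len(spec.genes)
    if n == 0:
        raise FixtureError("at least one gene required")
    required = 2 * GENE_SPACING + sum(g.length for g in spec.genes) + (n - 1) * GENE_SPACING
    length = spec.chromosome_length or required
    if length < required:
        raise FixtureError(
            f"chromosome_length {length} cannot pack {n} genes with "
            f"{GENE_SPACING} bp spacing (needs >= {required})"
        )
    chrom = list(_random_bases(rng, length, spec.background_gc))

    genes: list[GeneModel] = []
    truth: dict[str, dict] = {}
    pos = GENE_SPACING + 1
    for i, gspec in enumerate(spec.genes):
        gene = GeneModel(
            gene_id=f"SYN{i + 1:03d}", chromosome=spec.chromosome_name,
            start=pos, end=pos + gspec.length - 1, strand=gspec.strand,
        )
        orf = "ATG" + "".join(_random_bases(rng, gspec.length - 6, spec.background_gc)) + "TAA"
        # write the ORF across the gene span (transcription orientation)
        if gene.strand == "+":
            chrom[gene.start - 1 : gene.end] = list(orf)
        else:
            chrom[gene.start - 1 : gene.end] = list(reverse_complement(orf))

        # default primer windows: AT-rich where the pathology is planted,
        # guaranteed >= 30% GC elsewhere
        low = 5   # 5/24 = 20.8% GC -> fails the 30% floor
        ok = 10   # 10/24 = 41.7% GC
        cls = gspec.gc_class
        win5f = _window_with_gc(rng, 24, low if cls == "low_gc_5prime" else ok)
        win3r = _window_with_gc(rng, 24, low if cls == "low_gc_3prime" else ok)
        _write_gene_window(chrom, gene, -324, -301, win5f)
        _write_gene_window(chrom, gene, 301, 324, win3r)
        if cls == "low_gc_inner":
            # AT-rich fixed 5R window with a GC-rich run just upstream so the
            # extension rule can rescue it within the 35-nt cap
            _write_gene_window(chrom, gene, -24, -1, _window_with_gc(rng, 24, low))
            _write_gene_window(chrom, gene, -35, -25, _window_with_gc(rng, 11, 11))
        else:
            _write_gene_window(chrom, gene, -24, -1, _window_with_gc(rng, 24, ok))
        expect = {
            "normal": None, "low_gc_5prime": "reselect_5F",
            "low_gc_3prime": "reselect_3R", "low_gc_inner": "extend_5R",
        }[cls]
        truth[gene.gene_id] = {"gc_class": cls, "expected_rule": expect}
        genes.append(gene)
        pos = gene.end + GENE_SPACING + 1

    genome = Genome(
        sequences={spec.chromosome_name: "".join(chrom)},
        source=f"synthetic(seed={spec.seed})",
    )
    return genome, genes, truth


def write_fixture(spec: FixtureSpec, outdir: str | Path) -> dict[str, Path]:
    """Materialize a genome fixture as FASTA + GFF3 + truth JSON on disk."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome, genes, truth = generate_genome(spec)
    paths = {
        "fasta": outdir / "genome.fa",
        "gff3": outdir / "genes.gff3",
        "truth": outdir / "truth.json",
        "cassette": outdir / "cassette.fa",
    }
    write_genome(genome, paths["fasta"])
    write_annotation(genes, paths["gff3"])
    cassette = synthetic_cassette(
        spec.seed, spec.cassette_length, spec.marker_orf_start
    )
    with open(paths["cassette"], "w") as fh:
        fh.write(f">{cassette.name}\n")
        for i in range(0, cassette.length, 70):
            fh.write(cassette.sequence[i : i + 70] + "\n")
    paths["truth"].write_text(json.dumps(
        {"seed": spec.seed, "marker_orf_start": spec.marker_orf_start, "genes": truth},
        indent=2,
    ))
    return paths


def generate_colony_templates(
    genome: Genome, design: DeletionDesign, cassette: Cassette,
    mode: str = "subpopulation",
) -> dict[str, list[tuple[str, str]]]:
    """Template sets for the three colony genotypes.

    mode="subpopulation": the mixed colony holds deletant cells alongside
    wild-type cells (recombination happened in only part of the colony) —
    this is the scenario that yields bands in all three check reactions.
    mode="episomal": the mixed colony holds wild-type cells plus the
    retained linear transformation fragment.
    """
    deletant = apply_deletion(genome, design, cassette)
    wt = [(f"wt:{n}", s) for n, s in genome.sequences.items()]
    dl = [(f"del:{n}", s) for n, s in deletant.sequences.items()]
    if mode == "subpopulation":
        mixed = wt + dl
    elif mode == "episomal":
        mixed = wt + [("episome:construct", design.construct)]
    else:
        raise FixtureError(f"unknown mixed-colony mode {mode!r}")
    return {"wild_type": wt, "deletant": dl, "mixed": mixed}


_DEPTH_FOR_LABEL = {
    "very_sensitive": lambda wt: 0,
    "sensitive": lambda wt: wt - 2,
    "not_sensitive": lambda wt: wt,
    "resistant": lambda wt: wt + 1,
}


def generate_growth_readouts(
    effects: dict[str, dict[str, str]],
    wt_depth: int = 5,
    max_depth: int = 6,
) -> pd.DataFrame:
    """Spot-assay dilution depths that the classifier maps back to the
    intended calls exactly (the inverse of classify_sensitivity; no noise).

    effects: strain -> condition -> intended label.  Conditions absent from
    a strain's table default to not_sensitive.
    """
    if wt_depth < 3:
        raise FixtureError("wt_depth must be >= 3 so 'sensitive' is reachable")
    conditions = StressPanel.canonical().names
    rows = []
    for strain, table in effects.items():
        for cond in conditions:
            label = table.get(cond, "not_sensitive")
            if label not in _DEPTH_FOR_LABEL:
                raise FixtureError(f"unknown intended call {label!r}")
            depth = _DEPTH_FOR_LABEL[label](wt_depth)
            if depth > max_depth:
                raise FixtureError(
                    f"{strain}/{cond}: 'resistant' unreachable with wild type at "
                    f"depth {wt_depth} and only {max_depth} dilution spots"
                )
            rows.append((strain, cond, depth, wt_depth))
    return pd.DataFrame(rows, columns=["strain", "condition", "mutant_depth", "wt_depth"])


def synthetic_phenotype_table(
    seed: int = 0,
    n_strains: int = 281,
    n_affected: int = 77,
    n_multi: int = 35,
    n_dna: int = 10,
    n_lata: int = 10,
) -> PhenotypeMatrix:
    """A synthetic stand-in for the published strain-collection call table.

    The real supplementary call table is not shipped; this generator builds a
    281-strain x 16-condition matrix whose aggregate structure matches the
    printed collection statistics — n_affected strains touched by >= 1
    stress, n_multi of them by >= 3, n_dna strains sensitive to a
    DNA-metabolism drug (hydroxyurea / bleomycin / MMS) and n_lata to
    latrunculin A.  Which strains and conditions carry the calls is random
    (seeded); the aggregate counts are exact by construction, so the
    screen-scoring machinery can be exercised end to end.
    """
    if not (n_multi <= n_affected <= n_strains):
        raise FixtureError("need n_multi <= n_affected <= n_strains")
    if n_dna > n_affected or n_lata > n_affected:
        raise FixtureError("drug-set sizes cannot exceed n_affected")
    rng = np.random.default_rng(seed)
    panel = StressPanel.canonical().names
    special = {"hydroxyurea", "bleomycin", "MMS", "latrunculin_A"}
    dna_conds = ["hydroxyurea", "bleomycin", "MMS"]
    other = [c for c in panel if c not in special]

    strains = [f"del{i + 1:03d}" for i in range(n_strains)]
    affected = list(rng.permutation(n_strains)[:n_affected])
    multi, mild = affected[:n_multi], affected[n_multi:]
    n_dna_multi = min(6, n_dna, len(multi))
    dna_members = multi[:n_dna_multi] + mild[: n_dna - n_dna_multi]
    n_lata_multi = min(6, n_lata, max(0, len(multi) - n_dna_multi))
    lata_members = (
        multi[n_dna_multi : n_dna_multi + n_lata_multi]
        + mild[n_dna - n_dna_multi : n_dna - n_dna_multi + n_lata - n_lata_multi]
    )

    data = np.zeros((n_strains, len(panel)), dtype=int)
    col = {c: j for j, c in enumerate(panel)}

    def plant(i: int, conds: list[str], n_calls: int) -> None:
        chosen = rng.choice(len(conds), size=n_calls, replace=False)
        for j in chosen:
            data[i, col[conds[j]]] = int(rng.choice([1, 2]))

    for i in multi:
        plant(i, other, 3 + int(rng.integers(0, 3)))  # 3-5 sensitivity calls
        if rng.random() < 0.3:  # an extra resistance call, beyond the 3 floor
            free = [c for c in other if data[i, col[c]] == 0]
            if free:
                data[i, col[free[int(rng.integers(len(free)))]]] = -1
    for i in mild:
        if i in dna_members or i in lata_members:
            if rng.random() < 0.5:  # at most one extra call, staying below 3
                plant(i, other, 1)
        else:
            plant(i, other, 1 + int(rng.integers(0, 2)))
    for i in dna_members:
        c = dna_conds[int(rng.integers(3))]
        data[i, col[c]] = int(rng.choice([1, 2]))
    for i in lata_members:
        data[i, col["latrunculin_A"]] = int(rng.choice([1, 2]))

    return PhenotypeMatrix(
        data=pd.DataFrame(data, index=strains, columns=panel)
    )
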
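"""Deletion-primer design: flanking primers with cassette homology tails,
check primers, GC/length re-selection rules and fusion-construct assembly.

The strategy deletes an ORF by replacing it with a dominant selection
cassette.  Two flank amplicons (targeted ~300 bp each) are produced with
primer pairs 5F/5R and 3F/3R; the inner primers 5R and 3F carry 23-nt tails
complementary to the cassette termini, so a second, fusion PCR primed by the
flank products on the cassette template yields flank5–cassette–flank3
(~2 kb with a typical cassette).  Five check primers (5chk, 3chk, ORFchk on
the genome; kanRchk, kanFchk on the cassette) support three diagnostic
colony-PCR reactions plus a wild-type control.

Rules implemented:

* default primer windows: 5F at -324..-301, 5R at -24..-1, 3F at +1..+24,
  3R at +301..+324 (offsets in transcription orientation; default flanks are
  therefore 324 bp);
* every outer/check primer must have >=30% GC; failing outer primers are
  re-selected (24-35 nt, flank kept within 200-500 bp) by exhaustive search;
* the inner primers 5R/3F cannot move, so a low-GC inner primer is extended
  away from the ORF boundary up to 35 nt;
* check primers sit within 500 bp outside the homology arms (ORFchk within
  the first 100 bp of the ORF); kanRchk's 3' end lies 20 bp downstream of
  the marker ATG, kanFchk's 3' end 113 bp upstream of the cassette 3' end.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from delkit.genome_io import (
    GeneModel,
    Genome,
    GenomeIOError,
    extract,
    extract_gene_window,
    gene_relative_window,
    orf_window,
    reverse_complement,
)

OUTER_PRIMERS = ("5F", "3R")
INNER_PRIMERS = ("5R", "3F")
CHECK_PRIMERS = ("5chk", "3chk", "ORFchk", "kanRchk", "kanFchk")
PRIMER_NAMES = OUTER_PRIMERS + INNER_PRIMERS + CHECK_PRIMERS


class DesignError(ValueError):
    """Raised when no primer satisfying the design rules exists."""


def gc_content(seq: str) -> float:
    """GC fraction of a sequence; N counts as non-GC. Errors on empty input."""
    if not seq:
        raise DesignError("gc_content of empty sequence")
    seq = seq.upper()
    return (seq.count("G") + seq.count("C")) / len(seq)


def tm_estimate(seq: str, model: str = "wallace") -> float:
    """Melting-temperature estimate in degrees C.

    Default is the Wallace rule 2(A+T) + 4(G+C), which is deterministic and
    monotonically non-decreasing under extension by any base.  A
    nearest-neighbor estimate is available via model="nn" (Biopython's
    thermodynamic tables).
    """
    if len(seq) < 8:
        raise DesignError(f"tm_estimate needs >= 8 nt, got {len(seq)}")
    seq = seq.upper()
    if model == "wallace":
        gc = seq.count("G") + seq.count("C")
        at = len(seq) - gc  # N treated as weakly pairing (A/T weight)
        return float(2 * at + 4 * gc)
    if model == "nn":
        from Bio.SeqUtils import MeltingTemp

        return float(MeltingTemp.Tm_NN(seq))
    raise DesignError(f"unknown Tm model {model!r}")


@dataclass(frozen=True)
class Cassette:
    """Selection cassette used as replacement sequence and fusion template."""

    name: str
    sequence: str
    marker_orf_start: int  # 1-based offset of the resistance-gene ATG

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if set(seq) - set("ACGT"):
            raise DesignError(f"cassette {self.name!r} contains non-ACGT characters")
        if not (1 <= self.marker_orf_start <= len(seq)):
            raise DesignError(
                f"cassette {self.name!r}: marker_orf_start {self.marker_orf_start} "
                f"outside 1..{len(seq)}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Primer:
    """An oligo with its genomic (or cassette) anchor.

    `oligo` is written 5'->3'.  `gc_fraction` and `tm_C` are computed on the
    anchored portion only — homology tails never count.
    """

    name: str
    oligo: str
    tail_len: int = 0
    # genomic anchor: (chromosome, start, end, strand); None for cassette primers
    anchor: tuple[str, int, int, str] | None = None
    # cassette anchor: (cassette name, start, end, strand); None for genomic primers
    cassette_anchor: tuple[str, int, int, str] | None = None
    gc_fraction: float = 0.0
    tm_C: float = 0.0
    notes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.name not in PRIMER_NAMES:
            raise DesignError(f"unknown primer name {self.name!r}")
        if self.tail_len and self.name not in INNER_PRIMERS:
            raise DesignError(f"{self.name}: only 5R/3F carry cassette tails")
        if not (24 <= self.anchored_len <= 35):
            raise DesignError(
                f"{self.name}: anchored length {self.anchored_len} outside 24..35"
            )

    @property
    def anchored_oligo(self) -> str:
        """The genome/cassette-matching portion (tail stripped)."""
        return self.oligo[self.tail_len :]

    @property
    def anchored_len(self) -> int:
        return len(self.oligo) - self.tail_len

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "oligo": self.oligo,
            "tail_len": self.tail_len,
            "anchor": list(self.anchor) if self.anchor else None,
            "cassette_anchor": list(self.cassette_anchor) if self.cassette_anchor else None,
            "gc_fraction": round(self.gc_fraction, 4),
            "tm_C": round(self.tm_C, 2),
            "notes": list(self.notes),
        }

    @staticmethod
    def from_dict(d: dict) -> "Primer":
        return Primer(
            name=d["name"], oligo=d["oligo"], tail_len=d["tail_len"],
            anchor=tuple(d["anchor"]) if d.get("anchor") else None,
            cassette_anchor=tuple(d["cassette_anchor"]) if d.get("cassette_anchor") else None,
            gc_fraction=d.get("gc_fraction", 0.0), tm_C=d.get("tm_C", 0.0),
            notes=tuple(d.get("notes", ())),
        )


@dataclass(frozen=True)
class DesignConfig:
    """Tunable design constraints; defaults are the published rules."""

    flank_target: int = 300       # targeted flank length, bp
    flank_min: int = 200
    flank_max: int = 500
    primer_min: int = 24          # anchored primer length band, nt
    primer_max: int = 35
    min_gc: float = 0.30
    tail_len: int = 23            # cassette homology tail on 5R/3F
    chk_window: int = 500         # 5chk/3chk placed within this many bp outside the arm
    orf_chk_window: int = 100     # ORFchk within the first N bp of the ORF
    kanr_chk_offset: int = 20     # kanRchk 3' end, bp downstream of marker ATG
    kanf_chk_offset: int = 113    # kanFchk 3' end, bp upstream of cassette 3' end
    tm_target: float = 60.0
    tm_model: str = "wallace"
    stop_included_in_orf: bool = True  # +1 = first base after the stop codon

    @property
    def default_flank(self) -> int:
        # outer 24-mer at -(target+24)..-(target+1): flank spans outer start..-1
        return self.flank_target + self.primer_min


DEFAULT_CONFIG = DesignConfig()


@dataclass
class DeletionDesign:
    """Complete primer set, flank amplicons and fused construct for one gene."""

    gene: GeneModel
    primers: dict[str, Primer]
    flank5: tuple[int, int]  # genomic interval of the 5' homology arm
    flank3: tuple[int, int]
    flank5_len: int
    flank3_len: int
    flank5_seq: str  # transcription orientation
    flank3_seq: str
    cassette_name: str
    construct: str
    construct_len: int
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "schema": "delkit/1",
            "gene": {
                "gene_id": self.gene.gene_id, "chromosome": self.gene.chromosome,
                "start": self.gene.start, "end": self.gene.end,
                "strand": self.gene.strand, "name": self.gene.name,
            },
            "primers": {k: p.to_dict() for k, p in self.primers.items()},
            "flank5": list(self.flank5), "flank3": list(self.flank3),
            "flank5_len": self.flank5_len, "flank3_len": self.flank3_len,
            "flank5_seq": self.flank5_seq, "flank3_seq": self.flank3_seq,
            "cassette_name": self.cassette_name,
            "construct": self.construct, "construct_len": self.construct_len,
            "notes": self.notes,
        }

    @staticmethod
    def from_dict(d: dict) -> "DeletionDesign":
        g = d["gene"]
        return DeletionDesign(
            gene=GeneModel(g["gene_id"], g["chromosome"], g["start"], g["end"],
                           g["strand"], g.get("name")),
            primers={k: Primer.from_dict(p) for k, p in d["primers"].items()},
            flank5=tuple(d["flank5"]), flank3=tuple(d["flank3"]),
            flank5_len=d["flank5_len"], flank3_len=d["flank3_len"],
            flank5_seq=d["flank5_seq"], flank3_seq=d["flank3_seq"],
            cassette_name=d["cassette_name"],
            construct=d["construct"], construct_len=d["construct_len"],
            notes=list(d["notes"]),
        )


# ---------------------------------------------------------------------------
# primer construction helpers

def _window_primer(
    genome: Genome, gene: GeneModel, name: str, rel_start: int, rel_end: int,
    orientation: str, config: DesignConfig, notes: tuple[str, ...] = (),
) -> Primer:
    """Build a genomic primer from a gene-relative window.

    orientation 'fwd' = primer reads in the gene's transcription orientation;
    'rev' = reverse complement (points back toward lower transcript coords).
    """
    g_start, g_end = gene_relative_window(gene, rel_start, rel_end, genome)
    sense = extract(genome, gene.chromosome, g_start, g_end, gene.strand)
    if orientation == "fwd":
        oligo = sense
        strand = gene.strand
    else:
        oligo = reverse_complement(sense)
        strand = "-" if gene.strand == "+" else "+"
    return Primer(
        name=name, oligo=oligo, tail_len=0,
        anchor=(gene.chromosome, g_start, g_end, strand),
        gc_fraction=gc_content(oligo), tm_C=tm_estimate(oligo, config.tm_model),
        notes=notes,
    )


def default_primer_windows(
    genome: Genome, gene: GeneModel, config: DesignConfig = DEFAULT_CONFIG
) -> dict[str, Primer]:
    """Draft 5F/5R/3F/3R primers at the default windows (tails not attached).

    5F and 3R point toward the gene; 5R and 3F are the fixed 24-mers
    immediately adjacent to the ORF boundaries.
    """
    f = config.default_flank  # 324 by default
    p = config.primer_min
    try:
        return {
            "5F": _window_primer(genome, gene, "5F", -f, -f + p - 1, "fwd", config),
            "5R": _window_primer(genome, gene, "5R", -p, -1, "rev", config),
            "3F": _window_primer(genome, gene, "3F", 1, p, "fwd", config),
            "3R": _window_primer(genome, gene, "3R", f - p + 1, f, "rev", config),
        }
    except GenomeIOError as exc:
        raise DesignError(
            f"{gene.gene_id}: default primer windows do not fit the chromosome "
            f"({exc}); re-select the outer primer with a shorter flank"
        ) from exc


def needs_reselection(primer: Primer, config: DesignConfig = DEFAULT_CONFIG) -> tuple[bool, str]:
    """A primer fails if its anchored GC is below the floor or it contains N."""
    anchored = primer.anchored_oligo
    if "N" in anchored:
        return True, f"{primer.name}: window contains N"
    gc = gc_content(anchored)
    if gc < config.min_gc:
        return True, f"{primer.name}: GC {gc:.1%} < {config.min_gc:.0%}"
    return False, ""


def _feasible(seq: str, config: DesignConfig) -> bool:
    return "N" not in seq and gc_content(seq) >= config.min_gc


def reselect_outer_primer(
    genome: Genome, gene: GeneModel, side: str, config: DesignConfig = DEFAULT_CONFIG
) -> tuple[Primer, int]:
    """Relocate a failing outer primer (5F or 3R) by exhaustive search.

    Candidates are all (flank length F, primer length L) pairs with
    F in [flank_min, flank_max] and L in [primer_min, primer_max]; the primer
    occupies the outermost L bases of the F-bp flank.  Among candidates with
    >=30% GC and no N the choice minimizes |F - flank_target|, then
    |Tm - tm_target|, then (F, L) — a fully deterministic, strand-symmetric
    tie-break.  Returns the primer and the new flank length.
    """
    if side not in ("5", "3"):
        raise DesignError(f"side must be '5' or '3', got {side!r}")
    name = "5F" if side == "5" else "3R"
    best_key: tuple | None = None
    best: tuple[Primer, int] | None = None
    for flank in range(config.flank_min, config.flank_max + 1):
        for length in range(config.primer_min, config.primer_max + 1):
            if side == "5":
                rel = (-flank, -flank + length - 1)
                orientation = "fwd"
            else:
                rel = (flank - length + 1, flank)
                orientation = "rev"
            try:
                g_start, g_end = gene_relative_window(gene, rel[0], rel[1], genome)
            except GenomeIOError:
                continue
            sense = extract(genome, gene.chromosome, g_start, g_end, gene.strand)
            oligo = sense if orientation == "fwd" else reverse_complement(sense)
            if not _feasible(oligo, config):
                continue
            tm = tm_estimate(oligo, config.tm_model)
            key = (abs(flank - config.flank_target), abs(tm - config.tm_target), flank, length)
            if best_key is None or key < best_key:
                best_key = key
                strand = gene.strand if orientation == "fwd" else ("-" if gene.strand == "+" else "+")
                primer = Primer(
                    name=name, oligo=oligo, tail_len=0,
                    anchor=(gene.chromosome, g_start, g_end, strand),
                    gc_fraction=gc_content(oligo), tm_C=tm,
                    notes=(f"re-selected: flank {flank} bp, length {length} nt",),
                )
                best = (primer, flank)
    if best is None:
        raise DesignError(
            f"{gene.gene_id} {name}: no candidate with GC >= {config.min_gc:.0%} in "
            f"flank band [{config.flank_min},{config.flank_max}] x "
            f"length [{config.primer_min},{config.primer_max}]"
        )
    return best


def extend_inner_primer(
    genome: Genome, gene: GeneModel, primer: Primer,
    config: DesignConfig = DEFAULT_CONFIG,
) -> Primer:
    """Extend a low-GC inner primer (5R/3F) away from the ORF boundary.

    The ORF-adjacent end never moves.  Extension proceeds one base at a time
    up to 35 nt; if the GC floor is still unmet at 35 nt the 35-mer is
    returned with a warning note.
    """
    if primer.name not in INNER_PRIMERS:
        raise DesignError(f"extend_inner_primer applies to 5R/3F, not {primer.name}")
    if _feasible(primer.anchored_oligo, config):
        return primer
    last: Primer | None = None
    for length in range(primer.anchored_len, config.primer_max + 1):
        if primer.name == "5R":
            cand = _window_primer(
                genome, gene, "5R", -length, -1, "rev", config,
                notes=(f"extended to {length} nt",),
            )
        else:
            cand = _window_primer(
                genome, gene, "3F", 1, length, "fwd", config,
                notes=(f"extended to {length} nt",),
            )
        last = cand
        if _feasible(cand.anchored_oligo, config):
            return cand
    assert last is not None
    return replace(
        last,
        notes=last.notes + (f"warning: GC {last.gc_fraction:.1%} still below "
                            f"{config.min_gc:.0%} at {config.primer_max} nt",),
    )


def add_cassette_tails(
    primer_5r: Primer, primer_3f: Primer, cassette: Cassette,
    config: DesignConfig = DEFAULT_CONFIG,
) -> tuple[Primer, Primer]:
    """Attach the 23-nt cassette homology tails to the inner primers.

    The 5' flank product must end (top strand) with the first 23 cassette
    bases, so 5R gains reverse-complement(cassette[1..23]) at its 5' end; the
    3' flank product must start with the last 23 cassette bases, so 3F gains
    cassette[-23:].  Tails are excluded from GC/Tm bookkeeping.
    """
    t = config.tail_len
    if cassette.length < t:
        raise DesignError(f"cassette shorter than tail length {t}")
    tail5 = reverse_complement(cassette.sequence[:t])
    tail3 = cassette.sequence[-t:]
    tailed_5r = replace(primer_5r, oligo=tail5 + primer_5r.oligo, tail_len=t)
    tailed_3f = replace(primer_3f, oligo=tail3 + primer_3f.oligo, tail_len=t)
    return tailed_5r, tailed_3f


def _search_chk(
    genome: Genome, gene: GeneModel, name: str, side: str,
    flank_len: int, config: DesignConfig,
) -> Primer:
    """Place 5chk/3chk just outside the homology arm, within chk_window bp.

    Candidates are scored by (distance from the arm's outer edge, |Tm-target|,
    length); the nearest feasible site wins, keeping diagnostic products short.
    """
    best_key: tuple | None = None
    best: Primer | None = None
    for dist in range(0, config.chk_window):
        if best_key is not None and dist > best_key[0]:
            break  # distance is the primary key; nothing farther can win
        for length in range(config.primer_min, config.primer_max + 1):
            if dist + length > config.chk_window:
                continue
            if side == "5":  # forward primer strictly upstream of the arm
                rel_end = -flank_len - 1 - dist
                rel = (rel_end - length + 1, rel_end)
                orientation = "fwd"
            else:  # reverse primer strictly downstream of the arm
                rel_start = flank_len + 1 + dist
                rel = (rel_start, rel_start + length - 1)
                orientation = "rev"
            try:
                g_start, g_end = gene_relative_window(gene, rel[0], rel[1], genome)
            except GenomeIOError:
                continue
            sense = extract(genome, gene.chromosome, g_start, g_end, gene.strand)
            oligo = sense if orientation == "fwd" else reverse_complement(sense)
            if not _feasible(oligo, config):
                continue
            tm = tm_estimate(oligo, config.tm_model)
            key = (dist, abs(tm - config.tm_target), length)
            if best_key is None or key < best_key:
                best_key = key
                strand = gene.strand if orientation == "fwd" else ("-" if gene.strand == "+" else "+")
                best = Primer(
                    name=name, oligo=oligo, tail_len=0,
                    anchor=(gene.chromosome, g_start, g_end, strand),
                    gc_fraction=gc_content(oligo), tm_C=tm,
                )
    if best is None:
        raise DesignError(
            f"{gene.gene_id} {name}: no GC-feasible site within {config.chk_window} bp "
            f"outside the {side}' homology arm"
        )
    return best


def _orf_chk(genome: Genome, gene: GeneModel, config: DesignConfig) -> Primer:
    """Reverse primer anchored within the first orf_chk_window bp of the ORF."""
    best_key: tuple | None = None
    best: Primer | None = None
    limit = min(config.orf_chk_window, gene.length)
    for start in range(1, limit + 1):
        for length in range(config.primer_min, config.primer_max + 1):
            end = start + length - 1
            if end > limit:
                continue
            g_start, g_end = orf_window(gene, start, end)
            sense = extract(genome, gene.chromosome, g_start, g_end, gene.strand)
            oligo = reverse_complement(sense)
            if not _feasible(oligo, config):
                continue
            tm = tm_estimate(oligo, config.tm_model)
            key = (abs(tm - config.tm_target), start, length)
            if best_key is None or key < best_key:
                best_key = key
                strand = "-" if gene.strand == "+" else "+"
                best = Primer(
                    name="ORFchk", oligo=oligo, tail_len=0,
                    anchor=(gene.chromosome, g_start, g_end, strand),
                    gc_fraction=gc_content(oligo), tm_C=tm,
                )
    if best is None:
        raise DesignError(
            f"{gene.gene_id} ORFchk: no GC-feasible site in the first "
            f"{config.orf_chk_window} bp of the ORF"
        )
    return best


def _cassette_chk(cassette: Cassette, name: str, config: DesignConfig) -> Primer:
    """kanRchk / kanFchk, anchored on the cassette at the published offsets.

    kanRchk: reverse primer whose 3' end sits kanr_chk_offset bp downstream
    of the marker ATG.  kanFchk: forward primer whose 3' end sits
    kanf_chk_offset bp upstream of the cassette 3' end.  Starting length is
    24 nt, extended away from the fixed 3' end up to 35 nt if GC is low.
    """
    seq = cassette.sequence
    last: Primer | None = None
    for length in range(config.primer_min, config.primer_max + 1):
        if name == "kanRchk":
            start = cassette.marker_orf_start + config.kanr_chk_offset  # 3' end
            end = start + length - 1
            if end > cassette.length:
                break
            oligo = reverse_complement(seq[start - 1 : end])
            anchor = (cassette.name, start, end, "-")
        else:
            end = cassette.length - config.kanf_chk_offset  # 3' end
            start = end - length + 1
            if start < 1:
                break
            oligo = seq[start - 1 : end]
            anchor = (cassette.name, start, end, "+")
        primer = Primer(
            name=name, oligo=oligo, tail_len=0, cassette_anchor=anchor,
            gc_fraction=gc_content(oligo),
            tm_C=tm_estimate(oligo, config.tm_model),
        )
        last = primer
        if _feasible(oligo, config):
            return primer
    if last is None:
        raise DesignError(f"{name}: cassette too short for the published anchor offset")
    return replace(last, notes=(f"warning: GC {last.gc_fraction:.1%} below floor",))


def design_check_primers(
    genome: Genome, gene: GeneModel, flank5_len: int, flank3_len: int,
    cassette: Cassette, config: DesignConfig = DEFAULT_CONFIG,
) -> dict[str, Primer]:
    """The five diagnostic primers for the left/right/ORF check reactions."""
    return {
        "5chk": _search_chk(genome, gene, "5chk", "5", flank5_len, config),
        "3chk": _search_chk(genome, gene, "3chk", "3", flank3_len, config),
        "ORFchk": _orf_chk(genome, gene, config),
        "kanRchk": _cassette_chk(cassette, "kanRchk", config),
        "kanFchk": _cassette_chk(cassette, "kanFchk", config),
    }


def assemble_construct(
    flank5_seq: str, flank3_seq: str, cassette: Cassette,
    primer_5r: Primer, primer_3f: Primer, config: DesignConfig = DEFAULT_CONFIG,
) -> str:
    """Fuse flank5–cassette–flank3, verifying the 23-nt junction overlaps.

    The tails on 5R/3F must exactly reproduce the cassette termini; a
    mismatch means the fusion PCR could not prime and is a hard error.
    """
    t = config.tail_len
    if primer_5r.tail_len != t or primer_3f.tail_len != t:
        raise DesignError("inner primers lack cassette tails; run add_cassette_tails first")
    if reverse_complement(primer_5r.oligo[:t]) != cassette.sequence[:t]:
        raise DesignError("5R tail does not match the cassette 5' terminus")
    if primer_3f.oligo[:t] != cassette.sequence[-t:]:
        raise DesignError("3F tail does not match the cassette 3' terminus")
    return flank5_seq + cassette.sequence + flank3_seq


def design_gene_deletion(
    genome: Genome, gene: GeneModel, cassette: Cassette,
    config: DesignConfig = DEFAULT_CONFIG,
) -> DeletionDesign:
    """Run the full design pipeline for one gene.

    defaults -> GC checks -> outer re-selection / inner extension -> cassette
    tails -> check primers -> fusion-construct assembly.  Every deviation
    from the default windows is recorded in `notes`.
    """
    genome.validate_gene(gene)
    notes: list[str] = []
    drafts = default_primer_windows(genome, gene, config)

    flank5_len = flank3_len = config.default_flank
    p5f, p3r = drafts["5F"], drafts["3R"]
    bad, reason = needs_reselection(p5f, config)
    if bad:
        p5f, flank5_len = reselect_outer_primer(genome, gene, "5", config)
        notes.append(f"5F re-selected ({reason}); new flank {flank5_len} bp")
    bad, reason = needs_reselection(p3r, config)
    if bad:
        p3r, flank3_len = reselect_outer_primer(genome, gene, "3", config)
        notes.append(f"3R re-selected ({reason}); new flank {flank3_len} bp")

    p5r, p3f = drafts["5R"], drafts["3F"]
    bad, reason = needs_reselection(p5r, config)
    if bad:
        p5r = extend_inner_primer(genome, gene, p5r, config)
        notes.append(f"5R extended to {p5r.anchored_len} nt ({reason})")
    bad, reason = needs_reselection(p3f, config)
    if bad:
        p3f = extend_inner_primer(genome, gene, p3f, config)
        notes.append(f"3F extended to {p3f.anchored_len} nt ({reason})")

    p5r, p3f = add_cassette_tails(p5r, p3f, cassette, config)
    chks = design_check_primers(genome, gene, flank5_len, flank3_len, cassette, config)

    flank5_iv = gene_relative_window(gene, -flank5_len, -1, genome)
    flank3_iv = gene_relative_window(gene, 1, flank3_len, genome)
    flank5_seq = extract_gene_window(genome, gene, -flank5_len, -1)
    flank3_seq = extract_gene_window(genome, gene, 1, flank3_len)
    construct = assemble_construct(flank5_seq, flank3_seq, cassette, p5r, p3f, config)

    primers = {"5F": p5f, "5R": p5r, "3F": p3f, "3R": p3r, **chks}
    return DeletionDesign(
        gene=gene, primers=primers,
        flank5=flank5_iv, flank3=flank3_iv,
        flank5_len=flank5_len, flank3_len=flank3_len,
        flank5_seq=flank5_seq, flank3_seq=flank3_seq,
        cassette_name=cassette.name,
        construct=construct, construct_len=len(construct),
        notes=notes,
    )


def load_cassette(path: str, marker_orf_start: int, name: str | None = None) -> Cassette:
    """Read a single-record cassette FASTA with its marker-ATG offset."""
    from Bio import SeqIO

    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise DesignError(f"cassette FASTA must hold exactly one record, found {len(records)}")
    rec = records[0]
    return Cassette(
        name=name or rec.id, sequence=str(rec.seq).upper(),
        marker_orf_start=marker_orf_start,
    )
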
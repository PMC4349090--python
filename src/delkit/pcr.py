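"""In-silico genome editing and PCR: locus replacement, primer-site search,
amplicon prediction and the diagnostic three-reaction colony verdict.

Colony verification uses three reactions plus one control:

* left  = 5chk x kanRchk — spans the upstream junction into the cassette;
* right = kanFchk x 3chk — spans the cassette into the downstream junction;
* ORF   = 5chk x ORFchk  — detects the targeted ORF (absent in a deletant);
* the same ORF reaction on wild-type cells is the positive control that
  rules out a technical amplification failure.

A G418-resistant colony can be a mixed population — cells with the
correctly integrated cassette alongside cells retaining the target ORF —
which shows up as bands in all three reactions at once.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from delkit.design import Cassette, DeletionDesign, Primer
from delkit.genome_io import Genome, reverse_complement


class PCRError(ValueError):
    """Raised on inconsistent design/template combinations."""


VERDICTS = ("correct_deletion", "no_integration", "mixed_population", "ambiguous")


@dataclass(frozen=True)
class PrimerSite:
    """One anchored match of a primer on a template strand."""

    strand: str          # '+' = primer extends rightward, '-' = leftward
    start: int           # 1-based inclusive template coords of the anchored match
    end: int
    primer_name: str
    mismatches: int = 0

    @property
    def three_prime(self) -> int:
        """Template coordinate of the primer's 3' end."""
        return self.end if self.strand == "+" else self.start


@dataclass(frozen=True)
class Amplicon:
    """A predicted PCR product."""

    template_id: str
    start: int   # primed span on the template, 1-based inclusive
    end: int
    length: int  # includes incorporated tails
    sequence: str
    fwd_primer: str
    rev_primer: str


def apply_deletion(genome: Genome, design: DeletionDesign, cassette: Cassette) -> Genome:
    """Replace the gene span with the cassette (in gene orientation).

    Models the homologous-recombination outcome: ATG..stop inclusive is
    excised and the cassette integrates reading in the same direction as the
    deleted gene.  Errors if the genome no longer carries the wild-type flank
    sequences at the design's recorded anchors (e.g. deletion already applied).
    """
    gene = design.gene
    if gene.chromosome not in genome.sequences:
        raise PCRError(f"chromosome {gene.chromosome!r} not in genome")
    chrom = genome.sequences[gene.chromosome]
    from delkit.genome_io import extract

    for iv, expected, label in (
        (design.flank5, design.flank5_seq, "5' flank"),
        (design.flank3, design.flank3_seq, "3' flank"),
    ):
        try:
            found = extract(genome, gene.chromosome, iv[0], iv[1], gene.strand)
        except Exception as exc:
            raise PCRError(f"{gene.gene_id}: {label} anchor out of bounds ({exc})") from exc
        if found != expected:
            raise PCRError(
                f"{gene.gene_id}: {label} sequence at {iv[0]}..{iv[1]} does not match "
                "the design (genome already edited, or design/genome mismatch)"
            )
    insert = cassette.sequence if gene.strand == "+" else reverse_complement(cassette.sequence)
    edited = chrom[: gene.start - 1] + insert + chrom[gene.end :]
    sequences = dict(genome.sequences)
    sequences[gene.chromosome] = edited
    return Genome(sequences=sequences, source=f"{genome.source}|del({gene.gene_id})")


def find_primer_sites(
    template: str, primer: Primer | str, max_mismatch: int = 0
) -> list[PrimerSite]:
    """All anchored matches of a primer on either strand of a template.

    Only the anchored (non-tail) portion is matched; tails are incorporated
    into products later.  With max_mismatch > 0, the 3'-terminal 3 nt must
    still match exactly (mismatches there abolish priming).
    """
    if isinstance(primer, Primer):
        anchored = primer.anchored_oligo
        name = primer.name
    else:
        anchored = primer.upper()
        name = "<anon>"
    if not anchored:
        raise PCRError("primer has empty anchored portion")
    template = template.upper()
    sites: list[PrimerSite] = []
    rc = reverse_complement(anchored)
    L = len(anchored)
    if max_mismatch == 0:
        for query, strand in ((anchored, "+"), (rc, "-")):
            idx = template.find(query)
            while idx != -1:
                sites.append(PrimerSite(strand, idx + 1, idx + L, name))
                idx = template.find(query, idx + 1)
    else:
        for i in range(len(template) - L + 1):
            window = template[i : i + L]
            mm_plus = sum(a != b for a, b in zip(anchored, window))
            if mm_plus <= max_mismatch and anchored[-3:] == window[-3:]:
                sites.append(PrimerSite("+", i + 1, i + L, name, mm_plus))
            mm_minus = sum(a != b for a, b in zip(rc, window))
            # on the minus strand the primer 3' end maps to the window start
            if mm_minus <= max_mismatch and rc[:3] == window[:3]:
                sites.append(PrimerSite("-", i + 1, i + L, name, mm_minus))
    sites.sort(key=lambda s: (s.start, s.strand, s.primer_name))
    return sites


def simulate_pcr(
    template_id: str,
    template: str,
    fwd: Primer,
    rev: Primer,
    max_product: int = 5000,
    max_mismatch: int = 0,
) -> list[Amplicon]:
    """Predict all products of a two-primer PCR on one template.

    Every convergent (plus-strand, minus-strand) site pair drawn from either
    primer yields a product, provided the two 3' ends do not cross and the
    product (tails included) is at most max_product nt.  An empty list means
    no band.  Ordering is deterministic: (start, length, primer names).
    """
    primers = {fwd.name: fwd}
    primers[rev.name] = rev  # fwd is rev: single entry, still enumerated both ways
    plus_sites: list[tuple[PrimerSite, Primer]] = []
    minus_sites: list[tuple[PrimerSite, Primer]] = []
    for p in primers.values():
        for site in find_primer_sites(template, p, max_mismatch):
            (plus_sites if site.strand == "+" else minus_sites).append((site, p))
    products: list[Amplicon] = []
    for psite, pf in plus_sites:
        for msite, pr in minus_sites:
            if psite.start > msite.start or psite.end > msite.end:
                continue  # divergent or crossed 3' ends
            span = msite.end - psite.start + 1
            length = span + pf.tail_len + pr.tail_len
            if length > max_product:
                continue
            core = template[psite.start - 1 : msite.end]
            seq = pf.oligo[: pf.tail_len] + core + reverse_complement(pr.oligo[: pr.tail_len])
            products.append(
                Amplicon(
                    template_id=template_id, start=psite.start, end=msite.end,
                    length=length, sequence=seq,
                    fwd_primer=pf.name, rev_primer=pr.name,
                )
            )
    products.sort(key=lambda a: (a.start, a.length, a.fwd_primer, a.rev_primer))
    return products


def simulate_pcr_on_templates(
    templates: list[tuple[str, str]], fwd: Primer, rev: Primer, max_product: int = 5000
) -> list[Amplicon]:
    """simulate_pcr over a set of co-amplifying templates (one tube)."""
    out: list[Amplicon] = []
    for tid, seq in templates:
        out.extend(simulate_pcr(tid, seq, fwd, rev, max_product))
    return out


def classify_colony(left: bool, right: bool, orf: bool, wt_control: bool) -> str:
    """Verdict from the four band-presence observations.

    A missing wild-type ORF control band means the ORF reaction is
    uninterpretable (a technical failure cannot be ruled out) -> ambiguous.
    """
    if not wt_control:
        return "ambiguous"
    if left and right and not orf:
        return "correct_deletion"
    if left and right and orf:
        return "mixed_population"
    if not left and not right and orf:
        return "no_integration"
    return "ambiguous"


REACTIONS = ("left", "right", "orf")
GENOTYPES = ("wild_type", "deletant", "mixed")


@dataclass
class VerificationReport:
    """Predicted band sizes per reaction for each colony genotype, plus verdicts."""

    gene_id: str
    bands: dict[str, dict[str, list[int]]]   # genotype -> reaction -> product lengths
    wt_control_bands: list[int]              # ORF reaction on wild-type cells
    verdicts: dict[str, str]                 # genotype -> verdict

    def to_dict(self) -> dict:
        return {
            "schema": "delkit/1",
            "gene_id": self.gene_id,
            "bands": self.bands,
            "wt_control_bands": self.wt_control_bands,
            "verdicts": self.verdicts,
        }


def _genome_templates(genome: Genome, tag: str) -> list[tuple[str, str]]:
    return [(f"{tag}:{name}", seq) for name, seq in genome.sequences.items()]


def predict_check_bands(
    design: DeletionDesign,
    wild_type: Genome,
    deletant: Genome,
    max_product: int = 5000,
    extra_mixed_templates: list[tuple[str, str]] | None = None,
) -> VerificationReport:
    """Run the three check reactions in silico on each colony genotype.

    The mixed genotype pools wild-type and deletant templates (a colony whose
    cells are a mixture), so its band set is the union of the two.
    """
    for name in ("5chk", "3chk", "ORFchk", "kanRchk", "kanFchk"):
        if name not in design.primers:
            raise PCRError(f"design lacks check primer {name}")
    p = design.primers
    reactions = {
        "left": (p["5chk"], p["kanRchk"]),
        "right": (p["kanFchk"], p["3chk"]),
        "orf": (p["5chk"], p["ORFchk"]),
    }
    wt_templates = _genome_templates(wild_type, "wt")
    del_templates = _genome_templates(deletant, "del")
    mixed_templates = wt_templates + del_templates + (extra_mixed_templates or [])
    genotype_templates = {
        "wild_type": wt_templates,
        "deletant": del_templates,
        "mixed": mixed_templates,
    }
    bands: dict[str, dict[str, list[int]]] = {}
    for genotype, templates in genotype_templates.items():
        bands[genotype] = {}
        for rxn, (fwd, rev) in reactions.items():
            prods = simulate_pcr_on_templates(templates, fwd, rev, max_product)
            bands[genotype][rxn] = sorted(a.length for a in prods)
    wt_control = bands["wild_type"]["orf"]
    verdicts = {
        genotype: classify_colony(
            left=bool(bands[genotype]["left"]),
            right=bool(bands[genotype]["right"]),
            orf=bool(bands[genotype]["orf"]),
            wt_control=bool(wt_control),
        )
        for genotype in GENOTYPES
    }
    return VerificationReport(
        gene_id=design.gene.gene_id, bands=bands,
        wt_control_bands=list(wt_control), verdicts=verdicts,
    )
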
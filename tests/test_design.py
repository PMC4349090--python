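"""Primer design rules: GC/Tm arithmetic, default windows, re-selection and
extension (checked against brute-force oracles), tails and construct assembly."""

import numpy as np
import pytest

from delkit.design import (
    DEFAULT_CONFIG,
    Cassette,
    DesignError,
    add_cassette_tails,
    assemble_construct,
    default_primer_windows,
    design_check_primers,
    design_gene_deletion,
    extend_inner_primer,
    gc_content,
    needs_reselection,
    reselect_outer_primer,
    tm_estimate,
)
from delkit.genome_io import GeneModel, Genome, extract, reverse_complement
from tests.conftest import random_sequence


class TestGcContent:
    @pytest.mark.parametrize(
        "seq,expected",
        [("ATAT", 0.0), ("GCGC", 1.0), ("ATGCATGCAT", 0.4), ("ANNNT", 0.0)],
    )
    def test_values(self, seq, expected):
        assert gc_content(seq) == pytest.approx(expected)

    def test_empty_rejected(self):
        with pytest.raises(DesignError):
            gc_content("")


class TestTmEstimate:
    def test_gc_raises_tm(self):
        assert tm_estimate("GCGCGCGCGCGC") > tm_estimate("ATATATATATAT")

    def test_wallace_formula(self):
        # 2(A+T) + 4(G+C), checked directly
        rng = np.random.default_rng(3)
        for _ in range(20):
            seq = "".join(rng.choice(list("ACGT"), size=int(rng.integers(8, 40))))
            gc = seq.count("G") + seq.count("C")
            assert tm_estimate(seq) == 2 * (len(seq) - gc) + 4 * gc

    def test_extension_never_lowers_tm(self):
        rng = np.random.default_rng(4)
        for _ in range(30):
            seq = "".join(rng.choice(list("ACGT"), size=12))
            for base in "ACGT":
                assert tm_estimate(seq + base) >= tm_estimate(seq)

    def test_reverse_complement_symmetry(self):
        seq = "ATGCATTTGCGA"
        assert tm_estimate(seq) == tm_estimate(reverse_complement(seq))

    def test_too_short_rejected(self):
        with pytest.raises(DesignError):
            tm_estimate("ACGTACG")


class TestDefaultWindows:
    def test_plus_strand_anchors(self, small_genome, plus_gene):
        drafts = default_primer_windows(small_genome, plus_gene)
        anchors = {n: p.anchor for n, p in drafts.items()}
        assert anchors["5F"] == ("chrI", 1677, 1700, "+")
        assert anchors["5R"] == ("chrI", 1977, 2000, "-")
        assert anchors["3F"] == ("chrI", 2901, 2924, "+")
        assert anchors["3R"] == ("chrI", 3201, 3224, "-")

    def test_minus_strand_mirror(self, small_genome, minus_gene):
        drafts = default_primer_windows(small_genome, minus_gene)
        anchors = {n: p.anchor for n, p in drafts.items()}
        assert anchors["5F"] == ("chrI", 3201, 3224, "-")
        assert anchors["5R"] == ("chrI", 2901, 2924, "+")
        assert anchors["3F"] == ("chrI", 1977, 2000, "-")
        assert anchors["3R"] == ("chrI", 1677, 1700, "+")

    def test_oligos_match_genome(self, small_genome, plus_gene):
        drafts = default_primer_windows(small_genome, plus_gene)
        assert drafts["5F"].oligo == extract(small_genome, "chrI", 1677, 1700)
        assert drafts["5R"].oligo == reverse_complement(
            extract(small_genome, "chrI", 1977, 2000)
        )

    def test_default_flank_is_324(self):
        assert DEFAULT_CONFIG.default_flank == 324

    def test_gene_near_chromosome_end_rejected(self, small_genome):
        gene = GeneModel("edge", "chrI", 100, 900, "+")
        with pytest.raises(DesignError, match="re-select"):
            default_primer_windows(small_genome, gene)


class TestNeedsReselection:
    def _primer_with(self, n_gc: int):
        from delkit.design import Primer

        oligo = "G" * n_gc + "A" * (24 - n_gc)
        return Primer(name="5F", oligo=oligo, anchor=("chrI", 1, 24, "+"),
                      gc_fraction=gc_content(oligo), tm_C=tm_estimate(oligo))

    def test_seven_of_24_fails(self):
        flagged, reason = needs_reselection(self._primer_with(7))
        assert flagged and "GC" in reason

    def test_eight_of_24_passes(self):
        flagged, _ = needs_reselection(self._primer_with(8))
        assert not flagged

    def test_n_in_window_fails(self):
        from delkit.design import Primer

        oligo = "G" * 12 + "N" + "A" * 11
        p = Primer(name="5F", oligo=oligo, anchor=("chrI", 1, 24, "+"),
                   gc_fraction=gc_content(oligo), tm_C=tm_estimate(oligo))
        flagged, reason = needs_reselection(p)
        assert flagged and "N" in reason


def brute_force_reselect(genome, gene, side, config=DEFAULT_CONFIG):
    """Independent exhaustive argmin over all (flank, length) candidates.

    Enumerates windows with raw genomic arithmetic (plus-strand genes only)
    and replays the documented objective.
    """
    assert gene.strand == "+"
    chrom = genome.sequences[gene.chromosome]
    best_key, best = None, None
    for flank in range(config.flank_min, config.flank_max + 1):
        for length in range(config.primer_min, config.primer_max + 1):
            if side == "5":
                g_start = gene.start - flank           # 1-based window start
                if g_start < 1:
                    continue
                oligo = chrom[g_start - 1 : g_start - 1 + length]
            else:
                g_end = gene.end + flank
                if g_end > len(chrom):
                    continue
                oligo = reverse_complement(chrom[g_end - length : g_end])
            if len(oligo) < length:
                continue
            if "N" in oligo or gc_content(oligo) < config.min_gc:
                continue
            tm = tm_estimate(oligo)
            key = (abs(flank - config.flank_target), abs(tm - config.tm_target),
                   flank, length)
            if best_key is None or key < best_key:
                best_key, best = key, (oligo, flank)
    return best


class TestReselectOuterPrimer:
    def test_relocated_primer_obeys_rules(self, fixture_all_classes, cassette):
        genome, genes, truth = fixture_all_classes
        gene = next(g for g in genes if truth[g.gene_id]["gc_class"] == "low_gc_5prime")
        primer, flank = reselect_outer_primer(genome, gene, "5")
        assert 200 <= flank <= 500
        assert 24 <= primer.anchored_len <= 35
        assert primer.gc_fraction >= 0.30

    def test_matches_exhaustive_oracle(self):
        # plus-strand gene with an AT-rich default 5F window
        rng = np.random.default_rng(11)
        chrom = list(random_sequence(11, 8000))
        gene = GeneModel("g", "chrI", 3001, 3900, "+")
        chrom[3001 - 324 - 1 : 3001 - 301] = list("AT" * 12)  # default window fails
        genome = Genome({"chrI": "".join(chrom)})
        for side in ("5", "3"):
            primer, flank = reselect_outer_primer(genome, gene, side)
            oracle_oligo, oracle_flank = brute_force_reselect(genome, gene, side)
            assert (primer.oligo, flank) == (oracle_oligo, oracle_flank)

    def test_infeasible_band_errors(self):
        # entire searchable 5' band is poly-A
        chrom = "A" * 4000 + random_sequence(5, 4000, gc=0.5)
        gene = GeneModel("g", "chrI", 3001, 3900, "+")
        genome = Genome({"chrI": chrom})
        with pytest.raises(DesignError, match="no candidate"):
            reselect_outer_primer(genome, gene, "5")


class TestExtendInnerPrimer:
    def test_shortest_sufficient_extension(self, fixture_all_classes):
        genome, genes, truth = fixture_all_classes
        gene = next(g for g in genes if truth[g.gene_id]["gc_class"] == "low_gc_inner")
        draft = default_primer_windows(genome, gene)["5R"]
        extended = extend_inner_primer(genome, gene, draft)
        assert extended.gc_fraction >= 0.30
        # brute force: the first length in 24..35 whose window clears the floor
        from delkit.genome_io import extract_gene_window

        lengths_ok = [
            L for L in range(24, 36)
            if gc_content(extract_gene_window(genome, gene, -L, -1)) >= 0.30
        ]
        assert extended.anchored_len == lengths_ok[0]

    def test_noop_when_gc_fine(self, small_genome, plus_gene):
        draft = default_primer_windows(small_genome, plus_gene)["3F"]
        assert gc_content(draft.oligo) >= 0.30
        assert extend_inner_primer(small_genome, plus_gene, draft) is draft

    def test_cap_at_35_with_warning(self):
        # AT-only context: extension can never reach the floor
        chrom = "A" * 3000 + "ATG" + random_sequence(6, 894, gc=0.5) + "TAA" + "A" * 3000
        gene = GeneModel("g", "chrI", 3001, 3900, "+")
        genome = Genome({"chrI": chrom})
        draft = default_primer_windows(genome, gene)["5R"]
        extended = extend_inner_primer(genome, gene, draft)
        assert extended.anchored_len == 35
        assert any("warning" in n for n in extended.notes)

    def test_anchored_end_never_moves(self, fixture_all_classes):
        genome, genes, truth = fixture_all_classes
        gene = next(g for g in genes if truth[g.gene_id]["gc_class"] == "low_gc_inner")
        draft = default_primer_windows(genome, gene)["5R"]
        extended = extend_inner_primer(genome, gene, draft)
        # 5R is a reverse primer: its 5' oligo end is the ORF-adjacent base
        assert extended.oligo[: 1] == draft.oligo[: 1]
        assert extended.oligo[: 24] == draft.oligo[: 24]


class TestCassetteTails:
    def test_tailed_lengths_47(self, small_genome, plus_gene, cassette):
        drafts = default_primer_windows(small_genome, plus_gene)
        t5r, t3f = add_cassette_tails(drafts["5R"], drafts["3F"], cassette)
        assert len(t5r.oligo) == len(t3f.oligo) == 47
        assert t5r.tail_len == t3f.tail_len == 23

    def test_tails_reproduce_cassette_termini(self, small_genome, plus_gene, cassette):
        drafts = default_primer_windows(small_genome, plus_gene)
        t5r, t3f = add_cassette_tails(drafts["5R"], drafts["3F"], cassette)
        assert reverse_complement(t5r.oligo[:23]) == cassette.sequence[:23]
        assert t3f.oligo[:23] == cassette.sequence[-23:]

    def test_flank_product_ends_with_cassette_start(self, normal_design, cassette):
        """Simulated 5' flank PCR: the top strand must end with cassette[1..23]."""
        from delkit.pcr import simulate_pcr

        genome, design = normal_design
        chrom = genome.sequences[design.gene.chromosome]
        products = simulate_pcr("chrI", chrom, design.primers["5F"], design.primers["5R"])
        assert len(products) == 1
        assert products[0].sequence.endswith(cassette.sequence[:23])

    def test_gc_excludes_tail(self, small_genome, plus_gene, cassette):
        drafts = default_primer_windows(small_genome, plus_gene)
        t5r, _ = add_cassette_tails(drafts["5R"], drafts["3F"], cassette)
        assert t5r.gc_fraction == pytest.approx(gc_content(t5r.anchored_oligo))
        assert t5r.gc_fraction == drafts["5R"].gc_fraction


class TestCheckPrimers:
    def test_positions(self, normal_design, cassette):
        genome, design = normal_design
        gene = design.gene
        p = design.primers
        # 5chk strictly upstream of the 5F window, within 500 bp of the arm edge
        assert p["5chk"].anchor[2] < p["5F"].anchor[1]  # plus-strand gene
        assert p["5F"].anchor[1] - p["5chk"].anchor[1] <= 500
        # 3chk strictly downstream of the 3R window
        assert p["3chk"].anchor[1] > p["3R"].anchor[2]
        # ORFchk anchored within the first 100 bp of the ORF
        assert gene.start <= p["ORFchk"].anchor[1]
        assert p["ORFchk"].anchor[2] <= gene.start + 99

    def test_cassette_chk_offsets(self, cassette):
        from delkit.design import _cassette_chk

        kanr = _cassette_chk(cassette, "kanRchk", DEFAULT_CONFIG)
        kanf = _cassette_chk(cassette, "kanFchk", DEFAULT_CONFIG)
        # kanRchk: reverse primer, 3' end 20 bp downstream of the marker ATG
        assert kanr.cassette_anchor[1] == cassette.marker_orf_start + 20
        assert kanr.oligo == reverse_complement(
            cassette.sequence[kanr.cassette_anchor[1] - 1 : kanr.cassette_anchor[2]]
        )
        # kanFchk: forward primer, 3' end 113 bp upstream of the cassette 3' end
        assert kanf.cassette_anchor[2] == cassette.length - 113
        assert kanf.oligo in cassette.sequence

    def test_all_chk_gc_floor(self, normal_design):
        _, design = normal_design
        for name in ("5chk", "3chk", "ORFchk"):
            assert design.primers[name].gc_fraction >= 0.30


class TestAssembleConstruct:
    def test_default_length_2048(self, normal_design, cassette):
        _, design = normal_design
        assert design.flank5_len == design.flank3_len == 324
        assert design.construct_len == 324 + cassette.length + 324 == 2048

    def test_junction_unique(self, normal_design, cassette):
        _, design = normal_design
        probe = cassette.sequence[:23]
        assert design.construct.count(probe) == 1
        assert design.construct.index(probe) == design.flank5_len

    def test_untailed_primers_rejected(self, small_genome, plus_gene, cassette):
        drafts = default_primer_windows(small_genome, plus_gene)
        with pytest.raises(DesignError, match="tails"):
            assemble_construct("A" * 324, "T" * 324, cassette, drafts["5R"], drafts["3F"])

    def test_tail_cassette_mismatch_rejected(self, small_genome, plus_gene, cassette):
        drafts = default_primer_windows(small_genome, plus_gene)
        t5r, t3f = add_cassette_tails(drafts["5R"], drafts["3F"], cassette)
        other = Cassette("other", reverse_complement(cassette.sequence), 10)
        with pytest.raises(DesignError, match="terminus"):
            assemble_construct("A" * 324, "T" * 324, other, t5r, t3f)


class TestDesignGeneDeletion:
    def test_normal_gene_no_notes(self, normal_design):
        _, design = normal_design
        assert design.notes == []
        assert set(design.primers) == {
            "5F", "5R", "3F", "3R", "5chk", "3chk", "ORFchk", "kanRchk", "kanFchk"
        }

    def test_pathological_genes_note_rule(self, fixture_all_classes, cassette):
        genome, genes, truth = fixture_all_classes
        for gene in genes:
            expected = truth[gene.gene_id]["expected_rule"]
            design = design_gene_deletion(genome, gene, cassette)
            if expected is None:
                assert design.notes == []
            elif expected == "reselect_5F":
                assert any("5F re-selected" in n for n in design.notes)
            elif expected == "reselect_3R":
                assert any("3R re-selected" in n for n in design.notes)
            elif expected == "extend_5R":
                assert any("5R extended" in n for n in design.notes)

    def test_deterministic(self, fixture_all_classes, cassette):
        genome, genes, _ = fixture_all_classes
        a = design_gene_deletion(genome, genes[1], cassette)
        b = design_gene_deletion(genome, genes[1], cassette)
        assert a.to_dict() == b.to_dict()

    def test_strand_symmetry(self, fixture_all_classes, cassette):
        """Oligo sequences are invariant under reverse-complementing the genome."""
        genome, genes, _ = fixture_all_classes
        for gene in genes[:2]:
            n = genome.length_of(gene.chromosome)
            mirrored = Genome(
                {gene.chromosome: reverse_complement(genome.sequences[gene.chromosome])}
            )
            mirror_gene = GeneModel(
                gene.gene_id, gene.chromosome,
                n - gene.end + 1, n - gene.start + 1,
                "-" if gene.strand == "+" else "+",
            )
            d1 = design_gene_deletion(genome, gene, cassette)
            d2 = design_gene_deletion(mirrored, mirror_gene, cassette)
            for name in d1.primers:
                assert d1.primers[name].oligo == d2.primers[name].oligo, name
            assert d1.construct == d2.construct

    def test_construct_length_conservation(self, fixture_all_classes, cassette):
        genome, genes, _ = fixture_all_classes
        for gene in genes:
            d = design_gene_deletion(genome, gene, cassette)
            assert d.construct_len == d.flank5_len + cassette.length + d.flank3_len
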
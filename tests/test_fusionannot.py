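"""Annotation and classification: gene assignment, frame algebra, the
definite/likely rules, and round-trip consistency with the caller."""

import pytest

from trkfuse import cohort, fusionannot, svcall, synthdata
from trkfuse.fusionannot import Breakpoint, FusionAnnotation, GeneModel


def _call(chrom_a, pos_a, chrom_b, pos_b, strand_a="+", strand_b="+", support=8):
    return svcall.FusionCall(
        chrom_a, pos_a, strand_a, chrom_b, pos_b, strand_b, "N" * 120, support, True
    )


def _simple_gene(name="G", chrom="chr1", strand="+", start=1000, n_exons=4,
                 exon_len=120, intron_len=300, coding=True, kinase_exons=None):
    exons, pos = [], start
    for _ in range(n_exons):
        exons.append((pos, pos + exon_len))
        pos += exon_len + intron_len
    kd = None
    if kinase_exons:
        kd = (exons[kinase_exons[0] - 1][0], exons[kinase_exons[-1] - 1][1])
    return GeneModel(
        name=name, chrom=chrom, strand=strand, exons=tuple(exons),
        cds=tuple(exons) if coding else (), kinase_domain=kd,
    )


class TestGeneModelGeometry:
    def test_locate_exons_and_introns(self):
        g = _simple_gene()
        assert g.locate(1000) == ("exon", 1)
        assert g.locate(1119) == ("exon", 1)
        assert g.locate(1120) == ("intron", 1)
        assert g.locate(1420) == ("exon", 2)
        assert g.locate(999) is None  # 1 bp before the gene start
        assert g.locate(g.end) is None

    def test_minus_strand_ordinals_reverse(self):
        g = _simple_gene(strand="-")
        assert g.locate(1000) == ("exon", 4)  # genomic-first exon is last in transcript
        assert g.locate(1120) == ("intron", 3)

    def test_overlapping_exons_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            GeneModel("X", "chr1", "+", exons=((0, 100), (50, 150)))


class TestMapBreakpoints:
    def test_etv6_ntrk3_composition(self, gene_models):
        call = _call("chr12", 7400, "chr15", 27080)
        side_a, side_b = fusionannot.map_breakpoints_to_genes(call, gene_models)
        assert side_a.gene.name == "ETV6" and side_a.location == ("intron", 5)
        assert side_b.gene.name == "NTRK3" and side_b.location == ("intron", 14)
        assert side_a.retained_exons == (1, 5)
        assert side_b.retained_exons == (15, 19)

    def test_lmna_ntrk1_composition(self, gene_models):
        call = _call("chr1", 9840, "chr1", 35000)  # LMNA intron 2 / NTRK1 intron 10
        a = fusionannot.annotate_call(call, gene_models)
        assert a.composition() == "LMNA exon1-2-NTRK1 exon11-17"

    def test_intergenic_breakpoint_unassigned(self, gene_models):
        call = _call("chr12", 100, "chr15", 27080)
        side_a, side_b = fusionannot.map_breakpoints_to_genes(call, gene_models)
        assert side_a is None and side_b is not None
        assert fusionannot.annotate_call(call, gene_models) is None

    def test_one_bp_before_gene_start_is_intergenic(self, model_by_name, gene_models):
        etv6 = model_by_name["ETV6"]
        call = _call("chr12", etv6.start - 1, "chr15", 27080)
        side_a, _ = fusionannot.map_breakpoints_to_genes(call, gene_models)
        assert side_a is None

    def test_overlapping_genes_ambiguous(self, gene_models):
        extra = _simple_gene(name="OVL", chrom="chr12", start=7000, n_exons=3)
        call = _call("chr12", 7400, "chr15", 27080)
        with pytest.raises(fusionannot.AmbiguousGeneError):
            fusionannot.map_breakpoints_to_genes(call, list(gene_models) + [extra])


class TestJunctionFrame:
    def _partner(self, retained_cds, strand="+", retained="left"):
        # single-exon gene whose retained CDS length is exactly `retained_cds`
        g = GeneModel("P", "chrA", strand, exons=((0, 1000),), cds=((0, 1000),))
        pos = retained_cds if retained == "left" else 1000 - retained_cds
        return Breakpoint(g, pos, retained)

    def _ntrk(self, upstream_cds, strand="+", retained="right"):
        g = GeneModel(
            "NTRK9", "chrB", strand, exons=((0, 1200),), cds=((0, 1200),),
            kinase_domain=(900, 1200),
        )
        pos = upstream_cds if retained == "right" else 1200 - upstream_cds
        return Breakpoint(g, pos, retained)

    @pytest.mark.parametrize(
        "p,u,expected", [(300, 0, True), (301, 0, False), (300, 1, False), (301, 1, True)]
    )
    def test_frame_congruence(self, p, u, expected):
        in_strand, in_frame = fusionannot.junction_frame(self._partner(p), self._ntrk(u))
        assert in_strand is True and in_frame is expected

    @pytest.mark.parametrize(
        "p_strand,p_retained,n_strand,n_retained,expected",
        [
            ("+", "left", "+", "right", True),   # both read 5'->3' into/out of junction
            ("-", "right", "-", "left", True),   # same chimera on the opposite strands
            ("-", "left", "+", "right", False),  # partner contributes its 3' end
            ("+", "left", "-", "right", False),  # kinase side contributes its 5' end
        ],
    )
    def test_strand_orientation_table(self, p_strand, p_retained, n_strand, n_retained, expected):
        in_strand, _ = fusionannot.junction_frame(
            self._partner(300, p_strand, p_retained), self._ntrk(0, n_strand, n_retained)
        )
        assert in_strand is expected

    def test_noncoding_partner_never_in_frame(self):
        g = GeneModel("LNC", "chrA", "+", exons=((0, 1000),), cds=())
        bp = Breakpoint(g, 300, "left")
        in_strand, in_frame = fusionannot.junction_frame(bp, self._ntrk(0))
        assert in_strand is True and in_frame is False

    def test_invariant_to_noncoding_downstream_exons(self):
        """Extra non-coding exons past the kinase domain cannot change frame."""
        base = GeneModel(
            "NTRKX", "chrB", "+", exons=((0, 600), (900, 1200)),
            cds=((0, 600), (900, 1200)), kinase_domain=(900, 1200),
        )
        extended = GeneModel(
            "NTRKX", "chrB", "+", exons=((0, 600), (900, 1200), (1500, 1700)),
            cds=((0, 600), (900, 1200)), kinase_domain=(900, 1200),
        )
        p = self._partner(300)
        for u_pos in (0, 300, 600):
            f1 = fusionannot.junction_frame(p, Breakpoint(base, u_pos, "right"))
            f2 = fusionannot.junction_frame(p, Breakpoint(extended, u_pos, "right"))
            assert f1 == f2


class TestClassifyFusion:
    @pytest.mark.parametrize(
        "flags,expected",
        [
            ((True, True, True, False, False), "Definite"),
            ((True, True, True, True, True), "Definite"),
            ((True, False, True, False, True), "Likely"),
            ((True, False, True, True, False), "Likely"),
            ((False, False, True, True, False), "Likely"),
            ((True, False, True, False, False), "NotReportable"),
            ((True, True, False, True, True), "NotReportable"),
            ((False, False, False, True, True), "NotReportable"),
        ],
    )
    def test_rules(self, flags, expected):
        assert fusionannot.classify_fusion(*flags) == expected

    def test_table_fixture_reproduces_definite_likely_split(self):
        """Flags re-encoded from the transcribed fusion table give 34/7."""
        t2 = cohort.load_table2()
        results = []
        for row in t2.itertuples():
            in_frame = row.classification == "Definite"
            known = row.novelty == "Reported"
            hot = not known  # every out-of-frame novel partner sits in a hot region
            results.append(fusionannot.classify_fusion(True, in_frame, True, known, hot))
        assert results.count("Definite") == 34
        assert results.count("Likely") == 7

    def test_annotation_invariants_enforced(self):
        with pytest.raises(AssertionError):
            FusionAnnotation(
                "P", "NTRK1", (1, 2), (11, 17), in_strand=True, in_frame=False,
                kinase_domain_retained=True, classification="Definite",
                rearrangement_type="intrachromosomal", novelty="Reported",
            )


class TestRearrangementTypeAndNovelty:
    def test_rearrangement_type(self):
        assert fusionannot.rearrangement_type("chr1", "chr1") == "intrachromosomal"
        assert fusionannot.rearrangement_type("chr12", "chr15") == "interchromosomal"
        # distance is irrelevant on the same chromosome
        assert fusionannot.rearrangement_type("chr1", "chr1") == "intrachromosomal"

    def test_novelty_membership_case_insensitive(self):
        kb = fusionannot.load_known_partners()
        assert fusionannot.call_novelty("ETV6", kb) == "Reported"
        assert fusionannot.call_novelty("etv6", kb) == "Reported"
        assert fusionannot.call_novelty("INSRR", kb) == "Novel"

    def test_empty_symbol_rejected(self):
        with pytest.raises(ValueError):
            fusionannot.call_novelty("", {"ETV6"})


class TestRoundTrip:
    def test_simulated_event_annotates_to_planted_composition(self, toy_ref, gene_models):
        """Reads planted at (ETV6 intron 5, NTRK3 intron 14) come back as the
        same exon composition after calling + annotation."""
        event = synthdata.PlantedFusion("chr12", 7400, "chr15", 27080, n_support_pairs=8)
        records = synthdata.simulate_fusion_reads(toy_ref, event, 1000, seed=6)
        (call,) = svcall.call_pipeline(records, toy_ref)
        a = fusionannot.annotate_call(call, gene_models)
        assert a.composition() == "ETV6 exon1-5-NTRK3 exon15-19"
        assert a.classification == "Definite"
        assert a.rearrangement_type == "interchromosomal"
        assert a.novelty == "Reported"

    def test_hot_exon_rescue_for_out_of_frame_novel_partner(self, toy_ref, gene_models):
        """C7orf69 exon 1-3 -> NTRK3 intron 14 is out-of-frame (301 CDS bases)
        but lands in a hot intron, so it classifies as Likely."""
        # C7orf69 intron 3 does not exist (3 exons); break right after exon 3
        c7 = next(g for g in gene_models if g.name == "C7orf69")
        event = synthdata.PlantedFusion("chr7", c7.exons[2][1] - 20, "chr15", 27080, n_support_pairs=8)
        records = synthdata.simulate_fusion_reads(toy_ref, event, 500, seed=8)
        (call,) = svcall.call_pipeline(records, toy_ref)
        a = fusionannot.annotate_call(call, gene_models)
        assert a.partner_gene == "C7orf69" and a.ntrk_gene == "NTRK3"
        assert a.in_frame is False
        assert a.classification == "Likely"
        assert a.novelty == "Novel"
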
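"""Variant-effect classification on hand-built and randomly generated toy genes.

All gene models and sequences here are synthetic constructions for testing;
no real genome or annotation data is embedded.
"""

import numpy as np
import pytest
from Bio.Seq import Seq

from linepanel.effects import (
    AnnotationError,
    AnnotationModel,
    EffectSummary,
    classify_variant,
    effect_summary,
)
from linepanel.genotypes import SnpRecord
from linepanel.simulate import synthesize_reference, toy_annotation_gff3

# --- hand-built two-exon gene on a 400 bp chromosome ----------------------
# exon1 11-70, intron 71-100, exon2 101-160
# CDS 31-70 (40 bp, phase 0) + 101-132 (32 bp, phase 2) = 72 bp
CODING = "ATG" + "GCT" * 10 + "CAA" + "GCT" * 11 + "TAA"
assert len(CODING) == 72

GFF_PLUS = """##gff-version 3
chrT\ttoy\tgene\t11\t160\t.\t+\t.\tID=gene:g1
chrT\ttoy\tmRNA\t11\t160\t.\t+\t.\tID=tx:g1.t1;Parent=gene:g1
chrT\ttoy\texon\t11\t70\t.\t+\t.\tID=exon:g1.e1;Parent=tx:g1.t1
chrT\ttoy\texon\t101\t160\t.\t+\t.\tID=exon:g1.e2;Parent=tx:g1.t1
chrT\ttoy\tCDS\t31\t70\t.\t+\t0\tID=cds:g1.c1;Parent=tx:g1.t1
chrT\ttoy\tCDS\t101\t132\t.\t+\t2\tID=cds:g1.c2;Parent=tx:g1.t1
"""


def _genome_plus():
    seq = list("A" * 400)
    seq[30:70] = CODING[:40]
    seq[100:132] = CODING[40:]
    return {"chrT": "".join(seq)}


@pytest.fixture(scope="module")
def plus_model():
    return AnnotationModel.from_gff3(GFF_PLUS), _genome_plus()


def _snp(pos, ref, alt, chrom="chrT"):
    return SnpRecord(chrom, pos, ref, alt, 0.3)


class TestCodingClassification:
    def test_synonymous_third_base(self, plus_model):
        ann, genome = plus_model
        (call,) = classify_variant(_snp(36, "T", "C"), ann, genome)
        assert call.term == "synonymous_variant"
        assert call.aa_change == "p.Ala2Ala"

    def test_missense(self, plus_model):
        ann, genome = plus_model
        (call,) = classify_variant(_snp(34, "G", "A"), ann, genome)
        assert call.term == "missense_variant"
        assert call.aa_change == "p.Ala2Thr"

    def test_stop_gained(self, plus_model):
        ann, genome = plus_model
        # codon 12 is CAA (coding idx 33-35 -> genomic 64-66); C->T gives TAA
        (call,) = classify_variant(_snp(64, "C", "T"), ann, genome)
        assert call.term == "stop_gained"
        assert call.aa_change == "p.Gln12Ter"

    def test_splice_region_with_synonymous(self, plus_model):
        ann, genome = plus_model
        # third base of codon 13 sits 1 bp inside the exon1/intron boundary
        (call,) = classify_variant(_snp(69, "T", "C"), ann, genome)
        assert call.term == "synonymous_variant" and call.splice_region
        assert call.so_string == "splice_region_variant&synonymous_variant"

    def test_second_cds_exon_continues_reading_frame(self, plus_model):
        ann, genome = plus_model
        # genomic 102 is coding idx 41, third base of codon 14 (GCT -> GCC)
        (call,) = classify_variant(_snp(102, "T", "C"), ann, genome)
        assert call.term == "synonymous_variant"
        assert call.aa_change == "p.Ala14Ala"

    def test_ref_mismatch_raises(self, plus_model):
        ann, genome = plus_model
        with pytest.raises(AnnotationError, match="mismatch"):
            classify_variant(_snp(36, "G", "C"), ann, genome)


class TestNonCodingClassification:
    @pytest.mark.parametrize(
        "pos,ref,term",
        [
            (15, "A", "5_prime_UTR_variant"),
            (140, "A", "3_prime_UTR_variant"),
            (85, "A", "intron_variant"),
        ],
    )
    def test_gene_regions(self, plus_model, pos, ref, term):
        ann, genome = plus_model
        (call,) = classify_variant(_snp(pos, ref, "G"), ann, genome)
        assert call.term == term

    def test_intron_splice_region(self, plus_model):
        ann, genome = plus_model
        (call,) = classify_variant(_snp(73, "A", "G"), ann, genome)
        assert call.term == "intron_variant" and call.splice_region

    def test_flanks_and_intergenic(self, plus_model):
        ann, genome = plus_model
        (up,) = classify_variant(_snp(5, "A", "G"), ann, genome, flank_bp=10)
        assert up.term == "upstream_gene_variant"
        (down,) = classify_variant(_snp(165, "A", "G"), ann, genome, flank_bp=10)
        assert down.term == "downstream_gene_variant"
        (ig,) = classify_variant(_snp(300, "A", "G"), ann, genome, flank_bp=10)
        assert ig.term == "intergenic_variant" and ig.gene_id is None


class TestValidation:
    def test_cds_not_multiple_of_three_rejected(self):
        bad = GFF_PLUS.replace("chrT\ttoy\tCDS\t101\t132", "chrT\ttoy\tCDS\t101\t131")
        with pytest.raises(AnnotationError, match="divisible"):
            AnnotationModel.from_gff3(bad)

    def test_overlapping_exons_rejected(self):
        bad = GFF_PLUS.replace("chrT\ttoy\texon\t101\t160", "chrT\ttoy\texon\t60\t160")
        with pytest.raises(AnnotationError, match="overlap"):
            AnnotationModel.from_gff3(bad)


class TestStrandSymmetry:
    def test_mirrored_minus_strand_gene_classifies_identically(self, plus_model):
        ann, genome = plus_model
        L = 400
        mirrored_seq = str(Seq(genome["chrT"]).reverse_complement())
        gff_minus = """##gff-version 3
chrT\ttoy\tgene\t241\t390\t.\t-\t.\tID=gene:g1
chrT\ttoy\tmRNA\t241\t390\t.\t-\t.\tID=tx:g1.t1;Parent=gene:g1
chrT\ttoy\texon\t331\t390\t.\t-\t.\tID=exon:g1.e1;Parent=tx:g1.t1
chrT\ttoy\texon\t241\t300\t.\t-\t.\tID=exon:g1.e2;Parent=tx:g1.t1
chrT\ttoy\tCDS\t331\t370\t.\t-\t0\tID=cds:g1.c1;Parent=tx:g1.t1
chrT\ttoy\tCDS\t269\t300\t.\t-\t2\tID=cds:g1.c2;Parent=tx:g1.t1
"""
        ann_m = AnnotationModel.from_gff3(gff_minus)
        genome_m = {"chrT": mirrored_seq}
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        for pos, ref, alt in [(36, "T", "C"), (34, "G", "A"), (64, "C", "T"),
                              (69, "T", "C"), (85, "A", "G"), (140, "A", "G")]:
            (orig,) = classify_variant(_snp(pos, ref, alt), ann, genome)
            (mirr,) = classify_variant(
                _snp(L + 1 - pos, comp[ref], comp[alt]), ann_m, genome_m
            )
            assert (orig.term, orig.splice_region, orig.aa_change) == (
                mirr.term, mirr.splice_region, mirr.aa_change)


class TestBruteForceTranslationOracle:
    def test_random_toy_genome_cds_calls_match_retranslation(self):
        rng = np.random.default_rng(0)
        chrom_len = 120_000
        gff = toy_annotation_gff3(["chrZ"], chrom_len, gene_spacing_bp=20_000, seed=1)
        ann = AnnotationModel.from_gff3(gff)
        import pandas as pd
        from linepanel.genotypes import GenotypeMatrix

        pos = np.sort(rng.choice(np.arange(1, chrom_len), size=400, replace=False))
        refs = np.array(list("ACGT"))[rng.integers(0, 4, pos.size)]
        alts = np.array(list("ACGT"))[
            (np.searchsorted(np.array(list("ACGT")), refs)
             + rng.integers(1, 4, pos.size)) % 4
        ]
        sites = pd.DataFrame({"chrom": "chrZ", "pos": pos, "ref": refs, "alt": alts})
        G = GenotypeMatrix(["l1"], sites, np.zeros((1, pos.size), np.int8))
        genome = synthesize_reference(G, chrom_len, seed=2)
        seq = genome["chrZ"]
        n_coding = 0
        for snp in G.snp_records():
            calls = classify_variant(snp, ann, genome)
            for call in calls:
                if call.aa_change is None:
                    continue
                n_coding += 1
                tx = next(t for t in ann.transcripts
                          if t.transcript_id == call.transcript_id)
                cds = sorted(tx.cds)
                ref_cds = "".join(seq[a - 1 : b] for a, b, _ in cds)
                alt_seq = (seq[: snp.position - 1] + snp.alt_allele
                           + seq[snp.position :])
                alt_cds = "".join(alt_seq[a - 1 : b] for a, b, _ in cds)
                if tx.strand == "-":
                    ref_cds = str(Seq(ref_cds).reverse_complement())
                    alt_cds = str(Seq(alt_cds).reverse_complement())
                aa_ref = str(Seq(ref_cds).translate())
                aa_alt = str(Seq(alt_cds).translate())
                diff = [(i, a, b) for i, (a, b) in enumerate(zip(aa_ref, aa_alt))
                        if a != b]
                if not diff:
                    expected = "synonymous_variant"
                elif diff[0][2] == "*":
                    expected = "stop_gained"
                else:
                    expected = "missense_variant"
                assert call.term == expected, (snp, call)
        assert n_coding > 10   # the sweep actually exercised coding variants


class TestEffectSummary:
    def test_counts_and_ratio(self):
        s = EffectSummary.from_counts(12344, 6634, 89)
        assert s.n_nonsynonymous == 6723
        assert s.pn_ps == pytest.approx(0.545)

    def test_no_synonymous_gives_missing_ratio(self):
        s = EffectSummary.from_counts(0, 3, 1)
        assert s.pn_ps is None

    def test_unit_ratio(self):
        assert EffectSummary.from_counts(1, 1, 0).pn_ps == pytest.approx(1.0)

    def test_severity_selection_across_transcripts(self, plus_model):
        ann, genome = plus_model
        calls = classify_variant(_snp(36, "T", "C"), ann, genome)
        summ = effect_summary([calls])
        assert summ.n_synonymous == 1
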
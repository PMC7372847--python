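"""Lightweight variant-effect classification (Sequence Ontology terms).

Assigns each SNP a primary SO term per overlapping transcript —
coding changes by strand- and phase-aware codon translation
(synonymous_variant / missense_variant / stop_gained), exonic non-CDS as
5'/3' UTR, intronic, flanking (upstream/downstream within a configurable
distance, 5 kb by default) or intergenic — plus a splice-region flag for
variants 1-3 bp into an exon end or 3-8 bp into an intron.  The summary
reports category counts and the nonsynonymous/synonymous polymorphism count
ratio pN/pS (an unnormalised constraint proxy; no per-site rate correction
is applied, so it is not a dN/dS rate ratio).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gffutils
from Bio.Seq import Seq
from Bio.SeqUtils import seq3

from .genotypes import GenotypeMatrix, SnpRecord

#: severity ordering, most severe first; selection of the primary annotation
#: per SNP is by this total order (ties broken by transcript id).
SEVERITY_ORDER = (
    "stop_gained",
    "missense_variant",
    "splice_region_variant",
    "synonymous_variant",
    "5_prime_UTR_variant",
    "3_prime_UTR_variant",
    "intron_variant",
    "upstream_gene_variant",
    "downstream_gene_variant",
    "intergenic_variant",
)
_RANK = {t: i for i, t in enumerate(SEVERITY_ORDER)}

DEFAULT_FLANK_BP = 5_000
SPLICE_EXON_BP = 3      # 1-3 bp into the exon end abutting an intron
SPLICE_INTRON_BP = 8    # 3-8 bp into the intron (1-2 bp simplified in too)


class AnnotationError(ValueError):
    """Invalid gene model (CDS not divisible by 3, CDS outside exons, ...)."""


@dataclass
class Transcript:
    transcript_id: str
    gene_id: str
    chromosome: str
    strand: str
    exons: list[tuple[int, int]]          # 1-based inclusive, sorted
    cds: list[tuple[int, int, int]]       # (start, end, phase), genomic order

    def cds_span(self) -> tuple[int, int] | None:
        if not self.cds:
            return None
        return min(c[0] for c in self.cds), max(c[1] for c in self.cds)


@dataclass
class AnnotationModel:
    """Gene models keyed by chromosome; validated on construction."""

    transcripts: list[Transcript]
    by_chrom: dict[str, list[Transcript]] = field(default_factory=dict)

    def __post_init__(self):
        for tx in self.transcripts:
            self._validate(tx)
            self.by_chrom.setdefault(tx.chromosome, []).append(tx)

    @staticmethod
    def _validate(tx: Transcript) -> None:
        ex = sorted(tx.exons)
        for (a1, b1), (a2, b2) in zip(ex, ex[1:]):
            if a2 <= b1:
                raise AnnotationError(f"{tx.transcript_id}: overlapping exons")
        exonic = set()
        for a, b in ex:
            exonic.update(range(a, b + 1))
        cds_len = 0
        for a, b, _ in tx.cds:
            cds_len += b - a + 1
            if not set(range(a, b + 1)) <= exonic:
                raise AnnotationError(f"{tx.transcript_id}: CDS outside exons")
        if tx.cds:
            first_phase = tx.cds[0][2] if tx.strand == "+" else tx.cds[-1][2]
            # phase of the transcription-first CDS segment trims the frame
            if (cds_len - first_phase) % 3 != 0:
                raise AnnotationError(
                    f"{tx.transcript_id}: CDS length {cds_len} (phase {first_phase}) "
                    "not divisible by 3"
                )

    @classmethod
    def from_gff3(cls, gff3_source) -> "AnnotationModel":
        """Parse gene/mRNA/exon/CDS features from GFF3 text or a path."""
        text = (
            Path(gff3_source).read_text()
            if isinstance(gff3_source, (str, Path)) and "\n" not in str(gff3_source)
            else str(gff3_source)
        )
        db = gffutils.create_db(
            text, dbfn=":memory:", from_string=True, force=True,
            keep_order=True, merge_strategy="create_unique",
        )
        txs = []
        for mrna in db.features_of_type("mRNA"):
            gene_id = (mrna.attributes.get("Parent") or [mrna.id])[0]
            exons = sorted(
                (f.start, f.end) for f in db.children(mrna, featuretype="exon")
            )
            cds = sorted(
                (f.start, f.end, int(f.frame) if f.frame not in (None, ".") else 0)
                for f in db.children(mrna, featuretype="CDS")
            )
            txs.append(
                Transcript(mrna.id, gene_id, mrna.seqid, mrna.strand, exons, cds)
            )
        return cls(txs)


@dataclass(frozen=True)
class EffectCall:
    snp: SnpRecord
    gene_id: str | None
    transcript_id: str | None
    term: str                    # primary SO term
    splice_region: bool = False
    aa_change: str | None = None  # p.Ala224Ala style, coding variants only

    @property
    def so_string(self) -> str:
        if self.splice_region and self.term != "splice_region_variant":
            return f"splice_region_variant&{self.term}"
        return self.term

    @property
    def severity_rank(self) -> int:
        r = _RANK[self.term]
        if self.splice_region:
            r = min(r, _RANK["splice_region_variant"])
        return r


def _read_fasta(genome) -> dict[str, str]:
    if isinstance(genome, dict):
        return genome
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(genome), "fasta")}


def _splice_flag(pos: int, tx: Transcript) -> bool:
    """Near an exon/intron boundary: 1-3 bp into exon or 1-8 bp into intron."""
    ex = sorted(tx.exons)
    for k, (a, b) in enumerate(ex):
        has_intron_left = k > 0
        has_intron_right = k < len(ex) - 1
        if a <= pos <= b:
            if has_intron_left and pos - a < SPLICE_EXON_BP:
                return True
            if has_intron_right and b - pos < SPLICE_EXON_BP:
                return True
        if has_intron_right:
            nxt = ex[k + 1][0]
            if b < pos < nxt:
                d = min(pos - b, nxt - pos)
                if d <= SPLICE_INTRON_BP:
                    return True
    return False


def _classify_in_transcript(snp: SnpRecord, tx: Transcript, seq: str) -> EffectCall | None:
    pos = snp.position
    tx_start = min(a for a, _ in tx.exons)
    tx_end = max(b for _, b in tx.exons)
    if not (tx_start <= pos <= tx_end):
        return None
    in_exon = any(a <= pos <= b for a, b in tx.exons)
    splice = _splice_flag(pos, tx)
    if not in_exon:
        return EffectCall(snp, tx.gene_id, tx.transcript_id, "intron_variant", splice)
    # CDS?
    cds_sorted = sorted(tx.cds)
    in_cds = any(a <= pos <= b for a, b, _ in cds_sorted)
    if not in_cds:
        span = tx.cds_span()
        if span is None:
            term = "5_prime_UTR_variant"    # non-coding transcript: report by side
        else:
            left_of_cds = pos < span[0]
            if tx.strand == "+":
                term = "5_prime_UTR_variant" if left_of_cds else "3_prime_UTR_variant"
            else:
                term = "3_prime_UTR_variant" if left_of_cds else "5_prime_UTR_variant"
        return EffectCall(snp, tx.gene_id, tx.transcript_id, term, splice)
    # coding: build the CDS sequence and locate the variant codon
    cds_seq_parts = [seq[a - 1 : b] for a, b, _ in cds_sorted]
    cds_seq = "".join(cds_seq_parts)
    offset = 0
    cds_pos = None                          # 0-based along genomic-order CDS
    for (a, b, _), part in zip(cds_sorted, cds_seq_parts):
        if a <= pos <= b:
            cds_pos = offset + (pos - a)
        offset += len(part)
    if tx.strand == "+":
        phase = cds_sorted[0][2]
        coding = cds_seq[phase:]
        idx = cds_pos - phase
        ref_base, alt_base = snp.ref_allele, snp.alt_allele
    else:
        phase = cds_sorted[-1][2]
        coding = str(Seq(cds_seq).reverse_complement())[phase:]
        idx = (len(cds_seq) - 1 - cds_pos) - phase
        ref_base = str(Seq(snp.ref_allele).reverse_complement())
        alt_base = str(Seq(snp.alt_allele).reverse_complement())
    if idx < 0:                             # inside the trimmed phase overhang
        return EffectCall(snp, tx.gene_id, tx.transcript_id, "synonymous_variant", splice)
    if coding[idx] != ref_base:
        raise AnnotationError(
            f"reference mismatch at {snp.chromosome}:{snp.position}: "
            f"genome has {coding[idx]}, VCF says {snp.ref_allele}"
        )
    codon_i = idx // 3
    within = idx % 3
    codon_ref = coding[3 * codon_i : 3 * codon_i + 3]
    codon_alt = codon_ref[:within] + alt_base + codon_ref[within + 1 :]
    aa_ref = str(Seq(codon_ref).translate())
    aa_alt = str(Seq(codon_alt).translate())
    if aa_alt == "*" and aa_ref != "*":
        term = "stop_gained"
    elif aa_alt == aa_ref:
        term = "synonymous_variant"
    else:
        term = "missense_variant"           # includes stop/start loss, simplified
    aa = f"p.{seq3(aa_ref)}{codon_i + 1}{seq3(aa_alt)}".replace("Ter", "Ter")
    return EffectCall(snp, tx.gene_id, tx.transcript_id, term, splice, aa)


def classify_variant(
    snp: SnpRecord,
    ann: AnnotationModel,
    genome,
    flank_bp: int = DEFAULT_FLANK_BP,
) -> list[EffectCall]:
    """All effect calls for one SNP (one per overlapping/flanking transcript).

    Falls through to upstream/downstream within ``flank_bp`` (strand-aware)
    and finally a single intergenic call.  The reference allele is checked
    against the genome (mismatch raises).
    """
    seqs = _read_fasta(genome)
    if snp.chromosome not in seqs:
        raise ValueError(f"unknown chromosome {snp.chromosome}")
    seq = seqs[snp.chromosome]
    if seq[snp.position - 1] != snp.ref_allele:
        raise AnnotationError(
            f"reference mismatch at {snp.chromosome}:{snp.position}: "
            f"genome has {seq[snp.position - 1]}, VCF says {snp.ref_allele}"
        )
    calls: list[EffectCall] = []
    for tx in ann.by_chrom.get(snp.chromosome, []):
        c = _classify_in_transcript(snp, tx, seq)
        if c is not None:
            calls.append(c)
    if calls:
        return sorted(calls, key=lambda c: (c.severity_rank, c.transcript_id or ""))
    for tx in ann.by_chrom.get(snp.chromosome, []):
        tx_start = min(a for a, _ in tx.exons)
        tx_end = max(b for _, b in tx.exons)
        if tx_start - flank_bp <= snp.position < tx_start:
            term = "upstream_gene_variant" if tx.strand == "+" else "downstream_gene_variant"
            calls.append(EffectCall(snp, tx.gene_id, tx.transcript_id, term))
        elif tx_end < snp.position <= tx_end + flank_bp:
            term = "downstream_gene_variant" if tx.strand == "+" else "upstream_gene_variant"
            calls.append(EffectCall(snp, tx.gene_id, tx.transcript_id, term))
    if calls:
        return sorted(calls, key=lambda c: (c.severity_rank, c.transcript_id or ""))
    return [EffectCall(snp, None, None, "intergenic_variant")]


def classify_matrix(
    G: GenotypeMatrix, ann: AnnotationModel, genome, flank_bp: int = DEFAULT_FLANK_BP
) -> list[list[EffectCall]]:
    """Per-SNP call lists for a whole matrix (genome read once)."""
    seqs = _read_fasta(genome)
    return [classify_variant(s, ann, seqs, flank_bp) for s in G.snp_records()]


@dataclass(frozen=True)
class EffectSummary:
    counts: dict[str, int]
    n_synonymous: int
    n_missense: int
    n_nonsense: int
    n_nonsynonymous: int
    pn_ps: float | None           # None when no synonymous variants

    @classmethod
    def from_counts(cls, n_synonymous: int, n_missense: int, n_nonsense: int,
                    other: dict[str, int] | None = None,
                    ndigits: int = 3) -> "EffectSummary":
        counts = dict(other or {})
        counts.update(
            synonymous_variant=n_synonymous,
            missense_variant=n_missense,
            stop_gained=n_nonsense,
        )
        nonsyn = n_missense + n_nonsense
        ratio = round(nonsyn / n_synonymous, ndigits) if n_synonymous else None
        return cls(counts, n_synonymous, n_missense, n_nonsense, nonsyn, ratio)


def effect_summary(calls: Iterable[Sequence[EffectCall] | EffectCall],
                   ndigits: int = 3) -> EffectSummary:
    """Category counts over the most severe call per SNP, plus pN/pS.

    Accepts per-SNP call lists (the primary call is selected by severity) or
    already-primary calls.  pN/pS = (missense + stop_gained)/synonymous is
    reported missing (None) when there are no synonymous variants.
    """
    counter: Counter[str] = Counter()
    for item in calls:
        call = item if isinstance(item, EffectCall) else min(item, key=lambda c: c.severity_rank)
        counter[call.so_string] += 1
    n_syn = sum(v for k, v in counter.items() if k.endswith("synonymous_variant"))
    n_mis = sum(v for k, v in counter.items() if "missense_variant" in k)
    n_non = sum(v for k, v in counter.items() if "stop_gained" in k)
    return EffectSummary.from_counts(
        n_syn, n_mis, n_non,
        other={k: v for k, v in counter.items()},
        ndigits=ndigits,
    )
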
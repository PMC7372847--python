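"""Genotype matrices, brood phenotypes and line metadata for inbred-line panels.

The panel substrate is a matrix of biallelic SNP calls over iso-female inbred
lines.  Each line is nearly homozygous, so a call is one of four states:
ref-homozygote, alt-homozygote, residual heterozygote, or missing.  Phenotypes
are brood-level counts of male and female offspring (sex ratio = proportion
male) from single-foundress broods.

Call codes used throughout the package (``int8``):

====  =====================
code  meaning
====  =====================
0     homozygous reference
1     heterozygous
2     homozygous alternate
-1    missing
====  =====================
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

REF_HOM = np.int8(0)
HET = np.int8(1)
ALT_HOM = np.int8(2)
MISSING = np.int8(-1)

#: default GWAS filter settings: a SNP must be called in at least this many
#: lines, and exceed this minor-allele frequency, to enter the scan.
DEFAULT_MIN_CALLED_LINES = 18
DEFAULT_MAF_MIN = 0.04


class GenotypeError(ValueError):
    """Malformed genotype input (parse failure, duplicate site, bad shape)."""


class EmptyResultError(ValueError):
    """A filter chain removed every SNP."""


@dataclass(frozen=True)
class SnpRecord:
    """One biallelic SNP: location, alleles and panel minor-allele frequency."""

    chromosome: str
    position: int          # 1-based, VCF convention
    ref_allele: str
    alt_allele: str
    maf: float             # over non-missing, non-heterozygous line calls

    def __post_init__(self):
        if self.ref_allele == self.alt_allele:
            raise GenotypeError(
                f"ref == alt ({self.ref_allele}) at {self.chromosome}:{self.position}"
            )
        if not (0.0 <= self.maf <= 0.5 + 1e-12):
            raise GenotypeError(f"maf {self.maf} outside [0, 0.5]")


@dataclass(frozen=True)
class BroodRecord:
    """One female's brood: male/female offspring counts for one line."""

    line_id: str
    female_id: str
    n_males: int
    n_females: int

    def __post_init__(self):
        if self.n_males < 0 or self.n_females < 0:
            raise ValueError(
                f"negative offspring count for {self.line_id}/{self.female_id}"
            )

    @property
    def clutch_size(self) -> int:
        return self.n_males + self.n_females

    @property
    def sex_ratio(self) -> float:
        """Proportion male offspring."""
        return self.n_males / self.clutch_size


@dataclass(frozen=True)
class LineMetadata:
    line_id: str
    wolbachia_positive: bool = True
    excluded: bool = False
    exclusion_reason: str = ""


@dataclass
class FilterLog:
    """Ordered record of filter steps: (step, removed, remaining)."""

    steps: list[tuple[str, int, int]] = field(default_factory=list)

    def add(self, step: str, removed: int, remaining: int) -> None:
        self.steps.append((step, removed, remaining))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps, columns=["step", "removed", "remaining"])

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


class GenotypeMatrix:
    """Lines x SNPs biallelic call matrix.

    Parameters
    ----------
    line_ids : ordered line identifiers (rows).
    sites : DataFrame with columns ``chrom``, ``pos``, ``ref``, ``alt``
        (1-based positions, strictly increasing within chromosome).
    calls : int8 array, shape (n_lines, n_snps), coded 0/1/2/-1.
    """

    def __init__(self, line_ids: Sequence[str], sites: pd.DataFrame, calls: np.ndarray):
        calls = np.asarray(calls, dtype=np.int8)
        sites = sites.reset_index(drop=True)
        if calls.shape != (len(line_ids), len(sites)):
            raise GenotypeError(
                f"calls shape {calls.shape} != (n_lines={len(line_ids)}, n_snps={len(sites)})"
            )
        if not set(np.unique(calls)) <= {-1, 0, 1, 2}:
            raise GenotypeError("calls must be coded {-1, 0, 1, 2}")
        for chrom, grp in sites.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise GenotypeError(f"positions not strictly increasing on {chrom}")
        if (sites["ref"] == sites["alt"]).any():
            raise GenotypeError("ref == alt at some site")
        self.line_ids = list(line_ids)
        self.sites = sites
        self.calls = calls

    # -- basic geometry -------------------------------------------------
    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    @property
    def n_snps(self) -> int:
        return len(self.sites)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"<GenotypeMatrix {self.n_lines} lines x {self.n_snps} SNPs>"

    # -- per-SNP summaries ----------------------------------------------
    def allele_frequency(self) -> np.ndarray:
        """Alt-allele frequency per SNP over non-missing, non-het calls."""
        hom = (self.calls == REF_HOM) | (self.calls == ALT_HOM)
        n_called = hom.sum(axis=0)
        n_alt = (self.calls == ALT_HOM).sum(axis=0)
        with np.errstate(invalid="ignore"):
            return np.where(n_called > 0, n_alt / n_called, np.nan)

    def maf(self) -> np.ndarray:
        f = self.allele_frequency()
        return np.minimum(f, 1.0 - f)

    def n_called(self) -> np.ndarray:
        """Homozygous (usable) calls per SNP."""
        return ((self.calls == REF_HOM) | (self.calls == ALT_HOM)).sum(axis=0)

    def het_fraction_per_line(self) -> np.ndarray:
        """Residual heterozygosity: fraction of non-missing calls that are het."""
        nonmiss = (self.calls != MISSING).sum(axis=1)
        het = (self.calls == HET).sum(axis=1)
        with np.errstate(invalid="ignore"):
            return np.where(nonmiss > 0, het / nonmiss, np.nan)

    def snp_records(self) -> list[SnpRecord]:
        maf = self.maf()
        return [
            SnpRecord(r.chrom, int(r.pos), r.ref, r.alt, float(0.0 if np.isnan(m) else m))
            for r, m in zip(self.sites.itertuples(index=False), maf)
        ]

    def subset(self, line_mask=None, snp_mask=None) -> "GenotypeMatrix":
        line_mask = np.ones(self.n_lines, bool) if line_mask is None else np.asarray(line_mask)
        snp_mask = np.ones(self.n_snps, bool) if snp_mask is None else np.asarray(snp_mask)
        return GenotypeMatrix(
            [l for l, k in zip(self.line_ids, line_mask) if k],
            self.sites.loc[snp_mask],
            self.calls[np.ix_(line_mask, snp_mask)],
        )


# ---------------------------------------------------------------------------
# VCF I/O
# ---------------------------------------------------------------------------

def read_genotype_matrix(vcf_path) -> GenotypeMatrix:
    """Read one-sample-per-line VCF into a :class:`GenotypeMatrix`.

    Multi-allelic records are dropped (count logged); half-calls and missing
    genotypes become missing calls.  Duplicate (chrom, pos) records raise.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path))
    line_ids = list(vcf.samples)
    rows, chroms, poss, refs, alts = [], [], [], [], []
    n_multi = 0
    seen: set[tuple[str, int]] = set()
    for var in vcf:
        if len(var.ALT) != 1:
            n_multi += 1
            continue
        key = (var.CHROM, var.POS)
        if key in seen:
            raise GenotypeError(f"duplicate record at {var.CHROM}:{var.POS}")
        seen.add(key)
        calls = np.empty(len(line_ids), dtype=np.int8)
        for i, g in enumerate(var.genotypes):
            a = [x for x in g[:-1] if x is not None and x >= 0]
            if len(a) < 2:        # missing or half-call
                calls[i] = MISSING
            elif a[0] == a[1]:
                calls[i] = REF_HOM if a[0] == 0 else ALT_HOM
            else:
                calls[i] = HET
        rows.append(calls)
        chroms.append(var.CHROM)
        poss.append(var.POS)
        refs.append(var.REF)
        alts.append(var.ALT[0])
    vcf.close()
    if n_multi:
        log.info("dropped %d multi-allelic records", n_multi)
    sites = pd.DataFrame({"chrom": chroms, "pos": poss, "ref": refs, "alt": alts})
    calls = np.array(rows, dtype=np.int8).T if rows else np.empty((len(line_ids), 0), np.int8)
    G = GenotypeMatrix(line_ids, sites, calls)
    G.n_multiallelic_dropped = n_multi
    return G


_GT_STR = {int(REF_HOM): "0/0", int(HET): "0/1", int(ALT_HOM): "1/1", int(MISSING): "./."}


def write_genotype_matrix(G: GenotypeMatrix, vcf_path) -> None:
    """Write a minimal deterministic VCF 4.2 file (GT field only)."""
    lines = ["##fileformat=VCFv4.2", '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">']
    for chrom, grp in G.sites.groupby("chrom", sort=False):
        lines.append(f"##contig=<ID={chrom},length={int(grp['pos'].max()) + 1000}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(G.line_ids))
    for j, r in enumerate(G.sites.itertuples(index=False)):
        gts = "\t".join(_GT_STR[int(c)] for c in G.calls[:, j])
        lines.append(f"{r.chrom}\t{r.pos}\t{r.chrom}_{r.pos}\t{r.ref}\t{r.alt}\t.\tPASS\t.\tGT\t{gts}")
    Path(vcf_path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# phenotype / metadata tables
# ---------------------------------------------------------------------------

def read_brood_table(csv_source) -> list[BroodRecord]:
    """Read a brood CSV (line_id, female_id, n_males, n_females).

    Zero-clutch rows are dropped with a logged count; negative counts raise.
    """
    df = pd.read_csv(csv_source)
    required = {"line_id", "female_id", "n_males", "n_females"}
    if not required <= set(df.columns):
        raise ValueError(f"brood table missing columns {required - set(df.columns)}")
    if (df["n_males"] < 0).any() or (df["n_females"] < 0).any():
        raise ValueError("negative offspring counts in brood table")
    clutch = df["n_males"] + df["n_females"]
    n_zero = int((clutch == 0).sum())
    if n_zero:
        log.info("dropped %d zero-clutch broods", n_zero)
    df = df[clutch > 0]
    return [
        BroodRecord(str(r.line_id), str(r.female_id), int(r.n_males), int(r.n_females))
        for r in df.itertuples(index=False)
    ]


def broods_to_frame(broods: Iterable[BroodRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (b.line_id, b.female_id, b.n_males, b.n_females, b.clutch_size, b.sex_ratio)
            for b in broods
        ],
        columns=["line_id", "female_id", "n_males", "n_females", "clutch_size", "sex_ratio"],
    )


def write_brood_table(broods: Iterable[BroodRecord], csv_path) -> None:
    broods_to_frame(broods)[["line_id", "female_id", "n_males", "n_females"]].to_csv(
        csv_path, index=False
    )


def read_line_metadata(csv_source) -> list[LineMetadata]:
    df = pd.read_csv(csv_source)
    out = []
    for r in df.itertuples(index=False):
        out.append(
            LineMetadata(
                str(r.line_id),
                wolbachia_positive=bool(r.wolbachia_positive),
                excluded=bool(r.excluded),
                exclusion_reason=str(getattr(r, "exclusion_reason", "") or ""),
            )
        )
    return out


def write_line_metadata(meta: Iterable[LineMetadata], csv_path) -> None:
    pd.DataFrame(
        [(m.line_id, m.wolbachia_positive, m.excluded, m.exclusion_reason) for m in meta],
        columns=["line_id", "wolbachia_positive", "excluded", "exclusion_reason"],
    ).to_csv(csv_path, index=False)


# ---------------------------------------------------------------------------
# GWAS filters
# ---------------------------------------------------------------------------

def apply_gwas_filters(
    G: GenotypeMatrix,
    meta: Sequence[LineMetadata] | None = None,
    min_called_lines: int = DEFAULT_MIN_CALLED_LINES,
    maf_min: float = DEFAULT_MAF_MIN,
) -> tuple[GenotypeMatrix, FilterLog]:
    """Apply the panel GWAS filter chain, in order.

    1. drop lines flagged excluded or wolbachia-lost;
    2. set residual heterozygous calls to missing (within-line segregating
       sites carry no between-line information);
    3. drop SNPs fixed across retained lines;
    4. drop SNPs called in fewer than ``min_called_lines`` lines;
    5. drop SNPs with minor-allele frequency below ``maf_min``.

    Returns the filtered matrix and a :class:`FilterLog` of per-step counts.
    Raises :class:`EmptyResultError` if no SNP survives.
    """
    flog = FilterLog()
    if meta is not None:
        bad = {m.line_id for m in meta if m.excluded or not m.wolbachia_positive}
        keep = np.array([l not in bad for l in G.line_ids])
        removed = int((~keep).sum())
        G = G.subset(line_mask=keep)
        flog.add("lines_excluded", removed, G.n_lines)
        if G.n_lines < min_called_lines:
            raise ValueError(
                f"min_called_lines={min_called_lines} exceeds retained lines ({G.n_lines})"
            )
    calls = G.calls.copy()
    n_het = int((calls == HET).sum())
    calls[calls == HET] = MISSING
    G = GenotypeMatrix(G.line_ids, G.sites, calls)
    flog.add("het_to_missing_calls", n_het, G.n_snps)

    f = G.allele_frequency()
    fixed = np.isnan(f) | (f == 0.0) | (f == 1.0)
    G = G.subset(snp_mask=~fixed)
    flog.add("fixed_snps", int(fixed.sum()), G.n_snps)

    low_call = G.n_called() < min_called_lines
    G = G.subset(snp_mask=~low_call)
    flog.add("min_called_lines", int(low_call.sum()), G.n_snps)

    low_maf = G.maf() < maf_min
    G = G.subset(snp_mask=~low_maf)
    flog.add("maf_min", int(low_maf.sum()), G.n_snps)

    if G.n_snps == 0:
        raise EmptyResultError("no SNPs survived the GWAS filter chain")
    return G, flog
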
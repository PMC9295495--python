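"""Shared genomic types, coordinate conventions and variant normalization.

Internal coordinates are 0-based half-open throughout the package.  Conversion
to and from the 1-based conventions of VCF and GFF3 happens only at I/O
boundaries (:func:`to_internal` / :func:`to_vcf_pos`, and the readers below).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

logger = logging.getLogger("regent")

VALID_STRANDS = ("+", "-", ".")


class InputValidationError(ValueError):
    """Raised when an input record violates a precondition."""


@dataclass(frozen=True)
class ThresholdConfig:
    """Registry of the numeric constants used across the pipelines.

    af_max
        Rarity ceiling for both the pLoF and the in-trans candidate alleles
        (fraction, default 0.5%).
    balance_lo / balance_hi
        Open interval of acceptable heterozygous allele balance (fraction of
        reads supporting the alternate allele).
    splice_score_min
        Permissive splice-impact score threshold applied to intronic
        candidates in the trio scan.
    promoter_core_bp
        Core promoter: bases directly upstream of the TSS used by the trio
        scan.
    promoter_audit_bp
        Upstream window used by the variant-database census ("promoter2kb").
    promoter_minimal_bp
        Half-width of the minimal promoter (bases up- AND downstream of the
        TSS) used when no open-chromatin support exists.
    indel_max_len
        Small-variant scope: indels must be shorter than this (bp).
    """

    af_max: float = 0.005
    balance_lo: float = 0.25
    balance_hi: float = 0.75
    splice_score_min: float = 0.2
    promoter_core_bp: int = 200
    promoter_audit_bp: int = 2000
    promoter_minimal_bp: int = 250
    indel_max_len: int = 50
    pp4_max_genes: int = 3
    large_intronic_span_bp: int = 1_000_000

    def __post_init__(self) -> None:
        if not (0 < self.balance_lo < self.balance_hi < 1):
            raise InputValidationError("require 0 < balance_lo < balance_hi < 1")
        for name in ("promoter_core_bp", "promoter_audit_bp",
                     "promoter_minimal_bp", "indel_max_len"):
            if getattr(self, name) <= 0:
                raise InputValidationError(f"{name} must be > 0")


@dataclass(frozen=True, order=True)
class GenomeInterval:
    """0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise InputValidationError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise InputValidationError(
                f"require 0 <= start < end, got [{self.start}, {self.end})")
        if self.strand not in VALID_STRANDS:
            raise InputValidationError(f"bad strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, chrom: str, pos0: int) -> bool:
        return chrom == self.chrom and self.start <= pos0 < self.end

    def overlaps(self, other: "GenomeInterval") -> bool:
        return (self.chrom == other.chrom
                and self.start < other.end and other.start < self.end)


@dataclass
class VariantRecord:
    """A biallelic small variant; ``pos`` is 1-based as in VCF."""

    chrom: str
    pos: int
    ref: str
    alt: str
    id: str | None = None
    info: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise InputValidationError("pos must be >= 1")
        if not self.ref or not self.alt:
            raise InputValidationError("ref and alt must be non-empty")

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    @property
    def anchor0(self) -> int:
        """0-based position of the leftmost altered reference base.

        Deterministic single-base localisation used whenever a variant must
        be assigned to exactly one region (indels are placed at the first
        base where the two alleles disagree; pure insertions at the base
        following the shared anchor).
        """
        i = 0
        while i < len(self.ref) and i < len(self.alt) and self.ref[i] == self.alt[i]:
            i += 1
        if i == len(self.ref):  # pure insertion after shared prefix
            i = len(self.ref) - 1 if len(self.ref) else 0
            return self.pos - 1 + i + 1
        return self.pos - 1 + i

    def key(self) -> tuple:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class TranscriptModel:
    """Exon/CDS structure of one transcript plus its provenance tag.

    ``exons`` are sorted, disjoint, 0-based half-open genomic intervals.
    ``cds_start``/``cds_end`` bound the translated genomic span half-open;
    both are ``None`` for non-coding transcripts.  Provenance is one of
    ``MANE_Select``, ``MANE_Plus_Clinical`` or ``canonical``.
    """

    transcript_id: str
    gene_id: str
    gene_symbol: str
    chrom: str
    strand: str
    exons: list[GenomeInterval]
    cds_start: int | None = None
    cds_end: int | None = None
    provenance: str = "canonical"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise InputValidationError("transcript strand must be + or -")
        exons = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(exons, exons[1:]):
            if a.end > b.start:
                raise InputValidationError("exons must be disjoint and sorted")
        self.exons = exons
        if (self.cds_start is None) != (self.cds_end is None):
            raise InputValidationError("cds_start and cds_end must come together")
        if self.cds_start is not None:
            if not (self.start <= self.cds_start < self.cds_end <= self.end):
                raise InputValidationError("CDS outside transcript span")

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    @property
    def is_coding(self) -> bool:
        return self.cds_start is not None

    @property
    def tss(self) -> int:
        """0-based genomic position of the 5'-most transcribed base."""
        return self.start if self.strand == "+" else self.end - 1

    def span(self) -> GenomeInterval:
        return GenomeInterval(self.chrom, self.start, self.end, self.strand)

    def exonic_length(self) -> int:
        return sum(len(e) for e in self.exons)


# ---------------------------------------------------------------------------
# Coordinate conversion (VCF/GFF 1-based <-> internal 0-based)

def to_internal(pos_1based: int) -> int:
    """1-based position -> 0-based offset."""
    if pos_1based < 1:
        raise InputValidationError("1-based position must be >= 1")
    return pos_1based - 1


def to_vcf_pos(offset0: int) -> int:
    """0-based offset -> 1-based position (inverse of :func:`to_internal`)."""
    if offset0 < 0:
        raise InputValidationError("offset must be >= 0")
    return offset0 + 1


def harmonize_contig(name: str, use_chr_prefix: bool) -> str:
    """Map between the ``chr17`` and ``17`` contig dialects."""
    has = name.startswith("chr")
    if use_chr_prefix and not has:
        return "chr" + name
    if not use_chr_prefix and has:
        return name[3:]
    return name


# ---------------------------------------------------------------------------
# Sequence access

class SequenceProvider:
    """Uniform subsequence access over a dict of strings or a FASTA handle.

    Accepts ``{chrom: sequence}`` mappings or any object indexable as
    ``obj[chrom][start:end]`` (e.g. ``pyfaidx.Fasta``).
    """

    def __init__(self, source) -> None:
        self._source = source

    def fetch(self, chrom: str, start0: int, end0: int) -> str:
        if start0 < 0:
            start0 = 0
        seg = self._source[chrom][start0:end0]
        return str(seg).upper()

    def base(self, chrom: str, pos0: int) -> str:
        return self.fetch(chrom, pos0, pos0 + 1)


# ---------------------------------------------------------------------------
# Variant normalization

def normalize_variant(v: VariantRecord, reference) -> VariantRecord:
    """Left-align and make parsimonious a biallelic variant.

    Standard normalization: right-trim shared suffix bases, extending both
    alleles leftward with the preceding reference base whenever one allele
    would become empty, then left-trim shared prefixes down to a single
    anchor base.  Idempotent; raises on reference mismatch.
    """
    seq = reference if isinstance(reference, SequenceProvider) else SequenceProvider(reference)
    obs = seq.fetch(v.chrom, v.pos - 1, v.pos - 1 + len(v.ref))
    if obs != v.ref.upper():
        raise InputValidationError(
            f"reference mismatch at {v.chrom}:{v.pos}: expected {v.ref}, found {obs}")

    pos, ref, alt = v.pos, v.ref.upper(), v.alt.upper()
    if ref == alt:
        raise InputValidationError("ref and alt identical")

    while True:
        if ref and alt and ref[-1] == alt[-1] and (len(ref) > 1 or len(alt) > 1):
            ref, alt = ref[:-1], alt[:-1]
            if not ref or not alt:
                if pos == 1:
                    raise InputValidationError("cannot left-extend past contig start")
                pos -= 1
                b = seq.base(v.chrom, pos - 1)
                ref, alt = b + ref, b + alt
        elif len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
            ref, alt = ref[1:], alt[1:]
            pos += 1
        else:
            break
    return replace(v, pos=pos, ref=ref, alt=alt)


def split_multiallelic(chrom: str, pos: int, ref: str, alts: Sequence[str],
                       info: Mapping | None = None,
                       vid: str | None = None) -> list[VariantRecord]:
    """One biallelic :class:`VariantRecord` per alternate allele.

    Per-allele (Number=A) INFO values are split positionally when the value
    is a tuple/list of the same length as ``alts``.
    """
    out = []
    info = dict(info or {})
    for i, alt in enumerate(alts):
        if alt is None or alt in (".", "*", "<NON_REF>"):
            continue
        sub = {}
        for k, val in info.items():
            if isinstance(val, (tuple, list)) and len(val) == len(alts):
                sub[k] = val[i]
            else:
                sub[k] = val
        out.append(VariantRecord(chrom=chrom, pos=pos, ref=ref, alt=alt,
                                 id=vid, info=sub))
    return out


# ---------------------------------------------------------------------------
# File readers (thin wrappers; all conversion to internal coordinates is here)

def read_vcf_variants(path: str) -> list["VariantRecord"]:
    """Read a (possibly multi-allelic) VCF into biallelic VariantRecords."""
    import pysam

    records: list[VariantRecord] = []
    with pysam.VariantFile(path) as vf:
        for rec in vf:
            info = {k: rec.info.get(k) for k in rec.info.keys()}
            records.extend(split_multiallelic(
                rec.chrom, rec.pos, rec.ref, rec.alts or (), info, rec.id))
    return records


def read_transcripts_gff3(path: str) -> list[TranscriptModel]:
    """Parse transcript models from GFF3, recognising MANE provenance tags.

    Provenance is read from the mRNA/transcript feature's ``tag`` attribute
    (``MANE_Select`` / ``MANE_Plus_Clinical``); anything else is treated as
    ``canonical``.  GFF3 1-based inclusive coordinates become 0-based
    half-open here.
    """
    import gffutils

    db = gffutils.create_db(path, dbfn=":memory:", force=True,
                            keep_order=True, merge_strategy="create_unique")

    def first(feature, key, default=""):
        vals = feature.attributes.get(key, [])
        return vals[0] if vals else default

    out = []
    for ftype in ("mRNA", "transcript"):
        for tx in db.features_of_type(ftype):
            exons = [GenomeInterval(e.seqid, e.start - 1, e.end, e.strand)
                     for e in db.children(tx, featuretype="exon")]
            if not exons:
                continue
            cds = [(c.start - 1, c.end)
                   for c in db.children(tx, featuretype="CDS")]
            tags = ",".join(tx.attributes.get("tag", []))
            prov = "canonical"
            if "MANE_Select" in tags:
                prov = "MANE_Select"
            elif "MANE_Plus_Clinical" in tags:
                prov = "MANE_Plus_Clinical"
            gid = first(tx, "Parent", first(tx, "gene_id"))
            symbol = gid
            try:
                symbol = first(db[gid], "Name", gid)
            except gffutils.FeatureNotFoundError:
                pass
            out.append(TranscriptModel(
                transcript_id=tx.id, gene_id=gid, gene_symbol=symbol,
                chrom=tx.seqid, strand=tx.strand,
                exons=sorted(exons, key=lambda e: e.start),
                cds_start=min(s for s, _ in cds) if cds else None,
                cds_end=max(e for _, e in cds) if cds else None,
                provenance=prov))
    out.sort(key=lambda t: t.transcript_id)
    return out


def read_bed_intervals(path: str) -> list[GenomeInterval]:
    """BED4+ reader (0-based half-open, as BED already is)."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            strand = f[5] if len(f) > 5 and f[5] in ("+", "-") else "."
            out.append(GenomeInterval(f[0], int(f[1]), int(f[2]), strand))
    return out


def revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


_RC = str.maketrans("ACGTNacgtn", "TGCANtgcan")
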
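"""Interpretable-region construction and variant-to-region assignment.

Builds the per-gene region sets that the rest of the engine interprets
against: spliced UTRs, introns, a promoter under one of four definitions,
and distal cis-regulatory elements (CREs) admitted through a two-step
evidence filter plus a gene-disease validity gate.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field

from .core import GenomeInterval, InputValidationError, ThresholdConfig, TranscriptModel, VariantRecord

logger = logging.getLogger("regent")


class RegionClass(str, enum.Enum):
    five_prime_utr = "five_prime_utr"
    three_prime_utr = "three_prime_utr"
    intron = "intron"
    promoter = "promoter"
    cre = "cre"
    coding = "coding"
    other = "other"


PROMOTER_MODES = ("core200", "audit2kb", "minimal250", "epigenetic")

ELEMENT_EVIDENCE = frozenset({"open_chromatin", "H3K27Ac", "H3K4Me1", "tf_chip"})
LINK_EVIDENCE = frozenset({"chromatin_interaction", "perturbation", "eqtl"})
INTERPRETABLE_VALIDITY = frozenset({"definitive", "strong", "moderate"})
VALIDITY_LEVELS = frozenset(
    {"definitive", "strong", "moderate", "limited", "disputed", "none"})


@dataclass
class RegionSet:
    gene_id: str
    transcript_id: str
    regions: list[tuple[RegionClass, GenomeInterval]]
    promoter_mode: str

    def of_class(self, cls: RegionClass) -> list[GenomeInterval]:
        return [iv for c, iv in self.regions if c is cls]


@dataclass
class CRERecord:
    """Candidate cis-regulatory element with its element- and link-level
    evidence (Table-2 style vocabulary)."""

    interval: GenomeInterval
    element_evidence: set
    link_evidence: set
    target_gene: str
    tissue_context: str = ""

    def __post_init__(self) -> None:
        bad = set(self.element_evidence) - ELEMENT_EVIDENCE
        bad |= set(self.link_evidence) - LINK_EVIDENCE
        if bad:
            raise InputValidationError(f"unknown CRE evidence labels: {sorted(bad)}")


@dataclass
class GeneValidity:
    gene_id: str
    phenotype: str
    level: str
    source: str = "other"

    def __post_init__(self) -> None:
        if self.level not in VALIDITY_LEVELS:
            raise InputValidationError(f"unknown validity level {self.level!r}")


@dataclass
class RegionContext:
    """One (variant, gene, region) interpretation unit."""

    variant: VariantRecord
    gene_id: str
    transcript_id: str
    region_class: RegionClass
    sub_annotations: dict = field(default_factory=dict)
    via_cre: CRERecord | None = None


# ---------------------------------------------------------------------------

_PROVENANCE_RANK = {"MANE_Select": 0, "MANE_Plus_Clinical": 1, "canonical": 2}


def select_clinical_transcript(gene_id: str,
                               transcripts: list[TranscriptModel]) -> TranscriptModel:
    """Pick the clinically preferred transcript for a gene.

    Precedence MANE Select > MANE Plus Clinical > canonical, with a
    deterministic lexical tie-break on transcript_id.
    """
    cands = [t for t in transcripts if t.gene_id == gene_id]
    if not cands:
        raise KeyError(f"no transcript for gene {gene_id!r}")
    return min(cands, key=lambda t: (_PROVENANCE_RANK.get(t.provenance, 3),
                                     t.transcript_id))


def _utr_cds_partition(t: TranscriptModel):
    """Split exons into (5'UTR, coding, 3'UTR) genomic fragment lists."""
    left, mid, right = [], [], []
    for e in t.exons:
        seg_l = (e.start, min(e.end, t.cds_start))
        seg_m = (max(e.start, t.cds_start), min(e.end, t.cds_end))
        seg_r = (max(e.start, t.cds_end), e.end)
        if seg_l[0] < seg_l[1]:
            left.append(GenomeInterval(t.chrom, *seg_l, t.strand))
        if seg_m[0] < seg_m[1]:
            mid.append(GenomeInterval(t.chrom, *seg_m, t.strand))
        if seg_r[0] < seg_r[1]:
            right.append(GenomeInterval(t.chrom, *seg_r, t.strand))
    return left, mid, right


def promoter_interval(t: TranscriptModel, mode: str,
                      open_chromatin: list[GenomeInterval] | None = None,
                      cfg: ThresholdConfig = ThresholdConfig(),
                      contig_length: int | None = None) -> GenomeInterval | None:
    """Promoter window for one transcript under the requested definition.

    ``core200``/``audit2kb`` extend strictly upstream of the TSS in
    transcript orientation; ``minimal250`` covers 250 bp up- and downstream;
    ``epigenetic`` uses the union of open-chromatin peaks containing the
    TSS, falling back to minimal250 when no peak contains it.  Windows are
    clipped at contig edges; a window clipped to nothing (TSS at the very
    contig edge) yields None.
    """
    if mode not in PROMOTER_MODES:
        raise InputValidationError(f"unknown promoter mode {mode!r}")
    if mode == "epigenetic":
        peaks = [p for p in (open_chromatin or [])
                 if p.contains(t.chrom, t.tss)]
        if peaks:
            return GenomeInterval(t.chrom, min(p.start for p in peaks),
                                  max(p.end for p in peaks), t.strand)
        mode = "minimal250"

    if mode == "minimal250":
        half = cfg.promoter_minimal_bp
        if t.strand == "+":
            start, end = t.start - half, t.start + half
        else:
            start, end = t.end - half, t.end + half
    else:
        width = cfg.promoter_core_bp if mode == "core200" else cfg.promoter_audit_bp
        if t.strand == "+":
            start, end = t.start - width, t.start
        else:
            start, end = t.end, t.end + width
    start = max(start, 0)
    if contig_length is not None:
        end = min(end, contig_length)
    if start >= end:
        return None
    return GenomeInterval(t.chrom, start, end, t.strand)


def derive_gene_regions(t: TranscriptModel, promoter_mode: str = "core200",
                        open_chromatin: list[GenomeInterval] | None = None,
                        cfg: ThresholdConfig = ThresholdConfig(),
                        contig_length: int | None = None) -> RegionSet:
    """Derive the interpretable regions of one transcript.

    UTRs are the exonic sequence outside the CDS on the respective side
    (intron gaps between UTR exon fragments are classed as intron, not
    UTR); introns are the gaps between consecutive exons; the promoter
    follows ``promoter_mode``.
    """
    regions: list[tuple[RegionClass, GenomeInterval]] = []
    if t.is_coding:
        left, mid, right = _utr_cds_partition(t)
        five, three = (left, right) if t.strand == "+" else (right, left)
        regions += [(RegionClass.five_prime_utr, iv) for iv in five]
        regions += [(RegionClass.coding, iv) for iv in mid]
        regions += [(RegionClass.three_prime_utr, iv) for iv in three]
    else:
        logger.info("non-coding transcript %s: emitting introns only",
                    t.transcript_id)
    for a, b in zip(t.exons, t.exons[1:]):
        regions.append((RegionClass.intron,
                        GenomeInterval(t.chrom, a.end, b.start, t.strand)))
    prom = promoter_interval(t, promoter_mode, open_chromatin, cfg,
                             contig_length)
    if prom is not None:
        regions.append((RegionClass.promoter, prom))
    regions.sort(key=lambda ci: (ci[1].start, ci[1].end, ci[0].value))
    return RegionSet(gene_id=t.gene_id, transcript_id=t.transcript_id,
                     regions=regions, promoter_mode=promoter_mode)


def admit_candidate_cre(c: CRERecord, validity: GeneValidity | None
                        ) -> tuple[bool, list[str]]:
    """Two-step CRE filter plus gene-disease validity gate.

    Admitted iff the element carries at least one element-level mark AND at
    least one experimental link to the target gene AND the gene-disease
    validity is at least moderate (or PanelApp green).  Reasons name every
    failed gate; non-admitted elements are research variants.
    """
    reasons = []
    if not c.element_evidence:
        reasons.append("no_element_evidence")
    if not c.link_evidence:
        reasons.append("research_variant_no_gene_link")
    ok_validity = validity is not None and (
        validity.level in INTERPRETABLE_VALIDITY
        or validity.source == "PanelApp_green")
    if not ok_validity:
        reasons.append("gene_disease_validity_below_moderate")
    return (not reasons, reasons)


def assign_region_contexts(v: VariantRecord,
                           region_sets: list[RegionSet],
                           admitted_cres: list[CRERecord] | None = None,
                           transcripts: dict[str, TranscriptModel] | None = None,
                           ) -> list[RegionContext]:
    """All (gene, region) contexts a variant falls in.

    A variant may yield contexts for several genes at once — e.g. intronic
    in one gene while inside an admitted CRE linked to another.  The
    variant is localised to its leftmost altered base.  Returns an empty
    list when nothing interpretable overlaps.
    """
    pos0 = v.anchor0
    out: list[RegionContext] = []
    for rs in region_sets:
        hits = [(cls, iv) for cls, iv in rs.regions if iv.contains(v.chrom, pos0)]
        # within one transcript the non-promoter regions tile disjointly,
        # but a promoter window may overlap a neighbour's regions
        for cls, iv in hits:
            sub: dict = {}
            t = (transcripts or {}).get(rs.transcript_id)
            if cls is RegionClass.promoter and t is not None:
                sub["distance_to_tss"] = abs(pos0 - t.tss)
            if cls is RegionClass.intron:
                introns = rs.of_class(RegionClass.intron)
                sub["intron_index"] = introns.index(iv) if iv in introns else None
            out.append(RegionContext(variant=v, gene_id=rs.gene_id,
                                     transcript_id=rs.transcript_id,
                                     region_class=cls, sub_annotations=sub))
    for cre in admitted_cres or []:
        if cre.interval.contains(v.chrom, pos0):
            out.append(RegionContext(variant=v, gene_id=cre.target_gene,
                                     transcript_id="", region_class=RegionClass.cre,
                                     via_cre=cre))
    out.sort(key=lambda c: (c.gene_id, c.region_class.value))
    return out


# ---------------------------------------------------------------------------
# TSV / BED plumbing

def read_validity_tsv(path: str) -> dict[str, GeneValidity]:
    """Gene-disease validity registry: columns gene, phenotype, level, source."""
    import csv

    out = {}
    with open(path) as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            out[row["gene"]] = GeneValidity(
                gene_id=row["gene"], phenotype=row.get("phenotype", ""),
                level=row["level"], source=row.get("source", "other"))
    return out


def write_regions_bed(region_sets: list[RegionSet], path: str) -> None:
    with open(path, "w") as fh:
        for rs in region_sets:
            for cls, iv in rs.regions:
                name = f"{rs.gene_id}|{cls.value}|{rs.promoter_mode}"
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")
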
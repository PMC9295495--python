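"""Region census of a ClinVar-style VCF and transcript footprint statistics.

Quantifies how variants in a clinical variant database distribute over
coding sequence, UTRs, introns and the 2-kb upstream promoter window of
clinically preferred transcripts, how classification mix (P/LP, B/LB, VUS)
varies by region, and how large each region class's genomic footprint is.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .core import TranscriptModel, VariantRecord, split_multiallelic, ThresholdConfig
from .regions import RegionClass, derive_gene_regions

CATEGORIES = ("coding", "five_prime_utr", "three_prime_utr", "intron",
              "promoter2kb", "other")

#: ClinVar review statuses counted as high-confidence.
HIGH_CONFIDENCE_REVIEW = frozenset({
    "criteria_provided,_multiple_submitters,_no_conflicts",
    "reviewed_by_expert_panel",
    "practice_guideline"})
PATHOGENIC_SIG = frozenset({"Pathogenic", "Likely_pathogenic",
                            "Pathogenic/Likely_pathogenic"})
BENIGN_SIG = frozenset({"Benign", "Likely_benign", "Benign/Likely_benign"})
VUS_SIG = frozenset({"Uncertain_significance"})


@dataclass
class ClinVarRecord:
    variant: VariantRecord
    clnsig: str
    clnrevstat: str
    category: str | None = None


@dataclass
class AuditSummary:
    counts: pd.DataFrame  # index category, columns total/plp/blb/vus/hc_pathogenic
    vus_rate: pd.Series  # per-category VUS fraction
    hc_pathogenic_total: int
    hc_pathogenic_regulatory: int  # 5'UTR + 3'UTR + promoter2kb
    hc_pathogenic_regulatory_fraction: float


@dataclass
class FootprintStats:
    per_transcript: pd.DataFrame  # columns five_prime_utr_bp/cds_bp/three_prime_utr_bp/intron_total_bp
    means: dict
    shares: dict


# ---------------------------------------------------------------------------

def parse_clinvar_vcf(path: str) -> list[ClinVarRecord]:
    """Read a ClinVar-style VCF, preserving CLNSIG/CLNREVSTAT verbatim.

    Records missing either key are kept with an empty string.
    """
    import pysam

    out = []
    with pysam.VariantFile(path) as vf:
        for rec in vf:
            sig = rec.info.get("CLNSIG", "")
            rev = rec.info.get("CLNREVSTAT", "")
            sig = ",".join(sig) if isinstance(sig, tuple) else str(sig or "")
            rev = ",".join(rev) if isinstance(rev, tuple) else str(rev or "")
            for v in split_multiallelic(rec.chrom, rec.pos, rec.ref,
                                        rec.alts or ("N",), {}, rec.id):
                out.append(ClinVarRecord(variant=v, clnsig=sig, clnrevstat=rev))
    return out


def _primary_sig(clnsig: str) -> str:
    """Primary significance term before any comma-delimited modifiers."""
    return clnsig.split(",")[0].split("|")[0]


def is_high_confidence_pathogenic(r: ClinVarRecord) -> bool:
    return (r.clnrevstat in HIGH_CONFIDENCE_REVIEW
            and _primary_sig(r.clnsig) in PATHOGENIC_SIG)


def build_transcript_index(transcripts: list[TranscriptModel],
                           cfg: ThresholdConfig = ThresholdConfig()):
    """Precomputed per-transcript region sets (audit2kb promoter) for the
    MANE Select models."""
    index = []
    for t in transcripts:
        if t.provenance != "MANE_Select":
            continue
        rs = derive_gene_regions(t, promoter_mode="audit2kb", cfg=cfg)
        index.append((t, rs))
    return index


_PRECEDENCE = {RegionClass.coding: 0, RegionClass.five_prime_utr: 1,
               RegionClass.three_prime_utr: 2, RegionClass.intron: 3,
               RegionClass.promoter: 4}
_CAT_NAME = {RegionClass.coding: "coding",
             RegionClass.five_prime_utr: "five_prime_utr",
             RegionClass.three_prime_utr: "three_prime_utr",
             RegionClass.intron: "intron",
             RegionClass.promoter: "promoter2kb"}


def categorize_variant(v: VariantRecord, transcript_index) -> str:
    """Single region category per variant across all overlapping MANE
    Select transcripts, precedence coding > 5'UTR > 3'UTR > intron >
    promoter2kb; anything else is 'other'.

    Indels are localised by their leftmost altered base.
    """
    pos0 = v.anchor0
    best = None
    for _, rs in transcript_index:
        for cls, iv in rs.regions:
            if cls not in _PRECEDENCE:
                continue
            if iv.contains(v.chrom, pos0):
                rank = _PRECEDENCE[cls]
                if best is None or rank < best:
                    best = rank
    if best is None:
        return "other"
    return _CAT_NAME[[k for k, r in _PRECEDENCE.items() if r == best][0]]


def categorize_all(records: list[ClinVarRecord], transcript_index
                   ) -> list[ClinVarRecord]:
    for r in records:
        r.category = categorize_variant(r.variant, transcript_index)
    return records


def audit_summary(records: list[ClinVarRecord]) -> AuditSummary:
    """Per-category counts, class mix, VUS rates and the share of
    high-confidence pathogenic variants in regulatory regions."""
    rows = []
    for r in records:
        sig = _primary_sig(r.clnsig)
        rows.append({
            "category": r.category or "other",
            "plp": sig in PATHOGENIC_SIG,
            "blb": sig in BENIGN_SIG,
            "vus": sig in VUS_SIG,
            "hc_pathogenic": is_high_confidence_pathogenic(r)})
    df = pd.DataFrame(rows, columns=["category", "plp", "blb", "vus",
                                     "hc_pathogenic"])
    counts = (df.groupby("category").agg(total=("category", "size"),
                                         plp=("plp", "sum"),
                                         blb=("blb", "sum"),
                                         vus=("vus", "sum"),
                                         hc_pathogenic=("hc_pathogenic", "sum"))
              .reindex(CATEGORIES, fill_value=0))
    vus_rate = (counts["vus"] / counts["total"].where(counts["total"] > 0)
                ).fillna(0.0)
    hc_total = int(counts["hc_pathogenic"].sum())
    hc_reg = int(counts.loc[["five_prime_utr", "three_prime_utr",
                             "promoter2kb"], "hc_pathogenic"].sum())
    return AuditSummary(
        counts=counts, vus_rate=vus_rate,
        hc_pathogenic_total=hc_total,
        hc_pathogenic_regulatory=hc_reg,
        hc_pathogenic_regulatory_fraction=hc_reg / hc_total if hc_total else 0.0)


def region_footprint_stats(transcripts: list[TranscriptModel]) -> FootprintStats:
    """Spliced region lengths per coding transcript and cohort means.

    UTR and CDS lengths are spliced (sums of exonic fragments); introns are
    the total intron length, so per transcript
    5'UTR + CDS + 3'UTR + introns = transcript span.
    """
    rows = []
    for t in transcripts:
        if not t.is_coding:
            continue
        rs = derive_gene_regions(t, promoter_mode="core200")
        row = {"transcript_id": t.transcript_id}
        for cls, col in ((RegionClass.five_prime_utr, "five_prime_utr_bp"),
                         (RegionClass.coding, "cds_bp"),
                         (RegionClass.three_prime_utr, "three_prime_utr_bp"),
                         (RegionClass.intron, "intron_total_bp")):
            row[col] = sum(len(iv) for iv in rs.of_class(cls))
        rows.append(row)
    per_tx = pd.DataFrame(rows).set_index("transcript_id") if rows else \
        pd.DataFrame(columns=["five_prime_utr_bp", "cds_bp",
                              "three_prime_utr_bp", "intron_total_bp"])
    means = {c: int(round(per_tx[c].mean())) if len(per_tx) else 0
             for c in per_tx.columns}
    total = sum(means.values())
    shares = {c: means[c] / total if total else 0.0 for c in means}
    return FootprintStats(per_transcript=per_tx, means=means, shares=shares)
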
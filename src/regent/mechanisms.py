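"""Mechanism taxonomy and sequence-level triage detectors.

The taxonomy of mechanisms through which small non-coding variants cause
penetrant disease ships as a versioned TSV resource.  The detectors here
(uAUG/uORF scanner, splice-context classifier, polyA-motif check) are
sequence heuristics for triage and reporting only: they rank candidate
mechanisms but never activate evidence codes by themselves.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass
from importlib import resources

from .core import InputValidationError, TranscriptModel, VariantRecord, revcomp
from .regions import RegionClass, RegionContext

logger = logging.getLogger("regent")

STOP_CODONS = ("TAA", "TAG", "TGA")
POLYA_HEXAMERS = frozenset({"AATAAA", "ATTAAA"})


@dataclass(frozen=True)
class MechanismRecord:
    region_class: RegionClass
    mechanism: str
    vep_categories: tuple
    predictor_class: str
    exemplar: str


class SpliceClass(str, enum.Enum):
    canonical_donor = "canonical_donor"
    canonical_acceptor = "canonical_acceptor"
    donor_plus5 = "donor_plus5"
    splice_region = "splice_region"
    deep_intronic = "deep_intronic"
    none = "none"


@dataclass
class SpliceContext:
    klass: SpliceClass
    distance_to_junction: int | None = None
    intron_index: int | None = None


@dataclass
class UorfCall:
    creates_uAUG: bool
    frame_relative_to_cds: str | None = None  # in_frame / out_of_frame
    orf_type: str = "none"  # uORF / overlapping_oORF / cds_elongation / none
    kozak: str | None = None  # strong / moderate / weak


# ---------------------------------------------------------------------------
# Taxonomy resource

def load_taxonomy() -> list[MechanismRecord]:
    text = resources.files("regent").joinpath("data/mechanisms.tsv").read_text()
    rows = []
    lines = text.strip().splitlines()
    for line in lines[1:]:
        region, mech, veps, pred, ex = line.split("\t")
        rows.append(MechanismRecord(
            region_class=RegionClass(region), mechanism=mech,
            vep_categories=tuple(veps.split(",")), predictor_class=pred,
            exemplar=ex))
    return rows


_TAXONOMY: list[MechanismRecord] | None = None


def taxonomy() -> list[MechanismRecord]:
    global _TAXONOMY
    if _TAXONOMY is None:
        _TAXONOMY = load_taxonomy()
    return _TAXONOMY


# ---------------------------------------------------------------------------
# Splice context

def transcript_offset(t: TranscriptModel, pos0: int) -> int | None:
    """Spliced transcript-space offset of a genomic position, or None if
    the position is not exonic."""
    off = 0
    exons = t.exons if t.strand == "+" else list(reversed(t.exons))
    for e in exons:
        if e.start <= pos0 < e.end:
            return off + (pos0 - e.start if t.strand == "+" else e.end - 1 - pos0)
        off += len(e)
    return None


def classify_splice_context(v: VariantRecord, t: TranscriptModel) -> SpliceContext:
    """Splice-relevant position class, computed in transcript orientation.

    Canonical donor/acceptor are the first/last two intronic bases, the
    donor +5 position is singled out (elevated prior of splice disruption),
    splice_region covers intronic offsets 3-8 and the 1-3 exonic bases
    abutting a junction, and everything else intronic is deep_intronic.
    """
    pos0 = v.anchor0
    if not (t.start <= pos0 < t.end) or v.chrom != t.chrom:
        return SpliceContext(SpliceClass.none)

    introns = [(a.end, b.start) for a, b in zip(t.exons, t.exons[1:])]
    if t.strand == "-":
        tx_introns = list(reversed(introns))
    else:
        tx_introns = introns

    for idx, (s, e) in enumerate(tx_introns):
        if not (s <= pos0 < e):
            continue
        if t.strand == "+":
            d = pos0 - s + 1          # 1 = first intronic base after donor exon
            a = e - pos0              # 1 = last intronic base before acceptor exon
        else:
            d = e - pos0              # transcript orientation mirror
            a = pos0 - s + 1
        if d in (1, 2):
            return SpliceContext(SpliceClass.canonical_donor, d, idx)
        if a in (1, 2):
            return SpliceContext(SpliceClass.canonical_acceptor, a, idx)
        if d == 5:
            return SpliceContext(SpliceClass.donor_plus5, d, idx)
        if 3 <= d <= 8 or 3 <= a <= 8:
            return SpliceContext(SpliceClass.splice_region, min(d, a), idx)
        return SpliceContext(SpliceClass.deep_intronic, min(d, a), idx)

    # exonic: 1-3 bases from an internal junction
    for i, e in enumerate(t.exons):
        if not (e.start <= pos0 < e.end):
            continue
        dists = []
        if i > 0:  # junction on the genomic-left side
            dists.append(pos0 - e.start + 1)
        if i < len(t.exons) - 1:  # genomic-right side
            dists.append(e.end - pos0)
        if dists and min(dists) <= 3:
            return SpliceContext(SpliceClass.splice_region, min(dists), None)
        return SpliceContext(SpliceClass.none)
    return SpliceContext(SpliceClass.none)


# ---------------------------------------------------------------------------
# uAUG / uORF scanner

def _kozak_strength(seq: str, atg: int) -> str:
    """Kozak context graded on the (-3, +4) positions only."""
    m3 = seq[atg - 3] in "AG" if atg >= 3 else False
    p4 = seq[atg + 3] == "G" if atg + 3 < len(seq) else False
    if m3 and p4:
        return "strong"
    if m3 or p4:
        return "moderate"
    return "weak"


def scan_uaug(variant_offset: int, ref: str, alt: str, utr_sequence: str,
              cds_start_offset: int) -> UorfCall:
    """Detect uAUG creation by the alternate allele and classify the ORF.

    All inputs are in transcript orientation; ``utr_sequence`` starts at the
    transcript 5' end and must extend at least to ``cds_start_offset`` (the
    A of the annotated start codon).  The scanner checks the three codon
    windows covering the variant for an ATG created by the alternate allele,
    then scans in-frame codons from that ATG: a stop before the CDS start
    yields a discrete uORF; no stop yields an out-of-frame overlapping oORF
    or, in frame, an N-terminal CDS elongation.
    """
    if not (0 <= variant_offset < cds_start_offset):
        raise InputValidationError("variant must lie in the 5'UTR")
    if utr_sequence[variant_offset:variant_offset + len(ref)].upper() != ref.upper():
        raise InputValidationError("ref allele does not match UTR sequence")

    seq = utr_sequence.upper()
    mutated = seq[:variant_offset] + alt.upper() + seq[variant_offset + len(ref):]
    shift = len(alt) - len(ref)
    cds_mut = cds_start_offset + shift

    created = []
    lo = max(0, variant_offset - 2)
    hi = min(len(mutated) - 3, variant_offset + len(alt) - 1)
    for w in range(lo, hi + 1):
        if mutated[w:w + 3] != "ATG":
            continue
        # ignore windows unchanged from the reference (pre-existing uAUG)
        if shift == 0 and seq[w:w + 3] == "ATG":
            continue
        created.append(w)

    if not created:
        return UorfCall(creates_uAUG=False)

    w = created[0]
    kozak = _kozak_strength(mutated, w)
    frame = "in_frame" if (cds_mut - w) % 3 == 0 else "out_of_frame"
    i = w
    while i + 3 <= cds_mut:
        if mutated[i:i + 3] in STOP_CODONS and i > w:
            return UorfCall(True, frame, "uORF", kozak)
        i += 3
    orf = "cds_elongation" if frame == "in_frame" else "overlapping_oORF"
    return UorfCall(True, frame, orf, kozak)


def scan_uaug_genomic(v: VariantRecord, t: TranscriptModel, utr_sequence: str,
                      cds_start_offset: int) -> UorfCall:
    """Genomic-variant convenience wrapper around :func:`scan_uaug`."""
    toff = transcript_offset(t, v.anchor0)
    if toff is None:
        raise InputValidationError("variant is not exonic in this transcript")
    ref, alt = v.ref, v.alt
    if t.strand == "-":
        ref, alt = revcomp(ref), revcomp(alt)
        toff = toff - (len(ref) - 1)
    return scan_uaug(toff, ref, alt, utr_sequence, cds_start_offset)


# ---------------------------------------------------------------------------
# polyA signal motif

def check_polya_motif(utr3_sequence: str, variant_offset: int,
                      ref: str, alt: str) -> bool:
    """True iff the alternate allele destroys a canonical polyA hexamer.

    A hexamer window overlapping the variant that reads AATAAA/ATTAAA in the
    reference but reads as neither after the substitution counts as
    destroyed; converting one canonical hexamer into the other does not.
    """
    seq = utr3_sequence.upper()
    if seq[variant_offset:variant_offset + len(ref)] != ref.upper():
        raise InputValidationError("ref allele does not match 3'UTR sequence")
    mutated = seq[:variant_offset] + alt.upper() + seq[variant_offset + len(ref):]
    shift = len(alt) - len(ref)
    for w in range(max(0, variant_offset - 5), variant_offset + len(ref)):
        if seq[w:w + 6] not in POLYA_HEXAMERS:
            continue
        mut_w = w if w <= variant_offset else w + shift
        if mutated[mut_w:mut_w + 6] not in POLYA_HEXAMERS:
            return True
    return False


# ---------------------------------------------------------------------------
# Candidate mechanism ranking

def candidate_mechanisms(ctx: RegionContext, calls: dict | None = None
                         ) -> list[MechanismRecord]:
    """Taxonomy rows matching the context's region, detector hits first.

    ``calls`` may carry ``uorf`` (:class:`UorfCall`), ``splice``
    (:class:`SpliceContext`) and ``polya`` (bool) detector outputs; matching
    rows are promoted to the head of the list.
    """
    calls = calls or {}
    rows = [r for r in taxonomy() if r.region_class is ctx.region_class]
    if not rows:
        logger.warning("no mechanisms catalogued for region class %s",
                       ctx.region_class.value)
        return []

    promoted: list[str] = []
    uorf = calls.get("uorf")
    if isinstance(uorf, UorfCall) and uorf.creates_uAUG:
        promoted.append("n_terminal_elongation"
                        if uorf.orf_type == "cds_elongation" else "uAUG_creation")
    sc = calls.get("splice")
    if isinstance(sc, SpliceContext) and sc.klass in (
            SpliceClass.canonical_donor, SpliceClass.canonical_acceptor,
            SpliceClass.donor_plus5, SpliceClass.splice_region):
        promoted += ["canonical_splice_disruption", "splice_disruption"]
    if calls.get("polya"):
        promoted.append("polyA_signal_disruption")

    def rank(r: MechanismRecord) -> tuple:
        try:
            return (0, promoted.index(r.mechanism))
        except ValueError:
            return (1, 0)

    return sorted(rows, key=lambda r: (rank(r), r.mechanism))
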
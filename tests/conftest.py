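import numpy as np
import pytest

from regent.core import GenomeInterval, TranscriptModel
from regent.regions import RegionClass
from regent.simulate import SimConfig, make_toy_reference


@pytest.fixture(scope="session")
def toy_reference():
    return make_toy_reference(SimConfig(seed=11))


@pytest.fixture(scope="session")
def toy_transcripts(toy_reference):
    return toy_reference.transcripts


def random_transcript(rng: np.random.Generator, strand: str | None = None,
                      chrom: str = "chrT") -> TranscriptModel:
    """Small random multi-exon coding transcript for property tests."""
    strand = strand or ("+" if rng.random() < 0.5 else "-")
    n_exons = int(rng.integers(2, 6))
    exons, cursor = [], int(rng.integers(2500, 5000))
    for j in range(n_exons):
        length = int(rng.integers(40, 160))
        exons.append(GenomeInterval(chrom, cursor, cursor + length, strand))
        cursor += length + (int(rng.integers(30, 300)) if j < n_exons - 1 else 0)
    cds_start = exons[0].start + int(rng.integers(10, len(exons[0]) - 5))
    cds_end = exons[-1].end - int(rng.integers(10, len(exons[-1]) - 5))
    return TranscriptModel(
        transcript_id=f"TXR{int(rng.integers(1e6))}", gene_id="GR",
        gene_symbol="GR", chrom=chrom, strand=strand, exons=exons,
        cds_start=cds_start, cds_end=cds_end)


def brute_force_label(t: TranscriptModel, pos0: int) -> RegionClass | None:
    """Per-base region label computed directly from exon/CDS structure,
    independent of the interval arithmetic under test."""
    if not (t.start <= pos0 < t.end):
        return None
    in_exon = any(e.start <= pos0 < e.end for e in t.exons)
    if not in_exon:
        return RegionClass.intron
    if t.cds_start is None:
        return RegionClass.other
    if t.cds_start <= pos0 < t.cds_end:
        return RegionClass.coding
    before_cds = pos0 < t.cds_start
    if (before_cds and t.strand == "+") or (not before_cds and t.strand == "-"):
        return RegionClass.five_prime_utr
    return RegionClass.three_prime_utr


def mirror_transcript(t: TranscriptModel, contig_length: int) -> TranscriptModel:
    """Reverse-complement mirror: coordinates reflected through the contig."""
    L = contig_length
    exons = sorted((GenomeInterval(t.chrom, L - e.end, L - e.start,
                                   "-" if t.strand == "+" else "+")
                    for e in t.exons), key=lambda e: e.start)
    return TranscriptModel(
        transcript_id=t.transcript_id + "_mirror", gene_id=t.gene_id,
        gene_symbol=t.gene_symbol, chrom=t.chrom,
        strand="-" if t.strand == "+" else "+", exons=exons,
        cds_start=None if t.cds_start is None else L - t.cds_end,
        cds_end=None if t.cds_end is None else L - t.cds_start,
        provenance=t.provenance)
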
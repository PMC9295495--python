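"""Trio scan for rare non-coding variants in trans with a pLoF allele.

Given trio genotypes, a catalogue of biallelic (recessive) LoF disease
genes and per-gene non-coding region sets (introns, UTRs and a 200-bp core
promoter), the scan (1) finds probands carrying exactly one rare,
well-balanced, high-confidence pLoF per gene, (2) phases variants by
Mendelian transmission, and (3) reports rare non-coding variants in the
same gene inherited from the alternative parent, optionally filtering
intronic candidates by a permissive splice-impact score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from scipy.stats import chi2

from .core import InputValidationError, ThresholdConfig, VariantRecord, split_multiallelic
from .regions import RegionClass, RegionSet

logger = logging.getLogger("regent")

SCAN_REGION_CLASSES = (RegionClass.intron, RegionClass.five_prime_utr,
                       RegionClass.three_prime_utr, RegionClass.promoter)


@dataclass(frozen=True)
class TrioRecord:
    proband_id: str
    father_id: str
    mother_id: str

    def __post_init__(self) -> None:
        if len({self.proband_id, self.father_id, self.mother_id}) != 3:
            raise InputValidationError("trio requires three distinct samples")


@dataclass(frozen=True)
class AnnotationKeys:
    """INFO keys carrying the precomputed annotations the scan consumes."""

    gene: str = "GENE"
    lof: str = "LOF"  # value "HC" marks a high-confidence pLoF
    af: tuple = ("AF",)
    ac: str | None = "AC_REF"
    an: str | None = "AN_REF"
    nhomalt: str = "NHOMALT"
    splice: str = "SPLICEAI"


@dataclass
class SiteGenotypes:
    """One biallelic site with trio GT/AD."""

    variant: VariantRecord
    gt: dict  # sample -> tuple of allele indices (or None)
    ad: dict  # sample -> (ref_depth, alt_depth) or None


@dataclass
class InTransCandidate:
    variant: VariantRecord
    region_class: RegionClass
    transmitting_parent: str
    filtering_af: float
    homozygote_count: int
    splice_score: float | None = None


@dataclass
class SamplePlofPair:
    proband_id: str
    gene_id: str
    plof_variant: VariantRecord
    plof_parent: str
    candidates: list[InTransCandidate] = field(default_factory=list)


@dataclass
class ScanSummary:
    n_pairs: int
    n_pairs_with_candidate: int
    fraction_with_candidate: float
    mean_candidates_per_pair: float
    max_per_pair: int
    per_region: dict
    n_intronic_passing_splice_filter: int


# ---------------------------------------------------------------------------
# VCF access

def load_trio_vcf(path: str, trio: TrioRecord) -> list[SiteGenotypes]:
    """Read a multi-sample VCF into per-site biallelic trio genotypes."""
    import pysam

    sites: list[SiteGenotypes] = []
    with pysam.VariantFile(path) as vf:
        samples = list(vf.header.samples)
        for sid in (trio.proband_id, trio.father_id, trio.mother_id):
            if sid not in samples:
                raise InputValidationError(f"sample {sid} absent from VCF")
        for rec in vf:
            info = {k: rec.info.get(k) for k in rec.info.keys()}
            for v in split_multiallelic(rec.chrom, rec.pos, rec.ref,
                                        rec.alts or (), info, rec.id):
                alt_index = (rec.alts or ()).index(v.alt) + 1
                gt, ad = {}, {}
                for sid in (trio.proband_id, trio.father_id, trio.mother_id):
                    s = rec.samples[sid]
                    raw = s.get("GT")
                    if raw is None or any(a is None for a in raw):
                        gt[sid] = None
                    else:
                        # collapse other alt alleles so the site is biallelic
                        gt[sid] = tuple(1 if a == alt_index else 0 for a in raw)
                    depths = s.get("AD")
                    if depths is None or any(d is None for d in depths):
                        ad[sid] = None
                    else:
                        ad[sid] = (depths[0], depths[alt_index])
                sites.append(SiteGenotypes(v, gt, ad))
    return sites


# ---------------------------------------------------------------------------
# Genotype predicates

def _is_het(gt) -> bool:
    return gt is not None and len(gt) == 2 and sorted(gt) == [0, 1]


def _carries_alt(gt) -> bool | None:
    if gt is None:
        return None
    return any(a == 1 for a in gt)


def allele_balance(ad) -> float | None:
    if ad is None or (ad[0] + ad[1]) == 0:
        return None
    return ad[1] / (ad[0] + ad[1])


def transmitting_parent(site: SiteGenotypes, trio: TrioRecord) -> str | None:
    """Which parent transmitted a proband-heterozygous allele.

    Unambiguous only when exactly one parent carries the alternate allele;
    de novo (neither parent) and double-carrier configurations return None.
    Non-diploid genotypes are excluded from phasing.
    """
    gt_p = site.gt.get(trio.proband_id)
    if not _is_het(gt_p):
        return None
    fa = _carries_alt(site.gt.get(trio.father_id))
    mo = _carries_alt(site.gt.get(trio.mother_id))
    if fa is None or mo is None:
        return None
    if fa and not mo:
        return "father"
    if mo and not fa:
        return "mother"
    return None


def phase_by_transmission(site1: SiteGenotypes, site2: SiteGenotypes,
                          trio: TrioRecord) -> str:
    """Phase two proband-het variants: in_trans / in_cis / unknown."""
    t1 = transmitting_parent(site1, trio)
    t2 = transmitting_parent(site2, trio)
    if t1 is None or t2 is None:
        return "unknown"
    return "in_trans" if t1 != t2 else "in_cis"


def mendelian_error_rate(sites: list[SiteGenotypes], trio: TrioRecord) -> float:
    """Fraction of fully genotyped sites violating Mendelian transmission."""
    n = errors = 0
    for s in sites:
        gts = [s.gt.get(x) for x in (trio.proband_id, trio.father_id,
                                     trio.mother_id)]
        if any(g is None or len(g) != 2 for g in gts):
            continue
        n += 1
        p, f, m = gts
        possible = {tuple(sorted((a, b))) for a in f for b in m}
        if tuple(sorted(p)) not in possible:
            errors += 1
    return errors / n if n else 0.0


# ---------------------------------------------------------------------------
# Allele-frequency filters

def filtering_allele_frequency(ac: int | None, an: int | None,
                               point_af: float | None) -> float:
    """Confidence-bound filtering allele frequency.

    With allele counts available this is the lower bound of the one-sided
    95% CI of the population allele frequency (Poisson approximation,
    chi-square form); otherwise the point AF is used as a fallback.
    AC of zero yields 0.
    """
    if ac is not None and an:
        if ac <= 0:
            return 0.0
        return float(chi2.ppf(0.05, 2 * ac) / 2 / an)
    return float(point_af or 0.0)


def passes_af(info: dict, keys: AnnotationKeys, af_max: float,
              mode: str = "and") -> bool:
    """Rarity check over every AF source present.

    ``and`` (default, conservative): below threshold in every present
    source; ``or``: below threshold in at least one.
    """
    vals = [float(info[k]) for k in keys.af if info.get(k) is not None]
    if not vals:
        return True
    if mode == "or":
        return any(v < af_max for v in vals)
    return all(v < af_max for v in vals)


# ---------------------------------------------------------------------------
# Scan proper

def find_plof_pairs(sites: list[SiteGenotypes], trio: TrioRecord,
                    gene_list: set[str],
                    cfg: ThresholdConfig = ThresholdConfig(),
                    keys: AnnotationKeys = AnnotationKeys(),
                    af_mode: str = "and") -> list[SamplePlofPair]:
    """Probands with a single qualifying heterozygous pLoF per gene.

    Qualifying: high-confidence pLoF annotation, gene in the biallelic-LoF
    catalogue, AF below the rarity ceiling, proband heterozygous with
    allele balance strictly inside (balance_lo, balance_hi), and an
    unambiguous transmitting parent.  Genes where the proband carries two
    or more such pLoFs are excluded.
    """
    skipped = 0
    per_gene: dict[str, list[tuple[SiteGenotypes, str]]] = {}
    for s in sites:
        info = s.variant.info
        gene = info.get(keys.gene)
        if gene not in gene_list:
            continue
        if info.get(keys.lof) != "HC":  # absent annotation = not a pLoF
            continue
        if not passes_af(info, keys, cfg.af_max, af_mode):
            continue
        gt = s.gt.get(trio.proband_id)
        if gt is None or s.ad.get(trio.proband_id) is None:
            skipped += 1
            continue
        if not _is_het(gt):
            continue
        ab = allele_balance(s.ad.get(trio.proband_id))
        if ab is None or not (cfg.balance_lo < ab < cfg.balance_hi):
            continue
        parent = transmitting_parent(s, trio)
        if parent is None:
            continue
        per_gene.setdefault(gene, []).append((s, parent))
    if skipped:
        logger.warning("%d pLoF sites skipped for missing proband GT/AD",
                       skipped)

    pairs = []
    for gene in sorted(per_gene):
        hits = per_gene[gene]
        if len(hits) != 1:
            continue  # a single heterozygous pLoF is required
        site, parent = hits[0]
        pairs.append(SamplePlofPair(proband_id=trio.proband_id, gene_id=gene,
                                    plof_variant=site.variant,
                                    plof_parent=parent))
    return pairs


def scan_in_trans_noncoding(pair: SamplePlofPair, sites: list[SiteGenotypes],
                            trio: TrioRecord, region_set: RegionSet,
                            cfg: ThresholdConfig = ThresholdConfig(),
                            keys: AnnotationKeys = AnnotationKeys(),
                            apply_splice_filter: bool = False
                            ) -> SamplePlofPair:
    """Attach rare in-trans non-coding candidates to a sample-pLoF pair.

    Candidates lie in the gene's introns, UTRs or core promoter, were
    transmitted by the alternative parent to the pLoF, have filtering
    allele frequency below the ceiling and no observed reference-population
    homozygotes.  When the splice filter is on, intronic candidates
    additionally require a splice score at or above the permissive
    threshold; UTR and promoter candidates are unaffected.
    """
    other = "mother" if pair.plof_parent == "father" else "father"
    out = []
    for s in sites:
        if s.variant.key() == pair.plof_variant.key():
            continue
        pos0 = s.variant.anchor0
        hit_class = None
        for cls in SCAN_REGION_CLASSES:
            if any(iv.contains(s.variant.chrom, pos0)
                   for iv in region_set.of_class(cls)):
                hit_class = cls
                break
        if hit_class is None:
            continue
        if transmitting_parent(s, trio) != other:
            continue
        info = s.variant.info
        ac = info.get(keys.ac) if keys.ac else None
        an = info.get(keys.an) if keys.an else None
        point = next((info[k] for k in keys.af if info.get(k) is not None), None)
        faf = filtering_allele_frequency(
            int(ac) if ac is not None else None,
            int(an) if an is not None else None,
            float(point) if point is not None else None)
        if faf >= cfg.af_max:
            continue
        nhom = int(info.get(keys.nhomalt) or 0)
        if nhom != 0:
            continue
        score = info.get(keys.splice)
        score = float(score) if score is not None else None
        if (apply_splice_filter and hit_class is RegionClass.intron
                and (score is None or score < cfg.splice_score_min)):
            continue
        out.append(InTransCandidate(
            variant=s.variant, region_class=hit_class,
            transmitting_parent=other, filtering_af=faf,
            homozygote_count=nhom, splice_score=score))
    pair.candidates = out
    return pair


def summarize_scan(pairs: list[SamplePlofPair],
                   cfg: ThresholdConfig = ThresholdConfig()) -> ScanSummary:
    """Deterministic cohort summary of a completed scan."""
    n = len(pairs)
    counts = [len(p.candidates) for p in pairs]
    per_region = {cls.value: 0 for cls in SCAN_REGION_CLASSES}
    n_splice_pass = 0
    for p in pairs:
        for c in p.candidates:
            per_region[c.region_class.value] += 1
            if (c.region_class is RegionClass.intron
                    and c.splice_score is not None
                    and c.splice_score >= cfg.splice_score_min):
                n_splice_pass += 1
    with_cand = sum(1 for c in counts if c > 0)
    return ScanSummary(
        n_pairs=n,
        n_pairs_with_candidate=with_cand,
        fraction_with_candidate=with_cand / n if n else 0.0,
        mean_candidates_per_pair=sum(counts) / n if n else 0.0,
        max_per_pair=max(counts) if counts else 0,
        per_region=per_region,
        n_intronic_passing_splice_filter=n_splice_pass)


def run_trio_scan(sites: list[SiteGenotypes], trio: TrioRecord,
                  gene_list: set[str], region_sets: dict[str, RegionSet],
                  cfg: ThresholdConfig = ThresholdConfig(),
                  keys: AnnotationKeys = AnnotationKeys(),
                  apply_splice_filter: bool = False,
                  max_mendel_error_rate: float = 0.05
                  ) -> list[SamplePlofPair]:
    """End-to-end scan for one trio; aborts trios with poor Mendelian
    consistency (data-quality guard)."""
    mer = mendelian_error_rate(sites, trio)
    if mer > max_mendel_error_rate:
        logger.warning("trio %s aborted: Mendelian error rate %.1f%%",
                       trio.proband_id, 100 * mer)
        return []
    pairs = find_plof_pairs(sites, trio, gene_list, cfg, keys)
    out = []
    for pair in pairs:
        rs = region_sets.get(pair.gene_id)
        if rs is None:
            continue
        out.append(scan_in_trans_noncoding(pair, sites, trio, rs, cfg, keys,
                                           apply_splice_filter))
    return out
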
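"""Deterministic synthetic fixtures: toy genomes, trio cohorts,
ClinVar-like VCFs and the worked-example evidence worksheets.

Every generator is driven by a single integer seed and is byte-identical
across reruns.  The trio generator plants ground truth (pLoF alleles,
in-trans candidates at a chosen rate, in-cis decoys) and returns it as a
truth table, which downstream tests treat as the sufficient statistic.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import GenomeInterval, SequenceProvider, TranscriptModel, VariantRecord
from .census import ClinVarRecord
from .evidence import (AssayDescriptor, ContextFlags, EvidenceObservation,
                       PredictionSet, PriorVariantMatch, Strength, ToolCall,
                       TransPartner)
from .regions import RegionClass, RegionSet, derive_gene_regions
from .trans_scan import SiteGenotypes, TrioRecord

BASES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    seed: int = 1
    n_genes: int = 6
    exons_per_gene: tuple = (3, 6)
    exon_len: tuple = (80, 240)
    intron_len: tuple = (150, 600)
    intergenic_gap: int = 5000
    n_trios: int = 200
    lambda_in_trans: float = 0.9
    p_in_cis: float = 0.3
    p_af_decoy: float = 0.3
    af_rare_log10: tuple = (-5.0, -2.5)    # below the 0.5% rarity ceiling
    af_common_log10: tuple = (-2.2, -1.7)  # above it (filter decoys)
    clinvar_n: int = 1000
    clinvar_category_shares: dict = field(default_factory=lambda: {
        "coding": 0.50, "five_prime_utr": 0.10, "three_prime_utr": 0.10,
        "intron": 0.20, "promoter2kb": 0.05, "other": 0.05})
    clinvar_vus_rate: dict = field(default_factory=lambda: {
        "coding": 0.40, "five_prime_utr": 0.60, "three_prime_utr": 0.60,
        "intron": 0.50, "promoter2kb": 0.60, "other": 0.50})


@dataclass
class ToyReference:
    sequences: dict  # contig -> str
    transcripts: list
    contig_length: int

    @property
    def provider(self) -> SequenceProvider:
        return SequenceProvider(self.sequences)

    def region_sets(self, promoter_mode: str = "core200") -> dict:
        return {t.gene_id: derive_gene_regions(
                    t, promoter_mode, contig_length=self.contig_length)
                for t in self.transcripts}

    def write(self, out_dir: str) -> tuple[str, str]:
        os.makedirs(out_dir, exist_ok=True)
        fasta = os.path.join(out_dir, "toy.fa")
        gff = os.path.join(out_dir, "toy.gff3")
        with open(fasta, "w") as fh:
            for contig, seq in self.sequences.items():
                fh.write(f">{contig}\n")
                for i in range(0, len(seq), 60):
                    fh.write(seq[i:i + 60] + "\n")
        with open(gff, "w") as fh:
            fh.write("##gff-version 3\n")
            for t in self.transcripts:
                tag = f";tag={t.provenance}" if t.provenance != "canonical" else ""
                fh.write(f"{t.chrom}\ttoy\tgene\t{t.start + 1}\t{t.end}\t.\t"
                         f"{t.strand}\t.\tID={t.gene_id};Name={t.gene_symbol}\n")
                fh.write(f"{t.chrom}\ttoy\tmRNA\t{t.start + 1}\t{t.end}\t.\t"
                         f"{t.strand}\t.\tID={t.transcript_id};"
                         f"Parent={t.gene_id}{tag}\n")
                for e in t.exons:
                    fh.write(f"{t.chrom}\ttoy\texon\t{e.start + 1}\t{e.end}\t.\t"
                             f"{t.strand}\t.\tParent={t.transcript_id}\n")
                if t.is_coding:
                    fh.write(f"{t.chrom}\ttoy\tCDS\t{t.cds_start + 1}\t"
                             f"{t.cds_end}\t.\t{t.strand}\t0\t"
                             f"Parent={t.transcript_id}\n")
        return fasta, gff


def make_toy_transcript(rng: np.random.Generator, cfg: SimConfig, idx: int,
                        tx_start: int, strand: str,
                        provenance: str = "MANE_Select") -> TranscriptModel:
    n_exons = int(rng.integers(cfg.exons_per_gene[0], cfg.exons_per_gene[1] + 1))
    exons = []
    cursor = tx_start
    for j in range(n_exons):
        length = int(rng.integers(cfg.exon_len[0], cfg.exon_len[1] + 1))
        exons.append(GenomeInterval("chr1", cursor, cursor + length, strand))
        cursor += length
        if j < n_exons - 1:
            cursor += int(rng.integers(cfg.intron_len[0], cfg.intron_len[1] + 1))
    # CDS leaves >= 30 bp of UTR inside the first and last exon
    cds_start = exons[0].start + int(rng.integers(30, len(exons[0]) - 10))
    cds_end = exons[-1].end - int(rng.integers(30, len(exons[-1]) - 10))
    return TranscriptModel(
        transcript_id=f"TX{idx}", gene_id=f"GENE{idx}",
        gene_symbol=f"Gene{idx}", chrom="chr1", strand=strand,
        exons=exons, cds_start=cds_start, cds_end=cds_end,
        provenance=provenance)


def make_toy_reference(cfg: SimConfig) -> ToyReference:
    """Multi-exon coding genes on alternating strands, MANE-tagged.

    Genes are spaced far enough apart that 2-kb upstream promoter windows
    never reach a neighbouring transcript.
    """
    rng = np.random.default_rng(cfg.seed)
    transcripts = []
    cursor = cfg.intergenic_gap
    for i in range(cfg.n_genes):
        strand = "+" if i % 2 == 0 else "-"
        t = make_toy_transcript(rng, cfg, i, cursor, strand)
        transcripts.append(t)
        cursor = t.end + cfg.intergenic_gap
    contig_length = cursor + cfg.intergenic_gap
    seq = "".join(BASES[rng.integers(0, 4, contig_length)])
    return ToyReference(sequences={"chr1": seq}, transcripts=transcripts,
                        contig_length=contig_length)


# ---------------------------------------------------------------------------
# Trio cohort

@dataclass
class TrioSim:
    trio: TrioRecord
    sites: list


def _snv_at(ref: ToyReference, pos0: int, rng: np.random.Generator,
            info: dict) -> VariantRecord:
    refb = ref.sequences["chr1"][pos0]
    alts = [b for b in "ACGT" if b != refb]
    alt = alts[int(rng.integers(0, 3))]
    return VariantRecord(chrom="chr1", pos=pos0 + 1, ref=refb, alt=alt,
                         info=info)


def _trio_site(v: VariantRecord, trio: TrioRecord, parent: str,
               rng: np.random.Generator) -> SiteGenotypes:
    """Mendelian-consistent het-in-proband site transmitted by ``parent``."""
    depth = 30
    alt_reads = int(rng.integers(12, 19))  # balance within (0.25, 0.75)
    gt = {trio.proband_id: (0, 1),
          trio.father_id: (0, 1) if parent == "father" else (0, 0),
          trio.mother_id: (0, 1) if parent == "mother" else (0, 0)}
    ad = {s: (depth - alt_reads, alt_reads) if any(g) else (depth, 0)
          for s, g in gt.items()}
    return SiteGenotypes(v, gt, ad)


def make_trio_cohort(cfg: SimConfig, ref: ToyReference
                     ) -> tuple[list[TrioSim], pd.DataFrame]:
    """Plant per trio one het high-confidence pLoF plus in-trans
    non-coding candidates at rate ``lambda_in_trans`` and in-cis decoys at
    probability ``p_in_cis``; return the cohort and the truth table."""
    rng = np.random.default_rng(cfg.seed + 1)
    region_sets = ref.region_sets("core200")
    genes = [t.gene_id for t in ref.transcripts]
    by_gene = {t.gene_id: t for t in ref.transcripts}

    sims, truth = [], []
    for k in range(cfg.n_trios):
        trio = TrioRecord(f"P{k}", f"F{k}", f"M{k}")
        gene = genes[int(rng.integers(0, len(genes)))]
        t = by_gene[gene]
        rs = region_sets[gene]
        plof_parent = "father" if rng.random() < 0.5 else "mother"
        other = "mother" if plof_parent == "father" else "father"

        used: set[int] = set()
        cds_pos = int(rng.integers(t.cds_start, t.cds_end))
        used.add(cds_pos)
        plof = _snv_at(ref, cds_pos, rng, {
            "GENE": gene, "LOF": "HC", "AF": 1e-4, "NHOMALT": 0})
        sites = [_trio_site(plof, trio, plof_parent, rng)]
        truth.append(dict(trio=trio.proband_id, gene=gene, kind="plof",
                          pos=plof.pos, region="coding", parent=plof_parent,
                          splice_score=np.nan, passes_af=True))

        def plant(parent: str, kind: str, rare: bool = True) -> None:
            classes = [RegionClass.intron, RegionClass.five_prime_utr,
                       RegionClass.three_prime_utr, RegionClass.promoter]
            weights = np.array([0.85, 0.05, 0.05, 0.05])
            cls = classes[int(rng.choice(4, p=weights))]
            ivs = rs.of_class(cls)
            iv = ivs[int(rng.integers(0, len(ivs)))]
            pos0 = int(rng.integers(iv.start, iv.end))
            while pos0 in used:  # avoid stacking two plants on one base
                pos0 = int(rng.integers(iv.start, iv.end))
            used.add(pos0)
            band = cfg.af_rare_log10 if rare else cfg.af_common_log10
            af = 10 ** rng.uniform(*band)
            score = float(np.round(rng.random(), 3))
            info = {"GENE": gene, "AF": af, "NHOMALT": 0, "SPLICEAI": score}
            v = _snv_at(ref, pos0, rng, info)
            sites.append(_trio_site(v, trio, parent, rng))
            truth.append(dict(trio=trio.proband_id, gene=gene, kind=kind,
                              pos=v.pos, region=cls.value, parent=parent,
                              splice_score=score, passes_af=af < 0.005))

        for _ in range(int(rng.poisson(cfg.lambda_in_trans))):
            plant(other, "in_trans")
        if rng.random() < cfg.p_in_cis:
            plant(plof_parent, "in_cis")
        if rng.random() < cfg.p_af_decoy:  # rare-variant filter, failing side
            plant(other, "af_decoy", rare=False)
        sims.append(TrioSim(trio=trio, sites=sites))

    return sims, pd.DataFrame(
        truth, columns=["trio", "gene", "kind", "pos", "region", "parent",
                        "splice_score", "passes_af"])


def write_trio_vcf(sim: TrioSim, path: str) -> None:
    """Serialise one trio's sites as an uncompressed VCF 4.2 text file."""
    trio = sim.trio
    header = [
        "##fileformat=VCFv4.2",
        "##contig=<ID=chr1>",
        '##INFO=<ID=GENE,Number=1,Type=String,Description="Gene">',
        '##INFO=<ID=LOF,Number=1,Type=String,Description="LoF confidence">',
        '##INFO=<ID=AF,Number=1,Type=Float,Description="Allele frequency">',
        '##INFO=<ID=NHOMALT,Number=1,Type=Integer,Description="Homozygote count">',
        '##INFO=<ID=SPLICEAI,Number=1,Type=Float,Description="Splice score">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        f"{trio.proband_id}\t{trio.father_id}\t{trio.mother_id}"]
    lines = []
    for s in sorted(sim.sites, key=lambda x: x.variant.pos):
        v = s.variant
        info = ";".join(
            f"{k}={v.info[k]:.6g}" if isinstance(v.info[k], float)
            else f"{k}={v.info[k]}"
            for k in ("GENE", "LOF", "AF", "NHOMALT", "SPLICEAI")
            if v.info.get(k) is not None)
        cols = [v.chrom, str(v.pos), ".", v.ref, v.alt, ".", "PASS", info, "GT:AD"]
        for sid in (trio.proband_id, trio.father_id, trio.mother_id):
            gt = "/".join(map(str, s.gt[sid]))
            ad = ",".join(map(str, s.ad[sid]))
            cols.append(f"{gt}:{ad}")
        lines.append("\t".join(cols))
    with open(path, "w") as fh:
        fh.write("\n".join(header + lines) + "\n")


# ---------------------------------------------------------------------------
# ClinVar-like cohort

_SIG_POOL = {"plp": ("Pathogenic", "Likely_pathogenic"),
             "blb": ("Benign", "Likely_benign"),
             "vus": ("Uncertain_significance",)}
_REV_POOL = ("criteria_provided,_multiple_submitters,_no_conflicts",
             "reviewed_by_expert_panel", "practice_guideline",
             "criteria_provided,_single_submitter", "no_assertion_criteria_provided")


def make_clinvar_like(cfg: SimConfig, ref: ToyReference
                      ) -> tuple[list[ClinVarRecord], dict]:
    """ClinVar-style records with exactly planted category shares and
    per-category VUS rates; the truth dict carries the planted values."""
    from .census import build_transcript_index, categorize_variant

    rng = np.random.default_rng(cfg.seed + 2)
    index = build_transcript_index(ref.transcripts)
    region_sets = ref.region_sets("audit2kb")
    by_gene = {t.gene_id: t for t in ref.transcripts}

    counts = {c: int(round(s * cfg.clinvar_n))
              for c, s in cfg.clinvar_category_shares.items()}
    records: list[ClinVarRecord] = []
    truth_vus = {}
    cls_map = {"coding": RegionClass.coding,
               "five_prime_utr": RegionClass.five_prime_utr,
               "three_prime_utr": RegionClass.three_prime_utr,
               "intron": RegionClass.intron,
               "promoter2kb": RegionClass.promoter}

    for cat, n_cat in counts.items():
        n_vus = int(round(cfg.clinvar_vus_rate[cat] * n_cat))
        truth_vus[cat] = n_vus / n_cat if n_cat else 0.0
        for j in range(n_cat):
            for _ in range(200):  # rejection-sample until category matches
                if cat == "other":
                    pos0 = int(rng.integers(100, 2500))  # left margin, no gene
                else:
                    gene = ref.transcripts[int(rng.integers(0, len(ref.transcripts)))].gene_id
                    ivs = region_sets[gene].of_class(cls_map[cat])
                    iv = ivs[int(rng.integers(0, len(ivs)))]
                    pos0 = int(rng.integers(iv.start, iv.end))
                v = _snv_at(ref, pos0, rng, {})
                if categorize_variant(v, index) == cat:
                    break
            if j < n_vus:
                sig = "Uncertain_significance"
            elif j % 2 == 0:
                sig = _SIG_POOL["plp"][int(rng.integers(0, 2))]
            else:
                sig = _SIG_POOL["blb"][int(rng.integers(0, 2))]
            rev = _REV_POOL[int(rng.integers(0, len(_REV_POOL)))]
            records.append(ClinVarRecord(variant=v, clnsig=sig,
                                         clnrevstat=rev, category=None))
    truth = {"category_counts": counts, "vus_rate": truth_vus,
             "n": sum(counts.values())}
    return records, truth


def write_clinvar_vcf(records: list[ClinVarRecord], path: str) -> None:
    header = [
        "##fileformat=VCFv4.2",
        "##contig=<ID=chr1>",
        '##INFO=<ID=CLNSIG,Number=.,Type=String,Description="Clinical significance">',
        '##INFO=<ID=CLNREVSTAT,Number=.,Type=String,Description="Review status">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO"]
    lines = []
    for r in sorted(records, key=lambda x: x.variant.pos):
        v = r.variant
        info = f"CLNSIG={r.clnsig};CLNREVSTAT={r.clnrevstat}"
        lines.append("\t".join([v.chrom, str(v.pos), ".", v.ref, v.alt,
                                ".", ".", info]))
    with open(path, "w") as fh:
        fh.write("\n".join(header + lines) + "\n")


# ---------------------------------------------------------------------------
# Worked-example evidence worksheets

def worked_example_worksheets() -> dict:
    """Evidence bundles for three canonical example curations.

    Keys: ``cftr_initial``, ``cftr_updated``, ``pax6``, ``nf1_pm6``,
    ``nf1_ps2``, ``nf1_pp1``, ``nf1_ps3_moderate``, ``nf1_ps3_strong``.
    Each value is ``(observations, context)`` ready for the classifier.
    """
    out = {}

    # CFTR: deep-intronic variant creating a cryptic exon, in trans with a
    # known pathogenic coding allele; splice predictors disagreed.
    cftr_ctx = ContextFlags(gene_id="CFTR", lof_established_mechanism=True,
                            phenotype_discriminative=True,
                            n_genes_for_phenotype=1,
                            candidate_mechanisms=("splicing",))
    cftr_preds = PredictionSet(tools=[
        ToolCall("MaxEntScan", 8.1, "deleterious"),
        ToolCall("SpliceAI", 0.05, "benign"),
        ToolCall("TraP", 0.1, "benign")], target_gene_context="CFTR")
    cftr_base = [
        EvidenceObservation("PS3", Strength.Strong, AssayDescriptor(
            assay_class="rna_seq", tissue_expression_match=True,
            coverage_adequate=True, mechanisms_assessed=("splicing",),
            controls_validated=True)),
        EvidenceObservation("PM2", Strength.Supporting),
        EvidenceObservation("PP4", Strength.Supporting),
        EvidenceObservation("PP3", Strength.Supporting, cftr_preds),
    ]
    out["cftr_initial"] = (
        cftr_base + [EvidenceObservation("PM3", Strength.Moderate, TransPartner(
            phase="in_trans", partner_classification="Pathogenic"))],
        cftr_ctx)
    out["cftr_updated"] = (
        cftr_base + [EvidenceObservation("PM3", Strength.VeryStrong, TransPartner(
            phase="in_trans", partner_classification="Pathogenic"))],
        cftr_ctx)

    # PAX6: distal enhancer variant; reporter assay in the lens; de novo.
    pax6_ctx = ContextFlags(gene_id="PAX6", phenotype_discriminative=True,
                            n_genes_for_phenotype=1,
                            candidate_mechanisms=("tf_binding",))
    pax6_preds = PredictionSet(tools=[
        ToolCall("CADD", 17.4, "deleterious", mechanism="deleteriousness"),
        ToolCall("ReMM", 0.985, "deleterious", mechanism="deleteriousness"),
        ToolCall("FATHMM_MKL", 0.993, "deleterious", mechanism="deleteriousness")],
        genome_wide_flag=True, target_gene_context="PAX6")
    out["pax6"] = ([
        EvidenceObservation("PS2", Strength.Strong),
        EvidenceObservation("PS3", Strength.Moderate, AssayDescriptor(
            assay_class="reporter", controls_validated=True,
            mechanisms_assessed=("tf_binding",))),
        EvidenceObservation("PM2", Strength.Supporting),
        EvidenceObservation("PP3", Strength.Supporting, pax6_preds),
        EvidenceObservation("PP4", Strength.Supporting)], pax6_ctx)

    # NF1: uAUG-creating 5'UTR variant, out-of-frame overlapping ORF into a
    # strong Kozak, matching the impact of established pathogenic uAUGs.
    nf1_ctx = ContextFlags(gene_id="NF1", in_utr=True,
                           phenotype_discriminative=True,
                           n_genes_for_phenotype=1,
                           candidate_mechanisms=("translation",))
    nf1_base = [
        EvidenceObservation("PM5", Strength.Moderate, PriorVariantMatch(
            relation="same_predicted_impact", same_gene=True,
            mechanism="translation")),
        EvidenceObservation("PM2", Strength.Supporting),
        EvidenceObservation("PP4", Strength.Supporting)]
    out["nf1_pm6"] = (nf1_base + [EvidenceObservation("PM6", Strength.Moderate)],
                      nf1_ctx)
    out["nf1_ps2"] = (nf1_base + [EvidenceObservation("PS2", Strength.Strong)],
                      nf1_ctx)
    out["nf1_pp1"] = (nf1_base + [EvidenceObservation("PP1", Strength.Moderate)],
                      nf1_ctx)
    ps3_reporter = EvidenceObservation("PS3", Strength.Moderate, AssayDescriptor(
        assay_class="reporter", controls_validated=True,
        mechanisms_assessed=("translation",)))
    ps3_tissue = EvidenceObservation("PS3", Strength.Strong, AssayDescriptor(
        assay_class="rna_seq", tissue_expression_match=True,
        coverage_adequate=True, mechanisms_assessed=("translation",)))
    out["nf1_ps3_moderate"] = (
        nf1_base + [EvidenceObservation("PM6", Strength.Moderate), ps3_reporter],
        nf1_ctx)
    out["nf1_ps3_strong"] = (
        nf1_base + [EvidenceObservation("PM6", Strength.Moderate), ps3_tissue],
        nf1_ctx)
    return out
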
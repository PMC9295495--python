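# regent

**Region-aware ACMG/AMP evidence engine for variants in non-coding
regions of the genome.**

Most clinical variant interpretation is built around protein-coding
sequence, yet penetrant disease variants are increasingly found in
5'UTRs, 3'UTRs, introns, promoters and distal cis-regulatory elements
(CREs). `regent` is a library and CLI for laboratories and researchers
who need to interpret such variants reproducibly. It automates the
conservative workflow of:

1. **Region definition and filtering** — per-gene interpretable regions
   from MANE-style transcript models (spliced UTRs, introns, strand-aware
   promoters under four definitions), plus a two-step CRE filter
   (element-level epigenetic evidence AND an experimental link to the
   target gene) gated on gene-disease validity; anything failing a gate
   is a research variant, not evidence.
2. **Mechanism triage** — a machine-readable taxonomy of documented
   non-coding disease mechanisms with sequence-level detectors: a
   uAUG/uORF scanner (ORF type, frame, Kozak strength), a splice-context
   classifier (canonical sites, the donor +5 position, splice region,
   deep intronic) and a polyA-signal check.
3. **Evidence gating** — each proposed ACMG/AMP code (PVS1 … BP7) is
   validated against non-coding applicability rules: PM1 and PM2 capped
   at Supporting, PVS1 restricted to canonical splice sites in
   established-LoF genes, PS3/BS3 graded by assay class and validation
   state, PP3/BP4 restricted to the correct gene context, missense-only
   codes rejected, and mutually exclusive codes resolved (PVS1 × PP3,
   PS3 × PP3 on the same mechanism, …). Gates only cap or reject — never
   raise — a proposed strength.
4. **Combination** — the gated evidence is combined into the five-tier
   scale (Pathogenic / Likely Pathogenic / VUS / Likely Benign / Benign)
   by either the categorical combining table or the additive point scale
   (Supporting = 1, Moderate = 2, Strong = 4, VeryStrong = 8; P ≥ 10,
   LP 6–9); conflicting evidence yields VUS.

Two cohort pipelines sit on the same engine: a **trio scan** that finds
probands with a single rare heterozygous pLoF in a biallelic-LoF disease
gene and reports rare non-coding variants inherited in trans from the
other parent (informing PM3), and a **census** that categorises a
ClinVar-style VCF against MANE Select regions and quantifies per-region
classification mix, VUS rates and genomic footprints.

## Worked example

The engine ships the evidence worksheet of a deep-intronic *CFTR*
variant found in trans with p.Phe508del in a patient with cystic
fibrosis: a tissue-appropriate RNA assay demonstrated a 125-bp cryptic
exon (PS3 at Strong), the in-trans partner is an established pathogenic
allele (PM3), the variant is absent from population databases (PM2) and
the phenotype is gene-specific (PP4) — while splice predictors disagreed
with each other, so neither PP3 nor BP4 may be applied.

```bash
regent simulate worksheets --out demo/
regent classify --worksheet demo/cftr_initial.yaml
```

prints

```
classification	Likely Pathogenic
points	8
evidence	PM2: accepted (Supporting) [pm2_reduced_to_supporting]
evidence	PM3: accepted (Moderate) [ok]
evidence	PP3: rejected (-) [conflicting_tool_calls]
evidence	PP4: accepted (Supporting) [ok]
evidence	PS3: accepted (Strong) [ok]
```

One Strong + one Moderate + two Supporting items is a Likely Pathogenic
combination (8 points on the additive scale, inside the 6–9 band), and
the trail shows every gate action, including the rejected in-silico
code. Re-running with `demo/cftr_updated.yaml` — where later family
studies raise PM3 to VeryStrong — upgrades the classification to
`Pathogenic` (14 points).

Other subcommands: `regent regions` (BED export of interpretable
regions), `regent trans-scan` (trio pipeline), `regent clinvar-audit`
and `regent footprint` (census pipelines), `regent simulate`
(deterministic synthetic references, trio cohorts and ClinVar-like
VCFs). See `docs/methods.md` for the model, parameter defaults and
design choices.

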
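# Methods

`regent` automates a conservative interpretation workflow for small
variants (SNVs and indels < 50 bp) outside protein-coding sequence:
region definition and filtering, mechanism triage, ACMG/AMP evidence-code
gating with non-coding strength modulations, and evidence combination into
the five-tier scale. Two cohort pipelines are built on the same region
engine: a trio scan for rare non-coding variants in trans with a
heterozygous pLoF allele, and a region census of ClinVar-style variant
sets. This note records the model, the tunable parameters, the numerical
choices, and what the synthetic fixtures do and do not show.

## Coordinates and variant representation

Internally every interval is 0-based half-open; VCF positions (1-based)
and GFF3 intervals (1-based inclusive) are converted exactly once, at the
I/O boundary. Multi-allelic records are split into biallelic records
before any interpretation because every rule in the engine is per-allele.
Variants are normalized to the left-aligned parsimonious representation
(right-trim with left extension, then prefix trim), which is idempotent
and haplotype-preserving. Wherever a variant must be assigned to exactly
one region (the census, the trio scan), it is localised to its leftmost
altered base after normalization; this is a deterministic convention, not
a biological claim, and matters only for indels spanning a region
boundary. Contig-name dialects (`chr17` vs `17`) are harmonised by a
strip/add-prefix helper applied at load time.

## Region engine

Interpretation always uses one clinically preferred transcript per gene,
chosen with precedence MANE Select > MANE Plus Clinical > canonical and a
lexical tie-break on transcript id. The engine does not interpret against
multiple transcripts of the same gene.

For a coding transcript, the 5'/3'UTRs are the exonic fragments outside
the CDS on the respective side in transcript orientation, introns are the
gaps between consecutive exons, and UTR introns are classed as intron
(both cohort pipelines treat "intronic" as one class). These parts tile
the transcript span exactly and disjointly; the test suite checks this
base by base against an independent labeller on randomized transcripts.

Four promoter definitions are supported, all strand-aware (upstream means
5' of the TSS in transcript orientation):

| mode | window | used by |
|---|---|---|
| `core200` | 200 bp directly upstream | trio scan |
| `audit2kb` | 2 kb directly upstream | census (`promoter2kb`) |
| `minimal250` | 250 bp up- and downstream | fallback when no epigenetic support exists |
| `epigenetic` | union of open-chromatin peaks containing the TSS | when ATAC/DNase peaks are supplied |

Windows are clipped at contig edges; a window clipped to nothing is
omitted. When several overlapping peaks contain the TSS their union is
used, reading "the open-chromatin region surrounding the TSS" as one
contiguous region. The 2-kb audit promoter is not trimmed where it
overlaps a neighbouring gene's transcript; the census precedence (below)
resolves such positions in favour of the transcript feature.

Distal candidate CREs are admitted through a two-step evidence filter
plus a gene-level gate: at least one element-level mark (open chromatin,
H3K27Ac, H3K4Me1, TF ChIP), at least one experimental link to the target
gene (chromatin interaction, perturbation, eQTL), and gene-disease
validity at definitive/strong/moderate (or PanelApp green). Elements
failing any gate are research variants: excluded from interpretation with
the failed gates named. This is a filter, never evidence of pathogenicity.

A variant can yield several region contexts at once — e.g. intronic in
one gene while inside an admitted CRE linked to another — and each
context is interpreted separately against its own gene.

## Mechanism triage

A versioned TSV taxonomy maps each region class to the documented
mechanisms of penetrant non-coding disease (uAUG creation, uORF
perturbation, splice disruption, polyA-signal loss, TF-motif alteration,
enhancer disruption, and so on) with their VEP category strings and
predictor classes. Three sequence-level detectors rank these candidates:

* **uAUG/uORF scanner** — checks the three codon windows covering a 5'UTR
  variant for an ATG created by the alternate allele, then scans in-frame
  codons: a stop before the CDS start is a discrete uORF; no stop is an
  out-of-frame overlapping oORF or, in frame, an N-terminal elongation.
  Kozak strength is graded on the (−3, +4) positions only: both matching
  (A/G at −3, G at +4) is strong, one is moderate, neither weak. This is
  the minimal standard operationalisation of "strong Kozak consensus".
* **Splice-context classifier** — canonical donor/acceptor are the
  first/last two intronic bases; the donor +5 base is singled out because
  of its well-established elevated prior of splice disruption;
  splice_region follows the common 1–3 exonic / 3–8 intronic convention;
  anything else intronic is deep intronic.
* **polyA check** — true only if the alternate allele converts an
  AATAAA/ATTAAA hexamer overlapping the variant into a non-canonical
  hexamer; converting one canonical signal into the other is not a hit.

Detectors are triage only. They rank candidate mechanisms for reporting
and feed the BS3 mechanism-coverage check, but they never activate an
evidence code by themselves; in-silico support always routes through PP3
with explicit score inputs.

## Evidence gating

Each proposed code is validated against the non-coding applicability
rules; gates only cap or reject, never raise, a proposed strength.

* **PVS1** — only canonical ±1/2 splice sites in genes with an
  established LoF mechanism; rejected inside UTRs when the downstream
  impact is not clearly LoF, and for every other non-coding context (null
  effect cannot be predicted without data). Never combined with PP3.
* **PM1** — non-coding constraint is base-specific, so regional hotspot
  arguments never qualify; a recurrently pathogenic TF motif or a
  well-defined enhancer sub-region cluster does, always capped at
  Supporting. In-silico-only motif evidence is rejected with a pointer to
  PP3.
* **PS1/PM5** — analogy to an established pathogenic variant: PS1 at full
  strength at the same base, at Supporting for a different substitution
  at the same position predicted at least as deleterious; PM5 (capped
  Moderate) for variants elsewhere with exactly the same predicted impact
  on the same gene (e.g. a new out-of-frame oORF-creating uAUG in a gene
  with established pathogenic uAUGs). "Exactly the same impact" is
  operationalised as the relation taxonomy carried in the support payload
  and surfaced in the decision reasons rather than hidden.
* **PM3** — requires confirmed in-trans phase and both alleles below the
  rarity ceiling; one-step downgrade for genes with > 1 Mb of intronic
  sequence or when reference data mismatch the individual's genetic
  ancestry (both configurable). A helper computes the empirical
  exceedance P(score ≥ candidate) over the gene-wide score distribution
  so callers can downgrade PM3 when similar-scoring variants are
  commonplace in the gene.
* **PS3/BS3** — PS3 Strong only for patient RNA assays matched to the
  disease tissue with adequate depth; validated reporter/MAVE systems and
  disrupted chromatin interaction cap at Moderate (the artificial-assay
  caution; whether chromatin-interaction disruption may reach Strong is
  left at Moderate by default). BS3 requires biallelic expression,
  adequate coverage and a read-out covering every candidate mechanism of
  the context (a normal RNA result cannot clear a 5'UTR variant whose
  candidate mechanism is translational), or a direction of effect
  contradicting the gene's dosage mechanism.
* **PP3/BP4** — Supporting at most; scores computed for a different
  target gene are ignored (a splice score computed on a neighbouring
  gene's transcript says nothing about an enhancer's target); conflicting
  tool calls activate neither; genome-wide ML predictors add a caution
  reason; the donor +5 context is noted as an elevated prior without a
  strength change.
* **PP4** — only when the phenotype is discriminative and tied to at most
  `pp4_max_genes` genes (default 3; the guidance says "only, or one of
  very few" without a number, so this is a documented knob).
* **Pass-through** — frequency, de novo and segregation codes (BA1, BS1,
  BS2, BS4, PM2, PM6, PS2, PP1, …) apply as for coding variants, except
  PM2 defaults to Supporting per current SVI practice. PP2 and BP1 are
  missense-specific and always rejected.

Exclusivity resolution then drops codes that would double-count one
evidence source: PVS1 excludes PP3 outright; PS3, PM1 and PM5 exclude a
PP3 resting on the same mechanism tag (assay mechanisms, motif evidence,
or the same prediction); exclusions sharing no mechanism leave both codes
standing. Output is deterministic and order-insensitive; duplicate
proposals keep the strongest with a warning.

## Combination

Two combiners are provided and agree on every worked example. The
categorical mode encodes the 2015 combining table, counting codes by
final (gated) strength so a modulated code counts at its adjusted level.
The point mode uses the additive scale Supporting = 1, Moderate = 2,
Strong = 4, VeryStrong = 8 (benign negative) with cut-offs P ≥ 10, LP
6–9, VUS 0–5, LB −6…−1, B ≤ −7. BA1 is stand-alone and outranks
everything. Evidence meeting both a pathogenic and a benign combination
is conflicting and yields VUS; no clinical-judgement override is
implemented, keeping the engine deterministic. The categorical mode is
the default. An exhaustive test enumerates all multisets of ≤ 6
pathogenic and ≤ 3 benign codes against an independently written truth
table.

## Trio in-trans scan

Per trio: sites with > 5% Mendelian-error rate abort the trio (quality
guard). Probands are kept when they carry exactly one heterozygous
high-confidence pLoF per catalogued biallelic-LoF gene with AF below
0.5% and allele balance strictly inside (0.25, 0.75). "Below 0.5% in the
cohort and/or reference" is implemented as a strict AND over every AF
source present, with a documented OR option. Transmission phasing is
unambiguous only when exactly one parent carries the alternate allele;
de novo, double-carrier, missing and non-diploid configurations are
unknown and never phased. Candidates are variants in the gene's introns,
UTRs or 200-bp core promoter transmitted by the alternative parent, with
filtering allele frequency below 0.5% and zero reference-population
homozygotes. The filtering allele frequency is the lower bound of the
one-sided 95% CI of the population frequency (chi-square form of the
Poisson bound) when allele counts are available, else the point AF. The
optional splice filter requires a splice score ≥ 0.2 for intronic
candidates only; UTR and promoter candidates are unaffected, following
the scan's intronic-only filter scope.

## Census

ClinVar-style records keep CLNSIG/CLNREVSTAT verbatim; significance
matching uses the primary term before comma-delimited modifiers.
High-confidence pathogenic means review status in
{criteria_provided,_multiple_submitters,_no_conflicts;
reviewed_by_expert_panel; practice_guideline} and significance in
{Pathogenic; Likely_pathogenic; Pathogenic/Likely_pathogenic}. Each
variant receives one category across all overlapping MANE Select
transcripts with precedence coding > 5'UTR > 3'UTR > intron >
promoter2kb; variants overlapping no MANE Select transcript or its 2-kb
upstream window are "other". The precedence order mirrors the listing
order commonly used for consequence annotation; no standard rule exists for
multi-category overlaps; this is the single choice a full-scale
reproduction would be most sensitive to. Footprint statistics are spliced
lengths (sums of exonic fragments), so per transcript 5'UTR + CDS +
3'UTR + introns equals the transcript span exactly — this identity is
asserted on every input and fixes the interpretation of "region length"
as spliced, not genomic.

## Synthetic fixtures

The generators exist so every pipeline is testable with zero downloads;
their defaults are the study conditions the tests assert.

* **Toy reference** — six multi-exon coding genes on alternating strands,
  MANE-tagged, spaced 5 kb apart so 2-kb promoter windows never reach a
  neighbouring transcript. Byte-identical FASTA/GFF3 per seed.
* **Trio cohort** — 200 trios by default. Each trio carries one
  well-balanced heterozygous HC pLoF in one gene; qualifying in-trans
  non-coding candidates are planted at Poisson rate λ = 0.9 per
  sample-pLoF pair, 85%
  intronic, with AFs drawn log-uniform below the 0.5% ceiling and splice
  scores uniform on (0, 1). Separate decoys exercise the failure modes:
  in-cis variants (same transmitting parent, probability 0.3) and
  common-allele decoys above the AF ceiling (probability 0.3). The truth
  table is the sufficient statistic: recovery tests compare scan output
  to it, never to re-derived values.
* **ClinVar-like cohort** — 1000 records with exact integer planting of
  category shares (50% coding, 10% each UTR, 20% intron, 5% promoter,
  5% other) and per-category VUS rates (higher in UTRs/promoter than
  coding, the qualitative pattern seen in clinical databases), placed by
  rejection sampling until the global categoriser agrees with the target
  category.
* **Worksheets** — the three example curations (a deep-intronic
  cryptic-exon variant proven in trans in a recessive gene; a distal
  enhancer variant with a validated reporter assay and de novo origin; a
  uAUG-creating 5'UTR variant matching established pathogenic uAUGs)
  encoded as evidence bundles with full context flags, including the
  deliberately conflicting splice predictions that exclude PP3/BP4 in
  the first example.

What the fixtures do **not** emulate: linkage disequilibrium and
realistic haplotype structure, mutation-rate heterogeneity, sequencing
error, genotyping missingness, overlapping genes, alternative
transcripts, and real epigenomic peak geometry. Passing recovery tests
therefore demonstrates the correctness of the region arithmetic,
phasing logic and filters under clean conditions, not performance on
real cohort data; full-scale cohort figures from access-restricted
datasets are deliberately not asserted anywhere.

## Problem sizes and determinism

Default test and acceptance problem sizes — 200 trios, 1000 census
records, 100 randomized transcripts, exhaustive combiner enumeration of
~4200 multisets — were chosen so the whole suite runs in seconds on one
CPU while leaving every statistical check well-powered (3-SE recovery
bands, exact integer plantings). All randomness flows from a single
integer seed through `numpy.random.default_rng`; generators are
byte-deterministic, the engine itself contains no randomness, and
evidence evaluation is order-insensitive.

## Known limitations

* One transcript per gene; no multi-transcript or tissue-specific
  promoter switching.
* Enhancer–gene links are inputs, never inferred; no TAD derivation.
* Third-party predictor scores (splice, genome-wide deleteriousness,
  uORF annotators) are consumed as precomputed inputs only.
* PVS1 strength sub-levels from the LoF decision tree are consumed as
  the proposed strength, not re-derived.
* Phasing is transmission-based only (no read-backed phasing); sex
  chromosomes and non-diploid genotypes are excluded.
* The point scale and combining table are the general standards; no
  gene-specific (VCEP) customisations.
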
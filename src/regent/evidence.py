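"""ACMG/AMP evidence-code gating for non-coding region variants.

Each proposed evidence code is validated against the non-coding
applicability rules: codes that cannot apply outside protein-coding
sequence are rejected, several codes have their maximum strength capped
(gates only ever cap or reject, never raise), and mutually exclusive codes
resting on the same evidence source are resolved at the end.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field

from .core import ThresholdConfig
from .mechanisms import SpliceClass, SpliceContext

logger = logging.getLogger("regent")


class Strength(enum.IntEnum):
    """Evidence strength ladder, ordered weakest to strongest."""

    Supporting = 1
    Moderate = 2
    Strong = 3
    VeryStrong = 4
    StandAlone = 5

    def one_step_down(self) -> "Strength":
        return Strength(max(self.value - 1, Strength.Supporting.value))


PATHOGENIC_CODES = frozenset(
    {"PVS1", "PS1", "PS2", "PS3", "PS4", "PM1", "PM2", "PM3", "PM4", "PM5",
     "PM6", "PP1", "PP2", "PP3", "PP4", "PP5"})
BENIGN_CODES = frozenset(
    {"BA1", "BS1", "BS2", "BS3", "BS4", "BP1", "BP2", "BP3", "BP4", "BP5",
     "BP6", "BP7"})
ALL_CODES = PATHOGENIC_CODES | BENIGN_CODES

#: codes applied exactly as for coding variants (no extra non-coding rule);
#: PM2 is nevertheless reduced to Supporting per ClinGen SVI guidance.
PASS_THROUGH = frozenset({"BA1", "BS1", "BS2", "BS4", "PM2", "PM6", "PS2",
                          "PP1", "PS4", "PM4", "BP2", "BP3", "BP5", "BP6",
                          "BP7", "PP5"})
#: missense-specific codes, never applicable to non-coding variants.
INAPPLICABLE = frozenset({"PP2", "BP1"})


# ---------------------------------------------------------------------------
# Support payloads

@dataclass
class AssayDescriptor:
    """Structured description of a functional assay (PS3/BS3 support)."""

    assay_class: str  # rna_seq / reporter / mave / chromatin_interaction / other
    tissue_expression_match: bool = False
    coverage_adequate: bool = False
    mechanisms_assessed: tuple = ()
    biallelic_expression_shown: bool = False
    direction_of_effect: str = "none"  # increase / decrease / none
    controls_validated: bool = False


@dataclass
class ToolCall:
    name: str
    score: float
    threshold_call: str  # deleterious / benign / uninformative
    mechanism: str = ""  # splicing / tf_binding / deleteriousness ...

    def __post_init__(self) -> None:
        if not self.mechanism:
            lowered = self.name.lower()
            if any(k in lowered for k in ("splice", "maxent", "trap")):
                self.mechanism = "splicing"
            else:
                self.mechanism = "deleteriousness"


@dataclass
class PredictionSet:
    tools: list[ToolCall]
    genome_wide_flag: bool = False
    target_gene_context: str = ""


@dataclass
class PriorVariantMatch:
    relation: str  # same_nucleotide / same_position_diff_alt / same_predicted_impact
    prior_classification: str = "Pathogenic"
    predicted_impact_ge_prior: bool = True
    same_gene: bool = True
    mechanism: str = ""


@dataclass
class TransPartner:
    phase: str  # in_trans / in_cis / unknown
    partner_classification: str = "Pathogenic"
    partner_confirmed: bool = True
    variant_af: float = 0.0
    partner_af: float = 0.0


@dataclass
class ContextFlags:
    """Variant/gene context consulted by the gates."""

    gene_id: str = ""
    lof_established_mechanism: bool = False
    splice_context: SpliceContext = field(
        default_factory=lambda: SpliceContext(SpliceClass.none))
    in_utr: bool = False
    utr_impact_unclear: bool = False
    motif_only_insilico: bool = False
    recurrent_pathogenic_motif: bool = False
    enhancer_cluster: bool = False
    large_intronic_gene: bool = False
    ancestry_mismatch: bool = False
    n_genes_for_phenotype: int = 1
    phenotype_discriminative: bool = False
    gene_dosage_direction: str = "unknown"  # haploinsufficient / triplosensitive / both / unknown
    candidate_mechanisms: tuple = ()

    def __post_init__(self) -> None:
        if self.n_genes_for_phenotype < 0:
            raise ValueError("n_genes_for_phenotype must be >= 0")


@dataclass
class EvidenceObservation:
    code: str
    proposed_strength: Strength
    support: object | None = None

    def __post_init__(self) -> None:
        if self.code not in ALL_CODES:
            raise ValueError(f"unknown ACMG/AMP code {self.code!r}")


@dataclass
class EvidenceDecision:
    code: str
    outcome: str  # accepted / downgraded / rejected
    final_strength: Strength | None = None
    reasons: list[str] = field(default_factory=list)
    proposed_strength: Strength | None = None
    mechanisms: tuple = ()

    @property
    def accepted(self) -> bool:
        return self.outcome in ("accepted", "downgraded")


def _finalize(obs: EvidenceObservation, cap: Strength, reasons: list[str],
              mechanisms: tuple = ()) -> EvidenceDecision:
    """Accept at ``min(proposed, cap)``, recording a downgrade if capped."""
    final = min(obs.proposed_strength, cap)
    outcome = "accepted" if final == obs.proposed_strength else "downgraded"
    if outcome == "downgraded":
        reasons = reasons + [f"{obs.code}_capped_at_{Strength(cap).name}"]
    return EvidenceDecision(obs.code, outcome, Strength(final), reasons,
                            obs.proposed_strength, mechanisms)


def _reject(obs: EvidenceObservation, reasons: list[str]) -> EvidenceDecision:
    return EvidenceDecision(obs.code, "rejected", None, reasons,
                            obs.proposed_strength)


# ---------------------------------------------------------------------------
# Individual gates

def gate_pvs1(obs: EvidenceObservation, ctx: ContextFlags) -> EvidenceDecision:
    """PVS1 only for canonical splice sites in established-LoF genes.

    Null effect cannot be confidently predicted for other non-coding
    contexts without experimental data, and canonical sites inside UTRs are
    excluded when the downstream impact is not clearly loss-of-function.
    """
    assert obs.code == "PVS1"
    canonical = ctx.splice_context.klass in (SpliceClass.canonical_donor,
                                             SpliceClass.canonical_acceptor)
    if not canonical or not ctx.lof_established_mechanism:
        return _reject(obs, ["no_null_prediction_without_data"])
    if ctx.in_utr and ctx.utr_impact_unclear:
        return _reject(obs, ["utr_canonical_site_impact_unclear"])
    return _finalize(obs, Strength.VeryStrong, [], mechanisms=("splicing",))


def gate_pm1(obs: EvidenceObservation, ctx: ContextFlags) -> EvidenceDecision:
    """PM1 capped at Supporting; in-silico-only motif evidence routes to PP3.

    Non-coding constraint is base-specific, so regional hotspot reasoning
    ("many pathogenic variants in this UTR") never qualifies; a recurrently
    pathogenic TF motif or a well-defined enhancer sub-region cluster does.
    """
    assert obs.code == "PM1"
    if ctx.motif_only_insilico:
        return _reject(obs, ["use_pp3"])
    if not (ctx.recurrent_pathogenic_motif or ctx.enhancer_cluster):
        return _reject(obs, ["base_specific_constraint_no_hotspot"])
    return _finalize(obs, Strength.Supporting, ["pm1_cap_supporting"],
                     mechanisms=("tf_binding",))


def gate_ps1_pm5(obs: EvidenceObservation, ctx: ContextFlags) -> EvidenceDecision:
    """PS1/PM5 by analogy to an established pathogenic variant.

    PS1 applies at the same base (full proposed strength) or, at Supporting,
    for a different substitution at the same position predicted at least as
    deleterious.  PM5 covers variants elsewhere with exactly the same
    predicted impact on the same gene, capped at Moderate.
    """
    assert obs.code in ("PS1", "PM5")
    m = obs.support
    if not isinstance(m, PriorVariantMatch):
        raise TypeError(f"{obs.code} requires a PriorVariantMatch payload")
    mech = (m.mechanism,) if m.mechanism else ()
    if not m.predicted_impact_ge_prior:
        return _reject(obs, ["predicted_impact_below_prior"])
    if obs.code == "PS1":
        if m.relation == "same_nucleotide":
            return _finalize(obs, Strength.Strong, [], mech)
        if m.relation == "same_position_diff_alt":
            return _finalize(obs, Strength.Supporting,
                             ["ps1_splice_alike_cap_supporting"], mech)
        return _reject(obs, ["relation_not_ps1_eligible"])
    # PM5
    if m.relation == "same_predicted_impact" and m.same_gene:
        return _finalize(obs, Strength.Moderate, [], mech)
    return _reject(obs, ["relation_not_pm5_eligible"])


def gate_pm3(obs: EvidenceObservation, ctx: ContextFlags,
             cfg: ThresholdConfig = ThresholdConfig()) -> EvidenceDecision:
    """PM3 for a confirmed in-trans partner, with strict rarity cut-offs.

    The strength drops one step for genes with very large intronic search
    space or when reference allele-frequency data mismatch the individual's
    genetic ancestry.
    """
    assert obs.code == "PM3"
    p = obs.support
    if not isinstance(p, TransPartner):
        raise TypeError("PM3 requires a TransPartner payload")
    if p.phase != "in_trans":
        return _reject(obs, ["phase_not_confirmed_in_trans"])
    if not p.partner_confirmed:
        return _reject(obs, ["partner_classification_unconfirmed"])
    if p.variant_af >= cfg.af_max or p.partner_af >= cfg.af_max:
        return _reject(obs, ["allele_frequency_above_cutoff"])
    cap = obs.proposed_strength
    reasons: list[str] = []
    if ctx.large_intronic_gene:
        cap = min(cap, obs.proposed_strength.one_step_down())
        reasons.append("large_intronic_region_downgrade")
    if ctx.ancestry_mismatch:
        cap = min(cap, obs.proposed_strength.one_step_down())
        reasons.append("ancestry_mismatch_downgrade")
    return _finalize(obs, Strength(cap), reasons)


def pm3_gene_adjustment(candidate_score: float, gene_scores) -> float:
    """Empirical exceedance of a candidate's in-silico score within its gene.

    P(score >= candidate) under the distribution of per-base scores across
    the gene; adjusts PM3 for region size and localised mutability.  A high
    exceedance probability means similar-scoring variants are commonplace in
    the gene and PM3 deserves a downgrade.
    """
    import numpy as np

    scores = np.asarray(list(gene_scores), dtype=float)
    if scores.size == 0:
        raise ValueError("gene score distribution is empty")
    return float(np.count_nonzero(scores >= candidate_score) / scores.size)


def grade_ps3_bs3(obs: EvidenceObservation, ctx: ContextFlags) -> EvidenceDecision:
    """Grade functional-assay evidence by assay class and validation state.

    PS3 reaches Strong only for patient RNA assays matched to the disease
    tissue with adequate sequencing depth; reporter/MAVE systems are
    artificial and cap at Moderate when validated, as does disrupted
    chromatin interaction versus controls.  BS3 requires demonstration of
    biallelic expression, adequate coverage and an assay read-out covering
    every candidate mechanism of the context, or a direction of effect
    inconsistent with the gene's known dosage mechanism.
    """
    assert obs.code in ("PS3", "BS3")
    a = obs.support
    if not isinstance(a, AssayDescriptor):
        raise TypeError(f"{obs.code} requires an AssayDescriptor payload")
    mech = tuple(a.mechanisms_assessed)

    if obs.code == "PS3":
        if a.assay_class == "rna_seq":
            if a.tissue_expression_match and a.coverage_adequate:
                return _finalize(obs, Strength.Strong, [], mech)
            return _finalize(obs, Strength.Moderate,
                             ["rna_seq_strong_conditions_unmet"], mech)
        if a.assay_class in ("reporter", "mave"):
            if not a.controls_validated:
                return _reject(obs, ["artificial_assay_not_validated"])
            return _finalize(obs, Strength.Moderate,
                             ["artificial_assay_cap_moderate"], mech)
        if a.assay_class == "chromatin_interaction":
            if not a.controls_validated:
                return _reject(obs, ["no_control_comparison"])
            return _finalize(obs, Strength.Moderate,
                             ["chromatin_interaction_cap_moderate"], mech)
        return _reject(obs, ["assay_class_not_admissible"])

    # BS3
    contradiction = (
        (a.direction_of_effect == "increase"
         and ctx.gene_dosage_direction == "haploinsufficient")
        or (a.direction_of_effect == "decrease"
            and ctx.gene_dosage_direction == "triplosensitive"))
    if contradiction:
        return _finalize(obs, Strength.Strong,
                         ["direction_contradicts_gene_mechanism"], mech)
    if not a.biallelic_expression_shown:
        return _reject(obs, ["biallelic_expression_not_shown"])
    if not a.coverage_adequate:
        return _reject(obs, ["coverage_inadequate"])
    missing = set(ctx.candidate_mechanisms) - set(a.mechanisms_assessed)
    if missing:
        return _reject(obs, ["mechanisms_not_assessed:" + ",".join(sorted(missing))])
    return _finalize(obs, Strength.Strong, [], mech)


def gate_pp3_bp4(obs: EvidenceObservation, ctx: ContextFlags) -> EvidenceDecision:
    """In-silico predictions at Supporting, in the correct gene context only.

    Scores computed against a different target gene are ignored; conflicting
    calls activate neither PP3 nor BP4; the canonical donor +5 position is
    noted as carrying an elevated prior; genome-wide machine-learning
    predictors add a caution note.
    """
    assert obs.code in ("PP3", "BP4")
    preds = obs.support
    if not isinstance(preds, PredictionSet):
        raise TypeError(f"{obs.code} requires a PredictionSet payload")
    reasons: list[str] = []
    in_context = [t for t in preds.tools
                  if not ctx.gene_id or not preds.target_gene_context
                  or preds.target_gene_context == ctx.gene_id]
    if len(in_context) < len(preds.tools):
        reasons.append("out_of_context_scores_ignored")
    informative = [t for t in in_context if t.threshold_call != "uninformative"]
    if not informative:
        return _reject(obs, reasons + ["no_informative_in_context_scores"])
    calls = {t.threshold_call for t in informative}
    if calls == {"deleterious", "benign"} or len(calls) > 1:
        return _reject(obs, reasons + ["conflicting_tool_calls"])
    if preds.genome_wide_flag:
        reasons.append("genome_wide_predictor_caution")
    if ctx.splice_context.klass is SpliceClass.donor_plus5:
        reasons.append("donor_plus5_elevated_prior")
    mech = tuple(sorted({t.mechanism for t in informative}))
    want = "deleterious" if obs.code == "PP3" else "benign"
    if calls != {want}:
        return _reject(obs, reasons + [f"calls_do_not_support_{obs.code.lower()}"])
    return _finalize(obs, Strength.Supporting,
                     reasons + [f"{obs.code.lower()}_cap_supporting"], mech)


def gate_pp4(obs: EvidenceObservation, ctx: ContextFlags,
             cfg: ThresholdConfig = ThresholdConfig()) -> EvidenceDecision:
    """PP4 only for a discriminative phenotype tied to very few genes."""
    assert obs.code == "PP4"
    if not ctx.phenotype_discriminative:
        return _reject(obs, ["phenotype_not_discriminative"])
    if ctx.n_genes_for_phenotype > cfg.pp4_max_genes:
        return _reject(obs, ["too_many_candidate_genes"])
    return _finalize(obs, Strength.Supporting, [])


# ---------------------------------------------------------------------------
# Dispatch and exclusivity resolution

_CODE_SORT = sorted(ALL_CODES)


def evaluate_all(observations: list[EvidenceObservation], ctx: ContextFlags,
                 cfg: ThresholdConfig = ThresholdConfig()
                 ) -> list[EvidenceDecision]:
    """Gate every proposed code; deterministic output order by code id.

    Duplicate proposals for one code keep the strongest (with a warning);
    missense-specific codes are always rejected; pass-through codes are
    accepted at their proposed strength except PM2, which defaults to
    Supporting.
    """
    best: dict[str, EvidenceObservation] = {}
    for obs in observations:
        prev = best.get(obs.code)
        if prev is not None:
            logger.warning("duplicate proposal for %s; keeping strongest", obs.code)
            if obs.proposed_strength <= prev.proposed_strength:
                continue
        best[obs.code] = obs

    out: list[EvidenceDecision] = []
    for code in sorted(best, key=_CODE_SORT.index):
        obs = best[code]
        if code in INAPPLICABLE:
            out.append(_reject(obs, ["missense_specific_code"]))
        elif code == "PVS1":
            out.append(gate_pvs1(obs, ctx))
        elif code == "PM1":
            out.append(gate_pm1(obs, ctx))
        elif code in ("PS1", "PM5"):
            out.append(gate_ps1_pm5(obs, ctx))
        elif code == "PM3":
            out.append(gate_pm3(obs, ctx, cfg))
        elif code in ("PS3", "BS3"):
            out.append(grade_ps3_bs3(obs, ctx))
        elif code in ("PP3", "BP4"):
            out.append(gate_pp3_bp4(obs, ctx))
        elif code == "PP4":
            out.append(gate_pp4(obs, ctx, cfg))
        elif code == "PM2":
            out.append(_finalize(obs, Strength.Supporting,
                                 ["pm2_reduced_to_supporting"]))
        else:  # pass-through
            out.append(_finalize(obs, obs.proposed_strength, []))
    return out


def resolve_exclusivities(decisions: list[EvidenceDecision]
                          ) -> list[EvidenceDecision]:
    """Drop codes that would double-count one evidence source.

    PVS1 excludes PP3 outright; PS3 excludes PP3 when the assay assessed the
    predicted mechanism; PM1 excludes PP3 resting on the same motif
    evidence; PM5 is kept over PP3 resting on the same prediction.
    Exclusions sharing no mechanism leave both codes standing.
    """
    by_code = {d.code: d for d in decisions}
    pp3 = by_code.get("PP3")
    if pp3 is None or not pp3.accepted:
        return decisions

    def drop(reason: str) -> None:
        pp3.outcome = "rejected"
        pp3.final_strength = None
        pp3.reasons = pp3.reasons + [reason]

    pvs1 = by_code.get("PVS1")
    if pvs1 is not None and pvs1.accepted:
        drop("excluded_by_pvs1")
        return decisions
    for code, reason in (("PS3", "excluded_by_ps3_same_mechanism"),
                         ("PM1", "excluded_by_pm1_same_motif"),
                         ("PM5", "excluded_by_pm5_same_prediction")):
        other = by_code.get(code)
        if (other is not None and other.accepted
                and set(other.mechanisms) & set(pp3.mechanisms)):
            drop(reason)
            break
    return decisions
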
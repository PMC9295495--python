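"""Evidence-code gating: per-code rules, dispatch, and exclusivities."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from regent.evidence import (AssayDescriptor, ContextFlags,
                             EvidenceObservation, PredictionSet,
                             PriorVariantMatch, Strength, ToolCall,
                             TransPartner, evaluate_all, gate_pm1, gate_pm3,
                             gate_pp3_bp4, gate_pp4, gate_ps1_pm5, gate_pvs1,
                             grade_ps3_bs3, pm3_gene_adjustment,
                             resolve_exclusivities)
from regent.mechanisms import SpliceClass, SpliceContext


def obs(code, strength=Strength.Supporting, support=None):
    return EvidenceObservation(code, strength, support)


def ctx(**kw):
    splice = kw.pop("splice", None)
    c = ContextFlags(**kw)
    if splice:
        c.splice_context = SpliceContext(SpliceClass(splice))
    return c


class TestPVS1:
    def test_canonical_donor_lof_gene_accepted(self):
        d = gate_pvs1(obs("PVS1", Strength.VeryStrong),
                      ctx(splice="canonical_donor",
                          lof_established_mechanism=True))
        assert d.outcome == "accepted" and d.final_strength == Strength.VeryStrong

    def test_utr_canonical_site_with_unclear_impact_rejected(self):
        d = gate_pvs1(obs("PVS1", Strength.VeryStrong),
                      ctx(splice="canonical_acceptor",
                          lof_established_mechanism=True, in_utr=True,
                          utr_impact_unclear=True))
        assert d.outcome == "rejected"

    def test_deep_intronic_rejected(self):
        d = gate_pvs1(obs("PVS1", Strength.VeryStrong),
                      ctx(splice="deep_intronic",
                          lof_established_mechanism=True))
        assert d.outcome == "rejected"
        assert "no_null_prediction_without_data" in d.reasons


class TestPM1:
    def test_recurrent_motif_downgraded_to_supporting(self):
        d = gate_pm1(obs("PM1", Strength.Moderate),
                     ctx(recurrent_pathogenic_motif=True))
        assert d.outcome == "downgraded"
        assert d.final_strength == Strength.Supporting

    def test_regional_hotspot_reasoning_rejected(self):
        d = gate_pm1(obs("PM1", Strength.Moderate), ctx())
        assert d.outcome == "rejected"

    def test_insilico_only_routes_to_pp3(self):
        d = gate_pm1(obs("PM1", Strength.Moderate),
                     ctx(motif_only_insilico=True))
        assert d.outcome == "rejected" and "use_pp3" in d.reasons


class TestPS1PM5:
    def test_splice_alike_supporting(self):
        d = gate_ps1_pm5(obs("PS1", Strength.Strong, PriorVariantMatch(
            relation="same_position_diff_alt")), ctx())
        assert d.accepted and d.final_strength == Strength.Supporting

    def test_same_nucleotide_full_strength(self):
        # e.g. a uORF stop codon previously shown pathogenic
        d = gate_ps1_pm5(obs("PS1", Strength.Strong, PriorVariantMatch(
            relation="same_nucleotide")), ctx())
        assert d.accepted and d.final_strength == Strength.Strong

    def test_pm5_same_predicted_impact_moderate(self):
        d = gate_ps1_pm5(obs("PM5", Strength.Moderate, PriorVariantMatch(
            relation="same_predicted_impact", same_gene=True)), ctx())
        assert d.accepted and d.final_strength == Strength.Moderate

    def test_lesser_impact_rejected(self):
        d = gate_ps1_pm5(obs("PS1", Strength.Strong, PriorVariantMatch(
            relation="same_position_diff_alt",
            predicted_impact_ge_prior=False)), ctx())
        assert d.outcome == "rejected"

    def test_wrong_payload_type_raises(self):
        with pytest.raises(TypeError):
            gate_ps1_pm5(obs("PS1", Strength.Strong, TransPartner("in_trans")),
                         ctx())


class TestPM3:
    def test_confirmed_in_trans_accepted(self):
        d = gate_pm3(obs("PM3", Strength.Moderate,
                         TransPartner(phase="in_trans")), ctx())
        assert d.accepted and d.final_strength == Strength.Moderate

    def test_large_intronic_gene_downgraded(self):
        d = gate_pm3(obs("PM3", Strength.Moderate,
                         TransPartner(phase="in_trans")),
                     ctx(large_intronic_gene=True))
        assert d.final_strength == Strength.Supporting
        assert "large_intronic_region_downgrade" in d.reasons

    def test_unknown_phase_rejected(self):
        d = gate_pm3(obs("PM3", Strength.Moderate,
                         TransPartner(phase="unknown")), ctx())
        assert d.outcome == "rejected"

    def test_af_above_cutoff_rejected(self):
        d = gate_pm3(obs("PM3", Strength.Moderate,
                         TransPartner(phase="in_trans", variant_af=0.01)),
                     ctx())
        assert d.outcome == "rejected"


class TestPm3GeneAdjustment:
    def test_candidate_at_maximum(self):
        scores = np.arange(1000) / 1000.0
        assert pm3_gene_adjustment(scores.max(), scores) == pytest.approx(1 / 1000)

    def test_all_identical(self):
        assert pm3_gene_adjustment(0.5, [0.5] * 10) == 1.0

    def test_candidate_below_minimum(self):
        assert pm3_gene_adjustment(-1.0, [0.1, 0.2]) == 1.0

    def test_empty_distribution_raises(self):
        with pytest.raises(ValueError):
            pm3_gene_adjustment(0.5, [])


class TestPS3BS3:
    def test_tissue_matched_rna_seq_strong(self):
        d = grade_ps3_bs3(obs("PS3", Strength.Strong, AssayDescriptor(
            "rna_seq", tissue_expression_match=True, coverage_adequate=True,
            mechanisms_assessed=("splicing",))), ctx())
        assert d.accepted and d.final_strength == Strength.Strong

    def test_validated_reporter_caps_moderate(self):
        d = grade_ps3_bs3(obs("PS3", Strength.Strong, AssayDescriptor(
            "reporter", controls_validated=True)), ctx())
        assert d.final_strength == Strength.Moderate

    def test_unvalidated_reporter_rejected(self):
        d = grade_ps3_bs3(obs("PS3", Strength.Strong,
                              AssayDescriptor("reporter")), ctx())
        assert d.outcome == "rejected"

    def test_bs3_rejected_when_mechanism_not_assessed(self):
        # normal RNA result, but the 5'UTR variant could act on translation
        d = grade_ps3_bs3(obs("BS3", Strength.Strong, AssayDescriptor(
            "rna_seq", biallelic_expression_shown=True,
            coverage_adequate=True, mechanisms_assessed=("splicing",))),
            ctx(candidate_mechanisms=("splicing", "translation")))
        assert d.outcome == "rejected"
        assert any(r.startswith("mechanisms_not_assessed") for r in d.reasons)

    def test_bs3_direction_contradiction(self):
        d = grade_ps3_bs3(obs("BS3", Strength.Strong, AssayDescriptor(
            "reporter", direction_of_effect="increase")),
            ctx(gene_dosage_direction="haploinsufficient"))
        assert d.accepted

    def test_bs3_requires_biallelic_expression(self):
        d = grade_ps3_bs3(obs("BS3", Strength.Strong, AssayDescriptor(
            "rna_seq", coverage_adequate=True,
            mechanisms_assessed=("splicing",))),
            ctx(candidate_mechanisms=("splicing",)))
        assert d.outcome == "rejected"


class TestPP3BP4:
    def test_concordant_deleterious_supporting(self):
        preds = PredictionSet([ToolCall("SpliceAI", 0.8, "deleterious"),
                               ToolCall("CADD", 25, "deleterious")],
                              target_gene_context="G")
        d = gate_pp3_bp4(obs("PP3", Strength.Supporting, preds),
                         ctx(gene_id="G"))
        assert d.accepted and d.final_strength == Strength.Supporting

    def test_conflicting_calls_neither(self):
        preds = PredictionSet([ToolCall("MaxEntScan", 8, "deleterious"),
                               ToolCall("SpliceAI", 0.01, "benign")],
                              target_gene_context="G")
        for code in ("PP3", "BP4"):
            d = gate_pp3_bp4(obs(code, Strength.Supporting, preds),
                             ctx(gene_id="G"))
            assert d.outcome == "rejected"
            assert "conflicting_tool_calls" in d.reasons

    def test_wrong_gene_context_ignored(self):
        # a splice score computed for another gene's transcript is discarded
        preds = PredictionSet([ToolCall("SpliceAI", 0.0, "benign")],
                              target_gene_context="ELP4")
        d = gate_pp3_bp4(obs("BP4", Strength.Supporting, preds),
                         ctx(gene_id="PAX6"))
        assert d.outcome == "rejected"
        assert "no_informative_in_context_scores" in d.reasons

    def test_donor_plus5_prior_noted(self):
        preds = PredictionSet([ToolCall("SpliceAI", 0.9, "deleterious")],
                              target_gene_context="G")
        d = gate_pp3_bp4(obs("PP3", Strength.Supporting, preds),
                         ctx(gene_id="G", splice="donor_plus5"))
        assert d.accepted and "donor_plus5_elevated_prior" in d.reasons
        assert d.final_strength == Strength.Supporting


class TestPP4:
    def test_single_gene_discriminative_phenotype(self):
        d = gate_pp4(obs("PP4"), ctx(phenotype_discriminative=True,
                                     n_genes_for_phenotype=1))
        assert d.accepted

    def test_nonspecific_phenotype_rejected(self):
        assert gate_pp4(obs("PP4"), ctx()).outcome == "rejected"

    def test_too_many_genes_rejected(self):
        d = gate_pp4(obs("PP4"), ctx(phenotype_discriminative=True,
                                     n_genes_for_phenotype=10))
        assert d.outcome == "rejected"


class TestEvaluateAll:
    def test_pp2_always_rejected(self):
        (d,) = evaluate_all([obs("PP2", Strength.Supporting)], ctx())
        assert d.outcome == "rejected"

    def test_pm2_reduced_to_supporting(self):
        (d,) = evaluate_all([obs("PM2", Strength.Moderate)], ctx())
        assert d.final_strength == Strength.Supporting

    def test_ps2_pass_through(self):
        (d,) = evaluate_all([obs("PS2", Strength.Strong)], ctx())
        assert d.outcome == "accepted" and d.final_strength == Strength.Strong

    def test_duplicates_keep_strongest(self):
        out = evaluate_all([obs("PS2", Strength.Moderate),
                            obs("PS2", Strength.Strong)], ctx())
        assert len(out) == 1 and out[0].final_strength == Strength.Strong

    def test_order_insensitive_and_deterministic(self):
        observations = [obs("PS2", Strength.Strong),
                        obs("PM2", Strength.Supporting),
                        obs("PP4", Strength.Supporting)]
        c = ctx(phenotype_discriminative=True)
        a = evaluate_all(observations, c)
        b = evaluate_all(list(reversed(observations)), c)
        assert [(d.code, d.outcome, d.final_strength) for d in a] == \
            [(d.code, d.outcome, d.final_strength) for d in b]

    @given(st.sampled_from(["PM1"]),
           st.sampled_from(list(Strength)),
           st.booleans(), st.booleans(), st.booleans())
    @settings(derandomize=True, max_examples=60)
    def test_pm1_never_exceeds_supporting(self, code, strength, insilico,
                                          recurrent, cluster):
        c = ctx(motif_only_insilico=insilico,
                recurrent_pathogenic_motif=recurrent,
                enhancer_cluster=cluster)
        (d,) = evaluate_all([obs(code, strength)], c)
        assert d.final_strength is None or \
            d.final_strength <= Strength.Supporting

    @given(st.lists(st.sampled_from(
        ["PS2", "PM2", "PM6", "PP1", "BA1", "BS1", "BS2", "BS4"]),
        min_size=0, max_size=6),
        st.lists(st.sampled_from(list(Strength)), min_size=6, max_size=6))
    @settings(derandomize=True, max_examples=60)
    def test_no_gate_raises_proposed_strength(self, codes, strengths):
        observations = [obs(c, s) for c, s in zip(codes, strengths)]
        for d in evaluate_all(observations, ctx()):
            if d.final_strength is not None:
                assert d.final_strength <= d.proposed_strength


class TestExclusivities:
    def _accepted(self, code, strength, mechanisms=()):
        from regent.evidence import EvidenceDecision
        return EvidenceDecision(code, "accepted", strength,
                                proposed_strength=strength,
                                mechanisms=mechanisms)

    def test_pvs1_drops_pp3(self):
        out = resolve_exclusivities([
            self._accepted("PVS1", Strength.VeryStrong, ("splicing",)),
            self._accepted("PP3", Strength.Supporting, ("splicing",))])
        by = {d.code: d for d in out}
        assert by["PP3"].outcome == "rejected"
        assert by["PVS1"].accepted

    def test_ps3_same_mechanism_drops_pp3(self):
        out = resolve_exclusivities([
            self._accepted("PS3", Strength.Strong, ("splicing",)),
            self._accepted("PP3", Strength.Supporting, ("splicing",))])
        assert {d.code: d.outcome for d in out}["PP3"] == "rejected"

    def test_different_mechanism_keeps_both(self):
        out = resolve_exclusivities([
            self._accepted("PS3", Strength.Strong, ("transcription",)),
            self._accepted("PP3", Strength.Supporting, ("splicing",))])
        assert all(d.accepted for d in out)

    def test_pm5_same_prediction_drops_pp3(self):
        out = resolve_exclusivities([
            self._accepted("PM5", Strength.Moderate, ("translation",)),
            self._accepted("PP3", Strength.Supporting, ("translation",))])
        assert {d.code: d.outcome for d in out}["PP3"] == "rejected"
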
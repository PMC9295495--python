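"""Combination of gated evidence into a five-tier classification.

Two interchangeable combiners are provided: the categorical combining
table of the 2015 ACMG/AMP framework, and the additive point scale used in
UK ACGS best practice (Supporting=1, Moderate=2, Strong=4, VeryStrong=8;
Pathogenic >= 10, Likely Pathogenic 6-9, VUS 0-5, Likely Benign -6..-1,
Benign <= -7).  Codes are counted by their final (gated) strength, so a
code raised or lowered by the gates counts at its adjusted level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .core import ThresholdConfig
from .evidence import (BENIGN_CODES, ContextFlags, EvidenceDecision,
                       EvidenceObservation, Strength, evaluate_all,
                       resolve_exclusivities)

TIERS = ("Pathogenic", "LikelyPathogenic", "VUS", "LikelyBenign", "Benign")

POINT_VALUES = {Strength.Supporting: 1, Strength.Moderate: 2,
                Strength.Strong: 4, Strength.VeryStrong: 8,
                Strength.StandAlone: 8}


@dataclass(frozen=True)
class ClassifierPolicy:
    mode: str = "categorical"  # categorical / points
    path_min: int = 10
    lp_min: int = 6
    lb_max: int = -1
    benign_max: int = -7
    conflict_rule: str = "conflict_to_vus"


@dataclass
class Classification:
    tier: str
    applied: list[EvidenceDecision]
    points: int | None = None
    narrative: list[str] = field(default_factory=list)


def _strength_counts(decisions: list[EvidenceDecision]):
    """(pathogenic counts by strength, benign strong count, benign
    supporting-level count, BA1 flag) over accepted decisions."""
    pvs = ps = pm = pp = bs = bp = 0
    ba1 = False
    for d in decisions:
        if not d.accepted:
            continue
        s = d.final_strength
        if d.code in BENIGN_CODES:
            if d.code == "BA1" or s == Strength.StandAlone:
                ba1 = True
            elif s >= Strength.Strong:
                bs += 1
            else:
                bp += 1
        else:
            if s == Strength.StandAlone or s == Strength.VeryStrong:
                pvs += 1
            elif s == Strength.Strong:
                ps += 1
            elif s == Strength.Moderate:
                pm += 1
            else:
                pp += 1
    return pvs, ps, pm, pp, bs, bp, ba1


def combine_categorical(decisions: list[EvidenceDecision],
                        policy: ClassifierPolicy = ClassifierPolicy()) -> str:
    """Richards-style combining table over the final decision set.

    Stand-alone benign evidence (BA1) outranks everything; evidence meeting
    both a pathogenic and a benign combination is conflicting and yields
    VUS.
    """
    pvs, ps, pm, pp, bs, bp, ba1 = _strength_counts(decisions)
    if ba1:
        return "Benign"

    pathogenic = (
        (pvs >= 1 and (ps >= 1 or pm >= 2 or (pm == 1 and pp >= 1) or pp >= 2))
        or pvs >= 2
        or ps >= 2
        or (ps == 1 and (pm >= 3 or (pm == 2 and pp >= 2)
                         or (pm == 1 and pp >= 4))))
    likely_pathogenic = (
        (pvs == 1 and pm >= 1)
        or (ps == 1 and pm >= 1)
        or (ps == 1 and pp >= 2)
        or pm >= 3
        or (pm == 2 and pp >= 2)
        or (pm == 1 and pp >= 4))
    benign = bs >= 2
    likely_benign = (bs == 1 and bp >= 1) or bp >= 2

    path_dir = pathogenic or likely_pathogenic
    benign_dir = benign or likely_benign
    if path_dir and benign_dir:
        return "VUS"
    if pathogenic:
        return "Pathogenic"
    if likely_pathogenic:
        return "LikelyPathogenic"
    if benign:
        return "Benign"
    if likely_benign:
        return "LikelyBenign"
    return "VUS"


def combine_points(decisions: list[EvidenceDecision],
                   policy: ClassifierPolicy = ClassifierPolicy()
                   ) -> tuple[int, str]:
    """Signed point total and the tier it falls in."""
    total = 0
    for d in decisions:
        if not d.accepted:
            continue
        if d.code == "BA1":
            return -POINT_VALUES[Strength.StandAlone], "Benign"
        pts = POINT_VALUES[d.final_strength]
        total += -pts if d.code in BENIGN_CODES else pts
    if total >= policy.path_min:
        tier = "Pathogenic"
    elif total >= policy.lp_min:
        tier = "LikelyPathogenic"
    elif total > policy.lb_max:
        tier = "VUS"
    elif total > policy.benign_max:
        tier = "LikelyBenign"
    else:
        tier = "Benign"
    return total, tier


def classify(observations: list[EvidenceObservation], ctx: ContextFlags,
             policy: ClassifierPolicy = ClassifierPolicy(),
             cfg: ThresholdConfig = ThresholdConfig()) -> Classification:
    """Full pipeline: gate, resolve exclusivities, combine.

    The narrative records every gate action (acceptance, cap, rejection)
    with its rule-id reasons, so the combination is auditable.
    """
    decisions = resolve_exclusivities(evaluate_all(observations, ctx, cfg))
    narrative = []
    for d in decisions:
        label = d.final_strength.name if d.final_strength is not None else "-"
        why = ";".join(d.reasons) if d.reasons else "ok"
        narrative.append(f"{d.code}: {d.outcome} ({label}) [{why}]")

    points, pts_tier = combine_points(decisions, policy)
    cat_tier = combine_categorical(decisions, policy)
    tier = pts_tier if policy.mode == "points" else cat_tier
    narrative.append(f"tier={tier} points={points}")
    return Classification(tier=tier, applied=decisions, points=points,
                          narrative=narrative)
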
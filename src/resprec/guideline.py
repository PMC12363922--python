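"""Deterministic clinical-guideline rule engine for NIV and HFNC.

Encodes the ERS/ATS 2017 indications for noninvasive ventilation and the
ERS 2022 indications for high-flow nasal cannula over structured clinical
facts, produces a per-therapy verdict with matched criteria and a
confidence grade, and resolves the pair into a final label
(NIV / HFNC / Indifferent).  Missing measurements are handled with
tri-state logic: a criterion whose operands are absent is *unknown* and
never fires.

An adapter interface lets an external large language model stand in for the
rule evaluator; the default adapter is the deterministic engine itself, so
the pipeline runs fully offline.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from typing import Optional, Protocol

from pydantic import BaseModel, ValidationError

__all__ = [
    "ClinicalFacts",
    "FACT_NAMES",
    "TherapyEvaluation",
    "RecommendationRecord",
    "acute_respiratory_acidosis",
    "evaluate_niv",
    "evaluate_hfnc",
    "resolve_joint",
    "model_alignment",
    "evaluate_encounter",
    "build_llm_prompt",
    "parse_llm_response",
    "serialize_record",
    "RecommendationAdapter",
    "RuleEngineAdapter",
    "AdapterSettings",
]

UNKNOWN = "unknown"  # tri-state third value

FACT_NAMES = (
    "copd_exacerbation",
    "cardiogenic_pulmonary_edema",
    "neuromuscular_or_ohs",
    "post_extubation_high_risk",
    "post_extubation_low_risk_or_established_failure",
    "immunocompromised_mild_mod_arf",
    "postop_arf",
    "chest_trauma_arf",
    "de_novo_hypoxemic_rf",
    "niv_intolerant",
    "niv_contraindicated",
    "moderate_severe_arf",
    "postop_postextubation_high_risk",
)


@dataclass
class ClinicalFacts:
    """Structured facts feeding the rule engine.

    Measurements may be ``None`` (absent); boolean facts default to False.
    """

    ph: Optional[float] = None
    paco2: Optional[float] = None
    resp_rate: Optional[float] = None
    spo2: Optional[float] = None
    fio2: Optional[float] = None
    copd_exacerbation: bool = False
    cardiogenic_pulmonary_edema: bool = False
    neuromuscular_or_ohs: bool = False
    post_extubation_high_risk: bool = False
    post_extubation_low_risk_or_established_failure: bool = False
    immunocompromised_mild_mod_arf: bool = False
    postop_arf: bool = False
    chest_trauma_arf: bool = False
    de_novo_hypoxemic_rf: bool = False
    niv_intolerant: bool = False
    niv_contraindicated: bool = False
    moderate_severe_arf: bool = False
    postop_postextubation_high_risk: bool = False

    def __post_init__(self):
        if self.ph is not None and not 6.5 <= self.ph <= 8.0:
            raise ValueError(f"ph out of physiological range: {self.ph}")
        if self.paco2 is not None and self.paco2 <= 0:
            raise ValueError("paco2 must be positive")
        if self.fio2 is not None and not 0.21 <= self.fio2 <= 1.0:
            raise ValueError("fio2 must be in [0.21, 1.0]")


def acute_respiratory_acidosis(ph: Optional[float], paco2: Optional[float]):
    """Acute (or acute-on-chronic) respiratory acidosis: pH <= 7.35 with
    PaCO2 > 45 mmHg.  Returns True/False, or ``"unknown"`` when a decisive
    operand is absent."""
    ph_low = None if ph is None else ph <= 7.35
    co2_high = None if paco2 is None else paco2 > 45.0
    if ph_low is False or co2_high is False:
        return False
    if ph_low is None or co2_high is None:
        return UNKNOWN
    return True


@dataclass
class TherapyEvaluation:
    therapy: str  # "NIV" | "HFNC"
    recommendation: str  # "Yes" | "No" | "Either"
    confidence: str  # "high" | "medium" | "low"
    matched_criteria: list[str] = field(default_factory=list)
    explanation: str = ""

    def __post_init__(self):
        if self.recommendation == "Yes" and not self.matched_criteria:
            raise ValueError("recommendation Yes requires matched criteria")
        if not self.explanation:
            raise ValueError("explanation must be nonempty")


# criterion identifiers -> (kind, guideline line cited in explanations)
NIV_CRITERIA = {
    "niv_copd_acidosis": (
        "strong",
        "COPD exacerbation with acute or acute-on-chronic respiratory "
        "acidosis (pH <= 7.35, PaCO2 > 45 mmHg)",
    ),
    "niv_cardiogenic_edema": (
        "strong",
        "Acute respiratory failure due to cardiogenic pulmonary edema",
    ),
    "niv_neuromuscular_ohs_acidosis": (
        "strong",
        "Neuromuscular disease or obesity hypoventilation syndrome with "
        "acute or acute-on-chronic respiratory acidosis",
    ),
    "niv_postextubation_high_risk": (
        "strong",
        "Prophylactic NIV post-extubation in high-risk patients (not "
        "low-risk patients or established post-extubation failure)",
    ),
    "niv_immunocompromised": (
        "conditional",
        "Immunocompromised patients with mild-to-moderate acute "
        "respiratory failure (conditional recommendation)",
    ),
    "niv_postop_arf": (
        "conditional",
        "Post-operative acute respiratory failure (conditional "
        "recommendation)",
    ),
    "niv_chest_trauma": (
        "conditional",
        "Chest trauma patients with acute respiratory failure "
        "(conditional recommendation)",
    ),
}

HFNC_CRITERIA = {
    "hfnc_de_novo_hypoxemic": (
        "strong",
        "De novo (or acute) hypoxemic respiratory failure",
    ),
    "hfnc_postop_postextubation_high_risk": (
        "strong",
        "Post-operative post-extubation high-risk patients: HFNC "
        "preferred over conventional oxygen",
    ),
    "hfnc_niv_intolerant": (
        "strong",
        "Intolerant to NIV with moderate to severe acute respiratory "
        "failure present",
    ),
    "hfnc_mod_severe_no_niv_indication": (
        "strong",
        "Moderate to severe acute respiratory failure present without an "
        "indication for NIV",
    ),
}

HFNC_EXCLUSION = (
    "hfnc_excl_hypercapnic",
    "Acute hypercapnic respiratory failure: HFNC not first-line unless "
    "NIV is contraindicated or not tolerated",
)


def _niv_criteria_states(facts: ClinicalFacts) -> dict[str, object]:
    """Tri-state evaluation of each NIV indication."""
    acid = acute_respiratory_acidosis(facts.ph, facts.paco2)

    def both(flag: bool, other):
        if not flag:
            return False
        return other  # True / False / unknown

    return {
        "niv_copd_acidosis": both(facts.copd_exacerbation, acid),
        "niv_cardiogenic_edema": facts.cardiogenic_pulmonary_edema,
        "niv_neuromuscular_ohs_acidosis": both(facts.neuromuscular_or_ohs, acid),
        "niv_postextubation_high_risk": (
            facts.post_extubation_high_risk
            and not facts.post_extubation_low_risk_or_established_failure
        ),
        "niv_immunocompromised": facts.immunocompromised_mild_mod_arf,
        "niv_postop_arf": facts.postop_arf,
        "niv_chest_trauma": facts.chest_trauma_arf,
    }


def evaluate_niv(facts: ClinicalFacts) -> TherapyEvaluation:
    """Apply the NIV indication list; a stated contraindication forces No."""
    states = _niv_criteria_states(facts)
    if facts.niv_contraindicated:
        return TherapyEvaluation(
            therapy="NIV",
            recommendation="No",
            confidence="high",
            matched_criteria=[],
            explanation="NIV is contraindicated; indications not considered.",
        )
    fired = [c for c, s in states.items() if s is True]
    unknown_present = any(s == UNKNOWN for s in states.values())
    if fired:
        kinds = {NIV_CRITERIA[c][0] for c in fired}
        confidence = "high" if "strong" in kinds else "medium"
        lines = "; ".join(NIV_CRITERIA[c][1] for c in fired)
        return TherapyEvaluation(
            therapy="NIV", recommendation="Yes", confidence=confidence,
            matched_criteria=fired,
            explanation=f"Guideline indication(s) met: {lines}.",
        )
    confidence = "low" if unknown_present else "high"
    expl = (
        "No NIV indication established"
        + ("; some criteria unresolved due to missing measurements." if unknown_present else ".")
    )
    return TherapyEvaluation(
        therapy="NIV", recommendation="No", confidence=confidence,
        matched_criteria=[], explanation=expl,
    )


def evaluate_hfnc(facts: ClinicalFacts) -> TherapyEvaluation:
    """Apply the HFNC indication list after the hypercapnic exclusion.

    The exclusion fires when respiratory acidosis is established and NIV is
    neither contraindicated nor intolerated: HFNC is then not first-line.
    """
    acid = acute_respiratory_acidosis(facts.ph, facts.paco2)
    niv_escape = facts.niv_contraindicated or facts.niv_intolerant
    if acid is True and not niv_escape:
        return TherapyEvaluation(
            therapy="HFNC", recommendation="No", confidence="high",
            matched_criteria=[HFNC_EXCLUSION[0]],
            explanation=f"Exclusion applies: {HFNC_EXCLUSION[1]}.",
        )
    niv_indicated = evaluate_niv(facts).recommendation == "Yes"
    states = {
        "hfnc_de_novo_hypoxemic": facts.de_novo_hypoxemic_rf,
        "hfnc_postop_postextubation_high_risk": facts.postop_postextubation_high_risk,
        "hfnc_niv_intolerant": facts.niv_intolerant and facts.moderate_severe_arf,
        "hfnc_mod_severe_no_niv_indication": (
            facts.moderate_severe_arf and not niv_indicated
        ),
    }
    fired = [c for c, s in states.items() if s is True]
    unknown_present = acid == UNKNOWN
    if fired:
        lines = "; ".join(HFNC_CRITERIA[c][1] for c in fired)
        return TherapyEvaluation(
            therapy="HFNC", recommendation="Yes",
            confidence="low" if unknown_present else "high",
            matched_criteria=fired,
            explanation=f"Guideline indication(s) met: {lines}.",
        )
    return TherapyEvaluation(
        therapy="HFNC", recommendation="No",
        confidence="low" if unknown_present else "high",
        matched_criteria=[],
        explanation="No HFNC indication established"
        + ("; acid-base status unresolved." if unknown_present else "."),
    )


def resolve_joint(niv_eval: TherapyEvaluation, hfnc_eval: TherapyEvaluation) -> str:
    """Map the (NIV, HFNC) verdict pair to a final label.

    Yes/No -> NIV; No/Yes -> HFNC; ties (Yes/Yes, No/No) and any Either ->
    Indifferent (either option acceptable / no decisive indication)."""
    pair = (niv_eval.recommendation, hfnc_eval.recommendation)
    if pair == ("Yes", "No"):
        return "NIV"
    if pair == ("No", "Yes"):
        return "HFNC"
    return "Indifferent"


def model_alignment(model_label: str, final_label: str) -> tuple[bool, str]:
    """Counterfactual-model vs guideline alignment: aligned when the labels
    agree, or when the guideline verdict is Indifferent (either acceptable)."""
    norm = {"NIV_preferred": "NIV", "HFNC_preferred": "HFNC",
            "Indifferent": "Indifferent", "NIV": "NIV", "HFNC": "HFNC"}
    model = norm[model_label]
    if final_label == "Indifferent":
        return True, "Guideline verdict is Indifferent; either option acceptable."
    if model == final_label:
        return True, f"Model and guideline both favor {final_label}."
    return False, (
        f"Model favors {model} but the guideline-based decision is {final_label}."
    )


@dataclass
class RecommendationRecord:
    niv_recommendation: TherapyEvaluation
    hfnc_recommendation: TherapyEvaluation
    alignment: bool
    alignment_explanation: str
    final_label: str  # "NIV" | "HFNC" | "Indifferent"


def evaluate_encounter(facts: ClinicalFacts, model_label: str) -> RecommendationRecord:
    """Full deterministic evaluation of one encounter."""
    niv_eval = evaluate_niv(facts)
    hfnc_eval = evaluate_hfnc(facts)
    final = resolve_joint(niv_eval, hfnc_eval)
    aligned, expl = model_alignment(model_label, final)
    return RecommendationRecord(
        niv_recommendation=niv_eval,
        hfnc_recommendation=hfnc_eval,
        alignment=aligned,
        alignment_explanation=expl,
        final_label=final,
    )


# --------------------------------------------------------------------------
# prompt construction and structured-output parsing
# --------------------------------------------------------------------------

PROMPT_SECTIONS = (
    "Summarized Clinical Guidelines",
    "T0 Timestamp",
    "Counterfactual Model Output at T0",
    "Recent Clinical Parameters (pre-T0)",
    "Relevant Clinical Notes",
)

GUIDELINE_SUMMARY = (
    "NIV is recommended for: "
    + "; ".join(line for _, line in NIV_CRITERIA.values())
    + ". HFNC is recommended for: "
    + "; ".join(line for _, line in HFNC_CRITERIA.values())
    + f". HFNC exclusion: {HFNC_EXCLUSION[1]}."
)


def build_llm_prompt(
    guideline_summary: str,
    t0,
    model_label: str,
    rationale: list[tuple[str, float]],
    recent_parameters: dict[str, Optional[float]],
    notes: str,
) -> str:
    """Deterministic prompt document with a fixed section order.

    ``rationale`` is the ranked (feature, attribution) list from the
    counterfactual model; ``recent_parameters`` carries the latest pre-T0
    pH, PaCO2, respiratory rate, SpO2 and FiO2.
    """
    if guideline_summary is None or model_label is None or t0 is None:
        raise ValueError("missing required prompt component")
    rat = "\n".join(f"  {i+1}. {name}: {attr:+.4f}" for i, (name, attr) in enumerate(rationale))
    params = "\n".join(
        f"  {k}: " + ("not measured" if v is None else f"{v:.4g}")
        for k, v in recent_parameters.items()
    )
    body = {
        "Summarized Clinical Guidelines": guideline_summary,
        "T0 Timestamp": str(t0),
        "Counterfactual Model Output at T0": (
            f"Recommended modality: {model_label}\nTop feature attributions:\n{rat}"
            if rat else f"Recommended modality: {model_label}\n(no rationale provided)"
        ),
        "Recent Clinical Parameters (pre-T0)": params or "  none recorded",
        "Relevant Clinical Notes": notes if notes.strip() else "[no notes available]",
    }
    parts = []
    for section in PROMPT_SECTIONS:
        parts.append(f"## {section}\n{body[section]}")
    parts.append(
        "## Task\n(1) Assess whether the model recommendation aligns with the "
        "guidelines; (2) independently recommend NIV, HFNC, or Indifferent; "
        "(3) cite the relevant guideline statements. Return structured JSON."
    )
    return "\n\n".join(parts)


class _TherapyOut(BaseModel):
    recommendation: str
    confidence: str
    explanation: str


class _AlignmentOut(BaseModel):
    alignment: bool
    explanation: str


_VALID_REC = {"Yes", "No", "Either"}
_VALID_CONF = {"high", "medium", "low"}


class ResponseParseError(ValueError):
    pass


def _canonical_key(key: str) -> Optional[str]:
    """Lenient key normalisation: the published schema contains corrupted
    spellings (e.g. 'NIVjecommendation', 'ModeLalignment'); map anything
    containing the therapy name or 'alignment' to the canonical key."""
    flat = re.sub(r"[^a-z]", "", key.lower())
    if "hfnc" in flat:
        return "hfnc_recommendation"
    if "niv" in flat:
        return "niv_recommendation"
    if "alignment" in flat or "model" in flat:
        return "model_alignment"
    return None


def parse_llm_response(text: str, final_label: Optional[str] = None) -> RecommendationRecord:
    """Parse and validate a structured JSON response into a record.

    Raises :class:`ResponseParseError` naming the offending key/value for
    malformed JSON, missing keys, or out-of-enumeration values.
    """
    try:
        raw = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ResponseParseError(f"malformed JSON: {exc}") from exc
    if not isinstance(raw, dict):
        raise ResponseParseError("top-level JSON must be an object")
    mapped: dict[str, dict] = {}
    for key, val in raw.items():
        canon = _canonical_key(key)
        if canon:
            mapped[canon] = val
    out = {}
    for canon, model_cls, therapy in [
        ("niv_recommendation", _TherapyOut, "NIV"),
        ("hfnc_recommendation", _TherapyOut, "HFNC"),
    ]:
        if canon not in mapped:
            raise ResponseParseError(f"missing key: {canon}")
        try:
            parsed = model_cls.model_validate(mapped[canon])
        except ValidationError as exc:
            missing = [str(e["loc"][0]) for e in exc.errors()]
            raise ResponseParseError(
                f"invalid {canon}: missing/invalid field(s) {missing}"
            ) from exc
        if parsed.recommendation not in _VALID_REC:
            raise ResponseParseError(
                f"{canon}.recommendation not in {sorted(_VALID_REC)}: "
                f"{parsed.recommendation!r}"
            )
        if parsed.confidence not in _VALID_CONF:
            raise ResponseParseError(
                f"{canon}.confidence not in {sorted(_VALID_CONF)}: "
                f"{parsed.confidence!r}"
            )
        out[canon] = TherapyEvaluation(
            therapy=therapy,
            recommendation=parsed.recommendation,
            confidence=parsed.confidence,
            matched_criteria=mapped[canon].get("matched_criteria", []) or (
                ["(from response)"] if parsed.recommendation == "Yes" else []
            ),
            explanation=parsed.explanation,
        )
    if "model_alignment" not in mapped:
        raise ResponseParseError("missing key: model_alignment")
    try:
        align = _AlignmentOut.model_validate(mapped["model_alignment"])
    except ValidationError as exc:
        missing = [str(e["loc"][0]) for e in exc.errors()]
        raise ResponseParseError(
            f"invalid model_alignment: missing/invalid field(s) {missing}"
        ) from exc
    final = final_label or resolve_joint(out["niv_recommendation"], out["hfnc_recommendation"])
    return RecommendationRecord(
        niv_recommendation=out["niv_recommendation"],
        hfnc_recommendation=out["hfnc_recommendation"],
        alignment=align.alignment,
        alignment_explanation=align.explanation,
        final_label=final,
    )


def serialize_record(record: RecommendationRecord) -> str:
    """Canonical JSON serialization (inverse of :func:`parse_llm_response`)."""
    def therapy(ev: TherapyEvaluation):
        return {
            "recommendation": ev.recommendation,
            "confidence": ev.confidence,
            "explanation": ev.explanation,
            "matched_criteria": ev.matched_criteria,
        }

    return json.dumps(
        {
            "niv_recommendation": therapy(record.niv_recommendation),
            "hfnc_recommendation": therapy(record.hfnc_recommendation),
            "model_alignment": {
                "alignment": record.alignment,
                "explanation": record.alignment_explanation,
            },
        },
        sort_keys=True,
    )


# --------------------------------------------------------------------------
# adapter interface
# --------------------------------------------------------------------------

@dataclass
class AdapterSettings:
    """Recorded configuration for an external language-model adapter.

    ``temperature`` defaults to 0.1 (near-deterministic decoding); these
    fields are recorded metadata only — the default engine is rule-based
    and ignores them."""

    model_name: str = "rule-engine"
    temperature: float = 0.1


class RecommendationAdapter(Protocol):
    settings: AdapterSettings

    def recommend(self, prompt: str, facts: ClinicalFacts, model_label: str) -> str:
        """Return a structured JSON response for the prompt."""
        ...


class RuleEngineAdapter:
    """Default offline adapter: evaluates the deterministic rule engine and
    serializes its verdict in the structured response schema."""

    def __init__(self, settings: AdapterSettings | None = None):
        self.settings = settings or AdapterSettings()

    def recommend(self, prompt: str, facts: ClinicalFacts, model_label: str) -> str:
        record = evaluate_encounter(facts, model_label)
        return serialize_record(record)
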
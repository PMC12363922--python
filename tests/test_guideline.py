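"""Rule-engine semantics: indication logic, tri-state handling, joint
resolution, prompt/response plumbing."""

import itertools
import json

import pytest

from resprec.guideline import (
    AdapterSettings,
    ClinicalFacts,
    ResponseParseError,
    RuleEngineAdapter,
    TherapyEvaluation,
    UNKNOWN,
    acute_respiratory_acidosis,
    build_llm_prompt,
    evaluate_encounter,
    evaluate_hfnc,
    evaluate_niv,
    model_alignment,
    parse_llm_response,
    resolve_joint,
    serialize_record,
    GUIDELINE_SUMMARY,
    PROMPT_SECTIONS,
)

BOOL_FACTS = [
    "copd_exacerbation",
    "cardiogenic_pulmonary_edema",
    "neuromuscular_or_ohs",
    "post_extubation_high_risk",
    "immunocompromised_mild_mod_arf",
    "de_novo_hypoxemic_rf",
    "niv_intolerant",
    "niv_contraindicated",
    "moderate_severe_arf",
    "postop_postextubation_high_risk",
]


def flat_rule_table(facts: ClinicalFacts):
    """Independent flat re-statement of the guideline logic, written as one
    boolean expression per verdict (no shared helpers with the engine)."""
    ph, pco2 = facts.ph, facts.paco2
    if ph is None or pco2 is None:
        acid_true = False
    else:
        acid_true = (ph <= 7.35) and (pco2 > 45.0)

    if facts.niv_contraindicated:
        niv_yes = False
    else:
        niv_yes = (
            (facts.copd_exacerbation and acid_true)
            or facts.cardiogenic_pulmonary_edema
            or (facts.neuromuscular_or_ohs and acid_true)
            or (facts.post_extubation_high_risk
                and not facts.post_extubation_low_risk_or_established_failure)
            or facts.immunocompromised_mild_mod_arf
            or facts.postop_arf
            or facts.chest_trauma_arf
        )

    excl = acid_true and not (facts.niv_contraindicated or facts.niv_intolerant)
    if excl:
        hfnc_yes = False
    else:
        hfnc_yes = (
            facts.de_novo_hypoxemic_rf
            or facts.postop_postextubation_high_risk
            or (facts.niv_intolerant and facts.moderate_severe_arf)
            or (facts.moderate_severe_arf and not niv_yes)
        )

    if niv_yes and not hfnc_yes:
        final = "NIV"
    elif hfnc_yes and not niv_yes:
        final = "HFNC"
    else:
        final = "Indifferent"
    return ("Yes" if niv_yes else "No", "Yes" if hfnc_yes else "No", final)


@pytest.mark.parametrize(
    "ph,paco2,expected",
    [
        (7.35, 46.0, True),      # both thresholds exactly at the boundary
        (7.36, 60.0, False),     # pH just above the cutoff
        (7.20, 44.0, False),     # CO2 not retained
        (7.20, None, UNKNOWN),   # missing operand, pH alone cannot decide
        (None, 60.0, UNKNOWN),
        (None, 40.0, False),     # CO2 already rules it out
        (7.50, None, False),     # pH already rules it out
    ],
)
def test_respiratory_acidosis_tristate(ph, paco2, expected):
    assert acute_respiratory_acidosis(ph, paco2) == expected


def test_niv_copd_with_acidosis_fires():
    facts = ClinicalFacts(ph=7.30, paco2=55.0, copd_exacerbation=True)
    ev = evaluate_niv(facts)
    assert ev.recommendation == "Yes"
    assert "niv_copd_acidosis" in ev.matched_criteria
    assert ev.confidence == "high"


def test_niv_no_facts_gives_no():
    ev = evaluate_niv(ClinicalFacts(ph=7.42, paco2=38.0))
    assert ev.recommendation == "No"
    assert ev.matched_criteria == []


def test_niv_conditional_only_is_medium_confidence():
    ev = evaluate_niv(ClinicalFacts(ph=7.42, paco2=38.0,
                                    immunocompromised_mild_mod_arf=True))
    assert ev.recommendation == "Yes"
    assert ev.confidence == "medium"


def test_niv_contraindication_overrides_indications():
    facts = ClinicalFacts(ph=7.30, paco2=55.0, copd_exacerbation=True,
                          niv_contraindicated=True)
    assert evaluate_niv(facts).recommendation == "No"


def test_hfnc_de_novo_hypoxemic_fires():
    ev = evaluate_hfnc(ClinicalFacts(ph=7.42, paco2=38.0, de_novo_hypoxemic_rf=True))
    assert ev.recommendation == "Yes"


def test_hfnc_hypercapnic_exclusion_blocks_first_line():
    facts = ClinicalFacts(ph=7.30, paco2=55.0, copd_exacerbation=True,
                          de_novo_hypoxemic_rf=True)
    ev = evaluate_hfnc(facts)
    assert ev.recommendation == "No"
    assert "hfnc_excl_hypercapnic" in ev.matched_criteria


def test_hfnc_exclusion_lifted_when_niv_intolerant():
    facts = ClinicalFacts(ph=7.30, paco2=55.0, copd_exacerbation=True,
                          niv_intolerant=True, moderate_severe_arf=True)
    assert evaluate_hfnc(facts).recommendation == "Yes"


@pytest.mark.parametrize(
    "niv,hfnc,expected",
    [("Yes", "No", "NIV"), ("No", "Yes", "HFNC"), ("Yes", "Yes", "Indifferent"),
     ("No", "No", "Indifferent"), ("Either", "No", "Indifferent"),
     ("No", "Either", "Indifferent")],
)
def test_resolve_joint_mapping(niv, hfnc, expected):
    def ev(therapy, rec):
        return TherapyEvaluation(
            therapy=therapy, recommendation=rec, confidence="high",
            matched_criteria=["x"] if rec == "Yes" else [],
            explanation="test",
        )
    assert resolve_joint(ev("NIV", niv), ev("HFNC", hfnc)) == expected


@pytest.mark.parametrize(
    "model,final,expected",
    [("NIV_preferred", "NIV", True), ("HFNC_preferred", "NIV", False),
     ("HFNC_preferred", "Indifferent", True), ("Indifferent", "HFNC", False),
     ("HFNC_preferred", "HFNC", True)],
)
def test_model_alignment(model, final, expected):
    aligned, expl = model_alignment(model, final)
    assert aligned is expected
    assert expl


def test_truth_table_equivalence_against_flat_rules():
    """Engine verdicts match the independent flat rule table over all 2^10
    boolean combinations crossed with a 5x5 (pH, PaCO2) grid."""
    ph_grid = [7.20, 7.34, 7.35, 7.36, 7.50]
    paco2_grid = [30.0, 44.0, 45.0, 46.0, 70.0]
    for bits in itertools.product([False, True], repeat=len(BOOL_FACTS)):
        flags = dict(zip(BOOL_FACTS, bits))
        for ph in ph_grid:
            for paco2 in paco2_grid:
                facts = ClinicalFacts(ph=ph, paco2=paco2, **flags)
                niv = evaluate_niv(facts).recommendation
                hfnc = evaluate_hfnc(facts).recommendation
                final = resolve_joint(evaluate_niv(facts), evaluate_hfnc(facts))
                assert (niv, hfnc, final) == flat_rule_table(facts), flags


def test_adding_niv_indication_never_flips_yes_to_no():
    """Indication monotonicity (contraindication flag excepted)."""
    indications = ["copd_exacerbation", "cardiogenic_pulmonary_edema",
                   "neuromuscular_or_ohs", "post_extubation_high_risk",
                   "immunocompromised_mild_mod_arf", "postop_arf",
                   "chest_trauma_arf"]
    base_sets = [
        {}, {"cardiogenic_pulmonary_edema": True},
        {"copd_exacerbation": True}, {"postop_arf": True},
    ]
    for base in base_sets:
        before = evaluate_niv(ClinicalFacts(ph=7.30, paco2=50.0, **base))
        for extra in indications:
            after = evaluate_niv(
                ClinicalFacts(ph=7.30, paco2=50.0, **{**base, extra: True})
            )
            if before.recommendation == "Yes":
                assert after.recommendation == "Yes"


def test_prompt_sections_appear_exactly_once_and_deterministic():
    facts = ClinicalFacts(ph=7.31, paco2=52.0, copd_exacerbation=True)
    kwargs = dict(
        guideline_summary=GUIDELINE_SUMMARY,
        t0="2024-01-01T08:00",
        model_label="NIV_preferred",
        rationale=[("ph__baseline", -0.12), ("copd", -0.08)],
        recent_parameters={"ph": 7.31, "paco2": 52.0, "resp_rate": 28.0,
                           "spo2": 91.0, "fio2": None},
        notes="",
    )
    p1 = build_llm_prompt(**kwargs)
    p2 = build_llm_prompt(**kwargs)
    assert p1 == p2
    for section in PROMPT_SECTIONS:
        assert p1.count(f"## {section}") == 1
    assert "[no notes available]" in p1


def test_prompt_missing_component_raises():
    with pytest.raises(ValueError):
        build_llm_prompt(None, "t", "NIV_preferred", [], {}, "")


def test_parse_serialize_roundtrip():
    facts = ClinicalFacts(ph=7.30, paco2=55.0, copd_exacerbation=True)
    record = evaluate_encounter(facts, "NIV_preferred")
    text = serialize_record(record)
    parsed = parse_llm_response(text)
    assert parsed.niv_recommendation.recommendation == record.niv_recommendation.recommendation
    assert parsed.hfnc_recommendation.recommendation == record.hfnc_recommendation.recommendation
    assert parsed.alignment == record.alignment
    assert parsed.final_label == record.final_label
    # serialize again: stable
    assert serialize_record(parsed) == text


def test_parse_accepts_corrupted_key_spellings():
    text = json.dumps({
        "NIVjecommendation": {"recommendation": "Yes", "confidence": "high",
                              "explanation": "COPD with acidosis"},
        "HFNCjrecommendation": {"recommendation": "No", "confidence": "high",
                                "explanation": "hypercapnic exclusion"},
        "ModeLalignment": {"alignment": True, "explanation": "agrees"},
    })
    rec = parse_llm_response(text)
    assert rec.niv_recommendation.recommendation == "Yes"
    assert rec.final_label == "NIV"


@pytest.mark.parametrize(
    "payload,fragment",
    [
        ("not json at all", "malformed JSON"),
        (json.dumps({"niv_recommendation": {"recommendation": "Yes",
                                            "explanation": "x"},
                     "hfnc_recommendation": {"recommendation": "No",
                                             "confidence": "high",
                                             "explanation": "x"},
                     "model_alignment": {"alignment": True, "explanation": "x"}}),
         "confidence"),
        (json.dumps({"niv_recommendation": {"recommendation": "Maybe",
                                            "confidence": "high",
                                            "explanation": "x"},
                     "hfnc_recommendation": {"recommendation": "No",
                                             "confidence": "high",
                                             "explanation": "x"},
                     "model_alignment": {"alignment": True, "explanation": "x"}}),
         "recommendation"),
        (json.dumps({"hfnc_recommendation": {"recommendation": "No",
                                             "confidence": "high",
                                             "explanation": "x"}}),
         "niv_recommendation"),
    ],
)
def test_parse_rejects_invalid_payloads(payload, fragment):
    with pytest.raises(ResponseParseError, match=fragment):
        parse_llm_response(payload)


def test_rule_engine_adapter_emits_parseable_response():
    adapter = RuleEngineAdapter(AdapterSettings(model_name="offline", temperature=0.1))
    facts = ClinicalFacts(ph=7.42, paco2=38.0, de_novo_hypoxemic_rf=True)
    text = adapter.recommend("prompt", facts, "HFNC_preferred")
    rec = parse_llm_response(text)
    assert rec.final_label == "HFNC"
    assert adapter.settings.temperature == 0.1
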
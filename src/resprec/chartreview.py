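"""Structured chart-review rubric and tally arithmetic.

Each reviewed case carries a structured record: guideline congruence of the
recommendation, explanation accuracy (incorrect content, clinical
significance, missing content), harm likelihood/extent for flagged errors,
three physician agreement votes, and comprehension/retrieval/reasoning
flags.  The summary recomputes headline percentages from counts with
half-up integer rounding; harm percentages use the error-subset denominator
(cases with any accuracy error), not the full panel.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import pandas as pd

__all__ = ["ReviewRecord", "ReviewSummary", "validate_record",
           "summarize_reviews", "synthetic_review_panel",
           "records_from_frame"]

YESNO = {"yes", "no"}
HARM_LIKELIHOOD = {"low", "medium", "high", "na"}
HARM_EXTENT = {"none", "mild_moderate", "severe_death", "na"}
AGREEMENT = {"agree", "disagree", "partial"}
REASONING = {"yes", "no", "partial"}


@dataclass
class ReviewRecord:
    case_id: str
    congruent_with_guideline: str  # yes/no
    incorrect_content: str
    incorrect_clinically_significant: str
    missing_content: str
    harm_likelihood: str  # low/medium/high/na
    harm_extent: str  # none/mild_moderate/severe_death/na
    md1_agreement: str  # agree/disagree/partial
    md2_agreement: str
    md3_agreement: str
    comprehension_correct: str
    retrieval_correct: str
    reasoning_correct: str  # yes/no/partial
    incorrect_comprehension: str
    retrieval_error_or_hallucination: str
    incorrect_rationale: str

    @property
    def has_accuracy_error(self) -> bool:
        """Any error in LLM accuracy: incorrect content, missing clinical
        content, or a retrieval error / hallucination."""
        return "yes" in (
            self.incorrect_content,
            self.missing_content,
            self.retrieval_error_or_hallucination,
        )


_ENUMS = {
    "congruent_with_guideline": YESNO,
    "incorrect_content": YESNO,
    "incorrect_clinically_significant": YESNO,
    "missing_content": YESNO,
    "harm_likelihood": HARM_LIKELIHOOD,
    "harm_extent": HARM_EXTENT,
    "md1_agreement": AGREEMENT,
    "md2_agreement": AGREEMENT,
    "md3_agreement": AGREEMENT,
    "comprehension_correct": YESNO,
    "retrieval_correct": YESNO,
    "reasoning_correct": REASONING,
    "incorrect_comprehension": YESNO,
    "retrieval_error_or_hallucination": YESNO,
    "incorrect_rationale": YESNO,
}


def validate_record(record: ReviewRecord) -> list[str]:
    """Return a list of violations (empty when the record is valid).

    Enforces the option enumerations and the harm/NA invariant: harm fields
    are 'na' if and only if no accuracy error is flagged."""
    violations = []
    for name, allowed in _ENUMS.items():
        val = getattr(record, name)
        if val not in allowed:
            violations.append(f"{name}: {val!r} not in {sorted(allowed)}")
    has_err = record.has_accuracy_error
    if has_err and (record.harm_likelihood == "na" or record.harm_extent == "na"):
        violations.append("error flagged but harm fields are 'na'")
    if not has_err and (record.harm_likelihood != "na" or record.harm_extent != "na"):
        violations.append("no error flagged but harm fields are not 'na'")
    return violations


def _round_pct(count: int, denom: int) -> int:
    """Integer percentage, half-up (7/11 -> 64)."""
    if denom == 0:
        raise ValueError("empty denominator")
    return int(100.0 * count / denom + 0.5)


def _overall_agreement(record: ReviewRecord) -> bool:
    """Majority of the three physician votes; 'partial' counts as disagree."""
    votes = [record.md1_agreement, record.md2_agreement, record.md3_agreement]
    return sum(v == "agree" for v in votes) >= 2


@dataclass
class ReviewSummary:
    n: int
    counts: dict[str, int]
    percentages: dict[str, int]
    n_error_cases: int
    harm_likelihood_counts: dict[str, int]
    harm_extent_counts: dict[str, int]
    harm_likelihood_pct: dict[str, int]
    md_agreement_counts: dict[str, dict[str, int]]


def summarize_reviews(records: list[ReviewRecord]) -> ReviewSummary:
    """Tally a review panel into counts and rounded percentages."""
    if not records:
        raise ValueError("need at least one record")
    for rec in records:
        violations = validate_record(rec)
        if violations:
            raise ValueError(f"{rec.case_id}: " + "; ".join(violations))
    n = len(records)
    error_cases = [r for r in records if r.has_accuracy_error]
    ne = len(error_cases)

    counts = {
        "congruent_with_guideline": sum(r.congruent_with_guideline == "yes" for r in records),
        "incorrect_content": sum(r.incorrect_content == "yes" for r in records),
        "incorrect_clinically_significant": sum(
            r.incorrect_clinically_significant == "yes" for r in records
        ),
        "missing_content": sum(r.missing_content == "yes" for r in records),
        "overall_md_agreement": sum(_overall_agreement(r) for r in records),
        "comprehension_correct": sum(r.comprehension_correct == "yes" for r in records),
        "retrieval_correct": sum(r.retrieval_correct == "yes" for r in records),
        "reasoning_correct": sum(r.reasoning_correct == "yes" for r in records),
        "incorrect_comprehension": sum(r.incorrect_comprehension == "yes" for r in records),
        "retrieval_error_or_hallucination": sum(
            r.retrieval_error_or_hallucination == "yes" for r in records
        ),
        "incorrect_rationale": sum(r.incorrect_rationale == "yes" for r in records),
    }
    percentages = {k: _round_pct(v, n) for k, v in counts.items()}
    harm_lik = {lvl: sum(r.harm_likelihood == lvl for r in records)
                for lvl in ("low", "medium", "high", "na")}
    harm_ext = {lvl: sum(r.harm_extent == lvl for r in records)
                for lvl in ("none", "mild_moderate", "severe_death", "na")}
    harm_lik_pct = (
        {lvl: _round_pct(harm_lik[lvl], ne) for lvl in ("low", "medium", "high")}
        if ne else {}
    )
    md_counts = {
        md: {
            "agree": sum(getattr(r, f"{md}_agreement") == "agree" for r in records),
            "disagree": sum(getattr(r, f"{md}_agreement") == "disagree" for r in records),
            "partial": sum(getattr(r, f"{md}_agreement") == "partial" for r in records),
        }
        for md in ("md1", "md2", "md3")
    }
    return ReviewSummary(
        n=n,
        counts=counts,
        percentages=percentages,
        n_error_cases=ne,
        harm_likelihood_counts=harm_lik,
        harm_extent_counts=harm_ext,
        harm_likelihood_pct=harm_lik_pct,
        md_agreement_counts=md_counts,
    )


def records_from_frame(df: pd.DataFrame) -> list[ReviewRecord]:
    """Load review records from a delimited-file table (rubric field names)."""
    names = [f.name for f in fields(ReviewRecord)]
    missing = set(names) - set(df.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    return [ReviewRecord(**{k: str(row[k]) for k in names}) for _, row in df.iterrows()]


def synthetic_review_panel() -> list[ReviewRecord]:
    """Synthetic 20-case review panel used in examples and tests.

    Constructed so its tallies exercise every branch of the summary: 19/20
    guideline-congruent, 3 incorrect-content cases (all clinically
    significant), 6 missing-content cases, 11 distinct accuracy-error cases
    with harm likelihood 7 low / 3 medium / 1 high and harm extent
    4 none / 5 mild-moderate / 2 severe, and physician votes giving a
    13/20 majority agreement.
    """
    def rec(i, congruent="yes", incorrect="no", signif="no", missing="no",
            harm_lik="na", harm_ext="na", md=("agree", "agree", "agree"),
            compreh="yes", retrieval="yes", reasoning="yes",
            bad_compreh="no", halluc="no", bad_rationale="no"):
        return ReviewRecord(
            case_id=f"case{i:02d}",
            congruent_with_guideline=congruent,
            incorrect_content=incorrect,
            incorrect_clinically_significant=signif,
            missing_content=missing,
            harm_likelihood=harm_lik,
            harm_extent=harm_ext,
            md1_agreement=md[0], md2_agreement=md[1], md3_agreement=md[2],
            comprehension_correct=compreh,
            retrieval_correct=retrieval,
            reasoning_correct=reasoning,
            incorrect_comprehension=bad_compreh,
            retrieval_error_or_hallucination=halluc,
            incorrect_rationale=bad_rationale,
        )

    panel = [
        # 9 clean, fully agreed cases
        *[rec(i) for i in range(1, 10)],
        # 3 incorrect-content cases (clinically significant, hallucination)
        rec(10, incorrect="yes", signif="yes", harm_lik="high",
            harm_ext="severe_death", halluc="yes", bad_rationale="yes"),
        rec(11, incorrect="yes", signif="yes", harm_lik="medium",
            harm_ext="severe_death", halluc="yes", bad_rationale="yes"),
        rec(12, incorrect="yes", signif="yes", harm_lik="medium",
            harm_ext="mild_moderate", halluc="yes", bad_rationale="yes"),
        # 6 missing-content cases (one also a retrieval error)
        rec(13, missing="yes", harm_lik="medium", harm_ext="mild_moderate",
            halluc="yes", bad_rationale="yes"),
        rec(14, missing="yes", harm_lik="low", harm_ext="mild_moderate",
            md=("agree", "disagree", "disagree")),
        rec(15, missing="yes", harm_lik="low", harm_ext="mild_moderate",
            md=("agree", "disagree", "disagree")),
        rec(16, missing="yes", harm_lik="low", harm_ext="mild_moderate",
            md=("agree", "disagree", "disagree")),
        rec(17, missing="yes", harm_lik="low", harm_ext="none",
            md=("disagree", "agree", "disagree")),
        rec(18, missing="yes", harm_lik="low", harm_ext="none",
            md=("disagree", "disagree", "agree"), congruent="no"),
        # 2 pure retrieval-error cases
        rec(19, harm_lik="low", harm_ext="none", halluc="yes",
            md=("disagree", "disagree", "agree"), retrieval="no",
            bad_compreh="yes"),
        rec(20, harm_lik="low", harm_ext="none", halluc="yes",
            md=("partial", "partial", "disagree"), reasoning="partial"),
    ]
    return panel
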
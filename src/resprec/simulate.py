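"""Synthetic ICU cohort generator with known causal ground truth.

Emulates a cohort of ICU encounters flagged as high-risk for invasive
mechanical ventilation (IMV), each of which receives either high-flow nasal
cannula (HFNC) or noninvasive ventilation (NIV) as first respiratory
support.  The generating model is deliberately transparent:

* a latent severity scalar drives vitals/labs, the early-warning risk score,
  treatment assignment and both potential outcomes;
* treatment is drawn from a logistic propensity whose coupling to severity
  is ``confounding_strength`` (0 = randomised assignment);
* both potential IMV outcomes are Bernoulli draws from logistic models that
  share severity, so every encounter carries an exactly computable true
  individualized treatment effect (ITE = P(IMV|NIV) - P(IMV|HFNC));
* guideline-relevant clinical facts (COPD exacerbation, hypoxemic failure,
  blood-gas values, ...) are correlated with the covariates so the rule
  engine sees realistic inputs.

A single seed expands into independent substreams (covariates, series,
facts, outcomes) via :class:`numpy.random.SeedSequence`, so adding a channel
never perturbs unrelated draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .guideline import ClinicalFacts, FACT_NAMES

__all__ = [
    "SimulationConfig",
    "SyntheticEncounter",
    "CohortTruth",
    "generate_cohort",
    "generate_guideline_facts",
    "render_pseudo_notes",
    "extract_facts_from_note",
    "cohort_to_frames",
]

# time-series channels emitted per encounter: (name, mean, sd, severity loading)
CHANNELS = [
    ("heart_rate", 88.0, 12.0, 8.0),
    ("resp_rate", 22.0, 4.0, 4.0),
    ("spo2", 94.0, 2.5, -2.5),
    ("sbp", 118.0, 16.0, -6.0),
    ("temperature", 37.1, 0.5, 0.2),
    ("lactate", 1.8, 0.8, 0.9),
    ("ph", 7.38, 0.05, -0.03),
    ("paco2", 42.0, 7.0, 4.0),
]

# E[sigmoid(0.9*N(0,1) + N(0,0.7^2) - 0.3)], by Gaussian quadrature; used to
# centre the hypoxemia modifier so fact marginals are preserved exactly
HYPOXEMIA_MEAN = 0.4408647

DEFAULT_FACT_PREVALENCES = {
    "copd_exacerbation": 0.18,
    "cardiogenic_pulmonary_edema": 0.15,
    "neuromuscular_or_ohs": 0.04,
    "post_extubation_high_risk": 0.08,
    "post_extubation_low_risk_or_established_failure": 0.05,
    "immunocompromised_mild_mod_arf": 0.08,
    "postop_arf": 0.07,
    "chest_trauma_arf": 0.03,
    "de_novo_hypoxemic_rf": 0.35,
    "niv_intolerant": 0.05,
    "niv_contraindicated": 0.0,
    "moderate_severe_arf": 0.30,
    "postop_postextubation_high_risk": 0.06,
}


@dataclass
class SimulationConfig:
    """Parameters of the generating model.

    ``effect_niv`` / ``effect_hfnc`` are the log-odds contributions of each
    arm to the IMV outcome model; ``het_strength`` scales a zero-mean
    covariate-driven effect modifier so individual effects are
    heterogeneous even when the average effects match.
    ``unmeasured_frac`` is the fraction of severity variance hidden from
    every measured channel (it still drives treatment and outcome).
    """

    n_encounters: int = 2000
    seed: int = 0
    confounding_strength: float = 1.0
    effect_niv: float = 0.3
    effect_hfnc: float = -0.3
    het_strength: float = 0.8
    missing_rate: float = 0.3
    unmeasured_frac: float = 0.0
    acidosis_frac: float = 0.7
    fact_prevalences: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_FACT_PREVALENCES)
    )

    def validate(self) -> None:
        if self.n_encounters < 1:
            raise ValueError("n_encounters must be >= 1")
        for name, p in [
            ("missing_rate", self.missing_rate),
            ("unmeasured_frac", self.unmeasured_frac),
            ("acidosis_frac", self.acidosis_frac),
            *self.fact_prevalences.items(),
        ]:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if self.confounding_strength < 0:
            raise ValueError("confounding_strength must be nonnegative")
        unknown = set(self.fact_prevalences) - set(DEFAULT_FACT_PREVALENCES)
        if unknown:
            raise ValueError(f"unknown fact name(s): {sorted(unknown)}")


@dataclass
class SyntheticEncounter:
    encounter_id: str
    t0: float  # hours from admission
    raw_series: list[tuple[str, float, float]]  # (channel, time, value)
    statics: dict[str, float]
    facts: ClinicalFacts
    latent_severity: float
    propensity: float  # probability of NIV
    treatment: str  # "NIV" | "HFNC"
    y_imv_niv: int
    y_imv_hfnc: int
    imv: int
    mortality: int
    hospice: int


@dataclass
class CohortTruth:
    ite: np.ndarray  # per-encounter P(IMV|NIV) - P(IMV|HFNC)
    p_imv_niv: np.ndarray
    p_imv_hfnc: np.ndarray
    ate: float
    config: SimulationConfig


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def generate_cohort(config: SimulationConfig) -> tuple[list[SyntheticEncounter], CohortTruth]:
    """Draw a full cohort; identical config+seed gives identical output."""
    config.validate()
    n = config.n_encounters
    ss = np.random.SeedSequence(config.seed)
    rng_cov, rng_series, rng_facts, rng_out = [
        np.random.default_rng(s) for s in ss.spawn(4)
    ]

    # --- covariates ---------------------------------------------------------
    # severity splits into a measured and an independent hidden component;
    # features and the risk score see only sev_obs, treatment and outcome
    # respond to the full severity
    f = config.unmeasured_frac
    sev_obs = rng_cov.normal(size=n)
    sev_hid = rng_cov.normal(size=n)
    severity = np.sqrt(1.0 - f) * sev_obs + np.sqrt(f) * sev_hid

    age = np.clip(rng_cov.normal(62, 16, n), 18, 100)
    male = rng_cov.random(n) < 0.58
    copd = rng_cov.random(n) < 0.19
    chf = rng_cov.random(n) < 0.25
    immunocomp = rng_cov.random(n) < 0.08
    cci = rng_cov.poisson(2.3, n)
    sofa = np.clip(rng_cov.poisson(np.clip(1.6 + 0.8 * sev_obs, 0.1, None)), 0, 20)
    hypoxemia = _sigmoid(0.9 * sev_obs + rng_cov.normal(0, 0.7, n) - 0.3)  # 0..1 score
    ventio = np.clip(_sigmoid(1.2 * sev_obs + rng_cov.normal(0, 0.5, n)), 1e-3, 1 - 1e-3)

    # --- treatment assignment ----------------------------------------------
    # confounding_strength scales the entire covariate/severity coupling so
    # that 0 recovers randomised assignment exactly
    lin_t = (
        config.confounding_strength
        * (1.0 * severity + 0.8 * copd + 0.6 * chf - 0.8 * (hypoxemia - 0.5))
        - 0.2
    )
    propensity = np.clip(_sigmoid(lin_t), 1e-6, 1 - 1e-6)
    niv = rng_out.random(n) < propensity
    treatment = np.where(niv, "NIV", "HFNC")

    # --- potential outcomes -------------------------------------------------
    # zero-mean effect modifier: COPD pushes toward NIV benefit, hypoxemia
    # toward HFNC benefit
    modifier = (copd.astype(float) - 0.19) - (hypoxemia - 0.5)
    base = -1.4 + 0.9 * severity + 0.35 * sofa / 4.0 + 0.01 * (age - 62) / 16.0
    logit_niv = base + config.effect_niv + config.het_strength * modifier
    logit_hfnc = base + config.effect_hfnc - config.het_strength * modifier
    p_niv = _sigmoid(logit_niv)
    p_hfnc = _sigmoid(logit_hfnc)
    y_niv = (rng_out.random(n) < p_niv).astype(int)
    y_hfnc = (rng_out.random(n) < p_hfnc).astype(int)
    imv = np.where(niv, y_niv, y_hfnc)

    # mortality / hospice share severity; small dependence on IMV
    p_mort = _sigmoid(-1.1 + 0.8 * severity + 0.5 * imv)
    mortality = (rng_out.random(n) < p_mort).astype(int)
    hospice = ((rng_out.random(n) < 0.03) & (mortality == 0)).astype(int)

    # --- facts and series ---------------------------------------------------
    encounters: list[SyntheticEncounter] = []
    for i in range(n):
        covs = {
            "copd": bool(copd[i]),
            "chf": bool(chf[i]),
            "immunocompromised": bool(immunocomp[i]),
            "hypoxemia": float(hypoxemia[i]),
        }
        facts = generate_guideline_facts(
            covs, config.fact_prevalences, rng_facts,
            acidosis_frac=config.acidosis_frac,
        )
        series = _draw_series(rng_series, float(sev_obs[i]), config.missing_rate)
        statics = {
            "age": float(age[i]),
            "male": int(male[i]),
            "copd": int(copd[i]),
            "chf": int(chf[i]),
            "immunocompromised": int(immunocomp[i]),
            "cci": int(cci[i]),
            "sofa": int(sofa[i]),
            "hypoxemia_score": float(hypoxemia[i]),
            "ventio_score": float(ventio[i]),
        }
        encounters.append(
            SyntheticEncounter(
                encounter_id=f"enc{i:06d}",
                t0=72.0,
                raw_series=series,
                statics=statics,
                facts=facts,
                latent_severity=float(severity[i]),
                propensity=float(propensity[i]),
                treatment=str(treatment[i]),
                y_imv_niv=int(y_niv[i]),
                y_imv_hfnc=int(y_hfnc[i]),
                imv=int(imv[i]),
                mortality=int(mortality[i]),
                hospice=int(hospice[i]),
            )
        )

    truth = CohortTruth(
        ite=p_niv - p_hfnc,
        p_imv_niv=p_niv,
        p_imv_hfnc=p_hfnc,
        ate=float(np.mean(p_niv - p_hfnc)),
        config=config,
    )
    return encounters, truth


def _draw_series(rng: np.random.Generator, sev_obs: float, missing_rate: float):
    """Irregular measurements over the 48 h before T0, thinned by missingness."""
    out = []
    for name, mu, sd, load in CHANNELS:
        n_pts = rng.poisson(30)
        times = np.sort(rng.uniform(24.0, 72.0, n_pts))
        # enforce strictly increasing times (duplicates are measure-zero but
        # the downstream contract requires it)
        times = np.unique(times)
        drift = rng.normal(0, 0.05 * sd)
        vals = mu + load * sev_obs + drift * (times - 48.0) + rng.normal(0, sd * 0.5, times.size)
        keep = rng.random(times.size) >= missing_rate
        out.extend((name, float(t), float(v)) for t, v in zip(times[keep], vals[keep]))
    return out


def generate_guideline_facts(
    covariates: dict,
    fact_prevalences: dict[str, float],
    rng: np.random.Generator,
    acidosis_frac: float = 0.7,
) -> ClinicalFacts:
    """Draw guideline-relevant facts correlated with the encounter covariates.

    COPD comorbidity raises the odds of a COPD exacerbation; hypoxemia score
    raises the odds of de novo hypoxemic failure and moderate/severe ARF; a
    configurable fraction of hypercapnia-prone encounters receive blood-gas
    values meeting the respiratory-acidosis criterion (pH <= 7.35 and
    PaCO2 > 45 mmHg).
    """
    unknown = set(fact_prevalences) - set(DEFAULT_FACT_PREVALENCES)
    if unknown:
        raise ValueError(f"unknown fact name(s): {sorted(unknown)}")
    prev = {**{k: 0.0 for k in DEFAULT_FACT_PREVALENCES}, **fact_prevalences}

    def bern(p):
        return bool(rng.random() < p)

    def shifted(p, modifier, center, c):
        # mean-preserving covariate shift: E over the cohort of the returned
        # probability equals p exactly (the modifier is centred), and the
        # c-bound keeps the result inside [0, 1] without clipping
        return p + c * p * (1.0 - p) * (modifier - center)

    copd = float(covariates.get("copd", False))
    chf = float(covariates.get("chf", False))
    immuno = float(covariates.get("immunocompromised", False))
    hypox = float(covariates.get("hypoxemia", HYPOXEMIA_MEAN))

    flags = {}
    flags["copd_exacerbation"] = bern(
        shifted(prev["copd_exacerbation"], copd, 0.19, 1.2)
    )
    flags["cardiogenic_pulmonary_edema"] = bern(
        shifted(prev["cardiogenic_pulmonary_edema"], chf, 0.25, 1.2)
    )
    flags["neuromuscular_or_ohs"] = bern(prev["neuromuscular_or_ohs"])
    flags["post_extubation_high_risk"] = bern(prev["post_extubation_high_risk"])
    flags["post_extubation_low_risk_or_established_failure"] = bern(
        prev["post_extubation_low_risk_or_established_failure"]
    )
    flags["immunocompromised_mild_mod_arf"] = bern(
        shifted(prev["immunocompromised_mild_mod_arf"], immuno, 0.08, 1.05)
    )
    flags["postop_arf"] = bern(prev["postop_arf"])
    flags["chest_trauma_arf"] = bern(prev["chest_trauma_arf"])
    flags["de_novo_hypoxemic_rf"] = bern(
        shifted(prev["de_novo_hypoxemic_rf"], hypox, HYPOXEMIA_MEAN, 1.5)
    )
    flags["niv_intolerant"] = bern(prev["niv_intolerant"])
    flags["niv_contraindicated"] = bern(prev["niv_contraindicated"])
    flags["moderate_severe_arf"] = bern(
        shifted(prev["moderate_severe_arf"], hypox, HYPOXEMIA_MEAN, 1.5)
    )
    flags["postop_postextubation_high_risk"] = bern(prev["postop_postextubation_high_risk"])

    hypercapnia_prone = flags["copd_exacerbation"] or flags["neuromuscular_or_ohs"]
    acidotic = hypercapnia_prone and bern(acidosis_frac)
    if acidotic:
        ph = float(np.clip(rng.normal(7.27, 0.04), 6.9, 7.35))
        paco2 = float(np.clip(rng.normal(60, 8), 45.5, 110))
    else:
        ph = float(np.clip(rng.normal(7.40, 0.04), 7.36, 7.60))
        paco2 = float(np.clip(rng.normal(40, 5), 15, 45))

    return ClinicalFacts(
        ph=ph,
        paco2=paco2,
        resp_rate=float(np.clip(rng.normal(24 + 8 * hypox, 4), 8, 60)),
        spo2=float(np.clip(rng.normal(95 - 6 * hypox, 2), 70, 100)),
        fio2=float(np.clip(rng.normal(0.3 + 0.4 * hypox, 0.08), 0.21, 1.0)),
        **flags,
    )


# --------------------------------------------------------------------------
# pseudo-notes
# --------------------------------------------------------------------------

NOTE_HEADER = "CLINICAL NOTE (templated summary, 72h pre-T0)"

_FACT_SENTENCES = {
    "copd_exacerbation": "Patient presents with a COPD exacerbation.",
    "cardiogenic_pulmonary_edema": "Findings are consistent with cardiogenic pulmonary edema.",
    "neuromuscular_or_ohs": "History of neuromuscular disease or obesity hypoventilation syndrome.",
    "post_extubation_high_risk": "Recently extubated and considered high-risk for post-extubation failure.",
    "post_extubation_low_risk_or_established_failure": "Post-extubation course low-risk or failure already established.",
    "immunocompromised_mild_mod_arf": "Immunocompromised with mild-to-moderate acute respiratory failure.",
    "postop_arf": "Acute respiratory failure in the post-operative period.",
    "chest_trauma_arf": "Chest trauma with acute respiratory failure.",
    "de_novo_hypoxemic_rf": "De novo hypoxemic respiratory failure without chronic lung disease.",
    "niv_intolerant": "Patient is intolerant of noninvasive ventilation.",
    "niv_contraindicated": "Noninvasive ventilation is contraindicated.",
    "moderate_severe_arf": "Moderate to severe acute respiratory failure is present.",
    "postop_postextubation_high_risk": "Post-operative, post-extubation and high-risk for respiratory failure.",
}


def render_pseudo_notes(facts: ClinicalFacts) -> str:
    """Deterministic templated note: one sentence per active boolean fact,
    plus a measurement line for each recorded blood-gas/vital value."""
    lines = [NOTE_HEADER]
    for name in FACT_NAMES:
        if getattr(facts, name):
            lines.append(_FACT_SENTENCES[name])
    for meas in ("ph", "paco2", "resp_rate", "spo2", "fio2"):
        val = getattr(facts, meas)
        if val is not None:
            lines.append(f"MEAS {meas}={val:.4g}")
    return "\n".join(lines)


def extract_facts_from_note(note: str) -> ClinicalFacts:
    """Inverse of :func:`render_pseudo_notes` (round-trip exact on templates)."""
    sentence_to_fact = {v: k for k, v in _FACT_SENTENCES.items()}
    flags = {name: False for name in FACT_NAMES}
    meas: dict[str, float | None] = {k: None for k in ("ph", "paco2", "resp_rate", "spo2", "fio2")}
    for line in note.splitlines():
        line = line.strip()
        if line in sentence_to_fact:
            flags[sentence_to_fact[line]] = True
        elif line.startswith("MEAS "):
            key, val = line[5:].split("=")
            meas[key] = float(val)
    return ClinicalFacts(**meas, **flags)


# --------------------------------------------------------------------------
# tabular export
# --------------------------------------------------------------------------

def cohort_to_frames(encounters: list[SyntheticEncounter]):
    """Return (encounters table, long measurements table, facts table)."""
    enc_rows, meas_rows, fact_rows = [], [], []
    for e in encounters:
        row = {
            "encounter_id": e.encounter_id,
            "t0": e.t0,
            "treatment": e.treatment,
            "imv": e.imv,
            "mortality": e.mortality,
            "hospice": e.hospice,
            **e.statics,
        }
        enc_rows.append(row)
        meas_rows.extend(
            {"encounter_id": e.encounter_id, "channel": c, "time": t, "value": v}
            for c, t, v in e.raw_series
        )
        fact_rows.append({"encounter_id": e.encounter_id, **asdict(e.facts)})
    return (
        pd.DataFrame(enc_rows),
        pd.DataFrame(meas_rows, columns=["encounter_id", "channel", "time", "value"]),
        pd.DataFrame(fact_rows),
    )


def truth_to_frame(truth: CohortTruth, encounters: list[SyntheticEncounter]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "encounter_id": [e.encounter_id for e in encounters],
            "true_ite": truth.ite,
            "true_p_imv_niv": truth.p_imv_niv,
            "true_p_imv_hfnc": truth.p_imv_hfnc,
        }
    )
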
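"""Synthetic survey-cohort generator with known ground truth.

Emulates the statistical structure a questionnaire + 24-h-recall extract of
a national survey presents to the pipeline, with every generating parameter
explicit and echoed back as ground truth:

* per-parameter intakes are independent log-normals with median equal to the
  reference global mean and dispersion chosen so the sample SD approximates
  the reference SD (right-skewed and positive, the shape that motivates the
  DII's percentile transform);
* demographics are drawn from stated categorical/Gaussian marginals;
* condition flags are Bernoulli draws linked through a shared latent
  "cardiometabolic risk" factor so comorbidities co-occur, with at least one
  qualifying flag forced for a configurable fraction of participants;
* the HF label is Bernoulli(logit^-1(b0 + b_dii*DII + b_age*age +
  b_female*1[female] + b_bmi*BMI)), effect sizes configured as odds ratios;
* laboratory values are Gaussians with an optional additive mean shift in HF
  participants; missingness is injected completely at random per field.

Everything is reproducible from the single seed.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq
from scipy.special import expit

from .cohort import (
    DIET_PREFIX,
    EDUCATION_LEVELS,
    INCOME_LEVELS,
    QUALIFYING_CONDITIONS,
    RACE_LEVELS,
    SMOKING_LEVELS,
)
from .reference import ReferenceTable, load_reference_table
from .scoring import score_frame

__all__ = ["SyntheticConfig", "generate_intakes", "generate_cohort", "load_scenario",
           "save_scenario"]


def _default_demographics() -> dict:
    return {
        "age_mean": 59.0, "age_sd": 15.0, "age_range": [20.0, 85.0],
        "p_male": 0.48,
        "bmi_mean": 31.0, "bmi_sd": 7.0, "bmi_range": [15.0, 70.0],
        "race": {"Mexican American": 0.140, "Other Hispanic": 0.079,
                 "Non-Hispanic white": 0.453, "Non-Hispanic black": 0.248,
                 "Other race or multi-racial": 0.080},
        "education": {"<High school": 0.281, "High school": 0.240,
                      ">High school": 0.479},
        "income_band": {"<20,000 USD": 0.283, ">=20,000 USD": 0.717},
        "smoking": {"Smoking": 0.374, "Non-smoking": 0.626},
    }


def _default_condition_prevalences() -> dict:
    return {
        "hypertension": 0.35, "diabetes": 0.12, "prediabetes": 0.10,
        "coronary_artery_disease": 0.04, "angina": 0.025,
        "heart_attack": 0.04, "stroke": 0.04,
    }


def _default_hf_model() -> dict:
    # intercept solved once (numeric root-find at these marginals) for ~7%
    # HF prevalence; effect sizes stated as per-unit odds ratios
    return {"or_dii": 1.15, "or_age": 1.05, "or_female": 0.61, "or_bmi": 1.05,
            "intercept": -6.95}


def _default_missingness() -> dict:
    return {"heart_failure": 0.02, "diet": 0.05, "bmi": 0.03, "waist_cm": 0.03,
            "education": 0.002, "income_band": 0.04, "smoking": 0.50, "labs": 0.10}


def _default_lab_model() -> dict:
    # (mean, sd) in the non-HF group and an additive HF mean shift
    return {
        "lab_total_cholesterol": {"mean": 5.05, "sd": 1.14, "hf_shift": -0.44},
        "lab_hdl": {"mean": 1.36, "sd": 0.42, "hf_shift": -0.10},
        "lab_ldl": {"mean": 2.91, "sd": 0.93, "hf_shift": -0.33},
        "lab_triglyceride": {"mean": 1.62, "sd": 1.34, "hf_shift": 0.15},
        "lab_albumin": {"mean": 41.63, "sd": 3.42, "hf_shift": -1.36},
        "lab_globulin": {"mean": 30.0, "sd": 5.5, "hf_shift": 1.30},
        "lab_hemoglobin": {"mean": 13.98, "sd": 1.55, "hf_shift": -0.43},
        "lab_hematocrit": {"mean": 41.35, "sd": 4.38, "hf_shift": -1.06},
        "lab_bun": {"mean": 5.41, "sd": 2.45, "hf_shift": 2.02},
        "lab_creatinine": {"mean": 0.97, "sd": 0.58, "hf_shift": 0.33},
        "lab_uric_acid": {"mean": 339.32, "sd": 88.29, "hf_shift": 46.9},
        "lab_wbc": {"mean": 7.38, "sd": 2.50, "hf_shift": 0.22},
        "lab_pulse_rate": {"mean": 72.59, "sd": 12.79, "hf_shift": -1.75},
        "lab_systolic_bp": {"mean": 130.0, "sd": 20.0, "hf_shift": 2.0},
        "lab_diastolic_bp": {"mean": 71.10, "sd": 14.97, "hf_shift": -4.62},
    }


@dataclass
class SyntheticConfig:
    """All generating parameters for one synthetic cohort scenario."""

    n_participants: int = 20_000
    seed: int = 0
    reference: str | None = None  # path to a reference table; None = bundled
    spread_scale: float = 1.0  # multiplies the log-normal dispersion (0 => all at mean)
    demographics: dict = field(default_factory=_default_demographics)
    condition_prevalences: dict = field(default_factory=_default_condition_prevalences)
    latent_loading: float = 0.8  # shared-factor loading for flag co-occurrence
    qualifying_fraction: float = 0.60  # fraction guaranteed >=1 qualifying flag
    hf_model: dict = field(default_factory=_default_hf_model)
    missingness: dict = field(default_factory=_default_missingness)
    lab_model: dict = field(default_factory=_default_lab_model)

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        if self.spread_scale < 0:
            raise ValueError("spread_scale must be >= 0")
        probs = list(self.condition_prevalences.values()) + list(
            self.missingness.values()
        ) + [self.qualifying_fraction]
        if any(not (0 <= p <= 1) for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        for key in ("or_dii", "or_age", "or_female", "or_bmi"):
            if self.hf_model.get(key, 1.0) <= 0:
                raise ValueError(f"hf_model[{key!r}] must be a positive odds ratio")

    @property
    def betas(self) -> dict:
        """HF log-odds coefficients implied by the configured odds ratios."""
        return {
            "intercept": float(self.hf_model["intercept"]),
            "beta_dii": float(np.log(self.hf_model["or_dii"])),
            "beta_age": float(np.log(self.hf_model["or_age"])),
            "beta_female": float(np.log(self.hf_model["or_female"])),
            "beta_bmi": float(np.log(self.hf_model["or_bmi"])),
        }

    def load_reference(self) -> ReferenceTable:
        return load_reference_table(self.reference)

    def to_dict(self) -> dict:
        return {
            "n_participants": self.n_participants,
            "seed": self.seed,
            "reference": self.reference,
            "spread_scale": self.spread_scale,
            "demographics": copy.deepcopy(self.demographics),
            "condition_prevalences": dict(self.condition_prevalences),
            "latent_loading": self.latent_loading,
            "qualifying_fraction": self.qualifying_fraction,
            "hf_model": dict(self.hf_model),
            "missingness": dict(self.missingness),
            "lab_model": copy.deepcopy(self.lab_model),
        }


def load_scenario(path: str | Path, **overrides) -> SyntheticConfig:
    """Load a scenario YAML; keyword overrides (e.g. ``n_participants``) win."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    data.update(overrides)
    return SyntheticConfig(**data)


def save_scenario(config: SyntheticConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)


def _lognormal_sigma(cv: float) -> float:
    """Dispersion so that SD/median of the log-normal equals ``cv``."""
    if cv <= 0:
        return 0.0
    t = (1.0 + np.sqrt(1.0 + 4.0 * cv**2)) / 2.0
    return float(np.sqrt(np.log(t)))


def generate_intakes(
    config: SyntheticConfig,
    rng: np.random.Generator | None = None,
    n: int | None = None,
    reference: ReferenceTable | None = None,
) -> pd.DataFrame:
    """Right-skewed positive daily intakes, one column per food parameter.

    Each parameter is log-normal with median at its reference global mean and
    log-scale dispersion matched so SD/median approximates the reference
    coefficient of variation, scaled by ``config.spread_scale``.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n = n if n is not None else config.n_participants
    table = reference if reference is not None else config.load_reference()
    out = {}
    for name in table.names:
        ref = table[name]
        sigma = config.spread_scale * _lognormal_sigma(ref.global_sd / ref.global_mean)
        if sigma == 0:
            out[name] = np.full(n, ref.global_mean)
        else:
            out[name] = ref.global_mean * np.exp(rng.normal(0.0, sigma, size=n))
    return pd.DataFrame(out)


def _categorical(rng, levels, probs: Mapping[str, float], n: int) -> np.ndarray:
    p = np.array([probs[lv] for lv in levels], dtype=float)
    p = p / p.sum()
    return rng.choice(np.asarray(levels, dtype=object), size=n, p=p)


def _flag_intercept(target: float, loading: float) -> float:
    """Solve a in  E_U[expit(a + loading*U)] = target  for U ~ N(0, 1)."""
    nodes, weights = np.polynomial.hermite_e.hermegauss(41)
    weights = weights / weights.sum()

    def marginal(a):
        return float(np.sum(weights * expit(a + loading * nodes))) - target

    return brentq(marginal, -30, 30)


def generate_cohort(
    config: SyntheticConfig,
) -> tuple[pd.DataFrame, dict]:
    """Generate a full participant table plus the ground-truth metadata.

    Returns ``(participants, ground_truth)`` where ``participants`` has the
    canonical pipeline columns (demographics, condition flags, ``lab_*``,
    ``diet_*``) with missingness already injected, and ``ground_truth`` echoes
    the generating coefficients, the target odds ratios, the per-participant
    true DII and HF probability, and the achieved HF prevalence.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_participants
    demo = config.demographics
    table = config.load_reference()

    age = np.clip(rng.normal(demo["age_mean"], demo["age_sd"], n), *demo["age_range"])
    sex = np.where(rng.random(n) < demo["p_male"], "male", "female").astype(object)
    bmi = np.clip(rng.normal(demo["bmi_mean"], demo["bmi_sd"], n), *demo["bmi_range"])
    waist = 2.2 * bmi + 36.5 + rng.normal(0.0, 8.0, n)
    race = _categorical(rng, RACE_LEVELS, demo["race"], n)
    education = _categorical(rng, EDUCATION_LEVELS, demo["education"], n)
    income = _categorical(rng, INCOME_LEVELS, demo["income_band"], n)
    smoking = _categorical(rng, SMOKING_LEVELS, demo["smoking"], n)

    intakes = generate_intakes(config, rng=rng, n=n, reference=table)
    scored = score_frame(intakes, table, min_parameters=1)
    dii = scored["dii_total"].to_numpy()

    b = config.betas
    eta = (
        b["intercept"]
        + b["beta_dii"] * dii
        + b["beta_age"] * age
        + b["beta_female"] * (sex == "female")
        + b["beta_bmi"] * bmi
    )
    p_hf = expit(eta)
    hf = rng.random(n) < p_hf
    achieved = float(hf.mean())
    if achieved in (0.0, 1.0):
        warnings.warn(
            f"hf_model yields a degenerate empirical prevalence ({achieved:.3f})",
            stacklevel=2,
        )

    # comorbidity flags through a shared latent factor, so they co-occur
    latent = rng.normal(0.0, 1.0, n)
    flags: dict[str, np.ndarray] = {}
    for cond in QUALIFYING_CONDITIONS:
        prev = config.condition_prevalences.get(cond, 0.0)
        if prev <= 0:
            flags[cond] = np.zeros(n, dtype=bool)
            continue
        a = _flag_intercept(prev, config.latent_loading)
        flags[cond] = rng.random(n) < expit(a + config.latent_loading * latent)
    any_flag = np.logical_or.reduce(list(flags.values()))
    forced = (rng.random(n) < config.qualifying_fraction) & ~any_flag
    flags["hypertension"] = flags["hypertension"] | forced

    labs = {}
    for lab, spec in config.lab_model.items():
        vals = rng.normal(spec["mean"], spec["sd"], n) + spec.get("hf_shift", 0.0) * hf
        labs[lab] = np.clip(vals, 0.05 * spec["mean"], None)

    participants = pd.DataFrame(
        {
            "participant_id": [f"P{i:07d}" for i in range(n)],
            "age": age,
            "sex": sex,
            "race": race,
            "education": education.astype(object),
            "income_band": income.astype(object),
            "smoking": smoking.astype(object),
            "bmi": bmi,
            "waist_cm": waist,
            "heart_failure": np.where(hf, "yes", "no").astype(object),
        }
    )
    for cond, arr in flags.items():
        participants[cond] = np.where(arr, "yes", "no").astype(object)
    for lab, arr in labs.items():
        participants[lab] = arr
    for col in intakes.columns:
        participants[DIET_PREFIX + col] = intakes[col].to_numpy()

    # missingness, completely at random per field
    miss = config.missingness
    def _mask(col, p):
        if p > 0:
            participants.loc[rng.random(n) < p, col] = np.nan

    _mask("heart_failure", miss.get("heart_failure", 0.0))
    _mask("bmi", miss.get("bmi", 0.0))
    _mask("waist_cm", miss.get("waist_cm", 0.0))
    _mask("education", miss.get("education", 0.0))
    _mask("income_band", miss.get("income_band", 0.0))
    _mask("smoking", miss.get("smoking", 0.0))
    p_lab = miss.get("labs", 0.0)
    if p_lab > 0:
        for lab in labs:
            _mask(lab, p_lab)
    p_diet = miss.get("diet", 0.0)
    if p_diet > 0:
        diet_cols = [DIET_PREFIX + c for c in intakes.columns]
        participants.loc[rng.random(n) < p_diet, diet_cols] = np.nan

    ground_truth = {
        "n_participants": n,
        "seed": config.seed,
        "coefficients": b,
        "target_odds_ratios": {
            "dii": config.hf_model["or_dii"],
            "age": config.hf_model["or_age"],
            "female": config.hf_model["or_female"],
            "bmi": config.hf_model["or_bmi"],
        },
        "achieved_hf_prevalence": achieved,
        "true_dii": pd.Series(dii, index=participants.index, name="true_dii"),
        "true_p_hf": pd.Series(p_hf, index=participants.index, name="true_p_hf"),
    }
    return participants, ground_truth
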
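"""Synthetic SOEP-like panel generator with known ground truth.

The generator emulates the structure of a long-running German household
panel: annual waves 2009-2022, biennial self-reported diagnosis assessment
(2011, 2013, ..., 2021), binary sex assigned at birth, a latent gender
construct shifted by sex, ten gender-related indicator variables on mixed
scales, covariate regressions for caregiving- and income-related indicators,
pre-existing risk factors (smoking, hypertension, diabetes), binary incident
outcomes (migraine, stroke) driven by a linear-probability law, wave-specific
survey weights, and missing-at-random blanking.

Every person's true latent gender and true outcome timing are returned in a
separate truth table, never in the panel itself, so downstream stages
(incidence derivation, imputation, SEM fitting) can be validated against
ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .dag import DEFAULT_INDICATORS

__all__ = ["SyntheticConfig", "generate_panel", "inject_missingness"]

#: Sign pattern and anchor magnitudes of the measurement model: housework is
#: the strongest positive indicator (0.670), monthly income the strongest
#: negative one (-0.708); the remaining magnitudes are plausible fill-ins.
DEFAULT_LOADINGS = {
    "housework": 0.670,
    "childcare": 0.530,
    "parental_leave": 0.300,
    "wage": -0.600,
    "income": -0.708,
    "education": -0.300,
    "employment": -0.450,
    "risk_taking": -0.350,
    "political_interest": -0.350,
    "physician_visits": 0.200,
}

#: Cumulative-incidence-scale effects of the fitted structural model.
#: Migraine: strong positive sex effect, no direct gender effect.
#: Stroke: small negative sex effect, small positive gender effect.
DEFAULT_STRUCTURAL = {
    ("migraine", "intercept"): 0.020,
    ("migraine", "sex"): 0.044,
    ("stroke", "intercept"): 0.050,
    ("stroke", "sex"): -0.010,
    ("stroke", "gender"): 0.006,
}

#: Covariate effects on indicators: caregiving indicators respond to children
#: and partner in the household; income and wage to age (decades) and East
#: German residence.
DEFAULT_COVARIATE_EFFECTS = {
    ("housework", "children"): 0.40,
    ("housework", "partner"): 0.20,
    ("childcare", "children"): 0.70,
    ("childcare", "partner"): 0.10,
    ("income", "age10"): -0.05,
    ("income", "east"): -0.40,
    ("wage", "age10"): -0.03,
    ("wage", "east"): -0.30,
}

#: Marginal target frequencies for thresholded (binary/ordinal) indicators.
DEFAULT_INDICATOR_TYPES = {
    "parental_leave": ("binary", (0.02,)),
    "employment": ("ordinal", (0.38, 0.19, 0.23, 0.20)),
    "political_interest": ("ordinal", (0.25, 0.45, 0.25, 0.05)),
}

DEFAULT_MISSING_RATES = {
    "income": 0.20,
    "wage": 0.15,
    "physician_visits": 0.10,
    "risk_taking": 0.08,
    "housework": 0.05,
    "childcare": 0.05,
    "political_interest": 0.03,
    "education": 0.02,
    "sexual_orientation": 0.153,
    "partner": 0.029,
}

PROTECTED_COLUMNS = {"person_id", "wave", "sex"}


@dataclass
class SyntheticConfig:
    n_persons: int = 5000
    waves: tuple[int, ...] = tuple(range(2009, 2023))
    health_waves: tuple[int, ...] = (2011, 2013, 2015, 2017, 2019, 2021)
    sex_prevalence: float = 0.499          # share assigned female at birth
    gender_shift: float = 1.0              # latent mean female - male
    loadings: dict = field(default_factory=lambda: dict(DEFAULT_LOADINGS))
    indicator_noise_sd: float = 1.0
    indicator_types: dict = field(
        default_factory=lambda: dict(DEFAULT_INDICATOR_TYPES))
    covariate_effects: dict = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_EFFECTS))
    structural_effects: dict = field(
        default_factory=lambda: dict(DEFAULT_STRUCTURAL))
    prevalent_rates: dict = field(
        default_factory=lambda: {"migraine": 0.06, "stroke": 0.02})
    missing_rates: dict = field(default_factory=dict)
    partner_rate: float = 0.551
    children_probs: tuple[float, ...] = (0.690, 0.142, 0.169)
    east_rate: float = 0.21
    bi_homo_rate: float = 0.022
    immigration_probs: tuple[float, ...] = (0.725, 0.063, 0.213)  # none/indirect/direct
    smoking_rates: tuple[float, float] = (0.453, 0.339)           # male, female
    hypertension_rates: tuple[float, float] = (0.284, 0.259)
    diabetes_rates: tuple[float, float] = (0.089, 0.076)
    age_range: tuple[int, int] = (18, 80)
    weight_sigma: float = 0.5
    zero_weight_fraction: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        for name, p in [("sex_prevalence", self.sex_prevalence),
                        ("partner_rate", self.partner_rate),
                        ("east_rate", self.east_rate),
                        ("bi_homo_rate", self.bi_homo_rate),
                        ("zero_weight_fraction", self.zero_weight_fraction)]:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name}={p} outside [0, 1]")
        if set(self.health_waves) - set(self.waves):
            raise ValueError("health_waves must be a subset of waves")
        for probs in (self.children_probs, self.immigration_probs):
            # printed percentages may carry rounding slack
            if abs(sum(probs) - 1.0) > 5e-3:
                raise ValueError("category probabilities must sum to 1")
        for var, rate in self.missing_rates.items():
            if not 0.0 <= rate <= 0.245:
                raise ValueError(
                    f"missing rate for {var!r} is {rate}; allowed range [0, 0.245]")
        unknown = set(self.loadings) - set(DEFAULT_INDICATORS)
        if unknown:
            raise ValueError(f"loadings for unknown indicators: {sorted(unknown)}")


def _threshold(index: np.ndarray, kind: str, probs: tuple[float, ...],
               ) -> np.ndarray:
    """Discretize a Gaussian index by its empirical quantiles so the marginal
    category frequencies hit the requested targets."""
    if kind == "binary":
        cut = np.quantile(index, 1.0 - probs[0])
        return (index > cut).astype(float)
    cuts = np.quantile(index, np.cumsum(probs[:-1]))
    return np.searchsorted(cuts, index, side="right").astype(float)


def generate_panel(config: SyntheticConfig) -> tuple[pd.DataFrame, dict]:
    """Generate a long person-wave panel and its ground-truth sidecar.

    Identical ``(config, seed)`` yields identical output.  Raises if the
    linear-probability outcome law implies a probability outside ``[0, 1]``
    for any person (out-of-range probabilities are a configuration error, not
    something to truncate silently).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_persons
    waves = np.asarray(sorted(config.waves))
    health_waves = np.asarray(sorted(config.health_waves))

    female = rng.random(n) < config.sex_prevalence
    age0 = rng.integers(config.age_range[0], config.age_range[1] + 1, size=n)
    imm_p = np.asarray(config.immigration_probs) / sum(config.immigration_probs)
    immigration = rng.choice(
        np.array(["none", "indirect", "direct"]), size=n, p=imm_p)
    east = (rng.random(n) < config.east_rate).astype(int)
    partner = (rng.random(n) < config.partner_rate).astype(int)
    kid_p = np.asarray(config.children_probs) / sum(config.children_probs)
    children_n = rng.choice(np.arange(3), size=n, p=kid_p)
    bi_homo = (rng.random(n) < config.bi_homo_rate).astype(int)

    gender = config.gender_shift * female + rng.standard_normal(n)

    age10 = age0 / 10.0
    covariates = {
        "children": children_n.astype(float),
        "partner": partner.astype(float),
        "east": east.astype(float),
        "age10": age10,
    }
    indicators: dict[str, np.ndarray] = {}
    for ind in DEFAULT_INDICATORS:
        lam = config.loadings.get(ind, 0.0)
        val = lam * gender + config.indicator_noise_sd * rng.standard_normal(n)
        for (tgt, cov), beta in config.covariate_effects.items():
            if tgt == ind:
                val = val + beta * covariates[cov]
        if ind in config.indicator_types:
            kind, probs = config.indicator_types[ind]
            val = _threshold(val, kind, probs)
        indicators[ind] = val

    sex_rate = {"smoking": config.smoking_rates,
                "hypertension": config.hypertension_rates,
                "diabetes": config.diabetes_rates}
    risk_has = {}
    risk_onset = {}
    for rf, (rate_m, rate_f) in sex_rate.items():
        has = rng.random(n) < np.where(female, rate_f, rate_m)
        onset = rng.integers(2002, 2010, size=n)  # always before follow-up
        risk_has[rf] = has
        risk_onset[rf] = np.where(has, onset, -1)

    # outcomes: person-level cumulative incidence, linear in the effects
    predictor_values = {
        "intercept": np.ones(n),
        "sex": female.astype(float),
        "gender": gender,
        "partner": partner.astype(float),
        "sexual_orientation": bi_homo.astype(float),
        "age10": age10,
        "smoking": risk_has["smoking"].astype(float),
        "hypertension": risk_has["hypertension"].astype(float),
        "diabetes": risk_has["diabetes"].astype(float),
    }
    truth_person = {
        "person_id": np.arange(n),
        "sex": np.where(female, "female", "male"),
        "gender_true": gender,
    }
    outcome_names = sorted({o for o, _ in config.structural_effects})
    incident_wave = {}
    prevalent = {}
    for out in outcome_names:
        p = np.zeros(n)
        for (o, pred), beta in config.structural_effects.items():
            if o == out:
                if pred not in predictor_values:
                    raise ValueError(f"unknown outcome predictor {pred!r}")
                p = p + beta * predictor_values[pred]
        if (p < 0).any() or (p > 1).any():
            bad = int(((p < 0) | (p > 1)).sum())
            raise ValueError(
                f"implied {out} probability outside [0, 1] for {bad} persons; "
                "adjust intercepts/effects")
        prev = rng.random(n) < config.prevalent_rates.get(out, 0.0)
        inc = (rng.random(n) < p) & ~prev
        # an incident case needs an observable prior "no": switch waves start
        # at the second health wave
        if len(health_waves) < 2:
            raise ValueError("need at least two health waves for incidence")
        wave_pick = health_waves[1:][rng.integers(0, len(health_waves) - 1, size=n)]
        incident_wave[out] = np.where(inc, wave_pick, -1)
        prevalent[out] = prev
        truth_person[f"{out}_prob"] = p
        truth_person[f"{out}_prevalent"] = prev
        truth_person[f"{out}_incident_wave"] = incident_wave[out]
    for rf in sex_rate:
        truth_person[f"{rf}_flag"] = risk_has[rf]
        truth_person[f"{rf}_onset"] = risk_onset[rf]

    # expand to long format
    W = len(waves)
    pid = np.repeat(np.arange(n), W)
    wave_col = np.tile(waves, n)
    rows = {
        "person_id": pid,
        "wave": wave_col,
        "sex": np.repeat(np.where(female, "female", "male"), W),
        "age": np.repeat(age0, W) + (wave_col - waves[0]),
        "immigration": np.repeat(immigration, W),
        "east": np.repeat(east, W),
        "partner": np.repeat(partner, W),
        "children": np.repeat(
            np.array(["none", "single", "multiple"])[children_n], W),
        "sexual_orientation": np.repeat(
            np.where(bi_homo == 1, "probably bi- or homosexual",
                     "probably heterosexual"), W),
    }
    for ind in DEFAULT_INDICATORS:
        rows[ind] = np.repeat(indicators[ind], W)
    for rf in sex_rate:
        onset_rep = np.repeat(risk_onset[rf], W)
        rows[rf] = ((onset_rep >= 0) & (wave_col >= np.maximum(onset_rep, waves[0]))
                    ).astype(int)
    is_health = np.isin(wave_col, health_waves)
    for out in outcome_names:
        prev_rep = np.repeat(prevalent[out], W)
        inc_rep = np.repeat(incident_wave[out], W)
        resp = np.where(prev_rep, 1.0,
                        ((inc_rep >= 0) & (wave_col >= inc_rep)).astype(float))
        resp = np.where(is_health, resp, np.nan)
        rows[out] = resp

    weight = np.exp(config.weight_sigma * rng.standard_normal(n * W))
    zero_w = np.repeat(rng.random(n) < config.zero_weight_fraction, W)
    weight[zero_w] = 0.0
    rows["weight"] = weight

    panel = pd.DataFrame(rows)
    truth = {
        "persons": pd.DataFrame(truth_person),
        "config": asdict(config),
    }
    return panel, truth


def inject_missingness(
    panel: pd.DataFrame, config: SyntheticConfig,
) -> pd.DataFrame:
    """Blank values under a missing-at-random mechanism.

    The blanking probability for each cell depends only on always-observed
    variables (age, sex, wave) through a logistic model whose intercept is
    calibrated by bisection so the mean blanking probability equals the
    requested rate.  Keys (person id, wave) and sex are never blanked.
    """
    for var, rate in config.missing_rates.items():
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"missing rate for {var!r} outside [0, 1]")
        if var in PROTECTED_COLUMNS:
            raise ValueError(f"refusing to blank key variable {var!r}")
        if var not in panel.columns:
            raise ValueError(f"unknown variable {var!r}")
    out = panel.copy()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 104729]))
    z_age = (out["age"].to_numpy(float) - out["age"].mean()) / max(out["age"].std(), 1e-9)
    female = (out["sex"] == "female").to_numpy(float)
    z_wave = (out["wave"] - out["wave"].mean()) / max(out["wave"].std(), 1e-9)
    lin = 0.3 * z_age + 0.2 * female + 0.1 * z_wave

    def mean_p(alpha):
        return float(np.mean(1.0 / (1.0 + np.exp(-(alpha + lin)))))

    for var, rate in config.missing_rates.items():
        if rate <= 0.0:
            continue
        lo, hi = -20.0, 20.0
        for _ in range(80):
            mid = (lo + hi) / 2.0
            if mean_p(mid) < rate:
                lo = mid
            else:
                hi = mid
        p = 1.0 / (1.0 + np.exp(-((lo + hi) / 2.0 + lin)))
        blank = rng.random(len(out)) < p
        if out[var].dtype == object:
            out.loc[blank, var] = None
        else:
            out[var] = out[var].astype(float)
            out.loc[blank, var] = np.nan
    return out


def write_panel(panel: pd.DataFrame, truth: dict, prefix: str) -> None:
    """Write the panel as CSV plus a JSON truth sidecar."""
    panel.to_csv(f"{prefix}_panel.csv", index=False)
    config = {
        k: ({"->".join(kk): vv for kk, vv in v.items()}
            if isinstance(v, dict) and any(isinstance(kk, tuple) for kk in v)
            else v)
        for k, v in truth["config"].items()
    }
    sidecar = {
        "config": config,
        "persons": truth["persons"].to_dict(orient="list"),
    }
    with open(f"{prefix}_truth.json", "w") as fh:
        json.dump(sidecar, fh, default=lambda o: o.item() if hasattr(o, "item") else list(o))
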
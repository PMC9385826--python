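"""Synthetic cohorts with the statistical structure the evaluation assumes.

No patient-level data from scenario-based prognosis studies is publicly
deposited, so every downstream computation is exercised on simulated
cohorts built here.  The generator emulates a prognosis-consultation
study cohort:

* the clinician's estimated median survival (EST) is log-uniform over
  2-96 months;
* true survival is drawn from a parametric family (log-normal by
  default) whose median equals EST times a calibration bias factor
  (1 = perfectly calibrated clinician).  The default log-normal sigma,
  ln 2 / Phi^-1(0.75) ~ 1.0276, puts exactly half the mass in the
  most-likely band (0.5x to 2x the median), making the headline band
  probability analytic;
* observation is administratively censored at a single horizon when one
  is set; a small fraction of records lose their survival data entirely
  (emulating incomplete follow-up);
* questionnaire agreement is Bernoulli per question, with a log-odds
  hope effect raising agreement with the primary "helpful" item for
  patients whose hope score lies above the sample median;
* instrument item vectors are constructed to sum exactly to a per-patient
  target score drawn around the configured medians (13 anxiety / 38
  hope / 16 optimism).

:func:`oracle` returns the exact analytic band probabilities for each
survival family, the independent check for the Kaplan-Meier pipeline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import stats

from .cohort import PatientRecord, write_cohort
from .instruments import InstrumentDefinition, load_definitions

__all__ = [
    "SimulationConfig",
    "DEFAULT_SIGMA",
    "simulate",
    "simulate_to_csv",
    "oracle",
]

#: log-normal sigma for which P(0.5 M <= T <= 2 M) is exactly 0.5
DEFAULT_SIGMA = math.log(2) / stats.norm.ppf(0.75)

_CANCER_TYPES = {
    "pancreatic": 34, "nsclc": 34, "colorectal": 26, "prostate": 25,
    "breast": 19, "kidney": 17, "other": 67,
}
_ECOG = {0: 46, 1: 130, 2: 43, 3: 3}
_EDUCATION = {"year10_or_less": 58, "highschool_or_above": 81, "unknown": 7}
_TIME_FROM_DX = {"le_8_weeks": 99, "gt_8_weeks": 123}
_CONSULTATION = {"initial": 65, "second": 26, "third_or_later": 131}

#: marginal agreement probabilities for the non-primary questionnaire items
_QUESTIONNAIRE = {
    "makes_sense": 0.96, "helps_plans": 0.88, "gives_hope": 0.56,
    "reassures": 0.64, "improves_understanding": 0.88,
    "worried_anxious": 0.30, "upsets": 0.41,
    "useful_family": 0.75, "useful_doctor": 0.90,
}


@dataclass
class SimulationConfig:
    """Study conditions for one simulated cohort."""

    n_patients: int = 222
    est_min: float = 2.0
    est_max: float = 96.0
    survival_family: str = "lognormal"  # lognormal | exponential | weibull
    lognormal_sigma: float = DEFAULT_SIGMA
    weibull_shape: float = 1.5
    #: true survival median = EST * median_bias (1 = calibrated clinician)
    median_bias: float = 1.0
    censor_horizon_months: float | None = None
    #: fraction of patients with survival follow-up lost entirely
    survival_missing_rate: float = 7 / 222
    #: fraction of patients who never return a questionnaire
    questionnaire_nonresponse_rate: float = 1 - 146 / 222
    #: per-item missingness among returned questionnaires
    likert_missing_rate: float = 0.03
    #: baseline P(agree "helpful") for patients at-or-below the median
    #: hope score
    helpful_baseline: float = 58 / 68
    #: log-odds increase in agreeing "helpful" for above-median hope
    hope_effect_logodds: float = math.log(5.7)
    questionnaire_model: dict[str, float] = field(
        default_factory=lambda: dict(_QUESTIONNAIRE))
    #: target medians for (stai6, hhi, lotr) scores
    instrument_medians: tuple[int, int, int] = (13, 38, 16)
    instrument_spread: float = 3.5

    def __post_init__(self) -> None:
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        if not 0 < self.est_min < self.est_max:
            raise ValueError("EST bounds must satisfy 0 < est_min < est_max")
        if self.survival_family not in ("lognormal", "exponential", "weibull"):
            raise ValueError(
                f"unsupported survival family {self.survival_family!r}")
        if self.lognormal_sigma <= 0 or self.weibull_shape <= 0:
            raise ValueError("distribution shape parameters must be positive")
        if self.median_bias <= 0:
            raise ValueError("median_bias must be positive")
        for name in ("survival_missing_rate", "questionnaire_nonresponse_rate",
                     "likert_missing_rate", "helpful_baseline"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        defs = load_definitions()
        for (iid, d), med in zip(
                ((i, defs[i]) for i in ("stai6", "hhi", "lotr")),
                self.instrument_medians):
            if not d.score_min <= med <= d.score_max:
                raise ValueError(
                    f"target median {med} unattainable for {iid} "
                    f"(range {d.score_min}-{d.score_max})")


def _sample_categorical(rng, weights: dict, size: int) -> np.ndarray:
    keys = list(weights)
    p = np.array([weights[k] for k in keys], dtype=float)
    return rng.choice(np.array(keys, dtype=object), size=size, p=p / p.sum())


def _survival_times(rng, cfg: SimulationConfig, medians: np.ndarray
                    ) -> np.ndarray:
    n = len(medians)
    if cfg.survival_family == "lognormal":
        return medians * np.exp(cfg.lognormal_sigma * rng.standard_normal(n))
    if cfg.survival_family == "exponential":
        return rng.exponential(scale=medians / math.log(2))
    k = cfg.weibull_shape
    scale = medians / math.log(2) ** (1 / k)
    return scale * rng.weibull(k, size=n)


def _items_for_score(rng, d: InstrumentDefinition, score: int
                     ) -> list[int | None]:
    """A random response vector whose total equals ``score`` exactly."""
    scored = sorted(d.scored_items)
    k = len(scored)
    extra = score - k * d.scale_min
    caps = [d.scale_max - d.scale_min] * k
    alloc = rng.multivariate_hypergeometric(caps, extra)
    items: list[int | None] = [None] * d.n_items
    for idx, add in zip(scored, alloc):
        contribution = d.scale_min + int(add)
        if idx in d.reverse_items:
            items[idx - 1] = d.scale_min + d.scale_max - contribution
        else:
            items[idx - 1] = contribution
    for idx in range(1, d.n_items + 1):  # fillers
        if idx not in d.scored_items:
            items[idx - 1] = int(rng.integers(d.scale_min, d.scale_max + 1))
    return items


def _target_scores(rng, d: InstrumentDefinition, median: int, spread: float,
                   n: int) -> np.ndarray:
    raw = np.rint(median + spread * rng.standard_normal(n))
    return np.clip(raw, d.score_min, d.score_max).astype(int)


def simulate(config: SimulationConfig | None = None, seed: int = 0
             ) -> list[PatientRecord]:
    """Generate one cohort; fully reproducible from the seed."""
    cfg = config or SimulationConfig()
    rng = np.random.default_rng(seed)
    n = cfg.n_patients
    defs = load_definitions()

    age = np.clip(np.rint(67 + 12 * rng.standard_normal(n)), 27, 90).astype(int)
    sex = np.where(rng.random(n) < 0.61, "male", "female")
    cancer = _sample_categorical(rng, _CANCER_TYPES, n)
    ecog = _sample_categorical(rng, _ECOG, n).astype(int)
    education = _sample_categorical(rng, _EDUCATION, n)
    tfd = _sample_categorical(rng, _TIME_FROM_DX, n)
    consult = _sample_categorical(rng, _CONSULTATION, n)

    est = np.exp(rng.uniform(math.log(cfg.est_min), math.log(cfg.est_max), n))
    true_surv = _survival_times(rng, cfg, est * cfg.median_bias)
    if cfg.censor_horizon_months is None:
        ost = true_surv
        died = np.ones(n, dtype=bool)
    else:
        h = cfg.censor_horizon_months
        died = true_surv <= h
        ost = np.where(died, true_surv, h)
    surv_missing = rng.random(n) < cfg.survival_missing_rate

    # instrument target scores; the hope (hhi) median split drives the
    # "helpful" agreement model
    targets = {}
    for iid, med in zip(("stai6", "hhi", "lotr"), cfg.instrument_medians):
        targets[iid] = _target_scores(rng, defs[iid], med,
                                      cfg.instrument_spread, n)
    hhi_scores = targets["hhi"]
    hope_above = hhi_scores > np.median(hhi_scores)

    base_logit = math.log(cfg.helpful_baseline / (1 - cfg.helpful_baseline))
    p_helpful = 1 / (1 + np.exp(-(base_logit
                                  + cfg.hope_effect_logodds * hope_above)))
    no_questionnaire = rng.random(n) < cfg.questionnaire_nonresponse_rate

    def draw_likert(p_agree: float) -> str:
        if rng.random() < p_agree:
            return "strongly_agree" if rng.random() < 0.5 else "agree"
        u = rng.random()
        return "unsure" if u < 0.5 else ("disagree" if u < 0.8
                                         else "strongly_disagree")

    records: list[PatientRecord] = []
    for i in range(n):
        likert: dict[str, str | None] = {}
        instruments: dict[str, list[int | None]] = {}
        if no_questionnaire[i]:
            for q in ("helpful", *cfg.questionnaire_model):
                likert[q] = None
            for iid in targets:
                instruments[iid] = [None] * defs[iid].n_items
        else:
            for q, p in (("helpful", p_helpful[i]),
                         *cfg.questionnaire_model.items()):
                if rng.random() < cfg.likert_missing_rate:
                    likert[q] = None
                else:
                    likert[q] = draw_likert(p)
            for iid in targets:
                instruments[iid] = _items_for_score(
                    rng, defs[iid], int(targets[iid][i]))
        records.append(PatientRecord(
            patient_id=f"P{i + 1:05d}",
            age_years=int(age[i]),
            sex=str(sex[i]),
            cancer_type=str(cancer[i]),
            ecog=int(ecog[i]),
            education=str(education[i]),
            time_from_diagnosis=str(tfd[i]),
            consultation_number=str(consult[i]),
            est_months=float(est[i]),
            ost_months=None if surv_missing[i] else float(ost[i]),
            event=None if surv_missing[i] else (
                "died" if died[i] else "alive_censored"),
            likert_responses=likert,
            instrument_items=instruments,
        ))
    return records


def simulate_to_csv(path, config: SimulationConfig | None = None,
                    seed: int = 0) -> list[PatientRecord]:
    """Simulate and write the cohort CSV with a provenance header."""
    cfg = config or SimulationConfig()
    records = simulate(cfg, seed=seed)
    with open(path, "w", newline="") as fh:
        fh.write(f"# threescenarios-simulation seed={seed}\n")
        for k, v in asdict(cfg).items():
            fh.write(f"# {k}={v!r}\n")
        write_cohort(records, fh)
    return records


def _distribution(family: str, median: float, sigma: float = DEFAULT_SIGMA,
                  weibull_shape: float = 1.5):
    if family == "lognormal":
        return stats.lognorm(s=sigma, scale=median)
    if family == "exponential":
        return stats.expon(scale=median / math.log(2))
    if family == "weibull":
        return stats.weibull_min(
            c=weibull_shape,
            scale=median / math.log(2) ** (1 / weibull_shape))
    raise ValueError(f"unsupported survival family {family!r}")


def oracle(family: str, lower: float | None, upper: float | None,
           median: float = 1.0, sigma: float = DEFAULT_SIGMA,
           weibull_shape: float = 1.5) -> float:
    """Exact analytic band probability P(lower <= T <= upper).

    The distribution is continuous, so closed vs open endpoints are
    immaterial.  ``lower=None`` / ``upper=None`` extend the band to 0 /
    infinity.  The band bounds are absolute times, on the same scale as
    ``median``; pass ``median=1`` to work on the ratio scale.
    """
    dist = _distribution(family, median, sigma, weibull_shape)
    hi = 1.0 if upper is None else float(dist.cdf(upper))
    lo = 0.0 if lower is None else float(dist.cdf(lower))
    if upper is not None and lower is not None and upper < lower:
        raise ValueError(f"band bounds out of order: ({lower}, {upper})")
    return hi - lo
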
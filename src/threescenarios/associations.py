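"""Agreement summaries, univariable odds ratios, and the design-stage
sample-size calculation.

Likert responses are collapsed to agreement (agree + strongly agree) over
all non-missing responses; proportions get Wilson score intervals.
Associations between baseline characteristics and agreement are
unadjusted 2x2 odds ratios with Wald intervals and p-values — for a
saturated univariable logistic regression these closed forms equal the
model-based estimates exactly.  Multi-level covariates additionally get
an overall likelihood-ratio (G) test of independence across levels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .cohort import LIKERT_LEVELS, PatientRecord

__all__ = [
    "AgreementSummary",
    "ContingencyResult",
    "VariableAssociation",
    "collapse_agreement",
    "wilson_interval",
    "odds_ratio_2x2",
    "association_from_levels",
    "variable_association",
    "agreement_summary",
    "agreement_table",
    "required_sample_size",
    "format_or",
    "age_band",
    "est_band",
]

AGREE_LEVELS = frozenset({"agree", "strongly_agree"})


def collapse_agreement(responses) -> tuple[int, int]:
    """(numerator, denominator): agree/strongly-agree over non-missing.

    "unsure" counts in the denominator but not the numerator; missing
    (None or empty) responses count in neither.
    """
    num = den = 0
    for r in responses:
        if r is None or r == "" or r == "missing":
            continue
        if r not in LIKERT_LEVELS:
            raise ValueError(f"invalid Likert level {r!r}")
        den += 1
        if r in AGREE_LEVELS:
            num += 1
    return num, den


def wilson_interval(numerator: int, denominator: int,
                    confidence: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion."""
    if denominator <= 0:
        raise ValueError("Wilson interval undefined for zero denominator")
    if not 0 <= numerator <= denominator:
        raise ValueError(
            f"numerator {numerator} outside [0, {denominator}]")
    lo, hi = proportion_confint(numerator, denominator,
                                alpha=1 - confidence, method="wilson")
    # the closed form gives exactly 0 / 1 at the boundaries; clip the
    # floating-point residue
    return (max(float(lo), 0.0), min(float(hi), 1.0))


@dataclass(frozen=True)
class AgreementSummary:
    """Agreement proportion for one questionnaire item."""

    question_id: str
    numerator: int
    denominator: int

    @property
    def proportion(self) -> float | None:
        return (self.numerator / self.denominator
                if self.denominator else None)

    @property
    def ci(self) -> tuple[float, float] | None:
        if not self.denominator:
            return None
        return wilson_interval(self.numerator, self.denominator)

    def formatted(self) -> str:
        if not self.denominator:
            return f"{self.question_id}: no responses"
        lo, hi = self.ci
        return (f"{self.question_id}: {self.numerator}/{self.denominator} "
                f"({round(100 * self.proportion)}) "
                f"{round(100 * lo)}-{round(100 * hi)}")


def agreement_summary(question_id: str, responses) -> AgreementSummary:
    num, den = collapse_agreement(responses)
    return AgreementSummary(question_id, num, den)


def agreement_table(records: list[PatientRecord],
                    question_ids: list[str] | None = None) -> pd.DataFrame:
    """Per-question agreement proportions with Wilson CIs, as a table."""
    if question_ids is None:
        question_ids = sorted({q for r in records for q in r.likert_responses})
    rows = []
    for q in question_ids:
        s = agreement_summary(
            q, (r.likert_responses.get(q) for r in records))
        ci = s.ci
        rows.append({
            "question_id": q,
            "numerator": s.numerator,
            "denominator": s.denominator,
            "proportion": s.proportion,
            "percent": (round(100 * s.proportion)
                        if s.denominator else None),
            "ci_low": ci[0] if ci else None,
            "ci_high": ci[1] if ci else None,
        })
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ContingencyResult:
    """Unadjusted 2x2 odds ratio for one exposure level vs reference.

    Cells: a = exposed & agree, b = exposed & disagree,
    c = reference & agree, d = reference & disagree.  Any zero cell
    leaves the OR, CI and p undefined (None) — reported as NA, no
    continuity correction.
    """

    exposure_label: str
    reference_label: str
    a: int
    b: int
    c: int
    d: int
    odds_ratio: float | None
    ci_low: float | None
    ci_high: float | None
    p_value: float | None

    @property
    def defined(self) -> bool:
        return self.odds_ratio is not None


def odds_ratio_2x2(a: int, b: int, c: int, d: int,
                   exposure_label: str = "exposed",
                   reference_label: str = "reference",
                   confidence: float = 0.95) -> ContingencyResult:
    """Wald odds ratio for a 2x2 table.

    OR = ad/bc; CI = exp(ln OR +- z * sqrt(1/a + 1/b + 1/c + 1/d));
    two-sided p from the Wald z of ln OR.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("cell counts must be non-negative")
    if min(a, b, c, d) == 0:
        return ContingencyResult(exposure_label, reference_label,
                                 a, b, c, d, None, None, None, None)
    orr = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = stats.norm.ppf(0.5 + confidence / 2)
    log_or = math.log(orr)
    p = 2 * stats.norm.sf(abs(log_or) / se)
    return ContingencyResult(
        exposure_label, reference_label, a, b, c, d,
        odds_ratio=orr,
        ci_low=math.exp(log_or - z * se),
        ci_high=math.exp(log_or + z * se),
        p_value=float(p),
    )


def _lr_test_independence(table: np.ndarray) -> float:
    """Likelihood-ratio (G) test of independence on a levels x 2 table."""
    t = np.asarray(table, dtype=float)
    n = t.sum()
    expected = np.outer(t.sum(axis=1), t.sum(axis=0)) / n
    with np.errstate(divide="ignore", invalid="ignore"):
        g = 2 * np.where(t > 0, t * np.log(t / expected), 0.0).sum()
    df = (t.shape[0] - 1) * (t.shape[1] - 1)
    return float(stats.chi2.sf(g, df))


@dataclass
class VariableAssociation:
    """Per-level odds ratios vs the reference plus an overall p."""

    covariate: str
    reference_label: str
    results: list[ContingencyResult]
    overall_p: float | None
    reference_counts: tuple[int, int]  # (agree, disagree) in the reference

    def to_frame(self) -> pd.DataFrame:
        rows = [{
            "covariate": self.covariate, "level": self.reference_label,
            "agree": self.reference_counts[0],
            "disagree": self.reference_counts[1],
            "odds_ratio": None, "ci_low": None, "ci_high": None,
            "display": "ref", "overall_p": self.overall_p,
        }]
        for r in self.results:
            rows.append({
                "covariate": self.covariate, "level": r.exposure_label,
                "agree": r.a, "disagree": r.b,
                "odds_ratio": r.odds_ratio, "ci_low": r.ci_low,
                "ci_high": r.ci_high, "display": format_or(r),
                "overall_p": self.overall_p,
            })
        return pd.DataFrame(rows)


def association_from_levels(levels, responses, reference: str,
                            covariate: str = "covariate",
                            level_order: list[str] | None = None
                            ) -> VariableAssociation:
    """Univariable association of a categorical exposure with agreement.

    ``levels`` and ``responses`` are parallel per-patient sequences; a
    patient contributes only when both the level and the (Likert or
    boolean) response are non-missing.
    """
    counts: dict[str, list[int]] = {}
    for lv, resp in zip(levels, responses, strict=True):
        if lv is None or lv == "":
            continue
        if isinstance(resp, bool):
            agree = resp
        elif resp is None or resp == "" or resp == "missing":
            continue
        elif resp in LIKERT_LEVELS:
            agree = resp in AGREE_LEVELS
        else:
            raise ValueError(f"invalid response {resp!r}")
        cell = counts.setdefault(str(lv), [0, 0])
        cell[0 if agree else 1] += 1
    if reference not in counts:
        raise ValueError(
            f"reference level {reference!r} absent from the data "
            f"(observed levels: {sorted(counts)})")
    if len(counts) < 2:
        raise ValueError("covariate needs at least 2 observed levels")
    if level_order is None:
        level_order = sorted(lv for lv in counts if lv != reference)
    c, d = counts[reference]
    results = [
        odds_ratio_2x2(*counts[lv], c=c, d=d,
                       exposure_label=lv, reference_label=reference)
        for lv in level_order
    ]
    table = np.array([counts[reference]] + [counts[lv] for lv in level_order])
    overall_p = _lr_test_independence(table)
    return VariableAssociation(
        covariate=covariate, reference_label=reference, results=results,
        overall_p=overall_p, reference_counts=(c, d),
    )


def age_band(age_years: int) -> str:
    if age_years < 50:
        return "<50"
    if age_years <= 70:
        return "50-70"
    return ">70"


def est_band(est_months: float) -> str:
    if est_months < 9:
        return "<9 months"
    if est_months <= 15:
        return "9-15 months"
    return ">15 months"


_DERIVED = {"age_band": ("age_years", age_band),
            "est_band": ("est_months", est_band)}

_DEFAULT_REFERENCES = {
    "sex": "female",
    "education": "year10_or_less",
    "time_from_diagnosis": "le_8_weeks",
    "age_band": "<50",
    "est_band": "<9 months",
}


def variable_association(records: list[PatientRecord], covariate: str,
                         outcome: str, reference: str | None = None
                         ) -> VariableAssociation:
    """Association of one cohort field (or derived band) with agreement
    on a questionnaire item.

    ``covariate`` is a PatientRecord categorical field name or one of
    the derived groupings ``age_band`` / ``est_band``.
    """
    if covariate in _DERIVED:
        raw_field, fn = _DERIVED[covariate]
        levels = [fn(getattr(r, raw_field)) for r in records]
    else:
        levels = [getattr(r, covariate) for r in records]
        if covariate == "education":
            levels = [None if lv == "unknown" else lv for lv in levels]
    if reference is None:
        reference = _DEFAULT_REFERENCES.get(covariate)
        if reference is None:
            # most common level as reference
            vals = [lv for lv in levels if lv not in (None, "")]
            reference = max(set(vals), key=vals.count)
    responses = [r.likert_responses.get(outcome) for r in records]
    return association_from_levels(levels, responses, str(reference),
                                   covariate=covariate)


def format_or(result: ContingencyResult) -> str:
    """Display an OR row the way clinical tables print it: values < 1 at
    two decimals, 1-10 at one decimal, larger as whole numbers; halves
    round up."""
    if not result.defined:
        return "NA"

    def f(v: float) -> str:
        q = "0.01" if v < 1 else ("0.1" if v < 10 else "1")
        return str(Decimal(v).quantize(Decimal(q), rounding=ROUND_HALF_UP))

    return f"{f(result.odds_ratio)} ({f(result.ci_low)}-{f(result.ci_high)})"


def required_sample_size(p_low: float, p_high: float, power: float = 0.95,
                         alpha: float = 0.05, attrition: float = 0.0,
                         two_sided: bool = False) -> int:
    """Smallest n distinguishing two hypothetical true proportions.

    One-sample normal-approximation design for testing H0: p = p_low
    against H1: p = p_high:

        n0 = ((z_alpha * sqrt(p_low q_low) + z_power * sqrt(p_high q_high))
              / (p_high - p_low))**2

    rounded up, then inflated by 1/(1 - attrition) and rounded up again.
    """
    if not 0 < p_low < p_high < 1:
        raise ValueError(
            f"need 0 < p_low < p_high < 1, got ({p_low}, {p_high})")
    if not 0 <= attrition < 1:
        raise ValueError(f"attrition must be in [0, 1), got {attrition}")
    if not 0 < power < 1 or not 0 < alpha < 1:
        raise ValueError("power and alpha must be in (0, 1)")
    z_a = stats.norm.ppf(1 - (alpha / 2 if two_sided else alpha))
    z_b = stats.norm.ppf(power)
    n0 = ((z_a * math.sqrt(p_low * (1 - p_low))
           + z_b * math.sqrt(p_high * (1 - p_high)))
          / (p_high - p_low)) ** 2
    return math.ceil(math.ceil(n0) / (1 - attrition))
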
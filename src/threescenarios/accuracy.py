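"""Censoring-aware accuracy evaluation of survival estimates.

The evaluation's central quantity is the per-patient ratio of observed
to estimated survival time (OST/EST).  Patients alive at last follow-up
contribute a right-censored ratio, so all proportions are read off the
Kaplan-Meier (product-limit) distribution of the ratio rather than raw
counts.  The metrics are:

* calibration — P(ratio < 1) vs P(ratio > 1), each near 50% when the
  clinician's estimates are centrally unbiased;
* precision — P(0.67 <= ratio <= 1.33), observed survival within a third
  either side of the point estimate;
* scenario coverage — the mass of the ratio distribution falling in the
  worst-case (<= 0.25), most-likely (0.5 to 2) and best-case (>= 3)
  bands defined by the scenario multipliers.

Band probabilities honour closed/open endpoints exactly via left limits
of the survival function: for a closed band [a, b],
P(a <= R <= b) = S(a-) - S(b).

The model/results pair follows the usual fit-and-summarise pattern:
``RatioAccuracyModel(sample).fit()`` returns a
:class:`RatioAccuracyResults` carrying the six proportions with
confidence intervals, the fitted curve, ``summary()`` and ``plot()``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
from lifelines import KaplanMeierFitter
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .cohort import PatientRecord, RatioSample, build_ratio_sample
from .scenarios import DEFAULT_MULTIPLIERS, MultiplierConfig

__all__ = [
    "KMCurve",
    "km_fit",
    "km_prob_interval",
    "ProportionEstimate",
    "RatioAccuracyModel",
    "RatioAccuracyResults",
    "accuracy_report",
]


@dataclass
class KMCurve:
    """Product-limit survival estimate with risk sets and Greenwood terms.

    Arrays are aligned on the distinct event (death) times, in increasing
    order.  ``survival`` is the right-continuous step function value at
    each event time, S(0) = 1 before the first.  ``greenwood_terms`` holds
    the cumulative sum of d/(n(n-d)) used for Greenwood variances and
    covariances.
    """

    event_times: np.ndarray
    at_risk: np.ndarray
    deaths: np.ndarray
    survival: np.ndarray
    greenwood_terms: np.ndarray
    n_initial: int

    @property
    def greenwood_var(self) -> np.ndarray:
        """Greenwood variance of S at each event time."""
        return self.survival**2 * self.greenwood_terms

    def _idx_at(self, t: float) -> int:
        """Index of the last event time <= t, or -1 (S=1 region)."""
        return int(np.searchsorted(self.event_times, t, side="right")) - 1

    def _idx_before(self, t: float) -> int:
        """Index of the last event time strictly < t, or -1."""
        return int(np.searchsorted(self.event_times, t, side="left")) - 1

    def survival_at(self, t: float) -> float:
        """S(t), the probability of a ratio/time greater than t... right-
        continuous: includes any death mass exactly at t."""
        i = self._idx_at(t)
        return 1.0 if i < 0 else float(self.survival[i])

    def left_limit(self, t: float) -> float:
        """S(t-), the survival just below t (excludes mass exactly at t)."""
        i = self._idx_before(t)
        return 1.0 if i < 0 else float(self.survival[i])

    def _sv(self, t: float, left: bool) -> tuple[float, float]:
        """(S, cumulative Greenwood term) at t or t-."""
        i = self._idx_before(t) if left else self._idx_at(t)
        if i < 0:
            return 1.0, 0.0
        return float(self.survival[i]), float(self.greenwood_terms[i])


def km_fit(sample: RatioSample) -> KMCurve:
    """Fit the product-limit estimator to a censored ratio sample.

    Ties between deaths and censorings at the same value are resolved by
    processing deaths first (the standard convention).  Requires at least
    one observed death.
    """
    if len(sample) == 0:
        raise ValueError("cannot fit a Kaplan-Meier curve to an empty sample")
    if int(sample.events.sum()) == 0:
        raise ValueError(
            "cannot fit a Kaplan-Meier curve with zero observed events")
    kmf = KaplanMeierFitter()
    kmf.fit(sample.ratios, event_observed=sample.events)
    tbl = kmf.event_table
    ev = tbl[tbl["observed"] > 0]
    times = ev.index.to_numpy(dtype=float)
    deaths = ev["observed"].to_numpy(dtype=int)
    at_risk = ev["at_risk"].to_numpy(dtype=int)
    surv = (
        kmf.survival_function_.loc[ev.index, kmf.survival_function_.columns[0]]
        .to_numpy(dtype=float)
    )
    # cumulative d/(n(n-d)); the terminal n==d step sends S to 0 exactly,
    # where the variance is 0 by convention (the inf term never multiplies
    # a nonzero S^2)
    with np.errstate(divide="ignore"):
        terms = np.where(at_risk > deaths,
                         deaths / (at_risk * (at_risk - deaths)), np.inf)
    return KMCurve(
        event_times=times, at_risk=at_risk, deaths=deaths, survival=surv,
        greenwood_terms=np.cumsum(terms), n_initial=len(sample),
    )


def km_prob_interval(
    curve: KMCurve,
    lower: float | None = None,
    upper: float | None = None,
    closed_lower: bool = True,
    closed_upper: bool = True,
) -> float:
    """Probability mass the fitted distribution assigns to a band.

    ``lower=None`` means the band extends to 0; ``upper=None`` to
    infinity.  Closed endpoints include mass tied exactly at the
    endpoint (matching "<=" / ">=" band definitions); open endpoints
    exclude it.  A band outside the observed support returns 0 (or the
    boundary mass), never an error.
    """
    p, _ = _band_prob_var(curve, lower, upper, closed_lower, closed_upper)
    return p


def _band_prob_var(
    curve: KMCurve,
    lower: float | None,
    upper: float | None,
    closed_lower: bool = True,
    closed_upper: bool = True,
) -> tuple[float, float]:
    """Band probability and its Greenwood variance.

    P = S_a - S_b with S_a the survival entering the band (S(lower-) for
    a closed lower endpoint, S(lower) for open; 1 with no lower bound)
    and S_b the survival leaving it.  The variance uses
    Var(S_a - S_b) = S_a^2 C_a + S_b^2 C_b - 2 S_a S_b C_a with C the
    cumulative Greenwood sum — cov(S(s), S(t)) = S(s) S(t) C(s) for
    s <= t.  On uncensored data this reduces to binomial p(1-p)/n.
    """
    if lower is not None and upper is not None and not lower < upper:
        raise ValueError(f"band bounds out of order: ({lower}, {upper})")
    if lower is None:
        s_a, c_a = 1.0, 0.0
    else:
        s_a, c_a = curve._sv(lower, left=closed_lower)
    if upper is None:
        s_b, c_b = 0.0, 0.0
    else:
        s_b, c_b = curve._sv(upper, left=not closed_upper)
    if not math.isfinite(c_b):  # S_b == 0 terminal step
        c_b = 0.0
    if not math.isfinite(c_a):
        c_a = 0.0
    p = max(s_a - s_b, 0.0)
    var = s_a**2 * c_a + s_b**2 * c_b - 2 * s_a * s_b * c_a
    return p, max(var, 0.0)


@dataclass(frozen=True)
class ProportionEstimate:
    """A KM-derived proportion with a confidence interval."""

    value: float
    ci_low: float
    ci_high: float

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.value, self.ci_low, self.ci_high)


class RatioAccuracyModel:
    """Accuracy evaluation of clinician survival estimates.

    Parameters
    ----------
    sample:
        Censoring-aware sample of OST/EST ratios.
    precision_window:
        The (lower, upper) ratio window within which a point estimate
        counts as precise; default (0.67, 1.33).
    multipliers:
        Scenario multipliers defining the coverage bands; defaults to the
        standard 0.25 / 0.5–2 / 3 rules.
    """

    def __init__(
        self,
        sample: RatioSample,
        precision_window: tuple[float, float] = (0.67, 1.33),
        multipliers: MultiplierConfig = DEFAULT_MULTIPLIERS,
    ):
        if not 0 < precision_window[0] < precision_window[1]:
            raise ValueError(f"invalid precision window {precision_window}")
        self.sample = sample
        self.precision_window = (float(precision_window[0]),
                                 float(precision_window[1]))
        self.multipliers = multipliers

    @classmethod
    def from_records(cls, records: list[PatientRecord], **kwargs
                     ) -> "RatioAccuracyModel":
        return cls(build_ratio_sample(records), **kwargs)

    def fit(self, ci_method: str = "greenwood", alpha: float = 0.05
            ) -> "RatioAccuracyResults":
        """Fit the KM curve and evaluate all proportions.

        ``ci_method`` is "greenwood" (normal interval on the Greenwood
        standard error, truncated to [0, 1]) or "wilson" (Wilson score on
        an effective count of n_used successes).
        """
        if ci_method not in ("greenwood", "wilson"):
            raise ValueError(f"unknown ci_method {ci_method!r}")
        curve = km_fit(self.sample)
        m = self.multipliers
        z = stats.norm.ppf(1 - alpha / 2)
        n = curve.n_initial

        def est(lower, upper, closed_lower=True, closed_upper=True
                ) -> ProportionEstimate:
            p, var = _band_prob_var(curve, lower, upper,
                                    closed_lower, closed_upper)
            if ci_method == "greenwood":
                half = z * math.sqrt(var)
                lo, hi = max(p - half, 0.0), min(p + half, 1.0)
            else:
                lo, hi = proportion_confint(round(p * n), n, alpha=alpha,
                                            method="wilson")
            return ProportionEstimate(p, float(lo), float(hi))

        results = RatioAccuracyResults(
            model=self,
            curve=curve,
            p_ratio_below_1=est(None, 1.0, closed_upper=False),
            p_ratio_above_1=est(1.0, None, closed_lower=False),
            precision_proportion=est(*self.precision_window),
            worst_coverage=est(None, m.worst_upper_mult),
            ml_coverage=est(m.ml_lower_mult, m.ml_upper_mult),
            best_coverage=est(m.best_lower_mult, None),
            n_used=n,
            n_excluded=self.sample.excluded_count,
            ci_method=ci_method,
            alpha=alpha,
        )
        return results


@dataclass
class RatioAccuracyResults:
    """Fitted accuracy metrics; produced by :meth:`RatioAccuracyModel.fit`."""

    model: RatioAccuracyModel
    curve: KMCurve
    p_ratio_below_1: ProportionEstimate
    p_ratio_above_1: ProportionEstimate
    precision_proportion: ProportionEstimate
    worst_coverage: ProportionEstimate
    ml_coverage: ProportionEstimate
    best_coverage: ProportionEstimate
    n_used: int
    n_excluded: int
    ci_method: str
    alpha: float

    _LABELS = {
        "p_ratio_below_1": "Estimate longer than observed (ratio < 1)",
        "p_ratio_above_1": "Observed longer than estimate (ratio > 1)",
        "precision_proportion": "Precise point estimate",
        "worst_coverage": "Died within worst-case band",
        "ml_coverage": "Lived within most-likely band",
        "best_coverage": "Lived into best-case band",
    }

    def proportions(self) -> dict[str, ProportionEstimate]:
        return {k: getattr(self, k) for k in self._LABELS}

    def summary(self) -> str:
        m = self.model.multipliers
        w = self.model.precision_window
        bands = {
            "p_ratio_below_1": "ratio < 1",
            "p_ratio_above_1": "ratio > 1",
            "precision_proportion": f"{w[0]:g} <= ratio <= {w[1]:g}",
            "worst_coverage": f"ratio <= {m.worst_upper_mult:g}",
            "ml_coverage": f"{m.ml_lower_mult:g} <= ratio <= {m.ml_upper_mult:g}",
            "best_coverage": f"ratio >= {m.best_lower_mult:g}",
        }
        lines = [
            "Accuracy of estimated survival times (OST/EST ratio, "
            "Kaplan-Meier)",
            f"  n used = {self.n_used}, excluded (missing survival) = "
            f"{self.n_excluded}; CI: {self.ci_method}, "
            f"{100 * (1 - self.alpha):g}% level",
            "",
            f"  {'metric':44s} {'band':24s} {'%':>5s}  {'95% CI':>10s}",
        ]
        for key, label in self._LABELS.items():
            p = getattr(self, key)
            lines.append(
                f"  {label:44s} {bands[key]:24s} "
                f"{100 * p.value:5.1f}  {100 * p.ci_low:4.1f}-"
                f"{100 * p.ci_high:4.1f}"
            )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        out: dict = {
            "n_used": self.n_used,
            "n_excluded": self.n_excluded,
            "ci_method": self.ci_method,
            "alpha": self.alpha,
        }
        for key in self._LABELS:
            p = getattr(self, key)
            out[key] = {"value": p.value, "ci_low": p.ci_low,
                        "ci_high": p.ci_high}
        out["km_curve"] = {
            "ratio": self.curve.event_times.tolist(),
            "at_risk": self.curve.at_risk.tolist(),
            "deaths": self.curve.deaths.tolist(),
            "survival": self.curve.survival.tolist(),
        }
        return out

    def to_json(self, path=None, indent: int = 2) -> str:
        text = json.dumps(self.to_dict(), indent=indent, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    def plot(self, ax=None, log_x: bool = True):
        """Step plot of the KM distribution of the ratio (log-scaled axis)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        t = self.curve.event_times
        s = self.curve.survival
        xs = np.concatenate([[min(t[0] * 0.5, t[0])], t])
        ys = np.concatenate([[1.0], s])
        ax.step(xs, ys, where="post")
        if log_x:
            ax.set_xscale("log")
        for x in (self.model.multipliers.worst_upper_mult,
                  self.model.multipliers.ml_lower_mult, 1.0,
                  self.model.multipliers.ml_upper_mult,
                  self.model.multipliers.best_lower_mult):
            ax.axvline(x, color="grey", lw=0.6, ls=":")
        ax.set_xlabel("observed / estimated survival time")
        ax.set_ylabel("proportion with a larger ratio")
        ax.set_ylim(0, 1.02)
        return ax


def accuracy_report(
    sample: RatioSample,
    precision_window: tuple[float, float] = (0.67, 1.33),
    multipliers: MultiplierConfig = DEFAULT_MULTIPLIERS,
    ci_method: str = "greenwood",
) -> RatioAccuracyResults:
    """One-call evaluation: fit the KM curve and compute all metrics."""
    return RatioAccuracyModel(
        sample, precision_window=precision_window, multipliers=multipliers
    ).fit(ci_method=ci_method)
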
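"""Scenario bands for expected survival time.

A clinician's single estimate of "the median survival of a group of
similar patients" is converted into three scenarios by fixed multiples of
the estimate:

* worst-case:   shorter than 0.25 x median (approximates the 90th
  percentile of an overall-survival curve, i.e. the shortest ~10% of
  survival times);
* most likely:  0.5 x to 2 x median (approximately the inter-quartile
  range, 75th to 25th percentile);
* best-case:    3 x median or longer (approximates the 10th percentile,
  the longest ~10% of survival times).

The multiples are configurable so variant percentile approximations can
be explored; the defaults are the rules of thumb above.  A follow-up
contact schedule at fixed multiples of the estimate (0.25, 0.5, 1, 2,
3.3, 5) is derived the same way.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import yaml

__all__ = [
    "MultiplierConfig",
    "ScenarioSet",
    "compute_scenarios",
    "followup_schedule",
    "render_summary",
    "parse_summary",
    "format_duration",
    "DEFAULT_MULTIPLIERS",
]

#: months -> weeks conversion used only for display of short durations
WEEKS_PER_MONTH = 4.33


def _check_median(value: float) -> float:
    value = float(value)
    if not math.isfinite(value) or value <= 0:
        raise ValueError(
            f"estimated median survival must be a positive finite number "
            f"of months, got {value!r}"
        )
    return value


@dataclass(frozen=True)
class MultiplierConfig:
    """Multiples of the estimated median defining the scenario bands.

    ``worst_upper_mult`` is the upper bound of the worst-case band,
    ``ml_lower_mult``/``ml_upper_mult`` bound the most-likely band and
    ``best_lower_mult`` is the lower bound of the best-case band.
    ``followup_mults`` are the multiples of the estimate at which vital
    status is re-checked.
    """

    worst_upper_mult: float = 0.25
    ml_lower_mult: float = 0.5
    ml_upper_mult: float = 2.0
    best_lower_mult: float = 3.0
    followup_mults: tuple[float, ...] = (0.25, 0.5, 1.0, 2.0, 3.3, 5.0)

    def __post_init__(self) -> None:
        m = (self.worst_upper_mult, self.ml_lower_mult,
             self.ml_upper_mult, self.best_lower_mult)
        if not all(math.isfinite(x) for x in m):
            raise ValueError("multipliers must be finite")
        if not (0 < m[0] < m[1] < 1 < m[2] < m[3]):
            raise ValueError(
                "multipliers must satisfy 0 < worst_upper < ml_lower < 1 "
                f"< ml_upper < best_lower, got {m}"
            )
        f = tuple(float(x) for x in self.followup_mults)
        if not f or any(x <= 0 for x in f) or any(
                b <= a for a, b in zip(f, f[1:])):
            raise ValueError(
                "followup_mults must be positive and strictly increasing"
            )
        object.__setattr__(self, "followup_mults", f)

    @classmethod
    def from_yaml(cls, path) -> "MultiplierConfig":
        """Load a config from a YAML mapping; omitted keys keep defaults."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"multiplier config {path} must be a mapping")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown multiplier config keys: {sorted(unknown)}")
        if "followup_mults" in raw:
            raw["followup_mults"] = tuple(raw["followup_mults"])
        return cls(**raw)


DEFAULT_MULTIPLIERS = MultiplierConfig()


@dataclass(frozen=True)
class ScenarioSet:
    """The three survival scenarios anchored at an estimated median.

    All values are months.  The worst-case band is open above
    (``< worst_upper``), the most-likely band is closed
    (``[ml_lower, ml_upper]``) and the best-case band is closed below
    (``>= best_lower``).
    """

    median: float
    worst_upper: float
    ml_lower: float
    ml_upper: float
    best_lower: float

    def __post_init__(self) -> None:
        vals = (self.worst_upper, self.ml_lower, self.median,
                self.ml_upper, self.best_lower)
        if any(b <= a for a, b in zip(vals, vals[1:])):
            raise ValueError(f"scenario bounds out of order: {vals}")

    def as_dict(self) -> dict[str, float]:
        return {
            "median": self.median,
            "worst_upper": self.worst_upper,
            "ml_lower": self.ml_lower,
            "ml_upper": self.ml_upper,
            "best_lower": self.best_lower,
        }


def compute_scenarios(
    median_months: float,
    config: MultiplierConfig = DEFAULT_MULTIPLIERS,
) -> ScenarioSet:
    """Scale the estimated median into the three scenario bands.

    No rounding is applied here; display rounding happens only in
    :func:`render_summary`.
    """
    m = _check_median(median_months)
    return ScenarioSet(
        median=m,
        worst_upper=m * config.worst_upper_mult,
        ml_lower=m * config.ml_lower_mult,
        ml_upper=m * config.ml_upper_mult,
        best_lower=m * config.best_lower_mult,
    )


def followup_schedule(
    median_months: float,
    config: MultiplierConfig = DEFAULT_MULTIPLIERS,
) -> list[float]:
    """Calendar offsets (months) at which to update vital status."""
    m = _check_median(median_months)
    return [m * f for f in config.followup_mults]


def format_duration(months: float) -> str:
    """Human display of a duration: whole months at >= 3 months, whole
    weeks below that (so short bounds never display as "0 months")."""
    if months >= 3:
        return f"{math.floor(months + 0.5):d} months"
    weeks = math.floor(months * WEEKS_PER_MONTH + 0.5)
    return f"{weeks:d} weeks"


_NARRATIVES = {
    "most_likely": (
        "Most likely scenario",
        "About half of people in a similar situation ({frac}) would live "
        "for somewhere between {a} and {b}.",
    ),
    "best": (
        "Best-case scenario",
        "A small number of people in a similar situation ({frac}) would "
        "live longer than {a}, some considerably longer.",
    ),
    "worst": (
        "Worst-case scenario",
        "A small number of people in a similar situation ({frac}) would "
        "live less than {a}.",
    ),
}

_CAVEAT = (
    "These figures are estimates for groups of people in a similar "
    "situation; no one can say beforehand which scenario will apply to an "
    "individual person. They are intended to help with planning and "
    "should be revisited as circumstances change."
)

_BLOCK_BEGIN = "--- scenario-values ---"
_BLOCK_END = "--- end scenario-values ---"


def render_summary(
    scenario_set: ScenarioSet,
    patient_label: str = "",
    format: str = "text",
    schedule: list[float] | None = None,
    order: tuple[str, ...] = ("most_likely", "best", "worst"),
) -> str:
    """Render the one-page take-home summary.

    Deterministic: identical inputs give byte-identical output.  The
    rendered text ends with a machine-readable key=value block from which
    the unrounded :class:`ScenarioSet` can be recovered exactly
    (:func:`parse_summary`).
    """
    if format not in ("text", "markdown"):
        raise ValueError(f"unknown summary format: {format!r}")
    if set(order) != {"most_likely", "best", "worst"}:
        raise ValueError(f"order must be a permutation of the three scenarios, got {order}")
    s = scenario_set
    md = format == "markdown"

    def heading(text: str, level: int) -> list[str]:
        if md:
            return ["#" * level + " " + text, ""]
        underline = ("=" if level == 1 else "-") * len(text)
        return [text, underline, ""]

    lines: list[str] = []
    title = "Three scenarios for survival time"
    if patient_label:
        title += f" — {patient_label}"
    lines += heading(title, 1)
    lines.append(
        "Based on an estimated median survival of "
        f"{format_duration(s.median)} for a group of people in a similar "
        "situation, the three scenarios below describe the range of what "
        "might happen."
    )
    lines.append("")
    filled = {
        "most_likely": _NARRATIVES["most_likely"][1].format(
            frac="about 5 in 10",
            a=format_duration(s.ml_lower), b=format_duration(s.ml_upper)),
        "best": _NARRATIVES["best"][1].format(
            frac="about 1 in 10", a=format_duration(s.best_lower)),
        "worst": _NARRATIVES["worst"][1].format(
            frac="about 1 in 10", a=format_duration(s.worst_upper)),
    }
    for key in order:
        lines += heading(_NARRATIVES[key][0], 2)
        lines.append(filled[key])
        lines.append("")
    lines += heading("About these numbers", 2)
    lines.append(_CAVEAT)
    lines.append("")
    lines.append(_BLOCK_BEGIN)
    for k, v in s.as_dict().items():
        lines.append(f"{k}_months={v!r}")
    if schedule is not None:
        lines.append("schedule_months=" + ",".join(repr(x) for x in schedule))
    lines.append(_BLOCK_END)
    return "\n".join(lines) + "\n"


def parse_summary(text: str) -> tuple[ScenarioSet, list[float] | None]:
    """Recover the exact scenario values from a rendered summary."""
    m = re.search(
        re.escape(_BLOCK_BEGIN) + r"\n(.*?)" + re.escape(_BLOCK_END),
        text, re.S)
    if not m:
        raise ValueError("no machine-readable scenario block found")
    kv: dict[str, str] = {}
    for line in m.group(1).strip().splitlines():
        k, _, v = line.partition("=")
        kv[k] = v
    schedule = None
    if "schedule_months" in kv:
        schedule = [float(x) for x in kv.pop("schedule_months").split(",")]
    vals = {k.removesuffix("_months"): float(v) for k, v in kv.items()}
    return ScenarioSet(**vals), schedule
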
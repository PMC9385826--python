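"""Scoring of the patient-reported instruments and the median splits.

Three short instruments are supported out of the box — a six-item
state-anxiety short form (stai6), a 12-item hope index (hhi) and the
revised life-orientation test for optimism (lotr, 10 items of which 4
are unscored fillers).  Higher scores mean more anxiety, hope or
optimism respectively.  Scoring is the standard sum over scored items
with reverse-coded items mapped r -> min + max - r; any missing scored
item leaves the total missing.

Analyses dichotomise each score at the sample median.  The tie and
even-n conventions are explicit because published tables label the
reference group "below median": by default scores equal to the median
go to the "below" side, and for even n the median is the lower of the
two central order statistics (keeping the cut at an attainable integer
score).  Both are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import yaml

__all__ = [
    "InstrumentDefinition",
    "InstrumentScore",
    "MedianSplit",
    "load_definitions",
    "score_instrument",
    "reverse_score",
    "median_split",
]


@dataclass(frozen=True)
class InstrumentDefinition:
    """Scoring structure of one instrument."""

    instrument_id: str
    n_items: int
    scale_min: int
    scale_max: int
    reverse_items: frozenset[int]
    scored_items: frozenset[int]
    score_min: int
    score_max: int

    def __post_init__(self) -> None:
        all_items = frozenset(range(1, self.n_items + 1))
        if not self.scored_items <= all_items:
            raise ValueError(
                f"{self.instrument_id}: scored_items outside 1..{self.n_items}")
        if not self.reverse_items <= self.scored_items:
            raise ValueError(
                f"{self.instrument_id}: reverse_items must be scored items")
        k = len(self.scored_items)
        if (self.score_min, self.score_max) != (k * self.scale_min,
                                                k * self.scale_max):
            raise ValueError(
                f"{self.instrument_id}: score_range inconsistent with "
                f"{k} scored items on scale "
                f"[{self.scale_min}, {self.scale_max}]")


def _definition_from_mapping(instrument_id: str, raw: dict
                             ) -> InstrumentDefinition:
    n_items = int(raw["n_items"])
    lo, hi = (int(x) for x in raw["scale"])
    scored = frozenset(int(i) for i in raw.get(
        "scored_items", range(1, n_items + 1)))
    reverse = frozenset(int(i) for i in raw.get("reverse_items", ()))
    smin, smax = (int(x) for x in raw["score_range"])
    return InstrumentDefinition(
        instrument_id=instrument_id, n_items=n_items,
        scale_min=lo, scale_max=hi,
        reverse_items=reverse, scored_items=scored,
        score_min=smin, score_max=smax,
    )


def load_definitions(path=None) -> dict[str, InstrumentDefinition]:
    """Load instrument definitions from YAML (default: the shipped file)."""
    if path is None:
        text = (resources.files("threescenarios") / "data"
                / "instruments.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    return {iid: _definition_from_mapping(iid, mapping)
            for iid, mapping in raw.items()}


def reverse_score(value: int, definition: InstrumentDefinition) -> int:
    """Reverse-code a response; an involution on the item scale."""
    return definition.scale_min + definition.scale_max - value


@dataclass(frozen=True)
class InstrumentScore:
    instrument_id: str
    raw_score: int | None
    complete: bool


def score_instrument(definition: InstrumentDefinition,
                     items) -> InstrumentScore:
    """Total score of one response vector.

    ``items`` must have ``n_items`` entries (None for a missing item).
    Out-of-scale responses are rejected with their 1-based index; a
    missing scored item makes the total missing (fillers may be missing
    freely).
    """
    items = list(items)
    if len(items) != definition.n_items:
        raise ValueError(
            f"{definition.instrument_id}: expected {definition.n_items} "
            f"items, got {len(items)}")
    total = 0
    complete = True
    for idx, v in enumerate(items, start=1):
        if v is None:
            if idx in definition.scored_items:
                complete = False
            continue
        if not definition.scale_min <= v <= definition.scale_max:
            raise ValueError(
                f"{definition.instrument_id} item {idx}: response {v} "
                f"outside scale [{definition.scale_min}, "
                f"{definition.scale_max}]")
        if idx not in definition.scored_items:
            continue
        total += (reverse_score(v, definition)
                  if idx in definition.reverse_items else v)
    return InstrumentScore(definition.instrument_id,
                           total if complete else None, complete)


@dataclass
class MedianSplit:
    """Sample median and each patient's side of it.

    ``sides[i]`` is "below" / "above" for a complete score and None for
    a missing one.  ``degenerate`` flags an all-equal sample (empty
    "above" group).
    """

    median: float
    sides: list[str | None]
    n_below: int
    n_above: int
    degenerate: bool


def median_split(scores, ties_below: bool = True,
                 even_rule: str = "lower") -> MedianSplit:
    """Dichotomise scores at the sample median.

    ``scores`` may be numbers, None, or :class:`InstrumentScore`.
    ``even_rule`` is "lower" (lower central order statistic) or
    "midpoint" (their mean).
    """
    if even_rule not in ("lower", "midpoint"):
        raise ValueError(f"unknown even_rule {even_rule!r}")
    values: list[float | None] = []
    for s in scores:
        if isinstance(s, InstrumentScore):
            values.append(s.raw_score)
        else:
            values.append(s)
    complete = sorted(v for v in values if v is not None)
    if not complete:
        raise ValueError("median split needs at least one complete score")
    n = len(complete)
    if n % 2 == 1 or even_rule == "lower":
        med = float(complete[(n - 1) // 2])
    else:
        med = (complete[n // 2 - 1] + complete[n // 2]) / 2
    sides: list[str | None] = []
    for v in values:
        if v is None:
            sides.append(None)
        elif v < med or (ties_below and v == med):
            sides.append("below")
        else:
            sides.append("above")
    n_below = sides.count("below")
    n_above = sides.count("above")
    return MedianSplit(median=med, sides=sides, n_below=n_below,
                       n_above=n_above, degenerate=n_above == 0)
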
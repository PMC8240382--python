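"""Mapping observed climatic differences to viviparity hypotheses.

Three hypotheses compete to explain the evolution and maintenance of live
birth: the cold-climate hypothesis (CCH: viviparous populations sit in
colder climates), the maternal-manipulation hypothesis (MMH: viviparous
populations sit in less favourable climates - colder, warmer and/or more
variable), and the selfish-mother hypothesis (SMH: viviparous mothers avoid
risky, i.e. climatically variable, habitats and may prefer warmer ones).

Each hypothesis predicts a signed difference between viviparous and
oviparous populations in two variable families - climatic *variability*
(BIO2/BIO3/BIO4/BIO15) and *average temperature* (BIO1/BIO6/minTmax/
meanTmin).  The nine possible combinations of (variability difference,
average-temperature difference) each support a fixed set of hypothesis
predictions; this module holds that lookup and derives the observed
combination from a fitted classification tree's significant covariates.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import pandas as pd

from .bioclim import VARIABLE_CLASSES

__all__ = [
    "DifferencePattern",
    "PredictionCombination",
    "COMBINATION_TABLE",
    "classify_pattern",
    "supported_hypotheses",
]

#: enum values for a signed difference of viviparous relative to oviparous
UP, DOWN, NONE = "up_vivi", "down_vivi", "none"

_FOOTNOTES = {
    "a": (
        "if a hypothesis makes predictions on average temperature but not on "
        "variability (e.g. the CCH), combinations that include variance "
        "effects do not support it"
    ),
    "b": (
        "only if the negative effect of higher variability is smaller than "
        "the positive effect of increased temperature"
    ),
    "c": (
        "only if the negative effect of lower temperature is smaller than "
        "the positive effect of lower variability"
    ),
}


@dataclass(frozen=True)
class DifferencePattern:
    """Observed direction of viviparous-vs-oviparous climatic differences."""

    variability_diff: str  # up_vivi | down_vivi | none
    mean_temp_diff: str

    def __post_init__(self) -> None:
        for v in (self.variability_diff, self.mean_temp_diff):
            if v not in (UP, DOWN, NONE):
                raise ValueError(f"invalid pattern value {v!r}")


@dataclass(frozen=True)
class PredictionCombination:
    """One row of the 9-way combination table."""

    number: int
    pattern: DifferencePattern
    hypotheses: tuple[str, ...]  # subset of CCH/MMH/SMH, or empty
    predictions: tuple[str, ...]  # e.g. ("SMP_1",)
    footnotes: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "combination": self.number,
            "variability_diff": self.pattern.variability_diff,
            "mean_temp_diff": self.pattern.mean_temp_diff,
            "hypotheses": list(self.hypotheses),
            "predictions": list(self.predictions),
            "footnotes": {k: _FOOTNOTES[k] for k in self.footnotes},
        }


def _row(n, var, temp, hyps, preds, notes=()):
    return PredictionCombination(
        number=n,
        pattern=DifferencePattern(var, temp),
        hypotheses=tuple(hyps),
        predictions=tuple(preds),
        footnotes=tuple(notes),
    )


#: the nine (variability, average-temperature) combinations and the
#: hypothesis predictions each supports
COMBINATION_TABLE: tuple[PredictionCombination, ...] = (
    _row(1, NONE, NONE, (), ()),
    _row(2, NONE, DOWN, ("CCH", "MMH"), ("CCP_1", "MMP_1")),
    _row(3, NONE, UP, ("MMH", "SMH"), ("MMP_2", "SMP_2")),
    _row(4, UP, NONE, ("MMH",), ("MMP_3",)),
    _row(5, UP, DOWN, ("MMH",), ("MMP_1", "MMP_3"), ("a",)),
    _row(6, UP, UP, ("MMH", "SMH"), ("MMP_2", "MMP_3", "SMP_2"), ("a", "b")),
    _row(7, DOWN, NONE, ("SMH",), ("SMP_1",)),
    _row(8, DOWN, DOWN, ("SMH",), ("SMP_1",), ("a", "c")),
    _row(9, DOWN, UP, ("SMH",), ("SMP_1", "SMP_2"), ("a",)),
)

_LOOKUP = {(c.pattern.variability_diff, c.pattern.mean_temp_diff): c
           for c in COMBINATION_TABLE}


def supported_hypotheses(pattern: DifferencePattern) -> PredictionCombination:
    """Exact lookup of the combination supported by an observed pattern."""
    return _LOOKUP[(pattern.variability_diff, pattern.mean_temp_diff)]


def classify_pattern(
    importance: pd.DataFrame,
    variable_classes: dict | None = None,
) -> DifferencePattern:
    """Reduce a tree's importance table to a difference pattern.

    ``importance`` is the global importance frame of the pruned tree with
    ``significant`` and ``direction`` columns, direction being the sign of
    the variable's association with viviparity (-1: lower values for
    viviparous clades).  Within each variable family the significant
    variables vote by majority; an exact tie (conflicting directions) maps
    to "none" with a warning.
    """
    variable_classes = variable_classes or VARIABLE_CLASSES
    result = {}
    for family in ("variability", "average"):
        votes = [
            int(r.direction)
            for r in importance.itertuples()
            if r.significant
            and variable_classes.get(r.variable) == family
            and r.direction != 0
        ]
        total = sum(votes)
        if votes and total == 0:
            warnings.warn(
                f"significant {family} variables disagree in direction; "
                "treating the family as showing no difference"
            )
        result[family] = DOWN if total < 0 else UP if total > 0 else NONE
    return DifferencePattern(
        variability_diff=result["variability"], mean_temp_diff=result["average"]
    )


def combination_table_json() -> str:
    """Serialize the lookup (round-trips losslessly)."""
    return json.dumps([c.to_dict() for c in COMBINATION_TABLE], indent=2)
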
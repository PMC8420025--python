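"""IHC diagnostic performance: dichotomization rules and 2x2 contingency metrics.

Tissue-microarray cores are scored either on an ordinal 0-3 abundance scale
(0 = negative; 1: 1-10%; 2: >10-50%; 3: >50% of tumor cells positive) or, for
pattern markers such as LAMP1, categorically (N = negative, D = diffuse,
A = apical, F = focal).  A per-marker rule dichotomizes scores into
positive/negative calls; sensitivity, specificity, PPV and NPV follow from the
2x2 table of calls against the true histological subtype.

Default rules for the four renal markers:

* PLIN2 (ccRCC): positive when >10% of cells stain, i.e. ordinal score >= 2.
* TUBB3 (pRCC): same >10% cutoff, score >= 2.
* LAMP1 (chRCC): positive only for the diffuse staining pattern (D).
* HK1 (RO): positive at the top of the abundance scale, score 3
  (the ">90% cell positivity" clause of the published cutoff cannot be
  represented on the 0-3 abundance scale; score 3 = "abundant" is the
  closest ordinal reading — see the methods note).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence, Union

import pandas as pd

__all__ = [
    "IHCScoreTable",
    "OrdinalCutoff",
    "PatternEquals",
    "ContingencyTable",
    "DiagnosticMetrics",
    "MARKER_RULES",
    "MARKER_TARGETS",
    "dichotomize",
    "contingency",
    "metrics",
    "evaluate_marker",
]

ORDINAL_TOKENS = {"0", "1", "2", "3"}
PATTERN_TOKENS = {"N", "D", "A", "F"}


@dataclass
class IHCScoreTable:
    """Long-format scored cases: one row per (case, marker) pair."""

    rows: pd.DataFrame  # columns: case_id, subtype, marker, score (str)

    def __post_init__(self) -> None:
        required = {"case_id", "subtype", "marker", "score"}
        missing = required - set(self.rows.columns)
        if missing:
            raise ValueError(f"IHC table missing columns: {sorted(missing)}")
        self.rows = self.rows.astype(str)
        dup = self.rows.duplicated(subset=["case_id", "marker"])
        if dup.any():
            pair = self.rows.loc[dup, ["case_id", "marker"]].iloc[0]
            raise ValueError(
                f"duplicate score for case {pair.case_id!r}, marker {pair.marker!r}"
            )
        bad = ~self.rows["score"].isin(ORDINAL_TOKENS | PATTERN_TOKENS)
        if bad.any():
            raise ValueError(
                f"unknown score token {self.rows.loc[bad, 'score'].iloc[0]!r}"
            )

    def for_marker(self, marker: str) -> pd.DataFrame:
        sub = self.rows[self.rows["marker"] == marker]
        if sub.empty:
            raise ValueError(f"no scores for marker {marker!r}")
        return sub

    @property
    def markers(self) -> list[str]:
        return list(dict.fromkeys(self.rows["marker"]))

    @property
    def subtypes(self) -> list[str]:
        return list(dict.fromkeys(self.rows["subtype"]))


@dataclass(frozen=True)
class OrdinalCutoff:
    """Positive when the ordinal score is >= ``min_score``."""

    min_score: int

    def __post_init__(self) -> None:
        if not 0 <= self.min_score <= 3:
            raise ValueError("min_score must be in 0..3")


@dataclass(frozen=True)
class PatternEquals:
    """Positive when the categorical staining pattern equals ``pattern``."""

    pattern: str

    def __post_init__(self) -> None:
        if self.pattern not in PATTERN_TOKENS:
            raise ValueError(f"pattern must be one of {sorted(PATTERN_TOKENS)}")


Rule = Union[OrdinalCutoff, PatternEquals]

#: published dichotomization rules for the four renal TMA markers
MARKER_RULES: dict[str, Rule] = {
    "PLIN2": OrdinalCutoff(2),
    "TUBB3": OrdinalCutoff(2),
    "LAMP1": PatternEquals("D"),
    "HK1": OrdinalCutoff(3),
}

#: subtype each marker is meant to single out
MARKER_TARGETS: dict[str, str] = {
    "PLIN2": "ccRCC",
    "TUBB3": "pRCC",
    "LAMP1": "chRCC",
    "HK1": "RO",
}


@dataclass(frozen=True)
class ContingencyTable:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("contingency counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class DiagnosticMetrics:
    """Percentages in [0, 100], rounded to one decimal; None when undefined."""

    sensitivity: Optional[float]
    specificity: Optional[float]
    ppv: Optional[float]
    npv: Optional[float]


def dichotomize(table: IHCScoreTable, marker: str, rule: Rule) -> pd.Series:
    """Apply a per-marker rule; returns boolean calls indexed by case id."""
    sub = table.for_marker(marker)
    scores = sub["score"]
    if isinstance(rule, OrdinalCutoff):
        non_ordinal = ~scores.isin(ORDINAL_TOKENS)
        if non_ordinal.any():
            raise ValueError(
                f"ordinal cutoff rule applied to categorical score "
                f"{scores[non_ordinal].iloc[0]!r} for marker {marker!r}"
            )
        calls = scores.astype(int) >= rule.min_score
    else:
        ordinal = scores.isin(ORDINAL_TOKENS - {"0"})
        if ordinal.any():
            raise ValueError(
                f"pattern rule applied to ordinal score "
                f"{scores[ordinal].iloc[0]!r} for marker {marker!r}"
            )
        # "0" and "N" both denote negative staining for pattern markers
        calls = scores == rule.pattern
    return calls.set_axis(sub["case_id"])


def contingency(
    calls: Sequence[bool], labels: Sequence[str], target_subtype: str
) -> ContingencyTable:
    """Tally calls against true subtypes into a 2x2 table."""
    calls = pd.Series(list(calls), dtype=bool)
    labels = pd.Series(list(labels), dtype=str)
    if len(calls) != len(labels):
        raise ValueError("calls and labels must be aligned")
    if calls.empty:
        raise ValueError("empty input")
    is_target = labels == target_subtype
    return ContingencyTable(
        tp=int((calls & is_target).sum()),
        fp=int((calls & ~is_target).sum()),
        fn=int((~calls & is_target).sum()),
        tn=int((~calls & ~is_target).sum()),
    )


def _round1(x: float) -> float:
    # round half away from zero (values here are non-negative percentages)
    return float(Decimal(repr(x)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def _ratio(num: int, den: int, name: str) -> Optional[float]:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator)", stacklevel=3)
        return None
    return _round1(100.0 * num / den)


def metrics(ct: ContingencyTable) -> DiagnosticMetrics:
    """Sensitivity, specificity, PPV, NPV as percentages (one decimal)."""
    if ct.total == 0:
        raise ValueError("empty contingency table")
    return DiagnosticMetrics(
        sensitivity=_ratio(ct.tp, ct.tp + ct.fn, "sensitivity"),
        specificity=_ratio(ct.tn, ct.tn + ct.fp, "specificity"),
        ppv=_ratio(ct.tp, ct.tp + ct.fp, "PPV"),
        npv=_ratio(ct.tn, ct.tn + ct.fn, "NPV"),
    )


def evaluate_marker(
    table: IHCScoreTable,
    marker: str,
    target_subtype: Optional[str] = None,
    rule: Optional[Rule] = None,
) -> tuple[ContingencyTable, DiagnosticMetrics]:
    """Dichotomize one marker and score it against its target subtype."""
    if rule is None:
        rule = MARKER_RULES[marker]
    if target_subtype is None:
        target_subtype = MARKER_TARGETS[marker]
    sub = table.for_marker(marker)
    calls = dichotomize(table, marker, rule)
    ct = contingency(calls.to_numpy(), sub["subtype"].to_numpy(), target_subtype)
    return ct, metrics(ct)
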
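"""Labeled activity studies: the evaluation unit for detectors.

A study is a flat list of activity records, each one trace with an
impact / non-impact label, the activity type, and the subject/set it came
from.  The laboratory protocol this mirrors has 11 activities per set
(5 non-impact: slow/normal/fast walking, up/down stairs; 6 impact:
vertical jump, knee fall, horizontal fall, each on hard and soft floor).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .signal import AccelSeries

__all__ = ["ActivityRecord", "LabeledStudy", "IMPACT", "NON_IMPACT"]

IMPACT = "impact"
NON_IMPACT = "non_impact"
LABELS = (IMPACT, NON_IMPACT)


@dataclass
class ActivityRecord:
    series: AccelSeries
    label: str
    activity_type: str = ""
    subject_id: str = "s0"
    set_id: str = "0"
    source: str | None = None
    annotation: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {self.label!r}")


@dataclass
class LabeledStudy:
    activities: list

    @property
    def p(self) -> int:
        """Number of impact (positive) activities."""
        return sum(1 for a in self.activities if a.label == IMPACT)

    @property
    def n(self) -> int:
        """Number of non-impact (negative) activities."""
        return sum(1 for a in self.activities if a.label == NON_IMPACT)

    def __len__(self):
        return len(self.activities)

    def __iter__(self):
        return iter(self.activities)

    def units(self):
        """Distinct (subject_id, set_id) pairs, in first-seen order."""
        seen = []
        for a in self.activities:
            key = (a.subject_id, a.set_id)
            if key not in seen:
                seen.append(key)
        return seen

    def subset(self, unit_keys) -> "LabeledStudy":
        keys = set(unit_keys)
        return LabeledStudy(
            [a for a in self.activities if (a.subject_id, a.set_id) in keys]
        )

    def validate(self):
        if self.p < 1 or self.n < 1:
            raise ValueError(
                f"study needs >= 1 impact and >= 1 non-impact activity "
                f"(P={self.p}, N={self.n})"
            )
        return self
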
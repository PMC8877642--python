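"""Label codes, data usability, data confidentiality, and the final score.

Each masking level is encoded as an integer *label code*: for the three
string fields the code's tens digit counts masked characters and its ones
digit counts visible ones (name 03/12/21/30, age 02/11/20, phone 08/17/80);
the four categorical fields encode kept=1 / masked=0.

*Data usability* sums, over the string fields, the product of the two
digits of the label code, plus the face value of each categorical label.
The convention gives a fully visible name or phone (03, 08) a zero
contribution; that is a property of the published rule and is kept as is.
The maximum over the whole policy space is (1x2)+(1x1)+(1x7)+4 = 14.

*Data confidentiality* is the percentage of deduplicated masked-row groups
relative to the original row count, banded to a 0-15 score in steps of 3:
(0,20] -> 15, (20,40] -> 12, (40,60] -> 9, (60,80] -> 6, (80,99) -> 3,
[99,100) -> 1, exactly 100 -> 0. A cohort where every masked row is still
unique (100%) scores 0 — the de-identification achieved nothing.

*Final score* = usability + confidentiality band score (range 0-29).
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import pandas as pd

from .masking import MaskedRecord, MaskingPolicy, mask_cohort

__all__ = [
    "LabeledPolicy",
    "ScoreBreakdown",
    "label_code",
    "label_policy",
    "usability",
    "distinct_groups",
    "confidentiality_pct",
    "confidentiality_value",
    "final_score",
    "score_policy",
]

NAME_LABELS = {0: 3, 1: 12, 2: 21, 3: 30}
AGE_LABELS = {0: 2, 1: 11, 2: 20}
PHONE_LABELS = {"none": 8, "partial": 17, "full": 80}


@dataclass(frozen=True)
class LabeledPolicy:
    """Integer label codes for one masking policy; together with the cohort
    size these are the surrogate model's feature vector."""

    name_label: int
    age_label: int
    phone_label: int
    blood_label: int
    region_label: int
    illness_label: int
    smoking_label: int

    def __post_init__(self) -> None:
        if self.name_label not in NAME_LABELS.values():
            raise ValueError(f"invalid name label {self.name_label}")
        if self.age_label not in AGE_LABELS.values():
            raise ValueError(f"invalid age label {self.age_label}")
        if self.phone_label not in PHONE_LABELS.values():
            raise ValueError(f"invalid phone label {self.phone_label}")
        for f in ("blood_label", "region_label", "illness_label", "smoking_label"):
            if getattr(self, f) not in (0, 1):
                raise ValueError(f"invalid {f} {getattr(self, f)}")

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass(frozen=True)
class ScoreBreakdown:
    """Usability, confidentiality (percentage and band score) and final
    score for one (cohort, policy) pair."""

    usability: int
    confidentiality_pct: float
    confidentiality_value: int
    final_score: int


def label_code(field: str, level) -> int:
    """Label code for one field's masking level.

    `field` is one of name/age/phone/blood/region/illness/smoking; `level`
    is the policy level for that field (int, phone level string, or bool).
    """
    if field == "name":
        table = NAME_LABELS
    elif field == "age":
        table = AGE_LABELS
    elif field == "phone":
        table = PHONE_LABELS
    elif field in ("blood", "region", "illness", "smoking"):
        if not isinstance(level, bool):
            raise ValueError(f"categorical level must be a bool, got {level!r}")
        return 0 if level else 1
    else:
        raise ValueError(f"unknown field {field!r}")
    try:
        return table[level]
    except KeyError:
        raise ValueError(f"unknown {field} masking level {level!r}") from None


def label_policy(policy: MaskingPolicy) -> LabeledPolicy:
    """Encode a whole policy as its seven label codes."""
    return LabeledPolicy(
        name_label=label_code("name", policy.name_level),
        age_label=label_code("age", policy.age_level),
        phone_label=label_code("phone", policy.phone_level),
        blood_label=label_code("blood", policy.blood_mask),
        region_label=label_code("region", policy.region_mask),
        illness_label=label_code("illness", policy.illness_mask),
        smoking_label=label_code("smoking", policy.smoking_mask),
    )


def usability(labels: LabeledPolicy) -> int:
    """Data usability from the label codes alone (cohort-independent)."""
    digit_product = sum(
        (lab // 10) * (lab % 10)
        for lab in (labels.name_label, labels.age_label, labels.phone_label)
    )
    categorical = (
        labels.blood_label + labels.region_label + labels.illness_label + labels.smoking_label
    )
    return digit_product + categorical


def _masked_frame(masked) -> pd.DataFrame:
    if isinstance(masked, pd.DataFrame):
        return masked
    if len(masked) and isinstance(masked[0], MaskedRecord):
        return pd.DataFrame([m.as_tuple() for m in masked])
    return pd.DataFrame(masked)


def distinct_groups(masked) -> int:
    """Number of deduplicated groups: distinct 7-field masked tuples."""
    frame = _masked_frame(masked)
    if frame.empty:
        raise ValueError("empty masked cohort")
    return len(frame.drop_duplicates())


def confidentiality_pct(masked, n_original: int) -> float:
    """Deduplicated groups as a percentage of the original row count."""
    if n_original <= 0:
        raise ValueError(f"original cohort size must be >= 1, got {n_original}")
    return distinct_groups(masked) / n_original * 100.0


def confidentiality_value(pct: float) -> int:
    """Band a confidentiality percentage into the 0-15 step-3 score."""
    if not 0.0 < pct <= 100.0:
        raise ValueError(f"confidentiality percentage outside (0,100]: {pct}")
    if pct == 100.0:
        return 0
    if pct >= 99.0:
        return 1
    if pct > 80.0:
        return 3
    if pct > 60.0:
        return 6
    if pct > 40.0:
        return 9
    if pct > 20.0:
        return 12
    return 15


def final_score(labels: LabeledPolicy, pct: float) -> ScoreBreakdown:
    """Combine usability and the confidentiality band into the final score."""
    use = usability(labels)
    conf = confidentiality_value(pct)
    return ScoreBreakdown(
        usability=use,
        confidentiality_pct=pct,
        confidentiality_value=conf,
        final_score=use + conf,
    )


def score_policy(cohort: pd.DataFrame, policy: MaskingPolicy) -> ScoreBreakdown:
    """Score one policy against one cohort: mask, deduplicate, band, sum."""
    masked = mask_cohort(cohort, policy)
    pct = confidentiality_pct(masked, len(cohort))
    return final_score(label_policy(policy), pct)
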
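"""Masking-based de-identification of person records.

A :class:`MaskingPolicy` fixes, per field, how many character tokens or
digits are replaced by ``"*"``. Masking is the only de-identification
operator implemented (no generalization hierarchies, noise, or swapping).

Rendering conventions (these define group identity for deduplication, so
they are deterministic and documented):

* name — ``"Family G1-G2"``; tokens are masked in the fixed order
  given1, given2, family; a masked token renders as a single ``"*"``.
* age — two-digit decade string (``age % 100``, zero-padded); level 1 masks
  the ones digit, level 2 both digits. Ages 100-109 render by their last two
  digits so the two-digit labeling applies to every record.
* phone — ``partial`` keeps the ``010-`` prefix and the first random digit
  (``010-d***-****``); ``full`` masks all twelve characters.
* categoricals (region, illness, blood, smoking) — masked renders ``"*"``;
  smoking renders ``"O"`` (smoker) / ``"X"`` otherwise when unmasked.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, fields

import pandas as pd

__all__ = [
    "MaskingPolicy",
    "MaskedRecord",
    "mask_name",
    "mask_age",
    "mask_phone",
    "mask_categorical",
    "apply_policy",
    "mask_cohort",
]

PHONE_RE = re.compile(r"^010-\d{4}-\d{4}$")
PHONE_LEVELS = ("none", "partial", "full")


@dataclass(frozen=True)
class MaskingPolicy:
    """Per-field masking levels defining one de-identification methodology."""

    name_level: int = 0  # character tokens masked, 0..3
    age_level: int = 0  # digits masked, 0..2
    phone_level: str = "none"  # none | partial | full
    blood_mask: bool = False
    region_mask: bool = False
    illness_mask: bool = False
    smoking_mask: bool = False

    def __post_init__(self) -> None:
        if self.name_level not in (0, 1, 2, 3):
            raise ValueError(f"name_level must be 0..3, got {self.name_level}")
        if self.age_level not in (0, 1, 2):
            raise ValueError(f"age_level must be 0..2, got {self.age_level}")
        if self.phone_level not in PHONE_LEVELS:
            raise ValueError(f"phone_level must be one of {PHONE_LEVELS}, got {self.phone_level!r}")

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: dict) -> "MaskingPolicy":
        return cls(**d)

    def covers(self, other: "MaskingPolicy") -> bool:
        """True if this policy masks at least as much as `other` on every field."""
        return (
            self.name_level >= other.name_level
            and self.age_level >= other.age_level
            and PHONE_LEVELS.index(self.phone_level) >= PHONE_LEVELS.index(other.phone_level)
            and self.blood_mask >= other.blood_mask
            and self.region_mask >= other.region_mask
            and self.illness_mask >= other.illness_mask
            and self.smoking_mask >= other.smoking_mask
        )


@dataclass(frozen=True)
class MaskedRecord:
    """Masked string rendering of the seven fields of one record."""

    name: str
    age: str
    phone: str
    region: str
    illness: str
    blood: str
    smoking: str

    def as_tuple(self) -> tuple[str, ...]:
        return (self.name, self.age, self.phone, self.region, self.illness, self.blood, self.smoking)


def mask_name(family: str, given1: str, given2: str, level: int) -> str:
    """Mask `level` of the three name tokens, in the order given1, given2,
    family. Which token is masked does not change the label code, so the
    order is purely a reproducibility convention."""
    if level not in (0, 1, 2, 3):
        raise ValueError(f"name masking level must be 0..3, got {level}")
    g1 = "*" if level >= 1 else given1
    g2 = "*" if level >= 2 else given2
    fam = "*" if level >= 3 else family
    return f"{fam} {g1}-{g2}"


def mask_age(age: int, level: int) -> str:
    """Render the age as a two-digit string and mask `level` digits (ones
    digit first). Ages 100-109 are rendered by their last two digits."""
    if level not in (0, 1, 2):
        raise ValueError(f"age masking level must be 0..2, got {level}")
    if not 0 <= age <= 109:
        raise ValueError(f"age out of range [0,109]: {age}")
    digits = f"{age % 100:02d}"
    if level == 0:
        return digits
    if level == 1:
        return digits[0] + "*"
    return "**"


def mask_phone(phone: str, level: str) -> str:
    """Mask a mobile number: `partial` keeps the prefix and the first random
    digit; `full` masks every character including the prefix."""
    if level not in PHONE_LEVELS:
        raise ValueError(f"phone masking level must be one of {PHONE_LEVELS}, got {level!r}")
    if not PHONE_RE.match(phone):
        raise ValueError(f"malformed phone number: {phone!r}")
    if level == "none":
        return phone
    if level == "partial":
        return f"010-{phone[4]}***-****"
    return "***-****-****"


def mask_categorical(value, masked: bool) -> str:
    """A categorical field is either kept verbatim or collapsed to '*'."""
    return "*" if masked else str(value)


def _render_smoking(smoking: bool) -> str:
    return "O" if smoking else "X"


def apply_policy(cohort, policy: MaskingPolicy) -> list[MaskedRecord]:
    """Apply a policy record-wise; preserves length and row order.

    `cohort` may be a cohort DataFrame or a list of PersonRecord.
    """
    if isinstance(cohort, pd.DataFrame):
        if cohort.empty:
            raise ValueError("empty cohort")
        frame = mask_cohort(cohort, policy)
        return [MaskedRecord(**row) for row in frame.to_dict("records")]
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    out = []
    for rec in cohort:
        out.append(
            MaskedRecord(
                name=mask_name(rec.family, rec.given1, rec.given2, policy.name_level),
                age=mask_age(rec.age, policy.age_level),
                phone=mask_phone(rec.phone, policy.phone_level),
                region=mask_categorical(rec.region, policy.region_mask),
                illness=mask_categorical(rec.illness, policy.illness_mask),
                blood=mask_categorical(rec.blood, policy.blood_mask),
                smoking=mask_categorical(_render_smoking(rec.smoking), policy.smoking_mask),
            )
        )
    return out


def mask_cohort(cohort: pd.DataFrame, policy: MaskingPolicy) -> pd.DataFrame:
    """Vectorized masking of a whole cohort frame.

    Returns a frame of masked strings with columns
    name, age, phone, region, illness, blood, smoking, aligned row-for-row
    with the input. Identical to mapping the scalar operations over rows.
    """
    if cohort.empty:
        raise ValueError("empty cohort")
    n = len(cohort)

    # name: split "Family G1-G2" into tokens, mask in order g1, g2, family
    parts = cohort["name"].str.extract(r"^(?P<fam>\S+) (?P<g1>[^-]+)-(?P<g2>.+)$")
    if parts.isna().any().any():
        raise ValueError("malformed name; expected 'Family G1-G2'")
    g1 = pd.Series("*", index=cohort.index) if policy.name_level >= 1 else parts["g1"]
    g2 = pd.Series("*", index=cohort.index) if policy.name_level >= 2 else parts["g2"]
    fam = pd.Series("*", index=cohort.index) if policy.name_level >= 3 else parts["fam"]
    name = fam + " " + g1 + "-" + g2

    digits = (cohort["age"].astype(int) % 100).map("{:02d}".format)
    if policy.age_level == 0:
        age = digits
    elif policy.age_level == 1:
        age = digits.str[0] + "*"
    else:
        age = pd.Series("**", index=cohort.index)

    bad = ~cohort["phone"].str.match(PHONE_RE)
    if bad.any():
        raise ValueError("malformed phone number in cohort")
    if policy.phone_level == "none":
        phone = cohort["phone"].astype(str)
    elif policy.phone_level == "partial":
        phone = "010-" + cohort["phone"].str[4] + "***-****"
    else:
        phone = pd.Series("***-****-****", index=cohort.index)

    def cat(col: pd.Series, masked: bool) -> pd.Series:
        return pd.Series("*", index=cohort.index) if masked else col.astype(str)

    smoking_vis = cohort["smoking"].map(_render_smoking)
    return pd.DataFrame(
        {
            "name": name,
            "age": age,
            "phone": phone,
            "region": cat(cohort["region"], policy.region_mask),
            "illness": cat(cohort["illness"], policy.illness_mask),
            "blood": cat(cohort["blood"], policy.blood_mask),
            "smoking": cat(smoking_vis, policy.smoking_mask),
        },
        index=cohort.index,
    )
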
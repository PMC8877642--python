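"""Synthetic Korean EHR cohort generation from published demographic tables.

The generator reproduces the marginal distributions of seven personal-data
fields — family name, age, mobile-phone number, residential area, illness,
ABO blood type and smoking status — as printed in national statistics
(family-name registry, 2015 census, Red Cross blood statistics, MOHW smoking
rate). Fields are sampled independently; no inter-field correlation is
modeled. Every cohort is fully reproducible from a single integer seed.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "DemographicSpec",
    "PersonRecord",
    "load_demographics",
    "sample_categorical",
    "sample_age",
    "sample_phone",
    "generate_cohort",
    "read_cohort",
    "write_cohort",
    "GIVEN_SYLLABLES",
]

COHORT_COLUMNS = ["name", "age", "phone", "region", "illness", "blood", "smoking"]

# Fixed alphabet of 100 synthetic given-name syllable tokens (10 onsets x 10
# rimes). Opaque placeholders: no real given-name distribution is modeled.
_ONSETS = ["G", "N", "D", "R", "M", "B", "S", "J", "H", "Y"]
_RIMES = ["a", "eo", "o", "u", "eu", "i", "ae", "e", "an", "un"]
GIVEN_SYLLABLES = tuple(o + r for o in _ONSETS for r in _RIMES)


class ConfigurationError(ValueError):
    """Raised when a demographic table is missing or invalid."""


def _normalize(labels: list[str], printed: np.ndarray, what: str) -> np.ndarray:
    if len(printed) == 0:
        raise ConfigurationError(f"{what}: empty probability table")
    if np.any(printed < 0):
        raise ConfigurationError(f"{what}: negative probability")
    total = printed.sum()
    if total <= 0:
        raise ConfigurationError(f"{what}: probabilities sum to zero")
    return printed / total


@dataclass(frozen=True)
class DemographicSpec:
    """Normalized sampling weights plus the printed percentages they came from.

    ``*_printed`` keeps the values exactly as published (percent scale) for
    reporting; the ``*_p`` vectors are the renormalized probabilities actually
    used for sampling.
    """

    family_labels: tuple[str, ...]
    family_p: np.ndarray
    family_printed: np.ndarray
    age_bands: tuple[tuple[int, int], ...]
    age_p: np.ndarray
    age_printed: np.ndarray
    region_labels: tuple[str, ...]
    region_p: np.ndarray
    region_printed: np.ndarray
    blood_labels: tuple[str, ...]
    blood_p: np.ndarray
    blood_printed: np.ndarray
    smoking_prob: float
    smoking_printed: float
    illnesses: tuple[str, ...]
    version: str = "unversioned"

    def __post_init__(self) -> None:
        if len(self.family_labels) != 21:
            raise ConfigurationError(
                f"expected 21 family-name entries (20 leading + residual), got {len(self.family_labels)}"
            )
        if len(self.age_bands) != 11:
            raise ConfigurationError(f"expected 11 decade age bands, got {len(self.age_bands)}")
        if len(self.region_labels) != 17:
            raise ConfigurationError(f"expected 17 regions, got {len(self.region_labels)}")
        if set(self.blood_labels) != {"A", "B", "O", "AB"}:
            raise ConfigurationError(f"blood types must be A/B/O/AB, got {self.blood_labels}")
        if not 0.0 <= self.smoking_prob <= 1.0:
            raise ConfigurationError(f"smoking probability outside [0,1]: {self.smoking_prob}")
        if len(self.illnesses) != 5:
            raise ConfigurationError(f"expected 5 illness labels, got {len(self.illnesses)}")
        for vec in (self.family_p, self.age_p, self.region_p, self.blood_p):
            if not np.isclose(vec.sum(), 1.0):
                raise ConfigurationError("normalized probability vector does not sum to 1")


@dataclass(frozen=True)
class PersonRecord:
    """One synthetic individual. The name is always three character tokens:
    one family token plus two given tokens, rendered ``"Family G1-G2"``."""

    family: str
    given1: str
    given2: str
    age: int
    phone: str
    region: str
    illness: str
    blood: str
    smoking: bool

    @property
    def name(self) -> str:
        return f"{self.family} {self.given1}-{self.given2}"

    def to_row(self) -> dict:
        return {
            "name": self.name,
            "age": self.age,
            "phone": self.phone,
            "region": self.region,
            "illness": self.illness,
            "blood": self.blood,
            "smoking": self.smoking,
        }

    @classmethod
    def from_row(cls, row) -> "PersonRecord":
        family, given = str(row["name"]).split(" ", 1)
        given1, given2 = given.split("-", 1)
        return cls(
            family=family,
            given1=given1,
            given2=given2,
            age=int(row["age"]),
            phone=str(row["phone"]),
            region=str(row["region"]),
            illness=str(row["illness"]),
            blood=str(row["blood"]),
            smoking=bool(row["smoking"]),
        )


def _default_config_path() -> Path:
    return Path(importlib.resources.files("deidverify") / "data" / "demographics_kr2015.yaml")


def load_demographics(config: str | Path | dict | None = None) -> DemographicSpec:
    """Load and validate the demographic tables, renormalizing each printed
    percentage vector to a proper probability vector.

    Parameters
    ----------
    config
        Path to a YAML table file, an already-parsed mapping, or None for the
        packaged tables.
    """
    if config is None:
        config = _default_config_path()
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    try:
        fam = config["family_names"]
        bands = config["age_bands"]
        regions = config["regions"]
        blood = config["blood_types"]
        smoking = float(config["smoking_rate"])
        illnesses = [str(x) for x in config["illnesses"]]
    except KeyError as exc:  # pragma: no cover - message detail only
        raise ConfigurationError(f"missing demographic table: {exc}") from exc

    fam_labels = list(fam)
    fam_printed = np.asarray([float(fam[k]) for k in fam_labels])
    band_ranges = [(int(lo), int(hi)) for lo, hi, _ in bands]
    age_printed = np.asarray([float(p) for _, _, p in bands])
    region_labels = list(regions)
    region_printed = np.asarray([float(regions[k]) for k in region_labels])
    blood_labels = list(blood)
    blood_printed = np.asarray([float(blood[k]) for k in blood_labels])
    if smoking < 0:
        raise ConfigurationError("negative smoking rate")

    return DemographicSpec(
        family_labels=tuple(fam_labels),
        family_p=_normalize(fam_labels, fam_printed, "family names"),
        family_printed=fam_printed,
        age_bands=tuple(band_ranges),
        age_p=_normalize([str(b) for b in band_ranges], age_printed, "age bands"),
        age_printed=age_printed,
        region_labels=tuple(region_labels),
        region_p=_normalize(region_labels, region_printed, "regions"),
        region_printed=region_printed,
        blood_labels=tuple(blood_labels),
        blood_p=_normalize(blood_labels, blood_printed, "blood types"),
        blood_printed=blood_printed,
        smoking_prob=smoking / 100.0,
        smoking_printed=smoking,
        illnesses=tuple(illnesses),
        version=str(config.get("version", "unversioned")),
    )


def sample_categorical(weights, rng: np.random.Generator, size: int | None = None):
    """Draw category indices from a normalized weight vector.

    Shared sampler behind names, regions, blood types and illnesses.
    Deterministic for a given generator state.
    """
    weights = np.asarray(weights, dtype=float)
    if weights.size == 0:
        raise ValueError("empty weight vector")
    if size is None:
        return int(rng.choice(weights.size, p=weights))
    return rng.choice(weights.size, size=size, p=weights)


def sample_age(spec: DemographicSpec, rng: np.random.Generator, size: int | None = None):
    """Sample integer ages: decade band by band probability, then uniform
    within the band (the open '>100' band maps to 100-109)."""
    n = 1 if size is None else size
    band_idx = rng.choice(len(spec.age_bands), size=n, p=spec.age_p)
    lows = np.asarray([b[0] for b in spec.age_bands])
    highs = np.asarray([b[1] for b in spec.age_bands])
    ages = lows[band_idx] + rng.integers(0, highs[band_idx] - lows[band_idx] + 1)
    return int(ages[0]) if size is None else ages


def sample_phone(rng: np.random.Generator, used: set[str]) -> str:
    """Draw a fresh mobile number "010-dddd-dddd", rejection-sampling until
    the 8 random digits are unused, and record it in `used`."""
    if len(used) >= 10**8:
        raise RuntimeError("phone number space exhausted")
    while True:
        digits = rng.integers(0, 10**8)
        phone = f"010-{digits // 10000:04d}-{digits % 10000:04d}"
        if phone not in used:
            used.add(phone)
            return phone


def _sample_phones_vec(rng: np.random.Generator, n: int) -> np.ndarray:
    """Vectorized pairwise-distinct 8-digit suffixes (rejection on collisions)."""
    draws = rng.integers(0, 10**8, size=n)
    uniq, first_idx = np.unique(draws, return_index=True)
    while uniq.size < n:
        mask = np.ones(n, dtype=bool)
        mask[first_idx] = False
        draws[mask] = rng.integers(0, 10**8, size=int(mask.sum()))
        uniq, first_idx = np.unique(draws, return_index=True)
    d1 = draws // 10000
    d2 = draws % 10000
    return np.char.add(
        np.char.add("010-", np.char.zfill(d1.astype("U4"), 4)),
        np.char.add("-", np.char.zfill(d2.astype("U4"), 4)),
    )


def cohort_rng(seed: int, cohort_index: int = 0) -> np.random.Generator:
    """Per-cohort random stream derived deterministically from (seed, index)."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(cohort_index)]))


def generate_cohort(
    n: int,
    spec: DemographicSpec | None = None,
    seed: int = 0,
    cohort_index: int = 0,
) -> pd.DataFrame:
    """Generate a cohort of ``n`` synthetic person records.

    Returns a DataFrame with columns name, age, phone, region, illness,
    blood, smoking — one row per :class:`PersonRecord`. Identical
    (n, spec, seed, cohort_index) always yields an identical cohort.
    """
    if n < 1:
        raise ValueError(f"cohort size must be >= 1, got {n}")
    if spec is None:
        spec = load_demographics()
    rng = cohort_rng(seed, cohort_index)

    fam = np.asarray(spec.family_labels)[sample_categorical(spec.family_p, rng, size=n)]
    syll = np.asarray(GIVEN_SYLLABLES)
    g1 = syll[rng.integers(0, len(syll), size=n)]
    g2 = syll[rng.integers(0, len(syll), size=n)]
    names = np.char.add(np.char.add(fam.astype("U20"), " "), np.char.add(np.char.add(g1, "-"), g2))
    ages = sample_age(spec, rng, size=n)
    phones = _sample_phones_vec(rng, n)
    regions = np.asarray(spec.region_labels)[sample_categorical(spec.region_p, rng, size=n)]
    illness = np.asarray(spec.illnesses)[rng.integers(0, len(spec.illnesses), size=n)]
    blood = np.asarray(spec.blood_labels)[sample_categorical(spec.blood_p, rng, size=n)]
    smoking = rng.random(n) < spec.smoking_prob

    return pd.DataFrame(
        {
            "name": names,
            "age": ages.astype(int),
            "phone": phones,
            "region": regions,
            "illness": illness,
            "blood": blood,
            "smoking": smoking,
        }
    )


def cohort_records(cohort: pd.DataFrame) -> list[PersonRecord]:
    """Convert a cohort frame to a list of PersonRecord dataclasses."""
    return [PersonRecord.from_row(row) for _, row in cohort.iterrows()]


def write_cohort(cohort: pd.DataFrame, path: str | Path) -> None:
    cohort.to_csv(path, index=False)


def read_cohort(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"name": str, "phone": str})
    df["smoking"] = df["smoking"].astype(bool)
    return df[COHORT_COLUMNS]
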
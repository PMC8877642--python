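"""Regression-dataset construction over the full masking-policy space.

The policy space is the Cartesian product of 4 name levels x 3 age levels x
3 phone levels x 2^4 categorical masks = 576 policies. For each cohort size
(default {100, 500, 1000, 5000}) a cohort is generated and every policy is
scored against it, yielding one row per (size, replicate, policy):
8 independent variables (cohort size + 7 label codes) and the final score
as the dependent variable. Default design: 4 sizes x 1 replicate x 576
policies = 2304 rows.
"""

from __future__ import annotations

import itertools
from pathlib import Path

import pandas as pd

from .demographics import DemographicSpec, generate_cohort, load_demographics
from .masking import MaskingPolicy
from .scoring import label_policy, score_policy

__all__ = [
    "DATASET_COLUMNS",
    "FEATURE_COLUMNS",
    "DEFAULT_SIZES",
    "enumerate_policies",
    "build_dataset",
    "read_dataset",
    "write_dataset",
]

FEATURE_COLUMNS = ["n_samples", "name", "age", "phone", "blood", "region", "illness", "smoking"]
DATASET_COLUMNS = FEATURE_COLUMNS + ["final_score"]
DEFAULT_SIZES = (100, 500, 1000, 5000)


def enumerate_policies() -> list[MaskingPolicy]:
    """All 576 masking policies in canonical order (all-unmasked first,
    innermost-varying field last)."""
    return [
        MaskingPolicy(
            name_level=name,
            age_level=age,
            phone_level=phone,
            blood_mask=blood,
            region_mask=region,
            illness_mask=illness,
            smoking_mask=smoking,
        )
        for name, age, phone, blood, region, illness, smoking in itertools.product(
            (0, 1, 2, 3),
            (0, 1, 2),
            ("none", "partial", "full"),
            (False, True),
            (False, True),
            (False, True),
            (False, True),
        )
    ]


def build_dataset(
    sizes=DEFAULT_SIZES,
    replicates: int = 1,
    seed: int = 0,
    spec: DemographicSpec | None = None,
) -> pd.DataFrame:
    """Score every policy against a cohort of each size.

    Per-cohort random streams are derived from (seed, running cohort index),
    so regeneration with the same arguments is byte-identical. Returns a
    frame with columns n_samples, the 7 label codes, final_score.
    """
    sizes = list(sizes)
    if not sizes:
        raise ValueError("no cohort sizes given")
    if any(int(n) < 1 for n in sizes):
        raise ValueError(f"invalid cohort size in {sizes}")
    if replicates < 1:
        raise ValueError(f"replicates must be >= 1, got {replicates}")
    if spec is None:
        spec = load_demographics()

    policies = enumerate_policies()
    labeled = [label_policy(p).to_dict() for p in policies]
    rows: list[dict] = []
    cohort_index = 0
    for n in sizes:
        n = int(n)
        for _ in range(replicates):
            cohort = generate_cohort(n, spec, seed=seed, cohort_index=cohort_index)
            cohort_index += 1
            for policy, labels in zip(policies, labeled):
                breakdown = score_policy(cohort, policy)
                rows.append(
                    {
                        "n_samples": n,
                        "name": labels["name_label"],
                        "age": labels["age_label"],
                        "phone": labels["phone_label"],
                        "blood": labels["blood_label"],
                        "region": labels["region_label"],
                        "illness": labels["illness_label"],
                        "smoking": labels["smoking_label"],
                        "final_score": breakdown.final_score,
                    }
                )
    return pd.DataFrame(rows, columns=DATASET_COLUMNS)


def write_dataset(dataset: pd.DataFrame, path: str | Path) -> None:
    dataset.to_csv(path, index=False)


def read_dataset(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(DATASET_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"dataset missing columns {sorted(missing)}")
    return df[DATASET_COLUMNS]
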
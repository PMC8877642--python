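import pandas as pd
import pytest

from deidverify import (
    MaskingPolicy,
    build_dataset,
    generate_cohort,
    load_demographics,
    make_fixtures,
)

TABLE5_POLICY = MaskingPolicy(name_level=1, age_level=1, phone_level="partial", illness_mask=True)

ALL_MASKED = MaskingPolicy(
    name_level=3,
    age_level=2,
    phone_level="full",
    blood_mask=True,
    region_mask=True,
    illness_mask=True,
    smoking_mask=True,
)


@pytest.fixture(scope="session")
def spec():
    return load_demographics()


@pytest.fixture(scope="session")
def fixtures():
    return make_fixtures(seed=0)


@pytest.fixture(scope="session")
def cohort200(spec):
    return generate_cohort(200, spec, seed=7)


@pytest.fixture(scope="session")
def worked_example_record():
    return pd.DataFrame(
        [
            {
                "name": "Lee Jun-Hak",
                "age": 25,
                "phone": "010-7123-4567",
                "region": "Seoul",
                "illness": "bruise",
                "blood": "A",
                "smoking": False,
            }
        ]
    )


@pytest.fixture(scope="session")
def default_dataset():
    """The default 2304-row regression dataset (4 sizes x 576 policies)."""
    return build_dataset(seed=42)


def brute_force_distinct_groups(masked: pd.DataFrame) -> int:
    """O(n^2) pairwise-comparison oracle for the deduplicated-group count."""
    rows = [tuple(r) for r in masked.itertuples(index=False)]
    count = 0
    for i, row in enumerate(rows):
        if all(rows[j] != row for j in range(i)):
            count += 1
    return count
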
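"""End-to-end pipeline: generate → mask → score → build → train → explain.

One :class:`RunConfig` drives all six stages; every artifact is a plain CSV
(or JSON manifest) under the configured output directory, and two runs with
the same config produce byte-identical tabular artifacts.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .dataset import DEFAULT_SIZES, FEATURE_COLUMNS, build_dataset, write_dataset
from .demographics import generate_cohort, load_demographics, write_cohort
from .explain import compute_shap, direction_summary, feature_importance
from .masking import MaskingPolicy, mask_cohort
from .scoring import label_policy, score_policy
from .surrogate import METHODS, compare_models, split_dataset

__all__ = ["RunConfig", "run_pipeline", "make_fixtures"]

logger = logging.getLogger("deidverify")

# Mixed policy used for the per-stage mask/score artifacts; mirrors the
# worked usability example (one name token masked, one age digit masked,
# phone partially masked, illness masked, other categoricals kept).
EXAMPLE_POLICY = MaskingPolicy(
    name_level=1, age_level=1, phone_level="partial", illness_mask=True
)


@dataclass
class RunConfig:
    """Configuration for a full pipeline run."""

    seed: int = 42
    sizes: tuple[int, ...] = DEFAULT_SIZES
    replicates: int = 1
    methods: tuple[str, ...] = METHODS
    test_fraction: float = 0.2
    cv_folds: int = 5
    grids: dict | None = None  # per-method grid overrides
    outdir: Path = Path("deid-run")
    demographics: str | None = None  # path to alternate tables
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**{k: v for k, v in raw.items() if k in cls.__dataclass_fields__})
        cfg.sizes = tuple(int(s) for s in cfg.sizes)
        cfg.methods = tuple(cfg.methods)
        cfg.outdir = Path(cfg.outdir)
        return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages in order and return the run manifest.

    The manifest records the package version, seed, per-stage artifact
    paths, their SHA-256 hashes, and stage wall times. Any stage failure
    aborts with the stage name attached.
    """
    logging.basicConfig(level=config.log_level)
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    spec = load_demographics(config.demographics)
    artifacts: dict[str, str] = {}
    timings: dict[str, float] = {}
    stage = "generate"
    try:
        t0 = time.perf_counter()
        cohort = generate_cohort(int(config.sizes[0]), spec, seed=config.seed)
        cohort_path = out / "cohort.csv"
        write_cohort(cohort, cohort_path)
        artifacts[stage] = str(cohort_path)
        timings[stage] = time.perf_counter() - t0
        logger.info("generate: %d records -> %s", len(cohort), cohort_path)

        stage = "mask"
        t0 = time.perf_counter()
        masked = mask_cohort(cohort, EXAMPLE_POLICY)
        masked_path = out / "masked.csv"
        masked.to_csv(masked_path, index=False)
        artifacts[stage] = str(masked_path)
        timings[stage] = time.perf_counter() - t0

        stage = "score"
        t0 = time.perf_counter()
        breakdown = score_policy(cohort, EXAMPLE_POLICY)
        score_path = out / "score.csv"
        pd.DataFrame([breakdown.__dict__]).to_csv(score_path, index=False)
        artifacts[stage] = str(score_path)
        timings[stage] = time.perf_counter() - t0
        logger.info("score: %s", breakdown)

        stage = "build"
        t0 = time.perf_counter()
        dataset = build_dataset(config.sizes, config.replicates, seed=config.seed, spec=spec)
        dataset_path = out / "dataset.csv"
        write_dataset(dataset, dataset_path)
        artifacts[stage] = str(dataset_path)
        timings[stage] = time.perf_counter() - t0
        logger.info("build: %d rows -> %s", len(dataset), dataset_path)

        stage = "train"
        t0 = time.perf_counter()
        train, test = split_dataset(dataset, config.test_fraction, seed=config.seed)
        X_cols = FEATURE_COLUMNS
        report = compare_models(
            train[X_cols],
            train["final_score"],
            test[X_cols],
            test["final_score"],
            methods=config.methods,
            seed=config.seed,
            folds=config.cv_folds,
            grids=config.grids,
        )
        table_path = out / "model_comparison.csv"
        report.table.to_csv(table_path, index=False)
        artifacts[stage] = str(table_path)
        timings[stage] = time.perf_counter() - t0
        logger.info("train: best=%s\n%s", report.best_method, report.table)

        stage = "explain"
        t0 = time.perf_counter()
        shap_report = compute_shap(report.best_model, test[X_cols])
        shap_dir = out / "shap"
        shap_dir.mkdir(exist_ok=True)
        shap_report.to_frame().to_csv(shap_dir / "attributions.csv", index=False)
        ranking = feature_importance(shap_report)
        pd.DataFrame(
            {"feature": ranking, "mean_abs_shap": shap_report.mean_abs[ranking].to_numpy()}
        ).to_csv(shap_dir / "importance.csv", index=False)
        direction_summary(shap_report, test[X_cols]).to_csv(
            shap_dir / "directions.csv", index=False
        )
        artifacts[stage] = str(shap_dir / "importance.csv")
        timings[stage] = time.perf_counter() - t0
        logger.info("explain: ranking=%s", ranking)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "sizes": list(config.sizes),
        "replicates": config.replicates,
        "methods": list(config.methods),
        "artifacts": artifacts,
        "hashes": {k: _sha256(Path(v)) for k, v in artifacts.items()},
        "timings_s": {k: round(v, 3) for k, v in timings.items()},
        "best_method": report.best_method,
        "shap_ranking": ranking,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def make_fixtures(seed: int = 0, outdir: str | Path | None = None) -> dict:
    """Small deterministic cohorts and named policies for tests and demos.

    Includes a record/policy pair mirroring the worked usability example
    (labels name=12, age=11, phone=17, blood=1, region=1, illness=0,
    smoking=1, usability 13).
    """
    spec = load_demographics()
    fixtures = {
        "cohort_5": generate_cohort(5, spec, seed=seed, cohort_index=101),
        "cohort_6": generate_cohort(6, spec, seed=seed, cohort_index=102),
        "cohort_200": generate_cohort(200, spec, seed=seed, cohort_index=103),
        "policies": {
            "unmasked": MaskingPolicy(),
            "all_masked": MaskingPolicy(
                name_level=3,
                age_level=2,
                phone_level="full",
                blood_mask=True,
                region_mask=True,
                illness_mask=True,
                smoking_mask=True,
            ),
            "worked_example": EXAMPLE_POLICY,
        },
        "worked_example_record": pd.DataFrame(
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
        ),
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for key in ("cohort_5", "cohort_6", "cohort_200"):
            write_cohort(fixtures[key], outdir / f"{key}.csv")
        write_cohort(fixtures["worked_example_record"], outdir / "worked_example_record.csv")
        import yaml

        policies = {k: v.to_dict() for k, v in fixtures["policies"].items()}
        (outdir / "policies.yaml").write_text(yaml.safe_dump(policies))
    return fixtures
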
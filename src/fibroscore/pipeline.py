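"""End-to-end orchestration: simulate -> sample -> extract -> fit -> stats.

A run is fully described by a :class:`RunConfig` (YAML round-trippable);
one global seed is fanned out to per-stage child seeds by a fixed
derivation so each stage is independently reproducible.  Outputs are
plain CSV/JSON plus a manifest with the config hash and per-file SHA-256
digests; a rerun with the same config and seed reproduces every byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from fibroscore import __version__
from fibroscore.errors import ConfigError, InvalidArgumentError
from fibroscore.features import extract_qif, make_backend
from fibroscore.model import (
    FibrosisScoreRegressor,
    _model_from_estimator,
    make_lambda_grid,
    select_lambda_grouped_cv,
)
from fibroscore.patches import sample_patches
from fibroscore.slide_io import DermisMask, SlideRef
from fibroscore.stats import kappa_table, odds_ratio_table, slope_table, spearman_corr
from fibroscore.synthetic import (
    RaterProfile,
    generate_cohort,
    render_biopsy_slide,
    simulate_rater_scores,
)

log = logging.getLogger("fibroscore.pipeline")


@dataclass
class RunConfig:
    """Defaults mirror the pipeline's standard operating point: 100
    patches of 0.16 mm^2 per biopsy, a 16-value lambda grid from 1e-5 to
    1e3, visits at weeks 0/24/52, and slides rendered at 2 µm/px."""

    seed: int = 17
    n_patients: int = 20
    visits: list = field(default_factory=lambda: [0, 24, 52])
    patch_n: int = 100
    patch_area_mm2: float = 0.16
    backend: str = "texture32"
    backend_params: dict = field(default_factory=dict)
    lambda_n: int = 16
    lambda_log10_min: float = -5.0
    lambda_log10_max: float = 3.0
    cv: str = "group"
    slide_mpp: float = 2.0
    slide_height_px: int = 2048
    slide_width_px: int = 3072
    outdir: str = "fibroscore_run"
    log_level: str = "INFO"

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=True)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]


def validate_config(path) -> RunConfig:
    """Parse, default, and range-check a YAML config; reject unknown keys."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config must be a mapping, got {type(raw).__name__}")
    known = set(RunConfig.__dataclass_fields__)
    unknown = sorted(set(raw) - known)
    if unknown:
        raise ConfigError(f"unknown config key(s): {unknown}")
    cfg = RunConfig(**raw)
    if cfg.n_patients < 1:
        raise InvalidArgumentError("n_patients must be >= 1")
    if cfg.patch_n < 1:
        raise InvalidArgumentError("patch_n must be >= 1")
    if cfg.patch_area_mm2 <= 0:
        raise InvalidArgumentError("patch_area_mm2 must be > 0")
    if cfg.lambda_n < 2:
        raise InvalidArgumentError("lambda_n must be >= 2")
    if cfg.slide_mpp <= 0:
        raise InvalidArgumentError("slide_mpp must be > 0")
    if cfg.backend not in ("texture32", "cnn4096"):
        raise ConfigError(f"unknown backend {cfg.backend!r}")
    return cfg


def child_seeds(seed: int, n: int) -> list[int]:
    """Fixed seed fan-out (below 2^31) for per-stage reproducibility."""
    state = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32)
    return [int(s % (2**31)) for s in state]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


@dataclass
class RunReport:
    outdir: str
    manifest: dict
    scores: pd.DataFrame


def _stage(name):
    """Decorator tagging stage errors with the failing stage's name."""

    def wrap(fn):
        def inner(*a, **k):
            try:
                return fn(*a, **k)
            except Exception as e:
                e.add_note(f"pipeline stage: {name}")
                raise

        return inner

    return wrap


def run_end_to_end(config: RunConfig, outdir=None) -> RunReport:
    """Execute the full pipeline on synthetic data and write all outputs."""
    out = Path(outdir or config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)
    seeds = child_seeds(config.seed, 5)
    s_cohort, s_slides, s_patches, s_raters, s_cv = seeds

    cohort = _stage("simulate-cohort")(generate_cohort)(
        config.n_patients, seed=s_cohort, weeks=tuple(config.visits)
    )
    table = cohort.table

    backend = make_backend(config.backend, **config.backend_params)
    qifs, truths = [], []
    render = _stage("render-slide")(render_biopsy_slide)
    sample = _stage("sample-patches")(sample_patches)
    extract = _stage("extract-qif")(extract_qif)
    for i, row in table.iterrows():
        slide = render(
            severity=row["severity"],
            mpp=config.slide_mpp,
            height_px=config.slide_height_px,
            width_px=config.slide_width_px,
            seed=(s_slides + 7 * i) % (2**31),
        )
        ref = SlideRef(pixels=slide.image, mpp=slide.mpp, source_format="memory")
        pset = sample(
            ref, DermisMask(labels=slide.mask),
            n=config.patch_n, area_mm2=config.patch_area_mm2,
            seed=(s_patches + 13 * i) % (2**31), biopsy_id=row["biopsy_id"],
        )
        qifs.append(extract(ref, pset, backend))
        truths.append({"biopsy_id": row["biopsy_id"], **slide.truth})
        log.info("extracted %s: %d x %d", row["biopsy_id"], qifs[-1].n_patches, qifs[-1].D)

    truth_df = pd.DataFrame(truths)
    sheets = _stage("simulate-raters")(simulate_rater_scores)(
        truth_df,
        profiles=(RaterProfile("R1"), RaterProfile("R2")),
        sessions=2,
        seed=s_raters,
    )

    labels = table["mrss"].to_numpy(dtype=float)
    groups = table["patient_id"].to_numpy()
    grid = make_lambda_grid(config.lambda_n, config.lambda_log10_min, config.lambda_log10_max)
    lam_star, cv_table = _stage("select-lambda")(select_lambda_grouped_cv)(
        qifs, labels, groups, grid, seed=s_cv
    )
    est = FibrosisScoreRegressor(lam=lam_star).fit(qifs, labels)
    model = _model_from_estimator(
        est, meta={"seed": config.seed, "lambda_grid_n": grid.n, "cv": config.cv}
    )

    heldout = _stage("heldout-scores")(cross_val_scores)(
        qifs, labels, groups, lam_star, seed=s_cv
    )
    scores = table[["biopsy_id", "patient_id", "week", "mrss", "severity"]].copy()
    scores["fibrosis_score"] = est.predict(qifs)
    scores["fibrosis_score_heldout"] = heldout
    scores["n_patches"] = [q.n_patches for q in qifs]

    corr = spearman_corr(scores["fibrosis_score_heldout"], scores["mrss"])
    kappas = _stage("stats-kappa")(kappa_table)(sheets)
    predictor = scores.set_index("biopsy_id")["mrss"]
    or_mrss = _stage("stats-or")(odds_ratio_table)(sheets, predictor)
    or_mrss.insert(0, "predictor", "mrss")
    or_fib = _stage("stats-or")(odds_ratio_table)(
        sheets, scores.set_index("biopsy_id")["fibrosis_score_heldout"]
    )
    or_fib.insert(0, "predictor", "fibrosis_score")
    or_all = pd.concat([or_mrss, or_fib], ignore_index=True)
    slopes = _stage("stats-slope")(slope_table)(sheets, scores)

    files = {
        "scores.csv": lambda p: scores.to_csv(p, index=False),
        "kappa_table.csv": lambda p: kappas.to_csv(p, index=False),
        "or_table.csv": lambda p: or_all.to_csv(p, index=False),
        "slopes.csv": lambda p: slopes.to_csv(p, index=False),
        "cv_table.csv": lambda p: cv_table.to_csv(p, index=False),
        "rater_sheets.csv": lambda p: sheets.to_csv(p, index=False),
        "model.json": lambda p: Path(p).write_text(model.to_json()),
        "correlation.json": lambda p: Path(p).write_text(
            json.dumps({"rho": corr.rho, "p": corr.p, "n": corr.n})
        ),
    }
    for name, writer in files.items():
        writer(out / name)

    manifest = {
        "package_version": __version__,
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "child_seeds": seeds,
        "lambda_star": lam_star,
        "outputs": {name: _sha256(out / name) for name in files},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return RunReport(outdir=str(out), manifest=manifest, scores=scores)


def cross_val_scores(qifs, labels, groups, lam: float, seed: int = 0) -> np.ndarray:
    """Held-out Fibrosis Scores: each biopsy scored by the model fitted
    with its patient's biopsies excluded (same folds as lambda selection)."""
    from fibroscore.model import _as_matrix_list, _grouped_folds

    mats = _as_matrix_list(qifs)
    labels = np.asarray(labels, dtype=float)
    groups = np.asarray(groups)
    preds = np.full(len(mats), np.nan)
    for test_idx in _grouped_folds(groups, seed):
        train_idx = np.setdiff1d(np.arange(len(mats)), test_idx)
        est = FibrosisScoreRegressor(lam=lam).fit(
            [mats[i] for i in train_idx], labels[train_idx]
        )
        preds[test_idx] = est.predict([mats[i] for i in test_idx])
    return preds
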
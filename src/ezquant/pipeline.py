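"""End-to-end orchestration: simulate -> segment -> map -> classify ->
quantify -> grade -> stats, with config, logging and a reproducibility
manifest.

A run is fully determined by its :class:`RunConfig` (including the global
seed); per-stage child seeds are derived by stable hashing of stage names
so that adding a stage never shifts earlier random streams.  All tabular
outputs (CSV/JSON) are byte-identical across reruns of the same config.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort_stats import (
    anova_oneway,
    apply_bonferroni,
    fit_ar1_longitudinal,
    summarize_visits,
    ttest_unpaired,
)
from .defect_detect import FeatureConfig, PixelClassifierModel, classify, train_classifier
from .enface import CSFMask, csf_mask, thickness_map
from .geometry import DIALECTS, ScanGeometry, make_geometry
from .layer_seg import SegmentationConfig, segment_volume, volume_signal_quality
from .oct_synth import (
    CohortParams,
    FOLLOW_UP_VISITS,
    LesionSpec,
    OCTVolume,
    child_seed,
    simulate_cohort,
    simulate_volume,
)
from .quantify_grade import (
    GradabilityConfig,
    GradeThresholds,
    assess_gradability,
    measure_defect,
    qualitative_grade,
)

__all__ = [
    "RunConfig",
    "RunManifest",
    "PipelineError",
    "validate_config",
    "run_pipeline",
    "make_eye_volume",
    "train_default_classifier",
    "process_volume",
    "EyeResult",
]

logger = logging.getLogger("ezquant.pipeline")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the manifest records the failure point."""


@dataclass(frozen=True)
class RunConfig:
    """Everything a run needs; serializable to YAML."""

    dialect: str = "cirrus6mm"
    n_eyes: int = 12
    train_eyes: int = 8
    visits: tuple = FOLLOW_UP_VISITS
    noise_sd: float = 0.1
    seed: int = 0
    out_dir: str = "ezquant_run"
    t_normal: float = 0.02
    t_absent: float = 0.50
    quality_cutoff: float = 0.3
    blocked_cutoff: float = 0.25
    n_estimators: int = 60
    max_depth: int = 12
    cohort: dict = field(default_factory=dict)  # CohortParams overrides
    save_volumes: bool = False
    save_maps: bool = False

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.as_dict(), sort_keys=True))

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["visits"] = list(self.visits)
        return d

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if "visits" in data:
            data["visits"] = tuple(data["visits"])
        return cls(**data)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.as_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class RunManifest:
    config_hash: str
    outputs: dict  # path -> sha256
    versions: dict
    timestamps: dict
    log_path: str
    failed_stage: str | None = None


def validate_config(config: RunConfig) -> list[str]:
    """Return violations (empty iff every module invariant is satisfiable)."""
    violations = []
    if config.dialect not in DIALECTS:
        violations.append(f"dialect: unknown dialect {config.dialect!r}")
    if config.n_eyes <= 0:
        violations.append("n_eyes: must be positive")
    if config.train_eyes <= 0:
        violations.append("train_eyes: must be positive")
    if config.noise_sd < 0:
        violations.append("noise_sd: must be >= 0")
    if not config.t_normal < config.t_absent:
        violations.append(
            f"grading thresholds: t_normal ({config.t_normal}) must be < "
            f"t_absent ({config.t_absent})"
        )
    if not 0 <= config.quality_cutoff <= 1:
        violations.append("quality_cutoff: must be in [0, 1]")
    if not 0 <= config.blocked_cutoff <= 1:
        violations.append("blocked_cutoff: must be in [0, 1]")
    for v in config.visits:
        if v not in FOLLOW_UP_VISITS:
            violations.append(f"visits: unknown visit label {v!r}")
    probe = {
        "rho": "rho: |rho| must be < 1",
        "sigma": "sigma: must be > 0",
    }
    try:
        CohortParams(**{**config.cohort, "n_participants": config.n_eyes}).validate()
    except (TypeError, ValueError) as exc:
        matched = next((m for k, m in probe.items() if k in str(exc)), str(exc))
        violations.append(f"cohort: {matched}")
    return violations


def make_eye_volume(
    geometry: ScanGeometry,
    true_area_mm2: float,
    ungradable: bool,
    seed: int,
    noise_sd: float = 0.1,
    center_jitter_mm: float = 0.1,
) -> tuple[OCTVolume, "object"]:
    """Phantom for one eye-visit: a circular EZ defect of the requested
    area near the fovea, plus (optionally) a severity-1 shadow large enough
    to render the scan ungradable."""
    rng = np.random.default_rng(seed)
    cx = geometry.lateral_extent_mm / 2.0
    cy = geometry.bscan_extent_mm / 2.0
    lesions = []
    if true_area_mm2 > 0:
        radius = math.sqrt(true_area_mm2 / math.pi)
        jx, jy = rng.uniform(-center_jitter_mm, center_jitter_mm, size=2)
        lesions.append(
            LesionSpec("ez_defect", (cx + jx, cy + jy), radius, severity=1.0)
        )
    if ungradable:
        lesions.append(LesionSpec("shadow", (cx, cy), 0.45, severity=1.0))
    return simulate_volume(
        geometry, lesions, noise_sd=noise_sd, seed=int(rng.integers(0, 2**31))
    )


def train_default_classifier(
    geometry: ScanGeometry,
    n_train: int = 8,
    seed: int = 0,
    noise_sd: float = 0.1,
    feature_config: FeatureConfig | None = None,
    n_estimators: int = 60,
    max_depth: int = 12,
    seg_config: SegmentationConfig | None = None,
) -> PixelClassifierModel:
    """Train the pixel classifier on phantom maps with known defect masks.

    Training areas span zero through the central-subfield scale so both
    classes are well represented.
    """
    rng = np.random.default_rng(seed)
    labeled = []
    for i in range(n_train):
        # mix of intact maps and defects across the measurable area range
        area = 0.0 if i % 4 == 0 else float(rng.uniform(0.01, 0.4))
        vol, truth = make_eye_volume(
            geometry, area, False, seed=int(rng.integers(0, 2**31)), noise_sd=noise_sd
        )
        boundaries = segment_volume(vol, seg_config)
        emap = thickness_map(boundaries, geometry)
        labeled.append((emap, truth.defect_mask))
    return train_classifier(
        labeled,
        config=feature_config,
        seed=seed,
        n_estimators=n_estimators,
        max_depth=max_depth,
    )


@dataclass
class EyeResult:
    gradable: bool
    blocked_fraction: float
    raw_area_mm2: float
    reported_area_mm2: float
    present: bool
    grade: str
    enface: object = None  # EnFaceMap, for optional export
    defect_mask: object = None  # DefectMask, for optional export


def process_volume(
    volume: OCTVolume,
    model: PixelClassifierModel,
    csf: CSFMask | None = None,
    seg_config: SegmentationConfig | None = None,
    grad_config: GradabilityConfig | None = None,
    thresholds: GradeThresholds | None = None,
) -> EyeResult:
    """Segment, map, classify, quantify and grade a single volume."""
    geometry = volume.geometry
    csf = csf or csf_mask(geometry)
    boundaries = segment_volume(volume, seg_config)
    emap = thickness_map(boundaries, geometry)
    quality = volume_signal_quality(boundaries)
    gradability = assess_gradability(quality, csf, grad_config)
    mask = classify(emap, model, csf)
    measure = measure_defect(mask.mask, geometry)
    grade = qualitative_grade(measure, gradability, thresholds)
    return EyeResult(
        gradable=gradability.gradable,
        blocked_fraction=gradability.blocked_fraction,
        raw_area_mm2=measure.raw_area_mm2,
        reported_area_mm2=measure.reported_area_mm2,
        present=measure.present,
        grade=grade.value,
        enface=emap,
        defect_mask=mask,
    )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute the full demo pipeline and write all stage outputs.

    Stages: cohort simulation, classifier training, per-eye-visit imaging
    (simulate/segment/map/classify/quantify/grade), and cohort statistics.
    Returns the manifest; raises :class:`PipelineError` after writing a
    partial manifest if a stage fails.
    """
    violations = validate_config(config)
    if violations:
        raise PipelineError(f"invalid config: {violations}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)

    manifest = RunManifest(
        config_hash=config.config_hash(),
        outputs={},
        versions={
            "ezquant": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        timestamps={},
        log_path=str(log_path),
    )
    stage = "setup"
    try:
        t0 = time.time()
        config.to_yaml(out / "config.yaml")

        stage = "cohort"
        params = CohortParams(
            **{
                **config.cohort,
                "n_participants": config.n_eyes,
                "seed": child_seed(config.seed, "cohort"),
            }
        )
        cohort = simulate_cohort(params)
        cohort.to_csv(out / "cohort.csv", index=False)
        logger.info("cohort: %d rows", len(cohort))

        stage = "train"
        geometry = make_geometry(config.dialect)
        model = train_default_classifier(
            geometry,
            n_train=config.train_eyes,
            seed=child_seed(config.seed, "train"),
            noise_sd=config.noise_sd,
            n_estimators=config.n_estimators,
            max_depth=config.max_depth,
        )
        logger.info("classifier oob accuracy %.4f", model.oob_accuracy or float("nan"))

        stage = "imaging"
        csf = csf_mask(geometry)
        thresholds = GradeThresholds(config.t_normal, config.t_absent)
        grad_config = GradabilityConfig(config.quality_cutoff, config.blocked_cutoff)
        records = []
        followups = cohort[cohort["visit"].isin(config.visits)]
        for _, row in followups.iterrows():
            if pd.isna(row["vals_letters"]):
                continue  # missed visit: nothing to image
            seed_ev = child_seed(
                config.seed, f"vol:{row['participant_id']}:{row['visit']}"
            )
            vol, _truth = make_eye_volume(
                geometry,
                float(row["true_area_mm2"]),
                not bool(row["gradable"]),
                seed=seed_ev,
                noise_sd=config.noise_sd,
            )
            res = process_volume(vol, model, csf, None, grad_config, thresholds)
            if config.save_volumes or config.save_maps:
                from .io import write_enface_map, write_mask_png, write_volume_tiff

                eye_dir = out / "eyes"
                eye_dir.mkdir(exist_ok=True)
                stem = f"{row['participant_id']}_{row['visit']}"
                if config.save_volumes:
                    write_volume_tiff(vol, eye_dir / f"{stem}_volume.tiff")
                if config.save_maps:
                    write_enface_map(
                        res.enface,
                        eye_dir / f"{stem}_thickness.tiff",
                        eye_dir / f"{stem}_thickness.png",
                    )
                    write_mask_png(
                        res.defect_mask.mask, eye_dir / f"{stem}_defect.png"
                    )
            records.append(
                {
                    "participant_id": row["participant_id"],
                    "visit": str(row["visit"]),
                    "gradable": res.gradable,
                    "raw_area_mm2": res.raw_area_mm2,
                    "reported_area_mm2": (
                        res.reported_area_mm2 if res.gradable else np.nan
                    ),
                    "present": res.present if res.gradable else np.nan,
                    "grade": res.grade,
                }
            )
        results = pd.DataFrame(records)
        results.to_csv(out / "results.csv", index=False)
        logger.info("imaging: %d eye-visits", len(results))

        stage = "stats"
        merged = cohort.merge(
            results,
            on=["participant_id", "visit"],
            how="left",
            suffixes=("_gen", ""),
        )
        analysis = merged.copy()
        analysis["defect_area_mm2"] = analysis["reported_area_mm2"]
        analysis["grade"] = analysis["grade"].where(
            analysis["grade"].notna(), analysis["grade_gen"]
        )
        analysis["gradable"] = analysis["gradable"].where(
            analysis["gradable"].notna(), analysis["gradable_gen"]
        )
        summaries = summarize_visits(analysis, visits=config.visits)
        pd.DataFrame([dataclasses.asdict(s) for s in summaries]).to_csv(
            out / "visit_summary.csv", index=False
        )

        table1_rows, anova_ps = [], []
        for visit in config.visits:
            rows = analysis[
                (analysis["visit"] == visit) & analysis["defect_area_mm2"].notna()
            ]
            groups = {
                g: rows.loc[rows["grade"] == g, "defect_area_mm2"]
                for g in ("normal", "patchy", "absent")
            }
            groups = {g: v for g, v in groups.items() if len(v) >= 2}
            if len(groups) < 2:
                continue
            res = anova_oneway(groups)
            anova_ps.append(res.p)
            for g in groups:
                table1_rows.append(
                    {
                        "visit": visit,
                        "grade": g,
                        "n": res.group_n[g],
                        "mean_area_mm2": round(res.group_mean[g], 4),
                        "sd_area_mm2": round(res.group_sd[g], 4),
                        "anova_p": res.p,
                    }
                )
        pd.DataFrame(table1_rows).to_csv(out / "table1.csv", index=False)

        stats_json = {}
        try:
            fit = fit_ar1_longitudinal(analysis, "area_continuous")
            stats_json["ar1_area"] = {
                "params": fit.params.round(6).to_dict(),
                "se": fit.se.round(6).to_dict(),
                "rho": round(fit.rho, 6),
                "sigma": round(fit.sigma, 6),
                "loglik": round(fit.loglik, 4),
                "converged": fit.converged,
                "n_participants": fit.n_participants,
                "n_obs": fit.n_obs,
            }
        except ValueError as exc:
            stats_json["ar1_area"] = {"error": str(exc)}
        ttests = {}
        for visit in config.visits:
            rows = analysis[
                (analysis["visit"] == visit) & analysis["defect_area_mm2"].notna()
            ]
            a = rows.loc[~(rows["present"] == True), "vals_letters"]  # noqa: E712
            b = rows.loc[rows["present"] == True, "vals_letters"]  # noqa: E712
            if len(a) >= 2 and len(b) >= 2:
                t = ttest_unpaired(a, b)
                ttests[str(visit)] = {
                    "mean_no_defect": round(t.mean_a, 2),
                    "mean_defect": round(t.mean_b, 2),
                    "t": round(t.t, 4),
                    "p": t.p,
                }
        stats_json["ttest_vals_by_defect"] = ttests
        if anova_ps:
            stats_json["anova_bonferroni_significant"] = apply_bonferroni(anova_ps)
        (out / "stats.json").write_text(json.dumps(stats_json, indent=2))

        stage = "manifest"
        for f in sorted(out.iterdir()):
            if f.name not in ("manifest.json", "run.log") and f.is_file():
                manifest.outputs[f.name] = _sha256(f)
        manifest.timestamps["completed"] = time.strftime("%Y-%m-%dT%H:%M:%S")
        manifest.timestamps["elapsed_s"] = round(time.time() - t0, 2)
        (out / "manifest.json").write_text(
            json.dumps(dataclasses.asdict(manifest), indent=2)
        )
        logger.info("pipeline complete in %.1f s", time.time() - t0)
        return manifest
    except Exception as exc:
        manifest.failed_stage = stage
        (out / "manifest.json").write_text(
            json.dumps(dataclasses.asdict(manifest), indent=2)
        )
        logger.error("stage %s failed: %s", stage, exc)
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
    finally:
        logger.removeHandler(handler)
        handler.close()
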
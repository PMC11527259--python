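"""One-config, one-seed orchestration: simulate -> sample -> extract -> fit
-> score -> agreement -> trend -> association.

Every artifact is a deterministic function of the configuration: CSVs are
written with a fixed float format and sorted rows, JSON with sorted keys and
no timestamps, and the manifest records each artifact's SHA-256 alongside the
configuration hash.  Re-running the same configuration reproduces the
artifacts byte for byte (wall-clock timings go to a separate run.log that is
outside the determinism contract).
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .association import association_report
from .errors import PipelineError
from .features import extract_features, save_qif, texture_backend
from .histology import agreement_report, sheets_to_frame, trend_report
from .model import fit_fibrosis_model, make_lambda_grid
from .patches import sample_patches
from .synthetic import (
    CohortSpec,
    cohort_to_frame,
    render_biopsy,
    simulate_assessments,
    simulate_cohort,
)
from .synthetic.cohort import sheet_seed

_FLOAT_FORMAT = "%.10g"


class ImageConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    height_px: int = 2048
    width_px: int = 2048
    microns_per_pixel: float = Field(1.0, gt=0)


class PatchConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n: int = 100
    area_mm2: float = Field(0.16, gt=0)
    min_dermis_fraction: float = Field(0.9, gt=0, le=1)

    @field_validator("n")
    @classmethod
    def _positive_n(cls, v: int) -> int:
        if v <= 0:
            raise ValueError(f"patch count must be positive, got {v}")
        return v


class BackendConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    name: str = "texture"
    n_features: int = Field(4096, ge=1)


class GridConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n: int = 16
    lo: float = 1e-5
    hi: float = 1e3


class RunConfig(BaseModel):
    """Declarative run configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")
    seed: int = 0
    outdir: str = "fibroscore_run"
    n_subjects: int = Field(10, ge=3)
    visit_weeks: tuple[int, ...] = (0, 24, 52)
    rater_agreement: float = Field(0.8, ge=0, le=1)
    noise_sd_mrss: float = Field(2.0, ge=0)
    image: ImageConfig = ImageConfig()
    patch: PatchConfig = PatchConfig()
    backend: BackendConfig = BackendConfig()
    grid: GridConfig = GridConfig()
    cv: str | int = "auto"
    significance_threshold: float = 0.05
    save_images: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        payload = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**payload)

    def config_hash(self) -> str:
        # outdir is a storage location, not part of the scientific run
        canon = json.dumps(
            self.model_dump(exclude={"outdir"}), sort_keys=True, default=str
        )
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _write_csv(frame: pd.DataFrame, path: Path) -> None:
    frame.to_csv(path, index=False, float_format=_FLOAT_FORMAT)


def _write_json(payload, path: Path) -> None:
    path.write_text(json.dumps(payload, sort_keys=True, indent=1, default=str))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the manifest dict.

    Any stage failure aborts with :class:`PipelineError` naming the stage,
    after persisting a partial manifest.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": config.config_hash(),
        "config": config.model_dump(exclude={"outdir"}),
        "artifacts": {},
    }
    log_lines: list[str] = []
    stage = "init"

    def _register(name: str, path: Path) -> None:
        manifest["artifacts"][name] = {
            "path": path.name,
            "sha256": _sha256(path),
        }

    try:
        t_start = time.time()
        stage = "simulate"
        spec = CohortSpec(
            n_subjects=config.n_subjects,
            visit_weeks=tuple(config.visit_weeks),
            rater_agreement=config.rater_agreement,
            noise_sd_mrss=config.noise_sd_mrss,
            seed=config.seed,
        )
        subjects = simulate_cohort(spec)
        cohort_frame = cohort_to_frame(subjects)
        cohort_path = outdir / "cohort.csv"
        _write_csv(cohort_frame, cohort_path)
        _register("cohort", cohort_path)
        log_lines.append(f"simulate: {time.time() - t_start:.2f}s")

        stage = "sample+extract"
        t0 = time.time()
        backend = texture_backend(
            n_features=config.backend.n_features, seed=config.seed
        )
        qif_store = outdir / "qif.zarr"
        manifests, qifs = [], []
        mrss_totals: dict[str, float] = {}
        subject_of: dict[str, str] = {}
        week_of: dict[str, int] = {}
        for subj in subjects:
            for week in subj.visit_weeks:
                biopsy_id = f"{subj.subject_id}-w{week:03d}"
                image = render_biopsy(
                    severity=subj.severity[week],
                    microns_per_pixel=config.image.microns_per_pixel,
                    height_px=config.image.height_px,
                    width_px=config.image.width_px,
                    seed=subj.biopsy_seeds[week],
                    biopsy_id=biopsy_id,
                )
                if config.save_images:
                    from .synthetic.imaging import save_biopsy

                    save_biopsy(image, outdir / "images", biopsy_id)
                pset = sample_patches(
                    image,
                    n=config.patch.n,
                    patch_area_mm2=config.patch.area_mm2,
                    seed=subj.biopsy_seeds[week],
                    min_dermis_fraction=config.patch.min_dermis_fraction,
                )
                manifests.append(pset.manifest())
                qif = extract_features(pset, backend)
                save_qif(qif_store, qif)
                qifs.append(qif)
                mrss_totals[biopsy_id] = float(subj.mrss_total(week))
                subject_of[biopsy_id] = subj.subject_id
                week_of[biopsy_id] = week
        patch_path = outdir / "patch_manifest.csv"
        _write_csv(pd.concat(manifests, ignore_index=True), patch_path)
        _register("patch_manifest", patch_path)
        manifest["artifacts"]["qif_store"] = {"path": qif_store.name}
        log_lines.append(f"sample+extract: {time.time() - t0:.2f}s")

        stage = "fit"
        t0 = time.time()
        grid = make_lambda_grid(config.grid.n, config.grid.lo, config.grid.hi)
        model = fit_fibrosis_model(
            qifs, mrss_totals, subject_of, grid=grid, cv=config.cv, seed=config.seed
        )
        model_path = outdir / "model.json"
        model.to_json(model_path)
        _register("model", model_path)
        log_lines.append(f"fit: {time.time() - t0:.2f}s")

        stage = "score"
        scores = [model.score_biopsy(q) for q in qifs]
        scores_frame = pd.DataFrame(
            [
                {
                    "biopsy_id": s.biopsy_id,
                    "subject_id": subject_of[s.biopsy_id],
                    "week": week_of[s.biopsy_id],
                    "fibrosis_score": s.score,
                    "n_patches_used": s.n_patches_used,
                }
                for s in scores
            ]
        ).sort_values("biopsy_id")
        scores_path = outdir / "fibrosis_scores.csv"
        _write_csv(scores_frame, scores_path)
        _register("fibrosis_scores", scores_path)

        stage = "sheets"
        all_sheets = []
        for i, subj in enumerate(subjects):
            for week in subj.visit_weeks:
                all_sheets.extend(
                    simulate_assessments(
                        subj, week, config.rater_agreement,
                        seed=sheet_seed(config.seed, i, week), rounds=2,
                    )
                )
        sheets_frame = sheets_to_frame(all_sheets, subject_of, week_of)
        sheets_path = outdir / "score_sheets.csv"
        _write_csv(sheets_frame, sheets_path)
        _register("score_sheets", sheets_path)

        stage = "agreement"
        report = agreement_report(all_sheets)
        agree_path = outdir / "agreement.csv"
        _write_csv(report.inter_rater, agree_path)
        _register("agreement", agree_path)
        (outdir / "agreement.txt").write_text(report.to_text())

        stage = "trend"
        long_frame = sheets_frame.copy()
        trend = trend_report(long_frame)
        trend_path = outdir / "trend.csv"
        _write_csv(trend, trend_path)
        _register("trend", trend_path)

        stage = "association"
        assoc = association_report(
            [s for s in all_sheets if s.assessment_round == 1],
            mrss_totals,
            scores,
        )
        assoc_path = outdir / "association.csv"
        _write_csv(assoc.or_table, assoc_path)
        _register("association", assoc_path)
        corr_path = outdir / "correlation.json"
        _write_json(
            {
                "rho": assoc.correlation.rho,
                "p": assoc.correlation.p,
                "n": assoc.correlation.n,
            },
            corr_path,
        )
        _register("correlation", corr_path)

        stage = "manifest"
        manifest_path = outdir / "manifest.json"
        _write_json(manifest, manifest_path)
        (outdir / "run.log").write_text("\n".join(log_lines) + "\n")
        return manifest
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        _write_json(manifest, outdir / "manifest.json")
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(f"stage '{stage}' failed: {exc}") from exc
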
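"""End-to-end pipeline: simulate -> segment -> quantify -> analyze.

Each stage logs one machine-parsable line (``[stage] message``) and writes
its outputs under the run directory; the fully-resolved configuration and
package version are written next to them, so a rerun with the same config
and seed reproduces every numeric output.
"""

from __future__ import annotations

import json
import time
from pathlib import Path

import pandas as pd

import hefq
from hefq import cohort as cohort_stats
from hefq import quantify, segment
from hefq.config import RunConfig
from hefq.core import FOLLOWUP_WEEKS
from hefq.io import write_cohort, write_mask, write_volume
from hefq.synth import CohortParams, VolumeParams, apply_inclusion_filters, generate_cohort, generate_volume

__all__ = ["run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """A stage failure, tagged with the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


class _Log:
    def __init__(self, path: Path):
        self.path = path
        self.lines: list[str] = []

    def event(self, stage: str, message: str) -> None:
        line = f"[{stage}] {message}"
        self.lines.append(line)
        with open(self.path, "a") as fh:
            fh.write(line + "\n")


def _volume_params(config: RunConfig) -> VolumeParams:
    c = config.synth_volume
    return VolumeParams(
        n_blobs=c.n_blobs,
        blob_contrast_sd=c.blob_contrast_sd,
        noise_sd=c.noise_sd,
        n_fluid=c.n_fluid,
    )


def _cohort_params(config: RunConfig) -> CohortParams:
    c = config.synth_cohort
    return CohortParams(
        n_eyes=c.n_eyes,
        visit_noise_sd=c.visit_noise_sd,
        missing_rate=c.missing_rate,
        low_signal_rate=c.low_signal_rate,
        zero_baseline_rate=c.zero_baseline_rate,
    )


def run_pipeline(config: RunConfig, out_dir: str | Path) -> Path:
    """Run all four stages under ``out_dir`` and return that directory."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log = _Log(out_dir / "run.log")
    config.dump(out_dir / "config_resolved.yaml")
    (out_dir / "VERSION").write_text(hefq.__version__ + "\n")
    log.event("run", f"hefq {hefq.__version__} seed={config.seed}")

    # --- simulate + segment + quantify volumes -------------------------
    t0 = time.perf_counter()
    vol_dir = out_dir / "volumes"
    vol_dir.mkdir(exist_ok=True)
    records = []
    try:
        grid = quantify.build_etdrs_grid(
            config.geometry,
            None if config.quantify.center == "auto"
            else tuple(float(v) for v in config.quantify.center.split(",")),
        )
        for i in range(config.synth_volume.n_volumes):
            volume, surfaces, truth = generate_volume(
                config.geometry, _volume_params(config), seed=config.seed + i
            )
            write_volume(volume, vol_dir / f"volume_{i:03d}.tiff",
                         surfaces=surfaces, seed=config.seed + i)
            if config.segment.surfaces == "gradient":
                surfaces = segment.delineate_surfaces(volume, "gradient")
            mask = segment.segment_hrf_reference(volume, surfaces, config.segment.k_sd)
            mask = quantify.contiguity_filter(
                mask, config.quantify.min_size, config.quantify.connectivity
            )
            write_mask(mask, vol_dir / f"mask_{i:03d}.tiff")
            rec = quantify.regional_volumes(mask, grid, eye_id=f"vol{i:03d}")
            records.append(
                {
                    "volume": i,
                    "true_mm3": truth.true_volume_mm3,
                    "recovered_total_mm3": rec.total_mm3,
                    "csf_mm3": rec.csf_mm3,
                    "ir_mm3": rec.ir_mm3,
                    "or_mm3": rec.or_mm3,
                    "dice_vs_truth": segment.dice_coefficient(mask.mask, truth.hrf_mask),
                }
            )
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001 - re-tag with stage context
        raise PipelineError("simulate/segment/quantify", str(exc)) from exc
    pd.DataFrame(records).to_csv(out_dir / "volume_recovery.csv", index=False)
    log.event("quantify", f"{len(records)} volumes in {time.perf_counter() - t0:.1f}s")

    # --- simulate + analyze cohort -------------------------------------
    t0 = time.perf_counter()
    try:
        cohort, truth_rec = generate_cohort(_cohort_params(config), seed=config.seed)
        cohort, exclusions = apply_inclusion_filters(cohort)
        if cohort.n_eyes == 0:
            raise PipelineError("analyze", "empty cohort after inclusion filtering")
        write_cohort(cohort, out_dir / "cohort")
        exclusions.to_csv(out_dir / "cohort" / "exclusions.csv", index=False)

        summary = cohort_stats.summarize_trajectories(cohort)
        summary.to_csv(out_dir / "trajectory_summary.csv", index=False)

        tests = []
        for region in ("total", "csf", "ir", "or"):
            tests.extend(
                vars(t) for t in cohort_stats.paired_tests_vs_baseline(
                    cohort, region, FOLLOWUP_WEEKS, config.analyze.bonferroni_m
                )
            )
        with open(out_dir / "paired_tests.json", "w") as fh:
            json.dump(tests, fh, indent=2)

        cohort_stats.resolution_counts(cohort, 52).to_csv(
            out_dir / "resolution_w52.csv", index=False
        )

        frame = cohort_stats.analysis_frame(cohort)
        corr = cohort_stats.pearson_screen(
            frame,
            ["age", "hba1c", "dm_duration", "mean_arterial_bp", "bmi"],
            ["he_total_baseline", "or_he_baseline"],
        )
        corr.to_csv(out_dir / "correlations.csv", index=False)

        candidates = [
            "cst_w52", "or_he_baseline", "pseudophakic", "age", "hba1c",
            "dm_duration", "cst_baseline", "he_total_baseline",
            "mean_arterial_bp", "bmi",
        ]
        screen = cohort_stats.univariable_screen(
            frame, "va_w52", candidates, config.analyze.screen_threshold
        )
        passed = list(screen.loc[screen["passed"], "candidate"])
        model = cohort_stats.stepwise_fit(
            frame, "va_w52", passed,
            entry_p=config.analyze.entry_p,
            removal_p=config.analyze.removal_p,
            vif_max=config.analyze.vif_max,
            screen_log=screen,
        )
        with open(out_dir / "regression_va_w52.json", "w") as fh:
            json.dump(model.to_dict(), fh, indent=2)
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("analyze", str(exc)) from exc
    log.event(
        "analyze",
        f"{cohort.n_eyes} eyes analyzed ({len(exclusions)} excluded) "
        f"in {time.perf_counter() - t0:.1f}s",
    )
    return out_dir
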
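"""Subject- and cohort-level orchestration.

``run_subject`` executes the full scoring chain on one subject:
orientation alignment -> four-round registration to the atlas template ->
nearest-neighbour mask transform (or U-Net mask prediction first) ->
region overlaps -> deduction scoring -> core volume -> imaging severity
flags, then writes a JSON report (with the resolved configuration and
software version embedded) and an optional QC overlay.

``run_cohort`` maps ``run_subject`` over a manifest CSV, isolates subject
failures into a failure manifest, and runs the cohort-level severity
analysis (deduction frequencies, per-region association tests, ROC/Youden
thresholds) on the successful subjects.

Inputs are expected to be skull-stripped; a caller-supplied ``strip_hook``
may be configured to run a brain-extraction step first.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .atlas import AspectsAtlas, load_atlas
from .registration import DEFAULT_SCHEDULE, RegistrationError, register, transform_mask
from .scoring import (AspectsResult, DeductionRules, classify_severity_imaging,
                      core_volume, score_mask)
from .severity import (deduction_frequency, derive_thresholds,
                       normalized_frequency_map, region_association_tests,
                       severity_from_nihss)
from .volume_io import LabeledVolume, read_volume, write_volume

log = logging.getLogger("dwiaspects")


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    atlas_labels: str
    atlas_table: str
    atlas_template: str | None = None
    rules: DeductionRules = field(default_factory=DeductionRules)
    aspects_cutoff: int = 6
    volume_cutoff_mL: float = 27.86
    schedule: tuple[str, ...] = DEFAULT_SCHEDULE
    similarity: str = "mattes"
    seed: int = 0
    checkpoint: str | None = None      # U-Net weights; None = external-mask mode
    mask_in_template_space: bool = False
    write_overlay: bool = True
    make_plots: bool = False          # PNG figures (requires matplotlib)
    output_dir: str = "dwiaspects-out"
    log_level: str = "INFO"
    strip_hook: Callable[[LabeledVolume], LabeledVolume] | None = None

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        payload.update({k: v for k, v in overrides.items() if v is not None})
        rules = payload.pop("rules", None)
        cfg = cls(**payload)
        if isinstance(rules, dict):
            cfg.rules = DeductionRules(**rules)
        return cfg

    def resolved(self) -> dict:
        d = dataclasses.asdict(self)
        d["rules"] = dataclasses.asdict(self.rules)
        d.pop("strip_hook", None)
        d["schedule"] = list(self.schedule)
        d["version"] = __version__
        return d

    def load_atlas(self) -> AspectsAtlas:
        return load_atlas(self.atlas_labels, self.atlas_table, self.atlas_template)


def _overlay(lesion: LabeledVolume, atlas: AspectsAtlas) -> LabeledVolume:
    """QC map: atlas label where the lesion intersects a region, else 0."""
    data = np.where(lesion.data > 0, atlas.labels.data, 0).astype(np.int16)
    return LabeledVolume(data, atlas.labels.affine.copy())


def run_subject(
    config: RunConfig,
    dwi_path: str | Path | None,
    mask_path: str | Path | None = None,
    subject_id: str = "subject",
    atlas: AspectsAtlas | None = None,
) -> tuple[AspectsResult, dict]:
    """Score one subject; returns (result, report dict) and writes report files."""
    atlas = atlas or config.load_atlas()
    if mask_path is None and config.checkpoint is None:
        raise ConfigError("configure a mask source: an external mask path or a "
                          "segmenter checkpoint")

    dwi = read_volume(dwi_path) if dwi_path is not None else None
    if dwi is not None and config.strip_hook is not None:
        dwi = config.strip_hook(dwi)

    if mask_path is not None:
        native_mask = read_volume(mask_path)
        native_mask.data = (native_mask.data > 0).astype(np.uint8)
    else:
        from .unet import load_checkpoint, predict_mask
        if dwi is None:
            raise ConfigError("segmenter mode requires a DWI volume")
        model = load_checkpoint(config.checkpoint)
        native_mask = predict_mask(model, dwi)

    transform_info = None
    if config.mask_in_template_space:
        template_mask = native_mask
    else:
        if atlas.template is None:
            raise ConfigError("native-space input requires an atlas template "
                              "image to register against")
        if dwi is None:
            raise ConfigError("native-space input requires the DWI image "
                              "(the image drives registration, not the mask)")
        transform, _ = register(dwi, atlas.template, schedule=config.schedule,
                                similarity=config.similarity, seed=config.seed)
        template_mask = transform_mask(native_mask, transform, atlas.labels)
        transform_info = {"kind": transform.kind,
                          "matrix": transform.matrix.tolist(),
                          "round_metrics": transform.round_metrics}

    result = score_mask(template_mask, atlas, config.rules,
                        native_lesion=native_mask)
    flags = classify_severity_imaging(result, config.aspects_cutoff,
                                      config.volume_cutoff_mL)

    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = {
        "subject_id": subject_id,
        **result.to_dict(),
        "severity_flag_aspects": flags[0],
        "severity_flag_volume": flags[1],
        "registration": transform_info,
        "config": config.resolved(),
    }
    (outdir / f"{subject_id}_report.json").write_text(
        json.dumps(report, indent=2))
    if config.write_overlay:
        write_volume(_overlay(template_mask, atlas),
                     outdir / f"{subject_id}_overlay.nii.gz")
    return result, report


def run_cohort(config: RunConfig, manifest_path: str | Path) -> dict:
    """Score every manifest row, then run the severity analysis.

    Failing subjects are skipped with a logged reason and recorded in
    ``failures.csv``; more than 50% failures raises. Outputs (per-subject
    reports, a cohort score table, frequency/association CSVs and a
    threshold JSON) land in ``config.output_dir``.
    """
    manifest = pd.read_csv(manifest_path)
    if "mask_path" not in manifest.columns:
        raise ConfigError("manifest needs a mask_path column")
    atlas = config.load_atlas()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    rows, failures, scored = [], [], []
    for row in manifest.itertuples():
        sid = str(getattr(row, "subject_id", f"sub-{row.Index:04d}"))
        try:
            dwi = getattr(row, "volume_path", "") or None
            if isinstance(dwi, float):  # NaN from pandas
                dwi = None
            result, _ = run_subject(config, dwi, row.mask_path, sid, atlas)
        except (OSError, ValueError, RegistrationError, ConfigError) as exc:
            log.warning("subject %s failed: %s", sid, exc)
            failures.append({"subject_id": sid, "reason": str(exc)})
            continue
        nihss = getattr(row, "nihss", None)
        severity = getattr(row, "severity", None)
        if (severity is None or (isinstance(severity, float) and np.isnan(severity)) or severity == "") \
                and nihss is not None and not pd.isna(nihss):
            severity = severity_from_nihss(int(nihss))
        rows.append({
            "subject_id": sid,
            "reported_score": result.reported_score,
            "score_left": result.score_left,
            "score_right": result.score_right,
            "core_volume_mL": result.core_volume_mL,
            "native_volume_mL": result.native_volume_mL,
            "reported_hemisphere": result.reported_hemisphere,
            "nihss": nihss,
            "severity": severity,
        })
        if severity is not None:
            scored.append((result, str(severity)))

    if failures:
        pd.DataFrame(failures).to_csv(outdir / "failures.csv", index=False)
    if len(failures) > len(manifest) / 2:
        raise RuntimeError(f"{len(failures)}/{len(manifest)} subjects failed; "
                           "see failures.csv")

    scores_df = pd.DataFrame(rows)
    scores_df.to_csv(outdir / "cohort_scores.csv", index=False)

    summary: dict = {"n_scored": len(rows), "n_failed": len(failures)}
    if scored and len({s for _, s in scored}) >= 2:
        table = deduction_frequency(scored)
        table.rows.to_csv(outdir / "deduction_frequency.csv", index=False)
        normalized_frequency_map(table).to_csv(
            outdir / "normalized_frequency.csv", index=False)
        region_association_tests(scored).to_csv(
            outdir / "region_association.csv", index=False)
        labels = {s for _, s in scored}
        if "mild" in labels and (labels - {"mild"}):
            thr = derive_thresholds(scored)
            thr_payload = {
                "aspects": thr["aspects"].to_dict(),
                "volume": thr["volume"].to_dict(),
                "delong": thr["delong"],
            }
            (outdir / "thresholds.json").write_text(
                json.dumps(thr_payload, indent=2))
            summary["thresholds"] = thr_payload
            if config.make_plots:
                from .plots import (plot_deduction_histogram,
                                    plot_normalized_map, plot_roc)
                from .severity import dichotomize
                plot_deduction_histogram(table, outdir / "deduction_frequency.png")
                plot_normalized_map(table, outdir / "normalized_frequency.png")
                y = np.array([dichotomize(s) for _, s in scored])
                plot_roc({"aspects": thr["aspects"], "volume": thr["volume"]},
                         {"aspects": np.array([r.reported_score for r, _ in scored],
                                              dtype=float),
                          "volume": np.array([r.core_volume_mL for r, _ in scored])},
                         y, outdir / "roc.png")
    return summary
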
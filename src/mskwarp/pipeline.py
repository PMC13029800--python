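"""The end-to-end personalization pipeline.

Binds the stages together in the order an MRI-based personalization runs:

1. load (or synthesize) participant bone landmarks,
2. warp the generic model's muscle points, joint centers, wrap surfaces and
   skin markers onto the participant landmarks by penalized TPS,
3. apply optional manual point corrections,
4. build ISB segment frames and localize the geometry,
5. check muscle-point / wrap-surface intersections and shrink violating wrap
   radii,
6. optionally re-optimize via points against generic moment-arm references,
7. measure bone geometry and write machine-readable reports.

The pipeline is a pure function of (inputs, config, seed): rerunning with
the same inputs writes byte-identical model JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import anthropometry
from .core import ModelGeometry, TemplateDefinition, build_template, add_joint_center_doubles, save_model
from .frames import build_frames, localize
from .muscle_mech import check_wrap_violations, optimize_via_points, reduce_wrap_radii
from .slicer_io import read_markups, ras_to_isb
from .synthetic import make_fixture_model, make_reference_waveforms
from .tps import TpsConfig, warp_geometry, apply_manual_corrections


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[stage {stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    landmarks_path: str | None = None      # participant markups (.fcsv/.mrk.json)
    out_dir: str = "mskwarp_run"
    tps: TpsConfig = field(default_factory=TpsConfig)
    corrections: dict = field(default_factory=dict)
    optimize_muscles: list[str] = field(default_factory=list)
    seed: int = 0
    wrap_safety: float = 0.98

    def to_dict(self) -> dict:
        return {
            "landmarks_path": self.landmarks_path,
            "out_dir": self.out_dir,
            "tps": {"lambda_points": self.tps.lambda_points,
                    "lambda_surface": self.tps.lambda_surface},
            "corrections": self.corrections,
            "optimize_muscles": list(self.optimize_muscles),
            "seed": self.seed,
            "wrap_safety": self.wrap_safety,
        }


def run_pipeline(cfg: RunConfig, participant_landmarks=None,
                 template: TemplateDefinition | None = None,
                 generic_model: ModelGeometry | None = None) -> dict:
    """Run the full personalization; returns a summary dict of artifacts.

    ``participant_landmarks`` may be passed directly (ISB meters) instead of
    ``cfg.landmarks_path``.  All stage outputs are written under
    ``cfg.out_dir``.
    """
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "run_config.json").write_text(json.dumps(cfg.to_dict(), indent=1))

    # stage 1: inputs
    template = template or add_joint_center_doubles(build_template())
    model = generic_model or make_fixture_model(template)
    if participant_landmarks is None:
        if cfg.landmarks_path is None:
            raise PipelineError("load", "no participant landmarks given (path or object)")
        try:
            raw = read_markups(cfg.landmarks_path)
        except FileNotFoundError as e:
            raise PipelineError("load", f"landmark file not found: {cfg.landmarks_path}") from e
        participant_landmarks = ras_to_isb(raw)

    # stage 2: TPS warp
    try:
        common = [n for n in template.landmarks.names if n in participant_landmarks]
        tpl_ls = template.landmarks.subset(common)
        par_ls = participant_landmarks.subset(common)
        warped = warp_geometry(model, tpl_ls, par_ls, cfg.tps)
    except ValueError as e:
        raise PipelineError("warp", str(e)) from e

    # stage 3: manual corrections
    if cfg.corrections:
        warped = apply_manual_corrections(warped, cfg.corrections)

    # stage 4: frames + localization (kept alongside the global model)
    try:
        frames = build_frames(warped.landmarks)
        localized = localize(warped, frames)
    except ValueError as e:
        raise PipelineError("frames", str(e)) from e

    # stage 5: wrap-surface check / radius reduction (on the global model)
    violations = check_wrap_violations(warped)
    warped = reduce_wrap_radii(warped, cfg.wrap_safety)

    # stage 6: via-point optimization against generic references
    opt_report = {}
    if cfg.optimize_muscles:
        refs = make_reference_waveforms(model)
        for mname in cfg.optimize_muscles:
            per_joint = {j: wfs[mname] for j, wfs in refs.items() if mname in wfs}
            warped, rep = optimize_via_points(warped, mname, per_joint, seed=cfg.seed)
            opt_report[mname] = {"before": rep["before"].total, "after": rep["after"].total}

    # stage 7: measures + reports
    report = anthropometry.measure_model(warped)
    save_model(warped, out_dir / "personalized_model.json")
    frames2 = build_frames(warped.landmarks)
    save_model(localize(warped, frames2), out_dir / "personalized_model_local.json")
    summary = {
        "measures": report.measures_a,
        "units": report.units,
        "wrap_violations_before_reduction": [
            {"muscle": m, "point": p, "wrap": w, "distance_m": d}
            for m, p, w, d in violations],
        "via_point_optimization": opt_report,
        "model_path": str(out_dir / "personalized_model.json"),
    }
    (out_dir / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    return summary
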
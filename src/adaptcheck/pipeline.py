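"""End-to-end adaptive-check workflow.

Eight stages, in order: (1) data import; (2) isocenter-prealigned rigid
registration and combined-CT splicing; (3) CBCT HU calibration (synthetic
CT); (4) fraction-day influencer masks (a required input — supplied by the
phantom ground truth or by the user, standing in for learned
auto-segmentation); (5) intensity deformable registration planning CT ->
combined CT, rigid-organ contour propagation and deformed-CT production;
(6) label-mask construction and structure-guided ROI registration with
CTV/PTV propagation; (7) dose recomputation on the deformed CT with the
original plan; (8) dosimetric evaluation against the original plan and the
adapt / review / no-adaptation recommendation.

Every stage is deterministic, so re-running an identical configuration
reproduces the artifacts bit for bit.  Per-stage wall times are logged in
the run manifest but never asserted.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .combine import build_combined_ct, calibrate_hu, make_deformed_ct
from .core import ImageVolume, StructureSet, resample
from .dose import compute_plan_dose
from .evaluate import ARTPolicy, FractionReport, dsc, evaluate_fraction
from .phantom import PhantomCase, PhantomParams, generate_case
from .registration import (
    RegistrationConfig,
    prealign,
    propagate_mask,
    register_bspline,
    register_rigid,
)
from .roi import build_label_mask, propagate_targets, register_roi
from .rtio import write_image, write_report

log = logging.getLogger("adaptcheck.pipeline")

__all__ = ["PipelineConfig", "PipelineResult", "StageError", "run_adaptive_check",
           "run_cohort"]


class StageError(RuntimeError):
    """Raised when a workflow stage fails; carries the stage name and an
    inputs manifest so partial runs can be diagnosed."""

    def __init__(self, stage: str, manifest: dict, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.manifest = manifest
        self.cause = cause


@dataclass
class PipelineConfig:
    """Declarative run configuration; every knob is echoed into the manifest."""

    rigid: RegistrationConfig = field(default_factory=RegistrationConfig)
    deformable: RegistrationConfig = field(
        default_factory=lambda: RegistrationConfig(
            metric="mean_squared_difference", control_spacing=25.0,
            smoothness_weight=0.05, pyramid_levels=2, max_iterations=80,
        )
    )
    roi: RegistrationConfig = field(
        default_factory=lambda: RegistrationConfig(
            metric="mean_squared_difference", control_spacing=25.0,
            smoothness_weight=0.05, pyramid_levels=2, max_iterations=50,
        )
    )
    policy: ARTPolicy = field(default_factory=ARTPolicy)
    blend_mm: float = 5.0
    out_dir: str | None = None
    save_volumes: bool = False


@dataclass
class PipelineResult:
    report: FractionReport
    rigid_transform: object
    prealign_branch: str
    sct: ImageVolume
    combined_ct: ImageVolume
    dpct: ImageVolume
    dvf_dir: object
    dvf_roi: object
    fraction_dose: object
    fraction_structures: StructureSet  # on the planning grid
    propagated_targets: StructureSet
    timings: dict
    manifest: dict


def _fraction_masks_to_planning(case: PhantomCase, rigid) -> StructureSet:
    """Bring provider-supplied fraction-day masks (CBCT grid) into the
    planning frame via the estimated rigid transform."""
    grid = case.planning_ct.grid
    masks = {
        n: propagate_mask(case.fraction_structures.masks[n], rigid,
                          case.fraction_structures.grid, grid)
        for n in case.fraction_structures.names()
    }
    return StructureSet(grid, masks, dict(case.fraction_structures.roles))


def run_adaptive_check(case: PhantomCase, config: PipelineConfig | None = None) -> PipelineResult:
    """Run the eight-stage workflow on one fraction case.

    ``case`` supplies everything a clinical run reads from disk: planning
    CT + structures + plan + reference dose, the fraction CBCT, and the
    fraction-day organ masks.  Any stage error aborts with the stage name
    and an inputs manifest; artifacts produced so far are kept on the
    exception side.
    """
    cfg = config or PipelineConfig()
    manifest: dict = {"stages": {}, "config": {
        "blend_mm": cfg.blend_mm,
        "rigid": vars(cfg.rigid).copy(),
        "deformable": vars(cfg.deformable).copy(),
        "roi": vars(cfg.roi).copy(),
        "policy": vars(cfg.policy).copy(),
    }}
    timings: dict = {}

    def stage(name):
        class _Ctx:
            def __enter__(self_):
                self_.t0 = time.perf_counter()
                return self_

            def __exit__(self_, exc_type, exc, tb):
                dt = time.perf_counter() - self_.t0
                timings[name] = dt
                manifest["stages"][name] = {"seconds": dt, "ok": exc is None}
                log.info("stage %-22s %6.2f s %s", name, dt, "" if exc is None else "FAILED")
                if exc is not None and not isinstance(exc, StageError):
                    raise StageError(name, manifest, exc) from exc
                return False

        return _Ctx()

    with stage("1_import"):
        if case.planning_ct is None or case.cbct is None:
            raise ValueError("planning CT and fraction CBCT are both required")
        if case.fraction_structures is None:
            raise ValueError(
                "fraction-day organ masks are required (auto-segmentation is an "
                "external provider)"
            )
        plan = case.plan
        manifest["inputs"] = {
            "planning_grid": list(case.planning_ct.grid.size),
            "cbct_grid": list(case.cbct.grid.size),
            "isocenter": None if plan.isocenter is None else list(plan.isocenter),
            "prescription": plan.prescription_dose,
        }

    with stage("2_rigid"):
        pre = prealign(case.planning_ct, case.cbct, plan.isocenter)
        branch = pre.prealign_branch
        rigid = register_rigid(case.planning_ct, case.cbct, pre, cfg.rigid)
        manifest["prealign_branch"] = branch

    with stage("3_synthetic_ct"):
        ct_in_cbct = resample(case.planning_ct, case.cbct.grid, rigid.inverse(), "linear")
        fov_mask = case.cbct.values > -999.5
        sct = calibrate_hu(case.cbct, ct_in_cbct, fov_mask)

    with stage("4_fraction_masks"):
        frac_structs = _fraction_masks_to_planning(case, rigid)

    with stage("5_deformable"):
        combined = build_combined_ct(case.planning_ct, sct, rigid, fov_mask, cfg.blend_mm)
        dvf_dir = register_bspline(combined, case.planning_ct, None, cfg.deformable)
        grid = case.planning_ct.grid
        rigid_organ_masks = {
            n: propagate_mask(case.structures.masks[n], dvf_dir, grid, grid)
            for n in case.structures.with_role("rigid_organ")
        }
        dpct = make_deformed_ct(case.planning_ct, dvf_dir)

    with stage("6_roi_registration"):
        label_ct = build_label_mask(case.structures)
        label_frac = build_label_mask(frac_structs)
        dvf_roi = register_roi(label_ct, label_frac, cfg.roi)
        targets = propagate_targets(
            case.structures.subset([n for n in ("CTV", "PTV") if case.structures.has(n)]),
            dvf_roi,
        )

    with stage("7_dose"):
        fraction_dose = compute_plan_dose(dpct, plan, case.planning_ct.grid)

    with stage("8_evaluate"):
        eval_masks = dict(targets.masks)
        eval_roles = dict(targets.roles)
        for n in frac_structs.names():
            if frac_structs.roles[n] == "influencer":
                eval_masks[n] = frac_structs.masks[n]
                eval_roles[n] = "influencer"
        for n, m in rigid_organ_masks.items():
            if n not in eval_masks:
                eval_masks[n] = m
                eval_roles[n] = "rigid_organ"
        eval_structs = StructureSet(case.planning_ct.grid, eval_masks, eval_roles)
        reference_dose = case.reference_dose
        if reference_dose is None:
            reference_dose = compute_plan_dose(case.planning_ct, plan)
        report = evaluate_fraction(
            fraction_dose, eval_structs, reference_dose, case.structures, plan,
            cfg.policy,
        )

    result = PipelineResult(
        report=report, rigid_transform=rigid, prealign_branch=branch, sct=sct,
        combined_ct=combined, dpct=dpct, dvf_dir=dvf_dir, dvf_roi=dvf_roi,
        fraction_dose=fraction_dose, fraction_structures=frac_structs,
        propagated_targets=targets, timings=timings, manifest=manifest,
    )
    if cfg.out_dir:
        _write_artifacts(result, case, cfg)
    return result


def _write_artifacts(result: PipelineResult, case: PhantomCase, cfg: PipelineConfig):
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_report(result.report, out / "report")
    with open(out / "manifest.json", "w") as f:
        json.dump(result.manifest, f, indent=2)
    if cfg.save_volumes:
        write_image(result.sct, out / "sct.nii.gz")
        write_image(result.combined_ct, out / "combined_ct.nii.gz")
        write_image(result.dpct, out / "dpct.nii.gz")
        write_image(result.fraction_dose, out / "fraction_dose.nii.gz")


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

def propagation_dsc_table(case: PhantomCase, result: PipelineResult) -> dict:
    """Per-structure Dice of the three target-propagation routes against the
    ground-truth fraction anatomy, all in the planning frame: rigid (no
    deformation), intensity deformable registration, and ROI registration."""
    grid = case.planning_ct.grid
    gt = _fraction_masks_to_planning(case, result.rigid_transform)
    rows = {}
    for name in ("CTV", "PTV"):
        if not case.structures.has(name):
            continue
        truth = gt.get(name)
        planned = case.structures.get(name)
        via_dir = propagate_mask(planned, result.dvf_dir, grid, grid)
        via_roi = result.propagated_targets.get(name)
        rows[name] = {
            "rigid": dsc(planned, truth),
            "dir": dsc(via_dir, truth),
            "roi": dsc(via_roi, truth),
        }
    return rows


def run_cohort(
    params: PhantomParams | None = None,
    n_cases: int = 10,
    seed: int = 0,
    config: PipelineConfig | None = None,
):
    """Generate ``n_cases`` phantoms, run the full check on each, and return
    (per-fraction metric rows, DSC comparison rows) as pandas DataFrames.
    Deterministic given (params, n_cases, seed, config)."""
    import pandas as pd

    params = params or PhantomParams()
    cfg = config or PipelineConfig()
    metric_rows, dsc_rows = [], []
    for k in range(n_cases):
        case_seed = seed + k
        case = generate_case(params, case_seed)
        result = run_adaptive_check(case, cfg)
        for structure, metrics in result.report.metrics.items():
            for mname, vals in metrics.items():
                metric_rows.append(
                    {
                        "case": case_seed, "structure": structure, "metric": mname,
                        "original": vals.get("original"),
                        "fraction": vals.get("fraction"),
                        "delta": vals.get("delta"),
                        "recommendation": result.report.recommendation,
                    }
                )
        for structure, row in propagation_dsc_table(case, result).items():
            dsc_rows.append({"case": case_seed, "structure": structure, **row})
    metrics = pd.DataFrame(metric_rows)
    dscs = pd.DataFrame(dsc_rows)
    return metrics, dscs


def summarize_cohort(metrics, dscs):
    """Mean +- SD summaries of a cohort run (printable tables)."""
    m = (
        metrics.groupby(["structure", "metric"])[["original", "fraction", "delta"]]
        .agg(["mean", "std"])
    )
    d = dscs.groupby("structure")[["rigid", "dir", "roi"]].agg(["mean", "std"])
    return m, d
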
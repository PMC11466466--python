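"""Structure-guided ROI registration for target propagation.

The nine regions of interest around a cervical-cancer target — skin, left
and right femoral heads, pelvis, spinal cord, rectum, small intestine and
bladder — are combined into one label image with values 0-8 in that order
(air = 0), increasing with importance for the target.  A deformation field
is then optimized between the planning-day and fraction-day label images
and used to propagate CTV/PTV onto the anatomy of the day.  Because only
organ masks enter the objective, the result is completely insensitive to
CBCT intensity quality.

Labels are not registered on their raw integer values (arithmetic on labels
is meaningless): each label region is converted to a signed Euclidean
distance map clamped to +-20 mm, and a multi-channel sum of squared
differences across those maps is minimized with the shared B-spline engine.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .core import DisplacementField, ImageGrid, StructureSet
from .registration import RegistrationConfig, ffd_register_channels, propagate_mask

log = logging.getLogger("adaptcheck.roi")

__all__ = ["LABEL_ORDER", "LabelVolume", "build_label_mask", "register_roi",
           "propagate_targets"]

#: Fixed label assignment, ordered by increasing importance for the target.
LABEL_ORDER = [
    ("air", 0),
    ("skin", 1),
    ("femoral_head_l", 2),
    ("femoral_head_r", 3),
    ("pelvis", 4),
    ("spinal_cord", 5),
    ("rectum", 6),
    ("small_intestine", 7),
    ("bladder", 8),
]

_NAME_TO_LABEL = dict(LABEL_ORDER)
_SDF_CLAMP_MM = 20.0


@dataclass
class LabelVolume:
    """Integer label image on a grid; every voxel's label is in 0..8."""

    grid: ImageGrid
    labels: np.ndarray

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if tuple(self.labels.shape) != tuple(self.grid.size):
            raise ValueError("label array shape does not match grid")
        if self.labels.min() < 0 or self.labels.max() > 8:
            raise ValueError("labels must lie in 0..8")

    @property
    def mapping(self):
        return list(LABEL_ORDER)

    def counts(self) -> dict:
        vals, cnt = np.unique(self.labels, return_counts=True)
        return {int(v): int(c) for v, c in zip(vals, cnt)}

    def region(self, label: int) -> np.ndarray:
        """Binary region for a label.  Skin (1) means the whole body: every
        non-air voxel lies inside the skin surface."""
        if label == 1:
            return self.labels >= 1
        return self.labels == label


def build_label_mask(structures: StructureSet) -> LabelVolume:
    """Collapse ROI masks into one label image.

    Overlaps resolve to the highest (most target-important) label, and
    voxels outside the skin outline are forced to air.  Missing ROIs are
    allowed (logged); a missing skin is an error, since the body outline
    anchors the whole label image.
    """
    if not structures.has("skin"):
        raise ValueError("label mask requires a 'skin' structure (body outline)")
    labels = np.zeros(structures.grid.size, dtype=np.int16)
    for name, value in LABEL_ORDER[1:]:
        if not structures.has(name):
            log.info("ROI %s absent from structure set; skipped", name)
            continue
        m = structures.get(name)
        labels[m] = np.maximum(labels[m], value)
    labels[~structures.get("skin")] = 0
    return LabelVolume(structures.grid, labels)


def _signed_distance(mask: np.ndarray, spacing) -> np.ndarray:
    """Signed Euclidean distance map (mm), negative inside, clamped."""
    if not mask.any():
        return np.full(mask.shape, _SDF_CLAMP_MM)
    inside = ndimage.distance_transform_edt(mask, sampling=spacing)
    outside = ndimage.distance_transform_edt(~mask, sampling=spacing)
    return np.clip(outside - inside, -_SDF_CLAMP_MM, _SDF_CLAMP_MM)


def register_roi(
    mask_ct: LabelVolume,
    mask_cbct: LabelVolume,
    config: RegistrationConfig | None = None,
) -> DisplacementField:
    """Optimize the target-propagation DVF from the two label images.

    Each label present on both sides contributes one clamped signed-
    distance channel; absent labels are dropped from the objective (logged).
    The registration runs fixed = fraction-day labels, moving = planning-day
    labels, so the returned pull field maps a fraction-anatomy point to the
    corresponding planning-anatomy point — exactly what propagating planning
    contours onto the fraction anatomy requires.  Fewer than 3 shared
    non-air labels is an error (insufficient guidance).
    """
    cfg = config or RegistrationConfig(
        metric="mean_squared_difference", control_spacing=25.0,
        smoothness_weight=0.05, pyramid_levels=2, max_iterations=50,
    )
    shared = []
    for name, value in LABEL_ORDER[1:]:
        on_ct = bool(mask_ct.region(value).any())
        on_cbct = bool(mask_cbct.region(value).any())
        if on_ct and on_cbct:
            shared.append(value)
        elif on_ct != on_cbct:
            log.info("ROI %s present on one side only; channel dropped", name)
    if len(shared) < 3:
        raise ValueError(
            f"only {len(shared)} shared non-air labels; need >= 3 for guidance"
        )

    sp_f = mask_cbct.grid.spacing
    sp_m = mask_ct.grid.spacing
    fixed_ch = [_signed_distance(mask_cbct.region(v), sp_f) for v in shared]
    moving_ch = [_signed_distance(mask_ct.region(v), sp_m) for v in shared]
    return ffd_register_channels(
        fixed_ch, moving_ch, mask_cbct.grid, mask_ct.grid, cfg,
        active_band=0.4 * _SDF_CLAMP_MM,
    )


def propagate_targets(
    targets: StructureSet,
    dvf: DisplacementField,
    target_grid: ImageGrid | None = None,
) -> StructureSet:
    """Warp CTV/PTV through the ROI-registration field.

    Containment PTV >= CTV is repaired by union if the warp violates it
    (logged).  An empty input or output target is an error: an empty output
    flags an implausible deformation.
    """
    grid = target_grid or targets.grid
    out = {}
    for name in targets.names():
        m = targets.masks[name]
        if not m.any():
            raise ValueError(f"target {name} is empty before propagation")
        w = propagate_mask(m, dvf, targets.grid, grid)
        if not w.any():
            raise ValueError(
                f"target {name} vanished under propagation; deformation implausible"
            )
        out[name] = w
    if "CTV" in out and "PTV" in out:
        escaped = out["CTV"] & ~out["PTV"]
        if escaped.any():
            log.warning(
                "PTV no longer contains CTV after propagation (%d voxels); "
                "repairing by union", int(escaped.sum()),
            )
            out["PTV"] = out["PTV"] | out["CTV"]
    return StructureSet(grid, out, {n: "target" for n in out})
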
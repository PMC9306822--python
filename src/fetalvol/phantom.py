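"""Seeded synthetic phantoms of a late-first-trimester fetal trunk.

The generator emulates a transvaginal 3D ultrasound acquisition of the fetal
trunk as a grayscale Cartesian volume: five organs (heart, both lungs, both
kidneys) rendered as rotated ellipsoids with organ-vs-background intensity
contrast, multiplicative speckle noise and optional acoustic shadow cones.
Ellipsoids keep the ground-truth volume closed-form, (4/3)·π·a·b·c, which is
what the measurement pipeline is validated against.

Intensity defaults are chosen so that the clinical difficulty ranking is
reproduced qualitatively: lungs and heart are high-contrast against the
background (easy to delineate), kidneys sit only ~25 grayscale levels above
background (hard, mimicking poor demarcation from intestines and liver).

Speckle is a clamped multiplicative Gaussian field,
``I -> clip(I * (1 + sigma * Z), 0, 255)`` with one standard-normal draw per
voxel — a deliberate one-parameter simplification of Rayleigh envelope
statistics (see docs/methods.md).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import SpecificationError
from .voxvol import ORGAN_LABELS, SegmentMask, VoxelVolume

# Plausible analytic-volume range per organ (mm³), matching the spread of
# measured first-trimester organ volumes (heart ~39-409 mm³ etc.).
ORGAN_VOLUME_RANGES_MM3 = {
    "heart": (39.0, 409.0),
    "lung_right": (92.0, 811.0),
    "lung_left": (74.0, 543.0),
    "kidney_right": (28.0, 245.0),
    "kidney_left": (20.0, 216.0),
}

# ellipsoid semi-axis ratios (product ~1 so they scale an equivalent radius)
_AXIS_RATIOS = {
    "heart": (1.10, 0.95, 0.957),
    "lung_right": (0.85, 0.80, 1.47),
    "lung_left": (0.85, 0.80, 1.47),
    "kidney_right": (0.80, 0.75, 1.667),
    "kidney_left": (0.80, 0.75, 1.667),
}

# organ centers as fractions of the physical grid extent
_CENTER_FRACTIONS = {
    "lung_right": (0.30, 0.33, 0.68),
    "lung_left": (0.70, 0.33, 0.68),
    "heart": (0.50, 0.67, 0.62),
    "kidney_right": (0.31, 0.57, 0.27),
    "kidney_left": (0.69, 0.57, 0.27),
}

_ROTATIONS_DEG = {
    "heart": (0.0, 0.0, 0.0),
    "lung_right": (0.0, 0.0, 0.0),
    "lung_left": (0.0, 0.0, 0.0),
    "kidney_right": (0.0, 0.0, -15.0),
    "kidney_left": (0.0, 0.0, 15.0),
}

DEFAULT_BACKGROUND_INTENSITY = 60.0
DEFAULT_ORGAN_INTENSITIES = {
    "heart": 180.0,
    "lung_right": 170.0,
    "lung_left": 165.0,
    "kidney_right": 85.0,  # low contrast: poor demarcation from abdomen
    "kidney_left": 85.0,
}
DEFAULT_SPECKLE_SIGMA = 0.10
DEFAULT_SHAPE = (96, 96, 96)
DEFAULT_SPACING_MM = 0.35


@dataclass
class OrganSpec:
    """One organ as a rotated ellipsoid with a mean grayscale intensity.

    ``core_fraction`` > 0 carves a concentric low-intensity core (e.g. the
    heart blood pool) rendered at ``core_intensity``; the ground-truth mask
    still covers the full ellipsoid.
    """

    label: str
    center_mm: tuple[float, float, float]
    semi_axes_mm: tuple[float, float, float]
    rotation_deg: tuple[float, float, float] = (0.0, 0.0, 0.0)
    mean_intensity: float = 180.0
    core_fraction: float = 0.0
    core_intensity: float = 0.0

    def __post_init__(self) -> None:
        if any(a <= 0 for a in self.semi_axes_mm):
            raise SpecificationError(f"{self.label}: semi-axes must all be > 0")
        if not 0.0 <= self.core_fraction < 1.0:
            raise SpecificationError(f"{self.label}: core_fraction must be in [0, 1)")

    @property
    def analytic_volume_mm3(self) -> float:
        a, b, c = self.semi_axes_mm
        return 4.0 / 3.0 * math.pi * a * b * c


@dataclass
class ShadowCone:
    """Acoustic shadow: intensities inside the cone are multiplied by ``attenuation``."""

    apex_mm: tuple[float, float, float]
    axis: tuple[float, float, float]
    half_angle_deg: float
    attenuation: float


@dataclass
class PhantomSpec:
    shape: tuple[int, int, int] = DEFAULT_SHAPE
    spacing_mm: tuple[float, float, float] = (DEFAULT_SPACING_MM,) * 3
    background_intensity: float = DEFAULT_BACKGROUND_INTENSITY
    organs: list[OrganSpec] = field(default_factory=list)
    speckle_sigma: float = DEFAULT_SPECKLE_SIGMA
    shadow_cones: list[ShadowCone] = field(default_factory=list)
    seed: int = 0
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.speckle_sigma < 0:
            raise SpecificationError("speckle_sigma must be >= 0")
        for ints in [self.background_intensity] + [o.mean_intensity for o in self.organs]:
            if not 0.0 <= ints <= 255.0:
                raise SpecificationError(f"intensity {ints} outside [0, 255]")


@dataclass
class PhantomTruth:
    """A generated phantom together with its ground truth."""

    volume: VoxelVolume
    masks: dict[str, SegmentMask]
    analytic_volumes_mm3: dict[str, float]
    voxelized_volumes_mm3: dict[str, float]
    spec: PhantomSpec


def _voxelize_organ(organ: OrganSpec, spec: PhantomSpec):
    """Boolean mask of voxels whose physical centers fall inside the ellipsoid.

    Returns (slices, box_mask, box_core) restricted to a bounding box.
    """
    rot = Rotation.from_euler("xyz", organ.rotation_deg, degrees=True).as_matrix()
    r_max = max(organ.semi_axes_mm)
    slices, axes = [], []
    for a in range(3):
        n = spec.shape[a]
        sp = spec.spacing_mm[a]
        lo = organ.center_mm[a] - r_max - sp
        hi = organ.center_mm[a] + r_max + sp
        i0 = max(0, int(math.floor((lo - spec.origin_mm[a]) / sp - 0.5)))
        i1 = min(n, int(math.ceil((hi - spec.origin_mm[a]) / sp + 0.5)))
        i1 = max(i1, i0 + 1)
        slices.append(slice(i0, i1))
        axes.append(spec.origin_mm[a] + (np.arange(i0, i1) + 0.5) * sp)
    xx, yy, zz = np.meshgrid(*axes, indexing="ij")
    rel = np.stack(
        [xx - organ.center_mm[0], yy - organ.center_mm[1], zz - organ.center_mm[2]], axis=-1
    )
    local = rel @ rot  # rows are R^T @ rel
    q = (
        (local[..., 0] / organ.semi_axes_mm[0]) ** 2
        + (local[..., 1] / organ.semi_axes_mm[1]) ** 2
        + (local[..., 2] / organ.semi_axes_mm[2]) ** 2
    )
    box_mask = q <= 1.0
    box_core = q <= organ.core_fraction**2 if organ.core_fraction > 0 else None
    return tuple(slices), box_mask, box_core


def generate_phantom(spec: PhantomSpec) -> PhantomTruth:
    """Voxelize, compose and speckle one phantom; deterministic for a fixed seed."""
    labels = [o.label for o in spec.organs]
    if len(set(labels)) != len(labels):
        raise SpecificationError(f"duplicate organ labels in spec: {labels}")

    masks: dict[str, SegmentMask] = {}
    boxes = {}
    for organ in spec.organs:
        sl, box, core = _voxelize_organ(organ, spec)
        full = np.zeros(spec.shape, dtype=bool)
        full[sl] = box
        masks[organ.label] = SegmentMask(full, organ_label=organ.label)
        boxes[organ.label] = (sl, box, core)

    for i, a in enumerate(spec.organs):
        for b in spec.organs[i + 1 :]:
            if np.any(masks[a.label].data & masks[b.label].data):
                raise SpecificationError(
                    f"organs overlap after voxelization: ({a.label}, {b.label})"
                )

    img = np.full(spec.shape, float(spec.background_intensity))
    for organ in spec.organs:
        sl, box, core = boxes[organ.label]
        img[sl][box] = organ.mean_intensity
        if core is not None:
            img[sl][core] = organ.core_intensity

    if spec.shadow_cones:
        axes = [
            spec.origin_mm[a] + (np.arange(spec.shape[a]) + 0.5) * spec.spacing_mm[a]
            for a in range(3)
        ]
        xx, yy, zz = np.meshgrid(*axes, indexing="ij")
        for cone in spec.shadow_cones:
            d = np.stack(
                [xx - cone.apex_mm[0], yy - cone.apex_mm[1], zz - cone.apex_mm[2]], axis=-1
            )
            norm = np.linalg.norm(d, axis=-1)
            ax = np.asarray(cone.axis, dtype=float)
            ax = ax / np.linalg.norm(ax)
            with np.errstate(invalid="ignore", divide="ignore"):
                cosang = (d @ ax) / norm
            inside = (norm > 0) & (cosang >= math.cos(math.radians(cone.half_angle_deg)))
            img[inside] *= cone.attenuation

    if spec.speckle_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        img = img * (1.0 + spec.speckle_sigma * rng.standard_normal(spec.shape))
    img = np.clip(img, 0.0, 255.0)

    vol = VoxelVolume(
        img, spec.spacing_mm, spec.origin_mm, meta={"nominal_volume_angle_deg": 40}
    )
    voxel_mm3 = vol.voxel_volume_mm3
    return PhantomTruth(
        volume=vol,
        masks=masks,
        analytic_volumes_mm3={o.label: o.analytic_volume_mm3 for o in spec.organs},
        voxelized_volumes_mm3={lbl: m.voxel_count * voxel_mm3 for lbl, m in masks.items()},
        spec=spec,
    )


def _subject_seed(master_seed: int, subject_index: int) -> int:
    return int(np.random.SeedSequence([master_seed, subject_index]).generate_state(1)[0] % (2**31))


def default_study_spec(
    n_subjects: int,
    seed: int,
    shape: tuple[int, int, int] = DEFAULT_SHAPE,
    spacing_mm: float | tuple[float, float, float] = DEFAULT_SPACING_MM,
    speckle_sigma: float = DEFAULT_SPECKLE_SIGMA,
    heart_core: bool = False,
) -> list[PhantomSpec]:
    """Per-subject phantom specs emulating late-first-trimester growth.

    Each subject gets a size factor ``u`` ~ Uniform(0, 1); every organ's
    analytic volume is placed at ``min + (0.04 + 0.92 u) * (max - min)`` of its
    plausible range, so volumes stay inside the range and are monotone in the
    per-subject size factor (volumes grow together with fetal size).  Subject
    seeds are derived deterministically from the master seed, so any subject is
    regenerable in isolation.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    if np.isscalar(spacing_mm):
        spacing_mm = (float(spacing_mm),) * 3
    extent = tuple(shape[a] * spacing_mm[a] for a in range(3))
    specs = []
    for s in range(n_subjects):
        rng = np.random.default_rng([seed, s])
        u = float(rng.uniform())
        organs = []
        for label in ORGAN_LABELS:
            vmin, vmax = ORGAN_VOLUME_RANGES_MM3[label]
            vol = vmin + (0.04 + 0.92 * u) * (vmax - vmin)
            r_eq = (3.0 * vol / (4.0 * math.pi)) ** (1.0 / 3.0)
            ratios = _AXIS_RATIOS[label]
            semi = tuple(r * r_eq for r in ratios)
            # rescale exactly so (4/3)pi*a*b*c == vol despite ratio rounding
            corr = (vol / (4.0 / 3.0 * math.pi * semi[0] * semi[1] * semi[2])) ** (1.0 / 3.0)
            semi = tuple(a * corr for a in semi)
            kwargs = {}
            if label == "heart" and heart_core:
                kwargs = {"core_fraction": 0.45, "core_intensity": 100.0}
            organs.append(
                OrganSpec(
                    label=label,
                    center_mm=tuple(_CENTER_FRACTIONS[label][a] * extent[a] for a in range(3)),
                    semi_axes_mm=semi,
                    rotation_deg=_ROTATIONS_DEG[label],
                    mean_intensity=DEFAULT_ORGAN_INTENSITIES[label],
                    **kwargs,
                )
            )
        specs.append(
            PhantomSpec(
                shape=tuple(shape),
                spacing_mm=spacing_mm,
                organs=organs,
                speckle_sigma=speckle_sigma,
                seed=_subject_seed(seed, s),
            )
        )
    return specs
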
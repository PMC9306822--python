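"""Brush editing and simulated imperfect observers.

Manual segmentation is modelled at two levels:

* :func:`apply_brush` — the interactive spherical brush: voxels whose centers
  lie within a Euclidean radius (in voxel units) of the stroke center are
  added to or erased from the mask.

* :func:`simulate_segmentation` — a statistical stand-in for a human operator
  used in reproducibility experiments.  The ground-truth mask is rescaled
  about its centroid by a multiplicative size bias, then the boundary is
  displaced radially by a smooth random field built from real spherical
  harmonics of degree 1–3 with independent seeded coefficients.  The field is
  exactly mean-zero over directions with per-direction marginal
  N(0, jitter_sd²) (voxels); a constant radial offset, solved once per shape
  so that the *expected* voxel count equals the noiseless count, removes the
  volume inflation (~3·jitter_sd²/r²) that a raw mean-zero boundary
  displacement produces through convexity.  With probability ``miss_rate``
  the observer fails to produce a measurement, independently per
  subject/organ/repeat.

Results are deterministic given ``(seed, subject, organ, repeat)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.special import sph_harm_y

from .voxvol import ORGAN_LABELS, SegmentMask

_FACE_STRUCT = ndimage.generate_binary_structure(3, 1)
_LMAX = 3
_N_HARMONICS = sum(2 * l + 1 for l in range(1, _LMAX + 1))  # 15


@dataclass
class BrushStroke:
    """One spherical brush application in voxel coordinates."""

    center: tuple[int, int, int]
    radius: float  # voxels, may be fractional
    mode: str = "add"  # add | erase

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("brush radius must be > 0")
        if self.mode not in ("add", "erase"):
            raise ValueError(f"unknown brush mode {self.mode!r}")


@dataclass
class ObserverModel:
    """Statistical model of one operator's segmentation behaviour.

    scale_bias
        Multiplicative linear-size bias; 1.0 = unbiased.  The produced volume
        scales with ``scale_bias**3``.
    jitter_sd
        Standard deviation (voxels) of the smooth radial boundary displacement.
    miss_rate
        Probability of failing to produce a measurement for a subject/organ.
    """

    observer_id: str = "obs"
    scale_bias: float = 1.0
    jitter_sd: float = 1.25
    miss_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scale_bias <= 0:
            raise ValueError("scale_bias must be > 0")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be >= 0")
        if not 0.0 <= self.miss_rate <= 1.0:
            raise ValueError("miss_rate must be in [0, 1]")


def apply_brush(mask: SegmentMask, stroke: BrushStroke) -> SegmentMask:
    """Set (add) or clear (erase) all voxels within the stroke's ball.

    Idempotent for repeated identical strokes; voxels outside the ball are
    untouched.
    """
    shape = mask.data.shape
    c = tuple(int(x) for x in stroke.center)
    if not all(0 <= c[a] < shape[a] for a in range(3)):
        raise ValueError(f"stroke center {c} outside grid of shape {shape}")
    r = float(stroke.radius)
    ri = int(math.floor(r))
    sl = tuple(slice(max(0, c[a] - ri), min(shape[a], c[a] + ri + 1)) for a in range(3))
    grids = np.meshgrid(*[np.arange(s.start, s.stop) for s in sl], indexing="ij")
    dist2 = sum((g - c[a]) ** 2 for a, g in enumerate(grids))
    ball = dist2 <= r * r + 1e-12
    out = mask.data.copy()
    if stroke.mode == "add":
        out[sl][ball] = True
    else:
        out[sl][ball] = False
    return SegmentMask(out, organ_label=mask.organ_label)


def _real_sph_harm_basis(theta: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Orthonormal real spherical harmonics of degree 1..LMAX, shape (n, 15)."""
    cols = []
    for l in range(1, _LMAX + 1):
        for m in range(-l, l + 1):
            y = sph_harm_y(l, abs(m), theta, phi)
            if m == 0:
                cols.append(y.real)
            elif m > 0:
                cols.append(math.sqrt(2.0) * (-1.0) ** m * y.real)
            else:
                cols.append(math.sqrt(2.0) * (-1.0) ** m * y.imag)
    return np.stack(cols, axis=-1).astype(np.float64)


class SegmentationSampler:
    """Draws simulated observer segmentations of one ground-truth mask.

    Precomputes, on a padded bounding box around the truth, the signed
    Euclidean distance to the truth boundary, per-voxel directions from the
    truth centroid and the spherical-harmonic basis; each draw then only
    evaluates the random radial displacement field and thresholds the signed
    distance.  All sampling is in voxel units (displacements are isotropic in
    index space).
    """

    def __init__(self, truth: np.ndarray, scale_bias: float = 1.0, jitter_sd: float = 1.25):
        truth = np.asarray(truth, dtype=bool)
        if not truth.any():
            raise ValueError("truth mask is empty")
        self.shape = truth.shape
        self.scale_bias = float(scale_bias)
        self.jitter_sd = float(jitter_sd)

        idx = np.argwhere(truth)
        centroid = idx.mean(axis=0)
        r_max = float(np.sqrt(((idx - centroid) ** 2).sum(axis=1).max()))
        pad = int(math.ceil(4.0 + 3.0 * jitter_sd + max(0.0, scale_bias - 1.0) * r_max))
        lo = np.maximum(idx.min(axis=0) - pad, 0)
        hi = np.minimum(idx.max(axis=0) + pad + 1, np.asarray(self.shape))
        self.box = tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))
        tbox = truth[self.box]

        # half-voxel signed distance: the boundary interface sits at 0, the
        # adjacent voxel centers at ±0.5 — keeps the discrete volume response
        # to a radial displacement symmetric and nearly linear
        inside = ndimage.distance_transform_edt(tbox)
        outside = ndimage.distance_transform_edt(~tbox)
        self.signed_dist = np.where(tbox, 0.5 - inside, outside - 0.5).astype(np.float64)

        c_box = centroid - lo
        grids = np.meshgrid(*[np.arange(s.stop - s.start) for s in self.box], indexing="ij")
        rel = np.stack([g - c for g, c in zip(grids, c_box)], axis=-1).astype(np.float64)
        r = np.linalg.norm(rel, axis=-1)
        r_safe = np.where(r == 0, 1.0, r)
        ux, uy, uz = (rel[..., a] / r_safe for a in range(3))
        uz = np.where(r == 0, 1.0, uz)
        theta = np.arccos(np.clip(uz, -1.0, 1.0))
        phi = np.arctan2(uy, ux)
        self.basis = _real_sph_harm_basis(theta, phi).reshape(-1, _N_HARMONICS)

        if self.scale_bias != 1.0:
            coords = np.stack(
                [c + (g - c) / self.scale_bias for g, c in zip(grids, c_box)], axis=0
            ).reshape(3, -1)
            self._sd_flat = ndimage.map_coordinates(
                self.signed_dist, coords, order=1, mode="nearest"
            )
        else:
            self._sd_flat = self.signed_dist.reshape(-1)
        self._delta = self._volume_preserving_offset()

    def _volume_preserving_offset(self) -> float:
        """Constant radial offset delta making the expected voxel count equal
        the noiseless count.

        A voxel at (scaled) signed distance d is included iff the radial
        field exceeds ``scale_bias*d - delta``; each direction's field value
        is exactly N(0, jitter_sd²) (spherical-harmonic addition theorem), so
        the expected count is a sum of normal CDFs and the unbiasedness
        condition has a unique root, found by Newton iteration.
        """
        if self.jitter_sd == 0:
            return 0.0
        from scipy.special import ndtr

        sigma = self.jitter_sd
        x = self.scale_bias * self._sd_flat
        target = float((x <= 0).sum())
        near = np.abs(x) <= 8.0 * sigma
        base = float((x[~near] <= 0).sum())
        xn = x[near]
        delta = 0.0
        for _ in range(50):
            z = (delta - xn) / sigma
            f = base + float(ndtr(z).sum()) - target
            slope = float(np.exp(-0.5 * z**2).sum()) / (sigma * math.sqrt(2.0 * math.pi))
            if slope <= 0:
                break
            step = f / slope
            delta -= step
            if abs(step) < 1e-10:
                break
        return float(delta)

    def sample(self, rng: np.random.Generator, keep_largest: bool = True) -> np.ndarray:
        """One simulated segmentation as a boolean array on the full grid."""
        if self.jitter_sd > 0:
            coeffs = rng.standard_normal(_N_HARMONICS) * self.jitter_sd * math.sqrt(
                4.0 * math.pi / _N_HARMONICS
            )
            thresh = (self.basis @ coeffs + self._delta) / self.scale_bias
        else:
            thresh = 0.0
        box_mask = (self._sd_flat <= thresh).reshape(
            tuple(s.stop - s.start for s in self.box)
        )
        if keep_largest and box_mask.any():
            labels, n = ndimage.label(box_mask, structure=_FACE_STRUCT)
            if n > 1:
                sizes = ndimage.sum_labels(box_mask, labels, index=np.arange(1, n + 1))
                box_mask = labels == (1 + int(np.argmax(sizes)))
        out = np.zeros(self.shape, dtype=bool)
        out[self.box] = box_mask
        return out


def _observation_rng(model: ObserverModel, subject_index: int, organ_index: int,
                     repeat_index: int) -> np.random.Generator:
    return np.random.default_rng(
        [int(model.seed), int(subject_index), int(organ_index), int(repeat_index)]
    )


def simulate_segmentation(
    truth: SegmentMask,
    model: ObserverModel,
    repeat_index: int,
    subject_index: int = 0,
    sampler: SegmentationSampler | None = None,
) -> SegmentMask | None:
    """Simulate one observer segmentation of ``truth``; ``None`` = missed.

    Deterministic given ``(model.seed, subject_index, organ, repeat_index)``.
    A prebuilt :class:`SegmentationSampler` for the same truth/model may be
    passed to amortize precomputation; the random stream is identical.
    """
    if not truth.data.any():
        raise ValueError("cannot simulate segmentation of an empty truth mask")
    organ_index = (
        ORGAN_LABELS.index(truth.organ_label) if truth.organ_label in ORGAN_LABELS else 0
    )
    rng = _observation_rng(model, subject_index, organ_index, repeat_index)
    if rng.uniform() < model.miss_rate:
        return None
    if model.scale_bias == 1.0 and model.jitter_sd == 0.0:
        return SegmentMask(truth.data.copy(), organ_label=truth.organ_label)
    if sampler is None:
        sampler = SegmentationSampler(truth.data, model.scale_bias, model.jitter_sd)
    return SegmentMask(sampler.sample(rng), organ_label=truth.organ_label)
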
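"""Automated grayscale border refinement of a segmentation.

After manual segmentation, every voxel within a Euclidean radius (default 5
voxels) of the segment border is re-examined: let mu and s be the mean and
population SD of the volume intensities over the *pre-refinement* mask; a
shell voxel is included in the refined segment iff its grayscale lies within
``k_sd * s`` of mu (default one SD), otherwise it is excluded.  The rule is
applied symmetrically to shell voxels inside and outside the current mask, so
the pass can both trim the segment and grow it toward the anatomical
boundary.  mu and s are frozen for the whole pass (single-pass algorithm);
additional passes, each with re-estimated mu and s, are available via
``iterations``.

Interpretation notes (choices the algorithm statement leaves open):

* the "average grayscale" reference population is the current segment's own
  voxels — the only cohort the algorithm has;
* "radius of 5 voxels" is Euclidean distance in voxel units from each voxel
  center to the nearest border-voxel center (recorded in RefineStats);
* the SD is the population SD (divide by N); ``s = 0`` degenerates to
  exact-intensity-match inclusion;
* after refinement the largest face-connected component is kept
  (segmentations are single organs); disable with ``keep_largest=False``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import RefinementError
from .voxvol import SegmentMask, VoxelVolume

_STRUCTS = {
    "face": ndimage.generate_binary_structure(3, 1),
    "full": ndimage.generate_binary_structure(3, 3),
}


@dataclass
class RefineParams:
    radius: float = 5.0  # voxels
    k_sd: float = 1.0  # SD multiplier
    border_connectivity: str = "face"  # face (6-neighbor) | full (26-neighbor)
    iterations: int = 1
    keep_largest: bool = True

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be > 0")
        if self.k_sd < 0:
            raise ValueError("k_sd must be >= 0")
        if self.border_connectivity not in _STRUCTS:
            raise ValueError("border_connectivity must be 'face' or 'full'")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")


@dataclass
class RefineStats:
    """Run log of one refinement call (first-pass mu/s; cumulative counts)."""

    mu: float
    sd: float
    voxels_added: int
    voxels_removed: int
    n_border: int
    n_shell: int
    iterations: int
    radius: float
    k_sd: float
    border_connectivity: str
    distance_metric: str = "euclidean_voxel"
    component_voxels_dropped: int = 0

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def segment_border(mask: SegmentMask | np.ndarray, connectivity: str = "face") -> np.ndarray:
    """Boolean array marking mask voxels with >= 1 false/outside neighbor.

    Voxels outside the grid count as false, so a full-grid mask's border is
    the set of voxels on the grid faces.  An empty mask has an empty border.
    """
    data = mask.data if isinstance(mask, SegmentMask) else np.asarray(mask, dtype=bool)
    struct = _STRUCTS[connectivity]
    eroded = ndimage.binary_erosion(data, structure=struct, border_value=0)
    return data & ~eroded


def refine_segmentation(
    vol: VoxelVolume, mask: SegmentMask, params: RefineParams | None = None
) -> tuple[SegmentMask, RefineStats]:
    """Apply the grayscale border-refinement pass(es) to ``mask``.

    Voxels farther than ``params.radius`` from every border voxel never
    change label (locality).  Raises :class:`RefinementError` on an empty
    mask (mu and s are undefined).
    """
    params = params or RefineParams()
    mask.check_aligned(vol)
    if not mask.data.any():
        raise RefinementError("cannot refine an empty segmentation: mu, s undefined")

    data = vol.data
    current = mask.data.copy()
    first_mu = first_sd = None
    n_border = n_shell = 0
    rpad = int(np.ceil(params.radius)) + 1

    for _ in range(params.iterations):
        if not current.any():
            break
        vals = data[current]
        mu = float(vals.mean())
        sd = float(vals.std())  # population SD
        if first_mu is None:
            first_mu, first_sd = mu, sd

        border = segment_border(current, params.border_connectivity)
        idx = np.argwhere(border)
        lo = np.maximum(idx.min(axis=0) - rpad, 0)
        hi = np.minimum(idx.max(axis=0) + rpad + 1, np.asarray(current.shape))
        box = tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))

        # distance from every box voxel to the nearest border-voxel center;
        # exact because the box contains every border voxel
        dist = ndimage.distance_transform_edt(~border[box])
        shell = dist <= params.radius + 1e-9
        n_border = int(border.sum())
        n_shell = int(shell.sum())

        new_box = current[box].copy()
        new_box[shell] = np.abs(data[box][shell] - mu) <= params.k_sd * sd
        current[box] = new_box

    dropped = 0
    if params.keep_largest and current.any():
        labels, n = ndimage.label(current, structure=_STRUCTS["face"])
        if n > 1:
            sizes = ndimage.sum_labels(current, labels, index=np.arange(1, n + 1))
            keep = labels == (1 + int(np.argmax(sizes)))
            dropped = int(current.sum() - keep.sum())
            current = keep

    added = int((current & ~mask.data).sum())
    removed = int((mask.data & ~current).sum())
    stats = RefineStats(
        mu=first_mu,
        sd=first_sd,
        voxels_added=added,
        voxels_removed=removed,
        n_border=n_border,
        n_shell=n_shell,
        iterations=params.iterations,
        radius=params.radius,
        k_sd=params.k_sd,
        border_connectivity=params.border_connectivity,
        component_voxels_dropped=dropped,
    )
    return SegmentMask(current, organ_label=mask.organ_label), stats
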
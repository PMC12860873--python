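"""Semi-automatic lesion delineation at a relative SUVmax threshold.

The interactive protocol is seed + hill-climb + relative threshold +
connected component: a user supplies one seed voxel; the lesion-local
SUVmax is found by hill-climbing from the seed; the mask is the single
26-connected component containing that maximum whose voxels satisfy
SUV >= relative_threshold * SUVmax (default 40%).  Lesions smaller than
``min_voxels`` (default 64) are rejected at QC.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io import PETVolume, LesionMask


class SegmentationError(RuntimeError):
    pass


_STRUCTS = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


@dataclass(frozen=True)
class SegmentationConfig:
    """Delineation parameters.

    relative_threshold : fraction of lesion SUVmax kept (0 < t < 1)
    min_voxels : QC floor on segmented volume, in native-grid voxels
    connectivity : 3-D neighborhood order for components (6, 18 or 26)
    """

    relative_threshold: float = 0.40
    min_voxels: int = 64
    connectivity: int = 26

    def __post_init__(self) -> None:
        if not 0.0 < self.relative_threshold < 1.0:
            raise ValueError("relative_threshold must be in (0, 1)")
        if self.min_voxels < 1:
            raise ValueError("min_voxels must be >= 1")
        if self.connectivity not in _STRUCTS:
            raise ValueError("connectivity must be 6, 18 or 26")


def _hill_climb(values: np.ndarray, seed: tuple[int, int, int],
                struct: np.ndarray) -> tuple[int, int, int]:
    """Greedy ascent from seed to a local SUV maximum over the given neighborhood."""
    offsets = np.argwhere(struct) - 1
    current = tuple(int(c) for c in seed)
    shape = values.shape
    while True:
        best, best_val = current, values[current]
        for off in offsets:
            cand = (current[0] + off[0], current[1] + off[1], current[2] + off[2])
            if all(0 <= c < s for c, s in zip(cand, shape)) and values[cand] > best_val:
                best, best_val = cand, values[cand]
        if best == current:
            return current
        current = tuple(int(c) for c in best)


def segment_lesion(volume: PETVolume, seed_point, config: SegmentationConfig = SegmentationConfig()) -> LesionMask:
    """Delineate one lesion at ``relative_threshold`` x lesion-local SUVmax.

    The SUVmax anchoring the threshold is lesion-local (reached by
    hill-climbing from the seed), not the global image maximum, so other
    avid structures in the field of view cannot contaminate the contour.
    The relative rule makes the mask invariant to positive rescaling of
    the SUV image, and lowering the threshold can only grow the mask.
    """
    seed = tuple(int(s) for s in seed_point)
    if len(seed) != 3 or not all(0 <= s < n for s, n in zip(seed, volume.shape)):
        raise SegmentationError(f"seed {seed} outside grid {volume.shape}")
    if volume.values[seed] <= 0:
        raise SegmentationError(f"seed {seed} lies in background (SUV {volume.values[seed]:g})")

    struct = _STRUCTS[config.connectivity]
    peak = _hill_climb(volume.values, seed, struct)
    suvmax = float(volume.values[peak])
    fg = volume.values >= config.relative_threshold * suvmax
    labels, _ = ndimage.label(fg, structure=struct)
    lesion_label = labels[peak]
    if lesion_label == 0:  # cannot happen: peak satisfies the threshold
        raise SegmentationError("thresholded region empty at the peak")
    return LesionMask(values=labels == lesion_label, spacing=volume.spacing, affine=volume.affine)


@dataclass(frozen=True)
class QCDecision:
    accepted: bool
    reason: str


def qc_filter(mask: LesionMask, config: SegmentationConfig = SegmentationConfig()) -> QCDecision:
    """Reject lesions whose segmented volume falls below ``min_voxels``."""
    n = mask.voxel_count
    if n < config.min_voxels:
        return QCDecision(False, f"segmented volume {n} voxels < minimum {config.min_voxels}")
    return QCDecision(True, f"segmented volume {n} voxels >= minimum {config.min_voxels}")
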
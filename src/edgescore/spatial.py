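"""Spatial hotspot-displacement features and the Edge Proximity Score.

Three measurements anchor the score, all in physical mm on the native grid:

* DmaxC — Euclidean distance from the SUVmax voxel center to the lesion's
  (unweighted) geometric centroid;
* DmaxP — Euclidean distance from the SUVmax voxel center to the nearest
  background voxel center (anisotropic-spacing-aware distance transform);
* R_eq — radius of the sphere with the same volume as the lesion,
  R_eq = (3 V / 4 pi)^(1/3).

Both distances are normalized by the same R_eq (nDmaxC = DmaxC / R_eq,
nDmaxP = DmaxP / R_eq), so the score

    EPS = (nDmaxC - nDmaxP) / (nDmaxC + nDmaxP)

is zero exactly when the hotspot is equidistant from centroid and
perimeter, +1 in the edge limit and -1 in the center limit.  EPS > 0
defines the high-risk stratum.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Optional

import numpy as np
from scipy import ndimage

from .io import PETVolume, LesionMask


class InputError(ValueError):
    pass


@dataclass
class SpatialFeatures:
    """Hotspot geometry of one lesion; distances in mm, scores unitless."""

    hotspot_index: tuple[int, int, int]
    suvmax: float
    centroid_mm: tuple[float, float, float]
    DmaxC: float
    DmaxP: float
    R_eq: float
    nDmaxC: float
    nDmaxP: float
    EPS: Optional[float]
    risk_group: Optional[str]
    hotspot_tie: bool = False

    def to_dict(self) -> dict:
        d = asdict(self)
        d["hotspot_index"] = list(self.hotspot_index)
        d["centroid_mm"] = list(self.centroid_mm)
        return d


def locate_hotspot(volume: PETVolume, mask: LesionMask) -> tuple[tuple[int, int, int], float]:
    """Foreground voxel of maximal SUV; ties broken by lowest (i,j,k) in C order."""
    if mask.voxel_count == 0:
        raise InputError("empty mask")
    vals = np.where(mask.values, volume.values, -np.inf)
    flat = int(np.argmax(vals))  # argmax returns first occurrence in C order
    idx = np.unravel_index(flat, vals.shape)
    return tuple(int(i) for i in idx), float(volume.values[idx])


def _hotspot_is_tied(volume: PETVolume, mask: LesionMask, suvmax: float) -> bool:
    return int(np.count_nonzero((volume.values == suvmax) & mask.values)) > 1


def lesion_centroid(mask: LesionMask) -> np.ndarray:
    """Unweighted mean of foreground voxel-center physical coordinates (mm)."""
    if mask.voxel_count == 0:
        raise InputError("empty mask")
    idx = np.argwhere(mask.values).astype(np.float64)
    return mask.index_to_mm(idx.mean(axis=0))


def distance_to_centroid(hotspot_index, centroid_mm, geometry: PETVolume | LesionMask) -> float:
    """Euclidean mm distance between the hotspot voxel center and the centroid."""
    pos = geometry.index_to_mm(np.asarray(hotspot_index, dtype=np.float64))
    return float(np.linalg.norm(pos - np.asarray(centroid_mm, dtype=np.float64)))


def distance_to_perimeter(hotspot_index, mask: LesionMask) -> float:
    """Distance-transform distance (mm) from the hotspot to the nearest background voxel center.

    Uses the exact Euclidean distance transform with per-axis sampling, so
    anisotropic spacing is handled without resampling.  The mask is padded
    by one background layer so lesions touching the grid edge still see a
    boundary there.
    """
    hotspot = tuple(int(i) for i in hotspot_index)
    if not mask.values[hotspot]:
        raise InputError(f"hotspot {hotspot} outside the lesion mask")
    padded = np.pad(mask.values, 1, mode="constant", constant_values=False)
    dt = ndimage.distance_transform_edt(padded, sampling=mask.spacing)
    return float(dt[hotspot[0] + 1, hotspot[1] + 1, hotspot[2] + 1])


def normalize_distances(DmaxC: float, DmaxP: float, mask: LesionMask) -> tuple[float, float, float]:
    """Normalize both distances by the volume-equivalent sphere radius R_eq."""
    n = mask.voxel_count
    if n == 0:
        raise InputError("zero-volume mask")
    volume_mm3 = n * mask.voxel_volume_mm3
    r_eq = float((3.0 * volume_mm3 / (4.0 * np.pi)) ** (1.0 / 3.0))
    return DmaxC / r_eq, DmaxP / r_eq, r_eq


def compute_eps(nDmaxC: float, nDmaxP: float) -> Optional[float]:
    """(nDmaxC - nDmaxP)/(nDmaxC + nDmaxP); None if both distances are zero."""
    if nDmaxC < 0 or nDmaxP < 0:
        raise InputError("normalized distances must be non-negative")
    denom = nDmaxC + nDmaxP
    if denom == 0:
        return None  # degenerate lesion; propagated as missing, never NaN
    return (nDmaxC - nDmaxP) / denom


def stratify(eps: Optional[float]) -> Optional[str]:
    """Risk stratum at the geometric cutoff: 'high' iff EPS > 0, 'low' iff EPS <= 0."""
    if eps is None:
        return None
    return "high" if eps > 0 else "low"


def compute_spatial_features(volume: PETVolume, mask: LesionMask) -> SpatialFeatures:
    """Full spatial profile of one lesion: hotspot, distances, EPS, stratum."""
    if volume.shape != mask.shape:
        raise InputError(f"volume {volume.shape} and mask {mask.shape} grids differ")
    hotspot, suvmax = locate_hotspot(volume, mask)
    centroid = lesion_centroid(mask)
    dmax_c = distance_to_centroid(hotspot, centroid, mask)
    dmax_p = distance_to_perimeter(hotspot, mask)
    n_c, n_p, r_eq = normalize_distances(dmax_c, dmax_p, mask)
    eps = compute_eps(n_c, n_p)
    return SpatialFeatures(
        hotspot_index=hotspot,
        suvmax=suvmax,
        centroid_mm=tuple(float(c) for c in centroid),
        DmaxC=dmax_c,
        DmaxP=dmax_p,
        R_eq=r_eq,
        nDmaxC=n_c,
        nDmaxP=n_p,
        EPS=eps,
        risk_group=stratify(eps),
        hotspot_tie=_hotspot_is_tied(volume, mask, suvmax),
    )
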
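"""Conventional PET metrics and the bulk radiomics feature table.

The radiomics extractor is supporting plumbing behind a pinned, versioned
manifest of 115 features (24 first-order + 14 morphology + 26 GLCM +
16 GLRLM + 16 GLSZM + 5 NGTDM + 14 GLDM).  Before texture computation the
volume is resampled to an isotropic grid (default 2 mm; tri-linear for SUV,
nearest-neighbor for the mask) and discretized with a fixed bin size
(default 0.25 SUV).  The contract is the manifest: extraction always emits
one value per manifest entry, in manifest order, deterministically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import measure

from . import _texture
from .io import PETVolume, LesionMask
from .spatial import InputError


class RadiomicsError(RuntimeError):
    pass


MANIFEST_VERSION = "edgescore-115-v1"

_FIRSTORDER_NAMES = [
    "mean", "median", "minimum", "percentile_10", "percentile_25", "percentile_75",
    "percentile_90", "maximum", "range", "interquartile_range", "variance",
    "standard_deviation", "skewness", "kurtosis", "energy", "total_energy",
    "root_mean_squared", "mean_absolute_deviation", "robust_mean_absolute_deviation",
    "entropy", "uniformity", "coefficient_of_variation",
    "quartile_coefficient_of_dispersion", "median_absolute_deviation",
]

_MORPHOLOGY_NAMES = [
    "voxel_count", "volume_ml", "surface_area_mm2", "surface_to_volume_ratio",
    "sphericity", "compactness1", "compactness2", "spherical_disproportion",
    "maximum_3d_diameter_mm", "major_axis_length_mm", "minor_axis_length_mm",
    "least_axis_length_mm", "elongation", "flatness",
]


def _family_names() -> dict[str, list[str]]:
    return {
        "firstorder": _FIRSTORDER_NAMES,
        "morphology": _MORPHOLOGY_NAMES,
        "glcm": _texture.GLCM_NAMES,
        "glrlm": _texture.size_family_names("run"),
        "glszm": _texture.size_family_names("zone"),
        "ngtdm": ["coarseness", "contrast", "busyness", "complexity", "strength"],
        "gldm": _texture.size_family_names("dependence"),
    }


@dataclass(frozen=True)
class FeatureManifest:
    """Ordered, versioned list of radiomic feature names grouped by family."""

    names: tuple[str, ...]
    version: str = MANIFEST_VERSION

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise ValueError("manifest names must be unique")

    def __len__(self) -> int:
        return len(self.names)

    @classmethod
    def default(cls) -> "FeatureManifest":
        names = []
        for family, feats in _family_names().items():
            names.extend(f"{family}_{f}" for f in feats)
        return cls(names=tuple(names))

    def to_dict(self) -> dict:
        return {"version": self.version, "names": list(self.names)}


@dataclass(frozen=True)
class RadiomicsConfig:
    """Extraction parameters: isotropic resampling target and SUV bin width."""

    resample_spacing_mm: float = 2.0
    bin_width_suv: float = 0.25
    min_voxels: int = 64


@dataclass(frozen=True)
class ConventionalMetrics:
    """SUVmax, SUVmean, metabolic tumor volume (mL) and total lesion glycolysis."""

    SUVmax: float
    SUVmean: float
    MTV_ml: float
    TLG: float

    def to_dict(self) -> dict:
        return {"SUVmax": self.SUVmax, "SUVmean": self.SUVmean,
                "MTV_ml": self.MTV_ml, "TLG": self.TLG}


def conventional_metrics(volume: PETVolume, mask: LesionMask) -> ConventionalMetrics:
    """SUV statistics over the mask; MTV in mL; TLG = SUVmean x MTV."""
    if mask.voxel_count == 0:
        raise InputError("empty mask")
    vals = volume.values[mask.values]
    suvmax = float(vals.max())
    suvmean = float(vals.mean())
    mtv = mask.voxel_count * mask.voxel_volume_mm3 / 1000.0
    return ConventionalMetrics(SUVmax=suvmax, SUVmean=suvmean, MTV_ml=mtv, TLG=suvmean * mtv)


# ------------------------------------------------------------------ resampling

def _resample_isotropic(volume: PETVolume, mask: LesionMask, target_mm: float):
    zoom = volume.spacing / target_mm
    if np.allclose(zoom, 1.0):
        return volume.values.copy(), mask.values.copy()
    # grid_mode aligns cell edges, preserving the physical extent of the
    # lesion; corner-aligned zoom systematically erodes downsampled masks
    vals = ndimage.zoom(volume.values, zoom, order=1,
                        mode="grid-constant", grid_mode=True)
    msk = ndimage.zoom(mask.values.astype(np.uint8), zoom, order=0,
                       mode="grid-constant", grid_mode=True) > 0
    return vals, msk


def _crop_to_mask(vals: np.ndarray, msk: np.ndarray, pad: int = 1):
    idx = np.argwhere(msk)
    lo = np.maximum(idx.min(axis=0) - pad, 0)
    hi = np.minimum(idx.max(axis=0) + pad + 1, msk.shape)
    sl = tuple(slice(a, b) for a, b in zip(lo, hi))
    return vals[sl], msk[sl]


def _discretize(vals: np.ndarray, msk: np.ndarray, bin_width: float):
    """Fixed-bin-size gray levels: 1..Ng inside the mask, 0 outside."""
    levels = np.zeros(vals.shape, dtype=np.int64)
    inside = vals[msk]
    levels[msk] = np.floor((inside - inside.min()) / bin_width).astype(np.int64) + 1
    return levels, int(levels.max())


# ------------------------------------------------------------------ families

def _firstorder(vals: np.ndarray, voxel_vol: float, bin_width: float) -> dict[str, float]:
    x = vals.astype(np.float64)
    n = x.size
    mean = float(x.mean())
    p10, p25, p50, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])
    var = float(x.var())
    sd = float(np.sqrt(var))
    cm3 = float(((x - mean) ** 3).mean())
    cm4 = float(((x - mean) ** 4).mean())
    inner = x[(x >= p10) & (x <= p90)]
    # discretized histogram for entropy/uniformity
    g = np.floor((x - x.min()) / bin_width).astype(np.int64)
    p = np.bincount(g) / n
    p = p[p > 0]
    return {
        "mean": mean, "median": float(p50), "minimum": float(x.min()),
        "percentile_10": float(p10), "percentile_25": float(p25),
        "percentile_75": float(p75), "percentile_90": float(p90),
        "maximum": float(x.max()), "range": float(x.max() - x.min()),
        "interquartile_range": float(p75 - p25), "variance": var,
        "standard_deviation": sd,
        "skewness": cm3 / sd ** 3 if sd > 0 else 0.0,
        "kurtosis": cm4 / var ** 2 if var > 0 else 0.0,
        "energy": float((x ** 2).sum()),
        "total_energy": float(voxel_vol * (x ** 2).sum()),
        "root_mean_squared": float(np.sqrt((x ** 2).mean())),
        "mean_absolute_deviation": float(np.abs(x - mean).mean()),
        "robust_mean_absolute_deviation": float(np.abs(inner - inner.mean()).mean()) if inner.size else 0.0,
        "entropy": float(-(p * np.log2(p)).sum()),
        "uniformity": float((p ** 2).sum()),
        "coefficient_of_variation": sd / mean if mean != 0 else 0.0,
        "quartile_coefficient_of_dispersion": float((p75 - p25) / (p75 + p25)) if (p75 + p25) != 0 else 0.0,
        "median_absolute_deviation": float(np.median(np.abs(x - p50))),
    }


def _morphology(msk: np.ndarray, spacing_mm: float) -> dict[str, float]:
    n = int(msk.sum())
    voxel_vol = spacing_mm ** 3
    V = n * voxel_vol
    padded = np.pad(msk, 1).astype(np.float64)
    verts, faces, _, _ = measure.marching_cubes(padded, level=0.5,
                                                spacing=(spacing_mm,) * 3)
    A = float(measure.mesh_surface_area(verts, faces))
    coords = np.argwhere(msk).astype(np.float64) * spacing_mm
    centered = coords - coords.mean(axis=0)
    # PCA axis lengths (4*sqrt(eigenvalue) convention)
    ev = np.sort(np.linalg.eigvalsh(np.cov(centered.T)))[::-1] if n > 1 else np.zeros(3)
    ev = np.clip(ev, 0.0, None)
    axes = 4.0 * np.sqrt(ev)
    try:
        from scipy.spatial import ConvexHull
        hull_pts = coords[ConvexHull(coords, qhull_options="QJ").vertices]
    except Exception:
        hull_pts = coords
    d2 = ((hull_pts[:, None, :] - hull_pts[None, :, :]) ** 2).sum(axis=-1)
    max_diam = float(np.sqrt(d2.max()))
    r_eq = (3.0 * V / (4.0 * np.pi)) ** (1.0 / 3.0)
    sphericity = (np.pi ** (1.0 / 3.0)) * (6.0 * V) ** (2.0 / 3.0) / A
    return {
        "voxel_count": float(n),
        "volume_ml": V / 1000.0,
        "surface_area_mm2": A,
        "surface_to_volume_ratio": A / V,
        "sphericity": float(sphericity),
        "compactness1": float(V / (np.sqrt(np.pi) * A ** 1.5)),
        "compactness2": float(36.0 * np.pi * V ** 2 / A ** 3),
        "spherical_disproportion": float(A / (4.0 * np.pi * r_eq ** 2)),
        "maximum_3d_diameter_mm": max_diam,
        "major_axis_length_mm": float(axes[0]),
        "minor_axis_length_mm": float(axes[1]),
        "least_axis_length_mm": float(axes[2]),
        "elongation": float(np.sqrt(ev[1] / ev[0])) if ev[0] > 0 else 1.0,
        "flatness": float(np.sqrt(ev[2] / ev[0])) if ev[0] > 0 else 1.0,
    }


def extract_radiomics(volume: PETVolume, mask: LesionMask,
                      manifest: FeatureManifest | None = None,
                      config: RadiomicsConfig = RadiomicsConfig()) -> dict[str, float]:
    """One value per manifest entry, in manifest order; deterministic.

    Refuses lesions below the QC floor (64 voxels on the native grid), in
    line with the segmentation QC exclusion rule.
    """
    if manifest is None:
        manifest = FeatureManifest.default()
    if mask.voxel_count < config.min_voxels:
        raise RadiomicsError(
            f"mask has {mask.voxel_count} voxels < QC minimum {config.min_voxels}")
    vals, msk = _resample_isotropic(volume, mask, config.resample_spacing_mm)
    if not msk.any():  # extreme downsampling could erase the lesion
        raise RadiomicsError("mask vanished during resampling; lower resample_spacing_mm")
    vals, msk = _crop_to_mask(vals, msk)
    levels, n_levels = _discretize(vals, msk, config.bin_width_suv)
    voxel_vol = config.resample_spacing_mm ** 3

    values: dict[str, float] = {}
    fam = {
        "firstorder": lambda: _firstorder(vals[msk], voxel_vol, config.bin_width_suv),
        "morphology": lambda: _morphology(msk, config.resample_spacing_mm),
        "glcm": lambda: _texture.glcm_features(_texture.glcm_matrix(levels, n_levels)),
        "glrlm": lambda: _texture.glrlm_features(levels, n_levels),
        "glszm": lambda: _texture.glszm_features(levels, n_levels),
        "ngtdm": lambda: _texture.ngtdm_features(levels, n_levels),
        "gldm": lambda: _texture.gldm_features(levels, n_levels),
    }
    computed: dict[str, dict[str, float]] = {}
    record: dict[str, float] = {}
    for name in manifest.names:
        family, _, feat = name.partition("_")
        if family not in fam:
            raise RadiomicsError(f"unknown feature family in manifest entry {name!r}")
        if family not in computed:
            computed[family] = fam[family]()
        if feat not in computed[family]:
            raise RadiomicsError(f"unknown feature {name!r}")
        record[name] = float(computed[family][feat])
    return record
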
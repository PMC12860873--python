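"""Digital PET phantoms and simulated patient cohorts.

Phantoms are geometric lesions (sphere, ellipsoid, lobulated) on a uniform
background, with the SUVmax hotspot realized as an additive Gaussian bump
at a stated fractional radius, so the ground-truth spatial features
(nDmaxC = f, nDmaxP = 1 - f, EPS = 2f - 1 for a sphere) are known from
continuous geometry before any discretization.  PSF blur is applied before
noise so the pre-noise SUVmax voxel stays analytically known.

Cohorts emulate a surgical NSCLC population: marginal distributions (age, MTV,
SUVmax, nDmaxC, nDmaxP, stage mix, label prevalences, ~42% recurrence)
match the reported medians/IQRs and proportions; EPS is computed from the
generated distances by the score formula, never drawn directly; binary
invasiveness labels follow a logistic model in which EPS carries the
dominant effect; progression-free survival is exponential proportional
hazards with the reported multivariable hazard ratios as the default
effects, under independent uniform administrative censoring whose baseline
rate is solved at generation time to hit the target event fraction.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import ndimage, optimize

from .io import PETVolume, LesionMask
from .metrics import FeatureManifest


class SpecError(ValueError):
    pass


# ====================================================================== phantoms

@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one digital lesion phantom.

    radius_vox may be a scalar (sphere) or per-axis triple (ellipsoid).
    hotspot_fraction f places the SUVmax bump at f x radius along
    ``direction`` (f = 0 center, f = 1 boundary).
    """

    shape: str = "sphere"
    radius_vox: float | tuple[float, float, float] = 16.0
    hotspot_fraction: float = 0.5
    direction: tuple[float, float, float] = (1.0, 0.0, 0.0)
    peak_suv: float = 10.0
    lesion_suv: float = 6.0
    background_suv: float = 0.5
    bump_sigma_mm: float = 1.2
    psf_sigma_mm: float = 1.0
    noise_sigma: float = 0.0
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    margin_vox: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        radii = np.broadcast_to(np.asarray(self.radius_vox, dtype=float), (3,))
        if np.any(radii < 4):
            raise SpecError("radii must be >= 4 voxels")
        if not 0.0 <= self.hotspot_fraction <= 1.0:
            raise SpecError("hotspot_fraction must lie in [0, 1]")
        if not self.peak_suv > self.background_suv >= 0:
            raise SpecError("require peak_suv > background_suv >= 0")
        if self.shape not in ("sphere", "ellipsoid", "lobulated"):
            raise SpecError(f"unknown shape {self.shape!r}")

    @property
    def radii(self) -> np.ndarray:
        return np.broadcast_to(np.asarray(self.radius_vox, dtype=float), (3,)).copy()


def make_phantom(spec: PhantomSpec) -> tuple[PETVolume, LesionMask, dict]:
    """Build (volume, mask, analytic ground truth) for one phantom."""
    radii = spec.radii
    spacing = np.asarray(spec.spacing_mm, dtype=float)
    half = int(np.ceil(radii.max())) + spec.margin_vox
    n = 2 * half + 1
    center = np.array([half, half, half], dtype=float)

    idx = np.indices((n, n, n)).astype(float)
    rel = (idx - center.reshape(3, 1, 1, 1))  # voxel offsets from center
    inside = (np.sum((rel / radii.reshape(3, 1, 1, 1)) ** 2, axis=0)) <= 1.0

    if spec.shape == "lobulated":
        # two deterministic smaller lobes fused onto the main body
        for sgn, frac in ((1.0, 0.55), (-1.0, 0.45)):
            off = sgn * radii * np.array([0.7, 0.5, 0.0])
            lob_r = frac * radii
            rel_l = rel - off.reshape(3, 1, 1, 1)
            inside |= (np.sum((rel_l / lob_r.reshape(3, 1, 1, 1)) ** 2, axis=0)) <= 1.0

    direction = np.asarray(spec.direction, dtype=float)
    if np.linalg.norm(direction) == 0:
        raise SpecError("direction must be nonzero")
    direction = direction / np.linalg.norm(direction)
    hotspot_f = center + spec.hotspot_fraction * radii * direction
    hotspot = tuple(int(round(c)) for c in hotspot_f)
    if not inside[hotspot]:
        raise SpecError("hotspot location falls outside the lesion shape")

    values = np.where(inside, spec.lesion_suv, spec.background_suv).astype(float)
    if spec.psf_sigma_mm > 0:
        values = ndimage.gaussian_filter(values, sigma=spec.psf_sigma_mm / spacing)
    # hotspot bump imposed at imaging resolution after PSF blurring of the
    # anatomical scene, with its amplitude pinned so the specified voxel is
    # exactly the SUVmax voxel (ground truth stays analytic)
    base_at_hotspot = float(values[hotspot])
    if base_at_hotspot >= spec.peak_suv:
        raise SpecError("peak_suv does not exceed the blurred background at the hotspot")
    d_mm2 = np.zeros((n, n, n))
    for k in range(3):
        d_mm2 += ((idx[k] - hotspot[k]) * spacing[k]) ** 2
    values += (spec.peak_suv - base_at_hotspot) * np.exp(-d_mm2 / (2.0 * spec.bump_sigma_mm ** 2))
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        values = values + rng.normal(0.0, spec.noise_sigma, size=values.shape)
    values = np.clip(values, 0.0, None)

    volume = PETVolume(values=values, spacing=spacing)
    mask = LesionMask(values=inside, spacing=spacing)

    f = spec.hotspot_fraction
    r_mm = float(radii[0] * spacing[0])  # meaningful for spheres
    truth = {
        "hotspot_index": hotspot,
        "center_index": tuple(int(c) for c in center),
        "radius_mm": r_mm,
        "nDmaxC": f,
        "nDmaxP": 1.0 - f,
        "EPS": 2.0 * f - 1.0,
    }
    return volume, mask, truth


# ====================================================================== cohorts

def _lognormal_params(median: float, iqr: tuple[float, float]) -> tuple[float, float]:
    mu = np.log(median)
    sigma = np.log(iqr[1] / iqr[0]) / (2.0 * 0.6744897501960817)
    return mu, sigma


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of one simulated surgical NSCLC cohort.

    Defaults describe a surgical NSCLC cohort: n = 244; marginals matched to
    the reported medians/IQRs; invasiveness prevalences LVI 42.6%, VPI
    28.7%, STAS 34.8%; multivariable hazard ratios EPS-group 2.667, stage
    II-III 2.927, VPI 1.628, age 0.975/yr, MTV 1.005/mL; 42.2% events.
    """

    n: int = 244
    seed: int = 0
    age_median: float = 64.5
    age_iqr: tuple[float, float] = (59.0, 70.0)
    mtv_median: float = 16.126
    mtv_iqr: tuple[float, float] = (6.10, 48.05)
    suvmax_median: float = 9.5628
    suvmax_iqr: tuple[float, float] = (5.84, 17.87)
    ndmaxc_median: float = 0.49
    ndmaxc_iqr: tuple[float, float] = (0.32, 0.69)
    ndmaxp_median: float = 0.20
    ndmaxp_iqr: tuple[float, float] = (0.15, 0.36)
    stage_probs: tuple[float, float, float] = (0.377, 0.398, 0.225)
    female_prob: float = 0.59
    label_prevalence: Mapping[str, float] = field(
        default_factory=lambda: {"LVI": 0.426, "VPI": 0.287, "STAS": 0.348})
    # log-odds on each endpoint; EPS carries the dominant effect
    label_log_odds: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            "LVI": {"EPS": 2.5, "z_size": 0.4},
            "VPI": {"EPS": 2.5, "z_size": 0.3},
            "STAS": {"EPS": 2.5, "z_size": 0.3},
        })
    hr_eps_group: float = 2.667
    hr_stage: float = 2.927
    hr_vpi: float = 1.628
    hr_age_per_year: float = 0.975
    hr_mtv_per_ml: float = 1.005
    event_rate: float = 0.422
    censor_window_months: tuple[float, float] = (12.0, 120.0)
    n_noise_features: int | None = None  # None -> full default manifest
    feature_noise_sd: float = 0.8

    def __post_init__(self) -> None:
        if self.n < 20:
            raise SpecError("cohort size must be >= 20")
        for name, p in self.label_prevalence.items():
            if not 0.0 < p < 1.0:
                raise SpecError(f"prevalence of {name} must be in (0, 1)")
        if not 0.0 < self.event_rate < 1.0:
            raise SpecError("event_rate must be in (0, 1)")
        if not np.isclose(sum(self.stage_probs), 1.0):
            raise SpecError("stage_probs must sum to 1")


def radiomic_feature_columns(manifest: FeatureManifest | None = None) -> list[str]:
    if manifest is None:
        manifest = FeatureManifest.default()
    return list(manifest.names)


def candidate_feature_columns(manifest: FeatureManifest | None = None) -> list[str]:
    """All columns offered to the selection/classification stage."""
    return (["EPS", "nDmaxC", "nDmaxP", "SUVmax", "SUVmean", "MTV_ml", "TLG"]
            + radiomic_feature_columns(manifest))


def _solve_intercept(lp: np.ndarray, prevalence: float) -> float:
    """Intercept alpha so that mean sigmoid(alpha + lp) equals prevalence."""
    def f(a):
        return np.mean(1.0 / (1.0 + np.exp(-(a + lp)))) - prevalence
    return float(optimize.brentq(f, -50.0, 50.0))


def _solve_baseline_rate(lp: np.ndarray, target: float,
                         window: tuple[float, float]) -> float:
    """Baseline exponential rate so the expected event fraction hits target.

    With T ~ Exp(lam0 * e^lp) and independent C ~ Uniform(c_lo, c_hi),
    P(T <= C | lp) = 1 - (e^{-r c_lo} - e^{-r c_hi}) / (r (c_hi - c_lo)).
    """
    c_lo, c_hi = window
    rel = np.exp(lp)

    def event_prob(lam0):
        r = lam0 * rel
        return np.mean(1.0 - (np.exp(-r * c_lo) - np.exp(-r * c_hi)) / (r * (c_hi - c_lo)))

    return float(optimize.brentq(lambda l: event_prob(l) - target, 1e-8, 10.0))


def _feature_weights(name: str) -> np.ndarray:
    """Deterministic per-feature loading on the latent factors, keyed by name."""
    h = zlib.crc32(name.encode())
    rng = np.random.default_rng(h)
    return rng.uniform(-0.6, 0.6, size=3)


def make_cohort(spec: CohortSpec = CohortSpec()) -> pd.DataFrame:
    """Simulate one cohort table; seed-reproducible."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n

    age_sd = (spec.age_iqr[1] - spec.age_iqr[0]) / (2.0 * 0.6744897501960817)
    age = np.clip(rng.normal(spec.age_median, age_sd, n), 30.0, 92.0)
    sex_female = rng.random(n) < spec.female_prob
    stage = rng.choice(np.array(["I", "II", "III"]), size=n, p=spec.stage_probs)
    stage_adv = (stage != "I").astype(int)

    # log-normal marginals truncated at physiologically plausible maxima
    mu, sg = _lognormal_params(spec.mtv_median, spec.mtv_iqr)
    mtv = np.minimum(rng.lognormal(mu, sg, n), 250.0)
    mu, sg = _lognormal_params(spec.suvmax_median, spec.suvmax_iqr)
    suvmax = np.minimum(rng.lognormal(mu, sg, n), 40.0)
    suvmean = suvmax / 2.4 * rng.lognormal(0.0, 0.1, n)
    tlg = suvmean * mtv

    mu, sg = _lognormal_params(spec.ndmaxc_median, spec.ndmaxc_iqr)
    ndmaxc = rng.lognormal(mu, sg, n)
    mu, sg = _lognormal_params(spec.ndmaxp_median, spec.ndmaxp_iqr)
    ndmaxp = rng.lognormal(mu, sg, n)
    eps = (ndmaxc - ndmaxp) / (ndmaxc + ndmaxp)
    eps_group = (eps > 0).astype(int)

    # latent factors behind the radiomics-like feature block
    z_size = (np.log(mtv) - np.log(spec.mtv_median)) / max(_lognormal_params(spec.mtv_median, spec.mtv_iqr)[1], 1e-9)
    z_int = (np.log(suvmax) - np.log(spec.suvmax_median)) / max(_lognormal_params(spec.suvmax_median, spec.suvmax_iqr)[1], 1e-9)
    z_het = rng.normal(0.0, 1.0, n)
    latents = {"z_size": z_size, "z_int": z_int, "z_het": z_het, "EPS": eps}

    labels: dict[str, np.ndarray] = {}
    for endpoint, prev in spec.label_prevalence.items():
        effects = spec.label_log_odds.get(endpoint, {})
        lp = np.zeros(n)
        for var, beta in effects.items():
            lp += beta * latents[var]
        alpha = _solve_intercept(lp, prev)
        p = 1.0 / (1.0 + np.exp(-(alpha + lp)))
        labels[endpoint] = (rng.random(n) < p).astype(int)

    # survival: exponential PH with the default multivariable effects
    lp_surv = (np.log(spec.hr_eps_group) * eps_group
               + np.log(spec.hr_stage) * stage_adv
               + np.log(spec.hr_vpi) * labels["VPI"]
               + np.log(spec.hr_age_per_year) * (age - spec.age_median)
               + np.log(spec.hr_mtv_per_ml) * (mtv - spec.mtv_median))
    lam0 = _solve_baseline_rate(lp_surv, spec.event_rate, spec.censor_window_months)
    t_event = rng.exponential(1.0 / (lam0 * np.exp(lp_surv)))
    c_lo, c_hi = spec.censor_window_months
    t_cens = rng.uniform(c_lo, c_hi, n)
    pfs_event = (t_event <= t_cens).astype(int)
    pfs_months = np.minimum(t_event, t_cens)

    data = {
        "patient_id": [f"P{i:04d}" for i in range(n)],
        "age": age,
        "sex_female": sex_female.astype(int),
        "stage": stage,
        "stage_advanced": stage_adv,
        "LVI": labels["LVI"],
        "VPI": labels["VPI"],
        "STAS": labels["STAS"],
        "SUVmax": suvmax,
        "SUVmean": suvmean,
        "MTV_ml": mtv,
        "TLG": tlg,
        "nDmaxC": ndmaxc,
        "nDmaxP": ndmaxp,
        "EPS": eps,
        "eps_group": eps_group,
        "pfs_months": pfs_months,
        "pfs_event": pfs_event,
    }

    manifest = FeatureManifest.default()
    names = list(manifest.names)
    if spec.n_noise_features is not None:
        names = names[: spec.n_noise_features]
    noise = rng.normal(0.0, spec.feature_noise_sd, size=(n, len(names)))
    for j, name in enumerate(names):
        w = _feature_weights(name)
        data[name] = w[0] * z_size + w[1] * z_int + w[2] * z_het + noise[:, j]

    return pd.DataFrame(data)
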
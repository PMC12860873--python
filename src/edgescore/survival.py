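"""Prognostic arm: Cox regression, Kaplan-Meier stratification, a
points-based nomogram, time-dependent AUC and calibration.

The multivariable model uses the fixed covariate set
{age, TNM stage (II-III vs I), MTV, VPI, EPS risk group}; no stepwise
selection.  Ties are handled with the Efron approximation; confidence
intervals and p-values are Wald-based.  Time-dependent AUC is the
cumulative/dynamic definition with inverse-probability-of-censoring
weighting at the 1-, 3- and 5-year horizons.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import multivariate_logrank_test
from sksurv.metrics import cumulative_dynamic_auc
from sksurv.util import Surv

DEFAULT_COVARIATES = ("age", "stage_advanced", "MTV_ml", "VPI", "eps_group")
DEFAULT_HORIZONS = (12.0, 36.0, 60.0)  # months: 1-, 3-, 5-year PFS


class SurvivalError(RuntimeError):
    pass


@dataclass
class CovariateEffect:
    coef: float
    se: float
    hr: float
    ci_low: float
    ci_high: float
    p: float


@dataclass
class CoxResult:
    """Hazard ratios with Wald 95% CIs and p-values."""

    mode: str                     # 'univariable' or 'multivariable'
    n: int
    events: int
    effects: dict[str, CovariateEffect]
    fitter: CoxPHFitter | None = field(repr=False, default=None)
    duration_col: str = "pfs_months"
    event_col: str = "pfs_event"

    def to_dict(self) -> dict:
        return {
            "mode": self.mode, "n": self.n, "events": self.events,
            "covariates": {
                k: {"hr": e.hr, "ci_low": e.ci_low, "ci_high": e.ci_high,
                    "p": e.p, "coef": e.coef, "se": e.se}
                for k, e in self.effects.items()
            },
        }


def _effects_from_fitter(cph: CoxPHFitter) -> dict[str, CovariateEffect]:
    out = {}
    for cov in cph.params_.index:
        coef = float(cph.params_[cov])
        se = float(cph.standard_errors_[cov])
        out[cov] = CovariateEffect(
            coef=coef, se=se, hr=float(np.exp(coef)),
            ci_low=float(np.exp(coef - 1.959963984540054 * se)),
            ci_high=float(np.exp(coef + 1.959963984540054 * se)),
            p=float(cph.summary.loc[cov, "p"]),
        )
    return out


def cox_fit(cohort: pd.DataFrame, covariates: Sequence[str] = DEFAULT_COVARIATES,
            mode: str = "multivariable", duration_col: str = "pfs_months",
            event_col: str = "pfs_event") -> CoxResult:
    """Partial-likelihood Cox fit (Efron ties) of PFS on the covariates.

    In 'univariable' mode each covariate is fitted in its own model and the
    per-covariate effects are collected into one result.
    """
    events = int(cohort[event_col].sum())
    if events < 10:
        raise SurvivalError(f"only {events} events; need >= 10")
    covs = list(covariates)
    sub = cohort[covs]
    corr = sub.corr().to_numpy()
    iu = np.triu_indices(len(covs), k=1)
    if np.any(np.isclose(np.abs(corr[iu]), 1.0)):
        raise SurvivalError("perfectly collinear covariate pair present")

    if mode == "multivariable":
        cph = CoxPHFitter()
        try:
            cph.fit(cohort[covs + [duration_col, event_col]],
                    duration_col=duration_col, event_col=event_col)
        except ConvergenceError as exc:
            cond = np.linalg.cond(np.asarray(sub, dtype=float))
            raise SurvivalError(
                f"Cox fit did not converge (design condition number {cond:.3g}): {exc}"
            ) from exc
        return CoxResult(mode=mode, n=len(cohort), events=events,
                         effects=_effects_from_fitter(cph), fitter=cph,
                         duration_col=duration_col, event_col=event_col)
    if mode == "univariable":
        effects = {}
        for cov in covs:
            cph = CoxPHFitter()
            cph.fit(cohort[[cov, duration_col, event_col]],
                    duration_col=duration_col, event_col=event_col)
            effects.update(_effects_from_fitter(cph))
        return CoxResult(mode=mode, n=len(cohort), events=events,
                         effects=effects, fitter=None,
                         duration_col=duration_col, event_col=event_col)
    raise ValueError(f"unknown mode {mode!r}")


# ------------------------------------------------------------------- KM

def km_stratify(cohort: pd.DataFrame, group_col: str,
                duration_col: str = "pfs_months", event_col: str = "pfs_event"):
    """Product-limit curves per group, log-rank test, reverse-KM follow-up.

    Returns a dict with per-group survival curves (step functions with
    Greenwood CIs), the log-rank statistic/p-value, and the median
    follow-up estimated by reverse Kaplan-Meier (censoring as the event).
    """
    groups = cohort[group_col]
    levels = sorted(groups.dropna().unique())
    if len(levels) < 2:
        raise SurvivalError("need at least two groups to stratify")
    curves = {}
    for g in levels:
        sub = cohort[groups == g]
        if sub.empty:
            raise SurvivalError(f"empty group {g!r}")
        kmf = KaplanMeierFitter()
        kmf.fit(sub[duration_col], sub[event_col], label=str(g))
        curves[g] = {
            "survival": kmf.survival_function_,
            "ci": kmf.confidence_interval_,
            "median": float(kmf.median_survival_time_),
            "n": int(len(sub)),
        }
    lr = multivariate_logrank_test(cohort[duration_col], groups, cohort[event_col])
    rkm = KaplanMeierFitter()
    rkm.fit(cohort[duration_col], 1 - cohort[event_col])
    return {
        "curves": curves,
        "logrank_statistic": float(lr.test_statistic),
        "logrank_p": float(lr.p_value),
        "median_followup_reverse_km": float(rkm.median_survival_time_),
    }


# ------------------------------------------------------------------- nomogram

@dataclass
class NomogramModel:
    """Points representation of a multivariable Cox model.

    Each covariate's contribution is mapped linearly to points, anchored so
    the least hazardous observed value scores 0 and the largest absolute
    contribution across covariates spans 100 points.  Total points map
    invertibly to the linear predictor and hence to predicted survival
    S(t | x) = S0(t)^exp(lp - lp_mean) at each horizon.
    """

    covariates: list[str]
    betas: dict[str, float]
    ref_values: dict[str, float]      # covariate value scoring 0 points
    scale: float                      # lp units per 100 points
    lp_mean: float
    baseline_survival: pd.DataFrame   # lifelines baseline at covariate means
    horizons: tuple[float, ...] = DEFAULT_HORIZONS

    def points(self, values: Mapping[str, float]) -> dict[str, float]:
        pts = {c: 100.0 * self.betas[c] * (values[c] - self.ref_values[c]) / self.scale
               for c in self.covariates}
        pts["total"] = float(sum(pts.values()))
        return pts

    def points_to_lp(self, total_points: float) -> float:
        offset = sum(self.betas[c] * self.ref_values[c] for c in self.covariates)
        return self.scale * total_points / 100.0 + offset

    def lp_to_points(self, lp: float) -> float:
        offset = sum(self.betas[c] * self.ref_values[c] for c in self.covariates)
        return 100.0 * (lp - offset) / self.scale

    def _baseline_at(self, t: float) -> float:
        s = self.baseline_survival.iloc[:, 0]
        idx = s.index.to_numpy(dtype=float)
        pos = np.searchsorted(idx, t, side="right") - 1
        if pos < 0:
            return 1.0
        return float(s.iloc[pos])

    def predict_survival(self, total_points: float, horizon: float) -> float:
        lp = self.points_to_lp(total_points)
        return self._baseline_at(horizon) ** np.exp(lp - self.lp_mean)

    def predict_survival_from_values(self, values: Mapping[str, float],
                                     horizon: float) -> float:
        return self.predict_survival(self.points(values)["total"], horizon)


def build_nomogram(cox: CoxResult, cohort: pd.DataFrame,
                   horizons: Sequence[float] = DEFAULT_HORIZONS) -> NomogramModel:
    """Anchor a points scale to a fitted multivariable Cox model."""
    if cox.fitter is None or cox.mode != "multivariable":
        raise SurvivalError("nomogram requires a fitted multivariable model")
    covs = list(cox.effects.keys())
    betas = {c: cox.effects[c].coef for c in covs}
    ranges = {}
    refs = {}
    for c in covs:
        lo, hi = float(cohort[c].min()), float(cohort[c].max())
        if lo == hi:
            raise SurvivalError(f"degenerate covariate range for {c!r}")
        ranges[c] = abs(betas[c]) * (hi - lo)
        refs[c] = lo if betas[c] >= 0 else hi  # least hazardous end -> 0 points
    scale = max(ranges.values())
    lp_mean = float(sum(betas[c] * cohort[c].mean() for c in covs))
    return NomogramModel(covariates=covs, betas=betas, ref_values=refs,
                         scale=scale, lp_mean=lp_mean,
                         baseline_survival=cox.fitter.baseline_survival_,
                         horizons=tuple(horizons))


# ------------------------------------------------------------------- metrics

def time_dependent_auc(scores: np.ndarray, cohort: pd.DataFrame,
                       horizons: Sequence[float] = DEFAULT_HORIZONS,
                       duration_col: str = "pfs_months",
                       event_col: str = "pfs_event",
                       n_bootstrap: int = 200, seed: int = 0):
    """Cumulative/dynamic AUC(t) with IPCW, plus bootstrap 95% CIs.

    ``scores`` are risk scores (higher = earlier progression).  Horizons
    with no observed events before them are flagged and skipped.
    """
    t = cohort[duration_col].to_numpy(dtype=float)
    e = cohort[event_col].to_numpy(dtype=bool)
    scores = np.asarray(scores, dtype=float)
    y = Surv.from_arrays(event=e, time=t)
    out = {}
    rng = np.random.default_rng(seed)
    for h in horizons:
        if not np.any(e & (t <= h)):
            out[h] = {"auc": None, "ci": None, "flag": "no events before horizon"}
            continue
        if h >= t.max():
            out[h] = {"auc": None, "ci": None, "flag": "horizon beyond follow-up"}
            continue
        auc, _ = cumulative_dynamic_auc(y, y, scores, [h])
        boots = []
        for _ in range(n_bootstrap):
            idx = rng.integers(0, len(t), len(t))
            tb, eb, sb = t[idx], e[idx], scores[idx]
            if not np.any(eb & (tb <= h)) or h >= tb.max() or len(np.unique(sb)) < 2:
                continue
            try:
                yb = Surv.from_arrays(event=eb, time=tb)
                ab, _ = cumulative_dynamic_auc(yb, yb, sb, [h])
                boots.append(float(ab[0]))
            except ValueError:
                continue
        ci = (float(np.quantile(boots, 0.025)), float(np.quantile(boots, 0.975))) \
            if len(boots) >= 20 else None
        out[h] = {"auc": float(auc[0]), "ci": ci, "flag": None}
    return out


def calibration_curve(nomogram: NomogramModel, cohort: pd.DataFrame,
                      horizon: float, n_bins: int = 10,
                      duration_col: str = "pfs_months",
                      event_col: str = "pfs_event") -> pd.DataFrame:
    """Binned predicted vs observed (KM) survival at a horizon.

    Bins are quantiles of predicted probability; observed is the
    Kaplan-Meier estimate per bin with its Greenwood 95% CI.  Bins whose
    subjects are all censored before the horizon are flagged, not scored.
    """
    if horizon >= cohort[duration_col].max():
        raise SurvivalError("horizon beyond observed follow-up")
    pred = np.array([
        nomogram.predict_survival_from_values(row, horizon)
        for row in cohort[nomogram.covariates].to_dict("records")
    ])
    qs = np.quantile(pred, np.linspace(0, 1, n_bins + 1))
    qs[0], qs[-1] = -np.inf, np.inf
    bin_idx = np.searchsorted(qs, pred, side="right") - 1
    rows = []
    for b in range(n_bins):
        sel = bin_idx == b
        if sel.sum() == 0:
            continue
        t_b = cohort.loc[sel, duration_col]
        e_b = cohort.loc[sel, event_col]
        flagged = bool((t_b[e_b == 0] < horizon).all() and (e_b == 0).all()) or \
            not bool((t_b >= horizon).any() or (e_b[t_b <= horizon] == 1).any())
        row = {"bin": b, "n": int(sel.sum()), "predicted": float(pred[sel].mean()),
               "observed": np.nan, "ci_low": np.nan, "ci_high": np.nan,
               "flagged": flagged}
        if not flagged:
            kmf = KaplanMeierFitter()
            kmf.fit(t_b, e_b)
            row["observed"] = float(kmf.survival_function_at_times(horizon).iloc[0])
            ci = kmf.confidence_interval_
            idx = ci.index.to_numpy(dtype=float)
            pos = max(int(np.searchsorted(idx, horizon, side="right")) - 1, 0)
            row["ci_low"] = float(ci.iloc[pos, 0])
            row["ci_high"] = float(ci.iloc[pos, 1])
        rows.append(row)
    valid = [r for r in rows if not r["flagged"]]
    if len(valid) < 3:
        raise SurvivalError("fewer than 3 calibration bins with observable outcomes")
    return pd.DataFrame(rows)
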
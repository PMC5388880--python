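"""Network flow-change estimation from paired transit times.

Hypercapnia homogenizes microvascular transit times: when flow rises by a
factor ``k``, the dispersion of time-to-peak (TTP) across the vascular
network contracts by the same factor.  Regressing hypercapnic on
normocapnic TTP with an errors-in-variables (Deming / orthogonal) fit —
both axes carry measurement error — therefore yields a slope of ``1/k``,
and the network flow change is ``100 * (1/slope - 1)`` percent.  A slope
below 1 signals reduced TTP dispersion under hypercapnia, i.e. a flow
increase.

Uncertainty is summarized by a hierarchical case-resampling bootstrap
(animals resampled with replacement, falling back to vessels for
single-animal data), which respects between-animal variation without a
parametric mixed model.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "VesselRecord",
    "DemingFit",
    "deming_fit",
    "flow_change_from_slope",
    "network_flow_change",
    "reactivity_amyloid_regression",
    "group_summary",
    "records_to_frame",
]


@dataclass
class VesselRecord:
    """Per-vessel metadata with paired TTPs and derived quantities."""

    vessel_id: str
    animal_id: str
    genotype: str
    vessel_type: str
    ttp_normo: float
    ttp_hyper: float
    reactivity: float | None = None
    amyloid_load: float | None = None  # percent of the vessel surface

    def __post_init__(self) -> None:
        if self.ttp_normo <= 0 or self.ttp_hyper <= 0:
            raise ValueError("TTP values must be positive")
        if self.amyloid_load is not None and not 0.0 <= self.amyloid_load <= 100.0:
            raise ValueError("amyloid_load must lie in [0, 100] percent")


def records_to_frame(records: Iterable[VesselRecord]) -> pd.DataFrame:
    cols = [f.name for f in fields(VesselRecord)]
    return pd.DataFrame([{c: getattr(r, c) for c in cols} for r in records])


@dataclass
class DemingFit:
    """Orthogonal-regression fit and the derived flow change."""

    slope: float
    intercept: float
    lam: float
    n: int
    flow_change: float | None = None  # percent
    ci_low: float | None = None
    ci_high: float | None = None


def _deming_slope(x: np.ndarray, y: np.ndarray, lam: float) -> float:
    sxx = np.var(x, ddof=1)
    syy = np.var(y, ddof=1)
    sxy = np.cov(x, y, ddof=1)[0, 1]
    if sxy == 0.0:
        if np.isclose(syy, lam * sxx):
            raise ValueError("degenerate point cloud: regression direction undefined")
        # zero covariance with unequal variances: the principal axis is a
        # coordinate axis; a vertical axis has no finite slope
        if syy > lam * sxx:
            raise ValueError("zero covariance with dominant y-variance: slope infinite")
        return 0.0
    d = syy - lam * sxx
    return (d + np.sqrt(d * d + 4.0 * lam * sxy * sxy)) / (2.0 * sxy)


def deming_fit(x: Sequence[float], y: Sequence[float], lam: float = 1.0) -> DemingFit:
    """Closed-form Deming regression of y on x.

    With sample (co)variances ``s_xx, s_yy, s_xy`` the slope is
    ``[s_yy - lam*s_xx + sqrt((s_yy - lam*s_xx)^2 + 4*lam*s_xy^2)] / (2*s_xy)``
    and the intercept ``ybar - slope * xbar``.  ``lam`` is the ratio of the
    y- to x-error variances; ``lam = 1`` gives orthogonal regression
    (minimum summed squared perpendicular distance).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 paired observations")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    if lam <= 0:
        raise ValueError("lambda must be positive")
    slope = _deming_slope(x, y, lam)
    intercept = float(np.mean(y) - slope * np.mean(x))
    return DemingFit(slope=float(slope), intercept=intercept, lam=lam, n=x.size)


def flow_change_from_slope(slope: float) -> float:
    """Network flow change (percent) from the TTP regression slope: 100*(1/slope - 1)."""
    if slope <= 0:
        raise ValueError("flow change undefined for non-positive slope")
    return 100.0 * (1.0 / slope - 1.0)


def _group_center(x: np.ndarray, y: np.ndarray,
                  groups: np.ndarray | None) -> tuple[np.ndarray, np.ndarray]:
    if groups is None:
        return x - x.mean(), y - y.mean()
    xc = np.empty_like(x)
    yc = np.empty_like(y)
    for g in np.unique(groups):
        m = groups == g
        xc[m] = x[m] - x[m].mean()
        yc[m] = y[m] - y[m].mean()
    return xc, yc


def network_flow_change(
    records: Iterable[VesselRecord],
    vessel_filter: Callable[[VesselRecord], bool] | None = None,
    lam: float = 1.0,
    n_boot: int = 2000,
    seed: int | None = 0,
    ci_level: float = 0.95,
    center_by: str | None = "vessel_type",
) -> DemingFit:
    """Estimate the hypercapnic network flow change for a set of vessels.

    TTPs are mean-centered, fitted by orthogonal regression (``lam = 1``),
    and the flow change reported as ``100 * (1/slope - 1)`` percent with a
    percentile bootstrap CI.  The bootstrap resamples animals with
    replacement (keeping each animal's vessels together); when only one
    animal is present it falls back to resampling vessels.

    ``center_by`` names a record attribute (default ``"vessel_type"``)
    within whose levels the TTPs are mean-centered before the pooled fit.
    The estimator's premise — dispersion of transit-time *deviations*
    contracts by the flow factor — concerns within-class variation;
    systematic arrival-time offsets between vessel classes, whose mean
    response is governed by reactivity rather than by the dispersion
    contraction, would otherwise bias a pooled slope.  For a single-class
    subset this reduces to ordinary mean-centering (``center_by=None``).
    """
    recs = [r for r in records if vessel_filter is None or vessel_filter(r)]
    if len(recs) < 3:
        raise ValueError("need at least 3 vessels after filtering")
    x = np.array([r.ttp_normo for r in recs])
    y = np.array([r.ttp_hyper for r in recs])
    animals = np.array([r.animal_id for r in recs])
    groups = (np.array([getattr(r, center_by) for r in recs])
              if center_by is not None else None)

    xc, yc = _group_center(x, y, groups)
    fit = deming_fit(xc, yc, lam=lam)
    fit.flow_change = flow_change_from_slope(fit.slope) if fit.slope > 0 else None

    if n_boot > 0:
        rng = np.random.default_rng(seed)
        unique_animals = np.unique(animals)
        by_animal = {a: np.nonzero(animals == a)[0] for a in unique_animals}
        draws = []
        for _ in range(n_boot):
            if unique_animals.size > 1:
                chosen = rng.choice(unique_animals, size=unique_animals.size, replace=True)
                idx = np.concatenate([by_animal[a] for a in chosen])
            else:
                idx = rng.integers(0, x.size, size=x.size)
            if idx.size < 3:
                continue
            xb, yb = _group_center(x[idx], y[idx],
                                   groups[idx] if groups is not None else None)
            try:
                s = _deming_slope(xb, yb, lam)
            except ValueError:
                continue
            if s > 0:
                draws.append(flow_change_from_slope(s))
        if draws:
            lo = 100.0 * (1.0 - ci_level) / 2.0
            fit.ci_low = float(np.percentile(draws, lo))
            fit.ci_high = float(np.percentile(draws, 100.0 - lo))
    return fit


def reactivity_amyloid_regression(records: Iterable[VesselRecord]) -> dict[str, float]:
    """OLS of per-vessel reactivity (percent) on vascular amyloid load (percent).

    Returns slope, its standard error, intercept, R^2 and the two-sided p
    for slope = 0.  Records without an amyloid load are dropped.
    """
    recs = [r for r in records if r.amyloid_load is not None]
    if len(recs) < 3:
        raise ValueError("need at least 3 vessels with amyloid load")
    load = np.array([r.amyloid_load for r in recs], dtype=float)
    react = np.array([r.reactivity for r in recs], dtype=float)
    if np.any(~np.isfinite(react)):
        raise ValueError("all records need a finite reactivity")
    if np.var(load) == 0:
        raise ValueError("amyloid load has zero variance")
    model = sm.OLS(react, sm.add_constant(load)).fit()
    # constant response: slope and R^2 are exactly 0 (centered TSS vanishes)
    r_squared = float(model.rsquared) if np.var(react) > 0 else 0.0
    return {
        "slope": float(model.params[1]),
        "slope_se": float(model.bse[1]),
        "intercept": float(model.params[0]),
        "r_squared": r_squared,
        "p_value": float(model.pvalues[1]),
        "n": len(recs),
    }


def group_summary(records: Iterable[VesselRecord]) -> pd.DataFrame:
    """Mean +- SEM reactivity per genotype x vessel type, plus an ALL row.

    Cells with a single vessel report the mean with a missing SEM; empty
    cells are omitted.
    """
    df = records_to_frame(records)
    if df.empty:
        raise ValueError("no records")

    def summarize(g: pd.DataFrame) -> pd.Series:
        vals = g["reactivity"].astype(float)
        return pd.Series({
            "mean": vals.mean(),
            "sem": vals.sem() if len(vals) > 1 else np.nan,
            "n": len(vals),
        })

    per_type = (
        df.groupby(["genotype", "vessel_type"])[df.columns]
        .apply(summarize)
        .reset_index()
    )
    overall = df.groupby("genotype")[df.columns].apply(summarize).reset_index()
    overall["vessel_type"] = "ALL"
    out = pd.concat([overall, per_type], ignore_index=True)
    out["n"] = out["n"].astype(int)
    return out[["genotype", "vessel_type", "mean", "sem", "n"]]
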
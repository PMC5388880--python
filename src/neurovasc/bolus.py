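"""Gamma-variate bolus-transit modeling of per-vessel fluorescence time series.

A fluorescent dextran bolus passing through a microvessel produces a
fluorescence transient that is well described by the gamma-variate
function

    F(t) = b + A * (t - t0)^alpha * exp(-(t - t0) / beta)    for t > t0

(and F(t) = b otherwise), the classic model of an intravascular indicator
bolus.  The time-to-peak (TTP), measured from the injection trigger at
t = 0, is ``t0 + alpha * beta`` by calculus.  Cerebrovascular reactivity
is the percent shortening of TTP under a hypercapnic (CO2) challenge
relative to normocapnia.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "BolusTrace",
    "GammaVariateFit",
    "gamma_variate",
    "fit_gamma_variate",
    "vascular_reactivity",
    "classify_capillary",
]

VESSEL_TYPES = ("arteriole", "venule", "capillary")
CONDITIONS = ("normocapnia", "hypercapnia")

#: apparent-diameter cutoff below which a vessel is deemed a capillary (micrometres)
CAPILLARY_DIAMETER_UM = 10.0


@dataclass(frozen=True)
class BolusTrace:
    """One vessel's fluorescence-versus-time record under one capnia condition.

    ``time`` is seconds from the injection trigger on a uniform grid;
    ``fluorescence`` is in arbitrary units.
    """

    vessel_id: str
    vessel_type: str
    condition: str
    time: np.ndarray
    fluorescence: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        f = np.asarray(self.fluorescence, dtype=float)
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "fluorescence", f)
        if t.ndim != 1 or f.shape != t.shape:
            raise ValueError("time and fluorescence must be 1-D arrays of equal length")
        if t.size < 50:
            raise ValueError(f"trace needs >= 50 samples, got {t.size}")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(f))):
            raise ValueError("trace contains non-finite values")
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise ValueError("time must be strictly increasing")
        if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
            raise ValueError("time grid must be uniform")
        if self.vessel_type not in VESSEL_TYPES:
            raise ValueError(f"unknown vessel_type {self.vessel_type!r}")
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")

    @property
    def dt(self) -> float:
        """Sample (line) period in seconds."""
        return float(self.time[1] - self.time[0])


@dataclass(frozen=True)
class GammaVariateFit:
    """Fitted bolus-model parameters and the derived time-to-peak."""

    baseline: float
    amplitude: float
    t0: float
    alpha: float
    beta: float
    ttp: float
    rmse: float
    converged: bool


def gamma_variate(
    t: np.ndarray,
    baseline: float,
    amplitude: float,
    t0: float,
    alpha: float,
    beta: float,
) -> np.ndarray:
    """Evaluate ``b + A (t-t0)^alpha exp(-(t-t0)/beta)`` (zero before onset)."""
    t = np.asarray(t, dtype=float)
    dtp = np.clip(t - t0, 0.0, None)
    with np.errstate(invalid="ignore"):
        out = baseline + amplitude * dtp**alpha * np.exp(-dtp / beta)
    return np.where(t > t0, out, baseline)


def _peak_height_model(t, baseline, height, t0, alpha, beta):
    # Amplitude reparameterized as peak height above baseline: numerically
    # well conditioned for alpha up to ~20 where (t-t0)^alpha overflows.
    dtp = np.clip(t - t0, 0.0, None)
    peak = alpha * beta
    with np.errstate(invalid="ignore", divide="ignore"):
        # (dtp/peak)^alpha * exp(alpha - dtp/beta), equals 1 at dtp == peak
        log_shape = alpha * np.log(np.where(dtp > 0, dtp / peak, 1.0))
        out = baseline + height * np.exp(log_shape + alpha - dtp / beta)
    return np.where(t > t0, out, baseline)


def _moving_average(x: np.ndarray, window: int = 5) -> np.ndarray:
    kernel = np.ones(window) / window
    pad = window // 2
    xp = np.pad(x, pad, mode="edge")
    return np.convolve(xp, kernel, mode="valid")[: x.size]


def fit_gamma_variate(
    trace: BolusTrace,
    truncate_recirculation: bool = False,
    max_nfev: int = 200,
) -> GammaVariateFit:
    """Fit the gamma-variate bolus model to a trace by bounded least squares.

    Initialization is data driven: the baseline starts at the median of the
    pre-rise samples, onset at the first crossing of baseline + 3 pre-rise SD
    of a 5-sample moving average (smoothing is used for initialization only),
    shape ``alpha = 2``, and scale from the smoothed peak location.  Bounds:
    ``t0 in [0, t_peak]``, ``alpha in (0.1, 20]``, ``beta in (0.01, T]``.

    A trace with no suprathreshold rise above baseline yields a
    non-converged result (``converged=False``) rather than an exception;
    non-finite inputs are rejected by :class:`BolusTrace` itself.

    Parameters
    ----------
    trace
        The bolus passage record.
    truncate_recirculation
        When True the fit window ends at the first local minimum after the
        peak, discarding any second (recirculation) pass of the dye.
    """
    t = trace.time
    f = trace.fluorescence
    n = t.size

    smoothed = _moving_average(f, 5)
    peak_idx = int(np.argmax(smoothed))
    # pre-rise region: before the peak, at most the first tenth of the trace
    n_base = max(5, min(n // 10, peak_idx // 2))
    b0 = float(np.median(f[:n_base]))
    peak_height0 = float(smoothed[peak_idx] - b0)
    # sample-to-sample noise, insensitive to the smooth bolus trend
    sd_noise = float(np.std(np.diff(f)) / np.sqrt(2.0))

    rise_thresh = b0 + max(3.0 * sd_noise, 0.05 * max(peak_height0, 1e-12))
    above = np.nonzero(smoothed > rise_thresh)[0]
    no_rise = above.size == 0 or peak_height0 <= max(5.0 * sd_noise, 1e-12) or peak_idx == 0
    if no_rise:
        resid = f - b0
        return GammaVariateFit(
            baseline=b0, amplitude=0.0, t0=float("nan"), alpha=float("nan"),
            beta=float("nan"), ttp=float("nan"),
            rmse=float(np.sqrt(np.mean(resid**2))), converged=False,
        )

    t0_init = float(t[above[0]])
    t_peak = float(t[peak_idx])
    if t0_init >= t_peak:
        t0_init = max(t_peak - 2.0 * trace.dt, float(t[0]))

    if truncate_recirculation:
        post = smoothed[peak_idx:]
        minima = np.nonzero((post[1:-1] < post[:-2]) & (post[1:-1] < post[2:]))[0]
        if minima.size:
            end = peak_idx + 1 + int(minima[0]) + 1
            t, f = t[:end], f[:end]

    duration = float(t[-1] - t[0])
    alpha0 = 2.0
    beta0 = max((t_peak - t0_init) / alpha0, 0.011)
    x0 = np.array([b0, max(peak_height0, 1e-9), max(t0_init, 0.0), alpha0, beta0])
    fmin, fmax = float(f.min()), float(f.max())
    span = max(fmax - fmin, 1e-9)
    lower = np.array([fmin - span, 1e-12, 0.0, 0.1 + 1e-9, 0.01 + 1e-9])
    upper = np.array([fmax, 10.0 * span, t_peak, 20.0, duration])
    x0 = np.clip(x0, lower, upper)

    def residuals(p):
        return _peak_height_model(t, *p) - f

    sol = least_squares(
        residuals, x0, bounds=(lower, upper), method="trf",
        max_nfev=max_nfev, xtol=1e-12, ftol=1e-12, gtol=1e-12,
    )
    b, height, t0, alpha, beta = sol.x
    ttp = float(t0 + alpha * beta)
    rmse = float(np.sqrt(np.mean(sol.fun**2)))
    converged = bool(sol.success) and float(t[0]) <= ttp <= float(t[-1])
    # back out the classic-form amplitude A from the fitted peak height
    amplitude = float(height * np.exp(alpha - alpha * np.log(alpha * beta)))
    return GammaVariateFit(
        baseline=float(b), amplitude=amplitude, t0=float(t0), alpha=float(alpha),
        beta=float(beta), ttp=ttp, rmse=rmse, converged=converged,
    )


def vascular_reactivity(ttp_normo: float, ttp_hyper: float) -> float:
    """Percent TTP shortening under hypercapnia: ``100*(TTPn - TTPh)/TTPn``.

    Positive values mean faster bolus arrival during the CO2 challenge,
    i.e. preserved dilatory capacity.
    """
    if not (np.isfinite(ttp_normo) and np.isfinite(ttp_hyper)):
        raise ValueError("TTP values must be finite")
    if ttp_normo <= 0:
        raise ValueError("normocapnic TTP must be positive")
    if ttp_hyper <= 0:
        raise ValueError("hypercapnic TTP must be positive")
    return 100.0 * (ttp_normo - ttp_hyper) / ttp_normo


def classify_capillary(apparent_diameter: float) -> str:
    """Classify a vessel as ``'capillary'`` iff its apparent diameter is < 10 um."""
    if not np.isfinite(apparent_diameter) or apparent_diameter <= 0:
        raise ValueError("apparent diameter must be positive")
    return "capillary" if apparent_diameter < CAPILLARY_DIAMETER_UM else "non_capillary"
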
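"""Synthetic cohorts with fully known ground truth.

Three generators emulate the data streams of a neurovascular-dysfunction experiment:

* **Bolus-tracking cohorts** — paired normocapnia/hypercapnia fluorescence
  line-scan traces per vessel.  The generative model realizes the two core
  hemodynamic assumptions: per-vessel reactivity (TTP shortens by R_v percent
  on average) and transit-time homogenization (the *dispersion* of TTP
  contracts by the flow factor ``k = 1 + F/100`` under hypercapnia), so a
  mean-centered regression of hypercapnic on normocapnic TTP has slope 1/k.
* **PAC-bearing LFPs** — a theta carrier plus a gamma carrier whose envelope
  is modulated by the theta phase with controllable depth m, in 1/f + white
  noise.  The clean composite-signal modulation index is ``A_gamma * m / 2``.
* **Morphometry mask scenes** — vessel/mural-cell/plaque masks constructed
  pixel-exactly from requested coverage, detachment and plaque-size targets.

All generators are deterministic under a fixed seed; one seed is split
hierarchically so each sub-generator can be exercised in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .bolus import BolusTrace
from .morphometry import LabeledMask
from .pac import LFPRecording

__all__ = [
    "BolusCohortConfig",
    "PacSignalConfig",
    "MaskSceneConfig",
    "PacGroundTruth",
    "generate_bolus_cohort",
    "generate_pac_signal",
    "generate_mask_scene",
]


# ---------------------------------------------------------------------------
# bolus-tracking cohorts
# ---------------------------------------------------------------------------

def _default_n_vessels() -> dict[str, int]:
    # 147 vessels total, matching the size of the control cohort
    return {"arteriole": 60, "capillary": 45, "venule": 42}


def _default_mean_ttp() -> dict[str, float]:
    # arterioles receive the bolus before venules; capillaries in between
    return {"arteriole": 3.0, "capillary": 4.0, "venule": 5.0}


def _default_ttp_sd() -> dict[str, float]:
    return {"arteriole": 0.5, "capillary": 0.6, "venule": 0.7}


def _default_reactivity() -> dict[str, float]:
    # control-cohort reactivities by vessel type, percent
    return {"arteriole": 15.0, "capillary": 13.0, "venule": 15.0}


@dataclass
class BolusCohortConfig:
    """Generative parameters for a paired normo/hypercapnia bolus cohort.

    ``flow_change_true`` (percent) sets the dispersion contraction
    ``k = 1 + F/100``; ``reactivity_true_by_type`` (percent) sets the mean
    TTP shortening per vessel type.  Trace geometry follows the acquisition:
    20 ms line period, 11-13 s scans, TTP measured from the injection
    trigger at t = 0.
    """

    n_vessels_per_type: Mapping[str, int] = field(default_factory=_default_n_vessels)
    mean_ttp_by_type: Mapping[str, float] = field(default_factory=_default_mean_ttp)
    ttp_sd_by_type: Mapping[str, float] = field(default_factory=_default_ttp_sd)
    flow_change_true: float = 74.0
    reactivity_true_by_type: Mapping[str, float] = field(default_factory=_default_reactivity)
    line_period: float = 0.020
    scan_duration: float = 12.0
    noise_sd: float = 2.5
    baseline: float = 100.0
    amplitude: float = 50.0
    alpha_shape: float = 3.0
    onset_fraction: float = 0.5       # t0 as a fraction of the target TTP
    ttp_measurement_sd: float = 0.05  # seconds; epsilon on hypercapnic TTP
    n_animals: int = 9
    genotype: str = "nTg"
    seed: int = 0

    def validate(self) -> None:
        if self.line_period <= 0:
            raise ValueError("line_period must be positive")
        if not 0 < self.onset_fraction < 1:
            raise ValueError("onset_fraction must be in (0, 1)")
        if self.noise_sd < 0 or self.ttp_measurement_sd < 0:
            raise ValueError("noise SDs must be non-negative")
        if self.flow_change_true <= -100:
            raise ValueError("flow_change_true must exceed -100 percent")
        if self.alpha_shape <= 0:
            raise ValueError("alpha_shape must be positive")
        for v, sd in self.ttp_sd_by_type.items():
            if sd < 0:
                raise ValueError(f"ttp_sd_by_type[{v!r}] must be >= 0")
        for v, mu in self.mean_ttp_by_type.items():
            sd = self.ttp_sd_by_type[v]
            # nominal feasibility at +-4 SD; individual draws re-checked
            if not self._ttp_feasible(mu + 4.0 * sd) or mu - 4.0 * sd <= 0.1:
                raise ValueError(
                    f"mean_ttp_by_type[{v!r}]={mu} with SD {sd} does not fit the "
                    f"{self.scan_duration} s scan window"
                )

    def _ttp_feasible(self, ttp: float) -> bool:
        # trace must contain the peak plus a ~3 beta decay tail
        beta = (1.0 - self.onset_fraction) * ttp / self.alpha_shape
        return 0.1 < ttp and ttp + 3.0 * beta <= self.scan_duration


def _draw_ttp(rng: np.random.Generator, cfg: BolusCohortConfig, mu: float, sd: float,
              k: float, r_pct: float) -> tuple[float, float, float]:
    """Draw one vessel's latent deviation and its paired TTPs, rejecting
    tail draws whose bolus curve would not fit inside the scan window."""
    for _ in range(1000):
        delta = rng.normal(0.0, sd)
        eps = rng.normal(0.0, cfg.ttp_measurement_sd)
        ttp_n = mu + delta
        ttp_h = (1.0 - r_pct / 100.0) * mu + delta / k + eps
        if cfg._ttp_feasible(ttp_n) and cfg._ttp_feasible(ttp_h):
            return delta, ttp_n, ttp_h
    raise ValueError("could not draw a feasible TTP; config too close to the scan window")


def _make_trace(time: np.ndarray, ttp: float, cfg: BolusCohortConfig,
                rng: np.random.Generator, vessel_id: str, vtype: str,
                condition: str) -> BolusTrace:
    t0 = cfg.onset_fraction * ttp
    beta = (ttp - t0) / cfg.alpha_shape
    alpha = cfg.alpha_shape
    dtp = np.clip(time - t0, 0.0, None)
    with np.errstate(divide="ignore", invalid="ignore"):
        shape = np.exp(alpha * np.log(np.where(dtp > 0, dtp / (alpha * beta), 1.0))
                       + alpha - dtp / beta)
    clean = cfg.baseline + cfg.amplitude * np.where(time > t0, shape, 0.0)
    noisy = clean + rng.normal(0.0, cfg.noise_sd, size=time.size) if cfg.noise_sd > 0 else clean
    return BolusTrace(vessel_id=vessel_id, vessel_type=vtype, condition=condition,
                      time=time, fluorescence=noisy)


def generate_bolus_cohort(
    cfg: BolusCohortConfig,
) -> tuple[list[tuple[BolusTrace, BolusTrace]], pd.DataFrame]:
    """Generate paired bolus traces and the ground-truth vessel table.

    For vessel i of type v:

    * ``TTP_normo = mu_v + delta_i`` with ``delta_i ~ N(0, sd_v)``
    * ``TTP_hyper = (1 - R_v/100) * mu_v + delta_i / k + eps_i`` with
      ``k = 1 + F/100`` and small measurement noise ``eps_i``

    Each trace is the gamma-variate curve peaking exactly at the vessel's
    target TTP (peak height = ``cfg.amplitude``) plus white noise.  The
    returned table records every latent value (delta, both true TTPs, the
    realized per-vessel reactivity) alongside vessel/animal assignments.
    """
    cfg.validate()
    k = 1.0 + cfg.flow_change_true / 100.0
    root = np.random.SeedSequence(cfg.seed)
    ss_ttp, ss_noise = root.spawn(2)
    rng_ttp = np.random.default_rng(ss_ttp)
    rng_noise = np.random.default_rng(ss_noise)

    time = np.arange(0.0, cfg.scan_duration, cfg.line_period)
    pairs: list[tuple[BolusTrace, BolusTrace]] = []
    rows = []
    idx = 0
    for vtype, n in cfg.n_vessels_per_type.items():
        mu = cfg.mean_ttp_by_type[vtype]
        sd = cfg.ttp_sd_by_type[vtype]
        r_pct = cfg.reactivity_true_by_type[vtype]
        for _ in range(n):
            vid = f"{cfg.genotype}-v{idx:04d}"
            animal = f"{cfg.genotype}-a{idx % cfg.n_animals:02d}"
            delta, ttp_n, ttp_h = _draw_ttp(rng_ttp, cfg, mu, sd, k, r_pct)
            tr_n = _make_trace(time, ttp_n, cfg, rng_noise, vid, vtype, "normocapnia")
            tr_h = _make_trace(time, ttp_h, cfg, rng_noise, vid, vtype, "hypercapnia")
            pairs.append((tr_n, tr_h))
            rows.append({
                "vessel_id": vid, "animal_id": animal, "genotype": cfg.genotype,
                "vessel_type": vtype, "delta": delta,
                "ttp_normo_true": ttp_n, "ttp_hyper_true": ttp_h,
                "reactivity_true": 100.0 * (ttp_n - ttp_h) / ttp_n,
            })
            idx += 1
    return pairs, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# phase-amplitude-coupled LFPs
# ---------------------------------------------------------------------------

@dataclass
class PacSignalConfig:
    """Generative parameters for a theta-gamma coupled LFP.

    ``coupling_depth`` m in [0, 1] modulates the gamma envelope
    ``A_gamma * (1 + m cos(theta_phase - coupling_phase))``; the raw
    modulation index of the clean coupled component is ``A_gamma * m / 2``.
    """

    sampling_rate: float = 20_000.0
    duration: float = 120.0
    theta_freq: float = 6.0
    gamma_freq: float = 80.0
    theta_amp: float = 1.0
    gamma_amp: float = 0.2
    coupling_depth: float = 0.5
    coupling_phase: float = 0.0
    noise_white_sd: float = 1.0
    noise_pink_sd: float = 1.0
    freq_wander_hz: float = 0.15   # RMS of the theta instantaneous-frequency wander
    freq_wander_tau: float = 1.0   # seconds; correlation time of the wander
    seed: int = 0

    def validate(self) -> None:
        if self.sampling_rate <= 0 or self.duration <= 0:
            raise ValueError("sampling_rate and duration must be positive")
        if self.gamma_freq >= self.sampling_rate / 2:
            raise ValueError("gamma_freq must lie below the Nyquist frequency")
        if self.theta_freq <= 0 or self.gamma_freq <= self.theta_freq:
            raise ValueError("need 0 < theta_freq < gamma_freq")
        if not 0.0 <= self.coupling_depth <= 1.0:
            raise ValueError("coupling_depth must lie in [0, 1]")
        if self.noise_white_sd < 0 or self.noise_pink_sd < 0:
            raise ValueError("noise SDs must be non-negative")
        if self.freq_wander_hz < 0 or self.freq_wander_tau <= 0:
            raise ValueError("freq_wander_hz must be >= 0 and freq_wander_tau > 0")


@dataclass(frozen=True)
class PacGroundTruth:
    """Latent components of a generated PAC signal."""

    theta_phase: np.ndarray      # radians, unwrapped 2*pi*f_theta*t
    gamma_envelope: np.ndarray   # A_gamma * (1 + m cos(phase - phi_c))
    clean_mi: float              # analytic raw MI of the coupled component


def _pink_noise(rng: np.random.Generator, n: int, sd: float) -> np.ndarray:
    """1/f-amplitude noise via spectral shaping of white noise (DC zeroed)."""
    if sd == 0:
        return np.zeros(n)
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n)
    with np.errstate(divide="ignore", invalid="ignore"):
        spec = np.where(freqs > 0, spec / freqs, 0.0)
    pink = np.fft.irfft(spec, n)
    return pink * (sd / pink.std())


def generate_pac_signal(cfg: PacSignalConfig) -> tuple[LFPRecording, PacGroundTruth]:
    """Generate one LFP with theta-phase-modulated gamma amplitude.

    ``x(t) = A_th cos(phi(t)) + A_g (1 + m cos(phi(t) - phi_c)) cos(2 pi f_g t)
    + pink + white``, with ``phi(t) = 2 pi integral of (f_th + nu(t)) dt``.

    ``nu(t)`` is an Ornstein-Uhlenbeck frequency wander (RMS
    ``freq_wander_hz``, correlation time ``freq_wander_tau``) shared by the
    theta carrier and the gamma envelope.  A strictly periodic carrier
    would make circular time-shifts of the envelope equivalent to a
    constant phase offset, leaving the coupling (and its MI) intact in
    every shift surrogate; physiological theta holds its phase only over a
    few cycles, and the wander restores that property.  The smooth
    (band-limited) wander keeps the modulation sidebands inside the
    analysis filters, and the envelope/phase structure and analytic MI
    ``A_gamma * m / 2`` are unchanged.
    """
    cfg.validate()
    root = np.random.SeedSequence(cfg.seed)
    ss_white, ss_pink, ss_drift = root.spawn(3)
    n = int(round(cfg.duration * cfg.sampling_rate))
    t = np.arange(n) / cfg.sampling_rate
    phase = 2.0 * np.pi * cfg.theta_freq * t
    if cfg.freq_wander_hz > 0:
        dt = 1.0 / cfg.sampling_rate
        rho = np.exp(-dt / cfg.freq_wander_tau)
        eps = np.random.default_rng(ss_drift).normal(
            0.0, cfg.freq_wander_hz * np.sqrt(1.0 - rho * rho), n)
        # exact OU discretization; the AR(1) recursion runs in C via lfilter
        from scipy.signal import lfilter
        nu = lfilter([1.0], [1.0, -rho], eps)
        phase = phase + 2.0 * np.pi * np.cumsum(nu) * dt
    envelope = cfg.gamma_amp * (1.0 + cfg.coupling_depth
                                * np.cos(phase - cfg.coupling_phase))
    x = cfg.theta_amp * np.cos(phase) + envelope * np.cos(2.0 * np.pi * cfg.gamma_freq * t)
    x = x + _pink_noise(np.random.default_rng(ss_pink), n, cfg.noise_pink_sd)
    if cfg.noise_white_sd > 0:
        x = x + np.random.default_rng(ss_white).normal(0.0, cfg.noise_white_sd, n)
    rec = LFPRecording(samples=x, sampling_rate=cfg.sampling_rate,
                       channel_id="sim", animal_id="sim", genotype="sim")
    truth = PacGroundTruth(theta_phase=phase, gamma_envelope=envelope,
                           clean_mi=cfg.gamma_amp * cfg.coupling_depth / 2.0)
    return rec, truth


# ---------------------------------------------------------------------------
# morphometry mask scenes
# ---------------------------------------------------------------------------

@dataclass
class MaskSceneConfig:
    """Construction targets for a vessel/mural-cell/plaque mask scene.

    Mural cells are equal-size square blobs, so the achievable detachment
    fractions are multiples of ``1 / n_cells``.
    """

    image_shape: tuple[int, int] = (256, 256)
    pixel_size: float = 1.0
    plaque_areas: Sequence[float] = (100.0, 400.0)   # um^2
    coverage_fraction_true: float = 0.6
    detached_fraction_true: float = 0.3
    n_cells: int = 20
    cell_size: int = 4                               # pixels on a side
    seed: int = 0

    def validate(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        for frac in (self.coverage_fraction_true, self.detached_fraction_true):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        if self.coverage_fraction_true == 0:
            raise ValueError("coverage_fraction_true must be > 0 (cells exist)")
        if self.n_cells < 2 or self.cell_size < 1:
            raise ValueError("need at least 2 cells of positive size")
        px_area = self.pixel_size**2
        for a in self.plaque_areas:
            if round(a / px_area) < 1:
                raise ValueError(f"plaque area {a} um^2 below one pixel")


def _blob_rows(area_px: int, width: int) -> list[tuple[int, int]]:
    """Row-major fill pattern (row, run length) of an exact-area blob."""
    rows = []
    r = 0
    remaining = area_px
    while remaining > 0:
        run = min(width, remaining)
        rows.append((r, run))
        remaining -= run
        r += 1
    return rows


def generate_mask_scene(
    cfg: MaskSceneConfig,
) -> tuple[dict[str, LabeledMask], dict[str, object]]:
    """Construct lectin/desmin/plaque masks with pixel-exact ground truth.

    Returns masks keyed ``'lectin'`` (vessel, binary), ``'desmin'`` (binary),
    ``'desmin_instances'`` (one label per mural cell; attached cells touch,
    detached cells are >= 2 px from every other cell), and ``'plaques'``
    (binary, one component per requested area), plus a ground-truth record.
    """
    cfg.validate()
    h, w = cfg.image_shape
    cs = cfg.cell_size
    gap = 3  # chebyshev separation between non-touching placements

    n_det = int(round(cfg.detached_fraction_true * cfg.n_cells))
    n_att = cfg.n_cells - n_det
    if n_att == 1:
        raise ValueError(
            "one attached cell cannot touch anything; adjust n_cells or the fraction"
        )

    instances = np.zeros((h, w), dtype=np.int32)
    label = 0
    x, y = gap, gap

    def place_block(n_cells_in_block: int) -> None:
        nonlocal x, y, label
        block_w = n_cells_in_block * cs
        if x + block_w + gap > w:
            x = gap
            y += cs + gap
        if y + cs + gap > h:
            raise ValueError("image_shape too small for the requested cells")
        for j in range(n_cells_in_block):
            label += 1
            instances[y:y + cs, x + j * cs:x + (j + 1) * cs] = label
        x += block_w + gap

    # attached cells in touching pairs (plus one triple when the count is odd)
    detached_labels: list[int] = []
    remaining = n_att
    while remaining > 0:
        size = 3 if remaining == 3 else 2
        place_block(size)
        remaining -= size
    for _ in range(n_det):
        place_block(1)
        detached_labels.append(label)

    desmin = (instances > 0).astype(np.uint8)
    n_desmin = int(desmin.sum())

    # lectin = desmin plus filler vessel pixels to hit the coverage target
    target_lectin = int(round(n_desmin / cfg.coverage_fraction_true))
    lectin = desmin.copy()
    extra = target_lectin - n_desmin
    yy = y + cs + 2 * gap
    while extra > 0:
        if yy >= h:
            raise ValueError("image_shape too small for the requested coverage")
        run = min(extra, w - 2 * gap)
        lectin[yy, gap:gap + run] = 1
        extra -= run
        yy += 2  # leave blank rows so filler does not merge with anything

    # plaques in their own mask, exact pixel areas, well separated
    plaques = np.zeros((h, w), dtype=np.uint8)
    px_area = cfg.pixel_size**2
    areas_px = [int(round(a / px_area)) for a in cfg.plaque_areas]
    px_, py_ = gap, gap
    row_h = 0
    for area in areas_px:
        side = max(int(np.ceil(np.sqrt(area))), 1)
        if px_ + side + gap > w:
            px_ = gap
            py_ += row_h + gap
            row_h = 0
        for r, run in _blob_rows(area, side):
            if py_ + r >= h:
                raise ValueError("image_shape too small for the requested plaques")
            plaques[py_ + r, px_:px_ + run] = 1
        row_h = max(row_h, int(np.ceil(area / side)))
        px_ += side + gap

    masks = {
        "lectin": LabeledMask(lectin, cfg.pixel_size, "lectin"),
        "desmin": LabeledMask(desmin, cfg.pixel_size, "desmin"),
        "desmin_instances": LabeledMask(instances, cfg.pixel_size, "desmin"),
        "plaques": LabeledMask(plaques, cfg.pixel_size, "6F3D"),
    }
    det_px = int(np.isin(instances, detached_labels).sum())
    truth = {
        "coverage_fraction": n_desmin / lectin.sum(),
        "detached_fraction": det_px / n_desmin,
        "detached_labels": detached_labels,
        "n_cells": cfg.n_cells,
        "plaque_areas_px": areas_px,
    }
    return masks, truth
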
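"""Calibrated luminal Ca2+ analysis of trapped-dye fluorescence traces.

Covers the saturable-dye calibration F -> [Ca2+], smoothed-derivative flux
extraction with uptake/store-operated-entry peaks, epoch steady states,
the entry-flux vs luminal-Ca regression, and the luminal calcium-content
budget (B x [Ca2+] x volume fraction).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.signal import savgol_filter

__all__ = [
    "CalibrationParams", "FluorescenceTrace", "CalciumTrace", "FluxEstimate",
    "CalciumBudget", "SteadyState", "RegressionResult",
    "fluorescence_from_ca", "calibrate", "derive_flux", "steady_state",
    "soce_regression", "calcium_budget", "budget_fold_change",
]

#: in-situ dissociation constant of the trapped low-affinity dye, mM
DEFAULT_KD_MM = 0.8


@dataclass(frozen=True)
class CalibrationParams:
    """Saturable-binding calibration constants.

    F(ca) = F_min + (F_max - F_min) * ca / (K_D + ca); the calibration
    inverts this exactly.  K_D defaults to the in-situ value of 0.8 mM.
    """

    f_min: float
    f_max: float
    kd_mm: float = DEFAULT_KD_MM

    def __post_init__(self) -> None:
        if not self.f_max > self.f_min:
            raise ValueError("F_max must exceed F_min")
        if not self.kd_mm > 0:
            raise ValueError("K_D must be positive")


@dataclass
class FluorescenceTrace:
    """Timestamped trapped-dye fluorescence with solution-epoch labels."""

    time_s: np.ndarray
    f: np.ndarray
    calib: CalibrationParams
    epoch_labels: Optional[np.ndarray] = None
    #: label -> {"cyto_ca_um": float, "caffeine": bool}
    epoch_info: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.f = np.asarray(self.f, dtype=float)
        if self.time_s.shape != self.f.shape:
            raise ValueError("time and F must have equal length")
        if self.time_s.size >= 2 and not np.all(np.diff(self.time_s) > 0):
            raise ValueError("time must be strictly increasing")
        if self.epoch_labels is not None:
            self.epoch_labels = np.asarray(self.epoch_labels)
            if self.epoch_labels.shape != self.time_s.shape:
                raise ValueError("epoch_labels length mismatch")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"time_s": self.time_s, "F": self.f})
        if self.epoch_labels is not None:
            df["epoch_label"] = self.epoch_labels
        return df


@dataclass
class CalciumTrace:
    """Calibrated free luminal [Ca2+] in mM for one compartment."""

    time_s: np.ndarray
    ca_mm: np.ndarray
    compartment: str = "t_system"  # or "vacuole"
    epoch_labels: Optional[np.ndarray] = None
    epoch_info: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.ca_mm = np.asarray(self.ca_mm, dtype=float)
        if self.compartment not in ("t_system", "vacuole"):
            raise ValueError("compartment must be 't_system' or 'vacuole'")
        if np.any(self.ca_mm < 0):
            raise ValueError("calcium concentrations must be non-negative")
        if self.epoch_labels is not None:
            self.epoch_labels = np.asarray(self.epoch_labels)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"time_s": self.time_s, "ca_mm": self.ca_mm,
                           "compartment": self.compartment})
        if self.epoch_labels is not None:
            df["epoch_label"] = self.epoch_labels
        return df


class SteadyState(NamedTuple):
    value_mm: float
    steady: bool


class RegressionResult(NamedTuple):
    slope: float
    intercept: float
    r_squared: float


@dataclass
class FluxEstimate:
    """Peak luminal uptake and store-operated-entry fluxes (mM/s in lumen)."""

    peak_uptake: Optional[float]
    peak_soce: Optional[float]
    uptake_epoch: Optional[str]
    soce_epoch: Optional[str]
    flux: np.ndarray
    time_s: np.ndarray
    smoothing_window: int
    polyorder: int

    def per_fibre_volume(self, t_sys_vol_percent: float) -> dict:
        """Rescale peaks to per-fibre-volume units (uM/s per fibre volume)."""
        scale = t_sys_vol_percent / 100.0 * 1000.0
        return {
            "peak_uptake_um_per_s_fibre": None if self.peak_uptake is None else self.peak_uptake * scale,
            "peak_soce_um_per_s_fibre": None if self.peak_soce is None else self.peak_soce * scale,
        }


@dataclass(frozen=True)
class CalciumBudget:
    """Luminal calcium content per fibre volume: B x [Ca2+] x vol%."""

    b: float
    ca_t_sys_mm: float
    t_sys_vol_percent: float

    @property
    def content_um(self) -> float:
        """Content in uM relative to fibre volume (mM -> uM factor 1000)."""
        return self.b * self.ca_t_sys_mm * (self.t_sys_vol_percent / 100.0) * 1000.0


# ---------------------------------------------------------------------------
# operations


def fluorescence_from_ca(ca_mm, calib: CalibrationParams):
    """Forward saturable-binding map [Ca2+] -> F (exact inverse of calibrate)."""
    ca = np.asarray(ca_mm, dtype=float)
    return calib.f_min + (calib.f_max - calib.f_min) * ca / (calib.kd_mm + ca)


def calibrate(trace: FluorescenceTrace, saturation_guard: float = 0.98,
              out_of_range_tol: float = 0.02) -> CalciumTrace:
    """Convert fluorescence to luminal [Ca2+] via ca = K_D*(F-Fmin)/(Fmax-F).

    F is clamped into [F_min, F_max] when within ``out_of_range_tol`` of the
    range; values beyond that, or at/above the ``saturation_guard`` fraction
    of the range (where the hyperbolic transform diverges), raise.
    """
    calib = trace.calib
    rng = calib.f_max - calib.f_min
    f = trace.f.astype(float)
    low, high = calib.f_min - out_of_range_tol * rng, calib.f_max + out_of_range_tol * rng
    if np.any(f < low) or np.any(f > high):
        raise ValueError("fluorescence outside calibration range by more than "
                         f"{out_of_range_tol:.0%} of (F_max - F_min)")
    f = np.clip(f, calib.f_min, calib.f_max)
    if np.any(f >= calib.f_min + saturation_guard * rng):
        raise ValueError("fluorescence at or beyond the saturation guard "
                         f"({saturation_guard:.0%} of range); [Ca2+] unbounded")
    ca = calib.kd_mm * (f - calib.f_min) / (calib.f_max - f)
    return CalciumTrace(time_s=trace.time_s, ca_mm=ca,
                        epoch_labels=trace.epoch_labels, epoch_info=trace.epoch_info)


def _epoch_spans(labels: np.ndarray) -> list[tuple[str, slice]]:
    """Contiguous runs of identical epoch labels, in order."""
    spans = []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            spans.append((str(labels[start]), slice(start, i)))
            start = i
    return spans


def derive_flux(ca_trace: CalciumTrace, b: float = 1.0,
                smoothing_window: int = 5, polyorder: int = 2,
                elevated_cyto_um: float = 0.1) -> FluxEstimate:
    """Flux = B * d[Ca]/dt by Savitzky-Golay smoothed differentiation.

    Peak uptake is the flux maximum during non-caffeine epochs with
    elevated cytoplasmic Ca (``cyto_ca_um > elevated_cyto_um``); peak
    store-operated entry is the flux minimum during caffeine epochs.
    Epochs shorter than the smoothing window shrink it with a warning.
    """
    t, ca = ca_trace.time_s, ca_trace.ca_mm
    if t.size < 5:
        raise ValueError("need at least 5 samples to derive a flux")
    dt = float(np.median(np.diff(t)))
    window = int(smoothing_window) | 1
    if window > t.size:
        warnings.warn("smoothing window longer than trace; shrinking")
        window = (t.size - 1) | 1
    if polyorder >= window:
        polyorder = window - 1
    flux = b * savgol_filter(ca, window_length=window, polyorder=polyorder,
                             deriv=1, delta=dt)

    peak_uptake = peak_soce = None
    uptake_epoch = soce_epoch = None
    if ca_trace.epoch_labels is not None:
        for label, span in _epoch_spans(ca_trace.epoch_labels):
            if span.stop - span.start < 5:
                warnings.warn(f"epoch {label!r} shorter than 5 samples; skipped for peaks")
                continue
            info = ca_trace.epoch_info.get(label, {})
            seg = flux[span]
            if info.get("caffeine", False):
                m = float(seg.min())
                if peak_soce is None or m < peak_soce:
                    peak_soce, soce_epoch = m, label
            elif info.get("cyto_ca_um", 0.0) > elevated_cyto_um:
                m = float(seg.max())
                if peak_uptake is None or m > peak_uptake:
                    peak_uptake, uptake_epoch = m, label
    return FluxEstimate(peak_uptake=peak_uptake, peak_soce=peak_soce,
                        uptake_epoch=uptake_epoch, soce_epoch=soce_epoch,
                        flux=flux, time_s=t, smoothing_window=window,
                        polyorder=polyorder)


def steady_state(ca_trace: CalciumTrace, epoch: str,
                 tail_fraction: float = 0.2,
                 slope_tol_fraction: float = 0.01) -> SteadyState:
    """Mean of the final ``tail_fraction`` of an epoch.

    Flagged unsteady when the tail slope exceeds ``slope_tol_fraction`` of
    the epoch's [Ca2+] range per sample.
    """
    if not 0 < tail_fraction <= 1:
        raise ValueError("tail_fraction must be in (0, 1]")
    if ca_trace.epoch_labels is None:
        raise ValueError("trace carries no epoch labels")
    sel = np.flatnonzero(ca_trace.epoch_labels == epoch)
    if sel.size == 0:
        raise ValueError(f"epoch {epoch!r} not present in trace")
    ca_epoch = ca_trace.ca_mm[sel]
    n_tail = max(2, int(round(tail_fraction * sel.size)))
    tail = ca_epoch[-n_tail:]
    value = float(tail.mean())
    epoch_range = float(ca_epoch.max() - ca_epoch.min())
    slope = float(np.polyfit(np.arange(n_tail, dtype=float), tail, 1)[0])
    steady = epoch_range == 0 or abs(slope) <= slope_tol_fraction * epoch_range
    return SteadyState(value_mm=value, steady=bool(steady))


def soce_regression(points: Sequence[tuple[float, float]]) -> RegressionResult:
    """OLS of peak entry flux against luminal [Ca2+]: slope, intercept, r^2."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
        raise ValueError("need >= 2 (ca, flux) pairs")
    x, y = pts[:, 0], pts[:, 1]
    if np.allclose(x, x[0]):
        raise ValueError("all [Ca2+] values identical; slope undefined")
    res = stats.linregress(x, y)
    return RegressionResult(slope=float(res.slope), intercept=float(res.intercept),
                            r_squared=float(res.rvalue) ** 2)


def calcium_budget(b: float, ca_t_sys_mm: float, t_sys_vol_percent: float) -> CalciumBudget:
    """Luminal calcium content per fibre volume (uM) = B x ca x vol%/100 x 1000."""
    if b < 0 or ca_t_sys_mm < 0 or t_sys_vol_percent < 0:
        raise ValueError("budget inputs must be non-negative")
    return CalciumBudget(b=b, ca_t_sys_mm=ca_t_sys_mm, t_sys_vol_percent=t_sys_vol_percent)


def budget_fold_change(pre: CalciumBudget, post: CalciumBudget) -> float:
    if pre.content_um <= 0:
        raise ValueError("pre-condition budget content must be positive")
    return post.content_um / pre.content_um
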
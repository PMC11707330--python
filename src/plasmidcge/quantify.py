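"""Isoform quantification: windows, integration, fractions, deconvolution, sizing.

The pipeline's central quantity is the fraction of plasmid in each of the
three topological isoforms — linear (Lin, double-strand break product),
supercoiled (SC/CCC, intact) and open-circular (OC, nicked).  On a
background-corrected capillary electropherogram of pUC19 the three species
migrate as bands centered near 400 s, 500 s and 750 s respectively; each band
is integrated over a fixed time window and the areas are normalized to their
sum.  Agarose-gel lane profiles, whose OC and Lin bands can overlap, are
instead deconvolved by nonlinear least-squares fitting of Gaussians, and the
SC band intensity is divided by the SYBR-Gold attachment-efficiency ratio
(1.05 for SC vs OC of pUC19) before normalization.  A DNA ladder lane gives a
log-linear apparent-size calibration of the migration-time axis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import optimize, signal as sps

from .errors import (
    LadderMatchError,
    MarkerNotFoundError,
    UndefinedFractionError,
    ValidationError,
    WindowRangeError,
)
from .trace_io import LadderSpec, Trace

ISOFORMS = ("lin", "sc", "oc")


@dataclass(frozen=True)
class IsoformWindows:
    """Closed time intervals assigned to the Lin, SC and OC bands (seconds).

    Interval interiors must be pairwise disjoint (adjacent windows may share an
    endpoint) and each must satisfy start < end.
    """

    lin: Tuple[float, float] = (350.0, 450.0)
    sc: Tuple[float, float] = (450.0, 600.0)
    oc: Tuple[float, float] = (650.0, 850.0)

    def __post_init__(self) -> None:
        for name, (a, b) in self.items():
            if not (np.isfinite(a) and np.isfinite(b) and a < b):
                raise ValidationError(f"window {name}: need start < end, got ({a}, {b})")
        ivs = sorted(self.items(), key=lambda kv: kv[1][0])
        for (na, (_, ea)), (nb, (sb, _)) in zip(ivs, ivs[1:]):
            if ea > sb:
                raise ValidationError(f"windows {na} and {nb} overlap")

    def items(self):
        return [(k, getattr(self, k)) for k in ISOFORMS]

    def shifted(self, dt: float) -> "IsoformWindows":
        return IsoformWindows(
            lin=(self.lin[0] + dt, self.lin[1] + dt),
            sc=(self.sc[0] + dt, self.sc[1] + dt),
            oc=(self.oc[0] + dt, self.oc[1] + dt),
        )


DEFAULT_WINDOWS = IsoformWindows()


@dataclass(frozen=True)
class IsoformIntegrals:
    """Trapezoidal band areas (signal*seconds, >= 0) per isoform.

    ``clipped`` names windows whose raw integral was negative (noise after
    background subtraction) and was clipped to zero.
    """

    lin: float
    sc: float
    oc: float
    clipped: Tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for name in ISOFORMS:
            if getattr(self, name) < 0:
                raise ValidationError(f"integral {name} must be >= 0")

    @property
    def total(self) -> float:
        return self.lin + self.sc + self.oc


@dataclass(frozen=True)
class DyeCorrection:
    """Per-isoform dye attachment efficiencies (fluorescence per unit DNA).

    SYBR Gold binds the supercoiled form of pUC19 1.05x as efficiently as the
    open-circular form, so gel band intensities are divided by these factors
    before normalization.  Capillary quantification applies no correction
    (unit efficiencies); pass ``None`` to :func:`fractions_from_integrals`.
    """

    sc_efficiency: float = 1.05
    lin_efficiency: float = 1.0
    oc_efficiency: float = 1.0

    def __post_init__(self) -> None:
        if min(self.sc_efficiency, self.lin_efficiency, self.oc_efficiency) <= 0:
            raise ValidationError("dye efficiencies must be > 0")

    def as_tuple(self) -> Tuple[float, float, float]:
        return (self.lin_efficiency, self.sc_efficiency, self.oc_efficiency)


UNIT_DYE = DyeCorrection(sc_efficiency=1.0)


@dataclass(frozen=True)
class IsoformFractions:
    """Sum-normalized isoform fractions, each in [0, 1], summing to 1."""

    f_lin: float
    f_sc: float
    f_oc: float

    def __post_init__(self) -> None:
        for name in ("f_lin", "f_sc", "f_oc"):
            v = getattr(self, name)
            if not (-1e-12 <= v <= 1 + 1e-12):
                raise ValidationError(f"{name}={v} outside [0, 1]")
        if abs(self.f_lin + self.f_sc + self.f_oc - 1.0) > 1e-9:
            raise ValidationError("fractions must sum to 1 within 1e-9")

    def as_tuple(self) -> Tuple[float, float, float]:
        return (self.f_lin, self.f_sc, self.f_oc)


@dataclass
class GaussianPeak:
    """One Gaussian band: unit-area shape scaled by ``area``, width ``sigma``."""

    center: float
    sigma: float
    area: float
    label: Optional[str] = None

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValidationError("sigma must be > 0")
        if self.area < 0:
            raise ValidationError("area must be >= 0")

    def evaluate(self, x: np.ndarray) -> np.ndarray:
        z = (np.asarray(x, dtype=float) - self.center) / self.sigma
        return self.area * np.exp(-0.5 * z * z) / (self.sigma * np.sqrt(2 * np.pi))


@dataclass
class MultipeakFit:
    """Result of a Gaussian multipeak deconvolution of a lane profile."""

    peaks: list
    residual_rms: float
    converged: bool

    def __post_init__(self) -> None:
        labels = [p.label for p in self.peaks if p.label is not None]
        if len(set(labels)) != len(labels):
            raise ValidationError("peak labels must be unique")

    def evaluate(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return sum((p.evaluate(x) for p in self.peaks), np.zeros_like(x))


@dataclass
class SizeMap:
    """Log-linear apparent-size calibration: knots (migration time, size in bp)."""

    times: np.ndarray
    sizes_bp: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.sizes_bp = np.asarray(self.sizes_bp, dtype=float)
        if len(self.times) != len(self.sizes_bp) or len(self.times) < 2:
            raise ValidationError("size map needs >= 2 (time, size) knots")
        if not np.all(np.diff(self.times) > 0):
            raise ValidationError("knot times must be strictly increasing")
        if not np.all(np.diff(self.sizes_bp) > 0):
            raise ValidationError("knot sizes must be strictly increasing with time")


# ---------------------------------------------------------------------------
# shared numerics (used by both the functions below and estimators.py)
# ---------------------------------------------------------------------------


def _window_integral(time: np.ndarray, signal: np.ndarray, a: float, b: float) -> float:
    """Trapezoidal integral of signal over the closed window [a, b].

    Window endpoints need not lie on the grid; the signal is linearly
    interpolated there, which makes integration exactly additive when a window
    is split at any interior point.
    """
    if a < time[0] or b > time[-1]:
        raise WindowRangeError(
            f"window [{a}, {b}] outside time grid [{time[0]}, {time[-1]}]"
        )
    ya, yb = np.interp([a, b], time, signal)
    i0 = np.searchsorted(time, a, side="right")
    i1 = np.searchsorted(time, b, side="left")
    ts = np.concatenate(([a], time[i0:i1], [b]))
    ys = np.concatenate(([ya], signal[i0:i1], [yb]))
    return float(np.trapezoid(ys, ts))


def _robust_sigma(x: np.ndarray) -> float:
    """MAD-based robust noise standard deviation (1.4826 * MAD)."""
    x = np.asarray(x, dtype=float)
    return float(1.4826 * np.median(np.abs(x - np.median(x))))


def _multipeak_model(x: np.ndarray, params: np.ndarray) -> np.ndarray:
    out = np.zeros_like(x)
    for c, s, a in params.reshape(-1, 3):
        z = (x - c) / s
        out += a * np.exp(-0.5 * z * z) / (s * np.sqrt(2 * np.pi))
    return out


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def locate_windows(
    trace: Trace,
    defaults: IsoformWindows = DEFAULT_WINDOWS,
    marker_trace: Optional[Trace] = None,
    reference_marker_time: Optional[float] = None,
) -> IsoformWindows:
    """Place the three isoform windows, optionally anchored to an alignment marker.

    Band positions vary somewhat between capillaries, injection times and
    dilution buffers.  When an alignment-marker trace and its reference time
    are given, all three windows are rigidly shifted by (observed marker apex
    - reference time); otherwise the defaults are returned unchanged.  The
    observed apex is the argmax of the marker signal and must stand at least
    5x the marker lane's robust noise above its median.
    """
    if marker_trace is None or reference_marker_time is None:
        return defaults
    sig = marker_trace.signal
    sigma = _robust_sigma(sig)
    apex_height = float(np.max(sig) - np.median(sig))
    if apex_height <= 0 or (sigma > 0 and apex_height < 5 * sigma):
        raise MarkerNotFoundError(
            f"marker lane {marker_trace.lane_id!r}: no peak above 5x noise"
        )
    apex_time = float(marker_trace.time[int(np.argmax(sig))])
    return defaults.shifted(apex_time - reference_marker_time)


def integrate_windows(trace: Trace, windows: IsoformWindows) -> IsoformIntegrals:
    """Trapezoidal band areas of a background-corrected trace over the windows.

    Negative raw integrals (possible when noise dominates an empty window
    after background subtraction) are clipped to 0 and flagged in
    ``IsoformIntegrals.clipped`` with a warning.
    """
    values = {}
    clipped = []
    material = []
    for name, (a, b) in windows.items():
        raw = _window_integral(trace.time, trace.signal, a, b)
        if raw < 0:
            clipped.append(name)
            if raw < -1e-9 * (abs(raw) + np.abs(trace.signal).max()):
                material.append(name)
            raw = 0.0
        values[name] = raw
    if material:  # roundoff-scale negatives are flagged but not worth a warning
        warnings.warn(
            f"lane {trace.lane_id!r}: negative integral clipped to 0 in {material}",
            stacklevel=2,
        )
    return IsoformIntegrals(clipped=tuple(clipped), **values)


def fractions_from_integrals(
    integrals: IsoformIntegrals, correction: Optional[DyeCorrection] = None
) -> IsoformFractions:
    """Dye-corrected, sum-normalized isoform fractions.

    Each integral is divided by its isoform's dye attachment efficiency and
    the corrected amounts are normalized to sum to 1.  ``correction=None``
    applies unit efficiencies (the capillary convention); pass
    ``DyeCorrection()`` for gel data (SC efficiency 1.05).
    """
    eff = (correction or UNIT_DYE).as_tuple()
    amounts = np.array([integrals.lin, integrals.sc, integrals.oc]) / np.array(eff)
    total = amounts.sum()
    if total <= 0:
        raise UndefinedFractionError("total integrated intensity is zero")
    f = amounts / total
    return IsoformFractions(f_lin=float(f[0]), f_sc=float(f[1]), f_oc=float(f[2]))


def quantify_trace(
    trace: Trace,
    windows: IsoformWindows = DEFAULT_WINDOWS,
    correction: Optional[DyeCorrection] = None,
) -> Tuple[IsoformIntegrals, IsoformFractions]:
    """Integrate a background-corrected trace and normalize to fractions."""
    integrals = integrate_windows(trace, windows)
    return integrals, fractions_from_integrals(integrals, correction)


def fit_multipeak(
    profile: Trace, init: Sequence[GaussianPeak], max_iter: int = 2000
) -> MultipeakFit:
    """Deconvolve an overlapping lane profile into Gaussian bands.

    Nonlinear least squares over (center, sigma, area) per peak, with bounds
    sigma > 0 and area >= 0 and centers restricted to the profile's axis
    range.  On non-convergence within ``max_iter`` function evaluations the
    last iterate is returned with ``converged=False``; such fits must not be
    used downstream.  Recovered areas serve as integrals for
    :func:`fractions_from_integrals`, which is how overlapping OC/Lin gel
    bands are quantified when plain window integration would misassign mass.
    """
    if not 1 <= len(init) <= 5:
        raise ValidationError("init must contain between 1 and 5 peaks")
    x = profile.time
    y = profile.signal
    span = float(x[-1] - x[0])
    x0, lo, hi = [], [], []
    for p in init:
        x0 += [p.center, p.sigma, p.area]
        lo += [x[0], 1e-6 * span, 0.0]
        hi += [x[-1], span, np.inf]
    x0 = np.clip(x0, lo, hi)

    def residuals(params):
        return _multipeak_model(x, params) - y

    res = optimize.least_squares(
        residuals, x0, bounds=(lo, hi), max_nfev=max_iter, xtol=1e-14, ftol=1e-14
    )
    peaks = [
        GaussianPeak(center=float(c), sigma=float(s), area=float(a), label=p.label)
        for (c, s, a), p in zip(res.x.reshape(-1, 3), init)
    ]
    rms = float(np.sqrt(np.mean(res.fun**2)))
    return MultipeakFit(peaks=peaks, residual_rms=rms, converged=res.status > 0)


def calibrate_size(ladder_trace: Trace, spec: LadderSpec) -> SizeMap:
    """Pair detected ladder peaks with the ladder spec to build a size map.

    Peaks are local maxima at least 5x the lane's robust noise above its
    median, sorted by migration time; the i-th peak is paired with the i-th
    (smallest-first) band size.  A count mismatch is an error — no silent
    partial matching.
    """
    sig = ladder_trace.signal
    sigma = _robust_sigma(sig)
    floor = float(np.median(sig))
    height = floor + 5 * sigma if sigma > 0 else floor + 1e-12 * max(1.0, np.max(np.abs(sig)))
    idx, _ = sps.find_peaks(sig, height=height)
    if len(idx) != len(spec.bands):
        raise LadderMatchError(
            f"detected {len(idx)} ladder peaks but spec lists {len(spec.bands)} bands"
        )
    return SizeMap(times=ladder_trace.time[idx], sizes_bp=spec.sizes_bp)


def apparent_size(size_map: SizeMap, t) -> np.ndarray:
    """Apparent fragment size at migration time ``t``, log-linear in size.

    Interpolates log(size) linearly between knots; queries outside the knot
    range are extrapolated with the edge segments' slopes and flagged with a
    warning.
    """
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    kt, ls = size_map.times, np.log(size_map.sizes_bp)
    out = np.interp(t_arr, kt, ls)
    below = t_arr < kt[0]
    above = t_arr > kt[-1]
    if below.any():
        slope = (ls[1] - ls[0]) / (kt[1] - kt[0])
        out[below] = ls[0] + slope * (t_arr[below] - kt[0])
    if above.any():
        slope = (ls[-1] - ls[-2]) / (kt[-1] - kt[-2])
        out[above] = ls[-1] + slope * (t_arr[above] - kt[-1])
    if below.any() or above.any():
        warnings.warn("apparent_size query outside calibration knots: extrapolating", stacklevel=2)
    result = np.exp(out)
    return float(result[0]) if np.isscalar(t) or np.ndim(t) == 0 else result
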
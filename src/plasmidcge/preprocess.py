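"""Background correction, SNR estimation, saturation detection, QC filtering.

Raw capillary traces carry a slowly drifting background on top of the DNA
bands.  Two correction modes are supported, mirroring instrument practice:
subtracting a least-squares linear baseline fitted outside the isoform
windows, or subtracting the signal of a pure-buffer lane from the same
cartridge.  Quantification then only includes sample lanes with adequate
signal-to-noise ratio and overall signal intensity, and excludes lanes whose
detector clipped (saturation plateaus).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np

from . import quantify
from .errors import (
    AlignmentError,
    InsufficientBaselineError,
    NoiseEstimationError,
    ValidationError,
)
from .trace_io import Batch, Trace


@dataclass
class BaselineModel:
    """Background model: a fitted line, or a reference to a buffer lane."""

    kind: str  # "linear" | "buffer"
    intercept: float = 0.0
    slope: float = 0.0
    buffer_ref: Optional[str] = None

    def __post_init__(self) -> None:
        if self.kind not in ("linear", "buffer"):
            raise ValidationError(f"unknown baseline kind {self.kind!r}")
        if self.kind == "buffer" and self.buffer_ref is None:
            raise ValidationError("buffer baseline requires buffer_ref")
        if self.kind == "linear" and not (
            math.isfinite(self.intercept) and math.isfinite(self.slope)
        ):
            raise ValidationError("linear baseline needs finite intercept and slope")

    def predict(self, time: np.ndarray) -> np.ndarray:
        if self.kind != "linear":
            raise ValidationError("predict() only defined for linear baselines")
        return self.intercept + self.slope * np.asarray(time, dtype=float)


@dataclass
class QCReport:
    """Per-lane quality-control outcome; excluded lanes carry their reasons."""

    lane_id: str
    snr: dict
    total_intensity: float
    saturated: bool
    included: bool
    reasons: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.included and not self.reasons:
            raise ValidationError("excluded lane must carry at least one reason")


def _exclusion_mask(time: np.ndarray, windows: Sequence[Tuple[float, float]]) -> np.ndarray:
    """Boolean mask of samples falling inside any of the given time intervals."""
    mask = np.zeros(len(time), dtype=bool)
    for a, b in windows:
        mask |= (time >= a) & (time <= b)
    return mask


def fit_linear_baseline(
    trace: Trace, exclusion_windows: Sequence[Tuple[float, float]] = ()
) -> BaselineModel:
    """Least-squares line through the samples outside the exclusion windows.

    The exclusion windows are normally the three isoform windows, so the line
    is fitted to band-free background only.  Requires >= 10 remaining samples.
    """
    excluded = _exclusion_mask(trace.time, [tuple(w) for w in exclusion_windows])
    t, s = trace.time[~excluded], trace.signal[~excluded]
    if len(t) < 10:
        raise InsufficientBaselineError(
            f"lane {trace.lane_id!r}: only {len(t)} samples outside exclusion windows (< 10)"
        )
    slope, intercept = np.polyfit(t, s, 1)
    return BaselineModel(kind="linear", intercept=float(intercept), slope=float(slope))


def correct_background(
    trace: Trace, model: Optional[BaselineModel] = None, buffer: Optional[Trace] = None
) -> Trace:
    """Subtract the predicted background; returns a new trace, input untouched.

    With a linear model the fitted line is subtracted.  With ``buffer`` (pure
    running buffer measured in its own lane) the buffer signal is subtracted
    directly when grids match, else linearly resampled onto the trace grid
    first; non-overlapping grids are an error.
    """
    if buffer is not None:
        if buffer.time[-1] <= trace.time[0] or buffer.time[0] >= trace.time[-1]:
            raise AlignmentError(
                f"buffer lane {buffer.lane_id!r} grid does not overlap {trace.lane_id!r}"
            )
        if len(buffer.time) == len(trace.time) and np.array_equal(buffer.time, trace.time):
            background = buffer.signal
        else:
            background = np.interp(trace.time, buffer.time, buffer.signal)
        return trace.with_signal(trace.signal - background)
    if model is None:
        raise ValidationError("correct_background needs a model or a buffer trace")
    if model.kind == "buffer":
        raise ValidationError("buffer-kind model requires the buffer trace argument")
    return trace.with_signal(trace.signal - model.predict(trace.time))


def estimate_snr(trace: Trace, windows: "quantify.IsoformWindows") -> dict:
    """Per-window SNR = peak height inside / robust noise sigma outside.

    The noise scale is 1.4826 x the median absolute deviation of the signal
    over all samples outside every isoform window (robust to residual peaks).
    A zero noise estimate yields ``math.inf``.  The trace must already be
    background-corrected.
    """
    intervals = [w for _, w in windows.items()]
    outside = ~_exclusion_mask(trace.time, intervals)
    if not outside.any():
        raise NoiseEstimationError(
            f"lane {trace.lane_id!r}: no samples outside the isoform windows"
        )
    sigma = quantify._robust_sigma(trace.signal[outside])
    out = {}
    for name, (a, b) in windows.items():
        inside = (trace.time >= a) & (trace.time <= b)
        peak = float(np.max(trace.signal[inside])) if inside.any() else 0.0
        out[name] = math.inf if sigma == 0 else peak / sigma
    return out


def detect_saturation(trace: Trace, level: float, min_run: int = 5) -> bool:
    """True iff >= ``min_run`` consecutive samples sit at or above ``level``.

    Detector clipping produces flat-topped plateaus; a run-length criterion
    distinguishes them from single noise excursions.  ``level`` is the
    instrument's full-scale signal and must be supplied explicitly.
    """
    if level <= 0:
        raise ValidationError("saturation level must be > 0")
    above = trace.signal >= level
    run = 0
    for flag in above:
        run = run + 1 if flag else 0
        if run >= min_run:
            return True
    return False


def qc_filter(
    batch: Batch,
    windows: "quantify.IsoformWindows",
    min_snr: float = 10.0,
    min_total: float = 0.0,
    level: Optional[float] = None,
    min_run: int = 5,
) -> Tuple[Batch, list]:
    """Keep only sample lanes with adequate SNR, total intensity, no clipping.

    A sample lane is included iff its minimum over-window SNR >= ``min_snr``,
    its total integrated intensity >= ``min_total``, and it is not saturated.
    Buffer / alignment-marker / ladder lanes pass through untouched and get no
    report.  ``level=None`` skips the saturation check (the level is
    instrument-specific and is never inferred from the data).  Traces must be
    background-corrected; included signals are returned unaltered.
    """
    kept, reports = [], []
    for trace in batch:
        if trace.role != "sample":
            kept.append(trace)
            continue
        snr = estimate_snr(trace, windows)
        total = sum(
            quantify._window_integral(trace.time, trace.signal, a, b)
            for _, (a, b) in windows.items()
        )
        saturated = detect_saturation(trace, level, min_run) if level is not None else False
        reasons = []
        if min(snr.values()) < min_snr:
            reasons.append("snr")
        if total < min_total:
            reasons.append("total_intensity")
        if saturated:
            reasons.append("saturation")
        included = not reasons
        reports.append(
            QCReport(
                lane_id=trace.lane_id,
                snr=snr,
                total_intensity=float(total),
                saturated=saturated,
                included=included,
                reasons=reasons,
            )
        )
        if included:
            kept.append(trace)
    return Batch(traces=kept, run_params=dict(batch.run_params)), reports
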
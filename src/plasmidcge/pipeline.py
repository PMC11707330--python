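"""End-to-end lane quantification: background -> windows -> integrals -> fractions.

Glue between the per-trace operations and the study analyses: quantify every
sample lane of a batch, attach QC outcomes, and reshape the results for the
replicate / linearity / concentration / kinetics analyses and the TSV writer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

from . import preprocess, quantify, study
from .errors import UndefinedFractionError
from .quantify import (
    DEFAULT_WINDOWS,
    DyeCorrection,
    IsoformFractions,
    IsoformIntegrals,
    IsoformWindows,
)
from .trace_io import Batch


@dataclass
class LaneQuant:
    """Quantification record for one sample lane."""

    lane_id: str
    meta: dict
    integrals: Optional[IsoformIntegrals]
    fractions: Optional[IsoformFractions]
    snr: dict
    included: bool
    reasons: list = field(default_factory=list)
    saturated: bool = False


def quantify_batch(
    batch: Batch,
    windows: IsoformWindows = DEFAULT_WINDOWS,
    baseline: str = "linear",
    correction: Optional[DyeCorrection] = None,
    marker_reference_time: Optional[float] = None,
    min_snr: Optional[float] = None,
    min_total: float = 0.0,
    saturation_level: Optional[float] = None,
    min_run: int = 5,
) -> List[LaneQuant]:
    """Quantify every sample lane of a batch.

    Per lane: background-correct (``baseline='linear'`` fits a line outside
    the isoform windows; ``'buffer'`` subtracts the batch's buffer lane),
    optionally shift the windows to an alignment-marker apex, integrate,
    normalize to fractions, and estimate SNR.  QC is applied when ``min_snr``
    is given: lanes failing SNR / total-intensity / saturation checks are kept
    in the output but flagged ``included=False`` with reasons.  Lanes with no
    signal at all get ``fractions=None`` and reason ``no_signal``.
    """
    buffer_trace = next(iter(batch.by_role("buffer")), None)
    markers = batch.by_role("alignment_marker")
    records: List[LaneQuant] = []
    for trace in batch.by_role("sample"):
        if baseline == "buffer" and buffer_trace is not None:
            corrected = preprocess.correct_background(trace, buffer=buffer_trace)
            # buffer subtraction leaves any residual drift; refit a line on top
            model = preprocess.fit_linear_baseline(corrected, [w for _, w in windows.items()])
            corrected = preprocess.correct_background(corrected, model)
        else:
            model = preprocess.fit_linear_baseline(trace, [w for _, w in windows.items()])
            corrected = preprocess.correct_background(trace, model)
        lane_windows = windows
        if markers and marker_reference_time is not None:
            lane_windows = quantify.locate_windows(
                corrected, windows, markers[0], marker_reference_time
            )
        saturated = (
            preprocess.detect_saturation(trace, saturation_level, min_run)
            if saturation_level is not None
            else False
        )
        snr = preprocess.estimate_snr(corrected, lane_windows)
        integrals = quantify.integrate_windows(corrected, lane_windows)
        reasons = []
        try:
            fractions = quantify.fractions_from_integrals(integrals, correction)
        except UndefinedFractionError:
            fractions = None
            reasons.append("no_signal")
        if min_snr is not None and min(snr.values()) < min_snr:
            reasons.append("snr")
        if integrals.total < min_total:
            reasons.append("total_intensity")
        if saturated:
            reasons.append("saturation")
        records.append(
            LaneQuant(
                lane_id=trace.lane_id,
                meta=dict(trace.meta),
                integrals=integrals,
                fractions=fractions,
                snr=snr,
                included=not reasons,
                reasons=reasons,
                saturated=saturated,
            )
        )
    return records


def records_to_rows(records: Sequence[LaneQuant]) -> List[dict]:
    """Flatten LaneQuant records into dict rows for the quantification TSV."""
    rows = []
    for r in records:
        rows.append(
            {
                "lane_id": r.lane_id,
                "integral_lin": r.integrals.lin if r.integrals else None,
                "integral_sc": r.integrals.sc if r.integrals else None,
                "integral_oc": r.integrals.oc if r.integrals else None,
                "total": r.integrals.total if r.integrals else None,
                "f_lin": r.fractions.f_lin if r.fractions else None,
                "f_sc": r.fractions.f_sc if r.fractions else None,
                "f_oc": r.fractions.f_oc if r.fractions else None,
                "min_snr": min(r.snr.values()) if r.snr else None,
                "saturated": r.saturated,
                "included": r.included,
                "reasons": list(r.reasons),
            }
        )
    return rows


def summaries_by(
    records: Sequence[LaneQuant], meta_key: str, group_name: Optional[str] = None
) -> List[study.ReplicateSummary]:
    """Group included lanes by a metadata key and aggregate their replicates."""
    groups: Dict[float, list] = {}
    for r in records:
        if not r.included or r.fractions is None or r.meta.get(meta_key) is None:
            continue
        groups.setdefault(float(r.meta[meta_key]), []).append(r.fractions)
    name = group_name or meta_key
    return [
        study.aggregate_replicates(fracs, {name: level})
        for level, fracs in sorted(groups.items())
    ]


def linearity_from_records(
    records: Sequence[LaneQuant], reference_level: float = 1.0
) -> study.LinearityResult:
    """Mixture-linearity analysis straight from quantified lanes."""
    summaries = summaries_by(records, "prepared_sc_fraction", "prepared_sc")
    return study.mixture_linearity(summaries, reference_level)


def concentration_from_records(records: Sequence[LaneQuant]) -> study.ConcentrationResult:
    """Concentration-series analysis straight from quantified lanes."""
    import numpy as np

    groups: Dict[float, list] = {}
    for r in records:
        conc = r.meta.get("concentration_ng_per_uL")
        if not r.included or r.fractions is None or conc is None:
            continue
        groups.setdefault(float(conc), []).append(r)
    levels = []
    for conc, recs in sorted(groups.items()):
        summary = study.aggregate_replicates(
            [r.fractions for r in recs], {"concentration_ng_per_uL": conc}
        )
        totals = np.array([r.integrals.total for r in recs], dtype=float)
        levels.append(
            study.ConcentrationLevel(
                concentration_ng_per_uL=conc,
                summary=summary,
                total_intensity_mean=float(totals.mean()),
                total_intensity_sd=float(totals.std(ddof=1)) if len(totals) > 1 else float("nan"),
            )
        )
    return study.concentration_series(levels)


def kinetics_from_records(records: Sequence[LaneQuant]) -> study.KineticsResult:
    """Digestion-kinetics tabulation straight from quantified lanes."""
    fractions = {r.lane_id: r.fractions for r in records if r.included and r.fractions}
    # blind lanes carry incubation_time_min=None (present); absent keys stay
    # absent so kinetics_timecourse can report unannotated lanes
    times = {
        r.lane_id: r.meta["incubation_time_min"]
        for r in records
        if "incubation_time_min" in r.meta
    }
    runs = {r.lane_id: r.meta["run_index"] for r in records if r.meta.get("run_index") is not None}
    return study.kinetics_timecourse(fractions, times, runs)
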
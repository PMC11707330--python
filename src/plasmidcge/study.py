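"""Downstream study analyses: replicates, mixture linearity, concentration, kinetics.

Four analyses operate on per-lane isoform fractions produced by the
quantification pipeline:

* replicate aggregation — per-isoform mean and sample standard deviation
  (uncertainties are reported as the SD over replicates of the same sample);
* mixture linearity — measured SC content, normalized to the 100 %-SC
  reference, regressed against the prepared SC fraction of SC:OC mixtures
  (ordinary least squares; the headline quality figure is R^2);
* concentration independence — fractions should not move with DNA
  concentration while total integrated intensity tracks it (Pearson r);
* digestion kinetics — the linear fraction tabulated per incubation time and
  instrument run, with per-time deltas between the two back-to-back runs.
  No kinetic model is fitted; the first-order model lives in the simulator
  as ground truth only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .errors import AnnotationError, InsufficientDesignError, ValidationError
from .quantify import IsoformFractions


@dataclass
class ReplicateSummary:
    """Mean and sample SD of isoform fractions over replicate lanes."""

    group_key: dict
    mean_fractions: IsoformFractions
    sd_fractions: Dict[str, float]  # keys f_lin, f_sc, f_oc; NaN when undefined
    n: int
    sd_defined: bool = True  # False when n == 1 (flagged, not hidden)


@dataclass
class LinearityResult:
    """OLS fit of reference-normalized measured SC content vs prepared SC content."""

    slope: float
    intercept: float
    r_squared: float
    points: List[Tuple[float, float]]  # (prepared_sc, measured_sc_normalized)


@dataclass
class ConcentrationLevel:
    """One concentration level: fraction summary plus total-intensity statistics."""

    concentration_ng_per_uL: float
    summary: ReplicateSummary
    total_intensity_mean: float
    total_intensity_sd: float = float("nan")


@dataclass
class ConcentrationResult:
    """Concentration-independence check across dilution levels."""

    levels: List[ConcentrationLevel]
    fraction_range: float  # max - min of mean f_sc across levels
    intensity_correlation: float  # Pearson r, concentration vs mean total intensity


@dataclass
class KineticsRow:
    incubation_time_min: float
    run_index: int
    fractions: IsoformFractions
    n: int = 1


@dataclass
class KineticsResult:
    """Digestion time course: fractions per (time, run) and run-2 minus run-1 deltas."""

    rows: List[KineticsRow]
    deltas: Dict[float, float]  # time -> f_lin(run2) - f_lin(run1)
    blind: List[Tuple[int, IsoformFractions]] = field(default_factory=list)


def aggregate_replicates(
    fractions_list: Sequence[IsoformFractions], group_key: Optional[dict] = None
) -> ReplicateSummary:
    """Arithmetic mean and sample SD (n-1 denominator) of replicate fractions.

    With a single replicate the SD is undefined: it is reported as NaN with
    ``sd_defined=False`` rather than silently as zero.
    """
    if not fractions_list:
        raise ValidationError("cannot aggregate an empty replicate list")
    arr = np.array([f.as_tuple() for f in fractions_list], dtype=float)
    mean = arr.mean(axis=0)
    n = len(fractions_list)
    if n > 1:
        sd = arr.std(axis=0, ddof=1)
        sd_defined = True
    else:
        sd = np.full(3, np.nan)
        sd_defined = False
    return ReplicateSummary(
        group_key=dict(group_key or {}),
        mean_fractions=IsoformFractions(*map(float, mean)),
        sd_fractions={"f_lin": float(sd[0]), "f_sc": float(sd[1]), "f_oc": float(sd[2])},
        n=n,
        sd_defined=sd_defined,
    )


def mixture_linearity(
    summaries: Sequence[ReplicateSummary], reference_level: float = 1.0
) -> LinearityResult:
    """Regress measured (reference-normalized) SC content on prepared SC content.

    Each summary's ``group_key`` must carry ``prepared_sc``.  Measured values
    are each level's mean f_sc divided by the mean f_sc of the reference level
    (the samples without enzyme-treated plasmid added, i.e. prepared_sc == 1),
    so the reference plots at (1, 1).  Ordinary least squares; R^2 = 1 -
    SS_res/SS_tot over the same stored points.
    """
    levels: Dict[float, ReplicateSummary] = {}
    for s in summaries:
        if "prepared_sc" not in s.group_key:
            raise ValidationError("summary group_key lacks 'prepared_sc'")
        levels[float(s.group_key["prepared_sc"])] = s
    if len(levels) < 3:
        raise InsufficientDesignError(
            f"mixture linearity needs >= 3 distinct prepared levels, got {len(levels)}"
        )
    ref = next((s for x, s in levels.items() if abs(x - reference_level) < 1e-9), None)
    if ref is None:
        raise InsufficientDesignError(
            f"reference level prepared_sc == {reference_level} missing"
        )
    ref_fsc = ref.mean_fractions.f_sc
    if ref_fsc <= 0:
        raise InsufficientDesignError("reference level has mean f_sc <= 0")
    points = sorted(
        (x, s.mean_fractions.f_sc / ref_fsc) for x, s in levels.items()
    )
    x = np.array([p[0] for p in points])
    y = np.array([p[1] for p in points])
    fit = stats.linregress(x, y)
    return LinearityResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        points=points,
    )


def concentration_series(levels: Sequence[ConcentrationLevel]) -> ConcentrationResult:
    """Fraction spread and intensity correlation across a concentration series.

    ``fraction_range`` is the spread (max - min) of the mean SC fraction —
    near zero when quantification is concentration independent — while
    ``intensity_correlation`` is the Pearson r between concentration and mean
    total integrated intensity, which tracks the loaded DNA amount.
    """
    if len(levels) < 3:
        raise InsufficientDesignError(
            f"concentration series needs >= 3 levels, got {len(levels)}"
        )
    levels = sorted(levels, key=lambda lv: lv.concentration_ng_per_uL)
    f_sc = [lv.summary.mean_fractions.f_sc for lv in levels]
    conc = np.array([lv.concentration_ng_per_uL for lv in levels], dtype=float)
    totals = np.array([lv.total_intensity_mean for lv in levels], dtype=float)
    r = float(stats.pearsonr(conc, totals).statistic)
    return ConcentrationResult(
        levels=list(levels),
        fraction_range=float(max(f_sc) - min(f_sc)),
        intensity_correlation=r,
    )


def kinetics_timecourse(
    fractions_by_lane: Dict[str, IsoformFractions],
    times: Dict[str, Optional[float]],
    runs: Dict[str, int],
) -> KineticsResult:
    """Tabulate isoform fractions per (incubation time, run) for a digest series.

    Every quantified sample lane must appear in both ``times`` and ``runs``;
    missing lanes are an error listing them.  Lanes annotated with
    ``times[lane] is None`` are no-enzyme blind controls and are reported
    separately.  Replicate lanes sharing a (time, run) cell are averaged.
    ``deltas[t]`` is f_lin(run 2) - f_lin(run 1) at time t, the signature of
    continued digestion between the two back-to-back runs.
    """
    missing = sorted(k for k in fractions_by_lane if k not in times or k not in runs)
    if missing:
        raise AnnotationError(f"lanes missing time/run annotations: {missing}")
    blind: List[Tuple[int, IsoformFractions]] = []
    cells: Dict[Tuple[float, int], List[IsoformFractions]] = {}
    for lane, frac in fractions_by_lane.items():
        t, run = times[lane], int(runs[lane])
        if t is None or (isinstance(t, float) and math.isnan(t)):
            blind.append((run, frac))
            continue
        cells.setdefault((float(t), run), []).append(frac)
    rows = []
    for (t, run), fracs in sorted(cells.items()):
        arr = np.array([f.as_tuple() for f in fracs]).mean(axis=0)
        rows.append(
            KineticsRow(
                incubation_time_min=t,
                run_index=run,
                fractions=IsoformFractions(*map(float, arr)),
                n=len(fracs),
            )
        )
    by_run: Dict[int, Dict[float, float]] = {}
    for row in rows:
        by_run.setdefault(row.run_index, {})[row.incubation_time_min] = row.fractions.f_lin
    deltas = {}
    for t in sorted(by_run.get(1, {})):
        if t in by_run.get(2, {}):
            deltas[t] = by_run[2][t] - by_run[1][t]
    blind.sort(key=lambda br: br[0])
    return KineticsResult(rows=rows, deltas=deltas, blind=blind)
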
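"""Synthetic electropherogram and gel-profile generator with known ground truth.

Emulates the statistical structure of pUC19 (2686 bp) capillary densiograms:
a sharp linear-isoform peak near 400 s, a sharp, high supercoiled peak near
500 s, a broad, low open-circular peak near 750 s, linear baseline drift,
additive Gaussian detector noise, per-capillary migration-time jitter and
optional detector clipping.  Bands are unit-area Gaussians scaled by DNA
amount x detector response, so with noise, jitter and clipping disabled the
quantification pipeline recovers the generating fractions exactly (to
integration truncation) — the module's core round-trip guarantee.

Study-level designs are provided as batch generators: SC:OC mixture dilution
series, restriction-digest (SC -> Lin) time courses with a second
room-temperature re-run, and agarose-gel lane profiles with optionally
overlapping OC/Lin bands and the 1.05 SYBR-Gold SC attachment efficiency
baked in.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Tuple, Union

import numpy as np
import yaml

from .errors import ValidationError
from .quantify import IsoformWindows
from .trace_io import Batch, Trace, write_metadata_table, write_trace_table

import pandas as pd


@dataclass
class GroundTruth:
    """Per-isoform DNA amounts (arbitrary mass units) behind a simulated lane."""

    amount_lin: float = 0.0
    amount_sc: float = 0.0
    amount_oc: float = 0.0
    concentration_ng_per_uL: Optional[float] = None

    def __post_init__(self) -> None:
        if min(self.amount_lin, self.amount_sc, self.amount_oc) < 0:
            raise ValidationError("amounts must be >= 0")

    @property
    def total(self) -> float:
        return self.amount_lin + self.amount_sc + self.amount_oc

    def fractions(self) -> Tuple[float, float, float]:
        """True (f_lin, f_sc, f_oc); requires positive total."""
        if self.total <= 0:
            raise ValidationError("fractions undefined for a blank lane")
        return (
            self.amount_lin / self.total,
            self.amount_sc / self.total,
            self.amount_oc / self.total,
        )


@dataclass
class SimulationConfig:
    """Generative model parameters for synthetic traces.

    Defaults reproduce the instrument geometry: a 0-1320 s grid at 1 s steps,
    band centers (Lin, SC, OC) at 400/500/750 s with sigmas 5/8/30 s (sharp
    Lin and SC, broad low OC), a drifting linear baseline, additive Gaussian
    noise, and a per-capillary migration-time jitter of a few seconds (band
    positions vary somewhat between capillaries).  ``noise_sd`` defaults to
    1% of the peak height of a pure-SC lane of total mass 100.
    """

    seed: int = 0
    t_start: float = 0.0
    t_end: float = 1320.0
    dt: float = 1.0
    peak_centers: Tuple[float, float, float] = (400.0, 500.0, 750.0)  # lin, sc, oc
    peak_sigmas: Tuple[float, float, float] = (5.0, 8.0, 30.0)
    response: Tuple[float, float, float] = (1.0, 1.0, 1.0)  # signal per amount unit
    baseline: Tuple[float, float] = (2.0, 0.01)  # intercept, slope per second
    noise_sd: float = 0.05
    migration_jitter_sd: float = 2.0
    clip_level: Optional[float] = None

    def __post_init__(self) -> None:
        if min(self.peak_sigmas) <= 0:
            raise ValidationError("peak sigmas must be > 0")
        if self.dt <= 0:
            raise ValidationError("grid step must be > 0")
        if self.noise_sd < 0 or self.migration_jitter_sd < 0:
            raise ValidationError("noise_sd and migration_jitter_sd must be >= 0")

    def time_grid(self) -> np.ndarray:
        n = int(round((self.t_end - self.t_start) / self.dt)) + 1
        return self.t_start + self.dt * np.arange(n)

    def replace(self, **kw) -> "SimulationConfig":
        return dataclasses.replace(self, **kw)

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("peak_centers", "peak_sigmas", "response", "baseline"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path: Union[str, Path]) -> None:
        raw = dataclasses.asdict(self)
        for key in ("peak_centers", "peak_sigmas", "response", "baseline"):
            raw[key] = list(raw[key])
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)


def pure_sc_peak_height(config: SimulationConfig, total_mass: float = 100.0) -> float:
    """Apex signal of a noiseless, baseline-free pure-SC lane of given mass."""
    sigma = config.peak_sigmas[1]
    return total_mass * config.response[1] / (sigma * np.sqrt(2 * np.pi))


def matched_windows(config: SimulationConfig, n_sigma: float = 6.0) -> IsoformWindows:
    """Integration windows matched to the simulated bands (center +/- n_sigma).

    With the default 6 sigma half-widths each window captures all but ~2e-9 of
    its Gaussian's mass, which is what the exact (1e-6-level) round-trip
    guarantees are stated against; the field-default windows are narrower and
    truncate ~0.1% of the broad OC band.
    """
    (cl, cs, co), (sl, ss, so) = config.peak_centers, config.peak_sigmas
    return IsoformWindows(
        lin=(cl - n_sigma * sl, cl + n_sigma * sl),
        sc=(cs - n_sigma * ss, cs + n_sigma * ss),
        oc=(co - n_sigma * so, co + n_sigma * so),
    )


def _gaussian(t: np.ndarray, center: float, sigma: float) -> np.ndarray:
    z = (t - center) / sigma
    return np.exp(-0.5 * z * z) / (sigma * np.sqrt(2 * np.pi))


def simulate_trace(
    truth: GroundTruth,
    config: SimulationConfig,
    *,
    lane_id: str = "lane",
    role: str = "sample",
    capillary_id: Optional[str] = None,
    rng: Optional[np.random.Generator] = None,
    jitter_cache: Optional[dict] = None,
) -> Tuple[Trace, GroundTruth]:
    """Simulate one lane: sum of amount-scaled Gaussian bands + baseline + noise.

    signal(t) = sum_i amount_i * response_i * N(t; center_i + jitter, sigma_i)
                + intercept + slope*t + eps,  eps ~ N(0, noise_sd),

    clipped at ``clip_level`` when set.  Jitter is drawn once per capillary:
    pass a shared ``jitter_cache`` dict so lanes on the same capillary reuse
    the same shift.  Returns the trace together with its ground truth.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    t = config.time_grid()
    jitter = 0.0
    if config.migration_jitter_sd > 0:
        if jitter_cache is not None and capillary_id in jitter_cache:
            jitter = jitter_cache[capillary_id]
        else:
            jitter = float(rng.normal(0.0, config.migration_jitter_sd))
            if jitter_cache is not None and capillary_id is not None:
                jitter_cache[capillary_id] = jitter
    amounts = (truth.amount_lin, truth.amount_sc, truth.amount_oc)
    signal = config.baseline[0] + config.baseline[1] * t
    for amount, resp, center, sigma in zip(
        amounts, config.response, config.peak_centers, config.peak_sigmas
    ):
        if amount > 0:
            signal = signal + amount * resp * _gaussian(t, center + jitter, sigma)
    if config.noise_sd > 0:
        signal = signal + rng.normal(0.0, config.noise_sd, size=len(t))
    if config.clip_level is not None:
        signal = np.minimum(signal, config.clip_level)
    meta = {
        "capillary_id": capillary_id,
        "truth_lin": truth.amount_lin,
        "truth_sc": truth.amount_sc,
        "truth_oc": truth.amount_oc,
    }
    if truth.concentration_ng_per_uL is not None:
        meta["concentration_ng_per_uL"] = truth.concentration_ng_per_uL
    return Trace(lane_id=lane_id, role=role, time=t, signal=signal, meta=meta), truth


def _run_params(config: SimulationConfig) -> dict:
    return {
        "separation_time_s": config.t_end,
        "injection_voltage_kV": 2.0,
        "separation_voltage_kV": 4.0,
    }


def simulate_mixture_series(
    levels: Sequence[float],
    replicates: int,
    config: SimulationConfig,
    total_mass: float = 100.0,
) -> Batch:
    """SC:OC mixture dilution series: per level x, sc = x*M, oc = (1-x)*M, lin = 0.

    Produces ``len(levels) * replicates`` sample lanes annotated with
    ``prepared_sc_fraction`` and ``replicate_id``, plus one buffer lane.
    Capillaries are cycled 12-wide as on a 12-channel cartridge.
    """
    if any(not 0.0 <= x <= 1.0 for x in levels):
        raise ValidationError("prepared SC levels must lie in [0, 1]")
    rng = np.random.default_rng(config.seed)
    jitter_cache: dict = {}
    traces = []
    buffer_trace, _ = simulate_trace(
        GroundTruth(),
        config,
        lane_id="buffer",
        role="buffer",
        capillary_id="cap00",
        rng=rng,
        jitter_cache=jitter_cache,
    )
    traces.append(buffer_trace)
    n = 0
    for i, x in enumerate(levels):
        for r in range(replicates):
            truth = GroundTruth(amount_sc=x * total_mass, amount_oc=(1.0 - x) * total_mass)
            trace, _ = simulate_trace(
                truth,
                config,
                lane_id=f"mix{i:02d}_r{r}",
                capillary_id=f"cap{n % 12:02d}",
                rng=rng,
                jitter_cache=jitter_cache,
            )
            trace.meta["prepared_sc_fraction"] = float(x)
            trace.meta["replicate_id"] = r
            traces.append(trace)
            n += 1
    return Batch(traces=traces, run_params=_run_params(config))


def simulate_digestion_series(
    k: float,
    times: Sequence[float],
    run_gap_extra: float,
    config: SimulationConfig,
    total_mass: float = 100.0,
    include_blind: bool = True,
) -> Batch:
    """Restriction-digest time course: first-order SC -> Lin conversion.

    Run 1 applies f_lin(t) = 1 - exp(-k t) to an initially pure-SC mass.  Run
    2 duplicates run 1 but converts an additional fraction ``run_gap_extra``
    of each lane's *remaining* SC, modelling continued digestion at room
    temperature between the two back-to-back instrument runs.  A blind lane
    (no enzyme, ``incubation_time_min`` = None) is included per run.
    """
    if k < 0 or any(t < 0 for t in times):
        raise ValidationError("rate and incubation times must be >= 0")
    if not 0.0 <= run_gap_extra <= 1.0:
        raise ValidationError("run_gap_extra must lie in [0, 1]")
    rng = np.random.default_rng(config.seed)
    jitter_cache: dict = {}
    traces = []
    n = 0
    for run_index in (1, 2):
        lanes: list = []
        if include_blind:
            lanes.append((None, 0.0))
        for t_min in times:
            f1 = 1.0 - np.exp(-k * t_min)
            f = f1 if run_index == 1 else f1 + run_gap_extra * (1.0 - f1)
            lanes.append((t_min, float(f)))
        for t_min, f_lin in lanes:
            truth = GroundTruth(amount_lin=f_lin * total_mass, amount_sc=(1.0 - f_lin) * total_mass)
            tag = "blind" if t_min is None else f"t{t_min:g}"
            trace, _ = simulate_trace(
                truth,
                config,
                lane_id=f"run{run_index}_{tag}",
                capillary_id=f"cap{n % 12:02d}",
                rng=rng,
                jitter_cache=jitter_cache,
            )
            trace.meta["incubation_time_min"] = t_min
            trace.meta["run_index"] = run_index
            traces.append(trace)
            n += 1
    return Batch(traces=traces, run_params=_run_params(config))


# gel-position band layout for simulated agarose lanes (arbitrary position units)
AGE_SC_CENTER = 30.0
AGE_SC_SIGMA = 4.0
AGE_OC_CENTER = 60.0
AGE_BAND_SIGMA = 8.0
AGE_LIN_SEPARATED = 95.0
AGE_SC_EFFICIENCY = 1.05


def simulate_age_profile(
    truth: GroundTruth,
    config: SimulationConfig,
    overlap: bool = False,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[Trace, GroundTruth]:
    """Simulate a 1-D agarose lane intensity profile over gel position.

    The SC band fluoresces 1.05x per unit DNA relative to OC/Lin (SYBR-Gold
    attachment efficiency), so recovering the true amounts requires the dye
    correction.  With ``overlap=True`` the OC and Lin band centers sit only
    1.5 sigma apart — close enough that window integration misassigns mass and
    Gaussian deconvolution is required; otherwise they are well separated.
    The profile is background-free apart from the configured additive noise.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    pos = np.arange(0.0, 120.0 + 1e-9, 0.2)
    lin_center = AGE_OC_CENTER + 1.5 * AGE_BAND_SIGMA if overlap else AGE_LIN_SEPARATED
    signal = np.zeros_like(pos)
    signal += truth.amount_sc * AGE_SC_EFFICIENCY * _gaussian(pos, AGE_SC_CENTER, AGE_SC_SIGMA)
    signal += truth.amount_oc * _gaussian(pos, AGE_OC_CENTER, AGE_BAND_SIGMA)
    signal += truth.amount_lin * _gaussian(pos, lin_center, AGE_BAND_SIGMA)
    if config.noise_sd > 0:
        signal = signal + rng.normal(0.0, config.noise_sd, size=len(pos))
    meta = {
        "axis": "gel_position",
        "truth_lin": truth.amount_lin,
        "truth_sc": truth.amount_sc,
        "truth_oc": truth.amount_oc,
        "sc_center": AGE_SC_CENTER,
        "oc_center": AGE_OC_CENTER,
        "lin_center": lin_center,
    }
    return Trace(lane_id="age_lane", role="sample", time=pos, signal=signal, meta=meta), truth


def write_simulation(batch: Batch, out_prefix: Union[str, Path]) -> dict:
    """Emit a simulated batch as wide CSV + metadata TSV + ground-truth TSV.

    Returns the three paths written, keyed ``traces`` / ``metadata`` / ``truth``.
    """
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {
        "traces": out_prefix.with_suffix(".traces.csv"),
        "metadata": out_prefix.with_suffix(".metadata.tsv"),
        "truth": out_prefix.with_suffix(".truth.tsv"),
    }
    write_trace_table(batch, paths["traces"])
    truth_keys = ("truth_lin", "truth_sc", "truth_oc")
    metadata = {}
    truth_rows = []
    for t in batch:
        metadata[t.lane_id] = {"role": t.role} | {
            k: v for k, v in t.meta.items() if k not in truth_keys
        }
        if t.role == "sample":
            truth_rows.append({"lane_id": t.lane_id} | {k: t.meta.get(k) for k in truth_keys})
    write_metadata_table(metadata, paths["metadata"])
    pd.DataFrame(truth_rows).to_csv(paths["truth"], sep="\t", index=False)
    return paths
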
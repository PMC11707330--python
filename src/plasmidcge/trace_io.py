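"""Reading and writing of electropherogram trace tables and quantification results.

Capillary gel electrophoresis instruments export one wide CSV per run: the
first column is migration time in seconds, every further column is one lane's
detector signal, and the header row carries the lane identifiers.  Per-lane
metadata (role, concentration, prepared SC fraction, incubation time, ...)
travels in a sidecar TSV keyed by ``lane_id``.  Quantification results are
written as a TSV with a fixed column order that round-trips numerically.
"""

from __future__ import annotations

import csv
import dataclasses
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

ROLES = frozenset({"sample", "buffer", "alignment_marker", "ladder"})

#: columns of the sidecar metadata table, in canonical order
METADATA_COLUMNS = (
    "lane_id",
    "role",
    "capillary_id",
    "concentration_ng_per_uL",
    "prepared_sc_fraction",
    "incubation_time_min",
    "run_index",
    "replicate_id",
)


@dataclass
class Trace:
    """One lane's detector signal sampled over migration time.

    Parameters
    ----------
    lane_id : str
        Unique lane identifier (the CSV column header).
    role : str
        One of ``sample``, ``buffer``, ``alignment_marker``, ``ladder``.
    time : ndarray
        Migration time in seconds, strictly increasing, length >= 2.
    signal : ndarray
        Detector signal in arbitrary units, same length as ``time``, finite.
    meta : dict
        Optional acquisition metadata (capillary_id, concentration_ng_per_uL,
        prepared_sc_fraction, incubation_time_min, run_index, replicate_id...).
    """

    lane_id: str
    role: str
    time: np.ndarray
    signal: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValidationError(
                f"lane {self.lane_id!r}: unknown role {self.role!r}; "
                f"expected one of {sorted(ROLES)}"
            )
        self.time = np.asarray(self.time, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.time.ndim != 1 or self.signal.ndim != 1:
            raise ValidationError(f"lane {self.lane_id!r}: time and signal must be 1-D")
        if len(self.time) != len(self.signal):
            raise ValidationError(
                f"lane {self.lane_id!r}: time ({len(self.time)}) and signal "
                f"({len(self.signal)}) lengths differ"
            )
        if len(self.time) < 2:
            raise ValidationError(f"lane {self.lane_id!r}: need at least 2 samples")
        if not np.all(np.diff(self.time) > 0):
            raise ValidationError(
                f"lane {self.lane_id!r}: time grid is not strictly increasing"
            )
        if not np.all(np.isfinite(self.signal)):
            raise ValidationError(f"lane {self.lane_id!r}: signal contains non-finite values")

    def with_signal(self, signal: np.ndarray) -> "Trace":
        """Return a copy of this trace with a new signal vector (metadata shared)."""
        return dataclasses.replace(self, signal=np.asarray(signal, dtype=float))


@dataclass
class Batch:
    """An ordered collection of traces from one run, plus run parameters."""

    traces: list
    run_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [t.lane_id for t in self.traces]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate lane_id in batch: {dupes}")
        buf_caps: dict = {}
        for t in self.traces:
            if t.role == "buffer":
                cap = t.meta.get("capillary_id")
                if cap is not None and cap in buf_caps:
                    raise ValidationError(
                        f"more than one buffer trace on capillary {cap!r}: "
                        f"{buf_caps[cap]!r} and {t.lane_id!r}"
                    )
                buf_caps[cap] = t.lane_id

    def __iter__(self):
        return iter(self.traces)

    def __len__(self) -> int:
        return len(self.traces)

    def get(self, lane_id: str) -> Trace:
        for t in self.traces:
            if t.lane_id == lane_id:
                return t
        raise KeyError(lane_id)

    def by_role(self, role: str) -> list:
        return [t for t in self.traces if t.role == role]


@dataclass
class LadderSpec:
    """Ordered list of ladder bands, (size_bp, label), sizes strictly increasing."""

    bands: list  # of (size_bp, label)

    def __post_init__(self) -> None:
        sizes = [int(b[0]) for b in self.bands]
        if any(s <= 0 for s in sizes):
            raise ValidationError("ladder band sizes must be positive")
        if any(b - a <= 0 for a, b in zip(sizes, sizes[1:])):
            raise ValidationError("ladder band sizes must be strictly increasing")

    @property
    def sizes_bp(self) -> np.ndarray:
        return np.array([b[0] for b in self.bands], dtype=float)


def read_trace_table(
    path: Union[str, Path],
    metadata: Optional[dict] = None,
    *,
    delimiter: str = ",",
    decimal: str = ".",
) -> Batch:
    """Read a wide instrument-export CSV into a :class:`Batch`.

    The first column is migration time in seconds; each further column is one
    lane's signal; the header row gives lane ids.  ``metadata`` maps lane_id to
    a dict of per-lane annotations; the ``role`` key assigns lane roles
    (default ``sample``).  ``delimiter``/``decimal`` accommodate European
    instrument locales (``;`` / ``,``).

    Raises
    ------
    FormatError
        Empty table or no lane columns.
    ValidationError
        Duplicate header names, non-monotone time column, or non-numeric cells
        (reported with row indices).
    """
    path = Path(path)
    with open(path, newline="", encoding="utf-8") as fh:
        header_line = fh.readline()
    if not header_line.strip():
        raise FormatError(f"{path}: empty table")
    header = next(csv.reader(io.StringIO(header_line), delimiter=delimiter))
    header = [h.strip() for h in header]
    if len(set(header)) != len(header):
        dupes = sorted({h for h in header if header.count(h) > 1})
        raise ValidationError(f"{path}: duplicate header names {dupes}")
    if len(header) < 2:
        raise FormatError(f"{path}: need a time column plus at least one lane column")

    df = pd.read_csv(path, sep=delimiter, decimal=decimal, header=0, names=header, dtype=str)
    if df.empty:
        raise FormatError(f"{path}: table has a header but no data rows")

    if decimal != ".":
        df = df.apply(lambda col: col.str.replace(decimal, ".", regex=False))
    numeric = df.apply(lambda col: pd.to_numeric(col, errors="coerce"))
    bad_rows = numeric.index[numeric.isna().any(axis=1)].tolist()
    if bad_rows:
        raise ValidationError(
            f"{path}: non-numeric cells in data rows {bad_rows} (0-based, after header)"
        )

    time = numeric.iloc[:, 0].to_numpy(dtype=float)
    if not np.all(np.diff(time) > 0):
        raise ValidationError(f"{path}: time column is not strictly increasing")

    metadata = metadata or {}
    traces = []
    for lane_id in header[1:]:
        meta = dict(metadata.get(lane_id, {}))
        role = meta.pop("role", "sample") or "sample"
        traces.append(
            Trace(
                lane_id=lane_id,
                role=role,
                time=time,
                signal=numeric[lane_id].to_numpy(dtype=float),
                meta=meta,
            )
        )
    run_params = {"separation_time_s": float(time[-1])}
    return Batch(traces=traces, run_params=run_params)


def _coerce(value):
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    return value


def read_metadata_table(path: Union[str, Path]) -> dict:
    """Read the sidecar metadata TSV into a dict keyed by lane_id."""
    df = pd.read_csv(path, sep="\t")
    if "lane_id" not in df.columns:
        raise FormatError(f"{path}: metadata table must have a lane_id column")
    out: dict = {}
    for _, row in df.iterrows():
        rec = {k: _coerce(v) for k, v in row.items() if k != "lane_id"}
        out[str(row["lane_id"])] = rec
    return out


def write_metadata_table(metadata: dict, path: Union[str, Path]) -> None:
    """Write a lane_id-keyed metadata dict as the sidecar TSV."""
    rows = []
    for lane_id, rec in metadata.items():
        row = {"lane_id": lane_id}
        row.update(rec)
        rows.append(row)
    cols = [c for c in METADATA_COLUMNS if any(c in r for r in rows)] or ["lane_id"]
    extra = sorted({k for r in rows for k in r} - set(cols))
    pd.DataFrame(rows).reindex(columns=cols + extra).to_csv(path, sep="\t", index=False)


def read_ladder_spec(path: Union[str, Path]) -> LadderSpec:
    """Read a ladder specification TSV with columns ``size_bp`` and ``label``."""
    df = pd.read_csv(path, sep="\t")
    if "size_bp" not in df.columns:
        raise FormatError(f"{path}: ladder spec must have a size_bp column")
    labels = df["label"] if "label" in df.columns else df["size_bp"].astype(str)
    return LadderSpec(bands=list(zip(df["size_bp"].astype(int), labels.astype(str))))


#: fixed column order of the quantification TSV
QUANT_COLUMNS = (
    "lane_id",
    "integral_lin",
    "integral_sc",
    "integral_oc",
    "total",
    "f_lin",
    "f_sc",
    "f_oc",
    "min_snr",
    "saturated",
    "included",
    "reasons",
)


def write_quant_table(records: Sequence[dict], path: Union[str, Path]) -> None:
    """Write per-lane quantification records as a TSV.

    ``records`` is a sequence of dicts carrying at least ``lane_id``, the three
    integrals and the three fractions; QC fields default to benign values.
    Floats are printed with 12 significant digits (C locale) so a
    write-then-read round trip preserves them to better than 1e-9.
    """
    rows = []
    for rec in records:
        row = {c: rec.get(c) for c in QUANT_COLUMNS}
        if isinstance(row["reasons"], (list, tuple)):
            row["reasons"] = ";".join(row["reasons"])
        rows.append(row)
    df = pd.DataFrame(rows, columns=list(QUANT_COLUMNS))
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_quant_table(path: Union[str, Path]) -> list:
    """Read a quantification TSV back into a list of dicts (round trip)."""
    df = pd.read_csv(path, sep="\t")
    records = []
    for _, row in df.iterrows():
        rec = dict(row)
        rec["lane_id"] = str(rec["lane_id"])
        reasons = rec.get("reasons")
        if isinstance(reasons, str):
            rec["reasons"] = reasons.split(";") if reasons else []
        elif reasons is None or (isinstance(reasons, float) and np.isnan(reasons)):
            rec["reasons"] = []
        records.append(rec)
    return records


def write_trace_table(batch: Batch, path: Union[str, Path]) -> None:
    """Write a batch sharing one time grid as the wide instrument CSV format."""
    grid = batch.traces[0].time
    for t in batch.traces:
        if len(t.time) != len(grid) or not np.allclose(t.time, grid):
            raise ValidationError("all traces must share one time grid to write a wide CSV")
    data = {"time_s": grid}
    for t in batch.traces:
        data[t.lane_id] = t.signal
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.12g")
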
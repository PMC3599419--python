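"""Ventilator waveform model: reading, segmentation, and per-PEEP summaries.

The in-memory model has three layers:

* :class:`Breath` -- one respiratory cycle of sampled time / airway pressure /
  flow / volume, with the end-inspiratory zero-flow sample marked.
* :class:`PeepStep` -- all breaths recorded at one PEEP setting together with
  the summary quantities the estimators consume (plateau pressure, PEEP,
  tidal volume, inspiratory pressure swing, optional clinically measured
  dFRC).
* :class:`PatientDataset` -- the ordered PEEP steps of one patient's
  stepwise-PEEP recruitment manoeuvre.

Core units are fixed throughout the package: pressures in cmH2O, volumes in
L, flow in L/s, time in s.  The CSV reader converts from declared source
units at the boundary.
"""

from __future__ import annotations

import io
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml
from scipy.integrate import cumulative_trapezoid

from .errors import (
    InconsistentStepError,
    NoBreathError,
    WaveformError,
)

__all__ = [
    "CORE_UNITS",
    "WaveformDialect",
    "WaveformSeries",
    "Breath",
    "PeepStep",
    "PatientDataset",
    "read_waveform_csv",
    "write_waveform_csv",
    "segment_breaths",
    "detect_zero_flow",
    "summarize_step",
    "load_manifest",
    "write_manifest",
]

#: Default tolerance (L/s) below which sampled flow counts as "zero airflow".
DEFAULT_FLOW_TOLERANCE = 0.005

CORE_UNITS = {"time": "s", "pressure": "cmH2O", "flow": "L/s"}

# multiplicative factors into core units
_TIME_FACTORS = {"s": 1.0, "ms": 1e-3, "min": 60.0}
_PRESSURE_FACTORS = {"cmH2O": 1.0, "kPa": 10.19716, "hPa": 1.019716, "mbar": 1.019716}
_FLOW_FACTORS = {"L/s": 1.0, "mL/s": 1e-3, "L/min": 1.0 / 60.0, "mL/min": 1e-3 / 60.0}


@dataclass
class WaveformDialect:
    """Source units of a waveform CSV; the reader converts into core units."""

    time_unit: str = "s"
    pressure_unit: str = "cmH2O"
    flow_unit: str = "L/s"

    def factors(self) -> tuple[float, float, float]:
        try:
            return (
                _TIME_FACTORS[self.time_unit],
                _PRESSURE_FACTORS[self.pressure_unit],
                _FLOW_FACTORS[self.flow_unit],
            )
        except KeyError as exc:
            raise WaveformError(
                f"unknown unit tag {exc.args[0]!r}; known units: "
                f"time {sorted(_TIME_FACTORS)}, pressure {sorted(_PRESSURE_FACTORS)}, "
                f"flow {sorted(_FLOW_FACTORS)}"
            ) from None


@dataclass
class WaveformSeries:
    """A validated continuous recording in core units."""

    time: np.ndarray
    pressure: np.ndarray
    flow: np.ndarray

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.pressure = np.asarray(self.pressure, dtype=float)
        self.flow = np.asarray(self.flow, dtype=float)
        n = self.time.size
        if self.pressure.size != n or self.flow.size != n:
            raise WaveformError("time, pressure and flow must have equal length")
        for name, arr in (("time", self.time), ("pressure", self.pressure), ("flow", self.flow)):
            bad = np.flatnonzero(~np.isfinite(arr))
            if bad.size:
                raise WaveformError(f"non-finite value in column {name!r} at row {bad[0]}")
        if np.any(self.time < 0):
            row = int(np.flatnonzero(self.time < 0)[0])
            raise WaveformError(f"negative time at row {row}")
        dt = np.diff(self.time)
        if np.any(dt <= 0):
            row = int(np.flatnonzero(dt <= 0)[0]) + 1
            raise WaveformError(f"time not strictly increasing at row {row}")

    def __len__(self) -> int:
        return int(self.time.size)


@dataclass
class Breath:
    """One respiratory cycle in core units.

    ``volume`` is the running trapezoidal integral of ``flow`` re-zeroed at
    inspiration onset; end-expiratory lung volume is never inferred from the
    waveform integral.
    """

    time: np.ndarray
    pressure: np.ndarray
    flow: np.ndarray
    volume: np.ndarray
    insp_end_index: int
    set_peep: float = 0.0

    #: tolerance (L) for the volume-equals-integral-of-flow invariant
    _VOLUME_ATOL = 2e-3

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.pressure = np.asarray(self.pressure, dtype=float)
        self.flow = np.asarray(self.flow, dtype=float)
        self.volume = np.asarray(self.volume, dtype=float)
        n = self.time.size
        if n < 8:
            raise WaveformError(f"breath needs >= 8 samples, got {n}")
        if not (self.pressure.size == self.flow.size == self.volume.size == n):
            raise WaveformError("breath channels must have equal length")
        if np.any(np.diff(self.time) <= 0):
            raise WaveformError("breath time grid must be strictly increasing")
        if self.volume[0] != 0.0:
            raise WaveformError("breath volume must start at zero (re-zeroed at onset)")
        expected = cumulative_trapezoid(self.flow, self.time, initial=0.0)
        if not np.allclose(self.volume, expected, atol=self._VOLUME_ATOL, rtol=0.0):
            raise WaveformError(
                "volume channel is not the running integral of flow "
                f"(max deviation {np.max(np.abs(self.volume - expected)):.4g} L)"
            )
        if not 0 < self.insp_end_index < n:
            raise WaveformError(
                f"insp_end_index {self.insp_end_index} outside (0, {n})"
            )

    def __len__(self) -> int:
        return int(self.time.size)

    @property
    def duration(self) -> float:
        return float(self.time[-1] - self.time[0])

    def inspiratory_slice(self) -> slice:
        """Samples from inspiration onset through end-inspiratory zero flow."""
        return slice(0, self.insp_end_index + 1)


@dataclass
class PeepStep:
    """Summary of all breaths recorded at one PEEP setting.

    ``peep`` and ``plateau_pressure`` are plateau airway pressures measured at
    zero airflow at end expiration and end inspiration respectively.
    """

    peep: float
    plateau_pressure: float
    tidal_volume: float
    delta_paw: float
    measured_dfrc: Optional[float] = None
    breaths: list = field(default_factory=list)
    set_peep: Optional[float] = None

    def __post_init__(self) -> None:
        if self.peep < 0:
            raise InconsistentStepError(f"PEEP must be >= 0, got {self.peep}")
        if not self.plateau_pressure > self.peep:
            raise InconsistentStepError(
                f"plateau pressure {self.plateau_pressure:.3g} cmH2O not above "
                f"PEEP {self.peep:.3g} cmH2O"
            )
        if not self.tidal_volume > 0:
            raise InconsistentStepError(f"tidal volume must be > 0, got {self.tidal_volume}")
        if not math.isclose(self.delta_paw, self.plateau_pressure - self.peep,
                            rel_tol=0.0, abs_tol=1e-9):
            raise InconsistentStepError("delta_paw must equal plateau_pressure - peep")
        if self.measured_dfrc is not None and self.measured_dfrc < 0:
            raise InconsistentStepError("measured dFRC must be >= 0 when present")

    @property
    def level(self) -> float:
        """Nominal PEEP level of this step: the ventilator setting when known,
        else the measured end-expiratory pressure.

        Grouping across patients (calibration, β lookup, per-PEEP error
        statistics) keys on this level; the pressures entering the estimator
        formulas (ΔPEEP, ΔPaw) stay measured.
        """
        return float(self.set_peep if self.set_peep is not None else self.peep)


@dataclass
class PatientDataset:
    """Ordered stepwise-PEEP data for one patient."""

    patient_id: str
    cohort: str = ""
    steps: list = field(default_factory=list)
    #: ground-truth dFRC per PEEP (synthetic datasets only)
    true_dfrc: Optional[dict] = None

    def __post_init__(self) -> None:
        self.steps = sorted(self.steps, key=lambda s: s.peep)
        peeps = [s.peep for s in self.steps]
        if any(b - a <= 0 for a, b in zip(peeps, peeps[1:])):
            raise WaveformError(
                f"patient {self.patient_id}: step PEEPs must be strictly "
                f"increasing with no duplicates, got {peeps}"
            )

    @property
    def peeps(self) -> list:
        return [s.peep for s in self.steps]

    def step_at(self, peep: float, atol: float = 1e-6) -> PeepStep:
        """Step whose nominal PEEP level matches *peep*."""
        for s in self.steps:
            if math.isclose(s.level, peep, rel_tol=0.0, abs_tol=atol):
                return s
        raise KeyError(f"patient {self.patient_id} has no step at PEEP level {peep}")

    def measured_delta_dfrc(self, pairing: str = "consecutive") -> dict:
        """(ΔdFRC, ΔPEEP) keyed by the higher step's PEEP level.

        With ``pairing='consecutive'`` each step is referenced to the
        immediately preceding step with measured dFRC; with ``'baseline'``
        to the patient's first measured step.  ΔPEEP uses the measured
        end-expiratory pressures; the key is the nominal level.
        """
        if pairing not in ("consecutive", "baseline"):
            raise ValueError(f"unknown pairing {pairing!r}")
        measured = [s for s in self.steps if s.measured_dfrc is not None]
        out: dict = {}
        for k in range(1, len(measured)):
            ref = measured[k - 1] if pairing == "consecutive" else measured[0]
            cur = measured[k]
            out[cur.level] = (cur.measured_dfrc - ref.measured_dfrc, cur.peep - ref.peep)
        return out


# ---------------------------------------------------------------------------
# CSV I/O

_REQUIRED_COLUMNS = ("time", "pressure", "flow")


def read_waveform_csv(path, dialect: Optional[WaveformDialect] = None) -> WaveformSeries:
    """Read one continuous recording; convert into core units.

    The file has a header row naming at least ``time,pressure,flow``.  An
    optional second row may carry unit tags (e.g. ``s,cmH2O,mL/s``).  An
    explicitly passed *dialect* overrides the file's units row.
    """
    path = Path(path)
    with open(path, "r", encoding="utf-8") as fh:
        lines = [ln for ln in fh.read().splitlines()
                 if ln.strip() and not ln.lstrip().startswith("#")]
    if not lines:
        raise WaveformError(f"{path}: empty file")
    header = [c.strip() for c in lines[0].split(",")]
    colmap = {}
    for name in _REQUIRED_COLUMNS:
        matches = [i for i, c in enumerate(header) if c.lower() == name]
        if not matches:
            raise WaveformError(f"{path}: missing required column {name!r}")
        colmap[name] = matches[0]

    body_start = 1
    file_dialect = None
    if len(lines) > 1:
        second = [c.strip() for c in lines[1].split(",")]
        try:
            [float(v) for v in second[:len(header)]]
        except ValueError:
            file_dialect = WaveformDialect(
                time_unit=second[colmap["time"]],
                pressure_unit=second[colmap["pressure"]],
                flow_unit=second[colmap["flow"]],
            )
            body_start = 2
    use = dialect if dialect is not None else (file_dialect or WaveformDialect())
    ft, fp, ff = use.factors()

    rows = []
    for rownum, ln in enumerate(lines[body_start:], start=body_start + 1):
        cells = [c.strip() for c in ln.split(",")]
        try:
            rows.append([float(cells[colmap[name]]) for name in _REQUIRED_COLUMNS])
        except (ValueError, IndexError):
            raise WaveformError(f"{path}: could not parse numeric row {rownum}: {ln!r}") from None
    if not rows:
        raise WaveformError(f"{path}: no data rows")
    data = np.asarray(rows, dtype=float)
    try:
        return WaveformSeries(time=data[:, 0] * ft, pressure=data[:, 1] * fp, flow=data[:, 2] * ff)
    except WaveformError as exc:
        raise WaveformError(f"{path}: {exc}") from None


def write_waveform_csv(path, series: WaveformSeries,
                       dialect: Optional[WaveformDialect] = None) -> None:
    """Write a recording with a units row; inverse of :func:`read_waveform_csv`."""
    use = dialect or WaveformDialect()
    ft, fp, ff = use.factors()
    buf = io.StringIO()
    buf.write("time,pressure,flow\n")
    buf.write(f"{use.time_unit},{use.pressure_unit},{use.flow_unit}\n")
    for t, p, q in zip(series.time / ft, series.pressure / fp, series.flow / ff):
        buf.write(f"{t:.9g},{p:.9g},{q:.9g}\n")
    Path(path).write_text(buf.getvalue(), encoding="utf-8")


# ---------------------------------------------------------------------------
# Segmentation and zero-flow detection


def _zero_flow_indices(flow: np.ndarray, flow_tolerance: float) -> tuple[int, int]:
    """(insp_end, exp_end) sample indices of a single-breath flow trace."""
    n = flow.size
    neg = np.flatnonzero(flow < -flow_tolerance)
    exp_start = int(neg[0]) if neg.size else n
    if exp_start == n:
        warnings.warn("no expiratory phase detected; treating whole breath as inspiration")

    insp_candidates = np.flatnonzero(np.abs(flow[:exp_start]) <= flow_tolerance)
    # skip the onset sample itself so insp_end stays > 0
    insp_candidates = insp_candidates[insp_candidates > 0]
    if insp_candidates.size:
        insp_end = int(insp_candidates[-1])
    else:
        insp_end = 1 + int(np.argmin(np.abs(flow[1:exp_start])))
        warnings.warn(
            f"no inspiratory sample within flow tolerance {flow_tolerance} L/s; "
            "using minimum-|flow| sample"
        )

    if exp_start == n:
        exp_end = n - 1
    else:
        exp_candidates = np.flatnonzero(np.abs(flow[exp_start:]) <= flow_tolerance)
        if exp_candidates.size:
            exp_end = exp_start + int(exp_candidates[-1])
        else:
            exp_end = exp_start + int(np.argmin(np.abs(flow[exp_start:])))
            warnings.warn(
                f"no expiratory sample within flow tolerance {flow_tolerance} L/s; "
                "using minimum-|flow| sample"
            )
    return insp_end, exp_end


def detect_zero_flow(breath: Breath,
                     flow_tolerance: float = DEFAULT_FLOW_TOLERANCE) -> tuple[int, int]:
    """Locate end-inspiratory and end-expiratory zero-flow samples.

    The end-inspiratory index is the last inspiratory-phase sample with
    ``|flow| <= flow_tolerance`` (flow falling through zero); the
    end-expiratory index is the analogous sample at the breath end.  When no
    sample lies inside the tolerance the minimum-``|flow|`` sample of the
    phase is returned with a warning.
    """
    return _zero_flow_indices(breath.flow, flow_tolerance)


def segment_breaths(series: WaveformSeries,
                    min_breath_duration: float = 0.5,
                    set_peep: float = 0.0,
                    flow_tolerance: float = DEFAULT_FLOW_TOLERANCE) -> list:
    """Split a recording into breaths at inspiration onsets.

    An onset is an upward zero crossing of flow (previous sample negative,
    current non-negative); a recording that starts with non-negative flow is
    taken to start at an onset.  Each breath's volume is re-zeroed at its
    onset; fragments shorter than *min_breath_duration* are discarded.
    """
    flow = series.flow
    onsets = [int(i) for i in np.flatnonzero((flow[:-1] < 0) & (flow[1:] >= 0)) + 1]
    if not onsets:
        raise NoBreathError("no inspiration onset (negative-to-positive flow crossing) found")
    if flow[0] >= 0 and onsets[0] != 0:
        onsets.insert(0, 0)  # recording starts mid-onset

    bounds = onsets + [len(series)]
    breaths = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        if b - a < 8:
            continue
        t = series.time[a:b]
        if t[-1] - t[0] < min_breath_duration:
            continue
        q = series.flow[a:b]
        p = series.pressure[a:b]
        v = cumulative_trapezoid(q, t, initial=0.0)
        insp_end, _ = _zero_flow_indices(q, flow_tolerance)
        breaths.append(Breath(time=t, pressure=p, flow=q, volume=v,
                              insp_end_index=insp_end, set_peep=set_peep))
    if not breaths:
        raise NoBreathError("no breath longer than min_breath_duration found")
    return breaths


def summarize_step(breaths: Sequence[Breath], set_peep: float,
                   measured_dfrc: Optional[float] = None,
                   flow_tolerance: float = DEFAULT_FLOW_TOLERANCE) -> PeepStep:
    """Aggregate breaths at one PEEP setting into a :class:`PeepStep`.

    Plateau pressure, PEEP and tidal volume are medians across breaths of the
    end-inspiratory zero-flow pressure, end-expiratory zero-flow pressure and
    trapezoidal inspiratory flow integral respectively.
    """
    if not breaths:
        raise WaveformError("summarize_step requires at least one breath")
    plateaus, peeps, vts = [], [], []
    for br in breaths:
        insp_end, exp_end = detect_zero_flow(br, flow_tolerance)
        plateaus.append(br.pressure[insp_end])
        peeps.append(br.pressure[exp_end])
        sl = slice(0, insp_end + 1)
        vts.append(float(np.trapezoid(br.flow[sl], br.time[sl])))
    plateau = float(np.median(plateaus))
    peep = float(np.median(peeps))
    vt = float(np.median(vts))
    if plateau <= peep:
        raise InconsistentStepError(
            f"median plateau pressure {plateau:.3g} cmH2O not above median "
            f"PEEP {peep:.3g} cmH2O"
        )
    return PeepStep(peep=peep, plateau_pressure=plateau, tidal_volume=vt,
                    delta_paw=plateau - peep, measured_dfrc=measured_dfrc,
                    breaths=list(breaths), set_peep=set_peep)


# ---------------------------------------------------------------------------
# Dataset manifest


def load_manifest(path, dialect: Optional[WaveformDialect] = None,
                  min_breath_duration: float = 0.5,
                  flow_tolerance: float = DEFAULT_FLOW_TOLERANCE) -> list:
    """Load patients from a YAML manifest into :class:`PatientDataset` records.

    The manifest lists, per patient, the per-PEEP waveform CSV files (paths
    relative to the manifest), the set PEEP, and optionally the clinically
    measured dFRC in L.
    """
    path = Path(path)
    doc = yaml.safe_load(path.read_text(encoding="utf-8"))
    if not isinstance(doc, dict) or "patients" not in doc:
        raise WaveformError(f"{path}: manifest must contain a 'patients' list")
    patients = []
    for pat in doc["patients"]:
        steps = []
        for st in pat.get("steps", []):
            series = read_waveform_csv(path.parent / st["file"], dialect=dialect)
            breaths = segment_breaths(series, min_breath_duration=min_breath_duration,
                                      set_peep=float(st["set_peep"]),
                                      flow_tolerance=flow_tolerance)
            md = st.get("measured_dfrc")
            steps.append(summarize_step(breaths, set_peep=float(st["set_peep"]),
                                        measured_dfrc=None if md is None else float(md),
                                        flow_tolerance=flow_tolerance))
        patients.append(PatientDataset(patient_id=str(pat["patient_id"]),
                                       cohort=str(pat.get("cohort", "")),
                                       steps=steps))
    return patients


def write_manifest(path, entries: list, meta: Optional[dict] = None) -> None:
    """Write a dataset manifest.

    *entries* is a list of dicts ``{patient_id, cohort, steps: [{set_peep,
    file, measured_dfrc}]}`` with file paths relative to the manifest.
    """
    doc = dict(meta or {})
    doc["patients"] = entries
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False), encoding="utf-8")
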
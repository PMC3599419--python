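"""Population beta-constant calibration for the stress-strain dFRC methods.

The stress-strain estimators fold specific lung elastance, the lung/chest-
wall elastance ratio and the PEEP-dependent scaling into a single per-PEEP
population constant:

* multiple-breath (SSMB):  dFRC = (ΔdFRC / ΔPEEP) * β,   β in cmH2O
* single-breath  (SSSB):  dFRC = (Vt / ΔPaw) * β,  β1 = β / Vt  in cmH2O/L

Calibration analytically inverts these identities on a cohort with
clinically measured dFRC: β (or β1) is solved per patient and PEEP, and the
per-PEEP median across patients becomes the population constant, stored with
non-parametric dispersion (min, max, IQR).

β1 is kept in cmH2O/L internally; serialisation can convert to cmH2O/mL.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import BetaRangeError, CalibrationError
from .waveforms import PatientDataset

__all__ = [
    "BetaRow",
    "BetaTable",
    "BetaCalibration",
    "calibrate_beta_ssmb",
    "calibrate_beta1_sssb",
    "lookup_beta",
    "loo_evaluate",
    "read_beta_table",
    "write_beta_table",
]

_METHOD_UNITS = {"SSMB": "cmH2O", "SSSB": "cmH2O/L"}


@dataclass(frozen=True)
class BetaRow:
    """Population constant at one PEEP level with dispersion statistics."""

    peep: float
    median_value: float
    n_patients: int
    min: float
    max: float
    iqr: float

    def __post_init__(self):
        if self.n_patients < 1:
            raise CalibrationError("BetaRow needs n_patients >= 1")
        if not (self.min <= self.median_value <= self.max):
            raise CalibrationError(
                f"median {self.median_value} outside [min, max] = "
                f"[{self.min}, {self.max}] at PEEP {self.peep}"
            )


@dataclass
class BetaTable:
    """Per-PEEP population constants for one stress-strain method."""

    method: str
    rows: tuple = ()
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.method not in _METHOD_UNITS:
            raise CalibrationError(f"method must be one of {sorted(_METHOD_UNITS)}")
        rows = tuple(sorted(self.rows, key=lambda r: r.peep))
        peeps = [r.peep for r in rows]
        if len(set(peeps)) != len(peeps):
            raise CalibrationError(f"duplicate PEEP levels in table: {peeps}")
        self.rows = rows

    @property
    def units(self) -> str:
        return _METHOD_UNITS[self.method]

    @property
    def peeps(self) -> np.ndarray:
        return np.array([r.peep for r in self.rows])

    @property
    def medians(self) -> np.ndarray:
        return np.array([r.median_value for r in self.rows])

    def lookup(self, peep: float, policy: str = "refuse") -> tuple[float, bool]:
        """Constant at *peep*; returns ``(value, out_of_range)``.

        Exact calibrated PEEPs return the stored median; queries between
        calibrated PEEPs are linearly interpolated.  Outside the calibrated
        span the *policy* applies: ``refuse`` raises, ``clamp`` returns the
        nearest calibrated value with a warning.
        """
        if not self.rows:
            raise CalibrationError("empty beta table")
        if policy not in ("refuse", "clamp"):
            raise ValueError(f"unknown lookup policy {policy!r}")
        peeps, medians = self.peeps, self.medians
        exact = np.flatnonzero(np.isclose(peeps, peep, rtol=0.0, atol=1e-9))
        if exact.size:
            return float(medians[exact[0]]), False
        if peep < peeps[0] or peep > peeps[-1]:
            if policy == "refuse":
                raise BetaRangeError(
                    f"PEEP {peep} cmH2O outside calibrated range "
                    f"[{peeps[0]}, {peeps[-1]}] cmH2O ({self.method})"
                )
            warnings.warn(
                f"PEEP {peep} outside calibrated range [{peeps[0]}, {peeps[-1]}]; "
                "clamping to nearest calibrated value"
            )
            return float(medians[0] if peep < peeps[0] else medians[-1]), True
        return float(np.interp(peep, peeps, medians)), False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.rows])

    def summary(self) -> str:
        head = (f"Beta table [{self.method}], units {self.units}, "
                f"{len(self.rows)} PEEP level(s)")
        body = self.to_frame().to_string(index=False) if self.rows else "(empty)"
        return head + "\n" + body


class BetaCalibration:
    """Fit per-PEEP population constants from a cohort with measured dFRC.

    Parameters
    ----------
    cohort : sequence of PatientDataset
    method : {'ssmb', 'sssb'}
    pairing : {'consecutive', 'baseline'}
        SSMB only: reference each step to the immediately preceding measured
        step (matching a stepwise-PEEP protocol) or to the patient's first
        measured step.
    """

    def __init__(self, cohort: Sequence[PatientDataset], method: str = "ssmb",
                 pairing: str = "consecutive"):
        self.cohort = list(cohort)
        self.method = method.lower()
        if self.method not in ("ssmb", "sssb"):
            raise CalibrationError(f"unknown calibration method {method!r}")
        self.pairing = pairing
        if not self.cohort:
            raise CalibrationError("empty cohort")

    def _patient_betas(self) -> list:
        """(patient_id, peep, beta-or-beta1) triples."""
        out = []
        if self.method == "ssmb":
            for pat in self.cohort:
                measured = [s for s in pat.steps if s.measured_dfrc is not None]
                if len(measured) < 2:
                    raise CalibrationError(
                        f"patient {pat.patient_id} has {len(measured)} step(s) with "
                        "measured dFRC; SSMB calibration needs >= 2"
                    )
                deltas = pat.measured_delta_dfrc(pairing=self.pairing)
                for step in measured[1:]:
                    ddfrc, dpeep = deltas[step.level]
                    if ddfrc == 0:
                        warnings.warn(
                            f"patient {pat.patient_id}, PEEP {step.level}: "
                            "ΔdFRC = 0, excluded from calibration"
                        )
                        continue
                    out.append((pat.patient_id, step.level,
                                step.measured_dfrc * dpeep / ddfrc))
        else:
            for pat in self.cohort:
                for step in pat.steps:
                    if step.measured_dfrc is None:
                        continue
                    if step.tidal_volume <= 0 or step.delta_paw <= 0:
                        warnings.warn(
                            f"patient {pat.patient_id}, PEEP {step.peep}: "
                            "degenerate Vt or ΔPaw, excluded from calibration"
                        )
                        continue
                    beta = step.measured_dfrc * step.delta_paw / step.tidal_volume
                    out.append((pat.patient_id, step.level, beta / step.tidal_volume))
        return out

    def fit(self) -> BetaTable:
        triples = self._patient_betas()
        if not triples:
            raise CalibrationError("no usable (patient, PEEP) pairs for calibration")
        by_peep: dict = {}
        for _, peep, b in triples:
            by_peep.setdefault(round(peep, 9), []).append(b)
        rows = []
        for peep, vals in sorted(by_peep.items()):
            arr = np.asarray(vals, dtype=float)
            q25, q75 = np.percentile(arr, [25.0, 75.0])
            rows.append(BetaRow(peep=float(peep), median_value=float(np.median(arr)),
                                n_patients=int(arr.size), min=float(arr.min()),
                                max=float(arr.max()), iqr=float(q75 - q25)))
        cohorts = sorted({p.cohort for p in self.cohort if p.cohort})
        prov = {"cohorts": cohorts, "n_patients": len(self.cohort),
                "pairing": self.pairing}
        return BetaTable(method=self.method.upper(), rows=tuple(rows), provenance=prov)


def calibrate_beta_ssmb(cohort: Sequence[PatientDataset],
                        pairing: str = "consecutive") -> BetaTable:
    """Per-PEEP median β (cmH2O) for the multiple-breath method.

    β is solved per patient at each PEEP above the patient's first as
    measured dFRC times ΔPEEP/ΔdFRC over the step ending at that PEEP.
    """
    return BetaCalibration(cohort, "ssmb", pairing=pairing).fit()


def calibrate_beta1_sssb(cohort: Sequence[PatientDataset]) -> BetaTable:
    """Per-PEEP median β1 (cmH2O/L) for the single-breath method.

    β is solved per (patient, PEEP) as measured dFRC times ΔPaw/Vt and then
    normalised by tidal volume (β1 = β / Vt), which compensates for
    between-patient tidal-volume differences.
    """
    return BetaCalibration(cohort, "sssb").fit()


def lookup_beta(table: BetaTable, peep: float, policy: str = "refuse") -> float:
    """Population constant at *peep* (see :meth:`BetaTable.lookup`)."""
    value, _ = table.lookup(peep, policy=policy)
    return value


def loo_evaluate(cohort: Sequence[PatientDataset], method: str = "ssmb",
                 pairing: str = "consecutive", policy: str = "refuse") -> pd.DataFrame:
    """Leave-one-out estimates: each patient scored with a table calibrated
    on the remaining patients.

    Guards against the in-sample optimism of scoring patients against
    medians they contributed to.  Returns a DataFrame with columns
    ``patient_id, peep, measured, estimated``.
    """
    from .estimators import estimate_ssmb, estimate_sssb  # local: avoid cycle

    cohort = list(cohort)
    if len(cohort) < 3:
        raise CalibrationError("leave-one-out evaluation needs >= 3 patients")
    method = method.lower()
    records = []
    for i, pat in enumerate(cohort):
        rest = cohort[:i] + cohort[i + 1:]
        table = BetaCalibration(rest, method, pairing=pairing).fit()
        for step in pat.steps:
            if step.measured_dfrc is None:
                continue
            try:
                if method == "ssmb":
                    est = estimate_ssmb(pat, table, step.level,
                                        policy=policy, pairing=pairing)
                else:
                    est = estimate_sssb(step, table, policy=policy)
            except Exception:
                continue
            records.append({"patient_id": pat.patient_id, "peep": step.level,
                            "measured": step.measured_dfrc, "estimated": est.value})
    return pd.DataFrame.from_records(records,
                                     columns=["patient_id", "peep", "measured", "estimated"])


# ---------------------------------------------------------------------------
# Serialisation (structured text, bit-exact round trip)


def write_beta_table(path, table: BetaTable, volume_unit: str = "L") -> None:
    """Write a β table as YAML.

    For SSSB tables ``volume_unit='mL'`` serialises β1 in cmH2O/mL (the
    conventional reporting unit); values are converted back on read.
    """
    if volume_unit not in ("L", "mL"):
        raise ValueError("volume_unit must be 'L' or 'mL'")
    scale = 1.0
    units = table.units
    if table.method == "SSSB" and volume_unit == "mL":
        scale, units = 1e-3, "cmH2O/mL"
    doc = {
        "method": table.method,
        "units": units,
        "provenance": table.provenance,
        "rows": [
            {"peep": r.peep, "median_value": r.median_value * scale,
             "n_patients": r.n_patients, "min": r.min * scale,
             "max": r.max * scale, "iqr": r.iqr * scale}
            for r in table.rows
        ],
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False), encoding="utf-8")


def read_beta_table(path) -> BetaTable:
    """Read a β table written by :func:`write_beta_table`."""
    doc = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    try:
        method = doc["method"]
        units = doc["units"]
        rows_doc = doc["rows"]
    except (KeyError, TypeError) as exc:
        raise CalibrationError(f"{path}: malformed beta table ({exc})") from None
    scale = 1.0
    if method == "SSSB" and units == "cmH2O/mL":
        scale = 1e3
    elif units != _METHOD_UNITS.get(method):
        raise CalibrationError(f"{path}: unexpected units {units!r} for method {method!r}")
    rows = tuple(
        BetaRow(peep=float(r["peep"]), median_value=float(r["median_value"]) * scale,
                n_patients=int(r["n_patients"]), min=float(r["min"]) * scale,
                max=float(r["max"]) * scale, iqr=float(r["iqr"]) * scale)
        for r in rows_doc
    )
    return BetaTable(method=method, rows=rows, provenance=doc.get("provenance", {}))
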
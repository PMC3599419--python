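"""The four dFRC estimators.

* SSMB  (stress-strain, multiple breaths): dFRC = (ΔdFRC/ΔPEEP) * β, using
  the measured volume responsiveness across the PEEP step ending at the
  target PEEP and the per-PEEP population constant β.
* SSSB  (stress-strain, single breath): dFRC = β1 * Vt^2 / ΔPaw, from one
  PEEP level only, using the tidal-volume-normalised constant β1.
* SCSB  (single-compartment, single breath): V_Po = PEEP / Ers with Ers
  identified from one breath; V_Po is a dFRC proxy proportional to dFRC and
  uses no population constant.
* CM    (combined): SSSB while only one PEEP level is available, converting
  to SSMB once two or more levels with measured ΔdFRC exist -- a hard
  switch, never a blend.

Every estimate records the inputs it consumed, the β applied (if any) and
warning flags; estimates at PEEP below 5 cmH2O carry a low-PEEP caution
because estimation errors grow large there.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional

from .calibration import BetaTable
from .errors import (
    FlaggedFitError,
    InsufficientDataError,
    InvalidStepError,
)
from .identification import fit_single_compartment
from .waveforms import Breath, PatientDataset, PeepStep

__all__ = [
    "DfrcEstimate",
    "estimate_ssmb",
    "estimate_sssb",
    "estimate_scsb",
    "estimate_cm",
    "estimate_dataset",
    "LOW_PEEP_CAUTION",
]

#: below this PEEP (cmH2O) every estimate carries a caution flag
LOW_PEEP_CAUTION = 5.0


@dataclass(frozen=True)
class DfrcEstimate:
    """One estimator's output at one PEEP, with provenance."""

    method: str
    peep: float
    value: float
    beta_applied: Optional[tuple] = None  # (value, units)
    inputs_used: tuple = ()               # ((name, value), ...)
    flags: tuple = ()
    source_method: Optional[str] = None   # CM: which branch fired

    @property
    def inputs(self) -> dict:
        return dict(self.inputs_used)


def _common_flags(peep: float, value: float, out_of_range: bool = False) -> list:
    flags = []
    if peep < LOW_PEEP_CAUTION:
        flags.append("low-peep-caution")
    if out_of_range:
        flags.append("extrapolated-beta")
    if value < 0:
        flags.append("negative-estimate")
    return flags


def estimate_ssmb(patient: PatientDataset, table: BetaTable, target_peep: float,
                  policy: str = "refuse", pairing: str = "consecutive") -> DfrcEstimate:
    """Multiple-breath estimate at *target_peep*.

    Requires measured dFRC at the target step and at a reference step below
    it (the immediately preceding measured step, or the first step under
    baseline pairing).
    """
    if table.method != "SSMB":
        raise InvalidStepError(f"SSMB estimation needs an SSMB table, got {table.method}")
    deltas = patient.measured_delta_dfrc(pairing=pairing)
    key = None
    for peep in deltas:
        if math.isclose(peep, target_peep, rel_tol=0.0, abs_tol=1e-6):
            key = peep
            break
    if key is None:
        raise InsufficientDataError(
            f"patient {patient.patient_id}: no measured ΔdFRC across a step "
            f"ending at PEEP {target_peep}; SSMB needs two measured PEEP "
            "levels -- consider SSSB or CM"
        )
    ddfrc, dpeep = deltas[key]
    responsiveness = ddfrc / dpeep
    beta, oor = table.lookup(target_peep, policy=policy)
    value = responsiveness * beta
    return DfrcEstimate(
        method="SSMB", peep=float(target_peep), value=value,
        beta_applied=(beta, table.units),
        inputs_used=(("responsiveness", responsiveness),
                     ("delta_dfrc", ddfrc), ("delta_peep", dpeep)),
        flags=tuple(_common_flags(target_peep, value, oor)),
    )


def estimate_sssb(step: PeepStep, table: BetaTable,
                  policy: str = "refuse") -> DfrcEstimate:
    """Single-breath estimate from one PEEP step.

    Inverts the tidal-volume normalisation (β = β1 * Vt) and applies
    dFRC = (Vt/ΔPaw) * β = β1 * Vt^2 / ΔPaw.
    """
    if table.method != "SSSB":
        raise InvalidStepError(f"SSSB estimation needs an SSSB table, got {table.method}")
    if step.delta_paw <= 0:
        raise InvalidStepError(f"ΔPaw must be positive, got {step.delta_paw}")
    if step.tidal_volume <= 0:
        raise InvalidStepError(f"tidal volume must be positive, got {step.tidal_volume}")
    beta1, oor = table.lookup(step.level, policy=policy)
    value = beta1 * step.tidal_volume ** 2 / step.delta_paw
    return DfrcEstimate(
        method="SSSB", peep=step.level, value=value,
        beta_applied=(beta1, table.units),
        inputs_used=(("vt_over_delta_paw", step.tidal_volume / step.delta_paw),
                     ("tidal_volume", step.tidal_volume),
                     ("delta_paw", step.delta_paw)),
        flags=tuple(_common_flags(step.level, value, oor)),
    )


def estimate_scsb(breath: Breath, set_peep: Optional[float] = None) -> DfrcEstimate:
    """Single-compartment estimate V_Po = PEEP / Ers from one breath.

    Uses no population constant; the output is the un-rescaled dFRC proxy
    V_Po.  Refuses breaths whose fit is physiologically flagged.
    """
    peep = float(breath.set_peep if set_peep is None else set_peep)
    fit = fit_single_compartment(breath, "free")
    if not fit.valid:
        raise FlaggedFitError(
            f"single-compartment fit flagged ({', '.join(fit.flags)}): "
            f"Ers={fit.ers:.3g}, Rrs={fit.rrs:.3g}, Po={fit.po:.3g}"
        )
    value = peep / fit.ers
    return DfrcEstimate(
        method="SCSB", peep=peep, value=value, beta_applied=None,
        inputs_used=(("ers", fit.ers), ("rrs", fit.rrs), ("po", fit.po)),
        flags=tuple(_common_flags(peep, value)),
    )


def estimate_cm(patient_so_far: PatientDataset, ssmb_table: Optional[BetaTable],
                sssb_table: Optional[BetaTable], target_peep: float,
                policy: str = "refuse", pairing: str = "consecutive") -> DfrcEstimate:
    """Combined method: hard switch from SSSB to SSMB as data accrues.

    With a single available PEEP level (or no measured ΔdFRC across the step
    ending at *target_peep*) the SSSB branch fires; once two or more levels
    with measured ΔdFRC are available the SSMB branch fires.  The numeric
    output is identical to the delegated estimator's; the estimate records
    which branch produced it.
    """
    deltas = patient_so_far.measured_delta_dfrc(pairing=pairing)
    use_ssmb = any(math.isclose(p, target_peep, rel_tol=0.0, abs_tol=1e-6)
                   for p in deltas)
    if use_ssmb:
        if ssmb_table is None:
            raise InvalidStepError("CM SSMB branch requires an SSMB beta table")
        est = estimate_ssmb(patient_so_far, ssmb_table, target_peep,
                            policy=policy, pairing=pairing)
    else:
        if sssb_table is None:
            raise InvalidStepError("CM SSSB branch requires an SSSB beta table")
        step = patient_so_far.step_at(target_peep)
        est = estimate_sssb(step, sssb_table, policy=policy)
    return replace(est, method="CM", source_method=est.method)


def estimate_dataset(patient: PatientDataset, method: str,
                     ssmb_table: Optional[BetaTable] = None,
                     sssb_table: Optional[BetaTable] = None,
                     policy: str = "refuse",
                     pairing: str = "consecutive") -> list:
    """All estimable per-step estimates for one patient by one method.

    SSMB covers every step with a measured reference step below it; SSSB,
    SCSB and CM cover every step.  SCSB fits the step's first breath.
    Steps an estimator cannot serve are skipped.
    """
    method = method.lower()
    out = []
    for step in patient.steps:
        try:
            if method == "ssmb":
                out.append(estimate_ssmb(patient, ssmb_table, step.level,
                                         policy=policy, pairing=pairing))
            elif method == "sssb":
                out.append(estimate_sssb(step, sssb_table, policy=policy))
            elif method == "scsb":
                if not step.breaths:
                    continue
                out.append(estimate_scsb(step.breaths[0], set_peep=step.level))
            elif method == "cm":
                out.append(estimate_cm(patient, ssmb_table, sssb_table, step.level,
                                       policy=policy, pairing=pairing))
            else:
                raise ValueError(f"unknown method {method!r}")
        except (InsufficientDataError, FlaggedFitError):
            continue
    return out
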
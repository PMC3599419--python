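"""Single-compartment lung model identification.

The airway pressure of a passively ventilated single-compartment lung obeys
the equation of motion

    Paw(t) = Ers * V(t) + Rrs * Q(t) + Po

with respiratory elastance Ers (cmH2O/L), respiratory resistance Rrs
(cmH2O.s/L) and offset pressure Po (cmH2O, a combination of applied and
intrinsic PEEP).  The parameters are identified from the inspiratory portion
of one breath by the integral-based method: integrating the equation
cumulatively in time,

    int Paw dt = Ers * int V dt + Rrs * int Q dt + Po * t,

turns the fit into a linear least-squares problem on smooth cumulative-
integral regressors, which strongly attenuates sample-level measurement
noise.

Two intercept modes are available.  ``free`` estimates Po alongside Ers and
Rrs.  ``fixed`` pins Po to the ventilator's set PEEP, which is the same model
re-parameterised through Po = PEEP = Ers * V_Po; the two elastances agree
exactly when intrinsic PEEP is absent and diverge under auto-PEEP, which is
the basis of the :func:`compare_elastance_modes` diagnostic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .errors import UnidentifiableBreathError, WaveformError
from .waveforms import Breath

__all__ = [
    "SingleCompartmentModel",
    "SingleCompartmentResults",
    "fit_single_compartment",
    "compare_elastance_modes",
]

#: condition number above which the regressor matrix is declared unidentifiable
CONDITION_THRESHOLD = 1e8


@dataclass
class SingleCompartmentResults:
    """Identified single-compartment parameters for one breath."""

    ers: float
    rrs: float
    po: float
    rms_residual: float
    n_samples: int
    intercept_mode: str
    condition_number: float
    flags: tuple = ()

    @property
    def valid(self) -> bool:
        """Physiological plausibility: Ers > 0 and Rrs >= 0, unflagged."""
        return not self.flags

    @property
    def compliance(self) -> float:
        """Respiratory compliance 1/Ers, L/cmH2O."""
        return 1.0 / self.ers

    def summary(self) -> str:
        lines = [
            "Single-compartment fit (integral-based method)",
            "----------------------------------------------",
            f"  intercept mode    {self.intercept_mode}",
            f"  Ers               {self.ers:10.4f} cmH2O/L",
            f"  Rrs               {self.rrs:10.4f} cmH2O.s/L",
            f"  Po                {self.po:10.4f} cmH2O",
            f"  RMS residual      {self.rms_residual:10.4f} cmH2O",
            f"  n samples         {self.n_samples:10d}",
            f"  condition number  {self.condition_number:10.3g}",
        ]
        if self.flags:
            lines.append(f"  flags             {', '.join(self.flags)}")
        return "\n".join(lines)


class SingleCompartmentModel:
    """Least-squares identification of Ers, Rrs and Po from one breath.

    Parameters
    ----------
    breath : Breath
        The breath to fit; only the inspiratory portion (onset through the
        end-inspiratory zero-flow sample) enters the regression.
    intercept_mode : {'free', 'fixed'}
        ``free`` estimates the offset pressure Po; ``fixed`` pins it to the
        breath's set PEEP.
    cond_threshold : float
        Condition number of the regressor matrix above which the breath is
        declared unidentifiable.
    """

    def __init__(self, breath: Breath, intercept_mode: str = "free",
                 cond_threshold: float = CONDITION_THRESHOLD):
        if intercept_mode not in ("free", "fixed"):
            raise ValueError(f"intercept_mode must be 'free' or 'fixed', got {intercept_mode!r}")
        self.breath = breath
        self.intercept_mode = intercept_mode
        self.cond_threshold = cond_threshold

        sl = breath.inspiratory_slice()
        self.t = breath.time[sl] - breath.time[0]
        self.p = breath.pressure[sl]
        self.v = breath.volume[sl]
        self.q = breath.flow[sl]
        if self.t.size < 8:
            raise WaveformError(
                f"inspiratory portion has {self.t.size} samples; need >= 8"
            )
        if np.ptp(self.v) <= 0 or not np.any(self.q):
            raise WaveformError("degenerate inspiratory volume or flow")

    def fit(self) -> SingleCompartmentResults:
        t, p, v, q = self.t, self.p, self.v, self.q
        y = cumulative_trapezoid(p, t, initial=0.0)
        iv = cumulative_trapezoid(v, t, initial=0.0)
        iq = cumulative_trapezoid(q, t, initial=0.0)

        if self.intercept_mode == "free":
            X = np.column_stack([iv, iq, t])
        else:
            po = float(self.breath.set_peep)
            X = np.column_stack([iv, iq])
            y = y - po * t

        cond = float(np.linalg.cond(X[1:]))  # first row is identically zero
        if not np.isfinite(cond) or cond > self.cond_threshold:
            raise UnidentifiableBreathError(
                f"regressor condition number {cond:.3g} exceeds "
                f"{self.cond_threshold:.3g}; volume, flow and time histories "
                "are collinear over this inspiration"
            )
        theta, *_ = np.linalg.lstsq(X, y, rcond=None)
        if self.intercept_mode == "free":
            ers, rrs, po = (float(x) for x in theta)
        else:
            ers, rrs = (float(x) for x in theta)

        fitted_p = ers * v + rrs * q + po
        rms = float(np.sqrt(np.mean((p - fitted_p) ** 2)))
        flags = []
        if ers <= 0:
            flags.append("non-positive-elastance")
        if rrs < 0:
            flags.append("negative-resistance")
        return SingleCompartmentResults(
            ers=ers, rrs=rrs, po=po, rms_residual=rms, n_samples=int(t.size),
            intercept_mode=self.intercept_mode, condition_number=cond,
            flags=tuple(flags),
        )


def fit_single_compartment(breath: Breath, intercept_mode: str = "free",
                           cond_threshold: float = CONDITION_THRESHOLD) -> SingleCompartmentResults:
    """Fit the equation of motion to a breath's inspiratory portion."""
    return SingleCompartmentModel(breath, intercept_mode, cond_threshold).fit()


def compare_elastance_modes(breath: Breath, set_peep: float | None = None) -> tuple[float, float]:
    """Elastance from the free-intercept fit versus the PEEP-pinned fit.

    Returns ``(ers_free, ers_fixed)``.  The pair coincides when the breath's
    true offset pressure equals the set PEEP (no intrinsic PEEP) and diverges
    under auto-PEEP, supporting a scatter diagnostic of the assumption that
    the two model forms share one elastance.
    """
    if set_peep is not None and set_peep != breath.set_peep:
        breath = Breath(time=breath.time, pressure=breath.pressure, flow=breath.flow,
                        volume=breath.volume, insp_end_index=breath.insp_end_index,
                        set_peep=float(set_peep))
    ers_free = fit_single_compartment(breath, "free").ers
    ers_fixed = fit_single_compartment(breath, "fixed").ers
    return ers_free, ers_fixed
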
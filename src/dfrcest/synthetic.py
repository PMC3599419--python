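"""Virtual ventilated patients with known ground-truth dFRC.

Breaths follow the single-compartment equation of motion
``Paw = Ers*V + Rrs*Q + Po`` with a half-sine inspiratory flow profile
scaled to the set tidal volume, an end-inspiratory pause, and passive
exponential expiration (time constant Rrs/Ers, under which the simulated
airway pressure relaxes exactly to Po).  The offset pressure is
``Po = max(set PEEP, auto-PEEP)`` plus optional Gaussian pressure noise.

Ground-truth dFRC follows a logistic sigmoid in PEEP -- emulating the
naturally sigmoidal volume responsiveness of a recruitable lung, concave
over the upper clinical PEEP range -- and is held at the sigmoid's
auto-PEEP value below the auto-PEEP level (incomplete expiration keeps
those units recruited, producing the characteristic compliance break once
PEEP exceeds auto-PEEP).  The "clinically measured" dFRC is truth plus
Gaussian noise, floored at zero.

Default cohort parameters are adult-ICU-plausible fixtures (moderate-ARDS
elastance around 25 cmH2O/L, tidal volumes around 0.5 L), not values taken
from any particular cohort.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .errors import InfeasibleProfileError, WaveformError
from .waveforms import (
    Breath,
    PatientDataset,
    WaveformSeries,
    summarize_step,
    write_manifest,
    write_waveform_csv,
)

__all__ = [
    "SigmoidRecruitment",
    "VirtualPatientParams",
    "ParamSpec",
    "CohortSpec",
    "simulate_breath",
    "simulate_patient",
    "simulate_cohort",
    "make_eq8_consistent_cohort",
    "export_cohort",
]


@dataclass(frozen=True)
class SigmoidRecruitment:
    """Logistic ground-truth dFRC(PEEP): v_max / (1 + exp(-(PEEP-mid)/slope))."""

    v_max: float = 2.0     # L, recruitable volume asymptote
    peep_mid: float = 9.0  # cmH2O, half-recruitment PEEP
    slope: float = 3.5     # cmH2O, transition width

    def __post_init__(self):
        if self.v_max < 0:
            raise ValueError("v_max must be >= 0")
        if self.slope <= 0:
            raise ValueError("slope must be > 0")

    def __call__(self, peep: float) -> float:
        return self.v_max / (1.0 + math.exp(-(peep - self.peep_mid) / self.slope))


def half_sine_flow(t: np.ndarray, t_insp: float, vt: float) -> np.ndarray:
    """Inspiratory flow profile integrating to *vt* over [0, t_insp]."""
    qmax = math.pi * vt / (2.0 * t_insp)
    return qmax * np.sin(math.pi * t / t_insp)


@dataclass(frozen=True)
class VirtualPatientParams:
    """Mechanics, recruitment curve and noise levels of one virtual patient."""

    ers_true: float = 25.0        # cmH2O/L
    rrs_true: float = 10.0        # cmH2O.s/L
    vt_set: float = 0.5           # L
    resp_rate: float = 15.0       # breaths/min
    dfrc_curve: SigmoidRecruitment = field(default_factory=SigmoidRecruitment)
    auto_peep: float = 0.0        # cmH2O, 0 = none
    noise_sd_pressure: float = 0.0  # cmH2O
    noise_sd_dfrc: float = 0.0      # L
    seed: int = 0
    patient_id: str = "virtual"

    def __post_init__(self):
        for name in ("ers_true", "rrs_true", "vt_set", "resp_rate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("auto_peep", "noise_sd_pressure", "noise_sd_dfrc"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def true_dfrc(self, peep: float) -> float:
        """Sigmoid recruitment, held at the auto-PEEP value below it."""
        return self.dfrc_curve(max(peep, self.auto_peep))


def simulate_breath(params: VirtualPatientParams, set_peep: float,
                    fs: float = 50.0,
                    rng: Optional[np.random.Generator] = None,
                    flow_profile: Callable = half_sine_flow,
                    insp_fraction: float = 0.3,
                    pause: float = 0.3) -> Breath:
    """One equation-of-motion breath at *set_peep*.

    The volume channel is the trapezoidal running integral of the flow
    channel by construction, and the pressure channel is built from that
    same volume, so a noise-free breath is exactly consistent with the
    single-compartment model on the sampled grid.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    period = 60.0 / params.resp_rate
    n = int(round(period * fs))
    t = np.arange(n) / fs
    t_insp = insp_fraction * period
    t_pause_end = t_insp + pause
    tau = params.rrs_true / params.ers_true

    q = np.zeros(n)
    insp = t < t_insp
    q[insp] = flow_profile(t[insp], t_insp, params.vt_set)

    # Passive expiration Q = -V/tau, discretised with the trapezoid rule so
    # that the running trapezoidal volume decays exactly geometrically and
    # the sampled airway pressure relaxes exactly to Po.
    expi = np.flatnonzero(t >= t_pause_end)
    if expi.size:
        h = 1.0 / fs
        v_pause = float(np.trapezoid(q[:expi[0]], t[:expi[0]]))
        v0 = v_pause / (1.0 + h / (2.0 * tau))
        rho = (1.0 - h / (2.0 * tau)) / (1.0 + h / (2.0 * tau))
        v_exp = v0 * rho ** np.arange(expi.size)
        q[expi] = -v_exp / tau

    v = cumulative_trapezoid(q, t, initial=0.0)
    po = max(float(set_peep), params.auto_peep)
    p = params.ers_true * v + params.rrs_true * q + po
    if params.noise_sd_pressure > 0:
        p = p + rng.normal(0.0, params.noise_sd_pressure, size=n)

    # end-inspiratory zero flow: last pause sample
    insp_end = int(np.flatnonzero(t < t_pause_end)[-1])
    return Breath(time=t, pressure=p, flow=q, volume=v,
                  insp_end_index=insp_end, set_peep=float(set_peep))


def simulate_patient(params: VirtualPatientParams,
                     peep_protocol: Sequence[float],
                     fs: float = 50.0, n_breaths: int = 3) -> PatientDataset:
    """Stepwise-PEEP dataset for one virtual patient, ground truth attached.

    Per PEEP level, *n_breaths* breaths are generated and summarised; the
    measured dFRC is the sigmoid ground truth plus Gaussian noise, floored
    at zero.  Identical parameters (including seed) give bit-identical
    datasets.
    """
    protocol = [float(p) for p in peep_protocol]
    if any(p < 0 for p in protocol):
        raise WaveformError(f"PEEP protocol must be non-negative, got {protocol}")
    if any(b <= a for a, b in zip(protocol, protocol[1:])):
        raise WaveformError(f"PEEP protocol must be strictly increasing, got {protocol}")
    rng = np.random.default_rng(params.seed)
    steps, truth = [], {}
    for peep in protocol:
        breaths = [simulate_breath(params, peep, fs=fs, rng=rng)
                   for _ in range(n_breaths)]
        true_val = params.true_dfrc(peep)
        measured = true_val
        if params.noise_sd_dfrc > 0:
            measured = max(0.0, true_val + rng.normal(0.0, params.noise_sd_dfrc))
        steps.append(summarize_step(breaths, set_peep=peep, measured_dfrc=measured))
        truth[peep] = true_val
    return PatientDataset(patient_id=params.patient_id, cohort="synthetic",
                          steps=steps, true_dfrc=truth)


@dataclass(frozen=True)
class ParamSpec:
    """Population distribution of one parameter: mean and coefficient of variation."""

    mean: float
    cv: float = 0.0


@dataclass(frozen=True)
class CohortSpec:
    """Population distributions and protocol for a simulated cohort.

    Parameter heterogeneity is Gaussian with the stated coefficient of
    variation, truncated away from zero.  Mechanical parameters and tidal
    volume carry the bulk of the heterogeneity; the shape of the
    recruitment sigmoid (peep_mid, slope) varies only mildly, emulating a
    population over which a per-PEEP constant normalised volume response is
    approximately shared.

    With ``couple_recruitment`` enabled (default), the recruitable volume
    asymptote scales with body size through the set tidal volume,

        v_max_i = v_max.mean * (Vt_i / Vt.mean) * γ_i,

    where γ_i is a unit-mean patient deviate with CV ``v_max.cv``.  Tidal
    volumes are titrated per predicted body weight and lung volumes scale
    with it, so volume responsiveness tracks Vt across a population up to
    the deviation γ -- the stress-strain population hypothesis holding
    imperfectly, which is what makes the tidal-volume-normalised
    single-breath constant useful but fallible.  Disabling the coupling
    draws v_max independently.

    The default recruitment *shape* (peep_mid, slope) is shared across the
    population: a shared normalised volume response is precisely the
    per-PEEP population-constant assumption the stress-strain estimators
    encode, so the default cohort represents a population in which that
    assumption holds and heterogeneity lives in mechanics, tidal volume
    and recruitment magnitude.  Shape CVs can be raised to probe
    violations.
    """

    n_patients: int = 10
    ers: ParamSpec = ParamSpec(25.0, 0.20)
    rrs: ParamSpec = ParamSpec(10.0, 0.20)
    vt: ParamSpec = ParamSpec(0.5, 0.30)
    resp_rate: ParamSpec = ParamSpec(15.0, 0.20)
    v_max: ParamSpec = ParamSpec(2.0, 0.25)
    peep_mid: ParamSpec = ParamSpec(9.0, 0.0)
    slope: ParamSpec = ParamSpec(3.5, 0.0)
    couple_recruitment: bool = True
    auto_peep: float = 0.0
    noise_sd_pressure: float = 0.2
    noise_sd_dfrc: float = 0.05
    peep_protocol: tuple = (5.0, 10.0, 15.0)
    master_seed: int = 0
    cohort_label: str = "synthetic"

    def __post_init__(self):
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        prot = tuple(float(p) for p in self.peep_protocol)
        if any(b <= a for a, b in zip(prot, prot[1:])):
            raise ValueError("peep_protocol must be strictly increasing")


def _draw(rng: np.random.Generator, spec: ParamSpec) -> float:
    """Truncated-Gaussian draw: redraw while below 5% of the mean."""
    if spec.cv == 0:
        return spec.mean
    val = rng.normal(spec.mean, spec.cv * spec.mean)
    while val <= 0.05 * spec.mean:
        val = rng.normal(spec.mean, spec.cv * spec.mean)
    return float(val)


def draw_patient_params(spec: CohortSpec) -> list:
    """Deterministic per-patient parameter draws from a cohort spec."""
    ss = np.random.SeedSequence(spec.master_seed)
    children = ss.spawn(spec.n_patients + 1)
    rng = np.random.default_rng(children[0])
    out = []
    for i in range(spec.n_patients):
        seed = int(children[i + 1].generate_state(1)[0] & 0x7FFFFFFF)
        ers = _draw(rng, spec.ers)
        vt = _draw(rng, spec.vt)
        if spec.couple_recruitment:
            gamma = _draw(rng, ParamSpec(1.0, spec.v_max.cv))
            v_max = spec.v_max.mean * (vt / spec.vt.mean) * gamma
        else:
            v_max = _draw(rng, spec.v_max)
        out.append(VirtualPatientParams(
            ers_true=ers,
            rrs_true=_draw(rng, spec.rrs),
            vt_set=vt,
            resp_rate=_draw(rng, spec.resp_rate),
            dfrc_curve=SigmoidRecruitment(
                v_max=v_max,
                peep_mid=_draw(rng, spec.peep_mid),
                slope=_draw(rng, spec.slope),
            ),
            auto_peep=spec.auto_peep,
            noise_sd_pressure=spec.noise_sd_pressure,
            noise_sd_dfrc=spec.noise_sd_dfrc,
            seed=seed,
            patient_id=f"{spec.cohort_label}-{i:02d}",
        ))
    return out


def simulate_cohort(spec: CohortSpec, fs: float = 50.0,
                    n_breaths: int = 3) -> list:
    """Simulate a full cohort; reproducible from the master seed."""
    cohort = []
    for params in draw_patient_params(spec):
        pat = simulate_patient(params, spec.peep_protocol, fs=fs, n_breaths=n_breaths)
        pat.cohort = spec.cohort_label
        cohort.append(pat)
    return cohort


def make_eq8_consistent_cohort(beta_profile: dict, spec: CohortSpec,
                               fs: float = 50.0, n_breaths: int = 3) -> list:
    """Cohort whose measured dFRC satisfies the multiple-breath identity
    dFRC = (ΔdFRC/ΔPEEP)·β exactly under *beta_profile*.

    The waveforms are simulated as usual (dFRC noise forced to zero); the
    per-step dFRC values are then rebuilt by the recurrence implied by the
    identity: given dFRC at the first protocol PEEP,

        dFRC_k = dFRC_{k-1} * β_k / (β_k - ΔPEEP_k).

    A profile with β_k <= ΔPEEP_k at any step would force dFRC to be
    non-positive or unbounded and is rejected.  Used for exact-recovery
    tests of calibration and the multiple-breath estimator.
    """
    spec = replace(spec, noise_sd_dfrc=0.0, noise_sd_pressure=0.0)
    protocol = [float(p) for p in spec.peep_protocol]
    for peep in protocol[1:]:
        if peep not in beta_profile:
            raise InfeasibleProfileError(f"beta profile missing PEEP level {peep}")
    cohort = simulate_cohort(spec, fs=fs, n_breaths=n_breaths)
    out = []
    for pat in cohort:
        values = [pat.steps[0].measured_dfrc]
        if values[0] is None or values[0] <= 0:
            values[0] = 0.1  # positive anchor when the sigmoid starts at ~0
        for prev_peep, peep in zip(protocol, protocol[1:]):
            beta = float(beta_profile[peep])
            dpeep = peep - prev_peep
            if beta <= dpeep:
                raise InfeasibleProfileError(
                    f"beta({peep}) = {beta} <= ΔPEEP = {dpeep}: the identity "
                    "would force non-positive dFRC"
                )
            values.append(values[-1] * beta / (beta - dpeep))
        steps = [replace(s, measured_dfrc=v, breaths=s.breaths)
                 for s, v in zip(pat.steps, values)]
        out.append(PatientDataset(patient_id=pat.patient_id, cohort=pat.cohort,
                                  steps=steps,
                                  true_dfrc=dict(zip(protocol, values))))
    return out


# ---------------------------------------------------------------------------
# Export in the waveform-CSV + manifest + ground-truth-sidecar formats


def export_cohort(cohort: Sequence[PatientDataset], out_dir,
                  meta: Optional[dict] = None) -> dict:
    """Write a cohort as per-step waveform CSVs, a manifest and a
    ground-truth sidecar; returns the paths written.

    Breaths of one step are concatenated into a single continuous recording
    so that the file round-trips through segmentation.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries, files = [], []
    for pat in cohort:
        step_entries = []
        for k, step in enumerate(pat.steps):
            fname = f"{pat.patient_id}_step{k}.csv"
            series = _concatenate_breaths(step.breaths)
            write_waveform_csv(out_dir / fname, series)
            files.append(out_dir / fname)
            entry = {"set_peep": float(step.level), "file": fname}
            if step.measured_dfrc is not None:
                entry["measured_dfrc"] = float(step.measured_dfrc)
            step_entries.append(entry)
        entries.append({"patient_id": pat.patient_id, "cohort": pat.cohort,
                        "steps": step_entries})
    manifest = out_dir / "manifest.yaml"
    write_manifest(manifest, entries, meta=meta)

    sidecar = out_dir / "ground_truth.csv"
    lines = ["patient_id,peep,true_dfrc"]
    for key, value in (meta or {}).items():
        lines.insert(0, f"# {key}: {value}")
    for pat in cohort:
        for peep, val in sorted((pat.true_dfrc or {}).items()):
            lines.append(f"{pat.patient_id},{peep:.9g},{val:.9g}")
    sidecar.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return {"manifest": manifest, "ground_truth": sidecar, "waveforms": files}


def _concatenate_breaths(breaths: Sequence[Breath]) -> WaveformSeries:
    t_parts, p_parts, q_parts = [], [], []
    offset = 0.0
    for br in breaths:
        dt = br.time[1] - br.time[0]
        t_parts.append(br.time - br.time[0] + offset)
        p_parts.append(br.pressure)
        q_parts.append(br.flow)
        offset = t_parts[-1][-1] + dt
    return WaveformSeries(time=np.concatenate(t_parts),
                          pressure=np.concatenate(p_parts),
                          flow=np.concatenate(q_parts))
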
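import numpy as np
import pytest

from dfrcest import (
    PatientDataset,
    PeepStep,
    VirtualPatientParams,
    simulate_breath,
)

#: reference single-compartment parameters used throughout the suite
REF = dict(ers_true=25.0, rrs_true=10.0, vt_set=0.5)


@pytest.fixture
def ref_params():
    return VirtualPatientParams(**REF)


@pytest.fixture
def ref_breath(ref_params):
    """Noise-free equation-of-motion breath: Ers 25, Rrs 10, Po 5, Vt 0.5, 50 Hz."""
    return simulate_breath(ref_params, set_peep=5.0, fs=50.0)


def make_step(peep, measured_dfrc=None, tidal_volume=0.5, delta_paw=None,
              ers=25.0, set_peep=None):
    """Waveform-free PEEP step with plateau consistent with Ers * Vt."""
    if delta_paw is None:
        delta_paw = ers * tidal_volume
    return PeepStep(peep=float(peep), plateau_pressure=float(peep) + delta_paw,
                    tidal_volume=tidal_volume, delta_paw=delta_paw,
                    measured_dfrc=measured_dfrc,
                    set_peep=float(peep) if set_peep is None else set_peep)


def make_patient(dfrc_by_peep, patient_id="p0", **step_kwargs):
    steps = [make_step(peep, dfrc, **step_kwargs)
             for peep, dfrc in sorted(dfrc_by_peep.items())]
    return PatientDataset(patient_id=patient_id, cohort="test", steps=steps)
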
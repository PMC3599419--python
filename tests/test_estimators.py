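import numpy as np
import pytest

from dfrcest import (
    BetaRow,
    BetaTable,
    CohortSpec,
    FlaggedFitError,
    InsufficientDataError,
    VirtualPatientParams,
    calibrate_beta1_sssb,
    calibrate_beta_ssmb,
    estimate_cm,
    estimate_scsb,
    estimate_ssmb,
    estimate_sssb,
    make_eq8_consistent_cohort,
    simulate_breath,
    simulate_patient,
)
from dfrcest.waveforms import Breath, PatientDataset

from conftest import make_patient, make_step


def _table(method, values):
    rows = tuple(BetaRow(peep=p, median_value=v, n_patients=3,
                         min=v - 1, max=v + 1, iqr=0.5)
                 for p, v in sorted(values.items()))
    return BetaTable(method=method, rows=rows)


class TestSsmb:
    def test_direct_evaluation(self):
        pat = make_patient({5.0: 0.2, 10.0: 0.5})
        est = estimate_ssmb(pat, _table("SSMB", {10.0: 8.0}), 10.0)
        assert est.value == pytest.approx(0.3 / 5.0 * 8.0)  # 0.48 L
        assert est.beta_applied == (8.0, "cmH2O")
        assert est.inputs["responsiveness"] == pytest.approx(0.06)

    def test_zero_responsiveness_gives_zero(self):
        pat = make_patient({5.0: 0.4, 10.0: 0.4})
        est = estimate_ssmb(pat, _table("SSMB", {10.0: 8.0}), 10.0)
        assert est.value == 0.0

    def test_exact_on_consistent_cohort(self):
        profile = {10.0: 12.0, 15.0: 20.0}
        cohort = make_eq8_consistent_cohort(profile, CohortSpec(master_seed=5))
        table = calibrate_beta_ssmb(cohort)
        for pat in cohort:
            for peep in (10.0, 15.0):
                est = estimate_ssmb(pat, table, peep)
                assert est.value == pytest.approx(pat.true_dfrc[peep], rel=1e-3)

    def test_single_step_patient_refused(self):
        pat = make_patient({10.0: 0.5})
        with pytest.raises(InsufficientDataError, match="SSSB or CM"):
            estimate_ssmb(pat, _table("SSMB", {10.0: 8.0}), 10.0)


class TestSssb:
    def test_inverts_calibration_worked_example(self):
        step = make_step(10.0, tidal_volume=0.5, delta_paw=12.0)
        est = estimate_sssb(step, _table("SSSB", {10.0: 28.8}))
        assert est.value == pytest.approx(28.8 * 0.25 / 12.0)  # 0.6 L
        assert est.beta_applied == (28.8, "cmH2O/L")

    def test_zero_constant_gives_zero(self):
        step = make_step(10.0, tidal_volume=0.5, delta_paw=12.0)
        assert estimate_sssb(step, _table("SSSB", {10.0: 0.0})).value == 0.0

    def test_high_tidal_volume_overestimates(self):
        """A patient ventilated at twice the cohort-typical tidal volume at
        equal compliance is overestimated, the documented single-breath
        failure mode."""
        typical = [simulate_patient(
            VirtualPatientParams(seed=i, patient_id=f"t{i}"), [5.0, 10.0, 15.0])
            for i in range(5)]
        table = calibrate_beta1_sssb(typical)
        outlier_params = VirtualPatientParams(vt_set=1.0, seed=99)
        outlier = simulate_patient(outlier_params, [5.0, 10.0, 15.0])
        step = outlier.step_at(10.0)
        est = estimate_sssb(step, table)
        assert est.value > outlier.true_dfrc[10.0] * 1.5


class TestScsb:
    def test_vpo_from_fitted_elastance(self):
        params = VirtualPatientParams(ers_true=20.0)
        breath = simulate_breath(params, set_peep=10.0)
        est = estimate_scsb(breath)
        assert est.value == pytest.approx(0.5, rel=1e-3)
        assert est.beta_applied is None

    def test_zeep_gives_zero(self):
        breath = simulate_breath(VirtualPatientParams(), set_peep=0.0)
        est = estimate_scsb(breath)
        assert est.value == 0.0
        assert "low-peep-caution" in est.flags

    def test_vpo_linear_in_peep_at_constant_elastance(self):
        params = VirtualPatientParams(ers_true=25.0)
        peeps = [5.0, 10.0, 20.0]
        values = [estimate_scsb(simulate_breath(params, set_peep=p)).value
                  for p in peeps]
        assert values[1] == pytest.approx(2 * values[0], rel=1e-6)
        assert values[2] == pytest.approx(2 * values[1], rel=1e-6)

    def test_flagged_fit_refused(self, ref_breath):
        p = -25.0 * ref_breath.volume + 10.0 * ref_breath.flow + 5.0
        bad = Breath(time=ref_breath.time, pressure=p, flow=ref_breath.flow,
                     volume=ref_breath.volume,
                     insp_end_index=ref_breath.insp_end_index, set_peep=5.0)
        with pytest.raises(FlaggedFitError, match="non-positive-elastance"):
            estimate_scsb(bad)

    def test_nonlinear_truth_gives_concave_vpo_trace(self):
        """With sigmoidal recruitment, plotting V_Po against true dFRC bends:
        equal V_Po increments map onto shrinking dFRC increments near
        saturation."""
        params = VirtualPatientParams(ers_true=25.0)
        peeps = [5.0, 10.0, 15.0, 20.0]
        vpo = [estimate_scsb(simulate_breath(params, set_peep=p)).value
               for p in peeps]
        truth = [params.true_dfrc(p) for p in peeps]
        vpo_inc = np.diff(vpo)
        truth_inc = np.diff(truth)
        assert np.allclose(vpo_inc, vpo_inc[0], rtol=1e-6)  # linear proxy
        assert truth_inc[-1] < truth_inc[0]                 # saturating truth


class TestCombinedMethod:
    ssmb = _table("SSMB", {10.0: 8.0, 15.0: 10.0})
    sssb = _table("SSSB", {5.0: 20.0, 10.0: 28.8, 15.0: 30.0})

    def test_single_level_delegates_to_sssb(self):
        pat = make_patient({10.0: 0.5}, tidal_volume=0.5, delta_paw=12.0)
        cm = estimate_cm(pat, self.ssmb, self.sssb, 10.0)
        direct = estimate_sssb(pat.steps[0], self.sssb)
        assert cm.method == "CM" and cm.source_method == "SSSB"
        assert cm.value == direct.value
        assert cm.beta_applied == direct.beta_applied
        assert cm.flags == direct.flags

    def test_multi_level_delegates_to_ssmb(self):
        pat = make_patient({5.0: 0.2, 10.0: 0.5, 15.0: 0.8})
        cm = estimate_cm(pat, self.ssmb, self.sssb, 15.0)
        direct = estimate_ssmb(pat, self.ssmb, 15.0)
        assert cm.source_method == "SSMB"
        assert cm.value == direct.value
        assert cm.inputs_used == direct.inputs_used

    def test_streaming_replay_switches_once_and_never_reverts(self):
        full = make_patient({5.0: 0.2, 10.0: 0.5, 15.0: 0.8, 20.0: 1.0},
                            tidal_volume=0.5, delta_paw=12.0)
        ssmb = _table("SSMB", {10.0: 8.0, 15.0: 10.0, 20.0: 12.0})
        sssb = _table("SSSB", {5.0: 20.0, 10.0: 28.8, 15.0: 30.0, 20.0: 32.0})
        branches = []
        for k in range(1, len(full.steps) + 1):
            partial = PatientDataset(patient_id="p0", cohort="test",
                                     steps=full.steps[:k])
            est = estimate_cm(partial, ssmb, sssb, partial.steps[-1].peep)
            branches.append(est.source_method)
        assert branches[0] == "SSSB"
        assert branches[1:] == ["SSMB"] * (len(branches) - 1)


class TestHomogeneity:
    """Scaling all volumes by c scales volume outputs by c once the tables
    are recalibrated on the scaled cohort."""

    def test_ssmb_scaling(self):
        c = 2.5
        base = [make_patient({5.0: 0.2, 10.0: 0.5}, patient_id="a"),
                make_patient({5.0: 0.3, 10.0: 0.6}, patient_id="b")]
        scaled = [make_patient({5.0: 0.2 * c, 10.0: 0.5 * c}, patient_id="a"),
                  make_patient({5.0: 0.3 * c, 10.0: 0.6 * c}, patient_id="b")]
        est0 = estimate_ssmb(base[0], calibrate_beta_ssmb(base), 10.0)
        est1 = estimate_ssmb(scaled[0], calibrate_beta_ssmb(scaled), 10.0)
        assert est1.value == pytest.approx(c * est0.value, rel=1e-9)

    def test_sssb_scaling(self):
        c = 3.0
        base, scaled = [], []
        for i, (vt, dfrc) in enumerate([(0.4, 0.5), (0.6, 0.7)]):
            p = make_patient({}, patient_id=f"p{i}")
            p.steps = [make_step(10.0, dfrc, tidal_volume=vt, delta_paw=12.0)]
            base.append(p)
            q = make_patient({}, patient_id=f"p{i}")
            q.steps = [make_step(10.0, dfrc * c, tidal_volume=vt * c, delta_paw=12.0)]
            scaled.append(q)
        est0 = estimate_sssb(base[0].steps[0], calibrate_beta1_sssb(base))
        est1 = estimate_sssb(scaled[0].steps[0], calibrate_beta1_sssb(scaled))
        assert est1.value == pytest.approx(c * est0.value, rel=1e-9)
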
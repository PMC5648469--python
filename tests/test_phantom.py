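"""Synthetic-data generator: AIFs, cohorts, frame schedules, raw studies."""

import numpy as np
import pandas as pd
import pytest

from duoflow import (
    AIFParams, FrameSchedule, NoiseParams, PET_FRAMING, TERRITORY_SEGMENTS,
    build_frame_schedule, generate_aif, generate_cohort, synthesize_cmr_study,
    synthesize_pet_study,
)
from duoflow.phantom import FlowScenario, VirtualPatient, N_SEGMENTS
from duoflow.pet_kinetics import degrado_fit
from duoflow import cmr_signal


class TestGenerateAIF:
    def test_zero_amplitude_gives_zero_curve(self, times_90s):
        aif = generate_aif(AIFParams(amplitude=0.0), times_90s)
        assert np.all(aif.values == 0)

    def test_peak_at_t0_plus_alpha_beta(self):
        # d/dt of the gamma-variate vanishes at t = t0 + alpha*beta
        t = np.arange(0, 60, 0.001)
        aif = generate_aif(
            AIFParams(amplitude=1.0, onset_time=10.0, alpha=2.0, beta=4.0,
                      recirculation_fraction=0.0), t)
        assert t[np.argmax(aif.values)] == pytest.approx(18.0, abs=0.01)

    def test_linear_in_amplitude(self, times_90s):
        p1 = AIFParams(amplitude=1.0)
        p2 = AIFParams(amplitude=2.0)
        a1 = generate_aif(p1, times_90s).values
        a2 = generate_aif(p2, times_90s).values
        np.testing.assert_allclose(a2, 2 * a1, rtol=1e-12)

    def test_nonnegative_with_recirculation(self, times_90s):
        aif = generate_aif(AIFParams(amplitude=3.0, recirculation_fraction=0.3),
                           times_90s)
        assert np.all(aif.values >= 0)

    def test_non_monotone_times_rejected(self):
        with pytest.raises(ValueError):
            generate_aif(AIFParams(amplitude=1.0), np.array([0.0, 2.0, 1.0]))

    def test_for_peak_scales_to_requested_peak(self):
        p = AIFParams.for_peak(5.0, onset_time=0.0, beta=3.0)
        t = np.arange(0.001, 60, 0.001)
        vals = generate_aif(
            AIFParams(amplitude=p.amplitude, onset_time=0.0, beta=3.0,
                      recirculation_fraction=0.0), t).values
        assert vals.max() == pytest.approx(5.0, rel=1e-5)


class TestFrameSchedule:
    def test_dynamic_pet_framing_has_21_frames_over_4_min(self):
        sched = build_frame_schedule(PET_FRAMING)
        assert sched.n_frames == 21
        assert sched.total_duration == pytest.approx(240.0)

    def test_single_frame(self):
        sched = build_frame_schedule([(1, 10.0)])
        assert sched.n_frames == 1
        assert sched.frame_start[0] == 0.0
        assert sched.frame_duration[0] == 10.0

    def test_empty_spec_rejected(self):
        with pytest.raises(ValueError):
            build_frame_schedule([])

    def test_overlapping_frames_rejected(self):
        with pytest.raises(ValueError):
            FrameSchedule(frame_start=np.array([0.0, 3.0]),
                          frame_duration=np.array([5.0, 5.0]))


class TestCohort:
    def test_same_seed_reproduces_cohort(self):
        mix = {"normal": 0.5, "single_vessel": 0.3, "multi_vessel": 0.2}
        a = generate_cohort(6, mix, seed=42)
        b = generate_cohort(6, mix, seed=42)
        for pa, pb in zip(a, b):
            assert pa.scenario.label == pb.scenario.label
            pd.testing.assert_frame_equal(pa.true_flows, pb.true_flows)

    def test_multi_vessel_all_segments_below_cutoff(self):
        (p,) = generate_cohort(1, {"multi_vessel": 1.0}, seed=3)
        assert (p.true_flows["stress"] < 2.0).all()

    def test_normal_flows_within_configured_ranges(self):
        cohort = generate_cohort(100, {"normal": 1.0}, seed=5)
        for p in cohort:
            assert p.true_flows["rest"].between(0.6, 1.1).all()
            assert p.true_flows["stress"].between(2.0, 4.0).all()

    def test_single_vessel_lesion_confined_to_territory(self):
        cohort = generate_cohort(9, {"single_vessel": 1.0}, seed=8)
        for p in cohort:
            lesion = list(TERRITORY_SEGMENTS[p.scenario.territory])
            healthy = p.true_flows.drop(index=lesion)
            assert (p.true_flows.loc[lesion, "stress"] < 2.0).all()
            assert (healthy["stress"] >= 2.0).all()

    def test_patient_table_has_16_segments(self):
        (p,) = generate_cohort(1, {"normal": 1.0}, seed=1)
        assert len(p.true_flows) == N_SEGMENTS

    def test_bad_mix_rejected(self):
        with pytest.raises(ValueError):
            generate_cohort(2, {"normal": 0.7}, seed=1)


def _one_patient(seed=11, label="single_vessel"):
    (p,) = generate_cohort(1, {label: 1.0}, seed=seed)
    return p


class TestCMRSynthesis:
    def test_stress_series_has_90_timepoints(self):
        study = synthesize_cmr_study(_one_patient(), state="stress")
        assert study.highres.shape[0] == 90
        assert len(study.times) == 90

    def test_zero_flow_segment_stays_at_baseline(self):
        p = _one_patient()
        flows = p.true_flows.copy()
        flows.loc[1, "stress"] = 0.0
        p0 = VirtualPatient(patient_id="z", true_flows=flows,
                            scenario=p.scenario, seed=p.seed)
        study = synthesize_cmr_study(p0, state="stress")
        sel = study.segment_maps[0] == 1
        sig = study.highres[:, 0][:, sel]
        np.testing.assert_allclose(sig, np.broadcast_to(sig[0], sig.shape),
                                   rtol=1e-12)

    def test_noiseless_concentration_round_trip(self):
        """Forward-synthesized signal inverts back to the simulated [Gd]."""
        study = synthesize_cmr_study(_one_patient(), state="stress")
        lut = cmr_signal.build_lut(study.protocol, study.relax_myo,
                                   te=study.protocol.te1)
        conv = cmr_signal.signal_to_concentration(
            study.times, study.highres, lut, study.pd_highres)
        true = study.true_conc
        mask = true > 0.05  # relative error where meaningfully above baseline
        rel = np.abs(conv.series.concentration[mask] - true[mask]) / true[mask]
        assert rel.max() < 0.01

    def test_blood_pool_carries_aif(self):
        study = synthesize_cmr_study(_one_patient(), state="stress")
        lut = cmr_signal.build_lut(study.protocol_aif, study.relax_blood, te=None)
        corr = cmr_signal.t2star_correct(study.lowres_echo1, study.lowres_echo2,
                                         study.protocol_aif.te1,
                                         study.protocol_aif.te2)
        conv = cmr_signal.signal_to_concentration(study.times, corr.s0, lut,
                                                  study.pd_lowres)
        aif = cmr_signal.extract_aif(conv.series, study.blood_mask)
        true = study.true_aif.values
        sel = true > 0.1
        rel = np.abs(aif.values[sel] - true[sel]) / true[sel]
        assert rel.max() < 0.01

    def test_noise_is_reproducible_given_seed(self):
        p = _one_patient()
        noise = NoiseParams(cmr_sigma=0.02, seed=77)
        a = synthesize_cmr_study(p, state="stress", noise=noise)
        b = synthesize_cmr_study(p, state="stress", noise=noise)
        np.testing.assert_array_equal(a.highres, b.highres)


class TestPETSynthesis:
    def test_zero_flow_zero_vb_gives_zero_tac(self):
        p = _one_patient()
        flows = p.true_flows.copy()
        flows["stress"] = 0.0
        p0 = VirtualPatient(patient_id="z", true_flows=flows,
                            scenario=p.scenario, seed=p.seed)
        study = synthesize_pet_study(p0, state="stress", vb=0.0)
        for tac in study.tacs.values():
            np.testing.assert_allclose(tac.activity, 0.0, atol=1e-12)

    def test_noiseless_tac_refit_recovers_flow_within_2pct(self):
        p = _one_patient()
        study = synthesize_pet_study(p, state="stress")
        for seg in (1, 4, 9):  # lesion and remote segments
            fit = degrado_fit(study.tacs[seg], study.blood)
            true_k1 = study.true_params[seg].K1
            assert fit.params.K1 == pytest.approx(true_k1, rel=0.02)

    def test_tissue_scales_linearly_with_aif_amplitude(self, times_90s):
        """The kinetic system is linear in its input."""
        from duoflow.btex_kinetics import btex_forward, BTEXParams
        a1 = generate_aif(AIFParams(amplitude=2.0), times_90s)
        a2 = generate_aif(AIFParams(amplitude=4.0), times_90s)
        p = BTEXParams(Fp=1.5)
        c1 = btex_forward(p, a1, times_90s)
        c2 = btex_forward(p, a2, times_90s)
        np.testing.assert_allclose(c2, 2 * c1, rtol=1e-10, atol=1e-12)
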
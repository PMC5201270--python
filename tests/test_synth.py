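"""Generator contracts: PK, drug effects, beat synthesis, trial structure."""

import numpy as np
import pytest
from dataclasses import replace

from ecgrepol import synth
from ecgrepol.synth import (
    BeatParams,
    DRUG_REFERENCE_HOUR,
    PkModel,
    TrialDesign,
    apply_drug_effect,
    calibrate_effects,
    simulate_pk,
    synthesize_beat,
    synthesize_recording,
)


class TestPk:
    def test_zero_before_and_at_first_dose(self, pk_models):
        m = pk_models["dofetilide"]
        assert simulate_pk(m, [0.0])[0] == 0.0

    def test_three_dose_peak_lands_at_published_tmax(self, pk_models):
        """Cmax of the three-dose regimens occurs 12-14 h after first dose."""
        for drug in ("dofetilide", "mexiletine", "lidocaine"):
            assert 12.0 <= pk_models[drug].tmax_h() <= 14.0

    def test_linearity_in_dose(self, pk_models):
        m = pk_models["dofetilide"]
        doubled = PkModel(
            m.ka_per_h,
            m.ke_per_h,
            m.v_scaled,
            tuple(2 * d for d in m.dose_amounts),
            m.dose_times_h,
        )
        t = np.linspace(0, 24, 97)
        np.testing.assert_allclose(simulate_pk(doubled, t), 2 * simulate_pk(m, t))

    def test_concentrations_nonnegative(self, pk_models):
        for m in pk_models.values():
            assert np.all(simulate_pk(m, np.linspace(0, 48, 500)) >= 0)

    def test_ka_equal_ke_rejected(self):
        with pytest.raises(ValueError, match="flip-flop"):
            PkModel(0.5, 0.5, 1.0, (1,), (0.0,))

    def test_unsorted_times_rejected(self, pk_models):
        with pytest.raises(ValueError, match="sorted"):
            simulate_pk(pk_models["dofetilide"], [2.0, 1.0])


class TestDrugEffects:
    def test_zero_concentration_leaves_beat_unchanged(self, baseline_beat, pk_models):
        eff = calibrate_effects(pk_models)
        out = apply_drug_effect(baseline_beat, eff, {d: 0.0 for d in synth.DRUGS})
        assert out == baseline_beat

    def test_dofetilide_at_cmax_matches_population_targets(self, baseline_beat, pk_models):
        """Mean-subject J-Tpeak and QT changes reproduce the published
        placebo-corrected changes (raw scale) to < 0.5 ms."""
        eff = calibrate_effects(pk_models)
        cref = simulate_pk(pk_models["dofetilide"], [DRUG_REFERENCE_HOUR["dofetilide"]])[0]
        out = apply_drug_effect(baseline_beat, eff, {"dofetilide": cref})
        f_jtp = baseline_beat.rr_s**0.58
        f_qt = baseline_beat.rr_s ** (1 / 3)
        assert out.j_to_tpeak_ms - baseline_beat.j_to_tpeak_ms == pytest.approx(
            29.1 * f_jtp, abs=0.5
        )
        assert out.qt_ms - baseline_beat.qt_ms == pytest.approx(45.2 * f_qt, abs=0.5)

    def test_combination_mitigates_jtpeak_but_not_qt(self, baseline_beat, pk_models):
        """hERG + late-Na slopes: J-Tpeak nearly cancels (~1 ms) while QT
        prolongation persists (~17 ms), mirroring the combination arm."""
        eff = calibrate_effects(pk_models)
        conc = {
            d: simulate_pk(pk_models[d], [DRUG_REFERENCE_HOUR[d]])[0]
            for d in ("dofetilide", "mexiletine")
        }
        out = apply_drug_effect(baseline_beat, eff, conc)
        f_jtp = baseline_beat.rr_s**0.58
        f_qt = baseline_beat.rr_s ** (1 / 3)
        assert out.j_to_tpeak_ms - baseline_beat.j_to_tpeak_ms == pytest.approx(
            1.1 * f_jtp, abs=0.5
        )
        assert out.qt_ms - baseline_beat.qt_ms == pytest.approx(17.3 * f_qt, abs=0.5)

    def test_inadmissible_magnitude_raises(self, baseline_beat, pk_models):
        eff = calibrate_effects(pk_models)
        with pytest.raises(ValueError, match="admissible"):
            apply_drug_effect(baseline_beat, eff, {"mexiletine": 1e9})

    def test_negative_concentration_rejected(self, baseline_beat, pk_models):
        eff = calibrate_effects(pk_models)
        with pytest.raises(ValueError):
            apply_drug_effect(baseline_beat, eff, {"dofetilide": -1.0})


class TestBeatSynthesis:
    def test_symmetric_t_peaks_at_truth_center(self):
        p = BeatParams(
            qrs_duration_ms=90,
            j_to_tpeak_ms=250,
            sigma_asc_ms=28,
            sigma_desc_ms=28,
            t_amplitude_uv=500,
            t_tail_weight=0.0,
            rr_s=1.0,
        )
        wave, truth = synthesize_beat(p, 1000.0)
        tp = int(round(truth["t_peak_ms"]))
        window = wave[tp - 80 : tp + 81]
        assert int(np.argmax(window)) == 80  # sampled maximum at the truth peak

    def test_truth_qt_matches_baseline_qtc_band(self, baseline_beat):
        """Truth-derived QT after Fridericia lands in the published
        baseline band 397.1 +/- 14 ms."""
        _, truth = synthesize_beat(baseline_beat, 1000.0)
        qt = truth["t_end_ms"] - truth["qrs_onset_ms"]
        qtc = qt / truth["rr_s"] ** (1 / 3)
        assert abs(qtc - 397.1) < 14.0

    def test_amplitude_scaling_outside_qrs_is_linear(self, baseline_beat):
        wave1, t1 = synthesize_beat(baseline_beat, 1000.0)
        wave2, t2 = synthesize_beat(
            replace(baseline_beat, t_amplitude_uv=2 * baseline_beat.t_amplitude_uv),
            1000.0,
        )
        j = int(round(t1["qrs_offset_ms"])) + 15
        np.testing.assert_allclose(wave2[j:], 2 * wave1[j:], atol=1e-9)
        assert t1 == t2  # fiducials unchanged

    def test_low_rate_rejected(self, baseline_beat):
        with pytest.raises(ValueError, match="fs_hz"):
            synthesize_beat(baseline_beat, 200.0)

    def test_overlapping_qrs_t_rejected(self):
        p = BeatParams(
            qrs_duration_ms=90,
            j_to_tpeak_ms=40,
            sigma_asc_ms=40,
            sigma_desc_ms=24,
            t_amplitude_uv=500,
            t_tail_weight=0.05,
            rr_s=1.0,
        )
        with pytest.raises(ValueError, match="overlap"):
            synthesize_beat(p, 1000.0)


class TestRecording:
    def test_noise_free_recording_is_periodic(self, clean_recording):
        rr = [t.rr_s for t in clean_recording.truth]
        assert len(set(rr)) == 1
        period = clean_recording.truth[1].r_peak - clean_recording.truth[0].r_peak
        vm = clean_recording.vm()
        np.testing.assert_allclose(vm[:period], vm[period : 2 * period], atol=1e-9)

    def test_ten_seconds_at_unit_rr_gives_at_least_nine_beats(self, clean_recording):
        assert len(clean_recording.truth) >= 9

    def test_same_seed_is_bit_identical(self, baseline_beat):
        a = synthesize_recording(baseline_beat, noise_uv_rms=15, rr_variability=0.03, seed=7)
        b = synthesize_recording(baseline_beat, noise_uv_rms=15, rr_variability=0.03, seed=7)
        assert np.array_equal(a.samples, b.samples)
        assert [t.__dict__ for t in a.truth] == [t.__dict__ for t in b.truth]

    def test_quantization_step(self, noisy_recording):
        q = noisy_recording.samples / 2.5
        np.testing.assert_allclose(q, np.round(q), atol=1e-9)

    def test_negative_noise_rejected(self, baseline_beat):
        with pytest.raises(ValueError):
            synthesize_recording(baseline_beat, noise_uv_rms=-1.0)


class TestTrialStructure:
    def test_every_subject_in_every_arm_with_latin_square(self):
        design = TrialDesign(
            n_subjects=5,
            n_female=2,
            arms=("placebo", "dofetilide", "moxifloxacin"),
            timepoint_hours=(13.0,),
            replicates_per_timepoint=1,
            seed=0,
        )
        recs = list(synth.simulate_trial(design, noise_uv_rms=0.0))
        seen = {(r.metadata["subject"], r.metadata["arm"]) for r in recs}
        assert len(seen) == 5 * 3
        # within a subject, periods enumerate the arms exactly once
        for s in {m for m, _ in seen}:
            arm_periods = {
                (r.metadata["arm"], r.metadata["period"])
                for r in recs
                if r.metadata["subject"] == s
            }
            assert sorted(p for _, p in arm_periods) == [1, 2, 3]

    def test_placebo_arm_has_zero_drug_effect(self):
        """Zero-dose invariance: identical beat parameters, placebo vs a
        zero-slope active arm."""
        design = TrialDesign(
            n_subjects=3,
            n_female=1,
            arms=("placebo", "dofetilide"),
            timepoint_hours=(13.0,),
            replicates_per_timepoint=1,
            seed=4,
        )
        null = synth.DrugEffectModel(
            slopes={d: {k: 0.0 for k in ("j_to_tpeak_ms", "sigma_desc_ms", "t_amplitude_uv", "t_tail_weight")} for d in synth.DRUGS}
        )
        recs = list(synth.simulate_trial(design, effects=null, noise_uv_rms=0.0))
        by = {}
        for r in recs:
            key = (r.metadata["subject"], r.metadata["timepoint_h"])
            by.setdefault(key, []).append(r)
        for pair in by.values():
            if len(pair) == 2:
                qt_a = pair[0].truth[0].t_end - pair[0].truth[0].qrs_onset
                qt_b = pair[1].truth[0].t_end - pair[1].truth[0].qrs_onset
                assert qt_a == qt_b

    def test_single_subject_design_rejected(self):
        with pytest.raises(ValueError):
            TrialDesign(n_subjects=1, n_female=0)


class TestBiomarkerTrial:
    def test_population_delta_delta_targets_by_construction(self):
        """Noise-free, homogeneous-subject trial reproduces the published
        placebo-corrected changes at each drug's reference time-point."""
        design = TrialDesign(
            n_subjects=6, n_female=2, timepoint_hours=(2.0, 13.0), replicates_per_timepoint=1, seed=0
        )
        tab = synth.simulate_biomarker_trial(
            design,
            measurement_sd={k: 0.0 for k in synth.MEASUREMENT_SD},
            slope_cv=0.0,
            conc_cv=0.0,
            rr_within_sd=0.0,
            period_effect_frac=0.0,
        )
        from ecgrepol import exposure as ex, ratecorrect as rc

        corr = rc.correct_table(tab)
        biomarkers = ["qtc_ms", "jtpeakc_ms"]
        changes = ex.changes_from_baseline(corr, biomarkers)
        rows = ex.placebo_corrected_rows(changes, biomarkers)
        dof = rows[(rows.arm == "dofetilide") & (rows.timepoint_h == 13.0)]
        assert dof["qtc_ms"].mean() == pytest.approx(45.2, abs=0.05)
        assert dof["jtpeakc_ms"].mean() == pytest.approx(29.1, abs=0.05)
        mex = rows[(rows.arm == "mexiletine+dofetilide") & (rows.timepoint_h == 13.0)]
        assert mex["qtc_ms"].mean() == pytest.approx(17.3, abs=0.05)
        assert mex["jtpeakc_ms"].mean() == pytest.approx(1.1, abs=0.05)

    def test_reproducible_given_seed(self):
        design = TrialDesign(n_subjects=4, n_female=2, timepoint_hours=(13.0,), seed=9)
        a = synth.simulate_biomarker_trial(design)
        b = synth.simulate_biomarker_trial(design)
        assert a.equals(b)

    def test_subject_relabeling_preserves_pooled_summary(self):
        """Exchangeability: relabeling subject ids leaves pooled statistics
        untouched."""
        design = TrialDesign(n_subjects=4, n_female=2, timepoint_hours=(13.0,), seed=2)
        tab = synth.simulate_biomarker_trial(design)
        swapped = tab.copy()
        swapped["subject"] = swapped["subject"].map(
            lambda s: {"S01": "S02", "S02": "S01"}.get(s, s)
        )
        for col in ("qt_ms", "jtpeak_ms", "flatness_du"):
            assert sorted(tab[col]) == sorted(swapped[col])
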
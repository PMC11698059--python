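"""Generator contracts: bout scripting, signal signatures, study roster."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest
from scipy.signal import periodogram

import ethoseg as es
from ethoseg.behaviors import UNLABELED, Behavior
from ethoseg.synthetic import (
    BehaviorScript,
    InvalidProfileError,
    StudyConfig,
    source_species_profile,
    target_species_profile,
)


def _single_class_profile(behavior: Behavior) -> es.SpeciesProfile:
    base = source_species_profile()
    prevalence = {b: (1.0 if b == behavior else 0.0) for b in base.classes}
    return dataclasses.replace(base, prevalence=prevalence)


def _quiet_profile(**kw) -> es.SpeciesProfile:
    base = source_species_profile()
    return dataclasses.replace(base, **kw)


class TestBehaviorScript:
    def test_single_positive_weight_gives_single_class_script(self):
        profile = _single_class_profile(Behavior.RESTING)
        script = es.sample_behavior_script(profile, 60.0, rng_seed=0)
        assert {b for b, _ in script.segments} == {Behavior.RESTING}
        assert script.total_duration_s == pytest.approx(60.0)

    def test_all_zero_weights_rejected(self):
        base = source_species_profile()
        with pytest.raises(InvalidProfileError):
            dataclasses.replace(base, prevalence={b: 0.0 for b in base.classes})

    def test_nonpositive_duration_rejected(self):
        profile = source_species_profile()
        with pytest.raises(ValueError):
            es.sample_behavior_script(profile, 0.0, rng_seed=0)

    def test_duration_shares_track_prevalence_weights(self):
        """Mean per-class duration share over 100 scripts stays within
        +-15% (relative) of the prevalence-weight proportions."""
        profile = source_species_profile()
        totals = {b: 0.0 for b in profile.classes}
        for seed in range(100):
            script = es.sample_behavior_script(profile, 3600.0, rng_seed=seed)
            for b, d in script.class_durations().items():
                totals[b] += d
        grand = sum(totals.values())
        w = np.array([profile.prevalence[b] for b in profile.classes])
        w = w / w.sum()
        for b, target in zip(profile.classes, w):
            share = totals[b] / grand
            assert share == pytest.approx(target, rel=0.15), b

    def test_same_seed_same_script(self):
        profile = target_species_profile()
        s1 = es.sample_behavior_script(profile, 500.0, rng_seed=42)
        s2 = es.sample_behavior_script(profile, 500.0, rng_seed=42)
        assert s1.segments == s2.segments

    def test_no_immediate_self_transition(self):
        profile = source_species_profile()
        script = es.sample_behavior_script(profile, 3600.0, rng_seed=7)
        pairs = list(zip(script.segments, script.segments[1:]))
        assert all(a[0] != b[0] for a, b in pairs)


class TestRenderRecording:
    def test_resting_is_quiet_with_no_spectral_peak(self):
        profile = _quiet_profile(acc_noise_sd=0.02, jitter=0.0)
        script = BehaviorScript("r", [(Behavior.RESTING, 60.0)])
        rec = es.render_recording(script, profile, rng_seed=3)
        for ax in range(3):
            x = rec.acc[:, ax]
            assert x.std() <= 0.03
            f, p = periodogram(x - x.mean(), fs=20.0)
            band = (f > 0.3) & (f < 5.0)
            assert p[band].max() < 50 * np.median(p[band])

    def test_swimming_peak_at_carrier_frequency(self):
        profile = _quiet_profile(jitter=0.0)
        sigs = dict(profile.signatures)
        sigs[Behavior.SWIMMING] = dataclasses.replace(
            sigs[Behavior.SWIMMING], carrier_hz=1.0)
        profile = dataclasses.replace(profile, signatures=sigs)
        script = BehaviorScript("s", [(Behavior.SWIMMING, 60.0)])
        rec = es.render_recording(script, profile, rng_seed=3)
        stroke_axis = int(np.argmax(sigs[Behavior.SWIMMING].acc_amp))
        x = rec.acc[:, stroke_axis]
        f, p = periodogram(x - x.mean(), fs=20.0)
        assert abs(f[np.argmax(p)] - 1.0) <= 0.1

    def test_zero_noise_resting_is_exactly_gravity(self):
        profile = _quiet_profile(acc_noise_sd=0.0, gyro_noise_sd=0.0,
                                 pressure_noise_sd=0.0, jitter=0.0)
        script = BehaviorScript("z", [(Behavior.RESTING, 30.0)])
        rec = es.render_recording(script, profile, rng_seed=0)
        expected = np.asarray(profile.gravity)
        assert np.all(rec.acc == expected[None, :])
        assert np.all(rec.gyro == 0.0)

    def test_breathing_drives_pressure_to_surface(self):
        profile = _quiet_profile(jitter=0.0)
        script = BehaviorScript("b", [(Behavior.RESTING, 30.0),
                                      (Behavior.BREATHING, 20.0),
                                      (Behavior.RESTING, 30.0)])
        rec = es.render_recording(script, profile, rng_seed=2)
        p = rec.pressure_1hz
        assert p[30:50].min() < 0.2 * profile.depth  # reaches near-surface
        assert p[:25].min() > 0.5 * profile.depth

    def test_label_conservation(self):
        """Per-class rendered duration matches the script to within one
        sample per bout of that class."""
        profile = source_species_profile()
        script = es.sample_behavior_script(profile, 600.0, rng_seed=9)
        rec = es.render_recording(script, profile, rng_seed=9)
        n_seg = {b: sum(1 for c, _ in script.segments if c == b)
                 for b in profile.classes}
        for b, d in script.class_durations().items():
            rendered = int(np.sum(rec.labels == int(b)))
            assert abs(rendered - d * 20.0) <= n_seg[b]
        assert rec.n_samples == int(round(script.total_duration_s * 20))

    def test_render_deterministic(self):
        profile = target_species_profile()
        script = es.sample_behavior_script(profile, 120.0, rng_seed=5)
        r1 = es.render_recording(script, profile, rng_seed=6)
        r2 = es.render_recording(script, profile, rng_seed=6)
        assert np.array_equal(r1.acc, r2.acc)
        assert np.array_equal(r1.gyro, r2.gyro)
        assert np.array_equal(r1.pressure_1hz, r2.pressure_1hz)
        assert np.array_equal(r1.labels, r2.labels)

    def test_spectral_peak_classifier_separates_swim_from_rest(self):
        """Sanity floor: a trivial periodogram classifier tells 10 s
        swimming clips from resting clips with 100% accuracy, so the
        learning task is solvable from the generated signals."""
        profile = source_species_profile()
        correct = 0
        clips = []
        for seed in range(20):
            beh = Behavior.SWIMMING if seed % 2 else Behavior.RESTING
            script = BehaviorScript("c", [(beh, 10.0)])
            rec = es.render_recording(script, profile, rng_seed=100 + seed)
            clips.append((beh, rec.acc[:, 0]))
        for beh, x in clips:
            f, p = periodogram(x - x.mean(), fs=20.0)
            band = (f > 0.3) & (f < 3.0)
            is_swim = p[band].max() > 50 * np.median(p)
            correct += is_swim == (beh == Behavior.SWIMMING)
        assert correct == len(clips)


class TestStudyDatasets:
    def test_roster_counts_match_study_design(self):
        ds = es.make_study_datasets(StudyConfig(
            n_source=13, n_target=6, source_duration_s=60.0,
            target_duration_s=30.0, master_seed=0))
        assert len(ds.source) == 13
        assert len(ds.target) == 6

    def test_default_source_larger_than_target(self):
        cfg = StudyConfig()
        assert cfg.n_source > cfg.n_target
        assert cfg.source_duration_s > cfg.target_duration_s

    def test_bad_counts_rejected(self):
        with pytest.raises(es.synthetic.ConfigError):
            StudyConfig(n_source=0)

    def test_gaps_inserted(self, small_study):
        assert all(np.any(r.labels == UNLABELED) for r in small_study.source)

    def test_master_seed_reproducibility(self):
        cfg = StudyConfig(n_source=2, n_target=2, source_duration_s=60.0,
                          target_duration_s=30.0, master_seed=3)
        d1 = es.make_study_datasets(cfg)
        d2 = es.make_study_datasets(cfg)
        for a, b in zip(d1.source + d1.target, d2.source + d2.target):
            assert a.individual_id == b.individual_id
            assert np.array_equal(a.acc, b.acc)
            assert np.array_equal(a.labels, b.labels)

    def test_written_dataset_byte_identical_across_runs(self, tmp_path):
        cfg = StudyConfig(n_source=2, n_target=1, source_duration_s=30.0,
                          target_duration_s=30.0, master_seed=8)
        p1 = es.write_dataset(es.make_study_datasets(cfg), tmp_path / "a")
        p2 = es.write_dataset(es.make_study_datasets(cfg), tmp_path / "b")
        files1 = sorted(f.name for f in p1.iterdir())
        assert files1 == sorted(f.name for f in p2.iterdir())
        for name in files1:
            assert (p1 / name).read_bytes() == (p2 / name).read_bytes()
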
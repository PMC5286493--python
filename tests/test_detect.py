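import numpy as np
import pytest

from seeqrs import (
    DegenerateSignalError,
    DetectorConfig,
    ECGRecord,
    bandpass_filter,
    detect_qrs,
    generate_record,
    match_beats,
)
from seeqrs.detect import (
    apply_threshold,
    compute_threshold,
    enforce_refractory,
    localize_r_peaks,
)
from seeqrs.envelope import CandidatePeaks
from seeqrs.errors import InputError, ParameterError
from seeqrs.preprocess import FilteredSignal
from seeqrs.synthesize import SynthConfig

FS = 1000.0


def _stats_vector(mu, sigma, n=1000):
    """A vector with exactly the requested mean and population std."""
    half = np.array([-1.0, 1.0] * (n // 2))
    return mu + sigma * half


class TestThreshold:
    def test_first_branch_sigma_below_mu(self):
        v = _stats_vector(0.2, 0.1)
        assert compute_threshold(v, kappa=1.0) == pytest.approx(0.2 * (1 - 0.01))

    def test_second_branch_sigma_above_mu(self):
        v = _stats_vector(0.1, 0.5)
        assert compute_threshold(v, kappa=1.0) == pytest.approx(0.5 * (1 - 0.01))

    def test_branches_coincide_at_tie(self):
        v = _stats_vector(0.3, 0.3)
        assert compute_threshold(v, kappa=2.0) == pytest.approx(2.0 * 0.3 * (1 - 0.09))

    def test_empty_envelope_rejected(self):
        with pytest.raises(InputError):
            compute_threshold([], kappa=0.5)


class TestApplyThreshold:
    def test_strictly_greater_kept(self):
        c = CandidatePeaks(indices=[10, 20, 30], heights=[0.1, 0.9, 0.5])
        out = apply_threshold(c, 0.4)
        assert list(out.indices) == [20, 30]

    def test_threshold_above_all(self):
        c = CandidatePeaks(indices=[10, 20], heights=[0.1, 0.2])
        assert len(apply_threshold(c, 5.0)) == 0

    def test_minus_infinity_is_identity(self):
        c = CandidatePeaks(indices=[10, 20], heights=[0.1, 0.2])
        out = apply_threshold(c, -np.inf)
        assert np.array_equal(out.indices, c.indices)


class TestRefractory:
    def test_taller_wins_within_refractory(self):
        c = CandidatePeaks(indices=[100, 150], heights=[1.0, 2.0])
        out = enforce_refractory(c, 200)
        assert list(out.indices) == [150]

    def test_far_apart_both_kept(self):
        c = CandidatePeaks(indices=[100, 400], heights=[1.0, 2.0])
        out = enforce_refractory(c, 200)
        assert list(out.indices) == [100, 400]

    def test_cluster_collapses_to_global_maximum(self):
        rng = np.random.default_rng(0)
        idx = np.sort(rng.choice(np.arange(500, 650), size=5, replace=False))
        h = rng.uniform(0.5, 2.0, size=5)
        out = enforce_refractory(CandidatePeaks(indices=idx, heights=h), 200)
        assert len(out) == 1
        assert out.heights[0] == h.max()

    def test_survivors_respect_spacing(self):
        rng = np.random.default_rng(1)
        idx = np.sort(rng.choice(20_000, size=120, replace=False))
        h = rng.uniform(size=120)
        out = enforce_refractory(CandidatePeaks(indices=idx, heights=h), 250)
        if len(out) > 1:
            assert np.min(np.diff(out.indices)) >= 250


class TestLocalize:
    def test_refines_to_filtered_extremum(self):
        f = np.zeros(1000)
        f[497] = -3.0  # negative extremum; |f| localization is polarity-blind
        dets = localize_r_peaks(
            CandidatePeaks(indices=[500], heights=[1.0]),
            FilteredSignal(f=f, fs=FS),
            window=100,
        )
        assert list(dets.r_samples) == [497]

    def test_zero_window_is_identity(self):
        f = np.arange(1000, dtype=float)
        dets = localize_r_peaks(
            CandidatePeaks(indices=[100, 200], heights=[1.0, 2.0]),
            FilteredSignal(f=f, fs=FS),
            window=0,
        )
        assert list(dets.r_samples) == [100, 200]

    def test_negative_window_rejected(self):
        with pytest.raises(ParameterError):
            localize_r_peaks(
                CandidatePeaks(indices=[1], heights=[1.0]),
                FilteredSignal(f=np.zeros(10), fs=FS),
                window=-1,
            )


class TestDetectQRS:
    def test_clean_record_every_beat_within_13ms(self, clean_record, default_config):
        rec, ann = clean_record
        dets = detect_qrs(rec, cfg=default_config)
        assert len(dets) == len(ann) == 30
        for r in ann.r_samples:
            assert np.min(np.abs(dets.r_samples - r)) <= 13

    def test_flat_line_is_degenerate(self):
        rec = ECGRecord("flat", FS, ["x"], [np.zeros(5000)])
        with pytest.raises(DegenerateSignalError):
            detect_qrs(rec)

    def test_tall_sharp_t_waves_cause_no_false_positives(self, default_config):
        rec, ann = generate_record(
            SynthConfig(duration_s=30.0, t_over_r_ratio=0.8, seed=21)
        )
        dets = detect_qrs(rec, cfg=default_config)
        c = match_beats(dets, ann, tolerance=150)
        assert c.fp == 0
        assert c.fn == 0

    def test_scale_invariance_of_detection_indices(self, clean_record, default_config):
        rec, _ = clean_record
        scaled = ECGRecord(rec.record_id, rec.fs, list(rec.lead_names), 37.5 * rec.samples)
        a = detect_qrs(rec, cfg=default_config)
        b = detect_qrs(scaled, cfg=default_config)
        assert np.array_equal(a.r_samples, b.r_samples)

    def test_determinism(self, clean_record, default_config):
        rec, _ = clean_record
        a = detect_qrs(rec, cfg=default_config)
        b = detect_qrs(rec, cfg=default_config)
        assert np.array_equal(a.r_samples, b.r_samples)

    def test_detection_count_non_increasing_in_kappa(self, clean_record):
        rec, _ = clean_record
        counts = [
            len(detect_qrs(rec, cfg=DetectorConfig(kappa=k)))
            for k in (0.25, 0.5, 1.0, 2.0, 4.0, 8.0)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_refractory_spacing_holds_on_output(self, clean_record, default_config):
        rec, _ = clean_record
        dets = detect_qrs(rec, cfg=default_config)
        min_gap = int(round(default_config.refractory_s * rec.fs))
        assert np.min(np.diff(dets.r_samples)) >= min_gap


class TestDetectorConfig:
    def test_window_resolution_seconds_vs_samples(self):
        assert DetectorConfig(L=0.10).window_samples(1000.0) == 100
        assert DetectorConfig(L=80).window_samples(1000.0) == 80

    def test_invalid_values_rejected(self):
        with pytest.raises(ParameterError):
            DetectorConfig(band_low=20.0, band_high=16.0)
        with pytest.raises(ParameterError):
            DetectorConfig(kappa=-1.0)

    def test_from_json_file(self, tmp_path):
        p = tmp_path / "cfg.json"
        p.write_text('{"kappa": 0.8, "L": 0.05}')
        cfg = DetectorConfig.from_file(str(p))
        assert cfg.kappa == 0.8
        assert cfg.window_samples(1000.0) == 50

    def test_unknown_key_rejected(self, tmp_path):
        p = tmp_path / "cfg.json"
        p.write_text('{"kapa": 0.8}')
        with pytest.raises(ParameterError, match="kapa"):
            DetectorConfig.from_file(str(p))
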
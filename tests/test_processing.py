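import numpy as np
import pytest

from unfoldkit.errors import ConfigError, CorrectionError
from unfoldkit.processing import (
    CorrectedCurve,
    FilterDecision,
    ProcessingConfig,
    correct_curve,
    detect_events,
    filter_curve,
)
from unfoldkit.simulate import ForceExtensionCurve, SimulationConfig, simulate_curve


def _make_curve(force, rate=2500.0, speed=400.0, k=0.06, curve_id="t"):
    n = len(force)
    t = np.arange(1, n + 1) / rate
    return ForceExtensionCurve(
        time=t, piezo_position=speed * t, force=np.asarray(force, dtype=float),
        pulling_speed=speed, temperature=296.15, cantilever_k=k,
        sampling_rate=rate, curve_id=curve_id,
    )


from tests_support import fake_corrected as _fake_corrected  # noqa: E402


class TestCorrectCurve:
    def test_noiseless_separation_matches_truth_extension(self, clean_curve, processing_config):
        curve, truth = clean_curve
        corrected = correct_curve(curve, config=processing_config)
        for ev in truth.events:
            sep = corrected.tip_sample_separation[ev.sample_index]
            assert sep == pytest.approx(ev.extension, abs=0.1)

    def test_baseline_tilt_removed(self, processing_config):
        cfg = SimulationConfig(force_noise_sd=0.0)
        curve, _ = simulate_curve(cfg, np.random.default_rng(2), curve_id="tilt")
        tilted = ForceExtensionCurve(
            time=curve.time, piezo_position=curve.piezo_position,
            force=curve.force + 0.01 * curve.piezo_position + 3.0,
            pulling_speed=curve.pulling_speed, temperature=curve.temperature,
            cantilever_k=curve.cantilever_k, sampling_rate=curve.sampling_rate,
            curve_id="tilt",
        )
        corrected = correct_curve(tilted, config=processing_config)
        # the post-detachment tail should sit at zero force after correction
        tail = corrected.force[-200:]
        assert abs(tail.mean()) < 0.5

    def test_all_zero_trace_unusable(self, processing_config):
        curve = _make_curve(np.zeros(500))
        with pytest.raises(CorrectionError):
            correct_curve(curve, config=processing_config)

    def test_pure_noise_trace_unusable(self, processing_config):
        rng = np.random.default_rng(3)
        curve = _make_curve(rng.normal(0, 5.0, 2000))
        with pytest.raises(CorrectionError):
            correct_curve(curve, config=processing_config)


class TestDetectEvents:
    def test_noiseless_curve_yields_ruptures_plus_detachment(self, processing_config):
        cfg = SimulationConfig(force_noise_sd=0.0)
        window = processing_config.drop_window

        def drops(curve, indices):
            f = curve.force
            return [f[i] - f[i + 1:i + 1 + window].min() for i in indices]

        # pick a seed where all 9 ruptures and the detachment genuinely drop
        # by more than the detection threshold
        for seed in range(100):
            curve, truth = simulate_curve(cfg, np.random.default_rng(seed), curve_id="d")
            idx = [e.sample_index for e in truth.events]
            if truth.detachment_index is not None:
                idx = idx + [truth.detachment_index]
            if len(truth.events) == 9 and min(drops(curve, idx)) > 35.0:
                break
        else:
            pytest.fail("no qualifying curve found")
        corrected = correct_curve(curve, config=processing_config)
        events = detect_events(corrected, processing_config)
        assert len(events) == 10  # 9 unfoldings + final detachment peak
        assert all(b > a for a, b in zip(events, events[1:]))
        for detected, true_idx in zip(events, idx):
            assert abs(detected - true_idx) <= 2

    def test_flat_noise_has_no_events(self, processing_config):
        rng = np.random.default_rng(11)
        corrected = _fake_corrected(rng.normal(0, 5.0, 3000))
        assert detect_events(corrected, processing_config) == []

    def test_drop_min_must_be_positive(self):
        with pytest.raises(ConfigError):
            detect_events(_fake_corrected(np.zeros(100)), ProcessingConfig(drop_min=0.0))

    def test_one_event_per_tooth(self, processing_config):
        # a tooth with two near-equal maxima at its top is one rupture
        ramp = np.concatenate([
            np.linspace(0, 100, 200), [98, 101, 99, 100.5], np.full(200, 5.0),
        ])
        corrected = _fake_corrected(ramp)
        assert len(detect_events(corrected, processing_config)) == 1


class TestFilterCurve:
    def test_too_few_events(self, processing_config):
        corrected = _fake_corrected(np.zeros(100))
        decision = filter_curve(corrected, [10, 50], 9, processing_config)
        assert not decision.accepted and decision.reason_code == "too_few_events"

    def test_too_many_events(self, processing_config):
        corrected = _fake_corrected(np.zeros(3000))
        events = list(range(100, 1200, 100))  # 11 events, 9 domains
        decision = filter_curve(corrected, events, 9, processing_config)
        assert not decision.accepted and decision.reason_code == "too_many_events"

    def test_large_adhesion_rejected(self, processing_config):
        cfg = SimulationConfig(adhesion_artifact=True, force_noise_sd=0.0)
        curve, _ = simulate_curve(cfg, np.random.default_rng(1), curve_id="adh")
        corrected = correct_curve(curve, config=processing_config)
        events = detect_events(corrected, processing_config)
        decision = filter_curve(corrected, events, 9, processing_config)
        assert not decision.accepted and decision.reason_code == "large_adhesion"

    def test_irregular_spacing_rejected(self, processing_config):
        corrected = _fake_corrected(np.zeros(4000))
        sep = corrected.tip_sample_separation
        # find indices at separations 0,25,100,125,150 nm: one doubled gap
        targets = [10.0, 35.0, 110.0, 135.0, 160.0, 300.0]
        events = [int(np.argmin(np.abs(sep - s))) for s in targets]
        decision = filter_curve(corrected, events, 9, processing_config)
        assert not decision.accepted and decision.reason_code == "irregular_spacing"

    def test_clean_simulated_curve_accepted(self, processing_config, clean_curve):
        cfg = ProcessingConfig(fit_baseline=False)
        # regular-force construct: narrow unfolding-force distribution
        sim = SimulationConfig(pulling_speed=1600.0, detachment_force_mean="never",
                               delta_x=0.30, alpha0=1e-4)
        curve, truth = simulate_curve(sim, np.random.default_rng(8), curve_id="ok")
        corrected = correct_curve(curve, config=cfg)
        events = detect_events(corrected, cfg)
        decision = filter_curve(corrected, events, 9, cfg)
        assert decision.accepted and decision.reason_code == "ok"

    def test_decision_consistency_enforced(self):
        with pytest.raises(ValueError):
            FilterDecision(accepted=True, reason_code="too_few_events", n_events_detected=2)

    def test_filter_is_deterministic(self, processing_config, clean_curve):
        curve, _ = clean_curve
        corrected = correct_curve(curve, config=processing_config)
        events = detect_events(corrected, processing_config)
        d1 = filter_curve(corrected, events, 9, processing_config)
        d2 = filter_curve(corrected, events, 9, processing_config)
        assert d1 == d2


class TestAcceptanceRates:
    def test_clean_dataset_mostly_accepted(self):
        # narrow-force construct, no artifacts, no detachment: the filter must
        # pass nearly all curves that truly have >= 3 events
        pc = ProcessingConfig(fit_baseline=False)
        sim = SimulationConfig(pulling_speed=1600.0, detachment_force_mean="never",
                               adhesion_artifact=False, delta_x=0.30, alpha0=1e-4)
        children = np.random.SeedSequence(11).spawn(60)
        accepted = total = 0
        for child in children:
            curve, truth = simulate_curve(sim, np.random.default_rng(child), curve_id="x")
            if len(truth.events) < 3:
                continue
            total += 1
            corrected = correct_curve(curve, config=pc)
            if filter_curve(corrected, detect_events(corrected, pc), 9, pc).accepted:
                accepted += 1
        assert total > 40
        assert accepted / total >= 0.95

    def test_pure_noise_never_accepted(self, processing_config):
        rng = np.random.default_rng(21)
        accepted = 0
        for _ in range(20):
            curve = _make_curve(rng.normal(0, 5.0, 2500))
            try:
                corrected = correct_curve(curve, config=processing_config)
            except CorrectionError:
                continue  # unusable counts as not accepted
            events = detect_events(corrected, processing_config)
            if filter_curve(corrected, events, 9, processing_config).accepted:
                accepted += 1
        assert accepted == 0
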
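"""EEG chain: filtering, epoching, latency alignment, template projection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from noxsense import (EpochSet, extract_epochs, gen_template, preprocess_eeg,
                      project_template, reject_artifacts, summarise_subject,
                      woody_align)

FS = 2000.0


def _events(times, labels=None):
    return pd.DataFrame({"time_s": times,
                         "label": labels or ["experimental"] * len(times)})


class TestPreprocess:
    def test_notch_attenuates_mains(self):
        t = np.arange(0, 20, 1 / FS)
        x = np.sin(2 * np.pi * 50.0 * t)
        y = preprocess_eeg(x, FS)
        mid = slice(int(5 * FS), int(15 * FS))
        atten_db = 20 * np.log10(np.std(x[mid]) / np.std(y[mid]))
        assert atten_db >= 20.0

    def test_high_pass_removes_dc(self):
        x = np.full(int(20 * FS), 7.5)
        y = preprocess_eeg(x, FS)
        assert np.abs(y[int(5 * FS):int(15 * FS)]).max() < 0.05

    def test_stopband_mass_reduced(self, rng):
        from scipy.signal import periodogram
        x = rng.standard_normal(int(30 * FS))
        y = preprocess_eeg(x, FS)
        f, pxx_raw = periodogram(x, FS)
        _, pxx_filt = periodogram(y, FS)
        hi = f > 30.0
        assert pxx_filt[hi].sum() < 0.1 * pxx_raw[hi].sum()

    def test_low_rate_rejected(self):
        with pytest.raises(ValueError):
            preprocess_eeg(np.zeros(100), 60.0)


class TestEpochs:
    def test_constant_signal_zero_after_baseline(self):
        sig = np.full(int(30 * FS), 3.3)
        ep = extract_epochs(sig, FS, _events([10.0, 20.0]))
        np.testing.assert_allclose(ep.trials, 0.0, atol=1e-9)

    def test_index_arithmetic(self):
        sig = np.arange(int(30 * FS), dtype=float)
        ep = extract_epochs(sig, FS, _events([10.0]), baseline_correct=False)
        np.testing.assert_array_equal(ep.trials[0], np.arange(19000, 22000))
        assert ep.trials.shape[1] == 3000  # 1500 ms at 2 kHz

    def test_edge_event_flagged(self):
        sig = np.zeros(int(30 * FS))
        ep = extract_epochs(sig, FS, _events([0.1, 15.0]))
        assert not ep.accepted[0] and ep.reasons[0] == "edge"
        assert ep.accepted[1]

    def test_pre_stimulus_mean_is_zero(self, noisy_recording):
        rec = noisy_recording
        ep = extract_epochs(rec.signal, rec.sampling_rate, rec.events)
        pre = ep.trials[ep.accepted][:, :ep._pre_samples]
        np.testing.assert_allclose(pre.mean(axis=1), 0.0, atol=1e-9)


class TestArtifacts:
    def test_no_rejection_within_threshold(self):
        sig = np.zeros(int(40 * FS))
        ep = extract_epochs(sig, FS, _events([10.0, 20.0, 30.0]))
        out = reject_artifacts(ep, 100.0)
        assert out.accepted.all()

    def test_spiked_trials_counted_exactly(self, rng):
        sig = rng.normal(0, 5.0, int(60 * FS))
        times = [5.0, 15.0, 25.0, 35.0, 45.0]
        spiked = [1, 3]
        for k in spiked:
            sig[int((times[k] + 0.2) * FS)] = 500.0
        ep = extract_epochs(sig, FS, _events(times))
        out = reject_artifacts(ep, 100.0)
        assert list(np.flatnonzero(~out.accepted)) == spiked
        assert (out.reasons[~out.accepted] == "amplitude").all()


def _epochs_with_template(template, offsets_ms, amps=None, noise_sd=0.0,
                          seed=0, window=(400.0, 700.0)):
    """Build epochs embedding the template at 400 ms + offset per trial."""
    rng = np.random.default_rng(seed)
    n = len(offsets_ms)
    trials = rng.normal(0.0, noise_sd, (n, 3000))
    amps = amps if amps is not None else np.ones(n)
    for k, off in enumerate(offsets_ms):
        start = 1000 + int(round((window[0] + off) * FS / 1000.0))
        trials[k, start:start + 600] += amps[k] * template.samples
    return EpochSet(trials, FS, 500.0, 1000.0,
                    np.array(["experimental"] * n), np.ones(n, bool),
                    np.array([""] * n, object), np.zeros(n))


class TestWoody:
    def test_aligned_trial_zero_shift_unit_correlation(self, template):
        ep = _epochs_with_template(template, [0.0])
        out = woody_align(ep, template.samples, (400.0, 700.0), 50.0)
        assert out.shifts_ms[0] == 0.0
        assert not out.at_bound[0]

    def test_delayed_trial_recovers_negative_shift(self, template):
        ep = _epochs_with_template(template, [20.0], noise_sd=0.005, seed=4)
        out = woody_align(ep, template.samples, (400.0, 700.0), 50.0)
        assert abs(out.shifts_ms[0] - (-20.0)) <= 0.5

    def test_bound_clamping_flagged(self, template):
        ep = _epochs_with_template(template, [80.0])
        out = woody_align(ep, template.samples, (400.0, 700.0), 50.0)
        assert abs(out.shifts_ms[0]) == 50.0
        assert out.at_bound[0]

    def test_matches_independent_brute_force(self, template, rng):
        """Shift-for-shift agreement with an independently coded maximiser."""
        n = 60
        offs = rng.uniform(-40, 40, n)
        ep = _epochs_with_template(template, offs, noise_sd=0.02, seed=9)
        out = woody_align(ep, template.samples, (400.0, 700.0), 50.0)
        ref = template.samples
        start, J = 1800, 100  # window start sample, jitter bound in samples
        for k in range(n):
            best = None
            for d in range(-J, J + 1):
                w = ep.trials[k, start + d:start + d + 600]
                r = np.corrcoef(w, ref)[0, 1]
                key = (round(r, 12), -abs(d), -(-d))
                if best is None or key > best[0]:
                    best = (key, d)
            assert out.shifts_ms[k] == -best[1] * 1000.0 / FS

    def test_within_subject_average_mode_aligns(self, template, rng):
        offs = rng.uniform(-30, 30, 20)
        ep = _epochs_with_template(template, offs, noise_sd=0.01, seed=3)
        out = woody_align(ep, None, (400.0, 700.0), 50.0,
                          align_to="within_subject_average")
        # relative latencies recovered up to a common constant
        rel = out.shifts_ms + offs
        assert np.std(rel) * 1.0 <= 2.0  # ms

    def test_reference_length_mismatch_rejected(self, template):
        ep = _epochs_with_template(template, [0.0])
        with pytest.raises(ValueError):
            woody_align(ep, template.samples[:100], (400.0, 700.0), 50.0)


class TestProjection:
    def test_scaling_identity(self, template):
        ep = _epochs_with_template(template, [0.0], amps=[2.0])
        mags = project_template(ep, template, (400.0, 700.0))
        assert mags["magnitude"].iloc[0] == pytest.approx(2.0, abs=1e-10)

    def test_orthogonal_trial_zero(self, template):
        ep = _epochs_with_template(template, [0.0], amps=[0.0])
        tpl = template.samples
        orth = np.zeros(3000)
        v = np.roll(tpl, 300)          # same energy, near-orthogonal
        v = v - (v @ tpl) / (tpl @ tpl) * tpl   # exactly orthogonal in window
        orth[1800:2400] = v
        ep.trials[0] = orth
        mags = project_template(ep, template, (400.0, 700.0))
        assert abs(mags["magnitude"].iloc[0]) < 1e-10

    @settings(derandomize=True, max_examples=20)
    @given(a=st.floats(-3, 3), b=st.floats(-3, 3))
    def test_linearity_at_fixed_shift(self, a, b):
        template = gen_template()
        t1 = np.random.default_rng(1).normal(0, 1, 3000)
        t2 = np.random.default_rng(2).normal(0, 1, 3000)

        def mag(trial):
            ep = EpochSet(trial[None, :], FS, 500.0, 1000.0,
                          np.array(["experimental"]), np.ones(1, bool),
                          np.array([""], object), np.zeros(1))
            return project_template(ep, template, (400.0, 700.0))[
                "magnitude"].iloc[0]

        lhs = mag(a * t1 + b * t2)
        rhs = a * mag(t1) + b * mag(t2)
        assert lhs == pytest.approx(rhs, abs=1e-8)

    def test_mean_recovery_against_normal_equation_oracle(self, template, rng):
        n = 100
        ep = _epochs_with_template(template, np.zeros(n),
                                   amps=np.full(n, 0.7), noise_sd=0.02, seed=6)
        mags = project_template(ep, template, (400.0, 700.0))["magnitude"]
        # explicit one-regressor normal-equation solve per trial
        tpl = template.samples
        oracle = np.array([np.linalg.solve(
            np.array([[tpl @ tpl]]),
            np.array([ep.trials[k, 1800:2400] @ tpl]))[0] for k in range(n)])
        np.testing.assert_allclose(mags.to_numpy(), oracle, atol=1e-10)
        se = mags.std(ddof=1) / np.sqrt(n)
        assert abs(mags.mean() - 0.7) < 3 * se


class TestSummaries:
    def _mags(self, n, value=1.0, label="experimental", sid="s1"):
        return pd.DataFrame({
            "subject_id": [sid] * n, "event_label": [label] * n,
            "magnitude": [value] * n, "accepted": [True] * n,
        })

    def test_seven_trials_gives_missing_baseline(self):
        out = summarise_subject(self._mags(7))
        assert np.isnan(out["baseline_sensitivity"].iloc[0])
        assert out["n_accepted_experimental"].iloc[0] == 7

    def test_eight_trials_gives_mean(self):
        out = summarise_subject(self._mags(8, value=0.5))
        assert out["baseline_sensitivity"].iloc[0] == pytest.approx(0.5)

    def test_mean_of_decimal_ladder(self):
        df = self._mags(10)
        df["magnitude"] = np.arange(0.1, 1.05, 0.1)
        out = summarise_subject(df)
        assert out["baseline_sensitivity"].iloc[0] == pytest.approx(0.55)

    def test_rejected_trials_excluded(self):
        df = pd.concat([self._mags(9, 1.0), self._mags(3, 99.0)])
        df.iloc[9:, df.columns.get_loc("accepted")] = False
        out = summarise_subject(df)
        assert out["baseline_sensitivity"].iloc[0] == pytest.approx(1.0)
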
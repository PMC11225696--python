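"""Real-time preprocessing pipeline: filtering, rejection, re-referencing,
validity gate."""

import numpy as np
import pytest
from scipy import signal

from nbo import preproc, synth
from nbo.stimspace import ANGRY_0

CFG = preproc.PreprocessConfig()
N_TIMES = synth.EPOCH_TIMES_MS.size


def make_recording(continuous):
    onsets = 750 + 1000 * np.arange(12)
    return synth.BlockRecording(
        continuous=continuous, event_onsets=onsets, stimulus=ANGRY_0
    )


def blank_epochs(n_ch=8, value=0.0):
    return np.full((n_ch, 12, N_TIMES), float(value))


class TestSegmentFilterEpoch:
    def test_constant_offset_is_annihilated(self):
        rec = make_recording(np.full((8, 12500), 37.5))
        epochs = preproc.segment_filter_epoch(rec)
        np.testing.assert_allclose(epochs, 0.0, atol=1e-9)

    def test_baseline_window_mean_is_zero(self, noisefree_block):
        epochs = preproc.segment_filter_epoch(noisefree_block)
        base = epochs[..., CFG.baseline_slice].mean(axis=-1)
        np.testing.assert_allclose(base, 0.0, atol=1e-9)

    def test_onset_too_close_to_edge_raises(self):
        rec = make_recording(np.zeros((8, 12500)))
        rec.event_onsets[0] = 10
        with pytest.raises(ValueError):
            preproc.segment_filter_epoch(rec)

    def test_30hz_attenuated_by_designed_stopband_factor(self):
        """A 30 Hz sinusoid comes out attenuated by |H(30)|^2 (zero-phase =
        forward-backward application of the designed band-pass)."""
        fs, amp = 500, 50.0
        t = np.arange(12500) / fs
        rec = make_recording(
            np.tile(amp * np.sin(2 * np.pi * 30 * t), (8, 1))
        )
        epochs = preproc.segment_filter_epoch(rec)
        # oracle: squared magnitude of the designed filter at 30 Hz
        w, h = signal.sosfreqz(CFG.sos(), worN=[30.0], fs=fs)
        expected_amp = amp * np.abs(h[0]) ** 2
        # measure the 30 Hz amplitude by quadrature projection, away from
        # the epoch edges
        seg = epochs[0, 0, 100:400]
        tt = np.arange(seg.size) / fs
        c = seg @ np.cos(2 * np.pi * 30 * tt), seg @ np.sin(2 * np.pi * 30 * tt)
        measured = 2 * np.hypot(*c) / seg.size
        assert measured == pytest.approx(expected_amp, rel=0.15)

    def test_linearity_of_the_pipeline(self, noisefree_block):
        scaled = synth.BlockRecording(
            continuous=2.5 * noisefree_block.continuous,
            event_onsets=noisefree_block.event_onsets,
            stimulus=noisefree_block.stimulus,
        )
        a = preproc.segment_filter_epoch(noisefree_block)
        b = preproc.segment_filter_epoch(scaled)
        np.testing.assert_allclose(b, 2.5 * a, rtol=1e-9, atol=1e-9)

    def test_mirror_padding_equals_long_signal_filtering(self):
        """Filtering a mirror-padded segment matches filtering a three-fold
        longer signal that embeds the same segment centrally."""
        rng = np.random.default_rng(0)
        x = rng.normal(0, 20, 751)
        sos = CFG.sos()
        pad = x.size - 1
        via_pad = signal.sosfiltfilt(sos, preproc.mirror_pad(x, pad), padlen=0)
        centre = via_pad[pad : pad + x.size]
        # independent construction of the reflected long signal
        long = np.concatenate([x[1:][::-1], x, x[:-1][::-1]])
        oracle = signal.sosfiltfilt(sos, long, padlen=0)[pad : pad + x.size]
        assert np.max(np.abs(centre - oracle)) <= 1e-6


class TestCriteriaSelection:
    @pytest.mark.parametrize(
        "erp_min,expected_mode",
        [
            (-220.0, "less_conservative"),
            (-50.0, "default"),
            (-200.0, "default"),  # boundary: "equal to or higher" -> default
        ],
    )
    def test_selection_rule(self, erp_min, expected_mode):
        erp = np.zeros(N_TIMES)
        erp[300] = erp_min
        assert preproc.select_criteria(erp).mode == expected_mode

    def test_empty_erp_rejected(self):
        with pytest.raises(ValueError):
            preproc.select_criteria(np.array([]))

    def test_mode_fixes_both_thresholds_jointly(self):
        d = preproc.ArtifactCriteria.default()
        lc = preproc.ArtifactCriteria.less_conservative()
        assert (d.amp_threshold, d.range_threshold) == (200.0, 400.0)
        assert (lc.amp_threshold, lc.range_threshold) == (250.0, 500.0)


class TestArtifactRejection:
    def in_window_index(self):
        return CFG.interest_slice.start + 75  # ~400 ms

    def test_large_spike_invalid_under_both_criteria(self):
        epochs = blank_epochs(6, 1.0)
        epochs[0, 0, self.in_window_index()] = 300.0
        for criteria in (
            preproc.ArtifactCriteria.default(),
            preproc.ArtifactCriteria.less_conservative(),
        ):
            mask = preproc.reject_artifacts(epochs, criteria)
            assert not mask[0, 0]
            assert mask[1:].all()

    def test_range_450_split_decision(self):
        """-225..+225 uV (range 450): invalid under default, valid under the
        less conservative criteria."""
        epochs = blank_epochs(6, 1.0)
        i = self.in_window_index()
        epochs[2, 5, i] = 225.0
        epochs[2, 5, i + 10] = -225.0
        assert not preproc.reject_artifacts(
            epochs, preproc.ArtifactCriteria.default()
        )[2, 5]
        assert preproc.reject_artifacts(
            epochs, preproc.ArtifactCriteria.less_conservative()
        )[2, 5]

    def test_flat_channel_trial_invalid(self):
        epochs = blank_epochs(6, 1.0)
        epochs[3, 7, :] = 5e-5
        mask = preproc.reject_artifacts(
            epochs, preproc.ArtifactCriteria.default()
        )
        assert not mask[3, 7]

    def test_out_of_window_spike_does_not_reject(self):
        epochs = blank_epochs(6, 1.0)
        epochs[0, 0, 10] = 300.0  # inside the baseline, outside 250-800 ms
        mask = preproc.reject_artifacts(
            epochs, preproc.ArtifactCriteria.default()
        )
        assert mask.all()


class TestRereference:
    def test_constant_reference_shifts_interest_channels(self):
        epochs = blank_epochs(8)
        epochs[:6] = 3.0
        epochs[6:] = 7.0
        reref, ok = preproc.rereference(epochs)
        np.testing.assert_allclose(reref, 3.0 - 7.0)
        assert ok.all()

    def test_common_signal_cancels_exactly(self):
        rng = np.random.default_rng(1)
        common = rng.normal(0, 5, N_TIMES)
        epochs = blank_epochs(8)
        epochs[:] = common
        reref, _ = preproc.rereference(epochs)
        np.testing.assert_allclose(reref, 0.0, atol=1e-12)

    def test_antisymmetric_references_change_nothing(self):
        rng = np.random.default_rng(2)
        epochs = np.asarray(rng.normal(0, 5, (8, 12, N_TIMES)))
        epochs[7] = -epochs[6]
        reref, _ = preproc.rereference(epochs)
        np.testing.assert_allclose(reref, epochs[:6], atol=1e-12)

    def test_flat_reference_pair_flagged(self):
        epochs = blank_epochs(8, 1.0)
        epochs[6:, 4, :] = 0.0
        _, ok = preproc.rereference(epochs)
        assert not ok[4]
        assert ok[[i for i in range(12) if i != 4]].all()

    def test_rejection_runs_on_unreferenced_data(self):
        """A huge reference signal must not cause rejection: artifact
        decisions precede re-referencing."""
        epochs = blank_epochs(8, 1.0)
        epochs[6:, :, :] = 150.0  # pushes re-referenced data past -149 uV? no:
        # interest channels stay at 1 uV pre-reref; rejection sees only them
        rec_mask = preproc.reject_artifacts(
            epochs[:6], preproc.ArtifactCriteria.default()
        )
        assert rec_mask.all()
        reref, _ = preproc.rereference(epochs)
        assert np.all(reref < -100.0)  # would have been rejected post-reref


class TestValidityGate:
    @pytest.mark.parametrize(
        "n_valid,expected",
        [(12, True), (11, False), (72, True), (0, False)],
    )
    def test_threshold_at_16_percent_of_72(self, n_valid, expected):
        mask = np.zeros(72, dtype=bool)
        mask[:n_valid] = True
        block = preproc.validate_block(
            np.zeros((72, N_TIMES)), mask,
            preproc.ArtifactCriteria.default(),
        )
        assert block.is_valid is expected
        assert block.valid_fraction == pytest.approx(n_valid / 72)

    def test_zero_valid_has_no_erp(self):
        block = preproc.validate_block(
            np.zeros((72, N_TIMES)), np.zeros(72, dtype=bool),
            preproc.ArtifactCriteria.default(),
        )
        assert block.erp is None

    def test_summary_fields(self):
        mask = np.zeros(72, dtype=bool)
        mask[:20] = True
        block = preproc.validate_block(
            np.zeros((72, N_TIMES)), mask,
            preproc.ArtifactCriteria.less_conservative(),
        )
        s = block.summary()
        assert s["n_valid"] == 20
        assert s["is_valid"] is True
        assert s["criteria_mode"] == "less_conservative"

    def test_wrong_mask_length_rejected(self):
        with pytest.raises(ValueError):
            preproc.validate_block(
                np.zeros((60, N_TIMES)), np.zeros(60, dtype=bool),
                preproc.ArtifactCriteria.default(),
            )


class TestProcessBlock:
    def test_block_erp_baseline_zero_and_valid(self, noisefree_block):
        block = preproc.process_block(
            noisefree_block, preproc.ArtifactCriteria.less_conservative()
        )
        assert block.is_valid
        assert abs(block.erp[CFG.baseline_slice].mean()) < 1e-9

    def test_epochs_export_csv(self, tmp_path, noisefree_block):
        block = preproc.process_block(
            noisefree_block, preproc.ArtifactCriteria.less_conservative()
        )
        path = preproc.export_epochs_csv(block, tmp_path / "epochs.csv")
        import pandas as pd

        df = pd.read_csv(path)
        assert df.shape == (72, N_TIMES + 1)
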
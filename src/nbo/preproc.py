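"""Block-wise real-time ERP preprocessing.

From a continuous 12-trial block to a validated block-average ERP:

1. cut 1500 ms segments (-500..+1000 ms) around each stimulus onset;
2. per channel-trial: linear detrend, demean, mirror-pad by 1000 samples a
   side, zero-phase 0.1-20 Hz Butterworth band-pass;
3. crop to the -100..+800 ms epoch and subtract the -100..0 ms baseline mean;
4. reject channel-trials that are flat or exceed amplitude/range criteria
   within the 250-800 ms window of interest (artifact decisions are made on
   the *un-re-referenced* data);
5. re-reference surviving channel-trials to the P7/P8 average, trial by
   trial;
6. average the valid channel-trials into the block ERP and apply the 16 %
   validity gate (>= 12 of 72 channel-trials).

Two artifact criteria sets exist: *default* (+/-200 uV, 400 uV range) and
*less conservative* (+/-250 uV, 500 uV range).  The first block of a session
is processed under the less conservative set; if its ERP dips below -200 uV
the less conservative set is kept for the whole session, otherwise the
default set is applied from the second block on.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

from .synth import (
    BlockRecording,
    CHANNELS,
    CHANNELS_OF_INTEREST,
    EPOCH_TIMES_MS,
    N_TRIALS,
    REFERENCE_CHANNELS,
    SAMPLE_RATE,
)


@dataclass(frozen=True)
class PreprocessConfig:
    sample_rate: int = SAMPLE_RATE
    segment_window_ms: tuple[float, float] = (-500.0, 1000.0)
    pad_samples: int = 1000
    band_hz: tuple[float, float] = (0.1, 20.0)
    filter_order: int = 2  # per band edge; zero-phase via filtfilt
    epoch_window_ms: tuple[float, float] = (-100.0, 800.0)
    baseline_window_ms: tuple[float, float] = (-100.0, 0.0)
    interest_window_ms: tuple[float, float] = (250.0, 800.0)
    flat_threshold: float = 1e-4  # uV
    # a flat P7/P8 pair subtracts (at most) a constant that the baseline
    # correction removes anyway, so such trials stay valid by default; set
    # True to treat a flat reference pair as a broken electrode instead
    reject_flat_reference: bool = False
    validity_threshold: float = 0.16
    channel_trial_total: int = len(CHANNELS_OF_INTEREST) * N_TRIALS

    def sos(self) -> np.ndarray:
        return signal.butter(
            self.filter_order, self.band_hz, btype="bandpass",
            fs=self.sample_rate, output="sos",
        )

    def _ms_to_epoch_index(self, ms: float) -> int:
        step = 1000 / self.sample_rate
        return int(round((ms - self.epoch_window_ms[0]) / step))

    @property
    def interest_slice(self) -> slice:
        return slice(
            self._ms_to_epoch_index(self.interest_window_ms[0]),
            self._ms_to_epoch_index(self.interest_window_ms[1]) + 1,
        )

    @property
    def baseline_slice(self) -> slice:
        return slice(
            self._ms_to_epoch_index(self.baseline_window_ms[0]),
            self._ms_to_epoch_index(self.baseline_window_ms[1]) + 1,
        )


@dataclass(frozen=True)
class ArtifactCriteria:
    """Joint amplitude/range rejection thresholds (uV)."""

    mode: str
    amp_threshold: float
    range_threshold: float

    @classmethod
    def default(cls) -> "ArtifactCriteria":
        return cls(mode="default", amp_threshold=200.0, range_threshold=400.0)

    @classmethod
    def less_conservative(cls) -> "ArtifactCriteria":
        return cls(mode="less_conservative", amp_threshold=250.0,
                   range_threshold=500.0)

    @classmethod
    def from_mode(cls, mode: str) -> "ArtifactCriteria":
        if mode == "default":
            return cls.default()
        if mode == "less_conservative":
            return cls.less_conservative()
        raise ValueError(f"unknown criteria mode {mode!r}")


def mirror_pad(x: np.ndarray, pad: int) -> np.ndarray:
    """Even-symmetric (edge-excluding) mirror padding along the last axis."""
    return np.pad(x, [(0, 0)] * (x.ndim - 1) + [(pad, pad)], mode="reflect")


def segment_filter_epoch(
    recording: BlockRecording, config: PreprocessConfig = PreprocessConfig()
) -> np.ndarray:
    """Segment, detrend, demean, mirror-pad, band-pass filter, epoch and
    baseline-correct every channel-trial.

    Returns an array of shape ``(n_channels, n_trials, n_epoch_samples)`` on
    the -100..800 ms grid.  Raises if any onset lacks full segment support.
    """
    fs = config.sample_rate
    seg_lo = int(round(config.segment_window_ms[0] * fs / 1000))
    seg_hi = int(round(config.segment_window_ms[1] * fs / 1000))
    n_seg = seg_hi - seg_lo + 1
    n_samples = recording.continuous.shape[1]
    onsets = np.asarray(recording.event_onsets, dtype=int)
    if (onsets + seg_lo < 0).any() or (onsets + seg_hi >= n_samples).any():
        raise ValueError("stimulus onset too close to the recording edge")

    idx = onsets[:, None] + np.arange(seg_lo, seg_hi + 1)[None, :]
    segments = recording.continuous[:, idx]  # (n_ch, n_trials, n_seg)
    n_ch, n_trials, _ = segments.shape
    flat = segments.reshape(n_ch * n_trials, n_seg)

    flat = signal.detrend(flat, axis=-1, type="linear")
    flat = flat - flat.mean(axis=-1, keepdims=True)
    padded = mirror_pad(flat, config.pad_samples)
    filtered = signal.sosfiltfilt(config.sos(), padded, axis=-1, padlen=0)
    filtered = filtered[:, config.pad_samples : config.pad_samples + n_seg]

    ep_lo = int(round((config.epoch_window_ms[0] - config.segment_window_ms[0])
                      * fs / 1000))
    ep_hi = int(round((config.epoch_window_ms[1] - config.segment_window_ms[0])
                      * fs / 1000))
    epochs = filtered[:, ep_lo : ep_hi + 1]
    epochs = epochs - epochs[:, config.baseline_slice].mean(axis=-1, keepdims=True)
    return epochs.reshape(n_ch, n_trials, -1)


def reject_artifacts(
    epochs: np.ndarray,
    criteria: ArtifactCriteria,
    config: PreprocessConfig = PreprocessConfig(),
) -> np.ndarray:
    """Boolean valid mask per channel-trial.

    A channel-trial is invalid if, within the 250-800 ms window of interest,
    it is flat (max absolute amplitude below the flatness threshold), exceeds
    the amplitude threshold, or its peak-to-peak range exceeds the range
    threshold.  ``epochs`` may be any ``(..., n_trials, n_times)`` stack.
    """
    win = epochs[..., config.interest_slice]
    peak = np.abs(win).max(axis=-1)
    rng = win.max(axis=-1) - win.min(axis=-1)
    flat = peak < config.flat_threshold
    return ~(flat | (peak > criteria.amp_threshold) | (rng > criteria.range_threshold))


def rereference(
    epochs: np.ndarray, config: PreprocessConfig = PreprocessConfig()
) -> tuple[np.ndarray, np.ndarray]:
    """Subtract the trial-wise P7/P8 average from the channels of interest.

    Returns ``(rereferenced interest epochs (6, n_trials, n_times),
    reference_ok (n_trials,))`` where ``reference_ok`` is False for trials
    whose reference channels are *both* flat (those trials become invalid
    when ``config.reject_flat_reference`` is set).
    """
    n_interest = len(CHANNELS_OF_INTEREST)
    interest = epochs[:n_interest]
    refs = epochs[n_interest:]
    ref_mean = refs.mean(axis=0)  # (n_trials, n_times)
    win = refs[..., config.interest_slice]
    ref_flat = np.abs(win).max(axis=-1) < config.flat_threshold  # (2, n_trials)
    reference_ok = ~ref_flat.all(axis=0)
    return interest - ref_mean[None], reference_ok


@dataclass
class ValidatedBlock:
    """Preprocessed epochs, validity bookkeeping and the block ERP."""

    epochs: np.ndarray  # (72, n_times) re-referenced channel-trials
    valid_mask: np.ndarray  # (72,) bool
    criteria_used: ArtifactCriteria
    config: PreprocessConfig = field(default_factory=PreprocessConfig)

    @property
    def n_valid(self) -> int:
        return int(self.valid_mask.sum())

    @property
    def valid_fraction(self) -> float:
        return self.n_valid / self.config.channel_trial_total

    @property
    def is_valid(self) -> bool:
        return self.valid_fraction >= self.config.validity_threshold

    @property
    def erp(self) -> np.ndarray | None:
        """Average over valid channel-trials; None when nothing survived."""
        if self.n_valid == 0:
            return None
        return self.epochs[self.valid_mask].mean(axis=0)

    def summary(self) -> dict:
        return {
            "schema_version": 1,
            "n_valid": self.n_valid,
            "valid_fraction": self.valid_fraction,
            "is_valid": self.is_valid,
            "criteria_mode": self.criteria_used.mode,
        }


def validate_block(
    epochs: np.ndarray,
    valid_mask: np.ndarray,
    criteria: ArtifactCriteria,
    config: PreprocessConfig = PreprocessConfig(),
) -> ValidatedBlock:
    """Assemble a :class:`ValidatedBlock` from flat (72, n_times) epochs."""
    valid_mask = np.asarray(valid_mask, dtype=bool).reshape(-1)
    if valid_mask.size != config.channel_trial_total:
        raise ValueError(
            f"expected {config.channel_trial_total} channel-trials, "
            f"got {valid_mask.size}"
        )
    return ValidatedBlock(
        epochs=epochs.reshape(config.channel_trial_total, -1),
        valid_mask=valid_mask, criteria_used=criteria, config=config,
    )


def process_block(
    recording: BlockRecording,
    criteria: ArtifactCriteria,
    config: PreprocessConfig = PreprocessConfig(),
) -> ValidatedBlock:
    """The full single-block pipeline.

    Artifact rejection runs on un-re-referenced epochs; re-referencing is
    applied afterwards, trial by trial; trials whose reference pair is flat
    are invalidated.
    """
    epochs = segment_filter_epoch(recording, config)
    n_interest = len(CHANNELS_OF_INTEREST)
    mask = reject_artifacts(epochs[:n_interest], criteria, config)  # (6, n_trials)
    reref, reference_ok = rereference(epochs, config)
    if config.reject_flat_reference:
        mask = mask & reference_ok[None, :]
    return validate_block(reref, mask, criteria, config)


def select_criteria(first_block_erp: np.ndarray) -> ArtifactCriteria:
    """Choose the session's criteria from the first block's ERP.

    The first block is analysed under the less conservative set; if its most
    extreme negative excursion is below -200 uV, the less conservative set is
    kept for the session, otherwise (>= -200 uV) the default set applies.
    """
    erp = np.asarray(first_block_erp)
    if erp.size == 0:
        raise ValueError("empty ERP")
    if erp.min() < -200.0:
        return ArtifactCriteria.less_conservative()
    return ArtifactCriteria.default()


def export_epochs_csv(block: ValidatedBlock, path: str | Path) -> Path:
    """Epoch matrix as CSV: rows = channel-trials, columns = time in ms."""
    path = Path(path)
    cols = [f"{t:d}" for t in EPOCH_TIMES_MS]
    df = pd.DataFrame(block.epochs, columns=cols)
    df.insert(0, "valid", block.valid_mask.astype(int))
    df.to_csv(path, index=False, float_format="%.17g")
    return path


def write_block_summary_json(block: ValidatedBlock, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(block.summary(), indent=2))
    return path
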
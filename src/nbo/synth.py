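"""Simulated-infant EEG blocks with a programmable ground-truth Nc surface.

This module stands in for live acquisition.  Each simulated *block* is a
continuous 8-channel recording at 500 Hz containing 12 stimulus events.
Every event carries an Nc-like negative deflection on the six fronto-central
channels of interest whose depth is drawn around the infant's ground-truth
response surface at the presented grid cell, on top of white noise, an
optional common "reference" signal shared by all channels (removable by
re-referencing to P7/P8), large blink/movement transients, and occasional
flat channels.

Design notes
------------
* The deflection template is a raised-cosine (Hann) or triangular bump whose
  mean over its support is exactly ``depth / 2`` — this gives the Nc metric a
  closed-form oracle.
* P7 and P8 carry the common signal and noise but *no* Nc template, so
  re-referencing cannot cancel the target component.
* A block is a pure function of ``(profile.seed, block_index, stimulus)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .stimspace import StimulusCoord, distance_from_reference, grid

SAMPLE_RATE = 500
CHANNELS = ("Fz", "Fp1", "Fp2", "C1", "C2", "Cz", "P7", "P8")
CHANNELS_OF_INTEREST = CHANNELS[:6]
REFERENCE_CHANNELS = CHANNELS[6:]
N_TRIALS = 12

#: epoch sampling grid, closed interval -100..800 ms at 2 ms steps
EPOCH_TIMES_MS = np.arange(-100, 801, 2)
NC_WINDOW_MS = (250, 800)

_PREROLL = 750  # samples before the first onset (1.5 s)
_SPACING = 1000  # samples between onsets (2 s)
_POSTROLL = 751  # samples after the last onset


@dataclass(frozen=True)
class ResponseSurface:
    """Ground-truth expected Nc deflection depth (uV, <= 0) per grid cell."""

    values: dict[StimulusCoord, float]
    family: str = "custom"
    peak_coord: StimulusCoord | None = None
    contrast: float = 0.0

    def __post_init__(self) -> None:
        cells = set(grid())
        if set(self.values) != cells:
            raise ValueError("surface must define a value for all 16 grid cells")
        if any(v > 0 for v in self.values.values()):
            raise ValueError("surface values are deflection depths and must be <= 0")
        if self.family == "corner-peak":
            argmin = min(self.values, key=lambda c: (self.values[c], c))
            if self.peak_coord is None or argmin != self.peak_coord:
                raise ValueError("corner-peak surface must have its unique minimum "
                                 "at peak_coord")

    def __getitem__(self, coord: StimulusCoord) -> float:
        return self.values[coord]

    @property
    def argmin(self) -> StimulusCoord:
        """Cell with the deepest (most negative) expected deflection."""
        return min(self.values, key=lambda c: (self.values[c], c))


def make_surface(
    family: str,
    peak_coord: StimulusCoord | None = None,
    contrast: float = 6.0,
    baseline_depth: float = -4.0,
    emotion_slope: float = 0.0,
    gaze_slope: float = 0.0,
    values: dict[StimulusCoord, float] | None = None,
) -> ResponseSurface:
    """Construct a ground-truth response surface.

    families
    --------
    ``corner-peak``
        Deepest negativity ``baseline_depth - contrast`` at ``peak_coord``,
        decaying linearly with grid distance back to ``baseline_depth`` at
        the farthest cell.  Unique minimum by construction.
    ``plane``
        ``baseline_depth + emotion_slope * e + gaze_slope * g`` clipped at 0.
    ``flat``
        Constant ``baseline_depth``.
    ``custom``
        Use ``values`` as given.
    """
    if contrast < 0:
        raise ValueError("contrast must be >= 0")
    if baseline_depth > 0:
        raise ValueError("baseline_depth must be <= 0")
    cells = grid()
    if family == "flat":
        vals = {c: baseline_depth for c in cells}
    elif family == "plane":
        vals = {
            c: min(
                0.0,
                baseline_depth + emotion_slope * c.emotion_idx + gaze_slope * c.gaze_idx,
            )
            for c in cells
        }
    elif family == "corner-peak":
        if peak_coord is None:
            raise ValueError("corner-peak surface requires peak_coord")
        dmax = max(distance_from_reference(c, peak_coord) for c in cells)
        vals = {
            c: baseline_depth
            - contrast * (1.0 - distance_from_reference(c, peak_coord) / dmax)
            for c in cells
        }
    elif family == "custom":
        if values is None:
            raise ValueError("custom surface requires values")
        vals = dict(values)
    else:
        raise ValueError(f"unknown surface family {family!r}")
    return ResponseSurface(values=vals, family=family, peak_coord=peak_coord,
                           contrast=contrast)


def synth_epoch_template(
    depth: float,
    peak_latency_ms: float = 500.0,
    width_ms: float = 200.0,
    shape: str = "hann",
) -> np.ndarray:
    """A single-epoch Nc template on the -100..800 ms grid.

    Zero in the baseline, a single smooth negative deflection of the given
    depth centred at ``peak_latency_ms`` with support ``peak +/- width/2``
    confined to the 250-800 ms window of interest.  For both the Hann and
    the triangular shape the mean over the support equals ``depth / 2``.
    """
    if depth > 0:
        raise ValueError("depth must be <= 0 (a negative deflection)")
    lo, hi = peak_latency_ms - width_ms / 2, peak_latency_ms + width_ms / 2
    if not (NC_WINDOW_MS[0] <= peak_latency_ms <= NC_WINDOW_MS[1]):
        raise ValueError("peak latency must lie in the 250-800 ms Nc window")
    if lo < NC_WINDOW_MS[0] or hi > NC_WINDOW_MS[1]:
        raise ValueError("template support must lie within the 250-800 ms window")
    t = EPOCH_TIMES_MS.astype(float)
    wave = np.zeros_like(t)
    mask = (t >= lo) & (t <= hi)
    if shape == "hann":
        wave[mask] = depth * 0.5 * (
            1.0 + np.cos(2.0 * np.pi * (t[mask] - peak_latency_ms) / width_ms)
        )
    elif shape == "triangle":
        wave[mask] = depth * (
            1.0 - np.abs(t[mask] - peak_latency_ms) / (width_ms / 2.0)
        )
    else:
        raise ValueError(f"unknown template shape {shape!r}")
    return wave


@dataclass(frozen=True)
class InfantProfile:
    """Generative parameters for one simulated infant."""

    surface: ResponseSurface
    seed: int
    noise_sd: float = 10.0  # uV white noise per sample
    artifact_prob: float = 0.05  # per channel-trial
    flat_prob: float = 0.02  # per channel of interest, per block
    reference_noise_sd: float = 5.0  # uV common signal on all channels
    depth_jitter_frac: float = 0.1  # trial-to-trial sd as fraction of |depth|
    artifact_amp: float = 500.0  # uV transient peak
    template_peak_ms: float = 500.0
    template_width_ms: float = 200.0
    template_shape: str = "hann"

    def __post_init__(self) -> None:
        for p in (self.artifact_prob, self.flat_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.noise_sd < 0 or self.reference_noise_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")


def noise_free_profile(surface: ResponseSurface, seed: int) -> InfantProfile:
    """A deterministic infant: no noise, no artifacts, no depth jitter."""
    return InfantProfile(
        surface=surface, seed=seed, noise_sd=0.0, artifact_prob=0.0,
        flat_prob=0.0, reference_noise_sd=0.0, depth_jitter_frac=0.0,
    )


@dataclass
class BlockRecording:
    """Continuous 8-channel recording for one 12-trial block."""

    continuous: np.ndarray  # (8, n_samples) uV
    event_onsets: np.ndarray  # (12,) sample indices
    stimulus: StimulusCoord
    block_index: int = 0
    channel_labels: tuple[str, ...] = CHANNELS
    sample_rate: int = SAMPLE_RATE

    def __post_init__(self) -> None:
        if len(self.event_onsets) != N_TRIALS:
            raise ValueError(f"a block has exactly {N_TRIALS} events")


def _smooth_common_signal(rng: np.random.Generator, n: int, sd: float) -> np.ndarray:
    """Slowly varying (< ~5 Hz) signal shared by all channels."""
    if sd == 0:
        return np.zeros(n)
    knots = max(int(n / SAMPLE_RATE * 10), 4)  # a knot every 100 ms
    values = rng.normal(0.0, sd, knots)
    x = np.linspace(0, n - 1, knots)
    return np.interp(np.arange(n), x, values)


def simulate_block(
    profile: InfantProfile, stimulus: StimulusCoord, block_index: int
) -> BlockRecording:
    """Simulate one 12-trial block for a given stimulus.

    Deterministic given ``(profile.seed, block_index, stimulus)``.
    """
    rng = np.random.default_rng(
        [profile.seed, block_index, stimulus.emotion_idx, stimulus.gaze_idx]
    )
    onsets = _PREROLL + _SPACING * np.arange(N_TRIALS)
    n = int(onsets[-1]) + _POSTROLL
    data = rng.normal(0.0, profile.noise_sd, (len(CHANNELS), n)) \
        if profile.noise_sd > 0 else np.zeros((len(CHANNELS), n))

    common = _smooth_common_signal(rng, n, profile.reference_noise_sd)
    data += common[None, :]

    depth0 = profile.surface[stimulus]
    jitter_sd = profile.depth_jitter_frac * abs(depth0)
    # template samples start 50 samples (100 ms) before onset
    for i, onset in enumerate(onsets):
        depth = min(0.0, rng.normal(depth0, jitter_sd)) if jitter_sd > 0 else depth0
        template = synth_epoch_template(
            depth, profile.template_peak_ms, profile.template_width_ms,
            profile.template_shape,
        )
        sl = slice(onset - 50, onset - 50 + template.size)
        for ch in range(len(CHANNELS_OF_INTEREST)):
            data[ch, sl] += template

    # blink/movement transients: half-cosine bumps > threshold inside 250-800 ms
    half = 75 * SAMPLE_RATE // 1000  # 75 ms half-duration -> 37 samples
    for ch in range(len(CHANNELS_OF_INTEREST)):
        for onset in onsets:
            if rng.random() < profile.artifact_prob:
                centre_ms = rng.uniform(250 + 76, 800 - 76)
                c = int(onset + centre_ms * SAMPLE_RATE / 1000)
                k = np.arange(-half, half + 1)
                bump = profile.artifact_amp * 0.5 * (1 + np.cos(np.pi * k / half))
                data[ch, c - half : c + half + 1] += bump

    # flat channels: a channel of interest frozen for the whole block
    for ch in range(len(CHANNELS_OF_INTEREST)):
        if rng.random() < profile.flat_prob:
            data[ch, :] = 0.0

    return BlockRecording(
        continuous=data, event_onsets=onsets, stimulus=stimulus,
        block_index=block_index,
    )


# ---------------------------------------------------------------------------
# plain-text I/O


def write_block_csv(rec: BlockRecording, prefix: str | Path) -> tuple[Path, Path]:
    """Write a block as ``<prefix>.csv`` (one row per sample, columns =
    channels) plus an events sidecar ``<prefix>.events.csv``; lossless
    round-trip via :func:`read_block_csv`."""
    prefix = Path(prefix)
    data_path = prefix.with_suffix(".csv")
    events_path = prefix.with_suffix(".events.csv")
    df = pd.DataFrame(rec.continuous.T, columns=list(rec.channel_labels))
    # default float repr is shortest-round-trip: the CSV is lossless
    df.to_csv(data_path, index=False)
    ev = pd.DataFrame(
        {
            "onset_sample": rec.event_onsets,
            "stimulus": rec.stimulus.label,
            "block_index": rec.block_index,
        }
    )
    ev.to_csv(events_path, index=False)
    return data_path, events_path


def read_block_csv(prefix: str | Path) -> BlockRecording:
    prefix = Path(prefix)
    # round_trip parsing restores the written doubles bit-exactly
    df = pd.read_csv(prefix.with_suffix(".csv"), float_precision="round_trip")
    ev = pd.read_csv(prefix.with_suffix(".events.csv"))
    return BlockRecording(
        continuous=df.to_numpy().T,
        event_onsets=ev["onset_sample"].to_numpy(),
        stimulus=StimulusCoord.from_label(ev["stimulus"].iloc[0]),
        block_index=int(ev["block_index"].iloc[0]),
        channel_labels=tuple(df.columns),
    )


def profile_metadata(profile: InfantProfile) -> dict:
    """JSON-serialisable record of the generative parameters."""
    return {
        "schema_version": 1,
        "seed": profile.seed,
        "noise_sd": profile.noise_sd,
        "artifact_prob": profile.artifact_prob,
        "flat_prob": profile.flat_prob,
        "reference_noise_sd": profile.reference_noise_sd,
        "depth_jitter_frac": profile.depth_jitter_frac,
        "artifact_amp": profile.artifact_amp,
        "surface_family": profile.surface.family,
        "surface_values": {c.label: v for c, v in profile.surface.values.items()},
    }


def write_profile_json(profile: InfantProfile, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(profile_metadata(profile), indent=2))
    return path
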
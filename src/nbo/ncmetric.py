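"""Target brain measures computed from a block-average ERP.

The closed-loop objective is the *Nc negativity*: the sign-flipped mean
amplitude of the biggest negative deflection around the negative peak inside
the classic 250-800 ms Nc window, so that larger positive values mean
stronger negativity (stronger attentional engagement).  The deflection is
the contiguous run of strictly negative samples containing the most negative
in-window sample, clipped to the window; when the window contains no
negative sample the sign-flipped window mean is used as a fallback, keeping
the optimiser's scale uniform.

Two offline control measures accompany it: the traditional Nc mean amplitude
(signed mean over 250-800 ms) and the early-window mean (0-200 ms), which
the Nc manipulation is not expected to affect.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synth import EPOCH_TIMES_MS


@dataclass(frozen=True)
class NcWindows:
    nc_window_ms: tuple[float, float] = (250.0, 800.0)
    early_window_ms: tuple[float, float] = (0.0, 200.0)
    baseline_ms: tuple[float, float] = (-100.0, 0.0)


def _window_slice(times_ms: np.ndarray, window: tuple[float, float]) -> slice:
    lo = int(np.searchsorted(times_ms, window[0], side="left"))
    hi = int(np.searchsorted(times_ms, window[1], side="right"))
    if lo >= hi:
        raise ValueError(f"window {window} is empty on the epoch grid")
    return slice(lo, hi)


def nc_negativity(
    erp: np.ndarray,
    times_ms: np.ndarray = EPOCH_TIMES_MS,
    windows: NcWindows = NcWindows(),
) -> float:
    """Sign-flipped mean amplitude of the biggest negative deflection.

    Returns ``-mean(erp over the deflection)`` where the deflection is the
    maximal contiguous run of strictly negative samples containing the most
    negative sample of the 250-800 ms window, clipped to that window.  A flat
    negative plateau counts as a deflection.  If the window holds no negative
    sample, returns ``-mean(erp over the window)``.
    """
    erp = np.asarray(erp, dtype=float)
    sl = _window_slice(np.asarray(times_ms), windows.nc_window_ms)
    win = erp[sl]
    i_min = int(np.argmin(win))
    if win[i_min] >= 0.0:
        return float(-win.mean())
    lo = i_min
    while lo > 0 and win[lo - 1] < 0.0:
        lo -= 1
    hi = i_min
    while hi < win.size - 1 and win[hi + 1] < 0.0:
        hi += 1
    return float(-win[lo : hi + 1].mean())


def nc_mean_amplitude(
    erp: np.ndarray,
    times_ms: np.ndarray = EPOCH_TIMES_MS,
    windows: NcWindows = NcWindows(),
) -> float:
    """Traditional Nc mean amplitude: signed mean over 250-800 ms inclusive."""
    sl = _window_slice(np.asarray(times_ms), windows.nc_window_ms)
    return float(np.asarray(erp, dtype=float)[sl].mean())


def early_mean_amplitude(
    erp: np.ndarray,
    times_ms: np.ndarray = EPOCH_TIMES_MS,
    windows: NcWindows = NcWindows(),
) -> float:
    """Signed mean amplitude over the 0-200 ms control window."""
    sl = _window_slice(np.asarray(times_ms), windows.early_window_ms)
    return float(np.asarray(erp, dtype=float)[sl].mean())


def block_metrics(erp: np.ndarray) -> dict:
    """All three per-block measures, as logged per session block."""
    return {
        "nc_negativity": nc_negativity(erp),
        "nc_mean_amplitude": nc_mean_amplitude(erp),
        "early_mean_amplitude": early_mean_amplitude(erp),
    }
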
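"""HFECG extraction front end: Butterworth filter cascades and R-peak detection.

Two fixed IIR Butterworth cascades are used:

* **Filter 1** (ECG band, for R-peak detection): high-pass 0.5 Hz order 4,
  then low-pass 150 Hz order 12;
* **Filter 2** (HFECG band, the biometric feature): high-pass 40 Hz order 4,
  then low-pass 150 Hz order 12.

Both cascades are applied zero-phase (forward-backward), so the R-peak
times found on the Filter-1 path line up sample-exactly with the Filter-2
output they index into; the stated orders are the designed single-pass
orders.  R peaks are detected on the Filter-1 output with an adaptive
threshold (half the 2-second rolling maximum), a 250 ms refractory period
and positive polarity (lead-II convention).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal
from scipy.ndimage import maximum_filter1d

from .synth_ecg import ECGRecord

__all__ = [
    "FilterSpec",
    "F1_HIGHPASS",
    "F1_LOWPASS",
    "F2_HIGHPASS",
    "F2_LOWPASS",
    "RPeakList",
    "design_filter",
    "apply_filter1",
    "apply_filter2",
    "detect_r_peaks",
]

REFRACTORY_S = 0.25
EDGE_EXCLUDE_S = 0.5


@dataclass(frozen=True)
class FilterSpec:
    """One Butterworth stage (the characteristic is always Butterworth)."""

    kind: str  # "highpass" | "lowpass"
    cutoff: float  # Hz
    order: int

    def __post_init__(self) -> None:
        if self.kind not in ("highpass", "lowpass"):
            raise ValueError(f"unknown filter kind {self.kind!r}")
        if self.cutoff <= 0:
            raise ValueError("cutoff must be > 0")
        if self.order < 1:
            raise ValueError("order must be >= 1")


# Shipped presets.
F1_HIGHPASS = FilterSpec("highpass", 0.5, 4)
F1_LOWPASS = FilterSpec("lowpass", 150.0, 12)
F2_HIGHPASS = FilterSpec("highpass", 40.0, 4)
F2_LOWPASS = FilterSpec("lowpass", 150.0, 12)

_F1 = (F1_HIGHPASS, F1_LOWPASS)
_F2 = (F2_HIGHPASS, F2_LOWPASS)


@dataclass(frozen=True)
class RPeakList:
    """Detected R peaks: strictly increasing 0-based sample indices."""

    indices: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices, dtype=np.int64)
        object.__setattr__(self, "indices", idx)
        if len(idx) > 1 and not np.all(np.diff(idx) > 0):
            raise ValueError("R-peak indices must be strictly increasing")

    def __len__(self) -> int:
        return len(self.indices)

    @property
    def times(self) -> np.ndarray:
        return self.indices / self.fs


def design_filter(spec: FilterSpec, fs: float) -> np.ndarray:
    """Return second-order sections for a Butterworth stage.

    The single-pass magnitude response is -3 dB at the cutoff (Butterworth
    definition) and monotone in the stopband; all poles lie inside the
    unit circle.
    """
    if spec.cutoff >= fs / 2:
        raise ValueError(
            f"cutoff {spec.cutoff} Hz must be below the Nyquist frequency {fs / 2} Hz"
        )
    return signal.butter(spec.order, spec.cutoff, btype=spec.kind, fs=fs, output="sos")


def _as_series(record_or_series, fs: float | None):
    if isinstance(record_or_series, ECGRecord):
        return np.asarray(record_or_series.samples, dtype=float), record_or_series.fs
    if fs is None:
        raise ValueError("fs is required when passing a bare sample series")
    return np.asarray(record_or_series, dtype=float), fs


def _apply_cascade(x: np.ndarray, stages, fs: float) -> np.ndarray:
    max_order = max(s.order for s in stages)
    if len(x) < 3 * (2 * max_order):
        raise ValueError(
            f"series of {len(x)} samples is too short for a zero-phase "
            f"order-{max_order} cascade"
        )
    y = x
    for spec in stages:
        sos = design_filter(spec, fs)
        # pad by ~3 time constants of the slowest pole; the default pad is
        # far too short for the 0.5 Hz stage and leaks edge transients
        padlen = min(len(x) - 1, max(3 * (2 * spec.order + 1), int(3 * fs / spec.cutoff)))
        y = signal.sosfiltfilt(sos, y, padlen=padlen)
    return y


def apply_filter1(record_or_series, fs: float | None = None) -> np.ndarray:
    """ECG-band output (0.5–150 Hz), zero-phase; same length as input."""
    x, fs = _as_series(record_or_series, fs)
    return _apply_cascade(x, _F1, fs)


def apply_filter2(record_or_series, fs: float | None = None) -> np.ndarray:
    """HFECG-band output (40–150 Hz), zero-phase; same length as input."""
    x, fs = _as_series(record_or_series, fs)
    return _apply_cascade(x, _F2, fs)


def detect_r_peaks(filtered1: np.ndarray, fs: float) -> RPeakList:
    """Detect R peaks on a Filter-1 output series.

    Positive local maxima above 0.5x the rolling 2 s maximum of |x| are
    kept, at least 250 ms apart (larger peak wins a conflict); the first
    and last 0.5 s are excluded to avoid filter edge transients.  Each
    detection is refined to the maximum sample within +-25 ms.  A flat or
    empty series yields an empty list.
    """
    if fs <= 0:
        raise ValueError("fs must be > 0")
    x = np.asarray(filtered1, dtype=float)
    if len(x) == 0 or np.ptp(x) == 0:
        return RPeakList(np.empty(0, dtype=np.int64), fs)

    refractory = max(1, int(round(REFRACTORY_S * fs)))
    edge = int(round(EDGE_EXCLUDE_S * fs))
    win = max(1, int(round(2.0 * fs)))
    env = maximum_filter1d(np.abs(x), size=win, mode="nearest")
    thr = 0.5 * env

    cand, _ = signal.find_peaks(x, distance=refractory)
    cand = cand[(cand >= edge) & (cand < len(x) - edge)]
    cand = cand[(x[cand] > 0) & (x[cand] >= thr[cand])]

    # Refine to the maximum within +-25 ms.  Refinement runs on a 30 Hz
    # low-passed copy: broadband noise shifts the raw argmax by many
    # samples, which would de-phase the downstream synchronized averaging.
    smooth = signal.sosfiltfilt(signal.butter(4, 30.0, btype="lowpass", fs=fs, output="sos"), x)
    half = int(round(0.025 * fs))
    refined = []
    for p in cand:
        lo, hi = max(0, p - half), min(len(x), p + half + 1)
        refined.append(lo + int(np.argmax(smooth[lo:hi])))

    # Enforce the refractory period after refinement; larger peak wins.
    kept: list[int] = []
    for p in sorted(set(refined)):
        if kept and p - kept[-1] < refractory:
            if smooth[p] > smooth[kept[-1]]:
                kept[-1] = p
        else:
            kept.append(p)

    # Consistency prune: R peaks of one recording share a stable amplitude,
    # so anything far below the median kept peak (stray T waves, artifact
    # remnants) is rejected.
    if len(kept) >= 3:
        med = float(np.median(smooth[kept]))
        kept = [p for p in kept if smooth[p] >= 0.6 * med]
    return RPeakList(np.asarray(kept, dtype=np.int64), fs)
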
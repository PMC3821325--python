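"""Stage 2a — the five-landmark spike model and its 13 morphological features.

A candidate peak P is extended to five landmarks: A and B are the local
minima flanking the spike (its onset and offset), and — on a 5 Hz low-pass
filtered copy of the trial — Q is the highest point of the slow wave after
B and R its lowest point after Q.  A, P, B describe the spike portion;
B, Q, R the slow-wave portion.

From these landmarks 13 features in four families (duration, amplitude,
slope, area) are computed.  Three nested feature sets are used downstream:

* FS1 — the six conventional spike features
  (Dur_AP, Dur_PB, Amp_AP, Amp_PB, Slope_AP, Slope_PB);
* FS2 — FS1 plus the three slow-wave features
  (Dur_slowwave, Amp_slowwave, Area_slowwave);
* FS3 — FS2 plus four composite spike features
  (Dur_spike, Amp_spike, Slope_sharpness, Area_spike).

Durations are in samples, amplitudes in normalized units; areas are the
signed area between the waveform and the chord joining the segment's
endpoints, which makes them baseline-independent and zero for a flat
segment.  Spike features are read from the normalized signal; slow-wave
features are read from the filtered signal on which Q and R were located.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .io import Trial

__all__ = [
    "FeaturePoints",
    "FeatureVector",
    "FEATURE_SETS",
    "locate_spike_bounds",
    "lowpass_slow",
    "locate_slow_wave",
    "locate_feature_points",
    "extract_features",
    "select_features",
]


@dataclass(frozen=True)
class FeaturePoints:
    """Landmark indices and signal values for one candidate.

    ``a/p/b`` values are read from the normalized signal, ``q/r`` values
    from the 5 Hz low-pass filtered signal used to locate them.
    ``truncated`` flags candidates whose slow-wave search window was cut
    short by the trial end.
    """

    a_idx: int
    p_idx: int
    b_idx: int
    q_idx: int
    r_idx: int
    a_val: float
    p_val: float
    b_val: float
    q_val: float
    r_val: float
    truncated: bool = False

    def __post_init__(self) -> None:
        if not (self.a_idx < self.p_idx < self.b_idx <= self.q_idx < self.r_idx):
            raise ValueError(
                "landmark ordering violated: require A < P < B <= Q < R, got "
                f"{(self.a_idx, self.p_idx, self.b_idx, self.q_idx, self.r_idx)}"
            )
        if self.p_val < self.a_val or self.p_val < self.b_val:
            raise ValueError("P must be the spike peak (p_val >= a_val, b_val)")


@dataclass(frozen=True)
class FeatureVector:
    """The 13 morphological features of one candidate."""

    dur_ap: float
    dur_pb: float
    dur_spike: float
    dur_slowwave: float
    amp_ap: float
    amp_pb: float
    amp_spike: float
    amp_slowwave: float
    slope_ap: float
    slope_pb: float
    slope_sharpness: float
    area_spike: float
    area_slowwave: float


#: Ordered feature names of the nested feature sets.
FEATURE_SETS: dict[str, tuple[str, ...]] = {
    "FS1": ("dur_ap", "dur_pb", "amp_ap", "amp_pb", "slope_ap", "slope_pb"),
}
FEATURE_SETS["FS2"] = FEATURE_SETS["FS1"] + ("dur_slowwave", "amp_slowwave", "area_slowwave")
FEATURE_SETS["FS3"] = FEATURE_SETS["FS2"] + (
    "dur_spike",
    "amp_spike",
    "slope_sharpness",
    "area_spike",
)


def locate_spike_bounds(x: np.ndarray, p_idx: int) -> tuple[int, int]:
    """Find the local minima A (left) and B (right) flanking the peak P.

    Walking outward from P, the walk stops at the first turning point — the
    nearest sample at which the signal stops descending away from the peak
    (a flat neighbour counts as a turning point).  If the walk reaches the
    trial edge without turning, the spike is unbounded.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if p_idx <= 0 or p_idx >= n - 1:
        raise ValueError("peak at or within 1 sample of the trial edge")
    if not (x[p_idx - 1] < x[p_idx] >= x[p_idx + 1]):
        raise ValueError(f"index {p_idx} is not an upward peak")
    a = p_idx
    while a > 0 and x[a - 1] < x[a]:
        a -= 1
    b = p_idx
    while b < n - 1 and x[b + 1] < x[b]:
        b += 1
    if b == p_idx:  # flat plateau to the right of the peak
        raise ValueError("unbounded spike: peak has no descending right limb")
    if a == 0 or b == n - 1:
        raise ValueError("unbounded spike: no flanking minimum before trial edge")
    return a, b


def lowpass_slow(trial: Trial, cutoff_hz: float = 5.0, order: int = 4) -> Trial:
    """Zero-phase Butterworth low-pass used to isolate the slow-wave band.

    Zero-phase (forward-backward) filtering preserves landmark timing.
    """
    if not 0 < cutoff_hz < trial.fs / 2:
        raise ValueError(
            f"cutoff must lie in (0, Nyquist)=(0, {trial.fs / 2}), got {cutoff_hz}"
        )
    sos = butter(order, cutoff_hz, btype="low", fs=trial.fs, output="sos")
    y = sosfiltfilt(sos, trial.samples)
    return Trial(y, fs=trial.fs, trial_id=trial.trial_id, channel=trial.channel)


def locate_slow_wave(
    x_filtered: np.ndarray, p_idx: int, b_idx: int, max_window: int
) -> tuple[int, int, bool]:
    """Locate the slow-wave peak Q and end R on the filtered signal.

    Q is the highest point on (B, B + max_window) — the last window sample
    is excluded so that R always has room — and R the lowest point on
    (Q, B + max_window]; ties go to the earliest index and the window is
    truncated at the trial end (the returned flag reports truncation).
    """
    xf = np.asarray(x_filtered, dtype=float)
    n = xf.size
    if max_window < 2:
        raise ValueError("max_window must be >= 2")
    if b_idx >= n - 2:
        raise ValueError("no slow-wave room: B within 2 samples of the trial end")
    end = min(b_idx + max_window, n - 1)
    truncated = b_idx + max_window > n - 1
    q_idx = b_idx + 1 + int(np.argmax(xf[b_idx + 1 : end]))
    r_idx = q_idx + 1 + int(np.argmin(xf[q_idx + 1 : end + 1]))
    return q_idx, r_idx, truncated


def locate_feature_points(
    x: np.ndarray,
    x_filtered: np.ndarray,
    p_idx: int,
    max_window: int,
) -> FeaturePoints:
    """Locate all five landmarks around a candidate peak.

    ``x`` is the normalized trial, ``x_filtered`` its slow-band copy;
    ``max_window`` bounds the slow-wave search in samples.
    """
    a_idx, b_idx = locate_spike_bounds(x, p_idx)
    q_idx, r_idx, truncated = locate_slow_wave(x_filtered, p_idx, b_idx, max_window)
    return FeaturePoints(
        a_idx=a_idx,
        p_idx=p_idx,
        b_idx=b_idx,
        q_idx=q_idx,
        r_idx=r_idx,
        a_val=float(x[a_idx]),
        p_val=float(x[p_idx]),
        b_val=float(x[b_idx]),
        q_val=float(x_filtered[q_idx]),
        r_val=float(x_filtered[r_idx]),
        truncated=truncated,
    )


def _chord_excess_area(y: np.ndarray, lo: int, hi: int) -> float:
    """Trapezoidal integral of y over [lo, hi] minus the chord trapezoid."""
    seg = y[lo : hi + 1]
    chord = (y[lo] + y[hi]) / 2.0 * (hi - lo)
    return float(np.trapezoid(seg) - chord)


def extract_features(
    x: np.ndarray, pts: FeaturePoints, x_filtered: np.ndarray | None = None
) -> FeatureVector:
    """Compute the 13 morphological features from the five landmarks.

    Slow-wave amplitudes and areas are read from ``x_filtered`` when given
    (the signal on which Q and R were located); otherwise from ``x``.
    """
    x = np.asarray(x, dtype=float)
    xf = x if x_filtered is None else np.asarray(x_filtered, dtype=float)

    dur_ap = float(pts.p_idx - pts.a_idx)
    dur_pb = float(pts.b_idx - pts.p_idx)
    dur_spike = dur_ap + dur_pb
    dur_slowwave = float((pts.q_idx - pts.b_idx) + (pts.r_idx - pts.q_idx))

    amp_ap = pts.p_val - pts.a_val
    amp_pb = pts.p_val - pts.b_val
    amp_spike = (amp_ap + amp_pb) / 2.0
    b_val_f = float(xf[pts.b_idx])
    amp_slowwave = ((pts.q_val - b_val_f) + (pts.q_val - pts.r_val)) / 2.0

    slope_ap = amp_ap / dur_ap
    slope_pb = -amp_pb / dur_pb
    slope_sharpness = slope_ap - slope_pb

    area_spike = _chord_excess_area(x, pts.a_idx, pts.b_idx)
    area_slowwave = _chord_excess_area(xf, pts.b_idx, pts.r_idx)

    return FeatureVector(
        dur_ap=dur_ap,
        dur_pb=dur_pb,
        dur_spike=dur_spike,
        dur_slowwave=dur_slowwave,
        amp_ap=amp_ap,
        amp_pb=amp_pb,
        amp_spike=amp_spike,
        amp_slowwave=amp_slowwave,
        slope_ap=slope_ap,
        slope_pb=slope_pb,
        slope_sharpness=slope_sharpness,
        area_spike=area_spike,
        area_slowwave=area_slowwave,
    )


def select_features(fv: FeatureVector, which: str) -> np.ndarray:
    """Return the ordered numeric vector of feature set FS1, FS2 or FS3."""
    if which not in FEATURE_SETS:
        raise ValueError(f"unknown feature set {which!r}; expected one of {list(FEATURE_SETS)}")
    return np.array([getattr(fv, name) for name in FEATURE_SETS[which]], dtype=float)
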
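"""Synthetic single-channel EEG with ground-truth epileptiform events.

The generator emulates the statistical structure the detector assumes:

* **Background** — an amplitude-stable dominant rhythm (theta, default
  6.5 Hz) with a slowly wandering phase, riding on a weak band-limited
  (1–70 Hz) 1/f broadband floor.  Real scalp rhythms are far more
  amplitude-stable than Gaussian narrowband noise, and the split gives the
  two background properties independent handles: the rhythm sets the
  visible oscillation but — sitting where the k = 3 energy operator's gain
  sin²(kω) is small and having no envelope excursions — contributes no
  threshold crossings, while the floor share (default 0.2 of the variance)
  is calibrated so the smoothed k-NEO of pure background crosses the
  default threshold T = 1.8 roughly every other 10-s trial.  Background
  fluctuations then supply non-spike candidates in about the proportion of
  the three pattern classes (42 : 100 : 111) the classifier is meant to
  see, while the sub-5 Hz background component stays small enough
  (≈ 0.3 SD) for injected slow waves to stand out in the slow band.
* **Spikes** — pointed biphasic transients of 20–70 ms, modelled as
  asymmetric triangles (rise faster than fall, so the two half-wave slopes
  differ generically), with peak amplitude 4–8 background SDs.
* **Slow waves** — half-sine bumps of 150–500 ms and 1–3 background SDs,
  appended immediately after the spike's falling limb so that the spike
  offset B is shared between spike and slow wave.

Every level is deterministic under its seed; per-trial seeds are spawned
from the dataset seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np

from .io import EventAnnotation, Trial

__all__ = [
    "SimConfig",
    "gen_background",
    "gen_spike_waveform",
    "gen_slow_wave",
    "gen_trial",
    "gen_dataset",
    "write_dataset",
]

#: class name used for background-only trials (they carry no annotation)
NORMAL = "normal"
_CLASSES = ("single_spike", "spike_slow_wave", NORMAL)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions of the synthetic experiment.

    Durations are in ms, amplitudes in multiples of the background SD.
    The class sizes default to the 42 / 100 / 111 proportions of the
    three candidate classes.
    """

    fs: float = 256.0
    trial_seconds: float = 10.0
    n_single: int = 42
    n_slow: int = 100
    n_normal: int = 111
    spike_dur_ms: tuple[float, float] = (20.0, 70.0)
    spike_amp: tuple[float, float] = (5.0, 8.0)
    slow_dur_ms: tuple[float, float] = (150.0, 500.0)
    slow_amp: tuple[float, float] = (1.0, 3.0)
    events_per_trial: tuple[int, int] = (1, 1)
    bg_band_hz: tuple[float, float] = (1.0, 70.0)
    bg_rhythm_hz: float = 6.5
    bg_phase_jitter: float = 0.06
    bg_floor_share: float = 0.2
    bg_floor_exponent: float = 1.0
    bg_rms: float = 20.0
    edge_margin_s: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs * self.trial_seconds < 256:
            raise ValueError("trial must hold at least 256 samples")
        for lo, hi in (self.spike_dur_ms, self.slow_dur_ms):
            if not 0 < lo <= hi < 1000:
                raise ValueError("duration ranges must lie within (0, 1000) ms")
        for lo, hi in (self.spike_amp, self.slow_amp):
            if not 0 < lo <= hi:
                raise ValueError("amplitude ranges must be positive")
        if not 0 < self.bg_band_hz[0] < self.bg_band_hz[1] < self.fs / 2:
            raise ValueError("background band must lie inside (0, Nyquist)")
        if not 0.0 <= self.bg_floor_share <= 1.0:
            raise ValueError("bg_floor_share must lie in [0, 1]")
        if not self.bg_band_hz[0] < self.bg_rhythm_hz < self.bg_band_hz[1]:
            raise ValueError("bg_rhythm_hz must lie inside the background band")

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * self.trial_seconds))


def gen_background(cfg: SimConfig, seed: int, trial_id: str = "bg") -> Trial:
    """Band-limited stochastic background, zero mean, SD = ``cfg.bg_rms``.

    Sum of an amplitude-stable cosine rhythm at ``bg_rhythm_hz`` whose phase
    performs a slow random walk (``bg_phase_jitter`` rad/sample), and a
    broadband 1/f^α floor synthesized in the frequency domain with hard
    band edges, so the out-of-band floor power is exactly nil.  The two
    components are mixed so the floor carries ``bg_floor_share`` of the
    variance.
    """
    n = cfg.n_samples
    rng = np.random.default_rng(seed)
    t = np.arange(n)
    phase = 2.0 * np.pi * cfg.bg_rhythm_hz * t / cfg.fs + np.cumsum(
        rng.normal(0.0, cfg.bg_phase_jitter, n)
    )
    rhythm = np.sqrt(2.0) * np.cos(phase)  # unit variance
    freqs = np.fft.rfftfreq(n, 1.0 / cfg.fs)
    shape = np.zeros_like(freqs)
    band = (freqs >= cfg.bg_band_hz[0]) & (freqs <= cfg.bg_band_hz[1])
    shape[band] = freqs[band] ** (-cfg.bg_floor_exponent / 2.0)
    spec = (rng.standard_normal(freqs.size) + 1j * rng.standard_normal(freqs.size)) * shape
    floor = np.fft.irfft(spec, n)
    floor /= floor.std()
    x = np.sqrt(1.0 - cfg.bg_floor_share) * rhythm + np.sqrt(cfg.bg_floor_share) * floor
    x = (x - x.mean()) / x.std() * cfg.bg_rms
    return Trial(x, fs=cfg.fs, trial_id=trial_id)


def _n_support(dur_ms: float, fs: float) -> int:
    return max(5, int(round(dur_ms / 1000.0 * fs)))


def gen_spike_waveform(
    dur_ms: float, amp: float, fs: float, rise_frac: float = 0.4
) -> np.ndarray:
    """Pointed biphasic transient: an asymmetric triangle.

    Starts and ends at zero, has a single maximum of exactly ``amp`` and a
    support of ≈ dur_ms·fs/1000 samples; the rising limb occupies
    ``rise_frac`` of the duration (rise steeper than fall).
    """
    if not 0 < dur_ms < 1000:
        raise ValueError(f"spike duration out of range: {dur_ms} ms")
    if amp <= 0:
        raise ValueError("amplitude must be positive")
    n = _n_support(dur_ms, fs)
    peak = int(np.clip(round(rise_frac * (n - 1)), 1, n - 2))
    idx = np.arange(n, dtype=float)
    return np.interp(idx, [0.0, float(peak), float(n - 1)], [0.0, amp, 0.0])


def gen_slow_wave(dur_ms: float, amp: float, fs: float) -> np.ndarray:
    """Smooth unimodal bump: a half-sine of duration dur_ms peaking at amp.

    For the default 150–500 ms durations the dominant frequency
    (1000/(2·dur_ms) Hz) lies below ~3.3 Hz, inside the slow-wave band.
    """
    if not 0 < dur_ms < 1000:
        raise ValueError(f"slow-wave duration out of range: {dur_ms} ms")
    if amp <= 0:
        raise ValueError("amplitude must be positive")
    n = _n_support(dur_ms, fs)
    n += 1 - n % 2  # odd support so the peak sample equals amp exactly
    return amp * np.sin(np.linspace(0.0, np.pi, n))


def gen_trial(
    cls: str, cfg: SimConfig, seed: int, trial_id: str | None = None
) -> tuple[Trial, list[EventAnnotation]]:
    """One annotated trial of the given class.

    Spike classes get 1–2 injected events (``cfg.events_per_trial``), each
    kept ≥ ``cfg.edge_margin_s`` from the trial edges and ≥ 1 s apart; for
    ``spike_slow_wave`` the slow wave begins at the spike's last (zero)
    sample, sharing the offset point B.  ``normal`` trials are background
    only and carry no annotations.
    """
    if cls not in _CLASSES:
        raise ValueError(f"unknown class {cls!r}; expected one of {_CLASSES}")
    if trial_id is None:
        trial_id = f"{cls}_{seed}"
    rng = np.random.default_rng(seed)
    bg_seed = int(rng.integers(0, 2**31))
    trial = gen_background(cfg, bg_seed, trial_id=trial_id)
    x = trial.samples.copy()
    events: list[EventAnnotation] = []
    if cls != NORMAL:
        lo, hi = cfg.events_per_trial
        n_events = int(rng.integers(lo, hi + 1))
        margin = int(round(cfg.edge_margin_s * cfg.fs))
        min_gap = int(round(1.0 * cfg.fs))
        starts: list[int] = []
        for _ in range(n_events):
            for _attempt in range(1000):
                start = int(rng.integers(margin, x.size - margin))
                if all(abs(start - s) >= min_gap for s in starts):
                    starts.append(start)
                    break
            else:  # pragma: no cover - margin leaves ample room
                raise RuntimeError("could not place events with the required spacing")
        for start in sorted(starts):
            dur = rng.uniform(*cfg.spike_dur_ms)
            amp = rng.uniform(*cfg.spike_amp) * cfg.bg_rms
            spike = gen_spike_waveform(dur, amp, cfg.fs)
            x[start : start + spike.size] += spike
            peak_index = start + int(np.argmax(spike))
            if cls == "spike_slow_wave":
                sdur = rng.uniform(*cfg.slow_dur_ms)
                samp = rng.uniform(*cfg.slow_amp) * cfg.bg_rms
                slow = gen_slow_wave(sdur, samp, cfg.fs)
                b_point = start + spike.size - 1  # spike offset, shared with the slow wave
                stop = min(b_point + slow.size, x.size)
                x[b_point:stop] += slow[: stop - b_point]
            events.append(EventAnnotation(trial_id, peak_index, cls))
    return Trial(x, fs=cfg.fs, trial_id=trial_id), events


def gen_dataset(
    cfg: SimConfig,
) -> tuple[list[Trial], list[EventAnnotation], dict]:
    """The full annotated dataset: per-class trials plus a manifest.

    Per-trial seeds are spawned deterministically from ``cfg.seed``, so the
    dataset (and its manifest) is byte-identical across runs with the same
    configuration.
    """
    plan = (
        [("single_spike", i) for i in range(cfg.n_single)]
        + [("spike_slow_wave", i) for i in range(cfg.n_slow)]
        + [(NORMAL, i) for i in range(cfg.n_normal)]
    )
    trial_seeds = np.random.SeedSequence(cfg.seed).generate_state(len(plan)) % (2**31)
    trials: list[Trial] = []
    annotations: list[EventAnnotation] = []
    manifest_rows = []
    for (cls, i), tseed in zip(plan, trial_seeds):
        trial_id = f"{cls}_{i:03d}"
        trial, events = gen_trial(cls, cfg, int(tseed), trial_id=trial_id)
        trials.append(trial)
        annotations.extend(events)
        manifest_rows.append({"trial_id": trial_id, "class": cls, "seed": int(tseed)})
    manifest = {"config": asdict(cfg), "trials": manifest_rows}
    return trials, annotations, manifest


def write_dataset(
    trials: list[Trial],
    annotations: list[EventAnnotation],
    manifest: dict,
    out_dir: str | Path,
) -> None:
    """Write trials as CSV, annotations as TSV and the manifest as JSON."""
    from .io import write_annotations, write_trial

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for trial in trials:
        write_trial(trial, out / f"{trial.trial_id}.csv")
    write_annotations(annotations, out / "annotations.tsv")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
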
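"""Trial and annotation I/O plus run configuration.

A *trial* is a fixed-length excerpt of a single EEG channel — the unit of
review, normalization and detection.  Trials are stored as plain text
(one sample per row, comma- or whitespace-delimited) or read from EDF
recordings one channel at a time.  Event annotations (ground truth or
predictions) are tab-delimited tables of (trial_id, peak_index, label).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: The three pattern classes of the classification stage.
LABELS3 = ("single_spike", "spike_slow_wave", "non_spike")

#: Labels of the merged (two-class) problem.
LABELS2 = ("spike", "non_spike")

ANNOTATION_COLUMNS = ("trial_id", "peak_index", "label")


@dataclass(frozen=True)
class Trial:
    """One channel of sampled EEG.

    Parameters
    ----------
    samples : array-like of float
        Sampled potentials, arbitrary units (µV typical).
    fs : float
        Sampling rate in Hz; must be positive and finite.
    trial_id : str
        Identifier used to join trials with annotations.
    channel : str
        Electrode label in the 10–20 system (e.g. ``"Fp1"``).
    """

    samples: np.ndarray
    fs: float
    trial_id: str = ""
    channel: str = ""

    def __post_init__(self) -> None:
        x = np.asarray(self.samples, dtype=float)
        if x.ndim != 1 or x.size == 0:
            raise ValueError("empty signal")
        if not np.all(np.isfinite(x)):
            raise ValueError("trial contains non-finite samples")
        if not (math.isfinite(self.fs) and self.fs > 0):
            raise ValueError(f"sampling rate must be positive and finite, got {self.fs}")
        object.__setattr__(self, "samples", x)

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        return len(self) / self.fs


@dataclass(frozen=True, order=True)
class EventAnnotation:
    """A labelled event peak inside one trial (0-based sample index)."""

    trial_id: str
    peak_index: int
    label: str

    def __post_init__(self) -> None:
        if self.peak_index < 0:
            raise ValueError("peak_index must be non-negative")


@dataclass
class RunConfig:
    """Parameters shared by every stage of the pipeline.

    Defaults are the operating point used throughout: ``k=3`` matches the
    2.56–8.96 sample half-width range implied by 20–70 ms spikes at 256 Hz,
    ``T=1.8`` is the detection threshold on the smoothed energy of the
    z-normalized trial, and the 5 Hz low-pass isolates the slow-wave band.
    """

    k: int = 3
    T: float = 1.8
    slow_cutoff_hz: float = 5.0
    slow_window_s: float = 1.0
    rounds: int = 100
    max_depth: int = 1
    folds: int = 4
    repeats: int = 10
    match_tol: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if not self.T > 0:
            raise ValueError("threshold T must be > 0")
        if not self.slow_cutoff_hz > 0:
            raise ValueError("slow_cutoff_hz must be > 0")
        if self.rounds < 1 or self.folds < 2 or self.repeats < 1:
            raise ValueError("rounds >= 1, folds >= 2 and repeats >= 1 required")


def load_config(path: str | Path) -> RunConfig:
    """Read a flat ``key=value`` config file; unknown keys are rejected."""
    known = {f.name: f.type for f in fields(RunConfig)}
    kwargs: dict = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected key=value, got {raw!r}")
        key, value = (s.strip() for s in line.split("=", 1))
        if key not in known:
            raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
        caster = {"int": int, "float": float}.get(known[key], str)
        kwargs[key] = caster(value)
    return RunConfig(**kwargs)


def save_config(cfg: RunConfig, path: str | Path) -> None:
    lines = [f"{k}={v}" for k, v in asdict(cfg).items()]
    Path(path).write_text("\n".join(lines) + "\n")


def _read_csv_samples(path: Path) -> np.ndarray:
    values: list[float] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line:
                continue
            token = line.replace(",", " ").split()[0]
            try:
                values.append(float(token))
            except ValueError:
                if lineno == 1:  # optional single header line
                    continue
                raise ValueError(f"{path}:{lineno}: non-numeric row {raw!r}") from None
    if not values:
        raise ValueError(f"{path}: empty signal")
    return np.asarray(values)


def read_trial(
    path: str | Path,
    fs: float | None = None,
    format: str = "csv",
    channel: str | None = None,
    trial_id: str | None = None,
) -> Trial:
    """Read a single-channel trial from a delimited text file or EDF.

    For ``format="csv"`` the file holds one sample per row (an optional
    header line is skipped) and ``fs`` must be supplied.  For
    ``format="edf"`` the named ``channel`` is extracted and the sampling
    rate is taken from the EDF header.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if trial_id is None:
        trial_id = path.stem
    if format == "csv":
        if fs is None:
            raise ValueError("fs is required for csv input")
        return Trial(_read_csv_samples(path), fs=fs, trial_id=trial_id, channel=channel or "")
    if format == "edf":
        return _read_edf_channel(path, channel, trial_id)
    raise ValueError(f"unknown format {format!r}")


def _read_edf_channel(path: Path, channel: str | None, trial_id: str) -> Trial:
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise ImportError("EDF support requires the 'mne' package") from exc
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    if channel is None:
        if len(raw.ch_names) != 1:
            raise ValueError(
                f"EDF has {len(raw.ch_names)} channels; a channel name is required"
            )
        channel = raw.ch_names[0]
    if channel not in raw.ch_names:
        raise ValueError(f"unknown channel {channel!r}; available: {raw.ch_names}")
    data = raw.get_data(picks=[channel])[0]
    return Trial(data, fs=float(raw.info["sfreq"]), trial_id=trial_id, channel=channel)


def write_trial(trial: Trial, path: str | Path) -> None:
    """Write one sample per row with full float precision (lossless round-trip)."""
    np.savetxt(path, trial.samples, fmt="%.17g")


def write_annotations(events: Iterable[EventAnnotation], path: str | Path) -> None:
    """Write a TSV of events sorted by (trial_id, peak_index)."""
    rows = sorted(events, key=lambda e: (e.trial_id, e.peak_index))
    df = pd.DataFrame(
        [(e.trial_id, e.peak_index, e.label) for e in rows],
        columns=list(ANNOTATION_COLUMNS),
    )
    df.to_csv(path, sep="\t", index=False)


def read_annotations(path: str | Path) -> list[EventAnnotation]:
    df = pd.read_csv(path, sep="\t", dtype={"trial_id": str})
    missing = set(ANNOTATION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"annotation file missing columns: {sorted(missing)}")
    return [
        EventAnnotation(str(r.trial_id), int(r.peak_index), str(r.label))
        for r in df.itertuples()
    ]
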
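"""End-to-end plumbing: detect candidates, label them against annotations,
and build the feature table the classifier consumes.

A detected candidate is given the label of the nearest annotated event in
its trial within ``match_tol`` samples; unmatched candidates — background
fluctuations that crossed the detection threshold — become ``non_spike``
examples, exactly the negatives the second stage is meant to reject.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .detect import CandidatePoint, detect_candidates, normalize_trial
from .features import FEATURE_SETS, extract_features, locate_feature_points, lowpass_slow
from .io import EventAnnotation, RunConfig, Trial

__all__ = [
    "extract_candidate_features",
    "build_feature_table",
    "recovery_rate",
]

FEATURE_COLUMNS = FEATURE_SETS["FS3"]  # all 13, in the documented order


def extract_candidate_features(
    trial: Trial, candidates: Sequence[CandidatePoint], cfg: RunConfig | None = None
) -> pd.DataFrame:
    """Feature rows for the candidates of one trial.

    Candidates whose landmarks cannot be established (peak unbounded at a
    trial edge, or no room for a slow-wave window) are dropped and counted
    in the ``n_dropped`` attribute of the returned frame; candidates whose
    slow-wave window was merely truncated by the trial end are kept and
    flagged.
    """
    cfg = cfg or RunConfig()
    z = normalize_trial(trial)
    zf = lowpass_slow(z, cfg.slow_cutoff_hz)
    max_window = int(round(cfg.slow_window_s * trial.fs))
    rows = []
    n_dropped = 0
    for cand in candidates:
        try:
            pts = locate_feature_points(z.samples, zf.samples, cand.peak_index, max_window)
            fv = extract_features(z.samples, pts, zf.samples)
        except ValueError:
            n_dropped += 1
            continue
        row = {"trial_id": trial.trial_id, "peak_index": cand.peak_index}
        row.update({name: getattr(fv, name) for name in FEATURE_COLUMNS})
        row["truncated"] = pts.truncated
        rows.append(row)
    df = pd.DataFrame(rows, columns=["trial_id", "peak_index", *FEATURE_COLUMNS, "truncated"])
    df.attrs["n_dropped"] = n_dropped
    return df


def _label_candidates(
    df: pd.DataFrame, annotations: Iterable[EventAnnotation], match_tol: int
) -> pd.Series:
    by_trial: dict[str, list[EventAnnotation]] = {}
    for ann in annotations:
        by_trial.setdefault(ann.trial_id, []).append(ann)
    labels = []
    for row in df.itertuples():
        anns = by_trial.get(row.trial_id, [])
        label = "non_spike"
        best = match_tol + 1
        for ann in anns:
            d = abs(ann.peak_index - row.peak_index)
            if d <= match_tol and d < best:
                best, label = d, ann.label
        labels.append(label)
    return pd.Series(labels, index=df.index, name="label")


def build_feature_table(
    trials: Iterable[Trial],
    annotations: Iterable[EventAnnotation],
    cfg: RunConfig | None = None,
) -> pd.DataFrame:
    """Detect, extract and label candidates over a whole dataset.

    Returns one row per candidate with the 13 features, the matched class
    label, and the truncation flag.
    """
    cfg = cfg or RunConfig()
    annotations = list(annotations)
    frames = []
    for trial in trials:
        cands = detect_candidates(trial, cfg)
        if not cands:
            continue
        frame = extract_candidate_features(trial, cands, cfg)
        if not frame.empty:
            frames.append(frame)
    if not frames:
        return pd.DataFrame(
            columns=["trial_id", "peak_index", *FEATURE_COLUMNS, "truncated", "label"]
        )
    df = pd.concat(frames, ignore_index=True)
    df["label"] = _label_candidates(df, annotations, cfg.match_tol)
    return df


def recovery_rate(
    trials: Iterable[Trial],
    annotations: Iterable[EventAnnotation],
    cfg: RunConfig | None = None,
    tol: int = 3,
) -> float:
    """Percent of annotated event peaks recovered by candidate detection.

    An event counts as recovered when some candidate lies within ``tol``
    samples of its annotated peak.
    """
    cfg = cfg or RunConfig()
    annotations = list(annotations)
    if not annotations:
        raise ValueError("no annotated events to recover")
    cands_by_trial: dict[str, list[int]] = {}
    for trial in trials:
        cands_by_trial[trial.trial_id] = [
            c.peak_index for c in detect_candidates(trial, cfg)
        ]
    hits = sum(
        1
        for ann in annotations
        if any(abs(p - ann.peak_index) <= tol for p in cands_by_trial.get(ann.trial_id, []))
    )
    return 100.0 * hits / len(annotations)
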
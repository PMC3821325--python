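"""Quick-look plots for detection output and the five-landmark model."""

from __future__ import annotations

import numpy as np

from .detect import detect_candidates, k_neo, normalize_trial, smooth_psi
from .features import FeaturePoints, lowpass_slow
from .io import RunConfig, Trial

__all__ = ["plot_detection", "plot_feature_points"]


def plot_detection(trial: Trial, cfg: RunConfig | None = None, ax=None):
    """Normalized trial, smoothed k-NEO trace, threshold and candidates.

    Returns the matplotlib axes (created on demand).
    """
    import matplotlib.pyplot as plt

    cfg = cfg or RunConfig()
    if ax is None:
        _, ax = plt.subplots(figsize=(10, 4))
    z = normalize_trial(trial).samples
    psi = smooth_psi(k_neo(z, cfg.k), cfg.k)
    t = np.arange(z.size) / trial.fs
    ax.plot(t, z, lw=0.6, color="0.3", label="normalized EEG")
    ax.plot(t, psi, lw=0.8, color="tab:blue", label=f"smoothed $\\Psi_{{{cfg.k}}}$")
    ax.axhline(cfg.T, color="tab:red", ls="--", lw=0.8, label=f"T = {cfg.T}")
    for c in detect_candidates(trial, cfg):
        ax.axvline(c.peak_index / trial.fs, color="tab:orange", lw=0.8, alpha=0.7)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("normalized amplitude / energy")
    ax.legend(loc="upper right", fontsize=8)
    ax.set_title(trial.trial_id or "trial")
    return ax


def plot_feature_points(
    trial: Trial, pts: FeaturePoints, cfg: RunConfig | None = None, pad_s: float = 0.5, ax=None
):
    """Zoomed view of one candidate with the A, P, B, Q, R landmarks."""
    import matplotlib.pyplot as plt

    cfg = cfg or RunConfig()
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 4))
    z = normalize_trial(trial)
    zf = lowpass_slow(z, cfg.slow_cutoff_hz)
    pad = int(pad_s * trial.fs)
    lo = max(0, pts.a_idx - pad)
    hi = min(len(z), pts.r_idx + pad)
    t = np.arange(lo, hi) / trial.fs
    ax.plot(t, z.samples[lo:hi], lw=0.8, color="0.3", label="normalized EEG")
    ax.plot(t, zf.samples[lo:hi], lw=1.0, color="tab:blue", label="5 Hz low-pass")
    for name, idx, val in (
        ("A", pts.a_idx, pts.a_val),
        ("P", pts.p_idx, pts.p_val),
        ("B", pts.b_idx, pts.b_val),
        ("Q", pts.q_idx, pts.q_val),
        ("R", pts.r_idx, pts.r_val),
    ):
        ax.plot(idx / trial.fs, val, "o", ms=5, color="tab:red")
        ax.annotate(name, (idx / trial.fs, val), textcoords="offset points", xytext=(2, 6))
    ax.set_xlabel("time (s)")
    ax.set_ylabel("normalized amplitude")
    ax.legend(loc="best", fontsize=8)
    return ax
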
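"""Shared fixtures: synthetic datasets, a tiny EDF writer, hypothesis profile."""

from __future__ import annotations

import struct

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import neospike as ns

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_dataset():
    """A reduced annotated dataset for fast end-to-end unit tests."""
    cfg = ns.SimConfig(seed=7, n_single=8, n_slow=16, n_normal=18)
    trials, annotations, manifest = ns.gen_dataset(cfg)
    return cfg, trials, annotations, manifest


@pytest.fixture(scope="session")
def default_dataset():
    """The full default-condition dataset (42/100/111 trials, seed 0)."""
    cfg = ns.SimConfig(seed=0)
    trials, annotations, manifest = ns.gen_dataset(cfg)
    return cfg, trials, annotations, manifest


@pytest.fixture(scope="session")
def default_feature_table(default_dataset):
    cfg, trials, annotations, _ = default_dataset
    return ns.build_feature_table(trials, annotations, ns.RunConfig())


def write_minimal_edf(path, data: np.ndarray, fs: float, label: str = "Fp1") -> None:
    """Write a single-record, single-channel EDF file (16-bit samples)."""
    n = len(data)
    dur = n / fs
    pmin, pmax = float(data.min()), float(data.max())
    if pmax == pmin:
        pmax = pmin + 1.0
    dmin, dmax = -32768, 32767
    header = "".join(
        [
            "0".ljust(8),
            "X".ljust(80),
            "X".ljust(80),
            "01.01.00",
            "00.00.00",
            str(512).ljust(8),
            "".ljust(44),
            "1".ljust(8),
            f"{dur:g}".ljust(8),
            "1".ljust(4),
        ]
    )
    sig_header = "".join(
        [
            label.ljust(16),
            "".ljust(80),
            "uV".ljust(8),
            f"{pmin:.6g}".ljust(8),
            f"{pmax:.6g}".ljust(8),
            str(dmin).ljust(8),
            str(dmax).ljust(8),
            "".ljust(80),
            str(n).ljust(8),
            "".ljust(32),
        ]
    )
    digital = np.round((data - pmin) / (pmax - pmin) * (dmax - dmin) + dmin).astype("<i2")
    with open(path, "wb") as fh:
        fh.write(header.encode("ascii"))
        fh.write(sig_header.encode("ascii"))
        fh.write(digital.tobytes())
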
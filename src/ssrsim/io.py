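"""Waveform and configuration I/O.

Waveforms travel as two-column CSV (``time_ms, amplitude``) with a required
header row; the reader checks that the time axis is uniformly sampled.
Experiment configuration is JSON or TOML.
"""

from __future__ import annotations

import json
import tomllib
from pathlib import Path

import numpy as np
import pandas as pd

from .templates import AepTemplate

__all__ = ["read_waveform_csv", "write_waveform_csv", "load_config_file"]


def write_waveform_csv(path, samples: np.ndarray, fs: float) -> None:
    """Write a sampled wave as (time_ms, amplitude) CSV."""
    samples = np.asarray(samples, dtype=float)
    t_ms = np.arange(samples.size) / fs * 1000.0
    pd.DataFrame({"time_ms": t_ms, "amplitude": samples}).to_csv(path, index=False)


def read_waveform_csv(path) -> AepTemplate:
    """Read a (time_ms, amplitude) CSV into a non-parametric template.

    The time column must be uniformly sampled (relative jitter < 1e-6 of
    the step); the sampling rate is inferred from the step.
    """
    df = pd.read_csv(path)
    if list(df.columns[:2]) != ["time_ms", "amplitude"]:
        raise ValueError("waveform CSV must have columns time_ms, amplitude")
    t = df["time_ms"].to_numpy(dtype=float)
    if t.size < 2:
        raise ValueError("waveform needs at least two samples")
    steps = np.diff(t)
    step = steps.mean()
    if step <= 0 or np.any(np.abs(steps - step) > 1e-6 * step):
        raise ValueError("waveform CSV is not uniformly sampled")
    fs = 1000.0 / step
    samples = df["amplitude"].to_numpy(dtype=float)
    duration_ms = samples.size * step
    return AepTemplate(samples, fs, duration_ms)


def load_config_file(path) -> dict:
    """Load a JSON or TOML config file into a plain dict."""
    p = Path(path)
    if p.suffix.lower() == ".toml":
        with open(p, "rb") as fh:
            return tomllib.load(fh)
    with open(p) as fh:
        return json.load(fh)
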
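"""SSR synthesis by the circular-convolution superposition model.

A steady-state response y(t) is modelled as the circular convolution of a
transient template x(t) with a binary stimulus-onset train h(t), plus
optional additive noise:  y = x (*) h + n.  Constant inter-stimulus
intervals give a periodic SSR; the folded single cycle at the stimulus rate
is the quantity most analyses operate on.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .templates import AepTemplate

__all__ = [
    "StimulusSequence",
    "SsrSweep",
    "SsrCycle",
    "CLAD_PRESET_ISIS_MS",
    "build_constant_rate_sequence",
    "build_sequence_from_isis",
    "clad_preset_sequence",
    "synthesize_ssr",
    "extract_cycle",
    "synthesize_cycle",
]

def round_half_up(x) -> np.ndarray:
    """Round with halves away from zero (sample-index convention).

    Used for every time-to-sample conversion so that onset placement,
    sweep lengths and fold periods agree across modules.
    """
    return np.floor(np.asarray(x) + 0.5).astype(int)


#: Eight-click jittered sweep for the frequency-domain (CLAD) paradigm:
#: ISIs span 16-36.8 ms and sum to 200 ms, i.e. a 40 Hz mean stimulus rate.
#: Only the range endpoints and the mean rate are canonical; the interior
#: values are this package's choice of a well-conditioned jitter.
CLAD_PRESET_ISIS_MS: tuple[float, ...] = (16.0, 19.6, 21.6, 23.6, 25.6, 27.6, 29.2, 36.8)


@dataclass
class StimulusSequence:
    """Stimulus-onset train over one circular sweep.

    ``onsets`` are ascending sample indices; the implied binary train h has
    ones exactly there.  The sweep is circular: the interval from the last
    onset wraps around to the first.
    """

    onsets: np.ndarray
    sweep_length: int
    fs: float
    nominal_rate: float | None = None

    def __post_init__(self) -> None:
        self.onsets = np.asarray(self.onsets, dtype=int)
        if self.onsets.size == 0:
            raise ValueError("sequence needs at least one onset")
        if np.unique(self.onsets).size != self.onsets.size:
            raise ValueError("onsets must be unique")
        if np.any(self.onsets < 0) or np.any(self.onsets >= self.sweep_length):
            raise ValueError("onsets must lie inside the sweep")
        if not np.all(np.diff(self.onsets) > 0):
            raise ValueError("onsets must be ascending")

    @property
    def n_stim(self) -> int:
        return self.onsets.size

    @property
    def actual_mean_rate(self) -> float:
        return self.n_stim * self.fs / self.sweep_length

    def train(self) -> np.ndarray:
        h = np.zeros(self.sweep_length)
        h[self.onsets] = 1.0
        return h

    def to_json(self) -> str:
        return json.dumps(
            {
                "fs": self.fs,
                "onsets": self.onsets.tolist(),
                "sweep_length": int(self.sweep_length),
                "nominal_rate": self.nominal_rate,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "StimulusSequence":
        d = json.loads(text)
        return cls(
            np.asarray(d["onsets"]), d["sweep_length"], d["fs"], d.get("nominal_rate")
        )


@dataclass
class SsrSweep:
    """Synthesized response over one circular sweep."""

    samples: np.ndarray
    fs: float
    sequence: StimulusSequence

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.size != self.sequence.sweep_length:
            raise ValueError("sweep length does not match its sequence")


@dataclass
class SsrCycle:
    """One folded period of a constant-rate SSR."""

    samples: np.ndarray
    actual_rate: float
    fs: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.actual_rate <= 0:
            raise ValueError("rate must be positive")

    @property
    def period(self) -> int:
        return self.samples.size

    def peak_peak(self) -> float:
        return float(self.samples.max() - self.samples.min())


def build_constant_rate_sequence(rate: float, fs: float, n_stim: int) -> StimulusSequence:
    """Constant-rate onset train: onset k at round(k*fs/rate).

    The sweep length is round(n_stim*fs/rate), so the recorded actual mean
    rate (n_stim*fs/sweep_length) can differ from the nominal rate by the
    rounding of a non-integer period.
    """
    if rate <= 0:
        raise ValueError("rate must be positive")
    if n_stim < 1:
        raise ValueError("need at least one stimulus")
    if rate >= fs / 2:
        raise ValueError("period under two samples")
    onsets = round_half_up(np.arange(n_stim) * fs / rate)
    sweep_length = int(round_half_up(n_stim * fs / rate))
    return StimulusSequence(onsets, sweep_length, fs, nominal_rate=rate)


def build_sequence_from_isis(
    isis_ms: Sequence[float], fs: float, nominal_rate: float | None = None
) -> StimulusSequence:
    """Onset train from a circular list of inter-stimulus intervals (ms).

    The first onset sits at 0; the k-th at the cumulative sum of the first k
    ISIs; the last ISI wraps to the first onset, closing the sweep.
    """
    isis = np.asarray(list(isis_ms), dtype=float)
    if isis.size == 0:
        raise ValueError("need at least one ISI")
    if np.any(isis <= 0):
        raise ValueError("ISIs must be positive")
    edges_ms = np.concatenate([[0.0], np.cumsum(isis)])
    onsets = round_half_up(edges_ms[:-1] * fs / 1000.0)
    sweep_length = int(round_half_up(edges_ms[-1] * fs / 1000.0))
    if nominal_rate is None:
        nominal_rate = isis.size * 1000.0 / float(edges_ms[-1])
    return StimulusSequence(onsets, sweep_length, fs, nominal_rate=nominal_rate)


def clad_preset_sequence(fs: float = 10_000.0) -> StimulusSequence:
    """The default 8-click jittered sweep (16-36.8 ms ISIs, 40 Hz mean)."""
    return build_sequence_from_isis(CLAD_PRESET_ISIS_MS, fs)


def _wrap_to_length(x: np.ndarray, n: int) -> np.ndarray:
    """Fold x circularly into length n (zero-pad if shorter)."""
    if x.size <= n:
        out = np.zeros(n)
        out[: x.size] = x
        return out
    n_chunks = -(-x.size // n)
    padded = np.zeros(n_chunks * n)
    padded[: x.size] = x
    return padded.reshape(n_chunks, n).sum(axis=0)


def synthesize_ssr(
    template: AepTemplate,
    sequence: StimulusSequence,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> SsrSweep:
    """Circularly convolve a template with an onset train (+ optional noise).

    The template is zero-padded to the sweep length (or wrapped, if longer),
    then convolved with the binary train via FFT.  ``noise_sd`` adds white
    Gaussian noise; 0 gives a fully deterministic sweep.
    """
    if template.fs != sequence.fs:
        raise ValueError("template and sequence sampling rates differ")
    n = sequence.sweep_length
    xw = _wrap_to_length(template.samples, n)
    y = np.fft.irfft(np.fft.rfft(xw) * np.fft.rfft(sequence.train()), n=n)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, noise_sd, size=n)
    return SsrSweep(y, sequence.fs, sequence)


def extract_cycle(sweep: SsrSweep, rate: float) -> SsrCycle:
    """Fold a constant-rate sweep into a single averaged period.

    The period is m = round(fs/rate); the sweep must be an integer number of
    such periods (the sequence must have been built at this constant nominal
    rate).  For noise-free constant-rate sweeps every fold is identical, so
    the average equals any single fold.
    """
    seq = sweep.sequence
    m = int(round_half_up(sweep.fs / rate))
    if m < 1:
        raise ValueError("not a constant-rate sweep")
    n_folds = seq.n_stim
    if abs(seq.sweep_length - n_folds * m) > n_folds:
        raise ValueError("not a constant-rate sweep")
    expected = round_half_up(np.arange(n_folds) * sweep.fs / rate)
    if seq.n_stim != n_folds or not np.array_equal(seq.onsets, expected):
        raise ValueError("not a constant-rate sweep")
    idx = (np.arange(m)[None, :] + expected[:, None]) % seq.sweep_length
    cycle = sweep.samples[idx].mean(axis=0)
    actual_rate = sweep.fs / (seq.sweep_length / n_folds)
    return SsrCycle(cycle, actual_rate, sweep.fs)


def synthesize_cycle(template: AepTemplate, rate: float) -> SsrCycle:
    """Noise-free single cycle at a constant rate (direct wrap-sum).

    Equivalent to synthesizing a one-stimulus sweep of exactly one period
    and reading it back: cycle[t] = sum_k x[t + k*m] with m = round(fs/rate).
    """
    seq = build_constant_rate_sequence(rate, template.fs, 1)
    sweep = synthesize_ssr(template, seq)
    return extract_cycle(sweep, rate)
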
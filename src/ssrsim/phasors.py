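"""Harmonic phasor characterisation of steady-state cycles.

A periodic SSR cycle of M samples is summarised by the amplitude and phase
of its first few harmonics of the stimulus rate.  Convention: one-sided
cosine phasors, i.e. the k-th harmonic contributes
``amplitude_k * cos(2*pi*k*t/M + phase_k)`` with
``amplitude_k = (2/M) |sum_t cycle[t] exp(-i 2 pi k t / M)|`` and phase the
argument of that sum.  The fundamental f0 is exactly the stimulus rate
because harmonics are computed on the folded cycle, not the raw sweep.
"""

from __future__ import annotations

import cmath
import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .superposition import SsrCycle

__all__ = [
    "PhasorSet",
    "harmonic_phasors",
    "reconstruct_from_phasors",
    "compare_phasors",
]


@dataclass(frozen=True)
class Phasor:
    harmonic: int
    freq_hz: float
    amplitude: float
    phase_rad: float


@dataclass
class PhasorSet:
    """DC level plus one cosine phasor per harmonic of a cycle."""

    entries: tuple[Phasor, ...]
    f0: float
    dc: float
    label: str = ""

    def __post_init__(self) -> None:
        ks = [p.harmonic for p in self.entries]
        if ks != sorted(set(ks)) or any(k < 1 for k in ks):
            raise ValueError("harmonic indices must be unique, ascending, >= 1")
        if any(p.amplitude < 0 for p in self.entries):
            raise ValueError("amplitudes must be nonnegative")

    def amplitudes(self) -> np.ndarray:
        return np.array([p.amplitude for p in self.entries])

    def phases(self) -> np.ndarray:
        return np.array([p.phase_rad for p in self.entries])

    def to_json(self) -> str:
        return json.dumps(
            {
                "label": self.label,
                "f0_hz": self.f0,
                "dc": self.dc,
                "harmonics": [
                    {
                        "k": p.harmonic,
                        "freq_hz": p.freq_hz,
                        "amplitude": p.amplitude,
                        "phase_rad": p.phase_rad,
                    }
                    for p in self.entries
                ],
            }
        )


def harmonic_phasors(
    cycle: SsrCycle, n_harmonics: int = 3, label: str = ""
) -> PhasorSet:
    """Amplitude/phase phasors of the first ``n_harmonics`` harmonics."""
    x = cycle.samples
    M = x.size
    if M < 2 * n_harmonics + 1:
        raise ValueError("cycle too short for requested number of harmonics")
    entries = []
    t = np.arange(M)
    for k in range(1, n_harmonics + 1):
        coeff = np.sum(x * np.exp(-2j * np.pi * k * t / M))
        amp = 2.0 / M * abs(coeff)
        phase = cmath.phase(coeff) if amp > 0 else 0.0
        entries.append(Phasor(k, k * cycle.actual_rate, amp, phase))
    return PhasorSet(tuple(entries), cycle.actual_rate, float(x.mean()), label)


def reconstruct_from_phasors(phasors: PhasorSet, M: int) -> np.ndarray:
    """Time-domain cycle from dc + cosine phasors: the truncated Fourier sum."""
    t = np.arange(M)
    out = np.full(M, phasors.dc, dtype=float)
    for p in phasors.entries:
        out += p.amplitude * np.cos(2 * np.pi * p.harmonic * t / M + p.phase_rad)
    return out


def _wrap_phase(phi: np.ndarray) -> np.ndarray:
    return np.angle(np.exp(1j * phi))


def compare_phasors(sets: Sequence[PhasorSet]) -> pd.DataFrame:
    """Pairwise amplitude ratios and wrapped phase differences per harmonic.

    All sets must share the fundamental frequency and harmonic indices.
    Rows: (harmonic, set_i, set_j, amp_ratio = amp_i/amp_j, phase_diff_rad).
    """
    if len(sets) < 2:
        raise ValueError("need at least two phasor sets")
    f0 = sets[0].f0
    ks = [p.harmonic for p in sets[0].entries]
    for s in sets[1:]:
        if not np.isclose(s.f0, f0):
            raise ValueError("phasor sets have mismatched fundamental frequencies")
        if [p.harmonic for p in s.entries] != ks:
            raise ValueError("phasor sets have mismatched harmonic indices")
    rows = []
    for ki, k in enumerate(ks):
        for i in range(len(sets)):
            for j in range(i + 1, len(sets)):
                pi, pj = sets[i].entries[ki], sets[j].entries[ki]
                ratio = pi.amplitude / pj.amplitude if pj.amplitude > 0 else np.inf
                dphi = float(_wrap_phase(np.array(pi.phase_rad - pj.phase_rad)))
                rows.append(
                    {
                        "harmonic": k,
                        "set_i": sets[i].label or str(i),
                        "set_j": sets[j].label or str(j),
                        "amp_ratio": ratio,
                        "phase_diff_rad": dphi,
                    }
                )
    return pd.DataFrame(rows)
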
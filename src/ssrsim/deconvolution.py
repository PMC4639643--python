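"""Recovery of transient templates from overlapped steady-state responses.

Two linear inverses of the superposition model are provided:

* CLAD (continuous loop averaging deconvolution) — frequency-domain division
  Y(f)/H(f) over one jittered-ISI sweep, with optional Tikhonov
  regularisation.  Constant-ISI trains of more than one stimulus make H(f)
  vanish on all off-harmonic bins, so no solution exists — the classic
  degeneracy that motivates jittered designs.
* MSAD (multirate steady-state averaging deconvolution) — stacks single
  cycles recorded at several constant rates into a binary wrap matrix
  y = Hx and solves the system by least squares.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .superposition import SsrCycle, SsrSweep, StimulusSequence, round_half_up
from .templates import AepTemplate

__all__ = [
    "CladDiagnostics",
    "MsadSystem",
    "MSAD_PRESET_RATES",
    "clad_deconvolve",
    "msad_build",
    "msad_solve",
]

#: Eight constant rates for the multirate paradigm, spanning 27-62.5 Hz.
#: The endpoints are canonical; the interior spacing is this package's
#: choice of a well-conditioned rate set.
MSAD_PRESET_RATES: tuple[float, ...] = (27.0, 31.0, 35.5, 40.0, 45.0, 50.0, 55.5, 62.5)

# |H(f)| below this fraction of max|H| is treated as an exact zero when
# deciding invertibility of the unregularised spectral division.
_SINGULAR_RTOL = 1e-10


@dataclass
class CladDiagnostics:
    """Conditioning report for one frequency-domain deconvolution."""

    min_abs_transfer: float
    flagged_bins: int
    regularization: str

    def __post_init__(self) -> None:
        if self.min_abs_transfer < 0:
            raise ValueError("transfer magnitude cannot be negative")


@dataclass
class MsadSystem:
    """Stacked binary wrap matrix over a set of constant rates."""

    matrix: np.ndarray
    rates: tuple[float, ...]
    fs: float
    template_len: int
    periods: tuple[int, ...]
    condition_number: float


def clad_deconvolve(
    sweep: SsrSweep,
    sequence: StimulusSequence,
    template_len: int | None = None,
    eps: float = 1e-6,
    lam: float = 0.0,
) -> tuple[AepTemplate, CladDiagnostics]:
    """Frequency-domain deconvolution of one sweep by its onset train.

    Computes the inverse transform of Y(f) conj(H(f)) / (|H(f)|^2 + lam)
    (plain division when ``lam`` = 0) and truncates the estimate to
    ``template_len`` samples.  Diagnostics count bins with
    |H(f)| < eps * max|H|.

    Raises
    ------
    ValueError
        If ``lam`` = 0 and some |H(f)| is numerically zero ("sequence not
        invertible") — e.g. any constant-ISI train with more than one
        stimulus.
    """
    if sweep.fs != sequence.fs or sweep.samples.size != sequence.sweep_length:
        raise ValueError("sweep and sequence do not match")
    n = sequence.sweep_length
    if template_len is None:
        template_len = n
    if template_len > n:
        raise ValueError("template_len exceeds sweep length")

    H = np.fft.fft(sequence.train())
    Y = np.fft.fft(sweep.samples)
    absH = np.abs(H)
    max_abs = float(absH.max())
    diag = CladDiagnostics(
        min_abs_transfer=float(absH.min()),
        flagged_bins=int(np.sum(absH < eps * max_abs)),
        regularization="none" if lam == 0 else f"tikhonov({lam:g})",
    )
    if lam == 0:
        if absH.min() < _SINGULAR_RTOL * max_abs:
            raise ValueError(
                "sequence not invertible: onset-train spectrum has zero bins "
                "(constant-ISI degeneracy)"
            )
        X = Y / H
    else:
        X = Y * np.conj(H) / (absH**2 + lam)
    estimate = np.fft.ifft(X).real[:template_len]
    duration_ms = template_len / sweep.fs * 1000.0
    return AepTemplate(estimate, sweep.fs, duration_ms), diag


def msad_build(
    rates: Sequence[float], fs: float, template_len: int
) -> MsadSystem:
    """Assemble the stacked binary wrap matrix for a set of constant rates.

    For each rate with period m_i = round(fs/rate_i) the block has m_i rows;
    row t has ones at template columns t + k*m_i < template_len, i.e. the
    template samples that wrap onto cycle position t.

    Raises
    ------
    ValueError
        If the stacked matrix is rank-deficient ("underdetermined").
    """
    rates = tuple(float(r) for r in rates)
    if not rates:
        raise ValueError("need at least one rate")
    periods = tuple(int(round_half_up(fs / r)) for r in rates)
    if any(m < 1 for m in periods):
        raise ValueError("rate too high for sampling rate")
    blocks = []
    for m in periods:
        block = np.zeros((m, template_len))
        cols = np.arange(template_len)
        block[cols % m, cols] = 1.0
        blocks.append(block)
    matrix = np.vstack(blocks)
    if np.linalg.matrix_rank(matrix) < template_len:
        raise ValueError("MSAD system underdetermined; add rates")
    cond = float(np.linalg.cond(matrix))
    return MsadSystem(matrix, rates, fs, template_len, periods, cond)


def msad_solve(cycles: Sequence[SsrCycle], system: MsadSystem) -> AepTemplate:
    """Least-squares recovery of the template from multirate cycles.

    ``cycles`` must match ``system.rates`` in order, with lengths equal to
    the periods the system was built from.  Noise-free cycles from a
    full-column-rank system are recovered exactly (to numerical precision).
    """
    if len(cycles) != len(system.rates):
        raise ValueError("cycle count does not match system rates")
    for cyc, m in zip(cycles, system.periods):
        if cyc.samples.size != m:
            raise ValueError(
                f"cycle length {cyc.samples.size} does not match period {m}"
            )
    y = np.concatenate([c.samples for c in cycles])
    x, *_ = np.linalg.lstsq(system.matrix, y, rcond=None)
    duration_ms = system.template_len / system.fs * 1000.0
    return AepTemplate(x, system.fs, duration_ms)
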
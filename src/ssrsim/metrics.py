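"""Comparison statistics for evoked waves and steady-state cycles.

Implements the study's morphology metrics: peak-peak amplitude, pointwise
difference waves, the "significant percentage" (fraction of time samples at
which a pointwise two-tailed t-test across subjects is significant, with no
multiplicity correction — a deliberate reproduction of common evoked-
potential practice, not a statistical recommendation), the relative
difference between paired SSR cycles, rate sweeps over a grid of stimulus
rates, and the Pearson correlation used to relate difference amplitudes to
significance rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .superposition import SsrCycle, synthesize_cycle
from .templates import AepTemplate, SubjectGroup

__all__ = [
    "RateSweepResult",
    "peak_peak",
    "difference_wave",
    "significant_percentage",
    "relative_difference",
    "rate_sweep",
    "correlate",
]


def peak_peak(wave: np.ndarray) -> float:
    """max(wave) - min(wave); zero for a constant wave."""
    wave = np.asarray(wave, dtype=float)
    if wave.size == 0:
        raise ValueError("empty wave")
    return float(wave.max() - wave.min())


def difference_wave(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pointwise a - b for equal-length waves."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("length mismatch")
    return a - b


def _pointwise_pvalues(
    wavesA: np.ndarray, wavesB: np.ndarray, paired: bool, equal_var: bool
) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample two-tailed t-test p-values plus a means-differ mask."""
    if paired:
        res = stats.ttest_rel(wavesA, wavesB, axis=0)
    else:
        res = stats.ttest_ind(wavesA, wavesB, axis=0, equal_var=equal_var)
    p = np.asarray(res.pvalue, dtype=float)
    means_differ = wavesA.mean(axis=0) != wavesB.mean(axis=0)
    return p, means_differ


def significant_percentage(
    groupA: SubjectGroup,
    groupB: SubjectGroup,
    paired: bool = False,
    alpha: float = 0.05,
    *,
    equal_var: bool = True,
) -> tuple[float, np.ndarray]:
    """Percentage of time samples with a significant pointwise t-test.

    At every time sample a two-tailed t-test across subjects is run
    (pooled-variance two-sample when unpaired, ``equal_var=False`` for
    Welch; paired-difference t when ``paired``) and the fraction of samples
    with p < alpha is returned as a percentage, together with the boolean
    per-sample significance mask.  No multiple-testing correction is
    applied.  Samples with zero variance (possible only for degenerate
    noise-free groups) are counted significant iff the group means differ
    there.
    """
    if groupA.n_samples != groupB.n_samples:
        raise ValueError("groups have different wave lengths")
    if paired:
        if groupA.n_subjects != groupB.n_subjects or (
            groupA.subject_ids != groupB.subject_ids
        ):
            raise ValueError("paired test requires matching subject_ids")
    p, means_differ = _pointwise_pvalues(groupA.waves, groupB.waves, paired, equal_var)
    mask = np.where(np.isnan(p), means_differ, p < alpha)
    return 100.0 * float(mask.mean()), mask.astype(bool)


def relative_difference(cycle1: SsrCycle, cycle2: SsrCycle) -> float:
    """100 * pp(cycle1 - cycle2) / min(pp(cycle1), pp(cycle2)).

    The denominator is the smaller of the pair's peak-peak amplitudes, so
    values above 100% mean the difference wave is larger than the smaller
    cycle (antiphase pairs reach 200%).
    """
    d = difference_wave(cycle1.samples, cycle2.samples)
    denom = min(peak_peak(cycle1.samples), peak_peak(cycle2.samples))
    if denom == 0:
        raise ValueError("undefined relative difference: zero peak-peak")
    return 100.0 * peak_peak(d) / denom


@dataclass
class RateSweepResult:
    """Per-rate table of amplitudes and differences plus AEP reference levels.

    ``table`` columns: nominal_rate, actual_rate, pp1, pp2, pp_diff,
    rel_diff_pct, sig_pct (NaN when the inputs are bare templates).
    References are computed once from the source waves: peak-peak of each
    AEP, of their difference, and the AEP significant percentage.
    """

    table: pd.DataFrame
    ref_pp1: float
    ref_pp2: float
    ref_pp_diff: float
    ref_sig_pct: float = float("nan")
    meta: dict = field(default_factory=dict)

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for k, v in self.meta.items():
                fh.write(f"# {k}: {v}\n")
            fh.write(f"# ref_pp1: {self.ref_pp1!r}\n")
            fh.write(f"# ref_pp2: {self.ref_pp2!r}\n")
            fh.write(f"# ref_pp_diff: {self.ref_pp_diff!r}\n")
            fh.write(f"# ref_sig_pct: {self.ref_sig_pct!r}\n")
            self.table.to_csv(fh, sep="\t", index=False)


def _mean_template(source: AepTemplate | SubjectGroup) -> AepTemplate:
    if isinstance(source, AepTemplate):
        return source
    n = source.n_samples
    return AepTemplate(source.mean_wave(), source.fs, n / source.fs * 1000.0)


def _subject_templates(source: AepTemplate | SubjectGroup) -> list[AepTemplate]:
    if isinstance(source, AepTemplate):
        return [source]
    dur = source.n_samples / source.fs * 1000.0
    return [AepTemplate(w.copy(), source.fs, dur) for w in source.waves]


def rate_sweep(
    sourceA: AepTemplate | SubjectGroup,
    sourceB: AepTemplate | SubjectGroup,
    rates: Sequence[float],
    paired: bool = False,
    alpha: float = 0.05,
    *,
    amplitude_from: str = "group_mean",
) -> RateSweepResult:
    """Synthesize and compare SSR cycles over a grid of stimulus rates.

    For each rate a noise-free cycle is synthesized per subject (or from
    the bare template); amplitude metrics (pp1, pp2, pp_diff, rel_diff) use
    the group-mean cycle by default (``amplitude_from="subject_mean"``
    averages per-subject peak-peak values instead), while the per-subject
    cycle ensembles feed the pointwise significance test.  Reference levels
    come from the source AEPs themselves.
    """
    rates = list(rates)
    if not rates:
        raise ValueError("need at least one rate")
    if amplitude_from not in ("group_mean", "subject_mean"):
        raise ValueError("amplitude_from must be group_mean or subject_mean")
    groups = isinstance(sourceA, SubjectGroup) and isinstance(sourceB, SubjectGroup)

    meanA, meanB = _mean_template(sourceA), _mean_template(sourceB)
    if meanA.fs != meanB.fs or meanA.n_samples != meanB.n_samples:
        raise ValueError("sources must share fs and duration")
    subjA, subjB = _subject_templates(sourceA), _subject_templates(sourceB)

    ref_pp1 = peak_peak(meanA.samples)
    ref_pp2 = peak_peak(meanB.samples)
    ref_pp_diff = peak_peak(difference_wave(meanA.samples, meanB.samples))
    ref_sig = float("nan")
    if groups:
        ref_sig, _ = significant_percentage(sourceA, sourceB, paired, alpha)

    rows = []
    for rate in rates:
        cycA = [synthesize_cycle(t, rate) for t in subjA]
        cycB = [synthesize_cycle(t, rate) for t in subjB]
        mA = np.mean([c.samples for c in cycA], axis=0)
        mB = np.mean([c.samples for c in cycB], axis=0)
        if amplitude_from == "group_mean":
            pp1, pp2 = peak_peak(mA), peak_peak(mB)
        else:
            pp1 = float(np.mean([peak_peak(c.samples) for c in cycA]))
            pp2 = float(np.mean([peak_peak(c.samples) for c in cycB]))
        pp_diff = peak_peak(difference_wave(mA, mB))
        denom = min(peak_peak(mA), peak_peak(mB))
        rel = 100.0 * pp_diff / denom if denom > 0 else float("nan")
        sig = float("nan")
        if groups:
            ga = SubjectGroup(
                np.vstack([c.samples for c in cycA]), meanA.fs, sourceA.subject_ids
            )
            gb = SubjectGroup(
                np.vstack([c.samples for c in cycB]), meanB.fs, sourceB.subject_ids
            )
            sig, _ = significant_percentage(ga, gb, paired, alpha)
        rows.append(
            {
                "nominal_rate": float(rate),
                "actual_rate": cycA[0].actual_rate,
                "pp1": pp1,
                "pp2": pp2,
                "pp_diff": pp_diff,
                "rel_diff_pct": rel,
                "sig_pct": sig,
            }
        )
    return RateSweepResult(
        pd.DataFrame(rows), ref_pp1, ref_pp2, ref_pp_diff, ref_sig
    )


def correlate(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson correlation and two-sided p-value (t transform, n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length series of at least 3 points")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)
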
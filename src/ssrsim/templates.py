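"""Parametric transient AEP templates and synthetic subject groups.

Transient auditory-evoked potentials (ABR + MLR, <~70 ms) are modelled as a
sum of signed unimodal component waves — the canonical V(+), Na(-), Pa(+),
Nb(-), Pb(+) sequence — each parameterised by label, latency, width and
signed peak amplitude.  Component kernels are Gaussian bumps by default
(closed-form area, two parameters); a compact-support cubic B-spline kernel
is available as an alternative.  Groups of per-subject waveforms with
controlled inter-subject variability stand in for recorded cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "ComponentSpec",
    "AepTemplate",
    "SubjectGroup",
    "CANONICAL_COMPONENTS",
    "FIG_COMPONENTS_POSITIVE",
    "make_component_wave",
    "make_aep",
    "canonical_template",
    "canonical_pair",
    "shift_component",
    "generate_group",
]


@dataclass(frozen=True)
class ComponentSpec:
    """One evoked-potential component: a signed unimodal bump.

    Parameters
    ----------
    label : str
        Component name (``V``, ``Na``, ``Pa``, ``Nb``, ``Pb`` or free text).
    latency_ms : float
        Peak latency in milliseconds (>= 0).
    width_ms : float
        Kernel width (Gaussian sigma) in milliseconds (> 0).
    amplitude : float
        Signed peak value in arbitrary (microvolt-scale) units.
    """

    label: str
    latency_ms: float
    width_ms: float
    amplitude: float

    def __post_init__(self) -> None:
        if not self.label:
            raise ValueError("component label must be nonempty")
        if not self.width_ms > 0:
            raise ValueError("component width must be positive")
        if self.latency_ms < 0:
            raise ValueError("component latency must be nonnegative")


@dataclass
class AepTemplate:
    """A sampled transient AEP, optionally carrying its parametric components."""

    samples: np.ndarray
    fs: float
    duration_ms: float
    components: tuple[ComponentSpec, ...] | None = None
    kernel: str = "gaussian"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.duration_ms <= 0:
            raise ValueError("duration must be positive")
        n = int(round(self.duration_ms * self.fs / 1000.0))
        if self.samples.shape != (n,):
            raise ValueError(
                f"template length {self.samples.shape} does not match "
                f"round(duration*fs/1000) = {n}"
            )
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("template samples must be finite")

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def time_ms(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs * 1000.0

    def peak_peak(self) -> float:
        return float(self.samples.max() - self.samples.min())


@dataclass
class SubjectGroup:
    """Per-subject waveforms (subjects x time) sharing one sampling grid."""

    waves: np.ndarray
    fs: float
    subject_ids: tuple[str, ...]
    paired_key: str | None = None

    def __post_init__(self) -> None:
        self.waves = np.atleast_2d(np.asarray(self.waves, dtype=float))
        if self.waves.shape[0] < 2:
            raise ValueError("a group needs at least 2 subjects")
        if len(self.subject_ids) != self.waves.shape[0]:
            raise ValueError("subject_ids must match the number of rows")

    @property
    def n_subjects(self) -> int:
        return self.waves.shape[0]

    @property
    def n_samples(self) -> int:
        return self.waves.shape[1]

    def mean_wave(self) -> np.ndarray:
        return self.waves.mean(axis=0)


#: Canonical ABR/MLR component table (arbitrary units).  Latencies put the
#: wave-V -> Pa interval at exactly 25 ms, the separation that makes in-phase
#: summation — and hence SSR amplitude enhancement — happen at a 40 Hz
#: stimulus rate.
CANONICAL_COMPONENTS: tuple[ComponentSpec, ...] = (
    ComponentSpec("V", 6.0, 1.2, +0.30),
    ComponentSpec("Na", 18.0, 4.0, -0.35),
    ComponentSpec("Pa", 31.0, 5.0, +0.50),
    ComponentSpec("Nb", 40.0, 5.0, -0.40),
    ComponentSpec("Pb", 55.0, 7.0, +0.45),
)

#: Positive-area variant used by the ill-posedness demonstration: the same
#: five-component morphology, but with the positive components widened and the
#: negative ones weakened so that the superposed steady-state cycle stays
#: above the baseline at the demonstration rate.
FIG_COMPONENTS_POSITIVE: tuple[ComponentSpec, ...] = (
    ComponentSpec("V", 6.0, 2.0, +0.30),
    ComponentSpec("Na", 18.0, 3.0, -0.20),
    ComponentSpec("Pa", 31.0, 6.0, +0.60),
    ComponentSpec("Nb", 40.0, 4.0, -0.25),
    ComponentSpec("Pb", 55.0, 7.0, +0.50),
)

DEFAULT_FS = 10_000.0
DEFAULT_DURATION_MS = 100.0


def _cubic_bspline(u: np.ndarray) -> np.ndarray:
    """Cubic B-spline basis on support |u| < 2, peak value 2/3 at u = 0."""
    au = np.abs(u)
    out = np.zeros_like(au)
    inner = au < 1
    outer = (au >= 1) & (au < 2)
    out[inner] = 2.0 / 3.0 - au[inner] ** 2 + 0.5 * au[inner] ** 3
    out[outer] = (2.0 - au[outer]) ** 3 / 6.0
    return out


def make_component_wave(
    spec: ComponentSpec,
    fs: float = DEFAULT_FS,
    duration_ms: float = DEFAULT_DURATION_MS,
    kernel: str = "gaussian",
) -> np.ndarray:
    """Sample one component bump on a uniform grid.

    The bump peaks at ``spec.latency_ms`` with signed peak value
    ``spec.amplitude`` and decays to zero within a few widths.  ``kernel``
    selects the shape: ``"gaussian"`` (sigma = width) or ``"spline"``
    (cubic B-spline, half-support = 2*width).
    """
    if spec.latency_ms >= duration_ms:
        raise ValueError("component outside template window")
    n = int(round(duration_ms * fs / 1000.0))
    t_ms = np.arange(n) / fs * 1000.0
    u = (t_ms - spec.latency_ms) / spec.width_ms
    if kernel == "gaussian":
        # truncated at +-4 widths: compact support keeps component edits
        # (latency shifts, amplitude scales) strictly local in time
        wave = np.where(np.abs(u) < 4.0, np.exp(-0.5 * u**2), 0.0)
    elif kernel == "spline":
        wave = _cubic_bspline(u / 2.0) / (2.0 / 3.0)
    else:
        raise ValueError(f"unknown kernel {kernel!r}")
    return spec.amplitude * wave


def make_aep(
    components: Sequence[ComponentSpec],
    fs: float = DEFAULT_FS,
    duration_ms: float = DEFAULT_DURATION_MS,
    kernel: str = "gaussian",
) -> AepTemplate:
    """Sum component waves into a parametric template (empty list -> zeros)."""
    n = int(round(duration_ms * fs / 1000.0))
    samples = np.zeros(n)
    for spec in components:
        samples += make_component_wave(spec, fs, duration_ms, kernel)
    return AepTemplate(samples, fs, duration_ms, tuple(components), kernel)


def canonical_template(
    fs: float = DEFAULT_FS, duration_ms: float = DEFAULT_DURATION_MS
) -> AepTemplate:
    """The canonical five-component template (V-Pa separation 25 ms)."""
    return make_aep(CANONICAL_COMPONENTS, fs, duration_ms)


def _perturb_homo(
    components: Sequence[ComponentSpec], perturbation: float
) -> tuple[ComponentSpec, ...]:
    # Deterministic alternating-sign perturbation: +-3% amplitude, +-0.3 ms
    # latency at perturbation = 1, scaled linearly.
    out = []
    for i, c in enumerate(components):
        sign = 1.0 if i % 2 == 0 else -1.0
        out.append(
            replace(
                c,
                amplitude=c.amplitude * (1.0 + sign * 0.03 * perturbation),
                latency_ms=c.latency_ms + sign * 0.3 * perturbation,
            )
        )
    return tuple(out)


def _perturb_hetero(components: Sequence[ComponentSpec]) -> tuple[ComponentSpec, ...]:
    out = []
    for c in components:
        if c.label == "Pa":
            out.append(replace(c, amplitude=c.amplitude * 0.6))
        elif c.label == "Pb":
            out.append(replace(c, latency_ms=c.latency_ms + 8.0))
        elif c.label == "Nb":
            out.append(replace(c, amplitude=c.amplitude * 1.3))
        else:
            out.append(c)
    return tuple(out)


def canonical_pair(
    preset: str,
    fs: float = DEFAULT_FS,
    duration_ms: float = DEFAULT_DURATION_MS,
    *,
    perturbation: float = 1.0,
    fig7_delta_ms: float = 8.0,
) -> tuple[AepTemplate, AepTemplate]:
    """Build a template pair for one of the study conditions.

    ``"homo"``
        Two near-identical templates: the second has component amplitudes
        scaled by +-3% and latencies shifted by +-0.3 ms (times
        ``perturbation``), mimicking split-half averages of one cohort.
    ``"hetero"``
        Two clearly different templates: the second has Pa amplitude x0.6,
        Nb amplitude x1.3 and Pb latency +8 ms, mimicking averages from two
        different recording paradigms.
    ``"fig7"``
        Identical positive-area templates except for the Pb latency, shifted
        by ``fig7_delta_ms`` — the ill-posedness construction.
    """
    if preset == "homo":
        a = make_aep(CANONICAL_COMPONENTS, fs, duration_ms)
        b = make_aep(_perturb_homo(CANONICAL_COMPONENTS, perturbation), fs, duration_ms)
    elif preset == "hetero":
        a = make_aep(CANONICAL_COMPONENTS, fs, duration_ms)
        b = make_aep(_perturb_hetero(CANONICAL_COMPONENTS), fs, duration_ms)
    elif preset == "fig7":
        a = make_aep(FIG_COMPONENTS_POSITIVE, fs, duration_ms)
        b = shift_component(a, "Pb", fig7_delta_ms)
    else:
        raise ValueError(f"unknown preset {preset!r} (expected homo|hetero|fig7)")
    return a, b


def shift_component(template: AepTemplate, label: str, delta_ms: float) -> AepTemplate:
    """Rebuild ``template`` with one component's latency moved by ``delta_ms``."""
    if template.components is None:
        raise ValueError("not a parametric template")
    labels = [c.label for c in template.components]
    if label not in labels:
        raise ValueError("not a parametric template: no component " + repr(label))
    new = tuple(
        replace(c, latency_ms=c.latency_ms + delta_ms) if c.label == label else c
        for c in template.components
    )
    return make_aep(new, template.fs, template.duration_ms, template.kernel)


def generate_group(
    mean: AepTemplate,
    n: int,
    amp_cv: float = 0.0,
    latency_sd_ms: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    *,
    paired_key: str | None = None,
) -> SubjectGroup:
    """Draw ``n`` synthetic subjects around a mean template.

    Each subject wave is rebuilt from the mean's components with a
    per-subject multiplicative amplitude scale ~ Normal(1, amp_cv^2), an
    independent per-component latency jitter ~ Normal(0, latency_sd_ms^2),
    and additive white Gaussian noise of standard deviation ``noise_sd``.
    Per-subject random substreams are spawned from the master seed, so
    growing ``n`` never reshuffles earlier subjects.
    """
    if n < 2:
        raise ValueError("a group needs at least 2 subjects")
    parametric = mean.components is not None
    if (amp_cv > 0 or latency_sd_ms > 0) and not parametric:
        raise ValueError("amplitude/latency variability requires a parametric template")

    children = np.random.SeedSequence(seed).spawn(n)
    waves = np.empty((n, mean.n_samples))
    for i in range(n):
        rng = np.random.default_rng(children[i])
        if parametric and (amp_cv > 0 or latency_sd_ms > 0):
            scale = rng.normal(1.0, amp_cv) if amp_cv > 0 else 1.0
            comps = []
            for c in mean.components:
                lat = c.latency_ms + (
                    rng.normal(0.0, latency_sd_ms) if latency_sd_ms > 0 else 0.0
                )
                lat = min(max(lat, 0.0), mean.duration_ms - 1000.0 / mean.fs)
                comps.append(replace(c, latency_ms=lat, amplitude=c.amplitude * scale))
            wave = make_aep(comps, mean.fs, mean.duration_ms, mean.kernel).samples
        else:
            wave = mean.samples.copy()
        if noise_sd > 0:
            wave = wave + rng.normal(0.0, noise_sd, size=wave.size)
        waves[i] = wave
    ids = tuple(f"s{i:03d}" for i in range(n))
    return SubjectGroup(waves, mean.fs, ids, paired_key=paired_key)
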
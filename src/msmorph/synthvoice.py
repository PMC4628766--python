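"""Synthetic sustained-vowel generator with controlled dysphonic perturbations.

Generates /ah:/-like phonations as a sum of harmonics with a fixed
spectral rolloff, perturbed by the four mechanisms the morphological
parameters are designed to detect:

* **tremor** — a slow (2-15 Hz) sinusoidal modulation of the fundamental
  frequency (extent in % of f0) and optionally of the amplitude;
* **jitter** — Gaussian cycle-to-cycle perturbation of the glottal
  period (std in % of the period);
* **shimmer** — Gaussian cycle-to-cycle perturbation of the cycle
  amplitude (std in %);
* **additive noise** — white Gaussian noise scaled to a prescribed
  harmonics-to-noise ratio (dB).

Labeled corpora draw per-item parameters from four monotonically
worsening ranges emulating perceptual severity levels 0-3. The class
schedule straddles clinically typical ranges (e.g. jitter below 0.3% is
ordinarily considered normal, several percent clearly pathological) but
is a configuration of this generator, not a clinically calibrated claim.
No vowel-quality (formant) shaping is attempted: the features under
study operate on harmonic and modulation structure, which this source
model produces.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .audio import Waveform


@dataclass(frozen=True)
class VoiceSpec:
    """Generative parameters of one synthetic sustained vowel."""

    f0: float = 150.0                  # Hz
    duration: float = 1.0              # s
    sample_rate: int = 25000           # Hz
    n_harmonics: int = 20
    harmonic_rolloff: float = 12.0     # dB/octave amplitude decay
    jitter_pct: float = 0.0            # std of relative period deviation, %
    shimmer_pct: float = 0.0           # std of relative cycle amplitude, %
    tremor_freq: float = 5.0           # Hz
    tremor_extent_pct: float = 0.0     # peak f0 deviation, %
    am_tremor_extent_pct: float = 0.0  # peak amplitude deviation, %
    hnr_db: float = math.inf           # harmonics-to-noise ratio; inf = clean
    seed: int = 0

    def validate(self) -> None:
        if self.f0 <= 0 or self.duration <= 0 or self.sample_rate <= 0:
            raise ValueError("f0, duration and sample_rate must be positive")
        if self.sample_rate < 2 * self.f0 * self.n_harmonics:
            raise ValueError(
                f"aliasing: f0*n_harmonics = {self.f0 * self.n_harmonics:.0f}"
                f" Hz reaches the Nyquist frequency "
                f"{self.sample_rate / 2:.0f} Hz; lower n_harmonics or f0")
        for name in ("jitter_pct", "shimmer_pct", "tremor_extent_pct",
                     "am_tremor_extent_pct", "harmonic_rolloff"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if math.isnan(self.hnr_db):
            raise ValueError("hnr_db must be finite or +inf")


@dataclass
class LabeledCorpus:
    """Synthetic corpus: (waveform, severity label 0-3, generating spec)."""

    items: list  # of (Waveform, int, VoiceSpec)
    class_map: dict

    def __len__(self) -> int:
        return len(self.items)

    @property
    def labels(self) -> np.ndarray:
        return np.array([lab for _, lab, _ in self.items])

    @property
    def waveforms(self) -> list[Waveform]:
        return [w for w, _, _ in self.items]


def synth_vowel(spec: VoiceSpec, return_noise: bool = False):
    """Render a sustained vowel; deterministic for a given spec (incl. seed).

    The instantaneous f0 follows
    ``f0 * (1 + tremor_extent/100 * sin(2*pi*tremor_freq*t))`` with an
    additional per-cycle jitter factor; each glottal cycle carries a
    shimmer amplitude factor; harmonic h has amplitude
    ``h**(-rolloff/6.02)``. Broadband noise is scaled so the harmonic-to-
    noise power ratio equals ``hnr_db``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration * spec.sample_rate))
    dt = 1.0 / spec.sample_rate

    # per-cycle period sequence: tremor-modulated f0 plus jitter noise
    max_cycles = int(np.ceil(spec.duration * spec.f0 * 1.5)) + 4
    jit = rng.standard_normal(max_cycles) * spec.jitter_pct / 100.0
    shim = rng.standard_normal(max_cycles) * spec.shimmer_pct / 100.0
    noise_raw = rng.standard_normal(n)

    cycle_starts = [0.0]
    periods = []
    t0 = 0.0
    k = 0
    while t0 < spec.duration and k < max_cycles:
        f_inst = spec.f0 * (1.0 + spec.tremor_extent_pct / 100.0
                            * math.sin(2 * math.pi * spec.tremor_freq * t0))
        period = (1.0 / f_inst) * max(1.0 + jit[k], 0.2)
        periods.append(period)
        t0 += period
        cycle_starts.append(t0)
        k += 1

    # integrate piecewise-constant instantaneous frequency into phase
    t = np.arange(n) * dt
    starts = np.array(cycle_starts)
    periods_arr = np.array(periods)
    idx = np.clip(np.searchsorted(starts, t, side="right") - 1, 0,
                  len(periods_arr) - 1)
    phase = 2 * np.pi * (idx + (t - starts[idx]) / periods_arr[idx])

    h = np.arange(1, spec.n_harmonics + 1)
    amps = h ** (-spec.harmonic_rolloff / 6.0206)
    harm = np.sin(phase[:, None] * h[None, :]) @ amps

    amp = 1.0 + np.clip(shim[idx], -0.9, None)
    amp *= (1.0 + spec.am_tremor_extent_pct / 100.0
            * np.sin(2 * np.pi * spec.tremor_freq * t))
    voiced = harm * amp

    # fix overall harmonic RMS so waveforms stay within [-1, 1] headroom
    rms = np.sqrt(np.mean(voiced ** 2))
    if rms > 0:
        voiced *= 0.15 / rms

    if math.isinf(spec.hnr_db):
        noise = np.zeros(n)
    else:
        target_noise_rms = 0.15 * 10.0 ** (-spec.hnr_db / 20.0)
        noise = noise_raw * target_noise_rms

    w = Waveform(voiced + noise, spec.sample_rate)
    if return_noise:
        return w, noise
    return w


#: Default severity schedule: parameter ranges per class label. Ranges
#: worsen monotonically from a clean phonation (class 0) to a severely
#: perturbed one (class 3).
DEFAULT_CLASS_MAP: dict[int, dict[str, tuple[float, float]]] = {
    0: {"jitter_pct": (0.05, 0.3), "shimmer_pct": (0.3, 1.5),
        "tremor_extent_pct": (0.05, 0.5), "am_tremor_extent_pct": (0.1, 1.0),
        "tremor_freq": (2.0, 6.0), "hnr_db": (30.0, 40.0)},
    1: {"jitter_pct": (0.5, 1.0), "shimmer_pct": (2.0, 4.0),
        "tremor_extent_pct": (1.0, 2.0), "am_tremor_extent_pct": (2.0, 4.0),
        "tremor_freq": (3.0, 8.0), "hnr_db": (20.0, 26.0)},
    2: {"jitter_pct": (1.0, 2.0), "shimmer_pct": (4.0, 7.0),
        "tremor_extent_pct": (2.0, 4.0), "am_tremor_extent_pct": (4.0, 8.0),
        "tremor_freq": (4.0, 9.0), "hnr_db": (12.0, 18.0)},
    3: {"jitter_pct": (2.0, 4.0), "shimmer_pct": (7.0, 12.0),
        "tremor_extent_pct": (4.0, 8.0), "am_tremor_extent_pct": (8.0, 15.0),
        "tremor_freq": (4.0, 10.0), "hnr_db": (5.0, 12.0)},
}

F0_RANGE = (120.0, 220.0)   # Hz, drawn per item


def _ranges_overlap(class_map) -> bool:
    keys = ("jitter_pct", "tremor_extent_pct", "hnr_db")
    labels = sorted(class_map)
    for a, b in zip(labels[:-1], labels[1:]):
        for key in keys:
            lo_a, hi_a = sorted(class_map[a][key])
            lo_b, hi_b = sorted(class_map[b][key])
            if key == "hnr_db":      # decreasing with severity
                if lo_a < hi_b:
                    return True
            elif hi_a > lo_b:
                return True
    return False


def make_corpus(n_per_class: int, class_map=None, seed: int = 0,
                duration: float = 1.0, sample_rate: int = 25000,
                render: bool = True) -> LabeledCorpus:
    """Balanced 4-class corpus of synthetic vowels, fully reproducible.

    Per-item parameters are drawn uniformly from the class ranges with a
    seeded generator; every item can be regenerated from its stored
    :class:`VoiceSpec` alone.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    class_map = dict(class_map or DEFAULT_CLASS_MAP)
    if _ranges_overlap(class_map):
        warnings.warn("class parameter ranges overlap: classes will be "
                      "harder to separate")
    rng = np.random.default_rng(seed)
    items = []
    for label in sorted(class_map):
        ranges = class_map[label]
        for _ in range(n_per_class):
            draw = {k: float(rng.uniform(*ranges[k])) for k in ranges}
            spec = VoiceSpec(
                f0=float(rng.uniform(*F0_RANGE)),
                duration=duration, sample_rate=sample_rate,
                jitter_pct=draw["jitter_pct"],
                shimmer_pct=draw["shimmer_pct"],
                tremor_freq=draw["tremor_freq"],
                tremor_extent_pct=draw["tremor_extent_pct"],
                am_tremor_extent_pct=draw["am_tremor_extent_pct"],
                hnr_db=draw["hnr_db"],
                seed=int(rng.integers(0, 2 ** 31 - 1)),
            )
            wave = synth_vowel(spec) if render else None
            items.append((wave, label, spec))
    return LabeledCorpus(items=items, class_map=class_map)
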
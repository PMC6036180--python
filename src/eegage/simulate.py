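"""Synthetic resting-EEG cohorts with known age-dependent structure.

Each subject is a sum of band-limited oscillators (narrowband-filtered
Gaussian noise) plus 1/f^gamma background noise, on a standard 32-electrode
10-20 cap.  Band amplitudes and the alpha peak frequency are affine
functions of age: by default alpha amplitude and alpha peak frequency
decrease with age (the dominant adult maturation effects reported in the
EEG-aging literature), delta decreases mildly, and theta/beta increase
mildly.  A hemispheric-asymmetry multiplier drives the symmetry features,
and a common oscillator component shared across channels drives coherence
and envelope-correlation features.

The generator is the ground-truth source for recovery tests: every drawn
per-subject parameter is returned alongside the recording.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

from .montage import CAP_32_LABELS
from .recording import RawRecording

__all__ = ["OscillatorSpec", "SyntheticCohortSpec", "simulate_subject",
           "simulate_cohort", "channel_side"]


@dataclass(frozen=True)
class OscillatorSpec:
    """One band oscillator: affine-in-age amplitude and center frequency.

    ``amp_mid``/``center_mid`` are the values at the cohort mid-age (38 y);
    slopes are per year.  ``bandwidth`` is the width of the narrowband
    filter around the center, in Hz.  Amplitudes are RMS microvolts.
    """

    name: str
    amp_mid: float
    amp_slope: float
    center_mid: float
    center_slope: float
    bandwidth: float

    def amplitude(self, age: float) -> float:
        return max(self.amp_mid + self.amp_slope * (age - 38.0), 0.0)

    def center(self, age: float) -> float:
        return self.center_mid + self.center_slope * (age - 38.0)


DEFAULT_OSCILLATORS: list[OscillatorSpec] = [
    OscillatorSpec("delta", 9.0, -0.04, 2.0, 0.0, 2.0),
    OscillatorSpec("theta", 6.0, +0.04, 5.5, 0.0, 2.0),
    OscillatorSpec("alpha", 12.0, -0.15, 10.2, -0.025, 2.0),
    OscillatorSpec("beta", 5.0, +0.03, 20.0, 0.0, 8.0),
]


@dataclass
class SyntheticCohortSpec:
    """Generative parameters of a cohort.

    ``duration`` defaults to the full 8-minute protocol; tests use the
    short mode (<= 120 s), which only changes the epoch count downstream.
    ``snr`` is total oscillator variance over background-noise variance
    within the 0.5-30 Hz range.  ``common_frac`` is the fraction of each
    oscillator's amplitude shared across channels (drives connectivity).
    ``age_effects`` selects which age slopes are active: "all" (default),
    "alpha_amp" (age enters only through the alpha amplitude) or "none"
    (null cohort; the leakage canary).
    """

    n_subjects: int = 200
    age_lo: float = 18.0
    age_hi: float = 58.0
    labels: list[str] = field(default_factory=lambda: list(CAP_32_LABELS))
    fs: float = 250.0
    duration: float = 480.0
    oscillators: list[OscillatorSpec] = field(
        default_factory=lambda: list(DEFAULT_OSCILLATORS))
    amp_jitter: float = 0.20      # lognormal sigma of per-subject band amps
    freq_jitter: float = 0.30     # sd (Hz) of per-subject alpha peak
    asymmetry: float = 0.10       # right-hemisphere amplitude excess
    common_frac: float = 0.5      # shared-across-channels oscillator fraction
    noise_gamma: float = 1.0
    snr: float = 2.0
    sex_effect: float = 0.0       # optional amplitude multiplier for males
    age_effects: str = "all"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.age_effects not in ("all", "alpha_amp", "none"):
            raise ValueError("age_effects must be all|alpha_amp|none")

    def effective_oscillators(self) -> list[OscillatorSpec]:
        """Oscillator specs with the selected age slopes zeroed out."""
        if self.age_effects == "all":
            return list(self.oscillators)
        out = []
        for osc in self.oscillators:
            if self.age_effects == "alpha_amp" and osc.name == "alpha":
                out.append(replace(osc, center_slope=0.0))
            else:
                out.append(replace(osc, amp_slope=0.0, center_slope=0.0))
        return out


def channel_side(label: str) -> str:
    """'left', 'right' or 'midline' from a 10-20 label (odd/even/z rule)."""
    m = re.search(r"(\d+)$", label)
    if m is None:
        return "midline"
    return "left" if int(m.group(1)) % 2 == 1 else "right"


def _pink_noise(rng: np.random.Generator, n_ch: int, n: int, fs: float,
                gamma: float, band: tuple[float, float]) -> tuple[np.ndarray, float]:
    """1/f^gamma noise with unit in-band variance; returns (noise, 1.0)."""
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    shape = np.zeros_like(freqs)
    shape[1:] = freqs[1:] ** (-gamma / 2.0)
    coef = (rng.standard_normal((n_ch, freqs.size))
            + 1j * rng.standard_normal((n_ch, freqs.size))) * shape
    coef[:, 0] = 0.0
    x = np.fft.irfft(coef, n=n, axis=-1)
    inband = (freqs >= band[0]) & (freqs < band[1])
    # per-row in-band variance from the synthesized spectrum (Parseval)
    var = 2.0 * (np.abs(coef[:, inband]) ** 2).sum(axis=-1) / n ** 2
    return x / np.sqrt(var)[:, None], 1.0


def _narrowband(rng: np.random.Generator, shape: tuple, fs: float,
                lo: float, hi: float) -> np.ndarray:
    sos = signal.butter(2, [max(lo, 0.1), min(hi, fs / 2 * 0.99)],
                        btype="bandpass", fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, rng.standard_normal(shape), axis=-1)
    return x / x.std(axis=-1, keepdims=True)


def simulate_subject(spec: SyntheticCohortSpec, age: float, seed: int,
                     sex: str = "F") -> tuple[RawRecording, dict]:
    """Generate one subject's recording plus its ground-truth parameters."""
    rng = np.random.default_rng(seed)
    n = int(round(spec.duration * spec.fs))
    n_ch = len(spec.labels)
    sides = np.array([channel_side(lab) for lab in spec.labels])
    right = (sides == "right").astype(float)

    data = np.zeros((n_ch, n))
    truth: dict = {"age": age, "sex": sex, "seed": seed}
    total_osc_var = 0.0
    for osc in spec.effective_oscillators():
        amp = osc.amplitude(age) * float(np.exp(
            rng.normal(0.0, spec.amp_jitter)))
        center = osc.center(age) + (rng.normal(0.0, spec.freq_jitter)
                                    if osc.name == "alpha" else 0.0)
        if spec.sex_effect and sex == "M":
            amp *= 1.0 + spec.sex_effect
        lo, hi = center - osc.bandwidth / 2.0, center + osc.bandwidth / 2.0
        common = _narrowband(rng, (1, n), spec.fs, lo, hi)
        private = _narrowband(rng, (n_ch, n), spec.fs, lo, hi)
        mix = (np.sqrt(spec.common_frac) * common
               + np.sqrt(1.0 - spec.common_frac) * private)
        chan_amp = amp * (1.0 + spec.asymmetry * right)
        data += chan_amp[:, None] * mix
        total_osc_var += amp ** 2
        truth[f"amp_{osc.name}"] = amp
        truth[f"center_{osc.name}"] = center

    if spec.snr > 0:
        noise, _ = _pink_noise(rng, n_ch, n, spec.fs, spec.noise_gamma,
                               (0.5, 30.0))
        noise_rms = np.sqrt(total_osc_var / spec.snr)
        data += noise_rms * noise
        truth["noise_rms"] = noise_rms
    return RawRecording(data, spec.fs, list(spec.labels)), truth


def simulate_cohort(spec: SyntheticCohortSpec, out_dir=None):
    """Generate a cohort: (recordings, metadata DataFrame, ground truth).

    Ages are uniform on ``[age_lo, age_hi]``; the sex label is balanced and
    carries no generative effect unless ``sex_effect`` is set.  With
    ``out_dir`` given, recordings are written as EDF files and the returned
    first element is the list of paths instead of in-memory recordings.
    """
    from pathlib import Path

    import pandas as pd

    from .io import write_edf

    rng = np.random.default_rng(spec.seed)
    ages = rng.uniform(spec.age_lo, spec.age_hi, spec.n_subjects)
    sexes = np.array(["F", "M"] * spec.n_subjects)[: spec.n_subjects]
    rng.shuffle(sexes)
    child_seeds = rng.integers(0, 2 ** 31 - 1, spec.n_subjects)

    recordings, truth_rows, meta_rows = [], [], []
    for i in range(spec.n_subjects):
        sid = f"sub-{i:03d}"
        rec, truth = simulate_subject(spec, float(ages[i]), int(child_seeds[i]),
                                      sex=str(sexes[i]))
        truth["subject_id"] = sid
        truth_rows.append(truth)
        meta_rows.append({"subject_id": sid, "age": float(ages[i]),
                          "sex": str(sexes[i])})
        if out_dir is not None:
            path = Path(out_dir) / f"{sid}.edf"
            write_edf(path, rec)
            recordings.append(path)
        else:
            recordings.append(rec)

    meta = pd.DataFrame(meta_rows).set_index("subject_id")
    truth = pd.DataFrame(truth_rows).set_index("subject_id")
    if out_dir is not None:
        meta.to_csv(Path(out_dir) / "participants.csv")
        truth.to_csv(Path(out_dir) / "ground_truth.csv")
    return recordings, meta, truth
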
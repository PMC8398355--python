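"""Synthetic multichannel surface-EMG trial generator.

Surface EMG during a sustained contraction is well approximated by
band-limited Gaussian noise whose amplitude follows the contraction
envelope.  Each movement class is given a distinct per-channel signature:
which of the four muscles are active, how strongly, and where inside the
50-150 Hz band (the region that carries most sEMG spectral energy) each
muscle's carrier sits.  On top of the physiological component the
generator injects the two nuisances a recording rig produces: 50 Hz
powerline interference and slow (sub-6 Hz) motion-artifact drift.

Inter-individual variability is modelled as a multiplicative log-normal
gain per subject and channel, so that subject-wise train/test splits are
genuinely harder than trial-wise splits.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import signal

__all__ = [
    "AcquisitionSpec",
    "ActivationProfile",
    "NoiseSpec",
    "Trial",
    "Dataset",
    "default_profiles",
    "generate_trial",
    "generate_dataset",
]

_SEED_MOD = 2**31


@dataclass(frozen=True)
class AcquisitionSpec:
    """Recording-protocol constants: 4 muscles sampled at 2048 Hz for 5 s."""

    sampling_rate: float = 2048.0
    duration: float = 5.0
    n_channels: int = 4
    n_classes: int = 12
    trials_per_class_per_subject: int = 5
    n_subjects: int = 14

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0 or self.duration <= 0:
            raise ValueError("sampling_rate and duration must be positive")
        for name in ("n_channels", "n_classes", "trials_per_class_per_subject", "n_subjects"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    @property
    def samples_per_trial(self) -> int:
        return round(self.sampling_rate * self.duration)


@dataclass(frozen=True)
class ActivationProfile:
    """Per-class muscle-activation signature.

    ``gains[c]`` scales channel ``c``; ``bands[c]`` is the (low, high) Hz
    carrier band of that channel.  ``onset``/``offset`` delimit the active
    part of the trial as fractions; the envelope ramps up/down with raised
    cosines over ``ramp`` of the trial.
    """

    gains: tuple[float, ...]
    bands: tuple[tuple[float, float], ...]
    onset: float = 0.1
    offset: float = 0.9
    ramp: float = 0.1
    subject_scale: float = 1.0

    def __post_init__(self) -> None:
        if len(self.gains) != len(self.bands):
            raise ValueError("gains and bands must have equal length")
        if not all(np.isfinite(self.gains)) or any(g < 0 for g in self.gains):
            raise ValueError("gains must be finite and >= 0")
        for lo, hi in self.bands:
            if not (6.0 <= lo < hi <= 500.0):
                raise ValueError(f"carrier band ({lo}, {hi}) outside [6, 500] Hz")
        if not (0.0 <= self.onset < self.offset <= 1.0):
            raise ValueError("need 0 <= onset < offset <= 1")
        if max(self.gains) <= 0:
            raise ValueError("a valid class needs at least one channel with gain > 0")

    def scaled(self, factor: float) -> "ActivationProfile":
        return replace(self, subject_scale=self.subject_scale * factor)


@dataclass(frozen=True)
class NoiseSpec:
    """Additive nuisance components, in the same units as the signal."""

    baseline_rms: float = 0.05
    powerline_amplitude: float = 0.2
    drift_amplitude: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.baseline_rms, self.powerline_amplitude, self.drift_amplitude) < 0:
            raise ValueError("noise amplitudes must be >= 0")


@dataclass
class Trial:
    """One movement execution: [n_channels x samples] plus labels."""

    data: np.ndarray
    class_id: int
    subject_id: int
    acquisition: AcquisitionSpec
    preprocessed: bool = False
    seed: int | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("trial data must be 2-D [channels x samples]")
        expected = (self.acquisition.n_channels, self.acquisition.samples_per_trial)
        if self.data.shape != expected:
            raise ValueError(f"trial shape {self.data.shape} != acquisition {expected}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("trial data contains NaN/Inf")


def default_profiles(
    n_classes: int, n_channels: int, seed: int = 0
) -> list[ActivationProfile]:
    """Distinct, separable activation signatures for ``n_classes`` movements.

    Classes are separated on two axes at once: a binary active-channel mask
    (cycling through all non-empty masks) and a class-specific carrier-band
    centre swept across 60-140 Hz.  Either axis alone already makes all
    profiles pairwise distinct.
    """
    if n_classes < 2:
        raise ValueError("need at least 2 classes")
    if n_channels < 1:
        raise ValueError("need at least 1 channel")
    rng = np.random.default_rng(seed)
    n_masks = 2**n_channels - 1
    profiles: list[ActivationProfile] = []
    for c in range(n_classes):
        mask = (c % n_masks) + 1
        active = [(mask >> ch) & 1 for ch in range(n_channels)]
        centre = 60.0 + 80.0 * c / max(n_classes - 1, 1)
        gains, bands = [], []
        for ch in range(n_channels):
            gains.append(float(rng.uniform(0.8, 1.5)) if active[ch] else 0.0)
            lo = centre - 20.0 + 4.0 * ch
            bands.append((max(lo, 6.0), min(lo + 40.0, 500.0)))
        profiles.append(ActivationProfile(gains=tuple(gains), bands=tuple(bands)))
    return profiles


def _envelope(profile: ActivationProfile, n: int) -> np.ndarray:
    """Ramp-plateau-ramp contraction envelope with raised-cosine edges."""
    t = np.arange(n) / n
    env = np.zeros(n)
    on, off, ramp = profile.onset, profile.offset, profile.ramp
    rise = (t >= on) & (t < on + ramp)
    env[rise] = 0.5 * (1 - np.cos(np.pi * (t[rise] - on) / ramp))
    env[(t >= on + ramp) & (t <= off - ramp)] = 1.0
    fall = (t > off - ramp) & (t <= off)
    env[fall] = 0.5 * (1 - np.cos(np.pi * (off - t[fall]) / ramp))
    return env


def _band_noise(rng: np.random.Generator, n: int, fs: float, band: tuple[float, float]) -> np.ndarray:
    white = rng.standard_normal(n)
    sos = signal.butter(4, band, btype="bandpass", fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, white)
    rms = np.sqrt(np.mean(x**2))
    return x / rms if rms > 0 else x


def generate_trial(
    profile: ActivationProfile,
    class_id: int,
    subject_id: int,
    acq: AcquisitionSpec,
    noise: NoiseSpec,
    seed: int,
) -> Trial:
    """One [channels x samples] trial: enveloped band noise + nuisances."""
    rng = np.random.default_rng(seed)
    n = acq.samples_per_trial
    fs = acq.sampling_rate
    t = np.arange(n) / fs
    env = _envelope(profile, n)
    data = np.zeros((acq.n_channels, n))
    for ch in range(acq.n_channels):
        gain = profile.gains[ch] if ch < len(profile.gains) else 0.0
        if gain > 0:
            carrier = _band_noise(rng, n, fs, profile.bands[ch])
            data[ch] += gain * profile.subject_scale * env * carrier
        if noise.baseline_rms > 0:
            data[ch] += noise.baseline_rms * rng.standard_normal(n)
        if noise.powerline_amplitude > 0:
            data[ch] += noise.powerline_amplitude * np.sin(
                2 * np.pi * 50.0 * t + rng.uniform(0, 2 * np.pi)
            )
        if noise.drift_amplitude > 0:
            for f_drift in rng.uniform(0.2, 3.0, size=2):
                data[ch] += (
                    0.5
                    * noise.drift_amplitude
                    * np.sin(2 * np.pi * f_drift * t + rng.uniform(0, 2 * np.pi))
                )
    return Trial(data=data, class_id=class_id, subject_id=subject_id,
                 acquisition=acq, seed=seed)


@dataclass
class Dataset:
    """A generated corpus: trials plus a manifest describing how."""

    trials: list[Trial]
    acquisition: AcquisitionSpec
    noise: NoiseSpec
    manifest: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.trials)

    @property
    def subjects(self) -> list[int]:
        return sorted({t.subject_id for t in self.trials})

    def labels(self) -> np.ndarray:
        return np.array([t.class_id for t in self.trials])

    def manifest_json(self) -> str:
        return json.dumps(self.manifest, indent=2, sort_keys=True)


def generate_dataset(
    acq: AcquisitionSpec,
    noise: NoiseSpec,
    seed: int,
    profiles: Sequence[ActivationProfile] | None = None,
    subject_sigma: float = 0.15,
    channel_sigma: float = 0.10,
    trials_per_class_total: int | None = None,
) -> Dataset:
    """Full corpus: every (subject, class) cell filled, all seeds recorded.

    ``trials_per_class_total`` overrides the per-subject repetition count
    and distributes that many trials per class round-robin over subjects
    (preset for a 47-trials-per-action corpus).  Subject variability is a
    log-normal gain per subject (sigma ``subject_sigma``) refined per
    channel (sigma ``channel_sigma``).
    """
    if profiles is None:
        profiles = default_profiles(acq.n_classes, acq.n_channels, seed=seed)
    if len(profiles) != acq.n_classes:
        raise ValueError("one profile per class required")
    rng = np.random.default_rng(seed)
    subj_scale = {
        s: float(np.exp(rng.normal(0.0, subject_sigma))) for s in range(1, acq.n_subjects + 1)
    }
    chan_scale = {
        s: np.exp(rng.normal(0.0, channel_sigma, size=acq.n_channels))
        for s in range(1, acq.n_subjects + 1)
    }

    cells: list[tuple[int, int]] = []  # (subject, class) with repetition
    if trials_per_class_total is None:
        for s in range(1, acq.n_subjects + 1):
            for c in range(1, acq.n_classes + 1):
                cells.extend([(s, c)] * acq.trials_per_class_per_subject)
    else:
        for c in range(1, acq.n_classes + 1):
            for k in range(trials_per_class_total):
                cells.append((k % acq.n_subjects + 1, c))

    trials: list[Trial] = []
    inventory = []
    for subject_id, class_id in cells:
        trial_seed = int(rng.integers(_SEED_MOD))
        prof = profiles[class_id - 1]
        # per-channel subject gain folded into the profile's channel gains
        gains = tuple(
            g * float(chan_scale[subject_id][ch]) for ch, g in enumerate(prof.gains)
        )
        prof_s = replace(prof, gains=gains, subject_scale=subj_scale[subject_id])
        trials.append(
            generate_trial(prof_s, class_id, subject_id, acq, noise, trial_seed)
        )
        inventory.append(
            {"subject": subject_id, "class": class_id, "seed": trial_seed}
        )

    manifest = {
        "acquisition": {
            "sampling_rate": acq.sampling_rate,
            "duration": acq.duration,
            "n_channels": acq.n_channels,
            "n_classes": acq.n_classes,
            "trials_per_class_per_subject": acq.trials_per_class_per_subject,
            "n_subjects": acq.n_subjects,
        },
        "noise": {
            "baseline_rms": noise.baseline_rms,
            "powerline_amplitude": noise.powerline_amplitude,
            "drift_amplitude": noise.drift_amplitude,
        },
        "seed": seed,
        "subject_sigma": subject_sigma,
        "channel_sigma": channel_sigma,
        "trials": inventory,
    }
    return Dataset(trials=trials, acquisition=acq, noise=noise, manifest=manifest)


def write_manifest(dataset: Dataset, path: str | Path) -> None:
    Path(path).write_text(dataset.manifest_json())
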
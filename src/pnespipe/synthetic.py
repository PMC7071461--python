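"""Synthetic two-class resting-EEG cohort generator.

The signal model is deliberately simple and controllable: each channel is a
sum of independent band-limited Gaussian noises (white noise band-passed to
the conventional delta/theta/alpha/beta ranges), a 1/f^alpha broadband
background, and an optional 50 Hz line-noise sinusoid. Class structure is
injected through the relative linear power assigned to each band; subject-
level heterogeneity is a single lognormal multiplicative power factor drawn
once per band per subject, which is what makes subject-level and epoch-level
train/test splitting behave differently downstream.

Channels are generated independently (the downstream features are strictly
per-channel, so spatial covariance adds nothing to coverage). Everything is
a pure function of (profiles, spec, seed): per-subject random streams are
derived from the master seed with ``numpy.random.SeedSequence(seed).spawn``,
so subject k is reproducible on its own.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .montage import STANDARD_1020_19
from .recording import EEGRecording

#: Conventional EEG rhythm edges in Hz, half-open [low, high).
BAND_EDGES = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 32.0),
}

LINE_FREQ_HZ = 50.0


@dataclass
class ClassSpectralProfile:
    """Spectral recipe for one class of subjects.

    band_power maps rhythm name -> relative linear power (unitless, >= 0).
    background_power is the relative power of the 1/f^background_exponent
    broadband floor. subject_sd is the lognormal sigma of the per-subject,
    per-band multiplicative power jitter. line_noise_amp is the amplitude
    (microvolts) of an additive 50 Hz sinusoid, zero by default because the
    preprocessing notch is expected to remove it.
    """

    class_label: str
    band_power: dict = field(
        default_factory=lambda: {"delta": 1.0, "theta": 0.8, "alpha": 1.2, "beta": 0.6}
    )
    background_exponent: float = 1.0
    background_power: float = 0.5
    line_noise_amp: float = 0.0
    subject_sd: float = 0.1

    def __post_init__(self):
        unknown = set(self.band_power) - set(BAND_EDGES)
        if unknown:
            raise ValueError(f"unknown bands in profile: {sorted(unknown)}")
        powers = list(self.band_power.values()) + [self.background_power]
        if any(p < 0 for p in powers):
            raise ValueError("band powers must be non-negative")
        if not any(p > 0 for p in powers):
            raise ValueError("at least one band power must be positive")
        if self.subject_sd < 0:
            raise ValueError("subject_sd must be non-negative")


@dataclass
class CohortSpec:
    """Size and sampling layout of a synthetic cohort.

    Defaults mirror a 19-channel, 256 Hz, eyes-closed resting protocol with
    120 five-second epochs per subject.
    """

    n_per_class: int = 10
    n_channels: int = 19
    fs: float = 256.0
    epoch_len_s: float = 5.0
    n_epochs: int = 120
    seed: int = 0

    def __post_init__(self):
        if self.n_per_class < 1 or self.n_channels < 1:
            raise ValueError("n_per_class and n_channels must be >= 1")
        n = self.epoch_len_s * self.fs
        if abs(n - round(n)) > 1e-9:
            raise ValueError("epoch_len_s * fs must be an integer sample count")

    @property
    def epoch_samples(self) -> int:
        return int(round(self.epoch_len_s * self.fs))

    @property
    def samples_per_subject(self) -> int:
        return self.n_epochs * self.epoch_samples

    def channel_labels(self) -> tuple:
        if self.n_channels <= len(STANDARD_1020_19):
            return STANDARD_1020_19[: self.n_channels]
        extra = tuple(f"X{i}" for i in range(self.n_channels - len(STANDARD_1020_19)))
        return STANDARD_1020_19 + extra


def synthesize_band_noise(band, n_samples, fs, rng):
    """Zero-mean unit-variance Gaussian noise band-limited to ``band``.

    ``band`` is a (low, high) pair in Hz that must lie inside (0, fs/2).
    White noise is shaped with a 4th-order Butterworth band-pass applied
    forward-backward, then renormalised to unit sample variance so the
    caller controls power exactly by scaling.
    """
    low, high = band
    if not (0.0 < low < high < fs / 2.0):
        raise ValueError(f"band {band} outside (0, {fs / 2}) Hz")
    n_samples = int(n_samples)
    if n_samples == 0:
        return np.empty(0)
    white = rng.standard_normal(n_samples)
    sos = signal.butter(4, [low, high], btype="bandpass", fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, white)
    x -= x.mean()
    sd = x.std()
    if sd > 0:
        x /= sd
    return x


def _band_noise_multichannel(band, shape, fs, rng):
    """(n_channels, n_samples) independent band-limited unit-variance noise."""
    low, high = band
    if not (0.0 < low < high < fs / 2.0):
        raise ValueError(f"band {band} outside (0, {fs / 2}) Hz")
    white = rng.standard_normal(shape)
    sos = signal.butter(4, [low, high], btype="bandpass", fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, white, axis=-1)
    x -= x.mean(axis=-1, keepdims=True)
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def _background_noise(shape, exponent, fs, rng):
    """1/f^alpha broadband noise, unit variance per channel.

    The spectral envelope is flat below 1 Hz to avoid the 1/f singularity;
    the analysis band-pass removes that region anyway.
    """
    n = shape[-1]
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=-1)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    env = np.ones_like(f)
    above = f >= 1.0
    env[above] = f[above] ** (-exponent / 2.0)
    env[0] = 0.0
    x = np.fft.irfft(spec * env, n=n, axis=-1)
    x -= x.mean(axis=-1, keepdims=True)
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def generate_subject(profile, spec, subject_id, rng):
    """Simulate one subject's continuous recording.

    One lognormal power factor per band (and one for the background) is
    drawn first and applied to every channel, giving the subject-coherent
    spectral fingerprint that subject-level cross-validation must not leak.
    """
    n = spec.samples_per_subject
    shape = (spec.n_channels, n)
    jitter = {
        name: float(rng.lognormal(mean=0.0, sigma=profile.subject_sd))
        for name in list(BAND_EDGES) + ["background"]
    }
    data = np.zeros(shape)
    for name, edges in BAND_EDGES.items():
        p = profile.band_power.get(name, 0.0) * jitter[name]
        if p > 0:
            data += np.sqrt(p) * _band_noise_multichannel(edges, shape, spec.fs, rng)
    p_bg = profile.background_power * jitter["background"]
    if p_bg > 0:
        data += np.sqrt(p_bg) * _background_noise(
            shape, profile.background_exponent, spec.fs, rng
        )
    if profile.line_noise_amp > 0:
        t = np.arange(n) / spec.fs
        phases = rng.uniform(0.0, 2.0 * np.pi, size=(spec.n_channels, 1))
        data += profile.line_noise_amp * np.sin(
            2.0 * np.pi * LINE_FREQ_HZ * t[None, :] + phases
        )
    return EEGRecording(
        data=data,
        fs=spec.fs,
        channel_labels=spec.channel_labels(),
        subject_id=str(subject_id),
        class_label=profile.class_label,
    )


def generate_cohort(cnt_profile, pnes_profile, spec):
    """Simulate a labelled two-class cohort of ``2 * spec.n_per_class`` subjects.

    Returns recordings ordered CNT-class first. Subject streams are spawned
    from ``SeedSequence(spec.seed)`` in subject order, so the cohort is a
    pure function of (profiles, spec, seed).
    """
    if cnt_profile.class_label == pnes_profile.class_label:
        raise ValueError("the two profiles must have distinct class labels")
    children = np.random.SeedSequence(spec.seed).spawn(2 * spec.n_per_class)
    recordings = []
    k = 0
    for profile in (cnt_profile, pnes_profile):
        for i in range(spec.n_per_class):
            sid = f"{profile.class_label}{i + 1:02d}"
            rng = np.random.default_rng(children[k])
            recordings.append(generate_subject(profile, spec, sid, rng))
            k += 1
    return recordings


def default_profiles(alpha_ratio=2.0, subject_sd=0.1, line_noise_amp=0.0):
    """Convenience pair of profiles: identical except the second class's
    alpha power is multiplied by ``alpha_ratio``.

    The effect band, direction and size are free simulation parameters, not
    claims about PNES physiology; an alpha elevation is merely a detectable,
    plausible resting-state contrast. ``alpha_ratio=1`` gives a null cohort.
    """
    base = dict(
        background_exponent=1.0,
        background_power=0.5,
        subject_sd=subject_sd,
        line_noise_amp=line_noise_amp,
    )
    cnt = ClassSpectralProfile(class_label="CNT", **base)
    pnes = ClassSpectralProfile(class_label="PNES", **base)
    pnes.band_power = dict(pnes.band_power)
    pnes.band_power["alpha"] *= alpha_ratio
    return cnt, pnes
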
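"""In-memory containers for continuous EEG and epoched EEG."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class EEGRecording:
    """A continuous multichannel EEG signal.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal in microvolts.
    fs : float
        Sampling rate in Hz.
    channel_labels : tuple of str
        Ordered electrode names (10/20 convention); must be unique and match
        the channel count.
    subject_id, class_label : str, optional
        Cohort metadata carried through the pipeline.
    segments : list of (int, int), optional
        Half-open sample spans of artifact-free segments after masking.
        ``None`` means the whole recording is one clean segment. Epoching
        never cuts a window across a segment boundary.
    """

    data: np.ndarray
    fs: float
    channel_labels: tuple
    subject_id: str | None = None
    class_label: str | None = None
    segments: list | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D channels x samples array")
        if self.data.shape[0] < 1 or self.data.shape[1] < 1:
            raise ValueError("recording needs at least one channel and one sample")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        self.channel_labels = tuple(self.channel_labels)
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_labels)} labels for {self.data.shape[0]} channels"
            )
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def clean_segments(self) -> list:
        """Sample spans to epoch over (whole recording if never masked)."""
        if self.segments is None:
            return [(0, self.n_samples)]
        return list(self.segments)

    def replace(self, **kwargs) -> "EEGRecording":
        out = dict(
            data=self.data, fs=self.fs, channel_labels=self.channel_labels,
            subject_id=self.subject_id, class_label=self.class_label,
            segments=self.segments,
        )
        out.update(kwargs)
        return EEGRecording(**out)


@dataclass
class EpochSet:
    """A stack of fixed-length, non-overlapping, artifact-free epochs for
    one subject.

    ``epochs`` has shape (n_epochs, n_channels, epoch_samples) with
    epoch_samples = epoch_len_s * fs exactly.
    """

    epochs: np.ndarray
    fs: float
    epoch_len_s: float
    channel_labels: tuple
    subject_id: str | None = None
    class_label: str | None = None

    def __post_init__(self):
        self.epochs = np.asarray(self.epochs, dtype=float)
        if self.epochs.ndim != 3:
            raise ValueError("epochs must be (n_epochs, n_channels, samples)")
        expected = int(round(self.epoch_len_s * self.fs))
        if self.epochs.shape[0] and self.epochs.shape[2] != expected:
            raise ValueError(
                f"epoch length {self.epochs.shape[2]} != epoch_len_s*fs = {expected}"
            )
        self.channel_labels = tuple(self.channel_labels)

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    @property
    def n_channels(self) -> int:
        return self.epochs.shape[1]

    @property
    def epoch_samples(self) -> int:
        return self.epochs.shape[2]
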
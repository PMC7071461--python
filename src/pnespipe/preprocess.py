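"""Preprocessing: filtering, downsampling, artifact masking and epoching.

The canonical order for raw clinical input is downsample (512 -> 256 Hz),
then band-pass + notch at the final rate, then artifact masking, then
epoching. All filtering is zero-phase (forward-backward), which doubles the
effective order but keeps epochs time-aligned with the raw signal — the
standard choice for offline EEG.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .recording import EEGRecording, EpochSet


@dataclass
class FilterSpec:
    """Analysis filter: Butterworth band-pass plus mains notch.

    Defaults are a 3rd-order 1-70 Hz band-pass and a Q=30 notch at 50 Hz.
    The acquisition hardware's own 0.5 Hz high-pass is provenance only; the
    analysis high-pass at 1 Hz is what gets applied here.
    """

    bp_low: float = 1.0
    bp_high: float = 70.0
    order: int = 3
    notch_freq: float = 50.0
    notch_q: float = 30.0

    def validate(self, fs):
        if not (0.0 < self.bp_low < self.bp_high):
            raise ValueError("need 0 < bp_low < bp_high")
        if self.bp_high >= fs / 2.0:
            raise ValueError(f"bp_high={self.bp_high} must be below Nyquist {fs / 2}")
        if self.order < 1:
            raise ValueError("filter order must be >= 1")


@dataclass
class ArtifactAnnotation:
    """Manually reviewed artifact spans: half-open (start_s, end_s) intervals."""

    intervals: list

    def merged(self, duration_s=None):
        """Non-overlapping canonical form, sorted by start."""
        ivals = []
        for start, end in self.intervals:
            if start < 0 or end <= start:
                raise ValueError(f"invalid artifact interval ({start}, {end})")
            if duration_s is not None and end > duration_s + 1e-9:
                raise ValueError(
                    f"interval ({start}, {end}) exceeds recording duration {duration_s}"
                )
            ivals.append((float(start), float(end)))
        ivals.sort()
        merged = []
        for start, end in ivals:
            if merged and start <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], end))
            else:
                merged.append((start, end))
        return merged


def bandpass_notch(recording, spec=None):
    """Apply the Butterworth band-pass and 50 Hz notch, zero-phase."""
    spec = spec or FilterSpec()
    spec.validate(recording.fs)
    sos = signal.butter(
        spec.order, [spec.bp_low, spec.bp_high], btype="bandpass",
        fs=recording.fs, output="sos",
    )
    out = signal.sosfiltfilt(sos, recording.data, axis=-1)
    if spec.notch_freq and spec.notch_freq < recording.fs / 2.0:
        b, a = signal.iirnotch(spec.notch_freq, spec.notch_q, fs=recording.fs)
        out = signal.filtfilt(b, a, out, axis=-1)
    if not np.all(np.isfinite(out)):
        raise FloatingPointError("filtering produced non-finite values")
    return recording.replace(data=out)


def downsample(recording, target_fs):
    """Anti-alias filter and decimate to ``target_fs`` (integer ratio only)."""
    ratio = recording.fs / target_fs
    q = int(round(ratio))
    if abs(ratio - q) > 1e-9 or q < 1:
        raise ValueError(
            f"fs={recording.fs} is not an integer multiple of target {target_fs}"
        )
    if q == 1:
        return recording
    out = signal.decimate(recording.data, q, axis=-1, zero_phase=True)
    return recording.replace(data=out, fs=float(target_fs))


def apply_artifact_mask(recording, annotation):
    """Drop annotated spans and concatenate the clean remainder.

    Segment boundaries of the concatenated signal are recorded on the
    result so that epoching never places a window across a cut.
    """
    merged = annotation.merged(duration_s=recording.duration_s)
    if not merged:
        return recording.replace(segments=recording.clean_segments())
    fs = recording.fs
    keep = []
    cursor = 0
    for start_s, end_s in merged:
        start, end = int(round(start_s * fs)), int(round(end_s * fs))
        if start > cursor:
            keep.append((cursor, start))
        cursor = max(cursor, end)
    if cursor < recording.n_samples:
        keep.append((cursor, recording.n_samples))
    if not keep:
        raise ValueError("annotation masks the entire recording")
    data = np.concatenate([recording.data[:, s:e] for s, e in keep], axis=1)
    segments, offset = [], 0
    for s, e in keep:
        segments.append((offset, offset + (e - s)))
        offset += e - s
    return recording.replace(data=data, segments=segments)


def epoch(recording, epoch_len_s=5.0, max_epochs=None):
    """Cut non-overlapping, contiguous epochs, earliest first.

    Windows are half-open [i*L, (i+1)*L) in samples within each clean
    segment; a trailing partial window in a segment is discarded. At most
    ``max_epochs`` epochs are returned.
    """
    L = int(round(epoch_len_s * recording.fs))
    chunks = []
    for start, end in recording.clean_segments():
        n = (end - start) // L
        for i in range(n):
            chunks.append(recording.data[:, start + i * L:start + (i + 1) * L])
            if max_epochs is not None and len(chunks) >= max_epochs:
                break
        if max_epochs is not None and len(chunks) >= max_epochs:
            break
    epochs = (
        np.stack(chunks) if chunks
        else np.empty((0, recording.n_channels, L))
    )
    return EpochSet(
        epochs=epochs, fs=recording.fs, epoch_len_s=epoch_len_s,
        channel_labels=recording.channel_labels,
        subject_id=recording.subject_id, class_label=recording.class_label,
    )


def preprocess_recording(recording, filter_spec=None, target_fs=256.0,
                         annotation=None, epoch_len_s=5.0, max_epochs=120):
    """Full preprocessing chain: downsample -> filter -> mask -> epoch."""
    rec = recording
    if target_fs and rec.fs != target_fs:
        rec = downsample(rec, target_fs)
    rec = bandpass_notch(rec, filter_spec)
    if annotation is not None:
        rec = apply_artifact_mask(rec, annotation)
    return epoch(rec, epoch_len_s=epoch_len_s, max_epochs=max_epochs)
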
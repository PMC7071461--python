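"""Readers and writers: ASCII/CSV matrices, EDF, cohort manifests, artifact
annotation sidecars.

ASCII layout: one header row of channel labels, then one row per sample
(channels in columns). ``read_ascii_eeg`` also accepts the transposed
orientation (channels in rows, no header) when told so.

EDF writing is implemented here directly against the EDF field layout
(256-byte fixed header, 256 bytes per signal, int16 little-endian data
records) because the environment offers no EDF writer; reading goes through
MNE. Physical scaling is symmetric around zero, so the round-trip error is
bounded by half a digital step: (phys_max - phys_min) / 65535 / 2.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .recording import EEGRecording

# ---------------------------------------------------------------------------
# ASCII / CSV


def write_ascii_eeg(recording, path):
    """Write a recording as CSV: header row of channel labels, samples in rows."""
    path = Path(path)
    header = ",".join(recording.channel_labels)
    np.savetxt(path, recording.data.T, delimiter=",", header=header, comments="",
               fmt="%.17g")
    return path


def read_ascii_eeg(path, fs, labels=None, channels_in_rows=False):
    """Read a plain numeric matrix as an EEG recording.

    With the default orientation the first row is a header of channel labels
    and samples run down the rows; ``labels`` then overrides the header if
    given. With ``channels_in_rows=True`` the file is a raw channels x
    samples matrix with no header and ``labels`` is required.
    """
    path = Path(path)
    if path.stat().st_size == 0:
        raise ValueError(f"empty EEG file: {path}")
    if channels_in_rows:
        data = np.loadtxt(path, delimiter=",", ndmin=2)
        if labels is None:
            raise ValueError("labels are required for channels-in-rows files")
    else:
        with open(path) as fh:
            header = fh.readline().strip()
        file_labels = [tok.strip() for tok in header.split(",")]
        data = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2).T
        if labels is None:
            labels = file_labels
    labels = tuple(labels)
    if len(labels) != data.shape[0]:
        raise ValueError(
            f"{len(labels)} labels for {data.shape[0]} channels in {path}"
        )
    return EEGRecording(data=data, fs=fs, channel_labels=labels)


# ---------------------------------------------------------------------------
# EDF

_EDF_DIG_MIN, _EDF_DIG_MAX = -32768, 32767


def _pad(text, width):
    s = str(text)[:width]
    return s + " " * (width - len(s))


def _fmt_num(x, width=8):
    for fmt in ("%g", "%.6g", "%.4g", "%.2g"):
        s = fmt % x
        if len(s) <= width:
            return s
    return ("%g" % x)[:width]


def write_edf(recording, path, patient_id="X", recording_id="synthetic"):
    """Write a recording to EDF with 1-second data records.

    fs must be a positive integer; the signal is zero-padded to a whole
    number of seconds if needed (the pad is dropped again on read only if
    the caller crops).
    """
    path = Path(path)
    fs = int(round(recording.fs))
    if abs(fs - recording.fs) > 1e-9 or fs <= 0:
        raise ValueError("EDF writer requires an integer sampling rate")
    data = recording.data
    n_ch, n_samp = data.shape
    n_rec = int(np.ceil(n_samp / fs))
    if n_rec * fs != n_samp:
        pad = np.zeros((n_ch, n_rec * fs - n_samp))
        data = np.concatenate([data, pad], axis=1)

    phys_max = np.max(np.abs(data), axis=1)
    phys_max[phys_max == 0] = 1.0
    phys_min = -phys_max
    scale = (phys_max - phys_min) / (_EDF_DIG_MAX - _EDF_DIG_MIN)
    digital = np.round((data - phys_min[:, None]) / scale[:, None]) + _EDF_DIG_MIN
    digital = np.clip(digital, _EDF_DIG_MIN, _EDF_DIG_MAX).astype("<i2")

    header = b"".join(
        _pad(v, w).encode("ascii")
        for v, w in [
            ("0", 8), (patient_id, 80), (recording_id, 80),
            ("01.01.01", 8), ("00.00.00", 8),
            (256 * (1 + n_ch), 8), ("", 44), (n_rec, 8), ("1", 8), (n_ch, 4),
        ]
    )
    fields = []
    for vals, width in [
        (recording.channel_labels, 16),
        (["" for _ in range(n_ch)], 80),             # transducer
        (["uV"] * n_ch, 8),                          # physical dimension
        ([_fmt_num(v) for v in phys_min], 8),
        ([_fmt_num(v) for v in phys_max], 8),
        ([str(_EDF_DIG_MIN)] * n_ch, 8),
        ([str(_EDF_DIG_MAX)] * n_ch, 8),
        (["" for _ in range(n_ch)], 80),             # prefiltering
        ([str(fs)] * n_ch, 8),
        (["" for _ in range(n_ch)], 32),
    ]:
        fields.append(b"".join(_pad(v, width).encode("ascii") for v in vals))
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(b"".join(fields))
        for r in range(n_rec):
            block = digital[:, r * fs:(r + 1) * fs]
            fh.write(block.tobytes())
    return path


def read_edf(path, labels=None):
    """Read an EDF file into an EEG recording (microvolts).

    ``labels``, if given, selects and orders a channel subset by name. All
    selected channels must share one sampling rate.
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    sfreqs = {raw.info["sfreq"]}
    if len(sfreqs) != 1:
        raise ValueError("mixed sampling rates are not supported")
    rec = EEGRecording(
        data=raw.get_data() * 1e6,  # MNE loads EEG in volts
        fs=float(raw.info["sfreq"]),
        channel_labels=tuple(raw.ch_names),
        subject_id=None,
    )
    if labels is not None:
        idx = []
        for lab in labels:
            if lab not in rec.channel_labels:
                raise ValueError(f"channel {lab!r} not in {path}")
            idx.append(rec.channel_labels.index(lab))
        rec = rec.replace(data=rec.data[idx], channel_labels=tuple(labels))
    return rec


# ---------------------------------------------------------------------------
# Cohort manifest and artifact annotations


def write_manifest(entries, path):
    """Write a cohort manifest: list of {subject_id, class_label, path, fs}."""
    path = Path(path)
    with open(path, "w") as fh:
        json.dump({"subjects": list(entries)}, fh, indent=2, sort_keys=True)
    return path


def read_manifest(path):
    with open(path) as fh:
        doc = json.load(fh)
    return doc["subjects"]


def read_annotations(path):
    """Read an artifact annotation sidecar.

    Accepts JSON (list of [start_s, end_s] pairs, possibly under an
    "artifacts" key) or CSV with two columns start_s,end_s.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        with open(path) as fh:
            doc = json.load(fh)
        if isinstance(doc, dict):
            doc = doc["artifacts"]
        return [(float(a), float(b)) for a, b in doc]
    rows = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
    return [(float(a), float(b)) for a, b in rows]
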
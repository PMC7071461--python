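"""Welch PSD estimation and band-moment feature extraction.

The spectral estimate is the classic averaged modified periodogram: an epoch
of N samples is split into L = floor((N - M)/h) + 1 segments of M samples
with hop h = M * (1 - overlap), each segment is tapered (Hamming by default)
and its one-sided periodogram

    Pxx(f) = |DFT(x_i * w)(f)|^2 / (fs * M * U),   U = (1/M) * sum(w^2)

is computed in density convention (units^2/Hz), then the L periodograms are
averaged:  PxxW(f) = (1/L) * sum_i Pxx_i(f).  With the defaults (M = nfft =
256, 50% overlap) a 5 s epoch at 256 Hz (1280 samples) yields L = 9 segments
on a 1 Hz frequency grid.

Features: the PSD of each channel is sliced into delta (1-4), theta (4-8),
alpha (8-13), beta (13-32) and the whole band (1-32 Hz), half-open [low,
high) so shared edges count once, and each slice is summarised by four
statistical moments of its bin values: mean m, population standard
deviation d, Fisher-Pearson skewness v, and Pearson (non-excess) kurtosis
k. Biased (1/N) central moments are used; if d = 0 the slice is degenerate
and v = k = 0 by convention. 19 channels x 5 bands x 4 moments = 380
features per epoch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy.signal import get_window

from .recording import EpochSet

MOMENT_NAMES = ("m", "d", "v", "k")

#: Metadata columns of a feature table; everything else is a feature.
METADATA_COLUMNS = ("subject_id", "class_label", "epoch_index")


@dataclass
class BandDefinition:
    """A named frequency band, half-open [low, high) in Hz."""

    name: str
    low: float
    high: float

    def __post_init__(self):
        if not self.low < self.high:
            raise ValueError(f"band {self.name}: low must be < high")


DEFAULT_BANDS = (
    BandDefinition("delta", 1.0, 4.0),
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("alpha", 8.0, 13.0),
    BandDefinition("beta", 13.0, 32.0),
    BandDefinition("whole", 1.0, 32.0),
)


@dataclass
class WelchConfig:
    """Welch estimator geometry and taper."""

    window_len: int = 256
    overlap_frac: float = 0.5
    window_kind: str = "hamming"
    nfft: int | None = None
    fs: float = 256.0

    def __post_init__(self):
        if not (0.0 <= self.overlap_frac < 1.0):
            raise ValueError("overlap_frac must lie in [0, 1)")
        if self.nfft is None:
            self.nfft = self.window_len
        if self.window_len > self.nfft:
            raise ValueError("window_len must be <= nfft")

    @property
    def hop(self) -> int:
        h = int(round(self.window_len * (1.0 - self.overlap_frac)))
        return max(h, 1)

    @property
    def window(self) -> np.ndarray:
        return get_window(self.window_kind, self.window_len)

    @property
    def freqs(self) -> np.ndarray:
        return np.fft.rfftfreq(self.nfft, d=1.0 / self.fs)

    def n_segments(self, n_samples) -> int:
        if n_samples < self.window_len:
            raise ValueError(
                f"epoch of {n_samples} samples shorter than window {self.window_len}"
            )
        return (n_samples - self.window_len) // self.hop + 1


@dataclass
class Spectrum:
    """One-sided power spectral density (units^2/Hz) on a frequency axis."""

    freqs: np.ndarray
    power: np.ndarray


@dataclass
class PSDMap:
    """Per-epoch channels x frequency-bins Welch PSD with a shared axis."""

    freqs: np.ndarray
    power: np.ndarray  # (n_channels, n_bins)
    channel_labels: tuple = ()


def _onesided_scale(cfg):
    """Multiplier turning |rfft|^2 into one-sided density values."""
    w = cfg.window
    scale = np.full(cfg.nfft // 2 + 1, 2.0)
    scale[0] = 1.0
    if cfg.nfft % 2 == 0:
        scale[-1] = 1.0
    return scale / (cfg.fs * np.sum(w ** 2))


def modified_periodogram(segment, cfg):
    """Single-segment tapered periodogram (one-sided density)."""
    segment = np.asarray(segment, dtype=float)
    if segment.shape[-1] != cfg.window_len:
        raise ValueError(
            f"segment length {segment.shape[-1]} != window_len {cfg.window_len}"
        )
    spec = np.fft.rfft(segment * cfg.window, n=cfg.nfft)
    power = (spec.real ** 2 + spec.imag ** 2) * _onesided_scale(cfg)
    return Spectrum(freqs=cfg.freqs, power=power)


def welch_psd(x, cfg):
    """Welch PSD of one channel of one epoch: mean of segment periodograms."""
    x = np.asarray(x, dtype=float)
    L = cfg.n_segments(x.shape[-1])
    segs = sliding_window_view(x, cfg.window_len, axis=-1)[..., ::cfg.hop, :][..., :L, :]
    spec = np.fft.rfft(segs * cfg.window, n=cfg.nfft, axis=-1)
    power = (spec.real ** 2 + spec.imag ** 2).mean(axis=-2) * _onesided_scale(cfg)
    return Spectrum(freqs=cfg.freqs, power=power)


def psd_map(epoch, cfg, channel_labels=()):
    """Welch PSD of every channel of a channels x samples epoch."""
    epoch = np.asarray(epoch, dtype=float)
    if epoch.ndim != 2:
        raise ValueError("epoch must be channels x samples")
    spec = welch_psd(epoch, cfg)
    return PSDMap(freqs=spec.freqs, power=spec.power,
                  channel_labels=tuple(channel_labels))


def band_slice(psdmap, band):
    """Columns of the map with band.low <= f < band.high."""
    mask = (psdmap.freqs >= band.low) & (psdmap.freqs < band.high)
    if psdmap.freqs[-1] < band.low or band.high <= psdmap.freqs[0]:
        raise ValueError(f"band {band.name} outside the frequency axis")
    if not mask.any():
        raise ValueError(f"band {band.name} contains no frequency bins")
    power = psdmap.power[..., mask] if psdmap.power.ndim > 1 else psdmap.power[mask]
    return PSDMap(freqs=psdmap.freqs[mask], power=power,
                  channel_labels=psdmap.channel_labels)


def band_moments(values):
    """(m, d, v, k) of a vector of PSD bin values.

    Biased central moments; for a degenerate slice (d = 0) skewness and
    kurtosis are set to 0 so no NaN reaches the classifiers.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or values.size == 0:
        raise ValueError("band_moments expects a non-empty 1-D vector")
    m = values.mean()
    c = values - m
    d = np.sqrt(np.mean(c ** 2))
    if d == 0.0:
        return np.array([m, 0.0, 0.0, 0.0])
    v = np.mean(c ** 3) / d ** 3
    k = np.mean(c ** 4) / d ** 4
    return np.array([m, d, v, k])


def _moments_matrix(power):
    """Vectorised band moments along the last axis -> (..., 4)."""
    m = power.mean(axis=-1)
    c = power - m[..., None]
    d = np.sqrt(np.mean(c ** 2, axis=-1))
    with np.errstate(divide="ignore", invalid="ignore"):
        v = np.mean(c ** 3, axis=-1) / d ** 3
        k = np.mean(c ** 4, axis=-1) / d ** 4
    v = np.where(d == 0.0, 0.0, v)
    k = np.where(d == 0.0, 0.0, k)
    return np.stack([m, d, v, k], axis=-1)


def epoch_features(epoch, cfg=None, bands=DEFAULT_BANDS):
    """Feature row for one epoch: channel-major, then band, then moment.

    For 19 channels and the default five bands this is 19 * 5 * 4 = 380
    values in the fixed order (channel, band, m/d/v/k).
    """
    cfg = cfg or WelchConfig()
    pmap = psd_map(np.atleast_2d(np.asarray(epoch, dtype=float)), cfg)
    blocks = [_moments_matrix(band_slice(pmap, b).power) for b in bands]
    # blocks: per band (n_channels, 4) -> (n_channels, n_bands, 4)
    return np.stack(blocks, axis=1).reshape(-1)


def feature_names(channel_labels, bands=DEFAULT_BANDS):
    """Column names matching epoch_features' order: '<ch>_<band>_<moment>'."""
    return [
        f"{ch}_{band.name}_{mom}"
        for ch in channel_labels
        for band in bands
        for mom in MOMENT_NAMES
    ]


def parse_feature_name(name):
    """Inverse of feature_names for one column: (channel, band, moment)."""
    ch, band, mom = name.rsplit("_", 2)
    return ch, band, mom


def build_feature_table(epoch_sets, cfg=None, bands=DEFAULT_BANDS):
    """Stack per-epoch feature rows of many subjects into one table.

    Returns a DataFrame with metadata columns (subject_id, class_label,
    epoch_index) followed by the feature columns, rows ordered by (subject,
    epoch_index).
    """
    cfg = cfg or WelchConfig()
    epoch_sets = list(epoch_sets)
    labels = None
    for es in epoch_sets:
        if labels is None:
            labels = es.channel_labels
        elif es.channel_labels != labels:
            raise ValueError(
                f"channel mismatch: subject {es.subject_id} has {es.channel_labels}"
            )
    if labels is None:
        labels = ()
    names = feature_names(labels, bands)
    rows, meta = [], []
    for es in epoch_sets:
        if es.n_epochs == 0:
            continue
        spec = welch_psd(es.epochs, cfg)  # (n_epochs, n_channels, n_bins)
        pmap = PSDMap(freqs=spec.freqs, power=spec.power)
        blocks = [_moments_matrix(band_slice(pmap, b).power) for b in bands]
        feats = np.stack(blocks, axis=2).reshape(es.n_epochs, -1)
        rows.append(feats)
        meta.extend(
            (es.subject_id, es.class_label, i) for i in range(es.n_epochs)
        )
    if rows:
        table = pd.DataFrame(np.concatenate(rows), columns=names)
    else:
        table = pd.DataFrame(columns=names)
    md = pd.DataFrame(meta, columns=list(METADATA_COLUMNS))
    return pd.concat([md, table.reset_index(drop=True)], axis=1)


def feature_matrix(table):
    """(X, feature column names) of a feature table DataFrame."""
    cols = [c for c in table.columns if c not in METADATA_COLUMNS]
    return table[cols].to_numpy(dtype=float), cols
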
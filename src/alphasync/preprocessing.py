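"""Epoching, artifact rejection, epoch-count gating and zero-phase FIR filtering.

The analysis unit throughout the pipeline is the artifact-free 4 s epoch.
Band-pass filtering uses a windowed-sinc (Hanning) FIR of order 1800 at
1 kHz, applied forward and backward for zero phase, with 2000 samples of
reflection padding per side; at other sampling rates both numbers scale
proportionally so the impulse response keeps the same duration in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal

from .spectral import BandDefinition

#: reference design: order 1800 and 2000-sample padding at 1000 Hz
FIR_ORDER_AT_1KHZ = 1800
PAD_SAMPLES_AT_1KHZ = 2000
REFERENCE_RATE = 1000.0
MIN_EPOCHS_DEFAULT = 15


@dataclass
class SensorEpochs:
    """Epoched multi-channel sensor data.

    data : (n_epochs, n_channels, n_samples), field units (arbitrary scale)
    rate : sampling rate, Hz
    channel_positions : (n_channels, 3), meters
    channel_orientations : (n_channels, 3), unit norm
    """

    data: np.ndarray
    rate: float
    channel_positions: np.ndarray
    channel_orientations: np.ndarray
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, float)
        if self.data.ndim != 3:
            raise ValueError("data must be (epochs, channels, samples)")
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        self.channel_positions = np.asarray(self.channel_positions, float)
        self.channel_orientations = np.asarray(self.channel_orientations, float)
        norms = np.linalg.norm(self.channel_orientations, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("channel orientations must be unit norm")
        if not self.channel_names:
            self.channel_names = [f"MAG{i:03d}" for i in range(self.n_channels)]

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def epoch_length(self) -> float:
        """Epoch duration in seconds."""
        return self.n_samples / self.rate


def segment_epochs(continuous: np.ndarray, rate: float, epoch_seconds: float = 4.0,
                   channel_positions: np.ndarray | None = None,
                   channel_orientations: np.ndarray | None = None,
                   channel_names: list[str] | None = None) -> SensorEpochs:
    """Cut a continuous (channels × samples) recording into consecutive
    non-overlapping epochs, discarding the trailing remainder."""
    continuous = np.atleast_2d(np.asarray(continuous, float))
    n_channels, n_samples = continuous.shape
    samples_per_epoch = int(round(epoch_seconds * rate))
    if n_samples < samples_per_epoch:
        raise ValueError(
            f"recording of {n_samples / rate:.2f} s is shorter than one "
            f"{epoch_seconds:.2f} s epoch")
    n_epochs = n_samples // samples_per_epoch
    data = continuous[:, :n_epochs * samples_per_epoch]
    data = data.reshape(n_channels, n_epochs, samples_per_epoch).transpose(1, 0, 2)
    if channel_positions is None:
        channel_positions = np.zeros((n_channels, 3))
    if channel_orientations is None:
        channel_orientations = np.tile([0.0, 0.0, 1.0], (n_channels, 1))
    return SensorEpochs(data.copy(), rate, channel_positions, channel_orientations,
                        channel_names or [])


def reject_artifact_epochs(epochs: SensorEpochs,
                           amplitude_z_threshold: float = 6.0,
                           jump_z_threshold: float = 6.0
                           ) -> tuple[SensorEpochs, pd.DataFrame]:
    """Drop epochs with extreme amplitudes or sample-to-sample jumps.

    A simple automated stand-in for interactive artifact screening: an epoch
    is rejected when its maximum absolute amplitude z-score (per channel,
    with channel mean/sd pooled over all epochs) or its maximum absolute
    first-difference z-score exceeds the threshold.  Returns the surviving
    epochs (order preserved) and a rejection log.
    """
    if amplitude_z_threshold <= 0 or jump_z_threshold <= 0:
        raise ValueError("thresholds must be positive")
    x = epochs.data
    mu = x.mean(axis=(0, 2), keepdims=True)
    sd = x.std(axis=(0, 2), keepdims=True)
    sd[sd == 0] = 1.0
    amp_z = np.abs((x - mu) / sd).max(axis=(1, 2))

    d = np.diff(x, axis=2)
    dmu = d.mean(axis=(0, 2), keepdims=True)
    dsd = d.std(axis=(0, 2), keepdims=True)
    dsd[dsd == 0] = 1.0
    jump_z = np.abs((d - dmu) / dsd).max(axis=(1, 2))

    records = []
    keep = np.ones(epochs.n_epochs, bool)
    for e in range(epochs.n_epochs):
        if amp_z[e] > amplitude_z_threshold:
            keep[e] = False
            records.append({"epoch": e, "reason": "amplitude", "statistic": amp_z[e]})
        elif jump_z[e] > jump_z_threshold:
            keep[e] = False
            records.append({"epoch": e, "reason": "jump", "statistic": jump_z[e]})
    log = pd.DataFrame(records, columns=["epoch", "reason", "statistic"])
    kept = replace(epochs, data=x[keep])
    return kept, log


def enforce_min_epochs(epochs: SensorEpochs, minimum: int = MIN_EPOCHS_DEFAULT) -> bool:
    """Subject inclusion rule: at least ``minimum`` clean epochs."""
    return epochs.n_epochs >= minimum


def design_band_fir(band: BandDefinition, rate: float,
                    order: int | None = None) -> np.ndarray:
    """Windowed-sinc (Hanning) band-pass FIR coefficients.

    ``order`` defaults to 1800 at 1 kHz, scaled proportionally (and rounded
    to even, so the filter stays type-I linear phase) at other rates.
    """
    if order is None:
        order = scaled_order(rate)
    if band.high_edge >= rate / 2:
        raise ValueError("band upper edge above Nyquist")
    return signal.firwin(order + 1, [band.low_edge, band.high_edge],
                         window="hann", pass_zero=False, fs=rate)


def scaled_order(rate: float) -> int:
    order = int(round(FIR_ORDER_AT_1KHZ * rate / REFERENCE_RATE))
    return order + order % 2


def scaled_pad(rate: float) -> int:
    return int(round(PAD_SAMPLES_AT_1KHZ * rate / REFERENCE_RATE))


def _two_pass_filter(x: np.ndarray, b: np.ndarray, pad: int) -> np.ndarray:
    """Zero-phase band-pass along the last axis with reflection padding.

    Each pass is an FFT convolution with the (symmetric, zero-delay-centred)
    kernel; two passes square the magnitude response, doubling the stop-band
    attenuation in dB while keeping the phase response identically zero.
    """
    n = x.shape[-1]
    if pad > 0:
        xp = np.pad(x, [(0, 0)] * (x.ndim - 1) + [(pad, pad)], mode="reflect")
    else:
        xp = x
    kernel = b.reshape((1,) * (xp.ndim - 1) + (-1,))
    for _ in range(2):
        xp = signal.fftconvolve(xp, kernel, mode="same", axes=-1)
    return xp[..., pad:pad + n]


def bandpass_fir(epochs: SensorEpochs, band: BandDefinition,
                 order: int | None = None,
                 pad_samples: int | None = None) -> SensorEpochs:
    """Zero-phase band-pass of every epoch.

    Epochs are reflection-padded by ``pad_samples`` on each side (padding
    with neighbouring raw data is impossible once epochs are cut), filtered
    forward and backward, and the padding removed.
    """
    if order is None:
        order = scaled_order(epochs.rate)
    if pad_samples is None:
        pad_samples = scaled_pad(epochs.rate)
    n_taps = order + 1
    if epochs.n_samples + 2 * pad_samples <= n_taps:
        raise ValueError(
            f"epoch of {epochs.n_samples} samples plus 2×{pad_samples} padding "
            f"is too short for a {n_taps}-tap filter; need more than "
            f"{n_taps - 2 * pad_samples} samples per epoch")
    b = design_band_fir(band, epochs.rate, order)
    out = _two_pass_filter(epochs.data, b, pad_samples)
    return replace(epochs, data=out)
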
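"""Power spectra, individual alpha frequency (IAF) and band definition.

The analysis band is anchored to the alpha peak of the posterior-channel
power spectrum: the band spans IAF − 2.5 Hz to IAF + 2 Hz (the asymmetric
alpha width of Klimesch), so a sample-average IAF of 9.4 Hz yields the
6.9–11.4 Hz band.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

IAF_SEARCH_RANGE = (6.0, 13.0)
BAND_BELOW_IAF = 2.5
BAND_ABOVE_IAF = 2.0
MAX_RESOLUTION_HZ = 0.25


class NoAlphaPeakError(ValueError):
    """The averaged spectrum has no local maximum in the alpha search range."""


@dataclass(frozen=True)
class BandDefinition:
    """Frequency band anchored at an alpha peak; edges at IAF−2.5 / IAF+2 Hz."""

    iaf: float
    low_edge: float
    high_edge: float

    def __post_init__(self) -> None:
        if self.low_edge <= 0:
            raise ValueError("band lower edge must be positive")
        if not (np.isclose(self.low_edge, self.iaf - BAND_BELOW_IAF)
                and np.isclose(self.high_edge, self.iaf + BAND_ABOVE_IAF)):
            raise ValueError("band edges must be IAF-2.5 and IAF+2 Hz")

    @property
    def width(self) -> float:
        return self.high_edge - self.low_edge


def define_band(iaf: float) -> BandDefinition:
    """Analysis band from an alpha peak frequency: (IAF − 2.5, IAF + 2) Hz."""
    if iaf <= BAND_BELOW_IAF:
        raise ValueError(
            f"IAF of {iaf} Hz gives a non-positive lower band edge")
    return BandDefinition(iaf=iaf, low_edge=iaf - BAND_BELOW_IAF,
                          high_edge=iaf + BAND_ABOVE_IAF)


def power_spectrum(epochs, channel_subset: list[str] | None = None,
                   resolution: float = 0.2) -> pd.DataFrame:
    """Epoch-averaged Welch periodogram per channel.

    Each epoch is one Hann-windowed segment, zero-padded so the frequency
    grid is at most ``resolution`` Hz apart; per-epoch periodograms are
    averaged.  Returns a DataFrame indexed by frequency with one column per
    requested channel.
    """
    if epochs.n_epochs < 1:
        raise ValueError("need at least one epoch")
    names = list(epochs.channel_names)
    if channel_subset is None:
        idx = np.arange(epochs.n_channels)
    else:
        if not channel_subset:
            raise ValueError("channel subset is empty")
        unknown = [c for c in channel_subset if c not in names]
        if unknown:
            raise KeyError(f"unknown channels: {unknown}")
        idx = np.array([names.index(c) for c in channel_subset])
    x = epochs.data[:, idx, :]
    nfft = max(epochs.n_samples,
               int(2 ** np.ceil(np.log2(epochs.rate / resolution))))
    freqs, psd = signal.welch(x, fs=epochs.rate, window="hann",
                              nperseg=epochs.n_samples, noverlap=0,
                              nfft=nfft, axis=-1, detrend="constant")
    psd = psd.mean(axis=0).T  # (freqs, channels)
    return pd.DataFrame(psd, index=pd.Index(freqs, name="frequency"),
                        columns=[names[i] for i in idx])


def detect_iaf(spectrum: pd.DataFrame,
               search_range: tuple[float, float] = IAF_SEARCH_RANGE) -> float:
    """Frequency of the most prominent alpha peak of the channel-averaged
    spectrum.

    The peak must be a local maximum inside ``search_range``; a spectrum
    that only decreases (or increases) through the range raises
    :class:`NoAlphaPeakError` rather than silently returning a range edge.
    """
    freqs = spectrum.index.to_numpy(float)
    lo, hi = search_range
    if lo < freqs.min() or hi > freqs.max():
        raise ValueError("search range outside spectrum support")
    mean_power = spectrum.to_numpy(float).mean(axis=1)
    peaks, _ = signal.find_peaks(mean_power)
    in_range = peaks[(freqs[peaks] >= lo) & (freqs[peaks] <= hi)]
    if in_range.size == 0:
        raise NoAlphaPeakError(
            f"no local spectral maximum in {lo}-{hi} Hz")
    best = in_range[np.argmax(mean_power[in_range])]
    return float(freqs[best])
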
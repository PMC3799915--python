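"""Interpretation of fitted spatial-FIR filters.

A fitted column lives on the delay-embedded space, so it can be read two
ways: sliced by delay blocks it is a set of 2k+1 spatial filters, one per
time delay; sliced by channel it is a pool of channel-specific FIR filters
of 2k+1 taps each.  This module implements both readings plus the spectral
summaries typically plotted for them: the FIR magnitude response of a
channel's taps, the relative power spectrum of an (average) evoked
response before/after filtering, and class-averaged filtered waveforms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .core import SpatialSpectralModel, _condition_split
from .delay_embedding import embed, row_index
from .epochs_io import EEGEpochs
from .exceptions import ParameterError, ValidationError

__all__ = [
    "FIRCoefficients",
    "FrequencyResponse",
    "PowerSpectrum",
    "split_spatial_filters",
    "channel_fir",
    "frequency_response",
    "relative_power",
    "filtered_erp",
]


@dataclass
class FIRCoefficients:
    """2k+1 FIR taps of one channel extracted from one model column.

    ``taps[j]`` is the coefficient at delay ``i = j - k``, i.e. the taps are
    stored in delay order from ``-k`` to ``+k`` (symmetric, non-causal
    support).
    """

    taps: np.ndarray
    channel: int
    filter_id: int
    k: int

    def __post_init__(self) -> None:
        self.taps = np.asarray(self.taps, dtype=np.float64)
        if self.taps.shape != (2 * self.k + 1,):
            raise ValidationError(
                f"taps: expected length {2 * self.k + 1}, got {self.taps.shape}"
            )
        if not np.all(np.isfinite(self.taps)):
            raise ValidationError("taps: contains non-finite values")


@dataclass
class FrequencyResponse:
    """Complex frequency response on a uniform grid over [0, fs/2]."""

    freqs: np.ndarray
    H: np.ndarray

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=np.float64)
        self.H = np.asarray(self.H, dtype=np.complex128)
        if self.freqs.shape != self.H.shape:
            raise ValidationError("freqs: length does not match H")
        if np.any(np.diff(self.freqs) <= 0):
            raise ValidationError("freqs: must be strictly ascending")

    @property
    def magnitude(self) -> np.ndarray:
        return np.abs(self.H)


@dataclass
class PowerSpectrum:
    """Periodogram normalised to unit total mass."""

    freqs: np.ndarray
    relative_power: np.ndarray

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=np.float64)
        self.relative_power = np.asarray(self.relative_power, dtype=np.float64)
        if self.freqs.shape != self.relative_power.shape:
            raise ValidationError("freqs: length does not match relative_power")
        if np.any(self.relative_power < 0):
            raise ValidationError("relative_power: negative entries")
        if abs(self.relative_power.sum() - 1.0) > 1e-9:
            raise ValidationError("relative_power: does not sum to 1")


def _check_filter_id(model: SpatialSpectralModel, filter_id: int) -> int:
    filter_id = int(filter_id)
    if not 0 <= filter_id < model.W.shape[1]:
        raise ParameterError(
            f"filter_id: {filter_id} outside [0, {model.W.shape[1]})"
        )
    return filter_id


def split_spatial_filters(model: SpatialSpectralModel, filter_id: int):
    """Slice one column into its 2k+1 per-delay spatial filters.

    Returns a list of ``(delay, weights)`` pairs with ``delay`` running from
    ``-k`` to ``+k`` and ``weights`` of length ``n_channels``.  Concatenating
    the weights in delay order reconstructs the column exactly.
    """
    filter_id = _check_filter_id(model, filter_id)
    col = model.W[:, filter_id]
    C = model.n_channels
    return [
        (i, col[(i + model.k) * C : (i + model.k + 1) * C].copy())
        for i in range(-model.k, model.k + 1)
    ]


def channel_fir(
    model: SpatialSpectralModel, filter_id: int, channel: int
) -> FIRCoefficients:
    """Extract one channel's FIR taps from a model column.

    ``taps[i]`` is the column entry at ``row_index(i, channel)`` — the
    channel's weight across delay blocks.
    """
    filter_id = _check_filter_id(model, filter_id)
    if not 0 <= channel < model.n_channels:
        raise ParameterError(
            f"channel: {channel} outside [0, {model.n_channels})"
        )
    k = model.k
    taps = np.array(
        [
            model.W[row_index(i, channel, k, model.n_channels), filter_id]
            for i in range(-k, k + 1)
        ]
    )
    return FIRCoefficients(taps=taps, channel=channel, filter_id=filter_id, k=k)


def frequency_response(
    fir: FIRCoefficients, fs: float, n_points: int = 512
) -> FrequencyResponse:
    """Frequency response ``H(f) = sum_i taps[i] exp(-j 2 pi f i / fs)``.

    Evaluated on a uniform grid of ``n_points`` frequencies over
    ``[0, fs/2]``.  The symmetric non-causal support makes ``H`` complex in
    general; plots typically show ``|H|`` only.
    """
    if fs <= 0:
        raise ParameterError(f"fs: must be positive, got {fs}")
    if n_points < 2:
        raise ParameterError(f"n_points: must be >= 2, got {n_points}")
    freqs = np.linspace(0.0, fs / 2.0, n_points)
    delays = np.arange(-fir.k, fir.k + 1)
    H = np.exp(-2j * np.pi * np.outer(freqs, delays) / fs) @ fir.taps
    return FrequencyResponse(freqs=freqs, H=H)


def relative_power(series: np.ndarray, fs: float) -> PowerSpectrum:
    """Periodogram of a one-channel series, normalised to total mass 1."""
    series = np.asarray(series, dtype=np.float64).ravel()
    if series.size < 8:
        raise ValidationError(f"series: length {series.size} < 8")
    if not np.any(series):
        raise ValidationError("series: all-zero signal has no power spectrum")
    freqs, pxx = sps.periodogram(series, fs=fs, window="boxcar", detrend=False)
    return PowerSpectrum(freqs=freqs, relative_power=pxx / pxx.sum())


def filtered_erp(
    model: SpatialSpectralModel, epochs: EEGEpochs, filter_id: int
) -> dict[int, np.ndarray]:
    """Class-averaged waveform of trials projected onto one model column.

    Returns ``{1: mean series, 2: mean series}`` (condition 1 = smaller
    label value), each of length ``n_samples - 2k``.
    """
    filter_id = _check_filter_id(model, filter_id)
    if epochs.n_channels != model.n_channels:
        raise ValidationError(
            f"epochs: {epochs.n_channels} channels, model expects {model.n_channels}"
        )
    l1, l2 = _condition_split(epochs.labels)
    aug = embed(epochs, model.k)
    proj = np.einsum("d,tds->ts", model.W[:, filter_id], aug.data)
    return {
        1: proj[epochs.labels == l1].mean(axis=0),
        2: proj[epochs.labels == l2].mean(axis=0),
    }
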
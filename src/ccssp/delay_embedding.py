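"""Time-delay embedding: the augmentation that turns FIR taps into channels.

For an FIR half-order ``k``, every channel is replicated at the 2k+1 delays
``i = -k .. +k`` and the copies are stacked as extra rows, giving
``D = n_channels * (2k+1)`` rows per trial.  A spatial weight vector on this
augmented space is therefore simultaneously one spatial filter per delay
and one (2k+1)-tap FIR filter per channel.

Block layout is delay-major: all channels at delay ``-k`` first, then delay
``-k+1``, and so on — splitting a fitted filter into per-delay spatial
filters is a contiguous slice.  Only the valid region is retained (the
``k`` samples at each end, where some shift would run off the trial, are
dropped; no zero padding), so ``T' = n_samples - 2k``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .epochs_io import EEGEpochs
from .exceptions import ParameterError

__all__ = ["AugmentedEpochs", "embed", "row_index"]


@dataclass
class AugmentedEpochs:
    """Delay-embedded trials: ``(n_trials, D, T')`` with delay-major rows."""

    data: np.ndarray
    k: int
    n_channels: int
    labels: np.ndarray
    fs: float

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_rows(self) -> int:
        return self.data.shape[1]

    @property
    def n_valid_samples(self) -> int:
        return self.data.shape[2]


def row_index(delay: int, channel: int, k: int, n_channels: int) -> int:
    """Map ``(delay, channel)`` to its row in the augmented space.

    ``row = (delay + k) * n_channels + channel``; the mapping is a bijection
    onto ``0 .. n_channels*(2k+1) - 1``.
    """
    if not -k <= delay <= k:
        raise ParameterError(f"delay: {delay} outside [-{k}, {k}]")
    if not 0 <= channel < n_channels:
        raise ParameterError(f"channel: {channel} outside [0, {n_channels})")
    return (delay + k) * n_channels + channel


def embed(epochs: EEGEpochs, k: int) -> AugmentedEpochs:
    """Stack the 2k+1 delayed copies of every channel of every trial.

    The row for ``(delay i, channel c)`` at valid sample ``t`` equals the
    original channel ``c`` at sample ``t + k + i``.  ``k = 0`` returns the
    input data unchanged (D = C, T' = T).
    """
    k = int(k)
    if k < 0:
        raise ParameterError(f"k: must be non-negative, got {k}")
    T = epochs.n_samples
    if T <= 2 * k:
        raise ParameterError(
            f"k: epoch length {T} too short; need n_samples > 2k = {2 * k}"
        )
    C = epochs.n_channels
    Tp = T - 2 * k
    if k == 0:
        out = epochs.data.copy()
    else:
        out = np.empty((epochs.n_trials, C * (2 * k + 1), Tp))
        for i in range(-k, k + 1):
            block = slice((i + k) * C, (i + k + 1) * C)
            out[:, block, :] = epochs.data[:, :, k + i : k + i + Tp]
    return AugmentedEpochs(
        data=out, k=k, n_channels=C, labels=epochs.labels.copy(), fs=epochs.fs
    )
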
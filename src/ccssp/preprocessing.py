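"""Temporal filtering recipes and epoch segmentation.

Two named presets mirror the two study protocols:

* ``mi`` — motor-imagery trials band-pass filtered 8-30 Hz with a 5th-order
  Butterworth filter (causal by default; a zero-phase flag is available).
* ``rsvp`` — the continuous recording is high-pass filtered at 1 Hz twice,
  then low-pass filtered at 25 Hz, both with zero-phase linear-phase FIR
  filters (windowed sinc, order ``3*fs/cutoff`` rounded up to even), after
  which 0-500 ms event-locked epochs are cut.

Epoch windows are half-open ``[t0, t1)`` with 0-based sample indexing, so a
window of 0.5 s at 250 Hz always contains exactly 125 samples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import signal as sps

from .epochs_io import ContinuousEEG, EEGEpochs
from .exceptions import ParameterError, ValidationError

__all__ = [
    "FilterSpec",
    "apply_filter",
    "segment",
    "mi_bandpass",
    "preprocess_mi",
    "preprocess_rsvp",
    "PRESETS",
]


@dataclass(frozen=True)
class FilterSpec:
    """A temporal filter design plus how it is applied.

    Parameters
    ----------
    kind : {"bandpass-iir", "highpass", "lowpass"}
        ``bandpass-iir`` designs a Butterworth filter of the given order;
        ``highpass``/``lowpass`` design linear-phase windowed-sinc FIR
        filters (Hamming window).
    band : tuple of float
        One cutoff (highpass/lowpass) or two band edges in Hz; every cutoff
        must lie strictly inside ``(0, fs/2)`` at application time.
    order : int or None
        Filter order (>= 1).  ``None`` is allowed only for the FIR kinds and
        selects the default rule ``ceil_to_even(3 * fs / cutoff)``.
    passes : int
        Number of repeated applications of the same filter (default 1).
    zero_phase : bool
        Forward-backward application.  Default False (causal), matching the
        Butterworth recipe; the FIR presets set it True.
    """

    kind: str
    band: tuple
    order: int | None = None
    passes: int = 1
    zero_phase: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("bandpass-iir", "highpass", "lowpass"):
            raise ParameterError(f"kind: unknown filter kind {self.kind!r}")
        band = tuple(float(b) for b in np.atleast_1d(self.band))
        object.__setattr__(self, "band", band)
        expected = 2 if self.kind == "bandpass-iir" else 1
        if len(band) != expected:
            raise ParameterError(
                f"band: {self.kind} needs {expected} cutoff(s), got {len(band)}"
            )
        if any(b <= 0 for b in band) or (expected == 2 and band[0] >= band[1]):
            raise ParameterError(f"band: invalid cutoffs {band}")
        if self.order is not None and self.order < 1:
            raise ParameterError(f"order: must be >= 1, got {self.order}")
        if self.order is None and self.kind == "bandpass-iir":
            raise ParameterError("order: required for bandpass-iir")
        if self.passes < 1:
            raise ParameterError(f"passes: must be >= 1, got {self.passes}")


def _fir_order(spec: FilterSpec, fs: float) -> int:
    if spec.order is not None:
        return spec.order
    order = math.ceil(3 * fs / spec.band[0])
    return order + (order % 2)  # even order -> odd tap count, exact linear phase


def _filter_matrix(x: np.ndarray, spec: FilterSpec, fs: float) -> np.ndarray:
    """Filter each row of a (channels, samples) array."""
    if any(b >= fs / 2 for b in spec.band):
        raise ParameterError(
            f"band: cutoff {max(spec.band)} Hz is not below Nyquist {fs / 2} Hz"
        )
    y = x
    if spec.kind == "bandpass-iir":
        sos = sps.butter(spec.order, spec.band, btype="bandpass", fs=fs, output="sos")
        for _ in range(spec.passes):
            y = sps.sosfiltfilt(sos, y, axis=-1) if spec.zero_phase else sps.sosfilt(sos, y, axis=-1)
    else:
        numtaps = _fir_order(spec, fs) + 1
        b = sps.firwin(numtaps, spec.band[0], pass_zero=(spec.kind == "lowpass"), fs=fs)
        for _ in range(spec.passes):
            if spec.zero_phase:
                padlen = min(3 * numtaps, y.shape[-1] - 1)
                y = sps.filtfilt(b, [1.0], y, axis=-1, padlen=padlen)
            else:
                full = sps.lfilter(b, [1.0], np.concatenate(
                    [y, np.zeros(y.shape[:-1] + (numtaps // 2,))], axis=-1))
                y = full[..., numtaps // 2:]  # compensate the linear-phase delay
    return y


def apply_filter(obj, spec: FilterSpec):
    """Filter every channel of *obj* independently; shape is preserved.

    *obj* may be :class:`ContinuousEEG` or :class:`EEGEpochs`; the return
    type matches the input.  ``spec.passes = n`` applies the filter ``n``
    times in sequence.
    """
    if isinstance(obj, ContinuousEEG):
        return ContinuousEEG(
            data=_filter_matrix(obj.data, spec, obj.fs),
            fs=obj.fs,
            channel_names=list(obj.channel_names),
        )
    if isinstance(obj, EEGEpochs):
        if obj.n_trials == 0:
            return obj
        flat = obj.data.reshape(-1, obj.n_samples)
        out = _filter_matrix(flat, spec, obj.fs).reshape(obj.data.shape)
        return EEGEpochs(
            data=out, labels=obj.labels, fs=obj.fs, channel_names=list(obj.channel_names)
        )
    raise ValidationError("signal: expected ContinuousEEG or EEGEpochs")


def segment(
    cont: ContinuousEEG,
    onsets: Sequence[int],
    window: tuple,
    labels: Sequence[int],
) -> EEGEpochs:
    """Cut event-locked epochs out of a continuous recording.

    The window ``[t0, t1)`` is half-open: each epoch holds
    ``round((t1 - t0) * fs)`` samples starting at ``onset + round(t0 * fs)``;
    the sample at exactly ``t1`` is excluded.
    """
    t0, t1 = float(window[0]), float(window[1])
    if t1 <= t0:
        raise ParameterError(f"window: t1 must exceed t0, got {window}")
    onsets = [int(o) for o in onsets]
    labels = np.asarray(list(labels))
    if len(labels) != len(onsets):
        raise ValidationError(
            f"labels: {len(labels)} labels for {len(onsets)} onsets"
        )
    n_samp = round((t1 - t0) * cont.fs)
    off = round(t0 * cont.fs)
    names = cont.channel_names or [f"ch{c}" for c in range(cont.n_channels)]
    bad = [o for o in onsets if o + off < 0 or o + off + n_samp > cont.n_samples]
    if bad:
        raise ValidationError(
            f"onsets: window [{t0}, {t1}) s exceeds the recording for onsets {bad}"
        )
    if not onsets:
        return EEGEpochs(
            data=np.zeros((0, cont.n_channels, n_samp)),
            labels=np.zeros(0, dtype=np.int64),
            fs=cont.fs,
            channel_names=names,
        )
    data = np.stack([cont.data[:, o + off : o + off + n_samp] for o in onsets])
    return EEGEpochs(
        data=data, labels=labels, fs=cont.fs, channel_names=names
    )


# ---------------------------------------------------------------------------
# Named presets
# ---------------------------------------------------------------------------

def mi_bandpass(zero_phase: bool = False) -> FilterSpec:
    """The motor-imagery recipe: 8-30 Hz, 5th-order Butterworth."""
    return FilterSpec(kind="bandpass-iir", band=(8.0, 30.0), order=5,
                      zero_phase=zero_phase)


def preprocess_mi(epochs: EEGEpochs, zero_phase: bool = False) -> EEGEpochs:
    """Apply the ``mi`` preset to already-epoched trials."""
    return apply_filter(epochs, mi_bandpass(zero_phase=zero_phase))


def preprocess_rsvp(
    cont: ContinuousEEG,
    onsets: Sequence[int],
    labels: Sequence[int],
    window: tuple = (0.0, 0.5),
) -> EEGEpochs:
    """The ``rsvp`` preset: 1 Hz high-pass twice, 25 Hz low-pass, then
    0-500 ms event-locked epochs."""
    hp = FilterSpec(kind="highpass", band=(1.0,), passes=2, zero_phase=True)
    lp = FilterSpec(kind="lowpass", band=(25.0,), zero_phase=True)
    filtered = apply_filter(apply_filter(cont, hp), lp)
    return segment(filtered, onsets, window, labels)


PRESETS = {
    "mi": mi_bandpass(),
    "rsvp-highpass": FilterSpec(kind="highpass", band=(1.0,), passes=2, zero_phase=True),
    "rsvp-lowpass": FilterSpec(kind="lowpass", band=(25.0,), zero_phase=True),
}
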
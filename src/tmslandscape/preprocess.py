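"""ERP preprocessing of TMS-locked EEG epochs.

The stage order is fixed: amplitude-based trial rejection, trial
averaging to the event-related potential (ERP), zero-phase FIR bandpass
(1-50 Hz by default), decimation by 2 with anti-alias filtering, and
common-average re-referencing.  Epochs are 2 s windows centered on the
TMS pulse; after decimation the ERP keeps its 2 s duration at half the
sampling rate, so the pulse-locked halves are 500 samples each.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve, firwin

__all__ = [
    "EpochSet",
    "ErpSignal",
    "ArtifactRejectionError",
    "reject_artifacts",
    "average_erp",
    "bandpass_fir",
    "decimate",
    "rereference_common_average",
    "preprocess_pipeline",
    "design_bandpass",
    "zero_phase_filter",
]

DEFAULT_CHANNELS = ("F3", "FZ", "F4", "T3", "CZ", "T4", "P3", "PZ", "P4", "O1", "O2")


class ArtifactRejectionError(RuntimeError):
    """Raised when amplitude thresholding leaves no usable trials."""


@dataclass
class EpochSet:
    """Per-subject stack of TMS-locked EEG trials.

    ``data`` is (n_trials, n_channels, n_samples) in microvolts;
    ``pulse_sample`` marks the TMS pulse and must split the epoch into two
    equal halves.
    """

    data: np.ndarray
    fs_hz: float
    pulse_sample: int
    channel_labels: tuple[str, ...] = DEFAULT_CHANNELS
    subject_id: str | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be 3-D (trials x channels x samples)")
        self.channel_labels = tuple(self.channel_labels)
        if len(self.channel_labels) != self.data.shape[1]:
            raise ValueError("channel_labels length does not match data")
        if 2 * self.pulse_sample != self.data.shape[2]:
            raise ValueError(
                f"pulse_sample={self.pulse_sample} does not split the "
                f"{self.data.shape[2]}-sample epoch into equal halves"
            )

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]


@dataclass
class ErpSignal:
    """Trial-averaged EEG (channels x samples, microvolts)."""

    data: np.ndarray
    fs_hz: float
    n_trials_used: int
    pulse_sample: int
    channel_labels: tuple[str, ...] = DEFAULT_CHANNELS
    subject_id: str | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("ERP contains non-finite values")
        self.channel_labels = tuple(self.channel_labels)

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def copy_with(self, data: np.ndarray, **kwargs) -> "ErpSignal":
        fields = dict(
            fs_hz=self.fs_hz,
            n_trials_used=self.n_trials_used,
            pulse_sample=self.pulse_sample,
            channel_labels=self.channel_labels,
            subject_id=self.subject_id,
        )
        fields.update(kwargs)
        return ErpSignal(data=data, **fields)


# ---------------------------------------------------------------------------
# filtering primitives
# ---------------------------------------------------------------------------


def design_bandpass(
    low_hz: float, high_hz: float, fs_hz: float, numtaps: int | None = None
) -> np.ndarray:
    """Hamming-window FIR bandpass taps with an exact null at DC.

    The default order (about half a second of taps) keeps the transition
    bands a few hertz wide, which gives >= 40 dB stopband attenuation per
    pass; zero-phase application squares the magnitude response.  The taps
    are shifted to sum exactly to zero so a DC offset is removed exactly
    even though the lower band edge may sit close to 0 Hz.
    """
    if not (0.0 < low_hz < high_hz < fs_hz / 2.0):
        raise ValueError(
            f"invalid band ({low_hz}, {high_hz}) Hz for fs={fs_hz} Hz: "
            "need 0 < low < high < fs/2"
        )
    if numtaps is None:
        numtaps = int(round(0.5 * fs_hz)) | 1
    taps = firwin(numtaps, [low_hz, high_hz], pass_zero=False, fs=fs_hz, window="hamming")
    taps = taps - taps.sum() / numtaps  # force H(0) = 0
    return taps


def zero_phase_filter(x: np.ndarray, taps: np.ndarray, axis: int = -1) -> np.ndarray:
    """Forward-backward FIR filtering (zero phase, |H|^2 magnitude).

    Implemented as a single FFT convolution with the filter's
    autocorrelation kernel, after odd-reflection padding of the edges
    (the same boundary rule scipy's filtfilt uses).
    """
    x = np.asarray(x, dtype=float)
    x = np.moveaxis(x, axis, -1)
    n = x.shape[-1]
    kernel = np.convolve(taps, taps[::-1])
    pad = len(taps) - 1
    if pad >= n:
        raise ValueError(f"signal of {n} samples is too short for {len(taps)} taps")
    left = 2.0 * x[..., :1] - x[..., pad:0:-1]
    right = 2.0 * x[..., -1:] - x[..., -2 : -pad - 2 : -1]
    padded = np.concatenate([left, x, right], axis=-1)
    y = fftconvolve(padded, kernel[(np.newaxis,) * (x.ndim - 1)], mode="same")
    y = y[..., pad : pad + n]
    return np.moveaxis(y, -1, axis)


# ---------------------------------------------------------------------------
# pipeline stages
# ---------------------------------------------------------------------------


def reject_artifacts(epochs: EpochSet, threshold_uv: float = 75.0) -> EpochSet:
    """Drop trials whose absolute amplitude exceeds the threshold anywhere.

    Surviving trials keep their original order.  Raises
    :class:`ArtifactRejectionError` if nothing survives.
    """
    if threshold_uv <= 0:
        raise ValueError("threshold_uv must be positive")
    keep = np.abs(epochs.data).max(axis=(1, 2)) <= threshold_uv
    if not keep.any():
        raise ArtifactRejectionError(
            f"subject {epochs.subject_id!r}: all {epochs.n_trials} trials exceed "
            f"+-{threshold_uv} uV"
        )
    return EpochSet(
        data=epochs.data[keep],
        fs_hz=epochs.fs_hz,
        pulse_sample=epochs.pulse_sample,
        channel_labels=epochs.channel_labels,
        subject_id=epochs.subject_id,
    )


def average_erp(epochs: EpochSet) -> ErpSignal:
    """Pointwise trial mean, x'(t) = (1/N) sum_k x(t, k)."""
    if epochs.n_trials < 1:
        raise ValueError("cannot average an empty epoch set")
    return ErpSignal(
        data=epochs.data.mean(axis=0),
        fs_hz=epochs.fs_hz,
        n_trials_used=epochs.n_trials,
        pulse_sample=epochs.pulse_sample,
        channel_labels=epochs.channel_labels,
        subject_id=epochs.subject_id,
    )


def bandpass_fir(
    signal: ErpSignal,
    low_hz: float = 1.0,
    high_hz: float = 50.0,
    numtaps: int | None = None,
) -> ErpSignal:
    """Zero-phase FIR bandpass of every channel."""
    taps = design_bandpass(low_hz, high_hz, signal.fs_hz, numtaps)
    return signal.copy_with(zero_phase_filter(signal.data, taps, axis=-1))


def decimate(signal: ErpSignal, factor: int = 2) -> ErpSignal:
    """Downsample by an integer factor after anti-alias low-pass filtering.

    The anti-alias cutoff is 0.8x the new Nyquist frequency.  The sample
    count must divide evenly; the sampling rate and pulse index are
    remapped.
    """
    if factor < 1 or int(factor) != factor:
        raise ValueError("factor must be a positive integer")
    factor = int(factor)
    if factor == 1:
        return signal.copy_with(signal.data.copy())
    n = signal.n_samples
    if n % factor != 0:
        raise ValueError(f"{n} samples are not divisible by decimation factor {factor}")
    new_nyquist = signal.fs_hz / (2.0 * factor)
    taps = firwin(101, 0.8 * new_nyquist, fs=signal.fs_hz, window="hamming")
    filtered = zero_phase_filter(signal.data, taps, axis=-1)
    return signal.copy_with(
        filtered[:, ::factor],
        fs_hz=signal.fs_hz / factor,
        pulse_sample=signal.pulse_sample // factor,
    )


def rereference_common_average(signal: ErpSignal) -> ErpSignal:
    """Subtract the across-channel mean at every sample."""
    if signal.data.shape[0] < 2:
        raise ValueError("common-average reference needs at least 2 channels")
    return signal.copy_with(signal.data - signal.data.mean(axis=0, keepdims=True))


def preprocess_pipeline(
    epochs: EpochSet,
    *,
    reject_uv: float = 75.0,
    band_hz: tuple[float, float] = (1.0, 50.0),
    decim: int = 2,
) -> ErpSignal:
    """Full preprocessing chain in fixed order.

    reject -> average -> FIR bandpass -> decimate -> common-average
    re-reference.
    """
    clean = reject_artifacts(epochs, reject_uv)
    erp = average_erp(clean)
    erp = bandpass_fir(erp, *band_hz)
    erp = decimate(erp, decim)
    return rereference_common_average(erp)
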
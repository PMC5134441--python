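"""Signal conditioning and sliding-epoch segmentation of multi-channel sEMG.

The conditioning chain mirrors standard myoelectric practice: a causal
band-pass Butterworth (default 10–450 Hz, 6th order total), an optional
60 Hz notch for line interference, mean subtraction per channel and
full-wave rectification.  All filters are forward-pass IIR only so the
chain is usable online; no zero-phase (filtfilt) smoothing is performed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal as sps

from .errors import DegenerateInputError, InvalidConfigError, ValidationError

__all__ = [
    "Recording",
    "EpochSpec",
    "EpochWindows",
    "bandpass_filter",
    "notch_filter",
    "center_and_rectify",
    "epoch_signal",
    "read_signal_csv",
    "write_signal_csv",
]


@dataclass
class Recording:
    """A time × channel voltage matrix with its sampling rate.

    Parameters
    ----------
    signal
        Array of shape ``(n_samples, n_channels)`` in volts.
    fs
        Sampling rate in Hz (default 960).
    trial_id
        Identifier of the trial this recording belongs to.
    band_config
        Sensor-band placement tag, one of ``center/up/down/cw/ccw`` or
        ``synthetic``.
    """

    signal: np.ndarray
    fs: float = 960.0
    trial_id: str = "trial"
    band_config: str = "synthetic"

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim == 1:
            self.signal = self.signal[:, None]
        if self.signal.ndim != 2 or self.signal.shape[0] < 1 or self.signal.shape[1] < 1:
            raise InvalidConfigError("signal must be a non-empty (n_samples, n_channels) matrix")
        if not self.fs > 0:
            raise InvalidConfigError(f"sampling rate must be positive, got {self.fs}")
        if not np.isfinite(self.signal).all():
            raise InvalidConfigError("signal contains non-finite values")

    @property
    def n_samples(self) -> int:
        return self.signal.shape[0]

    @property
    def n_channels(self) -> int:
        return self.signal.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass(frozen=True)
class EpochSpec:
    """Sliding-window geometry: 125 ms windows with 100 ms overlap by default."""

    length_ms: float = 125.0
    overlap_ms: float = 100.0

    def __post_init__(self) -> None:
        if not 0 <= self.overlap_ms < self.length_ms:
            raise InvalidConfigError(
                f"need 0 <= overlap ({self.overlap_ms}) < length ({self.length_ms})"
            )

    @property
    def step_ms(self) -> float:
        return self.length_ms - self.overlap_ms

    def window_samples(self, fs: float) -> int:
        n = int(round(self.length_ms * fs / 1000.0))
        if n < 2:
            raise InvalidConfigError(f"epoch of {self.length_ms} ms is < 2 samples at fs={fs}")
        return n

    def step_samples(self, fs: float) -> int:
        n = int(round(self.step_ms * fs / 1000.0))
        if n < 1:
            raise InvalidConfigError(f"epoch step of {self.step_ms} ms is < 1 sample at fs={fs}")
        return n


@dataclass
class EpochWindows:
    """Stack of voltage windows plus the start time of each window.

    ``windows`` has shape ``(n_epochs, win_len, n_channels)``; ``start_times``
    is in seconds from recording start and advances by a constant step.
    """

    windows: np.ndarray
    start_times: np.ndarray
    fs: float
    spec: EpochSpec = field(default_factory=EpochSpec)

    @property
    def n_epochs(self) -> int:
        return self.windows.shape[0]

    @property
    def n_channels(self) -> int:
        return self.windows.shape[2]


def _validate_band(fs: float, *edges: float) -> None:
    for f in edges:
        if not 0 < f < fs / 2:
            raise InvalidConfigError(
                f"filter edge {f} Hz outside (0, fs/2) = (0, {fs / 2}) Hz"
            )


def _check_warmup(rec: Recording, order: int) -> None:
    # forward-pass IIR from zero state: require a few filter lengths of signal
    if rec.n_samples < 3 * (order + 1):
        raise DegenerateInputError(
            f"signal of {rec.n_samples} samples shorter than filter warm-up "
            f"({3 * (order + 1)} samples for order {order})"
        )


def bandpass_filter(
    rec: Recording, low_hz: float = 10.0, high_hz: float = 450.0, order: int = 6
) -> Recording:
    """Causal Butterworth band-pass, applied independently per channel.

    ``order`` is the total band-pass order (so ``order=6`` designs a
    3-pole-pair prototype); it must be even.
    """
    if order < 2 or order % 2:
        raise InvalidConfigError(f"band-pass order must be a positive even integer, got {order}")
    if not low_hz < high_hz:
        raise InvalidConfigError(f"need low ({low_hz}) < high ({high_hz})")
    _validate_band(rec.fs, low_hz, high_hz)
    _check_warmup(rec, order)
    sos = sps.butter(order // 2, [low_hz, high_hz], btype="bandpass", fs=rec.fs, output="sos")
    out = sps.sosfilt(sos, rec.signal, axis=0)
    return replace(rec, signal=out)


def notch_filter(rec: Recording, center_hz: float = 60.0, q: float = 30.0) -> Recording:
    """Second-order IIR notch (quality factor ``q``) run causally per channel."""
    _validate_band(rec.fs, center_hz)
    _check_warmup(rec, 2)
    b, a = sps.iirnotch(center_hz, q, fs=rec.fs)
    out = sps.lfilter(b, a, rec.signal, axis=0)
    return replace(rec, signal=out)


def center_and_rectify(rec: Recording) -> tuple[Recording, Recording]:
    """Per-channel mean removal, then full-wave rectification of the centered signal."""
    centered = rec.signal - rec.signal.mean(axis=0, keepdims=True)
    return replace(rec, signal=centered), replace(rec, signal=np.abs(centered))


def epoch_signal(rec: Recording, spec: EpochSpec | None = None) -> EpochWindows:
    """Cut a recording into overlapping windows.

    Windows are ``round(length_ms * fs / 1000)`` samples long, start every
    ``step_ms`` and any trailing samples that do not fill a full window are
    discarded, giving ``floor((n_samples - win_len) / step) + 1`` windows.
    """
    spec = spec or EpochSpec()
    win = spec.window_samples(rec.fs)
    step = spec.step_samples(rec.fs)
    if rec.n_samples < win:
        raise DegenerateInputError(
            f"recording of {rec.n_samples} samples shorter than one {win}-sample epoch"
        )
    n = (rec.n_samples - win) // step + 1
    idx = np.arange(n)[:, None] * step + np.arange(win)[None, :]
    windows = rec.signal[idx]  # (n, win, n_channels)
    start_times = np.arange(n) * (spec.step_ms / 1000.0)
    return EpochWindows(windows=windows, start_times=start_times, fs=rec.fs, spec=spec)


# ---------------------------------------------------------------------------
# delimited-text signal files


def write_signal_csv(rec: Recording, path) -> None:
    """Write ``time_s,ch1..chN`` rows; times are sample index / fs."""
    t = np.arange(rec.n_samples) / rec.fs
    cols = {"time_s": t}
    for j in range(rec.n_channels):
        cols[f"ch{j + 1}"] = rec.signal[:, j]
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.12g")


def read_signal_csv(path, trial_id: str | None = None, band_config: str = "synthetic") -> Recording:
    """Read a ``time_s,ch1..chN`` file, validating a constant sampling interval."""
    df = pd.read_csv(path)
    if "time_s" not in df.columns or df.shape[1] < 2:
        raise ValidationError(f"{path}: expected header 'time_s,ch1..chN'")
    chan_cols = [c for c in df.columns if c != "time_s"]
    t = df["time_s"].to_numpy(float)
    if len(t) < 2:
        raise ValidationError(f"{path}: need at least 2 samples")
    dt = np.diff(t)
    dt0 = np.median(dt)
    if dt0 <= 0 or np.abs(dt - dt0).max() > 1e-6 * dt0:
        raise ValidationError(f"{path}: sampling interval not constant within 1 ppm")
    fs = 1.0 / dt0
    sig = df[chan_cols].to_numpy(float)
    if not np.isfinite(sig).all():
        bad = np.argwhere(~np.isfinite(sig))[0]
        raise ValidationError(f"{path}: non-finite value at row {bad[0]}, column {chan_cols[bad[1]]}")
    return Recording(signal=sig, fs=fs, trial_id=trial_id or str(path), band_config=band_config)
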
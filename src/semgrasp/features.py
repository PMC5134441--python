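"""Per-epoch sEMG feature extraction and feature-set screening.

Twelve candidate features per channel: six time-domain statistics
(IAV, WFL, VAR, SSC, ZC, WAMP), three frequency-bin powers over
10–450 Hz (F1–F3) and three amplitude-histogram counts in 0.66 V bins
centered on 0 V (H1–H3).  A squared-Pearson screen (R² > 0.9 on every
channel) removes redundant features — on data with realistic amplitude
structure this removes VAR, which is amplitude-redundant with IAV,
taking 7 × 12 = 84 dimensions down to 77.  A bigram variant concatenates
the previous epoch's vector, doubling the dimensionality (154).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from .errors import (
    AlignmentError,
    DegenerateInputError,
    InvalidConfigError,
    InvalidInputError,
    ValidationError,
)
from .preprocess import EpochWindows

__all__ = [
    "FeatureConfig",
    "EpochFeatures",
    "time_domain_features",
    "freq_bin_features",
    "amp_bin_features",
    "extract_features",
    "correlation_screen",
    "select_features",
    "make_bigram",
    "read_features_csv",
    "write_features_csv",
]

ALL_FEATURES = ("IAV", "WFL", "VAR", "SSC", "ZC", "WAMP", "F1", "F2", "F3", "H1", "H2", "H3")


@dataclass(frozen=True)
class FeatureConfig:
    """Feature extraction parameters.

    ``wamp_threshold`` is in the same units as the stored signal (volts;
    5 mV default).  Frequency bins are equally spaced over
    ``[freq_lo, freq_hi]``; amplitude bins form a contiguous block of
    ``n_amp_bins`` bins of width ``amp_bin_width`` volts centered on 0 V.
    """

    wamp_threshold: float = 0.005
    freq_lo: float = 10.0
    freq_hi: float = 450.0
    n_freq_bins: int = 3
    amp_bin_width: float = 0.66
    n_amp_bins: int = 3
    included_features: tuple[str, ...] = ALL_FEATURES
    corr_r2_cutoff: float = 0.9

    def __post_init__(self) -> None:
        if not self.wamp_threshold > 0:
            raise InvalidConfigError("wamp_threshold must be > 0")
        if not self.freq_lo < self.freq_hi:
            raise InvalidConfigError("need freq_lo < freq_hi")
        if self.n_freq_bins < 1 or self.n_amp_bins < 1:
            raise InvalidConfigError("bin counts must be >= 1")
        if not 0 < self.corr_r2_cutoff <= 1:
            raise InvalidConfigError("corr_r2_cutoff must be in (0, 1]")
        unknown = set(self.included_features) - set(ALL_FEATURES)
        if unknown:
            raise InvalidConfigError(f"unknown features: {sorted(unknown)}")


@dataclass
class EpochFeatures:
    """Epochs × dimensions feature matrix with channel-major column names."""

    X: np.ndarray
    feature_names: list[str]
    start_times: np.ndarray
    ngram: str = "unigram"

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2 or self.X.shape[1] != len(self.feature_names):
            raise InvalidInputError("X must be (n_epochs, len(feature_names))")
        if not np.isfinite(self.X).all():
            raise InvalidInputError("feature matrix contains non-finite entries")
        if self.ngram not in ("unigram", "bigram"):
            raise InvalidInputError(f"ngram must be unigram|bigram, got {self.ngram!r}")

    @property
    def n_epochs(self) -> int:
        return self.X.shape[0]

    @property
    def dim(self) -> int:
        return self.X.shape[1]


def _sign_changes_rows(X: np.ndarray) -> np.ndarray:
    """Row-wise strict sign-change counts with zero samples skipped."""
    out = np.empty(X.shape[0])
    has_zero = np.any(X == 0.0, axis=1)
    s = np.sign(X)
    out[:] = np.count_nonzero(s[:, 1:] != s[:, :-1], axis=1)
    for i in np.flatnonzero(has_zero):  # exact zeros are rare; fall back per row
        out[i] = _sign_changes(X[i])
    return out


def _sign_changes(x: np.ndarray) -> int:
    """Count strict sign changes, skipping exact zeros (0 between +/- is one crossing)."""
    s = np.sign(x)
    s = s[s != 0]
    if s.size < 2:
        return 0
    return int(np.count_nonzero(s[1:] != s[:-1]))


def time_domain_features(
    window_centered: np.ndarray,
    window_rectified: np.ndarray | None = None,
    cfg: FeatureConfig | None = None,
) -> dict[str, float]:
    """Six time-domain features of one centered (mean-free) window.

    IAV = Σ|x|, WFL = Σ|Δx|, VAR = population variance, SSC = strict
    sign changes of consecutive first differences, ZC = strict sign
    changes of consecutive samples, WAMP = #{|Δx| > threshold}.  The
    rectified window, when given, is used for IAV (it equals |centered|).
    """
    cfg = cfg or FeatureConfig()
    x = np.asarray(window_centered, dtype=float).ravel()
    if x.size < 2:
        raise DegenerateInputError("time-domain features need a window of >= 2 samples")
    rect = np.abs(x) if window_rectified is None else np.asarray(window_rectified, float).ravel()
    dx = np.diff(x)
    return {
        "IAV": float(rect.sum()),
        "WFL": float(np.abs(dx).sum()),
        "VAR": float(np.mean(x**2) - np.mean(x) ** 2),
        "SSC": float(_sign_changes(dx)),
        "ZC": float(_sign_changes(x)),
        "WAMP": float(np.count_nonzero(np.abs(dx) > cfg.wamp_threshold)),
    }


def freq_bin_features(
    window_centered: np.ndarray, fs: float, cfg: FeatureConfig | None = None
) -> tuple[float, ...]:
    """Band powers (volts²) in equally spaced bins over [freq_lo, freq_hi].

    A single unwindowed (boxcar) periodogram of the centered window is
    summed over half-open frequency bins [edge_k, edge_{k+1}).
    """
    cfg = cfg or FeatureConfig()
    x = np.asarray(window_centered, dtype=float).ravel()
    if x.size < 4:
        raise DegenerateInputError("frequency features need a window of >= 4 samples")
    if cfg.freq_hi > fs / 2:
        raise InvalidConfigError(f"freq_hi={cfg.freq_hi} above Nyquist {fs / 2}")
    f, pxx = sps.periodogram(x, fs=fs, window="boxcar", detrend=False, scaling="spectrum")
    edges = np.linspace(cfg.freq_lo, cfg.freq_hi, cfg.n_freq_bins + 1)
    out = []
    for k in range(cfg.n_freq_bins):
        sel = (f >= edges[k]) & (f < edges[k + 1])
        if k == cfg.n_freq_bins - 1:  # close the top edge so freq_hi itself counts
            sel |= f == edges[k + 1]
        out.append(float(pxx[sel].sum()))
    return tuple(out)


def amp_bin_features(
    window_centered: np.ndarray, cfg: FeatureConfig | None = None
) -> tuple[float, ...]:
    """Sample counts in a block of amplitude bins centered on 0 V.

    Defaults give three 0.66 V bins with edges at ±0.33 and ±0.99 V,
    half-open on the right; samples outside the block are not counted.
    """
    cfg = cfg or FeatureConfig()
    x = np.asarray(window_centered, dtype=float).ravel()
    if x.size < 1:
        raise DegenerateInputError("amplitude features need a non-empty window")
    lo = -cfg.n_amp_bins * cfg.amp_bin_width / 2.0
    # small epsilon keeps nominal edge values (e.g. exactly -0.33 V) in their
    # right-closed neighbour despite binary rounding of the edge positions
    idx = np.floor((x - lo) / cfg.amp_bin_width + 1e-9).astype(int)
    counts = [float(np.count_nonzero(idx == k)) for k in range(cfg.n_amp_bins)]
    return tuple(counts)


def extract_features(
    epochs: EpochWindows,
    cfg: FeatureConfig | None = None,
    epochs_rectified: EpochWindows | None = None,
) -> EpochFeatures:
    """Assemble the unigram feature matrix, channel-major (ch1 features first).

    ``epochs`` holds the centered windows of all channels on one shared
    grid; ``epochs_rectified``, when given, must share that grid and is
    used for IAV.
    """
    cfg = cfg or FeatureConfig()
    if epochs_rectified is not None:
        if epochs_rectified.windows.shape != epochs.windows.shape or not np.array_equal(
            epochs_rectified.start_times, epochs.start_times
        ):
            raise AlignmentError("rectified epochs do not share the centered epoch grid")
    n_ep, win, n_ch = epochs.windows.shape
    if win < 2:
        raise DegenerateInputError("feature extraction needs windows of >= 2 samples")
    names = [f"ch{j + 1}:{feat}" for j in range(n_ch) for feat in cfg.included_features]
    X = np.empty((n_ep, len(names)))
    need_freq = any(f.startswith("F") for f in cfg.included_features)
    if need_freq and cfg.freq_hi > epochs.fs / 2:
        raise InvalidConfigError(f"freq_hi={cfg.freq_hi} above Nyquist {epochs.fs / 2}")
    for j in range(n_ch):
        W = epochs.windows[:, :, j]  # (n_ep, win)
        R = np.abs(W) if epochs_rectified is None else epochs_rectified.windows[:, :, j]
        dW = np.diff(W, axis=1)
        vals: dict[str, np.ndarray] = {
            "IAV": R.sum(axis=1),
            "WFL": np.abs(dW).sum(axis=1),
            "VAR": np.mean(W**2, axis=1) - np.mean(W, axis=1) ** 2,
            "SSC": _sign_changes_rows(dW),
            "ZC": _sign_changes_rows(W),
            "WAMP": np.count_nonzero(np.abs(dW) > cfg.wamp_threshold, axis=1).astype(float),
        }
        if need_freq:
            f, pxx = sps.periodogram(
                W, fs=epochs.fs, window="boxcar", detrend=False, scaling="spectrum", axis=-1
            )
            edges = np.linspace(cfg.freq_lo, cfg.freq_hi, cfg.n_freq_bins + 1)
            for k in range(cfg.n_freq_bins):
                sel = (f >= edges[k]) & (f < edges[k + 1])
                if k == cfg.n_freq_bins - 1:
                    sel |= f == edges[k + 1]
                vals[f"F{k + 1}"] = pxx[:, sel].sum(axis=1)
        lo = -cfg.n_amp_bins * cfg.amp_bin_width / 2.0
        idx = np.floor((W - lo) / cfg.amp_bin_width + 1e-9).astype(int)
        for k in range(cfg.n_amp_bins):
            vals[f"H{k + 1}"] = np.count_nonzero(idx == k, axis=1).astype(float)
        base = j * len(cfg.included_features)
        for off, feat in enumerate(cfg.included_features):
            X[:, base + off] = vals[feat]
    return EpochFeatures(X=X, feature_names=names, start_times=np.asarray(epochs.start_times), ngram="unigram")


def _base_feature(name: str) -> tuple[str, str]:
    ch, feat = name.split(":", 1)
    return ch, feat


def correlation_screen(
    feats: EpochFeatures, cfg: FeatureConfig | None = None
) -> tuple[EpochFeatures, list[str]]:
    """Drop features that are near-deterministic functions of an earlier one.

    For each ordered pair of candidate feature names, the later-listed
    feature is removed when the squared Pearson correlation with the
    earlier one exceeds ``corr_r2_cutoff`` on *every* channel.
    Zero-variance columns have undefined correlation and never trigger a
    removal.  The scan is deterministic given the configured feature order.
    """
    cfg = cfg or FeatureConfig()
    if feats.n_epochs < 3:
        raise DegenerateInputError("correlation screening needs >= 3 epochs")
    if feats.ngram != "unigram":
        raise InvalidInputError("screen unigram features before building bigrams")
    channels = sorted({_base_feature(n)[0] for n in feats.feature_names}, key=lambda c: int(c[2:]))
    present = [f for f in cfg.included_features if f"{channels[0]}:{f}" in feats.feature_names]
    col = {n: k for k, n in enumerate(feats.feature_names)}
    removed: list[str] = []
    for i, fi in enumerate(present):
        if fi in removed:
            continue
        for fj in present[i + 1 :]:
            if fj in removed:
                continue
            all_high = True
            for ch in channels:
                a = feats.X[:, col[f"{ch}:{fi}"]]
                b = feats.X[:, col[f"{ch}:{fj}"]]
                if a.std() == 0.0 or b.std() == 0.0:
                    all_high = False  # undefined correlation: never removes
                    break
                r = np.corrcoef(a, b)[0, 1]
                if not r * r > cfg.corr_r2_cutoff:
                    all_high = False
                    break
            if all_high:
                removed.append(fj)
    kept = [f for f in present if f not in removed]
    return select_features(feats, kept), removed


def select_features(feats: EpochFeatures, kept_base_features: list[str]) -> EpochFeatures:
    """Project a unigram matrix onto a frozen list of base feature names."""
    keep_idx = [
        k
        for k, n in enumerate(feats.feature_names)
        if _base_feature(n)[1] in kept_base_features
    ]
    return EpochFeatures(
        X=feats.X[:, keep_idx],
        feature_names=[feats.feature_names[k] for k in keep_idx],
        start_times=feats.start_times,
        ngram=feats.ngram,
    )


def make_bigram(feats: EpochFeatures) -> EpochFeatures:
    """Concatenate each epoch's vector with the previous epoch's.

    The first epoch has no predecessor and duplicates its own row, so the
    label and feature sequences keep equal length.  Dimensionality doubles.
    """
    if feats.ngram != "unigram":
        raise InvalidInputError("make_bigram expects unigram input")
    if feats.n_epochs < 1:
        raise DegenerateInputError("make_bigram needs at least one epoch")
    prev = np.vstack([feats.X[:1], feats.X[:-1]])
    names = [f"cur:{n}" for n in feats.feature_names] + [f"prev:{n}" for n in feats.feature_names]
    return EpochFeatures(
        X=np.hstack([feats.X, prev]),
        feature_names=names,
        start_times=feats.start_times,
        ngram="bigram",
    )


# ---------------------------------------------------------------------------
# CSV round-trip: header `start_time_s,ch1:IAV,...`; ngram on a leading `#` line


def write_features_csv(feats: EpochFeatures, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# ngram={feats.ngram}\n")
        df = pd.DataFrame(feats.X, columns=feats.feature_names)
        df.insert(0, "start_time_s", feats.start_times)
        df.to_csv(fh, index=False, float_format="%.17g")


def read_features_csv(path) -> EpochFeatures:
    with open(path) as fh:
        meta = fh.readline().strip()
        if not meta.startswith("# ngram="):
            raise ValidationError(f"{path}: missing '# ngram=' metadata line")
        ngram = meta.split("=", 1)[1]
        df = pd.read_csv(fh, float_precision="round_trip")
    if "start_time_s" not in df.columns:
        raise ValidationError(f"{path}: missing start_time_s column")
    names = [c for c in df.columns if c != "start_time_s"]
    return EpochFeatures(
        X=df[names].to_numpy(float),
        feature_names=names,
        start_times=df["start_time_s"].to_numpy(float),
        ngram=ngram,
    )
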
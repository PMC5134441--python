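"""Seeded generator of synthetic grasp-and-release sEMG trials.

Surface EMG is modeled phenomenologically as amplitude-modulated,
band-limited Gaussian noise: each of a small set of "muscle sources"
(a flexor-like source driving grasp-and-hold, an extensor-like source
bursting around release, and a broadband noise floor) owns a stationary
band-limited carrier whose amplitude is shaped by a state-dependent
activation envelope.  Channels are mixing-weighted sums of the sources,
with weights given by the angular position of each electrode around the
forearm relative to each source; sensor-band displacement is emulated by
rotating or tilting those weights.  Flexor activation begins an
anticipatory lead *before* the kinematic grasp time stamp and persists
through transport; the extensor burst before release is shorter and
weaker, so release is the hardest state to detect — mirroring the
asymmetry expected from grasp/release physiology.

Each trial contains two grasp-and-release movements by default, with a
kinematic event table emitted alongside the voltage matrix.  All
randomness flows from the (config, seed) pair, so trials are bit-exactly
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

from .errors import InvalidConfigError
from .labeling import KinematicEvents, label_intervals
from .pipeline import TrialData
from .preprocess import Recording

__all__ = ["SynthConfig", "SynthTrial", "generate_trial", "apply_sensor_shift", "generate_dataset"]

SHIFT_MODES = ("center", "up", "down", "cw", "ccw")


@dataclass(frozen=True)
class SynthConfig:
    """Generator parameters; defaults define the emulated study conditions.

    Amplitudes are volts.  Active-state peaks sit around 0.3–0.6 V and
    the noise floor around 0.012 V so that the 5 mV Wilson-amplitude
    threshold and the ±0.33/±0.99 V amplitude-bin edges both discriminate.
    Source pass-bands differ (flexor low, extensor mid-high, floor
    broadband) so spectral features carry state information beyond raw
    amplitude.
    """

    n_channels: int = 7
    fs: float = 960.0
    n_movements_per_trial: int = 2
    trial_duration_s: float | None = None
    steady_start_range: tuple[float, float] = (1.2, 1.8)
    transport_range: tuple[float, float] = (0.9, 1.4)
    gap_range: tuple[float, float] = (1.4, 2.0)
    tail_range: tuple[float, float] = (1.0, 1.5)
    anticipatory_lead_ms: float = 300.0
    flexor_amp: float = 0.35
    extensor_amp: float = 0.15
    extensor_tone: float = 0.50
    floor_amp: float = 0.04
    envelope_jitter: float = 0.15
    flexor_band: tuple[float, float] = (20.0, 100.0)
    extensor_band: tuple[float, float] = (120.0, 350.0)
    floor_band: tuple[float, float] = (10.0, 450.0)
    flexor_angle_deg: float = 0.0
    extensor_angle_deg: float = 160.0
    channel_spread_deg: float = 65.0
    band_rotation_deg: float = 0.0
    longitudinal_shift: float = 0.0
    sensor_shift_deg: float = 14.0  # ~1 cm on a 25.7 cm forearm circumference
    longitudinal_tilt: float = 0.30
    line_hum_amplitude: float = 0.0
    master_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("steady_start_range", "transport_range", "gap_range", "tail_range"):
            lo, hi = getattr(self, name)
            if not 0 < lo <= hi:
                raise InvalidConfigError(f"{name} must satisfy 0 < lo <= hi")
        if self.fs / 2 <= 450.0:
            raise InvalidConfigError("fs must exceed 900 Hz so the 10-450 Hz band fits")
        if self.n_channels < 1 or self.n_movements_per_trial < 1:
            raise InvalidConfigError("need >= 1 channel and >= 1 movement")
        if min(self.flexor_amp, self.extensor_amp, self.floor_amp) < 0:
            raise InvalidConfigError("amplitudes must be non-negative")

    def mixing_matrix(self) -> np.ndarray:
        """(3, n_channels) non-negative weights: flexor, extensor, floor rows."""
        ch_angles = 360.0 * np.arange(self.n_channels) / self.n_channels + self.band_rotation_deg
        w = np.empty((3, self.n_channels))
        for row, src_angle in enumerate((self.flexor_angle_deg, self.extensor_angle_deg)):
            d = np.abs((ch_angles - src_angle + 180.0) % 360.0 - 180.0)
            w[row] = np.exp(-0.5 * (d / self.channel_spread_deg) ** 2)
        w[2] = 1.0  # broadband floor couples evenly
        tilt = np.array([self.longitudinal_tilt, -self.longitudinal_tilt, 0.0])
        w *= np.exp(tilt * self.longitudinal_shift)[:, None]
        return w


@dataclass
class SynthTrial:
    """Generated recording + kinematic events + the generating state timeline.

    ``source_envelopes`` holds the per-sample flexor/extensor activation
    envelopes (before amplitude scaling) for inspection and testing.
    """

    recording: Recording
    events: KinematicEvents
    true_state_timeline: list[tuple[float, float, str]]
    source_envelopes: dict[str, np.ndarray] = field(default_factory=dict)

    def as_trial_data(self) -> TrialData:
        return TrialData(recording=self.recording, events=self.events)


def _band_noise(rng: np.random.Generator, n: int, band: tuple[float, float], fs: float) -> np.ndarray:
    """Unit-variance Gaussian noise band-limited to ``band``."""
    x = rng.standard_normal(n)
    sos = sps.butter(4, band, btype="bandpass", fs=fs, output="sos")
    y = sps.sosfilt(sos, x)
    return y / y.std()

def _smooth_noise(rng: np.random.Generator, n: int, fs: float, cutoff: float = 3.0) -> np.ndarray:
    """Slow unit-variance modulation used for within-state envelope jitter."""
    x = rng.standard_normal(n)
    sos = sps.butter(2, cutoff, btype="lowpass", fs=fs, output="sos")
    y = sps.sosfilt(sos, x)
    return y / y.std()


def _trapezoid(t: np.ndarray, on: float, full: float, hold_until: float, off: float) -> np.ndarray:
    """Piecewise-linear envelope: rise on->full, hold, decay hold_until->off."""
    env = np.zeros_like(t)
    rise = (t >= on) & (t < full)
    env[rise] = (t[rise] - on) / max(full - on, 1e-9)
    env[(t >= full) & (t < hold_until)] = 1.0
    fall = (t >= hold_until) & (t < off)
    env[fall] = 1.0 - (t[fall] - hold_until) / max(off - hold_until, 1e-9)
    return env


def _schedule(cfg: SynthConfig, rng: np.random.Generator) -> tuple[list[tuple[float, float]], float]:
    movements = []
    t = rng.uniform(*cfg.steady_start_range)
    for _ in range(cfg.n_movements_per_trial):
        t_g = t + 0.6  # room for the 500 ms grasp lead + anticipation
        t_r = t_g + rng.uniform(*cfg.transport_range)
        movements.append((t_g, t_r))
        t = t_r + rng.uniform(*cfg.gap_range)
    duration = movements[-1][1] + rng.uniform(*cfg.tail_range)
    if cfg.trial_duration_s is not None:
        if movements[-1][1] + 0.6 > cfg.trial_duration_s:
            raise InvalidConfigError(
                f"movement schedule ending {movements[-1][1]:.2f}s does not fit in "
                f"trial_duration_s={cfg.trial_duration_s}"
            )
        duration = cfg.trial_duration_s
    return movements, duration


def generate_trial(cfg: SynthConfig, seed: int, trial_id: str = "synth", band_config: str = "synthetic") -> SynthTrial:
    """Generate one two-movement trial, fully determined by (cfg, seed)."""
    rng = np.random.default_rng(seed)
    movements, duration = _schedule(cfg, rng)
    n = int(round(duration * cfg.fs))
    t = np.arange(n) / cfg.fs
    lead = cfg.anticipatory_lead_ms / 1000.0

    flexor_env = np.zeros(n)
    extensor_env = np.zeros(n)
    for t_g, t_r in movements:
        flexor_env = np.maximum(
            flexor_env, _trapezoid(t, t_g - lead, t_g - lead + 0.20, t_r, t_r + 0.35)
        )
        # weaker stabilizing extensor tone during transport, burst around release
        extensor_env = np.maximum(
            extensor_env, cfg.extensor_tone * _trapezoid(t, t_g - lead, t_g, t_r - lead, t_r)
        )
        extensor_env = np.maximum(
            extensor_env, _trapezoid(t, t_r - lead, t_r - 0.10, t_r + 0.10, t_r + 0.55)
        )
    if cfg.envelope_jitter > 0:
        flexor_env = flexor_env * np.clip(
            1.0 + cfg.envelope_jitter * _smooth_noise(rng, n, cfg.fs), 0.05, None
        )
        extensor_env = extensor_env * np.clip(
            1.0 + cfg.envelope_jitter * _smooth_noise(rng, n, cfg.fs), 0.05, None
        )

    carriers = np.stack(
        [
            _band_noise(rng, n, cfg.flexor_band, cfg.fs),
            _band_noise(rng, n, cfg.extensor_band, cfg.fs),
        ]
    )
    envs = np.stack([cfg.flexor_amp * flexor_env, cfg.extensor_amp * extensor_env])
    mix = cfg.mixing_matrix()
    sig = (envs * carriers).T @ mix[:2]  # (n, n_channels)
    for c in range(cfg.n_channels):
        sig[:, c] += cfg.floor_amp * mix[2, c] * _band_noise(rng, n, cfg.floor_band, cfg.fs)
    if cfg.line_hum_amplitude > 0:
        phases = rng.uniform(0, 2 * np.pi, cfg.n_channels)
        sig += cfg.line_hum_amplitude * np.sin(2 * np.pi * 60.0 * t[:, None] + phases[None, :])

    rec = Recording(signal=sig, fs=cfg.fs, trial_id=trial_id, band_config=band_config)
    events = KinematicEvents(movements=movements, trial_id=trial_id)
    timeline = label_intervals(events, release_len_ms=500.0, grasp_lead_ms=500.0)
    return SynthTrial(
        recording=rec,
        events=events,
        true_state_timeline=timeline,
        source_envelopes={"flexor": flexor_env, "extensor": extensor_env},
    )


def apply_sensor_shift(cfg: SynthConfig, magnitude: float = 1.0, mode: str = "cw") -> SynthConfig:
    """Return a config with the electrode band displaced.

    ``magnitude`` is in units of the nominal ~1 cm displacement:
    cw/ccw rotate the band by ±magnitude × ``sensor_shift_deg`` degrees;
    up/down translate it along the forearm, tilting per-source gains.
    ``center`` (or magnitude 0) returns the config unchanged.
    """
    if magnitude < 0:
        raise InvalidConfigError("shift magnitude must be >= 0")
    if mode not in SHIFT_MODES:
        raise InvalidConfigError(f"mode must be one of {SHIFT_MODES}, got {mode!r}")
    if mode == "center" or magnitude == 0:
        return cfg
    if mode == "cw":
        return replace(cfg, band_rotation_deg=cfg.band_rotation_deg + magnitude * cfg.sensor_shift_deg)
    if mode == "ccw":
        return replace(cfg, band_rotation_deg=cfg.band_rotation_deg - magnitude * cfg.sensor_shift_deg)
    sign = 1.0 if mode == "up" else -1.0
    return replace(cfg, longitudinal_shift=cfg.longitudinal_shift + sign * magnitude)


def generate_dataset(
    cfg: SynthConfig,
    n_trials: int,
    shift_schedule: tuple[str, ...] = SHIFT_MODES,
    seed: int | None = None,
) -> list[SynthTrial]:
    """Generate ``n_trials`` trials cycling through band configurations.

    Trial i uses configuration ``shift_schedule[i % len(shift_schedule)]``
    and a per-trial seed derived from the master seed, so trials are
    pairwise distinct but the dataset is reproducible as a whole.
    """
    if n_trials < 1:
        raise InvalidConfigError("n_trials must be >= 1")
    seed = cfg.master_seed if seed is None else seed
    rng = np.random.default_rng(seed)
    trial_seeds = rng.integers(0, 2**31 - 1, size=n_trials)
    trials = []
    for i in range(n_trials):
        mode = shift_schedule[i % len(shift_schedule)]
        shifted = apply_sensor_shift(cfg, magnitude=1.0, mode=mode)
        trials.append(
            generate_trial(shifted, int(trial_seeds[i]), trial_id=f"t{i:03d}", band_config=mode)
        )
    return trials
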
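"""Glue from raw recordings to aligned feature matrices and labels."""

from __future__ import annotations

from dataclasses import dataclass

from .features import EpochFeatures, FeatureConfig, extract_features
from .labeling import KinematicEvents, LabelSequence, assign_epoch_labels, label_intervals
from .preprocess import EpochSpec, Recording, bandpass_filter, center_and_rectify, epoch_signal, notch_filter

__all__ = ["TrialData", "PreparedTrial", "condition_recording", "prepare_trial"]


@dataclass
class TrialData:
    """A raw trial: multi-channel recording plus its kinematic event table."""

    recording: Recording
    events: KinematicEvents


@dataclass
class PreparedTrial:
    """Featurized trial on one epoch grid with aligned ground-truth labels.

    ``labels``/``events`` may be None for unlabeled prediction-only trials.
    """

    trial_id: str
    features: EpochFeatures  # unigram, unscreened
    labels: LabelSequence | None
    events: KinematicEvents | None


def condition_recording(
    rec: Recording,
    band: tuple[float, float] = (10.0, 450.0),
    band_order: int = 6,
    notch_hz: float | None = 60.0,
) -> tuple[Recording, Recording]:
    """Band-pass, optional notch, mean-subtract; returns (centered, rectified)."""
    out = bandpass_filter(rec, band[0], band[1], band_order)
    if notch_hz is not None:
        out = notch_filter(out, notch_hz)
    return center_and_rectify(out)


def prepare_trial(
    trial: TrialData,
    epoch_spec: EpochSpec | None = None,
    feature_cfg: FeatureConfig | None = None,
    release_len_ms: float = 500.0,
    grasp_lead_ms: float = 500.0,
    notch_hz: float | None = 60.0,
) -> PreparedTrial:
    """Condition, epoch, featurize and label one trial on a shared grid."""
    epoch_spec = epoch_spec or EpochSpec()
    feature_cfg = feature_cfg or FeatureConfig()
    centered, rectified = condition_recording(trial.recording, notch_hz=notch_hz)
    epochs = epoch_signal(centered, epoch_spec)
    epochs_rect = epoch_signal(rectified, epoch_spec)
    feats = extract_features(epochs, feature_cfg, epochs_rectified=epochs_rect)
    intervals = label_intervals(trial.events, release_len_ms, grasp_lead_ms)
    labels = assign_epoch_labels(intervals, feats.start_times, epoch_spec.length_ms)
    return PreparedTrial(
        trial_id=trial.recording.trial_id, features=feats, labels=labels, events=trial.events
    )
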
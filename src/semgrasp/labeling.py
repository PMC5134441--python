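"""Ground-truth intent labels from kinematic grasp/release time stamps.

Each movement contributes a release interval covering the ``release_len``
milliseconds before the kinematic release time stamp — truncated at the
grasp time stamp when the movement is shorter than that — and a grasp
interval from ``grasp_lead`` ms before the grasp time stamp up to the
start of the release interval.  Every epoch whose temporal center falls
in no such interval is labeled steady.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidConfigError, InvalidEventsError, UndefinedMetricError, ValidationError

__all__ = [
    "STATES",
    "KinematicEvents",
    "LabelSequence",
    "label_intervals",
    "assign_epoch_labels",
    "truncation_stats",
    "read_events_csv",
    "write_events_csv",
    "read_labels_csv",
    "write_labels_csv",
]

STATES = ("steady", "grasp", "release")


@dataclass
class KinematicEvents:
    """Ordered (grasp_time_s, release_time_s) pairs for one trial."""

    movements: list[tuple[float, float]]
    trial_id: str = "trial"

    def __post_init__(self) -> None:
        prev_end = -np.inf
        for t_g, t_r in self.movements:
            if not t_g < t_r:
                raise InvalidEventsError(
                    f"{self.trial_id}: grasp time {t_g} not before release time {t_r}"
                )
            if t_g < prev_end:
                raise InvalidEventsError(f"{self.trial_id}: movements overlap or are out of order")
            prev_end = t_r


@dataclass
class LabelSequence:
    """Per-epoch labels in {steady, grasp, release} on an epoch-start grid."""

    labels: np.ndarray
    start_times: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=object)
        self.start_times = np.asarray(self.start_times, dtype=float)
        if self.labels.shape != self.start_times.shape:
            raise InvalidEventsError("labels and start_times must have equal length")
        bad = set(self.labels) - set(STATES)
        if bad:
            raise InvalidEventsError(f"unknown labels: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.labels)


def label_intervals(
    events: KinematicEvents,
    release_len_ms: float = 500.0,
    grasp_lead_ms: float = 500.0,
) -> list[tuple[float, float, str]]:
    """Half-open grasp/release intervals for each movement; the rest is steady.

    Per movement with times (t_g, t_r): release = [max(t_r - L, t_g), t_r),
    grasp = [t_g - lead, release start).  Raises when intervals from
    adjacent movements would overlap.
    """
    if not release_len_ms > 0 or not grasp_lead_ms > 0:
        raise InvalidConfigError("release_len_ms and grasp_lead_ms must be > 0")
    rel = release_len_ms / 1000.0
    lead = grasp_lead_ms / 1000.0
    intervals: list[tuple[float, float, str]] = []
    prev_end = -np.inf
    for t_g, t_r in events.movements:
        rel_start = max(t_r - rel, t_g)
        g_start = t_g - lead
        if g_start < prev_end:
            raise InvalidEventsError(
                f"{events.trial_id}: grasp interval starting {g_start:.3f}s overlaps "
                f"previous movement ending {prev_end:.3f}s"
            )
        intervals.append((g_start, rel_start, "grasp"))
        intervals.append((rel_start, t_r, "release"))
        prev_end = t_r
    return intervals


def is_truncated(movement: tuple[float, float], release_len_ms: float) -> bool:
    t_g, t_r = movement
    return t_r - release_len_ms / 1000.0 < t_g


def assign_epoch_labels(
    intervals: list[tuple[float, float, str]],
    start_times: np.ndarray,
    epoch_length_ms: float,
) -> LabelSequence:
    """Label each epoch by the interval containing its temporal center.

    Intervals are half-open [start, end); an epoch centered exactly on a
    boundary takes the next interval's label.  Centers inside no interval
    are steady.
    """
    start_times = np.asarray(start_times, dtype=float)
    centers = start_times + epoch_length_ms / 2000.0
    labels = np.full(start_times.shape, "steady", dtype=object)
    for s, e, lab in intervals:
        labels[(centers >= s) & (centers < e)] = lab
    return LabelSequence(labels=labels, start_times=start_times)


def truncation_stats(
    events_list: list[KinematicEvents], release_len_ms: float = 500.0
) -> tuple[int, int, float]:
    """Count movements whose release window is cut short by the grasp time.

    Returns (n_truncated, n_total, percent rounded to 2 decimals).
    """
    n_total = sum(len(ev.movements) for ev in events_list)
    if n_total == 0:
        raise UndefinedMetricError("truncation percentage undefined for 0 movements")
    n_trunc = sum(
        is_truncated(m, release_len_ms) for ev in events_list for m in ev.movements
    )
    return n_trunc, n_total, round(100.0 * n_trunc / n_total, 2)


# ---------------------------------------------------------------------------
# CSV formats


def write_events_csv(events_list: list[KinematicEvents], path) -> None:
    rows = [
        {
            "trial_id": ev.trial_id,
            "movement_idx": k,
            "grasp_time_s": t_g,
            "release_time_s": t_r,
        }
        for ev in events_list
        for k, (t_g, t_r) in enumerate(ev.movements)
    ]
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.9g")


def read_events_csv(path) -> list[KinematicEvents]:
    df = pd.read_csv(path)
    need = {"trial_id", "movement_idx", "grasp_time_s", "release_time_s"}
    if not need <= set(df.columns):
        raise ValidationError(f"{path}: expected columns {sorted(need)}")
    out = []
    for tid, grp in df.groupby("trial_id", sort=False):
        grp = grp.sort_values("movement_idx")
        out.append(
            KinematicEvents(
                movements=list(zip(grp["grasp_time_s"], grp["release_time_s"])),
                trial_id=str(tid),
            )
        )
    return out


def write_labels_csv(seq: LabelSequence, path) -> None:
    pd.DataFrame({"start_time_s": seq.start_times, "label": seq.labels}).to_csv(
        path, index=False, float_format="%.9g"
    )


def read_labels_csv(path) -> LabelSequence:
    df = pd.read_csv(path)
    if not {"start_time_s", "label"} <= set(df.columns):
        raise ValidationError(f"{path}: expected columns start_time_s,label")
    return LabelSequence(
        labels=df["label"].to_numpy(object), start_times=df["start_time_s"].to_numpy(float)
    )
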
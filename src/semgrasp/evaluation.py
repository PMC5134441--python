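"""Trial-level cross-validation, confusion metrics and sensitivity sweeps.

Folds are drawn over whole trials so no epoch of a test trial ever
influences feature screening, mixture fitting or transition counts.
Accuracy is pooled epoch-level accuracy per fold; the mean and standard
deviation over folds are reported, with per-trial accuracies emitted for
inspection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidConfigError, InvalidInputError
from .features import EpochFeatures, FeatureConfig, correlation_screen, make_bigram, select_features
from .labeling import STATES, KinematicEvents, LabelSequence
from .models import (
    HMMModel,
    apply_voting,
    fit_gmm,
    fit_transitions,
    gmm_classify_sequence,
    hmm_classify,
)
from .pipeline import PreparedTrial, TrialData, prepare_trial
from .preprocess import EpochSpec

__all__ = [
    "Metrics",
    "SweepResult",
    "kfold_split",
    "f_score",
    "confusion_and_scores",
    "transition_window_analysis",
    "train_classifier",
    "predict_trial",
    "run_experiment",
    "sweep",
    "sweep_results_frame",
]

logger = logging.getLogger(__name__)


@dataclass
class Metrics:
    """Confusion (rows = kinematic truth, percent) plus per-class P/R/F."""

    raw_counts: np.ndarray
    confusion_pct: np.ndarray
    accuracy_pct: float
    precision_pct: dict[str, float]
    recall_pct: dict[str, float]
    f_score_pct: dict[str, float]


@dataclass
class SweepResult:
    """Per-fold accuracies for one experimental condition."""

    condition: dict
    fold_accuracies: list[float]
    mean_accuracy_pct: float
    sd_accuracy_pct: float
    per_trial_accuracy: dict[str, float] = field(default_factory=dict)
    pooled_metrics: Metrics | None = None


def kfold_split(trial_ids: list[str], k: int, seed: int) -> list[tuple[list[str], list[str]]]:
    """Whole-trial K folds: disjoint, covering, sizes differing by <= 1."""
    ids = list(trial_ids)
    if k < 2 or k > len(ids):
        raise InvalidConfigError(f"need 2 <= K <= n_trials ({len(ids)}), got {k}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    folds = np.array_split(order, k)
    out = []
    for f in folds:
        test = [ids[i] for i in f]
        train = [t for t in ids if t not in test]
        out.append((train, test))
    return out


def f_score(precision_pct: float, recall_pct: float) -> float:
    """Harmonic mean of precision and recall, both in percent."""
    if precision_pct + recall_pct == 0:
        return float("nan")
    return 2.0 * precision_pct * recall_pct / (precision_pct + recall_pct)


def confusion_and_scores(truth: LabelSequence, pred: LabelSequence) -> Metrics:
    if len(truth) != len(pred):
        raise InvalidInputError("truth and prediction sequences differ in length")
    idx = {s: i for i, s in enumerate(STATES)}
    raw = np.zeros((3, 3), dtype=int)
    for t, p in zip(truth.labels, pred.labels):
        raw[idx[t], idx[p]] += 1
    total = raw.sum()
    accuracy = 100.0 * np.trace(raw) / total
    row_sums = raw.sum(axis=1)
    col_sums = raw.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        confusion = 100.0 * raw / row_sums[:, None]
    precision, recall, fsc = {}, {}, {}
    for i, s in enumerate(STATES):
        precision[s] = 100.0 * raw[i, i] / col_sums[i] if col_sums[i] else float("nan")
        recall[s] = 100.0 * raw[i, i] / row_sums[i] if row_sums[i] else float("nan")
        if np.isnan(precision[s]) or np.isnan(recall[s]):
            fsc[s] = float("nan")
        else:
            fsc[s] = f_score(precision[s], recall[s])
    return Metrics(
        raw_counts=raw,
        confusion_pct=confusion,
        accuracy_pct=float(accuracy),
        precision_pct=precision,
        recall_pct=recall,
        f_score_pct=fsc,
    )


def transition_window_analysis(
    events_list: list[KinematicEvents],
    preds: list[LabelSequence],
    window_ms: float = 125.0,
    epoch_length_ms: float = 125.0,
    n_before: int = 4,
    n_after: int = 4,
) -> pd.DataFrame:
    """Predicted-label percentages in fixed windows around each time stamp.

    Non-overlapping ``window_ms`` windows tile [t - n_before*w, t + n_after*w)
    around every kinematic grasp and release time t.  An epoch belongs to
    the window containing its temporal center; percentages are aggregated
    over all trials.  Empty windows are reported with n_epochs = 0.
    """
    w = window_ms / 1000.0
    counts: dict[tuple[str, int], np.ndarray] = {
        (anchor, k): np.zeros(3)
        for anchor in ("grasp", "release")
        for k in range(-n_before, n_after)
    }
    idx = {s: i for i, s in enumerate(STATES)}
    for ev, pred in zip(events_list, preds):
        centers = pred.start_times + epoch_length_ms / 2000.0
        for t_g, t_r in ev.movements:
            for anchor, t0 in (("grasp", t_g), ("release", t_r)):
                k = np.floor((centers - t0) / w).astype(int)
                ok = (k >= -n_before) & (k < n_after)
                for ki, lab in zip(k[ok], pred.labels[ok]):
                    counts[(anchor, int(ki))][idx[lab]] += 1
    rows = []
    for (anchor, k), c in counts.items():
        n = c.sum()
        row = {"anchor": anchor, "window_idx": k, "n_epochs": int(n)}
        for i, s in enumerate(STATES):
            row[f"pct_{s}"] = 100.0 * c[i] / n if n else float("nan")
        rows.append(row)
    return pd.DataFrame(rows).sort_values(["anchor", "window_idx"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# training / prediction on prepared trials


def train_classifier(
    train_trials: list[PreparedTrial],
    ngram: str = "unigram",
    n_components: int = 5,
    reg: float = 0.05,
    alpha: float = 1.0,
    feature_cfg: FeatureConfig | None = None,
    seed: int = 0,
) -> tuple[HMMModel, list[str]]:
    """Screen features, fit per-state emission GMMs and transitions.

    Screening is fit on the pooled training matrix only and the kept
    feature list is frozen into the returned model.
    """
    feature_cfg = feature_cfg or FeatureConfig()
    pooled = EpochFeatures(
        X=np.vstack([t.features.X for t in train_trials]),
        feature_names=train_trials[0].features.feature_names,
        start_times=np.arange(sum(t.features.n_epochs for t in train_trials), dtype=float),
        ngram="unigram",
    )
    screened, removed = correlation_screen(pooled, feature_cfg)
    kept = []
    for name in feature_cfg.included_features:
        if name not in removed and any(n.endswith(":" + name) for n in pooled.feature_names):
            kept.append(name)
    logger.info("correlation screen removed %s; %d dims remain", removed, screened.dim)

    def observed(trial: PreparedTrial) -> EpochFeatures:
        x = select_features(trial.features, kept)
        return make_bigram(x) if ngram == "bigram" else x

    obs = [observed(t) for t in train_trials]
    X_all = np.vstack([o.X for o in obs])
    y_all = np.concatenate([t.labels.labels for t in train_trials])
    missing = [s for s in STATES if not np.any(y_all == s)]
    if missing:
        raise InvalidInputError(f"training data lacks states: {missing}")
    rng = np.random.default_rng(seed)
    emissions = {}
    for s in STATES:
        Xs = X_all[y_all == s]
        if Xs.shape[0] < n_components:
            raise InvalidInputError(
                f"state {s} has {Xs.shape[0]} epochs < K={n_components} components"
            )
        emissions[s] = fit_gmm(
            Xs, K=n_components, reg=reg, seed=int(rng.integers(2**31)), label=s
        )
    transitions = fit_transitions([t.labels for t in train_trials], alpha=alpha)
    hmm = HMMModel.uniform_pi(transitions, emissions, ngram)
    return hmm, kept


def predict_trial(
    hmm: HMMModel,
    trial: PreparedTrial,
    kept: list[str],
    classifier: str = "hmm",
    voting_n: int = 0,
) -> LabelSequence:
    obs = select_features(trial.features, kept)
    if hmm.ngram == "bigram":
        obs = make_bigram(obs)
    if classifier == "hmm":
        raw = hmm_classify(hmm, obs)
    elif classifier == "gmm":
        raw = gmm_classify_sequence(hmm.emissions, obs)
    else:
        raise InvalidConfigError(f"classifier must be gmm|hmm, got {classifier!r}")
    return apply_voting(raw, voting_n)


def run_experiment(
    prepared: list[PreparedTrial],
    classifier: str = "hmm",
    ngram: str = "unigram",
    n_components: int = 5,
    reg: float = 0.05,
    alpha: float = 1.0,
    voting_n: int = 0,
    cv_k: int = 10,
    feature_cfg: FeatureConfig | None = None,
    seed: int = 0,
    condition: dict | None = None,
) -> SweepResult:
    """Trial-level K-fold cross-validation of one classifier condition."""
    rng = np.random.default_rng(seed)
    fold_seed = int(rng.integers(2**31))
    ids = [t.trial_id for t in prepared]
    by_id = {t.trial_id: t for t in prepared}
    folds = kfold_split(ids, cv_k, fold_seed)
    fold_accs: list[float] = []
    per_trial: dict[str, float] = {}
    all_truth: list[str] = []
    all_pred: list[str] = []
    for fold_idx, (train_ids, test_ids) in enumerate(folds):
        fit_seed = int(rng.integers(2**31))
        train = [by_id[i] for i in train_ids]
        try:
            hmm, kept = train_classifier(
                train, ngram=ngram, n_components=n_components, reg=reg,
                alpha=alpha, feature_cfg=feature_cfg, seed=fit_seed,
            )
        except InvalidInputError as exc:
            logger.warning("skipping fold %d: %s", fold_idx, exc)
            continue
        n_correct = 0
        n_total = 0
        for tid in test_ids:
            trial = by_id[tid]
            pred = predict_trial(hmm, trial, kept, classifier=classifier, voting_n=voting_n)
            correct = int(np.sum(pred.labels == trial.labels.labels))
            per_trial[tid] = 100.0 * correct / len(pred)
            n_correct += correct
            n_total += len(pred)
            all_truth.extend(trial.labels.labels)
            all_pred.extend(pred.labels)
        fold_accs.append(100.0 * n_correct / n_total)
    grid = np.arange(len(all_truth), dtype=float)
    pooled = confusion_and_scores(
        LabelSequence(labels=np.array(all_truth, object), start_times=grid),
        LabelSequence(labels=np.array(all_pred, object), start_times=grid),
    )
    accs = np.asarray(fold_accs, dtype=float)
    return SweepResult(
        condition=dict(condition or {}, classifier=classifier, ngram=ngram,
                       n_components=n_components, voting_n=voting_n, cv_k=cv_k),
        fold_accuracies=fold_accs,
        mean_accuracy_pct=float(accs.mean()),
        sd_accuracy_pct=float(accs.std(ddof=1)) if len(accs) > 1 else 0.0,
        per_trial_accuracy=per_trial,
        pooled_metrics=pooled,
    )


SWEEP_AXES = ("components", "ngram", "classifier", "epoch_size", "release_len", "voting")

DEFAULT_SWEEP_VALUES = {
    "components": list(range(1, 16)),
    "ngram": ["unigram", "bigram"],
    "classifier": ["gmm", "hmm"],
    "epoch_size": [50, 125, 200, 275, 350, 425, 500],
    "release_len": [200, 300, 400, 500, 600],
    "voting": [0, 1, 2, 3, 4, 5],
}


def sweep(
    trials: list[TrialData],
    axis: str,
    values: list | None = None,
    classifier: str = "hmm",
    ngram: str = "unigram",
    n_components: int = 5,
    voting_n: int = 0,
    cv_k: int = 10,
    epoch_spec: EpochSpec | None = None,
    feature_cfg: FeatureConfig | None = None,
    release_len_ms: float = 500.0,
    seed: int = 0,
    overlap_fraction: float = 0.8,
) -> list[SweepResult]:
    """Re-run the cross-validated experiment along one sensitivity axis.

    ``epoch_size`` values re-derive epochs, features and labels with the
    window overlap held at ``overlap_fraction`` of the window length;
    ``release_len`` values re-derive labels only.  Every condition uses
    the same master seed so fold assignments stay comparable.
    """
    if axis not in SWEEP_AXES:
        raise InvalidConfigError(f"axis must be one of {SWEEP_AXES}, got {axis!r}")
    values = list(DEFAULT_SWEEP_VALUES[axis]) if values is None else list(values)
    epoch_spec = epoch_spec or EpochSpec()
    feature_cfg = feature_cfg or FeatureConfig()

    def prep(spec: EpochSpec, rel: float) -> list[PreparedTrial]:
        return [
            prepare_trial(t, epoch_spec=spec, feature_cfg=feature_cfg, release_len_ms=rel)
            for t in trials
        ]

    base_prepared: list[PreparedTrial] | None = None
    results = []
    for v in values:
        kw = dict(
            classifier=classifier, ngram=ngram, n_components=n_components,
            voting_n=voting_n, cv_k=cv_k, feature_cfg=feature_cfg, seed=seed,
        )
        if axis == "epoch_size":
            spec = EpochSpec(length_ms=float(v), overlap_ms=float(v) * overlap_fraction)
            prepared = prep(spec, release_len_ms)
        elif axis == "release_len":
            prepared = prep(epoch_spec, float(v))
        else:
            if base_prepared is None:
                base_prepared = prep(epoch_spec, release_len_ms)
            prepared = base_prepared
            if axis == "components":
                kw["n_components"] = int(v)
            elif axis == "ngram":
                kw["ngram"] = str(v)
            elif axis == "classifier":
                kw["classifier"] = str(v)
            elif axis == "voting":
                kw["voting_n"] = int(v)
        res = run_experiment(prepared, condition={"axis": axis, "value": v}, **kw)
        results.append(res)
    return results


def sweep_results_frame(results: list[SweepResult]) -> pd.DataFrame:
    """Tidy (condition, fold, accuracy) table for external statistics."""
    rows = []
    for res in results:
        cond = res.condition.get("value", res.condition)
        for fold, acc in enumerate(res.fold_accuracies):
            rows.append({"condition": cond, "fold": fold, "accuracy_pct": acc})
    return pd.DataFrame(rows)
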
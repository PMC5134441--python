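"""Gaussian-mixture emission models and a causal three-state HMM.

The intent classifier has hidden states S = (steady, grasp, release).
Each state's emission density over a feature vector F is a Gaussian
mixture

    p(F | theta) = sum_k rho_k N(F | mu_k, Sigma_k),

fit by expectation-maximization with k-means++ initialization and an
additive diagonal regularization (default 0.05) applied to every
component covariance at each M-step.  Transitions are bigram counts over
training label sequences with Laplace smoothing; the initial
distribution is uniform so the decoder makes no assumption about the
starting state.  Decoding is strictly causal: the forward recursion is
run in the log domain and each epoch is assigned the argmax of its
*filtered* posterior, using only past and present observations.  An
optional unanimous-voting smoother carries the previous output label
until the current and previous n raw labels all agree on a new one.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cholesky, solve_triangular
from scipy.special import logsumexp

from .errors import ClassificationError, InvalidConfigError, InvalidInputError
from .features import EpochFeatures, FeatureConfig
from .labeling import STATES, LabelSequence
from .preprocess import EpochSpec

__all__ = [
    "GMMModel",
    "TransitionMatrix",
    "HMMModel",
    "gmm_logpdf",
    "gmm_log_likelihoods",
    "fit_gmm",
    "gmm_classify",
    "gmm_classify_sequence",
    "fit_transitions",
    "forward_filter",
    "hmm_classify",
    "apply_voting",
    "save_model",
    "load_model",
]

logger = logging.getLogger(__name__)


@dataclass
class GMMModel:
    """Mixture parameters for one class: weights (K,), means (K, D), covs (K, D, D)."""

    weights: np.ndarray
    means: np.ndarray
    covariances: np.ndarray
    reg: float = 0.05
    label: str = ""
    log_likelihood_path: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, float)
        self.means = np.atleast_2d(np.asarray(self.means, float))
        self.covariances = np.asarray(self.covariances, float)
        if self.covariances.ndim == 2:
            self.covariances = self.covariances[None]
        if abs(self.weights.sum() - 1.0) > 1e-12:
            raise InvalidInputError("mixture weights must sum to 1")
        if self.means.shape[0] != self.K or self.covariances.shape[0] != self.K:
            raise InvalidInputError("inconsistent component counts")

    @property
    def K(self) -> int:
        return len(self.weights)

    @property
    def D(self) -> int:
        return self.means.shape[1]


def _chol_logpdf(X: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> np.ndarray:
    """Log N(x | mean, cov) for each row of X via a Cholesky factor."""
    L = cholesky(cov, lower=True)
    dev = solve_triangular(L, (X - mean).T, lower=True)
    maha = np.sum(dev**2, axis=0)
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    d = X.shape[1]
    return -0.5 * (d * np.log(2.0 * np.pi) + logdet + maha)


def gmm_log_likelihoods(model: GMMModel, X: np.ndarray) -> np.ndarray:
    """Row-wise log mixture density, computed stably in the log domain."""
    X = np.atleast_2d(np.asarray(X, float))
    if X.shape[1] != model.D:
        raise InvalidInputError(f"dimension mismatch: x has {X.shape[1]}, model has {model.D}")
    comp = np.stack(
        [
            np.log(model.weights[k]) + _chol_logpdf(X, model.means[k], model.covariances[k])
            for k in range(model.K)
        ]
    )
    return logsumexp(comp, axis=0)


def gmm_logpdf(model: GMMModel, x: np.ndarray) -> float:
    """Log mixture density at a single D-vector."""
    return float(gmm_log_likelihoods(model, np.asarray(x, float).reshape(1, -1))[0])


# ---------------------------------------------------------------------------
# EM fitting with k-means++ initialization


def _kmeanspp_centers(X: np.ndarray, K: int, rng: np.random.Generator) -> np.ndarray:
    """k-means++ seeding: iteratively sample points ~ squared distance to nearest center."""
    n = X.shape[0]
    centers = [X[rng.integers(n)]]
    for _ in range(1, K):
        d2 = np.min(
            np.stack([np.sum((X - c) ** 2, axis=1) for c in centers]), axis=0
        )
        total = d2.sum()
        if total <= 0:  # all points coincide with a center
            centers.append(X[rng.integers(n)])
            continue
        centers.append(X[rng.choice(n, p=d2 / total)])
    return np.stack(centers)


def _m_step(X, resp, reg):
    nk = resp.sum(axis=0)
    weights = nk / nk.sum()
    means = (resp.T @ X) / nk[:, None]
    D = X.shape[1]
    covs = np.empty((len(nk), D, D))
    for k in range(len(nk)):
        dev = X - means[k]
        covs[k] = (resp[:, k][:, None] * dev).T @ dev / nk[k]
        covs[k][np.diag_indices(D)] += reg
    return weights, means, covs


def fit_gmm(
    X: np.ndarray,
    K: int,
    reg: float = 0.05,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-6,
    label: str = "",
) -> GMMModel:
    """Fit a K-component Gaussian mixture by EM.

    k-means++ picks the initial means (seeded); initial responsibilities
    are the hard nearest-center assignment.  ``reg`` is added to every
    covariance diagonal at each M-step.  EM stops when the relative
    improvement of the mean log-likelihood drops below ``tol`` or after
    ``max_iter`` iterations.  A component that collapses to (near) zero
    responsibility is re-seeded from the point the model currently
    explains worst.
    """
    X = np.atleast_2d(np.asarray(X, float))
    n, D = X.shape
    if K < 1:
        raise InvalidConfigError("K must be >= 1")
    if n < K:
        raise InvalidConfigError(f"need at least K={K} rows, got {n}")
    rng = np.random.default_rng(seed)
    centers = _kmeanspp_centers(X, K, rng)
    d2 = np.stack([np.sum((X - c) ** 2, axis=1) for c in centers])
    assign = np.argmin(d2, axis=0)
    resp = np.zeros((n, K))
    resp[np.arange(n), assign] = 1.0
    # guard: every component needs some mass before the first M-step
    for k in range(K):
        if resp[:, k].sum() == 0:
            resp[np.argmax(d2.min(axis=0))] = 0.0
            resp[np.argmax(d2.min(axis=0)), k] = 1.0
    weights, means, covs = _m_step(X, resp, reg)

    ll_path: list[float] = []
    prev_ll = -np.inf
    for _ in range(max_iter):
        # E-step in log domain
        log_comp = np.stack(
            [np.log(weights[k]) + _chol_logpdf(X, means[k], covs[k]) for k in range(K)],
            axis=1,
        )  # (n, K)
        log_norm = logsumexp(log_comp, axis=1)
        ll = float(log_norm.mean())
        ll_path.append(ll)
        resp = np.exp(log_comp - log_norm[:, None])
        nk = resp.sum(axis=0)
        for k in np.flatnonzero(nk < 1e-10):
            worst = int(np.argmin(log_norm))
            logger.warning("re-seeding empty mixture component %d from worst-fit point", k)
            resp[worst] = 0.0
            resp[worst, k] = 1.0
            nk = resp.sum(axis=0)
        weights, means, covs = _m_step(X, resp, reg)
        if np.isfinite(prev_ll) and abs(ll - prev_ll) <= tol * max(1.0, abs(prev_ll)):
            break
        prev_ll = ll
    return GMMModel(
        weights=weights, means=means, covariances=covs, reg=reg, label=label,
        log_likelihood_path=ll_path,
    )


# ---------------------------------------------------------------------------
# classification


def _class_log_likelihoods(models: dict[str, GMMModel], X: np.ndarray) -> np.ndarray:
    missing = [s for s in STATES if s not in models]
    if missing:
        raise InvalidInputError(f"missing emission models for states: {missing}")
    return np.stack([gmm_log_likelihoods(models[s], X) for s in STATES], axis=1)


def gmm_classify(models: dict[str, GMMModel], x: np.ndarray) -> str:
    """Maximum-likelihood label for one feature vector.

    Ties break toward the first state in (steady, grasp, release) order.
    """
    ll = _class_log_likelihoods(models, np.asarray(x, float).reshape(1, -1))[0]
    if not np.isfinite(ll).any():
        raise ClassificationError("no class produced a finite density")
    return STATES[int(np.argmax(ll))]


def gmm_classify_sequence(models: dict[str, GMMModel], obs: EpochFeatures) -> LabelSequence:
    """Epoch-by-epoch maximum-likelihood labels (no temporal coupling)."""
    ll = _class_log_likelihoods(models, obs.X)
    if not np.isfinite(ll).any(axis=1).all():
        raise ClassificationError("an epoch produced no finite class density")
    labels = np.array([STATES[k] for k in np.argmax(ll, axis=1)], dtype=object)
    return LabelSequence(labels=labels, start_times=obs.start_times)


@dataclass
class TransitionMatrix:
    """Row-stochastic 3×3 matrix over (steady, grasp, release)."""

    T: np.ndarray
    alpha: float = 1.0

    def __post_init__(self) -> None:
        self.T = np.asarray(self.T, float)
        if self.T.shape != (3, 3):
            raise InvalidInputError("transition matrix must be 3x3")
        if np.max(np.abs(self.T.sum(axis=1) - 1.0)) > 1e-12:
            raise InvalidInputError("transition rows must sum to 1")
        if not (self.T > 0).all():
            raise InvalidInputError("Laplace-smoothed transitions must be strictly positive")


def fit_transitions(label_seqs: list[LabelSequence], alpha: float = 1.0) -> TransitionMatrix:
    """Pooled bigram counts with Laplace pseudocount ``alpha``.

    T_ij = (count(i->j) + alpha) / (count(i->.) + 3 alpha); transitions
    never cross sequence boundaries.  A never-visited state falls back to
    a uniform row (pure pseudocounts).
    """
    if alpha <= 0:
        raise InvalidConfigError("alpha must be > 0 to guarantee positive transitions")
    if not any(len(seq) >= 2 for seq in label_seqs):
        raise InvalidInputError("need at least one label sequence of length >= 2")
    idx = {s: i for i, s in enumerate(STATES)}
    counts = np.zeros((3, 3))
    for seq in label_seqs:
        codes = np.array([idx[l] for l in seq.labels])
        for a, b in zip(codes[:-1], codes[1:]):
            counts[a, b] += 1
    T = (counts + alpha) / (counts.sum(axis=1, keepdims=True) + 3 * alpha)
    return TransitionMatrix(T=T, alpha=alpha)


@dataclass
class HMMModel:
    """Three-state HMM: uniform prior, smoothed transitions, per-state GMM emissions."""

    pi: np.ndarray
    transitions: TransitionMatrix
    emissions: dict[str, GMMModel]
    ngram: str = "unigram"

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, float)
        if self.pi.shape != (3,) or abs(self.pi.sum() - 1.0) > 1e-12:
            raise InvalidInputError("pi must be a length-3 distribution")
        dims = {s: m.D for s, m in self.emissions.items()}
        if set(dims) != set(STATES) or len(set(dims.values())) != 1:
            raise InvalidInputError("need one emission model per state, all with equal D")
        if self.ngram not in ("unigram", "bigram"):
            raise InvalidInputError("ngram must be unigram|bigram")

    @classmethod
    def uniform_pi(cls, transitions: TransitionMatrix, emissions: dict[str, GMMModel], ngram: str):
        return cls(pi=np.full(3, 1.0 / 3.0), transitions=transitions, emissions=emissions, ngram=ngram)


def forward_filter(hmm: HMMModel, obs: EpochFeatures) -> np.ndarray:
    """Causal filtered posteriors P(state_e | o_1..o_e), shape (n_epochs, 3).

    The recursion runs in the log domain: at e=0 the prior is the initial
    distribution; afterwards it is the previous (normalized) posterior
    propagated through the transition matrix.  Each row is normalized, so
    only the relative emission likelihoods matter.
    """
    if obs.ngram != hmm.ngram:
        raise InvalidInputError(f"observation ngram {obs.ngram!r} != model ngram {hmm.ngram!r}")
    logB = _class_log_likelihoods(hmm.emissions, obs.X)  # (n, 3)
    n = logB.shape[0]
    post = np.empty((n, 3))
    log_prior = np.log(hmm.pi)
    logT = np.log(hmm.transitions.T)
    for e in range(n):
        log_alpha = log_prior + logB[e]
        norm = logsumexp(log_alpha)
        if not np.isfinite(norm):
            raise ClassificationError(f"all-state zero likelihood at epoch {e}")
        post[e] = np.exp(log_alpha - norm)
        with np.errstate(divide="ignore"):  # a zero posterior entry is a valid -inf
            log_prior = logsumexp(np.log(post[e])[:, None] + logT, axis=0)
    return post


def hmm_classify(hmm: HMMModel, obs: EpochFeatures) -> LabelSequence:
    """Per-epoch argmax of the filtered posterior (causal decoding)."""
    post = forward_filter(hmm, obs)
    labels = np.array([STATES[k] for k in np.argmax(post, axis=1)], dtype=object)
    return LabelSequence(labels=labels, start_times=obs.start_times)


def apply_voting(raw: LabelSequence, n: int) -> LabelSequence:
    """Unanimous voting over the current and previous ``n`` raw labels.

    n=0 returns the raw sequence.  Otherwise the carried label only
    changes at epoch e when raw[e-n..e] unanimously agree on a different
    label; the first n epochs pass through raw and update the carry.
    """
    if n < 0:
        raise InvalidConfigError("voting n must be >= 0")
    if n == 0:
        return LabelSequence(labels=raw.labels.copy(), start_times=raw.start_times)
    out = np.empty_like(raw.labels)
    carry = None
    for e in range(len(raw)):
        if e < n:
            carry = raw.labels[e]
            out[e] = carry
            continue
        window = raw.labels[e - n : e + 1]
        first = window[0]
        if first != carry and all(w == first for w in window):
            carry = first
        out[e] = carry
    return LabelSequence(labels=out, start_times=raw.start_times)


# ---------------------------------------------------------------------------
# serialization: one JSON container holding the full trained pipeline state


def _arr(a: np.ndarray) -> list:
    return np.asarray(a, float).tolist()


def save_model(
    path,
    hmm: HMMModel,
    kept_features: list[str],
    feature_cfg: FeatureConfig,
    epoch_spec: EpochSpec,
) -> None:
    """Serialize parameters plus the frozen feature pipeline settings.

    Floats go through JSON's repr round-trip, which is bit-exact for
    IEEE doubles.
    """
    doc = {
        "format": "semgrasp-model-v1",
        "ngram": hmm.ngram,
        "pi": _arr(hmm.pi),
        "transitions": {"T": _arr(hmm.transitions.T), "alpha": hmm.transitions.alpha},
        "emissions": {
            s: {
                "weights": _arr(m.weights),
                "means": _arr(m.means),
                "covariances": _arr(m.covariances),
                "reg": m.reg,
                "label": m.label,
            }
            for s, m in hmm.emissions.items()
        },
        "kept_features": list(kept_features),
        "feature_config": {
            "wamp_threshold": feature_cfg.wamp_threshold,
            "freq_lo": feature_cfg.freq_lo,
            "freq_hi": feature_cfg.freq_hi,
            "n_freq_bins": feature_cfg.n_freq_bins,
            "amp_bin_width": feature_cfg.amp_bin_width,
            "n_amp_bins": feature_cfg.n_amp_bins,
            "included_features": list(feature_cfg.included_features),
            "corr_r2_cutoff": feature_cfg.corr_r2_cutoff,
        },
        "epoch_spec": {"length_ms": epoch_spec.length_ms, "overlap_ms": epoch_spec.overlap_ms},
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def load_model(path) -> tuple[HMMModel, list[str], FeatureConfig, EpochSpec]:
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("format") != "semgrasp-model-v1":
        raise InvalidInputError(f"{path}: not a semgrasp model file")
    emissions = {
        s: GMMModel(
            weights=np.array(m["weights"]),
            means=np.array(m["means"]),
            covariances=np.array(m["covariances"]),
            reg=m["reg"],
            label=m["label"],
        )
        for s, m in doc["emissions"].items()
    }
    hmm = HMMModel(
        pi=np.array(doc["pi"]),
        transitions=TransitionMatrix(T=np.array(doc["transitions"]["T"]), alpha=doc["transitions"]["alpha"]),
        emissions=emissions,
        ngram=doc["ngram"],
    )
    fc = doc["feature_config"]
    feature_cfg = FeatureConfig(
        wamp_threshold=fc["wamp_threshold"],
        freq_lo=fc["freq_lo"],
        freq_hi=fc["freq_hi"],
        n_freq_bins=fc["n_freq_bins"],
        amp_bin_width=fc["amp_bin_width"],
        n_amp_bins=fc["n_amp_bins"],
        included_features=tuple(fc["included_features"]),
        corr_r2_cutoff=fc["corr_r2_cutoff"],
    )
    spec = EpochSpec(length_ms=doc["epoch_spec"]["length_ms"], overlap_ms=doc["epoch_spec"]["overlap_ms"])
    return hmm, list(doc["kept_features"]), feature_cfg, spec
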
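"""First-order linear-chain conditional random field over {O, D} labels.

The model assigns each label chain ``y`` for an observed protein ``x`` the
probability

    P(y | x) = exp( sum_i T[y_{i-1}, y_i] + sum_i sum_l W[l, y_i] x_{i,l} ) / Z(x)

where ``T`` holds one weight per ordered label pair (transition features:
indicators of a specific previous/current label pair; the first position has
no transition term), ``W`` holds one weight per (state feature, label) pair
(real-valued per-position features coupled to the current label), and ``Z(x)``
normalizes over all 2^L chains.  Inference (forward-backward, Viterbi) is
exact and carried out entirely in log space.

Training maximizes the L2-penalized conditional log-likelihood with L-BFGS.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp

__all__ = [
    "LabelAlphabet",
    "ObservationSequence",
    "LabeledSequence",
    "CRFModel",
    "TrainingConfig",
    "sequence_score",
    "log_partition",
    "posterior_marginals",
    "pairwise_marginals",
    "conditional_log_likelihood_and_gradient",
    "train",
    "viterbi_decode",
    "marginal_decode",
    "save_model",
    "load_model",
]


class CRFInputError(ValueError):
    """Raised for invalid observations, labels or configurations."""


@dataclass(frozen=True)
class LabelAlphabet:
    """The fixed two-symbol residue alphabet: O (ordered), D (disordered)."""

    labels: tuple[str, str] = ("O", "D")

    def __post_init__(self) -> None:
        if len(self.labels) != 2 or len(set(self.labels)) != 2:
            raise CRFInputError("label alphabet must contain exactly two distinct symbols")

    def index(self, symbol: str) -> int:
        try:
            return self.labels.index(symbol)
        except ValueError:
            raise CRFInputError(f"unknown label symbol {symbol!r}") from None

    def encode(self, chain: str) -> np.ndarray:
        """Label string -> int vector (O=0, D=1)."""
        lut = {s: i for i, s in enumerate(self.labels)}
        try:
            return np.array([lut[c] for c in chain], dtype=np.intp)
        except KeyError as exc:
            raise CRFInputError(f"label {exc.args[0]!r} not in alphabet {self.labels}") from None

    def decode(self, indices: Sequence[int]) -> str:
        return "".join(self.labels[i] for i in indices)


ALPHABET = LabelAlphabet()


class ObservationSequence:
    """A protein as the CRF sees it: an id plus an L x F state-feature matrix."""

    __slots__ = ("sequence_id", "features")

    def __init__(self, sequence_id: str, features: np.ndarray):
        features = np.asarray(features, dtype=float)
        if features.ndim != 2 or features.shape[0] < 1:
            raise CRFInputError(f"{sequence_id}: feature matrix must be 2-D with L >= 1")
        if not np.all(np.isfinite(features)):
            raise CRFInputError(f"{sequence_id}: non-finite feature values")
        self.sequence_id = sequence_id
        self.features = features

    @property
    def length(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    def __repr__(self) -> str:  # pragma: no cover
        return f"ObservationSequence({self.sequence_id!r}, L={self.length}, F={self.n_features})"


class LabeledSequence:
    """An observation together with its per-residue O/D label chain."""

    __slots__ = ("observation", "labels")

    def __init__(self, observation: ObservationSequence, labels: str):
        if len(labels) != observation.length:
            raise CRFInputError(
                f"{observation.sequence_id}: label chain length {len(labels)} "
                f"!= sequence length {observation.length}"
            )
        ALPHABET.encode(labels)  # validates symbols
        self.observation = observation
        self.labels = labels


@dataclass
class TrainingConfig:
    """Hyperparameters of penalized maximum-likelihood training.

    ``num_iterations`` and ``init_weight`` default to the values tuned for
    the disorder task (50 quasi-Newton iterations; all weights start at
    0.05).  ``l2_sigma_squared`` is the variance of the Gaussian prior on
    the weights.
    """

    num_iterations: int = 50
    init_weight: float = 0.05
    l2_sigma_squared: float = 100.0
    seed: int = 0
    convergence_tolerance: float = 1e-6

    def __post_init__(self) -> None:
        if self.num_iterations < 1:
            raise CRFInputError("num_iterations must be >= 1")
        if self.l2_sigma_squared <= 0:
            raise CRFInputError("l2_sigma_squared must be > 0")


@dataclass
class CRFModel:
    """Trained CRF parameters.

    transition_weights : (2, 2) array indexed (previous label, current label)
    state_weights      : (F, 2) array indexed (feature index, current label)
    """

    transition_weights: np.ndarray
    state_weights: np.ndarray
    alphabet: LabelAlphabet = field(default_factory=LabelAlphabet)
    config: TrainingConfig | None = None

    def __post_init__(self) -> None:
        self.transition_weights = np.asarray(self.transition_weights, dtype=float)
        self.state_weights = np.asarray(self.state_weights, dtype=float)
        if self.transition_weights.shape != (2, 2):
            raise CRFInputError("transition_weights must have shape (2, 2)")
        if self.state_weights.ndim != 2 or self.state_weights.shape[1] != 2:
            raise CRFInputError("state_weights must have shape (F, 2)")
        if not (
            np.all(np.isfinite(self.transition_weights))
            and np.all(np.isfinite(self.state_weights))
        ):
            raise CRFInputError("model weights must be finite")

    @property
    def n_features(self) -> int:
        return self.state_weights.shape[0]

    @classmethod
    def zeros(cls, n_features: int) -> "CRFModel":
        return cls(np.zeros((2, 2)), np.zeros((n_features, 2)))


def _check_obs(model: CRFModel, obs: ObservationSequence) -> None:
    if obs.n_features != model.n_features:
        raise CRFInputError(
            f"{obs.sequence_id}: observation has F={obs.n_features}, model expects "
            f"F={model.n_features}"
        )


def _state_scores(model: CRFModel, obs: ObservationSequence) -> np.ndarray:
    """(L, 2) matrix of per-position label scores sum_l W[l, y] x_{i,l}."""
    return obs.features @ model.state_weights


def sequence_score(model: CRFModel, obs: ObservationSequence, labels: str) -> float:
    """Unnormalized log-score of one label chain; exp(score - logZ) = P(y|x)."""
    _check_obs(model, obs)
    y = model.alphabet.encode(labels)
    if y.shape[0] != obs.length:
        raise CRFInputError(
            f"{obs.sequence_id}: labels length {y.shape[0]} != sequence length {obs.length}"
        )
    S = _state_scores(model, obs)
    score = float(S[np.arange(obs.length), y].sum())
    if obs.length > 1:
        score += float(model.transition_weights[y[:-1], y[1:]].sum())
    return score


def _forward(model: CRFModel, S: np.ndarray) -> np.ndarray:
    """Log-space forward messages; alpha[i, y] = log sum over prefixes ending in y."""
    L = S.shape[0]
    T = model.transition_weights
    alpha = np.empty((L, 2))
    alpha[0] = S[0]
    for i in range(1, L):
        cand = alpha[i - 1][:, None] + T  # (previous, current)
        alpha[i] = np.logaddexp(cand[0], cand[1]) + S[i]
    return alpha


def _backward(model: CRFModel, S: np.ndarray) -> np.ndarray:
    L = S.shape[0]
    T = model.transition_weights
    beta = np.empty((L, 2))
    beta[L - 1] = 0.0
    for i in range(L - 2, -1, -1):
        cand = T + S[i + 1] + beta[i + 1]  # (previous, current)
        beta[i] = np.logaddexp(cand[:, 0], cand[:, 1])
    return beta


def log_partition(model: CRFModel, obs: ObservationSequence) -> float:
    """log Z(x): log-sum over all 2^L chains, by the log-space forward recursion."""
    _check_obs(model, obs)
    S = _state_scores(model, obs)
    return float(logsumexp(_forward(model, S)[-1]))


def posterior_marginals(model: CRFModel, obs: ObservationSequence) -> np.ndarray:
    """(L, 2) matrix of P(y_i = y | x); each row sums to 1."""
    _check_obs(model, obs)
    S = _state_scores(model, obs)
    alpha = _forward(model, S)
    beta = _backward(model, S)
    log_marg = alpha + beta
    log_marg -= logsumexp(log_marg, axis=1, keepdims=True)
    return np.exp(log_marg)


def pairwise_marginals(model: CRFModel, obs: ObservationSequence) -> np.ndarray:
    """(L-1, 2, 2) array of P(y_i = a, y_{i+1} = b | x); empty for L = 1."""
    _check_obs(model, obs)
    S = _state_scores(model, obs)
    L = S.shape[0]
    if L == 1:
        return np.zeros((0, 2, 2))
    alpha = _forward(model, S)
    beta = _backward(model, S)
    logZ = logsumexp(alpha[-1])
    T = model.transition_weights
    out = np.empty((L - 1, 2, 2))
    for i in range(L - 1):
        out[i] = np.exp(alpha[i][:, None] + T + S[i + 1][None, :] + beta[i + 1][None, :] - logZ)
    return out


def conditional_log_likelihood_and_gradient(
    model: CRFModel,
    data: Sequence[LabeledSequence],
    config: TrainingConfig,
) -> tuple[float, tuple[np.ndarray, np.ndarray]]:
    """Penalized conditional log-likelihood and its gradient.

    Returns ``(ll, (grad_T, grad_W))`` where the gradient blocks have the
    shapes of ``model.transition_weights`` and ``model.state_weights``.  The
    gradient is empirical minus expected feature counts, minus ``w / sigma^2``.
    """
    if not data:
        raise CRFInputError("training data must be nonempty")
    F = model.n_features
    for seq in data:
        if seq.observation.n_features != F:
            raise CRFInputError(
                f"{seq.observation.sequence_id}: inconsistent feature dimension "
                f"{seq.observation.n_features} != {F}"
            )

    ll = 0.0
    grad_T = np.zeros((2, 2))
    grad_W = np.zeros((F, 2))
    eye = np.eye(2)
    for seq in data:
        obs = seq.observation
        X = obs.features
        y = model.alphabet.encode(seq.labels)
        S = X @ model.state_weights
        alpha = _forward(model, S)
        beta = _backward(model, S)
        logZ = float(logsumexp(alpha[-1]))

        score = float(S[np.arange(obs.length), y].sum())
        if obs.length > 1:
            score += float(model.transition_weights[y[:-1], y[1:]].sum())
        ll += score - logZ

        # node marginals
        log_marg = alpha + beta
        log_marg -= logsumexp(log_marg, axis=1, keepdims=True)
        marg = np.exp(log_marg)

        grad_W += X.T @ (eye[y] - marg)

        if obs.length > 1:
            np.add.at(grad_T, (y[:-1], y[1:]), 1.0)
            T = model.transition_weights
            grad_T -= np.exp(
                alpha[:-1, :, None] + T[None, :, :] + (S[1:] + beta[1:])[:, None, :] - logZ
            ).sum(axis=0)

    sigma2 = config.l2_sigma_squared
    ll -= (np.sum(model.transition_weights**2) + np.sum(model.state_weights**2)) / (2 * sigma2)
    grad_T -= model.transition_weights / sigma2
    grad_W -= model.state_weights / sigma2
    return ll, (grad_T, grad_W)


def _pack(T: np.ndarray, W: np.ndarray) -> np.ndarray:
    return np.concatenate([T.ravel(), W.ravel()])


def _unpack(w: np.ndarray, F: int) -> tuple[np.ndarray, np.ndarray]:
    return w[:4].reshape(2, 2), w[4:].reshape(F, 2)


def train(
    data: Sequence[LabeledSequence],
    config: TrainingConfig | None = None,
    iteration_log: list[float] | None = None,
) -> CRFModel:
    """Fit the CRF by L-BFGS ascent on the penalized conditional log-likelihood.

    All weights start at ``config.init_weight``; at most
    ``config.num_iterations`` quasi-Newton iterations are taken.  The
    accepted objective never falls below its value at initialization.
    """
    if config is None:
        config = TrainingConfig()
    if not data:
        raise CRFInputError("training data must be nonempty")
    F = data[0].observation.n_features

    def neg_objective(w: np.ndarray) -> tuple[float, np.ndarray]:
        T, W = _unpack(w, F)
        model = CRFModel(T, W)
        ll, (gT, gW) = conditional_log_likelihood_and_gradient(model, data, config)
        return -ll, -_pack(gT, gW)

    callback = None
    if iteration_log is not None:
        iteration_log.append(-neg_objective(np.full(4 + 2 * F, float(config.init_weight)))[0])
        callback = lambda wk: iteration_log.append(-neg_objective(wk)[0])  # noqa: E731

    w0 = np.full(4 + 2 * F, float(config.init_weight))
    result = minimize(
        neg_objective,
        w0,
        jac=True,
        method="L-BFGS-B",
        callback=callback,
        options={
            "maxiter": config.num_iterations,
            "ftol": config.convergence_tolerance,
            "maxls": 50,
        },
    )
    T, W = _unpack(result.x, F)
    return CRFModel(T, W, config=config)


def viterbi_decode(model: CRFModel, obs: ObservationSequence) -> str:
    """Highest-scoring label chain; score ties are broken in favor of O.

    The O-preference follows from O having index 0 and every argmax taking
    the first maximizer.
    """
    _check_obs(model, obs)
    S = _state_scores(model, obs)
    L = S.shape[0]
    T = model.transition_weights
    delta = np.empty((L, 2))
    back = np.zeros((L, 2), dtype=np.intp)
    delta[0] = S[0]
    for i in range(1, L):
        cand = delta[i - 1][:, None] + T  # (prev, cur)
        back[i] = np.argmax(cand, axis=0)
        delta[i] = cand[back[i], np.arange(2)] + S[i]
    path = np.empty(L, dtype=np.intp)
    path[-1] = int(np.argmax(delta[-1]))
    for i in range(L - 1, 0, -1):
        path[i - 1] = back[i, path[i]]
    return model.alphabet.decode(path)


def marginal_decode(model: CRFModel, obs: ObservationSequence, threshold: float = 0.5) -> str:
    """Label each position D iff its posterior disorder probability exceeds ``threshold``."""
    marg = posterior_marginals(model, obs)
    return model.alphabet.decode((marg[:, 1] > threshold).astype(np.intp))


_FORMAT_VERSION = 1


def save_model(model: CRFModel, path) -> None:
    """Serialize a model to versioned JSON; floats round-trip exactly."""
    payload = {
        "format": "disocrf-model",
        "version": _FORMAT_VERSION,
        "alphabet": list(model.alphabet.labels),
        "n_features": model.n_features,
        "transition_weights": model.transition_weights.tolist(),
        "state_weights": model.state_weights.tolist(),
        "config": asdict(model.config) if model.config is not None else None,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
        fh.write("\n")


def load_model(path) -> CRFModel:
    with open(path) as fh:
        payload = json.load(fh)
    if payload.get("format") != "disocrf-model":
        raise CRFInputError(f"{path}: not a disocrf model file")
    if payload.get("version") != _FORMAT_VERSION:
        warnings.warn(
            f"{path}: model format version {payload.get('version')} != {_FORMAT_VERSION}"
        )
    config = TrainingConfig(**payload["config"]) if payload.get("config") else None
    model = CRFModel(
        np.array(payload["transition_weights"], dtype=float),
        np.array(payload["state_weights"], dtype=float),
        alphabet=LabelAlphabet(tuple(payload["alphabet"])),
        config=config,
    )
    if model.n_features != payload["n_features"]:
        raise CRFInputError(f"{path}: inconsistent n_features in model file")
    return model
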
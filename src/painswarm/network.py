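"""Single-hidden-layer softmax classifier driven by a flat parameter vector.

The network is the search space of the swarm optimizer: one hidden layer of
ReLU units (256 by default) with optional inverted dropout, and a 2-unit
softmax output. All weights and biases live in a single real vector in the
fixed order (W1 row-major, b1, W2 row-major, b2), so a particle position *is*
a parameter set. Fitness is the mean negative log-likelihood of the labels
plus an L2 penalty (lambda = 0.01) on the weight matrices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import softmax as _softmax

PROB_FLOOR = 1e-12  # probability clip before the log


@dataclass(frozen=True)
class NetworkSpec:
    """Layer sizes and regularisation of the classifier."""

    n_input: int
    n_hidden: int = 256
    n_output: int = 2
    dropout_rate: float = 0.5

    def __post_init__(self) -> None:
        if min(self.n_input, self.n_hidden, self.n_output) < 1:
            raise ValueError("all layer sizes must be >= 1")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must lie in [0, 1)")

    @property
    def n_parameters(self) -> int:
        return (
            self.n_input * self.n_hidden
            + self.n_hidden
            + self.n_hidden * self.n_output
            + self.n_output
        )


@dataclass(frozen=True)
class FitnessConfig:
    """Fitness-evaluation settings.

    dropout_mode ``off`` keeps the fitness deterministic; an explicit
    ``dropout_mask`` (one fixed mask shared by all particles within an
    epoch) reproduces training-time dropout without making the swarm's
    objective a moving target between particles.
    """

    l2_lambda: float = 0.01
    dropout_mode: str = "off"  # {"off", "fixed_mask_per_epoch"}
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.l2_lambda < 0:
            raise ValueError("l2_lambda must be >= 0")
        if self.dropout_mode not in ("off", "fixed_mask_per_epoch"):
            raise ValueError(f"unknown dropout_mode {self.dropout_mode!r}")


def unflatten(
    values: np.ndarray, spec: NetworkSpec
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Split a flat parameter vector into (W1, b1, W2, b2)."""
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or values.size != spec.n_parameters:
        raise ValueError(
            f"parameter vector of length {values.size}, expected {spec.n_parameters}"
        )
    i, h, o = spec.n_input, spec.n_hidden, spec.n_output
    p = 0
    W1 = values[p : p + i * h].reshape(i, h)
    p += i * h
    b1 = values[p : p + h]
    p += h
    W2 = values[p : p + h * o].reshape(h, o)
    p += h * o
    b2 = values[p : p + o]
    return W1, b1, W2, b2


def flatten(
    W1: np.ndarray,
    b1: np.ndarray,
    W2: np.ndarray,
    b2: np.ndarray,
    spec: NetworkSpec,
) -> np.ndarray:
    """Concatenate structured weights into the canonical flat layout."""
    shapes = {
        "W1": (W1, (spec.n_input, spec.n_hidden)),
        "b1": (b1, (spec.n_hidden,)),
        "W2": (W2, (spec.n_hidden, spec.n_output)),
        "b2": (b2, (spec.n_output,)),
    }
    for name, (arr, want) in shapes.items():
        if np.shape(arr) != want:
            raise ValueError(f"{name} has shape {np.shape(arr)}, expected {want}")
    return np.concatenate(
        [np.ravel(W1), np.ravel(b1), np.ravel(W2), np.ravel(b2)]
    ).astype(float)


def forward(
    X: np.ndarray,
    params: np.ndarray,
    spec: NetworkSpec,
    dropout_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Forward pass; returns an (n, n_output) matrix of class probabilities.

    With a binary ``dropout_mask`` of length n_hidden, masked units output 0
    and survivors are scaled by 1/(1 - dropout_rate) (inverted dropout), so
    inference needs no rescaling.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != spec.n_input:
        raise ValueError(f"X has {X.shape[1]} columns, spec expects {spec.n_input}")
    params = np.asarray(params, dtype=float)
    if not np.all(np.isfinite(params)):
        raise FloatingPointError("non-finite parameter vector")
    W1, b1, W2, b2 = unflatten(params, spec)
    H = np.maximum(X @ W1 + b1, 0.0)
    if dropout_mask is not None:
        mask = np.asarray(dropout_mask, dtype=float)
        if mask.shape != (spec.n_hidden,):
            raise ValueError("dropout mask length must equal n_hidden")
        H = H * mask / (1.0 - spec.dropout_rate)
    return _softmax(H @ W2 + b2, axis=1)


def sample_dropout_mask(spec: NetworkSpec, rng: np.random.Generator) -> np.ndarray:
    """Bernoulli keep-mask over hidden units at rate 1 - dropout_rate."""
    return (rng.uniform(size=spec.n_hidden) >= spec.dropout_rate).astype(float)


def nll_l2_fitness(
    params: np.ndarray,
    X: np.ndarray,
    y: np.ndarray,
    cfg: FitnessConfig,
    spec: NetworkSpec,
    dropout_mask: np.ndarray | None = None,
) -> float:
    """Mean negative log-likelihood plus lambda * sum of squared weights.

    Biases are excluded from the penalty; probabilities are clipped at 1e-12
    before the log so the fitness stays finite for any parameter vector.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 0:
        raise ValueError("empty design matrix")
    y = np.asarray(y, dtype=int)
    if set(np.unique(y)) - set(range(spec.n_output)):
        raise ValueError("labels outside the output range")
    P = forward(X, params, spec, dropout_mask=dropout_mask)
    p_true = np.clip(P[np.arange(len(y)), y], PROB_FLOOR, None)
    nll = -float(np.mean(np.log(p_true)))
    W1, _, W2, _ = unflatten(params, spec)
    penalty = cfg.l2_lambda * (float(np.sum(W1**2)) + float(np.sum(W2**2)))
    return nll + penalty


def predict(
    X: np.ndarray, params: np.ndarray, spec: NetworkSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Hard labels and positive-class probabilities (dropout disabled).

    Ties (p0 == p1) break toward class 0.
    """
    P = forward(X, params, spec, dropout_mask=None)
    labels = np.argmax(P, axis=1)  # np.argmax returns the first (lowest) index on ties
    return labels, P[:, 1].copy()


def save_parameters(path, params: np.ndarray, spec: NetworkSpec) -> None:
    """Single-column parameter file with a JSON header line of the layout."""
    import json

    header = json.dumps(
        {
            "layout": "W1_row_major,b1,W2_row_major,b2",
            "n_input": spec.n_input,
            "n_hidden": spec.n_hidden,
            "n_output": spec.n_output,
            "dropout_rate": spec.dropout_rate,
        }
    )
    np.savetxt(path, np.asarray(params, dtype=float), header=header, comments="# ")


def load_parameters(path) -> tuple[np.ndarray, NetworkSpec]:
    import json

    with open(path) as fh:
        header = fh.readline().lstrip("# ").strip()
    meta = json.loads(header)
    params = np.loadtxt(path)
    spec = NetworkSpec(
        n_input=meta["n_input"],
        n_hidden=meta["n_hidden"],
        n_output=meta["n_output"],
        dropout_rate=meta["dropout_rate"],
    )
    return params, spec
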
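"""A small multilayer perceptron with test-time dropout, in numpy.

The classifier at the heart of the pipeline is a two-hidden-layer MLP
(ReLU activations, sigmoid output, binary cross-entropy loss) trained
with Adam.  Dropout is *not* used during training; it is applied only at
inference, where repeated stochastic forward passes with random subsets
of hidden units give a per-input predictive variance — the uncertainty
signal.  The intuition: a prediction supported by a distributed,
redundant representation survives the removal of most hidden units,
while a prediction carried by a few idiosyncratic units does not.

The network is deliberately tiny (~2k parameters) and the whole
implementation is plain vectorised numpy, which keeps single-CPU
training of large ensembles fast and exactly reproducible from a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class ModelSpec:
    """Architecture and optimisation settings for one ensemble member.

    ``dropout_rates`` are the probabilities of *dropping* a unit on the
    first and second hidden layers during test-time dropout passes.
    """

    input_width: int = 41
    hidden_sizes: tuple[int, int] = (64, 32)
    learning_rate: float = 1e-3
    batch_size: int = 8
    epochs: int = 10
    dropout_rates: tuple[float, float] = (0.8, 0.7)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * np.clip(z, -60.0, 60.0)))


class MLP:
    """Two-hidden-layer perceptron: ReLU, ReLU, sigmoid."""

    def __init__(self, spec: ModelSpec, rng: np.random.Generator) -> None:
        self.spec = spec
        d, (h1, h2) = spec.input_width, spec.hidden_sizes
        # He initialisation for the ReLU layers, Xavier for the output
        self.W1 = rng.normal(0.0, np.sqrt(2.0 / d), size=(d, h1))
        self.b1 = np.zeros(h1)
        self.W2 = rng.normal(0.0, np.sqrt(2.0 / h1), size=(h1, h2))
        self.b2 = np.zeros(h2)
        self.W3 = rng.normal(0.0, np.sqrt(1.0 / h2), size=(h2, 1))
        self.b3 = np.zeros(1)

    # -- forward -----------------------------------------------------------

    def _forward(self, X: np.ndarray):
        a1 = np.maximum(X @ self.W1 + self.b1, 0.0)
        a2 = np.maximum(a1 @ self.W2 + self.b2, 0.0)
        p = _sigmoid(a2 @ self.W3 + self.b3)[:, 0]
        return a1, a2, p

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Deterministic class-1 probabilities, one per row of ``X``."""
        return self._forward(np.asarray(X, dtype=np.float64))[2]

    def predict_dropout(
        self,
        X: np.ndarray,
        n_iter: int = 100,
        rates: tuple[float, float] | None = None,
        rng: np.random.Generator | None = None,
    ) -> np.ndarray:
        """(n_samples, n_iter) probabilities under random unit dropout.

        Each iteration draws one Bernoulli keep-mask per hidden layer
        (shared across samples — each pass evaluates one thinned
        sub-network, i.e. one random neuronal subset of the trained
        model).  Kept activations are rescaled by 1/keep-probability, as
        in standard (inverted) dropout, so the logit scale of the full
        network is preserved: a prediction backed by a saturated,
        distributed logit stays saturated under most masks (low
        variance), while a borderline prediction swings (high
        variance).
        """
        if rng is None:
            rng = np.random.default_rng()
        r1, r2 = rates if rates is not None else self.spec.dropout_rates
        X = np.asarray(X, dtype=np.float64)
        h1, h2 = self.spec.hidden_sizes
        keep1, keep2 = 1.0 - r1, 1.0 - r2
        out = np.empty((X.shape[0], n_iter))
        z1 = X @ self.W1 + self.b1
        for t in range(n_iter):
            m1 = (rng.random(h1) >= r1) / keep1 if keep1 > 0 else np.zeros(h1)
            m2 = (rng.random(h2) >= r2) / keep2 if keep2 > 0 else np.zeros(h2)
            a1 = np.maximum(z1, 0.0) * m1
            a2 = np.maximum(a1 @ self.W2 + self.b2, 0.0) * m2
            out[:, t] = _sigmoid(a2 @ self.W3 + self.b3)[:, 0]
        return out

    # -- training ----------------------------------------------------------

    def fit(self, X: np.ndarray, y: np.ndarray, rng: np.random.Generator) -> "MLP":
        """Train with Adam on minibatches of binary cross-entropy.

        Rows are reshuffled every epoch with ``rng``; the run is a pure
        function of the initial weights, the data and the generator
        state.
        """
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64)
        n = X.shape[0]
        if n == 0:
            raise ValueError("empty training set")
        params = [self.W1, self.b1, self.W2, self.b2, self.W3, self.b3]
        m = [np.zeros_like(p) for p in params]
        v = [np.zeros_like(p) for p in params]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        lr = self.spec.learning_rate
        t = 0
        for _epoch in range(self.spec.epochs):
            order = rng.permutation(n)
            for start in range(0, n, self.spec.batch_size):
                idx = order[start: start + self.spec.batch_size]
                Xb, yb = X[idx], y[idx]
                a1, a2, p = self._forward(Xb)
                if not np.all(np.isfinite(p)):
                    raise FloatingPointError(
                        f"non-finite predictions at step {t}; "
                        f"weight norms: {[float(np.abs(q).max()) for q in params]}"
                    )
                bsz = len(idx)
                # d(BCE)/dz3 for sigmoid output = (p - y) / batch
                d3 = (p - yb)[:, None] / bsz
                gW3 = a2.T @ d3
                gb3 = d3.sum(axis=0)
                d2 = (d3 @ self.W3.T) * (a2 > 0)
                gW2 = a1.T @ d2
                gb2 = d2.sum(axis=0)
                d1 = (d2 @ self.W2.T) * (a1 > 0)
                gW1 = Xb.T @ d1
                gb1 = d1.sum(axis=0)
                grads = [gW1, gb1, gW2, gb2, gW3, gb3]
                t += 1
                for p_i, g_i, m_i, v_i in zip(params, grads, m, v):
                    m_i += (1 - beta1) * (g_i - m_i)
                    v_i += (1 - beta2) * (g_i * g_i - v_i)
                    mhat = m_i / (1 - beta1 ** t)
                    vhat = v_i / (1 - beta2 ** t)
                    p_i -= lr * mhat / (np.sqrt(vhat) + eps)
        return self


def train_model(X: np.ndarray, y: np.ndarray, spec: ModelSpec,
                seed: int | np.random.SeedSequence) -> MLP:
    """Initialise and fit one MLP, fully determined by ``seed``."""
    rng = np.random.default_rng(seed)
    return MLP(spec, rng).fit(X, y, rng)
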
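"""A small feed-forward network for ordinal freshness classification.

Architecture (input 230 standardized features, 4-class softmax output):
four hidden layers of 32, 128, 128 and 64 units, sigmoid activation on the
first hidden layer and ReLU on the rest, dropout 0.1 after each hidden
layer during training, categorical cross-entropy loss, Adam optimizer
(lr 0.001), 80 epochs with mini-batches of 90.  Implemented directly in
numpy as a scikit-learn-compatible estimator so training is fully seeded
and reproducible.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .errors import ConfigError

_ACTIVATIONS = {"sigmoid", "relu"}


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class MLPFreshnessClassifier(ClassifierMixin, BaseEstimator):
    """Seeded numpy MLP with per-layer activations, dropout and Adam.

    Parameters
    ----------
    hidden_layer_sizes
        Units per hidden layer.
    activations
        One of ``"sigmoid"``/``"relu"`` per hidden layer; the output layer
        is always softmax.
    learning_rate, beta1, beta2, epsilon
        Adam hyperparameters.
    dropout
        Drop probability after each hidden activation (inverted dropout;
        applied during training only).
    epochs, batch_size
        Training schedule; the data are reshuffled each epoch.
    random_state
        Seeds weight initialization, shuffling and dropout masks.

    Attributes
    ----------
    classes_ : ndarray
        Sorted class labels seen in ``fit``.
    coefs_, intercepts_ : list of ndarray
        Fitted weights and biases per layer.
    loss_curve_ : list of float
        Mean cross-entropy per epoch.
    """

    def __init__(self, hidden_layer_sizes=(32, 128, 128, 64),
                 activations=("sigmoid", "relu", "relu", "relu"),
                 learning_rate=0.001, dropout=0.1, epochs=80, batch_size=90,
                 beta1=0.9, beta2=0.999, epsilon=1e-8, random_state=None):
        self.hidden_layer_sizes = hidden_layer_sizes
        self.activations = activations
        self.learning_rate = learning_rate
        self.dropout = dropout
        self.epochs = epochs
        self.batch_size = batch_size
        self.beta1 = beta1
        self.beta2 = beta2
        self.epsilon = epsilon
        self.random_state = random_state

    def _validate_params_(self) -> None:
        if len(self.hidden_layer_sizes) != len(self.activations):
            raise ConfigError("one activation per hidden layer is required")
        unknown = set(self.activations) - _ACTIVATIONS
        if unknown:
            raise ConfigError(f"unknown activations: {sorted(unknown)}")
        if not 0.0 <= self.dropout < 1.0:
            raise ConfigError(f"dropout must be in [0, 1), got {self.dropout}")

    def fit(self, X, y):
        self._validate_params_()
        X, y = check_X_y(X, y)
        X = X.astype(float)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        if len(self.classes_) < 2:
            raise ConfigError("training data contains a single class")
        n, d = X.shape
        self.n_features_in_ = d
        n_out = len(self.classes_)
        sizes = [d, *self.hidden_layer_sizes, n_out]

        rng = np.random.default_rng(self.random_state)
        # Glorot-uniform initialization
        self.coefs_ = [rng.uniform(-1, 1, (a, b)) * np.sqrt(6.0 / (a + b))
                       for a, b in zip(sizes[:-1], sizes[1:])]
        self.intercepts_ = [np.zeros(b) for b in sizes[1:]]

        onehot = np.zeros((n, n_out))
        onehot[np.arange(n), y_idx] = 1.0

        m_w = [np.zeros_like(w) for w in self.coefs_]
        v_w = [np.zeros_like(w) for w in self.coefs_]
        m_b = [np.zeros_like(b) for b in self.intercepts_]
        v_b = [np.zeros_like(b) for b in self.intercepts_]
        step = 0
        self.loss_curve_ = []

        for _epoch in range(self.epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, self.batch_size):
                batch = order[start:start + self.batch_size]
                xb, tb = X[batch], onehot[batch]
                acts, drops = self._forward(xb, rng, training=True)
                probs = acts[-1]
                epoch_loss += -float(
                    (tb * np.log(np.clip(probs, 1e-12, None))).sum())

                # backprop: softmax + cross-entropy -> (p - t) / m
                delta = (probs - tb) / len(batch)
                grads_w, grads_b = [], []
                for layer in range(len(self.coefs_) - 1, -1, -1):
                    a_prev = acts[layer]
                    grads_w.append(a_prev.T @ delta)
                    grads_b.append(delta.sum(axis=0))
                    if layer > 0:
                        delta = delta @ self.coefs_[layer].T
                        a = acts[layer]
                        if self.activations[layer - 1] == "relu":
                            delta = delta * (a > 0)
                        else:  # sigmoid
                            delta = delta * a * (1.0 - a)
                        if drops[layer - 1] is not None:
                            delta = delta * drops[layer - 1]
                grads_w.reverse()
                grads_b.reverse()

                step += 1
                lr_t = self.learning_rate * \
                    np.sqrt(1 - self.beta2 ** step) / (1 - self.beta1 ** step)
                for i in range(len(self.coefs_)):
                    m_w[i] = self.beta1 * m_w[i] + (1 - self.beta1) * grads_w[i]
                    v_w[i] = self.beta2 * v_w[i] + (1 - self.beta2) * grads_w[i] ** 2
                    self.coefs_[i] -= lr_t * m_w[i] / (np.sqrt(v_w[i]) + self.epsilon)
                    m_b[i] = self.beta1 * m_b[i] + (1 - self.beta1) * grads_b[i]
                    v_b[i] = self.beta2 * v_b[i] + (1 - self.beta2) * grads_b[i] ** 2
                    self.intercepts_[i] -= lr_t * m_b[i] / (np.sqrt(v_b[i]) + self.epsilon)
            self.loss_curve_.append(epoch_loss / n)
        return self

    def _forward(self, X, rng=None, training=False):
        """Return activations per layer and the dropout masks used."""
        acts = [X]
        drops: list[np.ndarray | None] = []
        a = X
        n_hidden = len(self.hidden_layer_sizes)
        for i in range(n_hidden):
            z = a @ self.coefs_[i] + self.intercepts_[i]
            if self.activations[i] == "relu":
                a = np.maximum(z, 0.0)
            else:
                a = 1.0 / (1.0 + np.exp(-z))
            if training and self.dropout > 0.0:
                keep = rng.random(a.shape) >= self.dropout
                scale = keep / (1.0 - self.dropout)
                a = a * scale
                drops.append(scale)
            else:
                drops.append(None)
            acts.append(a)
        z = a @ self.coefs_[-1] + self.intercepts_[-1]
        acts.append(_softmax(z))
        return acts, drops

    def predict_proba(self, X):
        check_is_fitted(self, "coefs_")
        X = check_array(X).astype(float)
        if X.shape[1] != self.n_features_in_:
            raise ConfigError(
                f"model expects {self.n_features_in_} features, got {X.shape[1]}"
            )
        acts, _ = self._forward(X, training=False)
        return acts[-1]

    def predict(self, X):
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]
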
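"""The two classifier families: Gaussian-kernel SVM and MLP network.

Both are scikit-learn-compatible estimators sharing the same scoring
surface (``predict`` / ``predict_proba``), so evaluation and input
switching are model-agnostic.  The SVM uses a fixed penalty C = 1.15
and a data-driven kernel width gamma = 1 / (n_classes * Xvar), where
Xvar is the scalar variance over all entries of the training matrix.
Class imbalance is countered with inverse-frequency weights
w_i = N / (n_classes * N_i), which satisfy sum_i w_i N_i = N.

The MLP is a small feed-forward network (default five 512-unit hidden
layers, each layer-normalised with 10% dropout, ReLU activations,
softmax output) trained for 15 epochs with batch size 32 under
class-weighted categorical cross-entropy and the Adam optimizer.  It is
implemented directly on numpy so training is fully deterministic under
a single seed.
"""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted, check_X_y, check_array

from .corpus import N_CLASSES

DEFAULT_C = 1.15


def compute_gamma(
    training_matrix: np.ndarray,
    n_classes: int = N_CLASSES,
    rule: str = "n_classes",
) -> float:
    """Kernel width gamma = 1 / (n * Xvar) from the training matrix.

    ``rule='n_classes'`` takes n = number of classes; ``rule='n_features'``
    swaps in the column count (the common library heuristic) as an
    escape hatch.  Xvar is the population variance over all entries.
    """
    X = np.asarray(training_matrix, dtype=float)
    x_var = float(X.var())
    if x_var <= 0.0:
        raise ValueError("training matrix has zero variance; gamma undefined")
    if rule == "n_classes":
        n = n_classes
    elif rule == "n_features":
        n = X.shape[1]
    else:
        raise ValueError(f"unknown gamma rule {rule!r}")
    return 1.0 / (n * x_var)


def compute_class_weights(
    training_labels: np.ndarray, n_classes: int = N_CLASSES
) -> dict[int, float]:
    """Inverse-frequency class weights w_i = N / (n * N_i).

    Classes absent from the training labels get weight 0 with a warning
    (they can never be predicted anyway).  The weights satisfy the
    identity sum_i w_i N_i = N.
    """
    y = np.asarray(training_labels, dtype=int)
    N = len(y)
    counts = np.bincount(y, minlength=n_classes)
    weights: dict[int, float] = {}
    for i in range(n_classes):
        if counts[i] == 0:
            warnings.warn(f"class {i} absent from training labels; weight set to 0")
            weights[i] = 0.0
        else:
            weights[i] = N / (n_classes * counts[i])
    return weights


class GaussianKernelSVC(BaseEstimator, ClassifierMixin):
    """RBF-kernel SVM with the data-driven gamma and inverse-frequency weights.

    Per-class scores for AUC come from pairwise-coupling probability
    estimates (``probability=True``), which are the standard way to get
    continuous multiclass scores out of an SVM.
    """

    def __init__(
        self,
        C: float = DEFAULT_C,
        gamma_rule: str = "n_classes",
        n_classes: int = N_CLASSES,
        use_class_weights: bool = True,
        random_state: int = 0,
    ):
        self.C = C
        self.gamma_rule = gamma_rule
        self.n_classes = n_classes
        self.use_class_weights = use_class_weights
        self.random_state = random_state

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        self.gamma_ = compute_gamma(X, self.n_classes, self.gamma_rule)
        self.class_weights_ = (
            compute_class_weights(y, self.n_classes)
            if self.use_class_weights
            else None
        )
        weight_arg = None
        if self.class_weights_ is not None:
            weight_arg = {c: w for c, w in self.class_weights_.items() if w > 0}
        self.svc_ = SVC(
            C=self.C,
            kernel="rbf",
            gamma=self.gamma_,
            class_weight=weight_arg,
            probability=True,
            random_state=self.random_state,
        )
        self.svc_.fit(X, y)
        self.classes_ = self.svc_.classes_
        return self

    def predict(self, X):
        check_is_fitted(self, "svc_")
        return self.svc_.predict(check_array(X))

    def predict_proba(self, X):
        check_is_fitted(self, "svc_")
        return self.svc_.predict_proba(check_array(X))


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _layer_norm_forward(x: np.ndarray, eps: float = 1e-5):
    mu = x.mean(axis=1, keepdims=True)
    var = x.var(axis=1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    return (x - mu) * inv, inv


def _layer_norm_backward(dy: np.ndarray, y: np.ndarray, inv: np.ndarray):
    # y is the normalised output; standard layer-norm gradient.
    return inv * (dy - dy.mean(axis=1, keepdims=True)
                  - y * (dy * y).mean(axis=1, keepdims=True))


class MlpClassifier(BaseEstimator, ClassifierMixin):
    """Feed-forward softmax classifier trained with Adam on numpy.

    Architecture: ``hidden_layers`` dense layers (default five of width
    512), each followed by layer normalisation, ReLU and inverted
    dropout, then a softmax output over the five classes.  The loss is
    categorical cross-entropy, optionally weighted per sample by the
    inverse-frequency class weights.  All randomness (weight init,
    batch shuffling, dropout masks) derives from ``random_state``.
    """

    def __init__(
        self,
        hidden_layers: tuple[int, ...] = (512, 512, 512, 512, 512),
        dropout: float = 0.10,
        epochs: int = 15,
        batch_size: int = 32,
        learning_rate: float = 1e-3,
        use_class_weights: bool = True,
        n_classes: int = N_CLASSES,
        random_state: int = 0,
    ):
        self.hidden_layers = hidden_layers
        self.dropout = dropout
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.use_class_weights = use_class_weights
        self.n_classes = n_classes
        self.random_state = random_state

    # -- internals ---------------------------------------------------------

    def _init_params(self, n_features: int, rng: np.random.Generator):
        sizes = [n_features, *self.hidden_layers, len(self.classes_)]
        self.weights_ = [
            rng.standard_normal((fan_in, fan_out)) * np.sqrt(2.0 / fan_in)
            for fan_in, fan_out in zip(sizes[:-1], sizes[1:])
        ]
        self.biases_ = [np.zeros(fan_out) for fan_out in sizes[1:]]

    def _forward(self, X: np.ndarray, rng: np.random.Generator | None):
        """Returns (probabilities, cache); rng=None disables dropout."""
        cache = []
        h = X
        n_hidden = len(self.weights_) - 1
        for layer in range(n_hidden):
            z = h @ self.weights_[layer] + self.biases_[layer]
            normed, inv = _layer_norm_forward(z)
            act = np.maximum(normed, 0.0)
            if rng is not None and self.dropout > 0.0:
                mask = (rng.random(act.shape) >= self.dropout) / (1.0 - self.dropout)
                dropped = act * mask
            else:
                mask = None
                dropped = act
            cache.append((h, normed, inv, act, mask))
            h = dropped
        logits = h @ self.weights_[-1] + self.biases_[-1]
        return _softmax(logits), (cache, h)

    def _backward(self, probs, y_onehot, sample_w, cache_all):
        cache, last_h = cache_all
        n = probs.shape[0]
        grads_w = [None] * len(self.weights_)
        grads_b = [None] * len(self.biases_)
        dlogits = (probs - y_onehot) * sample_w[:, None] / n
        grads_w[-1] = last_h.T @ dlogits
        grads_b[-1] = dlogits.sum(axis=0)
        dh = dlogits @ self.weights_[-1].T
        for layer in range(len(cache) - 1, -1, -1):
            h_in, normed, inv, act, mask = cache[layer]
            if mask is not None:
                dh = dh * mask
            dact = dh * (normed > 0.0)
            dz = _layer_norm_backward(dact, normed, inv)
            grads_w[layer] = h_in.T @ dz
            grads_b[layer] = dz.sum(axis=0)
            dh = dz @ self.weights_[layer].T
        return grads_w, grads_b

    # -- sklearn surface ---------------------------------------------------

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        X = X.astype(np.float64)
        self.classes_ = np.unique(y)
        class_index = {c: i for i, c in enumerate(self.classes_)}
        y_idx = np.array([class_index[v] for v in y])
        y_onehot = np.eye(len(self.classes_))[y_idx]

        if self.use_class_weights:
            weights = compute_class_weights(y, self.n_classes)
            sample_w = np.array([weights[int(v)] for v in y])
        else:
            sample_w = np.ones(len(y))

        rng = np.random.default_rng(self.random_state)
        self._init_params(X.shape[1], rng)
        m = [np.zeros_like(w) for w in self.weights_]
        v = [np.zeros_like(w) for w in self.weights_]
        mb = [np.zeros_like(b) for b in self.biases_]
        vb = [np.zeros_like(b) for b in self.biases_]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        step = 0
        self.loss_curve_ = []
        for _ in range(self.epochs):
            order = rng.permutation(len(X))
            epoch_loss, seen = 0.0, 0
            for lo in range(0, len(X), self.batch_size):
                batch = order[lo:lo + self.batch_size]
                probs, cache = self._forward(X[batch], rng)
                w_batch = sample_w[batch]
                nll = -np.log(np.maximum(probs[np.arange(len(batch)), y_idx[batch]],
                                         1e-12))
                epoch_loss += float((w_batch * nll).sum())
                seen += len(batch)
                grads_w, grads_b = self._backward(
                    probs, y_onehot[batch], w_batch, cache
                )
                step += 1
                lr_t = self.learning_rate * (
                    np.sqrt(1 - beta2 ** step) / (1 - beta1 ** step)
                )
                for k in range(len(self.weights_)):
                    m[k] = beta1 * m[k] + (1 - beta1) * grads_w[k]
                    v[k] = beta2 * v[k] + (1 - beta2) * grads_w[k] ** 2
                    self.weights_[k] -= lr_t * m[k] / (np.sqrt(v[k]) + eps)
                    mb[k] = beta1 * mb[k] + (1 - beta1) * grads_b[k]
                    vb[k] = beta2 * vb[k] + (1 - beta2) * grads_b[k] ** 2
                    self.biases_[k] -= lr_t * mb[k] / (np.sqrt(vb[k]) + eps)
            self.loss_curve_.append(epoch_loss / max(seen, 1))
        self.final_loss_ = self.loss_curve_[-1]
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "weights_")
        X = check_array(X).astype(np.float64)
        probs, _ = self._forward(X, rng=None)
        return probs

    def predict(self, X):
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]
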
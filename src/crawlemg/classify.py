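"""Coordination-mode classifiers over normalized envelope cycles.

Three classifiers are provided:

* a bidirectional LSTM implemented from scratch in numpy (forward pass,
  backpropagation through time, Adam), whose single-unit update follows the
  standard LSTM gate equations

      f_t = σ(W_fh h_{t-1} + W_fx x_t + b_f)      (forget gate)
      u_t = σ(W_uh h_{t-1} + W_ux x_t + b_u)      (update gate)
      o_t = σ(W_oh h_{t-1} + W_ox x_t + b_o)      (output gate)
      c̄_t = tanh(W_ch h_{t-1} + W_cx x_t + b_c)   (candidate state)
      c_t = f_t ∘ c_{t-1} + u_t ∘ c̄_t
      h_t = o_t ∘ tanh(c_t)

  The forward and (input-reversed) backward passes are concatenated and fed to
  four dense layers;

* an RBF-kernel SVM and a k-nearest-neighbour classifier (scikit-learn) over a
  decimated, flattened copy of the envelope matrix.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .features import EnvelopeCycle

__all__ = ["LSTMUnitParams", "lstm_unit_step", "ClassifierSpec",
           "BiLSTMClassifier", "SklearnEnvelopeClassifier", "train", "predict",
           "flatten_features"]


# ---------------------------------------------------------------------------
# LSTM unit reference
# ---------------------------------------------------------------------------

def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


@dataclass
class LSTMUnitParams:
    """Weights of a single LSTM unit, one matrix pair + bias per gate.

    ``W_*h`` are (H, H), ``W_*x`` are (H, D), biases are (H,).
    """

    W_fh: np.ndarray
    W_fx: np.ndarray
    W_uh: np.ndarray
    W_ux: np.ndarray
    W_oh: np.ndarray
    W_ox: np.ndarray
    W_ch: np.ndarray
    W_cx: np.ndarray
    b_f: np.ndarray
    b_u: np.ndarray
    b_o: np.ndarray
    b_c: np.ndarray

    def __post_init__(self):
        for name in ("W_fh", "W_fx", "W_uh", "W_ux", "W_oh", "W_ox",
                     "W_ch", "W_cx", "b_f", "b_u", "b_o", "b_c"):
            setattr(self, name, np.atleast_1d(np.asarray(getattr(self, name), float)))
        H, D = self.W_fx.reshape(self.W_fx.shape[0], -1).shape
        for name in ("W_fh", "W_uh", "W_oh", "W_ch"):
            if np.atleast_2d(getattr(self, name)).shape != (H, H):
                raise ValueError(f"{name} must be ({H}, {H})")
        for name in ("W_ux", "W_ox", "W_cx"):
            if np.atleast_2d(getattr(self, name)).shape != (H, D):
                raise ValueError(f"{name} must be ({H}, {D})")
        for name in ("b_f", "b_u", "b_o", "b_c"):
            if getattr(self, name).shape != (H,):
                raise ValueError(f"{name} must be ({H},)")

    @property
    def hidden_size(self) -> int:
        return self.b_f.shape[0]

    @classmethod
    def zeros(cls, hidden: int, inputs: int) -> "LSTMUnitParams":
        zh = np.zeros((hidden, hidden))
        zx = np.zeros((hidden, inputs))
        zb = np.zeros(hidden)
        return cls(zh, zx, zh.copy(), zx.copy(), zh.copy(), zx.copy(),
                   zh.copy(), zx.copy(), zb, zb.copy(), zb.copy(), zb.copy())

    @classmethod
    def from_stacked(cls, Wx: np.ndarray, Wh: np.ndarray, b: np.ndarray
                     ) -> "LSTMUnitParams":
        """Unpack the network's stacked (D,4H)/(H,4H)/(4H,) gate weights
        (gate order f, u, o, candidate)."""
        H = Wh.shape[0]
        Wf, Wu, Wo, Wc = (Wx[:, i * H:(i + 1) * H].T for i in range(4))
        Uf, Uu, Uo, Uc = (Wh[:, i * H:(i + 1) * H].T for i in range(4))
        bf, bu, bo, bc = (b[i * H:(i + 1) * H] for i in range(4))
        return cls(Uf, Wf, Uu, Wu, Uo, Wo, Uc, Wc, bf, bu, bo, bc)


def lstm_unit_step(
    params: LSTMUnitParams,
    x: np.ndarray,
    h_prev: np.ndarray,
    c_prev: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """One LSTM time step; returns the new hidden and cell states.

    Reference implementation of the gate equations above; gate activations lie
    in (0, 1) and |h| < 1 elementwise.
    """
    x = np.atleast_1d(np.asarray(x, float))
    h_prev = np.atleast_1d(np.asarray(h_prev, float))
    c_prev = np.atleast_1d(np.asarray(c_prev, float))
    H = params.hidden_size
    if h_prev.shape != (H,) or c_prev.shape != (H,):
        raise ValueError(f"state vectors must have shape ({H},)")
    if x.shape[0] != np.atleast_2d(params.W_fx).shape[1]:
        raise ValueError("input dimension mismatch")
    Wh2 = lambda W: np.atleast_2d(W)
    f = _sigmoid(Wh2(params.W_fh) @ h_prev + Wh2(params.W_fx) @ x + params.b_f)
    u = _sigmoid(Wh2(params.W_uh) @ h_prev + Wh2(params.W_ux) @ x + params.b_u)
    o = _sigmoid(Wh2(params.W_oh) @ h_prev + Wh2(params.W_ox) @ x + params.b_o)
    cbar = np.tanh(Wh2(params.W_ch) @ h_prev + Wh2(params.W_cx) @ x + params.b_c)
    c = f * c_prev + u * cbar
    h = o * np.tanh(c)
    return h, c


# ---------------------------------------------------------------------------
# Classifier specification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClassifierSpec:
    """Hyperparameters for one classifier.

    BiLSTM defaults are the study settings: 128 hidden units, Adam with
    learning rate 0.001, beta1 0.9, beta2 0.999, epsilon 1e-8, 60 epochs,
    batch size one-tenth of the training samples, dense head 256-128-64-K.
    SVM/KNN operate on each channel's envelope decimated to ``flat_points``
    time points and flattened.
    """

    kind: str = "svm"
    # bilstm
    hidden_units: int = 128
    dense_sizes: tuple[int, ...] = (256, 128, 64)
    learning_rate: float = 0.001
    beta_1: float = 0.9
    beta_2: float = 0.999
    epsilon: float = 1e-8
    epochs: int = 60
    batch_fraction: float = 0.1   # batch size = ceil(n_train * fraction)
    time_steps: int | None = None  # None: consume the full sequence
    # knn
    n_neighbors: int = 5
    metric: str = "euclidean"
    # svm
    kernel: str = "rbf"
    C: float = 1.0
    # svm/knn input representation
    flat_points: int = 100

    def __post_init__(self):
        if self.kind not in {"bilstm", "svm", "knn"}:
            raise ValueError(f"unknown classifier kind {self.kind!r}")

    def batch_size(self, n_train: int) -> int:
        return max(1, math.ceil(n_train * self.batch_fraction))

    def to_dict(self) -> dict:
        from dataclasses import asdict
        d = asdict(self)
        d["dense_sizes"] = list(self.dense_sizes)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ClassifierSpec":
        d = dict(d)
        if "dense_sizes" in d:
            d["dense_sizes"] = tuple(d["dense_sizes"])
        return cls(**d)


def flatten_features(samples: list[EnvelopeCycle], n_points: int = 100) -> np.ndarray:
    """Decimate each channel's envelope to ``n_points`` and flatten per sample."""
    out = []
    for s in samples:
        T = s.values.shape[0]
        idx = np.linspace(0, T - 1, n_points).round().astype(int)
        out.append(s.values[idx].ravel())
    return np.asarray(out)


# ---------------------------------------------------------------------------
# BiLSTM network (numpy)
# ---------------------------------------------------------------------------

def _glorot(rng, shape):
    limit = math.sqrt(6.0 / (shape[0] + shape[1]))
    return rng.uniform(-limit, limit, shape)


class _LSTMLayer:
    """Single-direction LSTM consuming (B, T, D), exposing the final hidden state."""

    def __init__(self, rng, d_in, hidden):
        self.H = hidden
        self.Wx = _glorot(rng, (d_in, 4 * hidden))
        self.Wh = _glorot(rng, (hidden, 4 * hidden))
        self.b = np.zeros(4 * hidden)
        self.b[:hidden] = 1.0  # forget-gate bias: retain memory early in training

    def params(self):
        return [self.Wx, self.Wh, self.b]

    def forward(self, X):
        B, T, _ = X.shape
        H = self.H
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        cache = []
        for t in range(T):
            z = X[:, t] @ self.Wx + h @ self.Wh + self.b
            f = _sigmoid(z[:, :H])
            u = _sigmoid(z[:, H:2 * H])
            o = _sigmoid(z[:, 2 * H:3 * H])
            g = np.tanh(z[:, 3 * H:])
            c_new = f * c + u * g
            tc = np.tanh(c_new)
            cache.append((X[:, t], h, c, f, u, o, g, tc))
            h = o * tc
            c = c_new
        return h, cache

    def backward(self, dh_last, cache):
        H = self.H
        dWx = np.zeros_like(self.Wx)
        dWh = np.zeros_like(self.Wh)
        db = np.zeros_like(self.b)
        dh = dh_last
        dc = np.zeros_like(dh_last)
        for x_t, h_prev, c_prev, f, u, o, g, tc in reversed(cache):
            do = dh * tc
            dc = dc + dh * o * (1.0 - tc ** 2)
            df = dc * c_prev
            du = dc * g
            dg = dc * u
            dz = np.concatenate(
                [df * f * (1 - f), du * u * (1 - u), do * o * (1 - o),
                 dg * (1 - g ** 2)], axis=1)
            dWx += x_t.T @ dz
            dWh += h_prev.T @ dz
            db += dz.sum(axis=0)
            dh = dz @ self.Wh.T
            dc = dc * f
        return [dWx, dWh, db]


class BiLSTMClassifier:
    """Bidirectional LSTM + four dense layers, trained with Adam.

    The input sequence feeds a forward LSTM and, order-reversed, a backward
    LSTM; their final hidden states are concatenated and passed through the
    dense head, ending in a softmax over the classes.
    """

    def __init__(self, spec: ClassifierSpec, seed: int = 0):
        if spec.kind != "bilstm":
            raise ValueError("spec.kind must be 'bilstm'")
        self.spec = spec
        self.seed = seed
        self.classes_: np.ndarray | None = None
        self.history: dict = {}

    # -- construction -------------------------------------------------------

    def _build(self, d_in: int, n_classes: int) -> None:
        rng = np.random.default_rng(self.seed)
        H = self.spec.hidden_units
        self.fwd = _LSTMLayer(rng, d_in, H)
        self.bwd = _LSTMLayer(rng, d_in, H)
        sizes = [2 * H, *self.spec.dense_sizes, n_classes]
        self.dense_W = [_glorot(rng, (a, b)) for a, b in zip(sizes[:-1], sizes[1:])]
        self.dense_b = [np.zeros(b) for b in sizes[1:]]
        self._shuffle_rng = rng

    def _all_params(self):
        return self.fwd.params() + self.bwd.params() + self.dense_W + self.dense_b

    def _sequence(self, samples: list[EnvelopeCycle]) -> np.ndarray:
        X = np.stack([s.values for s in samples])
        ts = self.spec.time_steps
        if ts is not None and ts != X.shape[1]:
            idx = np.linspace(0, X.shape[1] - 1, ts).round().astype(int)
            X = X[:, idx]
        return X

    # -- forward / backward -------------------------------------------------

    def _forward(self, X):
        h_f, cache_f = self.fwd.forward(X)
        h_b, cache_b = self.bwd.forward(X[:, ::-1])
        a = np.concatenate([h_f, h_b], axis=1)
        acts = [a]
        for i, (W, b) in enumerate(zip(self.dense_W, self.dense_b)):
            a = a @ W + b
            if i < len(self.dense_W) - 1:
                a = np.maximum(a, 0.0)
            acts.append(a)
        logits = acts[-1]
        logits = logits - logits.max(axis=1, keepdims=True)
        p = np.exp(logits)
        p /= p.sum(axis=1, keepdims=True)
        return p, acts, cache_f, cache_b

    def _backward(self, p, y_onehot, acts, cache_f, cache_b):
        B = p.shape[0]
        delta = (p - y_onehot) / B
        dW, db = [], []
        for i in reversed(range(len(self.dense_W))):
            a_prev = acts[i]
            dW.insert(0, a_prev.T @ delta)
            db.insert(0, delta.sum(axis=0))
            delta = delta @ self.dense_W[i].T
            if i > 0:
                delta = delta * (acts[i] > 0)
        H = self.spec.hidden_units
        g_f = self.fwd.backward(delta[:, :H], cache_f)
        g_b = self.bwd.backward(delta[:, H:], cache_b)
        return g_f + g_b + dW + db

    # -- training -----------------------------------------------------------

    def fit(self, samples: list[EnvelopeCycle]) -> "BiLSTMClassifier":
        labels = np.array([s.mode for s in samples])
        self.classes_ = np.unique(labels)
        if self.classes_.size < 2:
            raise ValueError("training set must contain at least 2 classes")
        y = np.searchsorted(self.classes_, labels)
        X = self._sequence(samples)
        n, _, d_in = X.shape
        self._build(d_in, self.classes_.size)
        Y = np.eye(self.classes_.size)[y]
        params = self._all_params()
        m = [np.zeros_like(p) for p in params]
        v = [np.zeros_like(p) for p in params]
        spec = self.spec
        bs = spec.batch_size(n)
        step = 0
        for _epoch in range(spec.epochs):
            order = self._shuffle_rng.permutation(n)
            for start in range(0, n, bs):
                sel = order[start:start + bs]
                p, acts, cf, cb = self._forward(X[sel])
                grads = self._backward(p, Y[sel], acts, cf, cb)
                step += 1
                for j, (param, g) in enumerate(zip(params, grads)):
                    m[j] = spec.beta_1 * m[j] + (1 - spec.beta_1) * g
                    v[j] = spec.beta_2 * v[j] + (1 - spec.beta_2) * g * g
                    mhat = m[j] / (1 - spec.beta_1 ** step)
                    vhat = v[j] / (1 - spec.beta_2 ** step)
                    param -= spec.learning_rate * mhat / (np.sqrt(vhat) + spec.epsilon)
        train_pred = self.predict(samples)
        self.history = {
            "epochs_run": spec.epochs,
            "final_train_accuracy": float(np.mean(train_pred == labels) * 100.0),
        }
        return self

    # -- inference ----------------------------------------------------------

    def predict_scores(self, samples: list[EnvelopeCycle]) -> np.ndarray:
        """Class-probability scores, rows summing to one."""
        if self.classes_ is None:
            raise RuntimeError("model is not trained")
        if not samples:
            return np.empty((0, 0))
        X = self._sequence(samples)
        scores = []
        for start in range(0, X.shape[0], 256):
            p, *_ = self._forward(X[start:start + 256])
            scores.append(p)
        return np.concatenate(scores)

    def predict(self, samples: list[EnvelopeCycle]) -> np.ndarray:
        if not samples:
            return np.array([], dtype=object)
        p = self.predict_scores(samples)
        return self.classes_[p.argmax(axis=1)]


def bilstm_forward(model: BiLSTMClassifier, sample: EnvelopeCycle) -> np.ndarray:
    """Class scores for one envelope cycle (nonnegative, summing to 1)."""
    return model.predict_scores([sample])[0]


# ---------------------------------------------------------------------------
# sklearn-backed classifiers and the common train/predict surface
# ---------------------------------------------------------------------------

class SklearnEnvelopeClassifier:
    """SVM or KNN over decimated flattened envelopes."""

    def __init__(self, spec: ClassifierSpec, seed: int = 0):
        self.spec = spec
        self.seed = seed
        if spec.kind == "svm":
            self.est = SVC(kernel=spec.kernel, C=spec.C,
                           decision_function_shape="ovr", random_state=seed)
        elif spec.kind == "knn":
            self.est = KNeighborsClassifier(n_neighbors=spec.n_neighbors,
                                            metric=spec.metric)
        else:
            raise ValueError(f"not an sklearn classifier kind: {spec.kind!r}")
        self.classes_: np.ndarray | None = None
        self.history: dict = {}

    def fit(self, samples: list[EnvelopeCycle]) -> "SklearnEnvelopeClassifier":
        labels = np.array([s.mode for s in samples])
        if np.unique(labels).size < 2:
            raise ValueError("training set must contain at least 2 classes")
        X = flatten_features(samples, self.spec.flat_points)
        self.est.fit(X, labels)
        self.classes_ = np.array(self.est.classes_)
        train_pred = self.predict(samples)
        self.history = {"final_train_accuracy":
                        float(np.mean(train_pred == labels) * 100.0)}
        return self

    def predict(self, samples: list[EnvelopeCycle]) -> np.ndarray:
        if self.classes_ is None:
            raise RuntimeError("model is not trained")
        if not samples:
            return np.array([], dtype=object)
        return self.est.predict(flatten_features(samples, self.spec.flat_points))


def train(spec: ClassifierSpec, train_set: list[EnvelopeCycle], seed: int = 0):
    """Train a classifier of the requested kind; deterministic given ``seed``."""
    if not train_set:
        raise ValueError("training set is empty")
    if spec.kind == "bilstm":
        model = BiLSTMClassifier(spec, seed)
    else:
        model = SklearnEnvelopeClassifier(spec, seed)
    return model.fit(train_set)


def predict(model, samples: list[EnvelopeCycle]) -> np.ndarray:
    """Predict one mode label per sample."""
    return model.predict(samples)
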
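"""Compact convolutional network scoring WTLCC matrices, plus hyper-search.

The network maps a K x J lagged-correlation matrix (treated as a one-channel
image; missing entries imputed as 0, i.e. "no correlation") to a score in
[0, 1] interpreted as P(unfavourable outcome). Patient-level decisions use
multiple-instance aggregation: the mean of all matrix scores for a patient,
called unfavourable iff the mean strictly exceeds 0.5. The penultimate dense
layer provides a fixed-length embedding; a patient embedding is the mean of
its matrix embeddings.

The implementation is pure numpy (channels-last, im2col convolutions, Adam,
class-weighted binary cross-entropy) and fully deterministic given a seed.
The hyperparameter search is a sequential model-based (TPE-style) optimizer
over the discrete space of signal pairs and WTLCC geometries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Mapping, Sequence, Tuple

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .types import OUTCOME_FAV, OUTCOME_UNFAV
from .wtlcc import WTLCCMatrix

__all__ = [
    "CNNConfig",
    "TrainedScorer",
    "train",
    "split_patients",
    "SearchSpace",
    "search",
]


@dataclass
class CNNConfig:
    """Architecture and training hyperparameters.

    ``conv_blocks`` is a sequence of (filters, kernel, pool) triples; each
    block is conv (same padding) -> ReLU -> max-pool. The final dense layer
    of width ``dense_width`` is the embedding. The smallest family that
    resolves lag structure in K x 240 matrices on a CPU.
    """

    conv_blocks: Tuple[Tuple[int, int, int], ...] = ((16, 3, 2), (32, 3, 2), (64, 3, 2))
    dense_width: int = 64
    pooling: str = "flatten"  # "flatten" keeps lag position; "gap" discards it
    dropout: float = 0.25
    learning_rate: float = 1e-3
    batch_size: int = 64
    epochs: int = 10
    class_weighting: str = "balanced"  # or "none"
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.conv_blocks) < 1:
            raise ValueError("need at least one conv block")
        if self.class_weighting not in ("none", "balanced"):
            raise ValueError("class_weighting must be 'none' or 'balanced'")
        if self.pooling not in ("flatten", "gap"):
            raise ValueError("pooling must be 'flatten' or 'gap'")


# ----------------------------------------------------------------------------
# layers (channels-last: x has shape (B, H, W, C))
# ----------------------------------------------------------------------------

def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(B,H,W,C) -> (B,H,W,k*k*C) patches with 'same' zero padding."""
    p = k // 2
    xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
    win = sliding_window_view(xp, (k, k), axis=(1, 2))  # (B,H,W,C,k,k)
    B, H, W = x.shape[0], x.shape[1], x.shape[2]
    return np.ascontiguousarray(win.transpose(0, 1, 2, 4, 5, 3)).reshape(B, H, W, -1)


class _Conv:
    """3x3 (or k x k) same-padding convolution, stride 1."""

    def __init__(self, c_in: int, filters: int, k: int, rng: np.random.Generator):
        scale = math.sqrt(2.0 / (k * k * c_in))  # He initialisation
        self.W = rng.normal(0.0, scale, (k * k * c_in, filters))
        self.b = np.zeros(filters)
        self.k, self.c_in, self.filters = k, c_in, filters

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        cols = _im2col(x, self.k)
        if train:
            self._cols, self._in_shape = cols, x.shape
        return cols @ self.W + self.b

    def backward(self, dz: np.ndarray):
        B, H, W, F = dz.shape
        self.dW = self._cols.reshape(-1, self.W.shape[0]).T @ dz.reshape(-1, F)
        self.db = dz.sum(axis=(0, 1, 2))
        # dx = "full" correlation of dz with the flipped kernel
        Wk = self.W.reshape(self.k, self.k, self.c_in, F)
        Wflip = Wk[::-1, ::-1]                       # rotate 180 deg
        Wback = Wflip.transpose(0, 1, 3, 2).reshape(self.k * self.k * F, self.c_in)
        dx = _im2col(dz, self.k) @ Wback
        return dx

    def params_grads(self):
        return [(self.W, self.dW), (self.b, self.db)]


class _ReLU:
    def forward(self, x, train):
        if train:
            self._mask = x > 0
        return np.maximum(x, 0.0)

    def backward(self, dz):
        return dz * self._mask

    def params_grads(self):
        return []


class _MaxPool:
    """(ph x pw) max pooling, stride = pool size; trailing rows/cols beyond a
    multiple of the pool are cropped (lag columns are abundant, nothing
    essential is lost). Rectangular pools allow wide pooling along the lag
    axis, which extracts the envelope of oscillatory lag profiles."""

    def __init__(self, p):
        self.ph, self.pw = (p, p) if np.isscalar(p) else tuple(p)

    def forward(self, x, train):
        ph, pw = self.ph, self.pw
        B, H, W, C = x.shape
        H2, W2 = H // ph, W // pw
        xc = x[:, :H2 * ph, :W2 * pw]
        xr = xc.reshape(B, H2, ph, W2, pw, C)
        out = xr.max(axis=(2, 4))
        if train:
            self._xr_shape = xr.shape
            self._in_shape = x.shape
            mask = xr == out[:, :, None, :, None, :]
            # split gradient among ties to conserve its sum
            self._mask = mask / mask.sum(axis=(2, 4), keepdims=True)
        return out

    def backward(self, dz):
        B, H2, ph, W2, pw, C = self._xr_shape
        dxr = self._mask * dz[:, :, None, :, None, :]
        dxc = dxr.reshape(B, H2 * ph, W2 * pw, C)
        dx = np.zeros(self._in_shape)
        dx[:, :H2 * ph, :W2 * pw] = dxc
        return dx

    def params_grads(self):
        return []


class _GlobalAvgPool:
    def forward(self, x, train):
        if train:
            self._in_shape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, dz):
        B, H, W, C = self._in_shape
        return np.broadcast_to(dz[:, None, None, :], self._in_shape) / (H * W)

    def params_grads(self):
        return []


class _Flatten:
    def forward(self, x, train):
        if train:
            self._in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dz):
        return dz.reshape(self._in_shape)

    def params_grads(self):
        return []


class _Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = rng.normal(0.0, math.sqrt(2.0 / n_in), (n_in, n_out))
        self.b = np.zeros(n_out)

    def forward(self, x, train):
        if train:
            self._x = x
        return x @ self.W + self.b

    def backward(self, dz):
        self.dW = self._x.T @ dz
        self.db = dz.sum(axis=0)
        return dz @ self.W.T

    def params_grads(self):
        return [(self.W, self.dW), (self.b, self.db)]


class _Dropout:
    def __init__(self, rate: float, rng: np.random.Generator):
        self.rate, self.rng = rate, rng

    def forward(self, x, train):
        if not train or self.rate <= 0:
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, dz):
        if self.rate <= 0:
            return dz
        return dz * self._mask

    def params_grads(self):
        return []


class _Net:
    """conv blocks -> GAP -> dense(embedding) -> ReLU -> dropout -> dense(1)."""

    def __init__(self, input_shape: Tuple[int, int], config: CNNConfig,
                 rng: np.random.Generator):
        self.layers: list = []
        c_in = 1
        h, w = input_shape
        for filters, kernel, pool in config.conv_blocks:
            self.layers.append(_Conv(c_in, filters, kernel, rng))
            self.layers.append(_ReLU())
            ph, pw = (pool, pool) if np.isscalar(pool) else tuple(pool)
            if ph > 1 or pw > 1:
                self.layers.append(_MaxPool((ph, pw)))
                h, w = h // ph, w // pw
            c_in = filters
        if min(h, w) < 1:
            raise ValueError("conv blocks pool the input away; reduce pooling")
        if config.pooling == "gap":
            self.layers.append(_GlobalAvgPool())
            n_feat = c_in
        else:
            self.layers.append(_Flatten())
            n_feat = h * w * c_in
        self.embed_dense = _Dense(n_feat, config.dense_width, rng)
        self.embed_relu = _ReLU()
        self.dropout = _Dropout(config.dropout, rng)
        self.head = _Dense(config.dense_width, 1, rng)
        self.input_shape = input_shape

    def forward(self, x: np.ndarray, train: bool = False,
                return_embedding: bool = False):
        h = x[..., None]  # (B, K, J, 1)
        for layer in self.layers:
            h = layer.forward(h, train)
        emb = self.embed_relu.forward(self.embed_dense.forward(h, train), train)
        if return_embedding:
            return emb
        h = self.dropout.forward(emb, train)
        logits = self.head.forward(h, train)[:, 0]
        return 1.0 / (1.0 + np.exp(-logits))

    def backward(self, dlogits: np.ndarray) -> None:
        dz = self.head.backward(dlogits[:, None])
        dz = self.dropout.backward(dz)
        dz = self.embed_relu.backward(dz)
        dz = self.embed_dense.backward(dz)
        for layer in reversed(self.layers):
            dz = layer.backward(dz)

    def all_layers(self):
        return self.layers + [self.embed_dense, self.embed_relu, self.dropout, self.head]


class _Adam:
    def __init__(self, net: _Net, lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.net, self.lr, self.b1, self.b2, self.eps = net, lr, beta1, beta2, eps
        self.t = 0
        self.state: Dict[int, Tuple[np.ndarray, np.ndarray]] = {}

    def step(self) -> None:
        self.t += 1
        for layer in self.net.all_layers():
            for param, grad in layer.params_grads():
                key = id(param)
                if key not in self.state:
                    self.state[key] = (np.zeros_like(param), np.zeros_like(param))
                m, v = self.state[key]
                m *= self.b1
                m += (1 - self.b1) * grad
                v *= self.b2
                v += (1 - self.b2) * grad**2
                mh = m / (1 - self.b1**self.t)
                vh = v / (1 - self.b2**self.t)
                param -= self.lr * mh / (np.sqrt(vh) + self.eps)


# ----------------------------------------------------------------------------
# training API
# ----------------------------------------------------------------------------

_LABEL_TO_INT = {OUTCOME_FAV: 0, OUTCOME_UNFAV: 1}


def _matrix_input(m: WTLCCMatrix) -> np.ndarray:
    x = m.values.copy()
    x[~np.isfinite(x)] = 0.0  # missing correlation -> 0 at the model boundary
    return x


@dataclass
class TrainedScorer:
    """A fitted matrix scorer: per-matrix scores, patient aggregation,
    penultimate-layer embeddings."""

    net: _Net
    config: CNNConfig
    input_shape: Tuple[int, int]
    history: List[float] = field(default_factory=list)

    @property
    def embedding_dim(self) -> int:
        return self.config.dense_width

    def _stack(self, matrices: Sequence[WTLCCMatrix]) -> np.ndarray:
        X = np.stack([_matrix_input(m) for m in matrices])
        if X.shape[1:] != self.input_shape:
            raise ValueError(
                f"matrix shape {X.shape[1:]} does not match model input "
                f"{self.input_shape}"
            )
        return X

    def score_matrices(self, matrices: Sequence[WTLCCMatrix],
                       batch: int = 256) -> np.ndarray:
        X = self._stack(matrices)
        return np.concatenate([
            self.net.forward(X[i:i + batch]) for i in range(0, len(X), batch)
        ])

    def score_patient(self, matrices: Sequence[WTLCCMatrix]) -> Tuple[float, str]:
        """Mean matrix score; unfavourable iff it strictly exceeds 0.5."""
        if len(matrices) == 0:
            raise ValueError("patient has no matrices")
        score = float(self.score_matrices(matrices).mean())
        return score, (OUTCOME_UNFAV if score > 0.5 else OUTCOME_FAV)

    def embed_matrices(self, matrices: Sequence[WTLCCMatrix],
                       batch: int = 256) -> np.ndarray:
        X = self._stack(matrices)
        return np.concatenate([
            self.net.forward(X[i:i + batch], return_embedding=True)
            for i in range(0, len(X), batch)
        ])

    def embed(self, matrices: Sequence[WTLCCMatrix]) -> np.ndarray:
        """Patient embedding: mean of per-matrix embeddings."""
        if len(matrices) == 0:
            raise ValueError("patient has no matrices")
        return self.embed_matrices(matrices).mean(axis=0)


def train(
    matrices: Sequence[WTLCCMatrix],
    labels: Mapping[str, str],
    config: CNNConfig,
) -> TrainedScorer:
    """Fit the scorer on labelled matrices (labels are per patient).

    Minimises class-weighted binary cross-entropy with Adam. The caller is
    responsible for patient-grouped splitting (see :func:`split_patients`);
    every matrix here is used for fitting. Deterministic given
    ``config.seed``.
    """
    if len(matrices) == 0:
        raise ValueError("no matrices to train on")
    missing = {m.patient_id for m in matrices} - set(labels)
    if missing:
        raise ValueError(f"matrices without labels for patients: {sorted(missing)}")
    y = np.array([_LABEL_TO_INT[labels[m.patient_id]] for m in matrices], float)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    shape = matrices[0].values.shape
    if any(m.values.shape != shape for m in matrices):
        raise ValueError("all matrices must share the same (K, J) shape")

    X = np.stack([_matrix_input(m) for m in matrices])
    rng = np.random.default_rng(config.seed)
    net = _Net(shape, config, rng)
    opt = _Adam(net, config.learning_rate)

    if config.class_weighting == "balanced":
        n_pos, n_neg = y.sum(), (1 - y).sum()
        w_pos, w_neg = len(y) / (2 * n_pos), len(y) / (2 * n_neg)
    else:
        w_pos = w_neg = 1.0
    weights = np.where(y == 1, w_pos, w_neg)

    history = []
    n = len(X)
    for _ in range(config.epochs):
        order = rng.permutation(n)
        losses = []
        for lo in range(0, n, config.batch_size):
            idx = order[lo:lo + config.batch_size]
            xb, yb, wb = X[idx], y[idx], weights[idx]
            p = net.forward(xb, train=True)
            eps = 1e-7
            pc = np.clip(p, eps, 1 - eps)
            loss = -np.mean(wb * (yb * np.log(pc) + (1 - yb) * np.log(1 - pc)))
            # d(loss)/d(logit) for sigmoid + weighted BCE
            dlogit = wb * (p - yb) / len(idx)
            net.backward(dlogit)
            opt.step()
            losses.append(loss)
        history.append(float(np.mean(losses)))

    return TrainedScorer(net=net, config=config, input_shape=shape, history=history)


def split_patients(
    patient_labels: Mapping[str, str],
    val_frac: float = 0.33,
    seed: int = 0,
) -> Tuple[List[str], List[str]]:
    """Stratified patient-level split; matrices never cross the split.

    Operates on patient ids only, which enforces the grouping structurally.
    """
    rng = np.random.default_rng(seed)
    train_ids: List[str] = []
    val_ids: List[str] = []
    for cls in (OUTCOME_FAV, OUTCOME_UNFAV):
        ids = sorted(p for p, lab in patient_labels.items() if lab == cls)
        if not ids:
            continue
        perm = rng.permutation(len(ids))
        n_val = max(1, int(round(val_frac * len(ids))))
        val_ids += [ids[i] for i in perm[:n_val]]
        train_ids += [ids[i] for i in perm[n_val:]]
    return sorted(train_ids), sorted(val_ids)


# ----------------------------------------------------------------------------
# sequential model-based hyperparameter search (TPE over a discrete space)
# ----------------------------------------------------------------------------

@dataclass
class SearchSpace:
    """Discrete space: signal pairs x WTLCC geometry x learning rate."""

    pairs: Tuple[Tuple[str, str], ...] = (
        ("icp", "lfhf"), ("icp", "brs"),
        ("cpp", "lfhf"), ("cpp", "brs"),
        ("prx", "lfhf"), ("prx", "brs"),
    )
    N_set: Tuple[int, ...] = (360, 720, 1080)
    S_set: Tuple[int, ...] = (15, 30, 60, 90)
    K_set: Tuple[int, ...] = (15, 30, 60)
    lr_set: Tuple[float, ...] = (1e-3,)
    budget: int = 20

    def dims(self) -> Dict[str, list]:
        return {
            "pair": list(self.pairs),
            "N": list(self.N_set),
            "S": list(self.S_set),
            "K": list(self.K_set),
            "lr": list(self.lr_set),
        }


def _tpe_propose(dims: Dict[str, list], trials: List[Tuple[dict, float]],
                 rng: np.random.Generator, gamma: float = 0.3,
                 n_candidates: int = 24) -> dict:
    """Tree-structured Parzen proposal for independent categorical dims.

    Trials are split into the top ``gamma`` fraction ("good") and the rest;
    each dimension gets add-one-smoothed categorical densities g and b, and
    the candidate maximising prod g/b among samples drawn from g wins.
    """
    scores = np.array([s for _, s in trials])
    order = np.argsort(-scores)
    n_good = max(1, int(np.ceil(gamma * len(trials))))
    good = {i for i in order[:n_good]}

    densities = {}
    for name, choices in dims.items():
        cg = np.ones(len(choices))
        cb = np.ones(len(choices))
        for i, (cand, _) in enumerate(trials):
            j = choices.index(cand[name])
            if i in good:
                cg[j] += 1
            else:
                cb[j] += 1
        densities[name] = (cg / cg.sum(), cb / cb.sum())

    best_cand, best_ratio = None, -np.inf
    for _ in range(n_candidates):
        cand = {}
        log_ratio = 0.0
        for name, choices in dims.items():
            g, b = densities[name]
            j = rng.choice(len(choices), p=g)
            cand[name] = choices[j]
            log_ratio += np.log(g[j]) - np.log(b[j])
        if log_ratio > best_ratio:
            best_cand, best_ratio = cand, log_ratio
    return best_cand


def search(
    space: SearchSpace,
    objective: Callable[[dict, int], float],
    seed: int = 0,
    n_startup: int = 5,
) -> Tuple[dict, float, List[Tuple[dict, float]]]:
    """Sequential model-based optimisation over the discrete space.

    ``objective(candidate, trial_seed)`` must return the validation
    patient-level AUC (higher is better). Returns the best candidate, its
    score, and the full trial log. Reproducible given ``seed``.
    """
    if space.budget < 1:
        raise ValueError("budget must be >= 1")
    dims = space.dims()
    rng = np.random.default_rng(seed)
    # balanced startup: each dimension cycles through a shuffled order of its
    # choices, so every option of the largest dimension is visited before the
    # model-based phase starts (quasi-random coverage, not iid sampling)
    n_startup = max(n_startup, min(space.budget // 2,
                                   max(len(c) for c in dims.values())))
    startup_order = {
        name: [choices[i] for i in rng.permutation(len(choices))]
        for name, choices in dims.items()
    }
    trials: List[Tuple[dict, float]] = []
    failures: List[str] = []
    for t in range(space.budget):
        if t < n_startup or len(trials) < 2:
            cand = {name: order[t % len(order)]
                    for name, order in startup_order.items()}
        else:
            cand = _tpe_propose(dims, trials, rng)
        trial_seed = int(rng.integers(0, 2**31))
        try:
            score = objective(cand, trial_seed)
        except Exception as exc:  # noqa: BLE001 - logged per trial
            failures.append(f"trial {t} {cand}: {exc}")
            continue
        trials.append((cand, float(score)))
    if not trials:
        raise RuntimeError("all trials failed:\n" + "\n".join(failures))
    best_cand, best_score = max(trials, key=lambda cs: cs[1])
    return best_cand, best_score, trials
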
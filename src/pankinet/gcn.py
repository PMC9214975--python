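"""Three-layer graph convolutional classifier, in plain NumPy.

The model stacks three graph convolutions

    F^l = act( L . F^{l-1} . W^l ),    F^0 = AF,

with kernel widths 64, 32 and 16, where ``L`` is the modified normalized
Laplacian and ``AF`` the atom-feature matrix of :mod:`pankinet.featurize`.
Each layer's feature map is reduced by global average pooling (GAP) over
the fixed padded atom dimension (N = 50); the three pooled vectors are
concatenated into a 112-dimensional graph embedding and fed to a single
affine softmax classifier with two outputs (active = class 0,
inactive = class 1).

Training minimizes cross-entropy with the ADAM optimizer
(lr 0.001, beta1 0.9, beta2 0.999) for 100 epochs by default. Forward,
backward and the optimizer are written directly in NumPy: the model is a
few thousand parameters on 50 x 50 graphs, and the explicit backward pass
is reused verbatim by the Grad-CAM attribution in
:mod:`pankinet.gradcam`. All randomness (weight initialization, epoch
shuffling) flows from a single integer seed, so training is bit-for-bit
reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import (accuracy_score, confusion_matrix,
                             matthews_corrcoef, roc_auc_score)

from .featurize import MAX_ATOMS, N_ATOM_FEATURES
from .pkfi import ACTIVE, ACTIVE_CLASS_INDEX, DataSplit

logger = logging.getLogger(__name__)

#: Kernel widths of the three graph-conv layers.
KERNELS = (64, 32, 16)

#: Length of the concatenated pooled embedding (64 + 32 + 16).
EMBEDDING_DIM = sum(KERNELS)

N_CLASSES = 2


@dataclass
class TrainConfig:
    epochs: int = 100
    learning_rate: float = 0.001
    beta1: float = 0.9
    beta2: float = 0.999
    batch_size: int = 32
    seed: int = 0
    class_weight: bool = False  # off by default: imbalance is not corrected

    def __post_init__(self):
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")


@dataclass
class ModelParams:
    """All trainable parameters plus the architecture they assume."""

    weights: list            # conv kernels W^1..W^3
    classifier_w: np.ndarray  # (112, 2)
    classifier_b: np.ndarray  # (2,)
    kernels: tuple = KERNELS
    activation: str = "relu"  # "relu" | "linear"
    n_features: int = N_ATOM_FEATURES
    train_loss: list = field(default_factory=list)

    def validate(self):
        dims = (self.n_features,) + tuple(self.kernels)
        for l, W in enumerate(self.weights):
            if W.shape != (dims[l], dims[l + 1]):
                raise ValueError(
                    f"layer {l + 1} kernel has shape {W.shape}, "
                    f"expected {(dims[l], dims[l + 1])}")
        emb = sum(self.kernels)
        if self.classifier_w.shape != (emb, N_CLASSES):
            raise ValueError("classifier weight shape mismatch")
        arrays = self.weights + [self.classifier_w, self.classifier_b]
        if not all(np.all(np.isfinite(a)) for a in arrays):
            raise ValueError("non-finite model parameters")


@dataclass
class EvalMetrics:
    acc: float
    mcc: float
    auroc: float
    confusion: np.ndarray  # rows true [neg, pos], cols predicted [neg, pos]
    flag: str = ""


def _glorot(rng, fan_in, fan_out):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def init_params(seed: int, kernels=KERNELS, activation: str = "relu",
                n_features: int = N_ATOM_FEATURES) -> ModelParams:
    """Seeded variance-scaling (Glorot uniform) initialization."""
    rng = np.random.default_rng(seed)
    dims = (n_features,) + tuple(kernels)
    weights = [_glorot(rng, dims[l], dims[l + 1]) for l in range(len(kernels))]
    emb = sum(kernels)
    return ModelParams(
        weights=weights,
        classifier_w=_glorot(rng, emb, N_CLASSES),
        classifier_b=np.zeros(N_CLASSES),
        kernels=tuple(kernels), activation=activation, n_features=n_features)


def _activate(Z, activation):
    if activation == "relu":
        return np.maximum(Z, 0.0)
    if activation == "linear":
        return Z
    raise ValueError(f"unknown activation {activation!r}")


def _activate_grad(Z, activation):
    if activation == "relu":
        return (Z > 0).astype(float)
    return np.ones_like(Z)


def graph_conv(F_prev: np.ndarray, L: np.ndarray, W: np.ndarray,
               activation: str = "relu") -> np.ndarray:
    """One graph convolution: ``act(L . F_prev . W)``.

    Padded (all-zero) rows of ``L`` keep their feature-map rows at zero.
    """
    if F_prev.shape[-2] != L.shape[-1] or F_prev.shape[-1] != W.shape[0]:
        raise ValueError(
            f"shape mismatch: L {L.shape}, F {F_prev.shape}, W {W.shape}")
    return _activate(L @ F_prev @ W, activation)


def global_average_pool(F: np.ndarray, n_atoms: int | None = None) -> np.ndarray:
    """Mean of a feature map over the atom dimension.

    By default the divisor is the fixed padded dimension (N = 50), so a
    padded and an unpadded tensor pool identically up to that constant.
    Passing ``n_atoms`` divides by the real atom count instead.
    """
    pooled = F.sum(axis=-2)
    divisor = float(F.shape[-2]) if n_atoms is None else float(n_atoms)
    return pooled / divisor


def _softmax(logits):
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def forward_batch(AF: np.ndarray, L: np.ndarray, params: ModelParams,
                  keep_cache: bool = False):
    """Batched forward pass.

    ``AF`` is (B, 50, 28) and ``L`` is (B, 50, 50); single graphs may be
    passed unbatched. Returns ``(probs, feature_maps)`` and, with
    ``keep_cache``, the intermediates needed by backprop/Grad-CAM.
    """
    F = AF
    caches, feature_maps, gaps = [], [], []
    for W in params.weights:
        M = L @ F            # neighborhood aggregation
        Z = M @ W
        F = _activate(Z, params.activation)
        caches.append((M, Z))
        feature_maps.append(F)
        gaps.append(global_average_pool(F))
    h = np.concatenate(gaps, axis=-1)
    logits = h @ params.classifier_w + params.classifier_b
    probs = _softmax(logits)
    if not np.all(np.isfinite(probs)):
        raise FloatingPointError("non-finite values in the forward pass")
    if keep_cache:
        return probs, feature_maps, {"caches": caches, "gaps": gaps, "h": h}
    return probs, feature_maps


def forward(graph, params: ModelParams):
    """Forward pass on one :class:`~pankinet.featurize.CompoundGraph`.

    Returns the two-class probability vector and the three feature maps
    (retained for Grad-CAM).
    """
    probs, fmaps = forward_batch(graph.AF, graph.L, params)
    return probs, fmaps


def _loss_and_grads(AF, L, y_index, params: ModelParams, sample_weight=None):
    """Mean cross-entropy and gradients for one batch.

    ``y_index`` holds class indices (0 = active). Returns
    ``(loss, grad_weights, grad_classifier_w, grad_classifier_b)``.
    """
    B = AF.shape[0]
    probs, _, cache = forward_batch(AF, L, params, keep_cache=True)
    p_true = probs[np.arange(B), y_index]
    w = np.ones(B) if sample_weight is None else sample_weight
    loss = float(np.mean(-w * np.log(np.clip(p_true, 1e-12, None))))

    y_onehot = np.zeros_like(probs)
    y_onehot[np.arange(B), y_index] = 1.0
    dlogits = (probs - y_onehot) * (w / B)[:, None]
    h = cache["h"]
    dWc = h.reshape(-1, h.shape[-1]).T @ dlogits.reshape(-1, N_CLASSES)
    dbc = dlogits.sum(axis=0)
    dh = dlogits @ params.classifier_w.T

    n_pad = AF.shape[-2]
    # split dh into the per-layer pooled gradients
    offsets = np.cumsum((0,) + params.kernels)
    dgaps = [dh[:, offsets[l]:offsets[l + 1]] for l in range(len(params.kernels))]

    grad_W = [None] * len(params.weights)
    dF = np.repeat(dgaps[-1][:, None, :], n_pad, axis=1) / n_pad
    for l in range(len(params.weights) - 1, -1, -1):
        M, Z = cache["caches"][l]
        dZ = dF * _activate_grad(Z, params.activation)
        grad_W[l] = np.einsum("bnk,bnd->kd", M, dZ)
        if l > 0:
            # L is symmetric, so L^T dZ == L dZ
            dF = L @ dZ @ params.weights[l].T
            dF += np.repeat(dgaps[l - 1][:, None, :], n_pad, axis=1) / n_pad
    return loss, grad_W, dWc, dbc


def train(split: DataSplit, graphs: dict, config: TrainConfig,
          params: ModelParams | None = None) -> ModelParams:
    """Train the classifier on the training half of a data split.

    ``graphs`` maps compound ids to featurized graphs. With
    ``config.epochs == 0`` the seeded initialization is returned
    unchanged. The per-epoch loss trajectory is stored on the returned
    parameters and logged.
    """
    labels = [lab for _, lab in split.train]
    if len(set(labels)) < 2:
        raise ValueError("training set must contain both classes")
    missing = [cid for cid, _ in split.train + split.test if cid not in graphs]
    if missing:
        raise ValueError(f"missing graphs for {len(missing)} compounds")

    AF = np.stack([graphs[cid].AF for cid, _ in split.train])
    L = np.stack([graphs[cid].L for cid, _ in split.train])
    y = np.array([ACTIVE_CLASS_INDEX if lab == ACTIVE else 1 - ACTIVE_CLASS_INDEX
                  for _, lab in split.train])

    if params is None:
        params = init_params(config.seed)
    params.validate()

    sample_weight = None
    if config.class_weight:
        counts = np.bincount(y, minlength=N_CLASSES)
        class_w = len(y) / (N_CLASSES * np.maximum(counts, 1))
        sample_weight = class_w[y]

    tensors = params.weights + [params.classifier_w, params.classifier_b]
    m = [np.zeros_like(t) for t in tensors]
    v = [np.zeros_like(t) for t in tensors]
    rng = np.random.default_rng(config.seed + 1)
    step = 0
    params.train_loss = []
    n = len(y)
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            sw = None if sample_weight is None else sample_weight[idx]
            loss, gW, gWc, gbc = _loss_and_grads(
                AF[idx], L[idx], y[idx], params, sample_weight=sw)
            epoch_loss += loss * len(idx)
            grads = gW + [gWc, gbc]
            step += 1
            lr_t = config.learning_rate * (
                np.sqrt(1 - config.beta2 ** step) / (1 - config.beta1 ** step))
            for t, (tensor, g) in enumerate(zip(tensors, grads)):
                m[t] = config.beta1 * m[t] + (1 - config.beta1) * g
                v[t] = config.beta2 * v[t] + (1 - config.beta2) * g * g
                tensor -= lr_t * m[t] / (np.sqrt(v[t]) + 1e-8)
        params.train_loss.append(epoch_loss / n)
        if (epoch + 1) % 20 == 0 or epoch == 0:
            logger.info("epoch %d/%d: train loss %.4f",
                        epoch + 1, config.epochs, params.train_loss[-1])
    return params


def predict_scores(params: ModelParams, compounds, graphs: dict) -> np.ndarray:
    """Positive-class (pan-family active) probability per compound."""
    AF = np.stack([graphs[cid].AF for cid in compounds])
    L = np.stack([graphs[cid].L for cid in compounds])
    probs, _ = forward_batch(AF, L, params)
    return probs[:, ACTIVE_CLASS_INDEX]


def metrics_from_scores(y_true: np.ndarray, scores: np.ndarray,
                        threshold: float = 0.5) -> EvalMetrics:
    """ACC/MCC/AUROC from binary truth and positive-class scores.

    ACC is the fraction of correct calls at the threshold, MCC the
    standard four-count correlation of the 2x2 confusion table, and AUROC
    the rank statistic of the scores. A single-class truth vector leaves
    AUROC undefined (NaN, flagged).
    """
    y_true = np.asarray(y_true)
    scores = np.asarray(scores)
    y_pred = (scores >= threshold).astype(int)
    acc = float(accuracy_score(y_true, y_pred))
    mcc = float(matthews_corrcoef(y_true, y_pred))
    flag = ""
    if len(set(y_true.tolist())) < 2:
        auroc = float("nan")
        flag = "single-class test set: AUROC undefined"
    else:
        auroc = float(roc_auc_score(y_true, scores))
    conf = confusion_matrix(y_true, y_pred, labels=[0, 1])
    return EvalMetrics(acc=acc, mcc=mcc, auroc=auroc, confusion=conf, flag=flag)


def evaluate(params: ModelParams, split_test, graphs: dict) -> EvalMetrics:
    """ACC, MCC and AUROC on a held-out test list of (compound, label)."""
    if not split_test:
        raise ValueError("test set is empty")
    compounds = [cid for cid, _ in split_test]
    y_true = np.array([1 if lab == ACTIVE else 0 for _, lab in split_test])
    scores = predict_scores(params, compounds, graphs)
    return metrics_from_scores(y_true, scores)
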
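"""Deep belief network classification head.

A stack of restricted Boltzmann machines is pretrained greedily with
contrastive divergence (CD-k): the first RBM has Gaussian visible units
(CNN features are real-valued; inputs are standardized beforehand), the
deeper ones are Bernoulli-Bernoulli and train on the previous layer's
hidden probabilities.  The pretrained stack seeds a sigmoid MLP that is
fine-tuned end-to-end with a softmax head, cross-entropy loss and Adam.
A fully connected baseline with identical layer sizes but random
initialization and no pretraining is provided for comparison.

Tiny RBMs (<= 20 units total) support exact log-likelihood evaluation by
enumerating the partition function, which the training rules are tested
against.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np

from . import nn

__all__ = [
    "RBM",
    "DBNConfig",
    "DBNClassifier",
    "sample_h_given_v",
    "sample_v_given_h",
    "cd_update",
    "exact_loglik",
    "reconstruction_error",
    "pretrain",
    "finetune",
    "fc_baseline",
]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -500, 500)))


@dataclass
class RBM:
    """Weights [n_visible x n_hidden] plus bias vectors."""

    weights: np.ndarray
    vbias: np.ndarray
    hbias: np.ndarray
    visible: str = "bernoulli"  # or "gaussian" (unit variance)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=np.float64)
        self.vbias = np.asarray(self.vbias, dtype=np.float64)
        self.hbias = np.asarray(self.hbias, dtype=np.float64)
        if self.weights.shape != (self.vbias.size, self.hbias.size):
            raise ValueError("weight matrix inconsistent with bias vectors")
        if self.visible not in ("bernoulli", "gaussian"):
            raise ValueError("visible unit family must be bernoulli or gaussian")
        if not all(
            np.all(np.isfinite(a)) for a in (self.weights, self.vbias, self.hbias)
        ):
            raise ValueError("non-finite RBM parameters")

    @property
    def n_visible(self) -> int:
        return self.vbias.size

    @property
    def n_hidden(self) -> int:
        return self.hbias.size

    @classmethod
    def initialize(cls, n_visible: int, n_hidden: int, visible: str = "bernoulli",
                   scale: float = 0.01, rng: np.random.Generator | None = None) -> "RBM":
        rng = rng or np.random.default_rng(0)
        return cls(
            weights=rng.normal(0.0, scale, size=(n_visible, n_hidden)),
            vbias=np.zeros(n_visible),
            hbias=np.zeros(n_hidden),
            visible=visible,
        )


def sample_h_given_v(
    rbm: RBM, v: np.ndarray, rng: np.random.Generator | int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Hidden probabilities logistic(vW + b_h) and a Bernoulli sample."""
    if isinstance(rng, (int, np.integer)) or rng is None:
        rng = np.random.default_rng(rng)
    v = np.atleast_2d(np.asarray(v, dtype=np.float64))
    if v.shape[1] != rbm.n_visible:
        raise ValueError(f"visible dimension {v.shape[1]} != {rbm.n_visible}")
    p = _sigmoid(v @ rbm.weights + rbm.hbias)
    return p, (rng.random(p.shape) < p).astype(np.float64)


def sample_v_given_h(
    rbm: RBM, h: np.ndarray, rng: np.random.Generator | int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Visible reconstruction given hidden states.

    Bernoulli visibles: probabilities + sample.  Gaussian visibles: the
    conditional mean (and the mean again in place of a sample; CD uses the
    mean-field reconstruction).
    """
    if isinstance(rng, (int, np.integer)) or rng is None:
        rng = np.random.default_rng(rng)
    h = np.atleast_2d(np.asarray(h, dtype=np.float64))
    if h.shape[1] != rbm.n_hidden:
        raise ValueError(f"hidden dimension {h.shape[1]} != {rbm.n_hidden}")
    mean = h @ rbm.weights.T + rbm.vbias
    if rbm.visible == "gaussian":
        return mean, mean
    p = _sigmoid(mean)
    return p, (rng.random(p.shape) < p).astype(np.float64)


def cd_update(
    rbm: RBM,
    batch: np.ndarray,
    k: int = 1,
    lr: float = 1e-3,
    rng: np.random.Generator | int | None = None,
) -> RBM:
    """One CD-k parameter update from a [n x n_visible] batch (in place).

    Gibbs sampling uses common random numbers across batch rows, so the
    update is an exact average over rows: duplicating a row leaves the
    update unchanged while each row's sample stays marginally Bernoulli.
    """
    if isinstance(rng, (int, np.integer)) or rng is None:
        rng = np.random.default_rng(rng)
    v0 = np.atleast_2d(np.asarray(batch, dtype=np.float64))
    n = v0.shape[0]
    ph0 = _sigmoid(v0 @ rbm.weights + rbm.hbias)
    h = (rng.random(rbm.n_hidden) < ph0).astype(np.float64)
    vk, phk = v0, ph0
    for _ in range(k):
        mean = h @ rbm.weights.T + rbm.vbias
        if rbm.visible == "gaussian":
            vk = mean
        else:
            vk = (rng.random(rbm.n_visible) < _sigmoid(mean)).astype(np.float64)
        phk = _sigmoid(vk @ rbm.weights + rbm.hbias)
        h = (rng.random(rbm.n_hidden) < phk).astype(np.float64)
    rbm.weights += lr * (v0.T @ ph0 - vk.T @ phk) / n
    rbm.vbias += lr * (v0 - vk).mean(axis=0)
    rbm.hbias += lr * (ph0 - phk).mean(axis=0)
    return rbm


def _free_energy(rbm: RBM, v: np.ndarray) -> np.ndarray:
    """F(v) = -v.b_v - sum_j log(1 + exp(vW + b_h)_j), Bernoulli visibles."""
    act = v @ rbm.weights + rbm.hbias
    return -(v @ rbm.vbias) - np.logaddexp(0.0, act).sum(axis=1)


def exact_loglik(rbm: RBM, data: np.ndarray) -> float:
    """Average log P(v) with the partition function enumerated exactly.

    Only feasible (and only allowed) for Bernoulli-visible RBMs with
    n_visible + n_hidden <= 20.
    """
    if rbm.visible != "bernoulli":
        raise ValueError("exact likelihood requires Bernoulli visible units")
    if rbm.n_visible + rbm.n_hidden > 20:
        raise ValueError("RBM too large to enumerate (n_visible + n_hidden > 20)")
    data = np.atleast_2d(np.asarray(data, dtype=np.float64))
    all_v = np.array(list(product([0.0, 1.0], repeat=rbm.n_visible)))
    log_z = np.logaddexp.reduce(-_free_energy(rbm, all_v))
    return float(np.mean(-_free_energy(rbm, data) - log_z))


def reconstruction_error(rbm: RBM, data: np.ndarray) -> float:
    """Mean squared error of the one-step mean-field reconstruction."""
    data = np.atleast_2d(np.asarray(data, dtype=np.float64))
    p = _sigmoid(data @ rbm.weights + rbm.hbias)
    recon, _ = sample_v_given_h(rbm, p)
    return float(np.mean((data - recon) ** 2))


@dataclass(frozen=True)
class DBNConfig:
    """Layer plan and training hyperparameters.

    The default stack mirrors the full pipeline: 50,176 CNN features ->
    1024 -> 1500 hidden units -> 12-way softmax.  CD steps, learning
    rates and epoch counts are exposed because the tuned originals were
    never published.
    """

    layer_sizes: tuple[int, ...] = (50176, 1024, 1500)
    n_classes: int = 12
    cd_steps: int = 1
    pretrain_epochs: int = 10
    pretrain_lr: float = 1e-3
    pretrain_batch: int = 32
    finetune_epochs: int = 50
    finetune_lr: float = 1e-3
    batch_size: int = 32
    gaussian_visible: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s < 1 for s in self.layer_sizes):
            raise ValueError("layer sizes must be positive")
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")


class DBNClassifier:
    """Sigmoid MLP seeded from a pretrained RBM stack, softmax head on top."""

    def __init__(self, layers: list[nn.Layer], config: DBNConfig,
                 scaler: tuple[np.ndarray, np.ndarray] | None = None):
        self.net = nn.Sequential(*layers)
        self.config = config
        self.scaler = scaler
        self.history: list[float] = []

    @classmethod
    def from_stack(cls, stack: list[RBM], config: DBNConfig,
                   rng: np.random.Generator,
                   scaler=None) -> "DBNClassifier":
        layers: list[nn.Layer] = []
        for rbm in stack:
            layers.append(nn.Linear(rbm.n_visible, rbm.n_hidden,
                                    weight=rbm.weights.copy(), bias=rbm.hbias.copy()))
            layers.append(nn.Sigmoid())
        layers.append(nn.Linear(config.layer_sizes[-1], config.n_classes, rng=rng))
        return cls(layers, config, scaler)

    @classmethod
    def random_init(cls, config: DBNConfig, rng: np.random.Generator,
                    scaler=None) -> "DBNClassifier":
        layers: list[nn.Layer] = []
        sizes = config.layer_sizes
        for n_in, n_out in zip(sizes[:-1], sizes[1:]):
            layers.append(nn.Linear(n_in, n_out, rng=rng))
            layers.append(nn.Sigmoid())
        layers.append(nn.Linear(sizes[-1], config.n_classes, rng=rng))
        return cls(layers, config, scaler)

    def _apply_scaler(self, x: np.ndarray) -> np.ndarray:
        if self.scaler is None:
            return x
        mean, std = self.scaler
        return (x - mean) / std

    def predict_proba(self, features: np.ndarray, scaled: bool = False) -> np.ndarray:
        x = np.atleast_2d(np.asarray(features, dtype=np.float64))
        if not scaled:
            x = self._apply_scaler(x)
        self.net.eval()
        return nn.softmax(self.net.forward(x))

    def predict(self, features: np.ndarray, scaled: bool = False) -> np.ndarray:
        return self.predict_proba(features, scaled=scaled).argmax(axis=1) + 1


def _validate_labels(labels: np.ndarray, n_classes: int) -> np.ndarray:
    labels = np.asarray(labels)
    if labels.min() < 1 or labels.max() > n_classes:
        raise ValueError(f"labels must lie in 1..{n_classes}")
    return labels - 1  # 0-based for the loss


def _train_supervised(
    clf: DBNClassifier,
    features: np.ndarray,
    labels: np.ndarray,
    config: DBNConfig,
    rng: np.random.Generator,
    extractor=None,
    images: np.ndarray | None = None,
) -> DBNClassifier:
    """Mini-batch Adam on softmax cross-entropy; joint mode backprops into
    the convolutional extractor when one is supplied."""
    y = _validate_labels(labels, config.n_classes)
    params = clf.net.params()
    if extractor is not None:
        if images is None:
            raise ValueError("joint fine-tuning requires the image batch")
        params = params + extractor.params()
    opt = nn.Adam(params, lr=config.finetune_lr)
    n = len(y)
    for _ in range(config.finetune_epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        clf.net.train()
        if extractor is not None:
            extractor.train()
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            if extractor is not None:
                feats4 = extractor.forward(np.transpose(images[idx], (0, 3, 1, 2)))
                x = feats4.reshape(len(idx), -1)
            else:
                x = features[idx]
            logits = clf.net.forward(x)
            loss, dlogits = nn.cross_entropy(logits, y[idx])
            opt.zero_grad()
            dx = clf.net.backward(dlogits)
            if extractor is not None:
                extractor.backward(dx.reshape(feats4.shape))
            opt.step()
            epoch_loss += loss * len(idx)
        clf.history.append(epoch_loss / n)
    return clf


def pretrain(config: DBNConfig, features: np.ndarray) -> list[RBM]:
    """Greedy layer-wise CD pretraining of the RBM stack.

    Layer l trains on the hidden probabilities of layer l-1; the raw
    features feed the first (Gaussian-visible) RBM and are expected to be
    standardized by the caller.
    """
    features = np.atleast_2d(np.asarray(features, dtype=np.float64))
    sizes = config.layer_sizes
    if features.shape[1] != sizes[0]:
        raise ValueError(
            f"feature dimension {features.shape[1]} != first layer {sizes[0]}"
        )
    rng = np.random.default_rng(config.seed)
    stack: list[RBM] = []
    x = features
    for depth, (nv, nh) in enumerate(zip(sizes[:-1], sizes[1:])):
        visible = "gaussian" if (depth == 0 and config.gaussian_visible) else "bernoulli"
        rbm = RBM.initialize(nv, nh, visible=visible, rng=rng)
        n = x.shape[0]
        for _ in range(config.pretrain_epochs):
            order = rng.permutation(n)
            for start in range(0, n, config.pretrain_batch):
                idx = order[start : start + config.pretrain_batch]
                cd_update(rbm, x[idx], k=config.cd_steps, lr=config.pretrain_lr, rng=rng)
        stack.append(rbm)
        x, _ = sample_h_given_v(rbm, x, rng)  # probabilities feed the next layer
    return stack


def finetune(
    stack: list[RBM],
    features: np.ndarray,
    labels: np.ndarray,
    config: DBNConfig,
    scaler: tuple[np.ndarray, np.ndarray] | None = None,
    extractor=None,
    images: np.ndarray | None = None,
) -> DBNClassifier:
    """Supervised fine-tuning of the pretrained stack plus softmax head."""
    rng = np.random.default_rng(config.seed + 1)
    clf = DBNClassifier.from_stack(stack, config, rng, scaler=scaler)
    return _train_supervised(clf, np.atleast_2d(features), labels, config, rng,
                             extractor=extractor, images=images)


def fc_baseline(
    features: np.ndarray,
    labels: np.ndarray,
    config: DBNConfig,
    scaler: tuple[np.ndarray, np.ndarray] | None = None,
) -> DBNClassifier:
    """Same layer sizes and training, random init, no generative pretraining."""
    rng = np.random.default_rng(config.seed + 1)
    clf = DBNClassifier.random_init(config, rng, scaler=scaler)
    return _train_supervised(clf, np.atleast_2d(features), labels, config, rng)
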
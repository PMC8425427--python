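"""Desk-scale training loop, Adam with L2 weight decay, plateau LR schedule,
inference and checkpointing."""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field

import numpy as np

from ..evaluation import RankedContacts
from .features import FeatureBundle, random_crop, PAIR_CHANNELS, SEQ_CHANNELS
from .loss import FocalLossConfig, focal_loss, focal_loss_grad
from .network import ContactNetwork, NetworkConfig


@dataclass
class TrainConfig:
    batch_size: int = 1
    learning_rate: float = 1e-3
    l2_coefficient: float = 1e-4
    lr_decay_factor: float = 0.2
    lr_patience_epochs: int = 2
    min_learning_rate: float = 1e-6
    max_crop_length: int = 400
    epochs: int = 20
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0 or self.min_learning_rate <= 0:
            raise ValueError("learning rates must be positive")
        if self.lr_patience_epochs < 1:
            raise ValueError("patience must be >= 1")


class Adam:
    """Adam over the network's parameter list; decoupled from the schedule."""

    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8,
                 l2=0.0):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2, self.eps, self.l2 = beta1, beta2, eps, l2
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]
        self.t = 0

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            if self.l2 and p.decay:
                g = g + self.l2 * p.value
            m[:] = b1 * m + (1 - b1) * g
            v[:] = b2 * v + (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class ReduceLROnPlateau:
    """Multiply the rate by *factor* after *patience* epochs without
    validation improvement; never below *min_lr*."""

    def __init__(self, optimizer: Adam, factor=0.2, patience=2, min_lr=1e-6):
        self.opt = optimizer
        self.factor, self.patience, self.min_lr = factor, patience, min_lr
        self.best = np.inf
        self.bad_epochs = 0

    def step(self, val_loss: float) -> float:
        if val_loss < self.best:
            self.best = val_loss
            self.bad_epochs = 0
        else:
            self.bad_epochs += 1
            if self.bad_epochs >= self.patience:
                self.opt.lr = max(self.opt.lr * self.factor, self.min_lr)
                self.bad_epochs = 0
        return self.opt.lr


def _epoch_loss(net, dataset, loss_cfg):
    losses = []
    for bundle, labels in dataset:
        p = net.forward(bundle, train=False)
        losses.append(focal_loss(p, labels.values, labels.mask, loss_cfg))
    return float(np.mean(losses))


def train(train_set, val_set, cfg: TrainConfig = TrainConfig(),
          net_cfg: NetworkConfig | None = None,
          net: ContactNetwork | None = None,
          loss_cfg: FocalLossConfig = FocalLossConfig(),
          max_steps: int | None = None):
    """Train a contact network on (FeatureBundle, ContactMap) pairs.

    Returns ``(net, history)`` where history holds per-epoch train and
    validation losses and the learning-rate trace.
    """
    if not train_set:
        raise ValueError("empty training set")
    if net is None:
        net = ContactNetwork(net_cfg or NetworkConfig(), seed=cfg.seed)
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(net.params(), lr=cfg.learning_rate, l2=cfg.l2_coefficient)
    sched = ReduceLROnPlateau(opt, cfg.lr_decay_factor, cfg.lr_patience_epochs,
                              cfg.min_learning_rate)
    history = {"train_loss": [], "val_loss": [], "lr": []}
    steps = 0
    for _ in range(cfg.epochs):
        order = rng.permutation(len(train_set))
        epoch_losses = []
        for idx in order:
            bundle, labels = train_set[idx]
            bundle, labels = random_crop(bundle, labels, cfg.max_crop_length,
                                         rng)
            net.zero_grad()
            p = net.forward(bundle, train=True)
            epoch_losses.append(focal_loss(p, labels.values, labels.mask,
                                           loss_cfg))
            net.backward(focal_loss_grad(p, labels.values, labels.mask,
                                         loss_cfg))
            opt.step()
            steps += 1
            if max_steps is not None and steps >= max_steps:
                break
        history["train_loss"].append(float(np.mean(epoch_losses)))
        val = (_epoch_loss(net, val_set, loss_cfg) if val_set
               else history["train_loss"][-1])
        history["val_loss"].append(val)
        history["lr"].append(sched.step(val))
        if max_steps is not None and steps >= max_steps:
            break
    return net, history


def ranked_contacts_from_map(prob: np.ndarray,
                             mask: np.ndarray | None = None,
                             length: int | None = None) -> RankedContacts:
    """Collapse a symmetric probability map to ranked unique pairs (i <= j).

    Sorted by probability descending, ties broken by (i, j) ascending.
    """
    L = prob.shape[0]
    iu, ju = np.triu_indices(L)
    scores = prob[iu, ju]
    if mask is not None:
        keep = np.asarray(mask, bool)[iu, ju]
        iu, ju, scores = iu[keep], ju[keep], scores[keep]
    order = np.lexsort((ju, iu, -scores))
    pairs = [(int(iu[k]), int(ju[k]), float(scores[k])) for k in order]
    return RankedContacts(pairs, length or L)


def predict(net: ContactNetwork, bundle: FeatureBundle) -> RankedContacts:
    """Ranked unique residue pairs from a trained network."""
    p = net.predict_map(bundle)
    return ranked_contacts_from_map(p, bundle.mask)


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------

def save_checkpoint(path: str, net: ContactNetwork,
                    train_cfg: TrainConfig | None = None) -> None:
    """Single-file archive: weights + architecture + channel-order metadata."""
    meta = {
        "network": asdict(net.cfg),
        "train": asdict(train_cfg) if train_cfg else None,
        "pair_channels": list(PAIR_CHANNELS),
        "seq_channels": list(SEQ_CHANNELS),
    }
    arrays = {f"param_{i}": p.value for i, p in enumerate(net.params())}
    np.savez(path, meta=json.dumps(meta), **arrays)


def load_checkpoint(path: str) -> ContactNetwork:
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["meta"]))
        net_cfg = meta["network"]
        net_cfg["filters_1d"] = tuple(net_cfg["filters_1d"])
        net_cfg["filters_2d_groups"] = tuple(net_cfg["filters_2d_groups"])
        net = ContactNetwork(NetworkConfig(**net_cfg))
        for i, p in enumerate(net.params()):
            val = data[f"param_{i}"]
            if val.shape != p.value.shape:
                raise ValueError("checkpoint does not match the architecture")
            p.value = val
    return net
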
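"""Y-shaped joint multi-modal network scoring drug–target pairs.

Six inputs (drug and target vector for each enabled modality) are each
projected into a shared-width joint space by an independent ReLU branch

    h_i = ReLU(W_M f(v_i) + b_M)

then concatenated and passed through two ReLU hidden layers (128, 32) and a
single sigmoid output giving the interaction probability.  Training
minimizes binary cross-entropy with the Adam optimizer and mini-batches,
with early stopping on a validation criterion (AUC by default: on small
validation splits BCE is dominated by calibration and can be minimized by
the untrained model, whereas ranking quality is what the evaluation
reports).  Dropout (default 0.3) is applied to the concatenated joint
vector during training only, which doubles as branch-level regularization;
optional decoupled weight decay shrinks weight matrices.

The network is implemented directly in NumPy: it is small (a few hundred
thousand parameters at most), runs fast on one CPU, and a self-contained
implementation keeps training bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

MODALITY_ORDER = ("sequence", "structure", "similarity")


@dataclass
class FusionConfig:
    """Architecture and training hyperparameters."""

    branch_width: int = 64
    hidden: tuple[int, int] = (128, 32)
    dropout: float = 0.3
    batch_size: int = 32
    learning_rate: float = 1e-3
    weight_decay: float = 0.0
    max_epochs: int = 200
    patience: int = 20
    monitor: str = "auc"  # early-stopping criterion: "auc" or "loss"
    n_models: int = 1  # score-averaged ensemble size
    seed: int = 0
    modalities: tuple[str, ...] = MODALITY_ORDER

    def __post_init__(self) -> None:
        self.hidden = tuple(self.hidden)
        self.modalities = tuple(
            m for m in MODALITY_ORDER if m in tuple(self.modalities)
        )
        if not self.modalities:
            raise ValueError("at least one modality must be enabled")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")
        if self.branch_width < 1 or any(h < 1 for h in self.hidden):
            raise ValueError("layer widths must be positive")
        if self.monitor not in ("auc", "loss"):
            raise ValueError("monitor must be 'auc' or 'loss'")
        if self.n_models < 1:
            raise ValueError("n_models must be >= 1")


@dataclass
class ModalityStore:
    """Per-entity feature vectors for each modality.

    ``vectors[modality][entity_id]`` is a 1-D array; all entities of one
    type share a dimension within a modality.
    """

    vectors: dict[str, dict[str, np.ndarray]] = field(default_factory=dict)

    def add(self, modality: str, table: Mapping[str, np.ndarray]) -> None:
        self.vectors.setdefault(modality, {}).update(
            {k: np.asarray(v, dtype=float) for k, v in table.items()}
        )

    def get(self, modality: str, entity: str) -> np.ndarray:
        try:
            return self.vectors[modality][entity]
        except KeyError:
            raise KeyError(f"entity {entity!r} has no {modality!r} vector") from None

    @property
    def modalities(self) -> tuple[str, ...]:
        return tuple(m for m in MODALITY_ORDER if m in self.vectors)


def assemble_pair(
    drug: str,
    target: str,
    store: ModalityStore,
    modalities: Sequence[str] = MODALITY_ORDER,
) -> tuple[np.ndarray, ...]:
    """Branch inputs for one pair in deterministic order.

    Order: (drug-sequence, target-sequence, drug-structure, target-structure,
    drug-similarity, target-similarity), restricted to enabled modalities.
    """
    enabled = [m for m in MODALITY_ORDER if m in tuple(modalities)]
    if not enabled:
        raise ValueError("no modality enabled")
    out: list[np.ndarray] = []
    for modality in enabled:
        out.append(store.get(modality, drug))
        out.append(store.get(modality, target))
    return tuple(out)


def _relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def bce_loss(y: np.ndarray, p: np.ndarray, eps: float = 1e-12) -> float:
    p = np.clip(p, eps, 1 - eps)
    return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


def _rank_auc(y: np.ndarray, s: np.ndarray) -> float:
    """Mann–Whitney AUC (used internally for the early-stopping monitor)."""
    from scipy.stats import rankdata

    pos = y == 1
    n1, n0 = int(pos.sum()), int((~pos).sum())
    if n1 == 0 or n0 == 0:
        return 0.5
    r = rankdata(s)
    return float((r[pos].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


class _Adam:
    """Adam optimizer over a flat list of parameter arrays."""

    def __init__(self, params: list[np.ndarray], lr: float) -> None:
        self.lr = lr
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


class JointModel:
    """The Y-shaped fusion network (parameters + forward/backward passes)."""

    def __init__(self, config: FusionConfig, input_dims: Sequence[int]) -> None:
        if not input_dims:
            raise ValueError("model needs at least one branch")
        expected = 2 * len(config.modalities)
        if len(input_dims) != expected:
            raise ValueError(
                f"{len(input_dims)} branch dims given but {expected} branches "
                f"expected for modalities {config.modalities}"
            )
        self.config = config
        self.input_dims = [int(d) for d in input_dims]
        rng = np.random.default_rng(config.seed)
        bw = config.branch_width
        h1, h2 = config.hidden

        def he(n_in: int, n_out: int) -> np.ndarray:
            return rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out))

        self.branch_w = [he(d, bw) for d in self.input_dims]
        self.branch_b = [np.zeros(bw) for _ in self.input_dims]
        concat = bw * len(self.input_dims)
        self.w1, self.b1 = he(concat, h1), np.zeros(h1)
        self.w2, self.b2 = he(h1, h2), np.zeros(h2)
        self.w3, self.b3 = he(h2, 1), np.zeros(1)
        self.history: list[dict[str, float]] = []
        self.best_epoch: int | None = None
        self._rng = rng

    # -- parameter plumbing -------------------------------------------------

    def parameters(self) -> list[np.ndarray]:
        return [
            *self.branch_w,
            *self.branch_b,
            self.w1,
            self.b1,
            self.w2,
            self.b2,
            self.w3,
            self.b3,
        ]

    def _snapshot(self) -> list[np.ndarray]:
        return [p.copy() for p in self.parameters()]

    def _restore(self, snapshot: list[np.ndarray]) -> None:
        for p, s in zip(self.parameters(), snapshot):
            p[...] = s

    @property
    def concat_width(self) -> int:
        return self.config.branch_width * len(self.input_dims)

    # -- forward / backward -------------------------------------------------

    def forward(
        self,
        inputs: Sequence[np.ndarray],
        train: bool = False,
        rng: np.random.Generator | None = None,
    ):
        """Scores for a batch; returns (p, cache) with cache for backprop."""
        hs = [
            _relu(x @ w + b)
            for x, w, b in zip(inputs, self.branch_w, self.branch_b)
        ]
        a = np.concatenate(hs, axis=1)
        if train and self.config.dropout > 0:
            if rng is None:
                rng = self._rng
            keep = 1.0 - self.config.dropout
            mask = (rng.random(a.shape) < keep) / keep
            ad = a * mask
        else:
            mask = None
            ad = a
        z1 = _relu(ad @ self.w1 + self.b1)
        z2 = _relu(z1 @ self.w2 + self.b2)
        logits = (z2 @ self.w3 + self.b3).ravel()
        p = _sigmoid(logits)
        cache = (inputs, hs, mask, ad, z1, z2)
        return p, cache

    def _backward(self, p: np.ndarray, y: np.ndarray, cache) -> list[np.ndarray]:
        inputs, hs, mask, ad, z1, z2 = cache
        n = len(y)
        dlogits = ((p - y) / n)[:, None]
        gw3 = z2.T @ dlogits
        gb3 = dlogits.sum(axis=0)
        dz2 = (dlogits @ self.w3.T) * (z2 > 0)
        gw2 = z1.T @ dz2
        gb2 = dz2.sum(axis=0)
        dz1 = (dz2 @ self.w2.T) * (z1 > 0)
        gw1 = ad.T @ dz1
        gb1 = dz1.sum(axis=0)
        da = dz1 @ self.w1.T
        if mask is not None:
            da = da * mask
        bw = self.config.branch_width
        g_branch_w, g_branch_b = [], []
        for i, (x, h) in enumerate(zip(inputs, hs)):
            dh = da[:, i * bw : (i + 1) * bw] * (h > 0)
            g_branch_w.append(x.T @ dh)
            g_branch_b.append(dh.sum(axis=0))
        return [*g_branch_w, *g_branch_b, gw1, gb1, gw2, gb2, gw3, gb3]

    # -- inference ----------------------------------------------------------

    def predict(self, inputs: Sequence[np.ndarray]) -> np.ndarray:
        p, _ = self.forward(inputs, train=False)
        return p

    # -- persistence ----------------------------------------------------------

    def save(self, path) -> None:
        """Self-describing checkpoint: config JSON + weights (npz)."""
        cfg = asdict(self.config)
        np.savez(
            path,
            __config__=np.frombuffer(json.dumps(cfg).encode(), dtype=np.uint8),
            __dims__=np.asarray(self.input_dims),
            **{f"p{i}": p for i, p in enumerate(self.parameters())},
        )

    @classmethod
    def load(cls, path) -> "JointModel":
        data = np.load(path)
        cfg = json.loads(bytes(data["__config__"]).decode())
        model = cls(FusionConfig(**cfg), list(data["__dims__"]))
        for i, p in enumerate(model.parameters()):
            p[...] = data[f"p{i}"]
        return model


def build_model(config: FusionConfig, input_dims: Sequence[int]) -> JointModel:
    """Construct an untrained model; concat width = branch_width × n_branches."""
    return JointModel(config, input_dims)


def _stack(pairs, store, modalities):
    cols = None
    for drug, target in pairs:
        vecs = assemble_pair(drug, target, store, modalities)
        if cols is None:
            cols = [[] for _ in vecs]
        for c, v in zip(cols, vecs):
            c.append(v)
    return [np.vstack(c) for c in cols]


def train(
    model: JointModel,
    train_inputs: Sequence[np.ndarray],
    train_labels: np.ndarray,
    val_inputs: Sequence[np.ndarray],
    val_labels: np.ndarray,
    config: FusionConfig | None = None,
) -> JointModel:
    """Train with Adam + early stopping; restores the best-validation weights.

    Inputs are lists of per-branch matrices (rows = pairs).  Raises on
    single-class training labels; warns when classes are imbalanced beyond
    2:1 (the sampling pipeline produces balanced sets).
    """
    cfg = config or model.config
    y = np.asarray(train_labels, dtype=float)
    yv = np.asarray(val_labels, dtype=float)
    n_pos = int(y.sum())
    if n_pos == 0 or n_pos == len(y):
        raise ValueError("training labels contain a single class")
    if not 1 / 3 <= n_pos / len(y) <= 2 / 3:
        logger.warning("train: labels imbalanced (%d/%d positive)", n_pos, len(y))
    rng = np.random.default_rng(cfg.seed + 1)
    opt = _Adam(model.parameters(), cfg.learning_rate)
    best_crit, best_snap, best_epoch, since_best = -np.inf, None, 0, 0
    n = len(y)
    matrices = [p for p in model.parameters() if p.ndim == 2]
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            xb = [x[idx] for x in train_inputs]
            p, cache = model.forward(xb, train=True, rng=rng)
            grads = model._backward(p, y[idx], cache)
            opt.step(model.parameters(), grads)
            if cfg.weight_decay:
                for w in matrices:
                    w -= cfg.learning_rate * cfg.weight_decay * w
            epoch_loss += bce_loss(y[idx], p) * len(idx)
        val_p = model.predict(val_inputs)
        val_loss = bce_loss(yv, val_p)
        val_auc = _rank_auc(yv, val_p)
        model.history.append(
            {
                "epoch": epoch,
                "train_loss": epoch_loss / n,
                "val_loss": val_loss,
                "val_auc": val_auc,
            }
        )
        crit = val_auc if cfg.monitor == "auc" else -val_loss
        if crit > best_crit + 1e-9:
            best_crit, best_snap, best_epoch, since_best = crit, model._snapshot(), epoch, 0
        else:
            since_best += 1
            if since_best >= cfg.patience:
                break
    if best_snap is not None:
        model._restore(best_snap)
    model.best_epoch = best_epoch
    return model


def train_ensemble(
    config: FusionConfig,
    train_inputs: Sequence[np.ndarray],
    train_labels: np.ndarray,
    val_inputs: Sequence[np.ndarray],
    val_labels: np.ndarray,
) -> list[JointModel]:
    """Train ``config.n_models`` independently seeded models on the same data.

    Score averaging over a few random restarts reduces the variance of the
    small-sample fits; the ensemble members differ only in initialization,
    mini-batch order and dropout masks.
    """
    models = []
    for k in range(config.n_models):
        cfg_k = FusionConfig(**{**asdict(config), "seed": config.seed + 7919 * k})
        m = JointModel(cfg_k, [x.shape[1] for x in train_inputs])
        train(m, train_inputs, train_labels, val_inputs, val_labels)
        models.append(m)
    return models


def predict_ensemble(models: Sequence[JointModel], inputs: Sequence[np.ndarray]) -> np.ndarray:
    """Mean predicted probability over ensemble members."""
    return np.mean([m.predict(inputs) for m in models], axis=0)


def train_on_pairs(
    model: JointModel,
    train_pairs: Sequence[tuple[str, str]],
    train_labels: np.ndarray,
    val_pairs: Sequence[tuple[str, str]],
    val_labels: np.ndarray,
    store: ModalityStore,
) -> JointModel:
    """Convenience wrapper assembling branch matrices from a ModalityStore."""
    mods = model.config.modalities
    return train(
        model,
        _stack(train_pairs, store, mods),
        train_labels,
        _stack(val_pairs, store, mods),
        val_labels,
    )


def score_pairs(
    model: JointModel,
    pairs: Sequence[tuple[str, str]],
    store: ModalityStore,
) -> np.ndarray:
    """One interaction probability per pair, order-preserving."""
    if not pairs:
        raise ValueError("no pairs to score")
    return model.predict(_stack(pairs, store, model.config.modalities))


def rank_candidates(
    model: JointModel,
    target: str,
    drugs: Sequence[str],
    store: ModalityStore,
) -> list[tuple[str, float]]:
    """Drugs ranked by predicted interaction with *target*, descending.

    Ties break lexicographically by drug id for determinism.
    """
    if not drugs:
        raise ValueError("empty candidate drug list")
    scores = score_pairs(model, [(d, target) for d in drugs], store)
    order = sorted(zip(drugs, scores), key=lambda t: (-t[1], t[0]))
    return [(d, float(s)) for d, s in order]
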
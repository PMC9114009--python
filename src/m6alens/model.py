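"""Residual dilated-convolution per-nucleotide m6A classifier.

The network starts with a width-1 convolution, passes through four residual
blocks of pre-activation units (BatchNorm -> ReLU -> dilated Conv, twice,
plus an identity skip), sums a width-1 projection of every block's output
into the penultimate layer, and ends with a width-1 convolution and softmax
over two classes (background, m6A).  The C context positions on each side
of a block are cropped before the loss, so labels are only ever read for
the B central positions.

Training follows a fixed recipe: Adam on masked categorical cross-entropy,
10 epochs, batch size 30, learning rate 1e-3 for the first 6 epochs then
halved every subsequent epoch.  Five independently-seeded members form the
default ensemble; the reported probability is the arithmetic mean of the
member outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from . import nn
from .genome_io import BlockPair, PreMrnaWindow, find_consensus_sites, one_hot_encode


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class ResNetBlockSpec:
    k: int   # number of kernels
    w: int   # window size
    ar: int  # dilation rate
    r: int   # repetitions of the two-conv unit

    def __post_init__(self):
        if min(self.k, self.w, self.ar, self.r) < 1:
            raise ConfigError("block parameters must be positive")

    @property
    def margin(self) -> int:
        """Receptive-field half-width contributed by the block (nt)."""
        return self.r * 2 * ((self.w - 1) // 2) * self.ar


DEFAULT_BLOCKS = (
    ResNetBlockSpec(32, 5, 1, 1),
    ResNetBlockSpec(32, 5, 2, 1),
    ResNetBlockSpec(32, 5, 4, 1),
    ResNetBlockSpec(32, 5, 8, 1),
)


@dataclass
class ModelConfig:
    blocks: tuple[ResNetBlockSpec, ...] = DEFAULT_BLOCKS
    B: int = 5000
    C: int = 5000
    classes: int = 2
    epochs: int = 10
    batch_size: int = 30
    lr_initial: float = 1e-3
    lr_halving_start_epoch: int = 7
    ensemble_size: int = 5
    seed: int = 0

    @property
    def margin(self) -> int:
        return sum(b.margin for b in self.blocks)

    def learning_rates(self) -> list[float]:
        """Per-epoch learning rates (epochs numbered from 1)."""
        first = self.lr_halving_start_epoch - 1
        return [
            self.lr_initial if e <= first
            else self.lr_initial * 2.0 ** -(e - first)
            for e in range(1, self.epochs + 1)
        ]

    def to_dict(self) -> dict:
        d = asdict(self)
        d["blocks"] = [asdict(b) for b in self.blocks]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        d["blocks"] = tuple(ResNetBlockSpec(**b) for b in d["blocks"])
        return cls(**d)


class _ResidualUnit:
    """Pre-activation residual unit: x + Conv(ReLU(BN(Conv(ReLU(BN(x))))))."""

    def __init__(self, k: int, w: int, ar: int, rng: np.random.Generator):
        self.bn1 = nn.BatchNorm1D(k)
        self.act1 = nn.ReLU()
        self.conv1 = nn.Conv1D(k, k, w, ar, rng)
        self.bn2 = nn.BatchNorm1D(k)
        self.act2 = nn.ReLU()
        self.conv2 = nn.Conv1D(k, k, w, ar, rng)
        self.layers = [self.bn1, self.act1, self.conv1, self.bn2, self.act2, self.conv2]

    def forward(self, x, train):
        h = self.conv1.forward(self.act1.forward(self.bn1.forward(x, train)))
        h = self.conv2.forward(self.act2.forward(self.bn2.forward(h, train)))
        return x + h

    def backward(self, dy):
        d = self.conv2.backward(dy)
        d = self.bn2.backward(self.act2.backward(d))
        d = self.conv1.backward(d)
        d = self.bn1.backward(self.act1.backward(d))
        return dy + d


class Network:
    """The full classifier; maps one-hot (N, B+2C, 4) to logits (N, B, 2)."""

    def __init__(self, config: ModelConfig, seed: int):
        rng = np.random.default_rng(seed)
        self.config = config
        k0 = config.blocks[0].k
        self.conv_in = nn.Conv1D(4, k0, 1, 1, rng)
        self.units: list[_ResidualUnit] = []
        self.block_of_unit: list[int] = []
        self.transitions: dict[int, nn.Conv1D] = {}
        c = k0
        for bi, spec in enumerate(config.blocks):
            if spec.k != c:
                self.transitions[bi] = nn.Conv1D(c, spec.k, 1, 1, rng)
                c = spec.k
            for _ in range(spec.r):
                self.units.append(_ResidualUnit(spec.k, spec.w, spec.ar, rng))
                self.block_of_unit.append(bi)
        k_skip = config.blocks[-1].k
        self.skips = [nn.Conv1D(k0, k_skip, 1, 1, rng)]
        self.skips += [nn.Conv1D(b.k, k_skip, 1, 1, rng) for b in config.blocks]
        self.conv_out = nn.Conv1D(k_skip, config.classes, 1, 1, rng)
        if config.margin > config.C:
            raise ConfigError(
                f"receptive field half-width {config.margin} exceeds context C={config.C}")

    # -- plumbing ----------------------------------------------------------
    def _all_layers(self):
        out = [self.conv_in]
        for u in self.units:
            out += u.layers
        out += list(self.transitions.values()) + self.skips + [self.conv_out]
        return out

    def params(self):
        return [p for l in self._all_layers() for p in l.params()]

    def grads(self):
        return [g for l in self._all_layers() for g in l.grads()]

    def weights_hash(self) -> str:
        import hashlib

        h = hashlib.sha256()
        for p in self.params():
            h.update(np.ascontiguousarray(p).tobytes())
        return h.hexdigest()

    # -- forward/backward --------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        C = self.config.C
        h = self.conv_in.forward(x)
        acc = self.skips[0].forward(h)
        self._bt_order = []
        prev_block = -1
        for ui, (u, bi) in enumerate(zip(self.units, self.block_of_unit)):
            if bi != prev_block and bi in self.transitions:
                h = self.transitions[bi].forward(h)
                self._bt_order.append(("t", bi))
            h = u.forward(h, train)
            self._bt_order.append(("u", ui))
            last_of_block = ui + 1 == len(self.units) or self.block_of_unit[ui + 1] != bi
            if last_of_block:
                acc = acc + self.skips[1 + bi].forward(h)
                self._bt_order.append(("s", bi))
            prev_block = bi
        logits = self.conv_out.forward(acc)
        self._full_len = logits.shape[1]
        return logits[:, C:self._full_len - C, :]

    def backward(self, dlogits_cropped: np.ndarray) -> None:
        C = self.config.C
        n, Bc, k = dlogits_cropped.shape
        dlogits = np.zeros((n, self._full_len, k))
        dlogits[:, C:C + Bc, :] = dlogits_cropped
        dacc = self.conv_out.backward(dlogits)
        dh = None
        for kind, idx in reversed(self._bt_order):
            if kind == "s":
                ds = self.skips[1 + idx].backward(dacc)
                dh = ds if dh is None else dh + ds
            elif kind == "u":
                dh = self.units[idx].backward(dh)
            else:  # transition conv
                dh = self.transitions[idx].backward(dh)
        dh = dh + self.skips[0].backward(dacc)
        self.conv_in.backward(dh)

    # -- scoring -----------------------------------------------------------
    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Softmax m6A-channel probabilities for the B central positions."""
        logits = self.forward(x, train=False)
        return nn.softmax(logits)[..., 1]


def build_network(config: ModelConfig, seed: int | None = None) -> Network:
    return Network(config, config.seed if seed is None else seed)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def train_member(blocks: list[BlockPair], config: ModelConfig, seed: int,
                 log: list | None = None) -> Network:
    if not blocks:
        raise ValueError("empty training dataset")
    net = Network(config, seed)
    opt = nn.Adam(net.params(), lr=config.lr_initial)
    rng = np.random.default_rng(seed + 1)
    X = np.stack([b.inputs for b in blocks])
    Y = np.stack([b.labels for b in blocks]).astype(np.int64)
    M = np.stack([b.mask for b in blocks])
    lrs = config.learning_rates()
    for epoch, lr in enumerate(lrs, start=1):
        opt.lr = lr
        order = rng.permutation(len(blocks))
        losses = []
        for s in range(0, len(blocks), config.batch_size):
            sel = order[s:s + config.batch_size]
            logits = net.forward(X[sel], train=True)
            loss, dlogits = nn.masked_cross_entropy(logits, Y[sel], M[sel])
            net.backward(dlogits)
            opt.step(net.grads())
            losses.append(loss)
        if log is not None:
            log.append({"epoch": epoch, "lr": lr, "loss": float(np.mean(losses))})
    return net


class EnsembleScorer:
    """Mean-of-members per-position m6A probability scorer.

    Satisfies the scorer contract: ``score(seq)`` returns one probability
    per position of ``seq``; ``margin`` is the receptive-field half-width
    so callers may rescore local subwindows after point mutations.
    """

    def __init__(self, members: list[Network], config: ModelConfig):
        if not members:
            raise ValueError("ensemble needs at least one member")
        self.members = members
        self.config = config

    @property
    def margin(self) -> int:
        return self.config.margin

    def _chunk(self, seq: str) -> tuple[np.ndarray, int]:
        B, C = self.config.B, self.config.C
        L = len(seq)
        n_blocks = max(1, -(-L // B))
        rows = []
        for i in range(n_blocks):
            w0, w1 = i * B - C, (i + 1) * B + C
            lo, hi = max(w0, 0), min(w1, L)
            rows.append("N" * (lo - w0) + seq[lo:hi] + "N" * (w1 - hi))
        X = np.stack([one_hot_encode(r) for r in rows])
        return X, L

    def member_scores(self, seq: str) -> np.ndarray:
        """(n_members, len(seq)) matrix of per-member probabilities."""
        X, L = self._chunk(seq)
        out = []
        for m in self.members:
            p = m.predict_proba(X)  # (n_blocks, B)
            out.append(p.reshape(-1)[:L])
        return np.asarray(out)

    def score(self, seq: str) -> np.ndarray:
        if len(seq) < 2 * self.config.margin + 1:
            raise ValueError("sequence shorter than the receptive field")
        return self.member_scores(seq).mean(axis=0)

    # -- persistence -------------------------------------------------------
    def save(self, path) -> None:
        arrays = {}
        for mi, m in enumerate(self.members):
            for pi, p in enumerate(m.params()):
                arrays[f"m{mi}_p{pi}"] = p
            bn = [l for u in m.units for l in u.layers if isinstance(l, nn.BatchNorm1D)]
            for bi, b in enumerate(bn):
                arrays[f"m{mi}_rm{bi}"] = b.running_mean
                arrays[f"m{mi}_rv{bi}"] = b.running_var
        np.savez(path, config=json.dumps(self.config.to_dict()),
                 n_members=len(self.members), **arrays)

    @classmethod
    def load(cls, path) -> "EnsembleScorer":
        data = np.load(path, allow_pickle=False)
        config = ModelConfig.from_dict(json.loads(str(data["config"])))
        members = []
        for mi in range(int(data["n_members"])):
            net = Network(config, seed=0)
            for pi, p in enumerate(net.params()):
                p[...] = data[f"m{mi}_p{pi}"]
            bn = [l for u in net.units for l in u.layers if isinstance(l, nn.BatchNorm1D)]
            for bi, b in enumerate(bn):
                b.running_mean = data[f"m{mi}_rm{bi}"]
                b.running_var = data[f"m{mi}_rv{bi}"]
            members.append(net)
        return cls(members, config)


def train_ensemble(blocks: list[BlockPair], config: ModelConfig,
                   log: list | None = None) -> EnsembleScorer:
    """Train ``ensemble_size`` members with distinct seeds and average them."""
    members = []
    for i in range(config.ensemble_size):
        member_log: list = []
        members.append(train_member(blocks, config, seed=config.seed + 1000 * i,
                                    log=member_log))
        if log is not None:
            log.append({"member": i, "epochs": member_log})
    return EnsembleScorer(members, config)


# ---------------------------------------------------------------------------
# scoring windows and sites
# ---------------------------------------------------------------------------

def score_window(scorer, window: PreMrnaWindow) -> np.ndarray:
    """Per-gene-body-position probabilities (flanks used as context only)."""
    probs = scorer.score(window.sequence)
    return probs[window.flank:window.flank + window.body_length]


def score_sites(scorer, window: PreMrnaWindow, mode: str = "RAC"):
    """Predictions restricted to consensus A positions, sorted by position."""
    import pandas as pd

    probs = scorer.score(window.sequence)
    rows = []
    for w in find_consensus_sites(window.sequence, mode):
        b = w - window.flank
        if not (0 <= b < window.body_length):
            continue
        rows.append({
            "gene_id": window.gene_id,
            "body_offset": b,
            "genomic_pos": window.to_genomic(w),
            "mode": mode,
            "probability": float(probs[w]),
        })
    return pd.DataFrame(rows, columns=["gene_id", "body_offset", "genomic_pos",
                                       "mode", "probability"])


def evaluate(y_true: np.ndarray, y_score: np.ndarray) -> dict[str, float]:
    """AUROC and AUPRC; raises on single-class input."""
    from sklearn.metrics import average_precision_score, roc_auc_score

    y_true = np.asarray(y_true)
    if len(np.unique(y_true)) < 2:
        raise ValueError("evaluation needs both classes present")
    return {
        "auroc": float(roc_auc_score(y_true, y_score)),
        "auprc": float(average_precision_score(y_true, y_score)),
    }
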
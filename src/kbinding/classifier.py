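"""Multi-label MLP binding predictor with k-binding-weighted sampling.

Architecture: embedded CDR3 sequence -> two hidden linear layers of 500 ReLU
units -> 7 linear outputs -> sigmoid, one binding probability per target.
The loss is the sum over targets of per-target binary cross-entropy,
minimized with Adam (learning rate 1e-4, weight decay 5e-4) for 10 epochs at
batch size 1028.

Class imbalance (non-binders vastly outnumber high-k binders) is handled by
stratified sampling with replacement: a k-binding stratum with n_k members
is sampled with per-example weight

    w_k = sqrt(n_0 / n_k)

so rarer, more cross-reactive strata are oversampled.  One epoch draws as
many examples as the dataset holds.

The network is implemented directly on numpy: forward/backward passes and
the Adam update are a few dense matrix products, which keeps training
bit-deterministic for a given seed and makes the sampling semantics exact.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

from .sequence_space import EmbeddingScheme, embed_many


@dataclass(frozen=True)
class ModelConfig:
    """Training hyperparameters (defaults are the reference settings)."""

    hidden_sizes: Tuple[int, ...] = (500, 500)
    output_dim: int = 7
    learning_rate: float = 1e-4
    weight_decay: float = 5e-4
    epochs: int = 10
    batch_size: int = 1028
    seed: int = 0

    def to_dict(self) -> Dict:
        return asdict(self)


@dataclass(frozen=True)
class StratumWeights:
    """Per-k sampling weights w_k = sqrt(n0 / n_k)."""

    weights: Dict[int, float]
    counts: Dict[int, int]

    @property
    def n0(self) -> int:
        return self.counts.get(0, 0)


def compute_stratum_weights(strata: Mapping[int, int]) -> StratumWeights:
    """w_k = sqrt(n0/n_k) for nonempty strata; empty strata get weight 0.

    Requires a nonempty k = 0 stratum (the weight formula is anchored on the
    non-binder count n0, so w_0 = 1 by construction).
    """
    n0 = int(strata.get(0, 0))
    if n0 == 0:
        raise ValueError("k=0 stratum is empty; stratum weights are undefined")
    weights = {
        int(k): (float(np.sqrt(n0 / nk)) if nk > 0 else 0.0)
        for k, nk in strata.items()
    }
    return StratumWeights(weights=weights, counts={int(k): int(v) for k, v in strata.items()})


def example_probabilities(k: np.ndarray, weights: StratumWeights) -> np.ndarray:
    """Per-example sampling probabilities proportional to w_{k(example)}."""
    w = np.array([weights.weights.get(int(ki), 0.0) for ki in k])
    total = w.sum()
    if total == 0:
        raise ValueError("all sampling weights are zero")
    return w / total


def weighted_sample_indices(
    k: np.ndarray, weights: StratumWeights, rng: np.random.Generator, size: int
) -> np.ndarray:
    """Draw ``size`` example indices with replacement, probability ∝ w_k."""
    return rng.choice(len(k), size=size, replace=True, p=example_probabilities(k, weights))


# ---------------------------------------------------------------------------
# the network
# ---------------------------------------------------------------------------

def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class MLP:
    """Two-hidden-layer ReLU perceptron with a 7-unit sigmoid head."""

    def __init__(self, input_dim: int, config: ModelConfig, rng: np.random.Generator):
        self.input_dim = int(input_dim)
        self.config = config
        sizes = [self.input_dim, *config.hidden_sizes, config.output_dim]
        self.W: List[np.ndarray] = []
        self.b: List[np.ndarray] = []
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
            # He initialization, appropriate for ReLU hidden units.
            std = np.sqrt(2.0 / fan_in)
            self.W.append(rng.normal(0.0, std, size=(fan_in, fan_out)).astype(np.float32))
            self.b.append(np.zeros(fan_out, dtype=np.float32))

    # -- forward --------------------------------------------------------
    def _forward(self, X: np.ndarray):
        acts = [X]
        h = X
        for Wl, bl in zip(self.W[:-1], self.b[:-1]):
            h = np.maximum(h @ Wl + bl, 0.0)
            acts.append(h)
        logits = h @ self.W[-1] + self.b[-1]
        return logits, acts

    def predict_logits(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float32)
        if X.ndim != 2 or X.shape[1] != self.input_dim:
            raise ValueError(
                f"expected input of width {self.input_dim}, got shape {X.shape}"
            )
        return self._forward(X)[0]

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Per-target binding probabilities in (0, 1)."""
        return _sigmoid(self.predict_logits(X).astype(np.float64))

    # -- training -------------------------------------------------------
    def fit(
        self,
        X: np.ndarray,
        y: np.ndarray,
        k: np.ndarray,
        rng: np.random.Generator,
    ) -> List[float]:
        """Train with stratum-weighted resampling; returns per-epoch losses."""
        cfg = self.config
        X = np.asarray(X, dtype=np.float32)
        y = np.asarray(y, dtype=np.float32)
        n = len(X)
        if y.shape != (n, cfg.output_dim):
            raise ValueError(f"labels must have shape ({n}, {cfg.output_dim})")
        strata = {int(kk): int(c) for kk, c in zip(*np.unique(k, return_counts=True))}
        if 0 not in strata:  # degenerate corpora (e.g. binder-only toys)
            probs = np.full(n, 1.0 / n)
        else:
            probs = example_probabilities(np.asarray(k), compute_stratum_weights(strata))

        mW = [np.zeros_like(w) for w in self.W]
        vW = [np.zeros_like(w) for w in self.W]
        mb = [np.zeros_like(b) for b in self.b]
        vb = [np.zeros_like(b) for b in self.b]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        t = 0
        losses: List[float] = []
        n_batches = max(1, int(np.ceil(n / cfg.batch_size)))
        for _epoch in range(cfg.epochs):
            draw = rng.choice(n, size=n, replace=True, p=probs)
            epoch_loss = 0.0
            for bi in range(n_batches):
                idx = draw[bi * cfg.batch_size : (bi + 1) * cfg.batch_size]
                if idx.size == 0:
                    continue
                Xb, yb = X[idx], y[idx]
                logits, acts = self._forward(Xb)
                p = _sigmoid(logits.astype(np.float64))
                # summed-over-targets binary cross-entropy, mean over batch
                eps_p = np.clip(p, 1e-12, 1 - 1e-12)
                loss = float(
                    -np.mean(
                        np.sum(yb * np.log(eps_p) + (1 - yb) * np.log(1 - eps_p), axis=1)
                    )
                )
                epoch_loss += loss * idx.size
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"non-finite training loss {loss} at epoch {_epoch}, "
                        f"batch {bi}; aborting"
                    )
                grad = ((p - yb) / idx.size).astype(np.float32)
                gW: List[np.ndarray] = [None] * len(self.W)  # type: ignore
                gb: List[np.ndarray] = [None] * len(self.b)  # type: ignore
                delta = grad
                for layer in range(len(self.W) - 1, -1, -1):
                    gW[layer] = acts[layer].T @ delta
                    gb[layer] = delta.sum(axis=0)
                    if layer > 0:
                        delta = (delta @ self.W[layer].T) * (acts[layer] > 0)
                t += 1
                lr_t = cfg.learning_rate * np.sqrt(1 - beta2**t) / (1 - beta1**t)
                for layer in range(len(self.W)):
                    g = gW[layer] + np.float32(cfg.weight_decay) * self.W[layer]
                    mW[layer] = beta1 * mW[layer] + (1 - beta1) * g
                    vW[layer] = beta2 * vW[layer] + (1 - beta2) * g * g
                    self.W[layer] -= lr_t * mW[layer] / (np.sqrt(vW[layer]) + eps)
                    g = gb[layer]
                    mb[layer] = beta1 * mb[layer] + (1 - beta1) * g
                    vb[layer] = beta2 * vb[layer] + (1 - beta2) * g * g
                    self.b[layer] -= lr_t * mb[layer] / (np.sqrt(vb[layer]) + eps)
            losses.append(epoch_loss / n)
        return losses


@dataclass
class TrainedModel:
    """A fitted MLP plus the metadata needed to reproduce it."""

    net: MLP
    config: ModelConfig
    scheme_name: str
    input_dim: int
    epoch_losses: List[float] = field(default_factory=list)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.net.predict_proba(X)

    def save(self, path) -> None:
        arrays = {}
        for i, (w, b) in enumerate(zip(self.net.W, self.net.b)):
            arrays[f"W{i}"] = w
            arrays[f"b{i}"] = b
        meta = json.dumps(
            {
                "config": self.config.to_dict(),
                "scheme": self.scheme_name,
                "input_dim": self.input_dim,
                "epoch_losses": self.epoch_losses,
            }
        )
        np.savez(path, __meta__=np.array(meta), **arrays)

    @classmethod
    def load(cls, path) -> "TrainedModel":
        data = np.load(path, allow_pickle=False)
        meta = json.loads(str(data["__meta__"]))
        cfg_d = meta["config"]
        cfg_d["hidden_sizes"] = tuple(cfg_d["hidden_sizes"])
        config = ModelConfig(**cfg_d)
        net = MLP(meta["input_dim"], config, np.random.default_rng(0))
        i = 0
        while f"W{i}" in data:
            net.W[i] = data[f"W{i}"]
            net.b[i] = data[f"b{i}"]
            i += 1
        return cls(net, config, meta["scheme"], meta["input_dim"], meta["epoch_losses"])


# ---------------------------------------------------------------------------
# profile-table front end
# ---------------------------------------------------------------------------

def make_xy(
    profiles: pd.DataFrame,
    targets: Sequence[str],
    scheme: EmbeddingScheme,
    sequence_column: str | None = None,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Embed a profile table into (X, y, k), in canonical row order.

    Rows are sorted by (sequence, label bits) so that training — whose
    sampler draws indices into this canonical order — is invariant to the
    incoming row order.  Masked tables may contain duplicate sequences with
    different labels; all rows are kept.
    """
    df = profiles.copy()
    if sequence_column is None:
        df["_seq"] = df["cdr3_alpha"].str.cat(df["cdr3_beta"])
    else:
        df["_seq"] = df[sequence_column]
    ycols = list(targets)
    df["_bits"] = df[ycols].to_numpy(dtype=int).dot(1 << np.arange(len(ycols)))
    df = df.sort_values(["_seq", "_bits"], kind="mergesort").reset_index(drop=True)
    X = embed_many(df["_seq"].tolist(), scheme)
    y = df[ycols].to_numpy(dtype=np.float32)
    k = df["k"].to_numpy(dtype=int) if "k" in df else y.sum(axis=1).astype(int)
    return X, y, k


def train(
    X: np.ndarray,
    y: np.ndarray,
    k: np.ndarray,
    config: ModelConfig,
    scheme_name: str = "",
) -> TrainedModel:
    """Train an MLP on embedded data; fully determined by ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    net = MLP(X.shape[1], config, rng)
    losses = net.fit(X, y, np.asarray(k), rng)
    return TrainedModel(net, config, scheme_name, X.shape[1], losses)
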
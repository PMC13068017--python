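"""Model/Results interface for attention-level classification.

:class:`AttentionClassifier` is constructed from a
:class:`~meanbci.features.FeatureSet` (or raw arrays) and an architecture
name; ``fit()`` trains with Adam + weight decay and returns an
:class:`AttentionClassifierResults` carrying the trained parameters,
training history, normalization statistics and diagnostics, with
``summary()``, ``predict()`` and channel-weight extraction.

Normalization is per-feature z-scoring with statistics computed from the
training data only; predicting before fitting (or loading) raises.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .core import DataError, STATE_ORDER
from .features import FeatureSet
from .models import MeanNetwork, build_network
from .nn import Adam, Tensor

__all__ = ["TrainConfig", "AttentionClassifier", "AttentionClassifierResults"]


@dataclass(frozen=True)
class TrainConfig:
    lr: float = 1e-3
    weight_decay: float = 1e-4
    batch_size: int = 64
    epochs: int = 30
    seed: int = 0


def _as_arrays(data, scalars=None, labels=None):
    if isinstance(data, FeatureSet):
        return data.freq_maps, data.scalars, data.labels, data.channel_names
    return (np.asarray(data, float), np.asarray(scalars, float),
            np.asarray(labels, dtype=object), None)


class AttentionClassifier:
    """Three-class attention-state classifier over fused feature instances."""

    def __init__(self, data, scalars=None, labels=None, arch: str = "mean",
                 config: TrainConfig | None = None,
                 class_order: tuple[str, ...] = STATE_ORDER):
        freq, scal, labs, ch_names = _as_arrays(data, scalars, labels)
        if freq.ndim != 3:
            raise DataError("freq maps must have shape (n, channels, columns)")
        self.freq = freq
        self.scalars = scal if scal is not None else np.zeros((freq.shape[0], 0))
        self.labels = labs
        self.channel_names = ch_names
        self.arch = arch
        self.config = config or TrainConfig()
        self.class_order = tuple(class_order)
        unknown = set(labs) - set(self.class_order)
        if unknown:
            raise DataError(f"labels outside the class set: {sorted(unknown)}")

    @classmethod
    def from_feature_set(cls, fs: FeatureSet, **kw) -> "AttentionClassifier":
        return cls(fs, **kw)

    # -- fitting ------------------------------------------------------------

    def fit(self, verbose: bool = False) -> "AttentionClassifierResults":
        cfg = self.config
        y = np.array([self.class_order.index(l) for l in self.labels])
        if len(np.unique(y)) < 2:
            raise DataError("training set must contain at least two classes")

        flat = np.concatenate(
            [self.freq.reshape(len(y), -1), self.scalars], axis=1
        )
        mu = flat.mean(axis=0)
        sd = flat.std(axis=0)
        sd[sd < 1e-12] = 1.0
        n_ch, n_cols = self.freq.shape[1], self.freq.shape[2]
        n_scal = self.scalars.shape[1]

        rng = np.random.default_rng(cfg.seed)
        net = build_network(self.arch, n_ch, n_cols, n_scal, rng)
        opt = Adam(net.parameters(), lr=cfg.lr, weight_decay=cfg.weight_decay)

        freq_n, scal_n = _normalize(self.freq, self.scalars, mu, sd)
        n = len(y)
        history = []
        for epoch in range(cfg.epochs):
            order = rng.permutation(n)
            losses = []
            for start in range(0, n, cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                fb = Tensor(freq_n[idx], requires_grad=False)
                sb = Tensor(scal_n[idx], requires_grad=False)
                logits = net(fb, sb)
                loss = logits.softmax_cross_entropy(y[idx])
                opt.zero_grad()
                loss.backward()
                opt.step()
                losses.append(float(loss.data))
            history.append(float(np.mean(losses)))
            if verbose:
                print(f"epoch {epoch + 1}/{cfg.epochs}  loss {history[-1]:.4f}")
        net.eval()
        return AttentionClassifierResults(
            model=self, network=net, norm_mean=mu, norm_sd=sd,
            history=history, class_order=self.class_order,
        )


def _normalize(freq, scalars, mu, sd):
    n = freq.shape[0]
    flat = np.concatenate([freq.reshape(n, -1), scalars], axis=1)
    flat = (flat - mu) / sd
    n_freq = freq.shape[1] * freq.shape[2]
    return (flat[:, :n_freq].reshape(freq.shape), flat[:, n_freq:])


@dataclass
class AttentionClassifierResults:
    """Trained classifier: parameters, history and inspection helpers."""

    model: AttentionClassifier
    network: object
    norm_mean: np.ndarray
    norm_sd: np.ndarray
    history: list[float]
    class_order: tuple[str, ...]

    def _check_fitted(self) -> None:
        if self.norm_mean is None or self.norm_sd is None:
            raise DataError("normalization statistics missing: train or load first")

    def predict_proba(self, freq: np.ndarray, scalars: np.ndarray,
                      batch: int = 256) -> np.ndarray:
        self._check_fitted()
        self.network.eval()
        freq_n, scal_n = _normalize(freq, scalars, self.norm_mean, self.norm_sd)
        out = []
        for start in range(0, freq.shape[0], batch):
            logits = self.network(
                Tensor(freq_n[start : start + batch]),
                Tensor(scal_n[start : start + batch]),
            )
            out.append(logits.softmax_probs())
        return np.concatenate(out, axis=0)

    def predict(self, data, scalars=None) -> np.ndarray:
        if isinstance(data, FeatureSet):
            freq, scal = data.freq_maps, data.scalars
        else:
            freq, scal = np.asarray(data, float), np.asarray(scalars, float)
        probs = self.predict_proba(freq, scal)
        return np.array([self.class_order[i] for i in probs.argmax(axis=1)], dtype=object)

    def extract_channel_weights(self, data, scalars=None) -> pd.DataFrame:
        """Per-channel attention-weight quantiles over a set of instances.

        Columns are min/q1/median/q3/max in the fixed fused channel order.
        Only meaningful for the MEAN architecture.
        """
        self._check_fitted()
        if not isinstance(self.network, MeanNetwork):
            raise DataError("channel weights are defined only for the MEAN architecture")
        if isinstance(data, FeatureSet):
            freq, scal, names = data.freq_maps, data.scalars, data.channel_names
        else:
            freq, scal = np.asarray(data, float), np.asarray(scalars, float)
            names = self.model.channel_names or tuple(
                f"ch{i}" for i in range(freq.shape[1])
            )
        self.network.eval()
        freq_n, scal_n = _normalize(freq, scal, self.norm_mean, self.norm_sd)
        weights = []
        for start in range(0, freq.shape[0], 256):
            self.network(Tensor(freq_n[start : start + 256]),
                         Tensor(scal_n[start : start + 256]))
            weights.append(self.network.channel_att.last_weights)
        w = np.concatenate(weights, axis=0)  # (n, channels)
        q = np.percentile(w, [0, 25, 50, 75, 100], axis=0)
        return pd.DataFrame(
            q.T, index=list(names), columns=["min", "q1", "median", "q3", "max"]
        )

    def summary(self) -> str:
        lines = [
            "Attention-level classifier results",
            "=" * 44,
            f"architecture:      {self.model.arch}",
            f"classes:           {', '.join(self.class_order)}",
            f"instances (train): {self.model.freq.shape[0]}",
            f"feature shape:     {self.model.freq.shape[1]} x {self.model.freq.shape[2]}"
            f" + {self.model.scalars.shape[1]} scalars",
            f"parameters:        {self.network.n_parameters()}",
            f"epochs:            {len(self.history)}",
            f"final train loss:  {self.history[-1]:.4f}" if self.history else "",
        ]
        return "\n".join(l for l in lines if l)

    # -- persistence --------------------------------------------------------

    def save(self, path: str | Path) -> None:
        path = Path(path)
        arrays = {f"p{i}": a for i, a in enumerate(self.network.state_arrays())}
        np.savez(
            path,
            norm_mean=self.norm_mean,
            norm_sd=self.norm_sd,
            history=np.asarray(self.history),
            meta=np.frombuffer(
                json.dumps({
                    "arch": self.model.arch,
                    "class_order": list(self.class_order),
                    "n_channels": int(self.model.freq.shape[1]),
                    "n_cols": int(self.model.freq.shape[2]),
                    "n_scalars": int(self.model.scalars.shape[1]),
                    "config": asdict(self.model.config),
                }).encode(), dtype=np.uint8),
            **arrays,
        )

    @staticmethod
    def load(path: str | Path) -> "AttentionClassifierResults":
        with np.load(Path(path), allow_pickle=False) as z:
            meta = json.loads(bytes(z["meta"]).decode())
            rng = np.random.default_rng(0)
            net = build_network(
                meta["arch"], meta["n_channels"], meta["n_cols"], meta["n_scalars"], rng
            )
            arrays = [z[f"p{i}"] for i in range(len(net.parameters()))]
            net.load_state_arrays(arrays)
            net.eval()
            dummy = AttentionClassifier(
                np.zeros((2, meta["n_channels"], meta["n_cols"])),
                np.zeros((2, meta["n_scalars"])),
                np.array([meta["class_order"][0], meta["class_order"][1]], dtype=object),
                arch=meta["arch"], config=TrainConfig(**meta["config"]),
                class_order=tuple(meta["class_order"]),
            )
            return AttentionClassifierResults(
                model=dummy, network=net,
                norm_mean=z["norm_mean"], norm_sd=z["norm_sd"],
                history=list(z["history"]), class_order=tuple(meta["class_order"]),
            )
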
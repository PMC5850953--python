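"""Phylogeny-aware convolutional network (Phylo-Conv layers + dense head).

The convolution here is not over a pixel grid but over the Euclidean
embedding of the phylogeny's leaves: for every meta-leaf the k nearest
meta-leaves (by embedded distance, self included first) are gathered and
convolved with a bank of filters.  After each Phylo-Conv layer the
meta-leaf coordinates are propagated as the unweighted centroid of the
gathered neighbours, so neighbourhoods remain defined for the next layer.
Neighbour indices and coordinates are data-independent and computed once,
before training.

The model is exposed statsmodels-style: build a :class:`PhyloCNN` from the
abundance matrix, labels and leaf coordinates, call :meth:`PhyloCNN.fit`,
and get a :class:`PhyloCNNResults` carrying the fitted weights, the
training history, ``summary()`` and ``adapt()`` (domain adaptation by
retraining a fresh output head with every other layer frozen).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd

from . import nn
from .embedding import LeafCoordinates

__all__ = [
    "PhyloCNNConfig",
    "NeighborIndex",
    "rank_neighbors",
    "update_coordinates",
    "phylo_conv_apply",
    "PhyloCNN",
    "PhyloCNNResults",
    "PhyloCNNClassifier",
]


@dataclass
class PhyloCNNConfig:
    """Hyperparameters of the phylogeny-aware CNN.

    Defaults follow the reference architecture: two Phylo-Conv layers of 16
    filters over 16 neighbours, max-pooling (window 2), a 64-unit dense
    layer with 0.25 dropout, SELU activations and Adam at learning rate
    5e-4.  For domain-adaptation runs the customary variant is ReLU
    activations, a 128-unit dense layer and a sigmoid head.
    """

    n_phyloconv_layers: int = 2
    n_filters: int = 16
    k_neighbors: int = 16
    dense_units: int = 64
    dropout_rate: float = 0.25
    conv_activation: str = "selu"
    dense_activation: str = "softmax"  # or "sigmoid" (binary head, 1 unit)
    learning_rate: float = 5e-4
    optimizer_name: str = "adam"
    pool_size: int = 2
    epochs: int = 100
    batch_size: int = 32
    early_stopping_patience: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_phyloconv_layers < 1:
            raise ValueError("need at least one Phylo-Conv layer")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.conv_activation not in nn.ACTIVATIONS:
            raise ValueError(f"unknown activation {self.conv_activation!r}")
        if self.dense_activation not in ("softmax", "sigmoid"):
            raise ValueError("dense_activation must be 'softmax' or 'sigmoid'")


@dataclass
class NeighborIndex:
    """k-nearest-neighbour table over meta-leaves.

    Row r lists the k nearest meta-leaves of meta-leaf r by embedded
    Euclidean distance, self first (distance zero), distance ties broken by
    ascending index for determinism.
    """

    idx: np.ndarray  # (m, k) integer

    def __post_init__(self) -> None:
        self.idx = np.asarray(self.idx, dtype=np.intp)
        m, k = self.idx.shape
        if np.any(self.idx < 0) or np.any(self.idx >= m):
            raise ValueError("neighbour indices out of range")
        if np.any(self.idx[:, 0] != np.arange(m)):
            raise ValueError("each row must start with self")
        for r in range(m):
            if len(set(self.idx[r])) != k:
                raise ValueError(f"duplicate neighbour in row {r}")

    @property
    def k(self) -> int:
        return self.idx.shape[1]

    @property
    def m(self) -> int:
        return self.idx.shape[0]


def rank_neighbors(coords: np.ndarray | LeafCoordinates, k: int) -> NeighborIndex:
    """k nearest neighbours of every meta-leaf, self first, ties by index."""
    pts = coords.coords if isinstance(coords, LeafCoordinates) else np.asarray(coords, float)
    m = pts.shape[0]
    if k > m:
        raise ValueError(f"k={k} exceeds number of meta-leaves {m}")
    diff = pts[:, None, :] - pts[None, :, :]
    d = np.sqrt(np.sum(diff**2, axis=-1))
    # self has distance exactly 0 but could tie with a coincident point of
    # lower index; force self to the front, then stable-sort the rest.
    np.fill_diagonal(d, -1.0)
    order = np.argsort(d, axis=1, kind="stable")  # ties broken by ascending index
    return NeighborIndex(order[:, :k])


def update_coordinates(coords: np.ndarray, nbr: NeighborIndex) -> np.ndarray:
    """Propagate coordinates to the next layer's meta-leaves.

    Each meta-leaf becomes a linear combination of the leaves it gathered;
    its coordinate is the unweighted centroid of its k neighbours'
    coordinates, fixed before training (data-independent).
    """
    pts = np.asarray(coords, float)
    if nbr.m != pts.shape[0]:
        raise ValueError("neighbour index inconsistent with coordinates")
    return pts[nbr.idx].mean(axis=1)


def phylo_conv_apply(
    channels: np.ndarray,
    nbr: NeighborIndex,
    weights: np.ndarray,
    bias: np.ndarray,
    activation: str = "linear",
) -> np.ndarray:
    """Apply one Phylo-Conv filter bank.

    ``channels`` is (n_samples, m, c_in); ``weights`` is (k, c_in,
    n_filters); output is (n_samples, m, n_filters) with
    ``out[s, r, f] = act(b_f + sum_{j,c} w[j,c,f] * channels[s, idx[r,j], c])``.
    """
    h = np.asarray(channels, float)
    w = np.asarray(weights, float)
    if h.ndim != 3:
        raise ValueError("channels must be (n_samples, m, c_in)")
    if nbr.m != h.shape[1]:
        raise ValueError("neighbour index inconsistent with channels")
    if w.shape[:2] != (nbr.k, h.shape[2]):
        raise ValueError("filter shape mismatch")
    gathered = h[:, nbr.idx, :]  # (n, m, k, c)
    z = np.einsum("nmkc,kcf->nmf", gathered, w) + bias
    act, _ = nn.ACTIVATIONS[activation]
    return act(z)


class _Net:
    """Internal trainable network: layers, forward/backward, Adam loop."""

    def __init__(self, config: PhyloCNNConfig, leaf_coords: np.ndarray, n_classes: int):
        cfg = config
        p = leaf_coords.shape[0]
        if cfg.k_neighbors > p:
            raise ValueError(f"k_neighbors={cfg.k_neighbors} exceeds n_features={p}")
        self.config = cfg
        self.n_classes = n_classes
        self.sigmoid_head = cfg.dense_activation == "sigmoid"
        if self.sigmoid_head and n_classes != 2:
            raise ValueError("sigmoid head requires exactly 2 classes")
        self.n_out = 1 if self.sigmoid_head else n_classes
        # precompute neighbour indices and propagated coordinates per layer
        self.neighbor_indices: list[NeighborIndex] = []
        self.layer_coords: list[np.ndarray] = [np.asarray(leaf_coords, float)]
        coords = self.layer_coords[0]
        for _ in range(cfg.n_phyloconv_layers):
            nbr = rank_neighbors(coords, cfg.k_neighbors)
            self.neighbor_indices.append(nbr)
            coords = update_coordinates(coords, nbr)
            self.layer_coords.append(coords)
        self.m = p
        self.m_pooled = p // cfg.pool_size
        if self.m_pooled < 1:
            raise ValueError("pooling collapses all meta-leaves")
        self.flat_dim = self.m_pooled * cfg.n_filters
        self.params: dict[str, np.ndarray] = {}
        self.frozen: set[str] = set()
        self.trained = False

    # -- parameters -----------------------------------------------------
    def init_params(self, rng: np.random.Generator) -> None:
        cfg = self.config
        c_in = 1
        for l in range(cfg.n_phyloconv_layers):
            fan_in = cfg.k_neighbors * c_in
            self.params[f"conv{l}_w"] = nn.glorot_uniform(
                rng, (cfg.k_neighbors, c_in, cfg.n_filters), fan_in, cfg.n_filters)
            self.params[f"conv{l}_b"] = np.zeros(cfg.n_filters)
            c_in = cfg.n_filters
        self.params["dense_w"] = nn.glorot_uniform(
            rng, (self.flat_dim, cfg.dense_units), self.flat_dim, cfg.dense_units)
        self.params["dense_b"] = np.zeros(cfg.dense_units)
        self.params["out_w"] = nn.glorot_uniform(
            rng, (cfg.dense_units, self.n_out), cfg.dense_units, self.n_out)
        self.params["out_b"] = np.zeros(self.n_out)

    def n_params(self, trainable_only: bool = False) -> int:
        items = self.params.items()
        return int(sum(v.size for k, v in items
                       if not (trainable_only and k in self.frozen)))

    # -- forward / backward ---------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None):
        cfg = self.config
        act, _ = nn.ACTIVATIONS[cfg.conv_activation]
        cache = {"h": [], "z": []}
        h = x[:, :, None]  # (n, m, 1)
        for l, nbr in enumerate(self.neighbor_indices):
            g = h[:, nbr.idx, :]  # (n, m, k, c)
            z = np.einsum("nmkc,kcf->nmf", g, self.params[f"conv{l}_w"]) \
                + self.params[f"conv{l}_b"]
            cache["h"].append(h)
            cache["z"].append(z)
            h = act(z)
        # max pool along meta-leaf axis, window = stride = pool_size
        n, m, f = h.shape
        mp = self.m_pooled
        pooled_in = h[:, : mp * cfg.pool_size, :].reshape(n, mp, cfg.pool_size, f)
        argmax = pooled_in.argmax(axis=2)
        pooled = np.take_along_axis(pooled_in, argmax[:, :, None, :], axis=2)[:, :, 0, :]
        cache["h_last"] = h
        cache["pool_argmax"] = argmax
        flat = pooled.reshape(n, -1)
        z1 = flat @ self.params["dense_w"] + self.params["dense_b"]
        a1 = act(z1)
        if train and cfg.dropout_rate > 0:
            mask = (rng.random(a1.shape) >= cfg.dropout_rate) / (1 - cfg.dropout_rate)
        else:
            mask = np.ones_like(a1)
        a1d = a1 * mask
        z2 = a1d @ self.params["out_w"] + self.params["out_b"]
        if self.sigmoid_head:
            probs = nn.sigmoid(z2)
        else:
            probs = nn.softmax(z2)
        cache.update(flat=flat, z1=z1, a1=a1, mask=mask, a1d=a1d, probs=probs)
        return probs, cache

    def loss(self, probs: np.ndarray, y_onehot: np.ndarray) -> float:
        eps = 1e-12
        if self.sigmoid_head:
            t = y_onehot[:, 1:2]
            return float(-np.mean(t * np.log(probs + eps)
                                  + (1 - t) * np.log(1 - probs + eps)))
        return float(-np.mean(np.sum(y_onehot * np.log(probs + eps), axis=1)))

    def backward(self, x: np.ndarray, y_onehot: np.ndarray, cache) -> dict:
        cfg = self.config
        _, dact = nn.ACTIVATIONS[cfg.conv_activation]
        n = x.shape[0]
        grads = {}
        if self.sigmoid_head:
            dz2 = (cache["probs"] - y_onehot[:, 1:2]) / n
        else:
            dz2 = (cache["probs"] - y_onehot) / n
        grads["out_w"] = cache["a1d"].T @ dz2
        grads["out_b"] = dz2.sum(axis=0)
        da1 = (dz2 @ self.params["out_w"].T) * cache["mask"]
        dz1 = da1 * dact(cache["z1"])
        grads["dense_w"] = cache["flat"].T @ dz1
        grads["dense_b"] = dz1.sum(axis=0)
        dflat = dz1 @ self.params["dense_w"].T
        mp, f = self.m_pooled, cfg.n_filters
        dpool = dflat.reshape(n, mp, f)
        dh = np.zeros_like(cache["h_last"])
        dwin = np.zeros((n, mp, cfg.pool_size, f))
        np.put_along_axis(dwin, cache["pool_argmax"][:, :, None, :],
                          dpool[:, :, None, :], axis=2)
        dh[:, : mp * cfg.pool_size, :] = dwin.reshape(n, mp * cfg.pool_size, f)
        for l in range(cfg.n_phyloconv_layers - 1, -1, -1):
            nbr = self.neighbor_indices[l]
            dz = dh * dact(cache["z"][l])
            g = cache["h"][l][:, nbr.idx, :]
            grads[f"conv{l}_w"] = np.einsum("nmkc,nmf->kcf", g, dz)
            grads[f"conv{l}_b"] = dz.sum(axis=(0, 1))
            dg = np.einsum("nmf,kcf->nmkc", dz, self.params[f"conv{l}_w"])
            dh_prev = np.zeros_like(cache["h"][l])
            np.add.at(dh_prev, (slice(None), nbr.idx), dg)
            dh = dh_prev
        return grads

    # -- training --------------------------------------------------------
    def fit(self, x: np.ndarray, y_onehot: np.ndarray,
            validation: tuple | None = None,
            verbose: bool = False) -> pd.DataFrame:
        cfg = self.config
        if np.isnan(x).any():
            raise ValueError("NaN in input matrix; clean the data before training")
        rng = np.random.default_rng(cfg.seed)
        if not self.params:
            self.init_params(rng)
        opt = nn.Adam(self.params, learning_rate=cfg.learning_rate)
        n = x.shape[0]
        rows = []
        best_val, best_params, patience = np.inf, None, 0
        for epoch in range(cfg.epochs):
            perm = rng.permutation(n)
            losses = []
            for start in range(0, n, cfg.batch_size):
                idx = perm[start:start + cfg.batch_size]
                probs, cache = self.forward(x[idx], train=True, rng=rng)
                losses.append(self.loss(probs, y_onehot[idx]))
                grads = self.backward(x[idx], y_onehot[idx], cache)
                opt.step(self.params, grads, frozen=self.frozen)
            row = {"epoch": epoch, "loss": float(np.mean(losses))}
            if validation is not None:
                vp, _ = self.forward(validation[0], train=False)
                row["val_loss"] = self.loss(vp, validation[1])
            rows.append(row)
            if verbose:
                print(f"epoch {epoch}: " + " ".join(f"{k}={v:.4f}" for k, v in row.items()
                                                    if k != "epoch"))
            if validation is not None and cfg.early_stopping_patience > 0:
                if row["val_loss"] < best_val - 1e-6:
                    best_val = row["val_loss"]
                    best_params = {k: v.copy() for k, v in self.params.items()}
                    patience = 0
                else:
                    patience += 1
                    if patience >= cfg.early_stopping_patience:
                        break
        if best_params is not None:
            self.params = best_params
        self.trained = True
        return pd.DataFrame(rows)


class PhyloCNN:
    """Phylogeny-aware CNN model bound to a dataset.

    Parameters
    ----------
    X:
        (n_samples, n_features) abundance matrix (array or DataFrame);
        features must be in the order of ``coords`` rows.
    y:
        per-sample class labels (any hashable values).
    coords:
        :class:`~phylocnn.embedding.LeafCoordinates` (or plain array) giving
        the Euclidean embedding of the features.
    config:
        :class:`PhyloCNNConfig`; defaults used when omitted.
    """

    def __init__(self, X, y, coords, config: PhyloCNNConfig | None = None):
        if isinstance(X, pd.DataFrame) and isinstance(coords, LeafCoordinates):
            coords = coords.reorder(list(X.columns))
        self.X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_, self.y_enc = np.unique(y, return_inverse=True)
        self.coords = coords.coords if isinstance(coords, LeafCoordinates) else np.asarray(coords, float)
        if self.coords.shape[0] != self.X.shape[1]:
            raise ValueError("coords rows must match feature count")
        self.config = config or PhyloCNNConfig()
        self.net = _Net(self.config, self.coords, n_classes=len(self.classes_))

    def _onehot(self, y_enc: np.ndarray) -> np.ndarray:
        out = np.zeros((len(y_enc), len(self.classes_)))
        out[np.arange(len(y_enc)), y_enc] = 1.0
        return out

    def fit(self, validation_data: tuple | None = None, verbose: bool = False) -> "PhyloCNNResults":
        val = None
        if validation_data is not None:
            xv, yv = validation_data
            yv_enc = np.searchsorted(self.classes_, np.asarray(yv))
            val = (np.asarray(xv, float), self._onehot(yv_enc))
        history = self.net.fit(self.X, self._onehot(self.y_enc), validation=val,
                               verbose=verbose)
        return PhyloCNNResults(self, history)

    @property
    def n_params(self) -> int:
        if not self.net.params:
            self.net.init_params(np.random.default_rng(self.config.seed))
        return self.net.n_params()


class PhyloCNNResults:
    """Fitted phylogeny-aware CNN: weights, history, prediction, adaptation."""

    def __init__(self, model: PhyloCNN, history: pd.DataFrame):
        self.model = model
        self.history = history
        self.params = model.net.params  # live reference to fitted weights

    def predict_proba(self, X) -> np.ndarray:
        probs, _ = self.model.net.forward(np.asarray(X, float), train=False)
        if self.model.net.sigmoid_head:
            return np.hstack([1 - probs, probs])
        return probs

    def predict(self, X) -> np.ndarray:
        return self.model.classes_[self.predict_proba(X).argmax(axis=1)]

    def score_mcc(self, X, y) -> float:
        from .dap import mcc, confusion_from_labels
        return mcc(confusion_from_labels(np.asarray(y), self.predict(X),
                                         classes=self.model.classes_))

    def summary(self) -> str:
        net, cfg = self.model.net, self.model.config
        lines = ["Phylogeny-aware CNN results",
                 "=" * 44,
                 f"{'n_samples':<28}{self.model.X.shape[0]:>16}",
                 f"{'n_features (leaves)':<28}{self.model.X.shape[1]:>16}",
                 f"{'n_classes':<28}{len(self.model.classes_):>16}",
                 f"{'Phylo-Conv layers':<28}{cfg.n_phyloconv_layers:>16}",
                 f"{'filters / neighbours':<28}{f'{cfg.n_filters} / {cfg.k_neighbors}':>16}",
                 f"{'dense units':<28}{cfg.dense_units:>16}",
                 f"{'activation':<28}{cfg.conv_activation:>16}",
                 f"{'head':<28}{cfg.dense_activation:>16}",
                 f"{'optimizer (lr)':<28}{f'{cfg.optimizer_name} ({cfg.learning_rate})':>16}",
                 f"{'total parameters':<28}{net.n_params():>16}",
                 f"{'trainable parameters':<28}{net.n_params(trainable_only=True):>16}",
                 f"{'epochs run':<28}{len(self.history):>16}",
                 f"{'final training loss':<28}{self.history['loss'].iloc[-1]:>16.4f}"]
        if "val_loss" in self.history:
            lines.append(f"{'final validation loss':<28}{self.history['val_loss'].iloc[-1]:>16.4f}")
        return "\n".join(lines)

    def save(self, path: str) -> None:
        """Save weights (.npz) and a JSON sidecar with config and classes."""
        np.savez(path, **self.params)
        meta = {"config": asdict(self.model.config),
                "classes": self.model.classes_.tolist()}
        with open(str(path) + ".json", "w") as fh:
            json.dump(meta, fh, indent=2)

    def adapt(self, X_new, y_new, n_new_classes: int | None = None,
              config: PhyloCNNConfig | None = None,
              validation_data: tuple | None = None) -> "PhyloCNNResults":
        """Domain adaptation: freeze everything, retrain a fresh output head.

        All Phylo-Conv and dense weights are frozen (bit-identical after
        retraining); the output layer is replaced by a freshly initialised
        head sized for the new task and is the only thing trained.
        """
        if not self.model.net.trained:
            warnings.warn("adapting an untrained model", stacklevel=2)
        base_cfg = config or self.model.config
        new_model = PhyloCNN(X_new, y_new, self.model.coords, config=base_cfg)
        if n_new_classes is not None and len(new_model.classes_) != n_new_classes:
            raise ValueError("n_new_classes inconsistent with labels in y_new")
        net = new_model.net
        rng = np.random.default_rng(base_cfg.seed)
        net.init_params(rng)
        for k, v in self.params.items():
            if not k.startswith("out_"):
                net.params[k] = v.copy()
        net.frozen = {k for k in net.params if not k.startswith("out_")}
        val = None
        if validation_data is not None:
            xv, yv = validation_data
            yv_enc = np.searchsorted(new_model.classes_, np.asarray(yv))
            val = (np.asarray(xv, float), new_model._onehot(yv_enc))
        history = net.fit(new_model.X, new_model._onehot(new_model.y_enc),
                          validation=val)
        return PhyloCNNResults(new_model, history)


class PhyloCNNClassifier:
    """scikit-learn-flavoured wrapper so the CNN plugs into the DAP.

    Holds the full-feature coordinates; when the protocol fits on a feature
    subset it passes ``feature_indices`` and the matching coordinate rows
    are used.
    """

    def __init__(self, coords, config: PhyloCNNConfig | None = None):
        self.full_coords = coords.coords if isinstance(coords, LeafCoordinates) else np.asarray(coords, float)
        self.config = config or PhyloCNNConfig()
        self.results_: PhyloCNNResults | None = None

    def fit(self, X, y, feature_indices=None):
        coords = self.full_coords if feature_indices is None else self.full_coords[feature_indices]
        cfg = self.config
        if cfg.k_neighbors > coords.shape[0]:
            cfg = replace(cfg, k_neighbors=coords.shape[0])
        model = PhyloCNN(X, y, coords, config=cfg)
        self.results_ = model.fit()
        return self

    def predict(self, X):
        return self.results_.predict(X)
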
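"""Burst grouping, feature extraction, and SOM-based load classification.

Spikes separated by less than 2.5 s belong to the same burst. Each burst
with at least ``min_spikes`` spikes is described by the three-dimensional
feature vector

    y = [log10 spike count, log10 mean ISI (s), SD of ISIs (s)]

normalized against a reference corpus of burst features,

    y' = (y - x_bar) / sigma_x * w,        w = [2, 2, 1]  (element-wise)

and classified by the best-matching node (Euclidean distance in y' space) of
a self-organizing map trained on the normalized reference corpus; the burst
inherits the load class (low / medium / high) of that node.

The normalization and classifier follow the scikit-learn estimator protocol
(`fit` / `transform` / `predict`, fitted attributes with trailing
underscores) so they compose with sklearn tooling.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

CLASS_ORDER = ("low", "medium", "high")
DEFAULT_WEIGHTS = (2.0, 2.0, 1.0)
FEATURE_NAMES = ("log10_count", "log10_mean_isi", "isi_sd")


@dataclass
class Burst:
    """A grouped run of spikes; features defined when n_spikes >= 3."""

    spike_times: np.ndarray
    features: np.ndarray | None = None
    label: str | None = None            # load class once classified
    sub_session: str | None = None

    def __post_init__(self) -> None:
        self.spike_times = np.asarray(self.spike_times, dtype=float)

    @property
    def start_s(self) -> float:
        return float(self.spike_times[0])

    @property
    def end_s(self) -> float:
        return float(self.spike_times[-1])

    @property
    def duration_s(self) -> float:
        """First-to-last-spike duration, the definition used by the
        high-load burst ratio."""
        return self.end_s - self.start_s

    @property
    def n_spikes(self) -> int:
        return int(self.spike_times.size)


def group_bursts(spike_times: np.ndarray, max_isi_s: float = 2.5,
                 min_spikes: int = 3,
                 strict: bool = True) -> tuple[list[Burst], np.ndarray]:
    """Partition sorted spike times into bursts at the 2.5 s ISI threshold.

    Maximal runs of consecutive spikes whose successive gaps are below
    ``max_isi_s`` (strictly below by default) form one burst; runs shorter
    than ``min_spikes`` are returned as loose, non-burst spikes — they still
    count toward the epileptic spike rate, but carry no feature vector.

    Returns ``(bursts, loose_spike_times)``.
    """
    t = np.asarray(spike_times, dtype=float)
    if np.any(np.diff(t) < 0):
        raise ValueError("spike_times must be sorted")
    if t.size == 0:
        return [], np.empty(0)
    gaps = np.diff(t)
    brk = gaps < max_isi_s if strict else gaps <= max_isi_s
    edges = np.flatnonzero(~brk) + 1
    runs = np.split(t, edges)
    bursts, loose = [], []
    for run in runs:
        if run.size >= min_spikes:
            b = Burst(run)
            if run.size >= 3:
                b.features = compute_features(b)
            bursts.append(b)
        else:
            loose.append(run)
    loose_t = np.concatenate(loose) if loose else np.empty(0)
    return bursts, loose_t


def compute_features(burst: Burst, ddof: int = 1) -> np.ndarray:
    """[log10 n_spikes, log10 mean ISI, SD of ISIs] for one burst.

    Sample SD (``ddof=1``) by default: small bursts dominate and the sample
    SD is the conservative convention.
    """
    if burst.n_spikes < 3:
        raise ValueError("feature vector requires at least 3 spikes "
                         "(>= 2 ISIs for an SD)")
    isis = np.diff(burst.spike_times)
    return np.array([
        np.log10(burst.n_spikes),
        np.log10(isis.mean()),
        isis.std(ddof=ddof),
    ])


def features_table(bursts: list[Burst]) -> pd.DataFrame:
    """Feature matrix of classifiable bursts as a DataFrame."""
    rows = [b.features for b in bursts if b.features is not None]
    return pd.DataFrame(rows, columns=list(FEATURE_NAMES))


class ReferenceScaler:
    """Weighted z-normalization against a reference burst corpus.

    ``transform`` maps y to (y − x̄)/σx · w element-wise, where x̄ and σx are
    the per-dimension mean and sample SD of the reference feature vectors
    and w defaults to [2, 2, 1]; the weights enter the feature space itself,
    so the subsequent Euclidean matching is weight-aware.
    """

    def __init__(self, weights=DEFAULT_WEIGHTS, ddof: int = 1):
        self.weights = weights
        self.ddof = ddof

    def get_params(self, deep: bool = True) -> dict:
        return {"weights": self.weights, "ddof": self.ddof}

    def set_params(self, **params) -> "ReferenceScaler":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X, y=None) -> "ReferenceScaler":
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] < 2:
            raise ValueError("need a 2-D corpus with at least 2 vectors")
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (X.shape[1],):
            raise ValueError(
                f"weights length {w.size} != {X.shape[1]} feature dims")
        self.mean_ = X.mean(axis=0)
        self.scale_ = X.std(axis=0, ddof=self.ddof)
        for d in np.flatnonzero(self.scale_ == 0):
            raise ValueError(
                f"zero variance in reference dimension {d} "
                f"({FEATURE_NAMES[d] if d < len(FEATURE_NAMES) else d})")
        self.weights_ = w
        return self

    def transform(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return (X - self.mean_) / self.scale_ * self.weights_

    def fit_transform(self, X, y=None) -> np.ndarray:
        return self.fit(X).transform(X)

    def inverse_transform(self, Xn) -> np.ndarray:
        Xn = np.atleast_2d(np.asarray(Xn, dtype=float))
        return Xn / self.weights_ * self.scale_ + self.mean_


# convenience aliases matching the procedural view of the pipeline
def fit_reference_stats(reference_features, weights=DEFAULT_WEIGHTS,
                        ddof: int = 1) -> ReferenceScaler:
    """Fit x̄, σx, w on the reference corpus (see :class:`ReferenceScaler`)."""
    return ReferenceScaler(weights, ddof).fit(np.asarray(reference_features))


def normalize_features(y, stats: ReferenceScaler) -> np.ndarray:
    """Apply y' = (y − x̄)/σx · w; vectorized over rows."""
    out = stats.transform(y)
    return out[0] if np.asarray(y).ndim == 1 else out


# ---------------------------------------------------------------------------
# self-organizing map


def _hex_positions(rows: int, cols: int) -> np.ndarray:
    """Node coordinates on a hexagonal (offset-row) grid, row-major order."""
    pos = np.zeros((rows * cols, 2))
    for r in range(rows):
        for c in range(cols):
            pos[r * cols + c] = (c + 0.5 * (r % 2), r * np.sqrt(3) / 2)
    return pos


def train_som(X: np.ndarray, grid_shape: tuple[int, int] = (10, 10),
              epochs: int = 50, lr: tuple[float, float] = (0.5, 0.01),
              seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Online Kohonen training on a hexagonal grid.

    Prototypes are initialized from random corpus samples; the learning rate
    and the Gaussian neighborhood radius decay linearly over epochs (radius
    from half the grid diagonal to 0.5). Returns ``(prototypes, positions)``
    with prototypes in row-major node order. Deterministic per seed.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] == 0:
        raise ValueError("training corpus must be a non-empty 2-D array")
    rows, cols = grid_shape
    if rows < 2 or cols < 2:
        raise ValueError("grid must be at least 2x2")
    n_nodes = rows * cols
    rng = np.random.default_rng(seed)
    protos = X[rng.integers(0, X.shape[0], n_nodes)].copy()
    protos += 1e-6 * rng.standard_normal(protos.shape)
    pos = _hex_positions(rows, cols)
    pos_d2 = ((pos[:, None, :] - pos[None, :, :]) ** 2).sum(-1)
    r0 = 0.5 * np.sqrt(rows ** 2 + cols ** 2)
    total = epochs * X.shape[0]
    step = 0
    for _ in range(epochs):
        for i in rng.permutation(X.shape[0]):
            frac = step / max(total - 1, 1)
            eta = lr[0] + (lr[1] - lr[0]) * frac
            radius = r0 + (0.5 - r0) * frac
            bmu = int(np.argmin(((protos - X[i]) ** 2).sum(1)))
            h = np.exp(-pos_d2[bmu] / (2.0 * radius ** 2))
            protos += eta * h[:, None] * (X[i] - protos)
            step += 1
    return protos, pos


def quantization_error(X: np.ndarray, prototypes: np.ndarray) -> float:
    """Mean distance from each vector to its best-matching prototype."""
    d = np.linalg.norm(X[:, None, :] - prototypes[None, :, :], axis=2)
    return float(d.min(axis=1).mean())


def assign_node_classes(prototypes: np.ndarray, scaler: ReferenceScaler,
                        count_thresholds: tuple[float, float] = (12.0, 80.0),
                        X_ref: np.ndarray | None = None,
                        y_ref: np.ndarray | None = None,
                        ) -> tuple[np.ndarray, list[str]]:
    """Label every SOM node low / medium / high.

    In label mode (reference features and labels given), each node takes the
    majority class of the reference vectors mapping to it; nodes with no
    mapped vectors fall back to the threshold rule on the back-transformed
    prototype spike count (cut points ``count_thresholds``, strict <).
    Returns ``(node_classes, log_messages)``.
    """
    lo_cut, hi_cut = count_thresholds
    if not lo_cut < hi_cut:
        raise ValueError("count_thresholds must be increasing")
    n_nodes = prototypes.shape[0]
    back = scaler.inverse_transform(prototypes)
    counts = 10.0 ** back[:, 0]
    by_threshold = np.where(counts < lo_cut, "low",
                            np.where(counts < hi_cut, "medium", "high"))
    log: list[str] = []
    if X_ref is None or y_ref is None:
        return by_threshold.astype(object), log
    y_ref = np.asarray(y_ref)
    d = np.linalg.norm(np.asarray(X_ref)[:, None, :] - prototypes[None],
                       axis=2)
    bmus = d.argmin(axis=1)
    classes = np.empty(n_nodes, dtype=object)
    for node in range(n_nodes):
        labels = y_ref[bmus == node]
        if labels.size == 0:
            classes[node] = by_threshold[node]
            log.append(f"node {node}: no mapped reference vectors, "
                       f"threshold fallback -> {by_threshold[node]}")
        else:
            vals, n = np.unique(labels, return_counts=True)
            classes[node] = vals[np.argmax(n)]
    return classes, log


def classify_burst(y_norm: np.ndarray, prototypes: np.ndarray,
                   node_classes: np.ndarray) -> str:
    """Class of the nearest prototype (Euclidean); ties -> lowest node index."""
    y_norm = np.asarray(y_norm, dtype=float)
    if not np.all(np.isfinite(y_norm)):
        raise ValueError("non-finite normalized feature vector")
    d2 = ((prototypes - y_norm) ** 2).sum(axis=1)
    return str(node_classes[int(np.argmin(d2))])


class SOMBurstClassifier:
    """Reference-normalized SOM classifier for burst load classes.

    ``fit(X, y)`` takes the *raw* reference feature vectors (and optionally
    their class labels): it fits the reference normalization, trains the SOM
    on the normalized corpus, and labels every node (majority reference
    label, else spike-count thresholds). ``predict(X)`` normalizes raw burst
    features with the fitted reference statistics and returns the class of
    each best-matching node.
    """

    def __init__(self, grid_shape=(10, 10), epochs: int = 50,
                 lr=(0.5, 0.01), weights=DEFAULT_WEIGHTS,
                 count_thresholds=(12.0, 80.0), random_state: int = 0):
        self.grid_shape = grid_shape
        self.epochs = epochs
        self.lr = lr
        self.weights = weights
        self.count_thresholds = count_thresholds
        self.random_state = random_state

    def get_params(self, deep: bool = True) -> dict:
        return {k: getattr(self, k) for k in
                ("grid_shape", "epochs", "lr", "weights",
                 "count_thresholds", "random_state")}

    def set_params(self, **params) -> "SOMBurstClassifier":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X, y=None) -> "SOMBurstClassifier":
        X = np.asarray(X, dtype=float)
        self.scaler_ = ReferenceScaler(self.weights).fit(X)
        Xn = self.scaler_.transform(X)
        self.prototypes_, self.positions_ = train_som(
            Xn, tuple(self.grid_shape), self.epochs, tuple(self.lr),
            self.random_state)
        self.node_classes_, self.fit_log_ = assign_node_classes(
            self.prototypes_, self.scaler_, tuple(self.count_thresholds),
            Xn, y if y is None else np.asarray(y))
        self.quantization_error_ = quantization_error(Xn, self.prototypes_)
        return self

    def predict(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        Xn = self.scaler_.transform(X)
        d = np.linalg.norm(Xn[:, None, :] - self.prototypes_[None], axis=2)
        return self.node_classes_[d.argmin(axis=1)].astype(object)

    def classify_bursts(self, bursts: list[Burst]) -> list[Burst]:
        """Attach a load class to every burst that has a feature vector."""
        feats = [b.features for b in bursts if b.features is not None]
        if feats:
            labels = iter(self.predict(np.vstack(feats)))
            for b in bursts:
                if b.features is not None:
                    b.label = str(next(labels))
        return bursts

    # -- portable JSON serialization -------------------------------------
    def to_json(self, path: str | Path) -> None:
        obj = {
            "format": "lfpburst-som/1",
            "params": {k: (list(v) if isinstance(v, tuple) else v)
                       for k, v in self.get_params().items()},
            "mean": self.scaler_.mean_.tolist(),
            "scale": self.scaler_.scale_.tolist(),
            "weights": self.scaler_.weights_.tolist(),
            "prototypes": self.prototypes_.tolist(),
            "node_classes": list(map(str, self.node_classes_)),
        }
        Path(path).write_text(json.dumps(obj))

    @classmethod
    def from_json(cls, path: str | Path) -> "SOMBurstClassifier":
        obj = json.loads(Path(path).read_text())
        if obj.get("format") != "lfpburst-som/1":
            raise ValueError("unrecognized SOM model file format")
        model = cls(**{k: (tuple(v) if isinstance(v, list) else v)
                       for k, v in obj["params"].items()})
        model.scaler_ = ReferenceScaler(tuple(obj["weights"]))
        model.scaler_.mean_ = np.asarray(obj["mean"])
        model.scaler_.scale_ = np.asarray(obj["scale"])
        model.scaler_.weights_ = np.asarray(obj["weights"])
        model.prototypes_ = np.asarray(obj["prototypes"])
        model.positions_ = _hex_positions(*model.grid_shape)
        model.node_classes_ = np.asarray(obj["node_classes"], dtype=object)
        return model
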
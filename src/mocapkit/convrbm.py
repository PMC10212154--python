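"""Convolutional restricted Boltzmann machine over per-frame point clouds.

The visible layer is the 3-channel, 32-position point-cloud slab of one
frame (or a stack of ``temporal_window`` consecutive frames, concatenated
along the channel axis). Hidden units are Bernoulli and organized as K
filters slid along the position axis in valid mode. Two visible-unit
types are supported:

* ``gaussian`` (default, used for real point clouds): quadratic visible
  term, energy ``E = sum (v - b_v)^2 / 2 - sum h b_h - sum h (W * v)``;
* ``bernoulli`` (used for enumerable toy models and exact-likelihood
  checks): linear visible term ``-sum v b_v``.

An optional autoregressive conditioning of order ``m`` adds linear
history terms to both bias sets; with ``m = 0`` the model is exactly a
plain (conv)RBM.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "ConvRBMModel",
    "Embedding",
    "SimilarityConfig",
    "init_model",
    "rbm_energy",
    "hidden_conditional",
    "visible_conditional",
    "free_energy",
    "train_cd",
    "encode",
    "find_similar_frames",
    "standardize",
    "auto_threshold",
]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


@dataclass
class ConvRBMModel:
    """Parameters of the convolutional RBM.

    ``filters`` has shape (K, C, w): K kernels of width w over C input
    channels; ``visible_bias`` has shape (C, P) with P the number of
    positions (32 for a single-frame point cloud); ``hidden_bias`` one
    scalar per filter (shared across positions). ``history_filters``
    holds the autoregressive bias maps (order m; empty arrays when m=0).
    """

    filters: np.ndarray  # (K, C, w)
    hidden_bias: np.ndarray  # (K,)
    visible_bias: np.ndarray  # (C, P)
    temporal_window: int = 1
    history_order: int = 0
    pool: int = 0  # 0 -> global max-pool at encode time
    visible_type: str = "gaussian"
    history_visible: np.ndarray = field(default_factory=lambda: np.zeros(0))
    history_hidden: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def __post_init__(self) -> None:
        self.filters = np.asarray(self.filters, dtype=float)
        self.hidden_bias = np.asarray(self.hidden_bias, dtype=float)
        self.visible_bias = np.asarray(self.visible_bias, dtype=float)
        K, C, w = self.filters.shape
        if K < 1:
            raise ValueError("need at least one filter")
        if w > self.visible_bias.shape[1]:
            raise ValueError("kernel width exceeds the position axis")
        if self.hidden_bias.shape != (K,):
            raise ValueError("hidden_bias must have one entry per filter")
        if self.visible_bias.shape[0] != C:
            raise ValueError("visible_bias channels must match filters")
        if self.visible_type not in ("gaussian", "bernoulli"):
            raise ValueError(f"unknown visible_type {self.visible_type!r}")
        if self.history_order < 0 or self.temporal_window < 1:
            raise ValueError("history_order >= 0 and temporal_window >= 1 required")

    @property
    def n_filters(self) -> int:
        return int(self.filters.shape[0])

    @property
    def n_positions(self) -> int:
        return int(self.visible_bias.shape[1])

    @property
    def n_hidden_positions(self) -> int:
        return self.n_positions - int(self.filters.shape[2]) + 1

    def copy(self) -> "ConvRBMModel":
        return replace(
            self,
            filters=self.filters.copy(),
            hidden_bias=self.hidden_bias.copy(),
            visible_bias=self.visible_bias.copy(),
            history_visible=self.history_visible.copy(),
            history_hidden=self.history_hidden.copy(),
        )


@dataclass
class Embedding:
    """Low-dimensional per-frame feature vectors (F x D, D < 96)."""

    vectors: np.ndarray
    source: str = ""

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.ndim != 2:
            raise ValueError("vectors must be (F, D)")
        if self.vectors.shape[1] >= 96:
            raise ValueError("embedding dimension must be below 96")
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("embedding contains non-finite entries")

    @property
    def n_frames(self) -> int:
        return int(self.vectors.shape[0])

    @property
    def dim(self) -> int:
        return int(self.vectors.shape[1])


@dataclass(frozen=True)
class SimilarityConfig:
    """Threshold + temporal-exclusion settings for similar-frame search."""

    threshold: float
    exclusion: int = 10

    def __post_init__(self) -> None:
        if self.threshold < 0:
            raise ValueError("threshold must be non-negative")
        if self.exclusion < 1:
            raise ValueError("exclusion must be at least 1")


def init_model(
    n_filters: int = 8,
    kernel_width: int = 5,
    n_channels: int = 3,
    n_positions: int = 32,
    temporal_window: int = 1,
    history_order: int = 0,
    visible_type: str = "gaussian",
    scale: float = 0.01,
    seed: int | np.random.Generator = 0,
) -> ConvRBMModel:
    """Random small-weight initialization, deterministic given the seed."""
    rng = np.random.default_rng(seed)
    C = n_channels * temporal_window
    return ConvRBMModel(
        filters=scale * rng.standard_normal((n_filters, C, kernel_width)),
        hidden_bias=np.zeros(n_filters),
        visible_bias=np.zeros((C, n_positions)),
        temporal_window=temporal_window,
        history_order=history_order,
        visible_type=visible_type,
        history_visible=(
            scale * rng.standard_normal((history_order, C, n_positions))
            if history_order
            else np.zeros(0)
        ),
        history_hidden=(
            scale * rng.standard_normal((history_order, n_filters))
            if history_order
            else np.zeros(0)
        ),
    )


def _dynamic_biases(
    model: ConvRBMModel, history: np.ndarray | None
) -> tuple[np.ndarray, np.ndarray]:
    """Visible (C, P) and hidden (K,) biases, with AR history terms added.

    ``history`` is (m, C, P): the m preceding slabs, most recent first.
    With ``history_order = 0`` (or no history given) these are exactly the
    static biases, so the conditional distributions reduce to the plain
    RBM's.
    """
    b_vis = model.visible_bias
    b_hid = model.hidden_bias
    if model.history_order and history is not None:
        hist = np.asarray(history, dtype=float)
        if hist.shape[0] != model.history_order:
            raise ValueError("history depth must equal history_order")
        # element-wise visible history maps; per-filter hidden terms driven
        # by each history slab's mean activation
        b_vis = b_vis + np.sum(model.history_visible * hist, axis=0)
        b_hid = b_hid + model.history_hidden.T @ hist.mean(axis=(1, 2))
    return b_vis, b_hid


def _correlate_valid(filters: np.ndarray, visible: np.ndarray) -> np.ndarray:
    """(K, C, w) filters against a (C, P) slab -> (K, P - w + 1) map."""
    K, C, w = filters.shape
    P = visible.shape[1]
    windows = np.lib.stride_tricks.sliding_window_view(visible, w, axis=1)  # (C, P-w+1, w)
    return np.einsum("kcw,cpw->kp", filters, windows)


def _correlate_full_T(filters: np.ndarray, hidden: np.ndarray, P: int) -> np.ndarray:
    """Transpose op: spread a (K, P-w+1) hidden map back to a (C, P) slab."""
    K, C, w = filters.shape
    out = np.zeros((C, P))
    for d in range(w):
        out[:, d : d + hidden.shape[1]] += np.einsum("kc,kp->cp", filters[:, :, d], hidden)
    return out


def _check_slab(model: ConvRBMModel, visible: np.ndarray) -> np.ndarray:
    v = np.asarray(visible, dtype=float)
    expected = (model.visible_bias.shape[0], model.n_positions)
    if v.shape != expected:
        raise ValueError(f"visible slab has shape {v.shape}, expected {expected}")
    return v


def rbm_energy(
    model: ConvRBMModel,
    visible: np.ndarray,
    hidden: np.ndarray,
    history: np.ndarray | None = None,
) -> float:
    """Joint energy E(v, h) of one visible slab and one hidden-state map."""
    v = _check_slab(model, visible)
    h = np.asarray(hidden, dtype=float)
    if h.shape != (model.n_filters, model.n_hidden_positions):
        raise ValueError(
            f"hidden states have shape {h.shape}, expected "
            f"{(model.n_filters, model.n_hidden_positions)}"
        )
    b_vis, b_hid = _dynamic_biases(model, history)
    if model.visible_type == "gaussian":
        vis_term = 0.5 * np.sum((v - b_vis) ** 2)
    else:
        vis_term = -np.sum(v * b_vis)
    act = _correlate_valid(model.filters, v)
    return float(vis_term - np.sum(h * b_hid[:, None]) - np.sum(h * act))


def hidden_conditional(
    model: ConvRBMModel, visible: np.ndarray, history: np.ndarray | None = None
) -> np.ndarray:
    """P(h = 1 | v) per hidden unit, shape (K, P - w + 1); all in (0, 1)."""
    v = _check_slab(model, visible)
    if not np.all(np.isfinite(v)):
        raise ValueError("visible slab contains non-finite values")
    _, b_hid = _dynamic_biases(model, history)
    return _sigmoid(b_hid[:, None] + _correlate_valid(model.filters, v))


def visible_conditional(
    model: ConvRBMModel, hidden: np.ndarray, history: np.ndarray | None = None
) -> np.ndarray:
    """Mean of v given h: bias plus the transposed filter sum.

    For Gaussian visibles this is the conditional mean of the unit-variance
    Gaussian; for Bernoulli visibles the activation probability.
    """
    h = np.asarray(hidden, dtype=float)
    b_vis, _ = _dynamic_biases(model, history)
    top = _correlate_full_T(model.filters, h, model.n_positions)
    if model.visible_type == "gaussian":
        return b_vis + top
    return _sigmoid(b_vis + top)


def free_energy(
    model: ConvRBMModel, visible: np.ndarray, history: np.ndarray | None = None
) -> float:
    """F(v) = -log sum_h exp(-E(v, h)), via the softplus identity."""
    v = _check_slab(model, visible)
    b_vis, b_hid = _dynamic_biases(model, history)
    if model.visible_type == "gaussian":
        vis_term = 0.5 * np.sum((v - b_vis) ** 2)
    else:
        vis_term = -np.sum(v * b_vis)
    act = b_hid[:, None] + _correlate_valid(model.filters, v)
    return float(vis_term - np.sum(np.logaddexp(0.0, act)))


def train_cd(
    model: ConvRBMModel,
    data: np.ndarray,
    k: int = 1,
    lr: float = 1e-3,
    epochs: int = 10,
    batch: int = 32,
    seed: int = 0,
) -> tuple[ConvRBMModel, list[float]]:
    """Contrastive-divergence training (CD-k), mini-batch, deterministic.

    ``data`` is (N, C, P) and should be standardized per channel for
    Gaussian visibles (a loud warning is emitted otherwise). Returns a new
    model plus the per-epoch mean squared one-step reconstruction error.
    With ``lr = 0`` the returned model equals the input exactly.
    """
    if k < 1:
        raise ValueError("k must be at least 1")
    data = np.asarray(data, dtype=float)
    if data.ndim != 3 or data.shape[1:] != (model.visible_bias.shape[0], model.n_positions):
        raise ValueError("data must be (N, C, P) matching the model")
    if model.visible_type == "gaussian":
        ch_mean = np.abs(data.mean(axis=(0, 2)))
        if np.any(ch_mean > 0.5):
            import warnings

            warnings.warn(
                "training data does not look standardized "
                f"(max |channel mean| = {ch_mean.max():.3g})",
                UserWarning,
            )
    rng = np.random.default_rng(seed)
    out = model.copy()
    n = data.shape[0]
    trace: list[float] = []
    for epoch in range(epochs):
        order = rng.permutation(n)
        recon_errs = []
        for start in range(0, n, batch):
            idx = order[start : start + batch]
            dW = np.zeros_like(out.filters)
            db_h = np.zeros_like(out.hidden_bias)
            db_v = np.zeros_like(out.visible_bias)
            for v0 in data[idx]:
                p_h0 = hidden_conditional(out, v0)
                vk = v0
                h = (rng.random(p_h0.shape) < p_h0).astype(float)
                for step in range(k):
                    vk = visible_conditional(out, h)
                    if out.visible_type == "bernoulli":
                        vk = (rng.random(vk.shape) < vk).astype(float)
                    p_hk = hidden_conditional(out, vk)
                    if step < k - 1:
                        h = (rng.random(p_hk.shape) < p_hk).astype(float)
                dW += _filter_grad(out, v0, p_h0) - _filter_grad(out, vk, p_hk)
                db_h += p_h0.sum(axis=1) - p_hk.sum(axis=1)
                db_v += v0 - vk
                recon_errs.append(float(np.mean((v0 - visible_conditional(out, p_h0)) ** 2)))
            m = len(idx)
            out.filters = out.filters + lr * dW / m
            out.hidden_bias = out.hidden_bias + lr * db_h / m
            out.visible_bias = out.visible_bias + lr * db_v / m
            if not (
                np.all(np.isfinite(out.filters))
                and np.all(np.isfinite(out.hidden_bias))
                and np.all(np.isfinite(out.visible_bias))
            ):
                raise FloatingPointError(f"CD update diverged (NaN) at epoch {epoch}")
        trace.append(float(np.mean(recon_errs)))
    return out, trace


def _filter_grad(model: ConvRBMModel, v: np.ndarray, p_h: np.ndarray) -> np.ndarray:
    """d/dW of sum_h p_h * (W * v): correlation of v windows with p_h."""
    K, C, w = model.filters.shape
    windows = np.lib.stride_tricks.sliding_window_view(v, w, axis=1)  # (C, P-w+1, w)
    return np.einsum("kp,cpw->kcw", p_h, windows)


def frames_to_slabs(point_clouds: np.ndarray, temporal_window: int = 1) -> np.ndarray:
    """(F, 96) point clouds -> (F - T + 1, 3*T, 32) visible slabs."""
    pc = np.asarray(point_clouds, dtype=float)
    if pc.ndim != 2 or pc.shape[1] % 32 != 0:
        raise ValueError("point clouds must be (F, 3*32)")
    F = pc.shape[0]
    T = temporal_window
    if T > F:
        raise ValueError("temporal_window exceeds the number of frames")
    slabs = pc.reshape(F, -1, 32)  # (F, 3, 32)
    if T == 1:
        return slabs
    return np.stack(
        [np.concatenate(slabs[t : t + T], axis=0) for t in range(F - T + 1)]
    )


def standardize(
    data: np.ndarray, stats: tuple[np.ndarray, np.ndarray] | None = None
) -> tuple[np.ndarray, tuple[np.ndarray, np.ndarray]]:
    """Zero-mean/unit-variance per channel over (N, C, P) slabs."""
    data = np.asarray(data, dtype=float)
    if stats is None:
        mean = data.mean(axis=(0, 2), keepdims=True)
        std = data.std(axis=(0, 2), keepdims=True)
        std[std < 1e-12] = 1.0
        stats = (mean, std)
    mean, std = stats
    return (data - mean) / std, stats


def encode(
    model: ConvRBMModel,
    features,
    source: str = "",
    stats: tuple[np.ndarray, np.ndarray] | None = None,
) -> Embedding:
    """Embed frames: hidden conditionals max-pooled along the position axis.

    ``features`` may be a list of :class:`~mocapkit.kinematics.PoseFeatureFrame`
    or an (F, 96) array of point clouds. With ``model.pool <= 0`` pooling is
    global and the embedding dimension equals the filter count K; a positive
    pool width splits the hidden positions into that many-wide regions and
    yields K * n_regions dimensions (still below 96 by the Embedding
    invariant). When the model was trained on standardized slabs, pass the
    same ``stats`` so encode sees the same scale.
    """
    if hasattr(features, "ndim"):
        pcs = np.asarray(features, dtype=float)
    else:
        pcs = np.stack([f.point_cloud for f in features])
    slabs = frames_to_slabs(pcs, model.temporal_window)
    if stats is not None:
        slabs, _ = standardize(slabs, stats)
    H = model.n_hidden_positions
    pool = model.pool if model.pool > 0 else H
    edges = list(range(0, H, pool))
    vecs = np.empty((slabs.shape[0], model.n_filters * len(edges)))
    for t, slab in enumerate(slabs):
        probs = hidden_conditional(model, slab)
        pooled = [probs[:, s : s + pool].max(axis=1) for s in edges]
        vecs[t] = np.concatenate(pooled)
    return Embedding(vectors=vecs, source=source)


def auto_threshold(embedding: Embedding, percentile: float = 15.0, seed: int = 0) -> float:
    """Distance threshold = given percentile of the pairwise distances."""
    d = cdist(embedding.vectors, embedding.vectors)
    iu = np.triu_indices(d.shape[0], k=1)
    if iu[0].size == 0:
        return 0.0
    return float(np.percentile(d[iu], percentile))


def find_similar_frames(
    embA: Embedding,
    embB: Embedding,
    config: SimilarityConfig,
) -> list[tuple[int, int, float]]:
    """All frame pairs with embedding distance <= threshold.

    When both embeddings are the same object (self-matching), pairs closer
    than ``config.exclusion`` frames in time are dropped and each pair is
    reported once with frameA < frameB. Results are sorted by ascending
    distance, ties by (frameA, frameB).
    """
    if embA.dim != embB.dim:
        raise ValueError("embeddings must share the feature dimension")
    d = cdist(embA.vectors, embB.vectors)
    self_match = embA is embB or (
        embA.source != "" and embA.source == embB.source and embA.n_frames == embB.n_frames
    )
    pairs: list[tuple[int, int, float]] = []
    ii, jj = np.nonzero(d <= config.threshold)
    for i, j in zip(ii.tolist(), jj.tolist()):
        if self_match:
            if j <= i or (j - i) < config.exclusion:
                continue
        pairs.append((i, j, float(d[i, j])))
    pairs.sort(key=lambda t: (t[2], t[0], t[1]))
    return pairs
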
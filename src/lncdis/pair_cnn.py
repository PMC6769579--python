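"""Local-representation branch: CNN over the node-pair embedding matrix.

For a candidate pair (lncRNA ``i``, disease ``j``) the pair embedding is the
2 x N matrix stacking the two nodes' full relational profiles — row 0 is row
``i`` of the heterogeneous adjacency (lncRNA similarities | disease
associations | miRNA interactions) and row 1 is row ``Nl+j`` (disease view of
the same relations).  The matrix is surrounded by a ring of zeros (4 x (N+2))
so the convolution can see its margins, passed through three
convolution + ReLU + stride-1 max-pool stages, flattened, dropped out and
projected onto a 2-class softmax.  Convolution is cross-correlation (no
filter flip), valid (no padding along the width), stride 1.

The first stage uses a 3 x 11 filter window; after it only 2 rows remain, so
the later stages use 2 x 11 filters with a single zero row appended to keep
the row dimension at 2.  All window shapes, filter counts and the row padding
are configurable per layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .hetnet import HeteroAdjacency
from .optim import Adam
from .attention_gcn import cross_entropy, glorot_uniform, softmax_rows


# ---------------------------------------------------------------------------
# pair embedding

def build_pair_embedding(het: HeteroAdjacency, i: int, j: int) -> np.ndarray:
    """2 x N embedding matrix of the pair (lncRNA ``i``, disease ``j``).

    By the block layout of the adjacency, row 0 equals row ``i`` of U and
    row 1 equals row ``Nl + j``; masked training associations must already be
    zeroed in ``het``.
    """
    cat = het.catalog
    if not 0 <= i < cat.Nl:
        raise IndexError(f"lncRNA index {i} out of range [0, {cat.Nl})")
    if not 0 <= j < cat.Nd:
        raise IndexError(f"disease index {j} out of range [0, {cat.Nd})")
    return np.stack([het.U[i], het.U[cat.disease_node(j)]])


def zero_pad(P: np.ndarray) -> np.ndarray:
    """Surround the 2 x N pair embedding with a ring of zeros -> 4 x (N+2)."""
    P = np.asarray(P)
    if P.ndim != 2 or P.shape[0] != 2:
        raise ValueError(f"pair embedding must be 2 x N, got {P.shape}")
    return np.pad(P, ((1, 1), (1, 1)))


def batch_pair_embeddings(het: HeteroAdjacency, lnc_idx: np.ndarray,
                          dis_idx: np.ndarray, dtype=np.float64) -> np.ndarray:
    """Stacked zero-padded embeddings, shape (B, 4, N+2)."""
    cat = het.catalog
    U = het.U.astype(dtype, copy=False)
    B = len(lnc_idx)
    out = np.zeros((B, 4, het.N + 2), dtype=dtype)
    out[:, 1, 1:-1] = U[np.asarray(lnc_idx)]
    out[:, 2, 1:-1] = U[cat.Nl + np.asarray(dis_idx)]
    return out


# ---------------------------------------------------------------------------
# convolution / pooling primitives (batched; thin single-map wrappers below)

def conv_forward(X: np.ndarray, W: np.ndarray, b: np.ndarray):
    """Valid stride-1 cross-correlation + bias + ReLU on (B, H, W, Cin).

    Returns ``(out, cache)``; ``W`` has shape (fh, fw, Cin, F).
    """
    Bn, H, Wd, Cin = X.shape
    fh, fw, Cin_w, F = W.shape
    if Cin_w != Cin:
        raise ValueError(f"filter expects {Cin_w} channels, input has {Cin}")
    if fh > H or fw > Wd:
        raise ValueError(f"filter window {(fh, fw)} larger than input {(H, Wd)}")
    Ho, Wo = H - fh + 1, Wd - fw + 1
    win = sliding_window_view(X, (fh, fw), axis=(1, 2))  # (B, Ho, Wo, Cin, fh, fw)
    cols = np.ascontiguousarray(win.transpose(0, 1, 2, 4, 5, 3)).reshape(-1, fh * fw * Cin)
    pre = (cols @ W.reshape(-1, F)).reshape(Bn, Ho, Wo, F) + b
    out = np.maximum(pre, 0.0)
    return out, (X.shape, cols, pre > 0, W)


def conv_backward(dout: np.ndarray, cache):
    x_shape, cols, mask, W = cache
    fh, fw, Cin, F = W.shape
    Bn, Ho, Wo, _ = dout.shape
    dpre = (dout * mask).reshape(-1, F)
    dW = (cols.T @ dpre).reshape(W.shape)
    db = dpre.sum(axis=0)
    dcols = (dpre @ W.reshape(-1, F).T).reshape(Bn, Ho, Wo, fh, fw, Cin)
    dX = np.zeros(x_shape, dtype=dout.dtype)
    for a in range(fh):
        for c in range(fw):
            dX[:, a : a + Ho, c : c + Wo, :] += dcols[:, :, :, a, c, :]
    return dX, dW, db


def pool_forward(X: np.ndarray, pool_h: int, pool_w: int):
    """Stride-1 sliding-window maximum per channel on (B, H, W, C)."""
    Bn, H, Wd, C = X.shape
    if pool_h > H or pool_w > Wd:
        raise ValueError(f"pool window {(pool_h, pool_w)} larger than input {(H, Wd)}")
    win = sliding_window_view(X, (pool_h, pool_w), axis=(1, 2))  # (B, Ho, Wo, C, ph, pw)
    flat = win.reshape(*win.shape[:4], pool_h * pool_w)
    arg = flat.argmax(axis=-1)
    out = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]
    return np.ascontiguousarray(out), (X.shape, arg, pool_h, pool_w)


def pool_backward(dout: np.ndarray, cache):
    x_shape, arg, pool_h, pool_w = cache
    Bn, Ho, Wo, C = dout.shape
    dX = np.zeros(x_shape, dtype=dout.dtype)
    bi, mi, ni, ci = np.indices(dout.shape, sparse=True)
    np.add.at(dX, (bi, mi + arg // pool_w, ni + arg % pool_w, ci), dout)
    return dX


@dataclass
class ConvLayerSpec:
    """One convolution + max-pool stage.

    ``row_pad`` zero rows are appended before the convolution so that 2-row
    maps can be processed by 2-row filters without shrinking to a single row.
    """

    W: np.ndarray  # (fh, fw, Cin, F)
    b: np.ndarray  # (F,)
    pool_h: int = 1
    pool_w: int = 2
    row_pad: int = 0

    @property
    def filters(self) -> int:
        return self.W.shape[3]


@dataclass
class RightHead:
    """Affine + softmax head on the flattened final feature map."""

    W: np.ndarray  # (2, flat)
    b: np.ndarray  # (2,)
    dropout_p: float = 0.5


def conv_layer(x: np.ndarray, spec: ConvLayerSpec) -> np.ndarray:
    """Single-map convolution stage (rows x cols x channels), ReLU applied."""
    out, _ = conv_forward(x[None], spec.W, spec.b)
    return out[0]


def max_pool(x: np.ndarray, pool_h: int, pool_w: int) -> np.ndarray:
    """Single-map stride-1 max pooling (rows x cols x channels)."""
    out, _ = pool_forward(x[None], pool_h, pool_w)
    return out[0]


def forward_right(Pprime: np.ndarray, layers: Sequence[ConvLayerSpec], head: RightHead,
                  train_mode: bool = False, rng: np.random.Generator | None = None):
    """Full right-branch forward pass for one padded pair embedding.

    In train mode each flattened activation is zeroed with probability
    ``dropout_p`` (``rng`` required); in eval mode all activations are scaled
    by ``1 - dropout_p`` instead, approximating the dropout ensemble mean.
    Returns ``(p, score)`` with ``score = p[1]``.
    """
    x = np.asarray(Pprime, dtype=np.float64)[None, :, :, None]
    for spec in layers:
        if spec.row_pad:
            x = np.pad(x, ((0, 0), (0, spec.row_pad), (0, 0), (0, 0)))
        x, _ = conv_forward(x, spec.W, spec.b)
        x, _ = pool_forward(x, spec.pool_h, spec.pool_w)
    q = x.reshape(1, -1)
    if train_mode:
        if rng is None:
            raise ValueError("train-mode dropout requires an rng")
        q = q * (rng.random(q.shape) >= head.dropout_p)
    else:
        q = q * (1.0 - head.dropout_p)
    p = softmax_rows(q @ head.W.T + head.b)[0]
    return p, float(p[1])


# ---------------------------------------------------------------------------
# trainable branch

@dataclass
class RightBranchConfig:
    n_conv: tuple[int, int, int] = (20, 30, 40)
    filter_h: int = 3   # first-layer filter rows
    filter_w: int = 11  # filter columns, all layers
    later_filter_h: int = 2
    pool_h: int = 1
    pool_w: int = 2
    dropout_p: float = 0.5
    row_pads: tuple[int, int, int] = (0, 1, 1)

    def layer_shapes(self) -> list[tuple[int, int, int, int]]:
        chans = (1,) + tuple(self.n_conv[:-1])
        heights = (self.filter_h, self.later_filter_h, self.later_filter_h)
        return [
            (h, self.filter_w, cin, f)
            for h, cin, f in zip(heights, chans, self.n_conv)
        ]


class RightBranch:
    """Trainable three-stage CNN + softmax head over padded pair embeddings."""

    def __init__(self, N: int, seed: int, lr: float = 0.0005,
                 config: RightBranchConfig | None = None, dtype=np.float64):
        self.config = config or RightBranchConfig()
        self.dtype = np.dtype(dtype)
        self.lr = lr
        rng = np.random.default_rng(seed)
        self.params: dict[str, np.ndarray] = {}
        for k, shape in enumerate(self.config.layer_shapes(), start=1):
            fh, fw, cin, f = shape
            fan_in, fan_out = fh * fw * cin, f
            limit = np.sqrt(6.0 / (fan_in + fan_out))
            self.params[f"W{k}"] = rng.uniform(-limit, limit, size=shape).astype(self.dtype)
            self.params[f"b{k}"] = np.zeros(f, dtype=self.dtype)
        flat = self.flat_dim(N)
        self.params["Wr"] = glorot_uniform(rng, (2, flat)).astype(self.dtype)
        self.params["br"] = np.zeros(2, dtype=self.dtype)
        self._opt: Adam | None = None

    def flat_dim(self, N: int) -> int:
        """Flattened feature length after the three stages on a 4 x (N+2) input."""
        cfg = self.config
        h, w = 4, N + 2
        for k, (fh, fw, _, f) in enumerate(cfg.layer_shapes()):
            h = h + cfg.row_pads[k] - fh + 1 - cfg.pool_h + 1
            w = w - fw + 1 - cfg.pool_w + 1
            if h < 1 or w < 1:
                raise ValueError("convolution chain collapses the feature map; check layer specs")
        return h * w * cfg.n_conv[-1]

    def layer_specs(self) -> list[ConvLayerSpec]:
        cfg = self.config
        return [
            ConvLayerSpec(
                W=self.params[f"W{k+1}"], b=self.params[f"b{k+1}"],
                pool_h=cfg.pool_h, pool_w=cfg.pool_w, row_pad=cfg.row_pads[k],
            )
            for k in range(3)
        ]

    def head(self) -> RightHead:
        return RightHead(self.params["Wr"], self.params["br"], self.config.dropout_p)

    def _forward(self, Pbatch: np.ndarray, train_mode: bool,
                 rng: np.random.Generator | None):
        cfg = self.config
        x = np.asarray(Pbatch, dtype=self.dtype)[..., None]
        caches = []
        for k in range(3):
            rp = cfg.row_pads[k]
            if rp:
                x = np.pad(x, ((0, 0), (0, rp), (0, 0), (0, 0)))
            x, ccache = conv_forward(x, self.params[f"W{k+1}"], self.params[f"b{k+1}"])
            x, pcache = pool_forward(x, cfg.pool_h, cfg.pool_w)
            caches.append((rp, ccache, pcache))
        q = x.reshape(x.shape[0], -1)
        if train_mode:
            if rng is None:
                raise ValueError("train-mode dropout requires an rng")
            mask = (rng.random(q.shape) >= cfg.dropout_p).astype(self.dtype)
            qd = q * mask
        else:
            mask = None
            qd = q * (1.0 - cfg.dropout_p)
        logits = qd @ self.params["Wr"].T + self.params["br"]
        P = softmax_rows(logits)
        return P, (caches, x.shape, qd, mask)

    def scores(self, Pbatch: np.ndarray) -> np.ndarray:
        """Eval-mode class-1 probabilities, shape (B,)."""
        P, _ = self._forward(Pbatch, train_mode=False, rng=None)
        return P[:, 1]

    def loss_and_grads(self, Pbatch: np.ndarray, labels: np.ndarray,
                       rng: np.random.Generator) -> tuple[float, dict[str, np.ndarray]]:
        """Train-mode batch cross-entropy and its parameter gradients."""
        P, (caches, map_shape, qd, mask) = self._forward(Pbatch, True, rng)
        loss = cross_entropy(P, labels)
        if not np.isfinite(loss):
            raise FloatingPointError("right-branch loss diverged")

        B = len(labels)
        dlogits = P.astype(self.dtype)
        dlogits[np.arange(B), labels] -= 1.0
        dlogits /= B
        grads: dict[str, np.ndarray] = {
            "Wr": dlogits.T @ qd,
            "br": dlogits.sum(axis=0),
        }
        dq = (dlogits @ self.params["Wr"]) * mask
        dx = dq.reshape(map_shape)
        for k in range(2, -1, -1):
            rp, ccache, pcache = caches[k]
            dx = pool_backward(dx, pcache)
            dx, dW, db = conv_backward(dx, ccache)
            if rp:
                dx = dx[:, :-rp, :, :]
            grads[f"W{k+1}"] = dW
            grads[f"b{k+1}"] = db
        return loss, grads

    def train_step(self, Pbatch: np.ndarray, labels: np.ndarray,
                   rng: np.random.Generator) -> float:
        """One Adam step on the batch cross-entropy; returns the loss."""
        loss, grads = self.loss_and_grads(Pbatch, labels, rng)
        if self._opt is None:
            self._opt = Adam(self.params, lr=self.lr)
        self._opt.step(grads)
        return loss
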
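"""Network-representation branch: feature attention + graph-convolution autoencoder.

For node ``i`` with topology feature vector ``u_i`` (row ``i`` of the
heterogeneous adjacency ``U``) the branch computes

* attention scores ``s_i = H_att tanh(W_att u_i + b_att)``, softmax-normalised
  to feature weights ``alpha_i``, giving the enhanced feature ``x_i = alpha_i * u_i``;
* node embeddings ``Z = softmax_rows(Utilde X W_enco)`` (one graph
  convolution through the normalised adjacency);
* a reconstruction ``Xhat = sigmoid(Utilde Z W_deco)`` trained to match ``X``
  under mean squared error;
* a pair score for lncRNA ``i`` / disease ``j``: the class-1 probability of a
  2-class softmax head on the concatenation ``[z_i, z_{Nl+j}]``.

Training runs in two phases: the attention and autoencoder parameters are
first fit to the reconstruction loss alone; the classification head is then
fit to the cross-entropy over labelled training pairs while the encoder and
attention parameters continue to receive gradients.  All gradients here are
hand-derived and are verified against finite differences in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .optim import Adam


# ---------------------------------------------------------------------------
# numerics

def softmax_rows(S: np.ndarray) -> np.ndarray:
    """Row-wise softmax, shifted for stability."""
    S = np.asarray(S, dtype=np.float64)
    shifted = S - S.max(axis=-1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_rows_backward(dY: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """VJP of :func:`softmax_rows` given output ``Y`` and cotangent ``dY``."""
    dot = (dY * Y).sum(axis=-1, keepdims=True)
    return (dY - dot) * Y


def sigmoid(t: np.ndarray) -> np.ndarray:
    """Standard logistic 1 / (1 + exp(-t))."""
    out = np.empty_like(t, dtype=np.float64)
    pos = t >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-t[pos]))
    e = np.exp(t[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def cross_entropy(P: np.ndarray, labels: np.ndarray) -> float:
    """Mean negative log-likelihood of ``labels`` under row distributions ``P``."""
    P = np.asarray(P, dtype=np.float64)
    idx = np.arange(P.shape[0])
    return float(-np.mean(np.log(np.clip(P[idx, labels], 1e-300, None))))


# ---------------------------------------------------------------------------
# parameter containers

@dataclass
class AttentionParams:
    """Feature-level attention parameters (all N x N / length-N)."""

    H: np.ndarray
    W: np.ndarray
    b: np.ndarray


@dataclass
class AutoencoderParams:
    """Graph-convolution encoder/decoder weights; ``n`` is the embedding width."""

    W_enco: np.ndarray
    W_deco: np.ndarray

    @property
    def n(self) -> int:
        return self.W_enco.shape[1]


@dataclass
class LeftHead:
    """2-class affine + softmax head over the concatenated pair embedding."""

    W: np.ndarray  # (2, 2n)
    b: np.ndarray  # (2,)


def glorot_uniform(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    fan_in, fan_out = shape[0], shape[-1]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


# ---------------------------------------------------------------------------
# forward operations (pure; used directly by tests and by the trainer below)

def attention_enhance(U: np.ndarray, params: AttentionParams) -> tuple[np.ndarray, np.ndarray]:
    """Apply feature-level attention to every node's topology feature row.

    Returns ``(alpha, X)`` where row ``i`` of ``alpha`` is the softmax weight
    vector over the N features of ``u_i`` and ``X = alpha * U`` elementwise.
    """
    U = np.asarray(U, dtype=np.float64)
    pre = U @ params.W.T + params.b  # row i = W u_i + b
    T = np.tanh(pre)
    S = T @ params.H.T  # row i = s_i
    alpha = softmax_rows(S)
    X = alpha * U
    if not np.isfinite(X).all():
        raise FloatingPointError("non-finite attention output (exploding parameters?)")
    return alpha, X


def encode(X: np.ndarray, Utilde: np.ndarray, params: AutoencoderParams) -> np.ndarray:
    """Graph-convolution encoding ``Z = softmax_rows(Utilde X W_enco)``."""
    Z = softmax_rows(Utilde @ X @ params.W_enco)
    if not np.isfinite(Z).all():
        raise FloatingPointError("non-finite encoder output")
    return Z


def decode(Z: np.ndarray, Utilde: np.ndarray, params: AutoencoderParams) -> np.ndarray:
    """Graph-convolution decoding ``Xhat = sigmoid(Utilde Z W_deco)``."""
    Xhat = sigmoid(Utilde @ Z @ params.W_deco)
    if not np.isfinite(Xhat).all():
        raise FloatingPointError("non-finite decoder output")
    return Xhat


def reconstruction_loss(X: np.ndarray, Xhat: np.ndarray) -> float:
    """Mean squared error over all N*N entries."""
    X = np.asarray(X, dtype=np.float64)
    Xhat = np.asarray(Xhat, dtype=np.float64)
    if X.shape != Xhat.shape:
        raise ValueError(f"shape mismatch: {X.shape} vs {Xhat.shape}")
    return float(np.mean((X - Xhat) ** 2))


def pair_score_left(z_lnc: np.ndarray, z_dis: np.ndarray, head: LeftHead) -> tuple[np.ndarray, float]:
    """Class distribution and class-1 score for one lncRNA/disease embedding pair."""
    z_lnc = np.asarray(z_lnc, dtype=np.float64)
    z_dis = np.asarray(z_dis, dtype=np.float64)
    if z_lnc.shape != z_dis.shape:
        raise ValueError(f"embedding length mismatch: {z_lnc.shape} vs {z_dis.shape}")
    k = np.concatenate([z_lnc, z_dis])
    p = softmax_rows(head.W @ k + head.b)
    return p, float(p[1])


# ---------------------------------------------------------------------------
# trainable branch

class LeftBranch:
    """Trainable attention + autoencoder + head with hand-derived gradients.

    Parameters
    ----------
    N : number of network nodes.
    n : embedding width.
    seed : seed for Glorot-uniform initialisation.
    lr : Adam learning rate used for both training phases.
    finetune_attention : when True, phase-2 classification gradients also
        update the attention parameters; by default those stay as fit by the
        reconstruction phase and phase 2 trains the head and fine-tunes the
        encoder weights only, which is markedly stabler on small networks.
    """

    PHASE1_KEYS = ("H", "W", "b", "We", "Wd")

    def __init__(self, N: int, n: int, seed: int, lr: float = 0.001,
                 finetune_attention: bool = False):
        rng = np.random.default_rng(seed)
        self.N = N
        self.n = n
        self.lr = lr
        self.phase2_keys = (
            ("H", "W", "b", "We", "Wl", "bl") if finetune_attention
            else ("We", "Wl", "bl")
        )
        self.params: dict[str, np.ndarray] = {
            "H": glorot_uniform(rng, (N, N)),
            "W": glorot_uniform(rng, (N, N)),
            "b": np.zeros(N),
            "We": glorot_uniform(rng, (N, n)),
            "Wd": glorot_uniform(rng, (n, N)),
            "Wl": glorot_uniform(rng, (2, 2 * n)),
            "bl": np.zeros(2),
        }
        self._opt1: Adam | None = None
        self._opt2: Adam | None = None

    # -- convenience views -------------------------------------------------
    @property
    def attention(self) -> AttentionParams:
        return AttentionParams(self.params["H"], self.params["W"], self.params["b"])

    @property
    def autoencoder(self) -> AutoencoderParams:
        return AutoencoderParams(self.params["We"], self.params["Wd"])

    @property
    def head(self) -> LeftHead:
        return LeftHead(self.params["Wl"], self.params["bl"])

    # -- forward with cache ------------------------------------------------
    def _forward_encoder(self, U: np.ndarray, Utilde: np.ndarray) -> dict[str, np.ndarray]:
        p = self.params
        pre = U @ p["W"].T + p["b"]
        T = np.tanh(pre)
        S = T @ p["H"].T
        alpha = softmax_rows(S)
        X = alpha * U
        M1 = Utilde @ X
        Z = softmax_rows(M1 @ p["We"])
        return {"T": T, "alpha": alpha, "X": X, "M1": M1, "Z": Z}

    def embeddings(self, U: np.ndarray, Utilde: np.ndarray) -> np.ndarray:
        """Node embeddings Z under the current parameters."""
        return self._forward_encoder(U, Utilde)["Z"]

    def _attention_backward(self, dX: np.ndarray, U: np.ndarray,
                            cache: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
        p = self.params
        dalpha = dX * U
        dS = softmax_rows_backward(dalpha, cache["alpha"])
        dH = dS.T @ cache["T"]
        dT = dS @ p["H"]
        dpre = dT * (1.0 - cache["T"] ** 2)
        return {"H": dH, "W": dpre.T @ U, "b": dpre.sum(axis=0)}

    def _encoder_backward(self, dZ: np.ndarray, Utilde: np.ndarray,
                          cache: dict[str, np.ndarray]) -> tuple[dict[str, np.ndarray], np.ndarray]:
        """Gradients of We and of X from a cotangent on Z."""
        p = self.params
        dK1 = softmax_rows_backward(dZ, cache["Z"])
        dWe = cache["M1"].T @ dK1
        dX = Utilde.T @ (dK1 @ p["We"].T)
        return {"We": dWe}, dX

    # -- phase 1: reconstruction -------------------------------------------
    def reconstruction_grads(self, U: np.ndarray, Utilde: np.ndarray
                             ) -> tuple[float, dict[str, np.ndarray]]:
        """Autoencoder MSE and its gradients w.r.t. the phase-1 parameters."""
        p = self.params
        cache = self._forward_encoder(U, Utilde)
        X, Z = cache["X"], cache["Z"]
        M2 = Utilde @ Z
        Xhat = sigmoid(M2 @ p["Wd"])
        N2 = X.size
        loss = float(np.mean((X - Xhat) ** 2))
        if not np.isfinite(loss):
            raise FloatingPointError("reconstruction loss diverged")

        dXhat = 2.0 * (Xhat - X) / N2
        dX_direct = -dXhat
        dK2 = dXhat * Xhat * (1.0 - Xhat)
        grads: dict[str, np.ndarray] = {"Wd": M2.T @ dK2}
        dZ = Utilde.T @ (dK2 @ p["Wd"].T)
        enc_grads, dX_enc = self._encoder_backward(dZ, Utilde, cache)
        grads.update(enc_grads)
        grads.update(self._attention_backward(dX_direct + dX_enc, U, cache))
        return loss, grads

    def reconstruction_step(self, U: np.ndarray, Utilde: np.ndarray,
                            update: bool = True) -> float:
        """One full-batch Adam step on the autoencoder MSE; returns the loss."""
        loss, grads = self.reconstruction_grads(U, Utilde)
        if update:
            if self._opt1 is None:
                self._opt1 = Adam({k: self.params[k] for k in self.PHASE1_KEYS}, lr=self.lr)
            self._opt1.step(grads)
        return loss

    # -- phase 2: pair classification --------------------------------------
    def classification_grads(self, U: np.ndarray, Utilde: np.ndarray,
                             lnc_nodes: np.ndarray, dis_nodes: np.ndarray,
                             labels: np.ndarray) -> tuple[float, dict[str, np.ndarray]]:
        """Pair cross-entropy and its gradients w.r.t. the phase-2 parameters."""
        p = self.params
        cache = self._forward_encoder(U, Utilde)
        Z = cache["Z"]
        K = np.concatenate([Z[lnc_nodes], Z[dis_nodes]], axis=1)
        logits = K @ p["Wl"].T + p["bl"]
        P = softmax_rows(logits)
        loss = cross_entropy(P, labels)
        if not np.isfinite(loss):
            raise FloatingPointError("classification loss diverged")

        B = len(labels)
        dlogits = P.copy()
        dlogits[np.arange(B), labels] -= 1.0
        dlogits /= B
        grads: dict[str, np.ndarray] = {
            "Wl": dlogits.T @ K,
            "bl": dlogits.sum(axis=0),
        }
        dK = dlogits @ p["Wl"]
        dZ = np.zeros_like(Z)
        np.add.at(dZ, lnc_nodes, dK[:, : self.n])
        np.add.at(dZ, dis_nodes, dK[:, self.n :])
        enc_grads, dX_enc = self._encoder_backward(dZ, Utilde, cache)
        grads.update(enc_grads)
        grads.update(self._attention_backward(dX_enc, U, cache))
        return loss, grads

    def classification_step(self, U: np.ndarray, Utilde: np.ndarray,
                            lnc_nodes: np.ndarray, dis_nodes: np.ndarray,
                            labels: np.ndarray, update: bool = True) -> float:
        """One cross-entropy Adam step on labelled pairs (global node indices)."""
        loss, grads = self.classification_grads(U, Utilde, lnc_nodes, dis_nodes, labels)
        if update:
            if self._opt2 is None:
                self._opt2 = Adam({k: self.params[k] for k in self.phase2_keys}, lr=self.lr)
            self._opt2.step({k: grads[k] for k in self.phase2_keys})
        return loss

    # -- inference ----------------------------------------------------------
    def score_pairs(self, U: np.ndarray, Utilde: np.ndarray,
                    lnc_nodes: np.ndarray, dis_nodes: np.ndarray) -> np.ndarray:
        """Class-1 probabilities for the given pairs of global node indices."""
        p = self.params
        Z = self.embeddings(U, Utilde)
        K = np.concatenate([Z[lnc_nodes], Z[dis_nodes]], axis=1)
        P = softmax_rows(K @ p["Wl"].T + p["bl"])
        return P[:, 1]
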
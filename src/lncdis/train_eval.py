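"""Training protocol and cross-validated evaluation of the two-branch model.

The protocol balances classes by sampling as many negative pairs (uniformly,
without replacement, from the zero cells of the association matrix) as there
are known positives, splits both classes into five folds, and for each fold
removes the test positives from the association matrix and *recomputes the
lncRNA functional similarity* from the remaining associations before
training, so no test label leaks into the network or the pair embeddings.
miRNA and disease similarities are not recomputed.

Each fold trains the network-representation branch (reconstruction phase,
then pair-classification phase) and the pair-CNN branch with Adam, scores
the held-out pairs with both branches and fuses them as
``lambda * score_left + (1 - lambda) * score_right``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np

from . import metrics
from .attention_gcn import LeftBranch
from .catalog import EntityCatalog
from .hetnet import HeteroAdjacency, assemble_U, normalize
from .metrics import auc_roc, aupr, confusion_at, sweep, topk_recall  # noqa: F401  (public surface)
from .pair_cnn import RightBranch, RightBranchConfig, batch_pair_embeddings
from .similarity import functional_similarity

logger = logging.getLogger(__name__)


@dataclass
class TrainConfig:
    """Hyperparameters of both branches and of the evaluation protocol.

    Defaults follow the tuned model configuration: fusion weight 0.8,
    embedding width 100, filter banks of 20/30/40 filters with a 3 x 11
    first-stage window, Adam at 0.001 (autoencoder branch) and 0.0005 (CNN
    branch), dropout 0.5.  Epoch counts and batch size govern the training
    schedule and are exposed because runtimes scale with them.
    """

    lambda_fuse: float = 0.8
    n: int = 100
    n_conv: tuple[int, int, int] = (20, 30, 40)
    n_f: int = 3
    n_d: int = 11
    lr_left: float = 0.001
    lr_right: float = 0.0005
    dropout_p: float = 0.5
    epochs_recon: int = 200
    epochs_cls: int = 100
    epochs_right: int = 15
    batch_size: int = 64
    seed: int = 0
    n_folds: int = 5
    n_permutations: int = 100
    topk_values: tuple[int, ...] = (10, 20, 30, 40, 50)
    right_dtype: str = "float32"

    def __post_init__(self):
        if not 0.0 < self.lambda_fuse < 1.0:
            raise ValueError(f"lambda_fuse must lie in (0, 1), got {self.lambda_fuse}")
        if self.lr_left <= 0 or self.lr_right <= 0:
            raise ValueError("learning rates must be positive")

    def right_config(self) -> RightBranchConfig:
        return RightBranchConfig(
            n_conv=tuple(self.n_conv), filter_h=self.n_f, filter_w=self.n_d,
            dropout_p=self.dropout_p,
        )


# ---------------------------------------------------------------------------
# protocol pieces

def sample_negatives(A: np.ndarray, count: int, seed: int) -> np.ndarray:
    """Uniform sample without replacement of ``count`` zero cells of ``A``.

    Returns an array of (lncRNA index, disease index) rows.
    """
    zeros = np.argwhere(np.asarray(A) == 0)
    if count > len(zeros):
        raise ValueError(f"requested {count} negatives but only {len(zeros)} zero cells exist")
    rng = np.random.default_rng(seed)
    pick = rng.choice(len(zeros), size=count, replace=False)
    return zeros[pick]


@dataclass
class FoldSplit:
    """Disjoint positive/negative fold subsets (arrays of pair rows)."""

    pos_folds: list[np.ndarray]
    neg_folds: list[np.ndarray]

    @property
    def n_folds(self) -> int:
        return len(self.pos_folds)

    def train_test(self, f: int):
        """(train_pos, train_neg, test_pos, test_neg) pair arrays for fold ``f``."""
        tr_pos = np.concatenate([p for k, p in enumerate(self.pos_folds) if k != f])
        tr_neg = np.concatenate([p for k, p in enumerate(self.neg_folds) if k != f])
        return tr_pos, tr_neg, self.pos_folds[f], self.neg_folds[f]


def _partition(pairs: np.ndarray, n_folds: int, rng: np.random.Generator) -> list[np.ndarray]:
    perm = rng.permutation(len(pairs))
    return [pairs[idx] for idx in np.array_split(perm, n_folds)]


def make_folds(positives: np.ndarray, negatives: np.ndarray, seed: int,
               n_folds: int = 5) -> FoldSplit:
    """Random near-equal partition of both classes into ``n_folds`` folds."""
    positives = np.asarray(positives)
    negatives = np.asarray(negatives)
    if len(positives) < n_folds:
        raise ValueError(f"need at least {n_folds} positives, got {len(positives)}")
    if len(negatives) < n_folds:
        raise ValueError(f"need at least {n_folds} negatives, got {len(negatives)}")
    rng = np.random.default_rng(seed)
    return FoldSplit(
        pos_folds=_partition(positives, n_folds, rng),
        neg_folds=_partition(negatives, n_folds, rng),
    )


def mask_and_recompute(A: np.ndarray, test_pairs: np.ndarray,
                       D: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Zero the held-out positives and recompute lncRNA similarity from the rest."""
    A = np.asarray(A)
    A_train = A.copy()
    for i, j in np.asarray(test_pairs).reshape(-1, 2):
        if A[i, j] != 1:
            raise ValueError(f"test pair ({i}, {j}) is not a positive in A")
        A_train[i, j] = 0
    return A_train, functional_similarity(A_train, D)


def fuse_scores(score_l, score_r, lam: float):
    """Weighted-sum fusion of the two branch probabilities."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"fusion weight must lie in [0, 1], got {lam}")
    return lam * np.asarray(score_l) + (1.0 - lam) * np.asarray(score_r)


# ---------------------------------------------------------------------------
# model training

@dataclass
class TrainedModel:
    """Both trained branches plus the (fold-masked) network they were fit on."""

    catalog: EntityCatalog
    config: TrainConfig
    left: LeftBranch
    right: RightBranch
    het: HeteroAdjacency
    Utilde: np.ndarray
    recon_losses: list[float] = field(default_factory=list)
    cls_losses: list[float] = field(default_factory=list)
    right_losses: list[float] = field(default_factory=list)

    def score_pairs(self, lnc_idx: np.ndarray, dis_idx: np.ndarray,
                    chunk: int = 256) -> dict[str, np.ndarray]:
        """Eval-mode left/right/fused scores for (lncRNA, disease) index arrays."""
        lnc_idx = np.asarray(lnc_idx)
        dis_idx = np.asarray(dis_idx)
        nodes_d = self.catalog.Nl + dis_idx
        score_l = self.left.score_pairs(self.het.U, self.Utilde, lnc_idx, nodes_d)
        parts = []
        for start in range(0, len(lnc_idx), chunk):
            Pb = batch_pair_embeddings(
                self.het, lnc_idx[start : start + chunk], dis_idx[start : start + chunk],
                dtype=self.right.dtype,
            )
            parts.append(self.right.scores(Pb))
        score_r = np.concatenate(parts) if parts else np.zeros(0)
        return {
            "left": score_l,
            "right": score_r.astype(np.float64),
            "fused": fuse_scores(score_l, score_r, self.config.lambda_fuse),
        }


def train_model(
    A_train: np.ndarray,
    L_train: np.ndarray,
    D: np.ndarray,
    M: np.ndarray,
    B: np.ndarray,
    C: np.ndarray,
    catalog: EntityCatalog,
    config: TrainConfig,
    train_pairs: np.ndarray,
    train_labels: np.ndarray,
    seed: int,
) -> TrainedModel:
    """Fit both branches on the masked network and the labelled training pairs."""
    het = assemble_U(L_train, D, M, A_train, B, C, catalog)
    Utilde = normalize(het).Utilde
    ss = np.random.SeedSequence(seed)
    init_left, init_right, shuf_seed, drop_seed = (
        int(s) for s in ss.generate_state(4) >> np.uint32(1)
    )

    train_pairs = np.asarray(train_pairs).reshape(-1, 2)
    train_labels = np.asarray(train_labels, dtype=np.int64)
    lnc_idx = train_pairs[:, 0]
    dis_nodes = catalog.Nl + train_pairs[:, 1]

    left = LeftBranch(catalog.N, config.n, seed=init_left, lr=config.lr_left)
    recon_losses, cls_losses = [], []
    for epoch in range(config.epochs_recon):
        recon_losses.append(left.reconstruction_step(het.U, Utilde))
        logger.debug("recon epoch %d loss %.6g", epoch, recon_losses[-1])
    for epoch in range(config.epochs_cls):
        cls_losses.append(
            left.classification_step(het.U, Utilde, lnc_idx, dis_nodes, train_labels))
        logger.debug("cls epoch %d loss %.6g", epoch, cls_losses[-1])

    right = RightBranch(catalog.N, seed=init_right, lr=config.lr_right,
                        config=config.right_config(), dtype=np.dtype(config.right_dtype))
    shuffle_rng = np.random.default_rng(shuf_seed)
    dropout_rng = np.random.default_rng(drop_seed)
    right_losses: list[float] = []
    for _ in range(config.epochs_right):
        order = shuffle_rng.permutation(len(train_labels))
        epoch_loss = 0.0
        for start in range(0, len(order), config.batch_size):
            batch = order[start : start + config.batch_size]
            Pb = batch_pair_embeddings(het, train_pairs[batch, 0], train_pairs[batch, 1],
                                       dtype=right.dtype)
            epoch_loss += right.train_step(Pb, train_labels[batch], dropout_rng) * len(batch)
        right_losses.append(epoch_loss / len(train_labels))
        logger.debug("cnn epoch %d loss %.6g", len(right_losses) - 1, right_losses[-1])

    if recon_losses:
        logger.info("reconstruction loss %.3g -> %.3g", recon_losses[0], recon_losses[-1])
    if right_losses:
        logger.info("right-branch loss %.3g -> %.3g", right_losses[0], right_losses[-1])
    return TrainedModel(catalog=catalog, config=config, left=left, right=right,
                        het=het, Utilde=Utilde, recon_losses=recon_losses,
                        cls_losses=cls_losses, right_losses=right_losses)


# ---------------------------------------------------------------------------
# cross-validated evaluation

def _fold_topk(model: TrainedModel, A: np.ndarray, A_train: np.ndarray,
               test_pos: np.ndarray, k_values) -> dict[int, float] | None:
    """Per-disease top-k recall of a fold's held-out positives.

    Candidates of disease ``j`` are the lncRNAs without a *training*
    association to ``j``; requested k values exceeding the smallest candidate
    list are dropped.
    """
    held: dict[int, set[int]] = {}
    for i, j in test_pos:
        held.setdefault(int(j), set()).add(int(i))
    if not held:
        return None
    rankings: dict[int, list[int]] = {}
    min_cand = np.inf
    for j in held:
        cands = np.flatnonzero(A_train[:, j] == 0)
        min_cand = min(min_cand, len(cands))
        s = model.score_pairs(cands, np.full(len(cands), j))["fused"]
        rankings[j] = [int(c) for c in cands[np.argsort(-s, kind="stable")]]
    ks = [k for k in k_values if k <= min_cand]
    if not ks:
        return None
    return topk_recall(rankings, held, ks)


def cross_validate(
    A: np.ndarray,
    D: np.ndarray,
    M: np.ndarray,
    B: np.ndarray,
    C: np.ndarray,
    catalog: EntityCatalog,
    config: TrainConfig,
    compute_topk: bool = True,
) -> dict:
    """Balanced five-fold cross-validation of the fused model.

    Returns an evaluation report with pooled and fold-averaged (macro) AUC and
    AUPR, pooled ROC/PR curves, top-k recalls, per-fold reconstruction-loss
    traces and a label-permutation AUC control.
    """
    A = np.asarray(A)
    positives = np.argwhere(A == 1)
    ss = np.random.SeedSequence(config.seed)
    neg_seed, fold_seed, perm_seed, *fold_train_seeds = (
        int(s) for s in ss.generate_state(3 + config.n_folds) >> np.uint32(1)
    )
    negatives = sample_negatives(A, len(positives), seed=neg_seed)
    folds = make_folds(positives, negatives, seed=fold_seed, n_folds=config.n_folds)

    pooled_scores: list[np.ndarray] = []
    pooled_labels: list[np.ndarray] = []
    fold_auc, fold_aupr = [], []
    recon_first, recon_last = [], []
    topk_tables: list[dict[int, float]] = []

    for f in range(config.n_folds):
        tr_pos, tr_neg, te_pos, te_neg = folds.train_test(f)
        A_train, L_train = mask_and_recompute(A, te_pos, D)
        train_pairs = np.concatenate([tr_pos, tr_neg])
        train_labels = np.r_[np.ones(len(tr_pos), dtype=np.int64),
                             np.zeros(len(tr_neg), dtype=np.int64)]
        model = train_model(A_train, L_train, D, M, B, C, catalog, config,
                            train_pairs, train_labels, seed=fold_train_seeds[f])

        test_pairs = np.concatenate([te_pos, te_neg])
        test_labels = np.r_[np.ones(len(te_pos), dtype=np.int64),
                            np.zeros(len(te_neg), dtype=np.int64)]
        scores = model.score_pairs(test_pairs[:, 0], test_pairs[:, 1])["fused"]
        pooled_scores.append(scores)
        pooled_labels.append(test_labels)
        fold_auc.append(auc_roc(scores, test_labels))
        fold_aupr.append(aupr(scores, test_labels))
        recon_first.append(model.recon_losses[0])
        recon_last.append(model.recon_losses[-1])
        if compute_topk:
            table = _fold_topk(model, A, A_train, te_pos, config.topk_values)
            if table:
                topk_tables.append(table)
        logger.info("fold %d: AUC %.4f AUPR %.4f", f, fold_auc[-1], fold_aupr[-1])

    all_scores = np.concatenate(pooled_scores)
    all_labels = np.concatenate(pooled_labels)
    perm_rng = np.random.default_rng(perm_seed)
    perm_aucs = [
        auc_roc(all_scores, perm_rng.permutation(all_labels))
        for _ in range(config.n_permutations)
    ]
    sw = sweep(all_scores, all_labels)

    topk: dict[int, float] = {}
    if topk_tables:
        for k in sorted({k for t in topk_tables for k in t}):
            vals = [t[k] for t in topk_tables if k in t]
            topk[k] = float(np.mean(vals))

    return {
        "auc_pooled": auc_roc(all_scores, all_labels),
        "aupr_pooled": aupr(all_scores, all_labels),
        "auc_folds": fold_auc,
        "aupr_folds": fold_aupr,
        "auc_macro": float(np.mean(fold_auc)),
        "aupr_macro": float(np.mean(fold_aupr)),
        "permuted_auc_mean": float(np.mean(perm_aucs)),
        "recon_loss_first": recon_first,
        "recon_loss_last": recon_last,
        "topk": topk,
        "curves": {
            "FPR": sw["FPR"].tolist(),
            "TPR": sw["TPR"].tolist(),
            "Recall": sw["Recall"].tolist(),
            "Precision": sw["Precision"].tolist(),
        },
        "n_positives": int(len(positives)),
        "n_negatives": int(len(negatives)),
        "config": asdict(config),
    }
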
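"""Literal scalar-loop reference implementations of every model operation.

These are intentionally naive (nested Python loops, no vectorisation) so
they form an independent oracle for the NumPy implementations: they share no
code path with the package beyond `math`/raw indexing.
"""

import math

import numpy as np


def softmax_vec(s):
    m = max(s)
    e = [math.exp(v - m) for v in s]
    tot = sum(e)
    return [v / tot for v in e]


def attention_oracle(U, H, W, b):
    """Per-node attention weights and enhanced features, element by element."""
    N = len(U)
    alpha = np.zeros((N, N))
    X = np.zeros((N, N))
    for i in range(N):
        pre = [sum(W[r][c] * U[i][c] for c in range(N)) + b[r] for r in range(N)]
        t = [math.tanh(v) for v in pre]
        s = [sum(H[r][c] * t[c] for c in range(N)) for r in range(N)]
        a = softmax_vec(s)
        for k in range(N):
            alpha[i][k] = a[k]
            X[i][k] = a[k] * U[i][k]
    return alpha, X


def encode_oracle(X, Utilde, We):
    N = len(X)
    n = len(We[0])
    Z = np.zeros((N, n))
    for i in range(N):
        pre = []
        for j in range(n):
            acc = 0.0
            for k in range(N):
                uk = sum(Utilde[i][m] * X[m][k] for m in range(N))
                acc += uk * We[k][j]
            pre.append(acc)
        Z[i] = softmax_vec(pre)
    return Z


def decode_oracle(Z, Utilde, Wd):
    N = len(Utilde)
    n = len(Z[0])
    Xhat = np.zeros((N, N))
    for i in range(N):
        for j in range(N):
            acc = 0.0
            for k in range(n):
                uz = sum(Utilde[i][m] * Z[m][k] for m in range(N))
                acc += uz * Wd[k][j]
            Xhat[i][j] = 1.0 / (1.0 + math.exp(-acc))
    return Xhat


def mse_oracle(X, Xhat):
    N = len(X)
    total = 0.0
    for i in range(N):
        for j in range(N):
            total += (X[i][j] - Xhat[i][j]) ** 2
    return total / (N * N)


def pair_head_oracle(z_a, z_b, W, b):
    """2-class softmax head on the concatenation of two embeddings."""
    k = list(z_a) + list(z_b)
    logits = [sum(W[c][m] * k[m] for m in range(len(k))) + b[c] for c in range(2)]
    p = softmax_vec(logits)
    return p, p[1]


def conv_oracle(x, W, b):
    """Valid stride-1 cross-correlation + bias + ReLU, quadruple loop."""
    H, Wd, Cin = x.shape
    fh, fw, _, F = W.shape
    Ho, Wo = H - fh + 1, Wd - fw + 1
    out = np.zeros((Ho, Wo, F))
    for m in range(Ho):
        for n in range(Wo):
            for k in range(F):
                acc = b[k]
                for a in range(fh):
                    for c in range(fw):
                        for ch in range(Cin):
                            acc += W[a][c][ch][k] * x[m + a][n + c][ch]
                out[m][n][k] = max(0.0, acc)
    return out


def pool_oracle(x, ph, pw):
    """Stride-1 sliding-window maximum per channel."""
    H, Wd, C = x.shape
    Ho, Wo = H - ph + 1, Wd - pw + 1
    out = np.zeros((Ho, Wo, C))
    for m in range(Ho):
        for n in range(Wo):
            for k in range(C):
                out[m][n][k] = max(
                    x[m + a][n + c][k] for a in range(ph) for c in range(pw)
                )
    return out


def flat_head_oracle(q, W, b):
    logits = [sum(W[c][m] * q[m] for m in range(len(q))) + b[c] for c in range(2)]
    p = softmax_vec(logits)
    return p, p[1]


def wang_profile_oracle(parents, disease, decay):
    """Wang semantic contributions by memoised recursion over descendants."""
    children = {}
    for t, ps in parents.items():
        for p in ps:
            children.setdefault(p, set()).add(t)

    memo = {}

    def contrib(term):
        if term in memo:
            return memo[term]
        if term == disease:
            value = 1.0
        else:
            below = [contrib(c) for c in children.get(term, ()) if reaches(c)]
            value = decay * max(below) if below else 0.0
        memo[term] = value
        return value

    reach_memo = {}

    def reaches(term):
        if term not in reach_memo:
            reach_memo[term] = term == disease or any(
                reaches(c) for c in children.get(term, ())
            )
        return reach_memo[term]

    return {t: contrib(t) for t in parents if reaches(t)}


def wang_similarity_oracle(parents, d1, d2, decay):
    p1 = wang_profile_oracle(parents, d1, decay)
    p2 = wang_profile_oracle(parents, d2, decay)
    shared = set(p1) & set(p2)
    if not shared:
        return 0.0
    return sum(p1[t] + p2[t] for t in shared) / (sum(p1.values()) + sum(p2.values()))


def best_match_oracle(Da, Db, D):
    """Best-match-average functional similarity of two disease index sets."""
    if not Da or not Db:
        return 0.0
    s1 = sum(max(D[d][e] for e in Db) for d in Da)
    s2 = sum(max(D[d][e] for d in Da) for e in Db)
    return (s1 + s2) / (len(Da) + len(Db))


def auc_pairwise_oracle(scores, labels):
    """O(P*N) Mann-Whitney AUC with ties counted one half."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))
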
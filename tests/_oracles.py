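"""Independent brute-force oracles used to verify the vectorized network ops.

Everything here is written with explicit Python loops over scalars (or
near-scalars) and never calls into ldinet's tensor code, so agreement with
the package is a genuine two-route check.
"""

import math

import numpy as np


def matmul_loops(a, b):
    a, b = np.asarray(a), np.asarray(b)
    out = np.zeros((a.shape[0], b.shape[1]))
    for i in range(a.shape[0]):
        for j in range(b.shape[1]):
            for k in range(a.shape[1]):
                out[i, j] += a[i, k] * b[k, j]
    return out


def softmax_row(row):
    m = max(row)
    e = [math.exp(v - m) for v in row]
    s = sum(e)
    return [v / s for v in e]


def scaled_dot_attention_loops(q, k, v):
    """softmax(q·kᵀ/√d_k)·v with scalar loops; q: Lq×d, k,v: Lk×d."""
    q, k, v = np.asarray(q), np.asarray(k), np.asarray(v)
    lq, d = q.shape
    lk = k.shape[0]
    out = np.zeros((lq, v.shape[1]))
    for i in range(lq):
        scores = [sum(q[i, t] * k[j, t] for t in range(d)) / math.sqrt(d)
                  for j in range(lk)]
        weights = softmax_row(scores)
        for c in range(v.shape[1]):
            out[i, c] = sum(weights[j] * v[j, c] for j in range(lk))
    return out


def multi_head_attention_loops(x_q, x_k, x_v, W_Q, W_K, W_V, W_O, heads):
    """Head-by-head attention: split the D×D projections into per-head blocks."""
    d = W_Q.shape[0]
    d_k = d // heads
    q_all = matmul_loops(x_q, W_Q)
    k_all = matmul_loops(x_k, W_K)
    v_all = matmul_loops(x_v, W_V)
    head_outs = []
    for h in range(heads):
        sl = slice(h * d_k, (h + 1) * d_k)
        head_outs.append(
            scaled_dot_attention_loops(q_all[:, sl], k_all[:, sl], v_all[:, sl]))
    concat = np.concatenate(head_outs, axis=1)
    return matmul_loops(concat, W_O)


def gelu_scalar(x):
    return 0.5 * x * (1.0 + math.erf(x / math.sqrt(2.0)))


def mlp_loops(x, W1, b1, W2, b2):
    """linear → GELU → linear, scalar loops, no dropout (eval mode)."""
    x = np.asarray(x)
    h = matmul_loops(x, W1) + b1
    h = np.vectorize(gelu_scalar)(h)
    return matmul_loops(h, W2) + b2


def layer_norm_loops(x, gamma, beta, eps=1e-6):
    x = np.asarray(x, dtype=float)
    out = np.zeros_like(x)
    for i in range(x.shape[0]):
        row = x[i]
        mu = sum(row) / len(row)
        var = sum((v - mu) ** 2 for v in row) / len(row)
        for j in range(len(row)):
            out[i, j] = (row[j] - mu) / math.sqrt(var + eps) * gamma[j] + beta[j]
    return out


def conv2d_same_loops(grid, weight, bias, kernel):
    """Direct nested-loop same-padded convolution on an h×w×C grid.

    weight layout matches the package: (kernel*kernel*C, C_out) with the
    (di, dj) tap at flat index (di*kernel + dj)*C + c.
    """
    h, w, c = grid.shape
    c_out = weight.shape[1]
    p = kernel // 2
    out = np.zeros((h, w, c_out))
    for i in range(h):
        for j in range(w):
            for o in range(c_out):
                acc = bias[o]
                for di in range(kernel):
                    for dj in range(kernel):
                        ii, jj = i + di - p, j + dj - p
                        if 0 <= ii < h and 0 <= jj < w:
                            for ch in range(c):
                                acc += grid[ii, jj, ch] * weight[(di * kernel + dj) * c + ch, o]
                out[i, j, o] = acc
    return out


def weighted_prf_loops(scores, targets, threshold=0.5):
    """Support-weighted P/R/F1 over label columns, computed label by label."""
    scores, targets = np.asarray(scores), np.asarray(targets)
    n, l = scores.shape
    per_label = []
    supports = []
    for j in range(l):
        tp = fp = fn = 0
        for i in range(n):
            pred = scores[i, j] >= threshold
            pos = targets[i, j] == 1
            if pred and pos:
                tp += 1
            elif pred and not pos:
                fp += 1
            elif not pred and pos:
                fn += 1
        p = tp / (tp + fp) if tp + fp else 0.0
        r = tp / (tp + fn) if tp + fn else 0.0
        f = 2 * p * r / (p + r) if p + r else 0.0
        per_label.append((p, r, f))
        supports.append(tp + fn)
    total = sum(supports)
    if total == 0:
        return 0.0, 0.0, 0.0
    pw = sum(s * v[0] for s, v in zip(supports, per_label)) / total
    rw = sum(s * v[1] for s, v in zip(supports, per_label)) / total
    fw = sum(s * v[2] for s, v in zip(supports, per_label)) / total
    return pw, rw, fw
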
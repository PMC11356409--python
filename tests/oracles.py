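"""Independent brute-force oracles used by the unit and acceptance suites.

Everything here is deliberately written as plain nested loops over numpy
scalars, sharing no code with the package's vectorised implementations.
"""

import numpy as np


def conv1x1(x: np.ndarray, weight: np.ndarray, bias: np.ndarray) -> np.ndarray:
    """1x1 convolution of a (c, w, h) array by explicit loops."""
    co = weight.shape[0]
    c, w, h = x.shape
    out = np.zeros((co, w, h))
    for o in range(co):
        for j in range(w):
            for k in range(h):
                acc = bias[o]
                for i in range(c):
                    acc += weight[o, i, 0, 0] * x[i, j, k]
                out[o, j, k] = acc
    return out


def _softmax_rows(scores: np.ndarray) -> np.ndarray:
    out = np.zeros_like(scores)
    for r in range(scores.shape[0]):
        row = scores[r] - scores[r].max()
        e = np.exp(row)
        out[r] = e / e.sum()
    return out


def naive_channel_attention(x, wq, bq, wk, bk, wv, bv):
    """Channel self-attention of a (c, w, h) array, three nested loops."""
    c, w, h = x.shape
    q = conv1x1(x, wq, bq).reshape(wq.shape[0], w * h)
    k = conv1x1(x, wk, bk).reshape(wk.shape[0], w * h)
    v = conv1x1(x, wv, bv).reshape(wv.shape[0], w * h)
    a = q.shape[0]
    scores = np.zeros((a, a))
    for i in range(a):
        for i2 in range(a):
            for p in range(w * h):
                scores[i, i2] += q[i, p] * k[i2, p]
    scores /= np.sqrt(c)
    attn = _softmax_rows(scores)
    out = np.zeros((v.shape[0], w * h))
    for i in range(a):
        for p in range(w * h):
            for i2 in range(a):
                out[i, p] += attn[i, i2] * v[i2, p]
    return out.reshape(v.shape[0], w, h), attn


def naive_spatial_attention(x, wq, bq, wk, bk, wv, bv):
    """Spatial self-attention of a (c, w, h) array, tokens = positions."""
    c, w, h = x.shape
    L = w * h
    q = conv1x1(x, wq, bq).reshape(wq.shape[0], L)
    k = conv1x1(x, wk, bk).reshape(wk.shape[0], L)
    v = conv1x1(x, wv, bv).reshape(wv.shape[0], L)
    a = q.shape[0]
    scores = np.zeros((L, L))
    for p in range(L):
        for p2 in range(L):
            for i in range(a):
                scores[p, p2] += q[i, p] * k[i, p2]
    scores /= np.sqrt(c)
    attn = _softmax_rows(scores)
    out = np.zeros((c, L))
    for i in range(c):
        for p in range(L):
            for p2 in range(L):
                out[i, p] += attn[p, p2] * v[i, p2]
    return out.reshape(c, w, h), attn


def attention_weights(layer):
    """Extract (wq, bq, wk, bk, wv, bv) float64 copies from an attention
    layer's 1x1 conv projections."""
    return (layer.q.weight.data.astype(float), layer.q.bias.data.astype(float),
            layer.k.weight.data.astype(float), layer.k.bias.data.astype(float),
            layer.v.weight.data.astype(float), layer.v.bias.data.astype(float))


def brute_force_surface_distances(pred_b, truth_b):
    """(HD, MSD) by the O(n^2) all-pairs definition."""
    pred_b = np.asarray(pred_b, dtype=float)
    truth_b = np.asarray(truth_b, dtype=float)
    d_pt = np.zeros(len(pred_b))
    for i, p in enumerate(pred_b):
        d_pt[i] = min(np.sqrt(((p - t) ** 2).sum()) for t in truth_b)
    d_tp = np.zeros(len(truth_b))
    for i, t in enumerate(truth_b):
        d_tp[i] = min(np.sqrt(((t - p) ** 2).sum()) for p in pred_b)
    hd = max(d_pt.max(), d_tp.max())
    msd = 0.5 * (d_pt.mean() + d_tp.mean())
    return hd, msd


def brute_force_boundary(mask):
    """Foreground pixels with a background 4-neighbour, by explicit loops."""
    mask = np.asarray(mask).astype(bool)
    hh, ww = mask.shape
    pts = []
    for r in range(hh):
        for c in range(ww):
            if not mask[r, c]:
                continue
            for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
                rr, cc = r + dr, c + dc
                if not (0 <= rr < hh and 0 <= cc < ww) or not mask[rr, cc]:
                    pts.append((r, c))
                    break
    return np.array(pts).reshape(-1, 2)
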
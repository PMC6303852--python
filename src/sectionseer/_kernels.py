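"""Single-threaded numba kernels for the per-example SGD inner loops.

Sentences are passed as CSR arrays (indptr, indices, weights) with weights
already normalized to sum to one per row, so the hidden state is the
weighted average of the touched embedding rows. Only the rows of V indexed
by a sentence's features are updated by that sentence's step (the sparse
update that makes training scale linearly in corpus size). The learning
rate decays linearly from its initial value to zero over all updates.

All kernels are deterministic: example order and negative samples are drawn
by the caller with a seeded generator and passed in as arrays.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def supervised_epoch(indptr, indices, weights, labels, order, V, U, lr0, t0, t_total):
    """One SGD pass over the examples in ``order`` (softmax + NLL).

    Mutates V and U in place. ``t0`` is the number of updates already done
    and ``t_total`` the total planned, for the linear learning-rate decay.
    """
    k, h = U.shape
    hid = np.empty(h, dtype=np.float64)
    ghid = np.empty(h, dtype=np.float64)
    z = np.empty(k, dtype=np.float64)
    for ii in range(order.shape[0]):
        i = order[ii]
        lr = lr0 * (1.0 - (t0 + ii) / t_total)
        lo, hi = indptr[i], indptr[i + 1]
        for d in range(h):
            hid[d] = 0.0
        for j in range(lo, hi):
            f = indices[j]
            w = weights[j]
            for d in range(h):
                hid[d] += w * V[f, d]
        m = -1e300
        for c in range(k):
            s = 0.0
            for d in range(h):
                s += U[c, d] * hid[d]
            z[c] = s
            if s > m:
                m = s
        tot = 0.0
        for c in range(k):
            z[c] = np.exp(z[c] - m)
            tot += z[c]
        y = labels[i]
        for d in range(h):
            ghid[d] = 0.0
        for c in range(k):
            g = z[c] / tot
            if c == y:
                g -= 1.0
            for d in range(h):
                ghid[d] += g * U[c, d]
                U[c, d] -= lr * g * hid[d]
        for j in range(lo, hi):
            f = indices[j]
            w = weights[j]
            for d in range(h):
                V[f, d] -= lr * w * ghid[d]


@njit(cache=True)
def dataset_logits(indptr, indices, weights, V, U):
    """Logit matrix (n_examples x k) for a CSR-encoded dataset."""
    n = indptr.shape[0] - 1
    k, h = U.shape
    out = np.empty((n, k), dtype=np.float64)
    hid = np.empty(h, dtype=np.float64)
    for i in range(n):
        for d in range(h):
            hid[d] = 0.0
        for j in range(indptr[i], indptr[i + 1]):
            f = indices[j]
            w = weights[j]
            for d in range(h):
                hid[d] += w * V[f, d]
        for c in range(k):
            s = 0.0
            for d in range(h):
                s += U[c, d] * hid[d]
            out[i, c] = s
    return out


@njit(cache=True)
def dataset_nll(indptr, indices, weights, labels, V, U):
    """Mean negative log-likelihood over a CSR-encoded dataset."""
    n = indptr.shape[0] - 1
    k, h = U.shape
    hid = np.empty(h, dtype=np.float64)
    z = np.empty(k, dtype=np.float64)
    total = 0.0
    for i in range(n):
        for d in range(h):
            hid[d] = 0.0
        for j in range(indptr[i], indptr[i + 1]):
            f = indices[j]
            w = weights[j]
            for d in range(h):
                hid[d] += w * V[f, d]
        m = -1e300
        for c in range(k):
            s = 0.0
            for d in range(h):
                s += U[c, d] * hid[d]
            z[c] = s
            if s > m:
                m = s
        lse = 0.0
        for c in range(k):
            lse += np.exp(z[c] - m)
        total += m + np.log(lse) - z[labels[i]]
    return total / n


@njit(cache=True)
def negative_sampling_epoch(
    indptr, indices, weights, targets, negatives, order, V, U, lr0, t0, t_total
):
    """One SGD pass of the negative-sampling objective over context pairs.

    For each pair: v_ctx is the weighted average of the context rows of V;
    the target output row is pushed toward v_ctx (label 1) and each sampled
    negative row away from it (label 0). Returns the summed loss of the
    pass, evaluated at the pre-update parameters of each step.
    """
    h = V.shape[1]
    n_neg = negatives.shape[1]
    ctx = np.empty(h, dtype=np.float64)
    gctx = np.empty(h, dtype=np.float64)
    loss = 0.0
    for ii in range(order.shape[0]):
        p = order[ii]
        lr = lr0 * (1.0 - (t0 + ii) / t_total)
        lo, hi = indptr[p], indptr[p + 1]
        for d in range(h):
            ctx[d] = 0.0
        for j in range(lo, hi):
            f = indices[j]
            w = weights[j]
            for d in range(h):
                ctx[d] += w * V[f, d]
        for d in range(h):
            gctx[d] = 0.0
        for m in range(n_neg + 1):
            if m == 0:
                wid = targets[p]
                label = 1.0
            else:
                wid = negatives[p, m - 1]
                label = 0.0
            s = 0.0
            for d in range(h):
                s += U[wid, d] * ctx[d]
            # stable softplus: loss term is softplus(-s) for the positive,
            # softplus(+s) for negatives
            x = -s if label == 1.0 else s
            if x > 0.0:
                loss += x + np.log1p(np.exp(-x))
            else:
                loss += np.log1p(np.exp(x))
            g = 1.0 / (1.0 + np.exp(-s)) - label  # sigmoid(s) - label
            for d in range(h):
                gctx[d] += g * U[wid, d]
                U[wid, d] -= lr * g * ctx[d]
        for j in range(lo, hi):
            f = indices[j]
            w = weights[j]
            for d in range(h):
                V[f, d] -= lr * w * gctx[d]
    return loss
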
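"""Hot inner loops for per-example SGD training.

Compiled with numba when available; the same functions run as plain Python
otherwise (slowly, but bit-identically).
"""

from __future__ import annotations

import math

import numpy as np

try:  # pragma: no cover - environment dependent
    from numba import njit
    HAVE_NUMBA = True
except Exception:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f
        if args and callable(args[0]):
            return args[0]
        return wrap


@njit(cache=True)
def sgd_epoch(wpt, wat, bh, wo, bo,
              core_feats, core_start, core_count,
              allele_idx, allele_enc, target, out_idx,
              order, lr):
    """One pass of per-example SGD updates, in the given example order.

    wpt: (H, Dp) peptide-side weights (transposed), wat: (H, Da)
    allele-side weights, bh: (H,) hidden biases, wo: (H, 2) output weights,
    bo: (2,) output biases.  Weights are updated in place.

    For each example the requested output neuron is evaluated on every
    candidate core, the max-scoring core is selected, and the squared-error
    gradient is backpropagated through that core only.
    """
    H = wpt.shape[0]
    Dp = wpt.shape[1]
    Da = wat.shape[1]
    ph = np.empty(H)
    hcur = np.empty(H)
    hbest = np.empty(H)
    gh = np.empty(H)
    for ii in range(order.shape[0]):
        t = order[ii]
        a = allele_idx[t]
        ae = allele_enc[a]
        o = out_idx[t]
        for j in range(H):
            s = bh[j]
            wj = wat[j]
            for k in range(Da):
                s += ae[k] * wj[k]
            ph[j] = s
        best_out = -1.0
        best_c = 0
        c0 = core_start[t]
        for c in range(core_count[t]):
            row = core_feats[c0 + c]
            opre = bo[o]
            for j in range(H):
                s = ph[j]
                wj = wpt[j]
                for k in range(Dp):
                    s += row[k] * wj[k]
                hj = 1.0 / (1.0 + math.exp(-s))
                hcur[j] = hj
                opre += hj * wo[j, o]
            out = 1.0 / (1.0 + math.exp(-opre))
            if out > best_out:
                best_out = out
                best_c = c
                for j in range(H):
                    hbest[j] = hcur[j]
        err = best_out - target[t]
        if err == 0.0:
            continue
        go = err * best_out * (1.0 - best_out)
        row = core_feats[c0 + best_c]
        for j in range(H):
            gh[j] = go * wo[j, o] * hbest[j] * (1.0 - hbest[j])
        for j in range(H):
            wo[j, o] -= lr * go * hbest[j]
        bo[o] -= lr * go
        for j in range(H):
            g = gh[j]
            if g == 0.0:
                continue
            glr = lr * g
            wj = wpt[j]
            for k in range(Dp):
                wj[k] -= glr * row[k]
            wj = wat[j]
            for k in range(Da):
                wj[k] -= glr * ae[k]
            bh[j] -= glr


@njit(cache=True)
def batch_scores(wpt, wat, bh, wo, bo,
                 core_feats, core_start, core_count,
                 allele_row, out_neuron):
    """Max-over-cores scores of one output neuron for a batch of records
    against a single allele encoding.  Returns (scores, argmax core index)."""
    n = core_start.shape[0]
    H = wpt.shape[0]
    Dp = wpt.shape[1]
    Da = wat.shape[1]
    ph = np.empty(H)
    for j in range(H):
        s = bh[j]
        wj = wat[j]
        for k in range(Da):
            s += allele_row[k] * wj[k]
        ph[j] = s
    scores = np.empty(n)
    best_cores = np.empty(n, dtype=np.int64)
    for t in range(n):
        best = -1.0
        bc = 0
        c0 = core_start[t]
        for c in range(core_count[t]):
            row = core_feats[c0 + c]
            opre = bo[out_neuron]
            for j in range(H):
                s = ph[j]
                wj = wpt[j]
                for k in range(Dp):
                    s += row[k] * wj[k]
                hj = 1.0 / (1.0 + math.exp(-s))
                opre += hj * wo[j, out_neuron]
            out = 1.0 / (1.0 + math.exp(-opre))
            if out > best:
                best = out
                bc = c
        scores[t] = best
        best_cores[t] = c0 + bc
    return scores, best_cores


@njit(cache=True)
def batch_mse(wpt, wat, bh, wo, bo,
              core_feats, core_start, core_count,
              allele_idx, allele_enc, target, out_idx, indices):
    """Mean squared error of the relevant output neuron over ``indices``."""
    total = 0.0
    H = wpt.shape[0]
    Dp = wpt.shape[1]
    Da = wat.shape[1]
    ph = np.empty(H)
    for ii in range(indices.shape[0]):
        t = indices[ii]
        a = allele_idx[t]
        ae = allele_enc[a]
        o = out_idx[t]
        for j in range(H):
            s = bh[j]
            wj = wat[j]
            for k in range(Da):
                s += ae[k] * wj[k]
            ph[j] = s
        best = -1.0
        c0 = core_start[t]
        for c in range(core_count[t]):
            row = core_feats[c0 + c]
            opre = bo[o]
            for j in range(H):
                s = ph[j]
                wj = wpt[j]
                for k in range(Dp):
                    s += row[k] * wj[k]
                hj = 1.0 / (1.0 + math.exp(-s))
                opre += hj * wo[j, o]
            out = 1.0 / (1.0 + math.exp(-opre))
            if out > best:
                best = out
        d = best - target[t]
        total += d * d
    if indices.shape[0] == 0:
        return 0.0
    return total / indices.shape[0]
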
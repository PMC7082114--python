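"""Independently coded brute-force oracles used by the acceptance checks.

Each function evaluates its definition literally (direct summation, explicit
sorting, tail enumeration) without sharing code with the implementations it
verifies.
"""

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import rankdata
from scipy import stats


def tmm_oracle(ys, yr, trim_m=0.3, trim_a=0.05):
    ys, yr = np.asarray(ys, float), np.asarray(yr, float)
    ns, nr = ys.sum(), yr.sum()
    keep = (ys > 0) & (yr > 0)
    ys, yr = ys[keep], yr[keep]
    m = np.log2((ys / ns) / (yr / nr))
    a = 0.5 * np.log2((ys / ns) * (yr / nr))
    n = len(m)
    rm, ra = rankdata(m), rankdata(a)
    lo_m, lo_a = np.floor(n * trim_m) + 1, np.floor(n * trim_a) + 1
    sel = (rm >= lo_m) & (rm <= n + 1 - lo_m) & (ra >= lo_a) & (ra <= n + 1 - lo_a)
    w = 1.0 / ((ns - ys[sel]) / (ns * ys[sel]) + (nr - yr[sel]) / (nr * yr[sel]))
    return 2.0 ** ((w * m[sel]).sum() / w.sum())


def logfc_oracle(ys, yr, ls, lr, prior):
    lbar = (ls + lr) / 2
    ps, pr = prior * ls / lbar, prior * lr / lbar
    return np.log2(((np.asarray(ys, float) + ps) / (ls + 2 * ps)) / ((np.asarray(yr, float) + pr) / (lr + 2 * pr)))


def quantile_oracle(mat):
    values = mat.to_numpy(float)
    n, k = values.shape
    target = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    for j in range(k):
        col = values[:, j]
        order = np.argsort(col, kind="stable")
        pos_of = np.empty(n, int)
        pos_of[order] = np.arange(n)
        for i in range(n):
            ties = np.flatnonzero(col == col[i])
            out[i, j] = target[[pos_of[t] for t in ties]].mean()
    return pd.DataFrame(out, index=mat.index, columns=mat.columns)


def q1_oracle(vals):
    s = np.sort(np.asarray(vals, float))
    h = 0.25 * (len(s) - 1)
    lo, hi = int(np.floor(h)), int(np.ceil(h))
    return s[lo] + (h - lo) * (s[hi] - s[lo])


def median_oracle(vals):
    s = np.sort(np.asarray(vals, float))
    n = len(s)
    return s[n // 2] if n % 2 else (s[n // 2 - 1] + s[n // 2]) / 2


def bh_oracle(p):
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


def welch_oracle(a, b):
    a, b = np.asarray(a, float), np.asarray(b, float)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    t = (a.mean() - b.mean()) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
    return t, 2 * stats.t.sf(abs(t), df)


def exact_test_oracle(y1, y2, lib1, lib2, phi):
    t = int(y1 + y2)
    if t == 0:
        return 1.0
    r = 1.0 / phi
    frac = lib1 / (lib1 + lib2)
    mu1, mu2 = t * frac, t * (1 - frac)

    def logpmf(k, mu):
        return (
            gammaln(k + r) - gammaln(r) - gammaln(k + 1)
            + r * np.log(r / (r + mu)) + k * np.log(mu / (r + mu))
        )

    probs = np.array([np.exp(logpmf(k, mu1) + logpmf(t - k, mu2)) for k in range(t + 1)])
    obs = probs[int(y1)]
    return probs[probs <= obs * (1 + 1e-10)].sum() / probs.sum()


def tss_window_oracle(intervals, tss, window, bin_size):
    """Per-base densification and explicit bin averaging ('+' strand)."""
    hi = int(max(e for _, e, _ in intervals))
    dense = np.zeros(hi)
    for s, e, v in intervals:
        dense[int(s) : int(e)] = v
    win = dense[tss - window : tss + window]
    return win.reshape(2 * window // bin_size, bin_size).mean(axis=1)
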
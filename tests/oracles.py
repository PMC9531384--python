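"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written as directly as possible (explicit Python loops,
textbook formulas) and never reuses package code paths.
"""

from __future__ import annotations

import math

import numpy as np


def glcm_bruteforce(levels, mask, offsets, symmetric, n_levels):
    """Pair-enumeration GLCM: explicit double loop over pixels and offsets."""
    h, w = levels.shape
    counts = np.zeros((n_levels, n_levels), dtype=float)
    for r in range(h):
        for c in range(w):
            if not mask[r, c]:
                continue
            for dr, dc in offsets:
                r2, c2 = r + dr, c + dc
                if 0 <= r2 < h and 0 <= c2 < w and mask[r2, c2]:
                    i, j = levels[r, c], levels[r2, c2]
                    counts[i, j] += 1
                    if symmetric:
                        counts[j, i] += 1
    total = counts.sum()
    if total == 0:
        raise ValueError("no pairs")
    return counts / total, int(total)


def features_bruteforce(P, log_base=2.0):
    """The nine texture features by direct double loops over the matrix."""
    n = P.shape[0]
    px = [sum(P[i][j] for j in range(n)) for i in range(n)]
    py = [sum(P[i][j] for i in range(n)) for j in range(n)]
    mu_x = sum(i * px[i] for i in range(n))
    mu_y = sum(j * py[j] for j in range(n))
    sig_x = math.sqrt(sum((i - mu_x) ** 2 * px[i] for i in range(n)))
    sig_y = math.sqrt(sum((j - mu_y) ** 2 * py[j] for j in range(n)))
    mu = 0.5 * (mu_x + mu_y)

    energy = contrast = entropy = homog = dissim = autocorr = variance = 0.0
    corr_num = 0.0
    for i in range(n):
        for j in range(n):
            p = P[i][j]
            energy += p * p
            contrast += p * (i - j) ** 2
            if p > 0:
                entropy -= p * math.log(p, log_base)
            homog += p / (1 + abs(i - j))
            dissim += p * abs(i - j)
            autocorr += i * j * p
            variance += (i - mu) ** 2 * p
            corr_num += (i - mu_x) * (j - mu_y) * p
    correlation = corr_num / (sig_x * sig_y) if sig_x * sig_y > 0 else float("nan")
    sum_average = 0.0
    for k in range(2 * n - 1):
        p_k = sum(P[i][k - i] for i in range(n) if 0 <= k - i < n)
        sum_average += k * p_k
    return {
        "energy": energy,
        "contrast": contrast,
        "entropy": entropy,
        "homogeneity": homog,
        "correlation": correlation,
        "sum_average": sum_average,
        "variance": variance,
        "dissimilarity": dissim,
        "autocorrelation": autocorr,
    }


def otsu_bruteforce(values):
    """Exhaustive scan over all candidate cuts for the between-class
    variance maximizer; returns (low-class max, high-class min)."""
    v = np.sort(np.asarray(values, dtype=float).ravel())
    uniq = np.unique(v)
    best, best_pair = -1.0, None
    n = v.size
    for k in range(uniq.size - 1):
        lo = v[v <= uniq[k]]
        hi = v[v > uniq[k]]
        w0, w1 = lo.size / n, hi.size / n
        bcv = w0 * w1 * (lo.mean() - hi.mean()) ** 2
        if bcv > best + 1e-15:
            best = bcv
            best_pair = (uniq[k], uniq[k + 1])
    return best_pair, best


def auc_pair_counting(scores, labels):
    """AUC = (concordant + 0.5 * ties) / (n1 * n0) by explicit enumeration."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    pos = scores[labels]
    neg = scores[~labels]
    conc = ties = 0
    for p in pos:
        for q in neg:
            if p > q:
                conc += 1
            elif p == q:
                ties += 1
    return (conc + 0.5 * ties) / (len(pos) * len(neg))


def icc2_closed_form(x, y):
    """ICC(2,1): two-way random effects, absolute agreement, single measure,
    from the classical ANOVA mean squares for n targets x 2 raters."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n, k = x.size, 2
    data = np.column_stack([x, y])
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((data - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
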
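"""Independent brute-force oracles used only by the tests.

Everything here is written as plain double loops over matrix cells or
case pairs, deliberately sharing no code with the package, so agreement
is evidence of correctness rather than of shared bugs.
"""

import math

import numpy as np

OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


def naive_glcm(levels, mask, n_levels, d, theta, symmetric=True,
               normalize=True):
    """Exhaustive pair enumeration over every pixel."""
    dr, dc = OFFSETS[theta]
    dr, dc = dr * d, dc * d
    h, w = levels.shape
    counts = np.zeros((n_levels, n_levels))
    for r in range(h):
        for c in range(w):
            r2, c2 = r + dr, c + dc
            if not mask[r, c]:
                continue
            if 0 <= r2 < h and 0 <= c2 < w and mask[r2, c2]:
                counts[levels[r, c], levels[r2, c2]] += 1
                if symmetric:
                    counts[levels[r2, c2], levels[r, c]] += 1
    if normalize and counts.sum() > 0:
        counts = counts / counts.sum()
    return counts


def _log(v, base):
    return math.log(v) / math.log(base)


def naive_glcm_features(p, log_base=2.0):
    """All 14 canonical features by cell-wise double loops."""
    G = len(p)
    px = [sum(p[i][j] for j in range(G)) for i in range(G)]
    py = [sum(p[i][j] for i in range(G)) for j in range(G)]
    mu_x = sum(i * px[i] for i in range(G))
    mu_y = sum(j * py[j] for j in range(G))
    sigma_x = math.sqrt(sum((i - mu_x) ** 2 * px[i] for i in range(G)))
    sigma_y = math.sqrt(sum((j - mu_y) ** 2 * py[j] for j in range(G)))
    p_diff = [0.0] * G
    for i in range(G):
        for j in range(G):
            p_diff[abs(i - j)] += p[i][j]
    mu_d = sum(k * p_diff[k] for k in range(G))

    auto = corr = prom = shade = contrast = dissim = energy = 0.0
    entropy = homog = idn = idm = hxy1 = 0.0
    for i in range(G):
        for j in range(G):
            v = p[i][j]
            auto += i * j * v
            contrast += (i - j) ** 2 * v
            prom += (i + j - mu_x - mu_y) ** 4 * v
            shade += (i + j - mu_x - mu_y) ** 3 * v
            dissim += abs(i - j) * v
            energy += v * v
            homog += v / (1 + abs(i - j))
            idn += v / (1 + abs(i - j) / G)
            idm += v / (1 + (i - j) ** 2)
            if v > 0:
                entropy -= v * _log(v, log_base)
                corr += (i - mu_x) * (j - mu_y) * v
                hxy1 -= v * _log(px[i] * py[j], log_base)
    degenerate = sigma_x * sigma_y == 0
    corr = 0.0 if degenerate else corr / (sigma_x * sigma_y)
    hx = -sum(v * _log(v, log_base) for v in px if v > 0)
    hy = -sum(v * _log(v, log_base) for v in py if v > 0)
    hxy = entropy
    denom = max(hx, hy)
    imc1 = 0.0 if (degenerate or denom == 0) else (hxy - hxy1) / denom
    diff_var = sum((k - mu_d) ** 2 * p_diff[k] for k in range(G))
    diff_ent = -sum(v * _log(v, log_base) for v in p_diff if v > 0)
    return {
        "glcm_autocorrelation": auto,
        "glcm_contrast": contrast,
        "glcm_correlation": corr,
        "glcm_cluster_prominence": prom,
        "glcm_cluster_shade": shade,
        "glcm_dissimilarity": dissim,
        "glcm_energy": energy,
        "glcm_entropy": entropy,
        "glcm_homogeneity": homog,
        "glcm_difference_variance": diff_var,
        "glcm_difference_entropy": diff_ent,
        "glcm_info_measure_correlation": imc1,
        "glcm_inverse_difference_normalized": idn,
        "glcm_inverse_difference_moment": idm,
    }


def naive_moments(xs):
    """Two-pass population moments by explicit summation."""
    n = len(xs)
    mean = sum(xs) / n
    var = sum((x - mean) ** 2 for x in xs) / n
    if var == 0:
        return mean, 0.0, 0.0, 0.0
    std = math.sqrt(var)
    skew = sum(((x - mean) / std) ** 3 for x in xs) / n
    kurt = sum(((x - mean) / std) ** 4 for x in xs) / n
    return mean, var, skew, kurt


def naive_auc(scores, truth):
    """Proportion of correctly ordered positive-negative pairs, ties 1/2."""
    pos = [s for s, t in zip(scores, truth) if t == 1]
    neg = [s for s, t in zip(scores, truth) if t == 0]
    total = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                total += 1.0
            elif sp == sn:
                total += 0.5
    return total / (len(pos) * len(neg))


def fisher_p_enumeration(k1, n1, k2, n2):
    """Two-sided Fisher p by exhaustive hypergeometric enumeration."""
    K = k1 + k2
    N = n1 + n2

    def hyper(x):
        return (math.comb(n1, x) * math.comb(n2, K - x)) / math.comb(N, K)

    p_obs = hyper(k1)
    total = 0.0
    for x in range(max(0, K - n2), min(K, n1) + 1):
        px = hyper(x)
        if px <= p_obs * (1 + 1e-12):
            total += px
    return min(total, 1.0)
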
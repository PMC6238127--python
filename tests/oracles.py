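"""Independent brute-force reference implementations used only by tests.

These deliberately use direct loops over cells / training points /
candidate thresholds so they stay structurally independent of the
vectorized production code they check.
"""

import itertools
import math

import numpy as np


def fgm_oracle(a, b, radius, halving):
    """Direct-loop fuzzy global matching of two aligned CategoricalMaps."""
    rows, cols = a.shape
    av, bv = a.values, b.values
    a_nodata, b_nodata = a.nodata_code, b.nodata_code

    def membership(values, nodata, r0, c0, cat):
        best = 0.0
        for r in range(rows):
            for c in range(cols):
                if values[r, c] != cat or values[r, c] == nodata:
                    continue
                d = math.hypot(r - r0, c - c0)
                if d <= radius:
                    best = max(best, 2.0 ** (-d / halving))
        return best

    sims = []
    for r in range(rows):
        for c in range(cols):
            if av[r, c] == a_nodata or bv[r, c] == b_nodata:
                continue
            s_ab = membership(av, a_nodata, r, c, bv[r, c])
            s_ba = membership(bv, b_nodata, r, c, av[r, c])
            sims.append(min(s_ab, s_ba))
    return sum(sims) / len(sims)


def auc_oracle(presence_scores, absence_scores):
    """Pairwise concordance count: ties count one half."""
    wins = 0.0
    for p in presence_scores:
        for a in absence_scores:
            if p > a:
                wins += 1.0
            elif p == a:
                wins += 0.5
    return wins / (len(presence_scores) * len(absence_scores))


def threshold_oracle(presence_scores, absence_scores):
    """Exhaustive scan over all unique candidate thresholds."""
    p = np.asarray(presence_scores, dtype=float)
    a = np.asarray(absence_scores, dtype=float)
    best_t, best_j = None, -np.inf
    for t in sorted(set(np.concatenate([p, a]))):
        sens = float((p >= t).mean())
        spec = float((a < t).mean())
        j = sens + spec - 1.0
        if j > best_j:  # strict: keeps the smallest tied threshold
            best_j, best_t = j, t
    return best_t


def bioclim_oracle(sorted_samples, layer_names, stack):
    """Per-cell loop version of the envelope score."""
    template = stack.template
    out = np.full(template.shape, np.nan)
    for r in range(template.n_rows):
        for c in range(template.n_cols):
            if not template.valid_mask[r, c]:
                continue
            score = 1.0
            for name in layer_names:
                x = stack[name].values[r, c]
                s = sorted_samples[name]
                if x < s[0] or x > s[-1]:
                    score = 0.0
                    break
                n = len(s)
                less = sum(1 for v in s if v < x)
                equal = sum(1 for v in s if v == x)
                f = (less + 0.5 * equal) / n
                score = min(score, min(2.0 * min(f, 1.0 - f), 1.0))
            out[r, c] = score
    return out


def domain_oracle(train, ranges, layer_names, stack):
    """Per-cell loop version of the max Gower similarity."""
    template = stack.template
    out = np.full(template.shape, np.nan)
    p = len(layer_names)
    for r in range(template.n_rows):
        for c in range(template.n_cols):
            if not template.valid_mask[r, c]:
                continue
            cell = [stack[name].values[r, c] for name in layer_names]
            best = -np.inf
            for row in train:
                d = sum(abs(cell[k] - row[k]) / ranges[k] for k in range(p)) / p
                best = max(best, 1.0 - d)
            out[r, c] = min(max(best, 0.0), 1.0)
    return out


def spearman_exact_p(x, y):
    """Exact two-sided permutation p-value for Spearman rho (tiny n)."""
    from scipy.stats import rankdata

    rx = rankdata(x)
    ry = rankdata(y)

    def pearson(a, b):
        a = np.asarray(a, dtype=float) - np.mean(a)
        b = np.asarray(b, dtype=float) - np.mean(b)
        return float(np.sum(a * b) / math.sqrt(np.sum(a * a) * np.sum(b * b)))

    rho = pearson(rx, ry)
    count = 0
    total = 0
    for perm in itertools.permutations(ry):
        total += 1
        if abs(pearson(rx, perm)) >= abs(rho) - 1e-12:
            count += 1
    return rho, count / total
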
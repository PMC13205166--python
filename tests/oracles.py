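"""Independent brute-force oracles shared by the test modules.

These deliberately avoid the package's vectorized code paths: co-occurrence
counting by triple loop, mutual information from Counter-based joint tables,
and greedy MRMR by exhaustive re-scoring.
"""

from collections import Counter

import numpy as np


def brute_force_pair_counts(volume_levels, mask, offset, ng):
    """Per-pair counting oracle for the symmetric GLCM of one offset."""
    counts = np.zeros((ng, ng))
    shape = mask.shape
    for i in range(shape[0]):
        for j in range(shape[1]):
            for k in range(shape[2]):
                ii, jj, kk = i + offset[0], j + offset[1], k + offset[2]
                if not (0 <= ii < shape[0] and 0 <= jj < shape[1] and 0 <= kk < shape[2]):
                    continue
                if mask[i, j, k] and mask[ii, jj, kk]:
                    a, b = volume_levels[i, j, k], volume_levels[ii, jj, kk]
                    counts[a, b] += 1
                    counts[b, a] += 1
    return counts


def oracle_bin(x, n_bins=4):
    """Equal-frequency binning (same lower-quantile convention)."""
    edges = np.quantile(x, [q / n_bins for q in range(1, n_bins)], method="lower")
    return np.searchsorted(edges, x, side="right")


def oracle_mi(a, b):
    """Plug-in mutual information (bits) from a Counter-based joint table.

    Summed with ``math.fsum`` so permutation-equivalent joint tables give
    bit-identical values.
    """
    import math

    n = len(a)
    joint = Counter(zip(a, b))
    pa = Counter(a)
    pb = Counter(b)
    terms = [
        (c / n) * np.log2((c / n) / ((pa[u] / n) * (pb[v] / n)))
        for (u, v), c in joint.items()
    ]
    return math.fsum(sorted(terms))


def oracle_greedy_mrmr(X, y, discrete=(), n_bins=4):
    """Exhaustive greedy MRMR under the difference criterion."""
    cols = list(X.columns)
    binned = {
        c: (tuple(X[c]) if c in discrete else tuple(oracle_bin(X[c].to_numpy(), n_bins)))
        for c in cols
    }
    yb = tuple(y)
    relevance = {c: oracle_mi(binned[c], yb) for c in cols}
    selected, scores = [], []
    remaining = list(cols)
    while remaining:
        best, best_score = None, -np.inf
        for c in remaining:  # first-seen wins ties = column order
            red = (
                np.mean([oracle_mi(binned[c], binned[s]) for s in selected])
                if selected
                else 0.0
            )
            score = round(relevance[c] - red, 10)  # noise-robust tie handling
            if score > best_score:
                best, best_score = c, score
        selected.append(best)
        scores.append(best_score)
        remaining.remove(best)
    return selected, scores


def oracle_pairwise_auc(scores, labels):
    """AUC by exhaustive concordant/tied pair enumeration."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    total, conc = 0, 0.0
    for i in np.where(labels == 1)[0]:
        for j in np.where(labels == 0)[0]:
            total += 1
            if scores[i] > scores[j]:
                conc += 1.0
            elif scores[i] == scores[j]:
                conc += 0.5
    return conc / total
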
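"""Independent brute-force oracles used to verify the implementation.

These deliberately avoid the package's vectorised code paths: plain Python
loops, ``math.exp``, and first-principles formulas only.
"""

import math


def brute_force_nll(thresholds, beta, y_labels, X, levels):
    """Ordinal-logistic negative log-likelihood by full enumeration.

    For every observation, the probability of *each* category is computed as
    a difference of logistic CDFs and the observed one picked out.
    """
    K = len(levels)
    total = 0.0
    for i, label in enumerate(y_labels):
        eta = 0.0
        for j in range(len(beta)):
            eta += X[i][j] * beta[j]
        cum = []
        for t in thresholds:
            z = t - eta
            cum.append(1.0 / (1.0 + math.exp(-z)))
        cum.append(1.0)
        probs = [cum[0]]
        for k in range(1, K):
            probs.append(cum[k] - cum[k - 1])
        total -= math.log(probs[levels.index(label)])
    return total


def average_ranks(values):
    """Average ranks (1-based) with ties shared, by direct enumeration."""
    n = len(values)
    ranks = [0.0] * n
    for i, v in enumerate(values):
        less = sum(1 for w in values if w < v)
        equal = sum(1 for w in values if w == v)
        ranks[i] = less + (equal + 1) / 2.0
    return ranks


def pearson_on_ranks(x, y):
    """Spearman rho as the Pearson correlation of average ranks."""
    rx, ry = average_ranks(list(x)), average_ranks(list(y))
    n = len(rx)
    mx = sum(rx) / n
    my = sum(ry) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    sxx = sum((a - mx) ** 2 for a in rx)
    syy = sum((b - my) ** 2 for b in ry)
    return sxy / math.sqrt(sxx * syy)
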
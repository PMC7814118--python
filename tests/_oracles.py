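"""Independent brute-force oracles used to check the fast implementations.

Everything here is deliberately naive (explicit loops, O(n^2) scans) and
shares no code with the package.
"""

import numpy as np


def concordance_pairwise(times, events, scores):
    """Harrell's C by exhaustive pair enumeration."""
    n = len(times)
    num = 0.0
    den = 0
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            usable = (events[i] == 1 and times[i] < times[j]) or (
                events[i] == 1 and events[j] == 0 and times[i] == times[j]
            )
            if not usable:
                continue
            den += 1
            if scores[i] > scores[j]:
                num += 1.0
            elif scores[i] == scores[j]:
                num += 0.5
    return num / den


def auc_mann_whitney(labels, scores):
    """AUC as the Mann-Whitney U statistic over all positive/negative pairs."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    u = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                u += 1.0
            elif p == q:
                u += 0.5
    return u / (len(pos) * len(neg))


def youden_at(values, labels, cut):
    """|sensitivity + specificity - 1| of the 'above cut' indicator, by direct
    counting (equals the maximum over the two cutpoint orientations)."""
    tp = sum(1 for v, y in zip(values, labels) if y == 1 and v > cut)
    fn = sum(1 for v, y in zip(values, labels) if y == 1 and v <= cut)
    fp = sum(1 for v, y in zip(values, labels) if y == 0 and v > cut)
    tn = sum(1 for v, y in zip(values, labels) if y == 0 and v <= cut)
    j_high = tp / (tp + fn) - fp / (fp + tn)
    return max(j_high, -j_high)


def best_cutpoint_exhaustive(values, labels, min_group_frac):
    """Exhaustive scan over every admissible midpoint candidate; returns
    (best metric value, list of candidates achieving it)."""
    v = sorted(set(values))
    n = len(values)
    floor_size = max(int(np.floor(min_group_frac * n)), 1)
    best = None
    argbest = []
    for a, b in zip(v[:-1], v[1:]):
        cut = (a + b) / 2.0
        n_high = sum(1 for x in values if x > cut)
        if min(n_high, n - n_high) < floor_size:
            continue
        j = youden_at(values, labels, cut)
        if best is None or j > best + 1e-12:
            best, argbest = j, [cut]
        elif abs(j - best) <= 1e-12:
            argbest.append(cut)
    return best, argbest


def empirical_survival(times, t):
    """Fraction surviving strictly past t (censor-free oracle)."""
    return sum(1 for x in times if x > t) / len(times)
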
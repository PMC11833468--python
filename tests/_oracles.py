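"""Independent brute-force oracles used to verify the package's metrics and
clustering. Everything here is written from first principles with explicit
loops — no scipy/sklearn calls and no imports from the package — so a test
comparing package output against these is a genuine dual-route check."""

from __future__ import annotations

import math


# -- confusion-matrix metrics -------------------------------------------------

def confusion(pred, gold):
    tp = fp = fn = tn = 0
    for p, g in zip(pred, gold):
        if p == 1 and g == 1:
            tp += 1
        elif p == 1 and g == 0:
            fp += 1
        elif p == 0 and g == 1:
            fn += 1
        else:
            tn += 1
    return tp, fp, fn, tn


def oracle_recall(pred, gold):
    tp, fp, fn, tn = confusion(pred, gold)
    return tp / (tp + fn) if tp + fn else None


def oracle_precision(pred, gold):
    tp, fp, fn, tn = confusion(pred, gold)
    return tp / (tp + fp) if tp + fp else None


def oracle_f1(pred, gold):
    tp, fp, fn, tn = confusion(pred, gold)
    denom = 2 * tp + fp + fn
    return 2 * tp / denom if denom else None


def oracle_accuracy(pred, gold):
    tp, fp, fn, tn = confusion(pred, gold)
    return (tp + tn) / len(pred)


def oracle_kappa(x, y):
    """Cohen's kappa on arbitrary categorical labels, direct from the formula;
    degenerate chance-agreement-1 handled as perfect->1.0 else 0.0."""
    n = len(x)
    labels = sorted(set(x) | set(y))
    p_o = sum(1 for a, b in zip(x, y) if a == b) / n
    p_e = 0.0
    for lab in labels:
        p_e += (sum(1 for a in x if a == lab) / n) * (sum(1 for b in y if b == lab) / n)
    if abs(1.0 - p_e) < 1e-12:
        return 1.0 if p_o == 1.0 else 0.0
    return (p_o - p_e) / (1.0 - p_e)


def oracle_auc(scores, gold):
    """ROC AUC by positive/negative pair counting with ties worth 1/2."""
    pos = [s for s, g in zip(scores, gold) if g == 1]
    neg = [s for s, g in zip(scores, gold) if g == 0]
    if not pos or not neg:
        return None
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


# -- count metrics ------------------------------------------------------------

def midranks(values):
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def oracle_spearman(x, y):
    """Spearman rho = Pearson correlation of midranks, by direct sums."""
    rx, ry = midranks(x), midranks(y)
    n = len(rx)
    mx, my = sum(rx) / n, sum(ry) / n
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    dx = math.sqrt(sum((a - mx) ** 2 for a in rx))
    dy = math.sqrt(sum((b - my) ** 2 for b in ry))
    if dx == 0 or dy == 0:
        return None
    return num / (dx * dy)


def oracle_mae(pred, gold):
    return sum(abs(p - g) for p, g in zip(pred, gold)) / len(pred)


def oracle_bin(value, bins):
    """Index of the bin whose left edge is the largest not exceeding value."""
    label = 0
    for i, edge in enumerate(bins):
        if value >= edge:
            label = i
    return label


def oracle_binned_kappa(pred, gold, bins):
    return oracle_kappa([oracle_bin(v, bins) for v in pred],
                        [oracle_bin(v, bins) for v in gold])


# -- cosine dedup -------------------------------------------------------------

def _cos(u, v):
    du = math.sqrt(sum(a * a for a in u))
    dv = math.sqrt(sum(b * b for b in v))
    return sum(a * b for a, b in zip(u, v)) / (du * dv)


def oracle_dedup(vectors, threshold):
    """Greedy first-kept scan: item i merges into the earliest kept item with
    cosine similarity >= threshold. Returns (kept indices, merge map)."""
    kept = []
    merge_map = {}
    for i, v in enumerate(vectors):
        target = None
        for j in kept:
            if _cos(vectors[j], v) >= threshold - 1e-12:
                target = j
                break
        if target is None:
            kept.append(i)
            merge_map[i] = i
        else:
            merge_map[i] = target
    return kept, merge_map


# -- exhaustive Ward linkage --------------------------------------------------

def oracle_ward(points):
    """Exhaustive agglomerative Ward: at each step evaluate the within-cluster
    variance increase of every cluster pair directly from the raw points and
    merge the minimum (ties: smallest index pair). Heights are sqrt(2 * dESS),
    the Euclidean-commensurate scale. Returns a list of merges as
    (frozenset_of_leaves_a, frozenset_of_leaves_b, height)."""
    pts = [list(map(float, p)) for p in points]
    clusters = [frozenset([i]) for i in range(len(pts))]
    merges = []
    while len(clusters) > 1:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                ca, cb = clusters[a], clusters[b]
                na, nb = len(ca), len(cb)
                mean_a = [sum(pts[i][d] for i in ca) / na for d in range(len(pts[0]))]
                mean_b = [sum(pts[i][d] for i in cb) / nb for d in range(len(pts[0]))]
                gap2 = sum((x - y) ** 2 for x, y in zip(mean_a, mean_b))
                d_ess = na * nb / (na + nb) * gap2
                if best is None or d_ess < best[0]:
                    best = (d_ess, a, b)
        d_ess, a, b = best
        merges.append((clusters[a], clusters[b], math.sqrt(2.0 * d_ess)))
        merged = clusters[a] | clusters[b]
        clusters = [c for k, c in enumerate(clusters) if k not in (a, b)] + [merged]
    return merges
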
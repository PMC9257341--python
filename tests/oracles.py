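"""Brute-force reference implementations, independent of the package code.

Everything here is written as the most literal O(n²) / per-pixel version of
each definition, so the optimized implementations can be checked exactly.
"""

import itertools
import math

import numpy as np


def brute_edges(points, radius):
    """All unordered index pairs with Euclidean distance <= radius."""
    pts = np.asarray(points, dtype=float)
    out = set()
    for i in range(len(pts)):
        for j in range(i + 1, len(pts)):
            if math.dist(pts[i], pts[j]) <= radius:
                out.add((i, j))
    return out


def brute_observed(points, labels, radius, cluster_a, cluster_b):
    """Fraction of A cells with at least one B cell within the radius."""
    pts = np.asarray(points, dtype=float)
    labels = list(labels)
    a_idx = [i for i, l in enumerate(labels) if l == cluster_a]
    if not a_idx:
        return float("nan")
    hits = 0
    for i in a_idx:
        for j in range(len(pts)):
            if j == i or labels[j] != cluster_b:
                continue
            if math.dist(pts[i], pts[j]) <= radius:
                hits += 1
                break
    return hits / len(a_idx)


def brute_expand(mask, distance):
    """Nearest-labeled-pixel expansion; ties go to the lower label id."""
    mask = np.asarray(mask)
    out = mask.copy()
    labeled = list(zip(*np.nonzero(mask)))
    for y in range(mask.shape[0]):
        for x in range(mask.shape[1]):
            if mask[y, x]:
                continue
            best_d2 = None
            best_label = None
            for ly, lx in labeled:
                d2 = (y - ly) ** 2 + (x - lx) ** 2
                lab = int(mask[ly, lx])
                if best_d2 is None or d2 < best_d2 or (d2 == best_d2 and lab < best_label):
                    best_d2, best_label = d2, lab
            if best_d2 is not None and best_d2 <= distance * distance:
                out[y, x] = best_label
    return out


def brute_fractions(mask, channel):
    """Per-label positive-pixel fraction by explicit pixel loop."""
    out = {}
    for lab in np.unique(mask):
        if lab == 0:
            continue
        total = pos = 0
        for y in range(mask.shape[0]):
            for x in range(mask.shape[1]):
                if mask[y, x] == lab:
                    total += 1
                    pos += int(channel[y, x] > 0)
        out[int(lab)] = pos / total
    return out


def enumerate_permutation_z(points, labels, radius, cluster_a, cluster_b):
    """Exact permutation z by enumerating all distinct label arrangements.

    Uses the population standard deviation over the uniform distribution on
    multiset permutations, which is what sampled permutations estimate.
    """
    labels = list(labels)
    obs_real = brute_observed(points, labels, radius, cluster_a, cluster_b)
    seen = set()
    vals = []
    for perm in itertools.permutations(labels):
        if perm in seen:
            continue
        seen.add(perm)
        vals.append(brute_observed(points, perm, radius, cluster_a, cluster_b))
    vals = np.array(vals)
    sd = vals.std(ddof=0)
    if sd == 0:
        return 0.0
    return (obs_real - vals.mean()) / sd
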
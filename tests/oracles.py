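"""Independent naive-loop oracles used to cross-check the package.

Everything here is written as directly as possible from the definitions —
per node, per transition, with explicit Python loops and sets — and shares
no code with the package implementations it checks.
"""

import itertools

import numpy as np


def brute_promiscuity(row, K):
    return len(set(int(x) for x in row)) / K


def brute_flexibility(row):
    T = len(row)
    return sum(1 for t in range(T - 1) if row[t] != row[t + 1]) / (T - 1)


def brute_cohesion_disjointedness(labels):
    """Per-node (cohesion, disjointedness) by explicit partner search."""
    labels = np.asarray(labels)
    n, T = labels.shape
    coh = [0] * n
    dis = [0] * n
    for i in range(n):
        for t in range(T - 1):
            if labels[i, t] == labels[i, t + 1]:
                continue
            partnered = any(
                j != i
                and labels[j, t] == labels[i, t]
                and labels[j, t + 1] == labels[i, t + 1]
                for j in range(n)
            )
            if partnered:
                coh[i] += 1
            else:
                dis[i] += 1
    return [c / (T - 1) for c in coh], [d / (T - 1) for d in dis]


def brute_metrics(labels, K):
    """All four metrics for one assignment matrix, as plain lists."""
    labels = np.asarray(labels)
    coh, dis = brute_cohesion_disjointedness(labels)
    return {
        "promiscuity": [brute_promiscuity(row, K) for row in labels],
        "flexibility": [brute_flexibility(row) for row in labels],
        "cohesion": coh,
        "disjointedness": dis,
    }


def best_two_community_partition(weights):
    """Exhaustive search for the 2-community split maximizing total
    within-community weight (n small)."""
    n = weights.shape[0]
    best, best_score = None, -np.inf
    for assignment in itertools.product([1, 2], repeat=n):
        if len(set(assignment)) < 2:  # both communities must be populated
            continue
        score = sum(
            weights[i, j]
            for i in range(n)
            for j in range(i + 1, n)
            if assignment[i] == assignment[j]
        )
        if score > best_score:
            best, best_score = assignment, score
    return np.array(best), best_score


def brute_retained_regions(coverage_values, columns, cov_thr, subj_frac):
    """Double-loop coverage-exclusion rule."""
    n_subj, n_reg = coverage_values.shape
    retained = []
    for j in range(n_reg):
        n_low = 0
        for i in range(n_subj):
            if coverage_values[i, j] < cov_thr:
                n_low += 1
        if n_low / n_subj <= subj_frac:
            retained.append(columns[j])
    return retained
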
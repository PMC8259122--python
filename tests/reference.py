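"""Naive loop-based reference implementations of the four FCA metrics.

Written directly from the defining formulas with explicit Python loops, and
kept deliberately independent of the vectorized package code so they can
serve as oracles.
"""

import math


def ref_decay(tau, threshold, floor):
    if tau > threshold:
        return 0.0
    b = threshold**2 / math.log(1.0 / floor)
    return math.exp(-(tau**2) / b)


def ref_clmfca(populations, capacities, probs, within):
    n_i, n_j = len(populations), len(capacities)
    ratios = []
    for j in range(n_j):
        dem = sum(populations[i] * probs[i][j] for i in range(n_i))
        ratios.append(capacities[j] / dem if dem > 0 else 0.0)
    scores = []
    for i in range(n_i):
        scores.append(sum(ratios[j] * probs[i][j] for j in range(n_j) if within[i][j]))
    return scores


def ref_two_sfca(populations, capacities, within):
    n_i, n_j = len(populations), len(capacities)
    ratios = []
    for j in range(n_j):
        pop = sum(populations[i] for i in range(n_i) if within[i][j])
        ratios.append(capacities[j] / pop if pop > 0 else 0.0)
    return [
        sum(ratios[j] for j in range(n_j) if within[i][j])
        for i in range(n_i)
    ]


def ref_three_sfca(populations, capacities, times, threshold, floor):
    n_i, n_j = len(populations), len(capacities)
    w = [[ref_decay(times[i][j], threshold, floor) for j in range(n_j)] for i in range(n_i)]
    g = []
    for i in range(n_i):
        s = sum(w[i])
        g.append([w[i][j] / s if s > 0 else 0.0 for j in range(n_j)])
    ratios = []
    for j in range(n_j):
        dem = sum(g[i][j] * w[i][j] * populations[i] for i in range(n_i))
        ratios.append(capacities[j] / dem if dem > 0 else 0.0)
    return [
        sum(g[i][j] * w[i][j] * ratios[j] for j in range(n_j))
        for i in range(n_i)
    ]


def ref_m2sfca(populations, capacities, times, threshold, floor):
    n_i, n_j = len(populations), len(capacities)
    w = [[ref_decay(times[i][j], threshold, floor) for j in range(n_j)] for i in range(n_i)]
    scores = []
    for i in range(n_i):
        total = 0.0
        for j in range(n_j):
            dem = sum(populations[k] * w[k][j] for k in range(n_i))
            if dem > 0:
                total += capacities[j] * w[i][j] ** 2 / dem
        scores.append(total)
    return scores
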
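"""Hand-written O(n^2) oracles, independent of the library's code paths."""

import numpy as np


def brute_neighbors(states, epsilon, theiler):
    n = len(states)
    out = []
    for i in range(n):
        lst = []
        for j in range(n):
            if abs(i - j) <= theiler:
                continue
            if np.max(np.abs(states[i] - states[j])) <= epsilon:
                lst.append(j)
        out.append(lst)
    return out


def brute_corr_sum(states, epsilons, theiler):
    n = len(states)
    counts = np.zeros(len(epsilons), dtype=int)
    n_pairs = 0
    for i in range(n):
        for j in range(i + theiler + 1, n):
            d = np.max(np.abs(states[i] - states[j]))
            n_pairs += 1
            counts += d <= epsilons
    return counts / n_pairs


def brute_recurrence_times(states, epsilon, Tmin, Tmax):
    n = len(states)
    M = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(n):
            M[i, j] = np.max(np.abs(states[i] - states[j])) <= epsilon
    hist = np.zeros(Tmax - Tmin + 1, dtype=int)
    for col in range(n):
        ones = [i for i in range(n) if M[i, col]]
        for a, b in zip(ones[:-1], ones[1:]):
            gap = b - a - 1
            if Tmin <= gap <= Tmax:
                hist[gap - Tmin] += 1
    return hist


def brute_det(M, lmin):
    """Fraction of off-diagonal recurrence points in diagonal lines >= lmin."""
    n = M.shape[0]
    total = int(M.sum()) - int(np.trace(M))
    in_lines = 0
    for off in range(1, n):
        for d in (np.diagonal(M, off), np.diagonal(M, -off)):
            run = 0
            for v in list(d) + [False]:
                if v:
                    run += 1
                else:
                    if run >= lmin:
                        in_lines += run
                    run = 0
    return in_lines / total if total else 0.0
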
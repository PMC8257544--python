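"""Independent brute-force oracles used by unit and acceptance tests.

These deliberately avoid the package's own algorithms: bursts are found
by exhaustively enumerating all candidate runs, and the test statistics
are computed from their textbook formulas.
"""

import math

import numpy as np


def brute_force_bursts(train, max_isi_ms, min_spikes):
    """All maximal runs with every ISI <= threshold and >= min_spikes spikes.

    Enumerates every (i, j) window, checks the ISI condition exhaustively,
    and keeps windows that cannot be extended on either side.
    """
    t = list(train)
    n = len(t)
    thr = max_isi_ms / 1000.0
    out = []
    for i in range(n):
        for j in range(i + min_spikes - 1, n):
            window_ok = all(t[k + 1] - t[k] <= thr for k in range(i, j))
            if not window_ok:
                break
            left_ext = i > 0 and t[i] - t[i - 1] <= thr
            right_ext = j < n - 1 and t[j + 1] - t[j] <= thr
            if not left_ext and not right_ext:
                out.append((t[i], t[j], j - i + 1))
    return out


def t_statistic(a, b):
    """Two-sample pooled-variance t statistic (textbook formula)."""
    a, b = list(a), list(b)
    na, nb = len(a), len(b)
    ma = sum(a) / na
    mb = sum(b) / nb
    va = sum((x - ma) ** 2 for x in a) / (na - 1)
    vb = sum((x - mb) ** 2 for x in b) / (nb - 1)
    sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    return (ma - mb) / math.sqrt(sp2 * (1 / na + 1 / nb))


def kruskal_wallis_h(a, b):
    """Kruskal-Wallis H with tie correction, from the rank-sum formula."""
    pooled = sorted(list(a) + list(b))
    n = len(pooled)
    # mid-ranks with ties
    ranks = {}
    i = 0
    while i < n:
        j = i
        while j < n and pooled[j] == pooled[i]:
            j += 1
        mid = (i + 1 + j) / 2.0
        ranks.setdefault(pooled[i], mid)
        i = j
    ra = sum(ranks[x] for x in a)
    rb = sum(ranks[x] for x in b)
    h = 12.0 / (n * (n + 1)) * (ra**2 / len(a) + rb**2 / len(b)) - 3 * (n + 1)
    # tie correction
    ties = 0.0
    for v in set(pooled):
        t = pooled.count(v)
        ties += t**3 - t
    denom = 1.0 - ties / (n**3 - n)
    return h / denom


def poisson_count_bounds(rate_hz, duration, n_sigma=3.0):
    mean = rate_hz * duration
    half = n_sigma * math.sqrt(mean)
    return mean - half, mean + half
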
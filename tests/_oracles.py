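"""Independent brute-force oracles used only by the tests.

These deliberately avoid the library's own algorithms: the window scan
enumerates every substring and aligns it globally; the k-mer distance and
the 2x2 chi-squared come from explicit set arithmetic and the textbook
statistic.  They are slow and simple on purpose.
"""

from __future__ import annotations

import numpy as np


def window_levenshtein_all(text: str, pattern: str, budget: int) -> list[tuple[int, int, int]]:
    """All (start, end, distance) windows of ``text`` (1-based inclusive)
    whose full global Levenshtein distance to ``pattern`` is <= budget,
    with window length within ``len(pattern) +/- budget``.  N mismatches
    every symbol.  NW recurrence vectorised across window start positions;
    otherwise a plain textbook DP."""
    m = len(pattern)
    n = len(text)
    hits: list[tuple[int, int, int]] = []
    arr = np.frombuffer(text.encode(), dtype=np.uint8)
    pat = np.frombuffer(pattern.encode(), dtype=np.uint8)
    n_byte = ord("N")
    for L in range(max(1, m - budget), m + budget + 1):
        if L > n:
            continue
        nw = n - L + 1
        # windows[w, j] = text[w + j]
        windows = np.lib.stride_tricks.sliding_window_view(arr, L)
        # D[j] holds column j of the DP matrix for every window at once
        D = np.empty((m + 1, L + 1, nw), dtype=np.int32)
        D[0, :, :] = np.arange(L + 1)[:, None]
        D[:, 0, :] = np.arange(m + 1)[:, None]
        for i in range(1, m + 1):
            pi = pat[i - 1]
            cost = ((windows != pi) | (windows == n_byte) | (pi == n_byte)).T.astype(np.int32)
            for j in range(1, L + 1):
                D[i, j] = np.minimum(
                    np.minimum(D[i - 1, j] + 1, D[i, j - 1] + 1),
                    D[i - 1, j - 1] + cost[j - 1],
                )
        dist = D[m, L]
        for w in np.nonzero(dist <= budget)[0]:
            hits.append((int(w) + 1, int(w) + L, int(dist[w])))
    return hits


def collapse_overlapping(hits: list[tuple[int, int, int]]) -> list[tuple[int, int, int]]:
    """Reduce every transitively-overlapping group of (start, end, distance)
    windows to its (min distance, leftmost, shortest) representative."""
    if not hits:
        return []
    groups: list[list[tuple[int, int, int]]] = []
    reach = -1
    for s, e, d in sorted(hits):
        if groups and s <= reach:
            groups[-1].append((s, e, d))
        else:
            groups.append([(s, e, d)])
            reach = -1
        reach = max(reach, e)
    return sorted(min(g, key=lambda h: (h[2], h[0], h[1] - h[0])) for g in groups)


def chi2_one_sided_oracle(table: np.ndarray) -> float:
    """Textbook 2x2 chi-squared (no continuity correction) converted to a
    one-sided p for 'row 1 proportion greater'."""
    from scipy.stats import chi2_contingency

    t = np.asarray(table, dtype=float)
    if 0 in t.sum(axis=0) or 0 in t.sum(axis=1):
        return 1.0
    stat, p_two, _, _ = chi2_contingency(t, correction=False)
    p1 = t[0, 0] / t[0].sum()
    p2 = t[1, 0] / t[1].sum()
    return p_two / 2 if p1 > p2 else 1 - p_two / 2


def kmer_distance_oracle(a: str, b: str, k: int) -> float:
    sa = {a[i : i + k] for i in range(len(a) - k + 1)}
    sb = {b[i : i + k] for i in range(len(b) - k + 1)}
    if not (sa | sb):
        return 0.0
    return 1.0 - len(sa & sb) / len(sa | sb)


def trapezoid_oracle(xy: list[tuple[float, float]]) -> float:
    """Piecewise-linear area by explicit pairwise trapezoids."""
    total = 0.0
    for (x0, y0), (x1, y1) in zip(xy, xy[1:]):
        total += (x1 - x0) * (y0 + y1) / 2
    return total
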
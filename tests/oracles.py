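"""Independent brute-force oracles used to cross-check the implementation.

These deliberately use naive O(n·w) loops and share no code with the
package's vectorized implementations.
"""

from __future__ import annotations

import numpy as np


def brute_extrema(positions, values, window):
    """Exhaustive sliding-window extrema with alternation, by plain loops.

    Returns (peak_indices, trough_indices).
    """
    pos = np.asarray(positions, float)
    x = np.asarray(values, float)
    n = len(x)
    half = window / 2.0
    eps = 1e-9 * max(window, 1.0)

    peaks, troughs = [], []
    for i in range(n):
        is_p = True
        is_t = True
        for j in range(n):
            if j == i:
                continue
            if abs(pos[j] - pos[i]) <= half + eps:
                if x[j] > x[i]:
                    is_p = False
                if x[j] < x[i]:
                    is_t = False
        if is_p and is_t:
            continue  # zero local contrast
        if i > 0 and x[i - 1] == x[i]:
            continue  # not the leftmost sample of its plateau
        if pos[i] - pos[0] < half - eps or pos[-1] - pos[i] < half - eps:
            continue  # incomplete window at the trace end
        if is_p:
            peaks.append(i)
        if is_t:
            troughs.append(i)

    # enforce alternation
    events = sorted([(i, "P") for i in peaks] + [(i, "T") for i in troughs])
    seq = []
    for i, t in events:
        if not seq or seq[-1][1] != t:
            seq.append((i, t))
            continue
        j = seq[-1][0]
        inserted = False
        if i - j > 1:
            segment = list(x[j + 1 : i])
            if t == "P":
                m = j + 1 + segment.index(min(segment))
                if x[m] < min(x[j], x[i]):
                    seq.append((m, "T"))
                    seq.append((i, "P"))
                    inserted = True
            else:
                m = j + 1 + segment.index(max(segment))
                if x[m] > max(x[j], x[i]):
                    seq.append((m, "P"))
                    seq.append((i, "T"))
                    inserted = True
        if not inserted:
            better = (t == "P" and x[i] > x[j]) or (t == "T" and x[i] < x[j])
            if better:
                seq[-1] = (i, t)
    # drop degenerate peak/trough pairs that do not differ
    changed = True
    while changed:
        changed = False
        for k in range(len(seq) - 1):
            (i, ti), (j, tj) = seq[k], seq[k + 1]
            hi, lo = (i, j) if ti == "P" else (j, i)
            if x[hi] <= x[lo]:
                del seq[k : k + 2]
                changed = True
                break
    return [i for i, t in seq if t == "P"], [i for i, t in seq if t == "T"]


def brute_delimit(flags, flank=1, merge_gap=2):
    """Enumerate DP runs and gaps by hand; returns list of (lo, hi, dp_lo, dp_hi).

    ``lo:hi`` is the section slice of the synapse, ``dp_lo:dp_hi`` the
    half-open span from first to last DP section.
    """
    n = len(flags)
    runs = []
    for i, f in enumerate(flags):
        if f and (i == 0 or not flags[i - 1]):
            j = i
            while j < n and flags[j]:
                j += 1
            runs.append((i, j))
    merged = []
    for r in runs:
        if merged and r[0] - merged[-1][1] < merge_gap:
            merged[-1] = (merged[-1][0], r[1])
        else:
            merged.append(r)
    out = []
    for a, b in merged:
        out.append((max(0, a - flank), min(n, b + flank), a, b))
    return out
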
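"""Independent brute-force oracles used to validate the fast implementations.

These deliberately re-derive each rule with plain Python loops and stay
independent of the code paths they check.
"""

from __future__ import annotations

import numpy as np


def brute_force_spike_detection(x, fs, k=4.0, refractory_ms=1.5,
                                pre_ms=1.0, post_ms=2.0,
                                sigma=None) -> np.ndarray:
    """Literal three-rule spike detection: threshold, refractory, exclusion.

    Returns surviving spike sample indices.
    """
    x = np.asarray(x, dtype=float)
    if sigma is None:
        sigma = np.median(np.abs(x)) / 0.6745
    thr = k * sigma
    a = np.abs(x)
    candidates = [i for i in range(1, x.size - 1)
                  if a[i] >= thr and a[i] >= a[i - 1] and a[i] > a[i + 1]]
    ref = int(round(refractory_ms * 1e-3 * fs))
    kept: list[int] = []
    for i in candidates:
        if not kept or i - kept[-1] >= ref:
            kept.append(i)
    pre = int(round(pre_ms * 1e-3 * fs))
    post = int(round(post_ms * 1e-3 * fs))
    final = [i for i in kept
             if not any(j != i and (i - pre) < j < (i + post) for j in kept)]
    return np.asarray(final, dtype=int)


def brute_force_changepoint(values, min_side=2) -> int:
    """Exhaustive scan for the split maximizing |mean_left - mean_right|,
    ties toward the earlier split."""
    v = np.asarray(values, dtype=float)
    best_k, best_c = None, -np.inf
    for k in range(min_side, v.size - min_side + 1):
        c = abs(v[:k].mean() - v[k:].mean())
        if c > best_c + 1e-15:
            best_k, best_c = k, c
    return best_k


def brute_force_entry_exit(nrms, threshold, min_run):
    """Scan for runs of supra-threshold NRMS; first run start, last run end."""
    above = [v >= threshold for v in nrms]
    runs = []
    i = 0
    n = len(above)
    while i < n:
        if above[i]:
            j = i
            while j < n and above[j]:
                j += 1
            if j - i >= min_run:
                runs.append((i, j - 1))
            i = j
        else:
            i += 1
    if not runs:
        return None
    return runs[0][0], runs[-1][1]
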
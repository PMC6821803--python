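"""Independent brute-force oracles and small utilities shared across tests.

These deliberately avoid the library's vectorized implementations: the burst
scanner is a plain Python loop, statistics are recomputed from first
principles, so agreement with the package is a genuine cross-check.
"""

from __future__ import annotations

import numpy as np


def brute_force_bursts(times: np.ndarray, isi_threshold: float, min_spikes: int) -> list[tuple[float, float, int]]:
    """Reference burst scanner: explicit loop over spikes, no numpy tricks."""
    out = []
    run = []
    for i, t in enumerate(times):
        if not run:
            run = [t]
            continue
        if t - run[-1] <= isi_threshold:
            run.append(t)
        else:
            if len(run) >= min_spikes:
                out.append((run[0], run[-1], len(run)))
            run = [t]
    if len(run) >= min_spikes:
        out.append((run[0], run[-1], len(run)))
    return out


def poisson_train(rng: np.random.Generator, rate: float, duration: float) -> np.ndarray:
    """Homogeneous Poisson spike times on [0, duration]."""
    n = rng.poisson(rate * duration)
    t = np.sort(rng.uniform(0.0, duration, n))
    if t.size > 1:  # strict ordering for SpikeTrain
        t = t[np.concatenate(([True], np.diff(t) > 0))]
    return t


def spaced_times(rng: np.random.Generator, n: int, duration: float, min_gap: float) -> np.ndarray:
    """n random times with pairwise gaps >= min_gap (greedy thinning)."""
    candidates = np.sort(rng.uniform(0.01, duration - 0.01, n * 3))
    out: list[float] = []
    last = -np.inf
    for x in candidates:
        if x - last >= min_gap:
            out.append(x)
            last = x
        if len(out) == n:
            break
    return np.asarray(out)


def match_spike_times(detected: np.ndarray, truth: np.ndarray, tol: float) -> int:
    """Greedy one-to-one matching; returns the number of true positives."""
    used = np.zeros(detected.size, dtype=bool)
    hits = 0
    for t in truth:
        d = np.abs(detected - t)
        d[used] = np.inf
        if d.size and d.min() <= tol:
            used[np.argmin(d)] = True
            hits += 1
    return hits
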
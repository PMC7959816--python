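"""Per-base brute-force oracles for the interval algebra.

Everything here works on explicit boolean masks over small (<=10 kb)
chromosomes, independent of the package's interval arithmetic.
"""

from __future__ import annotations

import numpy as np


def mask(pairs: list[tuple[int, int]], length: int) -> np.ndarray:
    m = np.zeros(length, dtype=bool)
    for s, e in pairs:
        m[s:e] = True
    return m


def runs(m: np.ndarray) -> list[tuple[int, int]]:
    """Maximal True runs of a boolean mask."""
    out = []
    in_run = False
    start = 0
    for i, v in enumerate(m):
        if v and not in_run:
            start, in_run = i, True
        elif not v and in_run:
            out.append((start, i))
            in_run = False
    if in_run:
        out.append((start, len(m)))
    return out


def merge_runs(m: np.ndarray, gap: int) -> np.ndarray:
    """Fill every False run strictly shorter than gap that lies between two
    True runs."""
    m = m.copy()
    rs = runs(m)
    for (s1, e1), (s2, _e2) in zip(rs, rs[1:]):
        if s2 - e1 < gap:
            m[e1:s2] = True
    return m


def random_pairs(rng: np.random.Generator, length: int, n: int) -> list[tuple[int, int]]:
    out = []
    for _ in range(n):
        s = int(rng.integers(0, length - 1))
        e = int(rng.integers(s + 1, min(length, s + 1 + rng.integers(1, 500)) + 1))
        out.append((s, min(e, length)))
    return out
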
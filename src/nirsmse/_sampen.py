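"""Template-match counting kernel for sample entropy.

The counting convention follows Richman & Moorman: with a series of length
``n`` and pattern length ``m``, both the length-``m`` and length-``m+1``
template sets contain ``n - m`` vectors (indices ``0 .. n-m-1``), so the two
pair counts are directly comparable. Matching uses the Chebyshev distance
with a ``<= r`` criterion and self-matches are excluded.
"""

from __future__ import annotations

import numpy as np


def _count_matches_py(x: np.ndarray, m: int, r: float) -> tuple[int, int]:
    # Vectorized fallback; O(n^2) memory-chunked over template rows.
    n = x.shape[0]
    nt = n - m
    a = 0
    b = 0
    # build template matrix of length m+1 once; the m-length check uses
    # its first m columns
    idx = np.arange(nt)[:, None] + np.arange(m + 1)[None, :]
    templ = x[idx]  # (nt, m+1)
    chunk = max(1, 2_000_000 // max(nt, 1))
    for start in range(0, nt - 1, chunk):
        stop = min(start + chunk, nt - 1)
        block = templ[start:stop]  # (c, m+1)
        diff = np.abs(block[:, None, :] - templ[None, :, :])  # (c, nt, m+1)
        match_m = (diff[:, :, :m] <= r).all(axis=2)
        match_m1 = match_m & (diff[:, :, m] <= r)
        # count only pairs (i, j) with j > i
        rows = np.arange(start, stop)[:, None]
        upper = np.arange(nt)[None, :] > rows
        b += int(np.count_nonzero(match_m & upper))
        a += int(np.count_nonzero(match_m1 & upper))
    return a, b


def _count_matches_impl(x, m, r):  # pragma: no cover - jitted
    n = x.shape[0]
    nt = n - m
    a = 0
    b = 0
    for i in range(nt - 1):
        for j in range(i + 1, nt):
            match = True
            for k in range(m):
                if abs(x[i + k] - x[j + k]) > r:
                    match = False
                    break
            if match:
                b += 1
                if abs(x[i + m] - x[j + m]) <= r:
                    a += 1
    return a, b


try:  # numba gives ~100x on the long acceptance series; fall back silently
    from numba import njit

    _count_matches_jit = njit(cache=True)(_count_matches_impl)
except ImportError:  # pragma: no cover
    _count_matches_jit = None


def count_matches(x: np.ndarray, m: int, r: float) -> tuple[int, int]:
    """Return ``(A, B)``: template-pair counts at lengths ``m+1`` and ``m``."""
    x = np.ascontiguousarray(x, dtype=np.float64)
    if _count_matches_jit is not None:
        a, b = _count_matches_jit(x, m, r)
        return int(a), int(b)
    return _count_matches_py(x, m, r)
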
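"""Sum-preserving integer rounding (largest-remainder apportionment)."""

from __future__ import annotations

import numpy as np


def round_preserving_sum(values, total: int = 100) -> np.ndarray:
    """Round non-negative reals summing to ``total`` to integers summing to ``total``.

    Largest-remainder method: take the floor of every value, then hand out
    the remaining units to the entries with the largest fractional parts.
    The result minimizes the total absolute deviation from the input among
    all non-negative integer vectors with the required sum; ties on the
    fractional part are broken by position (document order).

    Parameters
    ----------
    values : array-like of float
        Non-negative, summing to ``total`` within 1e−6.
    total : int
        Target integer sum (default 100, the point budget).

    Returns
    -------
    numpy.ndarray of int
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or v.size == 0:
        raise ValueError("values must be a non-empty 1-D array")
    if (v < 0).any():
        raise ValueError("values must be non-negative")
    if abs(v.sum() - total) > 1e-6:
        raise ValueError(f"values sum to {v.sum()!r}, expected {total}")
    # guard float fuzz so e.g. 26.000000001 floors to 26, not 25+carry
    v = np.round(v, 9)
    floors = np.floor(v).astype(int)
    remainder = v - floors
    short = int(round(total - floors.sum()))
    if short:
        # stable sort: descending remainder, earlier index wins ties
        order = np.argsort(-remainder, kind="stable")
        floors[order[:short]] += 1
    return floors


def naive_round(values) -> np.ndarray:
    """Plain nearest-integer rounding (half away from zero); may break the sum."""
    v = np.asarray(values, dtype=float)
    return np.floor(v + 0.5).astype(int)
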
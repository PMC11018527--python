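"""Small shared helpers: rounding conventions and interval arithmetic."""

from __future__ import annotations

import math

import numpy as np


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round ``x`` to ``ndigits`` decimals, halves away from zero.

    Python's built-in ``round`` uses banker's rounding; reported
    quantities here use the conventional half-away-from-zero rule.
    """
    factor = 10.0 ** ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


def percent(part: float, whole: float, ndigits: int = 1) -> float:
    """``part`` as a percentage of ``whole``, rounded half away from zero."""
    if whole == 0:
        raise ValueError("whole must be nonzero")
    return round_half_away(100.0 * part / whole, ndigits)


def merge_index_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Return maximal runs of True in ``mask`` as half-open (start, end)."""
    mask = np.asarray(mask, dtype=bool)
    if mask.size == 0:
        return []
    padded = np.concatenate([[False], mask, [False]])
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    return list(zip(starts.tolist(), ends.tolist()))


def sha256_file(path) -> str:
    import hashlib

    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
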
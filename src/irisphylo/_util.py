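"""Small shared numeric helpers."""

from __future__ import annotations

import math

import numpy as np


def round_half_up(x):
    """Round to the nearest integer, halves away from zero toward +inf.

    Python's built-in ``round`` rounds halves to even; channel means and
    consensus cluster counts are specified to round half *up* instead.
    """
    arr = np.asarray(x, dtype=float)
    out = np.floor(arr + 0.5).astype(int)
    return int(out) if np.isscalar(x) or arr.ndim == 0 else out


def spawn_seed(seed: int, *salt) -> int:
    """Derive a child seed (< 2**31) from a master seed and salt values."""
    ss = np.random.SeedSequence([int(seed) & 0x7FFFFFFF, *[abs(hash(s)) % (2**31) for s in salt]])
    return int(ss.generate_state(1)[0] % (2**31))


def check_rgb(rgb) -> tuple[int, int, int]:
    """Validate and return an integer RGB triple in [0, 255]."""
    r, g, b = rgb
    for c in (r, g, b):
        if not (0 <= c <= 255) or float(c) != int(c) and not float(c).is_integer():
            raise ValueError(f"RGB channel out of range or non-integer: {rgb!r}")
    return int(r), int(g), int(b)


def distance_from_black(rgb) -> float:
    """Euclidean distance of an RGB triple from black (0, 0, 0)."""
    r, g, b = rgb
    return math.sqrt(float(r) ** 2 + float(g) ** 2 + float(b) ** 2)
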
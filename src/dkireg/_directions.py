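"""Deterministic direction sets on the unit sphere.

All direction sets used for reporting scalar metrics are deterministic so
that repeated runs produce bit-identical maps.
"""

from __future__ import annotations

import numpy as np

_GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))


def fibonacci_sphere(n: int) -> np.ndarray:
    """Return ``n`` approximately uniform unit vectors (Fibonacci lattice).

    Deterministic: the same ``n`` always yields the same array.
    """
    if n < 1:
        raise ValueError("need at least one direction")
    i = np.arange(n, dtype=float)
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    phi = _GOLDEN_ANGLE * i
    dirs = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    return dirs / np.linalg.norm(dirs, axis=1, keepdims=True)


def circle_perpendicular(axis: np.ndarray, n: int) -> np.ndarray:
    """``n`` evenly spaced unit vectors in the plane perpendicular to ``axis``.

    The in-plane frame is chosen deterministically from the axis components
    (smallest-magnitude canonical axis seeds the first basis vector).
    """
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    seed = np.zeros(3)
    seed[int(np.argmin(np.abs(axis)))] = 1.0
    e1 = np.cross(axis, seed)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)
    theta = 2.0 * np.pi * np.arange(n) / n
    return np.outer(np.cos(theta), e1) + np.outer(np.sin(theta), e2)
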
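"""Periodic-boundary geometry (orthorhombic boxes, minimum-image convention)."""

from __future__ import annotations

import numpy as np

from .core import DomainError


def _check_box(box: np.ndarray) -> np.ndarray:
    box = np.asarray(box, dtype=float)
    if box.shape != (3,) or np.any(box <= 0):
        raise DomainError("box must be three positive edge lengths (Å)")
    return box


def minimum_image_displacement(a, b, box) -> np.ndarray:
    """Displacement ``b - a`` wrapped so each component lies in [-L/2, L/2).

    Works on single vectors or broadcastable arrays of vectors.
    """
    box = _check_box(box)
    d = np.asarray(b, dtype=float) - np.asarray(a, dtype=float)
    return d - box * np.floor(d / box + 0.5)


def minimum_image_distance(a, b, box) -> np.ndarray:
    """Minimum-image distance(s) between positions ``a`` and ``b``."""
    d = minimum_image_displacement(a, b, box)
    return np.linalg.norm(d, axis=-1)


def wrap_coords(coords: np.ndarray, box) -> np.ndarray:
    """Wrap coordinates into [0, L) per axis (for periodic KD-tree queries)."""
    box = _check_box(box)
    wrapped = np.mod(np.asarray(coords, dtype=float), box)
    # guard against coordinates landing exactly on L through rounding
    return np.where(wrapped >= box, 0.0, wrapped)
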
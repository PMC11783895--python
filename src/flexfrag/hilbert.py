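"""Hilbert space-filling curves in arbitrary dimension.

The Hilbert curve of order ``p`` in dimension ``n`` visits every cell of the
``2^p``-per-axis lattice exactly once while consecutive cells stay adjacent
(Manhattan distance 1).  This locality is what makes the curve useful for
flattening 3D voxel grids into 1D vectors and re-folding them into 2D
images with minimal loss of neighborhood structure.

The implementation follows the Gray-code (Skilling-style) transpose
construction; the base orientation is fixed so that the order-1 curve in 2D
runs (0,0) -> (0,1) -> (1,1) -> (1,0).
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

__all__ = ["hilbert_cell", "hilbert_index", "hilbert_cells"]


def _transpose_to_axes(x: list[int], order: int, dim: int) -> list[int]:
    n = 2 << (order - 1)
    # Gray decode
    t = x[dim - 1] >> 1
    for i in range(dim - 1, 0, -1):
        x[i] ^= x[i - 1]
    x[0] ^= t
    # undo excess work
    q = 2
    while q != n:
        p = q - 1
        for i in range(dim - 1, -1, -1):
            if x[i] & q:
                x[0] ^= p
            else:
                t = (x[0] ^ x[i]) & p
                x[0] ^= t
                x[i] ^= t
        q <<= 1
    return x


def _axes_to_transpose(x: list[int], order: int, dim: int) -> list[int]:
    m = 1 << (order - 1)
    q = m
    while q > 1:
        p = q - 1
        for i in range(dim):
            if x[i] & q:
                x[0] ^= p
            else:
                t = (x[0] ^ x[i]) & p
                x[0] ^= t
                x[i] ^= t
        q >>= 1
    for i in range(1, dim):
        x[i] ^= x[i - 1]
    t = 0
    q = m
    while q > 1:
        if x[dim - 1] & q:
            t ^= q - 1
        q >>= 1
    for i in range(dim):
        x[i] ^= t
    return x


def hilbert_cell(order: int, dim: int, index: int) -> tuple[int, ...]:
    """Lattice coordinates of the ``index``-th cell of the curve.

    ``0 <= index < 2**(dim*order)``; the inverse is :func:`hilbert_index`.
    """
    if order < 1 or dim < 1:
        raise ValueError("order and dim must be positive")
    total = 1 << (dim * order)
    if not 0 <= index < total:
        raise ValueError(f"index {index} out of range [0, {total})")
    # distribute index bits (MSB first) cyclically over the transpose
    x = [0] * dim
    for j in range(order):
        for i in range(dim):
            bit = (index >> (dim * order - 1 - (j * dim + i))) & 1
            x[i] |= bit << (order - 1 - j)
    return tuple(_transpose_to_axes(x, order, dim))


def hilbert_index(order: int, dim: int, cell) -> int:
    """Curve index of a lattice cell; inverse of :func:`hilbert_cell`."""
    side = 1 << order
    x = list(cell)
    if len(x) != dim or any(not 0 <= c < side for c in x):
        raise ValueError(f"cell {cell!r} outside the {side}^{dim} lattice")
    x = _axes_to_transpose(x, order, dim)
    index = 0
    for j in range(order):
        for i in range(dim):
            bit = (x[i] >> (order - 1 - j)) & 1
            index = (index << 1) | bit
    return index


@lru_cache(maxsize=8)
def hilbert_cells(order: int, dim: int) -> np.ndarray:
    """All cells in curve order: array of shape (2**(dim*order), dim)."""
    total = 1 << (dim * order)
    out = np.empty((total, dim), dtype=np.int64)
    for i in range(total):
        out[i] = hilbert_cell(order, dim, i)
    out.setflags(write=False)
    return out
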
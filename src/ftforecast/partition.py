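"""Uniform fuzzy partitions with raised-cosine basic functions.

A fuzzy partition of a closed interval ``[a, b]`` is a family of continuous
*basic functions* ``A_1 .. A_n`` that are normal at their nodes
(``A_k(x_k) = 1``), vanish outside the two cells adjacent to their node, rise
and fall monotonically on those cells, and sum to one everywhere on
``[a, b]``.  The *h-uniform* family used throughout this package places the
nodes equidistantly,

    x_k = a + h * (k - 1),    h = (b - a) / (n - 1),

and uses the raised-cosine bump

    A_k(x) = (1 + cos(pi * (x - x_k) / h)) / 2

restricted to ``[x_{k-1}, x_{k+1}]`` (half of that window at the two boundary
nodes, where the support is one-sided).  These partitions are the
approximation scaffold for the fuzzy transform: each basic function defines a
weighted local neighbourhood over which data are averaged.

Node indices in this module are 0-based, matching the array layout of
``FuzzyPartition.nodes``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "FuzzyPartition",
    "build_uniform_partition",
    "basis_value",
    "membership_matrix",
    "is_sufficiently_dense",
]


@dataclass(frozen=True)
class FuzzyPartition:
    """An h-uniform raised-cosine fuzzy partition of ``[a, b]``.

    Attributes
    ----------
    a, b : float
        Domain bounds, ``b > a``.
    n : int
        Number of nodes, at least 3.
    nodes : numpy.ndarray
        Equidistant nodes ``a = x_0 < x_1 < ... < x_{n-1} = b``.
    h : float
        Node spacing ``(b - a) / (n - 1)``.
    """

    a: float
    b: float
    n: int
    nodes: np.ndarray
    h: float


def build_uniform_partition(a: float, b: float, n: int) -> FuzzyPartition:
    """Construct an h-uniform fuzzy partition with ``n`` equidistant nodes.

    Parameters
    ----------
    a, b : float
        Domain bounds; ``b`` must exceed ``a``.
    n : int
        Node count, at least 3.

    Returns
    -------
    FuzzyPartition

    Raises
    ------
    ValueError
        If ``n < 3`` or ``b <= a``.
    """
    n = int(n)
    a = float(a)
    b = float(b)
    if n < 3:
        raise ValueError(f"a fuzzy partition needs at least 3 nodes, got n={n}")
    if not b > a:
        raise ValueError(f"domain must satisfy b > a, got a={a}, b={b}")
    h = (b - a) / (n - 1)
    nodes = a + h * np.arange(n)
    nodes[-1] = b  # guard against rounding drift at the right endpoint
    return FuzzyPartition(a=a, b=b, n=n, nodes=nodes, h=h)


def _support_bounds(partition: FuzzyPartition) -> tuple[np.ndarray, np.ndarray]:
    """Per-node support intervals: one cell on each side, half at the edges."""
    nodes = partition.nodes
    lo = np.concatenate(([nodes[0]], nodes[:-1]))
    hi = np.concatenate((nodes[1:], [nodes[-1]]))
    return lo, hi


def membership_matrix(partition: FuzzyPartition, x) -> np.ndarray:
    """Evaluate every basic function at every point of ``x``.

    Returns an array of shape ``(n, len(x))`` whose ``[k, i]`` entry is
    ``A_k(x[i])``.  Points outside ``[a, b]`` get zero membership everywhere.
    """
    x = np.atleast_1d(np.asarray(x, dtype=float))
    lo, hi = _support_bounds(partition)
    diff = x[None, :] - partition.nodes[:, None]
    inside = (x[None, :] >= lo[:, None]) & (x[None, :] <= hi[:, None])
    with np.errstate(invalid="ignore"):
        values = 0.5 * (1.0 + np.cos(np.pi * diff / partition.h))
    # clip absorbs rounding at support edges where cos(+-pi) ~ -1
    return np.where(inside, np.clip(values, 0.0, 1.0), 0.0)


def basis_value(partition: FuzzyPartition, k: int, x):
    """Membership ``A_k(x)`` of the k-th basic function (0-based ``k``).

    ``x`` may be a scalar or an array; out-of-domain points evaluate to 0
    rather than raising, so the function is total in ``x``.

    Raises
    ------
    IndexError
        If ``k`` is not in ``0 .. n-1``.
    """
    if not 0 <= k < partition.n:
        raise IndexError(f"node index {k} out of range for n={partition.n}")
    values = membership_matrix(partition, x)[k]
    if np.isscalar(x) or np.ndim(x) == 0:
        return float(values[0])
    return values


def is_sufficiently_dense(
    partition: FuzzyPartition, points
) -> tuple[bool, int | None]:
    """Check the solvability condition for the discrete fuzzy transform.

    A point set is *sufficiently dense* with respect to a partition when every
    basic function has positive membership at some point — otherwise the
    weighted averages of the direct transform are undefined at the uncovered
    node.

    Returns
    -------
    (flag, first_failing_node)
        ``flag`` is True when every node is covered; otherwise
        ``first_failing_node`` is the smallest 0-based index of an uncovered
        node.

    Raises
    ------
    ValueError
        If ``points`` is empty.
    """
    points = np.asarray(points, dtype=float)
    if points.size == 0:
        raise ValueError("density check requires a nonempty point set")
    covered = (membership_matrix(partition, points) > 0.0).any(axis=1)
    if covered.all():
        return True, None
    return False, int(np.argmin(covered))
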
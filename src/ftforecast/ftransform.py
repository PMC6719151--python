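"""Discrete direct and inverse fuzzy transforms of order 0 and 1.

The direct F-transform maps sampled function values onto one component per
partition node — the membership-weighted average of the samples covered by
that node's basic function:

    F_k = sum_i f(p_i) A_k(p_i) / sum_i A_k(p_i).

The inverse transform reconstructs a smooth approximation as the
membership-weighted blend ``sum_k F_k A_k(x)``.

The first-order (F1) transform refines each component from a local constant
to a local line ``F1_k(x) = c0_k + c1_k (x - x_k)``:

    c0_k = sum_i f(p_i) A_k(p_i)            / sum_i A_k(p_i)
    c1_k = sum_i f(p_i) (p_i - x_k) A_k(p_i) / sum_i (p_i - x_k)^2 A_k(p_i)

``c1_k`` approximates the derivative of f at the node (to first order in the
node spacing h), which lifts the inverse-transform reconstruction error from
O(h) to O(h^2) away from the domain edges.  At boundary nodes the support is
one-sided, so the constant part of f leaks into ``c1`` and the edge
components are less accurate — a property, not a defect, of the discrete
formulas.

Components can only be *constructed* from a sufficiently dense sample
(every node covered); evaluating stored components is always permitted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .partition import FuzzyPartition, is_sufficiently_dense, membership_matrix

__all__ = [
    "DensityError",
    "F0Components",
    "F1Components",
    "direct_f_transform",
    "inverse_f_transform",
    "f1_components",
    "f1_component_eval",
    "inverse_f1_transform",
]


class DensityError(ValueError):
    """The sample is not sufficiently dense: some node has no covered point."""

    def __init__(self, node: int):
        self.node = node
        super().__init__(
            f"point set is not sufficiently dense: node {node} has no point "
            "with positive membership"
        )


@dataclass(frozen=True)
class F0Components:
    """Order-0 components, one weighted average per node."""

    F: np.ndarray


@dataclass(frozen=True)
class F1Components:
    """First-order components: local intercepts ``c0`` and slopes ``c1``."""

    c0: np.ndarray
    c1: np.ndarray


def _checked_memberships(
    partition: FuzzyPartition, points, values
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    points = np.asarray(points, dtype=float)
    values = np.asarray(values, dtype=float)
    if points.shape != values.shape:
        raise ValueError(
            f"points and values must have equal length, got "
            f"{points.size} and {values.size}"
        )
    dense, failing = is_sufficiently_dense(partition, points)
    if not dense:
        raise DensityError(failing)
    return points, values, membership_matrix(partition, points)


def direct_f_transform(
    partition: FuzzyPartition, points, values
) -> F0Components:
    """Order-0 direct transform: per-node weighted averages of the samples.

    Raises
    ------
    DensityError
        If some node has no point with positive membership.
    ValueError
        On a points/values length mismatch.
    """
    _, values, A = _checked_memberships(partition, points, values)
    return F0Components(F=(A @ values) / A.sum(axis=1))


def inverse_f_transform(partition: FuzzyPartition, comps: F0Components, x):
    """Order-0 reconstruction ``sum_k F_k A_k(x)`` for ``x`` in ``[a, b]``."""
    x_arr = np.atleast_1d(np.asarray(x, dtype=float))
    if ((x_arr < partition.a) | (x_arr > partition.b)).any():
        raise ValueError(
            f"x outside the partition domain [{partition.a}, {partition.b}]"
        )
    out = comps.F @ membership_matrix(partition, x_arr)
    if np.isscalar(x) or np.ndim(x) == 0:
        return float(out[0])
    return out


def f1_components(partition: FuzzyPartition, points, values) -> F1Components:
    """First-order components: weighted local intercept and slope per node.

    A node whose covering points all sit exactly at the node has an
    unidentifiable local slope (zero denominator); its ``c1`` is set to 0 so
    the component falls back to the order-0 behaviour.
    """
    points, values, A = _checked_memberships(partition, points, values)
    c0 = (A @ values) / A.sum(axis=1)
    offsets = points[None, :] - partition.nodes[:, None]
    num = (A * offsets) @ values
    den = (A * offsets * offsets).sum(axis=1)
    c1 = np.divide(num, den, out=np.zeros_like(num), where=den > 0.0)
    return F1Components(c0=c0, c1=c1)


def f1_component_eval(
    comps: F1Components, partition: FuzzyPartition, k: int, x
):
    """The k-th local line ``c0_k + c1_k (x - x_k)`` (0-based ``k``)."""
    if not 0 <= k < partition.n:
        raise IndexError(f"node index {k} out of range for n={partition.n}")
    x_arr = np.asarray(x, dtype=float)
    out = comps.c0[k] + comps.c1[k] * (x_arr - partition.nodes[k])
    if np.isscalar(x) or np.ndim(x) == 0:
        return float(out)
    return out


def inverse_f1_transform(partition: FuzzyPartition, comps: F1Components, x):
    """First-order reconstruction: membership-weighted blend of local lines.

    Evaluates ``sum_k F1_k(x) A_k(x) / sum_k A_k(x)``.  The denominator is
    identically 1 inside ``[a, b]`` for a partition of unity; it is kept so
    the formula stays well defined for generalized partitions, and a point
    with zero total membership (outside the domain) raises.
    """
    x_arr = np.atleast_1d(np.asarray(x, dtype=float))
    A = membership_matrix(partition, x_arr)
    den = A.sum(axis=0)
    if (den <= 0.0).any():
        raise ValueError(
            "x has zero total membership (outside the partition domain)"
        )
    lines = comps.c0[:, None] + comps.c1[:, None] * (
        x_arr[None, :] - partition.nodes[:, None]
    )
    out = (lines * A).sum(axis=0) / den
    if np.isscalar(x) or np.ndim(x) == 0:
        return float(out[0])
    return out
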
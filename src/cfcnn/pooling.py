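"""Central pooling: position-dependent 1-D max-pooling kernels.

Ordinary max pooling treats every image position alike. When the network's
job is to classify the *centre* voxel of a patch, features near the centre
matter more than features near the edge. Central pooling therefore tiles each
axis with 1-D max-pooling kernels of sizes 1, 2 and 3 — size-1 kernels (which
pass values through unchanged) in the middle of the axis, larger kernels
towards the ends — so that the pooled map keeps centre detail and compresses
the periphery.

Kernel counts per axis of length ``O`` solve

    n1 + 2*n2 + 3*n3 = O      (kernels tile the axis exactly)
    n1 + n2 + n3     = O/2    (output is half the input)
    n1 + n3          = n2     (half of all kernels have size 2)

whose real solution is (O/8, O/4, O/8). For ``O`` not divisible by 8 the
floor counts leave a coverage residual ``r = O - (f1 + 2*f2 + 3*f3)`` with
``f1 = f3 = floor(O/8)``, ``f2 = floor(O/4)``, and a fixed look-up table
distributes ``r`` extra voxels over extra kernels. Row pooling is applied
first (1-D windows along each row), then column pooling, which together
equal a max over the rectangles formed by the two axis tilings.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .errors import DomainError, GeometryError

#: Extra kernels of size s (rows s=1,2,3) covering residual r (columns 0..7).
#: Every column satisfies 1*L[1,r] + 2*L[2,r] + 3*L[3,r] = r.
LOOKUP_TABLE = np.array(
    [
        [0, 1, 0, 1, 0, 0, 0, 0],  # s = 1
        [0, 0, 1, 1, 2, 1, 3, 2],  # s = 2
        [0, 0, 0, 0, 0, 1, 0, 1],  # s = 3
    ],
    dtype=np.int64,
)


def lookup_increment(size: int, residual: int) -> int:
    """Extra kernels of ``size`` assigned for a coverage ``residual``."""
    if size not in (1, 2, 3):
        raise DomainError(f"kernel size must be 1, 2 or 3, got {size}")
    if not 0 <= residual <= 7:
        raise DomainError(f"residual must be in 0..7, got {residual}")
    return int(LOOKUP_TABLE[size - 1, residual])


def solve_kernel_counts(O: int) -> tuple[int, int, int, int]:
    """Kernel counts ``(n1, n2, n3)`` and coverage residual ``r`` for axis length ``O``.

    Base counts are the floors of the ideal solution; the residual is the
    number of axis voxels the base counts leave uncovered; the look-up table
    converts the residual into extra kernels.

    >>> solve_kernel_counts(9)
    (2, 2, 1, 1)
    """
    if O < 1:
        raise DomainError(f"axis length must be >= 1, got {O}")
    f1 = O // 8
    f2 = O // 4
    f3 = O // 8
    r = O - (f1 + 2 * f2 + 3 * f3)
    n1 = f1 + lookup_increment(1, r)
    n2 = f2 + lookup_increment(2, r)
    n3 = f3 + lookup_increment(3, r)
    assert n1 + 2 * n2 + 3 * n3 == O
    return n1, n2, n3, r


def build_kernel_order(
    n1: int, n2: int, n3: int, odd_bias: str = "left"
) -> list[int]:
    """Symmetric left-to-right kernel-size layout for given counts.

    Size-3 kernels sit outermost and the size-1 run is centred: the combined
    size-2/3 flank is split between the two halves (odd remainders to the
    ``odd_bias`` side, size-3 first), and likewise the size-1 run itself.
    Centring the run — rather than splitting each size independently —
    guarantees that whenever size-1 kernels exist and the output length is
    odd, the centre output window has size 1, which is the point of the
    layer. "left" bias reproduces the printed {3, 2, 1, 1, 2} layout for
    counts (2, 2, 1).
    """
    if min(n1, n2, n3) < 0 or (n1, n2, n3) == (0, 0, 0):
        raise DomainError(f"invalid kernel counts {(n1, n2, n3)}")
    if odd_bias not in ("left", "right"):
        raise DomainError(f"odd_bias must be 'left' or 'right', got {odd_bias!r}")

    def ceil_half(n: int) -> int:
        return (n + 1) // 2 if odd_bias == "left" else n // 2

    l3 = ceil_half(n3)
    l_flank = ceil_half(n2 + n3)  # kernels of size 2 or 3 left of the centre run
    l2 = l_flank - l3
    l1 = ceil_half(n1)
    left = [3] * l3 + [2] * l2 + [1] * l1
    right = [1] * (n1 - l1) + [2] * (n2 - l2) + [3] * (n3 - l3)
    return left + right


@dataclass(frozen=True)
class PoolingPlan:
    """A fixed tiling of one axis by 1-D max-pooling kernels."""

    axis_length: int
    n1: int
    n2: int
    n3: int
    residual: int
    order: tuple[int, ...]

    def __post_init__(self) -> None:
        if sum(self.order) != self.axis_length:
            raise GeometryError(
                f"kernel sizes {self.order} do not tile axis of {self.axis_length}"
            )
        counts = (self.order.count(1), self.order.count(2), self.order.count(3))
        if counts != (self.n1, self.n2, self.n3):
            raise GeometryError(f"order {self.order} inconsistent with counts {counts}")

    @property
    def output_length(self) -> int:
        return self.n1 + self.n2 + self.n3

    @property
    def segments(self) -> list[tuple[int, int]]:
        """Half-open (start, stop) window bounds along the axis."""
        bounds = np.concatenate([[0], np.cumsum(self.order)])
        return [(int(a), int(b)) for a, b in zip(bounds[:-1], bounds[1:])]


@lru_cache(maxsize=None)
def plan_for_axis(O: int) -> PoolingPlan:
    """The central-pooling plan for an axis of length ``O`` (cached)."""
    n1, n2, n3, r = solve_kernel_counts(O)
    order = tuple(build_kernel_order(n1, n2, n3))
    return PoolingPlan(axis_length=O, n1=n1, n2=n2, n3=n3, residual=r, order=order)


@lru_cache(maxsize=None)
def as_uniform_max_pool(O: int) -> PoolingPlan:
    """A plan of all size-2 kernels: classic 2x2 / stride-2 max pooling."""
    if O < 2 or O % 2 != 0:
        raise DomainError(f"uniform 2x2 pooling needs a positive even axis, got {O}")
    n2 = O // 2
    return PoolingPlan(axis_length=O, n1=0, n2=n2, n3=0, residual=0,
                       order=(2,) * n2)


def central_pool_forward(
    feature_map: np.ndarray, row_plan: PoolingPlan, col_plan: PoolingPlan
) -> tuple[np.ndarray, np.ndarray]:
    """Pool a 2-D map with per-axis plans; also return the argmax map.

    Row pooling (1-D max windows along each row) followed by column pooling
    equals, per output cell, the max over the rectangular window formed by
    the two plans' segments. The argmax map stores, for each output cell, the
    (row, col) input coordinate that supplied the max — ties broken by lowest
    linear index — which makes the backward pass exact and deterministic.

    Returns
    -------
    pooled : (row_out, col_out) array
    argmax : (row_out, col_out, 2) int array of source coordinates
    """
    x = np.asarray(feature_map)
    if x.ndim != 2:
        raise GeometryError(f"feature map must be 2-D, got ndim={x.ndim}")
    if x.shape != (row_plan.axis_length, col_plan.axis_length):
        raise GeometryError(
            f"map shape {x.shape} does not match plans "
            f"({row_plan.axis_length}, {col_plan.axis_length})"
        )
    rseg = row_plan.segments
    cseg = col_plan.segments
    pooled = np.empty((len(rseg), len(cseg)), dtype=x.dtype)
    argmax = np.empty((len(rseg), len(cseg), 2), dtype=np.int64)
    for i, (r0, r1) in enumerate(rseg):
        for j, (c0, c1) in enumerate(cseg):
            window = x[r0:r1, c0:c1]
            flat = int(np.argmax(window))  # first occurrence = lowest linear index
            dr, dc = divmod(flat, window.shape[1])
            pooled[i, j] = window[dr, dc]
            argmax[i, j] = (r0 + dr, c0 + dc)
    return pooled, argmax


def central_pool_backward(
    upstream: np.ndarray, argmax: np.ndarray, input_shape: tuple[int, int]
) -> np.ndarray:
    """Route each upstream gradient to its recorded argmax input position."""
    upstream = np.asarray(upstream)
    if argmax.shape[:2] != upstream.shape or argmax.shape[2:] != (2,):
        raise GeometryError(
            f"argmax shape {argmax.shape} inconsistent with upstream {upstream.shape}"
        )
    grad = np.zeros(input_shape, dtype=float)
    rows = argmax[..., 0].ravel()
    cols = argmax[..., 1].ravel()
    # windows are non-overlapping so each (row, col) target is unique
    np.add.at(grad, (rows, cols), upstream.ravel())
    return grad
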
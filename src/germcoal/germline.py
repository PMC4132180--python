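"""Division-interval partitions and germline population trajectories.

The male germline is modeled as a sequence of ``D`` cell divisions from the
zygote to mature sperm (``D`` between 36 and 42 in flies).  Mutation rates are
estimated per *interval* of divisions rather than per division, so the first
object here is a partition of ``1..D`` into consecutive closed intervals
``[t_{i-1}+1, t_i]``.  The second object is the population trajectory
``N(0)..N(D)`` of germline cells, including the primordial-germ-cell (PGC)
bottleneck after the eighth division: the ``n8`` PGCs are descendants of
``n5`` ancestor cells present after the fifth division, which encodes how
biased (non-random) the PGC sampling is.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "ValidationError",
    "InfeasibleBottleneckError",
    "IntervalPartition",
    "GermlineDynamics",
    "RateVector",
    "resolve_partition",
    "build_dynamics",
    "division_interval_map",
]

CLEAVAGE = "cleavage"
PGC_EXPANSION = "pgc_expansion"
STEM = "stem"
SPERMATOGENESIS = "spermatogenesis"


class ValidationError(ValueError):
    """Invalid partition, trajectory, or rate configuration."""


class InfeasibleBottleneckError(ValidationError):
    """More PGCs requested than the chosen division-5 ancestors can produce."""


@dataclass(frozen=True)
class IntervalPartition:
    """Partition of divisions ``1..D`` into ``I`` consecutive closed intervals.

    ``boundaries`` holds the right endpoints ``t_1 < t_2 < ... < t_I = D``
    (``t_0 = 0`` is implicit), so interval ``i`` covers divisions
    ``[t_{i-1}+1, t_i]``.
    """

    boundaries: tuple[int, ...]
    D: int

    def __post_init__(self) -> None:
        b = self.boundaries
        if len(b) == 0 or b[-1] != self.D:
            raise ValidationError(f"last boundary must equal D={self.D}, got {b}")
        if any(b[i] >= b[i + 1] for i in range(len(b) - 1)) or b[0] < 1:
            raise ValidationError(f"boundaries must satisfy 0 < t_1 < ... < t_I: {b}")

    @property
    def I(self) -> int:
        """Number of intervals."""
        return len(self.boundaries)

    @property
    def widths(self) -> tuple[int, ...]:
        prev = (0,) + self.boundaries[:-1]
        return tuple(t - p for t, p in zip(self.boundaries, prev))

    @property
    def intervals(self) -> tuple[tuple[int, int], ...]:
        """Closed intervals ``(a_i, b_i)`` covering ``1..D``."""
        prev = (0,) + self.boundaries[:-1]
        return tuple((p + 1, t) for t, p in zip(self.boundaries, prev))

    def interval_of(self, d: int) -> int:
        """1-based interval index containing division ``d``."""
        if not 1 <= d <= self.D:
            raise ValidationError(f"division {d} outside 1..{self.D}")
        return int(np.searchsorted(self.boundaries, d)) + 1


def resolve_partition(spec: Sequence[int], D: int) -> IntervalPartition:
    """Resolve a boundary specification (possibly with negative shorthand).

    A negative entry ``-k`` means "the final interval covers the last ``k``
    divisions", i.e. it resolves to the boundary ``D - k``.  An empty spec
    yields the single interval ``[1, D]``.

    Parameters
    ----------
    spec
        Interval right-endpoints, excluding the final endpoint ``D``.
    D
        Total number of divisions (``>= 6``).
    """
    if D < 6:
        raise ValidationError(f"D must be >= 6, got {D}")
    resolved: list[int] = []
    for entry in spec:
        if entry == 0:
            raise ValidationError("boundary entry 0 is not a valid division")
        value = D + entry if entry < 0 else entry
        if not 1 <= value < D:
            raise ValidationError(
                f"boundary entry {entry} resolves to {value}, outside 1..{D - 1}"
            )
        if resolved and value <= resolved[-1]:
            raise ValidationError(
                f"boundary entry {entry} (resolves to {value}) breaks monotonicity "
                f"after {resolved[-1]}"
            )
        resolved.append(value)
    resolved.append(D)
    return IntervalPartition(tuple(resolved), D)


def division_interval_map(partition: IntervalPartition) -> dict[int, int]:
    """Total map ``d -> interval index`` over divisions ``1..D``."""
    return {d: partition.interval_of(d) for d in range(1, partition.D + 1)}


@dataclass(frozen=True)
class GermlineDynamics:
    """Population trajectory ``N(0)..N(D)`` of the male germline lineage.

    When ``n5``/``n8`` are set, the trajectory includes the PGC bottleneck:
    the ``n8 = N(8)`` PGCs are uniform draws from the ``8*n5`` division-8
    descendants of ``n5`` ancestor cells chosen at division 5.  ``n5 = 32``
    is the random-sampling limit (PGCs drawn uniformly from all 256 cells).

    ``plain`` trajectories (``n5 = n8 = None``) have no bottleneck and are
    used for miniature validation dynamics.
    """

    D: int
    N: tuple[int, ...]
    n5: int | None = None
    n8: int | None = None
    stem_cap: int | None = None
    stages: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if len(self.N) != self.D + 1:
            raise ValidationError("N must have length D+1")
        if self.N[0] != 1:
            raise ValidationError("N(0) must be 1")
        for i in range(1, self.D + 1):
            # the bottleneck division (8) may shrink the germline pool
            if self.has_bottleneck and i == 8:
                continue
            if not 1 <= self.N[i] <= 2 * self.N[i - 1]:
                raise ValidationError(
                    f"N({i})={self.N[i]} violates 1 <= N(i) <= 2*N(i-1)={2 * self.N[i - 1]}"
                )
            if self.N[i] < self.N[i - 1]:
                raise ValidationError(f"N({i}) decreases outside the bottleneck")
        if self.stages and len(self.stages) != self.D:
            raise ValidationError("stages must have length D (one label per division)")

    @property
    def has_bottleneck(self) -> bool:
        return self.n5 is not None

    @classmethod
    def plain(cls, N: Sequence[int]) -> "GermlineDynamics":
        """Bottleneck-free trajectory from an explicit ``N(0)..N(D)`` list."""
        N = tuple(int(x) for x in N)
        return cls(D=len(N) - 1, N=N, stages=("custom",) * (len(N) - 1))

    def describe(self) -> dict:
        """JSON-able summary used for caching/provenance keys."""
        return {
            "D": self.D,
            "n5": self.n5,
            "n8": self.n8,
            "stem_cap": self.stem_cap,
            "N": list(self.N),
        }


def build_dynamics(
    D: int = 38, n5: int = 6, n8: int = 8, stem_cap: int = 128
) -> GermlineDynamics:
    """Construct the standard germline trajectory with a PGC bottleneck.

    Cleavage doubles the population through division 7 (``N(i) = 2**i``);
    ``N(8) = n8`` PGCs are retained; the pool doubles (capped at
    ``stem_cap``) through division 14, stays constant during the stem-cell
    stage, and doubles across the final five spermatogenesis divisions.

    Raises
    ------
    InfeasibleBottleneckError
        If ``n8 > 8*n5`` (the PGCs could not all descend from ``n5``
        ancestors three divisions earlier).
    """
    if not 36 <= D <= 42:
        raise ValidationError(f"D must be in 36..42, got {D}")
    if not 1 <= n5 <= 32:
        raise ValidationError(f"n5 must be in 1..32, got {n5}")
    if n8 > 8 * n5:
        raise InfeasibleBottleneckError(
            f"n8={n8} exceeds 8*n5={8 * n5}: PGCs unreachable from n5 ancestors"
        )
    if not 1 <= n8 <= 256:
        raise ValidationError(f"n8 must be in 1..256, got {n8}")
    if stem_cap < n8:
        raise ValidationError(f"stem_cap={stem_cap} smaller than n8={n8}")

    N = [1]
    for i in range(1, 8):
        N.append(2 ** i)
    N.append(n8)
    for i in range(9, 15):
        N.append(min(n8 * 2 ** (i - 8), stem_cap))
    stem_pool = N[14]
    for i in range(15, D - 4):
        N.append(stem_pool)
    for j in range(1, 6):
        N.append(stem_pool * 2 ** j)

    stages = tuple(
        CLEAVAGE if i <= 8 else PGC_EXPANSION if i <= 14 else STEM if i <= D - 5 else SPERMATOGENESIS
        for i in range(1, D + 1)
    )
    return GermlineDynamics(D=D, N=tuple(N), n5=n5, n8=n8, stem_cap=stem_cap, stages=stages)


@dataclass(frozen=True)
class RateVector:
    """Per-interval mutation rates ``u_1..u_I`` (mutations per cell division)."""

    u: tuple[float, ...]
    partition: IntervalPartition

    def __post_init__(self) -> None:
        if len(self.u) != self.partition.I:
            raise ValidationError(
                f"rate vector length {len(self.u)} != interval count {self.partition.I}"
            )
        if any(x < 0 for x in self.u):
            raise ValidationError("mutation rates must be non-negative")

    @classmethod
    def of(cls, u: Sequence[float], partition: IntervalPartition) -> "RateVector":
        return cls(tuple(float(x) for x in u), partition)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.u, dtype=float)

    def per_division(self) -> np.ndarray:
        """Rate for each division ``1..D`` (length-``D`` array)."""
        out = np.empty(self.partition.D)
        for (a, b), ui in zip(self.partition.intervals, self.u):
            out[a - 1 : b] = ui
        return out
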
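"""Backward-in-time simulation of sperm genealogies through the germline.

A sample of ``f`` sperm (one per offspring line) is traced backward from
division ``D`` to the zygote through the population trajectory ``N(i)``.
At each step the ``N(i)`` daughter cells are assigned to the ``N(i-1)``
parents uniformly at random subject to the birth multiplicities: exactly
``N(i) - N(i-1)`` parents divide (two daughters) and the rest persist.
The PGC bottleneck is honored by routing lineages through the complete
binary subtrees rooted at the ``n5`` division-5 ancestor cells.

The quantity consumed by the pattern likelihood is the *branch profile*
``B(d, s)``: the number of ancestral branches at division ``d`` carrying
exactly ``s`` of the ``f`` sampled descendants.  A mutation arising at
division ``d`` on such a branch is inherited by ``s`` sampled lines, so
``B`` converts per-division mutation rates into expected counts of
mutations of each size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .germline import GermlineDynamics, IntervalPartition, ValidationError

__all__ = [
    "BranchProfile",
    "CoefficientSet",
    "simulate_genealogy",
    "simulate_genealogy_lineages",
    "simulate_coefficients",
    "pool_coefficients",
    "forward_population_oracle",
]


@dataclass
class BranchProfile:
    """Branch/descendant counts for one simulated genealogy.

    ``B[d-1, s-1]`` is the number of ancestral branches at division ``d``
    with exactly ``s`` sampled descendants; ``A(d) = sum_s B(d, s)``.
    """

    f: int
    D: int
    B: np.ndarray  # shape (D, f), integer

    @property
    def A(self) -> np.ndarray:
        """Ancestral branch count per division (length-``D``)."""
        return self.B.sum(axis=1)

    def check(self) -> None:
        weights = np.arange(1, self.f + 1)
        if not np.all(self.B @ weights == self.f):
            raise AssertionError("sum_s s*B(d,s) != f at some division")


def _slots_and_parent(d: int, dyn: GermlineDynamics, pos: np.ndarray) -> np.ndarray:
    """Map lineage positions at division ``d`` to parent labels at ``d-1``."""
    if dyn.has_bottleneck and 6 <= d <= 8:
        return pos // 2  # inside the n5 complete binary subtrees
    if dyn.has_bottleneck and d <= 5:
        return pos // 2  # full doubling, 2**d cells
    n_child, n_par = dyn.N[d], dyn.N[d - 1]
    b = n_child - n_par  # parents that divide
    return np.where(pos < 2 * b, pos // 2, b + (pos - 2 * b))


def _n_slots(d: int, dyn: GermlineDynamics) -> int:
    if dyn.has_bottleneck and 6 <= d <= 8:
        return dyn.n5 * 2 ** (d - 5)
    if dyn.has_bottleneck and d <= 5:
        return 2 ** d
    return dyn.N[d]


def _sample_leaves(f: int, dyn: GermlineDynamics, rng: np.random.Generator) -> np.ndarray:
    """Per-lineage descendant counts at division D (handles f > N(D))."""
    if dyn.N[dyn.D] >= f:
        return np.ones(f, dtype=np.int64)
    warnings.warn(
        f"sample size f={f} exceeds N(D)={dyn.N[dyn.D]}; sampling sperm with replacement",
        stacklevel=3,
    )
    counts = np.bincount(rng.integers(0, dyn.N[dyn.D], size=f))
    return counts[counts > 0].astype(np.int64)


def simulate_genealogy(
    f: int, dyn: GermlineDynamics, rng: np.random.Generator | int | None = None
) -> BranchProfile:
    """Simulate one sperm genealogy and tabulate its branch profile."""
    if f < 1:
        raise ValidationError("sample size f must be >= 1")
    rng = np.random.default_rng(rng)
    D = dyn.D
    B = np.zeros((D, f), dtype=np.int32)
    desc = _sample_leaves(f, dyn, rng)
    for d in range(D, 0, -1):
        B[d - 1] = np.bincount(desc, minlength=f + 1)[1:]
        if d == 1:
            break
        k = desc.size
        slots = _n_slots(d, dyn)
        pos = rng.choice(slots, size=k, replace=False)
        par = _slots_and_parent(d, dyn, pos)
        uniq, inv = np.unique(par, return_inverse=True)
        desc = np.bincount(inv, weights=desc).astype(np.int64)
    return BranchProfile(f=f, D=D, B=B)


def simulate_genealogy_lineages(
    f: int, dyn: GermlineDynamics, rng: np.random.Generator | int | None = None
) -> list[list[tuple[int, ...]]]:
    """Like :func:`simulate_genealogy` but keeps descendant leaf sets.

    Returns, for each division ``d`` (index ``d-1``), the list of branches as
    tuples of the leaf (line) indices each branch carries.  Used by the
    forward synthetic generator, which must know *which* lines inherit a
    mutation, not only how many.
    """
    if f < 1:
        raise ValidationError("sample size f must be >= 1")
    rng = np.random.default_rng(rng)
    D = dyn.D
    if dyn.N[D] >= f:
        groups: list[tuple[int, ...]] = [(i,) for i in range(f)]
    else:
        warnings.warn(
            f"sample size f={f} exceeds N(D)={dyn.N[D]}; sampling sperm with replacement",
            stacklevel=2,
        )
        cells = rng.integers(0, dyn.N[D], size=f)
        bucket: dict[int, list[int]] = {}
        for leaf, cell in enumerate(cells):
            bucket.setdefault(int(cell), []).append(leaf)
        groups = [tuple(v) for v in bucket.values()]
    out: list[list[tuple[int, ...]]] = [[] for _ in range(D)]
    for d in range(D, 0, -1):
        out[d - 1] = list(groups)
        if d == 1:
            break
        slots = _n_slots(d, dyn)
        pos = rng.choice(slots, size=len(groups), replace=False)
        par = _slots_and_parent(d, dyn, pos)
        merged: dict[int, tuple[int, ...]] = {}
        for p, g in zip(par, groups):
            p = int(p)
            merged[p] = merged.get(p, ()) + g
        groups = list(merged.values())
    return out


@dataclass
class CoefficientSet:
    """``M`` replicate branch profiles for one family size and dynamics."""

    f: int
    D: int
    M: int
    B: np.ndarray  # (M, D, f) integer
    dynamics: dict
    seed: int | None = None
    _cache: dict = field(default_factory=dict, repr=False)

    def interval_coeffs(self, partition: IntervalPartition) -> np.ndarray:
        """Per-replicate, per-interval branch coefficients.

        ``C[m, i, s-1] = sum_{d in interval i} B_m(d, s)`` — shape
        ``(M, I, f)``.  Cached per partition since the optimizer evaluates
        the likelihood many times under one partition.
        """
        if partition.D != self.D:
            raise ValidationError(
                f"partition D={partition.D} does not match coefficient D={self.D}"
            )
        key = partition.boundaries
        if key not in self._cache:
            starts = np.array((0,) + partition.boundaries[:-1])
            self._cache[key] = np.add.reduceat(
                self.B.astype(np.float64), starts, axis=1
            )
        return self._cache[key]


def simulate_coefficients(
    f: int, dyn: GermlineDynamics, M: int, seed: int | None = None
) -> CoefficientSet:
    """Simulate ``M`` independent genealogies (reproducible under ``seed``)."""
    if M < 1:
        raise ValidationError("M must be >= 1")
    rng = np.random.default_rng(seed)
    B = np.zeros((M, dyn.D, f), dtype=np.int32)
    for m in range(M):
        B[m] = simulate_genealogy(f, dyn, rng).B
    return CoefficientSet(f=f, D=dyn.D, M=M, B=B, dynamics=dyn.describe(), seed=seed)


def pool_coefficients(sets: list[CoefficientSet]) -> CoefficientSet:
    """Concatenate replicate sets (e.g. across grouped n5/n8 values)."""
    if not sets:
        raise ValidationError("nothing to pool")
    f, D = sets[0].f, sets[0].D
    for s in sets[1:]:
        if s.f != f or s.D != D:
            raise ValidationError(
                f"cannot pool coefficient sets with mismatched (f, D): "
                f"({s.f}, {s.D}) vs ({f}, {D})"
            )
    B = np.concatenate([s.B for s in sets], axis=0)
    dyn = {"pooled": [s.dynamics for s in sets]}
    return CoefficientSet(f=f, D=D, M=B.shape[0], B=B, dynamics=dyn, seed=None)


_FORWARD_MAX_CELLS = 4096


def forward_population_oracle(
    dyn: GermlineDynamics, f: int, rng: np.random.Generator | int | None = None
) -> BranchProfile:
    """Brute-force forward simulation used to validate the backward engine.

    Simulates every germline cell forward with explicit parent pointers,
    samples ``f`` sperm uniformly without replacement, and tabulates the same
    branch-profile statistic.  Refuses trajectories too large to enumerate.
    """
    rng = np.random.default_rng(rng)
    D = dyn.D
    if dyn.N[D] > _FORWARD_MAX_CELLS:
        raise ValidationError(
            f"forward oracle refuses N(D)={dyn.N[D]} > {_FORWARD_MAX_CELLS} cells"
        )
    if f > dyn.N[D]:
        raise ValidationError("forward oracle requires f <= N(D)")

    bot = dyn.has_bottleneck and D >= 9
    # sizes[d]: number of cells tracked at division d in the forward structure
    sizes = [1] * (D + 1)
    parent: list[np.ndarray | None] = [None] * (D + 1)
    pgc_cells: np.ndarray | None = None
    for d in range(1, D + 1):
        if bot and d <= 8:
            sizes[d] = 2 ** d
            parent[d] = np.arange(2 ** d) // 2
        elif bot and d == 9:
            # population at 8 is the n8 PGCs selected below
            sizes[d] = dyn.N[9]
            parent[d] = _forward_parent_assignment(dyn.n8, dyn.N[9], rng)
        else:
            sizes[d] = dyn.N[d]
            parent[d] = _forward_parent_assignment(sizes[d - 1], sizes[d], rng)
    if bot:
        anc5 = rng.choice(32, size=dyn.n5, replace=False)
        desc8 = np.flatnonzero(np.isin(np.arange(256) >> 3, anc5))
        pgc_cells = rng.choice(desc8, size=dyn.n8, replace=False)

    leaves = rng.choice(sizes[D], size=f, replace=False)
    counts = np.bincount(leaves, minlength=sizes[D]).astype(np.int64)
    B = np.zeros((D, f), dtype=np.int32)
    for d in range(D, 0, -1):
        pos = counts[counts > 0]
        B[d - 1] = np.bincount(pos, minlength=f + 1)[1:]
        if d == 1:
            break
        if bot and d == 9:
            up = np.bincount(parent[d], weights=counts, minlength=dyn.n8)
            counts = np.zeros(256, dtype=np.int64)
            counts[pgc_cells] = up.astype(np.int64)
        else:
            nprev = sizes[d - 1] if not (bot and d <= 8) else 2 ** (d - 1)
            counts = np.bincount(parent[d], weights=counts, minlength=nprev).astype(
                np.int64
            )
    return BranchProfile(f=f, D=D, B=B)


def _forward_parent_assignment(
    n_par: int, n_child: int, rng: np.random.Generator
) -> np.ndarray:
    """Random child->parent map: n_child-n_par parents divide, rest persist."""
    b = n_child - n_par
    if not 0 <= b <= n_par:
        raise ValidationError(f"cannot grow {n_par} -> {n_child} in one division")
    extra = rng.choice(n_par, size=b, replace=False) if b else np.empty(0, dtype=int)
    par = np.concatenate([np.arange(n_par), extra])
    return rng.permutation(par)
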
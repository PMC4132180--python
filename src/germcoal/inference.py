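"""Maximum-likelihood rate estimation, nested hypothesis tests, grid scans.

Rates are estimated per division interval by maximizing the genealogy-
averaged pattern likelihood.  Hypotheses H1..H7 impose equality classes on
the interval rates (H1: all equal; H2: all internal equal; pairwise
equalities for the rest) and are tested against the unconstrained H8 with
likelihood-ratio statistics; degrees of freedom are counted structurally as
the difference in free parameters.  The dynamics scan refits the model over
a grid of bottleneck assumptions (n5, n8 groups and total divisions D) and
reports each cell's log-likelihood deficit to the best cell.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .coalescent import CoefficientSet, pool_coefficients, simulate_coefficients
from .germline import (
    GermlineDynamics,
    IntervalPartition,
    RateVector,
    ValidationError,
    build_dynamics,
    resolve_partition,
)
from .patterns import PatternTally, TallyLikelihood

__all__ = [
    "ConvergenceError",
    "HypothesisSpec",
    "RateEstimate",
    "SummaryStats",
    "hypothesis",
    "fit_mle",
    "overall_rate",
    "classical_rate",
    "lr_test",
    "scan_dynamics",
    "ScanResult",
    "first_division_ratio",
    "male_female_ratio",
]

_RATE_FLOOR = 1e-12
_RATE_CEIL = 0.5
_SNAP = 1e-9


class ConvergenceError(RuntimeError):
    """Optimizer failed to produce a consistent maximum."""


@dataclass(frozen=True)
class HypothesisSpec:
    """Equality classes over interval indices (1-based).

    ``classes`` partitions ``1..I``; intervals in one class share a rate.
    ``df`` is relative to the unconstrained model H8.
    """

    id: str
    classes: tuple[tuple[int, ...], ...]

    @property
    def I(self) -> int:
        return sum(len(c) for c in self.classes)

    @property
    def n_free(self) -> int:
        return len(self.classes)

    @property
    def df(self) -> int:
        return self.I - self.n_free

    def expand(self, theta: np.ndarray) -> np.ndarray:
        """Map one value per class to a full length-``I`` rate vector."""
        u = np.empty(self.I)
        for value, cls in zip(theta, self.classes):
            for i in cls:
                u[i - 1] = value
        return u


def hypothesis(name: str, I: int) -> HypothesisSpec:
    """Build H1..H8 (plus H4b) for an ``I``-interval partition."""
    if I < 2:
        raise ValidationError("hypotheses need at least 2 intervals")
    singles = {i: (i,) for i in range(1, I + 1)}

    def merged(*groups: tuple[int, ...]) -> HypothesisSpec:
        used = set()
        classes = []
        for g in groups:
            classes.append(tuple(sorted(g)))
            used.update(g)
        for i in range(1, I + 1):
            if i not in used:
                classes.append(singles[i])
        return HypothesisSpec(name, tuple(sorted(classes)))

    name = name.upper().replace("H4B", "H4b")
    if name == "H1":
        return merged(tuple(range(1, I + 1)))
    if name == "H2":
        if I < 4:
            raise ValidationError("H2 needs >= 4 intervals")
        return merged(tuple(range(2, I)))
    if name == "H3":
        return merged((1, 2))
    if name == "H4":
        if I < 3:
            raise ValidationError("H4 needs >= 3 intervals")
        return merged((2, 3))
    if name == "H4b":
        if I < 4:
            raise ValidationError("H4b needs >= 4 intervals")
        return merged((3, 4))
    if name == "H5":
        if I < 3:
            raise ValidationError("H5 needs >= 3 intervals")
        return merged((I - 2, I - 1))
    if name == "H6":
        return merged((I - 1, I))
    if name == "H7":
        return merged((1, I))
    if name == "H8":
        return HypothesisSpec("H8", tuple(singles.values()))
    raise ValidationError(f"unknown hypothesis {name!r}")


@dataclass
class RateEstimate:
    """MLE of the interval rates under an (optional) constraint set."""

    u: RateVector
    loglik: float
    converged: bool
    n_starts: int
    hypothesis: str = "H8"

    def table(self) -> pd.DataFrame:
        """Rates in the display convention: ``u x 10^3`` to 3 dp."""
        return pd.DataFrame(
            {
                "interval": [f"[{a},{b}]" for a, b in self.u.partition.intervals],
                "u_x1000": [round(1000 * x, 3) for x in self.u.u],
            }
        )


@dataclass(frozen=True)
class SummaryStats:
    """Screen-level totals feeding the classical estimator."""

    m_t: int  # total mutations
    n_m: int  # total mutant lines
    lines: int
    mu_tilde: float


def fit_mle(
    tally: PatternTally,
    partition: IntervalPartition,
    coeffs_by_f: dict[int, CoefficientSet],
    constraints: HypothesisSpec | None = None,
    n_starts: int = 8,
    seed: int | None = 0,
    tol: float = 1e-8,
) -> RateEstimate:
    """Box-constrained multi-start MLE of per-interval mutation rates.

    Optimizes over log-rates (floor 1e-12) with L-BFGS-B from ``n_starts``
    starting points; rates below 1e-9 are snapped to 0 for reporting since
    boundary estimates are expected for quiet intervals.
    """
    spec = constraints if constraints is not None else hypothesis("H8", partition.I)
    if spec.I != partition.I:
        raise ValidationError(
            f"hypothesis is for {spec.I} intervals, partition has {partition.I}"
        )
    loglik = TallyLikelihood(tally, coeffs_by_f)

    if tally.total_families() == sum(tally.n_empty(f) for f in tally.sizes()):
        # no mutations anywhere: likelihood is maximized at u = 0 exactly
        u = RateVector.of([0.0] * partition.I, partition)
        return RateEstimate(u, 0.0, True, 0, spec.id)

    class_index = np.empty(partition.I, dtype=int)
    for c, cls in enumerate(spec.classes):
        for i in cls:
            class_index[i - 1] = c

    def objective(theta: np.ndarray) -> tuple[float, np.ndarray]:
        u_full = spec.expand(np.exp(theta))
        u = RateVector.of(u_full, partition)
        value, grad_u = loglik.value_and_grad(u)
        if not np.isfinite(value):
            return 1e30, np.zeros_like(theta)
        # chain rule through u_i = exp(theta_class(i)), summed over classes
        grad_theta = np.bincount(
            class_index, weights=grad_u * u_full, minlength=spec.n_free
        )
        return -value, -grad_theta

    # crude scale from the mutant-family fraction for the first start
    n_mut = sum(
        n for (f, _), n in tally.counts.items()
    )
    frac = max(n_mut / max(tally.total_families(), 1), 1e-4)
    flat = min(max(frac / partition.D, 1e-6), 0.1)

    rng = np.random.default_rng(seed)
    lo, hi = math.log(_RATE_FLOOR), math.log(_RATE_CEIL)
    bounds = [(lo, hi)] * spec.n_free
    # deterministic starts first: flat, then all mass on one class in turn
    # (the dominant local optima differ in which interval carries the bulk
    # of the rate, so every such basin gets its own start)
    widths = np.asarray(partition.widths, dtype=float)
    class_width = np.array(
        [sum(widths[i - 1] for i in cls) for cls in spec.classes]
    )
    starts = [np.full(spec.n_free, math.log(flat))]
    for c in range(spec.n_free):
        x0 = np.full(spec.n_free, math.log(1e-6))
        x0[c] = math.log(min(max(frac / class_width[c], 1e-6), _RATE_CEIL / 2))
        starts.append(x0)
    n_actual = max(n_starts, len(starts))
    while len(starts) < n_actual:
        starts.append(rng.uniform(math.log(1e-6), math.log(0.2), size=spec.n_free))
    best = None
    any_success = False
    for x0 in starts:
        res = optimize.minimize(
            objective, x0, method="L-BFGS-B", bounds=bounds, jac=True,
            options={"ftol": tol, "gtol": 1e-10, "maxiter": 500},
        )
        any_success = any_success or res.success
        if best is None or res.fun < best.fun:
            best = res
    u_full = spec.expand(np.exp(best.x))
    u_full = np.where(u_full < _SNAP, 0.0, u_full)
    estimate = RateEstimate(
        u=RateVector.of(u_full, partition),
        loglik=-float(best.fun),
        converged=bool(any_success and np.isfinite(best.fun)),
        n_starts=n_actual,
        hypothesis=spec.id,
    )
    return estimate


def overall_rate(u: RateVector | Sequence[float], partition: IntervalPartition | None = None) -> float:
    """Overall rate per generation: the width-weighted sum of interval rates."""
    if isinstance(u, RateVector):
        partition = u.partition
        u = u.u
    if partition is None:
        raise ValidationError("partition required when u is a bare sequence")
    if len(u) != partition.I:
        raise ValidationError("rate/partition length mismatch")
    return float(np.dot(partition.widths, u))


def classical_rate(n_mutants: int, n_lines: int) -> float:
    """Classical unbiased estimator: mutant lines per examined line."""
    if n_lines <= 0:
        raise ValidationError("line count must be positive")
    if not 0 <= n_mutants <= n_lines:
        raise ValidationError("mutant count must lie in [0, n_lines]")
    return n_mutants / n_lines


def lr_test(
    tally: PatternTally,
    hyp: HypothesisSpec | str,
    partition: IntervalPartition,
    coeffs_by_f: dict[int, CoefficientSet],
    n_starts: int = 8,
    seed: int | None = 0,
) -> tuple[float, int, float]:
    """Likelihood-ratio test of a constrained hypothesis against H8.

    Returns ``(statistic, df, p_value)`` with the chi-square upper-tail
    p-value.  A statistic negative beyond optimizer tolerance triggers a
    refit with more restarts; persistent failure raises
    :class:`ConvergenceError`.
    """
    if isinstance(hyp, str):
        hyp = hypothesis(hyp, partition.I)
    full = fit_mle(tally, partition, coeffs_by_f, None, n_starts, seed)
    restricted = fit_mle(tally, partition, coeffs_by_f, hyp, n_starts, seed)
    stat = 2.0 * (full.loglik - restricted.loglik)
    tol = 1e-4 * max(1.0, abs(full.loglik))
    if stat < -tol:
        full = fit_mle(tally, partition, coeffs_by_f, None, 4 * n_starts, seed)
        stat = 2.0 * (full.loglik - restricted.loglik)
        if stat < -tol:
            raise ConvergenceError(
                f"constrained fit beat the unconstrained one (stat={stat:.4g})"
            )
    stat = max(stat, 0.0)
    df = hyp.df
    return stat, df, float(stats.chi2.sf(stat, df))


@dataclass
class ScanResult:
    """Likelihood surface over germline-dynamics assumptions."""

    table: pd.DataFrame  # columns: n5_group, n8_group, D, loglik, delta, feasible
    optimum: tuple[tuple[int, int], tuple[int, int], int]

    def delta(self, n5_group, n8_group, D=None) -> float:
        t = self.table
        sel = (t.n5_group == tuple(n5_group)) & (t.n8_group == tuple(n8_group))
        if D is not None:
            sel &= t.D == D
        return float(t.loc[sel, "delta"].iloc[0])


def scan_dynamics(
    tally: PatternTally,
    n5_groups: Sequence[Sequence[int]],
    n8_groups: Sequence[Sequence[int]],
    partition_spec: Sequence[int],
    D_values: Sequence[int] = (38,),
    M: int = 1000,
    stem_cap: int = 128,
    n_starts: int = 4,
    seed: int | None = 0,
) -> ScanResult:
    """Grid scan of the likelihood over (n5, n8, D) assumptions.

    A grouped grid value (e.g. n5 in 5-6) is realized by pooling equal-size
    coefficient sets simulated at each integer in the group; each cell uses
    the same total replicate count ``M`` so log-likelihood deficits are
    comparable.  Infeasible members (n8 > 8*n5) are dropped; a cell with no
    feasible member is marked infeasible, never silently skipped.
    """
    ss = np.random.SeedSequence(seed)
    rows = []
    sizes = tally.sizes()
    for D in D_values:
        partition = resolve_partition(tuple(partition_spec), D)
        for n5g in n5_groups:
            for n8g in n8_groups:
                members = [
                    (a, b)
                    for a in n5g
                    for b in n8g
                    if 1 <= a <= 32 and 1 <= b <= min(256, 8 * a)
                ]
                row = {
                    "n5_group": tuple(n5g),
                    "n8_group": tuple(n8g),
                    "D": D,
                    "feasible": bool(members),
                    "members": len(members),
                    "loglik": np.nan,
                }
                if members:
                    coeffs_by_f = _cell_coefficients(
                        tally, members, D, stem_cap, M, ss
                    )
                    est = fit_mle(
                        tally, partition, coeffs_by_f, None, n_starts, seed
                    )
                    row["loglik"] = est.loglik
                rows.append(row)
    table = pd.DataFrame(rows)
    if not table.feasible.any():
        raise ValidationError("every scan cell is infeasible (n8 > 8*n5)")
    best = table.loglik.max()
    table["delta"] = best - table.loglik
    opt = table.loc[table.delta == 0].iloc[0]
    return ScanResult(
        table=table, optimum=(opt.n5_group, opt.n8_group, int(opt.D))
    )


def _cell_coefficients(
    tally: PatternTally,
    members: list[tuple[int, int]],
    D: int,
    stem_cap: int,
    M: int,
    ss: np.random.SeedSequence,
) -> dict[int, CoefficientSet]:
    """Pooled coefficient sets for one grid cell, with coverage retries.

    Every mutation size observed in the tally must occur on at least one
    simulated branch, otherwise its pattern would get Monte-Carlo
    probability zero; cells where a rare large size is missed are
    resimulated with doubled depth (the slight M heterogeneity only affects
    Monte-Carlo noise, not the expected likelihood).
    """
    needed = {
        f: {s for (ff, k) in tally.counts for s in k.sizes if ff == f}
        for f in tally.sizes()
    }
    coeffs_by_f: dict[int, CoefficientSet] = {}
    for f in tally.sizes():
        m_cell = M
        for attempt in range(4):
            per = _split_evenly(m_cell, len(members))
            sets = [
                simulate_coefficients(
                    f, build_dynamics(D, a, b, stem_cap), m,
                    seed=int(child.generate_state(1)[0] % 2 ** 31),
                )
                for (a, b), m, child in zip(members, per, ss.spawn(len(members)))
            ]
            pooled = pool_coefficients(sets)
            if all(np.any(pooled.B[:, :, s - 1]) for s in needed[f]):
                break
            m_cell *= 2
        # if still uncovered after the retries, the likelihood treats the
        # offending pattern as (near-)impossible under this cell and the
        # cell is penalized accordingly
        coeffs_by_f[f] = pooled
    return coeffs_by_f


def _split_evenly(total: int, parts: int) -> list[int]:
    base, rem = divmod(total, parts)
    return [base + (1 if i < rem else 0) for i in range(parts)]


def first_division_ratio(u: RateVector | Sequence[float]) -> float:
    """Ratio of the first-division rate to the mean internal-division rate.

    Computed exactly as the display convention prints it:
    ``u1 / [(u2 + u3 + 11*u4 + 18*u5) / 32]``.
    """
    vals = u.u if isinstance(u, RateVector) else tuple(u)
    if len(vals) < 5:
        raise ValidationError("first_division_ratio needs at least 5 intervals")
    denom = (vals[1] + vals[2] + 11 * vals[3] + 18 * vals[4]) / 32
    if denom == 0:
        return 0.0 if vals[0] == 0 else math.inf
    return vals[0] / denom


def male_female_ratio(
    first_div_ratio: float, male_divisions: int, female_divisions: int
) -> float:
    """Expected male:female mutation-rate ratio given cell-division counts.

    With the first division ``r`` times more mutable than the rest,
    a germline of ``n`` divisions accumulates ``r + n - 1`` rate units, so
    the expected ratio is ``(r + n_male - 1) / (r + n_female - 1)``.
    """
    if first_div_ratio <= 0 or male_divisions <= 0 or female_divisions <= 0:
        raise ValidationError("all inputs must be positive")
    return (first_div_ratio + male_divisions - 1) / (
        first_div_ratio + female_divisions - 1
    )
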
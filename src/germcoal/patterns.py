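"""Mutation patterns and the genealogy-averaged Poisson likelihood.

A family's mutations are summarized by a *pattern* — the multiset
``<i, j, k, ...>`` of mutation sizes, a size being the number of offspring
lines carrying one independent mutation.  Conditional on a genealogy ``G``
the number of mutations of size ``s`` is Poisson with mean
``lambda_s(G, u) = sum_d u_{I(d)} * B_G(d, s)``, independently across sizes;
the pattern probability is the Monte-Carlo average of the product of these
Poisson terms over stored genealogies.  The experiment-wide log-likelihood
is ``sum_f sum_kappa n_f(kappa) * log p_f(kappa)``, with explicit terms for
non-mutant families (the empty pattern).

Patterns whose sizes sum to more than the family size violate the
one-mutation-per-mutant bookkeeping and receive probability zero.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
from scipy.special import gammaln, logsumexp

from .coalescent import CoefficientSet
from .germline import RateVector, ValidationError

__all__ = [
    "MutationPattern",
    "PatternTally",
    "enumerate_patterns",
    "pattern_log_prob",
    "tally_log_likelihood",
    "TallyLikelihood",
]


@dataclass(frozen=True, order=True)
class MutationPattern:
    """Multiset of mutation sizes, stored as a sorted tuple (``()`` = none)."""

    sizes: tuple[int, ...]

    def __post_init__(self) -> None:
        if any(s < 1 for s in self.sizes):
            raise ValidationError("mutation sizes must be >= 1")
        object.__setattr__(self, "sizes", tuple(sorted(self.sizes)))

    @classmethod
    def of(cls, *sizes: int) -> "MutationPattern":
        return cls(tuple(sizes))

    @property
    def n_mutations(self) -> int:
        return len(self.sizes)

    @property
    def n_mutants(self) -> int:
        return sum(self.sizes)

    def multiplicities(self, f: int) -> np.ndarray:
        """Count of each size ``1..f`` (length-``f`` vector)."""
        m = np.zeros(f, dtype=np.int64)
        for s in self.sizes:
            if s <= f:
                m[s - 1] += 1
        return m

    def __str__(self) -> str:
        return "<" + ",".join(str(s) for s in self.sizes) + ">"


EMPTY = MutationPattern(())


@dataclass
class PatternTally:
    """Counts ``n_f(kappa)`` of patterns by family size.

    ``families`` records the total number of families of each size including
    non-mutant ones, so the empty-pattern count is implied:
    ``n_f(<>) = families[f] - sum_{kappa != <>} n_f(kappa)``.
    """

    counts: dict[tuple[int, MutationPattern], int] = field(default_factory=dict)
    families: dict[int, int] = field(default_factory=dict)

    def add(self, f: int, pattern: MutationPattern, n: int = 1) -> None:
        if pattern.n_mutants > f:
            raise ValidationError(
                f"pattern {pattern} has {pattern.n_mutants} mutants > family size {f}"
            )
        self.families[f] = self.families.get(f, 0) + n
        if pattern.sizes:
            key = (f, pattern)
            self.counts[key] = self.counts.get(key, 0) + n

    def n_empty(self, f: int) -> int:
        mutant = sum(n for (ff, k), n in self.counts.items() if ff == f)
        n0 = self.families.get(f, 0) - mutant
        if n0 < 0:
            raise ValidationError(f"more patterns than families for size {f}")
        return n0

    def sizes(self) -> list[int]:
        return sorted(self.families)

    def patterns_for(self, f: int) -> dict[MutationPattern, int]:
        return {k: n for (ff, k), n in self.counts.items() if ff == f}

    def total_families(self) -> int:
        return sum(self.families.values())

    def scaled(self, factor: int) -> "PatternTally":
        """Tally with every count multiplied by ``factor`` (testing aid)."""
        out = PatternTally()
        out.families = {f: n * factor for f, n in self.families.items()}
        out.counts = {k: n * factor for k, n in self.counts.items()}
        return out

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PatternTally):
            return NotImplemented
        return self.counts == other.counts and self.families == other.families


def enumerate_patterns(f: int) -> list[MutationPattern]:
    """All patterns with ``sum(sizes) <= f``, including the empty pattern.

    Guarded at ``f <= 8``: this is for normalization checks, not production.
    """
    if f > 8:
        raise ValidationError(f"enumerate_patterns refuses f={f} > 8")

    def parts(total: int, maximum: int) -> Iterator[tuple[int, ...]]:
        if total == 0:
            yield ()
            return
        for first in range(min(total, maximum), 0, -1):
            for rest in parts(total - first, first):
                yield (first,) + rest

    out = []
    for k in range(f + 1):
        out.extend(MutationPattern(p) for p in parts(k, k if k else 1))
    return out


def _log_lambda_terms(
    u: RateVector, coeffs: CoefficientSet
) -> tuple[np.ndarray, np.ndarray]:
    """Per-genealogy ``log lambda_s`` matrix and total mean, for one ``u``."""
    C = coeffs.interval_coeffs(u.partition)  # (M, I, f)
    lam = np.einsum("i,mif->mf", u.as_array(), C)
    tot = lam.sum(axis=1)
    with np.errstate(divide="ignore"):
        loglam = np.log(lam)
    return loglam, tot


def pattern_log_prob(
    pattern: MutationPattern, f: int, u: RateVector, coeffs: CoefficientSet
) -> float:
    """Log-probability of one mutation pattern for family size ``f``."""
    if coeffs.f != f:
        raise ValidationError(f"coefficient set is for f={coeffs.f}, not {f}")
    if pattern.n_mutants > f:
        warnings.warn(
            f"pattern {pattern} violates sum(sizes) <= f={f}; probability 0",
            stacklevel=2,
        )
        return -math.inf
    loglam, tot = _log_lambda_terms(u, coeffs)
    m = pattern.multiplicities(f).astype(float)
    active = m > 0  # 0*log(0) -> 0 convention: only active sizes contribute
    per_g = loglam[:, active] @ m[active] - tot
    norm = gammaln(m + 1).sum()
    return float(logsumexp(per_g) - math.log(coeffs.M) - norm)


class TallyLikelihood:
    """Pre-compiled likelihood of a tally: a pure function of the rates.

    Flattens the tally into per-family-size multiplicity matrices once, so the
    optimizer pays only a few dense matrix products per evaluation.
    """

    _COVERAGE_PENALTY = -1e12

    def __init__(self, tally: PatternTally, coeffs_by_f: dict[int, CoefficientSet]):
        missing = [f for f in tally.sizes() if f not in coeffs_by_f]
        if missing:
            raise ValidationError(
                f"missing coefficient sets for family sizes: {missing}"
            )
        self.coverage_gaps: list = []
        self._blocks = []
        for f in tally.sizes():
            coeffs = coeffs_by_f[f]
            if coeffs.f != f:
                raise ValidationError(
                    f"coefficient set labeled for f={coeffs.f} supplied for f={f}"
                )
            pats = [(EMPTY, tally.n_empty(f))] + sorted(
                tally.patterns_for(f).items()
            )
            pats = [(k, n) for k, n in pats if n > 0]
            if not pats:
                continue
            uncovered = np.zeros(len(pats), dtype=bool)
            for i, (k, _) in enumerate(pats):
                missing = [
                    s for s in set(k.sizes) if not np.any(coeffs.B[:, :, s - 1])
                ]
                if missing:
                    # no simulated genealogy can produce this size: the
                    # Monte-Carlo probability is zero however small the true
                    # one is; penalize hugely but keep the surface finite
                    uncovered[i] = True
                    self.coverage_gaps.append((f, k, missing))
                    warnings.warn(
                        f"no simulated branch of size {missing} for f={f}; "
                        f"pattern {k} treated as (near-)impossible — "
                        f"increase M",
                        stacklevel=2,
                    )
            mult = np.stack([k.multiplicities(f) for k, _ in pats]).astype(float)
            counts = np.array([n for _, n in pats], dtype=float)
            norms = gammaln(mult + 1).sum(axis=1)
            self._blocks.append((f, coeffs, mult, counts, norms, uncovered))

    def __call__(self, u: RateVector) -> float:
        return self.value_and_grad(u)[0]

    def value_and_grad(self, u: RateVector) -> tuple[float, np.ndarray]:
        """Log-likelihood and its gradient with respect to the rates.

        The likelihood is linear in the Poisson means, so the gradient is a
        softmax-weighted average over genealogies of ``m_s C/lambda - A``;
        exact gradients keep the quasi-Newton fits fast and reliable.
        """
        total = 0.0
        grad = np.zeros(u.partition.I)
        for f, coeffs, mult, counts, norms, uncovered in self._blocks:
            C = coeffs.interval_coeffs(u.partition)  # (M, I, f)
            lam = np.einsum("i,mif->mf", u.as_array(), C)
            CA = C.sum(axis=2)  # (M, I)
            tot = lam.sum(axis=1)
            with np.errstate(divide="ignore"):
                loglam = np.maximum(np.log(lam), -1e300)
            # -inf entries only matter where mult > 0; clip so 0 * log(0) = 0
            S = mult @ loglam.T - tot[None, :]
            A = logsumexp(S, axis=1)
            logp = A - math.log(coeffs.M) - norms
            logp = np.where(uncovered, self._COVERAGE_PENALTY, logp)
            total += float(counts @ logp)

            with np.errstate(invalid="ignore", over="ignore"):
                W = np.exp(S - A[:, None])  # softmax over genealogies
            W = np.nan_to_num(W, nan=0.0, posinf=0.0)
            eff = np.where(uncovered, 0.0, counts)  # penalty rows are flat
            NW = W * eff[:, None]
            Q = NW.T @ mult  # (M, f): weighted mutation multiplicities
            with np.errstate(divide="ignore", invalid="ignore"):
                R = np.where(lam > 0, Q / np.where(lam > 0, lam, 1.0), 0.0)
            grad += np.einsum("mf,mif->i", R, C)
            grad -= NW.sum(axis=0) @ CA
        return total, grad


def tally_log_likelihood(
    tally: PatternTally, u: RateVector, coeffs_by_f: dict[int, CoefficientSet]
) -> float:
    """Experiment log-likelihood ``sum_f sum_kappa n_f(kappa) log p_f(kappa)``."""
    return TallyLikelihood(tally, coeffs_by_f)(u)
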
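"""Forward simulation of complete screening experiments with known truth.

Each family is one father: a genealogy of its ``f`` offspring lines is drawn
from the coalescent engine, Poisson mutations are placed on ancestral
branches at the per-interval rates, and every mutation is inherited by the
sampled descendants of its branch.  A line carrying several mutations is
attributed to the earliest-division one (masking: a second high-lethality
mutation is undetectable once the first kills the homozygotes).  Observed
F3 counts are binomial around the baseline z/z proportion ``p0`` for
non-carriers and around the mutation's survival fraction for carriers, and
complementation crosses among candidate lines are simulated the same way.

Defaults emulate the original screen design: families of up to 35 initiated
lines thinned to ~28 recorded, >= 40 and on average ~118 F3 offspring per
line, baseline z/z proportion 0.175, and mutation lethalities uniform on
[0.97, 1].
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .coalescent import simulate_genealogy_lineages
from .germline import (
    GermlineDynamics,
    IntervalPartition,
    RateVector,
    ValidationError,
    build_dynamics,
    resolve_partition,
)
from .screen import CrossRecord, LineRecord

__all__ = [
    "SynthConfig",
    "TrueMutation",
    "FamilyTruth",
    "SimulatedExperiment",
    "generate_family",
    "simulate_crosses",
    "generate_experiment",
]

_REFERENCE_P0 = 0.175  # z/z proportion at which lethality is defined


def _default_rates() -> RateVector:
    # magnitudes typical of the >=97% lethality class
    part = resolve_partition((1, 2, 3, 14, -5), 38)
    return RateVector.of(
        [x * 1e-3 for x in (67.371, 1.258, 0.021, 0.031, 0.177, 1.954)], part
    )


@dataclass
class SynthConfig:
    """Study-design constants for the synthetic screen."""

    n_families: int = 200
    rates: RateVector = field(default_factory=_default_rates)
    dynamics: GermlineDynamics = field(default_factory=build_dynamics)
    lines_per_family: int | None = None  # None -> attrition model below
    lines_initiated: int = 35
    line_survival: float = 0.81  # thinning initiated -> recorded (mean ~28.3)
    min_lines: int = 2
    offspring_mean: float = 118.0
    offspring_min: int = 40
    p0: float = 0.175
    lethality_range: tuple[float, float] = (0.97, 1.0)
    candidate_threshold: float = 0.92
    cross_offspring: int = 100
    cross_policy: str = "adaptive"  # "adaptive" | "chain"
    design_alpha: float = 0.05  # bench-side complementation call during design
    extra_cross_fraction: float = 0.25  # extra random edges beyond the design
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0 < self.p0 <= 1 / 3:
            raise ValidationError("p0 must be in (0, 1/3]")
        lo, hi = self.lethality_range
        if not 0 <= lo <= hi <= 1:
            raise ValidationError("lethality_range must be within [0, 1]")
        if self.rates.partition.D != self.dynamics.D:
            raise ValidationError("rates partition and dynamics disagree on D")


@dataclass
class TrueMutation:
    """Ground truth for one simulated mutation."""

    id: int
    division: int
    lethality: float
    carriers: tuple[int, ...]  # lines inheriting the mutation
    attributed: tuple[int, ...]  # carriers not masked by an earlier mutation

    @property
    def masked(self) -> bool:
        return len(self.attributed) == 0


@dataclass
class FamilyTruth:
    family: str
    f: int
    mutations: list[TrueMutation]

    def mutant_lines(self) -> set[int]:
        return {c for m in self.mutations for c in m.carriers}

    def to_json(self) -> dict:
        return {
            "family": self.family,
            "f": self.f,
            "mutations": [asdict(m) for m in self.mutations],
        }


def _draw_family_size(config: SynthConfig, rng: np.random.Generator) -> int:
    if config.lines_per_family is not None:
        return config.lines_per_family
    f = int(rng.binomial(config.lines_initiated, config.line_survival))
    return max(f, config.min_lines)


def _survival_fraction(d: float, p0: float) -> float:
    # lethality is defined operationally against the 17.5% baseline
    return float(np.clip((1.0 - d) * p0 / _REFERENCE_P0, 0.0, 1.0))


def generate_family(
    config: SynthConfig, rng: np.random.Generator, family: str = "F1"
) -> tuple[list[LineRecord], FamilyTruth]:
    """Simulate one family's genealogy, mutations, and F3 counts."""
    f = _draw_family_size(config, rng)
    lineages = simulate_genealogy_lineages(f, config.dynamics, rng)
    per_div = config.rates.per_division()
    lo, hi = config.lethality_range

    mutations: list[TrueMutation] = []
    for d in range(1, config.dynamics.D + 1):
        branches = lineages[d - 1]
        rate = per_div[d - 1]
        if rate <= 0 or not branches:
            continue
        n_mut = rng.poisson(rate * len(branches))
        for _ in range(n_mut):
            branch = branches[rng.integers(len(branches))]
            mutations.append(
                TrueMutation(
                    id=len(mutations),
                    division=d,
                    lethality=float(rng.uniform(lo, hi)),
                    carriers=tuple(sorted(branch)),
                    attributed=(),
                )
            )

    # masking: each carrier line is attributed to its earliest mutation
    attribution: dict[int, int] = {}
    for mut in sorted(mutations, key=lambda m: (m.division, m.id)):
        for line in mut.carriers:
            attribution.setdefault(line, mut.id)
    for mut in mutations:
        mut.attributed = tuple(
            line for line in mut.carriers if attribution.get(line) == mut.id
        )

    lethality_of = {m.id: m.lethality for m in mutations}
    lines = []
    for i in range(f):
        total = config.offspring_min + int(
            rng.poisson(max(config.offspring_mean - config.offspring_min, 0.0))
        )
        mid = attribution.get(i)
        q = config.p0 if mid is None else _survival_fraction(lethality_of[mid], config.p0)
        zz = int(rng.binomial(total, q))
        lines.append(LineRecord(family=family, line=str(i), zz=zz, total=total))
    return lines, FamilyTruth(family=family, f=f, mutations=mutations)


def simulate_crosses(
    lines: Sequence[LineRecord],
    truth: FamilyTruth,
    config: SynthConfig,
    rng: np.random.Generator,
) -> list[CrossRecord]:
    """Simulate complementation crosses among candidate lines.

    Candidates are lines whose *observed* lethality reaches the candidate
    threshold.  The default ``adaptive`` design mirrors how screens resolve
    ambiguity: each candidate is crossed in turn against a representative of
    every group established so far until a cross fails to complement, at
    which point the line joins that group; a line complementing every
    representative founds a new group.  (A blind chain through the
    candidates — available as ``cross_policy="chain"`` — cannot separate
    two interleaved same-lethality mutations and is kept only for
    comparison.)  A fraction of extra random pairs is added for redundancy.

    A cross between two lines attributed to the same mutation shows that
    mutation's homozygote deficit; any other pair complements and shows
    baseline ``p0``.
    """
    candidates = [
        ln for ln in lines if 1.0 - ln.zz / ln.total > config.candidate_threshold
    ]
    if len(candidates) < 2:
        return []

    attribution = {
        line: m.id for m in truth.mutations for line in m.attributed
    }
    lethality_of = {m.id: m.lethality for m in truth.mutations}

    def outcome(a: LineRecord, b: LineRecord) -> CrossRecord:
        ma, mb = attribution.get(int(a.line)), attribution.get(int(b.line))
        if ma is not None and ma == mb:
            q = _survival_fraction(lethality_of[ma], config.p0)
        else:
            q = config.p0
        zz = int(rng.binomial(config.cross_offspring, q))
        return CrossRecord(
            family=truth.family, line_a=a.line, line_b=b.line,
            zz=zz, total=config.cross_offspring,
        )

    crosses: list[CrossRecord] = []
    seen: set[tuple[str, str]] = set()

    def perform(a: LineRecord, b: LineRecord) -> CrossRecord | None:
        key = tuple(sorted((a.line, b.line)))
        if key in seen:
            return None
        seen.add(key)
        c = outcome(a, b)
        crosses.append(c)
        return c

    order = [candidates[i] for i in rng.permutation(len(candidates))]
    if config.cross_policy == "chain":
        for a, b in zip(order[:-1], order[1:]):
            perform(a, b)
    elif config.cross_policy == "adaptive":
        from .screen import allelism_lr  # local import to avoid a cycle
        from scipy import stats as _stats

        representatives: list[LineRecord] = [order[0]]
        for ln in order[1:]:
            for rep in representatives:
                c = perform(ln, rep)
                if c is None:
                    continue
                lr = allelism_lr(ln.zz, ln.total, rep.zz, rep.total, c.zz, c.total)
                if _stats.chi2.sf(lr, 1) >= config.design_alpha:
                    break  # fails to complement: same mutation, stop here
            else:
                representatives.append(ln)
    else:
        raise ValidationError(f"unknown cross_policy {config.cross_policy!r}")

    n_extra = int(config.extra_cross_fraction * len(candidates))
    for _ in range(n_extra):
        i, j = rng.choice(len(candidates), size=2, replace=False)
        perform(candidates[i], candidates[j])
    return crosses


@dataclass
class SimulatedExperiment:
    """A full synthetic screen: line and cross tables plus the truth ledger."""

    lines: pd.DataFrame
    crosses: pd.DataFrame
    truth: list[FamilyTruth]
    config_seed: int | None

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "lines": outdir / "lines.tsv",
            "crosses": outdir / "crosses.tsv",
            "truth": outdir / "truth.json",
        }
        self.lines.to_csv(paths["lines"], sep="\t", index=False)
        self.crosses.to_csv(paths["crosses"], sep="\t", index=False)
        with open(paths["truth"], "w") as fh:
            json.dump(
                {
                    "seed": self.config_seed,
                    "families": [t.to_json() for t in self.truth],
                },
                fh,
                indent=1,
                sort_keys=True,
            )
        return paths


def generate_experiment(
    config: SynthConfig, seed: int | None = None
) -> SimulatedExperiment:
    """Simulate ``n_families`` independent families (reproducible by seed)."""
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    line_rows, cross_rows, truths = [], [], []
    for i in range(config.n_families):
        fam = f"F{i + 1}"
        lines, truth = generate_family(config, rng, family=fam)
        crosses = simulate_crosses(lines, truth, config, rng)
        truths.append(truth)
        for ln in lines:
            line_rows.append(
                {
                    "family": ln.family,
                    "line": ln.line,
                    "zz": ln.zz,
                    "total": ln.total,
                    "balancer_flag": int(ln.balancer_offspring_seen),
                }
            )
        for c in crosses:
            cross_rows.append(
                {
                    "family": c.family,
                    "line_a": c.line_a,
                    "line_b": c.line_b,
                    "zz": c.zz,
                    "total": c.total,
                }
            )
    lines_df = pd.DataFrame(
        line_rows, columns=["family", "line", "zz", "total", "balancer_flag"]
    )
    crosses_df = pd.DataFrame(
        cross_rows, columns=["family", "line_a", "line_b", "zz", "total"]
    )
    return SimulatedExperiment(
        lines=lines_df, crosses=crosses_df, truth=truths, config_seed=seed
    )
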
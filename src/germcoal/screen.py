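"""Allelism-screen analysis: QC, complementation tests, mutation delineation.

Raw screen data are per-line F3 counts (z/z homozygotes out of total
offspring) and per-cross counts between candidate mutant lines within a
family.  A line's *lethality* is ``d = 1 - zz/total``.  Two mutant lines
carry the same mutation when their cross shows a homozygote deficit similar
to the parents (non-complementation); the binomial likelihood-ratio statistic
for a cross is asymptotically chi-square(1) under the shared-mutation null.
Crosses within a family are tested at level ``alpha/m`` (``m`` = number of
crosses performed), lines joined by non-significant crosses are merged, and
each merged group becomes one mutation whose size enters the family's
mutation pattern.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
from scipy import stats
from scipy.special import xlogy

from .germline import ValidationError
from .patterns import MutationPattern, PatternTally
from .inference import SummaryStats, classical_rate

__all__ = [
    "LineRecord",
    "CrossRecord",
    "MutationGroup",
    "LethalityWindow",
    "ScreenConfig",
    "FamilyQC",
    "Delineation",
    "line_stats",
    "family_qc",
    "allelism_lr",
    "delineate_mutations",
    "extract_pattern",
    "tally_patterns",
    "exclude_high_mutant_families",
    "screen_family",
    "screen_experiment",
]


@dataclass(frozen=True)
class LineRecord:
    family: str
    line: str
    zz: int
    total: int
    balancer_offspring_seen: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.zz <= self.total:
            raise ValidationError(
                f"line {self.family}/{self.line}: zz={self.zz} outside 0..total={self.total}"
            )


@dataclass(frozen=True)
class CrossRecord:
    family: str
    line_a: str
    line_b: str
    zz: int
    total: int

    def __post_init__(self) -> None:
        if self.line_a == self.line_b:
            raise ValidationError(f"cross {self.family}: line crossed with itself")
        if not 0 <= self.zz <= self.total:
            raise ValidationError(
                f"cross {self.family} {self.line_a}x{self.line_b}: zz outside 0..total"
            )


@dataclass(frozen=True)
class MutationGroup:
    """One delineated mutation: its member lines and pooled lethality."""

    members: tuple[str, ...]
    zz: int
    total: int

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def zz_fraction(self) -> float:
        return self.zz / self.total if self.total else 0.0

    @property
    def lethality(self) -> float:
        return 1.0 - self.zz_fraction


@dataclass(frozen=True)
class LethalityWindow:
    """Half-open lethality window ``[lo, hi)``; the top window is ``[lo, 1]``."""

    lo: float
    hi: float = 1.0
    closed_top: bool = True

    def __contains__(self, d: float) -> bool:
        if self.closed_top and self.hi >= 1.0:
            return self.lo <= d <= 1.0
        return self.lo <= d < self.hi

    def label(self) -> str:
        if self.closed_top and self.hi >= 1.0:
            return f">={self.lo:.0%}" if self.lo > 0 else "all"
        return f"[{self.lo:.0%},{self.hi:.0%})"


@dataclass(frozen=True)
class ScreenConfig:
    """Screen-wide thresholds.

    ``alpha`` is the overall allelism significance level split across the
    ``m`` crosses of a family; ``untested_lethality_threshold`` is the
    lethality above which an uncrossed line is undeterminable and dropped
    (when other candidates were tested).
    """

    alpha: float = 0.10
    min_offspring: int = 40
    untested_lethality_threshold: float = 0.92
    windows: tuple[LethalityWindow, ...] = (
        LethalityWindow(0.99, 1.0),
        LethalityWindow(0.98, 0.99, closed_top=False),
        LethalityWindow(0.97, 0.98, closed_top=False),
    )

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must be in (0, 1)")


def line_stats(line: LineRecord) -> tuple[float, float]:
    """(z/z fraction, lethality d) for one line; errors on empty counts."""
    if line.total <= 0:
        raise ValidationError(f"line {line.family}/{line.line} has no offspring")
    frac = line.zz / line.total
    return frac, 1.0 - frac


@dataclass
class FamilyQC:
    """QC outcome: recorded lines, analysis lines, drop reasons."""

    family: str
    recorded: list[LineRecord]
    analyzed: list[LineRecord]
    dropped: list[tuple[str, str]]
    rejected: str | None = None

    @property
    def ok(self) -> bool:
        return self.rejected is None

    @property
    def size(self) -> int:
        """Family size for pattern purposes (lines entering the analysis)."""
        return len(self.analyzed)


def family_qc(
    lines: Sequence[LineRecord],
    crosses: Sequence[CrossRecord],
    config: ScreenConfig = ScreenConfig(),
) -> FamilyQC:
    """Apply line- and family-level quality control.

    Lines with balancer offspring in F3 (non-virgin females) or fewer than
    ``min_offspring`` examined offspring are disqualified.  A surviving line
    that exceeds the untested-lethality threshold but appears in no cross is
    removed as undeterminable — unless it is the family's only candidate, in
    which case no cross was possible and its identity is unambiguous.
    Families retaining fewer than two lines are rejected (a result, not an
    error).
    """
    family = lines[0].family if lines else ""
    dropped: list[tuple[str, str]] = []
    recorded: list[LineRecord] = []
    for ln in lines:
        if ln.balancer_offspring_seen:
            dropped.append((ln.line, "balancer offspring in F3"))
        elif ln.total < config.min_offspring:
            dropped.append((ln.line, f"fewer than {config.min_offspring} offspring"))
        else:
            recorded.append(ln)

    tested = {c.line_a for c in crosses} | {c.line_b for c in crosses}
    thr = config.untested_lethality_threshold
    candidates = [ln for ln in recorded if line_stats(ln)[1] > thr]
    analyzed = []
    for ln in recorded:
        _, d = line_stats(ln)
        undeterminable = (
            d > thr
            and ln.line not in tested
            and any(c.line != ln.line and c.line in tested for c in candidates)
        )
        if undeterminable:
            dropped.append((ln.line, "untested line above lethality threshold"))
        else:
            analyzed.append(ln)

    qc = FamilyQC(family=family, recorded=recorded, analyzed=analyzed, dropped=dropped)
    if len(analyzed) < 2:
        qc.rejected = "too few lines"
    return qc


def allelism_lr(z1: int, n1: int, z2: int, n2: int, z3: int, n3: int) -> float:
    """Binomial LR statistic for "same mutation" in a complementation cross.

    ``(z1, n1)`` and ``(z2, n2)`` are the parental lines' z/z and total F3
    counts, ``(z3, n3)`` the cross's.  Zero-count terms follow the
    ``0*log(0) = 0`` convention; the statistic is non-negative and is
    chi-square(1) under the null of a shared z/z proportion.
    """
    for label, n in (("n1", n1), ("n2", n2), ("n3", n3)):
        if n <= 0:
            raise ValidationError(f"{label} must be positive")

    def term(z: float, n: float, p: float) -> float:
        return float(xlogy(z, p) + xlogy(n - z, 1.0 - p))

    z12, n12 = z1 + z2, n1 + n2
    z123, n123 = z12 + z3, n12 + n3
    ll_alt = term(z12, n12, z12 / n12) + term(z3, n3, z3 / n3)
    ll_null = term(z123, n123, z123 / n123)
    return max(2.0 * (ll_alt - ll_null), 0.0)


@dataclass
class Delineation:
    """Mutation groups for one family plus the decisions that produced them."""

    groups: list[MutationGroup]
    alpha_per_test: float
    conflicts: list[dict] = field(default_factory=list)

    @property
    def n_groups(self) -> int:
        return len(self.groups)


def delineate_mutations(
    qc: FamilyQC,
    crosses: Sequence[CrossRecord],
    config: ScreenConfig = ScreenConfig(),
) -> Delineation:
    """Partition tested lines into mutations via complementation crosses.

    Each cross is tested at level ``alpha/m``; lines joined by non-significant
    crosses merge (union of connected components), significant crosses keep
    groups apart.  A significant cross whose endpoints are nevertheless
    connected through non-significant edges is a conflict: it is resolved
    deterministically by cutting the largest-statistic non-significant edge
    on the connecting path, and reported.  Surviving candidate lines in no
    cross (only possible when they were the lone candidate) form singleton
    groups.
    """
    by_line = {ln.line: ln for ln in qc.analyzed}
    crosses = [c for c in crosses if c.line_a in by_line and c.line_b in by_line]
    m = len(crosses)
    level = config.alpha / m if m else config.alpha

    graph = nx.Graph()
    significant: list[tuple[str, str, float]] = []
    for c in crosses:
        a, b = by_line[c.line_a], by_line[c.line_b]
        lr = allelism_lr(a.zz, a.total, b.zz, b.total, c.zz, c.total)
        p = float(stats.chi2.sf(lr, 1))
        graph.add_node(c.line_a)
        graph.add_node(c.line_b)
        if p < level:
            significant.append((c.line_a, c.line_b, lr))
        else:
            graph.add_edge(c.line_a, c.line_b, lr=lr)

    # lone candidates never crossed: their identity is unambiguous
    thr = config.untested_lethality_threshold
    tested = set(graph.nodes)
    for ln in qc.analyzed:
        if ln.line not in tested and line_stats(ln)[1] > thr:
            graph.add_node(ln.line)

    conflicts: list[dict] = []
    significant.sort(key=lambda e: -e[2])
    changed = True
    while changed:
        changed = False
        for a, b, lr in significant:
            if a in graph and b in graph and nx.has_path(graph, a, b):
                path = nx.shortest_path(graph, a, b)
                edges = list(zip(path[:-1], path[1:]))
                cut = max(edges, key=lambda e: graph.edges[e]["lr"])
                conflicts.append(
                    {"significant": (a, b), "cut": cut, "lr": graph.edges[cut]["lr"]}
                )
                graph.remove_edge(*cut)
                changed = True

    groups = []
    for comp in nx.connected_components(graph):
        members = tuple(sorted(comp))
        zz = sum(by_line[x].zz for x in members)
        total = sum(by_line[x].total for x in members)
        groups.append(MutationGroup(members=members, zz=zz, total=total))
    groups.sort(key=lambda g: g.members)
    return Delineation(groups=groups, alpha_per_test=level, conflicts=conflicts)


def extract_pattern(
    delineation: Delineation, window: LethalityWindow, family_size: int
) -> MutationPattern:
    """Mutation pattern: sizes of groups whose pooled lethality is in-window."""
    sizes = [g.size for g in delineation.groups if g.lethality in window]
    pattern = MutationPattern(tuple(sizes))
    if pattern.n_mutants > family_size:
        raise ValidationError(
            f"pattern {pattern} exceeds family size {family_size}: data integrity error"
        )
    return pattern


def tally_patterns(
    families: Iterable[tuple[int, MutationPattern]],
    n_lines: int | None = None,
) -> tuple[PatternTally, SummaryStats]:
    """Aggregate per-family patterns into a tally and summary statistics.

    ``families`` yields (family size, pattern).  ``n_lines`` overrides the
    examined-line total for the classical rate (defaults to the sum of
    family sizes).
    """
    tally = PatternTally()
    m_t = n_m = size_sum = 0
    for f, pattern in families:
        tally.add(f, pattern)
        m_t += pattern.n_mutations
        n_m += pattern.n_mutants
        size_sum += f
    lines = n_lines if n_lines is not None else size_sum
    mu = classical_rate(n_m, lines) if lines else 0.0
    return tally, SummaryStats(m_t=m_t, n_m=n_m, lines=lines, mu_tilde=mu)


def exclude_high_mutant_families(
    families: Sequence[tuple[int, MutationPattern]], threshold: float
) -> tuple[list[tuple[int, MutationPattern]], int]:
    """Drop families whose mutant-line fraction reaches ``threshold``.

    Guards the rate inference against sporadic pre-existing mutations, which
    surface as families that are (almost) all mutant.
    """
    if not 0 < threshold <= 1:
        raise ValidationError("threshold must be in (0, 1]")
    kept = [
        (f, k) for f, k in families if f == 0 or k.n_mutants / f < threshold
    ]
    return kept, len(families) - len(kept)


def screen_experiment(
    lines: Sequence[LineRecord],
    crosses: Sequence[CrossRecord],
    window: LethalityWindow,
    config: ScreenConfig = ScreenConfig(),
) -> tuple[PatternTally, SummaryStats, list[tuple[int, MutationPattern]]]:
    """Screen every family in a line/cross table and tally the patterns."""
    by_lines: dict[str, list[LineRecord]] = {}
    for ln in lines:
        by_lines.setdefault(ln.family, []).append(ln)
    by_crosses: dict[str, list[CrossRecord]] = {}
    for c in crosses:
        by_crosses.setdefault(c.family, []).append(c)
    results = []
    for fam, fam_lines in by_lines.items():
        res = screen_family(fam_lines, by_crosses.get(fam, []), window, config)
        if res is not None:
            results.append(res)
    tally, stats_ = tally_patterns(results)
    return tally, stats_, results


def screen_family(
    lines: Sequence[LineRecord],
    crosses: Sequence[CrossRecord],
    window: LethalityWindow,
    config: ScreenConfig = ScreenConfig(),
) -> tuple[int, MutationPattern] | None:
    """QC + delineation + pattern extraction for one family.

    Returns ``(family size, pattern)`` or ``None`` if the family fails QC.
    """
    qc = family_qc(lines, crosses, config)
    if not qc.ok:
        return None
    delineation = delineate_mutations(qc, crosses, config)
    return qc.size, extract_pattern(delineation, window, qc.size)
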
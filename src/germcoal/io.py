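"""Readers and writers for screen tables, pattern notation, and configs.

Tabular data travel as TSV with declared headers; the pattern-tally text
format mirrors the compact screen notation, one block per family size::

    families: 111
    20: <1>^11 <2> <3> <17> <1,1>^2

meaning 111 families of size 20 were screened, of which eleven showed one
single-line mutation, one each a 2-, 3- and 17-line mutation, and two a
pair of single-line mutations; the remaining 95 families are non-mutant.
"""

from __future__ import annotations

import hashlib
import json
import re
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from .germline import (
    GermlineDynamics,
    IntervalPartition,
    ValidationError,
    build_dynamics,
    resolve_partition,
)
from .patterns import MutationPattern, PatternTally
from .screen import CrossRecord, LineRecord, ScreenConfig, LethalityWindow

__all__ = [
    "read_lines",
    "read_crosses",
    "write_lines",
    "write_crosses",
    "parse_pattern_notation",
    "format_pattern_notation",
    "load_run_config",
    "RunConfig",
    "provenance",
]

_LINE_COLUMNS = ["family", "line", "zz", "total", "balancer_flag"]
_CROSS_COLUMNS = ["family", "line_a", "line_b", "zz", "total"]


def _read_table(path: str | Path, columns: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"family": str})
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    return df


def read_lines(path: str | Path) -> list[LineRecord]:
    """Read per-line F3 counts; malformed rows are reported by line number."""
    df = _read_table(path, _LINE_COLUMNS)
    records = []
    for idx, row in enumerate(df.itertuples(index=False), start=2):
        try:
            records.append(
                LineRecord(
                    family=str(row.family),
                    line=str(row.line),
                    zz=int(row.zz),
                    total=int(row.total),
                    balancer_offspring_seen=bool(row.balancer_flag),
                )
            )
        except (ValidationError, ValueError) as exc:
            raise ValidationError(f"{path}: row {idx}: {exc}") from exc
    return records


def read_crosses(path: str | Path) -> list[CrossRecord]:
    df = _read_table(path, _CROSS_COLUMNS)
    records = []
    for idx, row in enumerate(df.itertuples(index=False), start=2):
        try:
            records.append(
                CrossRecord(
                    family=str(row.family),
                    line_a=str(row.line_a),
                    line_b=str(row.line_b),
                    zz=int(row.zz),
                    total=int(row.total),
                )
            )
        except (ValidationError, ValueError) as exc:
            raise ValidationError(f"{path}: row {idx}: {exc}") from exc
    return records


def write_lines(records: Sequence[LineRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "family": r.family,
                "line": r.line,
                "zz": r.zz,
                "total": r.total,
                "balancer_flag": int(r.balancer_offspring_seen),
            }
            for r in records
        ],
        columns=_LINE_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


def write_crosses(records: Sequence[CrossRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "family": r.family,
                "line_a": r.line_a,
                "line_b": r.line_b,
                "zz": r.zz,
                "total": r.total,
            }
            for r in records
        ],
        columns=_CROSS_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


_PATTERN_RE = re.compile(r"<([0-9,\s]*)>(?:\^(\d+))?")
_SIZE_LINE_RE = re.compile(r"^(\d+)\s*:\s*(.*)$")
_FAMILIES_RE = re.compile(r"^families\s*:\s*(\d+)$")


def format_pattern_notation(tally: PatternTally) -> str:
    """Render a tally in the screen's compact pattern notation."""
    blocks = []
    for f in tally.sizes():
        parts = []
        for pattern, n in sorted(tally.patterns_for(f).items()):
            body = "<" + ",".join(str(s) for s in pattern.sizes) + ">"
            parts.append(body if n == 1 else f"{body}^{n}")
        blocks.append(f"families: {tally.families[f]}")
        blocks.append(f"{f}: " + " ".join(parts))
    return "\n".join(blocks) + "\n"


def parse_pattern_notation(text: str) -> PatternTally:
    """Parse the pattern-tally dialect; errors carry the offending position."""
    tally = PatternTally()
    pending_families: int | None = None
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fam_match = _FAMILIES_RE.match(line)
        if fam_match:
            if pending_families is not None:
                raise ValidationError(
                    f"line {lineno}: 'families:' header without a pattern line"
                )
            pending_families = int(fam_match.group(1))
            continue
        size_match = _SIZE_LINE_RE.match(line)
        if not size_match:
            raise ValidationError(f"line {lineno}: unrecognized pattern line: {raw!r}")
        f = int(size_match.group(1))
        body = size_match.group(2)
        consumed = 0
        n_mutant = 0
        for m in _PATTERN_RE.finditer(body):
            between = body[consumed : m.start()].strip()
            if between:
                raise ValidationError(
                    f"line {lineno}, col {consumed + m.start(1)}: stray text {between!r}"
                )
            sizes = tuple(int(x) for x in m.group(1).replace(" ", "").split(",") if x)
            count = int(m.group(2)) if m.group(2) else 1
            tally.add(f, MutationPattern(sizes), count)
            if sizes:
                n_mutant += count
            consumed = m.end()
        if body[consumed:].strip():
            raise ValidationError(
                f"line {lineno}: trailing text {body[consumed:].strip()!r}"
            )
        if pending_families is not None:
            if pending_families < n_mutant:
                raise ValidationError(
                    f"line {lineno}: families header {pending_families} < "
                    f"{n_mutant} mutant families"
                )
            tally.families[f] = (
                tally.families.get(f, 0) - n_mutant + pending_families
            )
            pending_families = None
    if pending_families is not None:
        raise ValidationError("dangling 'families:' header at end of input")
    return tally


class RunConfig:
    """Configuration for a pipeline run, loadable from YAML/JSON.

    Recognized keys: ``D``, ``n5``, ``n8``, ``stem_cap``, ``partition``
    (boundary spec, negative shorthand allowed), ``M`` (coalescent
    replicates), ``seed``, ``alpha``, ``min_offspring``, ``window``
    (minimum lethality, e.g. 0.97).
    """

    def __init__(self, raw: dict):
        self.raw = dict(raw)
        self.D = int(raw.get("D", 38))
        self.n5 = int(raw.get("n5", 6))
        self.n8 = int(raw.get("n8", 8))
        self.stem_cap = int(raw.get("stem_cap", 128))
        self.partition_spec = tuple(raw.get("partition", (1, 2, 3, 14, -5)))
        self.M = int(raw.get("M", 2000))
        self.seed = int(raw.get("seed", 0))
        self.alpha = float(raw.get("alpha", 0.10))
        self.min_offspring = int(raw.get("min_offspring", 40))
        self.window_lo = float(raw.get("window", 0.97))
        self.n_families = int(raw.get("n_families", 200))
        self.lines_per_family = raw.get("lines_per_family")

    @property
    def dynamics(self) -> GermlineDynamics:
        return build_dynamics(self.D, self.n5, self.n8, self.stem_cap)

    @property
    def partition(self) -> IntervalPartition:
        return resolve_partition(self.partition_spec, self.D)

    @property
    def screen_config(self) -> ScreenConfig:
        return ScreenConfig(alpha=self.alpha, min_offspring=self.min_offspring)

    @property
    def window(self) -> LethalityWindow:
        return LethalityWindow(self.window_lo, 1.0)


def load_run_config(path: str | Path) -> RunConfig:
    text = Path(path).read_text()
    raw = yaml.safe_load(text) or {}
    if not isinstance(raw, dict):
        raise ValidationError(f"{path}: config must be a mapping")
    return RunConfig(raw)


def provenance(seed: int | None, config_path: str | Path | None = None) -> dict:
    """Reproducibility stamp written next to every CLI output."""
    from importlib.metadata import version as _version

    stamp = {"seed": seed, "package": "germcoal"}
    try:
        stamp["version"] = _version("germcoal")
    except Exception:
        stamp["version"] = "unknown"
    if config_path is not None:
        stamp["config"] = str(config_path)
        stamp["config_sha256"] = hashlib.sha256(
            Path(config_path).read_bytes()
        ).hexdigest()
    return stamp


def write_provenance(path: str | Path, stamp: dict) -> None:
    with open(path, "w") as fh:
        json.dump(stamp, fh, indent=1, sort_keys=True)
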
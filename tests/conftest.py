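"""Shared fixtures: miniature dynamics, cached coefficient sets, and the
worked family-140 example reconstructed from its published F3 table."""

from __future__ import annotations

import pytest

from germcoal.coalescent import simulate_coefficients
from germcoal.germline import GermlineDynamics, build_dynamics, resolve_partition, RateVector
from germcoal.screen import CrossRecord, LineRecord


@pytest.fixture(scope="session")
def mini_dyn() -> GermlineDynamics:
    """Six-division pure-doubling trajectory, small enough to enumerate."""
    return GermlineDynamics.plain([2 ** i for i in range(7)])


@pytest.fixture(scope="session")
def std_dyn() -> GermlineDynamics:
    return build_dynamics(D=38, n5=6, n8=8, stem_cap=128)


@pytest.fixture(scope="session")
def part6():
    return resolve_partition((1, 2, 3, 14, -5), 38)


@pytest.fixture(scope="session")
def rates97(part6) -> RateVector:
    """Interval rates typical of the >=97% lethality class (x 10^-3)."""
    return RateVector.of(
        [x * 1e-3 for x in (67.371, 1.258, 0.021, 0.031, 0.177, 1.954)], part6
    )


@pytest.fixture(scope="session")
def coeffs20(std_dyn):
    """2000 cached genealogies for 20-line families (shared across tests)."""
    return simulate_coefficients(20, std_dyn, M=2000, seed=11)


@pytest.fixture(scope="session")
def coeffs5_mini(mini_dyn):
    return simulate_coefficients(5, mini_dyn, M=1500, seed=2)


# --- family 140: published F3 counts (line, z/z, total) -------------------

FAMILY140_TABLE = [
    ("1", 0, 110), ("2", 3, 90), ("3", 0, 56), ("5", 29, 112), ("6", 2, 72),
    ("9", 3, 127), ("11", 0, 120), ("12", 1, 64), ("14", 1, 101),
    ("15", 0, 70), ("16", 2, 63), ("18", 3, 71), ("19", 1, 54),
    ("24", 2, 103), ("28", 0, 62), ("29", 1, 125), ("30", 1, 118),
]

# chain through the 14 tested lines other than line 3, plus the 1x3 cross
# and one redundant edge; outcomes synthetic but shaped like the published
# cross diagram (1x3 clearly significant; 19x30 and 12x24 significant only
# before multiple-test adjustment)
FAMILY140_CROSSES = [
    ("1", "6", 2, 100), ("6", "9", 1, 101), ("9", "11", 2, 100),
    ("11", "12", 1, 100), ("12", "24", 7, 100), ("24", "14", 2, 100),
    ("14", "15", 0, 101), ("15", "16", 1, 100), ("16", "18", 3, 100),
    ("18", "19", 2, 100), ("19", "30", 6, 100), ("30", "28", 1, 100),
    ("28", "29", 0, 100), ("6", "15", 1, 100), ("1", "3", 8, 100),
]


@pytest.fixture()
def family140() -> tuple[list[LineRecord], list[CrossRecord]]:
    """The worked example: 17 recorded lines after initial QC.

    The family started with 30 lines; one had balancer offspring in F3, two
    had too few offspring, and the rest were lost before F3 (not in the
    table).  Cross outcomes are synthetic, chosen to reproduce the published
    delineation (groups {3} and the 14 other tested lines).
    """
    lines = [
        LineRecord("140", name, zz, total) for name, zz, total in FAMILY140_TABLE
    ]
    lines.append(LineRecord("140", "31", 5, 80, balancer_offspring_seen=True))
    lines.append(LineRecord("140", "32", 1, 30))
    lines.append(LineRecord("140", "33", 0, 20))
    crosses = [
        CrossRecord("140", a, b, zz, total) for a, b, zz, total in FAMILY140_CROSSES
    ]
    return lines, crosses
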
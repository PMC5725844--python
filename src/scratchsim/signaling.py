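"""Three-pathway motility arithmetic and the inhibition-scaled cell cycle.

The model abstracts L1 ectodomain signaling as two receptor arms — integrin
(A) and FGFR (B) — converging on FAK (C). Signaling is binary per arm; the
only quantitative knob is a linear inhibition scale per pathway:

* with no inhibition anywhere, cells move at ``uninhibited_motility``
  (0.23 μm/min for T98G);
* fully inhibiting arm B leaves traffic through A alone at
  ``base_motility_A`` (0.15 μm/min), and vice versa (0.13 μm/min via B);
* fully inhibiting the convergence point C caps motility at
  ``base_motility_C`` regardless of the upstream arms.

Accordingly each arm's deliverable rate interpolates linearly from the
uninhibited rate down to the *other* arm's isolated rate as the other arm
is inhibited, and the converged motility is the minimum of the three
deliverable rates. Inhibition also stretches the cell cycle through the
proliferation factor (reciprocal of the mean pathway response) and shifts
the S-phase share of the cycle between its two user-specified endpoints.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

from .params import SimulationParams

__all__ = [
    "PathwayState",
    "CycleSchedule",
    "pathway_rate",
    "pathway_centers",
    "effective_motility",
    "avg_inhibition",
    "theoretical_pct_S",
    "prolif_factor",
    "phase_boundaries",
    "PHASES",
]

PHASES = ("G1", "S", "G2", "M")


class PathwayState(NamedTuple):
    """Deliverable motility rates (μm/min) after inhibition scaling.

    ``rate_A`` is what the cell can achieve given the state of arm B (it
    degrades to ``base_motility_A`` as B is blocked), ``rate_B`` the mirror
    image, and ``cap_C`` what the FAK convergence point transmits.
    """

    rate_A: float
    rate_B: float
    cap_C: float


def pathway_rate(uninhibited: float, base: float, inhibition: float) -> float:
    """Linear interpolation between the uninhibited and base motility.

    Returns ``uninhibited − inhibition · (uninhibited − base)``: the full
    rate at inhibition 0, exactly ``base`` at inhibition 1.
    """
    if not 0.0 <= inhibition <= 1.0:
        raise ValueError(f"inhibition must be in [0, 1], got {inhibition}")
    if base >= uninhibited:
        raise ValueError(
            f"base motility ({base}) must be below the uninhibited rate "
            f"({uninhibited})"
        )
    return uninhibited - inhibition * (uninhibited - base)


def pathway_centers(p: SimulationParams) -> PathwayState:
    """Inhibition-determined deliverable rates for a cell under ``p``.

    Base_Motility_A is, by definition, the motility observed when pathway B
    is fully inhibited — so the A-arm rate degrades with *B's* inhibition
    level, and symmetrically for B. The C cap degrades with C's own
    inhibition.
    """
    u = p.uninhibited_motility
    return PathwayState(
        rate_A=pathway_rate(u, p.resolved_base("A"), p.inhibition_B),
        rate_B=pathway_rate(u, p.resolved_base("B"), p.inhibition_A),
        cap_C=pathway_rate(u, p.resolved_base("C"), p.inhibition_C),
    )


def effective_motility(state: PathwayState) -> float:
    """Converged motility mu (μm/min): the minimum deliverable rate.

    The FAK convergence point transmits the best joint signal the two
    receptor arms support, which in this parameterization is the smallest
    of the three deliverable rates; with nothing inhibited all three equal
    the uninhibited rate.
    """
    return min(state.rate_A, state.rate_B, state.cap_C)


def avg_inhibition(i_a: float, i_b: float, i_c: float) -> float:
    """Arithmetic mean of the three inhibition fractions.

    The mean pathway *response* is ``1 − avg_inhibition``; proliferation
    scales with the response.
    """
    for v in (i_a, i_b, i_c):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"inhibition fractions must be in [0, 1], got {v}")
    return (i_a + i_b + i_c) / 3.0


def theoretical_pct_S(pct_base: float, pct_max: float, avg_inh: float) -> float:
    """Target % of cells in S-phase at the given average inhibition.

    Point-slope line through the two user-measured endpoints: ``pct_base``
    at no inhibition, ``pct_max`` at full inhibition.
    """
    if pct_max > pct_base:
        raise ValueError("pct_max must not exceed pct_base")
    if not 0.0 <= avg_inh <= 1.0:
        raise ValueError(f"avg_inh must be in [0, 1], got {avg_inh}")
    return pct_base + avg_inh * (pct_max - pct_base)


def prolif_factor(avg_inh: float, floor: float = 0.05) -> float:
    """Cycle-lengthening factor: reciprocal of the mean pathway response.

    Equals 1 with no inhibition and grows monotonically with inhibition so
    that the cell cycle lasts longer, postponing mitosis; ``floor`` bounds
    the response away from zero (full inhibition gives a finite, strongly
    suppressed division rate rather than a division-by-zero).
    """
    if floor <= 0:
        raise ValueError("floor must be positive")
    return 1.0 / max(1.0 - avg_inh, floor)


def _round_half_up(x: float) -> int:
    return int(x + 0.5)


@dataclass(frozen=True)
class CycleSchedule:
    """Tick thresholds partitioning one cell cycle into G1 → S → G2 → M.

    A cell whose cycle counter ``c`` satisfies ``c < g1_end`` is in G1,
    ``c < s_end`` in S, ``c < g2_end`` in G2, else M; on reaching
    ``total_ticks`` the cell divides. Durations always sum exactly to
    ``total_ticks``.
    """

    doubling_ticks: int
    total_ticks: int
    g1_end: int
    s_end: int
    g2_end: int
    pct_s_effective: float
    prolif_factor: float

    @property
    def boundaries(self) -> tuple[int, int, int, int]:
        return (self.g1_end, self.s_end, self.g2_end, self.total_ticks)

    @property
    def durations(self) -> dict[str, int]:
        return {
            "G1": self.g1_end,
            "S": self.s_end - self.g1_end,
            "G2": self.g2_end - self.s_end,
            "M": self.total_ticks - self.g2_end,
        }

    def phase_of(self, cycle: int) -> str:
        if cycle < self.g1_end:
            return "G1"
        if cycle < self.s_end:
            return "S"
        if cycle < self.g2_end:
            return "G2"
        return "M"


def phase_boundaries(p: SimulationParams) -> CycleSchedule:
    """Build the cycle schedule implied by the parameter set.

    The uninhibited cycle spans ``doubling_ticks`` with a fixed M phase
    (``m_phase_fraction`` of it, default 5%), the S phase at its base
    percentage and the remainder split evenly between G1 and G2 (rounding
    remainder to G1). Under inhibition the whole cycle stretches by the
    proliferation factor; S occupies its interpolated percentage of the
    stretched cycle; M keeps its uninhibited duration; and the S-phase
    change is absorbed by G1 (``s_phase_to_g1``) or G2, the other of the
    two keeping its proportionally stretched length.
    """
    total0 = p.doubling_ticks
    m = _round_half_up(p.m_phase_fraction * total0)
    s0 = _round_half_up(p.pct_S_base / 100.0 * total0)
    rem0 = total0 - s0 - m
    if total0 <= 4 or rem0 < 2:
        raise ValueError(
            f"degenerate cell cycle: doubling time {total0} ticks leaves "
            f"{rem0} ticks for G1+G2"
        )
    g2_0 = rem0 // 2
    g1_0 = rem0 - g2_0

    avg = avg_inhibition(p.inhibition_A, p.inhibition_B, p.inhibition_C)
    pf = prolif_factor(avg, p.prolif_floor)
    pct_s = theoretical_pct_S(p.pct_S_base, p.pct_S_max_inhibition, avg)

    total = _round_half_up(total0 * pf)
    s = _round_half_up(pct_s / 100.0 * total)
    if p.s_phase_to_g1:
        g2 = _round_half_up(pf * g2_0)
        g1 = total - s - m - g2
    else:
        g1 = _round_half_up(pf * g1_0)
        g2 = total - s - m - g1
    if min(g1, s, g2, m) < 1:
        raise ValueError(
            "degenerate cell cycle: a phase would last less than one tick "
            f"(G1={g1}, S={s}, G2={g2}, M={m})"
        )
    return CycleSchedule(
        doubling_ticks=total0,
        total_ticks=total,
        g1_end=g1,
        s_end=g1 + s,
        g2_end=g1 + s + g2,
        pct_s_effective=pct_s,
        prolif_factor=pf,
    )
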
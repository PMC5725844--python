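"""Simulation parameter set: definition, validation and config loading.

Every user-facing control of the simulator lives in :class:`SimulationParams`.
The defaults reproduce the standard uninhibited T98G glioblastoma scenario:
a 24 h run at 1 tick = 1 simulated minute, uninhibited motility 0.23 μm/min,
pathway-isolated rates 0.15 (integrin alone) and 0.13 μm/min (FGFR alone),
28% of cells in S-phase dropping to 8% under full pathway inhibition, and a
24 h population doubling time.

Parameters are immutable per run; sweeps are separate runs.
"""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping

__all__ = ["SimulationParams", "ParameterError", "validate_params", "load_config"]


class ParameterError(ValueError):
    """A parameter violates its range or a cross-field constraint."""


@dataclass(frozen=True)
class SimulationParams:
    """The full control set for one simulation run.

    Motility rates are in μm/min, times in hours (converted to ticks at
    60 ticks/h internally), positions in patch units. Inhibition levels are
    fractions in [0, 1]; the config boundary also accepts percentages via
    the ``pct_decrease_*`` alternative parameterization of base motility.
    """

    # -- assay layout -----------------------------------------------------
    cellular_adhesion: bool = False
    time_scale_hours: int = 24          # simulated run length, 1..72 h
    scratch_line: int = 0               # x coordinate of the scratch edge
    world_width: int = 65               # patches; x spans [-(w-1)//2, (w-1)//2]
    world_height: int = 33
    patch_scale: float = 20.0           # μm per patch edge (~one cell diameter)

    # -- movement ---------------------------------------------------------
    randomness: float = 0.1             # P(random-walk step) per cell per tick
    l_randomness: float = 0.5           # P(random step) per ligand per tick
    ligand_speed: float = 0.25          # ligand step length, patch units/tick
    uninhibited_motility: float = 0.23  # μm/min, no pathway inhibited
    base_motility_A: float = 0.15       # μm/min through integrin (A) alone
    base_motility_B: float = 0.13       # μm/min through FGFR (B) alone
    base_motility_C: float = 0.13       # μm/min floor with FAK (C) inhibited
    pct_decrease_A: float | None = None  # alternative: max % motility loss
    pct_decrease_B: float | None = None
    pct_decrease_C: float | None = None
    inhibition_A: float = 0.0           # fraction of pathway A inhibited
    inhibition_B: float = 0.0
    inhibition_C: float = 0.0
    deviation_from_avg: float = 0.3     # μm/min half-width of motility noise
    motility_check: bool = False        # clamp the reported motility at zero
    dt: float | None = None             # tick time factor; None → 1/(√2·patch_scale)

    # -- proliferation ----------------------------------------------------
    pct_S_base: float = 28.0            # % of cells in S-phase, uninhibited
    pct_S_max_inhibition: float = 8.0   # % in S-phase at full inhibition
    doubling_time_hours: float = 24.0
    s_phase_to_g1: bool = True          # S-phase change absorbed by G1 (else G2)
    m_phase_fraction: float = 0.05      # M duration as fraction of uninhibited cycle
    prolif_floor: float = 0.05          # guard for the proliferation factor

    # -- crowding & adhesion ----------------------------------------------
    confluent_density: float = 0.9      # cells per patch behind the scratch
    crowding_threshold: int = 2         # patch is full at >= this many cells
    rest_length: float = 1.0            # adhesion spring rest length, patches
    spring_constant: float = 0.2        # adhesion spring step scale per tick
    link_radius: float = 1.5            # neighbor radius for adhesion links

    # -- bookkeeping ------------------------------------------------------
    trailers: bool = True               # record trails of the tracked cohort
    ligand_cap: int | None = None       # optional cap on total ligand agents
    seed: int = 0                       # RNG seed; explicit, never wall-clock

    # -- derived geometry -------------------------------------------------

    @property
    def x_min(self) -> int:
        return -((self.world_width - 1) // 2)

    @property
    def x_max(self) -> int:
        return self.world_width - 1 + self.x_min

    @property
    def y_min(self) -> int:
        return -((self.world_height - 1) // 2)

    @property
    def y_max(self) -> int:
        return self.world_height - 1 + self.y_min

    @property
    def ticks_total(self) -> int:
        """Planned run length in ticks (60 ticks = 1 simulated hour)."""
        return int(self.time_scale_hours) * 60

    @property
    def doubling_ticks(self) -> int:
        return int(round(self.doubling_time_hours * 60.0))

    @property
    def dt_effective(self) -> float:
        """Tick time factor.

        The default makes the realized per-tick displacement √2·mu·dt equal
        mu·(1 min)/patch_scale, so a cell moving at mu μm/min covers exactly
        mu μm of physical distance per tick.
        """
        if self.dt is not None:
            return self.dt
        return 1.0 / (2.0 ** 0.5 * self.patch_scale)

    def resolved_base(self, pathway: str) -> float:
        """Base motility for ``pathway`` in {'A','B','C'}.

        If the percent-decrease form is configured for the pathway it takes
        precedence: base = uninhibited · (1 − pct_decrease/100). Exactly one
        of the two forms is active per pathway.
        """
        pct = getattr(self, f"pct_decrease_{pathway}")
        if pct is not None:
            return self.uninhibited_motility * (1.0 - pct / 100.0)
        return getattr(self, f"base_motility_{pathway}")


_FIELDS = {f.name for f in dataclasses.fields(SimulationParams)}

_FRACTION_FIELDS = (
    "randomness",
    "l_randomness",
    "inhibition_A",
    "inhibition_B",
    "inhibition_C",
    "confluent_density",
)
_PERCENT_FIELDS = (
    "pct_S_base",
    "pct_S_max_inhibition",
    "pct_decrease_A",
    "pct_decrease_B",
    "pct_decrease_C",
)
_POSITIVE_FIELDS = (
    "patch_scale",
    "doubling_time_hours",
    "uninhibited_motility",
    "rest_length",
    "link_radius",
    "m_phase_fraction",
    "prolif_floor",
)
_NONNEGATIVE_FIELDS = (
    "ligand_speed",
    "deviation_from_avg",
    "spring_constant",
    "base_motility_A",
    "base_motility_B",
    "base_motility_C",
)


def validate_params(raw: Mapping[str, Any] | SimulationParams) -> SimulationParams:
    """Build a validated, immutable parameter set.

    ``raw`` may be a mapping of overrides (defaults fill the rest) or an
    existing :class:`SimulationParams` (revalidation is idempotent). Any
    violated invariant raises :class:`ParameterError` naming the field.
    """
    if isinstance(raw, SimulationParams):
        mapping: dict[str, Any] = dataclasses.asdict(raw)
    else:
        mapping = dict(raw)
        unknown = sorted(set(mapping) - _FIELDS)
        if unknown:
            raise ParameterError(f"unknown parameter(s): {', '.join(unknown)}")

    p = SimulationParams(**mapping)

    for name in _FRACTION_FIELDS:
        v = getattr(p, name)
        if not 0.0 <= v <= 1.0:
            raise ParameterError(f"{name} must be a fraction in [0, 1], got {v}")
    for name in _PERCENT_FIELDS:
        v = getattr(p, name)
        if v is not None and not 0.0 <= v <= 100.0:
            raise ParameterError(f"{name} must be a percentage in [0, 100], got {v}")
    for name in _POSITIVE_FIELDS:
        v = getattr(p, name)
        if not v > 0:
            raise ParameterError(f"{name} must be positive, got {v}")
    for name in _NONNEGATIVE_FIELDS:
        v = getattr(p, name)
        if v < 0:
            raise ParameterError(f"{name} must be non-negative, got {v}")

    if not 1 <= p.time_scale_hours <= 72:
        raise ParameterError(
            f"time_scale_hours must be in [1, 72] hours, got {p.time_scale_hours}"
        )
    if p.world_width < 3 or p.world_height < 3:
        raise ParameterError("world_width and world_height must each be >= 3 patches")
    if not p.x_min <= p.scratch_line <= p.x_max:
        raise ParameterError(
            f"scratch_line {p.scratch_line} outside world x-range "
            f"[{p.x_min}, {p.x_max}]"
        )
    if p.crowding_threshold < 1:
        raise ParameterError("crowding_threshold must be >= 1 cell per patch")
    if p.pct_S_max_inhibition > p.pct_S_base:
        raise ParameterError(
            "pct_S_max_inhibition exceeds pct_S_base: inhibition cannot raise "
            "the S-phase fraction"
        )
    if p.dt is not None and p.dt <= 0:
        raise ParameterError(f"dt must be positive, got {p.dt}")
    if p.ligand_cap is not None and p.ligand_cap < 0:
        raise ParameterError("ligand_cap must be non-negative")

    base_a, base_b, base_c = (p.resolved_base(x) for x in "ABC")
    for name, base in (("A", base_a), ("B", base_b), ("C", base_c)):
        if base >= p.uninhibited_motility:
            raise ParameterError(
                f"pathway {name} base motility ({base:g}) must be set lower "
                f"than uninhibited_motility ({p.uninhibited_motility:g})"
            )
    if base_c > base_a:
        raise ParameterError(
            f"pathway C base ({base_c:g}) exceeds A ({base_a:g}); the A and B "
            "bases must be greater than or equal to the C base"
        )
    if base_c > base_b:
        raise ParameterError(
            f"pathway C base ({base_c:g}) exceeds B ({base_b:g}); the A and B "
            "bases must be greater than or equal to the C base"
        )
    return p


def load_config(path: str | Path) -> SimulationParams:
    """Load a TOML config file and return the validated parameter set.

    Keys are the snake_case control names (the :class:`SimulationParams`
    field names); values given in the file are merged over the defaults.
    Unknown keys are rejected so typos cannot silently revert a control to
    its default.
    """
    path = Path(path)
    with path.open("rb") as fh:
        try:
            data = tomllib.load(fh)
        except tomllib.TOMLDecodeError as exc:
            raise ParameterError(f"could not parse config {path}: {exc}") from exc
    return validate_params(data)
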
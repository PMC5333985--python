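"""Compartment models: antigen panels, pool dynamics, and panel I/O.

A niche is a compartment with a volume and an antigen panel.  Replenished
species (the blood contract) hold a fixed concentration forever; depletable
species carry a mole budget that binding, clearance and cell death move
around.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .binding import (
    DomainError,
    EngagementBand,
    log_engagement_ratio,
    solve_equilibrium,
)

logger = logging.getLogger(__name__)

__all__ = [
    "NicheKind",
    "AntigenSpecies",
    "Niche",
    "make_antigen_panel",
    "free_antigen",
    "update_antigen_pool",
    "best_log_ratio",
    "write_panel",
    "read_panel",
]

#: Default blood plasma volume, liters.
BLOOD_VOLUME_L = 5.0


class NicheKind(str, enum.Enum):
    BONE_MARROW = "BONE_MARROW"
    BLOOD = "BLOOD"
    FOLLICLE = "FOLLICLE"
    GC = "GC"
    MEMORY_NICHE = "MEMORY_NICHE"


@dataclass(frozen=True)
class AntigenSpecies:
    """One antigen species in a niche panel.

    Depletable species track ``total_epitope`` in moles; replenished species
    pin ``fixed_concentration`` in molar and ignore all flows.
    """

    ag_id: str
    replenished: bool
    total_epitope: float = 0.0
    fixed_concentration: float = 0.0

    def __post_init__(self) -> None:
        if self.total_epitope < 0.0:
            raise DomainError(f"total_epitope must be >= 0, got {self.total_epitope}")
        if self.fixed_concentration < 0.0:
            raise DomainError("fixed_concentration must be >= 0")

    def concentration(self, volume: float) -> float:
        """Current total-epitope concentration (molar) in the given volume."""
        if self.replenished:
            return self.fixed_concentration
        return self.total_epitope / volume

    @classmethod
    def from_concentration(
        cls, ag_id: str, concentration: float, replenished: bool, volume: float
    ) -> "AntigenSpecies":
        if replenished:
            return cls(ag_id=ag_id, replenished=True, fixed_concentration=concentration)
        return cls(ag_id=ag_id, replenished=False, total_epitope=concentration * volume)


@dataclass
class Niche:
    kind: NicheKind
    volume: float
    panel: list[AntigenSpecies] = field(default_factory=list)
    band: EngagementBand = field(default_factory=EngagementBand)
    fate_ruleset: str | None = None

    def __post_init__(self) -> None:
        if not (self.volume > 0.0 and math.isfinite(self.volume)):
            raise DomainError(f"niche volume must be finite and > 0, got {self.volume}")
        if self.kind is NicheKind.BLOOD and any(
            not sp.replenished for sp in self.panel
        ):
            raise DomainError("BLOOD niches require every species to be replenished")

    def species(self, ag_id: str) -> AntigenSpecies:
        for sp in self.panel:
            if sp.ag_id == ag_id:
                return sp
        raise KeyError(f"no species {ag_id!r} in {self.kind.value} panel")


def make_antigen_panel(
    n_species: int,
    conc_low: float,
    conc_high: float,
    replenished: bool,
    volume: float,
    rng: np.random.Generator,
    prefix: str = "ag",
) -> list[AntigenSpecies]:
    """Draw a synthetic panel with log-uniform concentrations on [conc_low, conc_high]."""
    if n_species < 1:
        raise DomainError("n_species must be >= 1")
    if not (0.0 < conc_low < conc_high):
        raise DomainError(
            f"need 0 < conc_low < conc_high, got ({conc_low}, {conc_high})"
        )
    log_c = rng.uniform(math.log10(conc_low), math.log10(conc_high), size=n_species)
    return [
        AntigenSpecies.from_concentration(
            f"{prefix}{i:03d}", 10.0 ** c, replenished, volume
        )
        for i, c in enumerate(log_c)
    ]


def free_antigen(
    niche: Niche,
    species: AntigenSpecies,
    total_paratope: float,
    kd_apparent: float,
) -> float:
    """Free epitope concentration after equilibration against the niche's BCR load.

    Replenished pools are inexhaustible: their concentration is returned
    unchanged no matter the paratope load.  Depletable pools equilibrate via
    the mass-action quadratic.
    """
    if species.replenished:
        return species.fixed_concentration
    total_conc = species.concentration(niche.volume)
    if total_conc == 0.0:
        return 0.0
    if total_paratope == 0.0:
        return total_conc
    return solve_equilibrium(total_conc, total_paratope, kd_apparent).ag_free


def _flow(flows: float | Mapping[str, float], ag_id: str) -> float:
    if isinstance(flows, Mapping):
        value = float(flows.get(ag_id, 0.0))
    else:
        value = float(flows)
    if value < 0.0:
        raise DomainError(f"flows must be >= 0, got {value} for {ag_id!r}")
    return value


def update_antigen_pool(
    niche: Niche,
    consumed: float | Mapping[str, float] = 0.0,
    released_by_death: float | Mapping[str, float] = 0.0,
    cleared_by_antibody: float | Mapping[str, float] = 0.0,
) -> Niche:
    """Apply one step of mole flows to the niche panel.

    Flows may be scalars (applied to every species) or per-``ag_id``
    mappings.  Replenished species never change.  A depletable pool driven
    below zero is floored at zero with a logged warning.
    """
    new_panel: list[AntigenSpecies] = []
    for sp in niche.panel:
        if sp.replenished:
            new_panel.append(sp)
            continue
        delta = (
            -_flow(consumed, sp.ag_id)
            - _flow(cleared_by_antibody, sp.ag_id)
            + _flow(released_by_death, sp.ag_id)
        )
        total = sp.total_epitope + delta
        if total < 0.0:
            logger.warning(
                "antigen pool %s in %s driven below zero (%.3e mol); flooring at 0",
                sp.ag_id,
                niche.kind.value,
                total,
            )
            total = 0.0
        new_panel.append(replace(sp, total_epitope=total))
    return replace(niche, panel=new_panel)


def best_log_ratio(
    niche: Niche,
    kd_apparent: float,
    paratope_by_species: Mapping[str, float] | None = None,
) -> tuple[str, float]:
    """Species whose free-antigen log-ratio is closest to comfort (|log10| minimal).

    Used by memory niches, where survival may ride on abundant non-cognate
    antigen rather than the eliciting one.
    """
    if not niche.panel:
        raise DomainError("niche has an empty panel")
    best_id, best_ratio = "", math.inf
    for sp in niche.panel:
        paratope = 0.0
        if paratope_by_species is not None:
            paratope = float(paratope_by_species.get(sp.ag_id, 0.0))
        ag = free_antigen(niche, sp, paratope, kd_apparent)
        ratio = log_engagement_ratio(ag, kd_apparent)
        if abs(ratio) < abs(best_ratio):
            best_id, best_ratio = sp.ag_id, ratio
    return best_id, best_ratio


# --- panel I/O -------------------------------------------------------------

_PANEL_HEADER = "ag_id\tconcentration_molar\treplenished"


def write_panel(path: str | Path, panel: Sequence[AntigenSpecies], volume: float) -> None:
    """Write a panel as TSV with header ``ag_id, concentration_molar, replenished``."""
    lines = [_PANEL_HEADER]
    for sp in panel:
        lines.append(
            f"{sp.ag_id}\t{sp.concentration(volume):.9e}\t{str(sp.replenished).lower()}"
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_panel(path: str | Path, volume: float) -> list[AntigenSpecies]:
    """Read a TSV panel; bit-identical round trip with :func:`write_panel`."""
    text = Path(path).read_text(encoding="utf-8").strip().splitlines()
    if not text or text[0].replace(", ", "\t").replace(",", "\t") != _PANEL_HEADER:
        raise DomainError(f"bad panel header in {path}")
    panel = []
    for line in text[1:]:
        ag_id, conc, repl = line.split("\t")
        panel.append(
            AntigenSpecies.from_concentration(
                ag_id, float(conc), repl.strip().lower() == "true", volume
            )
        )
    return panel
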
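"""Clone-level state and fate rules.

Clones move vertically on the antigen-concentration × affinity map by
dividing or dying, and horizontally by receptor editing, isotype switching
and somatic hypermutation.  All operations are pure: they return new clone
instances and draw randomness only from the generator they are handed.
"""

from __future__ import annotations

import enum
import logging
import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .binding import AVOGADRO, DomainError, EngagementClass
from .niches import NicheKind

logger = logging.getLogger(__name__)

__all__ = [
    "Stage",
    "Isotype",
    "CycleState",
    "Fate",
    "FateAction",
    "BCellClone",
    "GermlineSampler",
    "SHMParams",
    "LETHAL",
    "ConfigurationError",
    "ContractError",
    "decide_fate",
    "classify_blood_fate",
    "divide_clone",
    "receptor_edit",
    "isotype_switch",
    "shm_mutate",
    "mzb_differentiate",
]

DEFAULT_POPULATION_CAP = 2 ** 20
DEFAULT_BCR_PER_CELL = 1e5
DEFAULT_EDIT_ATTEMPTS = 3
DEFAULT_DELTA_B1 = 1.5
DEFAULT_SWITCH_GAIN = 10.0
#: Per-step probability that a B1 clone in its band actually divides
#: ("dividing from time to time"); otherwise it persists in G1.
DEFAULT_P_B1_DIVIDE = 0.1


class ConfigurationError(RuntimeError):
    """A (stage, engagement, niche) combination outside the state machine."""


class ContractError(RuntimeError):
    """An operation was invoked with its preconditions violated."""


class Stage(str, enum.Enum):
    PRE_BI = "PRE_BI"
    LARGE_PRE_BII = "LARGE_PRE_BII"
    SMALL_PRE_BII = "SMALL_PRE_BII"
    IMMATURE = "IMMATURE"
    TRANSITIONAL = "TRANSITIONAL"
    FOLLICULAR_BII = "FOLLICULAR_BII"
    B1 = "B1"
    MZB = "MZB"
    GC_B = "GC_B"
    MEMORY = "MEMORY"
    PLASMABLAST = "PLASMABLAST"
    LLPC = "LLPC"


class Isotype(str, enum.Enum):
    IgM = "IgM"
    IgD = "IgD"
    IgG = "IgG"
    IgA = "IgA"
    IgE = "IgE"


_UNSWITCHED = frozenset({Isotype.IgM, Isotype.IgD})
_SWITCH_TARGETS = frozenset({Isotype.IgG, Isotype.IgA, Isotype.IgE})


class CycleState(str, enum.Enum):
    G0 = "G0"
    G1 = "G1"
    DIVIDING = "DIVIDING"


class Fate(str, enum.Enum):
    DIE = "DIE"
    REST_G0 = "REST_G0"
    PERSIST_G1 = "PERSIST_G1"
    DIVIDE = "DIVIDE"
    EDIT_RECEPTOR = "EDIT_RECEPTOR"
    SWITCH_ISOTYPE = "SWITCH_ISOTYPE"
    ENTER_GC = "ENTER_GC"
    EXIT_AS = "EXIT_AS"


@dataclass(frozen=True)
class FateAction:
    """One fate decision; ``exit_stage`` qualifies EXIT_AS/PERSIST_G1, and
    ``with_switch`` marks a DIVIDE that rides the class-switch path."""

    fate: Fate
    exit_stage: Stage | None = None
    with_switch: bool = False

    @property
    def label(self) -> str:
        if self.fate is Fate.EXIT_AS and self.exit_stage is not None:
            return f"EXIT_AS({self.exit_stage.value})"
        if self.with_switch:
            return f"{self.fate.value}+SWITCH"
        return self.fate.value


@dataclass(frozen=True)
class BCellClone:
    clone_id: str
    kd_intrinsic: float
    apparent_factor: float = 1.0
    n_cells: int = 1
    bcr_per_cell: float = DEFAULT_BCR_PER_CELL
    stage: Stage = Stage.SMALL_PRE_BII
    isotype: Isotype = Isotype.IgM
    mut_h: int = 0
    mut_l: int = 0
    edit_attempts_left: int = DEFAULT_EDIT_ATTEMPTS
    cycle_state: CycleState = CycleState.G1
    cognate: str | None = None

    def __post_init__(self) -> None:
        if self.kd_intrinsic <= 0.0 or not math.isfinite(self.kd_intrinsic):
            raise DomainError("kd_intrinsic must be finite and > 0")
        if self.apparent_factor <= 0.0:
            raise DomainError("apparent_factor must be > 0")
        if self.n_cells < 0 or self.mut_h < 0 or self.mut_l < 0:
            raise DomainError("counts must be >= 0")
        if self.edit_attempts_left < 0:
            raise DomainError("edit_attempts_left must be >= 0")

    @property
    def kd_apparent(self) -> float:
        return self.kd_intrinsic / self.apparent_factor

    def paratope_moles(self) -> float:
        """Total paratope contributed by the clone, in moles.

        Terminally differentiated LLPC have lost the BCR and contribute none.
        """
        if self.stage is Stage.LLPC:
            return 0.0
        return self.n_cells * self.bcr_per_cell / AVOGADRO

    def paratope_concentration(self, volume: float) -> float:
        return self.paratope_moles() / volume


@dataclass(frozen=True)
class GermlineSampler:
    """Log-uniform kd sampler for newly rearranged receptors."""

    kd_low: float = 1e-10
    kd_high: float = 1e-6

    def __post_init__(self) -> None:
        if not (0.0 < self.kd_low < self.kd_high):
            raise DomainError("need 0 < kd_low < kd_high")

    def sample(self, rng: np.random.Generator) -> float:
        return 10.0 ** rng.uniform(math.log10(self.kd_low), math.log10(self.kd_high))


@dataclass(frozen=True)
class SHMParams:
    """Somatic-hypermutation step model.

    Each mutation draw is a trichotomy: lethal with ``p_lethal``, otherwise
    deleterious (kd up) with ``p_del`` or beneficial (kd down) with
    ``p_beneficial``; the three must sum to 1.  Step sizes are half-normal
    on log10(kd).  Per-chain counters are hard-capped.
    """

    p_lethal: float = 0.3
    p_del: float = 0.5
    p_beneficial: float = 0.2
    p_heavy: float = 0.6
    sigma_step: float = 0.4
    cap_h: int = 30
    cap_l: int = 20
    kd_min: float = 2e-12
    kd_max: float = 1e-3

    def __post_init__(self) -> None:
        total = self.p_lethal + self.p_del + self.p_beneficial
        if abs(total - 1.0) > 1e-12:
            raise DomainError(f"mutation probabilities must sum to 1, got {total}")
        if not (0.0 < self.p_heavy < 1.0):
            raise DomainError("p_heavy must be in (0, 1)")
        if self.sigma_step <= 0.0 or self.cap_h < 0 or self.cap_l < 0:
            raise DomainError("bad SHM parameters")
        if not (0.0 < self.kd_min < self.kd_max):
            raise DomainError("need 0 < kd_min < kd_max")


class _Lethal:
    """Sentinel returned by :func:`shm_mutate` for a lethal mutation."""

    _instance: "_Lethal | None" = None

    def __new__(cls) -> "_Lethal":
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:  # pragma: no cover
        return "LETHAL"


LETHAL = _Lethal()


# --- fate decisions --------------------------------------------------------

def decide_fate(
    clone: BCellClone,
    engagement: EngagementClass,
    niche_kind: NicheKind,
    second_signal: bool,
    rng: np.random.Generator,
    *,
    log_ratio: float | None = None,
    delta_comfort: float = 0.5,
    delta_b1: float = DEFAULT_DELTA_B1,
    p_b1_divide: float = DEFAULT_P_B1_DIVIDE,
) -> FateAction:
    """Map (clone, engagement, niche, second signal) to one fate.

    The table is total over the configured state machine: every reachable
    combination yields an action, and unreachable ones (an LLPC, which has
    no BCR to engage) raise :class:`ConfigurationError` instead of falling
    through silently.  Immature/transitional clones in blood delegate to
    :func:`classify_blood_fate`, which needs the raw log-ratio.
    """
    if clone.n_cells <= 0:
        raise ContractError("decide_fate requires a clone with n_cells > 0")
    if clone.stage is Stage.LLPC:
        raise ConfigurationError("LLPC have no BCR; they take no engagement-driven fate")

    if niche_kind is NicheKind.BLOOD and clone.stage in (
        Stage.IMMATURE,
        Stage.TRANSITIONAL,
    ):
        if log_ratio is None:
            raise ContractError("blood fates for immature clones need log_ratio")
        return classify_blood_fate(
            clone,
            engagement,
            second_signal,
            log_ratio=log_ratio,
            delta_comfort=delta_comfort,
            delta_b1=delta_b1,
        )

    if engagement is EngagementClass.COMFORT:
        return FateAction(Fate.REST_G0)

    if engagement is EngagementClass.NEGLECT:
        return FateAction(Fate.DIE)

    if engagement is EngagementClass.UNDER:
        if niche_kind is NicheKind.BONE_MARROW:
            if clone.edit_attempts_left > 0:
                return FateAction(Fate.EDIT_RECEPTOR)
            return FateAction(Fate.DIE)
        if niche_kind is NicheKind.MEMORY_NICHE:
            # abundant non-cognate antigen keeps memory alive at low engagement
            return FateAction(Fate.REST_G0)
        if niche_kind is NicheKind.BLOOD and clone.stage is Stage.B1:
            return FateAction(Fate.PERSIST_G1)
        return FateAction(Fate.DIE)  # failed positive selection

    if engagement is EngagementClass.OVER:
        if niche_kind is NicheKind.BLOOD and clone.stage is Stage.B1:
            if rng.random() < p_b1_divide:
                return FateAction(Fate.DIVIDE)
            return FateAction(Fate.PERSIST_G1)
        if niche_kind is NicheKind.FOLLICLE and second_signal:
            return FateAction(Fate.ENTER_GC)
        return FateAction(Fate.DIVIDE)

    if engagement is EngagementClass.SATURATED:
        if niche_kind is NicheKind.BONE_MARROW:
            return FateAction(Fate.DIE)  # clonal deletion of aggressive self-binding
        if niche_kind is NicheKind.FOLLICLE and second_signal:
            return FateAction(Fate.ENTER_GC)
        return FateAction(Fate.DIVIDE)

    raise ConfigurationError(
        f"no rule for stage={clone.stage.value}, engagement={engagement.name}, "
        f"niche={niche_kind.value}"
    )


def classify_blood_fate(
    clone: BCellClone,
    engagement: EngagementClass,
    second_signal: bool,
    *,
    log_ratio: float,
    delta_comfort: float = 0.5,
    delta_b1: float = DEFAULT_DELTA_B1,
) -> FateAction:
    """Fate of an immature/transitional clone suspended in blood.

    Neglected clones die; comfortable ones rest (and may mature onward).
    Over-engagement splits on the log-ratio: a modest excess (within
    ``delta_b1``) sustains a self-replenishing B1 in G1; beyond that, a
    second signal buys marginal-zone differentiation by apparent-affinity
    modulation, and without one the clone mounts a primary TI response —
    division plus class switch.
    """
    if clone.stage not in (Stage.IMMATURE, Stage.TRANSITIONAL):
        raise ContractError(
            f"classify_blood_fate applies to IMMATURE/TRANSITIONAL, got {clone.stage}"
        )
    if engagement is EngagementClass.NEGLECT:
        return FateAction(Fate.DIE)
    if engagement is EngagementClass.COMFORT:
        return FateAction(Fate.REST_G0)
    if engagement is EngagementClass.UNDER:
        return FateAction(Fate.DIE)  # selecting antigen too dilute in blood
    # OVER / SATURATED
    if log_ratio <= delta_b1:
        return FateAction(Fate.PERSIST_G1, exit_stage=Stage.B1)
    if second_signal:
        return FateAction(Fate.EXIT_AS, exit_stage=Stage.MZB)
    return FateAction(Fate.DIVIDE, with_switch=True)


# --- clone transformations -------------------------------------------------

def divide_clone(
    clone: BCellClone,
    *,
    population_cap: int = DEFAULT_POPULATION_CAP,
    single_cell_mode: bool = False,
) -> BCellClone:
    """Synchronous division: cell count doubles (or +1 in single-cell mode).

    Growth beyond the population cap is clamped with a logged warning; a
    clone already at cap is returned unchanged.
    """
    if clone.n_cells < 1:
        raise ContractError("divide_clone requires n_cells >= 1")
    target = clone.n_cells + 1 if single_cell_mode else 2 * clone.n_cells
    if target > population_cap:
        logger.warning(
            "clone %s at population cap %d; clamping division", clone.clone_id,
            population_cap,
        )
        target = min(max(clone.n_cells, population_cap), population_cap)
    return replace(clone, n_cells=target, cycle_state=CycleState.DIVIDING)


def receptor_edit(
    clone: BCellClone,
    germline: GermlineSampler,
    rng: np.random.Generator,
) -> BCellClone:
    """Rearrange an alternate chain: resample kd, spend one editing attempt.

    Mutation counters reset — the edited receptor is a fresh germline one.
    """
    if clone.edit_attempts_left <= 0:
        raise ContractError("receptor_edit called with no editing attempts left")
    return replace(
        clone,
        kd_intrinsic=germline.sample(rng),
        edit_attempts_left=clone.edit_attempts_left - 1,
        mut_h=0,
        mut_l=0,
    )


def isotype_switch(
    clone: BCellClone,
    target_isotype: Isotype,
    switch_gain: float = DEFAULT_SWITCH_GAIN,
) -> BCellClone:
    """Class switch: apparent affinity gains ``switch_gain``; intrinsic kd unchanged."""
    if target_isotype not in _SWITCH_TARGETS:
        raise DomainError(f"cannot switch to {target_isotype}")
    if clone.isotype not in _UNSWITCHED:
        warnings.warn(
            f"clone {clone.clone_id} already switched to {clone.isotype.value}; no-op",
            stacklevel=2,
        )
        return clone
    return replace(
        clone,
        isotype=target_isotype,
        apparent_factor=clone.apparent_factor * switch_gain,
    )


def mzb_differentiate(clone: BCellClone, log_ratio: float) -> BCellClone:
    """Marginal-zone differentiation: desensitize apparent affinity into comfort.

    The apparent factor is divided by ``10**log_ratio`` so the post-adjustment
    log-ratio is ~0; it is set once here and frozen thereafter.
    """
    return replace(
        clone,
        stage=Stage.MZB,
        apparent_factor=clone.apparent_factor / (10.0 ** log_ratio),
        cycle_state=CycleState.G0,
    )


def shm_mutate(
    clone: BCellClone,
    params: SHMParams,
    rng: np.random.Generator,
) -> BCellClone | _Lethal:
    """One somatic-hypermutation draw on a germinal-center clone.

    Returns ``LETHAL`` for a lethal mutation; with both chains at cap the
    clone passes through unchanged.  Non-lethal mutations pick a chain
    (heavy with ``p_heavy``, skipping a capped chain), bump its counter and
    shift log10(kd) by a half-normal step — up for deleterious, down for
    beneficial — clamped to ``[kd_min, kd_max]``.
    """
    if clone.stage is not Stage.GC_B:
        raise ContractError("shm_mutate applies to GC_B clones")
    h_capped = clone.mut_h >= params.cap_h
    l_capped = clone.mut_l >= params.cap_l
    if h_capped and l_capped:
        return clone

    u = rng.random()
    if u < params.p_lethal:
        return LETHAL
    deleterious = u < params.p_lethal + params.p_del

    if h_capped:
        heavy = False
    elif l_capped:
        heavy = True
    else:
        heavy = rng.random() < params.p_heavy

    step = abs(rng.normal(0.0, params.sigma_step))
    log_kd = math.log10(clone.kd_intrinsic) + (step if deleterious else -step)
    log_kd = min(max(log_kd, math.log10(params.kd_min)), math.log10(params.kd_max))
    return replace(
        clone,
        kd_intrinsic=10.0 ** log_kd,
        mut_h=clone.mut_h + (1 if heavy else 0),
        mut_l=clone.mut_l + (0 if heavy else 1),
    )
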
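"""Germinal-center mutation–selection engine.

Each cycle is one light-zone/dark-zone pass: clones competitively capture a
fraction of the antigen pool in proportion to cell number × occupancy, run
capture-proportional divisions with somatic hypermutation, and are then
re-selected against the depleted pool — neglected clones die, comfortable
ones exit towards memory or antibody-secreting fates.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .agents import (
    LETHAL,
    BCellClone,
    CycleState,
    GermlineSampler,
    SHMParams,
    Stage,
    divide_clone,
    shm_mutate,
)
from .binding import (
    DomainError,
    EngagementBand,
    EngagementClass,
    classify_engagement,
    occupancy,
)
from .niches import AntigenSpecies

__all__ = [
    "GCParams",
    "GCState",
    "MaturationOutput",
    "capture_antigen",
    "division_count",
    "gc_cycle",
    "run_immunization_schedule",
]


@dataclass(frozen=True)
class GCParams:
    """Knobs of the capture → division → mutation loop.

    ``capture_ref`` is the captured-mole scale mapping to ``alpha`` divisions;
    when None it defaults to ``initial_pool / n_entrants`` (the per-capita
    share), so a lone founder taking the whole presented fraction (0.5 of
    the pool) performs 2 divisions in cycle 1 and an average competitor in a
    crowded GC does likewise.  ``pool_decay`` stands in for
    antibody-mediated clearance.
    """

    alpha: float = 4.0
    div_cap: int = 6
    capture_ref: float | None = None
    f_present: float = 0.5
    pool_decay: float = 0.10
    residual_frac: float = 0.01
    stochastic_capture: bool = False
    population_cap: int = 2 ** 20

    def __post_init__(self) -> None:
        if not (0.0 < self.f_present <= 1.0):
            raise DomainError("f_present must be in (0, 1]")
        if not (0.0 <= self.pool_decay < 1.0):
            raise DomainError("pool_decay must be in [0, 1)")
        if self.alpha < 0 or self.div_cap < 0:
            raise DomainError("alpha and div_cap must be >= 0")


@dataclass
class MaturationOutput:
    """Pooled exit compartments plus recomputable summary statistics."""

    memory: list[BCellClone] = field(default_factory=list)
    plasma: list[BCellClone] = field(default_factory=list)
    llpc: list[BCellClone] = field(default_factory=list)

    def all_clones(self) -> list[BCellClone]:
        return [*self.memory, *self.plasma, *self.llpc]

    def extend(self, other: "MaturationOutput") -> None:
        self.memory.extend(other.memory)
        self.plasma.extend(other.plasma)
        self.llpc.extend(other.llpc)

    def summary(self) -> dict:
        clones = self.all_clones()
        if not clones:
            return {
                "n_clones": 0,
                "geometric_mean_kd": None,
                "min_kd": None,
                "max_kd": None,
                "max_mut_h": 0,
                "max_mut_l": 0,
            }
        kds = np.array([c.kd_intrinsic for c in clones])
        return {
            "n_clones": len(clones),
            "n_memory": len(self.memory),
            "n_plasma": len(self.plasma),
            "n_llpc": len(self.llpc),
            "geometric_mean_kd": float(10.0 ** np.mean(np.log10(kds))),
            "min_kd": float(kds.min()),
            "max_kd": float(kds.max()),
            "max_mut_h": max(c.mut_h for c in clones),
            "max_mut_l": max(c.mut_l for c in clones),
        }

    def to_json(self) -> str:
        def clone_row(c: BCellClone) -> dict:
            return {
                "clone_id": c.clone_id,
                "kd_intrinsic": f"{c.kd_intrinsic:.9e}",
                "kd_apparent": f"{c.kd_apparent:.9e}",
                "n_cells": c.n_cells,
                "stage": c.stage.value,
                "isotype": c.isotype.value,
                "mut_h": c.mut_h,
                "mut_l": c.mut_l,
            }

        return json.dumps(
            {
                "memory": [clone_row(c) for c in self.memory],
                "plasma": [clone_row(c) for c in self.plasma],
                "llpc": [clone_row(c) for c in self.llpc],
                "summary": self.summary(),
            },
            indent=2,
            sort_keys=True,
        )


@dataclass
class GCState:
    """One germinal center: a depletable cognate pool plus centroblasts."""

    pool: AntigenSpecies
    volume: float
    clones: list[BCellClone]
    cycle_index: int = 0
    initial_pool: float = 0.0
    n_entrants: int = 0
    exited: MaturationOutput = field(default_factory=MaturationOutput)
    terminated: bool = False
    history: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.pool.replenished:
            raise DomainError("a germinal-center pool must be depletable")
        if self.initial_pool == 0.0:
            self.initial_pool = self.pool.total_epitope
        if self.n_entrants == 0:
            self.n_entrants = len(self.clones)

    @property
    def concentration(self) -> float:
        return self.pool.total_epitope / self.volume


def capture_antigen(
    clones: Sequence[BCellClone],
    pool: AntigenSpecies,
    volume: float,
    rng: np.random.Generator,
    f_present: float = 0.5,
    stochastic: bool = False,
) -> np.ndarray:
    """Allocate this cycle's presented antigen (moles) across competing clones.

    Weights are ``n_cells * occupancy(pool concentration, kd_apparent)`` so
    higher-affinity clones capture more in the same microenvironment.  The
    default split is deterministic and proportional; the stochastic mode
    multinomially samples discrete antigen packets.
    """
    if pool.total_epitope < 0:
        raise DomainError("pool must be >= 0")
    available = f_present * pool.total_epitope
    if not clones or available == 0.0:
        return np.zeros(len(clones))
    conc = pool.total_epitope / volume
    weights = np.array(
        [c.n_cells * occupancy(conc, c.kd_apparent) for c in clones], dtype=float
    )
    total = weights.sum()
    if total == 0.0:
        return np.zeros(len(clones))
    shares = weights / total
    if stochastic:
        n_packets = 1000
        counts = rng.multinomial(n_packets, shares)
        return available * counts / n_packets
    return available * shares


def division_count(captured: float, params: GCParams, capture_ref: float) -> int:
    """Divisions earned by captured antigen: linear in capture, hard-capped."""
    if captured < 0:
        raise DomainError("captured must be >= 0")
    if capture_ref <= 0:
        raise DomainError("capture_ref must be > 0")
    return min(params.div_cap, int(math.floor(params.alpha * captured / capture_ref)))


def _mutate_through_divisions(
    clone: BCellClone,
    n_divisions: int,
    params: GCParams,
    shm: SHMParams,
    rng: np.random.Generator,
) -> BCellClone:
    """Run a clone through its dark-zone divisions, mutating each round.

    The clone is treated as a homogeneous lineage: each division doubles the
    cells and draws one mutation applied clone-wide; a lethal draw kills the
    round's daughters (no net growth, no genotype change).
    """
    for _ in range(n_divisions):
        n_before = clone.n_cells
        clone = divide_clone(clone, population_cap=params.population_cap)
        mutated = shm_mutate(clone, shm, rng)
        if mutated is LETHAL:
            clone = replace(clone, n_cells=n_before)
        else:
            clone = mutated
    return clone


def gc_cycle(
    state: GCState,
    band: EngagementBand,
    params: GCParams,
    shm: SHMParams,
    rng: np.random.Generator,
) -> GCState:
    """One light-zone + dark-zone pass; mutates and returns ``state``.

    Captured antigen is consumed; the residual pool then decays by
    ``pool_decay``.  Selection against the depleted pool removes neglected
    clones and routes comfortable ones out: MEMORY while antigen remains
    plentiful, otherwise PLASMABLAST, with the cycle's top capturer taking
    the last antigen and exiting as an LLPC.
    """
    if not state.clones:
        state.terminated = True
        return state

    capture_ref = (
        params.capture_ref
        if params.capture_ref
        else state.initial_pool / max(1, state.n_entrants)
    )
    captured = capture_antigen(
        state.clones,
        state.pool,
        state.volume,
        rng,
        f_present=params.f_present,
        stochastic=params.stochastic_capture,
    )
    consumed = float(captured.sum())

    new_clones: list[BCellClone] = []
    divisions: list[int] = []
    for clone, cap_i in zip(state.clones, captured):
        d = division_count(float(cap_i), params, capture_ref)
        divisions.append(d)
        new_clones.append(_mutate_through_divisions(clone, d, params, shm, rng))

    pool_after = max(0.0, state.pool.total_epitope - consumed) * (1.0 - params.pool_decay)
    state.pool = replace(state.pool, total_epitope=pool_after)
    conc_after = state.concentration
    residual_threshold = params.residual_frac * state.initial_pool

    survivors: list[BCellClone] = []
    max_capture_idx = int(np.argmax(captured)) if len(captured) else -1
    for i, clone in enumerate(new_clones):
        engagement = classify_engagement(conc_after, clone.kd_apparent, band)
        state.history.append(
            {
                "cycle": state.cycle_index,
                "clone_id": clone.clone_id,
                "n_cells": clone.n_cells,
                "kd_apparent": clone.kd_apparent,
                "captured_moles": float(captured[i]),
                "divisions": divisions[i],
                "mut_h": clone.mut_h,
                "mut_l": clone.mut_l,
            }
        )
        if engagement is EngagementClass.NEGLECT:
            continue  # dies during selection
        if engagement is EngagementClass.COMFORT:
            if pool_after > residual_threshold:
                state.exited.memory.append(
                    replace(clone, stage=Stage.MEMORY, cycle_state=CycleState.G0)
                )
            elif i == max_capture_idx and captured[i] > 0:
                state.exited.llpc.append(
                    replace(clone, stage=Stage.LLPC, cycle_state=CycleState.G0)
                )
            else:
                state.exited.plasma.append(
                    replace(clone, stage=Stage.PLASMABLAST, cycle_state=CycleState.G1)
                )
            continue
        survivors.append(clone)

    # pool exhaustion: the lone remaining clone captured the last antigen
    # molecules and terminally differentiates instead of starving
    if pool_after <= residual_threshold and len(survivors) == 1:
        state.exited.llpc.append(
            replace(survivors[0], stage=Stage.LLPC, cycle_state=CycleState.G0)
        )
        survivors = []

    state.clones = survivors
    state.cycle_index += 1
    if not survivors:
        state.terminated = True
    return state


def run_immunization_schedule(
    founders: Sequence[BCellClone],
    schedule: Sequence[tuple[float, int]],
    config: "GCRunConfig",
    rng: np.random.Generator,
) -> MaturationOutput:
    """Run one germinal center per dose, chaining memory output between doses.

    ``schedule`` is a list of ``(dose concentration in molar, n_cycles)``.
    Each subsequent GC is seeded with the previous dose's memory exits plus
    fresh germline founders.  Exits from every dose pool into the returned
    :class:`MaturationOutput`.
    """
    if not schedule:
        raise DomainError("immunization schedule must contain at least one dose")
    output = MaturationOutput()
    carry: list[BCellClone] = list(founders)
    germline = GermlineSampler(config.germline_low, config.germline_high)
    clone_serial = 0
    for dose_idx, (dose_conc, n_cycles) in enumerate(schedule):
        entrants = [
            replace(c, stage=Stage.GC_B, cycle_state=CycleState.G1) for c in carry
        ]
        if dose_idx > 0:
            for _ in range(config.n_founders):
                entrants.append(
                    BCellClone(
                        clone_id=f"d{dose_idx}f{clone_serial}",
                        kd_intrinsic=germline.sample(rng),
                        stage=Stage.GC_B,
                    )
                )
                clone_serial += 1
        pool = AntigenSpecies(
            ag_id=f"dose{dose_idx}",
            replenished=False,
            total_epitope=dose_conc * config.volume,
        )
        state = GCState(pool=pool, volume=config.volume, clones=entrants)
        for _ in range(n_cycles):
            state = gc_cycle(state, config.band, config.params, config.shm, rng)
            if state.terminated:
                break
        output.extend(state.exited)
        carry = list(state.exited.memory)
    return output


@dataclass(frozen=True)
class GCRunConfig:
    """Bundle of settings for :func:`run_immunization_schedule`."""

    volume: float = 1e-9
    n_founders: int = 20
    germline_low: float = 1e-10
    germline_high: float = 1e-6
    band: EngagementBand = field(default_factory=EngagementBand)
    params: GCParams = field(default_factory=GCParams)
    shm: SHMParams = field(default_factory=SHMParams)


DEFAULT_DOSE_CONC = 1e-8
DEFAULT_CYCLES_PER_DOSE = 12
DEFAULT_N_DOSES = 3


def default_schedule() -> list[tuple[float, int]]:
    """The default repeated-immunization schedule: 3 identical doses."""
    return [(DEFAULT_DOSE_CONC, DEFAULT_CYCLES_PER_DOSE)] * DEFAULT_N_DOSES


def make_founders(
    n: int, config: GCRunConfig, rng: np.random.Generator, prefix: str = "f"
) -> list[BCellClone]:
    germline = GermlineSampler(config.germline_low, config.germline_high)
    return [
        BCellClone(
            clone_id=f"{prefix}{i}",
            kd_intrinsic=germline.sample(rng),
            stage=Stage.GC_B,
        )
        for i in range(n)
    ]
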
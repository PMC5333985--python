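"""Discrete-time scheduler tying niches and agents together.

One step is one decision epoch: for each niche in developmental order
(bone marrow → blood → follicle/GC → memory site) every resident clone has
its free antigen computed, its engagement classified and one fate applied;
pools are then updated and emigrants move on.  A single master seed drives
named substreams so full runs and module-level replays are bit-identical.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np

from .agents import (
    BCellClone,
    CycleState,
    Fate,
    FateAction,
    GermlineSampler,
    Isotype,
    Stage,
    decide_fate,
    divide_clone,
    isotype_switch,
    mzb_differentiate,
    receptor_edit,
)
from .binding import (
    DomainError,
    EngagementBand,
    EngagementClass,
    classify_engagement,
    log_engagement_ratio,
    occupancy,
    solve_equilibrium,
)
from .config import SimConfig
from .gc import GCRunConfig, MaturationOutput, make_founders, run_immunization_schedule
from .niches import (
    AntigenSpecies,
    Niche,
    NicheKind,
    best_log_ratio,
    free_antigen,
    make_antigen_panel,
    read_panel,
    update_antigen_pool,
)

__all__ = ["TrajectoryRecord", "SimResult", "simulate", "phase_map", "run_gc_ensemble"]

#: Niche processing order per step (developmental order).
NICHE_ORDER = (
    NicheKind.BONE_MARROW,
    NicheKind.BLOOD,
    NicheKind.FOLLICLE,
    NicheKind.MEMORY_NICHE,
)


@dataclass(frozen=True)
class TrajectoryRecord:
    step: int
    niche: str
    clone_id: str
    stage: str
    n_cells: int
    kd_apparent: float
    occupancy: float
    ag_free: float
    action: str


@dataclass
class SimResult:
    records: list[TrajectoryRecord]
    summary: dict
    niches: dict[NicheKind, Niche]
    clones: dict[NicheKind, list[BCellClone]]
    pool_history: list[dict[str, dict[str, float]]]
    gc_output: MaturationOutput


def _spawn_rngs(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(3)
    return {
        "panel": np.random.default_rng(children[0]),
        "fates": np.random.default_rng(children[1]),
        "gc": np.random.default_rng(children[2]),
    }


def build_niches(
    config: SimConfig, rng: np.random.Generator
) -> dict[NicheKind, Niche]:
    """Blood panel plus depletable mirrors at each niche's display efficiency."""
    if config.panel_file:
        blood_panel = read_panel(config.panel_file, config.blood.volume)
        blood_panel = [
            replace(
                sp,
                replenished=True,
                fixed_concentration=sp.concentration(config.blood.volume),
                total_epitope=0.0,
            )
            if not sp.replenished
            else sp
            for sp in blood_panel
        ]
    else:
        blood_panel = make_antigen_panel(
            config.blood.n_species,
            config.blood.conc_low,
            config.blood.conc_high,
            True,
            config.blood.volume,
            rng,
        )

    def mirror(nc, kind: NicheKind) -> Niche:
        panel = [
            AntigenSpecies.from_concentration(
                sp.ag_id,
                sp.fixed_concentration * nc.display_efficiency,
                False,
                nc.volume,
            )
            for sp in blood_panel
        ]
        return Niche(kind=kind, volume=nc.volume, panel=panel, band=config.band)

    return {
        NicheKind.BONE_MARROW: mirror(config.bone_marrow, NicheKind.BONE_MARROW),
        NicheKind.BLOOD: Niche(
            kind=NicheKind.BLOOD,
            volume=config.blood.volume,
            panel=blood_panel,
            band=config.band,
        ),
        NicheKind.FOLLICLE: mirror(config.follicle, NicheKind.FOLLICLE),
        NicheKind.MEMORY_NICHE: mirror(config.memory_niche, NicheKind.MEMORY_NICHE),
    }


def make_sim_founders(
    config: SimConfig,
    niche: Niche,
    rng: np.random.Generator,
) -> list[BCellClone]:
    germline = GermlineSampler(config.germline.kd_low, config.germline.kd_high)
    ag_ids = [sp.ag_id for sp in niche.panel]
    return [
        BCellClone(
            clone_id=f"c{i:04d}",
            kd_intrinsic=germline.sample(rng),
            bcr_per_cell=config.cells.bcr_per_cell,
            stage=Stage(config.founders.stage),
            edit_attempts_left=config.cells.edit_attempts,
            cognate=ag_ids[int(rng.integers(len(ag_ids)))],
        )
        for i in range(config.founders.n_clones)
    ]


def _clone_complex_moles(
    niche: Niche, species: AntigenSpecies, clone: BCellClone
) -> float:
    """Equilibrium complex (moles) between one clone's paratope and a pool."""
    conc = species.concentration(niche.volume)
    paratope = clone.paratope_concentration(niche.volume)
    if conc == 0.0 or paratope == 0.0:
        return 0.0
    eq = solve_equilibrium(conc, paratope, clone.kd_apparent)
    return eq.complex * niche.volume


def simulate(config: SimConfig) -> SimResult:
    """Run the full multi-niche loop for ``config.n_steps`` decision epochs."""
    rngs = _spawn_rngs(config.seed)
    niches = build_niches(config, rngs["panel"])
    germline = GermlineSampler(config.germline.kd_low, config.germline.kd_high)

    clones: dict[NicheKind, list[BCellClone]] = {kind: [] for kind in NICHE_ORDER}
    clones[NicheKind.BONE_MARROW] = make_sim_founders(
        config, niches[NicheKind.BONE_MARROW], rngs["fates"]
    )

    records: list[TrajectoryRecord] = []
    pool_history: list[dict[str, dict[str, float]]] = []
    gc_output = MaturationOutput()
    gc_entrants_total = 0

    for step in range(config.n_steps):
        moves: list[tuple[BCellClone, NicheKind]] = []
        gc_entrants: list[BCellClone] = []
        step_pools: dict[str, dict[str, float]] = {}

        for kind in NICHE_ORDER:
            niche = niches[kind]
            residents = clones[kind]
            if residents or True:
                paratope_conc: dict[str, float] = defaultdict(float)
                for c in residents:
                    if kind is not NicheKind.MEMORY_NICHE and c.cognate is not None:
                        paratope_conc[c.cognate] += c.paratope_concentration(
                            niche.volume
                        )

            survivors: list[BCellClone] = []
            consumed: dict[str, float] = defaultdict(float)
            released: dict[str, float] = defaultdict(float)

            for clone in residents:
                if clone.stage is Stage.LLPC:
                    # antigen-independent: persists, engages nothing
                    survivors.append(clone)
                    continue
                if kind is NicheKind.MEMORY_NICHE:
                    ag_id, _ = best_log_ratio(niche, clone.kd_apparent)
                    species = niche.species(ag_id)
                else:
                    species = niche.species(clone.cognate)
                ag_free = free_antigen(
                    niche, species, paratope_conc[species.ag_id], clone.kd_apparent
                )
                theta = occupancy(ag_free, clone.kd_apparent) if ag_free >= 0 else 0.0
                ratio = log_engagement_ratio(ag_free, clone.kd_apparent)
                engagement = classify_engagement(ag_free, clone.kd_apparent, niche.band)
                action = decide_fate(
                    clone,
                    engagement,
                    kind,
                    config.second_signal,
                    rngs["fates"],
                    log_ratio=ratio,
                    delta_comfort=niche.band.delta_comfort,
                    delta_b1=config.cells.delta_b1,
                    p_b1_divide=config.cells.p_b1_divide,
                )
                records.append(
                    TrajectoryRecord(
                        step=step,
                        niche=kind.value,
                        clone_id=clone.clone_id,
                        stage=clone.stage.value,
                        n_cells=clone.n_cells,
                        kd_apparent=clone.kd_apparent,
                        occupancy=theta,
                        ag_free=ag_free,
                        action=action.label,
                    )
                )

                if action.fate is Fate.DIE:
                    if not species.replenished:
                        released[species.ag_id] += _clone_complex_moles(
                            niche, species, clone
                        )
                    continue
                if action.fate is Fate.REST_G0:
                    clone = replace(clone, cycle_state=CycleState.G0)
                    if kind is NicheKind.BONE_MARROW and clone.stage in (
                        Stage.SMALL_PRE_BII,
                        Stage.IMMATURE,
                    ):
                        moves.append(
                            (replace(clone, stage=Stage.IMMATURE), NicheKind.BLOOD)
                        )
                        continue
                    if kind is NicheKind.BLOOD and clone.stage in (
                        Stage.IMMATURE,
                        Stage.TRANSITIONAL,
                    ):
                        moves.append(
                            (
                                replace(clone, stage=Stage.TRANSITIONAL),
                                NicheKind.FOLLICLE,
                            )
                        )
                        continue
                    if kind is NicheKind.FOLLICLE and clone.stage is Stage.TRANSITIONAL:
                        clone = replace(clone, stage=Stage.FOLLICULAR_BII)
                    survivors.append(clone)
                    continue
                if action.fate is Fate.PERSIST_G1:
                    if action.exit_stage is not None:
                        clone = replace(clone, stage=action.exit_stage)
                    survivors.append(replace(clone, cycle_state=CycleState.G1))
                    continue
                if action.fate is Fate.DIVIDE:
                    clone = divide_clone(
                        clone, population_cap=config.cells.population_cap
                    )
                    if action.with_switch and clone.isotype in (
                        Isotype.IgM,
                        Isotype.IgD,
                    ):
                        clone = isotype_switch(
                            clone, Isotype.IgG, config.cells.switch_gain
                        )
                    if not species.replenished:
                        consumed[species.ag_id] += _clone_complex_moles(
                            niche, species, clone
                        )
                    survivors.append(clone)
                    continue
                if action.fate is Fate.EDIT_RECEPTOR:
                    survivors.append(receptor_edit(clone, germline, rngs["fates"]))
                    continue
                if action.fate is Fate.EXIT_AS and action.exit_stage is Stage.MZB:
                    survivors.append(mzb_differentiate(clone, ratio))
                    continue
                if action.fate is Fate.ENTER_GC:
                    gc_entrants.append(
                        replace(clone, stage=Stage.GC_B, cycle_state=CycleState.G1)
                    )
                    continue
                if action.fate is Fate.SWITCH_ISOTYPE:
                    survivors.append(
                        isotype_switch(clone, Isotype.IgG, config.cells.switch_gain)
                    )
                    continue
                raise AssertionError(f"unhandled action {action}")  # pragma: no cover

            niches[kind] = update_antigen_pool(niche, consumed, released, 0.0)
            clones[kind] = survivors
            step_pools[kind.value] = {
                sp.ag_id: sp.concentration(niches[kind].volume)
                for sp in niches[kind].panel
            }

        for clone, dest in moves:
            clones[dest].append(clone)

        if gc_entrants:
            gc_entrants_total += len(gc_entrants)
            run_cfg = config.gc.run_config(config.band, config.shm, config.germline)
            out = run_immunization_schedule(
                gc_entrants,
                [(config.gc.dose_conc, config.gc.n_cycles)],
                run_cfg,
                rngs["gc"],
            )
            gc_output.extend(out)
            for mem in out.memory:
                clones[NicheKind.MEMORY_NICHE].append(mem)

        pool_history.append(step_pools)

    summary = {
        "n_steps": config.n_steps,
        "seed": config.seed,
        "population": {
            kind.value: {
                "n_clones": len(clones[kind]),
                "n_cells": int(sum(c.n_cells for c in clones[kind])),
                "stages": _stage_counts(clones[kind]),
            }
            for kind in NICHE_ORDER
        },
        "gc": {"entrants": gc_entrants_total, **gc_output.summary()},
    }
    return SimResult(
        records=records,
        summary=summary,
        niches=niches,
        clones=clones,
        pool_history=pool_history,
        gc_output=gc_output,
    )


def _stage_counts(residents: Iterable[BCellClone]) -> dict[str, int]:
    counts: dict[str, int] = defaultdict(int)
    for c in residents:
        counts[c.stage.value] += 1
    return dict(sorted(counts.items()))


def phase_map(
    grid_ag: np.ndarray,
    grid_kd: np.ndarray,
    band: EngagementBand = EngagementBand(),
) -> np.ndarray:
    """Engagement-class grid over (kd rows × ag columns), both log-spaced."""
    grid_ag = np.asarray(grid_ag, dtype=float)
    grid_kd = np.asarray(grid_kd, dtype=float)
    if grid_ag.size == 0 or grid_kd.size == 0:
        raise DomainError("phase_map grids must be non-empty")
    out = np.empty((grid_kd.size, grid_ag.size), dtype=np.int8)
    for i, kd in enumerate(grid_kd):
        for j, ag in enumerate(grid_ag):
            out[i, j] = int(classify_engagement(float(ag), float(kd), band))
    return out


def run_gc_ensemble(
    config: SimConfig, n_seeds: int, base_seed: int
) -> tuple[MaturationOutput, list[dict]]:
    """Repeated-immunization schedule over an ensemble of seeds.

    Returns the pooled output across seeds plus one summary dict per seed.
    """
    pooled = MaturationOutput()
    per_seed: list[dict] = []
    run_cfg = config.gc.run_config(config.band, config.shm, config.germline)
    schedule = config.gc.schedule()
    for k in range(n_seeds):
        rng = np.random.default_rng(np.random.SeedSequence([base_seed, k]))
        founders = make_founders(config.gc.n_founders, run_cfg, rng, prefix=f"s{k}f")
        out = run_immunization_schedule(founders, schedule, run_cfg, rng)
        pooled.extend(out)
        per_seed.append({"seed_index": k, **out.summary()})
    return pooled, per_seed
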
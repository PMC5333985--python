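"""Shared fixtures and small composed-run helpers."""

from __future__ import annotations

import logging
from dataclasses import replace

import numpy as np
import pytest

from gqm.agents import BCellClone, Stage, decide_fate, divide_clone
from gqm.binding import EngagementBand, EngagementClass, classify_engagement
from gqm.niches import AntigenSpecies, Niche, NicheKind, free_antigen, update_antigen_pool


@pytest.fixture(autouse=True)
def _quiet_population_cap_warnings():
    logging.getLogger("gqm.agents").setLevel(logging.ERROR)
    logging.getLogger("gqm.niches").setLevel(logging.ERROR)
    yield


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def band():
    return EngagementBand()


def make_clone(**kwargs) -> BCellClone:
    defaults = dict(clone_id="t0", kd_intrinsic=1e-8, stage=Stage.FOLLICULAR_BII)
    defaults.update(kwargs)
    return BCellClone(**defaults)


def run_depletion_to_comfort(
    kd: float,
    ag_conc: float,
    volume: float,
    band: EngagementBand,
    max_steps: int,
    rng: np.random.Generator,
    bcr_per_cell: float = 1e5,
) -> tuple[bool, int]:
    """Single clone in a depletable niche: divide while over-engaged.

    Composes free_antigen → classify → decide_fate → divide/update exactly as
    the engine does, and reports whether the clone reached COMFORT and when.
    """
    niche = Niche(
        kind=NicheKind.FOLLICLE,
        volume=volume,
        panel=[AntigenSpecies.from_concentration("ag", ag_conc, False, volume)],
        band=band,
    )
    clone = BCellClone(
        clone_id="c",
        kd_intrinsic=kd,
        stage=Stage.FOLLICULAR_BII,
        bcr_per_cell=bcr_per_cell,
    )
    from gqm.binding import solve_equilibrium

    for step in range(max_steps):
        sp = niche.panel[0]
        paratope = clone.paratope_concentration(volume)
        ag_free = free_antigen(niche, sp, paratope, clone.kd_apparent)
        engagement = classify_engagement(ag_free, clone.kd_apparent, band)
        if engagement is EngagementClass.COMFORT:
            return True, step
        action = decide_fate(clone, engagement, NicheKind.FOLLICLE, False, rng)
        if action.fate.value == "DIE":
            return False, step
        if action.fate.value == "DIVIDE":
            clone = divide_clone(clone)
            total_conc = sp.concentration(volume)
            if total_conc > 0:
                eq = solve_equilibrium(
                    total_conc, clone.paratope_concentration(volume), clone.kd_apparent
                )
                niche = update_antigen_pool(
                    niche, consumed={"ag": eq.complex * volume}
                )
    return False, max_steps
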
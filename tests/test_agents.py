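"""Clone fate rules and transformations."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gqm.agents import (
    LETHAL,
    BCellClone,
    ConfigurationError,
    ContractError,
    CycleState,
    Fate,
    GermlineSampler,
    Isotype,
    SHMParams,
    Stage,
    classify_blood_fate,
    decide_fate,
    divide_clone,
    isotype_switch,
    mzb_differentiate,
    receptor_edit,
    shm_mutate,
)
from gqm.binding import DomainError, EngagementClass
from gqm.niches import NicheKind

from conftest import make_clone


class TestDecideFate:
    def test_comfort_rests_in_g0(self, rng):
        clone = make_clone(stage=Stage.FOLLICULAR_BII)
        action = decide_fate(
            clone, EngagementClass.COMFORT, NicheKind.FOLLICLE, False, rng
        )
        assert action.fate is Fate.REST_G0

    def test_under_in_bone_marrow_edits_while_budget_lasts(self, rng):
        clone = make_clone(stage=Stage.SMALL_PRE_BII, edit_attempts_left=2)
        action = decide_fate(
            clone, EngagementClass.UNDER, NicheKind.BONE_MARROW, False, rng
        )
        assert action.fate is Fate.EDIT_RECEPTOR

    def test_under_in_bone_marrow_dies_when_budget_spent(self, rng):
        clone = make_clone(stage=Stage.SMALL_PRE_BII, edit_attempts_left=0)
        action = decide_fate(
            clone, EngagementClass.UNDER, NicheKind.BONE_MARROW, False, rng
        )
        assert action.fate is Fate.DIE

    def test_saturated_in_bone_marrow_is_clonal_deletion(self, rng):
        clone = make_clone(stage=Stage.IMMATURE, edit_attempts_left=3)
        for second in (False, True):
            action = decide_fate(
                clone, EngagementClass.SATURATED, NicheKind.BONE_MARROW, second, rng
            )
            assert action.fate is Fate.DIE

    def test_neglect_dies_outside_blood(self, rng):
        clone = make_clone(stage=Stage.FOLLICULAR_BII)
        action = decide_fate(
            clone, EngagementClass.NEGLECT, NicheKind.FOLLICLE, False, rng
        )
        assert action.fate is Fate.DIE

    def test_over_in_follicle_with_second_signal_enters_gc(self, rng):
        clone = make_clone(stage=Stage.FOLLICULAR_BII)
        action = decide_fate(clone, EngagementClass.OVER, NicheKind.FOLLICLE, True, rng)
        assert action.fate is Fate.ENTER_GC

    def test_over_without_second_signal_divides(self, rng):
        clone = make_clone(stage=Stage.FOLLICULAR_BII)
        action = decide_fate(clone, EngagementClass.OVER, NicheKind.FOLLICLE, False, rng)
        assert action.fate is Fate.DIVIDE

    def test_llpc_raises_configuration_error(self, rng):
        clone = make_clone(stage=Stage.LLPC)
        with pytest.raises(ConfigurationError):
            decide_fate(clone, EngagementClass.COMFORT, NicheKind.MEMORY_NICHE, False, rng)

    def test_empty_clone_violates_contract(self, rng):
        clone = make_clone(n_cells=0)
        with pytest.raises(ContractError):
            decide_fate(clone, EngagementClass.COMFORT, NicheKind.FOLLICLE, False, rng)

    def test_exhaustive_over_state_machine(self, rng):
        """Every (stage, engagement, niche) either returns an action or raises
        ConfigurationError deliberately — no silent fallthrough."""
        for stage, engagement, niche, second in itertools.product(
            Stage, EngagementClass, NicheKind, (False, True)
        ):
            if niche is NicheKind.GC:
                continue  # GC clones are driven by the gc_cycle loop
            clone = make_clone(stage=stage)
            try:
                action = decide_fate(
                    clone, engagement, niche, second, rng, log_ratio=1.0
                )
            except ConfigurationError:
                assert stage is Stage.LLPC
            else:
                assert action.fate in Fate


class TestClassifyBloodFate:
    def test_neglect_dies(self):
        clone = make_clone(stage=Stage.IMMATURE)
        action = classify_blood_fate(clone, EngagementClass.NEGLECT, False, log_ratio=-math.inf)
        assert action.fate is Fate.DIE

    def test_moderate_over_becomes_b1_in_g1(self):
        clone = make_clone(stage=Stage.IMMATURE)
        action = classify_blood_fate(
            clone, EngagementClass.OVER, False, log_ratio=1.0, delta_b1=1.5
        )
        assert action.fate is Fate.PERSIST_G1
        assert action.exit_stage is Stage.B1

    def test_strong_over_with_second_signal_is_mzb(self):
        clone = make_clone(stage=Stage.IMMATURE)
        action = classify_blood_fate(
            clone, EngagementClass.SATURATED, True, log_ratio=3.0
        )
        assert action.fate is Fate.EXIT_AS
        assert action.exit_stage is Stage.MZB
        adjusted = mzb_differentiate(clone, 3.0)
        # apparent-kd grows 10^3, restoring the log-ratio to ~0 (comfort)
        assert math.log10(adjusted.kd_apparent / clone.kd_apparent) == pytest.approx(3.0)

    def test_strong_over_without_second_signal_is_ti_response(self):
        clone = make_clone(stage=Stage.IMMATURE)
        action = classify_blood_fate(
            clone, EngagementClass.SATURATED, False, log_ratio=3.0
        )
        assert action.fate is Fate.DIVIDE
        assert action.with_switch

    def test_wrong_stage_violates_contract(self):
        clone = make_clone(stage=Stage.FOLLICULAR_BII)
        with pytest.raises(ContractError):
            classify_blood_fate(clone, EngagementClass.OVER, False, log_ratio=1.0)


class TestDivideClone:
    def test_doubles(self):
        assert divide_clone(make_clone(n_cells=1)).n_cells == 2
        assert divide_clone(make_clone(n_cells=64)).n_cells == 128

    def test_single_cell_mode_increments(self):
        assert divide_clone(make_clone(n_cells=5), single_cell_mode=True).n_cells == 6

    def test_clamped_at_population_cap(self, caplog):
        import logging

        logging.getLogger("gqm.agents").setLevel(logging.WARNING)
        clone = make_clone(n_cells=1024)
        with caplog.at_level("WARNING", logger="gqm.agents"):
            out = divide_clone(clone, population_cap=1024)
        assert out.n_cells == 1024
        assert any("population cap" in r.message for r in caplog.records)

    def test_other_fields_unchanged(self):
        clone = make_clone(n_cells=4, mut_h=3, mut_l=1)
        out = divide_clone(clone)
        assert (out.kd_intrinsic, out.mut_h, out.mut_l, out.isotype) == (
            clone.kd_intrinsic,
            clone.mut_h,
            clone.mut_l,
            clone.isotype,
        )


class TestReceptorEdit:
    def test_decrements_budget_and_resamples(self, rng):
        clone = make_clone(stage=Stage.SMALL_PRE_BII, edit_attempts_left=3, mut_h=2, mut_l=1)
        out = receptor_edit(clone, GermlineSampler(), rng)
        assert out.edit_attempts_left == 2
        assert out.mut_h == 0 and out.mut_l == 0
        assert 1e-10 <= out.kd_intrinsic <= 1e-6

    def test_no_budget_is_contract_violation(self, rng):
        clone = make_clone(edit_attempts_left=0)
        with pytest.raises(ContractError):
            receptor_edit(clone, GermlineSampler(), rng)

    def test_seeded_replay_identical(self):
        clone = make_clone(edit_attempts_left=3)
        g = GermlineSampler()
        kd1 = receptor_edit(clone, g, np.random.default_rng(99)).kd_intrinsic
        kd2 = receptor_edit(clone, g, np.random.default_rng(99)).kd_intrinsic
        assert kd1 == kd2

    def test_resamples_respect_germline_bounds(self, rng):
        g = GermlineSampler(kd_low=1e-10, kd_high=1e-6)
        draws = np.array([g.sample(rng) for _ in range(10_000)])
        assert draws.min() >= 1e-10
        assert draws.max() <= 1e-6
        # spans most of the configured range
        assert draws.min() < 1e-9 and draws.max() > 1e-7


class TestIsotypeSwitch:
    def test_switch_gain_lowers_apparent_kd(self):
        clone = make_clone(kd_intrinsic=1e-6, isotype=Isotype.IgM)
        out = isotype_switch(clone, Isotype.IgG, switch_gain=10.0)
        assert out.isotype is Isotype.IgG
        assert out.kd_apparent == pytest.approx(1e-7)
        assert out.kd_intrinsic == 1e-6

    def test_identity_gain(self):
        clone = make_clone(isotype=Isotype.IgD)
        out = isotype_switch(clone, Isotype.IgA, switch_gain=1.0)
        assert out.kd_apparent == clone.kd_apparent

    def test_double_switch_is_noop_with_warning(self):
        clone = make_clone(isotype=Isotype.IgG)
        with pytest.warns(UserWarning, match="already switched"):
            out = isotype_switch(clone, Isotype.IgE)
        assert out is clone

    def test_switch_to_igm_rejected(self):
        with pytest.raises(DomainError):
            isotype_switch(make_clone(), Isotype.IgM)


class TestSHM:
    def test_both_chains_capped_passes_through(self, rng):
        params = SHMParams()
        clone = make_clone(stage=Stage.GC_B, mut_h=params.cap_h, mut_l=params.cap_l)
        assert shm_mutate(clone, params, rng) is clone

    def test_requires_gc_stage(self, rng):
        with pytest.raises(ContractError):
            shm_mutate(make_clone(stage=Stage.MEMORY), SHMParams(), rng)

    def test_seeded_replay_identical(self):
        clone = make_clone(stage=Stage.GC_B)
        params = SHMParams()
        outs = []
        for _ in range(2):
            r = np.random.default_rng(4242)
            c = clone
            seq = []
            for _ in range(50):
                m = shm_mutate(c, params, r)
                if m is LETHAL:
                    seq.append("LETHAL")
                else:
                    c = m
                    seq.append((c.kd_intrinsic, c.mut_h, c.mut_l))
            outs.append(seq)
        assert outs[0] == outs[1]

    def test_outcome_rates_match_configuration(self, rng):
        """Across all draws, lethal/deleterious/beneficial land at their
        configured trichotomy rates (law of large numbers)."""
        params = SHMParams()
        clone = make_clone(stage=Stage.GC_B, kd_intrinsic=1e-8)
        n = 100_000
        lethal = deleterious = 0
        for _ in range(n):
            m = shm_mutate(clone, params, rng)
            if m is LETHAL:
                lethal += 1
            elif m.kd_intrinsic >= clone.kd_intrinsic:
                deleterious += 1
        se = 3.0 * math.sqrt(0.5 * 0.5 / n)
        assert lethal / n == pytest.approx(params.p_lethal, abs=se)
        assert deleterious / n == pytest.approx(params.p_del, abs=se)

    def test_kd_clamped_to_bounds(self, rng):
        params = SHMParams(kd_min=2e-12, kd_max=1e-3)
        clone = make_clone(stage=Stage.GC_B, kd_intrinsic=3e-12)
        for _ in range(500):
            m = shm_mutate(clone, params, rng)
            if m is not LETHAL:
                assert params.kd_min <= m.kd_intrinsic <= params.kd_max
                clone = m

    def test_capped_chain_is_skipped(self, rng):
        params = SHMParams()
        clone = make_clone(stage=Stage.GC_B, mut_h=params.cap_h, mut_l=0)
        for _ in range(200):
            m = shm_mutate(clone, params, rng)
            if m is not LETHAL:
                assert m.mut_h == params.cap_h
                clone = m
        assert clone.mut_l > 0

    @given(seed=st.integers(0, 2 ** 31), steps=st.integers(1, 300))
    @settings(max_examples=50, deadline=None)
    def test_mutation_counters_never_exceed_caps(self, seed, steps):
        params = SHMParams()
        r = np.random.default_rng(seed)
        clone = make_clone(stage=Stage.GC_B)
        for _ in range(steps):
            m = shm_mutate(clone, params, r)
            if m is not LETHAL:
                clone = m
            assert clone.mut_h <= params.cap_h
            assert clone.mut_l <= params.cap_l

    def test_probabilities_must_sum_to_one(self):
        with pytest.raises(DomainError):
            SHMParams(p_lethal=0.5, p_del=0.5, p_beneficial=0.5)


class TestB1SteadyState:
    def test_persists_in_g1_within_population_bounds(self, rng):
        """Inexhaustible niche, log-ratio inside the B1 band: the clone never
        dies and its population stays within [1, cap] over a long horizon."""
        clone = make_clone(stage=Stage.IMMATURE)
        cap = 4096
        alive = clone
        for _ in range(1000):
            action = decide_fate(
                alive, EngagementClass.OVER, NicheKind.BLOOD, False, rng, log_ratio=1.0
            )
            assert action.fate is not Fate.DIE
            if action.exit_stage is Stage.B1:
                alive = make_clone(stage=Stage.B1, n_cells=alive.n_cells)
            if action.fate is Fate.DIVIDE:
                alive = divide_clone(alive, population_cap=cap)
            assert 1 <= alive.n_cells <= cap
        assert alive.stage is Stage.B1
        assert alive.cycle_state in (CycleState.G1, CycleState.DIVIDING)
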
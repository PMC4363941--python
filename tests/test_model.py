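"""The actin/integrin/cofilin model: rule assembly per mechanism, severing
cascades, replenishment, orientation sampling, and whole-run invariants."""

import math

import numpy as np
import pytest

from actinsim.core import ModelConfigError
from actinsim.engine import EngineParams
from actinsim.model import (DefaultConstants, ModelParams, build_model,
                            build_rules, free_actin_count,
                            replenish_free_actin, sample_filament_orientation,
                            sever_and_dissolve)
from actinsim.observables import extract_filament_complexes

from conftest import build_filament, fast_engine, quarter_scale_params


class TestMechanismSelection:
    def test_direct_mechanism_has_no_cofreg_rules(self):
        p = ModelParams(rCofRegAppearance=0.0, pCofDeactAtInt=1.0)
        collision, timed, _ = build_rules(p)
        names = {r.name for r in collision} | {r.name for r in timed}
        assert "cofilin-deact-at-integrin" in names
        assert not any("cofreg" in n for n in names)

    def test_cofreg_mechanism_has_cascade_rules(self):
        p = ModelParams()  # CofReg mechanism by default
        collision, timed, _ = build_rules(p)
        names = {r.name for r in collision} | {r.name for r in timed}
        assert {"cofreg-appearance", "cofreg-disappearance",
                "cofilin-deact-by-cofreg"} <= names
        assert "cofilin-deact-at-integrin" not in names

    def test_both_mechanisms_enabled_is_an_error(self):
        with pytest.raises(ModelConfigError):
            ModelParams(rCofRegAppearance=2.0, pCofDeactAtInt=1.0).validate()

    def test_planar_surface_has_no_transfer_rules_but_fa_everywhere(self):
        collision, timed, transfer = build_rules(ModelParams(surface="planar"))
        assert transfer == []
        form = [r for r in timed if r.name == "fa-formation"]
        assert len(form) == 1 and form[0].pattern.region is None

    def test_pillar_surface_instant_fa_via_transfer(self):
        _, timed, transfer = build_rules(ModelParams(surface="pillars",
                                                     instantFA=True))
        assert any(t.attr_updates.get("focal") == "yes" for t in transfer)
        assert not any(r.name == "fa-formation" for r in timed)
        _, timed2, _ = build_rules(ModelParams(surface="pillars",
                                               instantFA=False))
        form = [r for r in timed2 if r.name == "fa-formation"]
        assert len(form) == 1 and form[0].pattern.region == "pillar"


def test_initial_state_counts_and_placement():
    """Default amounts (250 actin + 400 cofilin + 100 integrin) are placed
    overlap-free; all cofilin active, all integrin non-focal, no bonds."""
    state = build_model(ModelParams(seed=3))
    counts = state.species_counts()
    assert counts == {"actin": 250, "cofilin": 400, "integrin": 100}
    assert state.bond_count() == 0
    for p in state.particles.values():
        if p.species.name == "cofilin":
            assert p.attr["active"] == "yes"
        if p.species.name == "integrin":
            assert p.attr["focal"] == "no"
    state.audit()


class TestOrientationSampling:
    def test_zero_sigma_is_horizontal(self):
        rng = np.random.default_rng(0)
        assert sample_filament_orientation(0.0, rng) == 0.0

    def test_sample_sd_matches_sigma(self):
        rng = np.random.default_rng(1)
        draws = [sample_filament_orientation(15.0, rng) for _ in range(10_000)]
        assert 14.6 < float(np.std(draws)) < 15.4

    def test_unconstrained_passes_through_approach_direction(self):
        rng = np.random.default_rng(2)
        assert sample_filament_orientation(None, rng, 37.0) == 37.0
        with pytest.raises(ValueError):
            sample_filament_orientation(None, rng)


class TestSeveringCascade:
    """Hand-traced severing fixtures on an integrin–A1–…–A5 chain with the
    infinite-rate trunk-dissolution rule active."""

    def _chain_state(self, species):
        from actinsim.core import Model
        from actinsim.engine import SimulationState
        from actinsim.space import SpaceModel
        p = ModelParams()
        collision, timed, transfer = build_rules(p)
        model = Model(species, collision, timed, transfer,
                      orientation_sampler=lambda rng, app: 0.0)
        st = SimulationState(model, SpaceModel(20.0, 20.0),
                             EngineParams(seed=0), np.random.default_rng(0))
        integ, actins = build_filament(st, 5.0, 10.0, 0.0, 5)
        cof = st.add_particle("cofilin", 1.0, 1.0, {"active": "yes"})
        return st, integ, actins, cof

    def test_strike_interior_keeps_rooted_stump(self, species):
        st, integ, actins, cof = self._chain_state(species)
        sever_and_dissolve(st, cof, actins[2])  # strike A3
        a1, a2, a3, a4, a5 = actins
        assert integ.bonds["fa"] == (a1.id, "pointed")
        assert a1.bonds["barbed"] == (a2.id, "pointed")
        assert a2.bonds["barbed"] is None  # free barbed end, can regrow
        for freed in (a3, a4, a5):
            assert freed.nb == 0 and freed.mobile
        assert not integ.mobile and not a1.mobile and not a2.mobile
        st.audit()

    def test_strike_first_actin_frees_whole_chain_and_integrin_site(self, species):
        st, integ, actins, cof = self._chain_state(species)
        sever_and_dissolve(st, cof, actins[0])
        assert integ.bonds["fa"] is None and integ.mobile
        for a in actins:
            assert a.nb == 0 and a.mobile
        st.audit()

    def test_inactive_cofilin_is_a_contract_violation(self, species):
        st, integ, actins, cof = self._chain_state(species)
        st.set_attr(cof, "active", "no")
        with pytest.raises(ValueError):
            sever_and_dissolve(st, cof, actins[2])
        assert actins[2].nb == 2  # no state change

    def test_finite_dissolution_rate_defers_trunk_decay(self, species):
        """With rFilDissolution finite the severed trunk is not dissolved in
        the same timestep; its clocks fire later."""
        from actinsim.core import Model
        from actinsim.engine import SimulationState
        from actinsim.space import SpaceModel
        _, timed, _ = build_rules(ModelParams(rFilDissolution=0.5))
        model = Model(species, (), timed, (),
                      orientation_sampler=lambda rng, app: 0.0)
        st = SimulationState(model, SpaceModel(20.0, 20.0),
                             EngineParams(seed=0), np.random.default_rng(0))
        integ, actins = build_filament(st, 5.0, 10.0, 0.0, 5)
        cof = st.add_particle("cofilin", 1.0, 1.0, {"active": "yes"})
        sever_and_dissolve(st, cof, actins[2])
        # deferred: the orphaned trunk A4–A5 is still bonded right after
        assert actins[3].bonds["barbed"] == (actins[4].id, "pointed")
        st.run(60.0)  # trunk decays from the pointed end by rate
        assert actins[3].nb == 0 and actins[4].nb == 0
        # the rooted stump integrin–A1–A2 never dissolves
        assert integ.bonds["fa"] is not None and actins[1].nb == 1


class TestReplenishment:
    def test_noop_at_target(self):
        state = build_model(quarter_scale_params(seed=5))
        n0 = free_actin_count(state)
        assert replenish_free_actin(state, n0) == 0

    def test_tops_up_bound_actin_deficit(self, species):
        state = build_model(quarter_scale_params(seed=5))
        target = free_actin_count(state)
        # bind 4 actins into a filament by hand: the free pool drops by 4
        free = [p for p in state.particles.values()
                if p.species.name == "actin"][:4]
        prev = build_filament(state, 3.0, 3.0, 0.0, 0)[0]
        site = "fa"
        from actinsim.space import place_bound
        for a in free:
            x, y, orient = place_bound(prev, site, a.species, "pointed")
            state.move_particle(a, x, y)
            a.orient = orient
            state.bind(prev, site, a, "pointed")
            prev, site = a, "barbed"
        assert free_actin_count(state) == target - 4
        assert replenish_free_actin(state, target) == 4
        assert free_actin_count(state) == target

    def test_total_actin_never_decreases_over_a_run(self):
        params = quarter_scale_params(tEnd=4.0, seed=8)
        state = build_model(params, engine_params=fast_engine(8))
        from actinsim.observables import AmountRecorder
        rec = AmountRecorder()
        state.run(params.tEnd, recorders=[rec])
        actin = rec.to_frame()["actin"].to_numpy()
        assert (np.diff(actin) >= 0).all()


def test_run_invariants_conservation_and_filament_structure():
    """After a pillared run: cofilin and integrin are conserved; CofReg count
    equals creations − destructions; every filament complex has exactly one
    integrin at the pointed-most position; interior actins are doubly bound;
    each unbranched complex has exactly one free barbed end."""
    params = quarter_scale_params(tEnd=6.0, seed=4)
    state = build_model(params, engine_params=fast_engine(4))
    state.run(params.tEnd)
    counts = state.species_counts()
    assert counts["cofilin"] == params.nCofilin
    assert counts["integrin"] == params.nIntegrin
    assert counts.get("cofreg", 0) == (state.created_counts.get("cofreg", 0)
                                       - state.destroyed_counts.get("cofreg", 0))
    complexes = extract_filament_complexes(state)
    assert complexes, "expected filaments to have formed"
    for c in complexes:
        integrins = [m for m in c.members if c.species[m] == "integrin"]
        assert len(integrins) == 1
        assert c.root == integrins[0]
        root = state.particles[c.root]
        assert root.bonds["fa"] is not None
        free_barbed = 0
        for m in c.members:
            p = state.particles[m]
            if p.species.name != "actin":
                continue
            assert p.bonds["pointed"] is not None  # rooted chain
            if p.bonds["barbed"] is None:
                free_barbed += 1
        if not any(c.species[m] == "arp" for m in c.members):
            assert free_barbed == 1
    state.audit()


def test_pure_growth_without_cofilin_is_monotone():
    """With no cofilin, bonds are never destroyed: the bound-actin pool and
    the maximum filament length are non-decreasing, and the final average
    length is at least the first observed average."""
    params = quarter_scale_params(nCofilin=0, tEnd=8.0, seed=6,
                                  surface="planar")
    state = build_model(params, engine_params=fast_engine(6))
    from actinsim.observables import AmountRecorder, ComplexSizeRecorder
    am, cs = AmountRecorder(), ComplexSizeRecorder()
    state.run(params.tEnd, recorders=[am, cs])
    bonds = am.to_frame()["bonds"].to_numpy()
    assert (np.diff(bonds) >= 0).all()
    per_t = cs.to_frame().groupby("time")["main_chain_actins"]
    maxima = per_t.max().to_numpy()
    assert (np.diff(maxima) >= 0).all()
    means = per_t.mean()
    assert means.iloc[-1] >= means.iloc[0]


def test_cofreg_birth_death_balance():
    """Steady-state mean CofReg count ≈ nFA·rApp/rDis (birth–death balance),
    within 3 standard errors over replicates."""
    params = quarter_scale_params(nActin=0, nCofilin=0, tEnd=20.0,
                                  rCofRegAppearance=1.0,
                                  rCofRegDisappearance=1.0)
    obs, exp = [], []
    for seed in range(6):
        state = build_model(params, engine_params=fast_engine(seed),
                            rng=np.random.default_rng(seed))
        from actinsim.observables import AmountRecorder
        rec = AmountRecorder()
        state.run(params.tEnd, recorders=[rec])
        df = rec.to_frame()
        tail = df[df["time"] >= params.tEnd / 2]
        obs.append(float(tail["cofreg"].mean()))
        exp.append(float(tail["focal_integrin"].mean())
                   * params.rCofRegAppearance / params.rCofRegDisappearance)
    diff = np.array(obs) - np.array(exp)
    se = float(np.std(diff, ddof=1) / math.sqrt(len(diff)))
    assert abs(float(np.mean(diff))) <= 3 * se + 1e-9, (obs, exp)


def test_integrin_slowdown_variant_scales_diffusion_on_structures():
    """With slowdownFactor < 1, integrins inside pillar regions carry the
    reduced diffusion factor; it resets on leaving."""
    params = quarter_scale_params(nActin=0, nCofilin=0, slowdownFactor=0.2,
                                  tEnd=3.0, seed=9)
    state = build_model(params, engine_params=fast_engine(9))
    state.run(params.tEnd)
    seen_inside = seen_outside = 0
    for p in state.particles.values():
        if p.species.name != "integrin":
            continue
        if p.region is not None:
            assert p.d_factor == pytest.approx(0.2)
            seen_inside += 1
        else:
            assert p.d_factor == pytest.approx(1.0)
            seen_outside += 1
    assert seen_inside > 0 and seen_outside > 0


def test_hampered_entry_keeps_integrin_off_structures():
    """pIntegrinEnter = 0: integrins that start outside the structures never
    enter them (rejected crossings are blocked moves)."""
    params = quarter_scale_params(nActin=0, nCofilin=0, pIntegrinEnter=0.0,
                                  tEnd=3.0, seed=10)
    state = build_model(params, engine_params=fast_engine(10))
    outside0 = {p.id for p in state.particles.values()
                if p.species.name == "integrin" and p.region is None}
    state.run(params.tEnd)
    for pid in outside0:
        assert state.particles[pid].region is None


def test_constants_scale_with_protein_size():
    c = DefaultConstants()
    assert c.cofilin_diameter < c.cofreg_diameter < c.arp_diameter \
        < c.actin_diameter < c.integrin_diameter
    assert c.diffusion(c.cofilin_diameter) == pytest.approx(1.0)
    # D ∝ 1/√size: quadrupling the size halves D
    assert c.diffusion(4 * c.cofilin_diameter) == pytest.approx(0.5)
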
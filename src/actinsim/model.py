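"""The actin/integrin/cofilin model: species, reaction rules, scenario
construction for planar, pillared and grooved surfaces.

Biology captured (deliberately minimal):

* Free actin monomers diffuse; filaments are immobile and grow only at the
  barbed end.  Nucleation requires a focal-adhesion integrin (attribute
  ``focal=yes``), the only nucleation point, which binds the first actin's
  pointed end.  The filament axis is fixed at nucleation — either drawn from
  N(0, σ²) about the horizontal or, unconstrained, the direction from which
  the first actin approached.
* Integrins become focal adhesions on surface structures, either instantly on
  entering a structure or at rate ``rIntComplexFormation`` while inside; on a
  planar surface the whole domain has surface contact and the rate applies
  everywhere.  A focal adhesion with no filament bound dissolves at
  ``rFAdissolution``.
* Active cofilin severs on collision with a filament actin whose pointed end
  is occupied: the struck actin releases all bonds, and the orphaned
  downstream trunk dissolves (rate ``rFilDissolution``, ∞ by default, i.e.,
  within the same timestep).  Cofilin is deactivated either directly on
  contact with a focal adhesion (``pCofDeactAtInt``) or by a diffusible
  intermediate *CofReg* that appears near focal adhesions
  (``rCofRegAppearance``), decays (``rCofRegDisappearance``) and deactivates
  cofilin catalytically on collision.  Deactivated cofilin reactivates at
  ``rCofilinReactivation``.
* Optional Arp2/3-style branching at 70° to the growth axis (``nArp > 0``).
* Free actin is replenished periodically to its initial count, standing in
  for recruitment from the cytosol.

Sizes are in μm (actin deliberately oversized: one particle stands for a
filament-bundle segment), diffusion coefficients in μm²/a.u. and scale with
1/√size; rates are per a.u.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .core import (FREE, OCC, Bind, CollisionRule, Create, Destroy, Model,
                   ModelConfigError, Particle, ReactantPattern, SetAttr,
                   SpeciesDef, TimedRule, TransferRule, UnbindAll)
from .engine import EngineParams, SimulationState
from .space import build_surface_layout


@dataclass(frozen=True)
class DefaultConstants:
    """Calibrated physical constants (all config-overridable).

    Diameters are proportional to protein-size surrogates; diffusion scales
    with 1/√diameter, anchored at cofilin (the smallest particle, which also
    sets the engine step length) with D = 1 μm²/a.u.  The actin diameter of
    0.05 μm is the μm-per-particle conversion for filament lengths.
    """

    actin_diameter: float = 0.05
    integrin_diameter: float = 0.06
    cofilin_diameter: float = 0.02
    cofreg_diameter: float = 0.03
    arp_diameter: float = 0.04
    cofilin_diffusion: float = 1.0

    def diffusion(self, diameter: float) -> float:
        return self.cofilin_diffusion * math.sqrt(self.cofilin_diameter / diameter)


@dataclass
class ModelParams:
    """Scenario parameters; defaults are the base study conditions."""

    # amounts
    nActin: int = 250
    nCofilin: int = 400
    nIntegrin: int = 100
    nArp: int = 0
    # first-order rates (per a.u.)
    rCofRegAppearance: float = 2.0
    rCofRegDisappearance: float = 0.5
    rCofilinReactivation: float = 1.0
    rIntComplexFormation: float = 1.0
    rFAdissolution: float = 0.1
    rFilDissolution: float = math.inf
    # collision / transfer probabilities
    pSevering: float = 1.0
    pCofDeactAtInt: float = 0.0
    pIntegrinEnter: float = 1.0
    pElongation: float = 1.0
    pNucleation: float = 1.0
    # geometry and variants
    sigmaAngle: Optional[float] = 15.0  # degrees; None = unconstrained growth
    slowdownFactor: float = 1.0  # integrin diffusion factor on structures
    surface: str = "pillars"  # planar | pillars | grooves
    instantFA: bool = True  # FA on entry vs. by rate inside structures
    pillar_width: float = 5.0
    pitch: float = 10.0
    n_grid: int = 3
    tEnd: float = 48.0
    seed: int = 0
    constants: DefaultConstants = field(default_factory=DefaultConstants)

    def validate(self):
        for name in ("nActin", "nCofilin", "nIntegrin", "nArp"):
            if getattr(self, name) < 0:
                raise ModelConfigError(f"{name} must be >= 0")
        if self.pCofDeactAtInt > 0 and self.rCofRegAppearance > 0:
            raise ModelConfigError(
                "select one cofilin-regulation mechanism: set pCofDeactAtInt "
                "or rCofRegAppearance to 0")
        if self.surface not in ("planar", "pillars", "grooves"):
            raise ModelConfigError(f"unknown surface {self.surface!r}")

    def with_(self, **over) -> "ModelParams":
        return replace(self, **over)


def make_species(c: DefaultConstants) -> dict:
    """Species table.  Site angles are relative to each particle's 0° axis
    (the pointed/mother direction); the branch sites sit 70° off the growth
    axis, which is 180° from the pointed site."""
    return {
        "actin": SpeciesDef(
            "actin", c.actin_diameter / 2, c.diffusion(c.actin_diameter),
            sites=(("pointed", 0.0), ("barbed", 180.0),
                   ("branchL", 110.0), ("branchR", 250.0))),
        "integrin": SpeciesDef(
            "integrin", c.integrin_diameter / 2, c.diffusion(c.integrin_diameter),
            attributes={"focal": ("no", "yes")}, sites=(("fa", 0.0),)),
        "cofilin": SpeciesDef(
            "cofilin", c.cofilin_diameter / 2, c.cofilin_diffusion,
            attributes={"active": ("yes", "no")}),
        "cofreg": SpeciesDef(
            "cofreg", c.cofreg_diameter / 2, c.diffusion(c.cofreg_diameter)),
        "arp": SpeciesDef(
            "arp", c.arp_diameter / 2, c.diffusion(c.arp_diameter),
            sites=(("mother", 0.0), ("daughter", 180.0))),
    }


def sample_filament_orientation(sigma_deg: Optional[float], rng,
                                approach_direction: Optional[float] = None
                                ) -> float:
    """Filament axis at nucleation, in degrees.

    With ``sigma_deg`` set the axis is N(0, σ²) about the horizontal; without
    a constraint the filament grows in the direction from which the first
    actin approached the nucleating integrin.
    """
    if sigma_deg is not None:
        return float(rng.normal(0.0, sigma_deg))
    if approach_direction is None:
        raise ValueError("unconstrained orientation needs an approach direction")
    return float(approach_direction)


def build_rules(params: ModelParams) -> tuple:
    """(collision, timed, transfer) rule lists for one scenario."""
    structured = params.surface in ("pillars", "grooves")
    region_kind = {"pillars": "pillar", "grooves": "groove"}.get(params.surface)

    collision = [
        CollisionRule(
            "nucleation",
            ReactantPattern("integrin", attrs={"focal": "yes"},
                            sites={"fa": FREE}),
            ReactantPattern("actin", sites={"pointed": FREE, "barbed": FREE}),
            params.pNucleation,
            (Bind(0, "fa", 1, "pointed", orientation="sample"),)),
        CollisionRule(
            "elongation",
            ReactantPattern("actin", sites={"barbed": FREE, "pointed": OCC}),
            ReactantPattern("actin", sites={"pointed": FREE, "barbed": FREE}),
            params.pElongation,
            (Bind(0, "barbed", 1, "pointed"),)),
    ]
    if params.nArp > 0:
        for site in ("branchL", "branchR"):
            collision.append(CollisionRule(
                f"arp-attach-{site}",
                ReactantPattern("actin", sites={site: FREE, "pointed": OCC}),
                ReactantPattern("arp", sites={"mother": FREE, "daughter": FREE}),
                1.0,
                (Bind(0, site, 1, "mother"),)))
        collision.append(CollisionRule(
            "branch-start",
            ReactantPattern("arp", sites={"mother": OCC, "daughter": FREE}),
            ReactantPattern("actin", sites={"pointed": FREE, "barbed": FREE}),
            params.pNucleation,
            (Bind(0, "daughter", 1, "pointed"),)))
    collision.append(CollisionRule(
        "severing",
        ReactantPattern("cofilin", attrs={"active": "yes"}),
        ReactantPattern("actin", sites={"pointed": OCC}),
        params.pSevering,
        (UnbindAll(1),)))
    if params.pCofDeactAtInt > 0:
        collision.append(CollisionRule(
            "cofilin-deact-at-integrin",
            ReactantPattern("cofilin", attrs={"active": "yes"}),
            ReactantPattern("integrin", attrs={"focal": "yes"}),
            params.pCofDeactAtInt,
            (SetAttr(0, "active", "no"),)))
    if params.rCofRegAppearance > 0:
        collision.append(CollisionRule(
            "cofilin-deact-by-cofreg",
            ReactantPattern("cofreg"),
            ReactantPattern("cofilin", attrs={"active": "yes"}),
            1.0,
            (SetAttr(1, "active", "no"),)))

    timed = [
        TimedRule("fa-dissolution", 1, params.rFAdissolution,
                  ReactantPattern("integrin", attrs={"focal": "yes"},
                                  sites={"fa": FREE}),
                  (SetAttr(0, "focal", "no"),)),
        TimedRule("trunk-dissolution", 1, params.rFilDissolution,
                  ReactantPattern("actin", sites={"pointed": FREE, "barbed": OCC}),
                  (UnbindAll(0),)),
        TimedRule("cofilin-reactivation", 1, params.rCofilinReactivation,
                  ReactantPattern("cofilin", attrs={"active": "no"}),
                  (SetAttr(0, "active", "yes"),)),
    ]
    if params.nArp > 0:
        timed.append(TimedRule(
            "arp-dissolution", 1, params.rFilDissolution,
            ReactantPattern("arp", sites={"mother": FREE, "daughter": OCC}),
            (UnbindAll(0),)))
    if not (structured and params.instantFA):
        # FA formation by rate: inside structures, or anywhere on a planar
        # surface (the cell contacts a planar substrate with its whole body)
        timed.append(TimedRule(
            "fa-formation", 1, params.rIntComplexFormation,
            ReactantPattern("integrin", attrs={"focal": "no"},
                            region=region_kind if structured else None),
            (SetAttr(0, "focal", "yes"),)))
    if params.rCofRegAppearance > 0:
        timed.append(TimedRule(
            "cofreg-appearance", 1, params.rCofRegAppearance,
            ReactantPattern("integrin", attrs={"focal": "yes"}),
            (Create("cofreg", placement="adjacent"),)))
        timed.append(TimedRule(
            "cofreg-disappearance", 1, params.rCofRegDisappearance,
            ReactantPattern("cofreg"), (Destroy(0),)))

    transfer = []
    if structured:
        updates = {"focal": "yes"} if params.instantFA else {}
        transfer.append(TransferRule(
            "integrin-enter", "integrin", region_kind, "enter",
            params.pIntegrinEnter, attr_updates=updates,
            diffusion_factor=(params.slowdownFactor
                              if params.slowdownFactor != 1.0 else None)))
        if params.instantFA or params.slowdownFactor != 1.0:
            # instant FA stands for binding a surface-sensing agent that only
            # exists on the structure: an (unbound, hence mobile) integrin
            # that leaves the structure releases it again
            transfer.append(TransferRule(
                "integrin-leave", "integrin", region_kind, "leave", 1.0,
                attr_updates={"focal": "no"} if params.instantFA else {},
                diffusion_factor=(1.0 if params.slowdownFactor != 1.0
                                  else None)))
    return collision, timed, transfer


def build_model(params: ModelParams,
                engine_params: Optional[EngineParams] = None,
                rng=None) -> SimulationState:
    """Construct species, rules and an overlap-free initial state.

    All cofilin starts active, all integrin non-focal, no bonds; particles are
    placed uniformly at random without overlap.  The returned state carries a
    replenishment hook that tops free actin up to ``nActin`` each interval.
    """
    params.validate()
    species = make_species(params.constants)
    collision, timed, transfer = build_rules(params)
    sigma = params.sigmaAngle
    model = Model(
        species, collision, timed, transfer,
        orientation_sampler=lambda rng_, approach: sample_filament_orientation(
            sigma, rng_, approach))
    space = build_surface_layout(params.surface, params.pillar_width,
                                 params.pitch, params.n_grid)
    ep = engine_params or EngineParams(seed=params.seed)
    if rng is None:
        rng = np.random.default_rng(params.seed)
    state = SimulationState(
        model, space, ep, rng,
        replenish_hook=lambda s: replenish_free_actin(s, params.nActin))
    for species_name, count, attr in (
            ("actin", params.nActin, None),
            ("cofilin", params.nCofilin, {"active": "yes"}),
            ("integrin", params.nIntegrin, {"focal": "no"}),
            ("arp", params.nArp, None)):
        for _ in range(count):
            if state.create(species_name, attr=attr) is None:
                raise ModelConfigError(
                    f"cannot place {count} {species_name} without overlap; "
                    "domain too crowded")
    state.scenario = params  # type: ignore[attr-defined]
    return state


def free_actin_count(state: SimulationState) -> int:
    return sum(1 for p in state.particles.values()
               if p.species.name == "actin" and p.nb == 0)


def replenish_free_actin(state: SimulationState, target_count: int) -> int:
    """Top the free-actin pool back up to ``target_count``.

    Models recruitment from the cytosol: spawns the deficit at uniform random
    overlap-free positions; never removes actin.  Spawns that find no free
    spot are deferred to the next tick (counted in
    ``state.deferred_creates``).  Returns the number spawned.
    """
    deficit = target_count - free_actin_count(state)
    spawned = 0
    for _ in range(max(deficit, 0)):
        if state.create("actin") is not None:
            spawned += 1
    return spawned


def sever_and_dissolve(state: SimulationState, cofilin: Particle,
                       struck: Particle) -> None:
    """Severing hit: release every bond of the struck actin; the orphaned
    barbed-side trunk (pointed FREE, barbed OCC) then dissolves per the
    trunk-dissolution rule — instantly, cascading through the downstream
    chain and its branches, when its rate is infinite.  The integrin-side
    stump keeps its bonds and a FREE barbed end able to regrow.
    """
    if cofilin.attr.get("active") != "yes":
        raise ValueError("severing requires an active cofilin")
    if struck.bonds["pointed"] is None:
        raise ValueError("severing requires the struck actin's pointed end bound")
    state.unbind_all(struck)
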
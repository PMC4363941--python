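"""Domain types for species, particles, bonds and rules.

The simulator is rule-based: model behavior is expressed as collision-triggered
rules (second order, gated by a probability per collision), time-triggered rules
(zeroth/first order, exponential waiting times) and transfer rules (probability
of crossing a soft region boundary).  Rules are built in memory by the model
layer; there is no text-format rule language here.

Conventions
-----------
* Lengths in μm, time in arbitrary units (a.u.), angles in degrees.
* A particle's ``orient`` is the absolute bearing of its site-frame 0° axis;
  site angles are stored relative to that axis.  A bound particle always has a
  defined orientation; free monomers have ``orient is None``.
* A particle is mobile exactly when it has zero bonds — filaments never move.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Callable, Iterable, Mapping, Optional, Sequence

FREE = "FREE"
OCC = "OCC"


class ModelConfigError(ValueError):
    """Raised at model build time for ill-formed species/rule definitions."""


@dataclass(frozen=True)
class SpeciesDef:
    """Immutable description of a particle kind.

    Parameters
    ----------
    name : str
        Species identifier, unique within a model.
    radius : float
        Hard-disk radius in μm; strictly positive.
    diffusion : float
        Diffusion coefficient in μm²/a.u.; ``0`` means the species never moves.
    attributes : mapping
        Attribute name → finite tuple of admissible values.
    sites : sequence of (name, angle)
        Binding sites; angles in degrees in [0, 360), relative to the species'
        0° axis (the first site's angle need not be 0 but conventionally is).
    """

    name: str
    radius: float
    diffusion: float = 0.0
    attributes: Mapping[str, tuple] = field(default_factory=dict)
    sites: tuple = ()

    def __post_init__(self):
        if self.radius <= 0:
            raise ModelConfigError(f"species {self.name!r}: radius must be > 0")
        if self.diffusion < 0:
            raise ModelConfigError(f"species {self.name!r}: diffusion must be >= 0")
        names = [s for s, _ in self.sites]
        if len(names) != len(set(names)):
            raise ModelConfigError(f"species {self.name!r}: duplicate site names")
        for s, a in self.sites:
            if not (0.0 <= a < 360.0):
                raise ModelConfigError(
                    f"species {self.name!r}: site {s!r} angle {a} not in [0, 360)"
                )
        object.__setattr__(self, "attributes", dict(self.attributes))
        object.__setattr__(self, "sites", tuple(self.sites))

    @property
    def site_angles(self) -> dict:
        return dict(self.sites)

    @property
    def site_names(self) -> tuple:
        return tuple(s for s, _ in self.sites)

    @property
    def diameter(self) -> float:
        return 2.0 * self.radius


class Particle:
    """A positioned instance of a species: the unit of Brownian motion.

    Bonds are symmetric: if ``a.bonds[s] == (b.id, t)`` then
    ``b.bonds[t] == (a.id, s)``.  ``nb`` caches the number of occupied sites;
    mobility is ``nb == 0``.
    """

    __slots__ = (
        "id", "species", "x", "y", "attr", "bonds", "nb", "orient",
        "d_factor", "alive", "region", "move_tok", "clocks",
    )

    def __init__(self, pid: int, species: SpeciesDef, x: float, y: float,
                 attr: Optional[dict] = None):
        self.id = pid
        self.species = species
        self.x = x
        self.y = y
        self.attr = dict(attr) if attr else {}
        for k, vals in species.attributes.items():
            self.attr.setdefault(k, vals[0])
            if self.attr[k] not in vals:
                raise ModelConfigError(
                    f"particle of {species.name!r}: attribute {k}={self.attr[k]!r} "
                    f"not in {vals}")
        self.bonds = {s: None for s in species.site_names}
        self.nb = 0
        self.orient: Optional[float] = None
        self.d_factor = 1.0
        self.alive = True
        self.region: Optional[int] = None
        self.move_tok = 0
        self.clocks: dict = {}  # rule index -> (token, scheduled time)

    @property
    def mobile(self) -> bool:
        return self.alive and self.nb == 0

    @property
    def pos(self):
        return (self.x, self.y)

    def site_free(self, site: str) -> bool:
        return self.bonds[site] is None

    def __repr__(self):  # pragma: no cover - debugging aid
        return (f"<Particle {self.id} {self.species.name} "
                f"({self.x:.3f},{self.y:.3f}) bonds={self.nb}>")


@dataclass(frozen=True)
class ReactantPattern:
    """Left-hand-side pattern of a rule: species + attribute guards + site
    conditions (FREE/OCC/unconstrained) + optional region-kind context."""

    species: str
    attrs: Mapping[str, Any] = field(default_factory=dict)
    sites: Mapping[str, str] = field(default_factory=dict)
    region: Optional[str] = None  # region kind the particle's center must be in

    def __post_init__(self):
        for s, cond in self.sites.items():
            if cond not in (FREE, OCC):
                raise ModelConfigError(f"site condition must be FREE/OCC, got {cond!r}")
        object.__setattr__(self, "attrs", dict(self.attrs))
        object.__setattr__(self, "sites", dict(self.sites))

    def matches(self, p: Particle, space) -> bool:
        if p.species.name != self.species:
            return False
        for k, v in self.attrs.items():
            if p.attr.get(k) != v:
                return False
        for s, cond in self.sites.items():
            occupied = p.bonds[s] is not None
            if (cond == OCC) != occupied:
                return False
        if self.region is not None:
            if p.region is None:
                return False
            if space.regions[p.region].kind != self.region:
                return False
        return True


# ---------------------------------------------------------------------------
# Actions

@dataclass(frozen=True)
class Bind:
    """Bond ``reactants[anchor].anchor_site`` to ``reactants[child].child_site``.

    The child is relocated by angle-constrained placement relative to the
    anchor.  ``orientation='sample'`` asks the model's orientation sampler for a
    fresh filament axis (nucleation); ``None`` derives placement from the
    anchor's existing orientation.
    """

    anchor: int
    anchor_site: str
    child: int
    child_site: str
    orientation: Optional[str] = None


@dataclass(frozen=True)
class UnbindAll:
    target: int


@dataclass(frozen=True)
class SetAttr:
    target: int
    name: str
    value: Any


@dataclass(frozen=True)
class Destroy:
    target: int


@dataclass(frozen=True)
class Create:
    """Create a particle of ``species``.  Placement: ``'uniform'`` anywhere in
    the domain (overlap-free), ``'adjacent'`` at contact distance from
    reactant 0 in a uniform random direction."""

    species: str
    placement: str = "uniform"
    attr: Mapping[str, Any] = field(default_factory=dict)


Action = Any


@dataclass(frozen=True)
class CollisionRule:
    """Second-order, collision-triggered rule: fires with probability ``p``
    once two overlapping particles match the two patterns."""

    name: str
    a: ReactantPattern
    b: ReactantPattern
    probability: float
    actions: tuple

    def __post_init__(self):
        if not (0.0 <= self.probability <= 1.0):
            raise ModelConfigError(f"rule {self.name!r}: probability not in [0,1]")
        object.__setattr__(self, "actions", tuple(self.actions))


@dataclass(frozen=True)
class TimedRule:
    """Zeroth- or first-order rule with exponential waiting times.

    ``rate`` may be ``math.inf``: the rule then fires in the same timestep as
    the state change that made it applicable (used for filament trunk
    dissolution).
    """

    name: str
    order: int
    rate: float
    pattern: Optional[ReactantPattern] = None
    actions: tuple = ()

    def __post_init__(self):
        if self.order not in (0, 1):
            raise ModelConfigError(f"rule {self.name!r}: order must be 0 or 1")
        if self.rate < 0:
            raise ModelConfigError(f"rule {self.name!r}: rate must be >= 0")
        if self.order == 1 and self.pattern is None:
            raise ModelConfigError(f"rule {self.name!r}: order-1 rule needs a pattern")
        if self.order == 0:
            for act in self.actions:
                if not isinstance(act, Create):
                    raise ModelConfigError(
                        f"rule {self.name!r}: order-0 rules may only create entities")
        object.__setattr__(self, "actions", tuple(self.actions))


@dataclass(frozen=True)
class TransferRule:
    """Gate for a species' center crossing a soft region boundary."""

    name: str
    species: str
    region_kind: str
    direction: str  # 'enter' | 'leave'
    probability: float
    attr_updates: Mapping[str, Any] = field(default_factory=dict)
    diffusion_factor: Optional[float] = None  # sets the particle's d_factor

    def __post_init__(self):
        if self.direction not in ("enter", "leave"):
            raise ModelConfigError(f"rule {self.name!r}: direction enter/leave")
        if not (0.0 <= self.probability <= 1.0):
            raise ModelConfigError(f"rule {self.name!r}: probability not in [0,1]")
        object.__setattr__(self, "attr_updates", dict(self.attr_updates))


@dataclass
class Model:
    """Species plus rule sets; validated once at build time."""

    species: Mapping[str, SpeciesDef]
    collision_rules: Sequence[CollisionRule] = ()
    timed_rules: Sequence[TimedRule] = ()
    transfer_rules: Sequence[TransferRule] = ()
    orientation_sampler: Optional[Callable] = None  # (rng, approach_deg) -> deg

    def __post_init__(self):
        self.species = dict(self.species)
        self.collision_rules = list(self.collision_rules)
        self.timed_rules = list(self.timed_rules)
        self.transfer_rules = list(self.transfer_rules)
        self.validate()

    def _check_pattern(self, rname: str, pat: ReactantPattern):
        sp = self.species.get(pat.species)
        if sp is None:
            raise ModelConfigError(f"rule {rname!r}: unknown species {pat.species!r}")
        for a in pat.attrs:
            if a not in sp.attributes:
                raise ModelConfigError(
                    f"rule {rname!r}: species {sp.name!r} has no attribute {a!r}")
        for s in pat.sites:
            if s not in sp.site_names:
                raise ModelConfigError(
                    f"rule {rname!r}: species {sp.name!r} has no site {s!r}")

    def validate(self):
        for r in self.collision_rules:
            self._check_pattern(r.name, r.a)
            self._check_pattern(r.name, r.b)
            pats = (r.a, r.b)
            for act in r.actions:
                if isinstance(act, Bind):
                    for idx, site in ((act.anchor, act.anchor_site),
                                      (act.child, act.child_site)):
                        pat = pats[idx]
                        if pat.sites.get(site) != FREE:
                            raise ModelConfigError(
                                f"rule {r.name!r}: bind site {site!r} of reactant "
                                f"{idx} must carry a FREE condition")
        for r in self.timed_rules:
            if r.pattern is not None:
                self._check_pattern(r.name, r.pattern)
        for r in self.transfer_rules:
            if r.species not in self.species:
                raise ModelConfigError(
                    f"rule {r.name!r}: unknown species {r.species!r}")


# ---------------------------------------------------------------------------
# Matching

def match_collision_rule(rule: CollisionRule, a: Particle, b: Particle, space):
    """Try both pattern orders; return the (first, second) particle assignment
    satisfying the rule's patterns, or ``None``.

    Order-insensitive: ``match(rule, a, b)`` succeeds iff ``match(rule, b, a)``
    does, with the mirrored assignment.
    """
    if a is b:
        raise ValueError("collision requires two distinct particles")
    if rule.a.matches(a, space) and rule.b.matches(b, space):
        return (a, b)
    if rule.a.matches(b, space) and rule.b.matches(a, space):
        return (b, a)
    return None


def match_timed_rule(rule: TimedRule, p: Particle, space) -> bool:
    """Applicability of an order-1 rule to one particle."""
    if rule.order != 1:
        raise ValueError("match_timed_rule is for order-1 rules")
    return rule.pattern.matches(p, space)


def apply_actions(state, assignment: Sequence[Particle], actions: Iterable[Action],
                  moved: Optional[Particle] = None) -> bool:
    """Apply a matched rule's actions to the simulation state.

    Bind placements are computed and checked first; if any placement position
    overlaps a third particle the whole reaction is rolled back (nothing is
    committed) and ``False`` is returned.  Otherwise all actions are applied —
    bonds symmetrically, destroyed particles dropped from every index, created
    particles placed per their placement spec — and ``True`` is returned.
    Mobility flags and first-order clocks are maintained by the state methods.
    """
    binds = [act for act in actions if isinstance(act, Bind)]
    placements = []
    for act in binds:
        anchor = assignment[act.anchor]
        child = assignment[act.child]
        if anchor.bonds[act.anchor_site] is not None:
            raise RuntimeError(
                f"bind to occupied site {act.anchor_site!r} of particle {anchor.id}")
        if child.bonds[act.child_site] is not None:
            raise RuntimeError(
                f"bind to occupied site {act.child_site!r} of particle {child.id}")
        if act.orientation == "sample":
            approach = math.degrees(
                math.atan2(child.y - anchor.y, child.x - anchor.x)) % 360.0
            theta = state.model.orientation_sampler(state.rng, approach)
            anchor.orient = theta % 360.0
        place = state.plan_bind_placement(anchor, act.anchor_site,
                                          child, act.child_site)
        if place is None:
            return False
        placements.append((act, place))

    for act, (x, y, orient) in placements:
        anchor = assignment[act.anchor]
        child = assignment[act.child]
        state.move_particle(child, x, y, refresh=False)
        child.orient = orient
        state.bind(anchor, act.anchor_site, child, act.child_site)
    for act in actions:
        if isinstance(act, Bind):
            continue
        if isinstance(act, UnbindAll):
            state.unbind_all(assignment[act.target])
        elif isinstance(act, SetAttr):
            state.set_attr(assignment[act.target], act.name, act.value)
        elif isinstance(act, Destroy):
            state.destroy(assignment[act.target])
        elif isinstance(act, Create):
            near = assignment[0] if (act.placement == "adjacent" and assignment) else None
            state.create(act.species, attr=dict(act.attr), near=near)
        else:  # pragma: no cover - guarded by Model.validate
            raise ModelConfigError(f"unknown action {act!r}")
    return True
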
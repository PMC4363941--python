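"""Stochastic executor: Brownian move events with retry-on-collision,
first-order exponential clocks, transfer gating at soft region boundaries,
and collision-triggered reaction dispatch.

Time advances through a single event queue ordered by timestamp (ties broken
by insertion order).  Each mobile particle carries exactly one pending move
event; moving a particle consists of

1. proposing a displacement with per-axis components ~ N(0, 2·D·Δt), reflected
   at the domain walls;
2. if the center crosses a soft region boundary, evaluating transfer rules —
   a rejected crossing counts as a blocked attempt;
3. checking overlaps: on collision, the first matching collision rule is tried
   on the nearest overlapping partner (its probability rolled once); success
   applies the reaction and resolves residual overlap, failure undoes the
   attempt.  After ``max_attempts`` failures the particle keeps its old
   position; its next move event is scheduled regardless.

The per-particle time step is chosen so the per-axis step standard deviation
√(2·D·Δt) equals ``k`` times the smallest particle diameter in the model.
First-order reactions follow exponential waiting-time clocks that are redrawn
whenever a particle's applicability changes; an infinite rate fires within the
same timestep (used for filament trunk dissolution cascades).
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np

from .core import (Model, Particle, SpeciesDef, apply_actions,
                   match_collision_rule, match_timed_rule)
from .space import (EPS, SpaceModel, SpatialHash, find_overlaps, place_bound,
                    resolve_overlap)

# event kinds
_MOVE, _TIMED, _GLOBAL, _RECORD, _HOOK = 0, 1, 2, 3, 4


@dataclass
class EngineParams:
    """Executor tuning knobs.

    k
        Step-length factor: per-axis move standard deviation in units of the
        smallest particle diameter (1 = that diameter, the default).
    max_attempts
        Retries per move event before concluding there is no space to move.
    eps
        Overlap-resolution clearance (μm).
    seed
        RNG seed used when no generator is supplied.
    record_interval
        Observable recording cadence (a.u.).
    """

    k: float = 1.0
    max_attempts: int = 4
    eps: float = EPS
    seed: int = 0
    record_interval: float = 1.0

    def __post_init__(self):
        if self.k <= 0:
            raise ValueError("k must be > 0")
        if self.max_attempts < 1:
            raise ValueError("max_attempts must be >= 1")


def brownian_displacement(D: float, dt: float, rng) -> Tuple[float, float]:
    """One Brownian step: independent N(0, 2·D·dt) per axis."""
    if D < 0 or dt <= 0:
        raise ValueError("need D >= 0 and dt > 0")
    if D == 0.0:
        return (0.0, 0.0)
    sd = math.sqrt(2.0 * D * dt)
    d = rng.standard_normal(2)
    return (d[0] * sd, d[1] * sd)


def particle_timestep(species: SpeciesDef, params: EngineParams,
                      d_min: float) -> float:
    """Δt making the per-axis step sd equal k·d_min: Δt = (k·d_min)²/(2D)."""
    if species.diffusion <= 0:
        raise ValueError("particles with D = 0 receive no move events")
    return (params.k * d_min) ** 2 / (2.0 * species.diffusion)


class SimulationState:
    """Mutable world state plus the event queue.

    Invariants (see :meth:`audit`): bond symmetry; mobility == zero bonds;
    every live mobile particle with D > 0 has exactly one pending move event;
    no events pending for destroyed particles; no two non-bonded particles
    overlap by more than eps.
    """

    def __init__(self, model: Model, space: SpaceModel,
                 params: Optional[EngineParams] = None,
                 rng=None, replenish_hook: Optional[Callable] = None,
                 replenish_interval: float = 1.0):
        self.model = model
        self.space = space
        self.params = params or EngineParams()
        self.rng = rng if rng is not None else np.random.default_rng(self.params.seed)
        self.time = 0.0
        self.particles: Dict[int, Particle] = {}
        self._next_id = 0
        self._queue: List[tuple] = []
        self._norm_buf = np.empty(0)
        self._norm_ptr = 0
        self._seq = 0
        self._tok = 0
        self._inf_pending: List[Tuple[int, int]] = []
        self._draining = False
        self.replenish_hook = replenish_hook
        self.replenish_interval = replenish_interval
        self.rule_fire_log: List[Tuple[float, str]] = []
        self.collision_fires: Dict[str, int] = {}
        self.collision_pairs: set = set()  # distinct pairs with a rule match
        self.blocked_moves = 0
        self.collision_count = 0  # first-attempt collisions with a matching rule
        self.deferred_creates = 0
        self.created_counts: Dict[str, int] = {}
        self.destroyed_counts: Dict[str, int] = {}

        self.d_min = min(sp.diameter for sp in model.species.values())
        self.step_sd = self.params.k * self.d_min
        self.dt_species = {
            name: particle_timestep(sp, self.params, self.d_min)
            for name, sp in model.species.items() if sp.diffusion > 0
        }
        max_d = max(sp.diameter for sp in model.species.values())
        self.index = SpatialHash(max_d)

        self._timed1 = [(i, r) for i, r in enumerate(model.timed_rules)
                        if r.order == 1]
        for i, r in enumerate(model.timed_rules):
            if r.order == 0:
                if not math.isfinite(r.rate):
                    raise ValueError(f"order-0 rule {r.name!r} with infinite rate")
                if r.rate > 0:
                    self._push(self.time + self.rng.exponential(1.0 / r.rate),
                               _GLOBAL, 0, i, 0)

    # -- plumbing -----------------------------------------------------------

    def _push(self, t: float, kind: int, pid: int, aux: int, tok: int):
        heapq.heappush(self._queue, (t, self._seq, kind, pid, aux, tok))
        self._seq += 1

    def particle_dt(self, p: Particle) -> float:
        return self.dt_species[p.species.name] / p.d_factor

    def _normal2(self):
        # block-buffered standard normals for the move hot path
        ptr = self._norm_ptr
        buf = self._norm_buf
        if ptr + 2 > buf.shape[0]:
            buf = self._norm_buf = self.rng.standard_normal(4096)
            ptr = 0
        self._norm_ptr = ptr + 2
        return buf[ptr], buf[ptr + 1]

    def schedule_move(self, p: Particle):
        if p.species.diffusion <= 0:
            return
        p.move_tok += 1
        self._push(self.time + self.particle_dt(p), _MOVE, p.id, 0, p.move_tok)

    def cancel_moves(self, p: Particle):
        p.move_tok += 1

    # -- particle lifecycle -------------------------------------------------

    def add_particle(self, species: str, x: float, y: float,
                     attr: Optional[dict] = None) -> Particle:
        sp = self.model.species[species]
        p = Particle(self._next_id, sp, x, y, attr)
        self._next_id += 1
        p.region = self.space.region_of(x, y) if self.space.regions else None
        self.particles[p.id] = p
        self.created_counts[species] = self.created_counts.get(species, 0) + 1
        self.index.insert(p.id, x, y)
        if p.mobile:
            self.schedule_move(p)
        self.refresh_timed(p)
        self._drain()
        return p

    def destroy(self, p: Particle):
        if p.nb:
            self.unbind_all(p)
        p.alive = False
        p.clocks.clear()
        self.cancel_moves(p)
        self.index.remove(p.id, p.x, p.y)
        name = p.species.name
        self.destroyed_counts[name] = self.destroyed_counts.get(name, 0) + 1
        del self.particles[p.id]

    def create(self, species: str, attr: Optional[dict] = None,
               near: Optional[Particle] = None) -> Optional[Particle]:
        sp = self.model.species[species]
        pos = (self._position_near(sp, near) if near is not None
               else self.random_free_position(sp.radius))
        if pos is None:
            self.deferred_creates += 1
            return None
        return self.add_particle(species, pos[0], pos[1], attr)

    def _position_near(self, sp: SpeciesDef, near: Particle):
        d = sp.radius + near.species.radius + self.params.eps
        start = self.rng.uniform(0.0, 360.0)
        for i in range(24):
            ang = math.radians(start + i * 15.0)
            x, y = near.x + d * math.cos(ang), near.y + d * math.sin(ang)
            if not self.space.contains(x, y):
                continue
            if not self._occupied(x, y, sp.radius):
                return (x, y)
        return None

    def random_free_position(self, radius: float, tries: int = 100):
        for _ in range(tries):
            x = self.rng.uniform(radius, self.space.width - radius)
            y = self.rng.uniform(radius, self.space.height - radius)
            if not self._occupied(x, y, radius):
                return (x, y)
        return None

    def _occupied(self, x: float, y: float, radius: float) -> bool:
        for qid in self.index.neighborhood(x, y):
            q = self.particles[qid]
            if math.hypot(q.x - x, q.y - y) < radius + q.species.radius:
                return True
        return False

    def move_particle(self, p: Particle, x: float, y: float, refresh: bool = True):
        self.index.move(p.id, p.x, p.y, x, y)
        p.x, p.y = x, y
        if self.space.regions:
            nr = self.space.region_of(x, y)
            if nr != p.region:
                p.region = nr
                if refresh:
                    self.refresh_timed(p)
                    self._drain()

    # -- bonds / attributes -------------------------------------------------

    def plan_bind_placement(self, anchor: Particle, anchor_site: str,
                            child: Particle, child_site: str):
        """Placement for ``child`` bound to ``anchor``, or None if the target
        position overlaps a third particle (reaction must then roll back)."""
        x, y, orient = place_bound(anchor, anchor_site, child.species, child_site)
        if not self.space.contains(x, y):
            return None
        r = child.species.radius
        for qid in self.index.neighborhood(x, y):
            if qid in (anchor.id, child.id):
                continue
            q = self.particles[qid]
            if math.hypot(q.x - x, q.y - y) < r + q.species.radius - self.params.eps:
                return None
        return (x, y, orient)

    def bind(self, a: Particle, sa: str, b: Particle, sb: str):
        if a.bonds[sa] is not None or b.bonds[sb] is not None:
            raise RuntimeError("bind to occupied site")
        a.bonds[sa] = (b.id, sb)
        b.bonds[sb] = (a.id, sa)
        for p in (a, b):
            p.nb += 1
            if p.nb == 1:
                self.cancel_moves(p)  # bound => immobile
        self.refresh_timed(a)
        self.refresh_timed(b)
        self._drain()

    def unbind_all(self, p: Particle):
        """Release every bond of ``p`` symmetrically; freed particles diffuse
        again from their current positions."""
        partners = []
        for site, bond in p.bonds.items():
            if bond is None:
                continue
            q = self.particles[bond[0]]
            q.bonds[bond[1]] = None
            q.nb -= 1
            p.bonds[site] = None
            p.nb -= 1
            partners.append(q)
        p.orient = None
        for q in partners + [p]:
            if q.alive and q.nb == 0:
                q.orient = None
                self.schedule_move(q)
            self.refresh_timed(q)
        self._drain()

    def set_attr(self, p: Particle, name: str, value):
        p.attr[name] = value
        self.refresh_timed(p)
        self._drain()

    # -- first-order clocks -------------------------------------------------

    def refresh_timed(self, p: Particle):
        """Reconcile ``p``'s exponential clocks with its current applicability.

        Clocks are (re)drawn only when applicability changes; an applicable
        infinite-rate rule is queued to fire within the same timestep.
        """
        if not p.alive:
            p.clocks.clear()
            return
        for ridx, rule in self._timed1:
            app = match_timed_rule(rule, p, self.space)
            if math.isinf(rule.rate):
                if app:
                    self._inf_pending.append((p.id, ridx))
                continue
            has = ridx in p.clocks
            if app and not has and rule.rate > 0:
                self._tok += 1
                p.clocks[ridx] = self._tok
                self._push(self.time + self.rng.exponential(1.0 / rule.rate),
                           _TIMED, p.id, ridx, self._tok)
            elif not app and has:
                del p.clocks[ridx]

    def _drain(self):
        """Fire pending infinite-rate rules until quiescent (same timestep)."""
        if self._draining:
            return
        self._draining = True
        try:
            while self._inf_pending:
                pid, ridx = self._inf_pending.pop(0)
                p = self.particles.get(pid)
                if p is None or not p.alive:
                    continue
                rule = self.model.timed_rules[ridx]
                if match_timed_rule(rule, p, self.space):
                    self.rule_fire_log.append((self.time, rule.name))
                    apply_actions(self, (p,), rule.actions)
        finally:
            self._draining = False

    # -- moves --------------------------------------------------------------

    def attempt_move(self, p: Particle) -> bool:
        """One move event for ``p``; returns True if the position changed or a
        reaction fired."""
        sd = self.step_sd
        x0, y0, r0 = p.x, p.y, p.region
        f0 = p.d_factor
        rules = self.model.collision_rules
        for attempt in range(self.params.max_attempts):
            gx, gy = self._normal2()
            nx, ny = self.space.reflect(x0 + gx * sd, y0 + gy * sd)
            nr = self.space.region_of(nx, ny) if self.space.regions else None
            applied_tr = ()
            if nr != r0 and self.model.transfer_rules:
                ok, applied_tr = self._eval_transfer(p, r0, nr)
                if not ok:
                    continue  # rejected crossing: blocked attempt
            # tentative commit so patterns see the post-move configuration
            self.index.move(p.id, x0, y0, nx, ny)
            p.x, p.y, p.region = nx, ny, nr
            saved_attr = {}
            for tr in applied_tr:
                for k, v in tr.attr_updates.items():
                    saved_attr.setdefault(k, p.attr.get(k))
                    p.attr[k] = v
                if tr.diffusion_factor is not None:
                    p.d_factor = tr.diffusion_factor
            overlaps = find_overlaps(p, nx, ny, self.particles, self.index)
            if not overlaps:
                if nr != r0 or saved_attr or p.d_factor != f0:
                    self.refresh_timed(p)
                    self._drain()
                return True
            q = overlaps[0][1]
            reacted = False
            for rule in rules:
                asg = match_collision_rule(rule, p, q, self.space)
                if asg is None:
                    continue
                if attempt == 0:
                    self.collision_count += 1
                    self.collision_pairs.add(
                        (p.id, q.id) if p.id < q.id else (q.id, p.id))
                if rule.probability >= 1.0 or self.rng.random() < rule.probability:
                    reacted = apply_actions(self, asg, rule.actions, moved=p)
                    if reacted:
                        self.collision_fires[rule.name] = (
                            self.collision_fires.get(rule.name, 0) + 1)
                break  # first matching rule only; its gate is rolled once
            if reacted:
                if nr != r0 or saved_attr or p.d_factor != f0:
                    self.refresh_timed(p)
                self._drain()
                self._resolve_residual(p, q)
                return True
            # undo the attempt
            for k, v in saved_attr.items():
                p.attr[k] = v
            p.d_factor = f0
            self.index.move(p.id, nx, ny, x0, y0)
            p.x, p.y, p.region = x0, y0, r0
        self.blocked_moves += 1  # no space for the particle to move
        return False

    def _eval_transfer(self, p: Particle, r_old, r_new):
        """Gate a boundary crossing; returns (accepted, rules to apply)."""
        applied = []
        for region_idx, direction in ((r_old, "leave"), (r_new, "enter")):
            if region_idx is None:
                continue
            kind = self.space.regions[region_idx].kind
            for tr in self.model.transfer_rules:
                if (tr.species == p.species.name and tr.region_kind == kind
                        and tr.direction == direction):
                    if tr.probability < 1.0 and self.rng.random() >= tr.probability:
                        return False, ()
                    applied.append(tr)
                    break  # first matching rule per crossing
        return True, tuple(applied)

    def _resolve_residual(self, p: Particle, q: Particle):
        """After a reaction, nudge the moved particle clear of any remaining
        overlap (blocker first, then any third parties)."""
        if not p.alive or p.nb > 0:
            return
        if q.alive and math.hypot(p.x - q.x, p.y - q.y) < (
                p.species.radius + q.species.radius):
            x, y = resolve_overlap(p, q, self.space, self.rng, self.params.eps)
            self.move_particle(p, x, y)
        for _ in range(8):
            overlaps = find_overlaps(p, p.x, p.y, self.particles, self.index)
            if not overlaps:
                return
            x, y = resolve_overlap(p, overlaps[0][1], self.space, self.rng,
                                   self.params.eps)
            self.move_particle(p, x, y)
        # crowded neighborhood: fall back to a nearby free spot
        r = p.species.radius
        for scale in (2.0, 4.0, 8.0):
            for _ in range(16):
                ang = self.rng.uniform(0.0, 2.0 * math.pi)
                rad = self.rng.uniform(r, scale * self.step_sd + 2 * r)
                x, y = self.space.reflect(p.x + rad * math.cos(ang),
                                          p.y + rad * math.sin(ang))
                if not self._occupied_excluding(x, y, r, p.id):
                    self.move_particle(p, x, y)
                    return

    def _occupied_excluding(self, x, y, radius, pid) -> bool:
        for qid in self.index.neighborhood(x, y):
            if qid == pid:
                continue
            q = self.particles[qid]
            if math.hypot(q.x - x, q.y - y) < radius + q.species.radius:
                return True
        return False

    # -- main loop ----------------------------------------------------------

    def run(self, t_end: float, recorders: Sequence[Callable] = ()):
        """Process events in timestamp order until ``t_end``.

        Identical (model, params, seed) yield identical trajectories.  An
        empty queue before ``t_end`` simply advances time (quiescent system).
        """
        if t_end < self.time:
            raise ValueError("t_end before current time")
        for rec in recorders:
            rec(self)
        if recorders:
            self._push(self.time + self.params.record_interval, _RECORD, 0, 0, 0)
        if self.replenish_hook is not None:
            self._push(self.time + self.replenish_interval, _HOOK, 0, 0, 0)
        q = self._queue
        while q and q[0][0] <= t_end:
            t, _, kind, pid, aux, tok = heapq.heappop(q)
            self.time = t
            if kind == _MOVE:
                p = self.particles.get(pid)
                if p is None or not p.alive or p.nb > 0 or p.move_tok != tok:
                    continue  # stale event
                self.attempt_move(p)
                if p.alive and p.nb == 0:
                    self.schedule_move(p)
            elif kind == _TIMED:
                p = self.particles.get(pid)
                if p is None or not p.alive or p.clocks.get(aux) != tok:
                    continue
                del p.clocks[aux]
                rule = self.model.timed_rules[aux]
                if match_timed_rule(rule, p, self.space):
                    self.rule_fire_log.append((t, rule.name))
                    apply_actions(self, (p,), rule.actions)
                    self._drain()
                if p.alive:
                    self.refresh_timed(p)
                    self._drain()
            elif kind == _GLOBAL:
                rule = self.model.timed_rules[aux]
                self.rule_fire_log.append((t, rule.name))
                apply_actions(self, (), rule.actions)
                self._drain()
                self._push(t + self.rng.exponential(1.0 / rule.rate),
                           _GLOBAL, 0, aux, 0)
            elif kind == _RECORD:
                for rec in recorders:
                    rec(self)
                self._push(t + self.params.record_interval, _RECORD, 0, 0, 0)
            elif kind == _HOOK:
                self.replenish_hook(self)
                self._push(t + self.replenish_interval, _HOOK, 0, 0, 0)
        self.time = t_end
        for rec in recorders:
            rec(self)
        return self

    # -- audits -------------------------------------------------------------

    def species_counts(self) -> Dict[str, int]:
        out: Dict[str, int] = {}
        for p in self.particles.values():
            out[p.species.name] = out.get(p.species.name, 0) + 1
        return out

    def bond_count(self) -> int:
        return sum(p.nb for p in self.particles.values()) // 2

    def audit(self, overlap_tol: Optional[float] = None):
        """Full-state consistency check; raises AssertionError on violation."""
        tol = self.params.eps if overlap_tol is None else overlap_tol
        plist = list(self.particles.values())
        for p in plist:
            assert p.alive
            assert self.space.contains(p.x, p.y), f"particle {p.id} outside domain"
            nb = 0
            for site, bond in p.bonds.items():
                if bond is None:
                    continue
                nb += 1
                q = self.particles.get(bond[0])
                assert q is not None, f"dangling bond on {p.id}"
                assert q.bonds[bond[1]] == (p.id, site), "bond asymmetry"
            assert nb == p.nb, f"bond count cache wrong on {p.id}"
            assert p.mobile == (p.nb == 0)
        for i, p in enumerate(plist):
            partners = {b[0] for b in p.bonds.values() if b is not None}
            for q in plist[i + 1:]:
                if q.id in partners:
                    continue
                d = math.hypot(p.x - q.x, p.y - q.y)
                limit = p.species.radius + q.species.radius
                assert d >= limit - tol, (
                    f"non-bonded overlap {p.id}/{q.id}: {limit - d:.3g}")
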
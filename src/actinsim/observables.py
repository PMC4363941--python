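"""Filament-complex extraction and summary statistics.

Observables mirror what filament-tracing software reports on micrographs,
computed here on the simulated bond graph: average/maximum filament length,
axial orientation dispersion (0% = one preferred orientation, 100% = uniform),
the active-cofilin fractions on vs. between surface structures, and state
snapshots.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import networkx as nx
import numpy as np
import pandas as pd


@dataclass(frozen=True)
class FilamentComplex:
    """One connected component of the bond graph (a tree), rooted at its
    integrin when it has exactly one.

    ``main_chain`` is the longest simple root-to-leaf path, ``branches`` the
    recursively extracted off-trunk segments; both are tuples of particle
    ids, and ``centers``/``species`` capture a position/species snapshot at
    extraction time.
    """

    members: frozenset
    root: Optional[int]
    main_chain: tuple
    branches: tuple
    centers: Dict[int, Tuple[float, float]] = field(repr=False, default_factory=dict)
    species: Dict[int, str] = field(repr=False, default_factory=dict)

    @property
    def n_actin(self) -> int:
        return sum(1 for m in self.members if self.species[m] == "actin")

    @property
    def main_chain_actins(self) -> int:
        return sum(1 for m in self.main_chain if self.species[m] == "actin")

    def segments(self) -> List[tuple]:
        return [self.main_chain, *self.branches]


class BondGraphError(RuntimeError):
    pass


def _longest_path_from(tree: nx.Graph, root, weight) -> list:
    """Root-to-leaf path maximizing summed node weight (actin count), with
    path length as the deterministic tie-break."""
    best, best_key = [root], (weight[root], 1)
    stack = [(root, None, [root], weight[root])]
    while stack:
        node, parent, path, w = stack.pop()
        extended = False
        for nb in tree.neighbors(node):
            if nb != parent:
                stack.append((nb, node, path + [nb], w + weight[nb]))
                extended = True
        if not extended and (w, len(path)) > best_key:
            best, best_key = path, (w, len(path))
    return best


def _decompose(tree: nx.Graph, root, weight) -> Tuple[tuple, tuple]:
    """Trunk = actin-longest root-to-leaf path; off-trunk subtrees are
    decomposed recursively into their own (trunk, branches)."""
    trunk = _longest_path_from(tree, root, weight)
    on_trunk = set(trunk)
    branches: List[tuple] = []
    for i, node in enumerate(trunk):
        prev = trunk[i - 1] if i else None
        nxt = trunk[i + 1] if i + 1 < len(trunk) else None
        for nb in tree.neighbors(node):
            if nb in (prev, nxt) or nb in on_trunk:
                continue
            sub_nodes = _subtree_nodes(tree, nb, node)
            sub = tree.subgraph(sub_nodes)
            t, b = _decompose(sub, nb, weight)
            branches.append(t)
            branches.extend(b)
    return tuple(trunk), tuple(branches)


def _subtree_nodes(tree: nx.Graph, start, blocked) -> set:
    seen = {start}
    stack = [start]
    while stack:
        node = stack.pop()
        for nb in tree.neighbors(node):
            if nb != blocked and nb not in seen:
                seen.add(nb)
                stack.append(nb)
    return seen


def extract_filament_complexes(state) -> List[FilamentComplex]:
    """Connected components of the bond graph with at least one bond.

    Free particles are excluded.  A cyclic component violates the filament
    tree invariant and aborts with a diagnostic.
    """
    g = nx.Graph()
    for p in state.particles.values():
        if p.nb == 0:
            continue
        g.add_node(p.id)
        for bond in p.bonds.values():
            if bond is not None:
                g.add_edge(p.id, bond[0])
    out = []
    for comp in nx.connected_components(g):
        sub = g.subgraph(comp)
        if sub.number_of_edges() != len(comp) - 1:
            raise BondGraphError(f"cyclic bond graph in component {sorted(comp)}")
        species = {m: state.particles[m].species.name for m in comp}
        integrins = [m for m in comp if species[m] == "integrin"]
        if len(integrins) > 1:
            raise BondGraphError(
                f"component {sorted(comp)} contains {len(integrins)} integrins")
        root = integrins[0] if integrins else min(comp)
        weight = {m: 1 if species[m] == "actin" else 0 for m in comp}
        trunk, branches = _decompose(sub, root, weight)
        centers = {m: (state.particles[m].x, state.particles[m].y) for m in comp}
        out.append(FilamentComplex(
            members=frozenset(comp),
            root=integrins[0] if integrins else None,
            main_chain=trunk, branches=branches,
            centers=centers, species=species))
    out.sort(key=lambda c: min(c.members))
    return out


# ---------------------------------------------------------------------------
# Length statistics

@dataclass(frozen=True)
class LengthStats:
    """Filament length summary; averages are None when no filament exists."""

    n_complexes: int
    avg_main_particles: Optional[float]
    max_main_particles: Optional[int]
    avg_main_um: Optional[float]
    max_main_um: Optional[float]
    total_sizes: tuple  # actin count per complex


def length_stats(complexes: Sequence[FilamentComplex],
                 actin_diameter: float) -> LengthStats:
    """Averages/maxima of main-chain actin counts; μm = count × diameter."""
    if actin_diameter <= 0:
        raise ValueError("actin_diameter must be > 0")
    if not complexes:
        return LengthStats(0, None, None, None, None, ())
    lengths = [c.main_chain_actins for c in complexes]
    avg = float(np.mean(lengths))
    mx = int(max(lengths))
    return LengthStats(
        n_complexes=len(complexes),
        avg_main_particles=avg,
        max_main_particles=mx,
        avg_main_um=avg * actin_diameter,
        max_main_um=mx * actin_diameter,
        total_sizes=tuple(c.n_actin for c in complexes))


# ---------------------------------------------------------------------------
# Orientation dispersion

def principal_axis_deg(points: np.ndarray) -> float:
    """Fitted principal axis of a point cloud, as an axial angle in [0, 180)."""
    pts = np.asarray(points, dtype=float)
    pts = pts - pts.mean(axis=0)
    sxx = float(np.sum(pts[:, 0] ** 2))
    syy = float(np.sum(pts[:, 1] ** 2))
    sxy = float(np.sum(pts[:, 0] * pts[:, 1]))
    return math.degrees(0.5 * math.atan2(2.0 * sxy, sxx - syy)) % 180.0


def axial_dispersion(angles_deg, weights=None) -> float:
    """Normalized angular deviation of axial data, in percent.

    Doubles the angles (axial symmetry: θ and θ+180° are the same
    orientation), computes the weighted mean resultant length R̄ and returns
    the angular deviation √(2(1−R̄)) normalized by its maximum √2, i.e.,
    100·√(1−R̄): 0% for perfectly aligned segments, → 100% for orientations
    uniform on [0°, 180°).
    """
    a = np.radians(np.asarray(angles_deg, dtype=float)) * 2.0
    if a.size == 0:
        raise ValueError("need at least one orientation")
    w = np.ones_like(a) if weights is None else np.asarray(weights, dtype=float)
    wsum = w.sum()
    if wsum <= 0:
        raise ValueError("total weight must be positive")
    rbar = float(np.hypot((w * np.cos(a)).sum(), (w * np.sin(a)).sum()) / wsum)
    rbar = min(rbar, 1.0)
    return 100.0 * math.sqrt(1.0 - rbar)


def orientation_dispersion(complexes: Sequence[FilamentComplex]
                           ) -> Optional[float]:
    """Length-weighted axial dispersion over all chain segments.

    Each main chain and each branch chain contributes one axial segment whose
    orientation is the fitted principal axis of its member centers and whose
    weight is its particle count.  None when no segment has ≥ 2 particles.
    """
    angles, weights = [], []
    for c in complexes:
        for seg in c.segments():
            if len(seg) < 2:
                continue
            pts = np.array([c.centers[m] for m in seg])
            angles.append(principal_axis_deg(pts))
            weights.append(float(len(seg)))
    if not angles:
        return None
    return axial_dispersion(angles, weights)


# ---------------------------------------------------------------------------
# Regional cofilin statistics

@dataclass(frozen=True)
class RegionCofilinStats:
    """Active/total cofilin split by region class (on vs. between structures).

    ``fraction_on_structures``/``fraction_between`` are active/total per
    class; ``share_on_structures`` is the share of all cofilin located on
    structures.  ``planar`` flags a layout without regions, where the
    on-structure class is empty and "between" covers the whole domain.
    """

    on_active: int
    on_total: int
    between_active: int
    between_total: int
    planar: bool = False

    @property
    def fraction_on_structures(self) -> Optional[float]:
        return self.on_active / self.on_total if self.on_total else None

    @property
    def fraction_between(self) -> Optional[float]:
        return self.between_active / self.between_total if self.between_total else None

    @property
    def share_on_structures(self) -> Optional[float]:
        total = self.on_total + self.between_total
        return self.on_total / total if total else None


def cofilin_region_fractions(state) -> RegionCofilinStats:
    """Classify each cofilin by the region containing its center."""
    on_a = on_t = btw_a = btw_t = 0
    has_regions = bool(state.space.regions)
    for p in state.particles.values():
        if p.species.name != "cofilin":
            continue
        active = p.attr.get("active") == "yes"
        inside = p.region is not None
        if inside:
            on_t += 1
            on_a += active
        else:
            btw_t += 1
            btw_a += active
    return RegionCofilinStats(on_a, on_t, btw_a, btw_t, planar=not has_regions)


# ---------------------------------------------------------------------------
# Snapshots

_REGION_EDGE = "green"


def _particle_style(p) -> Tuple[str, float]:
    """Snapshot color scheme; returns (color, zorder)."""
    name = p.species.name
    if name == "actin":
        if p.nb == 0:
            return ("#2b2bb5", 2)  # free actin: purple/dark blue
        pointed = p.bonds["pointed"] is not None
        barbed = p.bonds["barbed"] is not None
        if pointed and not barbed:
            return ("#66ccee", 3)  # barbed-tip actin: light blue
        return ("magenta", 3)      # interior filament actin
    if name == "integrin":
        if p.nb > 0:
            return ("red", 4)          # filament-root integrin
        return ("#1a6b1a", 2) if p.region is not None else ("#8a5a2b", 2)
    if name == "cofilin":
        return ("#ff9933", 1) if p.attr.get("active") == "yes" else ("#bbbbbb", 1)
    if name == "cofreg":
        return ("#cccc00", 1)
    return ("#555555", 1)  # arp and anything else


def render_snapshot(state, path) -> None:
    """PNG of the current state: colored disks at true scale, surface-region
    outlines as green dashed rectangles."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    from matplotlib.patches import Circle, Rectangle

    fig, ax = plt.subplots(figsize=(6, 6))
    ax.set_xlim(0, state.space.width)
    ax.set_ylim(0, state.space.height)
    ax.set_aspect("equal")
    for r in state.space.regions:
        ax.add_patch(Rectangle((r.x0, r.y0), r.x1 - r.x0, r.y1 - r.y0,
                               fill=False, edgecolor=_REGION_EDGE,
                               linestyle="--", linewidth=1.2))
    for p in state.particles.values():
        color, z = _particle_style(p)
        ax.add_patch(Circle((p.x, p.y), p.species.radius, facecolor=color,
                            edgecolor="none", zorder=z))
    ax.set_xlabel("x (μm)")
    ax.set_ylabel("y (μm)")
    ax.set_title(f"t = {state.time:.1f} a.u.")
    fig.savefig(path, dpi=150)
    plt.close(fig)


# ---------------------------------------------------------------------------
# Time-series recorders (CSV-backed, per the simulator's output contract)

class AmountRecorder:
    """Per-time-point entity amounts: species counts, active cofilin, focal
    integrins, free vs. bound actin, CofReg count, bonds."""

    def __init__(self):
        self.rows: List[dict] = []

    def __call__(self, state):
        counts = state.species_counts()
        active = sum(1 for p in state.particles.values()
                     if p.species.name == "cofilin" and p.attr.get("active") == "yes")
        focal = sum(1 for p in state.particles.values()
                    if p.species.name == "integrin" and p.attr.get("focal") == "yes")
        free_actin = sum(1 for p in state.particles.values()
                         if p.species.name == "actin" and p.nb == 0)
        rcs = cofilin_region_fractions(state)
        self.rows.append({
            "time": state.time,
            "actin": counts.get("actin", 0),
            "free_actin": free_actin,
            "cofilin": counts.get("cofilin", 0),
            "active_cofilin": active,
            "integrin": counts.get("integrin", 0),
            "focal_integrin": focal,
            "cofreg": counts.get("cofreg", 0),
            "arp": counts.get("arp", 0),
            "bonds": state.bond_count(),
            "cofilin_on_structures": rcs.on_total,
            "active_cofilin_on_structures": rcs.on_active,
            "cofilin_between": rcs.between_total,
            "active_cofilin_between": rcs.between_active,
        })

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)


class ComplexSizeRecorder:
    """Per-time-point complex sizes (one row per filament complex)."""

    def __init__(self):
        self.rows: List[dict] = []

    def __call__(self, state):
        for i, c in enumerate(extract_filament_complexes(state)):
            self.rows.append({
                "time": state.time,
                "complex": i,
                "main_chain_actins": c.main_chain_actins,
                "total_actins": c.n_actin,
                "members": len(c.members),
            })

    def to_frame(self) -> pd.DataFrame:
        cols = ["time", "complex", "main_chain_actins", "total_actins", "members"]
        return pd.DataFrame(self.rows, columns=cols)
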
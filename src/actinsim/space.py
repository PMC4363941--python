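"""2D domain geometry: soft-boundary surface regions, collision queries,
overlap resolution and angle-constrained placement of bound particles.

The domain is a rectangle with reflective walls.  Surface structures (pillar
tops, grooves) are axis-aligned rectangles with *soft* boundaries: particles
may straddle the border; membership is decided by the particle's center, and
boundary points belong to the region (closed rectangles).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Tuple

EPS = 1e-6  # μm; overlap-resolution clearance and tie-breaking tolerance


class GeometryError(ValueError):
    pass


@dataclass(frozen=True)
class Region:
    id: int
    kind: str  # 'pillar' | 'groove'
    x0: float
    y0: float
    x1: float
    y1: float

    def contains(self, x: float, y: float) -> bool:
        return self.x0 <= x <= self.x1 and self.y0 <= y <= self.y1

    @property
    def area(self) -> float:
        return (self.x1 - self.x0) * (self.y1 - self.y0)


class SpaceModel:
    """Rectangular domain plus disjoint soft-boundary regions."""

    def __init__(self, width: float, height: float,
                 regions: Sequence[Region] = ()):
        if width <= 0 or height <= 0:
            raise GeometryError("domain area must be positive")
        self.width = float(width)
        self.height = float(height)
        self.regions: Tuple[Region, ...] = tuple(regions)
        for r in self.regions:
            if r.x0 < 0 or r.y0 < 0 or r.x1 > self.width or r.y1 > self.height:
                raise GeometryError(f"region {r.id} outside domain")
        for i, a in enumerate(self.regions):
            for b in self.regions[i + 1:]:
                if (a.x0 < b.x1 and b.x0 < a.x1 and a.y0 < b.y1 and b.y0 < a.y1):
                    raise GeometryError(f"regions {a.id} and {b.id} overlap")
        # flat bounds table for the hot region_of path
        self._bounds = [(r.x0, r.x1, r.y0, r.y1, r.id) for r in self.regions]

    @property
    def area(self) -> float:
        return self.width * self.height

    def contains(self, x: float, y: float) -> bool:
        return 0.0 <= x <= self.width and 0.0 <= y <= self.height

    def region_of(self, x: float, y: float) -> Optional[int]:
        """Id of the region whose closed rectangle contains (x, y), else None.

        Regions are disjoint in their interiors; a point on a shared outer
        boundary belongs to the first region in declaration order.
        """
        if not (0.0 <= x <= self.width and 0.0 <= y <= self.height):
            raise GeometryError(f"point ({x}, {y}) outside domain")
        for x0, x1, y0, y1, rid in self._bounds:
            if x0 <= x <= x1 and y0 <= y <= y1:
                return rid
        return None

    def region_kind(self, idx: Optional[int]) -> Optional[str]:
        return None if idx is None else self.regions[idx].kind

    def reflect(self, x: float, y: float) -> Tuple[float, float]:
        """Fold a proposed position back into the domain by wall reflection."""
        return (_fold(x, self.width), _fold(y, self.height))

    def region_area_fraction(self, kind: str = "pillar") -> float:
        """Exact share of the domain area covered by regions of ``kind``."""
        return sum(r.area for r in self.regions if r.kind == kind) / self.area


def _fold(v: float, w: float) -> float:
    # triangle-wave fold with period 2w implements specular reflection
    v = v % (2.0 * w)
    return 2.0 * w - v if v > w else v


def build_surface_layout(kind: str, pillar_width: float = 5.0,
                         pitch: float = 10.0, n: int = 3) -> SpaceModel:
    """Construct the simulated surface patch.

    planar
        Square domain (same side as the pillar layout would have), no regions.
    pillars
        n×n squares of side ``pillar_width`` at center spacing ``pitch``,
        centered in a square domain of side ``n*pitch - (pitch-pillar_width)/2``
        — the unique square that gives the default 3×3/5 μm/10 μm layout a
        pillar area share of 225/756.25 = 29.7%.
    grooves
        n full-height vertical stripes of width ``pillar_width`` at spacing
        ``pitch`` in the same domain.
    """
    if n < 1:
        raise GeometryError("n must be >= 1")
    if pillar_width > pitch:
        raise GeometryError("pillar_width must not exceed pitch")
    gap = pitch - pillar_width
    side = n * pitch - gap / 2.0
    if kind == "planar":
        return SpaceModel(side, side, ())
    # pillar/stripe centers, symmetric about the domain center
    first_center = (side - (n - 1) * pitch) / 2.0
    centers = [first_center + i * pitch for i in range(n)]
    half = pillar_width / 2.0
    regions: List[Region] = []
    if kind == "pillars":
        rid = 0
        for cy in centers:
            for cx in centers:
                regions.append(Region(rid, "pillar",
                                      cx - half, cy - half, cx + half, cy + half))
                rid += 1
    elif kind == "grooves":
        for rid, cx in enumerate(centers):
            regions.append(Region(rid, "groove", cx - half, 0.0, cx + half, side))
    else:
        raise GeometryError(f"unknown surface kind {kind!r}")
    return SpaceModel(side, side, regions)


# ---------------------------------------------------------------------------
# Collision queries

class SpatialHash:
    """Uniform-grid index over particle centers.

    Cell size is at least the largest particle diameter, so any two
    overlapping particles sit in the same or adjacent cells and a 3×3
    neighborhood query is exhaustive.
    """

    def __init__(self, cell: float):
        if cell <= 0:
            raise GeometryError("cell size must be positive")
        self.cell = cell
        self._cells: dict = {}

    def _key(self, x: float, y: float) -> Tuple[int, int]:
        return (int(x // self.cell), int(y // self.cell))

    def insert(self, pid: int, x: float, y: float):
        self._cells.setdefault(self._key(x, y), set()).add(pid)

    def remove(self, pid: int, x: float, y: float):
        k = self._key(x, y)
        cell = self._cells.get(k)
        if cell is not None:
            cell.discard(pid)
            if not cell:
                del self._cells[k]

    def move(self, pid: int, ox: float, oy: float, nx: float, ny: float):
        ok, nk = self._key(ox, oy), self._key(nx, ny)
        if ok != nk:
            self.remove(pid, ox, oy)
            self.insert(pid, nx, ny)

    def neighborhood(self, x: float, y: float) -> Iterable[int]:
        i, j = self._key(x, y)
        cells = self._cells
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                got = cells.get((i + di, j + dj))
                if got:
                    yield from got


def find_overlaps(p, x: float, y: float, particles: dict,
                  index: SpatialHash) -> List[Tuple[float, object]]:
    """All particles overlapping a disk of ``p.species.radius`` at (x, y).

    Overlap is strict (``dist < r1 + r2``; tangency is not a collision).  ``p``
    itself and its bonded partners are excluded — bonded contact is not a
    collision.  Returns (distance, particle) pairs sorted nearest-first.
    """
    rp = p.species.radius
    partners = {b[0] for b in p.bonds.values() if b is not None}
    out = []
    pid = p.id
    cells = index._cells
    c = index.cell
    i, j = int(x // c), int(y // c)
    hypot = math.hypot
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            got = cells.get((i + di, j + dj))
            if not got:
                continue
            for qid in got:
                if qid == pid or qid in partners:
                    continue
                q = particles[qid]
                d = hypot(q.x - x, q.y - y)
                if d < rp + q.species.radius:
                    out.append((d, q))
    if len(out) > 1:
        out.sort(key=lambda t: (t[0], t[1].id))
    return out


def resolve_overlap(moved, blocker, space: SpaceModel, rng,
                    eps: float = EPS) -> Tuple[float, float]:
    """Position for ``moved`` just clear of ``blocker``.

    The moved particle is pushed along the line of centers away from the
    blocker to distance r1+r2+eps; coincident centers get a uniform random
    direction.  A push past a wall is reflected back inside and re-checked.
    """
    target = moved.species.radius + blocker.species.radius + eps
    dx, dy = moved.x - blocker.x, moved.y - blocker.y
    d = math.hypot(dx, dy)
    if d < 1e-12:
        ang = rng.uniform(0.0, 2.0 * math.pi)
        dx, dy, d = math.cos(ang), math.sin(ang), 1.0
    ux, uy = dx / d, dy / d
    candidates = [(ux, uy), (-ux, -uy)]
    last = (moved.x, moved.y)
    for _ in range(16):
        for cx, cy in candidates:
            x, y = space.reflect(blocker.x + cx * target, blocker.y + cy * target)
            last = (x, y)
            if math.hypot(x - blocker.x, y - blocker.y) >= target - eps * 0.5:
                return x, y
        ang = rng.uniform(0.0, 2.0 * math.pi)  # corner: try fresh directions
        candidates = [(math.cos(ang), math.sin(ang))]
    return last


def place_bound(anchor, anchor_site: str, child_species, child_site: str
                ) -> Tuple[float, float, float]:
    """Angle-constrained placement of a new binding partner.

    The child's center is put at contact distance from the anchor in the
    direction ``anchor.orient + site angle``, independent of where the child
    collided from; the returned orientation makes the child's binding site
    point back at the anchor.
    """
    if anchor.orient is None:
        raise GeometryError(
            f"anchor particle {anchor.id} has no orientation for placement")
    bearing = (anchor.orient + anchor.species.site_angles[anchor_site]) % 360.0
    d = anchor.species.radius + child_species.radius
    rad = math.radians(bearing)
    x = anchor.x + d * math.cos(rad)
    y = anchor.y + d * math.sin(rad)
    child_orient = (bearing + 180.0 - child_species.site_angles[child_site]) % 360.0
    return x, y, child_orient
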
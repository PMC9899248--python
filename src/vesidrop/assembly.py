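"""Initial-configuration builders: vesicles, droplets, solvent fill.

The builders do exact bead bookkeeping: every built system satisfies

    total beads = 15 * (N_ol + N_il) + N_W_in + N_W_ex + N_S

by construction, and the census is returned in machine-readable form.
Placement uses jittered cubic lattices (and a Fibonacci-sphere lattice for
leaflets) so that no two beads start closer than 0.3 d, which the soft DPD
forces then relax quickly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .configuration import Configuration, merge
from .forcefield import ForceField, S, W, lipid_topology

RHO = 3.0  # bulk bead number density, beads per d^3

#: reference areas per lipid of the full-scale tensionless vesicle
AREA_PER_LIPID_OUTER = 1.14  # d^2, outer head layer
AREA_PER_LIPID_INNER = 1.02  # d^2, inner head layer
MONOLAYER_THICKNESS = 2.5    # d, radial span of one leaflet as assembled
MIDPLANE_GAP = 0.3           # d, half-gap between leaflet chain tips
MIN_AREA_PER_LIPID = 0.55    # hard floor; below this a leaflet is overfilled
MAX_AREA_PER_LIPID = 2.6

FULL_SCALE_N_LIPIDS = 10_100
FULL_SCALE_DIAMETER = 46.6        # d (outer head layer)
FULL_SCALE_N_W_ISP = 90_400       # interior waters of the assembled sphere
FULL_SCALE_EXTERIOR_TOTAL = 1_350_000  # exterior solution beads (W + S)


class AssemblyError(ValueError):
    pass


# ----------------------------------------------------------------------
# specs and bookkeeping
# ----------------------------------------------------------------------

@dataclass
class VesicleSpec:
    """Leaflet lipid numbers and geometry of a spherical vesicle."""

    n_outer: int
    n_inner: int
    outer_diameter: float = FULL_SCALE_DIAMETER
    n_water_in: int | None = None  # None: fill lumen to bulk density

    def __post_init__(self) -> None:
        if self.n_outer <= 0 or self.n_inner <= 0:
            raise AssemblyError("leaflet lipid numbers must be positive")

    @property
    def n_lipids(self) -> int:
        return self.n_outer + self.n_inner


@dataclass
class SolutionSpec:
    """Exterior solution composition."""

    n_solute: int
    n_water_ex: int

    @property
    def phi_S(self) -> float:
        """Solute mole fraction of the exterior solution."""
        tot = self.n_solute + self.n_water_ex
        return self.n_solute / tot if tot else 0.0

    def zeta(self, ff: ForceField) -> float:
        """Solubility, recomputed from the active force field."""
        return ff.solubility()


def leaflet_split(n_lipids: int, outer_diameter: float) -> tuple[int, int]:
    """Default outer/inner split proportional to head-layer areas."""
    r_out = outer_diameter / 2.0
    r_in = r_out - 2.0 * MONOLAYER_THICKNESS
    if r_in <= 0.5:
        raise AssemblyError("diameter too small for a bilayer shell")
    a_out = r_out ** 2 / AREA_PER_LIPID_OUTER
    a_in = r_in ** 2 / AREA_PER_LIPID_INNER
    n_out = int(round(n_lipids * a_out / (a_out + a_in)))
    return n_out, n_lipids - n_out


def reduced_vesicle_spec(n_lipids: int = 1000,
                         reshuffle: int = 0) -> VesicleSpec:
    """Down-scaled vesicle preserving the full-scale areas per lipid.

    The outer diameter is chosen so that both leaflets keep the per-lipid
    areas of the full-scale vesicle at fixed bilayer thickness (plain
    sqrt(N) area scaling would overfill the inner leaflet at small N).
    ``reshuffle`` moves that many lipids from the inner to the outer
    leaflet (negative: outer to inner), emulating the transbilayer-
    asymmetry control parameter.
    """
    t2 = 2.0 * MONOLAYER_THICKNESS
    # solve 4 pi (R^2/a_o + (R - t2)^2/a_i) = n_lipids for R
    ao, ai = AREA_PER_LIPID_OUTER, AREA_PER_LIPID_INNER
    a = 1.0 / ao + 1.0 / ai
    b = -2.0 * t2 / ai
    c = t2 ** 2 / ai - n_lipids / (4.0 * np.pi)
    disc = b * b - 4 * a * c
    if disc <= 0:
        raise AssemblyError("no geometric solution for this lipid number")
    r_out = (-b + np.sqrt(disc)) / (2 * a)
    n_out, n_in = leaflet_split(n_lipids, 2 * r_out)
    return VesicleSpec(n_outer=n_out + reshuffle, n_inner=n_in - reshuffle,
                       outer_diameter=2 * r_out)


def full_scale_census(n_solute: int,
                      n_lipids: int = FULL_SCALE_N_LIPIDS,
                      n_water_in: int = FULL_SCALE_N_W_ISP,
                      exterior_total: int = FULL_SCALE_EXTERIOR_TOTAL) -> dict:
    """Bead census of the full-scale vesicle + droplet system.

    Pure arithmetic: 15 beads per lipid, the interior water count of the
    initially assembled sphere, and an exterior solution of fixed total
    size in which ``n_solute`` W beads are replaced by S beads.
    """
    if not 0 <= n_solute <= exterior_total:
        raise AssemblyError("solute count outside the exterior solution size")
    lipid_beads = 15 * n_lipids
    n_water_ex = exterior_total - n_solute
    return {
        "lipid_beads": lipid_beads,
        "interior_W": n_water_in,
        "exterior_W": n_water_ex,
        "S": n_solute,
        "total": lipid_beads + n_water_in + n_water_ex + n_solute,
        "phi_S": SolutionSpec(n_solute, n_water_ex).phi_S,
    }


def droplet_initial_radius(n_solute: int, rho: float = RHO) -> float:
    """Radius of ``n_solute`` beads packed at bulk density into a sphere."""
    if n_solute <= 0:
        raise AssemblyError("droplet needs at least one solute bead")
    return float((3.0 * n_solute / (4.0 * np.pi * rho)) ** (1.0 / 3.0))


# ----------------------------------------------------------------------
# placement primitives
# ----------------------------------------------------------------------

def _jittered_lattice(n: int, rng: np.random.Generator, lo, hi,
                      inside=None, exclude: np.ndarray | None = None,
                      box: np.ndarray | None = None,
                      exclude_r: float = 0.45,
                      periodic: bool = False) -> np.ndarray:
    """Exactly ``n`` points on a jittered cubic lattice inside a region.

    ``inside`` is a vectorized predicate on (m, 3) points (None: whole
    bbox); ``exclude`` are existing bead positions (minimum-image if
    ``box`` given) that candidate sites must stay ``exclude_r`` away from.
    The lattice spacing shrinks until enough sites exist; jitter is capped
    so the minimum inter-point distance stays above 0.3 d.
    """
    lo = np.asarray(lo, float)
    hi = np.asarray(hi, float)
    span = hi - lo
    spacing = RHO ** (-1.0 / 3.0)  # 0.693 d at bulk density
    tree = None
    if exclude is not None and len(exclude):
        tree = cKDTree(exclude, boxsize=box if periodic else None)
    for _ in range(25):
        ncell = np.maximum((span / spacing).astype(int), 1)
        actual = span / ncell
        axes = [lo[k] + (np.arange(ncell[k]) + 0.5) * actual[k]
                for k in range(3)]
        pts = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
        if inside is not None:
            pts = pts[inside(pts)]
        # jitter before the exclusion test so placed beads keep their
        # clearance from existing ones
        jit = max(min(0.25 * actual.min(), 0.45 * (actual.min() - 0.31)), 0.0)
        pts = pts + rng.uniform(-jit, jit, size=pts.shape)
        if tree is not None and len(pts):
            d, _ = tree.query(pts, k=1)
            pts = pts[d > exclude_r]
        if len(pts) >= n:
            sel = rng.choice(len(pts), size=n, replace=False)
            return pts[sel]
        spacing *= 0.93
    raise AssemblyError(
        f"could not place {n} beads: region too small or too crowded")


def _fibonacci_sphere(n: int) -> np.ndarray:
    """n roughly equidistant unit vectors (golden-angle spiral)."""
    k = np.arange(n) + 0.5
    phi = np.pi * (1.0 + np.sqrt(5.0)) * k
    cos_t = 1.0 - 2.0 * k / n
    sin_t = np.sqrt(np.clip(1.0 - cos_t ** 2, 0.0, None))
    return np.stack([sin_t * np.cos(phi), cos_t, sin_t * np.sin(phi)], axis=1)


def _tangent_frame(u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ref = np.zeros_like(u)
    ref[np.abs(u[:, 0]) < 0.9, 0] = 1.0
    ref[np.abs(u[:, 0]) >= 0.9, 1] = 1.0
    t1 = np.cross(u, ref)
    t1 /= np.linalg.norm(t1, axis=1, keepdims=True)
    t2 = np.cross(u, t1)
    return t1, t2


# ----------------------------------------------------------------------
# builders
# ----------------------------------------------------------------------

def _place_leaflet(n: int, head_radius: float, inward: bool, center,
                   rng: np.random.Generator) -> np.ndarray:
    """Bead positions for one leaflet; (n, 15, 3), lipid bead order.

    ``inward`` True places chains pointing toward larger radii (inner
    leaflet, heads facing the lumen); False points chains toward the
    vesicle midsurface from outside.  Jitter is tangential only, so the
    radial stacking distance of bonded beads is preserved exactly.
    """
    u = _fibonacci_sphere(n)
    t1, t2 = _tangent_frame(u)
    sgn = 1.0 if inward else -1.0  # radial direction of increasing level
    step = (MONOLAYER_THICKNESS - MIDPLANE_GAP) / 7.0
    jit = rng.uniform(-0.05, 0.05, size=(n, 15, 2))
    pos = np.empty((n, 15, 3))
    # head trimer: H1 (index 1) at the head surface, H0/H2 one level in
    lvl = {1: 0.0, 0: 1.0, 2: 1.0}
    side = {0: +0.28, 2: -0.28, 1: 0.0}
    for b in (0, 1, 2):
        r = head_radius + sgn * lvl[b] * step
        pos[:, b, :] = (center + u * r + t1 * side[b]
                        + t1 * jit[:, b, :1] + t2 * jit[:, b, 1:])
    # chains: A (3..8) under H0, B (9..14) under H2
    for first, off in ((3, +0.28), (9, -0.28)):
        for k in range(6):
            b = first + k
            r = head_radius + sgn * (2.0 + k) * step
            pos[:, b, :] = (center + u * r + t1 * off
                            + t1 * jit[:, b, :1] + t2 * jit[:, b, 1:])
    return pos


def build_vesicle(spec: VesicleSpec, ff: ForceField | None = None,
                  seed: int = 0, box=None,
                  relax_steps: int = 300) -> tuple[Configuration, dict]:
    """Assemble a two-leaflet spherical vesicle with interior water.

    Inner-leaflet heads face the lumen, outer-leaflet heads the exterior.
    The assembled shell is relaxed by capped-displacement minimization
    (``relax_steps`` steps) before being returned.  Returns the
    configuration (centered in the box, exterior unfilled) and a metadata
    dict with the census and geometric radii.
    """
    ff = ff or ForceField()
    rng = np.random.default_rng(seed)
    r_head_out = spec.outer_diameter / 2.0
    r_mid = r_head_out - MONOLAYER_THICKNESS
    r_head_in = r_mid - MONOLAYER_THICKNESS
    if r_head_in <= 0.8:
        raise AssemblyError("diameter cannot accommodate two leaflets")
    for n_leaf, r_leaf, which in ((spec.n_outer, r_head_out, "outer"),
                                  (spec.n_inner, r_head_in, "inner")):
        apl = 4.0 * np.pi * r_leaf ** 2 / n_leaf
        if apl < MIN_AREA_PER_LIPID:
            raise AssemblyError(
                f"{which} leaflet overfilled: {apl:.2f} d^2 per lipid "
                f"< floor {MIN_AREA_PER_LIPID}")
        if apl > MAX_AREA_PER_LIPID:
            raise AssemblyError(
                f"{which} leaflet underfilled: {apl:.2f} d^2 per lipid")
    if box is None:
        box = np.full(3, np.ceil(spec.outer_diameter + 9.0))
    box = np.asarray(box, float)
    if box.min() < spec.outer_diameter + 2.0:
        raise AssemblyError("box too small for the vesicle")
    center = box / 2.0

    outer = _place_leaflet(spec.n_outer, r_head_out, inward=False,
                           center=center, rng=rng)
    inner = _place_leaflet(spec.n_inner, r_head_in, inward=True,
                           center=center, rng=rng)
    lipid_pos = np.vstack([outer.reshape(-1, 3), inner.reshape(-1, 3)])
    species, bonds, angles = lipid_topology(spec.n_lipids)
    molecule = np.repeat(np.arange(spec.n_lipids, dtype=np.int32), 15)

    # interior water
    r_lumen = r_head_in - 0.7
    n_w = spec.n_water_in
    if n_w is None:
        n_w = int(round(RHO * 4.0 / 3.0 * np.pi * r_lumen ** 3))
    if n_w > 0:
        def inside(p):
            return np.linalg.norm(p - center, axis=1) < r_lumen
        wpos = _jittered_lattice(
            n_w, rng, center - r_lumen, center + r_lumen, inside=inside,
            exclude=lipid_pos, box=box, periodic=True)
    else:
        wpos = np.empty((0, 3))
    n_total = 15 * spec.n_lipids + n_w
    cfg = Configuration(
        box=box,
        positions=np.vstack([lipid_pos, wpos]),
        velocities=np.zeros((n_total, 3)),
        species=np.concatenate([species,
                                np.full(len(wpos), W, dtype=np.int8)]),
        molecule=np.concatenate([molecule,
                                 np.full(len(wpos), -1, dtype=np.int32)]),
        bonds=bonds,
        angles=angles,
    )
    if relax_steps > 0:
        from .engine import DPDSimulation
        DPDSimulation(cfg, ff, seed=seed).minimize(relax_steps,
                                                   max_disp=0.05)
    meta = {
        "center": center,
        "r_head_out": r_head_out,
        "r_mid": r_mid,
        "r_head_in": r_head_in,
        "n_outer": spec.n_outer,
        "n_inner": spec.n_inner,
        "n_water_in": n_w,
        "lipid_beads": 15 * spec.n_lipids,
    }
    assert cfg.n_beads == 15 * spec.n_lipids + n_w
    return cfg, meta


def build_droplet(n_solute: int, ff: ForceField | None = None, seed: int = 0,
                  box=None, center=None,
                  existing: Configuration | None = None) -> Configuration:
    """A water-free spherical droplet of S beads at bulk density.

    The droplet must fit inside the box with 1 d clearance and must not
    overlap any bead of ``existing``.
    """
    radius = droplet_initial_radius(n_solute)
    if box is None:
        box = np.full(3, np.ceil(2 * radius + 6.0))
    box = np.asarray(box, float)
    if center is None:
        center = box / 2.0
    center = np.asarray(center, float)
    if 2 * radius + 2.0 > box.min():
        raise AssemblyError("droplet does not fit in box with clearance")
    rng = np.random.default_rng(seed)
    if n_solute == 1:
        pts = center[None, :].copy()
    else:
        def inside(p):
            return np.linalg.norm(p - center, axis=1) < radius

        exclude = existing.positions if existing is not None else None
        pts = _jittered_lattice(
            n_solute, rng, center - radius, center + radius, inside=inside,
            exclude=exclude, box=box, periodic=True)
        if existing is not None:
            d, _ = cKDTree(existing.positions, boxsize=box).query(pts, k=1)
            if d.min() <= 0.3:
                raise AssemblyError("droplet overlaps existing beads")
    return Configuration(
        box=box,
        positions=pts,
        velocities=np.zeros((n_solute, 3)),
        species=np.full(n_solute, S, dtype=np.int8),
    )


def fill_and_bookkeep(cfg: Configuration, rho: float = RHO, seed: int = 0,
                      exclude_spheres=() ,
                      n_water_in: int = 0) -> tuple[Configuration, SolutionSpec, dict]:
    """Add exterior water until the global density reaches ``rho``.

    ``exclude_spheres`` is a sequence of (center, radius) kept water-free
    (e.g. the region enclosed by a vesicle's outer head layer, whose lumen
    water was already placed by the builder).  ``n_water_in`` is the
    number of already-present interior waters, needed only to split the
    census.  Returns (filled configuration, solution spec, census).
    """
    n_target = int(round(rho * cfg.volume))
    n_add = n_target - cfg.n_beads
    if n_add < 0:
        raise AssemblyError("box too small: target density already exceeded")
    rng = np.random.default_rng(seed)

    def inside(p):
        ok = np.ones(len(p), dtype=bool)
        for c, r in exclude_spheres:
            dr = p - np.asarray(c)
            dr -= cfg.box * np.round(dr / cfg.box)
            ok &= np.linalg.norm(dr, axis=1) > r
        return ok

    if n_add > 0:
        wpos = _jittered_lattice(
            n_add, rng, np.zeros(3), cfg.box, inside=inside,
            exclude=cfg.positions, box=cfg.box, periodic=True)
        add = Configuration(
            box=cfg.box.copy(),
            positions=wpos,
            velocities=np.zeros((n_add, 3)),
            species=np.full(n_add, W, dtype=np.int8),
        )
        filled = merge(cfg, add)
    else:
        filled = cfg.copy()
    counts = filled.species_counts()
    census = {
        "lipid_beads": counts["H"] + counts["C"],
        "interior_W": int(n_water_in),
        "exterior_W": counts["W"] - int(n_water_in),
        "S": counts["S"],
        "total": filled.n_beads,
    }
    sol = SolutionSpec(n_solute=census["S"], n_water_ex=census["exterior_W"])
    census["phi_S"] = sol.phi_S
    return filled, sol, census
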
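"""Synthetic fixtures with machine-readable ground truth.

Every generator returns a :class:`Fixture` whose ``truth`` dict records
the values the analysis modules must recover: the two-bead virial, the
slab bead bookkeeping, the prescribed contact angles of a mock
vesicle-droplet couple, analytic loop circularities, or the engulfment
state of a constructed membrane topology.  Fixtures are deterministic
given their seed and do not emulate dynamics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import ellipe

from .assembly import RHO, _fibonacci_sphere, _jittered_lattice
from .configuration import Configuration
from .forcefield import C, H, S, W, ForceField
from .geometry import GeometryError
from .stress import RadialStressProfile


@dataclass
class Fixture:
    """A generated test system plus its ground truth."""

    kind: str
    truth: dict
    seed: int = 0
    config: Configuration | None = None
    points: dict | None = field(default=None, repr=False)


# ----------------------------------------------------------------------
# thermodynamic oracles
# ----------------------------------------------------------------------

def make_thermo_fixture(kind: str, **params) -> Fixture:
    """Oracle micro-systems: ``ideal_gas`` or ``two_bead``.

    ideal_gas: ``n`` beads at ``temperature`` with all force amplitudes
    zero; truth: excess pressure exactly 0.
    two_bead: a frozen pair at separation ``r`` with force amplitude
    ``f``; truth: the single-pair virial f (1 - r) r (0 beyond cutoff).
    """
    seed = int(params.pop("seed", 0))
    rng = np.random.default_rng(seed)
    if kind == "ideal_gas":
        n = int(params.pop("n", 1000))
        box = np.asarray(params.pop("box", (8.0, 8.0, 8.0)), float)
        temperature = float(params.pop("temperature", 1.0))
        pos = _jittered_lattice(n, rng, np.zeros(3), box)
        vel = rng.normal(0.0, math.sqrt(temperature), (n, 3))
        vel -= vel.mean(axis=0)
        cfg = Configuration(box=box, positions=pos, velocities=vel,
                            species=np.full(n, W, dtype=np.int8))
        ff = ForceField(f=np.zeros((4, 4)))
        return Fixture(kind=kind, seed=seed, config=cfg,
                       truth={"excess_pressure": 0.0,
                              "forcefield": ff})
    if kind == "two_bead":
        r = float(params.pop("r", 0.5))
        f = float(params.pop("f", 25.0))
        box = np.asarray(params.pop("box", (10.0, 10.0, 10.0)), float)
        sp = params.pop("species", (W, S))
        pos = np.array([box / 2.0 - [r / 2.0, 0, 0],
                        box / 2.0 + [r / 2.0, 0, 0]])
        cfg = Configuration(box=box, positions=pos,
                            velocities=np.zeros((2, 3)),
                            species=np.array(sp, dtype=np.int8))
        fmat = np.full((4, 4), f)
        virial = f * (1.0 - r) * r if r < 1.0 else 0.0
        return Fixture(kind=kind, seed=seed, config=cfg,
                       truth={"pair_virial": virial, "r": r,
                              "forcefield": ForceField(f=fmat)})
    raise ValueError(f"unknown thermo fixture kind: {kind!r}")


# ----------------------------------------------------------------------
# planar slab
# ----------------------------------------------------------------------

def make_planar_slab(thickness: float = 10.0, box=(16.0, 16.0, 32.0),
                     ff: ForceField | None = None, seed: int = 0,
                     axis: int = 2) -> Fixture:
    """An S slab in W at bulk density, two interfaces normal to ``axis``.

    Pre-equilibration bookkeeping is exact: N_S = round(thickness * area
    * rho) solute beads inside the centered slab, water elsewhere, total
    round(rho * V).  The slab must be thicker than two interfacial widths
    (~ sqrt(kBT / Sigma_ab) each) to have two independent interfaces.
    """
    ff = ff or ForceField()
    box = np.asarray(box, float)
    width = math.sqrt(1.0 / 3.0)  # interfacial width estimate at Sigma ~ 3
    if thickness < 4.0 * width or thickness > box[axis] - 4.0 * width:
        raise ValueError("slab too thin (or box too full) for two interfaces")
    rng = np.random.default_rng(seed)
    area = float(np.prod(box)) / box[axis]
    n_s = int(round(thickness * area * RHO))
    lo = (box[axis] - thickness) / 2.0
    hi = (box[axis] + thickness) / 2.0

    def in_slab(p):
        return (p[:, axis] >= lo) & (p[:, axis] < hi)

    def out_slab(p):
        return ~in_slab(p)

    spos = _jittered_lattice(n_s, rng, np.zeros(3), box, inside=in_slab)
    n_total = int(round(RHO * np.prod(box)))
    n_w = n_total - n_s
    wpos = _jittered_lattice(n_w, rng, np.zeros(3), box, inside=out_slab,
                             exclude=spos, box=box, periodic=True,
                             exclude_r=0.35)
    pos = np.vstack([spos, wpos])
    species = np.concatenate([np.full(n_s, S, np.int8),
                              np.full(n_w, W, np.int8)])
    vel = rng.normal(0.0, 1.0, pos.shape)
    vel -= vel.mean(axis=0)
    cfg = Configuration(box=box, positions=pos, velocities=vel,
                        species=species)
    zeta = ff.solubility()
    return Fixture(kind="planar_slab", seed=seed, config=cfg,
                   truth={"n_solute": n_s, "n_water": n_w,
                          "n_total": n_total, "n_interfaces": 2,
                          "axis": axis, "zeta": zeta})


# ----------------------------------------------------------------------
# mock axisymmetric vesicle-droplet couple
# ----------------------------------------------------------------------

def _sample_cap(rng, center_y: float, radius: float, omega_max: float,
                pole: float, density: float) -> np.ndarray:
    """Uniform points on a spherical cap about the y axis.

    The cap spans polar angles [0, omega_max] from the pole at
    ``center_y + pole * radius``.
    """
    area = 2.0 * np.pi * radius ** 2 * (1.0 - math.cos(omega_max))
    n = max(int(area * density), 16)
    cos_w = rng.uniform(math.cos(omega_max), 1.0, n)
    sin_w = np.sqrt(np.clip(1.0 - cos_w ** 2, 0.0, None))
    chi = rng.uniform(0.0, 2.0 * np.pi, n)
    return np.column_stack([
        radius * sin_w * np.cos(chi),
        center_y + pole * radius * cos_w,
        radius * sin_w * np.sin(chi),
    ])


def _sample_disc(rng, r_max: float, density: float) -> np.ndarray:
    n = max(int(np.pi * r_max ** 2 * density), 16)
    r = r_max * np.sqrt(rng.uniform(0.0, 1.0, n))
    chi = rng.uniform(0.0, 2.0 * np.pi, n)
    return np.column_stack([r * np.cos(chi), np.zeros(n), r * np.sin(chi)])


def make_mock_couple(theta_alpha_star: float, psi_co: float, R_co: float,
                     noise: float = 0.1, seed: int = 0,
                     density: float = 8.0) -> Fixture:
    """Axisymmetric vesicle-droplet surface cloud with prescribed angles.

    Surfaces of revolution patched from circular arcs: the droplet
    interface (ab) and the membrane segment under the droplet (ag) are
    spherical caps whose closed-form tangents at the contact circle
    realize the requested intrinsic contact angle ``theta_alpha_star``
    and contour tilt ``psi_co`` (degrees); the outer membrane segment
    (bg) is a torus arc continuing smoothly outward.  Gaussian positional
    noise of scale ``noise`` is added.  Raises for geometrically
    inconsistent angle pairs (interface dipping through the membrane).
    """
    th = float(theta_alpha_star)
    ps = float(psi_co)
    if not (0.0 < th < 180.0) or not (0.0 <= ps < 90.0) or R_co <= 0:
        raise GeometryError("angles/radius outside their valid ranges")
    phi = th - ps  # elevation angle of the interface tangent at contact
    if phi <= 2.0 or phi >= 178.0:
        raise GeometryError(
            "geometrically inconsistent parameters: the interface would "
            "graze or intersect the membrane segment")
    rng = np.random.default_rng(seed)
    phi_r = math.radians(phi)
    ps_r = math.radians(ps)
    # droplet interface: cap above the contact plane
    c_ab = -R_co / math.tan(phi_r)
    R_ab = R_co / math.sin(phi_r)
    ab = _sample_cap(rng, c_ab, R_ab, phi_r, +1.0, density)
    # membrane under the droplet: cap below the plane (or a flat disc)
    if ps < 1e-9:
        ag = _sample_disc(rng, R_co, density)
    else:
        c_ag = R_co / math.tan(ps_r)
        R_ag = R_co / math.sin(ps_r)
        ag = _sample_cap(rng, c_ag, R_ag, ps_r, -1.0, density)
    # outer membrane: torus arc with tangent continuity at the contact
    t_hat = np.array([math.cos(ps_r), math.sin(ps_r)])
    n_hat = np.array([math.sin(ps_r), -math.cos(ps_r)])
    R_t = 0.45 * R_co
    arc_center = np.array([R_co, 0.0]) + R_t * n_hat
    s_max = math.radians(100.0)
    n_arc = max(int(density * s_max * R_t * 2 * np.pi * R_co / 4), 64)
    s = rng.uniform(0.0, s_max, n_arc)
    rr = arc_center[0] - R_t * (n_hat[0] * np.cos(s) - t_hat[0] * np.sin(s))
    yy = arc_center[1] - R_t * (n_hat[1] * np.cos(s) - t_hat[1] * np.sin(s))
    keep = rr > 0.2
    chi = rng.uniform(0.0, 2.0 * np.pi, keep.sum())
    bg = np.column_stack([rr[keep] * np.cos(chi), yy[keep],
                          rr[keep] * np.sin(chi)])
    points = {"ab": ab, "ag": ag, "bg": bg}
    if noise > 0:
        for k in points:
            points[k] = points[k] + rng.normal(0.0, noise, points[k].shape)
    return Fixture(kind="mock_couple", seed=seed, points=points,
                   truth={"theta_alpha_star": th, "psi_co": ps,
                          "R_co": float(R_co), "noise": float(noise)})


# ----------------------------------------------------------------------
# contact-line loops with analytic circularity
# ----------------------------------------------------------------------

def make_loop(kind: str, seed: int = 0, n: int = 200, noise: float = 0.0,
              **params) -> Fixture:
    """Closed 3D loops with analytic perimeter/circularity ground truth.

    kinds: ``circle`` (radius), ``ellipse`` (a, b; perimeter from the
    complete elliptic integral), ``stadium`` (straight length L, cap
    radius r; the tight-lipped morphology).  Points are returned in
    shuffled order.
    """
    rng = np.random.default_rng(seed)
    if kind == "circle":
        R = float(params.pop("radius", 10.0))
        t = np.linspace(0.0, 2 * np.pi, n, endpoint=False)
        pts = np.column_stack([R * np.cos(t), R * np.sin(t), np.zeros(n)])
        truth = {"perimeter": 2 * np.pi * R, "area": np.pi * R ** 2,
                 "circularity": 1.0, "R": R}
    elif kind == "ellipse":
        a = float(params.pop("a", 10.0))
        b = float(params.pop("b", 5.0))
        t = np.linspace(0.0, 2 * np.pi, n, endpoint=False)
        pts = np.column_stack([a * np.cos(t), b * np.sin(t), np.zeros(n)])
        e2 = 1.0 - (min(a, b) / max(a, b)) ** 2
        per = 4.0 * max(a, b) * ellipe(e2)
        area = np.pi * a * b
        truth = {"perimeter": per, "area": area,
                 "circularity": 4 * np.pi * area / per ** 2, "a": a, "b": b}
    elif kind == "stadium":
        L = float(params.pop("L", 16.0))
        r = float(params.pop("r", 2.0))
        per = 2.0 * L + 2.0 * np.pi * r
        area = 2.0 * r * L + np.pi * r ** 2
        frac_straight = 2 * L / per
        n_st = int(n * frac_straight / 2)
        n_cap = (n - 2 * n_st) // 2
        xs = np.linspace(-L / 2, L / 2, n_st)
        top = np.column_stack([xs, np.full(n_st, r)])
        bot = np.column_stack([xs[::-1], np.full(n_st, -r)])
        t1 = np.linspace(-np.pi / 2, np.pi / 2, n_cap)
        cap1 = np.column_stack([L / 2 + r * np.cos(t1), r * np.sin(t1)])
        cap2 = np.column_stack([-L / 2 - r * np.cos(t1), -r * np.sin(t1)])
        xy = np.vstack([top, cap1[np.argsort(t1)], bot, cap2])
        pts = np.column_stack([xy, np.zeros(len(xy))])
        truth = {"perimeter": per, "area": area,
                 "circularity": 4 * np.pi * area / per ** 2, "L": L, "r": r}
    else:
        raise ValueError(f"unknown loop kind: {kind!r}")
    if noise > 0:
        pts = pts + rng.normal(0.0, noise, pts.shape)
    pts = pts[rng.permutation(len(pts))]
    return Fixture(kind=f"loop_{kind}", seed=seed,
                   points={"loop": pts}, truth=truth)


# ----------------------------------------------------------------------
# constructed engulfment topologies
# ----------------------------------------------------------------------

def _bilayer_shell(center: np.ndarray, radius: float,
                   spacing: float = 0.55) -> tuple[np.ndarray, np.ndarray]:
    """Connected spherical membrane sandwich: H faces, C core.

    Head beads on both faces mirror a real bilayer, so a wrapped droplet
    is in contact with head beads as it would be with the inner leaflet.
    """
    pts = []
    spc = []
    for dr, code in ((+0.45, H), (0.0, C), (-0.45, H)):
        r = radius + dr
        npts = max(int(4 * np.pi * r ** 2 / spacing ** 2), 32)
        u = _fibonacci_sphere(npts)
        pts.append(center + r * u)
        spc.append(np.full(npts, code, np.int8))
    return np.vstack(pts), np.concatenate(spc)


def make_nested_shells(seed: int = 0, box_edge: float = 16.0,
                       r_outer: float = 5.5, r_inner: float = 3.2,
                       r_droplet: float = 1.8) -> Fixture:
    """Two disjoint nested membrane shells around a droplet: fission state.

    The constructed end state of an axisymmetric engulfment pathway: the
    intraluminal vesicle (inner shell enclosing the droplet) has separated
    from the outer vesicle, so the membrane bead graph has two connected
    components.  Water fills all aqueous compartments.
    """
    rng = np.random.default_rng(seed)
    box = np.full(3, box_edge)
    center = box / 2.0
    p1, s1 = _bilayer_shell(center, r_outer)
    p2, s2 = _bilayer_shell(center, r_inner)
    mol = np.concatenate([np.zeros(len(p1), np.int32),
                          np.ones(len(p2), np.int32)])
    n_drop = int(round(RHO * 4 / 3 * np.pi * r_droplet ** 3))

    def in_drop(p):
        return np.linalg.norm(p - center, axis=1) < r_droplet

    pd = _jittered_lattice(n_drop, rng, center - r_droplet,
                           center + r_droplet, inside=in_drop)
    existing = np.vstack([p1, p2, pd])
    n_total = int(round(RHO * box_edge ** 3))
    n_w = n_total - len(existing)

    def outside_droplet(p):
        return np.linalg.norm(p - center, axis=1) > r_droplet + 0.4

    pw = _jittered_lattice(n_w, rng, np.zeros(3), box, exclude=existing,
                           inside=outside_droplet, box=box, periodic=True,
                           exclude_r=0.45)
    pos = np.vstack([existing, pw])
    species = np.concatenate([s1, s2, np.full(n_drop, S, np.int8),
                              np.full(n_w, W, np.int8)])
    molecule = np.concatenate([mol, np.full(n_drop + n_w, -1, np.int32)])
    cfg = Configuration(box=box, positions=pos, velocities=np.zeros_like(pos),
                        species=species, molecule=molecule)
    return Fixture(kind="nested_shells", seed=seed, config=cfg,
                   truth={"state": "fission", "n_membrane_components": 2})


def make_engulfment_state(state: str, seed: int = 0,
                          box_edge: float = 16.0) -> Fixture:
    """Constructed single-membrane states: ``free`` or ``complete``.

    free: droplet far from a closed vesicle shell; complete: droplet
    tightly wrapped by the shell with no solute-exterior contact (the
    defining condition of a closed membrane neck).
    """
    rng = np.random.default_rng(seed)
    box = np.full(3, box_edge)
    center = box / 2.0
    if state == "free":
        shell_c = center - np.array([box_edge / 4, 0, 0])
        drop_c = center + np.array([box_edge / 4, 0, 0])
        r_shell, r_drop = 3.0, 1.6
        truth_state = "free"
    elif state == "complete":
        shell_c = center
        drop_c = center
        r_shell, r_drop = 4.0, 3.0
        truth_state = "complete-closed-neck"
    else:
        raise ValueError("state must be 'free' or 'complete'")
    p1, s1 = _bilayer_shell(shell_c, r_shell)
    n_drop = int(round(RHO * 4 / 3 * np.pi * r_drop ** 3))

    def in_drop(p):
        return np.linalg.norm(p - drop_c, axis=1) < r_drop

    pd = _jittered_lattice(n_drop, rng, drop_c - r_drop, drop_c + r_drop,
                           inside=in_drop)
    existing = np.vstack([p1, pd])
    n_w = int(round(RHO * box_edge ** 3)) - len(existing)

    def outside_droplet(p):
        return np.linalg.norm(p - drop_c, axis=1) > r_drop + 0.4

    pw = _jittered_lattice(n_w, rng, np.zeros(3), box, exclude=existing,
                           inside=outside_droplet, box=box, periodic=True,
                           exclude_r=0.45)
    pos = np.vstack([existing, pw])
    species = np.concatenate([s1, np.full(n_drop, S, np.int8),
                              np.full(n_w, W, np.int8)])
    molecule = np.concatenate([np.zeros(len(p1), np.int32),
                               np.full(n_drop + n_w, -1, np.int32)])
    cfg = Configuration(box=box, positions=pos, velocities=np.zeros_like(pos),
                        species=species, molecule=molecule)
    return Fixture(kind=f"engulfment_{state}", seed=seed, config=cfg,
                   truth={"state": truth_state})


# ----------------------------------------------------------------------
# injected stress profiles
# ----------------------------------------------------------------------

def make_injected_radial_profile(lobes, r_mid: float, r_max: float = 20.0,
                                 bin_width: float = 0.2) -> Fixture:
    """A synthetic s(r) made of rectangular lobes, with analytic tensions.

    ``lobes`` is a sequence of (r_lo, r_hi, height); lobe edges should be
    multiples of ``bin_width`` for the bin sums to reproduce the analytic
    integrals exactly.  The chain density is a narrow peak at ``r_mid``.
    """
    nbins = int(round(r_max / bin_width))
    r = (np.arange(nbins) + 0.5) * bin_width
    s = np.zeros(nbins)
    sig_il = 0.0
    sig_ol = 0.0
    for lo, hi, h in lobes:
        sel = (r > lo) & (r < hi)
        s[sel] += h
        lo_i, hi_i = max(lo, 0.0), hi
        if hi_i <= r_mid:
            sig_il += h * (hi_i - lo_i)
        elif lo_i >= r_mid:
            sig_ol += h * (hi_i - lo_i)
        else:
            sig_il += h * (r_mid - lo_i)
            sig_ol += h * (hi_i - r_mid)
    rho_c = np.exp(-0.5 * ((r - r_mid) / (2 * bin_width)) ** 2)
    profile = RadialStressProfile(
        r=r, P_N=s, P_T=np.zeros(nbins), rho_C=rho_c, bin_width=bin_width,
        center=np.zeros(3), n_frames=1)
    return Fixture(kind="injected_profile", points={"profile": profile},
                   truth={"Sigma": sig_il + sig_ol, "Sigma_il": sig_il,
                          "Sigma_ol": sig_ol, "R_mid": r_mid})
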
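"""Morphological analysis of vesicle-droplet states.

Extracts droplet size and shape, the membrane-droplet contact line and its
circularity, the contact angles entering the force balance at the contact
line, and the engulfment state (free / partial / complete / fission).

Conventions: a bead is "in contact" with a phase when a bead of that phase
lies within the force cutoff 1.0 d.  A closed membrane neck (complete
engulfment) means no solute bead remains in contact with the exterior bulk
phase.  Fission is detected as the lipid-bead proximity graph splitting
into two or more connected components.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .configuration import Configuration
from .forcefield import C, H, S, W
from .stress import periodic_com

CONTACT_CUTOFF = 1.0          # d; force cutoff radius
AXISYM_CIRCULARITY = 0.95     # circularity threshold for axisymmetry
AREA_PER_SURFACE_BEAD = 3.0 ** (-2.0 / 3.0)  # d^2 at bulk density


class GeometryError(ValueError):
    pass


# ----------------------------------------------------------------------
# clustering helpers
# ----------------------------------------------------------------------

def _components(pos: np.ndarray, box=None,
                cutoff: float = CONTACT_CUTOFF) -> np.ndarray:
    """Connected-component label per point of the proximity graph."""
    n = len(pos)
    if n == 0:
        return np.empty(0, dtype=int)
    tree = cKDTree(pos, boxsize=box)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    graph = coo_matrix(
        (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n))
    _, labels = connected_components(graph, directed=False)
    return labels


def majority_cluster(pos: np.ndarray, box=None,
                     cutoff: float = CONTACT_CUTOFF,
                     min_size: int = 10) -> np.ndarray:
    """Indices of the largest proximity cluster; error if below min_size."""
    labels = _components(pos, box, cutoff)
    if labels.size == 0:
        raise GeometryError("no beads to cluster")
    counts = np.bincount(labels)
    best = int(np.argmax(counts))
    if counts[best] < min_size:
        raise GeometryError(
            f"no majority cluster above {min_size} beads "
            f"(largest has {counts[best]})")
    return np.flatnonzero(labels == best)


def interior_exterior_water(cfg: Configuration,
                            cutoff: float = CONTACT_CUTOFF):
    """Split W beads into exterior (bulk beta) and interior (gamma) sets.

    Uses connectivity of the W proximity graph: an intact bilayer
    disconnects the lumen water from the bulk.  The exterior component is
    the one containing the W bead farthest from the lipid center of mass.
    Returns (exterior_idx, interior_idx) as indices into the full
    configuration.  Raises if there is no lipid membrane or only a single
    water component (pore / leak).
    """
    wmask = cfg.species == W
    lipid = cfg.molecule >= 0
    if not lipid.any():
        raise GeometryError("no membrane: interior/exterior is undefined")
    widx = np.flatnonzero(wmask)
    labels = _components(cfg.positions[wmask], cfg.box, cutoff)
    com = periodic_com(cfg.positions[lipid], cfg.box)
    dr = cfg.positions[wmask] - com
    dr -= cfg.box * np.round(dr / cfg.box)
    dist = np.linalg.norm(dr, axis=1)
    ext_label = labels[int(np.argmax(dist))]
    if (labels == ext_label).all():
        raise GeometryError(
            "water phase is singly connected: membrane has a pore")
    ext = widx[labels == ext_label]
    inn = widx[labels != ext_label]
    return ext, inn


# ----------------------------------------------------------------------
# droplet shape
# ----------------------------------------------------------------------

@dataclass
class DropletShape:
    diameter: float       # d; from the half-maximum of the radial density
    asphericity: float    # 0 for a sphere (gyration-tensor based)
    center: np.ndarray
    n_beads: int


def measure_droplet_shape(cfg: Configuration, bin_width: float = 0.5,
                          min_size: int = 50) -> DropletShape:
    """Diameter and asphericity of the majority solute cluster.

    The diameter is twice the radius at which the radial S-bead density
    falls to half its central plateau value (linear interpolation between
    bins); the asphericity is the normalized gyration-tensor invariant
    [(l1-l2)^2 + (l2-l3)^2 + (l3-l1)^2] / [2 (l1+l2+l3)^2], which vanishes
    for a sphere.
    """
    smask = cfg.species == S
    if not smask.any():
        raise GeometryError("no solute beads")
    spos = cfg.positions[smask]
    cluster = majority_cluster(spos, cfg.box, min_size=min_size)
    pts = spos[cluster]
    center = periodic_com(pts, cfg.box)
    dr = pts - center
    dr -= cfg.box * np.round(dr / cfg.box)
    r = np.linalg.norm(dr, axis=1)
    r_guess = (len(pts) / (4.0 / 3.0 * np.pi * 3.0)) ** (1.0 / 3.0)
    nbins = max(int(np.ceil((2.5 * r_guess) / bin_width)), 8)
    edges = np.arange(nbins + 1) * bin_width
    hist, _ = np.histogram(r, bins=edges)
    shell = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    rho = hist / shell
    centers = 0.5 * (edges[1:] + edges[:-1])
    core = centers < 0.6 * r_guess
    plateau = rho[core].mean() if core.any() else rho[0]
    if plateau <= 0:
        raise GeometryError("empty density core: not a compact droplet")
    half = 0.5 * plateau
    r_half = centers[-1]
    for k in range(len(rho) - 1):
        if rho[k] >= half > rho[k + 1]:
            frac = (rho[k] - half) / (rho[k] - rho[k + 1])
            r_half = centers[k] + frac * bin_width
            break
    gyr = dr.T @ dr / len(pts)
    lam = np.sort(np.linalg.eigvalsh(gyr))
    tr = lam.sum()
    asph = (((lam[0] - lam[1]) ** 2 + (lam[1] - lam[2]) ** 2
             + (lam[2] - lam[0]) ** 2) / (2.0 * tr ** 2)) if tr > 0 else 0.0
    return DropletShape(diameter=2.0 * r_half, asphericity=float(asph),
                        center=center, n_beads=len(pts))


# ----------------------------------------------------------------------
# contact line
# ----------------------------------------------------------------------

@dataclass
class ContactGeometry:
    """Contact line descriptors; angle fields filled by the angle fit."""

    L_cl: float = float("nan")
    circularity: float = float("nan")
    R_co: float = float("nan")         # reported only when axisymmetric
    axisymmetric: bool = False
    closed_neck: bool = False
    n_points: int = 0
    centroid: np.ndarray | None = None
    axis: np.ndarray | None = None     # best-fit plane normal
    theta_alpha_star: float = float("nan")  # degrees
    psi_co: float = float("nan")            # degrees


def order_loop(points: np.ndarray, two_opt_passes: int = 2) -> np.ndarray:
    """Order a noisy closed loop of points by nearest-neighbor chaining.

    A limited 2-opt pass repairs crossings, which matters for elongated
    (tight-lipped) loops.  Returns an index permutation.
    """
    n = len(points)
    if n < 3:
        raise GeometryError("need at least 3 points to order a loop")
    remaining = set(range(1, n))
    order = [0]
    tree = cKDTree(points)
    while remaining:
        last = points[order[-1]]
        for k in (8, 64, n):
            dist, idx = tree.query(last, k=min(k, n))
            idx = np.atleast_1d(idx)
            nxt = next((int(i) for i in idx if int(i) in remaining), None)
            if nxt is not None:
                break
        order.append(nxt)
        remaining.discard(nxt)
    order = np.array(order)
    for _ in range(two_opt_passes):
        improved = False
        p = points[order]
        nxt = np.roll(p, -1, axis=0)
        seg = np.linalg.norm(p - nxt, axis=1)
        for i in range(n - 2):
            for j in range(i + 2, n - (1 if i == 0 else 0)):
                # reverse order[i+1..j] if it shortens the tour
                a, b = p[i], p[(i + 1) % n]
                c, d = p[j], p[(j + 1) % n]
                delta = (np.linalg.norm(a - c) + np.linalg.norm(b - d)
                         - seg[i] - seg[j])
                if delta < -1e-12:
                    order[i + 1:j + 1] = order[i + 1:j + 1][::-1]
                    p = points[order]
                    nxt = np.roll(p, -1, axis=0)
                    seg = np.linalg.norm(p - nxt, axis=1)
                    improved = True
        if not improved:
            break
    return order


def loop_descriptors(points: np.ndarray) -> tuple[float, float, np.ndarray, np.ndarray]:
    """(length, circularity, centroid, plane normal) of an ordered loop."""
    centroid = points.mean(axis=0)
    rel = points - centroid
    _, _, vt = np.linalg.svd(rel, full_matrices=False)
    normal = vt[2]
    u, v = vt[0], vt[1]
    x = rel @ u
    y = rel @ v
    length = float(np.sqrt(np.diff(np.append(x, x[0])) ** 2
                           + np.diff(np.append(y, y[0])) ** 2).sum())
    area = 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
    circ = 4.0 * np.pi * area / length ** 2 if length > 0 else float("nan")
    return length, float(circ), centroid, normal


def extract_contact_line(head_pos: np.ndarray, alpha_pos: np.ndarray,
                         beta_pos: np.ndarray, box=None,
                         cutoff: float = CONTACT_CUTOFF,
                         axisym_threshold: float = AXISYM_CIRCULARITY) -> ContactGeometry:
    """Contact line from bead positions.

    The contact-line point set consists of membrane head beads within
    ``cutoff`` of both the droplet (alpha) phase and the exterior bulk
    (beta) phase.  When the neck has sealed (droplet no longer touches the
    beta phase) the residual seam is reported with ``closed_neck=True``.
    """
    if len(head_pos) == 0:
        raise GeometryError("no head beads supplied")
    ta = cKDTree(alpha_pos, boxsize=box)
    tb = cKDTree(beta_pos, boxsize=box)
    na = ta.query_ball_point(head_pos, cutoff, return_length=True)
    nb = tb.query_ball_point(head_pos, cutoff, return_length=True)
    sel = (np.asarray(na) > 0) & (np.asarray(nb) > 0)
    pts = head_pos[sel]
    geo = ContactGeometry(n_points=int(sel.sum()))
    if len(pts) < 6:
        # no open contact line; closed-neck indicator with the seam extent
        geo.closed_neck = True
        geo.L_cl = 0.0
        if len(pts) >= 2:
            geo.L_cl = float(np.linalg.norm(
                pts.max(axis=0) - pts.min(axis=0)))
        return geo
    if box is not None:
        # unwrap about the first point so the loop is contiguous
        ref = pts[0]
        pts = pts - np.asarray(box) * np.round((pts - ref) / box)
    order = order_loop(pts)
    length, circ, centroid, normal = loop_descriptors(pts[order])
    geo.L_cl = length
    geo.circularity = circ
    geo.centroid = centroid
    geo.axis = normal
    geo.axisymmetric = circ >= axisym_threshold
    if geo.axisymmetric:
        geo.R_co = float(np.linalg.norm(pts - centroid, axis=1).mean())
    return geo


# ----------------------------------------------------------------------
# contact angles (axisymmetric)
# ----------------------------------------------------------------------

def _kasa_circle(x: np.ndarray, y: np.ndarray):
    """Algebraic (Kasa) circle fit; returns (cx, cy, R)."""
    A = np.column_stack([2 * x, 2 * y, np.ones_like(x)])
    b = x ** 2 + y ** 2
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    cx, cy, c = sol
    r2 = c + cx ** 2 + cy ** 2
    if r2 <= 0:
        raise GeometryError("degenerate circle fit")
    return float(cx), float(cy), float(np.sqrt(r2))


class _QuadCurve:
    """Local quadratic contour model eta = a + b xi + c xi^2 in a frame
    aligned with the point cloud's principal direction.

    Short noisy arcs defeat algebraic circle fits (the sagitta is of the
    order of the noise), but the tangent direction from a rotated-frame
    quadratic is stable.
    """

    def __init__(self, pts2d: np.ndarray, origin: np.ndarray):
        d = pts2d - origin
        _, _, vt = np.linalg.svd(d - d.mean(axis=0), full_matrices=False)
        self.origin = np.asarray(origin, float)
        self.e1, self.e2 = vt[0], vt[1]
        xi = d @ self.e1
        eta = d @ self.e2
        A = np.column_stack([np.ones_like(xi), xi, xi ** 2])
        self.coef, *_ = np.linalg.lstsq(A, eta, rcond=None)
        self.xi_mean = float(xi.mean())

    def eval(self, xi: float) -> np.ndarray:
        a, b, c = self.coef
        return self.origin + xi * self.e1 + (a + b * xi + c * xi * xi) * self.e2

    def tangent(self, xi: float) -> np.ndarray:
        a, b, c = self.coef
        t = self.e1 + (b + 2 * c * xi) * self.e2
        return t / np.linalg.norm(t)

    def residual_xi(self, p: np.ndarray) -> tuple[float, float]:
        d = p - self.origin
        xi = float(d @ self.e1)
        a, b, c = self.coef
        return float(d @ self.e2 - (a + b * xi + c * xi * xi)), xi


def _intersect_curves(c1: _QuadCurve, c2: _QuadCurve,
                      half_window: float) -> np.ndarray:
    """Point on curve 1 where it crosses curve 2 (nearest the origin)."""
    xis = np.linspace(-half_window, half_window, 161)
    f = np.array([c2.residual_xi(c1.eval(x))[0] for x in xis])
    sign_change = np.flatnonzero(np.sign(f[:-1]) != np.sign(f[1:]))
    if len(sign_change):
        k = sign_change[np.argmin(np.abs(xis[sign_change]))]
        lo, hi = xis[k], xis[k + 1]
        flo = f[k]
        for _ in range(40):  # bisection
            mid = 0.5 * (lo + hi)
            fm = c2.residual_xi(c1.eval(mid))[0]
            if flo * fm <= 0:
                hi = mid
            else:
                lo, flo = mid, fm
        return c1.eval(0.5 * (lo + hi))
    return c1.eval(float(xis[np.argmin(np.abs(f))]))


def measure_contact_angles(surfaces: dict, window: float = 3.0,
                           min_points: int = 20,
                           contact_cutoff: float = 1.2) -> ContactGeometry:
    """Intrinsic contact angle, contour tilt and contact radius.

    ``surfaces`` maps labels to (n, 3) point clouds: "ab" the droplet
    interface, "ag" the membrane segment under the droplet (and optionally
    "bg").  The state must be axisymmetric.  The two contours are circle-
    fitted in the (r, y) half-plane within a window of the contact line;
    the refined contact point is the intersection of the two fitted
    circles, and the angles come from the fitted tangents: theta_alpha_star
    between the interface and the alpha-gamma segment (measured through
    the droplet phase), psi_co the tilt of the membrane contour against
    the contact-line plane.  Angles are in degrees.
    """
    for key in ("ab", "ag"):
        if key not in surfaces or len(surfaces[key]) == 0:
            raise GeometryError(f"missing surface '{key}'")
    ab = np.asarray(surfaces["ab"], float)
    ag = np.asarray(surfaces["ag"], float)
    # contact band: ag points adjacent to the ab surface
    tab = cKDTree(ab)
    near = tab.query_ball_point(ag, contact_cutoff, return_length=True)
    loop = ag[np.asarray(near) > 0]
    if len(loop) < 6:
        raise GeometryError("no contact loop: surfaces do not meet")
    # symmetry axis: normal of the band's best-fit plane, through the
    # center of an in-plane circle fit (a plain centroid is biased by
    # azimuthal sampling noise)
    centroid0 = loop.mean(axis=0)
    rel = loop - centroid0
    _, _, vt = np.linalg.svd(rel, full_matrices=False)
    axis = vt[2]
    u, v = vt[0], vt[1]
    cx, cy, r_band = _kasa_circle(rel @ u, rel @ v)
    centroid = centroid0 + cx * u + cy * v
    in_plane = np.column_stack([(loop - centroid) @ u,
                                (loop - centroid) @ v])
    radial_spread = float(np.linalg.norm(in_plane, axis=1).std())
    if radial_spread > 0.25 * r_band:
        raise GeometryError(
            "contact band is strongly noncircular: not axisymmetric")
    geo = ContactGeometry(centroid=centroid, axis=axis, n_points=len(loop),
                          axisymmetric=True)

    def cyl(pts):
        rel = pts - centroid
        yy = rel @ axis
        rr = np.linalg.norm(rel - np.outer(yy, axis), axis=1)
        return np.column_stack([rr, yy])

    r0 = float(r_band)
    contact = np.array([r0, 0.0])
    fits = {}
    for _ in range(3):  # refine contact point and windows
        for name, pts in (("ab", cyl(ab)), ("ag", cyl(ag))):
            dist = np.linalg.norm(pts - contact, axis=1)
            sel = (dist < window) & (pts[:, 0] > 0.25 * r0)
            if sel.sum() < min_points:
                raise GeometryError(
                    f"fit window underpopulated for '{name}' "
                    f"({int(sel.sum())} points)")
            fits[name] = (_QuadCurve(pts[sel], contact), pts[sel])
        contact = _intersect_curves(fits["ab"][0], fits["ag"][0], window)
    t_ab, t_ag = [], []
    for name, store in (("ab", t_ab), ("ag", t_ag)):
        curve, pts = fits[name]
        _, xi_c = curve.residual_xi(contact)
        t = curve.tangent(xi_c)
        # orient from the contact point into the surface's interior
        if np.dot(t, curve.e1) * (curve.xi_mean - xi_c) < 0:
            t = -t
        store.append(t)
    t_ab, t_ag = t_ab[0], t_ag[0]
    theta = np.degrees(np.arccos(np.clip(np.dot(t_ab, t_ag), -1.0, 1.0)))
    psi = np.degrees(np.arctan2(abs(t_ag[1]), abs(t_ag[0])))
    geo.theta_alpha_star = float(theta)
    geo.psi_co = float(psi)
    geo.R_co = float(contact[0])
    geo.L_cl = 2.0 * np.pi * geo.R_co
    return geo


# ----------------------------------------------------------------------
# engulfment classification
# ----------------------------------------------------------------------

@dataclass
class EngulfmentReport:
    """Summary of a vesicle-droplet state."""

    state: str                    # free | partial-open-neck | complete-closed-neck | fission
    symmetry: str                 # axisymmetric | nonaxisymmetric | undetermined
    area_contact: float = 0.0     # A_ag estimate, d^2
    area_free: float = 0.0        # A_bg estimate, d^2
    area_interface: float = 0.0   # alpha-beta interface estimate, d^2
    droplet_diameter: float = float("nan")
    circularity: float = float("nan")
    n_membrane_components: int = 1
    contact: ContactGeometry | None = None


def classify_state(cfg: Configuration,
                   cutoff: float = CONTACT_CUTOFF) -> EngulfmentReport:
    """Classify a configuration into free / partial / complete / fission.

    Always returns a report; fields that cannot be measured (e.g. droplet
    diameter without solute) are NaN.
    """
    lipid = cfg.molecule >= 0
    smask = cfg.species == S
    hmask = cfg.species == H
    n_comp = 1
    if lipid.any():
        labels = _components(cfg.positions[lipid], cfg.box, cutoff)
        n_comp = int(labels.max()) + 1 if labels.size else 0
    report = EngulfmentReport(state="free", symmetry="undetermined",
                              n_membrane_components=n_comp)
    if smask.any():
        try:
            report.droplet_diameter = measure_droplet_shape(cfg).diameter
        except GeometryError:
            pass
    if not lipid.any() or not smask.any():
        return report
    spos = cfg.positions[smask]
    lpos = cfg.positions[lipid]
    stree = cKDTree(spos, boxsize=cfg.box)
    touching = stree.query_ball_point(lpos, cutoff, return_length=True)
    touched_lipid = np.asarray(touching) > 0
    hpos = cfg.positions[hmask]
    h_alpha = np.asarray(
        stree.query_ball_point(hpos, cutoff, return_length=True)) > 0
    report.area_contact = float(h_alpha.sum()) * AREA_PER_SURFACE_BEAD
    try:
        ext_idx, _ = interior_exterior_water(cfg)
    except GeometryError:
        ext_idx = np.flatnonzero(cfg.species == W)
    bpos = cfg.positions[ext_idx]
    if len(bpos):
        btree = cKDTree(bpos, boxsize=cfg.box)
        s_beta = np.asarray(
            btree.query_ball_point(spos, cutoff, return_length=True)) > 0
        h_beta = np.asarray(
            btree.query_ball_point(hpos, cutoff, return_length=True)) > 0
    else:
        s_beta = np.zeros(len(spos), dtype=bool)
        h_beta = np.zeros(len(hpos), dtype=bool)
    report.area_interface = float(s_beta.sum()) * AREA_PER_SURFACE_BEAD
    report.area_free = float((h_beta & ~h_alpha).sum()) * AREA_PER_SURFACE_BEAD
    if n_comp >= 2:
        report.state = "fission"
    elif not touched_lipid.any():
        report.state = "free"
    elif not s_beta.any():
        report.state = "complete-closed-neck"
    else:
        report.state = "partial-open-neck"
    if touched_lipid.any() and len(bpos):
        try:
            geo = extract_contact_line(hpos, spos, bpos, box=cfg.box,
                                       cutoff=cutoff)
            report.contact = geo
            report.circularity = geo.circularity
            if geo.closed_neck:
                report.symmetry = "undetermined"
            else:
                report.symmetry = ("axisymmetric" if geo.axisymmetric
                                   else "nonaxisymmetric")
        except GeometryError:
            pass
    return report
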
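"""Stress-profile calculus: bilayer, leaflet, segment and interfacial tensions.

All tensions derive from differences between normal and tangential
components of the local pressure tensor:

* spherical geometry (vesicles): the radial stress profile
  s(r) = P_N(r) - P_T(r); the bilayer tension is Sigma = Int_0^inf s(r) dr
  and the two leaflet tensions split that integral at the midsurface
  radius R_mid, located at the peak of the chain-bead density.
* planar geometry (slabs): the analogous profile along the interface
  normal, divided by the number of interfaces in the periodic box.
* axisymmetric geometry (vesicle-droplet couples): a 2D map s(r, y) on a
  cylindrical grid; segment and interfacial tensions are line integrals of
  s across the respective surface segment inside labeled integration boxes.

The pairwise virial is assigned in space along the straight interbead line
(Irving-Kirkwood contour) with length-proportional apportioning; only the
conservative (and bonded) forces enter, since the thermostat pair forces
time-average to zero.  Kinetic contributions are included per bead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .configuration import Configuration
from .forcefield import BondedParams, ForceField

DEFAULT_BIN_WIDTH = 0.2  # d, radial/planar bin width
MAP_CELL = 1.0           # d, axisymmetric grid mesh
N_SUBSEGMENTS = 20       # Irving-Kirkwood line discretization
N_BLOCKS = 5             # block averaging for SEMs


class StressError(ValueError):
    pass


def periodic_com(pos: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Center of mass under periodic boundaries (circular-mean method)."""
    theta = 2.0 * np.pi * pos / box
    mean = np.arctan2(np.sin(theta).mean(axis=0), np.cos(theta).mean(axis=0))
    return (mean / (2.0 * np.pi)) % 1.0 * box


def _block_sem(x: np.ndarray, n_blocks: int = N_BLOCKS) -> float:
    x = np.asarray(x, float)
    if x.size < n_blocks or n_blocks < 2:
        return float("nan")
    usable = (x.size // n_blocks) * n_blocks
    blocks = x[:usable].reshape(n_blocks, -1).mean(axis=1)
    return float(blocks.std(ddof=1) / np.sqrt(n_blocks))


def _as_frames(frames) -> list[Configuration]:
    if isinstance(frames, Configuration):
        return [frames]
    out = list(frames)
    if not out:
        raise StressError("empty trajectory window")
    return out


# ----------------------------------------------------------------------
# radial profiles (spherical vesicles)
# ----------------------------------------------------------------------

@dataclass
class RadialStressProfile:
    """Shell-binned P_N, P_T and chain-bead density about a center."""

    r: np.ndarray            # bin centers, d
    P_N: np.ndarray          # kBT / d^3
    P_T: np.ndarray
    rho_C: np.ndarray        # chain beads / d^3
    bin_width: float
    center: np.ndarray
    n_frames: int = 1
    frame_s: np.ndarray | None = field(default=None, repr=False)

    @property
    def s(self) -> np.ndarray:
        """Stress profile s(r) = P_N - P_T."""
        return self.P_N - self.P_T

    def r_mid(self) -> float:
        """Midsurface radius: peak of the chain-bead density profile."""
        if not np.any(self.rho_C > 0):
            raise StressError("no chain-bead density peak: no bilayer in range")
        return float(self.r[int(np.argmax(self.rho_C))])


@dataclass
class TensionReport:
    """Bilayer tension and its leaflet split, with block-average SEMs."""

    Sigma: float
    Sigma_ol: float
    Sigma_il: float
    R_mid: float
    Sigma_sem: float = float("nan")
    Sigma_ol_sem: float = float("nan")
    Sigma_il_sem: float = float("nan")
    n_samples: int = 1


def radial_stress_profile(frames, ff: ForceField | None = None,
                          bonded: BondedParams | None = None,
                          center=None, bin_width: float = DEFAULT_BIN_WIDTH,
                          r_max: float | None = None,
                          nsub: int = N_SUBSEGMENTS,
                          include_kinetic: bool = True) -> RadialStressProfile:
    """Radial stress profile averaged over a trajectory window.

    ``center`` may be an explicit point (error if the lipid center of mass
    drifts more than 1 d from it in any frame) or None, in which case the
    lipid center of mass is recomputed every frame.
    """
    ff = ff or ForceField()
    bonded = bonded or BondedParams()
    frames = _as_frames(frames)
    box = frames[0].box
    if r_max is None:
        r_max = float(box.min()) / 2.0
    nbins = int(np.ceil(r_max / bin_width))
    vol = (4.0 / 3.0) * np.pi * (
        ((np.arange(nbins) + 1) * bin_width) ** 3
        - (np.arange(nbins) * bin_width) ** 3)
    PN = np.zeros(nbins)
    PT = np.zeros(nbins)
    RC = np.zeros(nbins)
    frame_s = np.zeros((len(frames), nbins))
    fixed_center = None if center is None else np.asarray(center, float)
    for k, cfg in enumerate(frames):
        lipid = cfg.molecule >= 0
        c = (periodic_com(cfg.positions[lipid], cfg.box) if lipid.any()
             else cfg.box / 2.0)
        if fixed_center is not None:
            if lipid.any() and np.linalg.norm(c - fixed_center) > 1.0:
                raise StressError(
                    "center drift > 1 d across window without recentering")
            c = fixed_center
        pi, pj = _kernels.build_pair_list(cfg.positions, cfg.box, 1.0)
        pn, pt, rc = _kernels.radial_stress_bins(
            cfg.positions, cfg.velocities, cfg.species, ff.f, cfg.box,
            cfg.bonds, cfg.angles, bonded.k_bond, bonded.l0,
            bonded.k_angle, bonded.theta0, pi, pj, c, bin_width, nbins,
            nsub, include_kinetic)
        PN += pn / vol
        PT += pt / vol
        RC += rc / vol
        frame_s[k] = (pn - pt) / vol
    n = len(frames)
    return RadialStressProfile(
        r=(np.arange(nbins) + 0.5) * bin_width,
        P_N=PN / n, P_T=PT / n, rho_C=RC / n,
        bin_width=bin_width, center=np.asarray(c, float),
        n_frames=n, frame_s=frame_s)


def tensions_from_profile(profile: RadialStressProfile,
                          n_blocks: int = N_BLOCKS) -> TensionReport:
    """Integrate s(r) into bilayer and leaflet tensions.

    The leaflet split is at R_mid; Sigma = Sigma_ol + Sigma_il holds
    exactly because the two sums partition the same bins.
    """
    r_mid = profile.r_mid()
    dr = profile.bin_width
    inner = profile.r <= r_mid
    s = profile.s
    sig_il = float(s[inner].sum() * dr)
    sig_ol = float(s[~inner].sum() * dr)
    report = TensionReport(
        Sigma=sig_il + sig_ol, Sigma_ol=sig_ol, Sigma_il=sig_il,
        R_mid=r_mid, n_samples=profile.n_frames)
    if profile.frame_s is not None and profile.n_frames >= n_blocks:
        per_frame_il = profile.frame_s[:, inner].sum(axis=1) * dr
        per_frame_ol = profile.frame_s[:, ~inner].sum(axis=1) * dr
        report.Sigma_il_sem = _block_sem(per_frame_il, n_blocks)
        report.Sigma_ol_sem = _block_sem(per_frame_ol, n_blocks)
        report.Sigma_sem = _block_sem(per_frame_il + per_frame_ol, n_blocks)
    return report


# ----------------------------------------------------------------------
# planar profiles (slabs)
# ----------------------------------------------------------------------

@dataclass
class PlanarStressProfile:
    """Slice-binned normal/transverse pressure along one axis."""

    z: np.ndarray
    P_N: np.ndarray
    P_T: np.ndarray
    bin_width: float
    axis: int
    n_interfaces: int
    n_frames: int = 1
    frame_s: np.ndarray | None = field(default=None, repr=False)

    @property
    def s(self) -> np.ndarray:
        return self.P_N - self.P_T

    def tension_per_interface(self) -> float:
        """Integral of s along the normal / number of interfaces."""
        return float(self.s.sum() * self.bin_width / self.n_interfaces)

    def tension_sem(self, n_blocks: int = N_BLOCKS) -> float:
        if self.frame_s is None:
            return float("nan")
        per = self.frame_s.sum(axis=1) * self.bin_width / self.n_interfaces
        return _block_sem(per, n_blocks)


def planar_stress_profile(frames, ff: ForceField | None = None,
                          bonded: BondedParams | None = None,
                          axis: int = 2, bin_width: float = DEFAULT_BIN_WIDTH,
                          n_interfaces: int = 2,
                          include_kinetic: bool = True,
                          check_wrap: bool = True) -> PlanarStressProfile:
    """Stress profile across a planar slab, periodic in the transverse plane.

    Raises if the minority (S) slab touches both box faces along the
    normal, i.e. spans the periodic boundary without unwrapping.
    """
    ff = ff or ForceField()
    bonded = bonded or BondedParams()
    frames = _as_frames(frames)
    box = frames[0].box
    L = float(box[axis])
    nbins = int(round(L / bin_width))
    bin_w = L / nbins
    area = float(np.prod(box)) / L
    vol = area * bin_w
    PN = np.zeros(nbins)
    PT = np.zeros(nbins)
    frame_s = np.zeros((len(frames), nbins))
    for k, cfg in enumerate(frames):
        if check_wrap:
            _check_slab_wrap(cfg, axis, nbins)
        pi, pj = _kernels.build_pair_list(cfg.positions, cfg.box, 1.0)
        pn, pt = _kernels.planar_stress_bins(
            cfg.positions, cfg.velocities, cfg.species, ff.f, cfg.box,
            cfg.bonds, bonded.k_bond, bonded.l0, pi, pj, axis, nbins,
            include_kinetic)
        PN += pn / vol
        PT += pt / vol
        frame_s[k] = (pn - pt) / vol
    n = len(frames)
    return PlanarStressProfile(
        z=(np.arange(nbins) + 0.5) * bin_w, P_N=PN / n, P_T=PT / n,
        bin_width=bin_w, axis=axis, n_interfaces=n_interfaces,
        n_frames=n, frame_s=frame_s)


def _check_slab_wrap(cfg: Configuration, axis: int, nbins: int) -> None:
    from .forcefield import S as S_CODE
    smask = cfg.species == S_CODE
    if not smask.any():
        return
    zs = cfg.positions[smask, axis]
    L = cfg.box[axis]
    # coarse 1 d slices: enough beads per slice for a stable occupancy test
    coarse = max(int(L), 4)
    hist, _ = np.histogram(zs, bins=coarse, range=(0.0, L))
    occupied = hist > 0.3 * hist.max()
    if occupied[0] and occupied[-1]:
        raise StressError(
            "slab spans the periodic boundary; recenter (unwrap) it first")


# ----------------------------------------------------------------------
# axisymmetric stress maps (vesicle-droplet couples)
# ----------------------------------------------------------------------

@dataclass
class AxisymStressMap:
    """Cylindrical-grid local stress for an axisymmetric state.

    ``s = P_yy - (P_rr + P_phiphi)/2``: the component along the symmetry
    axis minus the mean of the two transverse components.
    """

    r: np.ndarray            # radial cell centers
    y: np.ndarray            # axial cell centers (relative to y0)
    P_yy: np.ndarray         # (nr, ny)
    P_trans: np.ndarray
    counts: np.ndarray       # beads per cell (occupancy diagnostics)
    cell: float
    axis_point: tuple        # (x, z) of the symmetry axis
    y0: float
    n_frames: int = 1
    frame_s: np.ndarray | None = field(default=None, repr=False)

    @property
    def s(self) -> np.ndarray:
        return self.P_yy - self.P_trans


@dataclass
class IntegrationBox:
    """Rectangular (r, y) region crossed perpendicular to a segment."""

    r_min: float
    r_max: float
    y_min: float
    y_max: float
    path_axis: str  # 'r' or 'y': direction of the integration path

    def __post_init__(self):
        if self.path_axis not in ("r", "y"):
            raise ValueError("path_axis must be 'r' or 'y'")
        if self.r_min >= self.r_max or self.y_min >= self.y_max:
            raise ValueError("degenerate integration box")

    def overlaps(self, other: "IntegrationBox") -> bool:
        return not (self.r_max <= other.r_min or other.r_max <= self.r_min
                    or self.y_max <= other.y_min or other.y_max <= self.y_min)


@dataclass
class SegmentTensions:
    """Interfacial and membrane-segment tensions from an axisymmetric map."""

    Sigma_ab: float = float("nan")   # alpha-beta interfacial tension
    Sigma_ag: float = float("nan")   # alpha-gamma membrane segment
    Sigma_bg: float = float("nan")   # beta-gamma membrane segment
    Sigma_ab_sem: float = float("nan")
    Sigma_ag_sem: float = float("nan")
    Sigma_bg_sem: float = float("nan")


def axisym_stress_map(frames, ff: ForceField | None = None,
                      bonded: BondedParams | None = None,
                      axis_point=None, y0: float | None = None,
                      r_max: float | None = None, y_half: float | None = None,
                      cell: float = MAP_CELL, nsub: int = N_SUBSEGMENTS,
                      include_kinetic: bool = True,
                      circularity: float | None = None,
                      circularity_threshold: float = 0.95) -> AxisymStressMap:
    """2D local stress map about a symmetry axis parallel to y.

    ``circularity`` (when supplied from the geometry module) must exceed
    the axisymmetry threshold, mirroring the restriction of the contact-
    line force balance to axisymmetric shapes.
    """
    if circularity is not None and circularity < circularity_threshold:
        raise StressError(
            f"state is not axisymmetric (circularity {circularity:.3f} < "
            f"{circularity_threshold}); refusing the axisymmetric analysis")
    ff = ff or ForceField()
    bonded = bonded or BondedParams()
    frames = _as_frames(frames)
    box = frames[0].box
    if axis_point is None:
        axis_point = (box[0] / 2.0, box[2] / 2.0)
    if y0 is None:
        y0 = box[1] / 2.0
    if r_max is None:
        r_max = min(box[0], box[2]) / 2.0
    if y_half is None:
        y_half = box[1] / 2.0
    nr = int(np.ceil(r_max / cell))
    ny = 2 * int(np.ceil(y_half / cell))
    rr = np.arange(nr)
    vol = (np.pi * (((rr + 1) * cell) ** 2 - (rr * cell) ** 2) * cell)
    vol = vol[:, None]
    PYY = np.zeros((nr, ny))
    PTR = np.zeros((nr, ny))
    CNT = np.zeros((nr, ny))
    frame_s = np.zeros((len(frames), nr, ny))
    for k, cfg in enumerate(frames):
        pi, pj = _kernels.build_pair_list(cfg.positions, cfg.box, 1.0)
        pyy, ptr, cnt = _kernels.axisym_stress_bins(
            cfg.positions, cfg.velocities, cfg.species, ff.f, cfg.box,
            cfg.bonds, bonded.k_bond, bonded.l0, pi, pj,
            float(axis_point[0]), float(axis_point[1]), float(y0), cell,
            nr, ny, nsub, include_kinetic)
        PYY += pyy / vol
        PTR += ptr / vol
        CNT += cnt
        frame_s[k] = (pyy - ptr) / vol
    n = len(frames)
    return AxisymStressMap(
        r=(rr + 0.5) * cell,
        y=(np.arange(ny) - ny / 2 + 0.5) * cell,
        P_yy=PYY / n, P_trans=PTR / n, counts=CNT / n, cell=cell,
        axis_point=tuple(axis_point), y0=float(y0), n_frames=n,
        frame_s=frame_s)


def _box_tension(s_grid: np.ndarray, amap: AxisymStressMap,
                 b: IntegrationBox) -> float:
    ir = (amap.r >= b.r_min) & (amap.r < b.r_max)
    iy = (amap.y >= b.y_min) & (amap.y < b.y_max)
    if not ir.any() or not iy.any():
        raise StressError("integration box contains no grid cells")
    sub = s_grid[np.ix_(ir, iy)]
    if b.path_axis == "y":
        per_line = sub.sum(axis=1) * amap.cell  # integrate along y
    else:
        per_line = sub.sum(axis=0) * amap.cell  # integrate along r
    return float(per_line.mean())


def segment_and_interface_tensions(amap: AxisymStressMap,
                                   boxes: dict,
                                   min_occupancy: float = 0.1,
                                   n_blocks: int = N_BLOCKS) -> SegmentTensions:
    """Integrate the stress map across each labeled surface segment.

    ``boxes`` maps segment names among {"ab", "ag", "bg"} to
    :class:`IntegrationBox` placed over the interface / membrane segments
    near the symmetry axis.  Boxes must be pairwise disjoint (a box
    touching two segments, e.g. across a narrow neck, must be repositioned).
    Raises when a requested segment has essentially no beads in its box.
    """
    names = list(boxes)
    unknown = set(names) - {"ab", "ag", "bg"}
    if unknown:
        raise StressError(f"unknown segment labels: {sorted(unknown)}")
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            if boxes[a].overlaps(boxes[b]):
                raise StressError(
                    f"integration boxes '{a}' and '{b}' overlap; reposition "
                    "them so each crosses a single surface segment")
    out = SegmentTensions()
    for name, b in boxes.items():
        ir = (amap.r >= b.r_min) & (amap.r < b.r_max)
        iy = (amap.y >= b.y_min) & (amap.y < b.y_max)
        if not ir.any() or not iy.any() or \
                amap.counts[np.ix_(ir, iy)].mean() < min_occupancy:
            raise StressError(
                f"segment '{name}' missing: integration box is empty")
        val = _box_tension(amap.s, amap, b)
        sem = float("nan")
        if amap.frame_s is not None and amap.n_frames >= n_blocks:
            per = np.array([_box_tension(fs, amap, b)
                            for fs in amap.frame_s])
            sem = _block_sem(per, n_blocks)
        setattr(out, f"Sigma_{name}", val)
        setattr(out, f"Sigma_{name}_sem", sem)
    return out
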
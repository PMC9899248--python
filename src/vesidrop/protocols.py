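"""In-silico experimental protocols: deflation, tensionless-volume search,
staged engulfment runs.

Vesicle volume is tracked by the dimensionless parameter
nu = N_W_in / N_W_isp, the ratio of the current interior water bead count
to that of the initially assembled sphere.  Osmotic deflation is pure bead
bookkeeping: interior water beads are relocated to voids in the exterior
solution, conserving every species count exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .configuration import Configuration
from .engine import DPDSimulation
from .forcefield import BondedParams, ForceField, S, W
from .geometry import (EngulfmentReport, GeometryError, classify_state,
                       interior_exterior_water, majority_cluster)
from .stress import radial_stress_profile, tensions_from_profile


class ProtocolError(RuntimeError):
    pass


@dataclass
class VolumeState:
    """Interior-water bookkeeping of a vesicle."""

    n_water_in: int
    n_water_isp: int     # interior waters of the initially assembled sphere
    nu0: float | None = None

    @property
    def nu(self) -> float:
        return self.n_water_in / self.n_water_isp

    def __post_init__(self):
        if not 0 < self.n_water_in <= self.n_water_isp:
            raise ProtocolError("volume parameter must satisfy 0 < nu <= 1")


@dataclass
class ProtocolSchedule:
    """Deflation schedule and equilibration/termination settings."""

    delta_nu: float = 0.1
    steps_per_stage: int = 2000       # equilibration span per deflation step
    sample_every: int = 20
    tension_tolerance: float = 0.05   # |Sigma| below which "tensionless"
    max_stages: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.delta_nu <= 0 or self.tension_tolerance <= 0:
            raise ProtocolError("delta_nu and tolerance must be positive")


# ----------------------------------------------------------------------
# deflation
# ----------------------------------------------------------------------

def deflate_to(cfg: Configuration, target_nu: float, state: VolumeState,
               seed: int = 0, void_min_dist: float = 0.35) -> VolumeState:
    """Relocate interior water beads to the exterior until nu = target_nu.

    Modifies ``cfg`` in place; exactly round((nu - target_nu) * N_W_isp)
    interior W beads move to random exterior voids.  The total bead count
    and all species counts are unchanged.  Raises if the membrane has a
    pore (interior and exterior water connected) or the target exceeds
    the current volume.
    """
    n_move = int(round((state.nu - target_nu) * state.n_water_isp))
    if n_move < 0:
        raise ProtocolError("target_nu exceeds the current volume")
    if n_move == 0:
        return state
    ext_idx, int_idx = interior_exterior_water(cfg)  # raises on pore
    if n_move > len(int_idx):
        raise ProtocolError("not enough interior water beads to remove")
    rng = np.random.default_rng(seed)
    movers = rng.choice(int_idx, size=n_move, replace=False)
    keep = np.ones(cfg.n_beads, dtype=bool)
    keep[movers] = False
    tree = cKDTree(cfg.positions[keep], boxsize=cfg.box)
    ext_pos = cfg.positions[ext_idx]
    placed = 0
    for _ in range(200):
        if placed >= n_move:
            break
        anchors = ext_pos[rng.integers(0, len(ext_pos),
                                       size=4 * (n_move - placed))]
        cand = (anchors + rng.uniform(-1.2, 1.2, anchors.shape)) % cfg.box
        d, _ = tree.query(cand, k=1)
        good = cand[d > void_min_dist]
        take = min(len(good), n_move - placed)
        if take:
            sel = movers[placed:placed + take]
            cfg.positions[sel] = good[:take]
            cfg.velocities[sel] = 0.0
            tree = cKDTree(
                np.vstack([cfg.positions[keep], cfg.positions[movers[:placed + take]]]),
                boxsize=cfg.box)
            placed += take
    if placed < n_move:
        raise ProtocolError("could not find exterior voids for all waters")
    return VolumeState(n_water_in=state.n_water_in - n_move,
                       n_water_isp=state.n_water_isp, nu0=state.nu0)


# ----------------------------------------------------------------------
# tensionless-volume search
# ----------------------------------------------------------------------

@dataclass
class TensionlessResult:
    nu0: float
    crossed_zero: bool
    table: list  # (nu, Sigma) pairs examined


def find_tensionless_volume(sigma_of_nu, nu_range=(0.8, 1.0),
                            tolerance: float = 0.05,
                            max_iter: int = 40) -> TensionlessResult:
    """Locate nu0 where the bilayer tension crosses zero.

    ``sigma_of_nu`` is either a callable nu -> Sigma (e.g. measuring an
    equilibrated, deflated vesicle) or a table of (nu, Sigma) pairs.
    Bisection refines the bracketing interval until |Sigma| < tolerance
    or the interval is exhausted.  Without a sign change the flagged
    argmin of |Sigma| is returned.
    """
    table: list[tuple[float, float]] = []
    if callable(sigma_of_nu):
        fn = sigma_of_nu
        lo, hi = float(nu_range[0]), float(nu_range[1])
        s_lo, s_hi = fn(lo), fn(hi)
        table += [(lo, s_lo), (hi, s_hi)]
        if s_lo * s_hi > 0:
            best = min(table, key=lambda t: abs(t[1]))
            return TensionlessResult(nu0=best[0], crossed_zero=False,
                                     table=table)
        for _ in range(max_iter):
            mid = 0.5 * (lo + hi)
            s_mid = fn(mid)
            table.append((mid, s_mid))
            if abs(s_mid) < tolerance or (hi - lo) < 1e-4:
                return TensionlessResult(nu0=mid, crossed_zero=True,
                                         table=table)
            if s_lo * s_mid <= 0:
                hi, s_hi = mid, s_mid
            else:
                lo, s_lo = mid, s_mid
        return TensionlessResult(nu0=0.5 * (lo + hi), crossed_zero=True,
                                 table=table)
    # tabulated route
    pts = sorted((float(n), float(s)) for n, s in sigma_of_nu)
    if len(pts) < 2:
        raise ProtocolError("need at least two (nu, Sigma) entries")
    table = list(pts)
    for (n1, s1), (n2, s2) in zip(pts[:-1], pts[1:]):
        if s1 == 0.0:
            return TensionlessResult(nu0=n1, crossed_zero=True, table=table)
        if s1 * s2 < 0:
            nu0 = n1 + (n2 - n1) * (-s1) / (s2 - s1)
            return TensionlessResult(nu0=nu0, crossed_zero=True, table=table)
    if pts[-1][1] == 0.0:
        return TensionlessResult(nu0=pts[-1][0], crossed_zero=True,
                                 table=table)
    best = min(pts, key=lambda t: abs(t[1]))
    return TensionlessResult(nu0=best[0], crossed_zero=False, table=table)


def measure_bilayer_tension(cfg: Configuration, ff: ForceField,
                            bonded: BondedParams, seed: int = 0,
                            equil_steps: int = 500, sample_steps: int = 500,
                            frame_every: int = 50):
    """Equilibrate briefly and integrate the radial stress profile."""
    sim = DPDSimulation(cfg.copy(), ff, bonded, seed=seed)
    sim.run(equil_steps)
    frames = []
    sim.run(sample_steps, frame_every=frame_every,
            frame_callback=lambda c, s: frames.append(c.copy()))
    prof = radial_stress_profile(frames, ff, bonded)
    return tensions_from_profile(prof)


# ----------------------------------------------------------------------
# engulfment run
# ----------------------------------------------------------------------

@dataclass
class EngulfmentRun:
    """Per-stage record of a staged deflation/engulfment protocol."""

    reports: list = field(default_factory=list)      # EngulfmentReport
    nus: list = field(default_factory=list)
    terminated: str = "schedule-end"


def place_droplet_near(vesicle: Configuration, meta: dict,
                       droplet: Configuration, gap: float = 1.0):
    """Insert droplet beads adjacent to the vesicle membrane (+x side).

    Returns (merged configuration, droplet center, droplet radius); the
    center/radius pair is what exterior filling must keep water-free.
    """
    from .configuration import merge
    drop = droplet.copy()
    r_drop = float(
        np.linalg.norm(drop.positions - drop.positions.mean(0), axis=1).max())
    center = meta["center"] + np.array(
        [meta["r_head_out"] + r_drop + gap, 0.0, 0.0])
    drop.positions += center - drop.positions.mean(axis=0)
    drop.box = vesicle.box.copy()
    drop.wrap()
    return merge(vesicle, drop), center, r_drop


def run_engulfment(cfg: Configuration, state: VolumeState,
                   schedule: ProtocolSchedule,
                   ff: ForceField | None = None,
                   bonded: BondedParams | None = None) -> EngulfmentRun:
    """Staged deflation with per-stage equilibration and classification.

    After each deflation step of ``schedule.delta_nu`` the couple is
    equilibrated and classified; the run terminates at complete
    engulfment, fission, or the end of the schedule.  Aborts if the
    droplet dissolves (no majority S cluster: below phase coexistence).
    """
    ff = ff or ForceField()
    bonded = bonded or BondedParams()
    sim = DPDSimulation(cfg, ff, bonded, seed=schedule.seed)
    run = EngulfmentRun()
    for stage in range(schedule.max_stages):
        sim.run(schedule.steps_per_stage)
        smask = cfg.species == S
        if smask.any():
            try:
                cluster = majority_cluster(cfg.positions[smask], cfg.box,
                                           min_size=max(
                                               10, int(0.5 * smask.sum())))
            except GeometryError as err:
                raise ProtocolError(
                    "droplet dissolved: below coexistence") from err
        report = classify_state(cfg)
        run.reports.append(report)
        run.nus.append(state.nu)
        if report.state == "complete-closed-neck":
            run.terminated = "complete"
            return run
        if report.state == "fission":
            run.terminated = "fission"
            return run
        target = state.nu - schedule.delta_nu
        if target <= 0.05:
            break
        state = deflate_to(cfg, target, state, seed=schedule.seed + stage)
        sim._compute_forces()
    run.terminated = "schedule-end"
    return run
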
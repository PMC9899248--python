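"""Minimal DPD engine: thermostatted velocity-Verlet dynamics.

The integrator is the standard DPD velocity-Verlet scheme: half kick,
drift, force evaluation with the half-kicked velocities entering the
dissipative force, half kick.  All pair forces are antisymmetric, so total
momentum is conserved to floating-point accumulation.  The random force
draws from a counter-based per-pair hash RNG keyed on (seed, step, pair),
making trajectories bit-reproducible and independent of iteration order.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .configuration import Configuration
from .forcefield import BondedParams, ForceField


class OverlappingBeadsError(ValueError):
    """Two beads at exactly zero separation: force direction undefined."""


class UnstableTimestepError(RuntimeError):
    """A bead moved farther than d/2 in one step."""


@dataclass
class ThermoObservables:
    """Block of thermodynamic observables from a trajectory window.

    ``pressure`` is the excess (virial-only) pressure Sigma f.r / (3V),
    excluding the ideal-gas kinetic contribution rho kBT, matching the
    convention in which the bulk DPD water value is quoted.
    """

    temperature: float
    pressure: float
    momentum: np.ndarray
    n_samples: int
    pressure_sem: float = 0.0
    temperature_sem: float = 0.0


@dataclass
class ThermoSeries:
    """Per-sample records accumulated while running."""

    steps: list = field(default_factory=list)
    temperature: list = field(default_factory=list)
    virial: list = field(default_factory=list)


def kinetic_temperature(cfg: Configuration, mass: float = 1.0) -> float:
    v2 = np.einsum("ij,ij->", cfg.velocities, cfg.velocities)
    return float(mass * v2 / (3.0 * cfg.n_beads))


def total_momentum(cfg: Configuration, mass: float = 1.0) -> np.ndarray:
    return mass * cfg.velocities.sum(axis=0)


def pairwise_force(cfg: Configuration, ff: ForceField, i: int, j: int,
                   step: int = 0, seed: int = 0,
                   parts: str = "c") -> np.ndarray:
    """Force on bead ``i`` from bead ``j``.

    ``parts`` selects components: "c" conservative only, "cd" adds the
    dissipative force, "cdr" the full DPD force.  Raises
    :class:`OverlappingBeadsError` for exactly coincident beads.
    """
    dr = cfg.minimum_image(i, j)
    r = float(np.linalg.norm(dr))
    if r == 0.0:
        raise OverlappingBeadsError(f"beads {i} and {j} coincide")
    if r >= ff.d:
        return np.zeros(3)
    e = dr / r
    w = 1.0 - r / ff.d
    f = ff.f[cfg.species[i], cfg.species[j]] * w
    if "d" in parts:
        dv = cfg.velocities[i] - cfg.velocities[j]
        f += -ff.gamma * w * w * float(e @ dv)
    if "r" in parts:
        u = _kernels.pair_uniform(seed, step, i, j)
        f += ff.sigma / np.sqrt(ff.dt) * w * (np.sqrt(12.0) * (u - 0.5))
    return f * e


class DPDSimulation:
    """Drives a :class:`Configuration` forward in time.

    Parameters
    ----------
    cfg
        Initial configuration (advanced in place).
    ff
        Force field, thermostat and timestep parameters.
    bonded
        Bond/bending parameters for the lipid topology.
    seed
        Master seed for the random force stream.
    """

    def __init__(self, cfg: Configuration, ff: ForceField | None = None,
                 bonded: BondedParams | None = None, seed: int = 0):
        self.cfg = cfg
        self.ff = ff or ForceField()
        self.bonded = bonded or BondedParams()
        self.seed = int(seed)
        self.step_count = 0
        self.series = ThermoSeries()
        self._forces = np.zeros_like(cfg.positions)
        self._virial = 0.0
        self._compute_forces()

    # ------------------------------------------------------------------
    def _compute_forces(self, brute_force: bool = False) -> None:
        cfg, ff = self.cfg, self.ff
        self._forces[:] = 0.0
        kernel = (_kernels.nonbonded_forces_bruteforce if brute_force
                  else _kernels.nonbonded_forces)
        sigma_dt = ff.sigma / np.sqrt(ff.dt) if ff.gamma > 0 else 0.0
        virial, overlap = kernel(
            cfg.positions, cfg.velocities, cfg.species, ff.f, cfg.box,
            ff.gamma, sigma_dt, self.seed, self.step_count, self._forces)
        if overlap:
            raise OverlappingBeadsError(
                "configuration contains exactly coincident beads")
        if cfg.bonds.size or cfg.angles.size:
            _, vb = _kernels.bonded_forces(
                cfg.positions, cfg.box, cfg.bonds, cfg.angles,
                self.bonded.k_bond, self.bonded.l0,
                self.bonded.k_angle, self.bonded.theta0, self._forces)
            virial += vb
        self._virial = virial

    @property
    def forces(self) -> np.ndarray:
        return self._forces.copy()

    @property
    def virial(self) -> float:
        """Current conservative + bonded pair virial Sigma f.r."""
        return self._virial

    def excess_pressure(self) -> float:
        """Instantaneous virial pressure, kinetic term excluded."""
        return self._virial / (3.0 * self.cfg.volume)

    # ------------------------------------------------------------------
    def run(self, n_steps: int, sample_every: int = 0,
            frame_every: int = 0, frame_callback=None) -> ThermoSeries:
        """Advance ``n_steps``; optionally sample thermo / frames.

        Raises :class:`UnstableTimestepError` if any bead moves more than
        d/2 in a single step.
        """
        cfg, ff = self.cfg, self.ff
        dt = ff.dt
        half = 0.5 * dt / ff.mass
        max_step2 = (0.5 * ff.d) ** 2
        for _ in range(n_steps):
            cfg.velocities += half * self._forces
            disp2 = dt * dt * np.einsum(
                "ij,ij->i", cfg.velocities, cfg.velocities).max()
            if disp2 > max_step2:
                raise UnstableTimestepError(
                    f"unstable timestep: displacement {np.sqrt(disp2):.3f} d "
                    f"> d/2 at step {self.step_count}")
            cfg.positions += dt * cfg.velocities
            cfg.wrap()
            self.step_count += 1
            self._compute_forces()
            cfg.velocities += half * self._forces
            if sample_every and self.step_count % sample_every == 0:
                self.series.steps.append(self.step_count)
                self.series.temperature.append(
                    kinetic_temperature(cfg, ff.mass))
                self.series.virial.append(self._virial)
            if frame_every and frame_callback is not None \
                    and self.step_count % frame_every == 0:
                frame_callback(cfg, self.step_count)
        return self.series

    def minimize(self, n_steps: int = 1000, max_disp: float = 0.05) -> None:
        """Capped-displacement steepest descent (no thermostat, no inertia).

        Used to relax freshly assembled configurations before dynamics.
        """
        cfg = self.cfg
        gamma_save, self.ff.gamma = self.ff.gamma, 0.0
        try:
            for _ in range(n_steps):
                self._compute_forces()
                f = self._forces
                fmax = np.sqrt(np.einsum("ij,ij->i", f, f).max())
                if fmax < 1e-10:
                    break
                scale = min(max_disp / fmax, 0.02)
                cfg.positions += scale * f
                cfg.wrap()
        finally:
            self.ff.gamma = gamma_save
        cfg.velocities[:] = 0.0
        self._compute_forces()

    def trajectory_hash(self) -> str:
        """SHA-256 over positions and velocities (determinism checks)."""
        h = hashlib.sha256()
        h.update(self.cfg.positions.tobytes())
        h.update(self.cfg.velocities.tobytes())
        return h.hexdigest()


def measure_thermo(sim: DPDSimulation, discard: int = 0,
                   n_blocks: int = 5) -> ThermoObservables:
    """Average the sampled window into a :class:`ThermoObservables`.

    ``discard`` drops the first samples (equilibration); SEMs come from
    block averages over ``n_blocks`` blocks.
    """
    vir = np.asarray(sim.series.virial[discard:], dtype=float)
    temp = np.asarray(sim.series.temperature[discard:], dtype=float)
    if vir.size == 0:
        raise ValueError("empty thermo window: nothing sampled")
    volume = sim.cfg.volume
    p = vir / (3.0 * volume)
    return ThermoObservables(
        temperature=float(temp.mean()),
        pressure=float(p.mean()),
        momentum=total_momentum(sim.cfg, sim.ff.mass),
        n_samples=int(vir.size),
        pressure_sem=_block_sem(p, n_blocks),
        temperature_sem=_block_sem(temp, n_blocks),
    )


def _block_sem(x: np.ndarray, n_blocks: int) -> float:
    if x.size < n_blocks or n_blocks < 2:
        return float("nan")
    usable = (x.size // n_blocks) * n_blocks
    blocks = x[:usable].reshape(n_blocks, -1).mean(axis=1)
    return float(blocks.std(ddof=1) / np.sqrt(n_blocks))
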
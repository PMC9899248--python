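"""Particle configuration container: periodic box, beads, topology."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .forcefield import SPECIES

_EMPTY_BONDS = np.empty((0, 2), dtype=np.int32)
_EMPTY_ANGLES = np.empty((0, 3), dtype=np.int32)


@dataclass
class Configuration:
    """A snapshot of the bead system.

    Attributes
    ----------
    box
        Cuboid edge lengths (Lx, Ly, Lz) in units of d; periodic in all
        three directions.
    positions, velocities
        (N, 3) arrays in units of d and d/tau.
    species
        (N,) int8 type codes into :data:`vesidrop.forcefield.SPECIES`.
    molecule
        (N,) int32 molecule id; -1 for unbonded solvent beads, >= 0 for
        lipid molecules.
    bonds, angles
        Bonded topology as index pairs / triples.
    """

    box: np.ndarray
    positions: np.ndarray
    velocities: np.ndarray
    species: np.ndarray
    molecule: np.ndarray = None
    bonds: np.ndarray = field(default_factory=lambda: _EMPTY_BONDS.copy())
    angles: np.ndarray = field(default_factory=lambda: _EMPTY_ANGLES.copy())

    def __post_init__(self) -> None:
        self.box = np.asarray(self.box, dtype=np.float64).reshape(3)
        self.positions = np.ascontiguousarray(self.positions, dtype=np.float64)
        if self.velocities is None:
            self.velocities = np.zeros_like(self.positions)
        self.velocities = np.ascontiguousarray(self.velocities, dtype=np.float64)
        self.species = np.ascontiguousarray(self.species, dtype=np.int8)
        n = len(self.positions)
        if self.positions.shape != (n, 3) or self.velocities.shape != (n, 3):
            raise ValueError("positions/velocities must be (N, 3)")
        if self.species.shape != (n,):
            raise ValueError("species must be (N,)")
        if np.any(self.species < 0) or np.any(self.species >= len(SPECIES)):
            raise ValueError("species codes outside {H, C, W, S}")
        if self.molecule is None:
            self.molecule = np.full(n, -1, dtype=np.int32)
        self.molecule = np.ascontiguousarray(self.molecule, dtype=np.int32)
        self.bonds = np.ascontiguousarray(self.bonds, dtype=np.int32).reshape(-1, 2)
        self.angles = np.ascontiguousarray(self.angles, dtype=np.int32).reshape(-1, 3)
        for arr, what in ((self.bonds, "bond"), (self.angles, "angle")):
            if arr.size and (arr.min() < 0 or arr.max() >= n):
                raise ValueError(f"{what} references bead index outside configuration")
        if np.any(self.box <= 0):
            raise ValueError("box edges must be positive")
        self.wrap()

    # ------------------------------------------------------------------
    @property
    def n_beads(self) -> int:
        return len(self.positions)

    @property
    def volume(self) -> float:
        return float(np.prod(self.box))

    @property
    def density(self) -> float:
        return self.n_beads / self.volume

    def wrap(self) -> None:
        """Fold all positions into the primary box [0, L)."""
        np.mod(self.positions, self.box, out=self.positions)

    def copy(self) -> "Configuration":
        return Configuration(
            box=self.box.copy(),
            positions=self.positions.copy(),
            velocities=self.velocities.copy(),
            species=self.species.copy(),
            molecule=self.molecule.copy(),
            bonds=self.bonds.copy(),
            angles=self.angles.copy(),
        )

    def species_counts(self) -> dict:
        """Number of beads of each species, keyed by letter."""
        return {name: int(np.sum(self.species == i)) for i, name in enumerate(SPECIES)}

    def minimum_image(self, i: int, j: int) -> np.ndarray:
        """Displacement r_i - r_j under the minimum-image convention."""
        dr = self.positions[i] - self.positions[j]
        dr -= self.box * np.round(dr / self.box)
        return dr


def merge(a: Configuration, b: Configuration) -> Configuration:
    """Concatenate two configurations sharing the same box.

    Bead indices of ``b``'s topology are shifted; molecule ids of ``b`` are
    renumbered above ``a``'s.
    """
    if not np.allclose(a.box, b.box):
        raise ValueError("cannot merge configurations with different boxes")
    off = a.n_beads
    mol_b = b.molecule.copy()
    if mol_b.size and mol_b.max() >= 0:
        mol_b[mol_b >= 0] += int(a.molecule.max(initial=-1)) + 1
    return Configuration(
        box=a.box.copy(),
        positions=np.vstack([a.positions, b.positions]),
        velocities=np.vstack([a.velocities, b.velocities]),
        species=np.concatenate([a.species, b.species]),
        molecule=np.concatenate([a.molecule, mol_b]),
        bonds=np.vstack([a.bonds, b.bonds + off]) if (a.bonds.size or b.bonds.size)
        else _EMPTY_BONDS.copy(),
        angles=np.vstack([a.angles, b.angles + off]) if (a.angles.size or b.angles.size)
        else _EMPTY_ANGLES.copy(),
    )
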
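"""DPD force field: bead species and pairwise force parameters.

The model contains four bead species — lipid head (H), lipid chain (C),
water (W) and solute (S) — interacting through the soft, purely repulsive
DPD conservative force

    F_ij = f_ij (1 - r_ij/d) r_hat       for r_ij < d,  0 otherwise,

together with the standard pairwise dissipative and random forces that form
the DPD thermostat.  All quantities are expressed in simulation units: the
bead diameter d (0.8 nm) as length unit, the thermal energy k_B T as energy
unit, and the bead mass m as mass unit, so that the intrinsic time unit is
tau = d sqrt(m / k_B T).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Bead species, in the order used for integer type codes.
SPECIES = ("H", "C", "W", "S")

H, C, W, S = 0, 1, 2, 3

#: Map species letter -> integer type code.
SPECIES_INDEX = {name: i for i, name in enumerate(SPECIES)}

#: d in nanometers, used only when writing unit headers.
D_NM = 0.8


def default_force_matrix() -> np.ndarray:
    """Pairwise force amplitudes f_ij in units of k_B T / d.

    The H/C beads interact identically with W and S beads (f_HW = f_HS and
    f_CW = f_CS), so water and solute have the same affinity for the
    membrane and the droplet contact angle comes out close to 90 degrees.
    The large f_WS = 70 drives liquid-liquid phase separation of the W/S
    mixture at small solute fractions.
    """
    f = np.empty((4, 4), dtype=np.float64)
    #             H    C    W    S
    f[H] = (30.0, 50.0, 25.0, 25.0)
    f[C] = (50.0, 10.0, 75.0, 75.0)
    f[W] = (25.0, 75.0, 25.0, 70.0)
    f[S] = (25.0, 75.0, 70.0, 25.0)
    return f


@dataclass
class ForceField:
    """Complete interaction parameter set.

    Parameters
    ----------
    f
        Symmetric 4x4 matrix of conservative force amplitudes, k_B T / d.
    d
        Bead diameter; the length unit (1 by construction).
    kBT
        Thermal energy; the energy unit (1 by construction).
    gamma
        Dissipative (friction) coefficient of the DPD thermostat.  The
        random-force amplitude is tied to it by the fluctuation-dissipation
        relation sigma^2 = 2 gamma k_B T and is not settable independently.
    dt
        Integration timestep in units of tau.
    mass
        Bead mass; the mass unit.
    """

    f: np.ndarray = field(default_factory=default_force_matrix)
    d: float = 1.0
    kBT: float = 1.0
    gamma: float = 4.5
    dt: float = 0.01
    mass: float = 1.0

    def __post_init__(self) -> None:
        self.f = np.asarray(self.f, dtype=np.float64)
        if self.f.shape != (4, 4):
            raise ValueError("force matrix must be 4x4 (H, C, W, S)")
        if not np.allclose(self.f, self.f.T):
            raise ValueError("force matrix must be symmetric")
        if np.any(self.f < 0):
            raise ValueError("force amplitudes must be non-negative")
        if self.d <= 0 or self.kBT <= 0 or self.gamma < 0 or self.dt <= 0:
            raise ValueError("d, kBT, dt must be positive; gamma >= 0")

    @property
    def sigma(self) -> float:
        """Random-force amplitude from fluctuation-dissipation."""
        return float(np.sqrt(2.0 * self.gamma * self.kBT))

    def solubility(self) -> float:
        """Solubility zeta = (f_WW + f_SS) / (2 f_WS) of S beads in water.

        Recomputed from the active force matrix; 0.357 for the default
        parameters.
        """
        return float((self.f[W, W] + self.f[S, S]) / (2.0 * self.f[W, S]))


@dataclass
class BondedParams:
    """Intramolecular potentials for the lipid.

    Harmonic bonds U = (k_bond/2)(r - l0)^2 and a cosine bending potential
    U = k_angle (1 - cos(theta - theta0)) with straight rest geometry
    (theta0 = pi), which agrees with a harmonic angle of the same stiffness
    to second order and is smooth at the rest angle.
    """

    k_bond: float = 128.0   # k_B T / d^2
    l0: float = 0.5         # d
    k_angle: float = 15.0   # k_B T
    theta0: float = np.pi   # straight chains

    def __post_init__(self) -> None:
        if self.k_bond < 0 or self.k_angle < 0 or self.l0 <= 0:
            raise ValueError("bonded stiffnesses must be >= 0 and l0 > 0")


# Lipid architecture: 3 head (H) beads in a row, two hydrocarbon chains of
# 6 chain (C) beads each, attached to the first and last head bead.
LIPID_N_BEADS = 15

#: species code per bead inside one lipid (H0 H1 H2, chain A C0..C5, chain B C6..C11)
LIPID_SPECIES = np.array([H, H, H] + [C] * 12, dtype=np.int8)

#: bonds (local indices) within one lipid: head trimer + two linear hexamer chains
LIPID_BONDS = np.array(
    [(0, 1), (1, 2),
     (0, 3), (3, 4), (4, 5), (5, 6), (6, 7), (7, 8),
     (2, 9), (9, 10), (10, 11), (11, 12), (12, 13), (13, 14)],
    dtype=np.int32,
)

#: bending triples along each chain, including the head attachment bead
LIPID_ANGLES = np.array(
    [(0, 3, 4), (3, 4, 5), (4, 5, 6), (5, 6, 7), (6, 7, 8),
     (2, 9, 10), (9, 10, 11), (10, 11, 12), (11, 12, 13), (12, 13, 14)],
    dtype=np.int32,
)


def lipid_topology(n_lipids: int, offset: int = 0):
    """Replicate the single-lipid bond/angle lists for ``n_lipids`` molecules.

    Returns ``(species, bonds, angles)`` arrays with bead indices starting at
    ``offset``.  Raises for non-positive counts.
    """
    if n_lipids <= 0:
        raise ValueError("n_lipids must be positive")
    reps = np.arange(n_lipids, dtype=np.int64) * LIPID_N_BEADS + offset
    species = np.tile(LIPID_SPECIES, n_lipids)
    bonds = (LIPID_BONDS[None, :, :] + reps[:, None, None]).reshape(-1, 2)
    angles = (LIPID_ANGLES[None, :, :] + reps[:, None, None]).reshape(-1, 3)
    return species, bonds.astype(np.int32), angles.astype(np.int32)
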
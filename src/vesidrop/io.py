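"""File formats: LAMMPS-style data/dump, extended XYZ, census tables.

All coordinates are stored in units of d; headers record the physical
mapping d = 0.8 nm and the reduced units kBT = tau = m = 1.  Species are
stored as letters (XYZ) or as type codes 1..4 in the order H, C, W, S
(LAMMPS-style files).
"""

from __future__ import annotations

import json

import numpy as np

from .configuration import Configuration
from .forcefield import D_NM, SPECIES, SPECIES_INDEX

UNITS_COMMENT = f"units: d = {D_NM} nm, kBT = 1, tau = 1, m = 1"


class FormatError(ValueError):
    pass


# ----------------------------------------------------------------------
# LAMMPS-style data files (topology + state)
# ----------------------------------------------------------------------

def write_data(path, cfg: Configuration) -> None:
    """Write a LAMMPS-style data file (atom_style full dialect)."""
    with open(path, "w") as fh:
        fh.write(f"# vesidrop data file; {UNITS_COMMENT}\n\n")
        fh.write(f"{cfg.n_beads} atoms\n")
        fh.write(f"{len(cfg.bonds)} bonds\n")
        fh.write(f"{len(cfg.angles)} angles\n")
        fh.write(f"{len(SPECIES)} atom types\n")
        fh.write("1 bond types\n1 angle types\n\n")
        for ax, name in zip(cfg.box, ("x", "y", "z")):
            fh.write(f"0.0 {ax:.8f} {name}lo {name}hi\n")
        fh.write("\nMasses\n\n")
        for i, name in enumerate(SPECIES):
            fh.write(f"{i + 1} 1.0  # {name}\n")
        fh.write("\nAtoms  # full: id mol type q x y z\n\n")
        for i in range(cfg.n_beads):
            x, y, z = cfg.positions[i]
            fh.write(f"{i + 1} {int(cfg.molecule[i]) + 1} "
                     f"{int(cfg.species[i]) + 1} 0.0 "
                     f"{x:.8f} {y:.8f} {z:.8f}\n")
        fh.write("\nVelocities\n\n")
        for i in range(cfg.n_beads):
            vx, vy, vz = cfg.velocities[i]
            fh.write(f"{i + 1} {vx:.8f} {vy:.8f} {vz:.8f}\n")
        if len(cfg.bonds):
            fh.write("\nBonds\n\n")
            for k, (a, b) in enumerate(cfg.bonds):
                fh.write(f"{k + 1} 1 {a + 1} {b + 1}\n")
        if len(cfg.angles):
            fh.write("\nAngles\n\n")
            for k, (a, b, c) in enumerate(cfg.angles):
                fh.write(f"{k + 1} 1 {a + 1} {b + 1} {c + 1}\n")


def read_data(path) -> Configuration:
    """Read the data-file dialect written by :func:`write_data`."""
    with open(path) as fh:
        lines = [ln.split("#")[0].strip() for ln in fh]
    counts = {}
    box = np.zeros(3)
    section = None
    atoms = {}
    vels = {}
    bonds = []
    angles = []
    for ln in lines:
        if not ln:
            continue
        toks = ln.split()
        if len(toks) >= 2 and toks[1] in ("atoms", "bonds", "angles"):
            counts[toks[1]] = int(toks[0])
            continue
        if len(toks) == 4 and toks[2].endswith("lo"):
            box["xyz".index(toks[2][0])] = float(toks[1]) - float(toks[0])
            continue
        if toks[0] in ("Masses", "Atoms", "Velocities", "Bonds", "Angles"):
            section = toks[0]
            continue
        if ln.endswith("types"):
            continue
        if section == "Atoms":
            if len(toks) < 7:
                raise FormatError(f"malformed Atoms line: {ln!r}")
            i = int(toks[0]) - 1
            typ = int(toks[2]) - 1
            if not 0 <= typ < len(SPECIES):
                raise FormatError(f"species code {typ + 1} outside H,C,W,S")
            atoms[i] = (int(toks[1]) - 1, typ,
                        float(toks[4]), float(toks[5]), float(toks[6]))
        elif section == "Velocities":
            vels[int(toks[0]) - 1] = tuple(map(float, toks[1:4]))
        elif section == "Bonds":
            bonds.append((int(toks[2]) - 1, int(toks[3]) - 1))
        elif section == "Angles":
            angles.append((int(toks[2]) - 1, int(toks[3]) - 1,
                           int(toks[4]) - 1))
    n = counts.get("atoms", len(atoms))
    if len(atoms) != n:
        raise FormatError(f"expected {n} atoms, parsed {len(atoms)}")
    pos = np.zeros((n, 3))
    vel = np.zeros((n, 3))
    species = np.zeros(n, np.int8)
    mol = np.full(n, -1, np.int32)
    for i, (m, t, x, y, z) in atoms.items():
        mol[i] = m
        species[i] = t
        pos[i] = (x, y, z)
    for i, v in vels.items():
        vel[i] = v
    return Configuration(box=box, positions=pos, velocities=vel,
                         species=species, molecule=mol,
                         bonds=np.array(bonds, np.int32).reshape(-1, 2),
                         angles=np.array(angles, np.int32).reshape(-1, 3))


# ----------------------------------------------------------------------
# LAMMPS-style dump (trajectory frames, no topology)
# ----------------------------------------------------------------------

def write_dump(fh, cfg: Configuration, step: int = 0) -> None:
    """Append one frame to an open dump file handle."""
    fh.write("ITEM: TIMESTEP\n%d\n" % step)
    fh.write("ITEM: NUMBER OF ATOMS\n%d\n" % cfg.n_beads)
    fh.write("ITEM: BOX BOUNDS pp pp pp\n")
    for ax in cfg.box:
        fh.write(f"0.0 {ax:.8f}\n")
    fh.write("ITEM: ATOMS id type x y z vx vy vz\n")
    for i in range(cfg.n_beads):
        x, y, z = cfg.positions[i]
        vx, vy, vz = cfg.velocities[i]
        fh.write(f"{i + 1} {int(cfg.species[i]) + 1} "
                 f"{x:.6f} {y:.6f} {z:.6f} {vx:.6f} {vy:.6f} {vz:.6f}\n")


def read_dump(path):
    """Yield (step, Configuration) frames from a dump file.

    The ``type`` column is mandatory; frames without it are rejected.
    """
    with open(path) as fh:
        lines = fh.read().splitlines()
    k = 0
    frame_idx = 0
    while k < len(lines):
        if not lines[k].startswith("ITEM: TIMESTEP"):
            raise FormatError(f"malformed frame {frame_idx} at line {k + 1}")
        step = int(lines[k + 1])
        n = int(lines[k + 3])
        box = np.array([float(lines[k + 5 + a].split()[1])
                        - float(lines[k + 5 + a].split()[0])
                        for a in range(3)])
        header = lines[k + 8].split()[2:]
        if "type" not in header:
            raise FormatError(
                f"frame {frame_idx}: dump is missing the species column")
        cols = {name: header.index(name) for name in header}
        pos = np.zeros((n, 3))
        vel = np.zeros((n, 3))
        species = np.zeros(n, np.int8)
        for row in range(n):
            toks = lines[k + 9 + row].split()
            i = int(toks[cols["id"]]) - 1
            typ = int(toks[cols["type"]]) - 1
            if not 0 <= typ < len(SPECIES):
                raise FormatError(
                    f"frame {frame_idx}: species {typ + 1} outside H,C,W,S")
            species[i] = typ
            pos[i] = [float(toks[cols[c]]) for c in "xyz"]
            if "vx" in cols:
                vel[i] = [float(toks[cols[c]]) for c in ("vx", "vy", "vz")]
        yield step, Configuration(box=box, positions=pos, velocities=vel,
                                  species=species)
        k += 9 + n
        frame_idx += 1


# ----------------------------------------------------------------------
# extended XYZ
# ----------------------------------------------------------------------

def write_extxyz(path, cfg: Configuration, comment_extra: str = "") -> None:
    lattice = " ".join(
        f"{v:.8f}" for v in np.diag(cfg.box).flatten())
    with open(path, "w") as fh:
        fh.write(f"{cfg.n_beads}\n")
        fh.write(f'Lattice="{lattice}" '
                 f'Properties=species:S:1:pos:R:3:vel:R:3 '
                 f'd_nm={D_NM} {comment_extra}\n')
        for i in range(cfg.n_beads):
            x, y, z = cfg.positions[i]
            vx, vy, vz = cfg.velocities[i]
            fh.write(f"{SPECIES[cfg.species[i]]} "
                     f"{x:.8f} {y:.8f} {z:.8f} "
                     f"{vx:.8f} {vy:.8f} {vz:.8f}\n")


def read_extxyz(path) -> Configuration:
    with open(path) as fh:
        lines = fh.read().splitlines()
    n = int(lines[0])
    comment = lines[1]
    if 'Lattice="' not in comment:
        raise FormatError("extended XYZ frame lacks a Lattice record")
    lat = comment.split('Lattice="')[1].split('"')[0].split()
    lat = np.array(lat, float).reshape(3, 3)
    box = np.diag(lat)
    pos = np.zeros((n, 3))
    vel = np.zeros((n, 3))
    species = np.zeros(n, np.int8)
    for row in range(n):
        toks = lines[2 + row].split()
        if toks[0] not in SPECIES_INDEX:
            raise FormatError(f"unknown species {toks[0]!r} (not H, C, W, S)")
        species[row] = SPECIES_INDEX[toks[0]]
        pos[row] = [float(t) for t in toks[1:4]]
        if len(toks) >= 7:
            vel[row] = [float(t) for t in toks[4:7]]
    return Configuration(box=box, positions=pos, velocities=vel,
                         species=species)


def read_configuration(path) -> Configuration:
    """Dispatch on extension: .data/.lmp, .xyz/.extxyz, .dump (last frame)."""
    p = str(path)
    if p.endswith((".xyz", ".extxyz")):
        return read_extxyz(p)
    if p.endswith((".dump", ".lammpstrj")):
        cfg = None
        for _, cfg in read_dump(p):
            pass
        if cfg is None:
            raise FormatError("dump file contains no frames")
        return cfg
    return read_data(p)


# ----------------------------------------------------------------------
# census / reports
# ----------------------------------------------------------------------

def census_to_tsv(census: dict, path) -> None:
    with open(path, "w") as fh:
        fh.write("quantity\tvalue\n")
        for k, v in census.items():
            fh.write(f"{k}\t{v}\n")


def census_to_json(census: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(census, fh, indent=1)
        fh.write("\n")


def profile_to_tsv(profile, path) -> None:
    """Write a radial or planar stress profile as TSV (r, P_N, P_T, s)."""
    coord = profile.r if hasattr(profile, "r") else profile.z
    with open(path, "w") as fh:
        fh.write("r\tP_N\tP_T\ts\n")
        for r, pn, pt, s in zip(coord, profile.P_N, profile.P_T, profile.s):
            fh.write(f"{r:.6f}\t{pn:.8f}\t{pt:.8f}\t{s:.8f}\n")
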
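"""Serializable run configuration: force-field overrides, bonded
parameters, protocol schedule and seeds in one YAML/JSON document.

A run is reproduced bit for bit by its config plus seed; the document
stores only overrides, so absent keys mean package defaults.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .forcefield import SPECIES_INDEX, BondedParams, ForceField
from .protocols import ProtocolSchedule


@dataclass
class RunConfig:
    """Overrides applied on top of the package defaults.

    ``forcefield`` accepts scalar keys (gamma, dt, mass) and a ``pairs``
    mapping like ``{"WS": 70, "HC": 50}`` for individual force
    amplitudes (symmetric by construction).
    """

    forcefield: dict = field(default_factory=dict)
    bonded: dict = field(default_factory=dict)
    schedule: dict = field(default_factory=dict)
    seed: int = 0
    outdir: str = "."

    # ------------------------------------------------------------------
    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        data = (json.loads(text) if str(path).endswith(".json")
                else yaml.safe_load(text)) or {}
        unknown = set(data) - {"forcefield", "bonded", "schedule", "seed",
                               "outdir"}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    # ------------------------------------------------------------------
    def build_forcefield(self) -> ForceField:
        opts = dict(self.forcefield)
        pairs = opts.pop("pairs", {})
        f = ForceField().f.copy()
        for key, value in pairs.items():
            if len(key) != 2 or any(c not in SPECIES_INDEX for c in key):
                raise ValueError(f"bad species pair {key!r} (use e.g. 'WS')")
            i, j = SPECIES_INDEX[key[0]], SPECIES_INDEX[key[1]]
            f[i, j] = f[j, i] = float(value)
        return ForceField(f=f, **opts)

    def build_bonded(self) -> BondedParams:
        opts = dict(self.bonded)
        if "theta0_degrees" in opts:
            opts["theta0"] = np.radians(opts.pop("theta0_degrees"))
        return BondedParams(**opts)

    def build_schedule(self) -> ProtocolSchedule:
        return ProtocolSchedule(seed=self.seed, **self.schedule)
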
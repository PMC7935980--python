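"""Superparamagnetic particle specifications: bead monomers and rigid dimers."""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = ["BeadSpec", "DimerSpec", "Population"]


@dataclass(frozen=True)
class BeadSpec:
    """A superparamagnetic bead.

    Defaults describe 2.8 μm streptavidin-coated beads: density
    1.6e3 kg/m³ and saturation magnetization 11.2 A·m²/kg (the latter is an
    informational cap on the induced moment; transport here stays in the
    linear, unsaturated regime).  The volume susceptibility is an effective
    value and is calibratable.
    """

    radius_m: float = 1.4e-6
    susceptibility: float = 0.7
    density_kg_m3: float = 1.6e3
    sat_magnetization_am2_kg: float = 11.2

    def __post_init__(self):
        if self.radius_m <= 0 or self.susceptibility <= 0 or self.density_kg_m3 <= 0:
            raise ValueError("radius, susceptibility and density must be positive")

    @property
    def volume_m3(self) -> float:
        return 4.0 / 3.0 * math.pi * self.radius_m**3

    @property
    def mass_kg(self) -> float:
        return self.density_kg_m3 * self.volume_m3

    @property
    def moment_cap_am2(self) -> float:
        """Saturation moment: the induced moment may never exceed this."""
        return self.sat_magnetization_am2_kg * self.mass_kg


@dataclass(frozen=True)
class DimerSpec:
    """Two identical touching beads rigidly linked through an analyte bridge.

    The bond axis lies in the chip plane; ``phi_rad`` is the angle of the
    longitudinal axis (bead-to-bead) from +x.  The default π/2 orients the
    axis along y, orthogonal to the transport direction, which is how dimers
    travel below the critical frequency.
    """

    bead: BeadSpec = field(default_factory=BeadSpec)
    phi_rad: float = math.pi / 2.0

    def __post_init__(self):
        object.__setattr__(self, "phi_rad", float(self.phi_rad) % (2.0 * math.pi))

    @property
    def bond_vector(self) -> np.ndarray:
        """In-plane unit vector along the longitudinal axis."""
        return np.array([math.cos(self.phi_rad), math.sin(self.phi_rad)])

    @property
    def half_separation_m(self) -> float:
        """Centre of either bead sits this far from the dimer centre (= r)."""
        return self.bead.radius_m

    def bead_centers_m(self, center_m: np.ndarray, phi_rad: float | None = None) -> np.ndarray:
        """(2, 2) array of in-plane bead-centre coordinates for a given pose."""
        phi = self.phi_rad if phi_rad is None else phi_rad
        u = np.array([math.cos(phi), math.sin(phi)]) * self.half_separation_m
        c = np.asarray(center_m, dtype=float)
        return np.stack([c + u, c - u])

    @property
    def total_volume_m3(self) -> float:
        return 2.0 * self.bead.volume_m3


@dataclass
class Population:
    """A mixed population of monomers and dimers placed on an array.

    ``species`` holds "monomer"/"dimer" per particle; ``positions_um`` the
    in-plane start positions; ``stuck`` flags particles nonspecifically
    immobilized on the surface (drawn at generation time).
    """

    species: list[str]
    positions_um: np.ndarray
    monomer: BeadSpec = field(default_factory=BeadSpec)
    dimer: DimerSpec = field(default_factory=DimerSpec)
    stuck: np.ndarray | None = None

    def __post_init__(self):
        self.positions_um = np.atleast_2d(np.asarray(self.positions_um, dtype=float))
        if self.positions_um.shape != (len(self.species), 2):
            raise ValueError("positions must have shape (n_particles, 2)")
        if any(s not in ("monomer", "dimer") for s in self.species):
            raise ValueError("species entries must be 'monomer' or 'dimer'")
        if self.stuck is None:
            self.stuck = np.zeros(len(self.species), dtype=bool)
        else:
            self.stuck = np.asarray(self.stuck, dtype=bool)

    def __len__(self) -> int:
        return len(self.species)

    @property
    def dimer_fraction(self) -> float:
        return sum(s == "dimer" for s in self.species) / len(self.species)
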
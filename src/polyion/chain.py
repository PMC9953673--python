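"""Shared data model for coarse-grained polyelectrolyte ensembles.

One bead per residue, explicit ions, a cubic periodic box.  All coordinates
and lengths are in Å.  Frame spacing carries its own unit string ("ps" for
imported MD trajectories, "sweep" for Monte Carlo output) so downstream
relaxation times are always reported in a declared unit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "ChainSpec",
    "IonRecord",
    "SaltSpec",
    "Frame",
    "Ensemble",
    "poly_d",
    "poly_e",
    "poly_k",
    "poly_r",
    "poly_gs",
]

#: default bead diameters (Å) by role
BEAD_DIAMETER = 3.8
#: weak-excluded-volume bead for the near-ideal neutral control
NEUTRAL_BEAD_DIAMETER = 1.0
MONOVALENT_CATION_DIAMETER = 2.3
DIVALENT_CATION_DIAMETER = 3.0
ANION_DIAMETER = 3.6
DEFAULT_BOND_LENGTH = 3.8  # Cα-Cα virtual bond, Å


@dataclass(frozen=True)
class ChainSpec:
    """A homo- or hetero-polymer chain of charged beads.

    Parameters
    ----------
    n_residues : int
        Number of beads (≥ 2).
    residue_labels : sequence of str
        One single-letter code per bead.
    bead_charge : sequence of float
        Per-residue signed charge in elementary-charge units.
    bond_length : float
        Rest length of the virtual bond between consecutive beads, Å.
    bead_diameter : float
        Excluded-volume diameter of a bead, Å.
    """

    n_residues: int
    residue_labels: tuple[str, ...]
    bead_charge: tuple[float, ...]
    bond_length: float = DEFAULT_BOND_LENGTH
    bead_diameter: float = BEAD_DIAMETER

    def __post_init__(self) -> None:
        if self.n_residues < 2:
            raise ValueError(f"n_residues must be ≥ 2, got {self.n_residues}")
        if self.bond_length <= 0:
            raise ValueError("bond_length must be positive")
        if self.bead_diameter <= 0:
            raise ValueError("bead_diameter must be positive")
        object.__setattr__(self, "residue_labels", tuple(self.residue_labels))
        object.__setattr__(
            self, "bead_charge", tuple(float(q) for q in self.bead_charge)
        )
        if len(self.residue_labels) != self.n_residues:
            raise ValueError(
                f"residue_labels has length {len(self.residue_labels)}, "
                f"expected {self.n_residues}"
            )
        if len(self.bead_charge) != self.n_residues:
            raise ValueError(
                f"bead_charge has length {len(self.bead_charge)}, "
                f"expected {self.n_residues}"
            )

    @property
    def net_charge(self) -> float:
        return float(sum(self.bead_charge))

    @property
    def charges(self) -> np.ndarray:
        return np.asarray(self.bead_charge, dtype=float)


def _homopolymer(letter: str, charge: float, n: int, bond_length: float,
                 bead_diameter: float) -> ChainSpec:
    return ChainSpec(
        n_residues=n,
        residue_labels=(letter,) * n,
        bead_charge=(charge,) * n,
        bond_length=bond_length,
        bead_diameter=bead_diameter,
    )


def poly_d(n: int = 30, bond_length: float = DEFAULT_BOND_LENGTH,
           bead_diameter: float = BEAD_DIAMETER) -> ChainSpec:
    """Poly-aspartate: one −1 bead per residue."""
    return _homopolymer("D", -1.0, n, bond_length, bead_diameter)


def poly_e(n: int = 30, bond_length: float = DEFAULT_BOND_LENGTH,
           bead_diameter: float = BEAD_DIAMETER) -> ChainSpec:
    """Poly-glutamate: one −1 bead per residue."""
    return _homopolymer("E", -1.0, n, bond_length, bead_diameter)


def poly_k(n: int = 30, bond_length: float = DEFAULT_BOND_LENGTH,
           bead_diameter: float = BEAD_DIAMETER) -> ChainSpec:
    """Poly-lysine: one +1 bead per residue."""
    return _homopolymer("K", +1.0, n, bond_length, bead_diameter)


def poly_r(n: int = 30, bond_length: float = DEFAULT_BOND_LENGTH,
           bead_diameter: float = BEAD_DIAMETER) -> ChainSpec:
    """Poly-arginine: one +1 bead per residue."""
    return _homopolymer("R", +1.0, n, bond_length, bead_diameter)


def poly_gs(n: int = 30, bond_length: float = DEFAULT_BOND_LENGTH,
            bead_diameter: float = NEUTRAL_BEAD_DIAMETER) -> ChainSpec:
    """Neutral glycine-serine control (alternating G/S, zero charge).

    The default bead diameter is small (1 Å) so the control samples a
    near-ideal coil, matching its measured scaling exponent of ≈ 0.5.
    """
    labels = tuple("G" if i % 2 == 0 else "S" for i in range(n))
    return ChainSpec(
        n_residues=n,
        residue_labels=labels,
        bead_charge=(0.0,) * n,
        bond_length=bond_length,
        bead_diameter=bead_diameter,
    )


CHAIN_FACTORIES = {
    "polyD": poly_d,
    "polyE": poly_e,
    "polyK": poly_k,
    "polyR": poly_r,
    "polyGS": poly_gs,
}


@dataclass(frozen=True)
class IonRecord:
    """A single explicit ion: species tag, signed valence, position, diameter."""

    species_label: str
    valence: int
    position: tuple[float, float, float]
    diameter: float

    def __post_init__(self) -> None:
        if self.valence == 0:
            raise ValueError("ion valence must be nonzero")
        if self.diameter <= 0:
            raise ValueError("ion diameter must be positive")
        pos = tuple(float(x) for x in self.position)
        if len(pos) != 3 or not all(np.isfinite(pos)):
            raise ValueError(f"ion position must be a finite 3-vector, got {pos}")
        object.__setattr__(self, "position", pos)


@dataclass(frozen=True)
class SaltSpec:
    """Added salt and chain neutralization.

    ``concentration`` is the molar concentration of whole salt formula units.
    A 1:1 salt (cation_valence=+1) contributes one cation and one anion per
    unit; a 2:1 salt (cation_valence=+2) one divalent cation and two
    monovalent anions.  ``neutralize_chain`` adds monovalent counterions to
    cancel the net chain charge exactly; it is mandatory for a charged chain
    at zero added salt (the "0 M" condition is a counterion-only system).
    """

    cation_valence: int = 1
    anion_valence: int = -1
    concentration: float = 0.0
    neutralize_chain: bool = True

    def __post_init__(self) -> None:
        if self.cation_valence not in (1, 2):
            raise ValueError("cation_valence must be +1 or +2")
        if self.anion_valence != -1:
            raise ValueError("anion_valence must be -1")
        if self.concentration < 0:
            raise ValueError("concentration must be ≥ 0")

    def validate_for_chain(self, spec: ChainSpec) -> None:
        if (self.concentration == 0 and abs(spec.net_charge) > 0
                and not self.neutralize_chain):
            raise ValueError(
                "a charged chain at zero salt requires neutralize_chain=True"
            )


@dataclass
class Frame:
    """One trajectory snapshot: chain bead coordinates plus ion records."""

    chain_coords: np.ndarray
    ions: list[IonRecord] = field(default_factory=list)
    box_edge: float = 0.0
    frame_index: int = 0
    frame_spacing: float = 1.0

    def __post_init__(self) -> None:
        self.chain_coords = np.asarray(self.chain_coords, dtype=float)
        if self.chain_coords.ndim != 2 or self.chain_coords.shape[1] != 3:
            raise ValueError(
                f"chain_coords must be (n, 3), got {self.chain_coords.shape}"
            )
        if not np.all(np.isfinite(self.chain_coords)):
            raise ValueError("chain_coords contains non-finite values")

    @property
    def n_residues(self) -> int:
        return self.chain_coords.shape[0]

    def ion_coords(self) -> np.ndarray:
        if not self.ions:
            return np.empty((0, 3))
        return np.array([ion.position for ion in self.ions], dtype=float)

    def ion_valences(self) -> np.ndarray:
        return np.array([ion.valence for ion in self.ions], dtype=int)

    def total_charge(self, spec: ChainSpec) -> float:
        return spec.net_charge + float(sum(i.valence for i in self.ions))


@dataclass
class Ensemble:
    """An ordered set of frames of one chain, with provenance metadata."""

    spec: ChainSpec
    frames: list[Frame]
    salt: SaltSpec | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if len(self.frames) < 1:
            raise ValueError("an ensemble requires at least one frame")
        n = self.spec.n_residues
        box = self.frames[0].box_edge
        prev_index = None
        for k, fr in enumerate(self.frames):
            if fr.n_residues != n:
                raise ValueError(
                    f"frame {k} has {fr.n_residues} beads, chain spec says {n}"
                )
            if fr.box_edge != box:
                raise ValueError(f"frame {k} box_edge {fr.box_edge} != {box}")
            if box > 0 and box <= 2 * self.spec.bond_length:
                raise ValueError("box_edge must exceed 2 × bond_length")
            if prev_index is not None and fr.frame_index <= prev_index:
                raise ValueError("frame_index must be strictly increasing")
            prev_index = fr.frame_index

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self) -> Iterator[Frame]:
        return iter(self.frames)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def box_edge(self) -> float:
        return self.frames[0].box_edge

    @property
    def frame_spacing(self) -> float:
        return self.frames[0].frame_spacing

    @property
    def spacing_unit(self) -> str:
        return str(self.metadata.get("spacing_unit", "frame"))

    def coordinates(self) -> np.ndarray:
        """Stacked chain coordinates, shape (n_frames, n_residues, 3)."""
        return np.stack([fr.chain_coords for fr in self.frames])
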
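"""Reading and writing ensembles and sequences.

Two on-disk trajectory dialects are supported:

``pdb_multimodel``
    One MODEL per frame; each chain bead is an ATOM record named "CA" in
    chain A, ions are single-atom HETATM residues.  Coordinates carry PDB's
    three-decimal precision.  The periodic box is stored in CRYST1.

``columnar``
    The package's own diffable text layout: a JSON header line carrying the
    chain spec, salt, box and frame spacing, followed by one whitespace-
    separated row per particle per frame
    (``frame_index kind species valence diameter x y z``).

FASTA reading (for the proteome repeat census) goes through Bio.SeqIO with
whitespace stripping and alphabet validation on top.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

import biotite.structure as bstruc
from biotite.structure.io.pdb import PDBFile

from .chain import (
    ANION_DIAMETER,
    DIVALENT_CATION_DIAMETER,
    MONOVALENT_CATION_DIAMETER,
    ChainSpec,
    Ensemble,
    Frame,
    IonRecord,
    SaltSpec,
)

__all__ = [
    "ParseError",
    "StructuralError",
    "read_ensemble",
    "write_ensemble",
    "read_fasta",
    "DEFAULT_ION_RESIDUE_NAMES",
]


class ParseError(ValueError):
    """A record in an input file could not be parsed."""


class StructuralError(ValueError):
    """Frames of a trajectory are mutually inconsistent."""


#: PDB residue names recognized as ions, with their assumed valence
DEFAULT_ION_RESIDUE_NAMES = {
    "NA": 1, "SOD": 1, "MG": 2, "CL": -1, "CLA": -1,
}

_AA3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "E": "GLU", "Q": "GLN", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
    "X": "UNK",
}
_AA1 = {v: k for k, v in _AA3.items()}

_RESIDUE_CHARGE = {"D": -1.0, "E": -1.0, "K": 1.0, "R": 1.0}


def _ion_diameter(valence: int) -> float:
    if valence >= 2:
        return DIVALENT_CATION_DIAMETER
    if valence == 1:
        return MONOVALENT_CATION_DIAMETER
    return ANION_DIAMETER


def _infer_format(path: Path, format_hint: str | None) -> str:
    if format_hint is not None:
        if format_hint not in ("pdb_multimodel", "columnar"):
            raise ValueError(f"unknown format hint {format_hint!r}")
        return format_hint
    if path.suffix.lower() in (".pdb", ".ent"):
        return "pdb_multimodel"
    return "columnar"


def read_ensemble(path, format_hint: str | None = None,
                  ion_residue_names: dict[str, int] | None = None) -> Ensemble:
    """Read a trajectory file into an :class:`Ensemble`.

    Frames are returned in file order.  For PDB input, bead coordinates are
    taken from the "CA" atom of each non-ion residue and ions are recognized
    by residue name (default set: NA, CL, MG, SOD, CLA).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _infer_format(path, format_hint)
    if fmt == "pdb_multimodel":
        return _read_pdb(path, ion_residue_names or DEFAULT_ION_RESIDUE_NAMES)
    return _read_columnar(path)


def write_ensemble(ensemble: Ensemble, path, format_hint: str | None = None) -> None:
    """Write an ensemble so that :func:`read_ensemble` can recover it."""
    ensemble.validate()
    path = Path(path)
    fmt = _infer_format(path, format_hint)
    if fmt == "pdb_multimodel":
        _write_pdb(ensemble, path)
    else:
        _write_columnar(ensemble, path)


# ---------------------------------------------------------------- PDB

def _prevalidate_pdb(path: Path) -> None:
    # biotite's errors do not carry line numbers; check coordinate fields
    # up front so malformed records are reported by line.
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(("ATOM  ", "HETATM")):
                try:
                    float(line[30:38])
                    float(line[38:46])
                    float(line[46:54])
                except (ValueError, IndexError):
                    raise ParseError(
                        f"{path}, line {lineno}: malformed coordinate record"
                    ) from None


def _read_pdb(path: Path, ion_names: dict[str, int]) -> Ensemble:
    _prevalidate_pdb(path)
    pdb = PDBFile.read(str(path))
    n_models = pdb.get_model_count()
    # parse model by model so inconsistent residue counts raise a clear
    # structural error instead of biotite's stacking failure
    arrays = []
    for m in range(1, n_models + 1):
        arrays.append(pdb.get_structure(model=m))
    counts = {len(a) for a in arrays}
    if len(counts) > 1:
        raise StructuralError(
            f"{path}: models differ in atom count ({sorted(counts)})"
        )

    first = arrays[0]
    is_ion = np.array([rn in ion_names for rn in first.res_name])
    is_bead = (first.atom_name == "CA") & ~is_ion
    n_res = int(is_bead.sum())
    if n_res < 2:
        raise StructuralError(f"{path}: fewer than 2 chain beads found")
    labels = tuple(_AA1.get(rn, "X") for rn in first.res_name[is_bead])
    charges = tuple(_RESIDUE_CHARGE.get(lab, 0.0) for lab in labels)

    box = first.box
    box_edge = float(box[0, 0]) if box is not None else 0.0

    spec = ChainSpec(n_residues=n_res, residue_labels=labels,
                     bead_charge=charges)
    frames = []
    for k, arr in enumerate(arrays):
        a_ion = np.array([rn in ion_names for rn in arr.res_name])
        a_bead = (arr.atom_name == "CA") & ~a_ion
        if int(a_bead.sum()) != n_res:
            raise StructuralError(
                f"{path}: model {k + 1} has {int(a_bead.sum())} beads, "
                f"model 1 has {n_res}"
            )
        ions = []
        for rn, xyz in zip(arr.res_name[a_ion], arr.coord[a_ion]):
            val = ion_names[rn]
            ions.append(IonRecord(species_label=str(rn), valence=val,
                                  position=tuple(xyz),
                                  diameter=_ion_diameter(val)))
        frames.append(Frame(chain_coords=arr.coord[a_bead].astype(float),
                            ions=ions, box_edge=box_edge, frame_index=k))
    return Ensemble(spec=spec, frames=frames,
                    metadata={"source": str(path), "format": "pdb_multimodel"})


def _write_pdb(ensemble: Ensemble, path: Path) -> None:
    spec = ensemble.spec
    n_ions = len(ensemble.frames[0].ions)
    n_atoms = spec.n_residues + n_ions
    arrays = []
    for fr in ensemble.frames:
        if len(fr.ions) != n_ions:
            raise StructuralError(
                "PDB output requires a constant ion count across frames"
            )
        arr = bstruc.AtomArray(n_atoms)
        coords = np.empty((n_atoms, 3))
        coords[: spec.n_residues] = fr.chain_coords
        for i in range(spec.n_residues):
            arr.chain_id[i] = "A"
            arr.res_id[i] = i + 1
            arr.res_name[i] = _AA3.get(spec.residue_labels[i], "UNK")
            arr.atom_name[i] = "CA"
            arr.element[i] = "C"
            arr.hetero[i] = False
        for j, ion in enumerate(fr.ions):
            i = spec.n_residues + j
            coords[i] = ion.position
            arr.chain_id[i] = "B"
            arr.res_id[i] = j + 1
            name = ion.species_label.upper()[:3] or "ION"
            arr.res_name[i] = name
            arr.atom_name[i] = name
            arr.element[i] = name[:2].capitalize()
            arr.hetero[i] = True
        arr.coord = coords
        if fr.box_edge > 0:
            arr.box = np.eye(3) * fr.box_edge
        arrays.append(arr)
    stack = bstruc.stack(arrays)
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


# ---------------------------------------------------------------- columnar

_COLUMNAR_MAGIC = "# polyion columnar trajectory v1"


def _write_columnar(ensemble: Ensemble, path: Path) -> None:
    spec = ensemble.spec
    header = {
        "n_residues": spec.n_residues,
        "residue_labels": "".join(spec.residue_labels),
        "bead_charge": list(spec.bead_charge),
        "bond_length": spec.bond_length,
        "bead_diameter": spec.bead_diameter,
        "box_edge": ensemble.box_edge,
        "frame_spacing": ensemble.frame_spacing,
        "metadata": ensemble.metadata,
    }
    if ensemble.salt is not None:
        s = ensemble.salt
        header["salt"] = {
            "cation_valence": s.cation_valence,
            "anion_valence": s.anion_valence,
            "concentration": s.concentration,
            "neutralize_chain": s.neutralize_chain,
        }
    rows = []
    for fr in ensemble.frames:
        for i, xyz in enumerate(fr.chain_coords):
            rows.append((fr.frame_index, "bead", spec.residue_labels[i], 0,
                         spec.bead_diameter, xyz[0], xyz[1], xyz[2]))
        for ion in fr.ions:
            rows.append((fr.frame_index, "ion", ion.species_label,
                         ion.valence, ion.diameter, *ion.position))
    df = pd.DataFrame(
        rows,
        columns=["frame_index", "kind", "species", "valence", "diameter",
                 "x", "y", "z"],
    )
    with open(path, "w") as fh:
        fh.write(_COLUMNAR_MAGIC + "\n")
        fh.write("# " + json.dumps(header) + "\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6f")


def _read_columnar(path: Path) -> Ensemble:
    with open(path) as fh:
        magic = fh.readline().rstrip("\n")
        if magic != _COLUMNAR_MAGIC:
            raise ParseError(f"{path}, line 1: not a polyion columnar trajectory")
        header_line = fh.readline()
        if not header_line.startswith("# "):
            raise ParseError(f"{path}, line 2: missing JSON header")
        try:
            header = json.loads(header_line[2:])
        except json.JSONDecodeError as exc:
            raise ParseError(f"{path}, line 2: bad JSON header ({exc})") from None
        # keep_default_na: "NA" is a sodium species tag, not a missing value
        df = pd.read_csv(fh, sep="\t", keep_default_na=False,
                         dtype={"species": str})

    labels = tuple(header["residue_labels"])
    spec = ChainSpec(
        n_residues=int(header["n_residues"]),
        residue_labels=labels,
        bead_charge=tuple(header["bead_charge"]),
        bond_length=float(header["bond_length"]),
        bead_diameter=float(header["bead_diameter"]),
    )
    salt = None
    if "salt" in header:
        salt = SaltSpec(**header["salt"])
    box_edge = float(header["box_edge"])
    spacing = float(header["frame_spacing"])

    frames = []
    for idx, grp in df.groupby("frame_index", sort=False):
        beads = grp[grp["kind"] == "bead"]
        if len(beads) != spec.n_residues:
            raise StructuralError(
                f"{path}: frame {idx} has {len(beads)} beads, "
                f"header says {spec.n_residues}"
            )
        ions = [
            IonRecord(species_label=str(r.species), valence=int(r.valence),
                      position=(r.x, r.y, r.z), diameter=float(r.diameter))
            for r in grp[grp["kind"] == "ion"].itertuples()
        ]
        frames.append(Frame(chain_coords=beads[["x", "y", "z"]].to_numpy(),
                            ions=ions, box_edge=box_edge,
                            frame_index=int(idx), frame_spacing=spacing))
    return Ensemble(spec=spec, frames=frames, salt=salt,
                    metadata=dict(header.get("metadata", {})))


# ---------------------------------------------------------------- FASTA

def read_fasta(path) -> list[tuple[str, str]]:
    """Read a FASTA file into ``[(identifier, sequence), ...]`` in file order.

    Sequences are uppercased and internal whitespace is removed; residues
    outside A–Z raise a validation error listing the offending characters.
    An empty file yields an empty list.
    """
    path = Path(path)
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = "".join(str(rec.seq).split()).upper()
        bad = sorted({c for c in seq if not c.isalpha()})
        if bad:
            raise ParseError(
                f"{path}: sequence {rec.id!r} contains non-alphabetic "
                f"characters {bad}"
            )
        records.append((rec.id, seq))
    return records
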
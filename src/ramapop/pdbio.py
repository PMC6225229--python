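"""PDB reading/writing for single conformations and multi-model ensembles.

Files are standard PDB: one ATOM record per heavy atom, coordinates in Å,
occupancy/B-factor 1.00/0.00, the element column populated, and for
ensembles one MODEL/ENDMDL block per frame.  Parsing is delegated to
biotite; a pre-scan attaches line numbers to malformed records.
"""

from __future__ import annotations

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .geometry import AtomRecord, Conformation
from .residues import ATOMIC_MASS, ELECTRON_COUNT

__all__ = ["PDBParseError", "write_conformation", "read_conformation",
           "write_ensemble", "read_ensemble"]


class PDBParseError(ValueError):
    """Raised for malformed PDB records; carries the offending line number."""

    def __init__(self, line_number: int, message: str):
        super().__init__(f"line {line_number}: {message}")
        self.line_number = line_number


def _to_atom_array(atoms: list[AtomRecord], coords: np.ndarray) -> struc.AtomArray:
    n = len(atoms)
    arr = struc.AtomArray(n)
    arr.coord = np.asarray(coords, dtype=np.float32)
    arr.set_annotation("atom_name", np.array([a.name for a in atoms]))
    arr.set_annotation("element", np.array([a.element for a in atoms]))
    arr.set_annotation("res_id", np.array([a.residue_index for a in atoms]))
    arr.set_annotation("res_name", np.array([a.residue_name for a in atoms]))
    arr.set_annotation("chain_id", np.array(["A"] * n))
    arr.set_annotation("hetero", np.array([a.residue_name in ("ACE", "NH2")
                                           for a in atoms]))
    arr.set_annotation("occupancy", np.ones(n, dtype=np.float32))
    arr.set_annotation("b_factor", np.zeros(n, dtype=np.float32))
    return arr


def write_conformation(conf: Conformation, path) -> None:
    """Write one conformation as a single-model PDB file."""
    pdb = PDBFile()
    pdb.set_structure(_to_atom_array(conf.atoms, conf.coordinates))
    pdb.write(str(path))


def write_ensemble(confs: list[Conformation], path) -> None:
    """Write an ensemble as a multi-model PDB (one MODEL block per frame)."""
    if not confs:
        raise ValueError("empty ensemble")
    n = len(confs[0].atoms)
    for c in confs:
        if len(c.atoms) != n:
            raise ValueError("inconsistent atom counts across frames")
    template = _to_atom_array(confs[0].atoms, confs[0].coordinates)
    stack = struc.stack([template] * len(confs))
    stack.coord = np.stack([c.coordinates for c in confs]).astype(np.float32)
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


def _prescan(path) -> None:
    """Validate ATOM/HETATM fixed-width records, reporting line numbers."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.startswith(("ATOM", "HETATM")):
                continue
            if len(line.rstrip("\n")) < 54:
                raise PDBParseError(lineno, "truncated ATOM record")
            try:
                float(line[30:38])
                float(line[38:46])
                float(line[46:54])
                int(line[22:26])
            except ValueError:
                raise PDBParseError(
                    lineno, "unparsable coordinate or residue number field"
                ) from None


def _records_from_array(arr: struc.AtomArray) -> list[AtomRecord]:
    atoms = []
    for name, element, res_id, res_name in zip(
            arr.atom_name, arr.element, arr.res_id, arr.res_name):
        el = str(element).capitalize()
        if el not in ATOMIC_MASS:
            raise ValueError(f"unsupported element {element!r} in PDB file")
        atoms.append(AtomRecord(
            name=str(name), element=el,
            mass=ATOMIC_MASS[el], electrons=ELECTRON_COUNT[el],
            residue_index=int(res_id), residue_name=str(res_name),
        ))
    return atoms


def read_conformation(path) -> Conformation:
    """Read the first (or only) model of a PDB file."""
    _prescan(path)
    arr = PDBFile.read(str(path)).get_structure(model=1)
    return Conformation(atoms=_records_from_array(arr),
                        coordinates=np.asarray(arr.coord, dtype=float))


def read_ensemble(path) -> list[Conformation]:
    """Read a multi-model PDB into a list of conformations."""
    _prescan(path)
    stack = PDBFile.read(str(path)).get_structure()
    if isinstance(stack, struc.AtomArray):
        stack = struc.stack([stack])
    atoms = _records_from_array(stack[0])
    return [
        Conformation(atoms=atoms,
                     coordinates=np.asarray(stack.coord[i], dtype=float),
                     frame_id=i)
        for i in range(stack.stack_depth())
    ]
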
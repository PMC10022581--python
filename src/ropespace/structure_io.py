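"""Reading and writing protein structures as per-chain molecules.

Each polymer chain of a structure file becomes one :class:`ChainModel` — the
unit the rest of the package operates on (one chain = one molecule = one
point in conformational space).  Hydrogens are dropped on load, alternate
conformations are collapsed to the highest-occupancy one, and non-polymer
heteroatoms (waters, ligands) are discarded.

Reading goes through gemmi (PDB and mmCIF); writing uses an in-repo
fixed-column PDB formatter so that output is byte-deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

from .topology import THREE_TO_ONE


class StructureFormatError(ValueError):
    """Raised when a structure file cannot be parsed."""


class EmptyStructureError(ValueError):
    """Raised when a file contains no polymer chains."""


@dataclass
class AtomRecord:
    chain_id: str
    residue_number: int
    insertion_code: str
    residue_name: str
    atom_name: str
    element: str
    position: np.ndarray  # (3,) Angstrom
    occupancy: float = 1.0
    alt_loc: str = ""
    bfactor: float = 0.0

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        if not np.all(np.isfinite(self.position)):
            raise ValueError(f"non-finite position for atom {self.atom_name}")
        if not self.atom_name:
            raise ValueError("empty atom name")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"occupancy {self.occupancy} outside [0, 1]")

    @property
    def residue_key(self) -> tuple[int, str]:
        return (self.residue_number, self.insertion_code)


@dataclass
class ChainModel:
    """One polypeptide chain from one structure file."""

    model_name: str
    ordered_residues: list[tuple[int, str, str]]  # (number, icode, name)
    atoms: list[AtomRecord]
    one_letter_sequence: str = ""

    def __post_init__(self):
        if not self.one_letter_sequence:
            self.one_letter_sequence = "".join(
                THREE_TO_ONE.get(name, "X") for _, _, name in self.ordered_residues
            )
        keys = {(num, ic) for num, ic, _ in self.ordered_residues}
        for atom in self.atoms:
            if atom.residue_key not in keys:
                raise ValueError(
                    f"atom {atom.atom_name} references unknown residue {atom.residue_key}"
                )

    def __len__(self) -> int:
        return len(self.ordered_residues)

    def residue_atoms(self) -> dict[tuple[int, str], dict[str, AtomRecord]]:
        """Atoms grouped by residue, keyed (residue_number, insertion_code)."""
        out: dict[tuple[int, str], dict[str, AtomRecord]] = {
            (num, ic): {} for num, ic, _ in self.ordered_residues
        }
        for atom in self.atoms:
            out[atom.residue_key][atom.atom_name] = atom
        return out

    def coordinates(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float)


def _pick_alt(atoms: list[gemmi.Atom]) -> gemmi.Atom:
    # highest occupancy wins; ties broken by lexicographically first altloc
    return min(atoms, key=lambda a: (-a.occ, a.altloc))


def load_structure(path: str | Path) -> list[ChainModel]:
    """Load a PDB/mmCIF file into one ChainModel per polymer chain.

    Only the first MODEL block is used; hydrogens and non-polymer HETATM
    records are dropped; alternate locations collapse to the highest-occupancy
    conformer.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise StructureFormatError(f"{path}: {exc}") from exc
    st.setup_entities()
    st.remove_hydrogens()
    if len(st) == 0:
        raise EmptyStructureError(f"{path}: no models")
    model = st[0]
    stem = path.name.split(".")[0]
    chains: list[ChainModel] = []
    for chain in model:
        polymer = chain.get_polymer()
        if len(polymer) == 0:
            continue
        poly_keys = {
            (res.seqid.num, res.seqid.icode.strip()) for res in polymer
        }
        ordered: list[tuple[int, str, str]] = []
        atoms: list[AtomRecord] = []
        for res in chain:
            key = (res.seqid.num, res.seqid.icode.strip())
            if key not in poly_keys:
                continue  # non-polymer HETATM (waters, ligands)
            ordered.append((key[0], key[1], res.name))
            by_name: dict[str, list[gemmi.Atom]] = {}
            for atom in res:
                if atom.element.is_hydrogen:
                    continue
                by_name.setdefault(atom.name, []).append(atom)
            for name in by_name:
                atom = _pick_alt(by_name[name])
                atoms.append(
                    AtomRecord(
                        chain_id=chain.name,
                        residue_number=key[0],
                        insertion_code=key[1],
                        residue_name=res.name,
                        atom_name=name,
                        element=atom.element.name,
                        position=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                        occupancy=min(max(atom.occ, 0.0), 1.0),
                        alt_loc=atom.altloc if atom.altloc != "\x00" else "",
                    )
                )
        chains.append(
            ChainModel(
                model_name=f"{stem}_{chain.name}",
                ordered_residues=ordered,
                atoms=atoms,
            )
        )
    if not chains:
        raise EmptyStructureError(f"{path}: no polymer chains")
    return chains


def write_structure(chain: ChainModel, path: str | Path) -> None:
    """Write a ChainModel as fixed-column PDB ATOM records."""
    if not chain.atoms:
        raise ValueError("refusing to write a chain with no atoms")
    lines = []
    chain_id = chain.atoms[0].chain_id or "A"
    for i, atom in enumerate(chain.atoms, start=1):
        x, y, z = atom.position
        if any(abs(v) >= 10000 or not math.isfinite(v) for v in (x, y, z)):
            raise ValueError(f"coordinate overflows PDB fixed-width field: {atom}")
        name = atom.atom_name
        # PDB convention: 1-char element names start in column 14
        name_field = f" {name:<3s}" if len(name) < 4 else name
        lines.append(
            f"ATOM  {i:5d} {name_field}{'':1s}{atom.residue_name:>3s} "
            f"{chain_id:1s}{atom.residue_number:4d}{atom.insertion_code or ' ':1s}   "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}{atom.bfactor:6.2f}"
            f"          {atom.element:>2s}"
        )
    lines.append("TER")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def write_multi_frame(chains: list[ChainModel], path: str | Path) -> None:
    """Write several conformations of one chain as MODEL/ENDMDL frames."""
    import io

    buf = io.StringIO()
    for k, chain in enumerate(chains, start=1):
        tmp = Path(str(path) + f".frame{k}")
        write_structure(chain, tmp)
        body = tmp.read_text().replace("END\n", "")
        tmp.unlink()
        buf.write(f"MODEL {k:8d}\n{body}ENDMDL\n")
    buf.write("END\n")
    Path(path).write_text(buf.getvalue())
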
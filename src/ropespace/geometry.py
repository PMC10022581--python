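"""Internal-coordinate machinery: dihedrals, atom trees and NeRF rebuilds.

A chain is represented as a spanning tree of its heavy atoms rooted at the
first backbone nitrogen of each ordered segment.  Every atom deeper than the
root trio carries (bond length, bond angle, torsion) relative to its parent,
grandparent and great-grandparent; rebuilding walks the tree and places each
atom by natural-extension-of-reference-frame (NeRF) geometry.  Bond lengths
and angles are taken from the ideal-geometry table, so conformations are
parameterised purely by their torsions.

Torsion identity follows the atom-name-quadruple convention: a torsion is
named by its four atom names with residue offsets, assigned to the residue
of the middle two atoms (the earlier residue when they span two), and two
quadruples match in either their forward or reverse reading.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .ideal import IdealGeometry
from .structure_io import AtomRecord, ChainModel
from .topology import SIDECHAIN_BONDS

PEPTIDE_CUTOFF = 2.0  # Angstrom, max C(i)-N(i+1) distance for a continuous chain
DISULFIDE_CUTOFF = 2.5  # Angstrom, SG-SG


class UndefinedDihedralError(ValueError):
    """Raised when the middle triplet of a dihedral is collinear."""


def wrap_angle(deg):
    """Wrap angle(s) in degrees to the interval (-180, 180]."""
    wrapped = -np.mod(-np.asarray(deg, dtype=float) + 180.0, 360.0) + 180.0
    return float(wrapped) if np.isscalar(deg) else wrapped


def measure_dihedral(p1, p2, p3, p4) -> float:
    """Signed dihedral angle in degrees, cis = 0, trans = 180.

    Sign follows the right-hand rule about the p2->p3 bond (IUPAC).
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b0 = p1 - p2
    b1 = p3 - p2
    b2 = p4 - p3
    n1 = np.linalg.norm(b1)
    if n1 < 1e-9:
        raise UndefinedDihedralError("coincident middle points")
    b1 = b1 / n1
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    if np.linalg.norm(v) < 1e-9 or np.linalg.norm(w) < 1e-9:
        raise UndefinedDihedralError("collinear triplet, dihedral undefined")
    x = np.dot(v, w)
    y = np.dot(np.cross(b1, v), w)
    return wrap_angle(math.degrees(math.atan2(y, x)))


def nerf_place(a, b, c, length: float, angle_deg: float, torsion_deg: float):
    """Place atom D from frame atoms (A, B, C) and internal coordinates.

    dihedral(A, B, C, D) == torsion_deg and angle(B, C, D) == angle_deg.
    """
    theta = math.radians(angle_deg)
    chi = math.radians(torsion_deg)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array(
        [-length * math.cos(theta),
         length * math.sin(theta) * math.cos(chi),
         length * math.sin(theta) * math.sin(chi)]
    )
    return c + d[0] * bc + d[1] * m + d[2] * n


@dataclass(frozen=True, order=True)
class TorsionKey:
    """Cross-structure identity of one torsion angle.

    ``residue`` anchors the key (chain ordinal before reference mapping,
    reference position after); ``atoms``/``offsets`` give the canonical
    reading of the quadruple, chosen as the lexicographically smaller of the
    forward and reverse directions.
    """

    residue: int
    atoms: tuple[str, str, str, str]
    offsets: tuple[int, int, int, int]

    @classmethod
    def from_quadruple(cls, names, residues) -> "TorsionKey":
        anchor = min(residues[1], residues[2])
        fwd = tuple((n, r - anchor) for n, r in zip(names, residues))
        rev = tuple(reversed(fwd))
        quad = min(fwd, rev)
        return cls(anchor, tuple(n for n, _ in quad), tuple(o for _, o in quad))

    def reanchored(self, residue: int) -> "TorsionKey":
        return replace(self, residue=residue)

    @property
    def span(self) -> int:
        return max(self.offsets) - min(self.offsets)

    def _matches(self, names, offsets) -> bool:
        fwd = tuple(zip(self.atoms, self.offsets))
        return fwd == tuple(zip(names, offsets)) or tuple(reversed(fwd)) == tuple(
            zip(names, offsets)
        )

    @property
    def is_phi(self) -> bool:
        return self._matches(("C", "N", "CA", "C"), (-1, 0, 0, 0))

    @property
    def is_psi(self) -> bool:
        return self._matches(("N", "CA", "C", "N"), (0, 0, 0, 1))

    @property
    def is_omega(self) -> bool:
        return self._matches(("CA", "C", "N", "CA"), (0, 0, 1, 1))

    def __str__(self) -> str:
        parts = [
            f"{n}[{o:+d}]" if o else n for n, o in zip(self.atoms, self.offsets)
        ]
        return f"{self.residue}:" + "-".join(parts)


@dataclass
class InternalModel:
    """Torsion-tree representation of one chain."""

    model_name: str
    chain_id: str
    residues: list[tuple[int, str, str]]  # chain residues (number, icode, name)
    atom_names: list[str]
    atom_res: np.ndarray  # ordinal into residues, per atom
    parent: np.ndarray
    gp: np.ndarray
    ggp: np.ndarray
    lengths: np.ndarray
    angles: np.ndarray
    torsions: np.ndarray  # degrees in (-180, 180], NaN where undefined
    bonded: np.ndarray  # torsion quadruple is a bonded path (real torsion)
    segment: np.ndarray
    extra_quadruples: list[tuple[int, int, int, int]] = field(default_factory=list)
    occupancies: np.ndarray | None = None

    def __post_init__(self):
        finite = np.isfinite(self.torsions)
        self.torsions[finite] = wrap_angle(self.torsions[finite])

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    def copy(self) -> "InternalModel":
        return InternalModel(
            self.model_name,
            self.chain_id,
            list(self.residues),
            list(self.atom_names),
            self.atom_res.copy(),
            self.parent.copy(),
            self.gp.copy(),
            self.ggp.copy(),
            self.lengths.copy(),
            self.angles.copy(),
            self.torsions.copy(),
            self.bonded.copy(),
            self.segment.copy(),
            list(self.extra_quadruples),
            None if self.occupancies is None else self.occupancies.copy(),
        )

    def torsion_atoms(self) -> np.ndarray:
        """Indices of atoms carrying a real (bonded-quadruple) torsion."""
        return np.flatnonzero(self.bonded & np.isfinite(self.torsions))

    def descendants(self) -> list[list[int]]:
        """Per atom, the indices moved by changing that atom's torsion
        (the atom itself plus its whole subtree)."""
        children: list[list[int]] = [[] for _ in range(self.n_atoms)]
        for i, p in enumerate(self.parent):
            if p >= 0:
                children[p].append(i)
        out: list[list[int]] = [None] * self.n_atoms  # type: ignore
        for i in range(self.n_atoms - 1, -1, -1):
            sub = [i]
            for ch in children[i]:
                sub.extend(out[ch])
            out[i] = sub
        return out

    def rebuild_coords(self) -> np.ndarray:
        """NeRF rebuild; each segment is placed in a canonical frame
        (root atom at the origin shifted per segment to avoid overlap)."""
        coords = np.zeros((self.n_atoms, 3))
        seg_offset = 0.0
        for i in range(self.n_atoms):
            p, g, gg = self.parent[i], self.gp[i], self.ggp[i]
            if p < 0:
                if i > 0:
                    seg_offset += 100.0  # separate frame per segment
                coords[i] = (seg_offset, 0.0, 0.0)
            elif g < 0:
                coords[i] = coords[p] + np.array([self.lengths[i], 0.0, 0.0])
            elif gg < 0:
                theta = math.radians(self.angles[i])
                u = np.array([-math.cos(theta), math.sin(theta), 0.0])
                coords[i] = coords[p] + self.lengths[i] * u
            else:
                coords[i] = nerf_place(
                    coords[gg], coords[g], coords[p],
                    self.lengths[i], self.angles[i], self.torsions[i],
                )
        return coords

    def to_chain(self, coords: np.ndarray | None = None) -> ChainModel:
        if coords is None:
            coords = self.rebuild_coords()
        atoms = []
        for i, name in enumerate(self.atom_names):
            num, icode, resname = self.residues[self.atom_res[i]]
            occ = 1.0 if self.occupancies is None else float(self.occupancies[i])
            atoms.append(
                AtomRecord(
                    chain_id=self.chain_id,
                    residue_number=num,
                    insertion_code=icode,
                    residue_name=resname,
                    atom_name=name,
                    element=name[0],
                    position=coords[i].copy(),
                    occupancy=occ,
                )
            )
        return ChainModel(
            model_name=self.model_name,
            ordered_residues=list(self.residues),
            atoms=atoms,
        )

    def local_torsion_keys(self) -> list[tuple[TorsionKey, int]]:
        """(key anchored at chain ordinal, atom index) for every real torsion."""
        out = []
        for i in self.torsion_atoms():
            idx = (self.ggp[i], self.gp[i], self.parent[i], i)
            names = tuple(self.atom_names[j] for j in idx)
            res = tuple(int(self.atom_res[j]) for j in idx)
            out.append((TorsionKey.from_quadruple(names, res), int(i)))
        return out


def _geom_length(geom: IdealGeometry, child_res: str, parent_res_ord: int,
                 child_res_ord: int, child: str, parent: str,
                 parent_resname: str) -> float:
    if parent_res_ord != child_res_ord:  # peptide C(i)-N(i+1)
        return geom.length(parent_resname, "C", "N+")
    return geom.length(child_res, child, parent)


def _build_tree(chain: ChainModel, geom: IdealGeometry, use_ideal: bool):
    """Shared tree construction for extraction and synthetic generation."""
    res_atoms = chain.residue_atoms()
    residues = chain.ordered_residues
    n_res = len(residues)

    def has_backbone(i):
        key = (residues[i][0], residues[i][1])
        return all(a in res_atoms[key] for a in ("N", "CA", "C"))

    # segment assignment: split at missing backbone or broken peptide bond
    seg_id = [-1] * n_res
    seg = -1
    prev_ok = False
    for i in range(n_res):
        if not has_backbone(i):
            prev_ok = False
            continue
        key = (residues[i][0], residues[i][1])
        if prev_ok:
            pkey = (residues[i - 1][0], residues[i - 1][1])
            d = np.linalg.norm(
                res_atoms[pkey]["C"].position - res_atoms[key]["N"].position
            )
            if d >= PEPTIDE_CUTOFF:
                seg += 1
        else:
            seg += 1
        seg_id[i] = seg
        prev_ok = True

    atom_names: list[str] = []
    atom_res: list[int] = []
    parent: list[int] = []
    coords: list[np.ndarray] = []
    occs: list[float] = []
    index: dict[tuple[int, str], int] = {}

    def add_atom(res_i: int, name: str, parent_key):
        key = (residues[res_i][0], residues[res_i][1])
        rec = res_atoms[key].get(name)
        if rec is None:
            return
        p = -1 if parent_key is None else index.get(parent_key, -2)
        if p == -2:
            return  # parent missing: atom cannot join the tree
        index[(res_i, name)] = len(atom_names)
        atom_names.append(name)
        atom_res.append(res_i)
        parent.append(p)
        coords.append(rec.position)
        occs.append(rec.occupancy)

    for i in range(n_res):
        if seg_id[i] < 0:
            continue
        resname = residues[i][2]
        first = i == 0 or seg_id[i - 1] != seg_id[i]
        add_atom(i, "N", None if first else (i - 1, "C"))
        add_atom(i, "CA", (i, "N"))
        add_atom(i, "C", (i, "CA"))
        add_atom(i, "O", (i, "C"))
        for pname, cname in SIDECHAIN_BONDS.get(resname, []):
            add_atom(i, cname, (i, pname))

    n = len(atom_names)
    parent_a = np.array(parent, dtype=int)
    atom_res_a = np.array(atom_res, dtype=int)
    gp = np.array([parent_a[p] if p >= 0 else -1 for p in parent_a], dtype=int)
    ggp = np.array([parent_a[g] if g >= 0 else -1 for g in gp], dtype=int)
    bonded = np.ones(n, dtype=bool)

    # first-residue CB has no bonded great-grandparent; borrow C as a frame atom
    for i in range(n):
        if parent_a[i] >= 0 and gp[i] >= 0 and ggp[i] < 0:
            res_i = atom_res_a[i]
            c_idx = index.get((res_i, "C"))
            if c_idx is not None and c_idx != i and c_idx < i:
                ggp[i] = c_idx
                bonded[i] = False

    coords_a = np.array(coords) if coords else np.zeros((0, 3))
    lengths = np.full(n, np.nan)
    angles = np.full(n, np.nan)
    torsions = np.full(n, np.nan)
    segment = np.array([seg_id[r] for r in atom_res_a], dtype=int)

    for i in range(n):
        p, g, gg = parent_a[i], gp[i], ggp[i]
        if p < 0:
            continue
        child_res = residues[atom_res_a[i]][2]
        if use_ideal:
            lengths[i] = _geom_length(
                geom, child_res, atom_res_a[p], atom_res_a[i],
                atom_names[i], atom_names[p], residues[atom_res_a[p]][2],
            )
        else:
            lengths[i] = np.linalg.norm(coords_a[i] - coords_a[p])
        if g < 0:
            continue
        if use_ideal:
            cn, pn, gn = atom_names[i], atom_names[p], atom_names[g]
            ri, rp, rg = atom_res_a[i], atom_res_a[p], atom_res_a[g]
            if ri != rp:  # child is N of the next residue
                angles[i] = geom.angle(residues[rp][2], gn, pn, "N+")
            elif rg != rp:  # grandparent in previous residue (C-)
                angles[i] = geom.angle(child_res, "C-", pn, cn)
            else:
                angles[i] = geom.angle(child_res, cn, pn, gn)
        else:
            v1 = coords_a[g] - coords_a[p]
            v2 = coords_a[i] - coords_a[p]
            cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
            angles[i] = math.degrees(math.acos(np.clip(cosang, -1, 1)))
        if gg < 0:
            continue
        torsions[i] = measure_dihedral(
            coords_a[gg], coords_a[g], coords_a[p], coords_a[i]
        )

    # geometric disulfide detection (SSBOND records are unreliable)
    extra: list[tuple[int, int, int, int]] = []
    sgs = [i for i, nm in enumerate(atom_names) if nm == "SG"]
    for a in range(len(sgs)):
        for b in range(a + 1, len(sgs)):
            i, j = sgs[a], sgs[b]
            if np.linalg.norm(coords_a[i] - coords_a[j]) < DISULFIDE_CUTOFF:
                cb_i = index.get((int(atom_res_a[i]), "CB"))
                cb_j = index.get((int(atom_res_a[j]), "CB"))
                if cb_i is not None and cb_j is not None:
                    extra.append((cb_i, i, j, cb_j))

    model = InternalModel(
        model_name=chain.model_name,
        chain_id=chain.atoms[0].chain_id if chain.atoms else "A",
        residues=list(residues),
        atom_names=atom_names,
        atom_res=atom_res_a,
        parent=parent_a,
        gp=gp,
        ggp=ggp,
        lengths=lengths,
        angles=angles,
        torsions=torsions,
        bonded=bonded,
        segment=segment,
        extra_quadruples=extra,
        occupancies=np.array(occs) if occs else None,
    )
    return model, coords_a


def extract_internal(chain: ChainModel, geometry: IdealGeometry | None = None,
                     use_ideal: bool = True) -> InternalModel:
    """Measure torsions from the chain's own coordinates while resetting bond
    lengths and angles to ideal values (pass ``use_ideal=False`` to keep the
    measured local geometry instead)."""
    geom = geometry or IdealGeometry.default()
    model, _ = _build_tree(chain, geom, use_ideal)
    return model


def rebuild_cartesian(internal: InternalModel,
                      anchor: np.ndarray | None = None) -> ChainModel:
    """Rebuild Cartesian coordinates from the torsion tree.

    With ``anchor`` (an (n_atoms, 3) array of target positions) each segment
    is rigidly superposed onto its matching anchor atoms; otherwise the
    canonical frame is used (root at origin, first bond on +x).
    """
    coords = internal.rebuild_coords()
    if anchor is not None:
        from .coords import kabsch  # local import: coords depends on geometry

        anchor = np.asarray(anchor, dtype=float)
        for seg in np.unique(internal.segment):
            sel = internal.segment == seg
            if sel.sum() >= 3:
                sup = kabsch(coords[sel], anchor[sel])
                coords[sel] = coords[sel] @ sup.rotation.T + sup.translation
    return internal.to_chain(coords)


def extra_torsion_values(internal: InternalModel,
                         coords: np.ndarray | None = None):
    """Measured values of off-tree torsions (disulfides) from coordinates."""
    if coords is None:
        coords = internal.rebuild_coords()
    out = []
    for (i1, i2, i3, i4) in internal.extra_quadruples:
        names = tuple(internal.atom_names[j] for j in (i1, i2, i3, i4))
        res = tuple(int(internal.atom_res[j]) for j in (i1, i2, i3, i4))
        key = TorsionKey.from_quadruple(names, res)
        out.append((key, measure_dihedral(
            coords[i1], coords[i2], coords[i3], coords[i4])))
    return out


def internal_from_sequence(sequence: str, geometry: IdealGeometry | None = None,
                           phi: float = -57.0, psi: float = -47.0,
                           model_name: str = "synthetic",
                           chain_id: str = "A") -> InternalModel:
    """Build an ideal-geometry InternalModel for a one-letter sequence.

    Backbone torsions default to an alpha-helical (phi, psi); omega is trans,
    side chains start from chi = 180 with tetrahedral/planar branch offsets.
    """
    from .topology import ONE_TO_THREE, is_sp2

    geom = geometry or IdealGeometry.default()
    residues = [(i + 1, "", ONE_TO_THREE[aa]) for i, aa in enumerate(sequence)]
    phis = np.broadcast_to(np.asarray(phi, dtype=float), (len(sequence),))
    psis = np.broadcast_to(np.asarray(psi, dtype=float), (len(sequence),))

    atom_names: list[str] = []
    atom_res: list[int] = []
    parent: list[int] = []
    torsions: list[float] = []
    bonded: list[bool] = []
    index: dict[tuple[int, str], int] = {}
    first_child_torsion: dict[int, float] = {}

    def add(res_i, name, parent_key, torsion, is_bonded=True):
        p = -1 if parent_key is None else index[parent_key]
        index[(res_i, name)] = len(atom_names)
        atom_names.append(name)
        atom_res.append(res_i)
        parent.append(p)
        torsions.append(torsion)
        bonded.append(is_bonded)

    for i, (num, icode, resname) in enumerate(residues):
        first = i == 0
        add(i, "N", None if first else (i - 1, "C"), psis[i - 1] if not first else np.nan)
        add(i, "CA", (i, "N"), 180.0)  # omega
        add(i, "C", (i, "CA"), phis[i] if not first else np.nan)
        add(i, "O", (i, "C"), wrap_angle(psis[i] + 180.0))
        for pname, cname in SIDECHAIN_BONDS.get(resname, []):
            p_idx = index[(i, pname)]
            if cname == "CB":
                add(i, "CB", (i, pname), wrap_angle(phis[i] - 122.5), not first)
            elif p_idx in first_child_torsion:
                step = 180.0 if is_sp2(resname, pname) else 120.0
                add(i, cname, (i, pname),
                    wrap_angle(first_child_torsion[p_idx] + step))
            else:
                first_child_torsion[p_idx] = 180.0
                add(i, cname, (i, pname), 180.0)

    n = len(atom_names)
    parent_a = np.array(parent, dtype=int)
    atom_res_a = np.array(atom_res, dtype=int)
    gp = np.array([parent_a[p] if p >= 0 else -1 for p in parent_a], dtype=int)
    ggp = np.array([parent_a[g] if g >= 0 else -1 for g in gp], dtype=int)
    bonded_a = np.array(bonded, dtype=bool)
    for i in range(n):
        if parent_a[i] >= 0 and gp[i] >= 0 and ggp[i] < 0 and atom_names[i] == "CB":
            c_idx = index[(atom_res_a[i], "C")]
            ggp[i] = c_idx
            bonded_a[i] = False

    lengths = np.full(n, np.nan)
    angles = np.full(n, np.nan)
    tors = np.array(torsions, dtype=float)
    for i in range(n):
        p, g = parent_a[i], gp[i]
        if p < 0:
            continue
        child_res = residues[atom_res_a[i]][2]
        lengths[i] = _geom_length(
            geom, child_res, atom_res_a[p], atom_res_a[i],
            atom_names[i], atom_names[p], residues[atom_res_a[p]][2],
        )
        if g < 0:
            continue
        cn, pn, gn = atom_names[i], atom_names[p], atom_names[g]
        ri, rp, rg = atom_res_a[i], atom_res_a[p], atom_res_a[g]
        if ri != rp:
            angles[i] = geom.angle(residues[rp][2], gn, pn, "N+")
        elif rg != rp:
            angles[i] = geom.angle(child_res, "C-", pn, cn)
        else:
            angles[i] = geom.angle(child_res, cn, pn, gn)

    tors[(parent_a < 0) | (gp < 0) | (ggp < 0)] = np.nan
    return InternalModel(
        model_name=model_name,
        chain_id=chain_id,
        residues=residues,
        atom_names=atom_names,
        atom_res=atom_res_a,
        parent=parent_a,
        gp=gp,
        ggp=ggp,
        lengths=lengths,
        angles=angles,
        torsions=tors,
        bonded=bonded_a,
        segment=np.zeros(n, dtype=int),
    )


def build_torsion_keys(internal: InternalModel, mapping=None):
    """Map every real torsion to its cross-structure :class:`TorsionKey`.

    ``mapping`` is a :class:`~ropespace.entity.ResidueMapping`; offsets are
    recomputed in reference coordinates so indels do not scramble identities.
    Without a mapping, keys stay anchored at chain ordinals.  Returns a dict
    ``TorsionKey -> atom index``.
    """
    out: dict[TorsionKey, int] = {}
    for i in internal.torsion_atoms():
        idx = (internal.ggp[i], internal.gp[i], internal.parent[i], i)
        names = tuple(internal.atom_names[j] for j in idx)
        if mapping is None:
            res = tuple(int(internal.atom_res[j]) for j in idx)
        else:
            ref = [mapping.reference_position(int(internal.atom_res[j])) for j in idx]
            if any(r is None for r in ref):
                continue
            res = tuple(ref)  # type: ignore
        out[TorsionKey.from_quadruple(names, res)] = int(i)
    return out
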
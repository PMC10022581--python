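"""Atomic-coordinate comparator: Kabsch superposition and coordinate ordination.

The coordinate-derived conformational space is the classical alternative to
the torsion-angle space: every member is rigidly superposed onto a chosen
reference, the superposed (x, y, z) coordinates become the feature vector,
and the same correlation -> SVD pipeline produces the ordination.  Unlike the
torsion space it depends on the choice of reference structure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np


@dataclass
class SuperpositionResult:
    rotation: np.ndarray  # 3x3 proper rotation
    translation: np.ndarray  # 3-vector, Angstrom
    rmsd: float

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points) @ self.rotation.T + self.translation


def kabsch(moving: np.ndarray, fixed: np.ndarray) -> SuperpositionResult:
    """Least-squares optimal rigid superposition of ``moving`` onto ``fixed``.

    Closed-form SVD solution with the reflection branch corrected by the
    determinant sign, so the rotation is always proper.
    """
    moving = np.asarray(moving, dtype=float)
    fixed = np.asarray(fixed, dtype=float)
    if moving.shape != fixed.shape or moving.ndim != 2 or moving.shape[1] != 3:
        raise ValueError("matched (n, 3) point sets required")
    n = moving.shape[0]
    if n < 3:
        raise ValueError("at least 3 matched pairs required")
    cm = moving.mean(axis=0)
    cf = fixed.mean(axis=0)
    a = moving - cm
    b = fixed - cf
    h = a.T @ b
    u, s, vt = np.linalg.svd(h)
    if s[1] < 1e-12:
        raise ValueError("degenerate (collinear) point geometry")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rotation = vt.T @ corr @ u.T
    moved = a @ rotation.T
    rmsd = float(np.sqrt(np.mean(np.sum((moved - b) ** 2, axis=1))))
    translation = cf - rotation @ cm
    return SuperpositionResult(rotation=rotation, translation=translation, rmsd=rmsd)


def superposed_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """RMSD between two matched point sets after optimal superposition."""
    return kabsch(a, b).rmsd


def choose_reference(entity, override: str | None = None) -> str:
    """Pick the reference member for coordinate clustering.

    The member with the most modelled residues wins, subject to not
    exceeding the reference-sequence length (more residues than the
    reference sequence indicates tags or chimeras); ties break to the
    lexicographically first model name.  ``override`` selects manually.
    """
    if not entity.members:
        raise ValueError("entity has no members")
    if override is not None:
        entity.get_member(override)  # raises KeyError if absent
        return override
    limit = len(entity.reference_sequence)
    eligible = [
        (len(chain.ordered_residues), chain.model_name)
        for chain, _ in entity.members
        if len(chain.ordered_residues) <= limit
    ]
    if not eligible:  # every member exceeds the sequence; take the closest
        eligible = [
            (-len(chain.ordered_residues), chain.model_name)
            for chain, _ in entity.members
        ]
        return min(eligible, key=lambda t: (-t[0], t[1]))[1]
    return min(eligible, key=lambda t: (-t[0], t[1]))[1]


def _atom_map(chain, mapping) -> dict[tuple[int, str], np.ndarray]:
    """(reference position, atom name) -> coordinates for one member."""
    ordinal_of = {
        (num, ic): i for i, (num, ic, _) in enumerate(chain.ordered_residues)
    }
    out = {}
    for atom in chain.atoms:
        ref = mapping.reference_position(ordinal_of[atom.residue_key])
        if ref is not None:
            out[(ref, atom.atom_name)] = atom.position
    return out


class CoordinateSpace:
    """Model: ordination of superposed atomic coordinates.

    Every member is superposed onto the reference by the Kabsch algorithm
    over atoms matched by atom name and sequence alignment; the superposed
    (x, y, z) of the reference's atoms, with missing atoms contributing a
    zero triple after centering, feed the same correlation -> SVD pipeline
    as the torsion space.
    """

    def __init__(self, entity, reference: str | None = None):
        self.entity = entity
        self.reference = choose_reference(entity, override=reference)

    def fit(self):
        from .space import EmbeddedDifferences, correlation_matrix, svd_space

        ref_chain, ref_mapping = self.entity.get_member(self.reference)
        ref_atoms = _atom_map(ref_chain, ref_mapping)
        columns = sorted(ref_atoms)
        col_index = {key: i for i, key in enumerate(columns)}
        n_cols = len(columns)

        names, rows, present = [], [], []
        for chain, mapping in self.entity.members:
            atoms = _atom_map(chain, mapping)
            shared = [key for key in columns if key in atoms]
            if len(shared) < 3:
                warnings.warn(
                    f"member {chain.model_name} shares fewer than 3 atoms "
                    "with the reference; excluded", stacklevel=2,
                )
                continue
            moving = np.array([atoms[key] for key in shared])
            fixed = np.array([ref_atoms[key] for key in shared])
            sup = kabsch(moving, fixed)
            placed = sup.apply(moving)
            row = np.zeros((n_cols, 3))
            mask = np.zeros(n_cols, dtype=bool)
            for key, pos in zip(shared, placed):
                row[col_index[key]] = pos
                mask[col_index[key]] = True
            names.append(chain.model_name)
            rows.append(row)
            present.append(mask)

        values = np.array(rows)  # members x atoms x 3
        mask = np.array(present)
        # per-component mean over members possessing the atom; missing -> 0
        with np.errstate(invalid="ignore"):
            sums = np.where(mask[:, :, None], values, 0.0).sum(axis=0)
            counts = mask.sum(axis=0)[:, None]
            means = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
        centered = np.where(mask[:, :, None], values - means[None], 0.0)
        emb = EmbeddedDifferences(
            vectors=centered.reshape(len(names), -1),
            present=mask,
            columns=columns,
            names=names,
            components=3,
        )
        corr = correlation_matrix(emb)
        return svd_space(corr, emb, None, kind="coordinate",
                         with_axis_deltas=False)


def coord_conf_space(entity, reference: str | None = None):
    """Convenience wrapper: fit the coordinate-derived conformational space."""
    return CoordinateSpace(entity, reference=reference).fit()
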
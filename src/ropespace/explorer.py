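"""Interpret principal axes as structural motions on a reference chain.

An axis of the torsion-angle space is a per-torsion angular delta.  Applying
``s x delta`` (s from -1 to +1) to a reference structure's torsions and
rebuilding on ideal geometry materialises the motion as a series of
physically sensible frames: interpolation happens in torsion space, so every
frame keeps exact ideal bond lengths and angles.  Ordered segments are
superposed back onto the reference individually, since a chain break leaves
the relative placement of the flanking segments undetermined.

Hinge residues are scored by Ramachandran deviation — the summed |delta| of
a residue's phi and psi along the axis — and arbitrary atom-to-atom marker
distances can be measured across all members of an entity to annotate the
space with interpretable structural coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coords import _atom_map
from .geometry import (InternalModel, TorsionKey, build_torsion_keys,
                       wrap_angle)
from .space import ConformationalSpace
from .structure_io import ChainModel, write_multi_frame

DEFAULT_FRACTIONS = (-1.0, -0.5, 0.0, 0.5, 1.0)


@dataclass
class AxisMotion:
    """Torsion deltas of one principal axis, attached to a reference member."""

    axis: int
    reference: str
    deltas: dict[TorsionKey, float]
    missing: list[TorsionKey] = field(default_factory=list)

    def __post_init__(self):
        for key, value in self.deltas.items():
            if not np.isfinite(value):
                raise ValueError(f"non-finite delta for {key}")


def axis_motion(space: ConformationalSpace, axis: int, reference: str,
                refined_reference: InternalModel,
                mapping=None) -> AxisMotion:
    """Restrict an axis's torsion deltas to the keys the reference possesses.

    Deltas for torsions absent from the reference (disordered loops,
    mutations) are dropped and reported in ``missing`` so the user can judge
    whether the motion is distorted mid-backbone.
    """
    if space.axis_torsion_deltas is None:
        raise ValueError("space carries no torsion deltas (coordinate space?)")
    if not 0 <= axis < len(space.axis_torsion_deltas):
        raise IndexError(f"axis {axis} beyond computed rank")
    if reference not in space.names:
        raise KeyError(f"{reference} is not a member of this space")
    ref_keys = build_torsion_keys(refined_reference, mapping)
    deltas, missing = {}, []
    for key, value in space.axis_torsion_deltas[axis].items():
        if key in ref_keys:
            deltas[key] = value
        else:
            missing.append(key)
    return AxisMotion(axis=axis, reference=reference, deltas=deltas,
                      missing=missing)


def apply_motion(motion: AxisMotion, refined_reference: InternalModel,
                 s: float, mapping=None) -> ChainModel:
    """Rebuild the reference with torsions displaced by ``s`` times the axis.

    Each ordered segment of the result is rigidly superposed back onto the
    reference rebuild; ``s = 0`` reproduces the reference exactly.
    """
    if abs(s) > 1.0:
        raise ValueError("slider position must lie in [-1, 1]")
    from .geometry import rebuild_cartesian

    ref_coords = refined_reference.rebuild_coords()
    if s == 0.0:
        return refined_reference.to_chain(ref_coords)
    keymap = build_torsion_keys(refined_reference, mapping)
    displaced = refined_reference.copy()
    for key, delta in motion.deltas.items():
        idx = keymap[key]
        displaced.torsions[idx] = wrap_angle(
            displaced.torsions[idx] + s * delta)
    return rebuild_cartesian(displaced, anchor=ref_coords)


def materialize_frames(motion: AxisMotion, refined_reference: InternalModel,
                       path, fractions=DEFAULT_FRACTIONS, mapping=None) -> None:
    """Write the motion as a multi-frame (MODEL/ENDMDL) PDB."""
    frames = [apply_motion(motion, refined_reference, s, mapping=mapping)
              for s in fractions]
    write_multi_frame(frames, path)


def ramachandran_deviation(motion: AxisMotion) -> pd.Series:
    """Per-residue hinge score: |delta phi| + |delta psi| along the axis.

    Residues missing one of the two angles contribute only the defined term;
    side-chain-only deltas never score.
    """
    scores: dict[int, float] = {}
    for key, delta in motion.deltas.items():
        if key.is_phi or key.is_psi:
            scores[key.residue] = scores.get(key.residue, 0.0) + abs(delta)
    return pd.Series(scores, dtype=float).sort_index()


def marker_distance(entity, atom_a: tuple[int, str],
                    atom_b: tuple[int, str]) -> pd.Series:
    """Within-member distance between two reference-anchored atoms.

    ``atom_a``/``atom_b`` are (1-based reference position, atom name); the
    result has one entry per member, NaN where either atom is absent.  The
    series can be attached to a project as numeric metadata.
    """
    out = {}
    for chain, mapping in entity.members:
        atoms = _atom_map(chain, mapping)
        pa, pb = atoms.get(atom_a), atoms.get(atom_b)
        out[chain.model_name] = (
            float(np.linalg.norm(pa - pb)) if pa is not None and pb is not None
            else np.nan
        )
    name = f"{atom_a[0]}{atom_a[1]}_to_{atom_b[0]}{atom_b[1]}"
    return pd.Series(out, name=name)


def bfactor_colored_reference(refined_reference: InternalModel,
                              profile: pd.Series) -> ChainModel:
    """Reference rebuild with Ramachandran scores in the B-factor column,
    so molecular viewers can color the backbone by hinge strength."""
    chain = refined_reference.to_chain()
    by_pos = profile.to_dict()
    for atom in chain.atoms:
        atom.bfactor = float(by_pos.get(atom.residue_number, 0.0))
    return chain
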
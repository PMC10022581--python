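"""Protein entities: reference sequences, membership and residue mapping.

An *entity* is a protein defined by a reference amino-acid sequence.
Candidate chains are globally aligned to that sequence; chains with at
least 10 residues and 80% identity become members.  The recorded residue
mapping puts every chain residue onto a reference position so that torsion
identities are comparable across structures — including across point
mutations (shared columns persist while atom names stay congruent) and
indels (the register is corrected by the alignment).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import Align

from .geometry import (InternalModel, TorsionKey, build_torsion_keys,
                       extra_torsion_values)
from .structure_io import ChainModel

log = logging.getLogger(__name__)

MIN_RESIDUES = 10
MIN_IDENTITY = 0.80


@dataclass
class ResidueMapping:
    """Alignment-derived mapping of chain residues to reference positions.

    ``chain_to_ref`` maps 0-based chain residue ordinals to 1-based
    reference positions; unaligned residues are absent.  ``mutations``
    lists (reference position, reference letter, chain letter).
    """

    chain_to_ref: dict[int, int]
    identity_fraction: float
    aligned_length: int
    mutations: list[tuple[int, str, str]] = field(default_factory=list)
    score: float = 0.0

    def reference_position(self, chain_ordinal: int) -> int | None:
        return self.chain_to_ref.get(chain_ordinal)

    def __post_init__(self):
        positions = [self.chain_to_ref[k] for k in sorted(self.chain_to_ref)]
        if any(b <= a for a, b in zip(positions, positions[1:])):
            raise ValueError("residue mapping must be strictly increasing")


_ALIGNER = Align.PairwiseAligner()
_ALIGNER.mode = "global"
_ALIGNER.match_score = 1.0
_ALIGNER.mismatch_score = -1.0
_ALIGNER.open_gap_score = -5.0
_ALIGNER.extend_gap_score = -1.0


def align_sequence(chain_seq: str, reference: str) -> ResidueMapping:
    """Needleman-Wunsch global alignment of a chain sequence to the reference.

    Scoring: match +1, mismatch -1, gap open -5, gap extend -1 (affine; the
    first gap position costs -5).  Identity is counted over chain residues
    aligned to a reference position, so fragments of a long reference are
    not penalised.
    """
    if not chain_seq or not reference:
        raise ValueError("both sequences must be non-empty")
    aln = _ALIGNER.align(reference, chain_seq)[0]
    chain_to_ref: dict[int, int] = {}
    mutations: list[tuple[int, str, str]] = []
    identical = 0
    for (r0, r1), (c0, c1) in zip(*aln.aligned):
        for k in range(r1 - r0):
            ref_pos = r0 + k  # 0-based
            chain_pos = c0 + k
            chain_to_ref[chain_pos] = ref_pos + 1
            if reference[ref_pos] == chain_seq[chain_pos]:
                identical += 1
            else:
                mutations.append(
                    (ref_pos + 1, reference[ref_pos], chain_seq[chain_pos])
                )
    aligned = len(chain_to_ref)
    identity = identical / aligned if aligned else 0.0
    return ResidueMapping(
        chain_to_ref=chain_to_ref,
        identity_fraction=identity,
        aligned_length=aligned,
        mutations=mutations,
        score=float(aln.score),
    )


@dataclass
class Entity:
    """A protein defined by its reference sequence, plus admitted members."""

    name: str
    reference_sequence: str
    members: list[tuple[ChainModel, ResidueMapping]] = field(default_factory=list)

    def __post_init__(self):
        seq = self.reference_sequence
        if not seq:
            raise ValueError("reference sequence must be non-empty")
        bad = set(seq) - set("ACDEFGHIKLMNPQRSTVWYX")
        if bad:
            raise ValueError(f"non-standard letters in reference sequence: {bad}")

    @classmethod
    def from_fasta(cls, path, name: str | None = None) -> "Entity":
        from Bio import SeqIO

        record = next(SeqIO.parse(str(path), "fasta"))
        return cls(name=name or record.id, reference_sequence=str(record.seq).upper())

    @property
    def member_names(self) -> list[str]:
        return [chain.model_name for chain, _ in self.members]

    def get_member(self, model_name: str) -> tuple[ChainModel, ResidueMapping]:
        for chain, mapping in self.members:
            if chain.model_name == model_name:
                return chain, mapping
        raise KeyError(model_name)


def admit_member(entity: Entity, chain: ChainModel) -> tuple[bool, ResidueMapping]:
    """Admit a chain if it has >= 10 residues and >= 80% identity."""
    mapping = align_sequence(chain.one_letter_sequence, entity.reference_sequence)
    admitted = (
        len(chain.ordered_residues) >= MIN_RESIDUES
        and mapping.identity_fraction >= MIN_IDENTITY
    )
    if admitted:
        entity.members.append((chain, mapping))
    return admitted, mapping


def build_torsion_table(entity: Entity,
                        refined: dict[str, InternalModel]) -> pd.DataFrame:
    """molecules x torsion-identity matrix of angles in degrees.

    Columns are the union of :class:`TorsionKey` over members; entries a
    member does not possess are NaN.  Disulfide (off-tree) torsions are
    measured from each member's rebuilt coordinates.
    """
    rows: dict[str, dict] = {}
    for chain, mapping in entity.members:
        name = chain.model_name
        if name not in refined:
            raise KeyError(f"member {name} has no refined internal model")
        internal = refined[name]
        keys = build_torsion_keys(internal, mapping)
        row = {key: float(internal.torsions[idx]) for key, idx in keys.items()}
        for (key, value), quad in zip(
            extra_torsion_values(internal), internal.extra_quadruples
        ):
            ref = [
                mapping.reference_position(int(internal.atom_res[j])) for j in quad
            ]
            if all(r is not None for r in ref):
                anchored = TorsionKey.from_quadruple(
                    tuple(internal.atom_names[j] for j in quad), tuple(ref)
                )
                row[anchored] = value
        rows[name] = row
    table = pd.DataFrame.from_dict(rows, orient="index")
    table = table.reindex(sorted(table.columns), axis=1)
    # warn when a pair of members shares no columns at all
    present = table.notna().to_numpy()
    shared = present @ present.T
    n = len(table)
    if n > 1 and (shared[~np.eye(n, dtype=bool)] == 0).any():
        warnings.warn(
            "some member pairs share zero torsion columns; clustering will degrade",
            stacklevel=2,
        )
    return table
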
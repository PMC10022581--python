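"""Synthetic multi-structure ensembles with planted torsion motions.

The generator emulates the statistical structure the torsion-space method
assumes: a base chain built on ideal geometry whose conformers differ by a
small number of independent linear torsion "modes" (each molecule gets a
coefficient per mode) plus wrapped angular noise.  Optional two-group
coefficient splits emulate condition contrasts such as cryo-cooled vs
room-temperature collection; per-molecule point mutations and missing loops
emulate the messiness of real multi-dataset collections.  Ground truth
(coefficients, mode definitions, group labels) is returned — and written —
alongside the structures, so every downstream stage can be tested against
planted values.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .entity import ResidueMapping
from .geometry import (TorsionKey, build_torsion_keys, extract_internal,
                       internal_from_sequence, wrap_angle)
from .structure_io import ChainModel, write_structure


@dataclass
class ModeSpec:
    """One independent torsion motion.

    ``deltas`` maps reference-position-anchored torsion identities to the
    angular amplitude (degrees) applied per unit coefficient.
    ``coefficients`` is ``"uniform"`` (U[-1, 1]), ``"two_group"`` (+1 for the
    first half of the molecules, -1 for the second) or an explicit array.
    """

    deltas: dict[TorsionKey, float]
    coefficients: str | np.ndarray = "uniform"


@dataclass
class EnsembleSpec:
    """Parameters of a synthetic multi-structure ensemble."""

    n_molecules: int
    n_residues: int = 30
    sequence: str | None = None  # default poly-alanine of n_residues
    modes: list[ModeSpec] = field(default_factory=list)
    noise_sd: float = 0.0  # degrees, wrapped normal on every torsion
    mutations: dict[int, list[tuple[int, str]]] = field(default_factory=dict)
    deletions: dict[int, tuple[int, int]] = field(default_factory=dict)
    missing_loops: dict[int, tuple[int, int]] = field(default_factory=dict)
    phi: float = -57.0  # alpha-helical backbone base
    psi: float = -47.0
    name_prefix: str = "synth"
    seed: int = 0

    def __post_init__(self):
        if self.n_molecules < 2:
            raise ValueError("n_molecules must be >= 2")
        if self.sequence is None:
            self.sequence = "A" * self.n_residues
        self.n_residues = len(self.sequence)
        for mode in self.modes:
            for amp in mode.deltas.values():
                if not np.isfinite(amp):
                    raise ValueError("mode amplitudes must be finite")


def phi_psi_mode(residues, amplitude: float,
                 include=("phi", "psi")) -> dict[TorsionKey, float]:
    """Mode deltas touching the Ramachandran angles of given 1-based residues."""
    deltas: dict[TorsionKey, float] = {}
    for r in residues:
        if "phi" in include:
            deltas[TorsionKey(r, ("C", "N", "CA", "C"), (-1, 0, 0, 0))] = amplitude
        if "psi" in include:
            deltas[TorsionKey(r, ("N", "CA", "C", "N"), (0, 0, 0, 1))] = amplitude
    return deltas


def scatter_mode(rng: np.random.Generator, n_residues: int, n_torsions: int,
                 amplitude: float, exclude_keys=()) -> dict[TorsionKey, float]:
    """Amplitude on ``n_torsions`` phi/psi angles drawn at random positions."""
    exclude = set(exclude_keys)
    candidates = [
        key
        for r in range(2, n_residues)  # avoid termini
        for key in phi_psi_mode([r], amplitude)
        if key not in exclude
    ]
    picks = rng.choice(len(candidates), size=n_torsions, replace=False)
    return {candidates[int(i)]: amplitude for i in picks}


def _identity_mapping(sequence: str, deleted: set[int]) -> ResidueMapping:
    """Ordinal -> 1-based reference position, skipping deleted positions."""
    chain_to_ref = {}
    ordinal = 0
    for ref_pos in range(1, len(sequence) + 1):
        if ref_pos in deleted:
            continue
        chain_to_ref[ordinal] = ref_pos
        ordinal += 1
    return ResidueMapping(chain_to_ref=chain_to_ref, identity_fraction=1.0,
                          aligned_length=len(chain_to_ref))


def _mode_coefficients(mode: ModeSpec, n: int, rng) -> np.ndarray:
    if isinstance(mode.coefficients, str):
        if mode.coefficients == "uniform":
            return rng.uniform(-1.0, 1.0, n)
        if mode.coefficients == "two_group":
            return np.where(np.arange(n) < n // 2, 1.0, -1.0)
        raise ValueError(f"unknown coefficient generator {mode.coefficients!r}")
    coeff = np.asarray(mode.coefficients, dtype=float)
    if coeff.shape != (n,):
        raise ValueError("explicit coefficients must have one value per molecule")
    return coeff


def generate_ensemble(spec: EnsembleSpec, out_dir: str | Path | None = None
                      ) -> tuple[list[ChainModel], dict]:
    """Generate the ensemble; returns (chains, ground-truth record).

    With ``out_dir`` the chains are written as PDB files plus a
    ``truth.json``; a fixed seed makes the output byte-identical.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_molecules
    coeffs = [_mode_coefficients(m, n, rng) for m in spec.modes]
    group_labels = None
    for k, m in enumerate(spec.modes):
        if isinstance(m.coefficients, str) and m.coefficients == "two_group":
            group_labels = ["A" if c > 0 else "B" for c in coeffs[k]]

    chains: list[ChainModel] = []
    skipped: list[list[str]] = []
    torsion_truth: list[dict[str, float]] = []
    for m in range(n):
        seq = list(spec.sequence)
        for pos, letter in spec.mutations.get(m, []):
            seq[pos - 1] = letter
        deleted = set()
        if m in spec.deletions:
            lo, hi = spec.deletions[m]
            deleted = set(range(lo, hi + 1))
        kept_seq = "".join(s for i, s in enumerate(seq, 1) if i not in deleted)
        internal = internal_from_sequence(
            kept_seq, phi=spec.phi, psi=spec.psi,
            model_name=f"{spec.name_prefix}{m:03d}_A",
        )
        mapping = _identity_mapping("".join(seq), deleted)
        keymap = build_torsion_keys(internal, mapping)
        missed: list[str] = []
        for k, mode in enumerate(spec.modes):
            c = coeffs[k][m]
            for key, amp in mode.deltas.items():
                idx = keymap.get(key)
                if idx is None:
                    missed.append(str(key))
                    continue
                internal.torsions[idx] = wrap_angle(
                    internal.torsions[idx] + c * amp)
        if spec.noise_sd > 0:
            ta = internal.torsion_atoms()
            internal.torsions[ta] = wrap_angle(
                internal.torsions[ta] + rng.normal(0, spec.noise_sd, len(ta)))
        skipped.append(missed)
        torsion_truth.append(
            {str(key): float(internal.torsions[idx])
             for key, idx in build_torsion_keys(internal, mapping).items()}
        )
        chain = internal.to_chain()
        if m in spec.missing_loops:
            lo, hi = spec.missing_loops[m]
            keep = lambda num: not (lo <= num <= hi)  # noqa: E731
            chain = ChainModel(
                model_name=chain.model_name,
                ordered_residues=[r for r in chain.ordered_residues
                                  if keep(r[0])],
                atoms=[a for a in chain.atoms if keep(a.residue_number)],
            )
        chains.append(chain)

    truth = {
        "seed": spec.seed,
        "noise_sd": spec.noise_sd,
        "modes": [
            {str(key): float(amp) for key, amp in mode.deltas.items()}
            for mode in spec.modes
        ],
        "coefficients": [[float(v) for v in c] for c in coeffs],
        "groups": group_labels,
        "molecules": [c.model_name for c in chains],
        "skipped_deltas": skipped,
        "torsions": torsion_truth,
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for chain in chains:
            write_structure(chain, out / f"{chain.model_name[:-2]}.pdb")
        (out / "truth.json").write_text(
            json.dumps(truth, sort_keys=True, indent=1) + "\n")
    return chains, truth


def perturb_geometry(chain: ChainModel, length_sd: float, angle_sd: float,
                     seed: int) -> ChainModel:
    """Jitter measured bond lengths/angles and rebuild.

    Produces an "experimental-like" deposit that is no longer exactly
    representable on ideal geometry, so a naive ideal-geometry rebuild of its
    measured torsions drifts along the chain.
    """
    if length_sd < 0 or angle_sd < 0:
        raise ValueError("standard deviations must be non-negative")
    from .geometry import rebuild_cartesian
    from .refine import target_coordinates

    internal = extract_internal(chain, use_ideal=False)
    rng = np.random.default_rng(seed)
    if length_sd > 0:
        sel = np.isfinite(internal.lengths)
        internal.lengths[sel] += rng.normal(0, length_sd, int(sel.sum()))
    if angle_sd > 0:
        sel = np.isfinite(internal.angles)
        internal.angles[sel] += rng.normal(0, angle_sd, int(sel.sum()))
    # anchor each segment back onto the input so sd = 0 is the identity
    return rebuild_cartesian(internal, anchor=target_coordinates(chain, internal))
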
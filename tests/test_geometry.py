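import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ropespace.coords import superposed_rmsd
from ropespace.geometry import (TorsionKey, UndefinedDihedralError,
                                build_torsion_keys, extract_internal,
                                internal_from_sequence, measure_dihedral,
                                rebuild_cartesian, wrap_angle)
from ropespace.structure_io import ChainModel

from .oracles import dihedral_normal_form


class TestDihedral:
    def test_trans_and_cis_reference_values(self):
        zigzag = [[0, 0, 0], [1, 0, 0], [1.5, 1, 0], [2.5, 1, 0]]
        assert measure_dihedral(*zigzag) == pytest.approx(180.0)
        eclipsed = [[0, 0, 0], [1, 0, 0], [1.5, 1, 0], [0.5, 1, 0]]
        assert measure_dihedral(*eclipsed) == pytest.approx(0.0)

    def test_matches_independent_normal_form_oracle(self, rng):
        for _ in range(100):
            pts = rng.normal(size=(4, 3)) * 3.0
            try:
                ours = measure_dihedral(*pts)
            except UndefinedDihedralError:
                continue
            assert ours == pytest.approx(dihedral_normal_form(*pts), abs=1e-9)

    def test_collinear_middle_triplet_raises(self):
        with pytest.raises(UndefinedDihedralError):
            measure_dihedral([0, 1, 0], [0, 0, 0], [1, 0, 0], [2, 0, 0])

    @given(st.floats(-720, 720))
    @settings(max_examples=60, deadline=None)
    def test_wrap_is_periodic_and_in_range(self, angle):
        w = wrap_angle(angle)
        assert -180.0 < w <= 180.0
        assert wrap_angle(angle + 360.0) == pytest.approx(w, abs=1e-9)


class TestExtractRebuild:
    def test_extraction_recovers_planted_torsions(self, mixed_chain):
        internal, chain = mixed_chain
        measured = extract_internal(chain)
        ours = measured.torsions
        truth = internal.torsions
        both = np.isfinite(ours) & np.isfinite(truth)
        assert np.abs(wrap_angle(ours[both] - truth[both])).max() < 1e-6

    @pytest.mark.parametrize("n_res", [6, 60])
    def test_rebuild_after_extract_is_identity_up_to_rigid_motion(self, n_res):
        internal = internal_from_sequence("AQV" * (n_res // 3))
        chain = internal.to_chain()
        rebuilt = rebuild_cartesian(extract_internal(chain))
        assert superposed_rmsd(chain.coordinates(),
                               rebuilt.coordinates()) < 1e-6

    def test_chain_gap_splits_torsion_graph(self, helix20):
        _, chain = helix20
        # drop residue 11 entirely: no torsion may span residues 10-12
        kept = [r for r in chain.ordered_residues if r[0] != 11]
        atoms = [a for a in chain.atoms if a.residue_number != 11]
        gapped = ChainModel("gap_A", kept, atoms)
        internal = extract_internal(gapped)
        keys = build_torsion_keys(internal)
        ordinals = {r: i for i, r in enumerate(n for n, _, _ in kept)}
        lo, hi = ordinals[10], ordinals[12]
        for key in keys:
            touched = {key.residue + o for o in key.offsets}
            assert not (lo in touched and hi in touched)
        assert internal.segment.max() == 1  # two ordered segments

    def test_glycine_emits_no_sidechain_torsions(self):
        internal = internal_from_sequence("AGA")
        keys = build_torsion_keys(internal)
        gly_keys = [k for k in keys if k.residue == 1]
        assert all(set(k.atoms) <= {"N", "CA", "C", "O"} for k in gly_keys)

    def test_torsion_edit_moves_only_downstream_atoms(self, helix20):
        internal, _ = helix20
        edited = internal.copy()
        keys = build_torsion_keys(edited)
        phi10 = next(k for k in keys if k.is_phi and k.residue == 10)
        idx = keys[phi10]
        edited.torsions[idx] = wrap_angle(edited.torsions[idx] + 10.0)
        before = internal.rebuild_coords()
        after = edited.rebuild_coords()
        moved = np.linalg.norm(after - before, axis=1) > 1e-12
        descendants = set(edited.descendants()[idx])
        assert set(np.flatnonzero(moved)) == descendants

    def test_perturbed_geometry_rebuild_drifts(self):
        """Small bond-length/angle noise makes the naive ideal-geometry
        rebuild walk away from the original path."""
        from ropespace.synthetic import perturb_geometry

        internal = internal_from_sequence("A" * 100)
        chain = internal.to_chain()
        deposit = perturb_geometry(chain, length_sd=0.02, angle_sd=2.0, seed=3)
        naive = rebuild_cartesian(extract_internal(deposit))
        drift = superposed_rmsd(deposit.coordinates(), naive.coordinates())
        assert drift > 1.0


class TestTorsionKeys:
    def test_forward_and_reverse_quadruples_are_one_identity(self):
        fwd = TorsionKey.from_quadruple(("N", "CA", "C", "N"), (5, 5, 5, 6))
        rev = TorsionKey.from_quadruple(("N", "C", "CA", "N"), (6, 5, 5, 5))
        assert fwd == rev

    def test_inter_residue_torsion_assigned_to_earlier_residue(self):
        omega = TorsionKey.from_quadruple(("CA", "C", "N", "CA"), (7, 7, 8, 8))
        assert omega.residue == 7
        assert omega.is_omega

    def test_phi_psi_classification(self):
        phi = TorsionKey.from_quadruple(("C", "N", "CA", "C"), (3, 4, 4, 4))
        psi = TorsionKey.from_quadruple(("N", "CA", "C", "N"), (4, 4, 4, 5))
        assert phi.is_phi and phi.residue == 4
        assert psi.is_psi and psi.residue == 4
        assert not phi.is_psi and not psi.is_phi

    def test_lysine_arginine_share_keys_up_to_delta_carbon(self):
        lys = internal_from_sequence("AKA")
        arg = internal_from_sequence("ARA")
        lys_keys = set(build_torsion_keys(lys))
        arg_keys = set(build_torsion_keys(arg))
        backbone = {"N", "CA", "C", "O"}
        shared_side = {
            k for k in lys_keys & arg_keys
            if k.residue == 1 and not set(k.atoms[1:3]) <= backbone
        }  # side-chain torsion: the rotating (middle) bond is beyond CA
        chi1 = TorsionKey.from_quadruple(("N", "CA", "CB", "CG"), (1, 1, 1, 1))
        chi2 = TorsionKey.from_quadruple(("CA", "CB", "CG", "CD"), (1, 1, 1, 1))
        assert shared_side == {chi1, chi2}


def test_disulfide_detected_as_inter_residue_torsion():
    """Two cysteines brought within bonding distance yield one extra
    (off-tree) torsion assigned to the earlier residue."""
    internal = internal_from_sequence("ACGGGGCA", phi=-80.0, psi=60.0)
    chain = internal.to_chain()
    coords = chain.coordinates()
    sg = [i for i, a in enumerate(chain.atoms) if a.atom_name == "SG"]
    if np.linalg.norm(coords[sg[0]] - coords[sg[1]]) >= 2.5:
        # force proximity: translate the second SG next to the first
        chain.atoms[sg[1]].position = (
            chain.atoms[sg[0]].position + np.array([2.0, 0.0, 0.0]))
    measured = extract_internal(chain)
    assert len(measured.extra_quadruples) == 1
    from ropespace.geometry import extra_torsion_values

    (key, value), = extra_torsion_values(measured)
    assert key.atoms[0] == "CB" and key.atoms[-1] == "CB"
    assert np.isfinite(value)
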
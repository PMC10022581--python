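import numpy as np
import pytest

from ropespace.explorer import (apply_motion, axis_motion, marker_distance,
                                materialize_frames, ramachandran_deviation)
from ropespace.geometry import (build_torsion_keys, extract_internal,
                                wrap_angle)
from ropespace.ideal import IdealGeometry
from ropespace.synthetic import EnsembleSpec, ModeSpec, phi_psi_mode

from .conftest import ensemble_space


@pytest.fixture(scope="module")
def hinge_setup():
    """Ensemble whose single mode lives in the Ramachandran angles of
    residues 10-12 only."""
    mode = phi_psi_mode([10, 11, 12], 12.0)
    spec = EnsembleSpec(14, 20, modes=[ModeSpec(mode, "uniform")],
                        noise_sd=0.5, seed=17)
    entity, table, space, truth = ensemble_space(spec)
    reference = entity.member_names[0]
    chain, mapping = entity.get_member(reference)
    refined = extract_internal(chain)
    motion = axis_motion(space, 0, reference, refined, mapping)
    return space, motion, refined, mapping


class TestAxisMotion:
    def test_complete_reference_reports_no_missing_keys(self, hinge_setup):
        _, motion, _, _ = hinge_setup
        assert motion.missing == []
        assert motion.deltas

    def test_reference_missing_a_loop_reports_dropped_deltas(self, hinge_setup):
        space, _, refined, mapping = hinge_setup
        from ropespace.structure_io import ChainModel

        chain = refined.to_chain()
        keep = lambda n: not (11 <= n <= 12)  # noqa: E731
        partial = ChainModel(
            model_name=chain.model_name,
            ordered_residues=[r for r in chain.ordered_residues
                              if keep(r[0])],
            atoms=[a for a in chain.atoms if keep(a.residue_number)],
        )
        from ropespace.entity import align_sequence

        part_map = align_sequence(partial.one_letter_sequence,
                                  "A" * 20)
        motion = axis_motion(space, 0, space.names[0],
                             extract_internal(partial), None)
        assert motion.missing  # dropped deltas are reported

    def test_axis_beyond_rank_is_an_error(self, hinge_setup):
        space, _, refined, mapping = hinge_setup
        with pytest.raises(IndexError):
            axis_motion(space, 99, space.names[0], refined, mapping)
        with pytest.raises(KeyError):
            axis_motion(space, 0, "nobody_A", refined, mapping)


class TestApplyMotion:
    def test_slider_zero_reproduces_the_reference_exactly(self, hinge_setup):
        _, motion, refined, mapping = hinge_setup
        frame = apply_motion(motion, refined, 0.0, mapping)
        assert np.abs(frame.coordinates()
                      - refined.rebuild_coords()).max() < 1e-9

    def test_plus_minus_one_are_symmetric_in_torsion_space(self, hinge_setup):
        _, motion, refined, mapping = hinge_setup
        plus = extract_internal(apply_motion(motion, refined, 1.0, mapping))
        minus = extract_internal(apply_motion(motion, refined, -1.0, mapping))
        keys = build_torsion_keys(refined, mapping)
        for key, delta in motion.deltas.items():
            if abs(delta) < 1e-9:
                continue
            idx = keys[key]
            up = wrap_angle(plus.torsions[idx] - refined.torsions[idx])
            down = wrap_angle(minus.torsions[idx] - refined.torsions[idx])
            assert up == pytest.approx(-down, abs=1e-5)

    def test_torsion_linearity_of_composition(self, hinge_setup):
        """torsions(s1) + torsions(s2) - torsions(0) == torsions(s1+s2)."""
        _, motion, refined, mapping = hinge_setup
        keys = build_torsion_keys(refined, mapping)
        s1, s2 = 0.3, 0.45
        f = {s: extract_internal(apply_motion(motion, refined, s, mapping))
             for s in (s1, s2, s1 + s2)}
        for key in motion.deltas:
            idx = keys[key]
            lhs = wrap_angle(f[s1].torsions[idx] + f[s2].torsions[idx]
                             - refined.torsions[idx])
            rhs = wrap_angle(f[s1 + s2].torsions[idx])
            assert wrap_angle(lhs - rhs) == pytest.approx(0.0, abs=1e-5)

    def test_frames_keep_ideal_bond_geometry(self, hinge_setup):
        """Torsion interpolation never violates bond lengths or angles."""
        _, motion, refined, mapping = hinge_setup
        geom = IdealGeometry.default()
        for s in (-1.0, 0.5, 1.0):
            frame = apply_motion(motion, refined, s, mapping)
            measured = extract_internal(frame, geom, use_ideal=False)
            ideal = extract_internal(frame, geom, use_ideal=True)
            sel = np.isfinite(measured.lengths) & np.isfinite(ideal.lengths)
            assert np.abs(measured.lengths[sel] - ideal.lengths[sel]).max() < 1e-6
            sel = np.isfinite(measured.angles) & np.isfinite(ideal.angles)
            assert np.abs(measured.angles[sel] - ideal.angles[sel]).max() < 1e-6

    def test_slider_outside_range_rejected(self, hinge_setup):
        _, motion, refined, mapping = hinge_setup
        with pytest.raises(ValueError):
            apply_motion(motion, refined, 1.5, mapping)

    def test_multi_frame_export(self, hinge_setup, tmp_path):
        _, motion, refined, mapping = hinge_setup
        out = tmp_path / "motion.pdb"
        materialize_frames(motion, refined, out, mapping=mapping)
        text = out.read_text()
        assert text.count("MODEL") == 5 and text.count("ENDMDL") == 5


class TestRamachandran:
    def test_hinge_mode_localizes_to_planted_residues(self, hinge_setup):
        _, motion, _, _ = hinge_setup
        profile = ramachandran_deviation(motion)
        top3 = set(profile.sort_values(ascending=False).index[:3])
        assert top3 == {10, 11, 12}

    def test_zero_deltas_score_zero(self, hinge_setup):
        _, motion, _, _ = hinge_setup
        flat = type(motion)(axis=0, reference=motion.reference,
                            deltas={k: 0.0 for k in motion.deltas})
        assert (ramachandran_deviation(flat) == 0.0).all()

    def test_sidechain_only_deltas_score_zero(self):
        from ropespace.geometry import TorsionKey

        chi1 = TorsionKey(5, ("N", "CA", "CB", "CG"), (0, 0, 0, 0))
        from ropespace.explorer import AxisMotion

        motion = AxisMotion(axis=0, reference="x_A", deltas={chi1: 30.0})
        profile = ramachandran_deviation(motion)
        assert profile.sum() == 0.0


class TestMarkerDistance:
    def test_same_atom_gives_zero_everywhere(self, hinge_setup):
        spec = EnsembleSpec(4, 12, seed=2)
        entity, _, _, _ = ensemble_space(spec)
        series = marker_distance(entity, (5, "CA"), (5, "CA"))
        assert (series == 0.0).all()

    def test_distance_matches_direct_euclidean(self):
        spec = EnsembleSpec(3, 12, seed=4)
        entity, _, _, _ = ensemble_space(spec)
        chain, mapping = entity.members[0]
        series = marker_distance(entity, (2, "CA"), (9, "CA"))
        atoms = {(a.residue_number, a.atom_name): a.position
                 for a in chain.atoms}
        expected = np.linalg.norm(atoms[(2, "CA")] - atoms[(9, "CA")])
        assert series[chain.model_name] == pytest.approx(expected, abs=1e-9)

    def test_member_lacking_the_residue_gets_nan(self):
        spec = EnsembleSpec(3, 14, missing_loops={1: (7, 9)}, seed=5)
        entity, _, _, _ = ensemble_space(spec)
        series = marker_distance(entity, (3, "CA"), (8, "CA"))
        names = entity.member_names
        assert np.isnan(series[names[1]])
        assert np.isfinite(series[names[0]]) and np.isfinite(series[names[2]])
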
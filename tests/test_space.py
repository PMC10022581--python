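import numpy as np
import pandas as pd
import pytest

from ropespace.geometry import TorsionKey
from ropespace.space import (TorsionSpace, center_differences,
                             correlation_matrix, embed, subset_space,
                             svd_space)
from ropespace.synthetic import EnsembleSpec, ModeSpec, scatter_mode

from .conftest import ensemble_space
from .oracles import circular_mean_vector, pearson_two_pass


def key(i):
    return TorsionKey(i, ("N", "CA", "C", "N"), (0, 0, 0, 1))


def table_from(values, names=None):
    values = np.asarray(values, dtype=float)
    names = names or [f"m{i}" for i in range(values.shape[0])]
    return pd.DataFrame(values, index=names,
                        columns=[key(j) for j in range(values.shape[1])])


class TestCentering:
    def test_symmetric_pair_centers_to_plus_minus_half_gap(self):
        diff = center_differences(table_from([[10.0], [20.0]]))
        assert diff.values[:, 0] == pytest.approx([-5.0, 5.0])

    def test_circular_mean_across_the_branch_cut(self):
        """{179, -179} average to 180, not to the arithmetic 0."""
        diff = center_differences(table_from([[179.0], [-179.0]]))
        assert diff.circular_means[0] == pytest.approx(
            circular_mean_vector([179.0, -179.0]))
        assert abs(diff.circular_means[0]) == pytest.approx(180.0)
        assert sorted(diff.values[:, 0]) == pytest.approx([-1.0, 1.0])

    def test_equal_values_center_to_zero(self):
        diff = center_differences(table_from([[42.0], [42.0], [42.0]]))
        assert np.allclose(diff.values, 0.0)

    def test_requires_two_molecules(self):
        with pytest.raises(ValueError):
            center_differences(table_from([[1.0]]))


class TestEmbedding:
    def test_reference_angles(self):
        diff = center_differences(table_from([[0.0, 0.0], [180.0, 90.0]]))
        # bypass centering: feed a raw difference matrix
        diff.values = np.array([[0.0, 90.0], [np.nan, -90.0]])
        emb = embed(diff)
        assert emb.vectors[0, :2] == pytest.approx([0.0, 1.0])  # t = 0
        assert emb.vectors[0, 2:] == pytest.approx([1.0, 0.0])  # t = 90

    def test_missing_angle_is_exact_zero_vector(self):
        table = table_from([[10.0, 5.0], [20.0, np.nan], [30.0, -5.0]])
        emb = embed(center_differences(table))
        assert emb.vectors[1, 2] == 0.0 and emb.vectors[1, 3] == 0.0
        assert not emb.present[1, 1]


class TestCorrelation:
    def test_identical_molecules_correlate_at_one(self, rng):
        row = rng.uniform(-30, 30, 8)
        emb = embed(center_differences(table_from(
            [row, row, row + rng.normal(0, 5, 8)])))
        corr = correlation_matrix(emb)
        assert corr[0, 1] == pytest.approx(1.0)

    def test_matches_two_pass_pearson_oracle(self, rng):
        table = table_from(rng.uniform(-60, 60, size=(5, 12)))
        diff = center_differences(table)
        emb = embed(diff)
        corr = correlation_matrix(emb)
        centered = emb.vectors - emb.vectors.mean(axis=0)
        for i in range(5):
            for j in range(i + 1, 5):
                assert corr[i, j] == pytest.approx(
                    pearson_two_pass(centered[i], centered[j]), abs=1e-12)

    def test_symmetric_with_unit_diagonal(self, rng):
        table = table_from(rng.uniform(-60, 60, size=(6, 10)))
        corr = correlation_matrix(embed(center_differences(table)))
        assert np.array_equal(corr, corr.T)
        assert np.allclose(np.diag(corr), 1.0)

    def test_too_few_matched_keys_yield_zero(self):
        vals = np.full((2, 4), np.nan)
        vals[0, :2] = [10.0, 20.0]
        vals[1, 2:] = [5.0, 15.0]
        vals[:, 0] = [1.0, 2.0]  # exactly one shared column
        corr = correlation_matrix(embed(center_differences(table_from(vals))))
        assert corr[0, 1] == 0.0


class TestSvdSpace:
    def fit(self, values):
        table = table_from(values)
        diff = center_differences(table)
        emb = embed(diff)
        return svd_space(correlation_matrix(emb), emb, diff)

    def test_duplicate_molecules_project_to_identical_points(self, rng):
        row_a = rng.uniform(-40, 40, 10)
        row_b = rng.uniform(-40, 40, 10)
        space = self.fit([row_a, row_a, row_b])
        d = np.linalg.norm(space.projections[0] - space.projections[1])
        assert d < 1e-9

    def test_eigenvalues_sorted_non_increasing(self, rng):
        space = self.fit(rng.uniform(-40, 40, size=(7, 9)))
        assert np.all(np.diff(space.eigenvalues) <= 1e-12)

    def test_identical_molecules_degenerate_but_finite(self):
        """All-identical input: no crash, eigenvalues flatten to trace/N and
        no molecule is differentiated from any other."""
        space = self.fit(np.tile(np.linspace(-30, 30, 6), (4, 1)))
        assert np.all(np.isfinite(space.projections))
        assert space.eigenvalues.sum() == pytest.approx(4.0)  # trace preserved
        p = space.projections
        d = np.linalg.norm(p[:, None] - p[None, :], axis=-1)
        assert d.max() < 1e-9  # indistinguishable molecules coincide

    def test_label_permutation_equivariance(self, rng):
        values = rng.uniform(-40, 40, size=(8, 12))
        space = self.fit(values)
        perm = rng.permutation(8)
        space_p = self.fit(values[perm])
        # compare pairwise distances (axis signs may differ)
        def dists(s):
            p = s.projections[:, :3]
            return np.linalg.norm(p[:, None] - p[None, :], axis=-1)
        assert np.allclose(dists(space)[np.ix_(perm, perm)][0],
                           dists(space_p)[0], atol=1e-9)

    def test_axis_deltas_reconstruct_planted_mode_direction(self, rng):
        mode = rng.normal(0, 10, 12)
        coeff = np.linspace(-1, 1, 9)
        values = coeff[:, None] * mode[None, :]
        space = self.fit(values)
        deltas = np.array([space.axis_torsion_deltas[0][key(j)]
                           for j in range(12)])
        r = np.corrcoef(deltas, mode)[0, 1]
        assert abs(r) > 0.99


class TestModelResults:
    def test_planted_two_group_modes_dominate_and_recover(self):
        rng = np.random.default_rng(7)
        m1 = scatter_mode(rng, 24, 20, 25.0)
        m2 = scatter_mode(rng, 24, 20, 17.0, exclude_keys=m1)
        c1 = rng.choice([-1.0, 1.0], 30)
        c2 = rng.choice([-1.0, 1.0], 30)
        c2 -= (c1 @ c2) / (c1 @ c1) * c1
        spec = EnsembleSpec(30, 24, modes=[ModeSpec(m1, c1), ModeSpec(m2, c2)],
                            noise_sd=2.0, seed=3)
        _, _, space, _ = ensemble_space(spec)
        pos = np.clip(space.eigenvalues, 0, None)
        assert pos[:2].sum() / pos.sum() >= 0.9
        for c in (c1, c2):
            best = max(abs(np.corrcoef(c, space.projections[:, a])[0, 1])
                       for a in range(2))
            assert best >= 0.95

    def test_subset_of_everything_reproduces_the_space(self, rng):
        table = table_from(rng.uniform(-40, 40, size=(6, 10)))
        space = TorsionSpace(table).fit()
        again = subset_space(table, list(table.index))
        assert np.allclose(np.abs(space.projections),
                           np.abs(again.projections), atol=1e-9)

    def test_subset_within_one_group_drops_the_group_mode(self):
        rng = np.random.default_rng(5)
        mode = scatter_mode(rng, 20, 16, 8.0)
        spec = EnsembleSpec(20, 20, modes=[ModeSpec(mode, "two_group")],
                            noise_sd=1.0, seed=8)
        _, table, space, truth = ensemble_space(spec)
        share_full = space.explained_fraction(0)
        group_a = [m for m, g in zip(truth["molecules"], truth["groups"])
                   if g == "A"]
        sub = subset_space(table, group_a)
        assert sub.explained_fraction(0) < share_full

    def test_subset_of_one_is_an_error(self, rng):
        table = table_from(rng.uniform(-40, 40, size=(4, 6)))
        with pytest.raises(ValueError):
            subset_space(table, [table.index[0]])

    def test_summary_and_exports(self, rng, tmp_path):
        table = table_from(rng.uniform(-40, 40, size=(5, 8)))
        space = TorsionSpace(table).fit()
        text = space.summary()
        assert "molecules: 5" in text
        space.to_json(tmp_path / "s.json")
        space.to_tsv(tmp_path / "s.tsv")
        frame = pd.read_csv(tmp_path / "s.tsv", sep="\t", index_col=0)
        assert list(frame.index) == list(table.index)
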
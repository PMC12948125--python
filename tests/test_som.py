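import numpy as np
import pytest
from scipy import ndimage
from scipy.stats import spearmanr

import snpsom
from snpsom.snp_score import ScoreMatrix
from snpsom.som import SOMModel, _assign


def scores_from(arr):
    arr = np.asarray(arr, dtype=float)
    return ScoreMatrix(
        values=arr,
        snp_ids=[f"snp{i}" for i in range(arr.shape[0])],
        sample_ids=[f"s{j}" for j in range(arr.shape[1])],
    )


class TestTraining:
    def test_single_snp_codebook_converges_to_profile(self):
        x = np.array([[1.0, -0.5, 0.25, -0.75]])
        with pytest.warns(UserWarning, match="under-populated"):
            model = snpsom.train_som(scores_from(x), width=2, height=2,
                                     epochs=200, seed=0)
        bmu = model.assignment[0]
        assert np.linalg.norm(model.codebook[bmu] - x[0]) < 1e-3

    def test_two_orthogonal_clusters_map_to_disjoint_contiguous_regions(self):
        rng = np.random.default_rng(5)
        a = np.tile([2.0, 2.0, -1, -1, -1, -1], (40, 1))
        b = np.tile([-1, -1, -1, 2.0, 2.0, 2.0], (40, 1))
        x = np.vstack([a, b]) + rng.normal(scale=0.05, size=(80, 6))
        model = snpsom.train_som(scores_from(x), width=6, height=6,
                                 epochs=30, seed=1)
        units_a = set(model.assignment[:40])
        units_b = set(model.assignment[40:])
        assert not units_a & units_b
        for units in (units_a, units_b):
            mask = np.zeros(36, dtype=bool)
            mask[list(units)] = True
            _, n = ndimage.label(mask.reshape(6, 6), structure=np.ones((3, 3)))
            assert n == 1

    def test_determinism_bit_identical(self, small_sim):
        geno, _ = small_sim
        sc = snpsom.compute_snp_score(geno)
        m1 = snpsom.train_som(sc, width=6, height=6, epochs=3, seed=9)
        m2 = snpsom.train_som(sc, width=6, height=6, epochs=3, seed=9)
        assert np.array_equal(m1.codebook, m2.codebook)
        assert np.array_equal(m1.assignment, m2.assignment)

    def test_bmu_assignment_is_brute_force_optimal(self, small_model, small_sim):
        geno, _ = small_sim
        x = snpsom.compute_snp_score(geno).values
        code = small_model.codebook
        brute = np.array(
            [np.argmin([np.sum((x[i] - c) ** 2) for c in code])
             for i in range(x.shape[0])]
        )
        assert np.array_equal(small_model.assignment, brute)

    def test_quantization_error_non_increasing_with_epochs(self, small_sim):
        geno, _ = small_sim
        sc = snpsom.compute_snp_score(geno)
        qe = [
            snpsom.quantization_error(
                snpsom.train_som(sc, width=8, height=8, epochs=e, seed=4), sc
            )
            for e in (1, 4, 8)
        ]
        assert qe[1] <= qe[0] * 1.01
        assert qe[2] <= qe[1] * 1.01

    def test_topology_preservation(self, small_model):
        """Grid distance and codebook distance correlate over unit pairs."""
        coords = small_model.unit_coords().astype(float)
        rng = np.random.default_rng(0)
        pairs = rng.integers(0, small_model.n_units, size=(2000, 2))
        pairs = pairs[pairs[:, 0] != pairs[:, 1]]
        gd = np.linalg.norm(coords[pairs[:, 0]] - coords[pairs[:, 1]], axis=1)
        cd = np.linalg.norm(
            small_model.codebook[pairs[:, 0]] - small_model.codebook[pairs[:, 1]],
            axis=1,
        )
        rho = spearmanr(gd, cd).statistic
        assert rho > 0.3

    def test_non_finite_input_rejected(self):
        x = np.array([[0.0, np.nan, 1.0]])
        with pytest.raises(ValueError, match="non-finite"):
            snpsom.train_som(scores_from(x), width=2, height=2, epochs=1)

    def test_constant_matrix_warns_and_yields_constant_codebook(self):
        x = np.zeros((30, 4))
        with pytest.warns(UserWarning, match="constant"):
            model = snpsom.train_som(scores_from(x), width=3, height=3, epochs=2)
        assert np.allclose(model.codebook, model.codebook[0])


class TestPortraits:
    def test_portrait_equals_codebook_column(self, small_model):
        sid = small_model.sample_ids[3]
        p = snpsom.sample_portrait(small_model, sid)
        assert np.array_equal(p.values, small_model.codebook[:, 3])
        assert p.grid.shape == (small_model.height, small_model.width)

    def test_unknown_sample_rejected(self, small_model):
        with pytest.raises(KeyError, match="nobody"):
            snpsom.sample_portrait(small_model, "nobody")

    def test_mean_portrait_singleton_and_negation(self):
        code = np.array([[1.0, -1.0], [0.5, -0.5], [2.0, -2.0], [0.0, 0.0]])
        model = SOMModel(
            width=2, height=2, codebook=code,
            assignment=np.zeros(1, dtype=int), snp_ids=["snp0"],
            sample_ids=["a", "b"],
        )
        single = snpsom.mean_portrait(model, ["a"])
        assert np.array_equal(single.values, code[:, 0])
        both = snpsom.mean_portrait(model, ["a", "b"])
        assert np.allclose(both.values, 0.0)
        with pytest.raises(ValueError, match="empty"):
            snpsom.mean_portrait(model, [])

    def test_mean_over_all_samples_near_zero(self, small_model):
        """Row-centered scores propagate to near-zero codebook means."""
        p = snpsom.mean_portrait(small_model, small_model.sample_ids)
        assert np.abs(p.values).mean() < 0.05


class TestSupportingMaps:
    def test_population_map_conserves_snp_count(self, small_model):
        maps = snpsom.supporting_maps(small_model)
        assert maps["population_map"].sum() == len(small_model.snp_ids)

    def test_constant_codebook_gives_zero_variance_and_d(self):
        model = SOMModel(
            width=3, height=3, codebook=np.ones((9, 4)),
            assignment=np.zeros(2, dtype=int), snp_ids=["a", "b"],
            sample_ids=list("wxyz"),
        )
        maps = snpsom.supporting_maps(model)
        assert np.allclose(maps["variance_map"], 0)
        assert np.allclose(maps["d_map"], 0)

    def test_d_map_peaks_around_an_outlier_unit(self):
        code = np.zeros((9, 2))
        code[4] = [10.0, 10.0]  # center unit of the 3x3 grid is the outlier
        model = SOMModel(
            width=3, height=3, codebook=code,
            assignment=np.zeros(1, dtype=int), snp_ids=["a"],
            sample_ids=["u", "v"],
        )
        d = snpsom.supporting_maps(model)["d_map"]
        # hand computation: every neighbor of unit 4 includes one distance of
        # sqrt(200); unit 4 itself is sqrt(200) from all 8 neighbors
        assert d[4] == pytest.approx(np.sqrt(200.0))
        assert d[0] == pytest.approx(np.sqrt(200.0) / 3.0)
        assert np.argmax(d) == 4


def test_save_load_round_trip(tmp_path, small_model):
    snpsom.save_model(small_model, tmp_path / "model")
    back = snpsom.load_model(tmp_path / "model")
    assert np.allclose(back.codebook, small_model.codebook)
    assert np.array_equal(back.assignment, small_model.assignment)
    assert back.snp_ids == small_model.snp_ids
    assert back.sample_ids == small_model.sample_ids
    # assignment still BMU-optimal after the text round trip
    x = back.codebook[back.assignment]
    assert np.array_equal(_assign(x, back.codebook), back.assignment)
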
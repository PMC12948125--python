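import numpy as np
import pandas as pd
import pytest

import snpsom
from snpsom.som import Portrait, SOMModel

from oracles import spot_oracle


def portrait(grid, subject="p"):
    grid = np.asarray(grid, dtype=float)
    return Portrait(
        values=grid.ravel(), width=grid.shape[1], height=grid.shape[0],
        subject=subject,
    )


class TestDetect:
    def test_flat_portrait_has_no_spots(self):
        assert snpsom.detect_spots(portrait(np.ones((6, 6)))).spots == []

    def test_single_high_block(self):
        g = np.zeros((6, 6))
        g[1:3, 1:3] = 5.0
        ss = snpsom.detect_spots(portrait(g), quantile=0.95, min_units=3)
        assert len(ss.spots) == 1
        assert sorted(ss.spots[0].units) == [7, 8, 13, 14]
        assert ss.spots[0].label == "A"

    def test_two_blocks_labelled_by_peak(self):
        g = np.zeros((7, 6))
        g[0:2, 0:2] = 3.0  # lower peak
        g[5:7, 3:6] = 7.0  # higher peak -> label A
        ss = snpsom.detect_spots(portrait(g), quantile=0.8, min_units=3)
        assert [sp.label for sp in ss.spots] == ["A", "B"]
        assert ss.spots[0].peak_value == 7.0
        assert len(ss.spots[0].units) == 6
        assert len(ss.spots[1].units) == 4

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_flood_fill_oracle_on_random_grids(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(30):
            g = rng.integers(0, 3, size=(5, 5)).astype(float)
            q = float(rng.choice([0.5, 0.8, 0.98]))
            mu = int(rng.choice([1, 2, 3]))
            got = snpsom.detect_spots(portrait(g), quantile=q, min_units=mu)
            expect = spot_oracle(g, q, mu)
            assert [(sp.peak_value, tuple(sp.units)) for sp in got.spots] == expect

    def test_member_snps_attached_from_model(self, small_model):
        p = snpsom.sample_portrait(small_model, small_model.sample_ids[0])
        ss = snpsom.detect_spots(p, quantile=0.9, min_units=1, model=small_model)
        union: set = set()
        for sp in ss.spots:
            members = set(sp.snp_ids)
            assert not members & union  # disjoint across spots
            union |= members
        assert len(union) <= len(small_model.snp_ids)


class TestSummaryMaps:
    def test_identical_portraits_give_binary_map(self):
        g = np.zeros((6, 6))
        g[0:2, 0:2] = 4.0
        over, _ = snpsom.summary_maps([portrait(g)] * 5, quantile=0.95)
        assert set(np.unique(over)) <= {0.0, 1.0}
        assert over.sum() == 4  # exactly the high block

    def test_disjoint_spots_have_bounded_fractions(self):
        grids = []
        for i in range(3):
            g = np.zeros((6, 6))
            g[2 * i : 2 * i + 2, 0:2] = 4.0
            grids.append(portrait(g, subject=f"p{i}"))
        over, _ = snpsom.summary_maps(grids, quantile=0.95)
        assert over.max() <= 1 / 3 + 1e-12

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            snpsom.summary_maps([])


class TestProfilesAndNetworks:
    def _model(self):
        code = np.array(
            [[1.0, 2.0, 3.0], [0.0, 1.0, 0.5], [2.0, 4.0, 6.0], [-1.0, -2.0, -3.0]]
        )
        return SOMModel(
            width=2, height=2, codebook=code,
            assignment=np.array([0, 1, 2, 3]),
            snp_ids=[f"snp{i}" for i in range(4)],
            sample_ids=["a", "b", "c"],
        )

    def _spotset(self, units_by_label):
        from snpsom.spots import Spot, SpotSet

        spots = [
            Spot(label=lab, units=np.asarray(u), peak_value=1.0, centroid=(0, 0))
            for lab, u in units_by_label.items()
        ]
        return SpotSet(spots=spots, source="test", threshold=0.5, width=2, height=2)

    def test_single_unit_spot_profile_is_codebook_row(self):
        model = self._model()
        ss = self._spotset({"A": [2]})
        prof = snpsom.spot_profiles(ss, model)
        assert np.allclose(prof.loc["A"], model.codebook[2])

    def test_whole_map_spot_profile_is_codebook_mean(self):
        model = self._model()
        ss = self._spotset({"A": [0, 1, 2, 3]})
        prof = snpsom.spot_profiles(ss, model)
        assert np.allclose(prof.loc["A"], model.codebook.mean(axis=0))

    def test_correlation_network_signs_and_threshold(self):
        prof = pd.DataFrame(
            [[1.0, 2.0, 0.0], [2.0, 4.0, 0.0], [-1.0, -2.0, 0.0]],
            index=["A", "B", "C"],
            columns=["s1", "s2", "s3"],
        )
        net = snpsom.spot_correlation_network(prof)
        weights = {(a, b): w for a, b, w in net.edges}
        assert weights[("A", "B")] == pytest.approx(1.0)
        assert weights[("A", "C")] == pytest.approx(-1.0)
        empty = snpsom.spot_correlation_network(prof, edge_threshold=1.01)
        assert empty.edges == []

    def test_correlation_network_needs_two_spots(self):
        prof = pd.DataFrame([[1.0, 2.0]], index=["A"], columns=["x", "y"])
        with pytest.raises(ValueError, match="2 spots"):
            snpsom.spot_correlation_network(prof)


class TestCooccurrence:
    def _grids(self, with_a, with_b, seed=0):
        # low-level noise keeps the quantile threshold above background even
        # when a block is absent, so absent blocks are never detected
        g = np.random.default_rng(seed).normal(0.0, 0.01, size=(6, 6))
        if with_a:
            g[0:2, 0:2] = 5.0
        if with_b:
            g[4:6, 4:6] = 4.0
        return g

    def _reference(self):
        ref = portrait(self._grids(True, True), subject="ref")
        return snpsom.detect_spots(ref, quantile=0.85, min_units=3)

    def test_joint_presence_everywhere(self):
        ports = [portrait(self._grids(True, True, i), f"p{i}") for i in range(4)]
        net = snpsom.spot_cooccurrence(
            ports, self._reference(), quantile=0.85, min_units=3
        )
        assert net.edges == [("A", "B", 1.0)]

    def test_disjoint_presence_no_edge(self):
        ports = [portrait(self._grids(True, False, 0), "p0"),
                 portrait(self._grids(True, False, 1), "p1"),
                 portrait(self._grids(False, True, 2), "p2"),
                 portrait(self._grids(False, True, 3), "p3")]
        net = snpsom.spot_cooccurrence(
            ports, self._reference(), quantile=0.85, min_units=3
        )
        assert net.edges == []

    def test_three_of_five_joint_presence_makes_edge(self):
        ports = (
            [portrait(self._grids(True, True, i), f"p{i}") for i in range(3)]
            + [portrait(self._grids(True, False, 3), "p3"),
               portrait(self._grids(False, False, 4), "p4")]
        )
        net = snpsom.spot_cooccurrence(
            ports, self._reference(), quantile=0.85, min_units=3
        )
        assert net.edges == [("A", "B", pytest.approx(0.6))]

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            snpsom.spot_cooccurrence([], self._reference())
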
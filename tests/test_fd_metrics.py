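import itertools

import numpy as np
import pandas as pd
import pytest

from reeffd import (
    Community,
    cwm,
    expand_traits,
    functional_dispersion,
    functional_evenness,
    functional_richness,
    rao_simpson_redundancy,
    rarefaction,
)
from reeffd.distances import DistanceMatrix, TraitSpace

from conftest import make_random_matrix
from oracles import fdis_brute, feve_brute, rao_brute, rarefaction_exact


def space_from_points(points: np.ndarray, labels=None) -> TraitSpace:
    labels = labels or [f"sp{i}" for i in range(len(points))]
    coords = pd.DataFrame(
        points, index=labels, columns=[f"PCoA{i + 1}" for i in range(points.shape[1])]
    )
    lam = np.ones(points.shape[1])
    return TraitSpace(coordinates=coords, eigenvalues=lam,
                      variance_fractions=lam / lam.sum())


def community(**ab) -> Community:
    return Community(site="s", depth_bin=0.0, abundances=ab)


class TestCwm:
    def test_single_species_equals_its_row(self):
        rng = np.random.default_rng(0)
        bm = make_random_matrix(rng, n_species=4)
        sp = bm.species[0]
        out = cwm(community(**{sp: 3.0}), bm)
        assert np.allclose(out.to_numpy(), bm.data.loc[sp].to_numpy())

    def test_sqrt_weighting_hand_case(self):
        # a=4 (carries the category) vs a=1 (does not): sqrt weights 2 and 1
        from reeffd.trait_coding import TraitTable

        table = TraitTable(
            schema={"t": ("yes", "no")},
            assignments={
                "A": {"t": frozenset(["yes"])},
                "B": {"t": frozenset(["no"])},
            },
        )
        bm = expand_traits(table)
        out = cwm(community(A=4.0, B=1.0), bm)
        assert out[("t", "yes")] == pytest.approx(2 / 3)

    def test_universal_category_is_one(self):
        rng = np.random.default_rng(1)
        bm = make_random_matrix(rng, n_species=6)
        bm.data.iloc[:, 0] = 1
        out = cwm(community(**{s: float(i + 1) for i, s in enumerate(bm.species)}), bm)
        assert out.iloc[0] == pytest.approx(1.0)
        assert ((out >= 0) & (out <= 1)).all()

    def test_trait_block_sums_bounded(self):
        rng = np.random.default_rng(2)
        bm = make_random_matrix(rng, n_species=8, trait_sizes=(3, 4))
        out = cwm(community(**{s: 1.0 for s in bm.species}), bm)
        for trait in bm.traits:
            block = out[trait].sum()
            n_cat = len(out[trait])
            assert 1.0 - 1e-9 <= block <= n_cat + 1e-9


class TestFunctionalRichness:
    def test_unit_square_area(self):
        sp = space_from_points(np.array([[0, 0], [1, 0], [1, 1], [0, 1.0]]))
        c = community(sp0=1.0, sp1=1.0, sp2=1.0, sp3=1.0)
        assert functional_richness(sp, c) == pytest.approx(1.0)

    def test_interior_point_does_not_change_hull(self):
        pts = np.array([[0, 0], [1, 0], [1, 1], [0, 1], [0.5, 0.5]])
        sp = space_from_points(pts)
        inner = functional_richness(sp, [f"sp{i}" for i in range(5)])
        outer = functional_richness(sp, [f"sp{i}" for i in range(4)])
        assert inner == pytest.approx(outer)

    def test_degenerate_collinear_is_zero_with_warning(self):
        sp = space_from_points(np.array([[0, 0], [1, 1], [2, 2.0]]))
        with pytest.warns(UserWarning, match="degenerate"):
            assert functional_richness(sp, ["sp0", "sp1", "sp2"]) == 0.0

    def test_monotone_under_species_addition(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(10, 2))
        sp = space_from_points(pts)
        labels = [f"sp{i}" for i in range(10)]
        areas = [functional_richness(sp, labels[: k + 3]) for k in range(8)]
        assert all(a2 >= a1 - 1e-12 for a1, a2 in zip(areas, areas[1:]))


class TestFunctionalEvenness:
    def test_equally_spaced_equal_abundance_is_one(self):
        pts = np.array([[float(i), 0.0] for i in range(5)])
        sp = space_from_points(pts)
        c = community(**{f"sp{i}": 2.0 for i in range(5)})
        assert functional_evenness(sp, c) == pytest.approx(1.0)

    def test_three_point_hand_formula(self):
        # species at 0, 1, 10 on a line, equal abundances
        sp = space_from_points(np.array([[0.0, 0], [1.0, 0], [10.0, 0]]))
        c = community(sp0=1.0, sp1=1.0, sp2=1.0)
        w = 1 / 3
        ew = [1.0 / (2 * w), 9.0 / (2 * w)]
        pew = [e / sum(ew) for e in ew]
        expected = (sum(min(p, 0.5) for p in pew) - 0.5) / (1 - 0.5)
        assert functional_evenness(sp, c) == pytest.approx(expected)
        assert expected == pytest.approx(0.2)

    def test_invariant_to_coordinate_rescaling(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(6, 3))
        ab = {f"sp{i}": float(rng.uniform(0.5, 3)) for i in range(6)}
        f1 = functional_evenness(space_from_points(pts), community(**ab))
        f2 = functional_evenness(space_from_points(pts * 7.3), community(**ab))
        assert f1 == pytest.approx(f2)

    def test_fewer_than_three_species_is_missing(self):
        sp = space_from_points(np.array([[0.0, 0], [1.0, 0]]))
        with pytest.warns(UserWarning):
            assert np.isnan(functional_evenness(sp, community(sp0=1.0, sp1=1.0)))


class TestFunctionalDispersion:
    def test_single_species_zero(self):
        sp = space_from_points(np.array([[2.0, 3.0]]))
        assert functional_dispersion(sp, community(sp0=5.0)) == 0.0

    def test_two_equal_species_half_distance(self):
        sp = space_from_points(np.array([[0.0, 0.0], [3.0, 4.0]]))
        assert functional_dispersion(sp, community(sp0=2.0, sp1=2.0)) == pytest.approx(2.5)

    def test_matches_brute_loop(self):
        rng = np.random.default_rng(6)
        pts = rng.normal(size=(8, 4))
        ab = {f"sp{i}": float(rng.uniform(0.1, 5)) for i in range(8)}
        sp = space_from_points(pts)
        c = community(**ab)
        w = np.sqrt([ab[f"sp{i}"] for i in range(8)])
        assert functional_dispersion(sp, c) == pytest.approx(
            fdis_brute(pts, w / w.sum()), abs=1e-12
        )


class TestRaoSimpsonRedundancy:
    def make_d(self, values, labels):
        return DistanceMatrix(labels=labels, values=np.asarray(values, dtype=float))

    def test_identical_species_redundancy_equals_simpson(self):
        d = self.make_d(np.zeros((3, 3)), ["a", "b", "c"])
        q, simpson, r = rao_simpson_redundancy(d, community(a=1.0, b=2.0, c=3.0))
        assert q == pytest.approx(0.0)
        assert r == pytest.approx(simpson)

    def test_maximally_distinct_species_zero_redundancy(self):
        d = self.make_d(np.ones((3, 3)) - np.eye(3), ["a", "b", "c"])
        q, simpson, r = rao_simpson_redundancy(d, community(a=1.0, b=1.0, c=4.0))
        assert q == pytest.approx(simpson)
        assert r == pytest.approx(0.0, abs=1e-12)

    def test_mixed_case_matches_double_loop(self):
        rng = np.random.default_rng(7)
        v = rng.uniform(0, 1, size=(3, 3))
        v = (v + v.T) / 2
        np.fill_diagonal(v, 0)
        d = self.make_d(v, ["a", "b", "c"])
        ab = {"a": 4.0, "b": 1.0, "c": 2.25}
        q, simpson, r = rao_simpson_redundancy(d, community(**ab))
        w = np.sqrt([4.0, 1.0, 2.25])
        p = w / w.sum()
        qb, sb, rb = rao_brute(v, p)
        assert (q, simpson, r) == pytest.approx((qb, sb, rb), abs=1e-12)

    def test_corrected_distances_rejected(self):
        d = self.make_d(1.5 * (np.ones((3, 3)) - np.eye(3)), ["a", "b", "c"])
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            rao_simpson_redundancy(d, community(a=1.0, b=1.0, c=1.0))

    def test_duplicating_a_zero_distance_species_preserves_rao(self):
        # split species c into two identical halves at distance 0
        v = np.array([[0, 0.4, 0.6], [0.4, 0, 0.2], [0.6, 0.2, 0]])
        d = self.make_d(v, ["a", "b", "c"])
        q1, _, _ = rao_simpson_redundancy(d, community(a=1.0, b=1.0, c=4.0),
                                          sqrt_transform=False)
        v2 = np.array(
            [
                [0, 0.4, 0.6, 0.6],
                [0.4, 0, 0.2, 0.2],
                [0.6, 0.2, 0, 0],
                [0.6, 0.2, 0, 0],
            ]
        )
        d2 = self.make_d(v2, ["a", "b", "c1", "c2"])
        q2, _, _ = rao_simpson_redundancy(
            d2, community(a=1.0, b=1.0, c1=2.0, c2=2.0), sqrt_transform=False
        )
        assert q1 == pytest.approx(q2, abs=1e-12)


class TestRarefaction:
    def test_single_unit_single_point(self):
        curve = rarefaction([{"a", "b", "c"}], seed=1)
        assert len(curve) == 1
        assert curve["mean"].iloc[0] == 3

    def test_identical_units_flat_curve(self):
        curve = rarefaction([{"a", "b"}] * 4, seed=1)
        assert (curve["mean"] == 2).all()
        assert (curve["sd"] == 0).all()

    def test_small_case_matches_exhaustive_enumeration(self):
        sets = [{"a", "b"}, {"b", "c"}, {"c", "d", "e"}, {"a"}]
        curve = rarefaction(sets, n_draws=4000, seed=3)
        for m in (1, 2, 3):
            exact = rarefaction_exact([set(s) for s in sets], m)
            assert curve.loc[curve["size"] == m, "mean"].iloc[0] == pytest.approx(
                exact, abs=0.1
            )
        # full size is exact by construction
        assert curve["mean"].iloc[-1] == 5

    def test_entity_mode_uses_mapping(self):
        sets = [{"a", "b"}, {"c"}]
        curve = rarefaction(sets, unit="entity", entity_of={"a": "E1", "b": "E1", "c": "E2"},
                            seed=0)
        assert curve["mean"].iloc[-1] == 2


def test_metric_order_invariance():
    """FEve/FDis/Rao are invariant to the ordering of community species."""
    rng = np.random.default_rng(12)
    pts = rng.normal(size=(7, 3))
    labels = [f"sp{i}" for i in range(7)]
    sp = space_from_points(pts, labels)
    ab = {l: float(rng.uniform(0.2, 4)) for l in labels}
    v = rng.uniform(0, 1, size=(7, 7))
    v = (v + v.T) / 2
    np.fill_diagonal(v, 0)
    d = DistanceMatrix(labels=labels, values=v)

    c1 = community(**ab)
    c2 = community(**dict(reversed(list(ab.items()))))
    assert functional_evenness(sp, c1) == pytest.approx(functional_evenness(sp, c2))
    assert functional_dispersion(sp, c1) == pytest.approx(functional_dispersion(sp, c2))
    assert rao_simpson_redundancy(d, c1) == pytest.approx(rao_simpson_redundancy(d, c2))
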
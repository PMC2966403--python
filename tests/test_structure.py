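"""AMOVA ΦST, geographic distances, Mantel tests and latitude bands."""

import numpy as np
import pytest

from phylogeocat.seqio import SequenceAlignment
from phylogeocat.structure import (
    AmovaResult,
    DistanceMatrix,
    GroupingError,
    GroupingScheme,
    UndefinedCorrelationError,
    amova,
    assign_latitudinal_class,
    great_circle_matrix,
    haversine_km,
    mantel,
    pairwise_difference_matrix,
    pairwise_phist,
    population_distance_matrix,
)


def _aln(pairs):
    return SequenceAlignment(tuple(pairs))


class TestPairwiseDifferences:
    def test_identical_zero_matrix(self):
        aln = _aln([("a", "ACGT"), ("b", "ACGT")])
        assert pairwise_difference_matrix(aln).values.sum() == 0

    def test_three_site_difference(self):
        aln = _aln([("a", "AAAA"), ("b", "ATTT")])
        assert pairwise_difference_matrix(aln, "strict").values[0, 1] == 3

    def test_matches_per_site_oracle(self):
        rng = np.random.default_rng(11)
        seqs = ["".join(rng.choice(list("ACGT"), size=25)) for _ in range(6)]
        aln = _aln([(f"s{i}", s) for i, s in enumerate(seqs)])
        dm = pairwise_difference_matrix(aln, "strict")
        for i in range(6):
            for j in range(6):
                expect = sum(a != b for a, b in zip(seqs[i], seqs[j]))
                assert dm.values[i, j] == expect


def _two_pop_dist(within=0.0, between=5.0):
    labels = ("a1", "a2", "b1", "b2")
    v = np.full((4, 4), between)
    v[0, 1] = v[1, 0] = within
    v[2, 3] = v[3, 2] = within
    np.fill_diagonal(v, 0.0)
    return DistanceMatrix(labels, v), GroupingScheme(
        "g", {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
    )


class TestAmova:
    def test_fixed_populations_give_phi_one(self):
        dm, g = _two_pop_dist(within=0.0, between=6.0)
        assert amova(dm, g, n_perm=0).phi_st == pytest.approx(1.0)

    def test_identical_compositions_give_phi_near_zero(self):
        aln = _aln(
            [("a1", "AAAA"), ("a2", "TTTT"), ("b1", "AAAA"), ("b2", "TTTT")]
        )
        dm = pairwise_difference_matrix(aln, "strict")
        g = GroupingScheme("g", {"a1": "A", "a2": "A", "b1": "B", "b2": "B"})
        res = amova(dm, g, n_perm=0)
        assert res.phi_st <= 0.0 + 1e-12  # estimator may go negative

    def test_invariant_under_relabelling_and_order(self):
        rng = np.random.default_rng(5)
        n = 10
        v = rng.integers(0, 8, size=(n, n)).astype(float)
        v = np.triu(v, 1)
        v = v + v.T
        labels = tuple(f"s{i}" for i in range(n))
        dm = DistanceMatrix(labels, v)
        assign = {l: ("P" if i < 5 else "Q") for i, l in enumerate(labels)}
        base = amova(dm, GroupingScheme("g", assign), n_perm=0).phi_st
        # relabel populations
        swapped = {l: ("X" if p == "Q" else "Y") for l, p in assign.items()}
        assert amova(dm, GroupingScheme("g", swapped), n_perm=0).phi_st == pytest.approx(base)
        # permute sample order
        perm = rng.permutation(n)
        dm2 = DistanceMatrix(
            tuple(labels[i] for i in perm), v[np.ix_(perm, perm)]
        )
        assert amova(dm2, GroupingScheme("g", assign), n_perm=0).phi_st == pytest.approx(base)

    def test_single_population_guarded(self):
        dm, _ = _two_pop_dist()
        g = GroupingScheme("g", {l: "one" for l in dm.labels})
        with pytest.raises(GroupingError):
            amova(dm, g)

    def test_all_singletons_guarded(self):
        dm, _ = _two_pop_dist()
        g = GroupingScheme("g", {l: l for l in dm.labels})
        with pytest.raises(GroupingError):
            amova(dm, g)

    def test_permutation_p_includes_observed(self):
        dm, g = _two_pop_dist()
        res = amova(dm, g, n_perm=99, seed=0)
        assert res.p >= 1.0 / 100.0

    def test_negative_component_flagged(self):
        aln = _aln(
            [("a1", "AAAA"), ("a2", "TTTT"), ("b1", "AAAA"), ("b2", "TTTT")]
        )
        dm = pairwise_difference_matrix(aln, "strict")
        g = GroupingScheme("g", {"a1": "A", "a2": "A", "b1": "B", "b2": "B"})
        res = amova(dm, g, n_perm=0)
        assert res.negative_component == (res.sigma2_among < 0)


class TestPairwisePhist:
    def test_each_pair_matches_direct_single_pair_call(self):
        rng = np.random.default_rng(21)
        n = 12
        v = rng.integers(0, 9, size=(n, n)).astype(float)
        v = np.triu(v, 1)
        v = v + v.T
        labels = tuple(f"s{i}" for i in range(n))
        dm = DistanceMatrix(labels, v)
        assign = {l: "PQR"[i % 3] for i, l in enumerate(labels)}
        g = GroupingScheme("g", assign)
        table = pairwise_phist(dm, g, n_perm=0)
        for pair, res in table.items():
            pa, pb = sorted(pair)
            keep = [l for l in labels if assign[l] in (pa, pb)]
            sub = dm.submatrix(keep)
            direct = amova(
                sub,
                GroupingScheme("d", {l: assign[l] for l in keep}),
                n_perm=0,
            )
            assert res.phi_st == pytest.approx(direct.phi_st)
        assert len(table) == 3  # no self-pairs


class TestGeography:
    def test_identical_points(self):
        assert haversine_km(12.0, 77.0, 12.0, 77.0) == 0.0

    def test_one_degree_longitude_at_equator(self):
        assert haversine_km(0, 0, 0, 1) == pytest.approx(6371.0 * np.pi / 180.0, rel=1e-9)

    def test_antipodal_points(self):
        assert haversine_km(0, 0, 0, 180) == pytest.approx(np.pi * 6371.0, rel=1e-9)

    def test_population_matrix_is_mean_of_cross_pairs(self):
        coords = {"a1": (0.0, 0.0), "a2": (0.0, 2.0), "b1": (0.0, 10.0)}
        g = GroupingScheme("g", {"a1": "A", "a2": "A", "b1": "B"})
        dm = population_distance_matrix(coords, g)
        expect = (haversine_km(0, 0, 0, 10) + haversine_km(0, 2, 0, 10)) / 2
        assert dm.values[dm.labels.index("A"), dm.labels.index("B")] == pytest.approx(expect)

    def test_population_losing_all_members_is_error(self):
        coords = {"a1": (0.0, 0.0), "b1": None}
        g = GroupingScheme("g", {"a1": "A", "b1": "B"})
        with pytest.warns(UserWarning):
            with pytest.raises(GroupingError):
                population_distance_matrix(coords, g)


class TestMantel:
    def _matrix(self, rng, n=4):
        v = rng.uniform(1, 10, size=(n, n))
        v = np.triu(v, 1)
        v = v + v.T
        np.fill_diagonal(v, 0.0)
        return DistanceMatrix(tuple(f"p{i}" for i in range(n)), v)

    def test_self_correlation_is_one(self):
        dm = self._matrix(np.random.default_rng(2))
        res = mantel(dm, dm)
        assert res.r == pytest.approx(1.0)

    def test_small_instance_uses_exact_enumeration(self):
        rng = np.random.default_rng(3)
        a, b = self._matrix(rng), self._matrix(rng)
        res = mantel(a, b)
        assert res.exact and res.n_perm == 24

    def test_permutation_routine_agrees_with_enumeration(self):
        """Monte-Carlo p on a 4-pop instance converges to the exact
        enumeration value."""
        from itertools import permutations

        rng = np.random.default_rng(4)
        a, b = self._matrix(rng), self._matrix(rng)
        exact = mantel(a, b).p

        # independent brute-force enumeration oracle
        def tri(m):
            return m[np.tril_indices(4, -1)]

        x = tri(a.values)
        r_obs = np.corrcoef(x, tri(b.values))[0, 1]
        rs = [
            np.corrcoef(x, tri(b.values[np.ix_(p, p)]))[0, 1]
            for p in permutations(range(4))
        ]
        oracle = np.mean([r >= r_obs - 1e-12 for r in rs])
        assert exact == pytest.approx(oracle)

    def test_agrees_with_skbio(self):
        import skbio

        rng = np.random.default_rng(8)
        a, b = self._matrix(rng, n=7), self._matrix(rng, n=7)
        ours = mantel(a, b, n_perm=2000, seed=1)
        r_skbio, _, _ = skbio.stats.distance.mantel(
            skbio.DistanceMatrix(a.values, a.labels),
            skbio.DistanceMatrix(b.values, b.labels),
            permutations=0,
        )
        assert ours.r == pytest.approx(r_skbio, rel=1e-9)

    def test_constant_matrix_rejected(self):
        v = np.ones((4, 4)) - np.eye(4)
        dm = DistanceMatrix(("a", "b", "c", "d"), v)
        with pytest.raises(UndefinedCorrelationError):
            mantel(dm, dm)


class TestLatitudinalBands:
    @pytest.mark.parametrize(
        "lat,band",
        [
            (15.0, "10N-19.9N"),
            (19.95, "10N-19.9N"),  # gap closes downward
            (20.0, "20N-28.9N"),
            (28.95, "20N-28.9N"),
            (29.0, "29N-35N"),
            (35.0, "29N-35N"),
        ],
    )
    def test_band_assignment(self, lat, band):
        assert assign_latitudinal_class(lat) == band

    def test_out_of_range_warns(self):
        with pytest.warns(UserWarning):
            assert assign_latitudinal_class(5.0) == "unclassified"


def test_phist_decreases_with_migration():
    """Two-island ΦST falls monotonically as scaled migration rises."""
    from phylogeocat.synthetic_data import DemographyModel, simulate_alignment

    medians = []
    for M in (0.1, 1.0, 10.0):
        phis = []
        for s in range(10):
            model = DemographyModel(
                kind="two_island", theta=5.0, M=M, T=5.0, samples=(12, 12)
            )
            sim = simulate_alignment(model, L=601, seed=3000 + 17 * s)
            dm = pairwise_difference_matrix(sim.alignment, "strict")
            g = GroupingScheme("deme", sim.populations)
            phis.append(amova(dm, g, n_perm=0).phi_st)
        medians.append(float(np.median(phis)))
    assert medians[0] > medians[1] > medians[2]
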
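"""BIOCLIM envelopes, raster I/O, pseudo-absences and AUC evaluation."""

import numpy as np
import pandas as pd
import pytest

from phylogeocat.niche import (
    ClimateStack,
    EnvelopeModel,
    Grid,
    PointError,
    PresenceRecords,
    SamplingError,
    auc_mann_whitney,
    correlation_filter,
    evaluate_auc,
    extract_values,
    fit_envelope,
    pseudo_absences,
    read_ascii_grid,
    replicate_protocol,
    score_points,
    suitability,
    threshold_map,
    write_ascii_grid,
)


class TestAsciiGrid:
    def test_round_trip(self, tmp_path):
        rng = np.random.default_rng(1)
        vals = rng.normal(size=(6, 8)).round(4)
        vals[0, 0] = np.nan
        g = Grid(values=vals, xll=70.0, yll=8.0, cellsize=0.25)
        p = tmp_path / "layer.asc"
        write_ascii_grid(g, p)
        back = read_ascii_grid(p)
        np.testing.assert_allclose(back.values, vals, rtol=1e-6)
        assert (back.xll, back.yll, back.cellsize) == (70.0, 8.0, 0.25)

    def test_cell_center_round_trips(self):
        g = Grid(values=np.zeros((10, 10)), xll=70.0, yll=8.0, cellsize=0.5)
        lat, lon = g.center_of(3, 7)
        assert g.cell_of(lat, lon) == (3, 7)


class TestExtraction:
    def test_cell_center_value_exact(self, gradient_stack):
        ref = gradient_stack.reference
        lat, lon = ref.center_of(4, 9)
        table = extract_values(gradient_stack, PresenceRecords(points=((lat, lon),)))
        assert table["bio5"][0] == pytest.approx(20.0 + 0.5 * 4)
        assert table["bio13"][0] == pytest.approx(100.0 + 2.0 * 9)

    def test_outside_extent_rejected(self, gradient_stack):
        with pytest.raises(PointError):
            extract_values(gradient_stack, PresenceRecords(points=((55.0, 0.0),)))

    def test_nodata_cell_rejected(self):
        vals = np.ones((4, 4))
        vals[2, 2] = np.nan
        g = Grid(values=vals, xll=0.0, yll=0.0, cellsize=1.0)
        stack = ClimateStack(layers={"x": g})
        lat, lon = g.center_of(2, 2)
        with pytest.raises(PointError):
            extract_values(stack, PresenceRecords(points=((lat, lon),)))

    def test_analytic_gradient_raster(self, gradient_stack):
        ref = gradient_stack.reference
        pts, expect5 = [], []
        for r, c in [(0, 0), (5, 5), (19, 3)]:
            pts.append(ref.center_of(r, c))
            expect5.append(20.0 + 0.5 * r)
        table = extract_values(gradient_stack, PresenceRecords(points=tuple(pts)))
        np.testing.assert_allclose(table["bio5"], expect5)


class TestCorrelationFilter:
    def test_identical_columns_one_removed(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=100)
        df = pd.DataFrame({"a": x, "b": x, "c": rng.normal(size=100)})
        assert correlation_filter(df) == ["a", "c"]

    def test_independent_columns_all_kept(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame({f"v{i}": rng.normal(size=400) for i in range(5)})
        assert correlation_filter(df) == [f"v{i}" for i in range(5)]

    def test_constructed_correlation_pair(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=300)
        y = 0.9 * x + np.sqrt(1 - 0.81) * rng.normal(size=300)  # r ~ 0.9
        z = rng.normal(size=300)
        df = pd.DataFrame({"x": x, "y": y, "z": z})
        kept = correlation_filter(df, r_max=0.7)
        assert kept == ["x", "z"]

    def test_priority_order_wins(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=200)
        df = pd.DataFrame({"low": x, "high": x + 1e-9 * rng.normal(size=200)})
        kept = correlation_filter(df, priority=["high", "low"])
        assert kept == ["high"]

    def test_constant_column_warned_and_dropped(self):
        rng = np.random.default_rng(6)
        df = pd.DataFrame({"c": np.ones(50), "a": rng.normal(size=50),
                           "b": rng.normal(size=50)})
        with pytest.warns(UserWarning):
            kept = correlation_filter(df)
        assert "c" not in kept


class TestEnvelope:
    def test_tail_zero_is_min_max(self):
        df = pd.DataFrame({"v": [3.0, 1.0, 9.0, 4.0, 6.0]})
        m = fit_envelope(df, tail=0.0)
        assert m.envelopes["v"] == (1.0, 9.0)

    def test_stated_quantile_rule_on_1_to_100(self):
        df = pd.DataFrame({"v": np.arange(1.0, 101.0)})
        m = fit_envelope(df, tail=0.025)
        lo, hi = m.envelopes["v"]
        assert lo == pytest.approx(3.475)
        assert hi == pytest.approx(97.525)

    def test_constant_variable_degenerate(self):
        df = pd.DataFrame({"v": np.full(10, 7.0)})
        m = fit_envelope(df)
        assert m.envelopes["v"] == (7.0, 7.0)

    def test_too_few_presences(self):
        with pytest.raises(ValueError):
            fit_envelope(pd.DataFrame({"v": [1.0, 2.0]}))

    def test_json_round_trip(self, tmp_path):
        df = pd.DataFrame({"v": np.arange(1.0, 21.0)})
        m = fit_envelope(df, tail=0.05)
        p = tmp_path / "model.json"
        m.to_json(p)
        back = EnvelopeModel.from_json(p)
        assert back.envelopes == m.envelopes
        np.testing.assert_allclose(back.training["v"], m.training["v"])


class TestSuitability:
    def _uniform_model(self):
        df = pd.DataFrame({"bio5": np.linspace(0.0, 100.0, 101)})
        return fit_envelope(df, tail=0.0)

    def test_median_cell_scores_one(self):
        m = self._uniform_model()
        vals = np.full((3, 3), 50.0)
        stack = ClimateStack(
            layers={"bio5": Grid(values=vals, xll=0, yll=0, cellsize=1.0)}
        )
        suit, member = suitability(m, stack)
        assert suit.values[1, 1] == pytest.approx(1.0, abs=0.02)
        assert member.values[1, 1] == 1.0

    def test_outside_any_envelope_scores_zero(self):
        m = self._uniform_model()
        vals = np.full((2, 2), 200.0)
        stack = ClimateStack(
            layers={"bio5": Grid(values=vals, xll=0, yll=0, cellsize=1.0)}
        )
        suit, member = suitability(m, stack)
        assert (suit.values == 0.0).all()
        assert (member.values == 0.0).all()

    def test_tent_closed_form_on_uniform_training(self):
        m = self._uniform_model()
        xs = np.array([[10.0, 25.0, 50.0, 75.0, 90.0]])
        stack = ClimateStack(
            layers={"bio5": Grid(values=xs, xll=0, yll=0, cellsize=1.0)}
        )
        suit, _ = suitability(m, stack)
        # percentile of x on uniform(0,100) is ~x/100
        expect = 1.0 - 2.0 * np.abs(xs / 100.0 - 0.5)
        np.testing.assert_allclose(suit.values, expect, atol=0.03)

    def test_training_presences_score_positive_at_tail_zero(self, gradient_stack):
        ref = gradient_stack.reference
        rng = np.random.default_rng(8)
        pts = tuple(
            ref.center_of(int(r), int(c))
            for r, c in zip(rng.integers(0, 20, 25), rng.integers(0, 20, 25))
        )
        pts = tuple(dict.fromkeys(pts))
        pres = PresenceRecords(points=pts)
        m = fit_envelope(extract_values(gradient_stack, pres), tail=0.0)
        assert (score_points(m, gradient_stack, pres) > 0).all()

    def test_missing_variable_key_error(self, gradient_stack):
        df = pd.DataFrame({"bio99": np.arange(10.0)})
        m = fit_envelope(df)
        with pytest.raises(KeyError):
            suitability(m, gradient_stack)


class TestPseudoAbsences:
    def test_deterministic_for_seed(self, gradient_stack):
        a = pseudo_absences(gradient_stack, 30, seed=4)
        b = pseudo_absences(gradient_stack, 30, seed=4)
        assert a.points == b.points

    def test_exhaustive_draw_covers_valid_cells(self, gradient_stack):
        n = int(gradient_stack.valid_mask().sum())
        pts = pseudo_absences(gradient_stack, n, seed=1)
        assert len(set(pts.points)) == n

    def test_oversampling_rejected(self, gradient_stack):
        n = int(gradient_stack.valid_mask().sum())
        with pytest.raises(SamplingError):
            pseudo_absences(gradient_stack, n + 1)

    def test_spatially_uniform(self, gradient_stack):
        """Chi-square on grid quadrants over many draws."""
        from scipy.stats import chisquare

        counts = np.zeros(4)
        for seed in range(40):
            pts = pseudo_absences(gradient_stack, 100, seed=seed)
            ref = gradient_stack.reference
            for lat, lon in pts.points:
                r, c = ref.cell_of(lat, lon)
                counts[(r >= 10) * 2 + (c >= 10)] += 1
        _, p = chisquare(counts)
        assert p > 1e-3


class TestAuc:
    def test_perfect_separation(self):
        assert auc_mann_whitney([0.9, 0.8], [0.1, 0.2, 0.3]) == 1.0

    def test_identical_distributions(self):
        assert auc_mann_whitney([0.5, 0.5], [0.5, 0.5]) == 0.5

    def test_matches_pair_counting_oracle(self):
        rng = np.random.default_rng(9)
        pos = rng.uniform(size=12)
        neg = rng.uniform(size=15)
        pairs = sum(
            1.0 if p > n else (0.5 if p == n else 0.0) for p in pos for n in neg
        )
        assert auc_mann_whitney(pos, neg) == pytest.approx(pairs / (12 * 15))

    def test_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(10)
        pos = rng.normal(1.0, 1.0, size=40)
        neg = rng.normal(0.0, 1.0, size=60)
        y = np.concatenate([np.ones(40), np.zeros(60)])
        s = np.concatenate([pos, neg])
        assert auc_mann_whitney(pos, neg) == pytest.approx(roc_auc_score(y, s))

    def test_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(12)
        pos = rng.uniform(size=20)
        neg = rng.uniform(size=20)
        base = auc_mann_whitney(pos, neg)
        assert auc_mann_whitney(np.exp(3 * pos), np.exp(3 * neg)) == pytest.approx(base)


class TestReplicateProtocol:
    def _tight_presences(self, stack, n=40):
        """Presences confined to a narrow bio5 band (rows 8..11)."""
        ref = stack.reference
        pts = []
        for r in range(8, 12):
            for c in range(20):
                pts.append(ref.center_of(r, c))
        rng = np.random.default_rng(3)
        idx = rng.choice(len(pts), size=n, replace=False)
        return PresenceRecords(points=tuple(pts[i] for i in idx))

    def test_separable_presences_beat_chance(self, gradient_stack):
        pres = self._tight_presences(gradient_stack)
        reps = replicate_protocol(pres, gradient_stack, n_reps=6, seed=5)
        aucs = [r.auc for r in reps]
        assert np.mean(aucs) > 0.7

    def test_background_presences_are_chance(self, gradient_stack):
        pres = pseudo_absences(gradient_stack, 60, seed=77)
        reps = replicate_protocol(pres, gradient_stack, n_reps=6, seed=6)
        assert abs(np.mean([r.auc for r in reps]) - 0.5) < 0.12

    def test_fixed_seed_bit_identical(self, gradient_stack):
        pres = self._tight_presences(gradient_stack)
        a = replicate_protocol(pres, gradient_stack, n_reps=4, seed=9)
        b = replicate_protocol(pres, gradient_stack, n_reps=4, seed=9)
        assert a == b


class TestThresholdMap:
    def test_constructed_presences_never_exceed(self, gradient_stack):
        from phylogeocat.synthetic_data import sample_presences

        pres = sample_presences(
            gradient_stack, lambda v: v["bio5"] < 27.0, n=50, seed=2, jitter=False
        )
        rep = threshold_map(gradient_stack, "bio5", pres, threshold=27.0)
        assert rep.n_exceeding == 0
        assert rep.max < 27.0

    def test_constant_raster_zero_width_ci(self):
        vals = np.full((5, 5), 12.5)
        stack = ClimateStack(layers={"x": Grid(values=vals, xll=0, yll=0, cellsize=1.0)})
        pts = tuple(stack.reference.center_of(r, c) for r, c in [(1, 1), (2, 2), (3, 3)])
        rep = threshold_map(stack, "x", PresenceRecords(points=pts), threshold=20.0)
        assert rep.ci95 == (12.5, 12.5)

    def test_t_interval_closed_form(self, gradient_stack):
        from scipy.stats import t as t_dist

        ref = gradient_stack.reference
        pts = tuple(ref.center_of(r, 0) for r in range(10))
        rep = threshold_map(gradient_stack, "bio5", PresenceRecords(points=pts), 99.0)
        vals = 20.0 + 0.5 * np.arange(10)
        half = t_dist.ppf(0.975, 9) * vals.std(ddof=1) / np.sqrt(10)
        assert rep.mean == pytest.approx(vals.mean())
        assert rep.ci95[1] - rep.mean == pytest.approx(half)


def test_envelope_recovers_simulated_occupancy_threshold():
    """Hard bio5 < T occupancy yields an upper envelope within one
    quantile step of T."""
    from phylogeocat.synthetic_data import (
        GradientSpec,
        sample_presences,
        simulate_climate_stack,
    )

    T = 30.0
    stack = simulate_climate_stack(
        (50, 50), [GradientSpec("bio5", base=15.0, row_slope=0.5, noise_sd=0.3)],
        seed=21,
    )
    pres = sample_presences(stack, lambda v: v["bio5"] < T, n=140, seed=22, jitter=False)
    table = extract_values(stack, pres)
    model = fit_envelope(table, tail=0.0)
    hi = model.envelopes["bio5"][1]
    vals = np.sort(np.asarray(table["bio5"]))
    step = float(np.max(np.diff(vals)))
    assert hi <= T
    assert T - hi <= max(step, 1.0)
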
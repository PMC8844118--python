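import numpy as np
import pandas as pd
import pytest

from climatch.grids import GridSpec
from climatch.synthetic_climate import (
    GeneratorConfig,
    aggregate_resolution,
    consensus_variable_selection,
    generate_climate_pair,
    local_focal_r,
    pairwise_between_version_r,
    resample_bilinear,
    rescale_temperature_units,
    vif_stepwise,
    VifReport,
)

from conftest import make_grid, make_stack


def tiny_config(**kw):
    defaults = dict(
        n_rows=24, n_cols=24, cell_size=10.0, origin_y=240.0,
        variable_names=("v1", "v2"), spatial_correlation_length=30.0,
        latitudinal_gradient_strength=1.0, between_version_decorrelation=0.0,
        seed=0,
    )
    defaults.update(kw)
    return GeneratorConfig(**defaults)


class TestGeneratePair:
    def test_zero_decorrelation_gives_identical_versions(self):
        pair = generate_climate_pair(tiny_config(between_version_decorrelation=0.0))
        for name in pair.current_a.variables:
            assert np.array_equal(pair.current_a[name].values, pair.current_b[name].values)

    def test_zero_shift_future_equals_current(self):
        cfg = tiny_config(scenarios=("scen45",), scenario_shift={"scen45": 0.0},
                          gcms=("g1",), gcm_perturbation_sd=0.0)
        pair = generate_climate_pair(cfg)
        fut = pair.futures[("A", "scen45", "g1", "2070")]
        for name in fut.variables:
            assert np.allclose(fut[name].values, pair.current_a[name].values)

    def test_same_seed_bit_identical(self):
        a1 = generate_climate_pair(tiny_config(seed=42))
        a2 = generate_climate_pair(tiny_config(seed=42))
        for name in a1.current_a.variables:
            assert np.array_equal(a1.current_b[name].values, a2.current_b[name].values)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            tiny_config(n_rows=1)
        with pytest.raises(ValueError):
            tiny_config(between_version_decorrelation=1.5)

    def test_decorrelation_lowers_pairwise_r(self):
        """Monte-Carlo over replicate seeds: a variable at d = 0.5 correlates
        less between versions than one at d = 0.1."""
        mean_r = {0.1: [], 0.5: []}
        for seed in range(10):
            cfg = tiny_config(
                variable_names=("lo", "hi"),
                between_version_decorrelation={"lo": 0.1, "hi": 0.5},
                latitudinal_gradient_strength=0.0,
                seed=seed,
            )
            pair = generate_climate_pair(cfg)
            diag = pairwise_between_version_r(pair.current_a, pair.current_b,
                                              n_points=64, n_sets=3, seed=seed)
            mean_r[0.1].append(diag.pairwise_r["lo"].mean())
            mean_r[0.5].append(diag.pairwise_r["hi"].mean())
        assert np.mean(mean_r[0.5]) < np.mean(mean_r[0.1])

    def test_monotone_decorrelation_profile(self):
        """Mean between-version r is non-increasing in d over 5 levels x 10 seeds."""
        levels = [0.0, 0.25, 0.5, 0.75, 1.0]
        means = []
        for d in levels:
            rs = []
            for seed in range(10):
                cfg = tiny_config(between_version_decorrelation=d,
                                  latitudinal_gradient_strength=0.0, seed=seed)
                pair = generate_climate_pair(cfg)
                diag = pairwise_between_version_r(pair.current_a, pair.current_b,
                                                  n_points=64, n_sets=2, seed=seed)
                rs.append(diag.pairwise_r.to_numpy().mean())
            means.append(np.mean(rs))
        assert all(means[i] >= means[i + 1] - 0.02 for i in range(len(means) - 1))
        assert means[0] > means[-1]


class TestAggregate:
    def test_constant_grid_stays_constant(self):
        stack = make_stack({"a": np.full((6, 6), 3.25)})
        agg = aggregate_resolution(stack, 3)
        assert np.allclose(agg["a"].values, 3.25)
        assert agg.spec.cell_size == 3.0

    def test_two_by_two_block_mean(self):
        stack = make_stack({"a": [[1.0, 3.0], [5.0, 7.0]]})
        agg = aggregate_resolution(stack, 2)
        assert agg["a"].values.shape == (1, 1)
        assert agg["a"].values[0, 0] == 4.0

    def test_global_mean_preserved_when_divisible(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(size=(8, 12))
        stack = make_stack({"a": vals})
        agg = aggregate_resolution(stack, 4)
        assert np.isclose(agg["a"].values.mean(), vals.mean())

    def test_masked_cells_excluded(self):
        mask = np.zeros((2, 2), dtype=bool)
        mask[0, 0] = True
        grid = make_grid([[99.0, 3.0], [5.0, 7.0]], mask=mask, name="a")
        from climatch.grids import ClimateStack

        agg = aggregate_resolution(ClimateStack({"a": grid}), 2)
        assert agg["a"].values[0, 0] == pytest.approx(5.0)

    def test_factor_below_two_rejected(self):
        with pytest.raises(ValueError):
            aggregate_resolution(make_stack({"a": np.ones((4, 4))}), 1)


class TestResampleBilinear:
    def test_constant_source_constant_target(self):
        stack = make_stack({"a": np.full((4, 4), 2.5)}, cell_size=10.0)
        target = GridSpec(n_rows=7, n_cols=7, origin_x=0.0, origin_y=40.0, cell_size=40 / 7)
        out = resample_bilinear(stack, target)
        assert np.allclose(out["a"].values, 2.5)

    def test_identity_when_specs_match(self):
        vals = np.arange(16, dtype=float).reshape(4, 4)
        stack = make_stack({"a": vals}, cell_size=5.0)
        out = resample_bilinear(stack, stack.spec)
        assert np.allclose(out["a"].values, vals)

    def test_midpoint_of_four_centers(self):
        # 2x2 source: top row 0s, bottom row 10s; the midway point gets 5.
        stack = make_stack({"a": [[0.0, 0.0], [10.0, 10.0]]}, cell_size=2.0)
        target = GridSpec(n_rows=1, n_cols=1, origin_x=1.0, origin_y=3.0, cell_size=2.0)
        out = resample_bilinear(stack, target)
        assert out["a"].values[0, 0] == pytest.approx(5.0)

    def test_disjoint_extents_rejected(self):
        stack = make_stack({"a": np.ones((4, 4))}, cell_size=1.0)
        far = GridSpec(n_rows=2, n_cols=2, origin_x=100.0, origin_y=104.0, cell_size=1.0)
        with pytest.raises(ValueError, match="disjoint"):
            resample_bilinear(stack, far)


class TestRescaleUnits:
    def test_divide_by_ten(self):
        stack = make_stack({"t": np.full((2, 2), 215.0), "p": np.full((2, 2), 30.0)})
        out = rescale_temperature_units(stack, {"t"}, divisor=10)
        assert np.allclose(out["t"].values, 21.5)
        assert np.allclose(out["p"].values, 30.0)

    def test_divisor_one_is_identity_and_op_is_stateless(self):
        stack = make_stack({"t": np.full((2, 2), 215.0)})
        assert np.allclose(rescale_temperature_units(stack, {"t"}, 1)["t"].values, 215.0)
        twice = rescale_temperature_units(rescale_temperature_units(stack, {"t"}), {"t"})
        assert np.allclose(twice["t"].values, 2.15)

    def test_unknown_variable_rejected(self):
        stack = make_stack({"t": np.ones((2, 2))})
        with pytest.raises(KeyError):
            rescale_temperature_units(stack, {"nope"})


class TestVifStepwise:
    def test_orthogonal_variables_all_vif_one(self):
        rng = np.random.default_rng(0)
        raw = rng.normal(size=(50, 4))
        q, _ = np.linalg.qr(raw - raw.mean(axis=0))  # centered, hence exactly orthogonal after standardization
        df = pd.DataFrame(q, columns=list("abcd"))
        rep = vif_stepwise(df)
        assert set(rep.retained) == set("abcd")
        assert all(v == pytest.approx(1.0, abs=1e-9) for v in rep.vif.values())

    def test_closed_form_for_correlation_point_nine(self):
        # construct two columns with sample correlation exactly 0.9
        rng = np.random.default_rng(1)
        raw = rng.normal(size=(100, 2))
        q, _ = np.linalg.qr(raw - raw.mean(axis=0))
        z1, z2 = q[:, 0], q[:, 1]
        df = pd.DataFrame({"a": z1, "b": 0.9 * z1 + np.sqrt(1 - 0.81) * z2})
        rep = vif_stepwise(df, threshold=10)
        expected = 1.0 / (1.0 - 0.81)
        assert set(rep.retained) == {"a", "b"}
        for v in rep.vif.values():
            assert v == pytest.approx(expected, rel=1e-9)

    def test_exact_collinearity_removed(self):
        rng = np.random.default_rng(2)
        x1 = rng.normal(size=60)
        x2 = rng.normal(size=60)
        df = pd.DataFrame({"x1": x1, "x2": x2, "x3": x1 + x2})
        rep = vif_stepwise(df)
        assert len(rep.dropped) == 1
        assert all(np.isfinite(v) and v <= 10 for v in rep.vif.values())

    def test_constant_column_rejected(self):
        df = pd.DataFrame({"a": np.arange(10.0), "b": np.ones(10)})
        with pytest.raises(ValueError, match="constant"):
            vif_stepwise(df)

    def test_cross_check_against_statsmodels(self):
        from statsmodels.stats.outliers_influence import variance_inflation_factor

        rng = np.random.default_rng(3)
        X = rng.normal(size=(80, 4))
        X[:, 3] = 0.7 * X[:, 0] + 0.5 * rng.normal(size=80)
        df = pd.DataFrame(X, columns=list("abcd"))
        rep = vif_stepwise(df, threshold=1e9)  # no removals: compare raw VIFs
        std = (df - df.mean()) / df.std(ddof=1)
        for j, c in enumerate("abcd"):
            ref = variance_inflation_factor(std.to_numpy(), j)
            assert rep.vif[c] == pytest.approx(ref, rel=1e-6)


class TestConsensus:
    def _reports(self, counts: dict[str, int], n: int):
        reports = {}
        for i in range(n):
            retained = tuple(v for v, c in counts.items() if i < c)
            reports[i] = VifReport(vif={}, retained=retained, dropped=(), threshold=10)
        return reports

    def test_strict_majority_rule(self):
        reports = self._reports({"always": 6, "half": 3, "four": 4}, 6)
        kept = consensus_variable_selection(reports)
        assert kept == {"always", "four"}

    def test_empty_reports_rejected(self):
        with pytest.raises(ValueError):
            consensus_variable_selection({})


class TestPairwiseR:
    def test_identical_stacks_r_one(self, small_pair):
        a = small_pair.current_a
        diag = pairwise_between_version_r(a, a, n_points=49, n_sets=3, seed=0)
        assert np.allclose(diag.pairwise_r.to_numpy(), 1.0)

    def test_sign_flip_r_minus_one(self, small_pair):
        a = small_pair.current_a
        neg = a.map_values(lambda v: -v)
        diag = pairwise_between_version_r(a, neg, n_points=49, n_sets=3, seed=0)
        assert np.allclose(diag.pairwise_r.to_numpy(), -1.0)

    def test_white_noise_attenuation(self):
        """B = A + noise with sd(noise) = sd(A) attenuates r toward 1/sqrt(2)."""
        rng = np.random.default_rng(5)
        vals = rng.normal(size=(40, 40))
        rs = []
        for seed in range(20):
            noise = np.random.default_rng(100 + seed).normal(size=(40, 40)) * vals.std()
            a = make_stack({"v": vals})
            b = make_stack({"v": vals + noise})
            diag = pairwise_between_version_r(a, b, n_points=100, n_sets=2, seed=seed)
            rs.append(diag.pairwise_r["v"].mean())
        assert np.mean(rs) == pytest.approx(1 / np.sqrt(2), abs=0.04)


class TestLocalFocalR:
    def test_identical_grids_r_one(self, small_pair):
        g = small_pair.current_a["bio1"]
        out = local_focal_r(g, g, window=5)
        keep = ~out.spec.mask
        assert np.allclose(out.values[keep], 1.0)

    def test_constant_grid_fully_masked(self):
        g = make_grid(np.random.default_rng(0).normal(size=(6, 6)))
        const = g.with_values(np.full((6, 6), 1.0))
        out = local_focal_r(g, const)
        assert out.spec.mask.all()

    def test_even_window_rejected(self):
        g = make_grid(np.zeros((6, 6)))
        with pytest.raises(ValueError):
            local_focal_r(g, g, window=4)

    def test_matches_direct_pearson_oracle_everywhere(self):
        """Oracle equivalence on a 10x10 instance: every cell equals the
        direct Pearson formula on its (truncated) neighborhood pairs."""
        rng = np.random.default_rng(8)
        a = rng.normal(size=(10, 10))
        b = 0.5 * a + rng.normal(size=(10, 10))
        ga, gb = make_grid(a), make_grid(b)
        out = local_focal_r(ga, gb, window=5)
        h = 2
        for i in range(10):
            for j in range(10):
                sl = np.s_[max(0, i - h) : i + h + 1, max(0, j - h) : j + h + 1]
                wa, wb = a[sl].ravel(), b[sl].ravel()
                expected = np.corrcoef(wa, wb)[0, 1]
                assert out.values[i, j] == pytest.approx(expected, abs=1e-9)
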
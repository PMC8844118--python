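import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from climatch.presets import SPECIES_PRESETS, default_generator_config
from climatch.synthetic_climate import generate_climate_pair
from climatch.virtual_species import (
    ConversionParams,
    PcaNiche,
    ResponseFunction,
    eval_response,
    occurrence_probability,
    realize_presence_absence,
    sample_presabs,
    samples_from_csv,
    samples_to_csv,
    suitability_from_pca_niche,
    suitability_from_responses,
)

from conftest import make_grid, make_stack


class TestResponses:
    def test_sigmoid_inflection_is_half(self):
        fn = ResponseFunction("increasing_sigmoid", "v", x0=5.0, s=1.0)
        assert eval_response(fn, 5.0) == pytest.approx(0.5)

    def test_bell_mode_is_one(self):
        fn = ResponseFunction("gaussian_bell", "v", x0=2.5, s=6.0)
        assert eval_response(fn, 2.5) == pytest.approx(1.0)

    def test_sigmoid_closed_form(self):
        fn = ResponseFunction("increasing_sigmoid", "v", x0=5.0, s=1.0)
        assert eval_response(fn, 7.0) == pytest.approx(1 / (1 + np.exp(-2)), rel=1e-6)

    def test_decreasing_complements_increasing(self):
        inc = ResponseFunction("increasing_sigmoid", "v", x0=0.0, s=2.0)
        dec = ResponseFunction("decreasing_sigmoid", "v", x0=0.0, s=2.0)
        x = np.linspace(-5, 5, 11)
        assert np.allclose(eval_response(inc, x) + eval_response(dec, x), 1.0)

    def test_nonpositive_scale_rejected(self):
        with pytest.raises(ValueError):
            ResponseFunction("increasing_sigmoid", "v", x0=0.0, s=0.0)

    @settings(max_examples=50, deadline=None)
    @given(st.floats(-1e3, 1e3), st.floats(-50, 50), st.floats(0.01, 50))
    def test_bounded_unit_interval(self, x, x0, s):
        for kind in ("increasing_sigmoid", "decreasing_sigmoid", "gaussian_bell",
                     "threshold_logistic"):
            val = eval_response(ResponseFunction(kind, "v", x0=x0, s=s), x)
            assert 0.0 <= val <= 1.0


class TestSuitabilityFromResponses:
    def test_constant_product_flagged(self):
        stack = make_stack({"v": np.zeros((3, 3))})
        # sigmoid of a constant field is constant: rescale undefined
        fn = ResponseFunction("increasing_sigmoid", "v", x0=0.0, s=1.0)
        with pytest.raises(ValueError, match="constant"):
            suitability_from_responses(stack, [fn])

    def test_product_annihilator_maps_to_zero(self):
        vals = np.array([[0.0, 5.0], [10.0, 20.0]])
        stack = make_stack({"v": vals})
        fn = ResponseFunction("gaussian_bell", "v", x0=20.0, s=3.0)
        hs = suitability_from_responses(stack, [fn])
        assert hs.values[0, 0] == pytest.approx(0.0, abs=1e-12)
        assert hs.values[1, 1] == pytest.approx(1.0)

    def test_matches_manual_product_and_rescale(self):
        vals_a = np.array([[0.0, 2.0], [4.0, 6.0]])
        vals_b = np.array([[100.0, 90.0], [80.0, 120.0]])
        stack = make_stack({"a": vals_a, "b": vals_b})
        f1 = ResponseFunction("increasing_sigmoid", "a", x0=3.0, s=1.5)
        f2 = ResponseFunction("threshold_logistic", "b", x0=100.0, s=5.0)
        prod = eval_response(f1, vals_a) * eval_response(f2, vals_b)
        expected = (prod - prod.min()) / (prod.max() - prod.min())
        hs = suitability_from_responses(stack, [f1, f2])
        assert np.allclose(hs.values, expected)

    def test_missing_variable_rejected(self):
        stack = make_stack({"a": np.zeros((2, 2))})
        fn = ResponseFunction("increasing_sigmoid", "zzz", x0=0.0, s=1.0)
        with pytest.raises(KeyError):
            suitability_from_responses(stack, [fn])


class TestPcaNiche:
    def test_broader_niche_covers_more_cells(self, small_pair):
        stack = small_pair.current_a
        broad = suitability_from_pca_niche(
            stack, PcaNiche(niche_center=(0.0, 0.0), niche_breadth=(2.0, 2.0)), seed=1
        )
        narrow = suitability_from_pca_niche(
            stack, PcaNiche(niche_center=(0.0, 0.0), niche_breadth=(0.3, 0.3)), seed=1
        )
        assert (broad.values > 0.5).mean() > (narrow.values > 0.5).mean()

    def test_anticorrelated_variables_collapse_to_pc1(self):
        rng = np.random.default_rng(0)
        v = rng.normal(size=(10, 10))
        stack = make_stack({"a": v, "b": -v})
        hs = suitability_from_pca_niche(
            stack, PcaNiche(niche_center=(0.0, 0.0), niche_breadth=(1.0, 1.0),
                            background_sample_size=100), seed=0
        )
        # with all variance on PC1, suitability is a function of "a" alone
        order = np.argsort(v.ravel())
        prof = hs.values.ravel()[order]
        # unimodal in the PC1 coordinate: increases to the max then decreases
        peak = np.argmax(prof)
        assert np.all(np.diff(prof[: peak + 1]) >= -1e-9)
        assert np.all(np.diff(prof[peak:]) <= 1e-9)

    def test_background_smaller_than_p_rejected(self, small_pair):
        niche = PcaNiche(niche_center=(0, 0), niche_breadth=(1, 1), background_sample_size=2)
        with pytest.raises(ValueError):
            suitability_from_pca_niche(small_pair.current_a, niche)


class TestOccurrenceProbability:
    def test_half_probability_at_inflection(self):
        hs = make_grid(np.full((2, 2), 0.6))
        prob = occurrence_probability(hs, ConversionParams(alpha=-0.05, beta=0.6))
        assert np.allclose(prob.values, 0.5)

    def test_closed_form_at_full_suitability(self):
        hs = make_grid(np.full((2, 2), 1.0))
        prob = occurrence_probability(hs, ConversionParams(alpha=-0.05, beta=0.6))
        assert prob.values[0, 0] == pytest.approx(1 / (1 + np.exp(-8)), rel=1e-6)

    def test_generalist_params_give_wider_occurrence_at_moderate_hs(self):
        # lower beta converts moderate suitability to near-certain occurrence
        hs = make_grid(np.full((2, 2), 0.5))
        generalist = occurrence_probability(hs, ConversionParams(alpha=-0.01, beta=0.4))
        restricted = occurrence_probability(hs, ConversionParams(alpha=-0.05, beta=0.8))
        assert generalist.values[0, 0] > restricted.values[0, 0]

    def test_strictly_monotone_for_negative_alpha(self):
        hs = make_grid(np.linspace(0, 1, 100).reshape(10, 10))
        prob = occurrence_probability(hs, ConversionParams(alpha=-0.05, beta=0.5))
        flat = prob.values.ravel()
        assert np.all(np.diff(flat) > 0)
        assert flat.min() > 0 and flat.max() < 1

    def test_zero_alpha_rejected(self):
        with pytest.raises(ValueError):
            ConversionParams(alpha=0.0, beta=0.5)


class TestRealizePresenceAbsence:
    def test_degenerate_probabilities(self):
        ones = make_grid(np.ones((5, 5)))
        zeros = make_grid(np.zeros((5, 5)))
        assert realize_presence_absence(ones, seed=0).values.all()
        assert not realize_presence_absence(zeros, seed=0).values.any()

    def test_prevalence_within_binomial_bound(self):
        p = 0.3
        prob = make_grid(np.full((100, 100), p))
        pa = realize_presence_absence(prob, seed=1)
        bound = 3 * np.sqrt(p * (1 - p) / 10000)
        assert abs(pa.values.mean() - p) < bound


class TestSampling:
    def test_perfect_detection_all_presences(self):
        pa = make_grid(np.ones((30, 30)))
        samples = sample_presabs(pa, n_points=100, n_samples=3, detection=1.0, seed=0)
        assert all(len(s.points) == 100 for s in samples)
        assert all((s.points["label"] == 1).all() for s in samples)

    def test_zero_detection_all_absences(self):
        pa = make_grid(np.ones((30, 30)))
        samples = sample_presabs(pa, n_points=100, n_samples=3, detection=0.0, seed=0)
        assert all((s.points["label"] == 0).all() for s in samples)

    def test_detection_rate_recovered_within_binomial_bound(self):
        pa = make_grid(np.ones((130, 130)))
        samples = sample_presabs(pa, n_points=300, n_samples=50, detection=0.75, seed=2)
        pooled = np.concatenate([s.points["label"].to_numpy() for s in samples])
        bound = 3 * np.sqrt(0.75 * 0.25 / pooled.size)
        assert abs(pooled.mean() - 0.75) < bound

    def test_too_few_eligible_cells_rejected(self):
        pa = make_grid(np.ones((5, 5)))
        with pytest.raises(ValueError, match="eligible"):
            sample_presabs(pa, n_points=100, n_samples=1, seed=0)

    def test_csv_round_trip_bit_exact(self, tmp_path, alpine_maps):
        _, _, pa = alpine_maps
        samples = sample_presabs(pa, n_points=50, n_samples=2, detection=0.75, seed=3)
        path = tmp_path / "s.csv"
        samples_to_csv(samples, path)
        back = samples_from_csv(path)
        for orig, rt in zip(samples, back):
            assert (orig.points["x"].to_numpy() == rt.points["x"].to_numpy()).all()
            assert (orig.points["y"].to_numpy() == rt.points["y"].to_numpy()).all()
            assert (orig.points["label"].to_numpy() == rt.points["label"].to_numpy()).all()

    def test_buffered_sampling_raises_prevalence_of_rare_species(self):
        """For a low-prevalence species, restricting sampling to a buffer
        around seed presences yields higher sample prevalence than sampling
        the whole extent (checked over 10 seeds)."""
        wins = 0
        for seed in range(10):
            rng = np.random.default_rng(200 + seed)
            vals = np.zeros((40, 40))
            # rare species: one small occupied patch
            vals[5:9, 5:9] = 1.0
            pa = make_grid(vals, cell_size=10.0)
            buffered = sample_presabs(
                pa, strategy="buffered", buffer_km=60.0, n_seed_presences=10,
                n_points=100, n_samples=1, detection=1.0, seed=seed,
            )[0]
            whole = sample_presabs(pa, n_points=100, n_samples=1, detection=1.0, seed=seed)[0]
            if buffered.prevalence >= whole.prevalence:
                wins += 1
        assert wins >= 9


class TestPrevalenceOrdering:
    def test_generalist_exceeds_constrained_species(self):
        """Extent-wide prevalence under the study's conversion parameters:
        the generalist exceeds every climate-constrained archetype
        (checked over 5 generator seeds)."""
        for seed in range(5):
            cfg = default_generator_config(seed=seed, n_rows=40, n_cols=40,
                                           scenarios=(), gcms=())
            stack = generate_climate_pair(cfg).current_a
            prevalence = {}
            for name, preset in SPECIES_PRESETS.items():
                if preset.niche_kind == "responses":
                    hs = suitability_from_responses(stack, preset.responses)
                else:
                    hs = suitability_from_pca_niche(stack, preset.pca_niche, seed=seed)
                prob = occurrence_probability(hs, preset.conversion)
                pa = realize_presence_absence(prob, seed=seed)
                prevalence[name] = pa.values.mean()
            for other in ("alpine", "mediterranean", "restricted"):
                assert prevalence["generalist"] > prevalence[other]
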
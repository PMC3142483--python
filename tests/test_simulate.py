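import math
from dataclasses import replace

import numpy as np
import pytest

from aomquant import (DAYS_PER_MONTH, CompositionModel, MicroscopeGeometry,
                      TruthModel, evolve, simulate_clone_library,
                      simulate_counts, simulate_probe_counts, simulate_study,
                      sphere_volume)
from aomquant.errors import InvalidInputError


def simple_truth(**kwargs):
    defaults = dict(
        sample_id="T", geometry=MicroscopeGeometry.unit(),
        single_cell_concentration=2.0, class_concentrations={5: 5.0},
        probe_single_fractions={"P": 0.2}, probe_class_fractions={"P": {5: 0.4}},
        n_replicates=1, n_fields=100)
    defaults.update(kwargs)
    return TruthModel(**defaults)


class TestSimulateCounts:
    def test_zero_concentrations_give_zero_counts(self):
        t = simple_truth(single_cell_concentration=0.0, class_concentrations={5: 0.0})
        df = simulate_counts(t, seed=1)
        assert (df["count"] == 0).all()

    def test_same_seed_identical_tables(self):
        t = simple_truth()
        a, b = simulate_counts(t, seed=9), simulate_counts(t, seed=9)
        assert a.equals(b)
        assert not a.equals(simulate_counts(t, seed=10))

    def test_poisson_mean_recovery(self):
        # lambda = 5, 10,000 fields: empirical mean within 3*sqrt(5/n)
        t = simple_truth(class_concentrations={5: 5.0}, n_fields=10_000)
        df = simulate_counts(t, seed=3)
        agg = df[df.object_type == "aggregate"]["count"]
        assert abs(agg.mean() - 5.0) < 3 * math.sqrt(5.0 / 10_000)

    def test_lambda_overflow_rejected(self):
        t = simple_truth(class_concentrations={5: 2e6})
        with pytest.raises(InvalidInputError):
            simulate_counts(t, seed=1)

    def test_overdispersion_inflates_variance(self):
        t_p = simple_truth(class_concentrations={5: 5.0}, n_fields=20_000)
        t_nb = replace(t_p, overdispersion=1.0)  # var = mu + mu^2
        var_p = simulate_counts(t_p, 2)[lambda d: d.object_type == "aggregate"]["count"].var()
        var_nb = simulate_counts(t_nb, 2)[lambda d: d.object_type == "aggregate"]["count"].var()
        assert var_nb > 2 * var_p

    def test_design_shape(self):
        t = simple_truth(n_replicates=4, n_fields=50)
        df = simulate_counts(t, seed=1)
        assert df.replicate_id.nunique() == 4
        assert df.groupby("replicate_id").field_id.nunique().eq(50).all()


class TestSimulateProbeCounts:
    def test_fraction_one_saturates(self):
        t = simple_truth(probe_single_fractions={"P": 1.0},
                         probe_class_fractions={"P": {5: 1.0}})
        df = simulate_probe_counts(t, seed=4)
        assert (df.probe_count == df.dapi_count).all()

    def test_fraction_zero_is_below_detection(self):
        t = simple_truth(probe_single_fractions={"P": 0.0},
                         probe_class_fractions={"P": {5: 0.0}})
        df = simulate_probe_counts(t, seed=4)
        assert (df.probe_count == 0).all()
        res = CompositionModel(df, t.geometry).fit()
        assert res.fraction("T", "P", "aggregates").below_detection

    def test_binomial_fraction_recovery(self):
        t = simple_truth(probe_class_fractions={"P": {5: 0.37}}, n_fields=5_000)
        df = simulate_probe_counts(t, seed=6)
        agg = df[df.object_type == "aggregate"]
        n = agg.dapi_count.sum()
        est = agg.probe_count.sum() / n
        assert abs(est - 0.37) < 3 * math.sqrt(0.37 * 0.63 / n)

    def test_washout_preserves_fractions(self):
        t = simple_truth(class_concentrations={5: 20.0},
                         probe_class_fractions={"P": {5: 0.4}},
                         n_fields=5_000, washout_retention=0.5)
        df = simulate_probe_counts(t, seed=8)
        agg = df[df.object_type == "aggregate"]
        # washing halves the DAPI expectation but not the probe fraction
        assert agg.dapi_count.mean() == pytest.approx(10.0, rel=0.05)
        frac = agg.probe_count.sum() / agg.dapi_count.sum()
        assert frac == pytest.approx(0.4, abs=3 * math.sqrt(0.4 * 0.6 / agg.dapi_count.sum()))

    def test_invalid_fraction_rejected(self):
        with pytest.raises(InvalidInputError):
            simple_truth(probe_class_fractions={"P": {5: 1.5}})


class TestEvolve:
    def test_zero_elapsed_is_identity(self):
        t = simple_truth()
        t2 = evolve(t, 0.0, {"P": 2.5})
        assert t2.class_concentrations[5] == pytest.approx(t.class_concentrations[5])
        assert t2.probe_class_fractions["P"][5] == pytest.approx(0.4)

    def test_one_doubling_time_doubles_group(self):
        t = simple_truth()
        td = 2.0
        t2 = evolve(t, td * DAYS_PER_MONTH, {"P": td})
        assert t2.group_biovolume("P") == pytest.approx(2 * t.group_biovolume("P"))

    def test_closed_form_factor(self):
        # 286 days at a 2.5-month doubling time: factor 2^(286/76.1) = 13.53
        t = simple_truth()
        t2 = evolve(t, 286.0, {"P": 2.5})
        factor = t2.group_biovolume("P") / t.group_biovolume("P")
        assert factor == pytest.approx(2 ** (286.0 / (2.5 * DAYS_PER_MONTH)), rel=1e-12)
        assert factor == pytest.approx(13.53, abs=0.005)

    def test_negative_elapsed_rejected(self):
        with pytest.raises(InvalidInputError):
            evolve(simple_truth(), -1.0, {"P": 2.5})


class TestSimulateCloneLibrary:
    def test_degenerate_composition(self):
        lib = simulate_clone_library({"g": 1.0}, 50, seed=1)
        assert lib.group_counts == {"g": 50}

    def test_multinomial_mean(self):
        counts = [simulate_clone_library({"a": 0.88, "b": 0.12}, 50, seed=s).group_counts["a"]
                  for s in range(400)]
        mc_se = np.std(counts, ddof=1) / math.sqrt(len(counts))
        assert abs(np.mean(counts) - 44.0) < 3 * mc_se

    def test_seed_reproducible(self):
        a = simulate_clone_library({"a": 0.5, "b": 0.5}, 50, seed=3)
        assert a == simulate_clone_library({"a": 0.5, "b": 0.5}, 50, seed=3)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(InvalidInputError):
            simulate_clone_library({"a": 0.5, "b": 0.4}, 50, seed=1)
        with pytest.raises(InvalidInputError):
            simulate_clone_library({"a": 1.0}, 0, seed=1)


class TestStudyPreset:
    def test_truth_matches_published_summaries(self, study_truth):
        s1, s2 = study_truth.s1, study_truth.s2
        assert s1.total_biovolume() == pytest.approx(1.28e9, rel=1e-9)
        assert s2.total_biovolume() == pytest.approx(4.49e9, rel=1e-9)
        assert s1.group_fraction("EelMS932", "biovolume") == pytest.approx(0.134, abs=1e-6)
        assert s1.group_fraction("EelMS932", "aggregates") == pytest.approx(0.371, abs=1e-6)
        assert s2.group_fraction("DSS658", "biovolume") == pytest.approx(0.606, abs=1e-6)
        # S1 big-aggregate concentration is the published 2.22e5/ml
        big = sum(s1.class_concentrations[d] for d in range(11, 16))
        assert big == pytest.approx(2.22e5, rel=1e-9)
        small = sum(s1.class_concentrations[d] for d in range(2, 6))
        agg = sum(s1.class_concentrations.values())
        assert small / agg == pytest.approx(0.7335, abs=1e-6)

    def test_implied_doubling_time(self, study_truth):
        assert study_truth.doubling_time_months("EelMS932") == pytest.approx(2.52, abs=0.01)

    def test_round_trip_truth_dict(self, study_truth):
        back = TruthModel.from_dict(study_truth.s1.to_dict())
        assert back.total_biovolume() == pytest.approx(study_truth.s1.total_biovolume())
        assert back.probe_class_fractions == study_truth.s1.probe_class_fractions

    def test_study_tables_validate_and_reproduce(self, study_truth):
        a = simulate_study(study_truth, seed=2)
        b = simulate_study(study_truth, seed=2)
        assert a["counts"].equals(b["counts"])
        assert a["probe_counts"].equals(b["probe_counts"])
        assert a["clone_libraries"] == b["clone_libraries"]
        assert set(a["counts"].sample_id) == {"S1", "S2"}
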
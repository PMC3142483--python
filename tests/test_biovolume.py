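import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from aomquant import (BiovolumeModel, MicroscopeGeometry, SizeClassCounts,
                      counts_to_concentration, quantify_sample,
                      replicate_summary, sphere_volume)
from aomquant.errors import InvalidGeometryError, InvalidInputError, SchemaError
from tests.conftest import make_counts


class TestSphereVolume:
    @pytest.mark.parametrize("d,expected", [
        (0.0, 0.0),
        (0.45, math.pi / 6 * 0.45**3),   # 0.04771 um^3, the single-cell volume
        (10.0, 523.5987755982988),
    ])
    def test_closed_form(self, d, expected):
        assert sphere_volume(d) == pytest.approx(expected, rel=1e-12, abs=0.0)

    def test_negative_diameter_rejected(self):
        with pytest.raises(InvalidInputError):
            sphere_volume(-1.0)

    @given(st.floats(min_value=0.0, max_value=1e3),
           st.floats(min_value=1e-6, max_value=1e3))
    def test_strictly_increasing(self, d, delta):
        assert sphere_volume(d + delta) > sphere_volume(d)

    def test_vectorized(self):
        v = sphere_volume(np.array([1.0, 2.0]))
        assert v == pytest.approx([math.pi / 6, math.pi / 6 * 8])


class TestCountsToConcentration:
    def test_unit_geometry(self, unit_geometry):
        assert counts_to_concentration([5, 5, 5], unit_geometry) == pytest.approx(5.0)

    def test_scaled_geometry(self):
        geom = MicroscopeGeometry(dilution_factor=2000, filtered_volume_ml=0.5,
                                  filter_effective_area_um2=100.0, field_area_um2=1.0)
        assert counts_to_concentration([3, 3], geom) == pytest.approx(1.2e6)

    def test_all_zero_counts(self, unit_geometry):
        assert counts_to_concentration([0, 0, 0], unit_geometry) == 0.0

    def test_empty_fields_rejected(self, unit_geometry):
        with pytest.raises(InvalidInputError):
            counts_to_concentration([], unit_geometry)

    def test_invalid_geometry_rejected(self):
        with pytest.raises(InvalidGeometryError):
            MicroscopeGeometry(filtered_volume_ml=0.0)
        with pytest.raises(InvalidGeometryError):
            MicroscopeGeometry(field_area_um2=0.0)
        with pytest.raises(InvalidGeometryError):
            MicroscopeGeometry(field_area_um2=2.0, filter_effective_area_um2=1.0)


class TestReplicateSummary:
    def test_identical_replicates(self):
        assert replicate_summary([2, 2, 2, 2]) == (2.0, 0.0)

    def test_spread_replicates(self):
        mean, se = replicate_summary([1, 2, 3, 4])
        assert mean == pytest.approx(2.5)
        assert se == pytest.approx(math.sqrt(5 / 3) / 2, rel=1e-12)  # 0.6455

    def test_single_replicate_flagged(self):
        with pytest.warns(UserWarning, match="single replicate"):
            mean, se = replicate_summary([7.0])
        assert mean == 7.0 and math.isnan(se)

    def test_empty_rejected(self):
        with pytest.raises(InvalidInputError):
            replicate_summary([])


def brute_force_quantify(df, geometry, single_cell_diameter=0.45):
    """Independent enumeration oracle: plain loops, no pandas groupby."""
    records = {}
    for _, row in df.iterrows():
        key = (row.replicate_id, row.field_id)
        records.setdefault(key, {"single": 0, "agg": {}})
        if row.object_type == "single_cell":
            records[key]["single"] += row["count"]
        else:
            c = int(row.diameter_class_um)
            records[key]["agg"][c] = records[key]["agg"].get(c, 0) + row["count"]
    reps = sorted({k[0] for k in records})
    classes = sorted({c for rec in records.values() for c in rec["agg"]})
    out = {"classes": classes, "conc": {}, "single": [], "total_bv": []}
    for r in reps:
        fields = [records[k] for k in records if k[0] == r]
        n = len(fields)
        single_conc = sum(f["single"] for f in fields) / n * geometry.scale_factor
        out["single"].append(single_conc)
        total = single_conc * math.pi / 6 * single_cell_diameter**3
        for c in classes:
            conc = sum(f["agg"].get(c, 0) for f in fields) / n * geometry.scale_factor
            out["conc"].setdefault(c, []).append(conc)
            total += conc * math.pi / 6 * c**3
        out["total_bv"].append(total)
    return out


class TestQuantifySample:
    def test_single_class_only(self):
        # two replicates, one field each, one aggregate of class 10 per field;
        # geometry scaling one count/field to 1e5 objects/ml
        geom = MicroscopeGeometry(dilution_factor=1, filtered_volume_ml=1,
                                  filter_effective_area_um2=1e5, field_area_um2=1.0)
        counts = make_counts(reps=2, fields=1, aggregates={10: {(0, 0): 1, (1, 0): 1}})
        res = quantify_sample(counts, geom)
        assert res.per_class.loc[10, "concentration_mean"] == pytest.approx(1e5)
        assert res.per_class.loc[10, "biovolume_mean"] == pytest.approx(5.23599e7, rel=1e-5)
        assert res.aggregate_biovolume_share == pytest.approx(1.0)

    def test_all_zero_counts_share_zero(self, unit_geometry):
        counts = make_counts(reps=2, fields=2, aggregates={5: {}})
        with pytest.warns(UserWarning, match="zero total biovolume"):
            res = quantify_sample(counts, unit_geometry)
        assert res.total_biovolume == 0.0
        assert res.aggregate_biovolume_share == 0.0

    def test_matches_brute_force_oracle(self):
        geom = MicroscopeGeometry(dilution_factor=5, filtered_volume_ml=2,
                                  filter_effective_area_um2=10.0, field_area_um2=1.0)
        counts = make_counts(
            reps=2, fields=3,
            singles={(0, 0): 4, (0, 1): 2, (1, 2): 5},
            aggregates={4: {(0, 0): 1, (1, 1): 2},
                        10: {(0, 2): 1, (1, 0): 1, (1, 1): 1}})
        oracle = brute_force_quantify(counts, geom)
        res = quantify_sample(counts, geom)
        for c in oracle["classes"]:
            om, ose = np.mean(oracle["conc"][c]), np.std(oracle["conc"][c], ddof=1) / math.sqrt(2)
            assert res.per_class.loc[c, "concentration_mean"] == pytest.approx(om, rel=1e-12)
            assert res.per_class.loc[c, "concentration_se"] == pytest.approx(ose, rel=1e-12)
        assert res.single_cell_concentration == pytest.approx(np.mean(oracle["single"]), rel=1e-12)
        assert res.total_biovolume == pytest.approx(np.mean(oracle["total_bv"]), rel=1e-12)
        assert res.total_biovolume_se == pytest.approx(
            np.std(oracle["total_bv"], ddof=1) / math.sqrt(2), rel=1e-12)

    def test_conservation_of_biovolume(self):
        geom = MicroscopeGeometry.default(dilution_factor=100)
        rng = np.random.default_rng(42)
        aggs = {c: {(r, f): int(rng.integers(0, 5)) for r in range(3) for f in range(4)}
                for c in range(2, 16)}
        singles = {(r, f): int(rng.integers(0, 40)) for r in range(3) for f in range(4)}
        res = quantify_sample(make_counts(reps=3, fields=4, singles=singles,
                                          aggregates=aggs), geom)
        total = res.single_cell_biovolume + res.per_class["biovolume_mean"].sum()
        assert res.total_biovolume == pytest.approx(total, rel=1e-9)
        assert res.aggregate_biovolume == pytest.approx(
            res.per_class["biovolume_mean"].sum(), rel=1e-9)

    @pytest.mark.parametrize("factor", [2.0, 7.0])
    def test_dilution_linearity(self, factor):
        counts = make_counts(reps=2, fields=2,
                             singles={(0, 0): 3, (1, 1): 5},
                             aggregates={6: {(0, 1): 2, (1, 0): 1}})
        g1 = MicroscopeGeometry(dilution_factor=100, filtered_volume_ml=1,
                                filter_effective_area_um2=50, field_area_um2=1)
        g2 = MicroscopeGeometry(dilution_factor=100 * factor, filtered_volume_ml=1,
                                filter_effective_area_um2=50, field_area_um2=1)
        r1, r2 = quantify_sample(counts, g1), quantify_sample(counts, g2)
        assert r2.total_biovolume == pytest.approx(factor * r1.total_biovolume, rel=1e-12)
        assert (r2.per_class["concentration_mean"].to_numpy()
                == pytest.approx(factor * r1.per_class["concentration_mean"].to_numpy(),
                                 rel=1e-12))

    def test_unknown_diameter_class_rejected(self, unit_geometry):
        counts = make_counts(aggregates={99: {(0, 0): 1}})
        with pytest.raises(SchemaError, match="99"):
            quantify_sample(counts, unit_geometry)

    def test_two_samples_need_selection(self, unit_geometry):
        df = pd.concat([make_counts("A"), make_counts("B")], ignore_index=True)
        with pytest.raises(InvalidInputError):
            BiovolumeModel(df, unit_geometry)
        res = BiovolumeModel(df, unit_geometry, sample_id="B").fit()
        assert res.sample_id == "B"


def test_results_plot_smoke():
    import matplotlib

    matplotlib.use("Agg")
    counts = make_counts(reps=2, fields=2, singles={(0, 0): 3},
                         aggregates={5: {(0, 0): 1, (1, 1): 2}})
    res = quantify_sample(counts, MicroscopeGeometry.unit())
    ax = res.plot()
    assert len(ax) == 2


class TestSizeClassCounts:
    def test_negative_counts_rejected(self):
        with pytest.raises(InvalidInputError):
            SizeClassCounts("A", "1", "1", single_cell_count=-1)

    def test_frame_round_trip(self):
        recs = [SizeClassCounts("A", "1", "1", 3, {4: 1, 10: 2}),
                SizeClassCounts("A", "1", "2", 0, {4: 0, 10: 1})]
        back = SizeClassCounts.set_from_frame(SizeClassCounts.set_to_frame(recs))
        assert back == recs
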
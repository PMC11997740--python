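"""SOC stock computation: layer formula, depth aggregation, subsoil
imputation and patch-cover weighting."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from savanna_carbon.soil import (
    DEPTH_CLASSES,
    DEPTH_THICKNESS_CM,
    PatchCover,
    SoilCore,
    aggregate_core,
    impute_subsoil,
    plot_soil_compartments,
    soc_stock_layer,
    weight_by_patch,
)


def make_core(conc=5.0, bd=1.5, max_depth=100, plot="p1", patch="under_tree"):
    classes = DEPTH_CLASSES if max_depth == 100 else DEPTH_CLASSES[:4]
    return SoilCore(
        plot_id=plot, patch_type=patch,
        concentration={c: conc for c in classes},
        bulk_density={c: bd for c in classes},
        max_depth=max_depth,
    )


class TestLayerStock:
    @pytest.mark.parametrize(
        "conc,bd,thick,expected",
        [(0.0, 1.5, 10.0, 0.0), (5.0, 1.5, 10.0, 7.5), (3.0, 1.6, 20.0, 9.6)],
    )
    def test_stock_formula(self, conc, bd, thick, expected):
        assert soc_stock_layer(conc, bd, thick) == pytest.approx(expected)

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            soc_stock_layer(-1.0, 1.5, 10.0)


class TestCoreAggregation:
    def test_uniform_core_thickness_weighted(self):
        # conc=5, bd=1.5: topsoil = 7.5*3; subsoil = 15+15+22.5
        out = aggregate_core(make_core())
        assert out["topsoil_soc"] == pytest.approx(22.5)
        assert out["subsoil_soc"] == pytest.approx(52.5)

    def test_zero_concentrations(self):
        out = aggregate_core(make_core(conc=0.0, bd=1.0))
        # bulk density 1.0 is below the plausibility window; use 1.2
        out = aggregate_core(make_core(conc=0.0, bd=1.2))
        assert out["topsoil_soc"] == 0.0 and out["subsoil_soc"] == 0.0

    def test_matches_brute_force_class_summation(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            conc = {c: float(rng.uniform(0, 10)) for c in DEPTH_CLASSES}
            bd = {c: float(rng.uniform(0.9, 1.9)) for c in DEPTH_CLASSES}
            core = SoilCore("p", "bare", conc, bd)
            out = aggregate_core(core)
            brute = sum(conc[c] * bd[c] * DEPTH_THICKNESS_CM[c] / 10.0 for c in DEPTH_CLASSES)
            assert out["topsoil_soc"] + out["subsoil_soc"] == pytest.approx(brute, rel=1e-12)
        assert sum(DEPTH_THICKNESS_CM.values()) == 100.0

    def test_missing_unimputed_class_rejected(self):
        with pytest.raises(ValueError):
            aggregate_core(make_core(max_depth=50))


class TestImputation:
    def test_mean_of_two_neighbours(self):
        short = make_core(max_depth=50)
        n1 = make_core(conc=2.0, bd=1.0 + 0.45, plot="n1")  # bd must be in range
        n2 = make_core(conc=4.0, bd=1.45, plot="n2")
        imputed = impute_subsoil(short, [n1, n2])
        expected_50_70 = (n1.class_stock("50-70") + n2.class_stock("50-70")) / 2
        assert imputed.class_stock("50-70") == pytest.approx(expected_50_70)
        assert set(imputed.imputed_classes) == {"50-70", "70-100"}

    def test_single_neighbour_copies_its_stock(self):
        short = make_core(max_depth=50)
        n1 = make_core(conc=3.0, plot="n1")
        imputed = impute_subsoil(short, [n1])
        assert imputed.class_stock("70-100") == pytest.approx(n1.class_stock("70-100"))

    def test_measured_classes_untouched(self):
        short = make_core(conc=7.0, max_depth=50)
        before = short.class_stock("0-10")
        impute_subsoil(short, [make_core(plot="n1")])
        assert short.class_stock("0-10") == before

    def test_full_depth_core_is_noop(self):
        core = make_core()
        assert impute_subsoil(core, []) is core

    def test_no_eligible_neighbour_rejected_with_diagnostic(self):
        with pytest.raises(ValueError, match="neighbour"):
            impute_subsoil(make_core(max_depth=50), [make_core(max_depth=50, plot="n")])


class TestPatchWeighting:
    def test_single_patch_identity(self):
        cover = PatchCover("p", {"under_tree": 1.0})
        vals = {"under_tree": {"topsoil_soc": 10.0, "subsoil_soc": 20.0}}
        out = weight_by_patch(vals, cover)
        assert out == {"topsoil_soc": 10.0, "subsoil_soc": 20.0}

    def test_equal_covers_average(self):
        cover = PatchCover("p", {"under_tree": 0.5, "bare": 0.5})
        vals = {
            "under_tree": {"topsoil_soc": 10.0, "subsoil_soc": 10.0},
            "bare": {"topsoil_soc": 20.0, "subsoil_soc": 30.0},
        }
        out = weight_by_patch(vals, cover)
        assert out["topsoil_soc"] == pytest.approx(15.0)
        assert out["subsoil_soc"] == pytest.approx(20.0)

    def test_three_patches_match_dot_product_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            w = rng.dirichlet([2, 2, 2])
            v = rng.uniform(5, 40, size=(3, 2))
            cover = PatchCover("p", dict(zip(("under_tree", "between_trees", "bare"), w)))
            vals = {
                p: {"topsoil_soc": v[i, 0], "subsoil_soc": v[i, 1]}
                for i, p in enumerate(("under_tree", "between_trees", "bare"))
            }
            out = weight_by_patch(vals, cover)
            assert out["topsoil_soc"] == pytest.approx(w @ v[:, 0], rel=1e-12)
            assert out["subsoil_soc"] == pytest.approx(w @ v[:, 1], rel=1e-12)

    @given(
        w=st.lists(st.floats(0.01, 1.0), min_size=3, max_size=3),
        v=st.lists(st.floats(0.0, 60.0), min_size=3, max_size=3),
        k=st.floats(0.1, 5.0),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_bounded_and_homogeneous(self, w, v, k):
        w = np.array(w) / sum(w)
        patches = ("under_tree", "between_trees", "bare")
        cover = PatchCover("p", dict(zip(patches, w)))
        vals = {p: {"topsoil_soc": vi, "subsoil_soc": vi} for p, vi in zip(patches, v)}
        out = weight_by_patch(vals, cover)
        assert min(v) - 1e-9 <= out["topsoil_soc"] <= max(v) + 1e-9
        scaled = {p: {"topsoil_soc": k * vi, "subsoil_soc": k * vi} for p, vi in zip(patches, v)}
        assert weight_by_patch(scaled, cover)["topsoil_soc"] == pytest.approx(
            k * out["topsoil_soc"], rel=1e-9
        )

    def test_unsampled_patch_with_cover_renormalises(self):
        cover = PatchCover("p", {"under_tree": 0.6, "between_trees": 0.2, "bare": 0.2})
        vals = {
            "under_tree": {"topsoil_soc": 10.0, "subsoil_soc": 0.0},
            "between_trees": {"topsoil_soc": 20.0, "subsoil_soc": 0.0},
        }
        out = weight_by_patch(vals, cover)
        assert out["topsoil_soc"] == pytest.approx((0.6 * 10 + 0.2 * 20) / 0.8)

    def test_invalid_cover_simplex_rejected(self):
        with pytest.raises(ValueError):
            PatchCover("p", {"under_tree": 0.7, "bare": 0.7})


class TestPlotLevel:
    def test_plot_table_flags_imputed_plots(self, dataset):
        out = plot_soil_compartments(dataset.soil, dataset.plots)
        assert len(out) == len(dataset.plots)
        assert out["subsoil_imputed"].any()
        assert (out["topsoil_soc"] > 0).all() and (out["subsoil_soc"] > 0).all()
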
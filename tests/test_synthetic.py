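"""Tests of the synthetic generators: geometric oracle and trait simulation."""
import math

import numpy as np
import pytest

from spermhelix import geometry as geo
from spermhelix import phylostats as ps
from spermhelix import synthetic as syn


def constant_spec(**kw) -> syn.HelixSpec:
    base = dict(
        flagellum_length_um=100.0,
        base_flagellum_diameter_um=0.30,
        tip_flagellum_diameter_um=0.30,
        midpiece_fraction=0.80,
        base_minor_axis_um=0.10,
        tip_minor_axis_um=0.10,
        base_major_axis_um=0.20,
        tip_major_axis_um=0.20,
        pitch_base_um=4.0,
        pitch_tip_um=4.0,
    )
    base.update(kw)
    return syn.HelixSpec(**base)


class TestSimulateTree:
    def test_ultrametric_unit_height(self):
        tree = syn.simulate_tree(3, seed=5)
        depths = [leaf.distance_from_root() for leaf in tree.leaf_node_iter()]
        assert len(depths) == 3
        assert all(d == pytest.approx(1.0, abs=1e-9) for d in depths)

    def test_same_seed_same_newick(self):
        a = syn.simulate_tree(10, seed=4).as_string(schema="newick")
        b = syn.simulate_tree(10, seed=4).as_string(schema="newick")
        assert a == b
        c = syn.simulate_tree(10, seed=5).as_string(schema="newick")
        assert a != c

    def test_bifurcating_tip_and_node_counts(self):
        tree = syn.simulate_tree(55, seed=1)
        tips = list(tree.leaf_node_iter())
        internal = [n for n in tree.preorder_node_iter() if not n.is_leaf()]
        assert len(tips) == 55
        assert len(internal) == 54

    def test_too_few_species(self):
        with pytest.raises(ValueError):
            syn.simulate_tree(2, seed=0)


class TestTrueHelixVolume:
    def test_matches_analytic_helix_for_constant_tube(self):
        spec = constant_spec()
        # analytic: area x total arc length of a helix with winding radius
        # r_flag + minor/2 and constant pitch
        a = 0.30 / 2 + 0.10 / 2
        L = spec.midpiece_length_um
        arc = L * math.sqrt(1.0 + (2 * math.pi * a / 4.0) ** 2)
        expected = math.pi * 0.1 * 0.05 * arc
        assert syn.true_helix_volume(spec) == pytest.approx(expected, rel=1e-9)

    def test_volume_vanishes_with_midpiece(self):
        v = syn.true_helix_volume(constant_spec(midpiece_fraction=1e-4))
        assert 0 < v < 1e-3

    def test_halving_step_convergence(self):
        spec = syn.HelixSpec()
        v1 = syn.true_helix_volume(spec, n_steps=2000)
        v2 = syn.true_helix_volume(spec, n_steps=4000)
        assert v2 == pytest.approx(v1, rel=1e-7)

    def test_requires_enough_steps(self):
        with pytest.raises(ValueError):
            syn.true_helix_volume(syn.HelixSpec(), n_steps=10)


class TestProjectMeasurements:
    def test_noise_free_inversion_of_minor_axis(self):
        spec = syn.HelixSpec()
        cell = syn.project_measurements(spec)
        by_loc = {}
        for m in cell.measurements:
            if m.kind in (geo.FLAGELLUM_WIDTH, geo.FLAGELLUM_PLUS_MINOR):
                by_loc.setdefault(m.center_position_um, {})[m.kind] = m.value_um
        checked = 0
        for z, kinds in by_loc.items():
            minor = geo.minor_axis_diameter(
                kinds[geo.FLAGELLUM_PLUS_MINOR], kinds[geo.FLAGELLUM_WIDTH]
            )
            assert minor == pytest.approx(float(spec.minor_axis(z)), rel=1e-9)
            checked += 1
        assert checked > 10

    def test_all_major_missing_breaks_imputation(self):
        noise = syn.MeasurementNoiseSpec(
            cv=0.0, p_missing_value=1.0, p_obscured_section=0.0
        )
        spec = syn.HelixSpec()
        cell = syn.project_measurements(spec, noise, seed=0)
        with pytest.raises(geo.InsufficientDataError):
            geo.assemble_gyre_geometries(cell)

    def test_noise_spread_matches_lognormal_cv(self):
        spec = constant_spec()
        noise = syn.MeasurementNoiseSpec(
            cv=0.02, p_missing_value=0.0, p_obscured_section=0.0
        )
        vals = []
        for s in range(40):
            cell = syn.project_measurements(spec, noise, seed=s)
            vals.extend(
                m.value_um
                for m in cell.measurements
                if m.kind == geo.FLAGELLUM_WIDTH
            )
        spread = np.std(np.log(vals))
        assert spread == pytest.approx(0.02, rel=0.15)

    def test_estimator_close_to_integral_oracle(self):
        spec = syn.HelixSpec()
        truth = syn.true_helix_volume(spec)
        est = geo.cell_volume(syn.project_measurements(spec)).total_volume_um3
        assert abs(est - truth) / truth < 0.10


class TestSimulateSpeciesTraits:
    def test_independent_limit_lambda_zero(self, small_tree):
        spec = syn.ComparativeSimSpec(n_species=8, lambda_true=0.0)
        devs = []
        for s in range(400):
            df, _ = syn.simulate_species_traits(small_tree, spec, seed=s)
            devs.append(df["log_flagellum"].to_numpy())
        D = np.array(devs)
        corr = np.corrcoef(D.T)
        off = corr[~np.eye(8, dtype=bool)]
        assert np.max(np.abs(off)) < 0.2  # MC error only

    def test_brownian_limit_matches_tree_covariance(self, small_tree):
        spec = syn.ComparativeSimSpec(n_species=8, lambda_true=1.0, bm_sd=1.0)
        devs = []
        for s in range(600):
            df, _ = syn.simulate_species_traits(small_tree, spec, seed=10_000 + s)
            devs.append(df["log_flagellum"].to_numpy())
        emp = np.cov(np.array(devs).T)
        C = ps.phylo_covariance(small_tree).matrix
        assert np.max(np.abs(emp - C)) < 0.25  # elementwise, MC tolerance

    def test_zero_rate_degenerates_to_root(self, small_tree):
        spec = syn.ComparativeSimSpec(n_species=8, bm_sd=1e-12, allometry_sd=1e-12)
        df, _ = syn.simulate_species_traits(small_tree, spec, seed=0)
        assert df["log_flagellum"].std() < 1e-6


class TestSimulateRepeatMeasures:
    def test_zero_cv_gives_identical_repeats_and_icc_one(self):
        tbl, icc = syn.simulate_repeat_measures([1.0, 2.0, 3.0], cv=0.0, seed=0)
        assert icc == 1.0
        assert (tbl.groupby("point_id")["value"].nunique() == 1).all()

    def test_balanced_variances_give_icc_half(self):
        vals = [0.0, 1.0, 2.0, 3.0]
        sd_b = float(np.std(vals, ddof=1))
        cv = sd_b / float(np.mean(np.abs(vals)))
        _, icc = syn.simulate_repeat_measures(vals, cv=cv, seed=0)
        assert icc == pytest.approx(0.5, abs=1e-12)


class TestGenerateDataset:
    def test_seeded_determinism_and_distinct_seeds(self, tmp_path):
        a = syn.generate_dataset(
            syn.ComparativeSimSpec(n_species=10), seed=3, out_dir=tmp_path / "a"
        )
        b = syn.generate_dataset(
            syn.ComparativeSimSpec(n_species=10), seed=3, out_dir=tmp_path / "b"
        )
        for name in ("measurements.csv", "cells.csv", "species.csv", "tree.nwk",
                     "truth.json"):
            assert (tmp_path / "a" / name).read_bytes() == (
                tmp_path / "b" / name
            ).read_bytes()
        c = syn.generate_dataset(syn.ComparativeSimSpec(n_species=10), seed=4)
        assert not c.measurements.equals(a.measurements)

    def test_truth_has_volume_for_every_cell(self, default_bundle):
        for cell in default_bundle.cells:
            assert f"true_volume_um3.{cell.cell_id}" in default_bundle.truth

    def test_bundle_round_trips_through_readers(self, tmp_path):
        from spermhelix import io as shio

        bundle = syn.generate_dataset(
            syn.ComparativeSimSpec(n_species=8), seed=5, out_dir=tmp_path
        )
        cells = shio.read_cell_records(
            tmp_path / "measurements.csv", tmp_path / "cells.csv"
        )
        assert len(cells) == len(bundle.cells)
        orig = {c.cell_id: c for c in bundle.cells}
        for c in cells:
            o = orig[c.cell_id]
            assert c.midpiece_length_um == pytest.approx(o.midpiece_length_um)
            assert len(c.measurements) == len(o.measurements)
        tree = shio.read_tree(tmp_path / "tree.nwk", species=[c.species for c in cells])
        assert len(list(tree.leaf_node_iter())) == 8

    def test_one_family_is_turdidae(self, default_bundle):
        fams = {c.family for c in default_bundle.cells}
        assert "Turdidae" in fams
        n_turd = sum(c.family == "Turdidae" for c in default_bundle.cells)
        assert 3 <= n_turd <= 10
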
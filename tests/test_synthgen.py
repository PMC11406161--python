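"""Design generation, trajectory simulation and corruption rules."""

import math

import numpy as np
import pytest

import ewlphylo as e
from ewlphylo import prep
from tests.conftest import make_individual


class TestMakeDesign:
    def test_study_scale_one_species(self):
        design = e.make_design(8, e.DEFAULT_PROFILES[:1], seed=0)
        assert len(design) == 32
        cells = {}
        for ind in design:
            key = (ind.treatment.water_present, ind.treatment.temperature_c)
            cells[key] = cells.get(key, 0) + 1
        assert set(cells.values()) == {8}

    def test_three_species_minimal(self):
        assert len(e.make_design(1, e.DEFAULT_PROFILES, seed=0)) == 12

    def test_balance_and_svl_ranges(self):
        design = e.make_design(5, e.DEFAULT_PROFILES, seed=2)
        by_cell = {}
        for ind in design:
            key = (ind.species, ind.treatment.water_present, ind.treatment.temperature_c)
            by_cell[key] = by_cell.get(key, 0) + 1
            lo, hi = {p.name: p.svl_range_mm for p in e.DEFAULT_PROFILES}[ind.species]
            assert lo <= ind.svl_mm <= hi
        assert max(by_cell.values()) - min(by_cell.values()) <= 1

    def test_determinism(self):
        a = e.make_design(3, e.DEFAULT_PROFILES, seed=42)
        b = e.make_design(3, e.DEFAULT_PROFILES, seed=42)
        assert [(x.id, x.svl_mm, x.date, x.housing_group) for x in a] == [
            (x.id, x.svl_mm, x.date, x.housing_group) for x in b
        ]

    def test_empty_species_rejected(self):
        with pytest.raises(ValueError):
            e.make_design(8, [], seed=0)

    def test_ids_unique(self):
        design = e.make_design(8, e.DEFAULT_PROFILES, seed=1)
        assert len({ind.id for ind in design}) == len(design)


class TestSimulateSeries:
    def test_deterministic_loss_over_hour(self, zero_variance_truth):
        """Without noise, a -0.0019 ln g/min slope drops ln mass by exactly
        0.114 over 60 min out of water."""
        ind = make_individual()
        s = e.simulate_series(ind, zero_variance_truth, [0, 20, 40, 60], seed=0)
        drop = math.log(s.masses[0]) - math.log(s.masses[-1])
        assert drop == pytest.approx(0.0019 * 60, abs=1e-12)

    def test_net_uptake_slope_in_water(self, zero_variance_truth):
        """In water the baseline species gains at -0.0019 + 0.0023 =
        +0.0004 ln g/min (independent scalar computation)."""
        ind = make_individual(water=True)
        s = e.simulate_series(ind, zero_variance_truth, [0, 60], seed=0)
        slope = (math.log(s.masses[1]) - math.log(s.masses[0])) / 60.0
        expected = (
            zero_variance_truth.coefficients["Time"]
            + zero_variance_truth.coefficients["Water-Time"]
        )
        assert expected == pytest.approx(-0.0019 + 0.0023, abs=1e-15)
        assert slope == pytest.approx(expected, abs=1e-12)

    def test_single_time_point(self, zero_variance_truth):
        s = e.simulate_series(make_individual(), zero_variance_truth, [0], seed=0)
        assert s.n_obs == 1 and s.masses[0] > 0

    def test_nonincreasing_times_rejected(self, zero_variance_truth):
        with pytest.raises(ValueError):
            e.simulate_series(make_individual(), zero_variance_truth, [0, 20, 20], seed=0)

    def test_linear_predictor_exact_for_all_cells(self, zero_variance_truth):
        """Zero-variance trajectories are exactly linear in time with the
        analytic species/water slope."""
        c = zero_variance_truth.coefficients
        for species, short in [
            ("Xenopus_tropicalis", None),
            ("Rhinella_marina", "R.marina"),
            ("Phyllobates_terribilis", "P.terribilis"),
        ]:
            for water in (False, True):
                ind = make_individual(species=species, svl=50.0, water=water)
                s = e.simulate_series(ind, zero_variance_truth, [0, 15, 30, 60], seed=0)
                lnm = np.log(s.masses)
                slopes = np.diff(lnm) / np.diff(s.times)
                expected = c["Time"] + (c[f"{short}-Time"] if short else 0.0)
                if water:
                    expected += c["Water-Time"] + (
                        c[f"{short}-Water-Time"] if short else 0.0
                    )
                assert np.allclose(slopes, expected, atol=1e-12)

    def test_masses_positive(self, table1_truth):
        ind = make_individual()
        s = e.simulate_series(ind, table1_truth, [0, 20, 40, 60], seed=5)
        assert np.all(s.masses > 0)


class TestLagAutocorrelation:
    def test_kernel_value_recovered_at_reference_lag(self):
        """Empirical residual correlation at a 20-min lag over many series
        converges to rho."""
        truth = e.TruthTable(
            coefficients={
                n: (1.5 if n == "Intercept" else 0.0) for n in e.COEFFICIENT_NAMES
            },
            variances={"frog": 0.0, "housing": 0.0, "date": 0.0, "species": 0.0, "error": 0.04},
            rho=0.7,
        )
        ind = make_individual()
        rng_pairs = []
        for i in range(2000):
            s = e.simulate_series(ind, truth, [0, 20, 40, 60], seed=i)
            r = np.log(s.masses) - 1.5
            rng_pairs.append(r)
        R = np.array(rng_pairs)
        lag_pairs = np.concatenate([np.stack([R[:, i], R[:, i + 1]], 1) for i in range(3)])
        corr = np.corrcoef(lag_pairs[:, 0], lag_pairs[:, 1])[0, 1]
        assert corr == pytest.approx(0.7, abs=0.04)


class TestCorruptSeries:
    def make_series(self, masses=(10.0, 9.9, 9.8, 9.7)):
        return e.MassSeries("f1", [0, 20, 40, 60], np.array(masses, float))

    def test_identity_when_disabled(self):
        s = self.make_series()
        out = e.corrupt_series(s, excretion_prob=0.0, missing_prob=0.0, seed=1)
        assert np.array_equal(out.masses, s.masses)
        assert list(out.status) == list(s.status)
        assert not out.dropout

    def test_forced_excretion_records_event(self):
        s = self.make_series((10.0, 10.0, 10.0, 10.0))
        out = e.corrupt_series(
            s,
            excretion_prob=0.0,
            missing_prob=0.0,
            seed=1,
            excretion_events=[(1, 0.02)],
        )
        assert out.excreted_g[1] == pytest.approx(0.2)
        assert np.allclose(out.masses[1:], 9.8)
        assert out.masses[0] == 10.0

    def test_dropout_truncates_before_threshold_crossing(self):
        s = self.make_series((10.0, 9.5, 8.5, 7.5))  # 25% loss by t=60
        out = e.corrupt_series(s, excretion_prob=0.0, missing_prob=0.0, seed=1)
        assert out.dropout
        assert out.status[3] == prep.STATUS_TRUNCATED
        assert np.isnan(out.masses[3])
        assert out.status[2] == prep.STATUS_OBSERVED  # 15% loss retained

    def test_bad_threshold_rejected(self):
        with pytest.raises(ValueError):
            e.corrupt_series(self.make_series(), dropout_threshold=0.0, seed=0)

    def test_exact_masking_count(self):
        series = [self.make_series() for _ in range(10)]
        for i, s in enumerate(series):
            s.individual_id = f"f{i}"
        out = e.corrupt_experiment(series, seed=3, n_missing_exact=7, excretion_prob=0.0)
        n_masked = sum(int(np.sum(s.status == prep.STATUS_MASKED)) for s in out)
        assert n_masked == 7


class TestTruthPresets:
    def test_table1_time_coefficient(self, table1_truth):
        assert table1_truth.coefficients["Time"] == -0.0019

    def test_null_zeroes_slopes(self):
        t = e.truth_parameters("null")
        nonzero = {k for k, v in t.coefficients.items() if v != 0.0}
        assert nonzero <= {"Intercept"}

    def test_o2_has_no_marginal_water_effect(self):
        t = e.truth_parameters("fig1:O2")
        slopes = e.synthgen.scenario_slopes(t)
        assert slopes[(1, 26.0)] == pytest.approx(slopes[(0, 26.0)])

    def test_unknown_preset_rejected(self):
        with pytest.raises(ValueError):
            e.truth_parameters("fig1:O9")

    def test_truth_roundtrip_json(self, tmp_path, table1_truth):
        p = tmp_path / "truth.json"
        table1_truth.to_json(p)
        back = e.TruthTable.from_json(p)
        assert back.coefficients == table1_truth.coefficients
        assert back.variances == table1_truth.variances


class TestExperimentIO:
    def test_csv_roundtrip(self, small_experiment, tmp_path):
        design, sim = small_experiment
        path = tmp_path / "data.csv"
        corrupted = e.corrupt_experiment(sim.series, seed=9, excretion_prob=0.5)
        e.synthgen.write_long_csv(corrupted, design, path)
        series, individuals = e.synthgen.read_long_csv(path)
        assert len(series) == len(corrupted)
        orig = {s.individual_id: s for s in corrupted}
        for s in series:
            o = orig[s.individual_id]
            assert np.allclose(s.times, o.times)
            mask = ~np.isnan(o.masses)
            assert np.allclose(s.masses[mask], o.masses[mask])
            assert list(s.status) == list(o.status)

    def test_same_seed_identical_tables(self, small_experiment, tmp_path):
        design, _ = small_experiment
        truth = e.truth_parameters("table1")
        a = e.simulate_experiment(design, truth, seed=11)
        b = e.simulate_experiment(design, truth, seed=11)
        for sa, sb in zip(a.series, b.series):
            assert np.array_equal(sa.times, sb.times)
            assert np.array_equal(sa.masses, sb.masses)


class TestSampleTrees:
    def test_taxa_and_ultrametric(self):
        trees = e.sample_trees(10, seed=0)
        labels = {t.label for t in trees.taxon_namespace}
        assert labels == {
            "Xenopus_tropicalis",
            "Rhinella_marina",
            "Phyllobates_terribilis",
        }
        t = trees[0]
        t.calc_node_root_distances(return_leaf_distances_only=True)
        depths = [lf.root_distance for lf in t.leaf_node_iter()]
        assert max(depths) - min(depths) < 1e-3
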
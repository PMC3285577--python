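"""Generative simulator: genealogy sampling, mutation/measurement model,
cohort scenarios and the simulation studies."""

import dataclasses

import numpy as np
import pytest
from scipy.stats import kstest

import mslineage as ms
from mslineage.signature_io import compute_root_signature, read_panel, read_signature_table, write_panel, write_signature_table
from mslineage.stepwise_model import StepwiseModel, step_diff_pmf
from mslineage.synthetic_data import (
    SimScenario,
    _mouse_depths,
    default_panel,
    estimator_benchmark,
    mutate_and_measure,
    progenitor_power_study,
    scenario_cohort,
    simulate_genealogy,
)


class TestScenarioValidation:
    def test_too_many_progenitors_rejected(self):
        with pytest.raises(ValueError):
            SimScenario(n_progenitors=300, restriction_division=8)

    def test_restriction_must_precede_depth(self):
        with pytest.raises(ValueError):
            SimScenario(td=8, restriction_division=8)


class TestGenealogy:
    def test_identical_paths_have_zero_separation(self):
        gen = simulate_genealogy(SimScenario(n_cells=2, n_progenitors=1, seed=0))
        gen.cells[1].path = gen.cells[0].path
        assert gen.divergence(0, 1) == 0

    def test_progenitor_prefixes_bound_divergence_time(self):
        scn = SimScenario(n_cells=40, n_progenitors=8, seed=3)
        gen = simulate_genealogy(scn)
        tr = scn.restriction_division
        prefixes = {c.path[:tr] for c in gen.cells}
        assert len(prefixes) <= scn.n_progenitors
        # cells in different progenitor prefixes diverged before division Tr
        for i in range(5):
            for j in range(i + 1, 5):
                a, b = gen.cells[i], gen.cells[j]
                if a.path[:tr] != b.path[:tr]:
                    lcp = gen.divergence(i, j)
                    assert lcp >= 2 * (scn.td - tr)

    def test_prefix_divergences_match_explicit_tree_oracle(self):
        # explicit full binary tree at Td=10, parent-pointer LCA walk
        td = 10
        rng = np.random.default_rng(5)
        scn = SimScenario(td=td, restriction_division=4,
                          n_progenitors=2**4, n_cells=40, seed=5)
        gen = simulate_genealogy(scn, rng)
        mine = [gen.divergence(i, j) for i in range(40) for j in range(i + 1, 40)]

        def explicit_divergence(rng, n):
            # leaves are indices in [2^td, 2^(td+1)); parent = i // 2
            leaves = rng.integers(2**td, 2**(td + 1), size=n)
            out = []
            for i in range(n):
                for j in range(i + 1, n):
                    a, b = int(leaves[i]), int(leaves[j])
                    da = db = 0
                    while a != b:
                        if a >= b:
                            a //= 2
                            da += 1
                        else:
                            b //= 2
                            db += 1
                    out.append(da + db)
            return out

        oracle = explicit_divergence(np.random.default_rng(6), 40)
        assert kstest(mine, oracle).pvalue > 0.01


class TestMutateAndMeasure:
    def test_mu_zero_gives_all_zero_deviations(self):
        scn = SimScenario(mu=0.0, dropout=0.0, seed=1)
        cells = mutate_and_measure(simulate_genealogy(scn), scn)
        assert all(v == 0 for c in cells for v in c.deviations.values())

    def test_no_dropout_gives_full_allele_complement(self):
        scn = SimScenario(dropout=0.0, seed=1)
        cells = mutate_and_measure(simulate_genealogy(scn), scn)
        assert all(c.n_alleles == 2 * scn.n_loci for c in cells)

    def test_mean_mutant_fraction_matches_analytic_pmf(self):
        # P(deviation != 0 at depth Td) = 1 - P(0 | Td, mu); average over
        # independent genealogies to respect within-tree correlation
        scn = SimScenario(dropout=0.0, n_cells=5, n_progenitors=256)
        p_expected = 1.0 - step_diff_pmf(0, scn.td, scn.mu)
        means = []
        for seed in range(40):
            cfg = dataclasses.replace(scn, seed=seed)
            cells = mutate_and_measure(simulate_genealogy(cfg), cfg)
            frac = np.mean([
                sum(v != 0 for v in c.deviations.values()) / c.n_alleles
                for c in cells
            ])
            means.append(frac)
        se = np.std(means, ddof=1) / np.sqrt(len(means))
        assert abs(np.mean(means) - p_expected) <= 3 * se

    def test_pcr_repeats_share_genotype_with_independent_dropout(self):
        scn = SimScenario(pcr_repeat_pairs=2, seed=3)
        cells = mutate_and_measure(simulate_genealogy(scn), scn)
        by_id = {c.cell_id: c for c in cells}
        rep = by_id["c000_rep"]
        orig = by_id["c000"]
        assert rep.is_pcr_repeat_of == "c000"
        shared = rep.deviations.keys() & orig.deviations.keys()
        assert all(rep.deviations[k] == orig.deviations[k] for k in shared)
        assert rep.deviations.keys() != orig.deviations.keys()

    def test_gv_multiallele_flags_excluded_from_deviations(self):
        scn = SimScenario(gv_multiallele_rate=0.1, seed=4)
        cells = mutate_and_measure(simulate_genealogy(scn), scn)
        assert any(c.multiallelic_loci for c in cells)
        for c in cells:
            assert not c.multiallelic_loci & c.loci_present()

    def test_seeded_determinism_byte_identical_tables(self, tmp_path):
        scn = SimScenario(mode="renewal", ages_days=(27, 268), seed=13)
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        for p in (p1, p2):
            cohort = scenario_cohort(scn)
            cells = [c for _, cs in cohort.values() for c in cs]
            write_signature_table(cells, p)
        assert p1.read_bytes() == p2.read_bytes()


class TestCohortScenarios:
    def test_static_mode_depths_equal_td(self):
        scn = SimScenario(mode="static")
        rng = np.random.default_rng(0)
        assert _mouse_depths(scn, 100, 0, 5, rng) == [scn.td] * scn.n_cells

    def test_renewal_mode_adds_divisions_with_age(self):
        scn = SimScenario(mode="renewal", renewal_divisions_per_100d=2.0)
        rng = np.random.default_rng(0)
        young = _mouse_depths(scn, 27, 0, 2, rng)[0]
        old = _mouse_depths(scn, 268, 1, 2, rng)[0]
        assert young == round(scn.td + 2.0 * 27 / 100)
        assert old - young == pytest.approx(round(268 * 0.02) - round(27 * 0.02), abs=1)

    def test_production_line_young_mouse_samples_full_range(self):
        scn = SimScenario(mode="production_line", n_cells=400,
                          birth_depth_range=(13, 25))
        rng = np.random.default_rng(1)
        depths = _mouse_depths(scn, 12, 0, 5, rng)
        assert min(depths) == 13 and max(depths) == 25

    def test_production_line_older_mice_sample_deeper_bands(self):
        scn = SimScenario(mode="production_line", n_cells=100,
                          birth_depth_range=(13, 25))
        rng = np.random.default_rng(1)
        first = np.mean(_mouse_depths(scn, 100, 0, 4, rng))
        last = np.mean(_mouse_depths(scn, 300, 3, 4, rng))
        assert last > first

    def test_unknown_mode_is_an_error(self):
        scn = dataclasses.replace(SimScenario(), mode="warp")
        with pytest.raises(ValueError, match="warp"):
            _mouse_depths(scn, 10, 0, 1, np.random.default_rng(0))

    def test_pipeline_closure_via_tsv_roundtrip(self, tmp_path):
        # scenario tables must pass IO validation, QC and full reconstruction
        scn = SimScenario(n_cells=8, seed=30, ages_days=(27,))
        cohort = scenario_cohort(scn)
        (age, cells), = cohort.values()
        sig_path, panel_path = tmp_path / "sig.tsv", tmp_path / "panel.tsv"
        write_signature_table(cells, sig_path)
        write_panel(default_panel(scn.n_loci), panel_path)
        back = read_signature_table(sig_path, read_panel(panel_path))
        back = ms.apply_qc(back, min_alleles=25)
        assert len(back) == len(cells)
        depths = ms.estimate_depths(back, StepwiseModel())
        assert len(depths) == len(cells)
        assert all(d >= 0 for d in depths.values())


class TestSimulationStudies:
    def test_mu_zero_corner_bias_is_minus_td(self):
        table = estimator_benchmark(td_values=(25,), n_iter=3,
                                    scn=SimScenario(mu=0.0), seed=1)
        assert (table["mean_estimate"] == 0).all()
        assert (table["bias"] == -25).all()

    def test_tree_ml_less_biased_than_squared_distance_on_clean_data(self):
        table = estimator_benchmark(td_values=(25,), n_iter=15, seed=2)
        bias = dict(zip(table["estimator"], table["bias"].abs()))
        assert bias["tree_ml"] <= bias["squared_distance"]

    def test_more_iterations_shrink_sem(self):
        t_small = estimator_benchmark(td_values=(25,), n_iter=8, seed=5)
        t_big = estimator_benchmark(td_values=(25,), n_iter=32, seed=5)
        sem_small = t_small.loc[t_small.estimator == "tree_ml", "sem"].iloc[0]
        sem_big = t_big.loc[t_big.estimator == "tree_ml", "sem"].iloc[0]
        # 4x iterations should halve the SEM, within 30%
        assert sem_big <= sem_small * 0.5 * 1.3 + 1e-9

    def test_single_progenitor_always_detected(self):
        table = progenitor_power_study(np_grid=(1,), n_trees=10, seed=7)
        assert table["detection_fraction"].iloc[0] == 1.0

    def test_many_progenitors_rarely_detected(self):
        table = progenitor_power_study(np_grid=(30,), n_trees=10, seed=7)
        assert table["detection_fraction"].iloc[0] < 0.5
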
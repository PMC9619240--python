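import math

import pytest

from tadfscreen.evolve import (
    EvolutionConfig,
    _converged,
    accumulate_optimal,
    energy_sieve,
    material_abundance,
    run_evolution,
    select_random_training,
    select_top_fraction,
    trajectory_frame,
)
from tadfscreen.fragments import ConfigError, Library
from tadfscreen.mutate import MutationSpec
from tadfscreen.oracle import CompletenessError, PropertyResult, ResultStatus

from conftest import small_config


class TestSelectRandomTraining:
    def test_ten_percent_of_thousand_is_hundred(self):
        lib = Library.from_smiles([f"{'C' * k}c1ccccc1" for k in range(12)])
        # arithmetic check on the real floor-with-minimum rule
        assert len(select_random_training(lib, 0.10, seed=0)) == 1
        assert len(select_random_training(lib, 0.5, seed=0)) == 6
        assert max(1, math.floor(0.10 * 1000)) == 100

    def test_minimum_of_one(self):
        lib = Library.from_smiles(["c1ccccc1", "c1ccncc1", "Cc1ccccc1", "Fc1ccccc1", "COc1ccccc1"])
        assert len(select_random_training(lib, 0.10, seed=1)) == 1

    def test_seeded_and_without_replacement(self):
        lib = Library.from_smiles([f"{'C' * k}c1ccccc1" for k in range(10)])
        a = select_random_training(lib, 0.5, seed=9)
        b = select_random_training(lib, 0.5, seed=9)
        assert a == b
        assert len(set(a)) == len(a)

    def test_empty_library_rejected(self):
        with pytest.raises(ConfigError):
            select_random_training(Library(), 0.1, seed=0)


class TestSelectTopFraction:
    def test_smallest_gap_wins(self):
        preds = {f"m{i}": 0.1 * (i + 1) for i in range(10)}
        assert select_top_fraction(preds, 0.10) == ["m0"]

    def test_ties_break_lexicographically(self):
        preds = {"b": 0.5, "a": 0.5, "c": 0.5}
        assert select_top_fraction(preds, 0.34) == ["a"]

    def test_selection_arithmetic_at_scale(self):
        preds = {f"m{i:04d}": i / 1000 for i in range(1000)}
        assert len(select_top_fraction(preds, 0.10)) == 100

    def test_order_independent(self):
        preds = {"x": 0.3, "y": 0.1, "z": 0.2}
        reversed_preds = dict(reversed(list(preds.items())))
        assert select_top_fraction(preds, 0.67) == select_top_fraction(reversed_preds, 0.67)


class TestMaterialAbundance:
    def test_ten_in_a_thousand(self):
        gaps = [0.05] * 10 + [0.5] * 990
        assert material_abundance(gaps, 0.15) == pytest.approx(0.010)

    def test_extremes(self):
        assert material_abundance([0.5, 0.9], 0.15) == 0.0
        assert material_abundance([0.01, 0.02], 0.15) == 1.0

    def test_threshold_is_strict(self):
        assert material_abundance([0.15], 0.15) == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ConfigError):
            material_abundance([], 0.15)


class TestEnergySieve:
    @pytest.mark.parametrize(
        "e,color",
        [(3.00, "blue"), (2.65, "green"), (2.00, "red"), (2.80, "green"), (2.50, "green")],
    )
    def test_color_assignment(self, e, color):
        assert energy_sieve({"m": e})["m"] == color

    def test_partition_is_total(self):
        values = {f"m{i}": 1.5 + i * 0.05 for i in range(60)}
        colors = energy_sieve(values)
        assert set(colors) == set(values)
        assert set(colors.values()) <= {"blue", "green", "red"}

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            energy_sieve({"m": float("nan")})


class TestAccumulateOptimal:
    def test_first_generation_counts(self):
        gaps = {f"m{i}": 0.05 if i < 10 else 0.5 for i in range(1000)}
        acc = accumulate_optimal(set(), gaps, 0.15)
        assert len(acc) == 10

    def test_union_semantics(self):
        acc = accumulate_optimal(set(), {f"a{i}": 0.01 for i in range(10)}, 0.15)
        acc = accumulate_optimal(acc, {f"a{i}": 0.01 for i in range(10)}, 0.15)
        assert len(acc) == 10
        acc = accumulate_optimal(acc, {f"b{i}": 0.01 for i in range(73)}, 0.15)
        assert len(acc) == 83


class TestConfig:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"train_fraction": 1.5},
            {"select_fraction": 0.0},
            {"library_cap": 0},
            {"optimal_gap_threshold": -0.1},
            {"sieve_blue_min": 2.0, "sieve_red_max": 2.5},
            {"criterion_logic": "majority"},
            {"target_abundance": 1.2},
        ],
    )
    def test_invalid_values_rejected(self, kwargs):
        config = EvolutionConfig(**kwargs)
        with pytest.raises(ConfigError):
            config.validate()

    def test_defaults_are_valid(self):
        EvolutionConfig().validate()


class TestConvergence:
    def test_no_targets_never_converges_early(self):
        assert not _converged(EvolutionConfig(), n_acc=10**6, omega=1.0)

    def test_any_logic(self):
        config = EvolutionConfig(target_n_acc=100, target_abundance=0.9)
        assert _converged(config, n_acc=100, omega=0.1)
        assert _converged(config, n_acc=0, omega=0.95)

    def test_all_logic(self):
        config = EvolutionConfig(target_n_acc=100, target_abundance=0.9, criterion_logic="all")
        assert not _converged(config, n_acc=100, omega=0.1)
        assert _converged(config, n_acc=100, omega=0.95)


class TestRunEvolution:
    def test_report_count_and_generation_indexing(self, small_evolution):
        reports = small_evolution.reports
        assert len(reports) == small_config().max_generations + 1
        assert [r.n_g for r in reports] == list(range(len(reports)))

    def test_accumulated_counts_monotone(self, small_evolution):
        counts = [r.n_acc_opt_mols for r in small_evolution.reports]
        assert counts == sorted(counts)

    def test_sieve_partitions_every_generation(self, small_evolution):
        for r in small_evolution.reports:
            assert r.sieve_blue + r.sieve_green + r.sieve_red == r.n_tot

    def test_parents_carried_into_next_generation(self, small_evolution):
        libs = small_evolution.libraries
        for earlier, later in zip(libs, libs[1:]):
            survivors = set(earlier.smiles()) & set(later.smiles())
            assert len(survivors) >= 1  # selected parents persist

    def test_mspr_reported_from_first_mutation_generation(self, small_evolution):
        assert small_evolution.reports[0].delta_mspr is None
        for r in small_evolution.reports[1:]:
            assert 0.0 <= r.delta_mspr <= 1.0
            assert r.n_inter >= 0

    def test_bit_reproducible(self, small_evolution, small_fragments):
        rerun = run_evolution(small_config(), small_fragments)
        first = trajectory_frame(small_evolution.reports).to_csv(index=False)
        second = trajectory_frame(rerun.reports).to_csv(index=False)
        assert first == second
        assert small_evolution.accumulated == rerun.accumulated

    def test_completeness_failure_reports_generation(self, small_fragments):
        def broken_engine(smiles):
            from tadfscreen.chem import canonicalize

            return PropertyResult(canonicalize(smiles), None, None, ResultStatus.GEOMETRY_FAILED)

        with pytest.raises(CompletenessError, match="generation 0"):
            run_evolution(small_config(), small_fragments, engine=broken_engine)

    def test_invalid_config_rejected_before_work(self, small_fragments):
        config = small_config()
        config.train_fraction = 2.0
        with pytest.raises(ConfigError):
            run_evolution(config, small_fragments)
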
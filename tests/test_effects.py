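"""Percent-difference statistics and the permutation screen."""

import itertools
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from biochar_cba.effects import (
    average_percent_diff,
    build_effect_table,
    cumulative_percent_diff,
    percent_diff_per_harvest,
    permutation_factorial_test,
)
from biochar_cba.trial import TrialDesign, generate_trial

from conftest import make_noiseless_model, records_from_means


class TestPercentDiff:
    def test_hand_computed_single_harvest(self):
        """Control mean 2.0 g, treatment mean 2.5 g -> +25.0."""
        df = records_from_means({
            "control": [[1.5, 2.5]],     # mean 2.0
            "B": [[2.0, 3.0]],           # mean 2.5
        })
        assert percent_diff_per_harvest(df, "B", "dry").tolist() == [25.0]

    def test_hand_computed_cumulative(self):
        """Harvest means C=(1,1), T=(1.5,1.1): 100 x (2.6-2)/2 = +30.0."""
        df = records_from_means({
            "control": [[0.5, 1.5], [1.0, 1.0]],
            "B": [[1.5, 1.5], [1.0, 1.2]],
        })
        assert cumulative_percent_diff(df, "B", "dry") == pytest.approx(30.0)

    def test_spreadsheet_oracle_three_by_three(self):
        """<=3 subjects per arm, <=3 harvests: exact match to hand values."""
        df = records_from_means({
            "control": [[2.0, 3.0, 4.0], [5.0, 5.0, 5.0], [1.0, 2.0, 3.0]],
            "F": [[3.0, 3.0, 3.0], [6.0, 7.0, 8.0], [2.0, 2.0, 2.0]],
        })
        # harvest means: C = 3, 5, 2; F = 3, 7, 2
        per = percent_diff_per_harvest(df, "F", "dry")
        assert per.tolist() == pytest.approx([0.0, 40.0, 0.0])
        assert average_percent_diff(df, "F", "dry") == pytest.approx(40.0 / 3)
        assert cumulative_percent_diff(df, "F", "dry") == pytest.approx(20.0)

    def test_single_harvest_cumulative_reduces_to_per_harvest(self):
        df = records_from_means({"control": [[2.0, 2.0]], "B": [[2.4, 2.6]]})
        per = percent_diff_per_harvest(df, "B", "dry")
        assert cumulative_percent_diff(df, "B", "dry") == pytest.approx(per.iloc[0])

    def test_missing_control_is_reference_error(self):
        df = records_from_means({"B": [[1.0, 2.0]]})
        with pytest.raises(ValueError, match="control"):
            percent_diff_per_harvest(df, "B", "dry")

    def test_empty_harvest_cell_rejected(self):
        df = records_from_means({
            "control": [[1.0, 1.0], [1.0, 1.0]],
            "B": [[1.0, 1.0], [1.0, 1.0]],
        })
        df = df[~((df["biochar"] == 1) & (df["harvest_index"] == 2))]
        with pytest.raises(ValueError, match="empty harvest"):
            cumulative_percent_diff(df, "B", "dry")

    @given(scale=st.floats(0.01, 1e4))
    @settings(max_examples=30, deadline=None)
    def test_scale_invariance(self, scale):
        """Multiplying every biomass by a constant changes no percent diff."""
        df = records_from_means({
            "control": [[2.0, 3.0], [4.0, 5.0]],
            "B": [[3.0, 3.5], [4.5, 6.0]],
        })
        scaled = df.assign(dry_g=df["dry_g"] * scale, fresh_g=df["fresh_g"] * scale)
        for matter in ("dry", "fresh"):
            np.testing.assert_allclose(
                percent_diff_per_harvest(scaled, "B", matter),
                percent_diff_per_harvest(df, "B", matter),
            )
            assert cumulative_percent_diff(scaled, "B", matter) == pytest.approx(
                cumulative_percent_diff(df, "B", matter)
            )


class TestEffectTable:
    def test_zero_noise_no_effect_table_is_zeros(self, pot_brachiaria):
        df = generate_trial(pot_brachiaria, make_noiseless_model(pot_brachiaria, {}))
        table = build_effect_table(df, "dry")
        assert np.allclose(table.to_frame().to_numpy(), 0.0)

    def test_structure_mirrors_design(self, default_pot_records):
        """One column per non-control treatment; harvests + 2 summary rows."""
        table = build_effect_table(default_pot_records, "dry")
        assert len(table.treatments) == 7  # 2^3 - control
        assert "control" not in table.treatments
        frame = table.to_frame()
        assert list(frame.index[-2:]) == ["average", "cumulative"]
        assert frame.shape == (8, 7)

    def test_average_row_is_mean_of_harvest_rows(self, default_pot_records):
        table = build_effect_table(default_pot_records, "dry")
        np.testing.assert_allclose(
            table.average.to_numpy(), table.per_harvest.mean(axis=0).to_numpy()
        )

    def test_csv_round_trip(self, tmp_path, default_pot_records):
        table = build_effect_table(default_pot_records, "fresh")
        path = tmp_path / "effects.csv"
        table.to_csv(path)
        back = pd.read_csv(path, index_col="harvest")
        np.testing.assert_allclose(back.to_numpy(), table.to_frame().to_numpy())


def _null_records(seed, replicates=5):
    design = TrialDesign(grass="brachiaria", factors=("biochar",),
                         replicates=replicates,
                         harvest_days=(68, 139, 207, 269, 361, 454))
    model = replace(make_noiseless_model(design, {}, seed=seed),
                    subject_sd=0.1, residual_sd=0.15)
    return generate_trial(design, model)


class TestPermutationTest:
    def test_p_value_floor(self):
        res = permutation_factorial_test(_null_records(0), "biochar",
                                         n_permutations=99, seed=1)
        assert res.p_value >= 1.0 / 100

    def test_all_tied_totals_give_p_one(self, pot_brachiaria):
        """Identical subject totals: every permuted stat ties the observed
        one, so the counting formula (1 + n)/(n + 1) returns exactly 1."""
        df = generate_trial(pot_brachiaria, make_noiseless_model(pot_brachiaria, {}))
        res = permutation_factorial_test(df, "biochar", n_permutations=199, seed=0)
        assert res.p_value == 1.0

    def test_strong_separation_hits_near_minimum_p(self, pot_brachiaria):
        """Multiplier 1.5 and negligible noise: p at/near 1/(n+1)."""
        model = replace(make_noiseless_model(pot_brachiaria, {"B": 1.5}),
                        residual_sd=1e-6)
        df = generate_trial(pot_brachiaria, model)
        sub = df[(df["fertilizer"] == 0) & (df["inoculant"] == 0)]
        res = permutation_factorial_test(sub, "biochar", n_permutations=999, seed=2)
        # complete separation of 5 vs 5 distinct totals: exact p = 2/252
        assert res.p_value < 0.05

    def test_monte_carlo_matches_exhaustive_enumeration(self):
        """Independent oracle: enumerate all label assignments of 4 vs 4
        subjects and compare the exact permutation p with the MC estimate."""
        rng = np.random.default_rng(11)
        totals = rng.normal(10.0, 2.0, size=8)
        on = np.array([True] * 4 + [False] * 4)
        obs = abs(totals[on].mean() - totals[~on].mean())
        stats = [
            abs(totals[list(idx)].mean()
                - np.delete(totals, list(idx)).mean())
            for idx in itertools.combinations(range(8), 4)
        ]
        exact_p = np.mean([s >= obs - 1e-12 for s in stats])

        df = records_from_means({
            "control": [[t for t, o in zip(totals, on) if not o]],
            "B": [[t for t, o in zip(totals, on) if o]],
        })
        res = permutation_factorial_test(df, "biochar", n_permutations=4999, seed=3)
        mc_se = np.sqrt(exact_p * (1 - exact_p) / 4999)
        assert abs(res.p_value - exact_p) < 4 * mc_se + 1e-3

    def test_interaction_contrast_detects_pure_interaction(self):
        """Cell means with m11 - m10 - m01 + m00 != 0 but null margins."""
        df = records_from_means({
            "control": [[10.0, 10.1, 9.9]],
            "B": [[12.0, 12.1, 11.9]],
            "F": [[12.0, 11.9, 12.1]],
            "B+F": [[10.0, 9.9, 10.1]],
        })
        res = permutation_factorial_test(df, "biochar:fertilizer",
                                         n_permutations=999, seed=4)
        assert res.observed == pytest.approx(4.0, abs=0.2)
        assert res.p_value < 0.05

    def test_unknown_factor_rejected(self):
        with pytest.raises(ValueError, match="unknown factor"):
            permutation_factorial_test(_null_records(1), "lime")

    def test_too_few_subjects_per_level_rejected(self):
        df = records_from_means({"control": [[1.0, 2.0, 3.0]], "B": [[1.5]]})
        with pytest.raises(ValueError, match="fewer than 2"):
            permutation_factorial_test(df, "biochar")

    def test_too_few_permutations_rejected(self):
        with pytest.raises(ValueError, match="99"):
            permutation_factorial_test(_null_records(2), "biochar",
                                       n_permutations=50)
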
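"""Statistics layer: medians, Mann-Whitney, slopes, bootstrap, interaction."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import scfskit as sk
from scfskit.stats import (
    AdhesionDataset,
    average_slope,
    bootstrap_resample,
    discrete_slope,
    holm_adjust,
    interaction_epsilon,
    interaction_test,
    mann_whitney_medians,
    median_forces,
    significance_stars,
    slope_difference_test,
)
from scfskit.synthetic import additive_config, simulate_adhesion_table

finite = st.floats(-1e-6, 1e-6, allow_nan=False)


def tiny_dataset(forces_by_time, condition="c", cell_prefix="cell"):
    records = []
    times = sorted(forces_by_time)
    n = len(forces_by_time[times[0]])
    for i in range(n):
        for t in times:
            records.append((f"{cell_prefix}{i}", condition, float(t),
                            forces_by_time[t][i]))
    return AdhesionDataset.from_records(records)


class TestMedians:
    def test_odd_and_even_n(self):
        ds = tiny_dataset({5.0: [1e-9, 2e-9, 3e-9]})
        assert median_forces(ds, "c")[5.0] == 2e-9
        ds4 = tiny_dataset({5.0: [1e-9, 2e-9, 3e-9, 4e-9]})
        assert median_forces(ds4, "c")[5.0] == 2.5e-9

    def test_unknown_condition(self):
        ds = tiny_dataset({5.0: [1e-9]})
        with pytest.raises(KeyError):
            median_forces(ds, "nope")

    def test_simulator_medians_monotone(self):
        config = additive_config(seed=3, n_cells=10)
        table = simulate_adhesion_table(config)
        ds = AdhesionDataset(table)
        med = median_forces(ds, "AB")
        values = [med[t] for t in sorted(med)]
        assert np.all(np.diff(values) > 0)


def exact_mw_p(a, b):
    """Brute-force two-sided Mann-Whitney p by enumerating rank assignments."""
    a, b = list(a), list(b)
    n, m = len(a), len(b)
    pooled = sorted(a + b)
    u_obs = sum(x > y for x in a for y in b)
    us = []
    for positions in itertools.combinations(range(n + m), n):
        xs = [pooled[i] for i in positions]
        ys = [pooled[i] for i in range(n + m) if i not in positions]
        us.append(sum(x > y for x in xs for y in ys))
    us = np.array(us)
    p = 2.0 * min(np.mean(us <= u_obs), np.mean(us >= u_obs))
    return u_obs, min(1.0, p)


class TestMannWhitney:
    @pytest.mark.parametrize("a, b", [
        ([1.0, 2.0, 3.0], [10.0, 11.0, 12.0]),
        ([1.0, 5.0, 9.0], [2.0, 3.0, 4.0]),
        ([0.2, 0.7, 1.4, 2.2], [0.5, 0.9, 1.1]),
    ])
    def test_small_sample_exact_matches_enumeration(self, a, b):
        u, p = mann_whitney_medians(a, b)
        u_oracle, p_oracle = exact_mw_p(a, b)
        assert u == u_oracle
        assert p == pytest.approx(p_oracle, abs=1e-12)

    def test_separated_samples_give_p_point_one(self):
        u, p = mann_whitney_medians([1, 2, 3], [10, 11, 12])
        assert u == 0.0
        assert p == pytest.approx(0.1, abs=1e-12)

    def test_identical_samples_not_significant(self):
        _, p = mann_whitney_medians([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p >= 0.99

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_medians([], [1.0])

    def test_type_one_error_rate(self):
        rng = np.random.default_rng(99)
        rejections = 0
        reps = 500
        for _ in range(reps):
            a = rng.lognormal(0.0, 0.4, 10)
            b = rng.lognormal(0.0, 0.4, 10)
            _, p = mann_whitney_medians(a, b)
            rejections += p < 0.05
        assert 0.03 <= rejections / reps <= 0.08


class TestSlopes:
    def test_hand_arithmetic(self):
        assert discrete_slope(1e-9, 2.5e-9, 5.0, 20.0) == pytest.approx(1e-10)
        assert discrete_slope(1e-9, 1e-9, 5.0, 20.0) == 0.0

    @given(F1=finite, F2=finite, t1=st.floats(0, 100), t2=st.floats(101, 200))
    def test_antisymmetric_in_forces(self, F1, F2, t1, t2):
        assert discrete_slope(F1, F2, t1, t2) == -discrete_slope(
            F2, F1, t1, t2)

    def test_equal_times_rejected(self):
        with pytest.raises(ValueError):
            discrete_slope(1.0, 2.0, 5.0, 5.0)

    def test_average_slope_hand_value(self):
        medians = {5: 1e-9, 20: 2.5e-9, 50: 4e-9, 120: 6e-9}
        expected = np.mean([1e-10, 0.05e-9, (2e-9 / 70.0)])
        assert average_slope(medians) == pytest.approx(expected, rel=1e-12)

    def test_constant_medians_zero_slope(self):
        assert average_slope({5: 2e-9, 20: 2e-9, 120: 2e-9}) == 0.0

    @given(c=st.floats(-1e-11, 1e-11),
           grid=st.lists(st.floats(1.0, 500.0), min_size=2, max_size=6,
                         unique=True))
    def test_linear_profile_recovers_rate(self, c, grid):
        medians = {t: c * t for t in grid}
        assert average_slope(medians) == pytest.approx(c, rel=1e-9,
                                                       abs=1e-26)

    def test_single_time_point_rejected(self):
        with pytest.raises(ValueError, match="slope undefined"):
            average_slope({5: 1e-9})


class _IdentityRng:
    """Degenerate generator: resample indices 0..size-1 (identity)."""

    def integers(self, low, high, size):
        return np.arange(size)


class TestBootstrapResample:
    def make_ds(self, n=10):
        rng = np.random.default_rng(7)
        data = {5.0: rng.uniform(0, 2e-9, n), 20.0: rng.uniform(0, 2e-9, n)}
        return tiny_dataset(data)

    def test_identity_resample_returns_original(self):
        ds = self.make_ds()
        out = bootstrap_resample(ds, "c", 10, _IdentityRng())
        left = ds.df.sort_values(["cell_id", "contact_time_s"]).reset_index(
            drop=True)
        right = out.df[list(ds.df.columns)].sort_values(
            ["cell_id", "contact_time_s"]).reset_index(drop=True)
        pd.testing.assert_frame_equal(left, right)

    def test_containment_and_size(self, rng):
        ds = self.make_ds()
        out = bootstrap_resample(ds, "c", 6, rng)
        assert out.df["replicate"].nunique() == 6
        assert set(out.df["cell_id"]) <= set(ds.df["cell_id"])
        # whole cells: every drawn replicate covers the full time grid
        per_rep = out.df.groupby("replicate")["contact_time_s"].nunique()
        assert (per_rep == 2).all()

    def test_multinomial_frequencies(self, rng):
        ds = self.make_ds(n=10)
        counts = {f"cell{i}": 0 for i in range(10)}
        reps, size = 1000, 10
        for _ in range(reps):
            out = bootstrap_resample(ds, "c", size, rng)
            for cell in out.df[out.df["contact_time_s"] == 5.0]["cell_id"]:
                counts[cell] += 1
        total = reps * size
        p = 1.0 / 10
        band = 3 * math.sqrt(p * (1 - p) * total)
        for cell, count in counts.items():
            assert abs(count - total * p) < band

    def test_absent_condition_rejected(self, rng):
        with pytest.raises(KeyError):
            bootstrap_resample(self.make_ds(), "nope", 5, rng)


class TestSlopeDifferenceTest:
    def test_self_comparison_is_null(self, study_dataset):
        result = slope_difference_test(
            study_dataset, study_dataset, condition_a="pKO-b1",
            condition_b="pKO-b1", seed=5)
        assert result.p_value >= 0.99
        assert result.stars == "NS"

    def test_strong_difference_detected(self, study_dataset):
        result = slope_difference_test(
            study_dataset, study_dataset, condition_a="pKO-b1",
            condition_b="pKO-aV", seed=5)
        assert result.p_value < 0.05
        assert (result.slope_obs["pKO-b1"] > result.slope_obs["pKO-aV"])

    def test_deterministic_under_seed(self, study_dataset):
        kwargs = dict(condition_a="pKO-b1", condition_b="pKO-aV", seed=42)
        r1 = slope_difference_test(study_dataset, study_dataset, **kwargs)
        r2 = slope_difference_test(study_dataset, study_dataset, **kwargs)
        assert r1.p_value == r2.p_value
        for key in r1.boot_slopes:
            assert np.array_equal(r1.boot_slopes[key], r2.boot_slopes[key])

    def test_record_order_invariance(self, study_dataset):
        shuffled = AdhesionDataset(
            study_dataset.df.sample(frac=1.0, random_state=1))
        kwargs = dict(condition_a="pKO-b1", condition_b="pKO-aV", seed=42)
        p1 = slope_difference_test(study_dataset, study_dataset,
                                   **kwargs).p_value
        p2 = slope_difference_test(shuffled, shuffled, **kwargs).p_value
        assert p1 == p2

    def test_degenerate_inputs_rejected(self, study_dataset):
        with pytest.raises(ValueError):
            slope_difference_test(study_dataset, study_dataset,
                                  condition_a="pKO-b1", condition_b="pKO-aV",
                                  B=1)
        single_time = AdhesionDataset(
            study_dataset.df[study_dataset.df["contact_time_s"] == 5.0])
        with pytest.raises(ValueError):
            slope_difference_test(single_time, single_time,
                                  condition_a="pKO-b1", condition_b="pKO-aV")

    def test_wilcoxon_method_runs(self, study_dataset):
        result = slope_difference_test(
            study_dataset, study_dataset, condition_a="pKO-b1",
            condition_b="pKO-aV", seed=5, method="wilcoxon")
        assert 0.0 <= result.p_value <= 1.0


class TestInteractionEpsilon:
    def test_hand_arithmetic(self):
        eps = interaction_epsilon(2e-9, 0.2e-9, 1.5e-9, 1.8e-9)
        assert eps == pytest.approx(-1.1e-9, rel=1e-12)

    @given(fa=finite, fb=finite, f0=finite)
    def test_additive_null_gives_zero(self, fa, fb, f0):
        assert interaction_epsilon(fa + fb - f0, f0, fa, fb) == pytest.approx(
            0.0, abs=1e-18)

    @given(fab=finite, f0=finite, fa=finite, fb=finite)
    def test_symmetric_in_a_and_b(self, fab, f0, fa, fb):
        assert interaction_epsilon(fab, f0, fa, fb) == pytest.approx(
            interaction_epsilon(fab, f0, fb, fa), rel=1e-9, abs=1e-20)


class TestInteractionTest:
    ROLES = ["pKO-aV-b1", "pKO-aV", "pKO-b1", "pKO"]

    def test_competition_pattern_detected(self, study_dataset):
        result = interaction_test(study_dataset, self.ROLES, seed=4)
        j120 = int(np.argmax(result.contact_times))
        assert result.contact_times[j120] == 120.0
        assert result.sign[j120] == "negative"
        assert result.epsilon_obs[j120] < 0

    def test_sign_consistent_with_p_and_alpha(self, study_dataset):
        result = interaction_test(study_dataset, self.ROLES, seed=4)
        for j, sign in enumerate(result.sign):
            if result.p_per_time[j] >= result.alpha:
                assert sign == "none"
            else:
                med = np.median(result.boot_epsilon[:, j])
                assert sign == ("positive" if med > 0 else "negative")

    def test_missing_condition_named_in_error(self, study_dataset):
        with pytest.raises(ValueError, match="ghost"):
            interaction_test(study_dataset,
                             ["pKO-aV-b1", "ghost", "pKO-b1", "pKO"])

    def test_minimum_bootstrap_enforced(self, study_dataset):
        with pytest.raises(ValueError, match=">= 10"):
            interaction_test(study_dataset, self.ROLES, B=1)

    def test_deterministic_and_order_invariant(self, study_dataset):
        r1 = interaction_test(study_dataset, self.ROLES, seed=8)
        shuffled = AdhesionDataset(
            study_dataset.df.sample(frac=1.0, random_state=2))
        r2 = interaction_test(shuffled, self.ROLES, seed=8)
        assert np.array_equal(r1.p_per_time, r2.p_per_time)
        assert np.array_equal(r1.epsilon_obs, r2.epsilon_obs)

    def test_wilcoxon_method_runs(self, study_dataset):
        result = interaction_test(study_dataset, self.ROLES, seed=4,
                                  method="wilcoxon")
        assert np.all((result.p_per_time >= 0) & (result.p_per_time <= 1))

    def test_wilcoxon_on_bootstrap_is_anticonservative(self):
        """Applying a signed-rank test to the bootstrap replicates treats
        their spread as if it were replication of independent experiments;
        under a true additive null it rejects far more often than the
        percentile test, which stays near the nominal level."""
        reps = 40
        rej_wilcoxon = rej_percentile = 0
        for rep in range(reps):
            ds = AdhesionDataset(
                simulate_adhesion_table(additive_config(seed=500 + rep)))
            for method, counter in (("wilcoxon", "w"), ("percentile", "p")):
                result = interaction_test(ds, ["AB", "A", "B", "0"],
                                          B=100, seed=rep, method=method)
                hit = int(np.any(result.p_per_time < 0.05))
                if counter == "w":
                    rej_wilcoxon += hit
                else:
                    rej_percentile += hit
        assert rej_wilcoxon / reps > 0.5
        assert rej_wilcoxon > 2 * rej_percentile


class TestReportingHelpers:
    @pytest.mark.parametrize("p, stars", [
        (0.00005, "****"), (0.0005, "***"), (0.005, "**"), (0.02, "*"),
        (0.05, "NS"), (0.9, "NS"),
    ])
    def test_star_convention(self, p, stars):
        assert significance_stars(p) == stars

    def test_holm_adjustment_known_example(self):
        adjusted = holm_adjust([0.01, 0.04, 0.03, 0.005])
        assert adjusted == pytest.approx([0.03, 0.06, 0.06, 0.02])
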
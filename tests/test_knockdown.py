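"""2^-ddCt quantification, ANOVA/Tukey, densitometry ratios."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as scipy_stats

from nhejscope import (
    ddct_fold,
    densitometry_ratio,
    one_way_anova,
    simulate_ct_table,
    simulate_densitometry,
    tukey_hsd,
)
from nhejscope.errors import StatisticsError, TableError


def _ct_table(rows):
    return pd.DataFrame(rows, columns=["group", "sample", "gene_role", "replicate", "ct"])


def _flat_table(groups: dict, ref_ct=18.0, target_base=24.0):
    """Noise-free table: group -> ddCt shift of the target gene."""
    rows = []
    for g, shift in groups.items():
        for rep in (1, 2):
            rows.append((g, f"{g}_s1", "target", rep, target_base + shift))
            rows.append((g, f"{g}_s1", "reference", rep, ref_ct))
    return _ct_table(rows)


class TestDdctFold:
    def test_equal_dct_gives_fold_one(self):
        res = ddct_fold(_flat_table({"control": 0.0, "treated": 0.0}), "control")
        treated = next(r for r in res if r.group == "treated")
        assert treated.fold == pytest.approx(1.0)
        assert treated.percent_reduction == pytest.approx(0.0)

    def test_two_cycle_shift_is_fourfold_down(self):
        res = ddct_fold(_flat_table({"control": 0.0, "treated": 2.0}), "control")
        treated = next(r for r in res if r.group == "treated")
        assert treated.delta_delta_ct == pytest.approx(2.0)
        assert treated.fold == pytest.approx(0.25)
        assert treated.percent_reduction == pytest.approx(75.0)

    def test_fold_021_is_79_percent_reduction(self):
        shift = -math.log2(0.21)
        res = ddct_fold(_flat_table({"control": 0.0, "g1": shift}), "control")
        g1 = next(r for r in res if r.group == "g1")
        assert g1.fold == pytest.approx(0.21)
        assert g1.percent_reduction == pytest.approx(79.0)

    def test_control_is_exactly_one(self):
        res = ddct_fold(_flat_table({"control": 0.0, "t": 1.3}), "control")
        control = next(r for r in res if r.group == "control")
        assert control.delta_delta_ct == 0.0
        assert control.fold == 1.0

    def test_fold_strictly_decreasing_in_ddct(self):
        shifts = [0.5, 1.0, 2.5, 4.0]
        res = ddct_fold(
            _flat_table({"control": 0.0, **{f"g{i}": s for i, s in enumerate(shifts)}}),
            "control",
        )
        folds = [r.fold for r in res if r.group != "control"]
        assert all(a > b for a, b in zip(folds, folds[1:]))

    def test_missing_reference_rows_named(self):
        rows = [
            ("control", "s1", "target", 1, 24.0),
            ("control", "s1", "reference", 1, 18.0),
            ("t", "s9", "target", 1, 24.0),
        ]
        with pytest.raises(TableError, match="s9"):
            ddct_fold(_ct_table(rows), "control")

    def test_unknown_control_rejected(self):
        with pytest.raises(TableError):
            ddct_fold(_flat_table({"control": 0.0}), "mock")

    def test_per_replicate_pairing_matches_means_when_balanced(self):
        table, _ = simulate_ct_table({"t": 0.4}, noise_sd=0.05, n_reps=3, seed=4)
        a = ddct_fold(table, "control")
        b = ddct_fold(table, "control", per_replicate_pairing=True)
        for x, y in zip(a, b):
            assert x.delta_ct == pytest.approx(y.delta_ct)

    def test_noise_free_simulation_roundtrip(self):
        table, truth = simulate_ct_table({"g1": 0.25, "g2": 0.42}, noise_sd=0.0, seed=1)
        res = {r.group: r.fold for r in ddct_fold(table, "control")}
        for g, f in truth.items():
            assert res[g] == pytest.approx(f)

    def test_light_noise_recovery(self):
        """Mean recovered fold over 50 simulated tables stays near truth."""
        folds = []
        for seed in range(50):
            table, _ = simulate_ct_table({"g1": 0.21}, noise_sd=0.1, seed=seed)
            folds.append(next(r.fold for r in ddct_fold(table, "control") if r.group == "g1"))
        assert np.mean(folds) == pytest.approx(0.21, abs=0.03)


class TestAnova:
    def test_hand_computed_sums_of_squares(self):
        """{1,2,3},{2,3,4},{3,4,5}: SSB = 6, SSW = 6, F = (6/2)/(6/6) = 3."""
        res = one_way_anova([[1, 2, 3], [2, 3, 4], [3, 4, 5]])
        assert res.f == pytest.approx(3.0)
        assert (res.df_between, res.df_within) == (2, 6)
        assert res.p == pytest.approx(float(scipy_stats.f.sf(3.0, 2, 6)))

    def test_agrees_with_scipy_f_oneway(self, rng):
        groups = [list(rng.normal(m, 1.0, 5)) for m in (0.0, 0.5, 2.0)]
        res = one_way_anova(groups)
        ref = scipy_stats.f_oneway(*groups)
        assert res.f == pytest.approx(float(ref.statistic))
        assert res.p == pytest.approx(float(ref.pvalue))

    def test_three_groups_of_three_df_structure(self):
        res = one_way_anova([[1.0, 1.1, 0.9], [0.2, 0.25, 0.22], [0.4, 0.41, 0.44]])
        assert (res.df_between, res.df_within) == (2, 6)

    def test_identical_means_f_zero(self):
        res = one_way_anova([[1, 2, 3], [3, 1, 2], [2, 3, 1]])
        assert res.f == pytest.approx(0.0)

    def test_degenerate_input_rejected(self):
        with pytest.raises(StatisticsError):
            one_way_anova([[1.0, 1.0], [1.0, 1.0]])
        with pytest.raises(StatisticsError):
            one_way_anova([[1.0], [2.0, 3.0]])

    def test_location_and_scale_invariance(self, rng):
        groups = [list(rng.normal(m, 1.0, 4)) for m in (0, 1, 3)]
        f0 = one_way_anova(groups).f
        shifted = [[v + 100.0 for v in g] for g in groups]
        scaled = [[v * 7.0 for v in g] for g in groups]
        assert one_way_anova(shifted).f == pytest.approx(f0)
        assert one_way_anova(scaled).f == pytest.approx(f0)


class TestTukey:
    def test_identical_groups_p_near_one(self):
        pairs = tukey_hsd([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0], [5.0, 6.0, 7.0]],
                          ["a", "b", "c"])
        ab = next(p for p in pairs if {p.group_i, p.group_j} == {"a", "b"})
        assert ab.p_adj > 0.95

    def test_separated_groups_all_significant(self, rng):
        groups = [list(rng.normal(m, 0.1, 3)) for m in (0.0, 5.0, 10.0)]
        pairs = tukey_hsd(groups)
        assert len(pairs) == 3
        assert all(p.p_adj < 0.05 for p in pairs)

    def test_pair_count_quadratic(self, rng):
        groups = [list(rng.normal(0, 1, 3)) for _ in range(5)]
        assert len(tukey_hsd(groups)) == 5 * 4 // 2

    def test_agrees_with_statsmodels(self, rng):
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        groups = [list(rng.normal(m, 1.0, 4)) for m in (0.0, 1.0, 2.5)]
        ours = tukey_hsd(groups, ["g0", "g1", "g2"])
        values = np.concatenate(groups)
        labels = np.repeat(["g0", "g1", "g2"], 4)
        sm = pairwise_tukeyhsd(values, labels)
        for pair, p_sm in zip(ours, sm.pvalues):
            assert pair.p_adj == pytest.approx(float(p_sm), abs=1e-6)


class TestDensitometry:
    def test_equal_ratios_normalize_to_one(self):
        table = pd.DataFrame(
            {"group": ["control"] * 2 + ["t"] * 2, "replicate": [1, 2, 1, 2],
             "od_target": [0.8, 0.8, 0.8, 0.8], "od_loading": [1.0, 1.0, 1.0, 1.0]}
        )
        out, gs = densitometry_ratio(table, "control")
        assert np.allclose(out["normalized"], 1.0)
        assert gs is None  # zero variance: F undefined, ratios still given

    def test_halved_ratio(self):
        table = pd.DataFrame(
            {"group": ["control", "t"], "replicate": [1, 1],
             "od_target": [1.0, 0.5], "od_loading": [1.0, 1.0]}
        )
        out, gs = densitometry_ratio(table, "control")
        assert gs is None  # too few replicates for group statistics
        assert out.loc[out["group"] == "t", "normalized"].iloc[0] == pytest.approx(0.5)

    def test_nonpositive_loading_rejected(self):
        table = pd.DataFrame(
            {"group": ["control"], "replicate": [1],
             "od_target": [1.0], "od_loading": [0.0]}
        )
        with pytest.raises(TableError):
            densitometry_ratio(table, "control")

    def test_simulated_ratio_recovery(self):
        table, _ = simulate_densitometry({"t": 0.4}, noise_sd=0.1, n_reps=200, seed=9)
        out, gs = densitometry_ratio(table, "control")
        mean_t = out.loc[out["group"] == "t", "normalized"].mean()
        assert mean_t == pytest.approx(0.4, abs=0.03)
        assert gs is not None and gs.anova.p < 0.001
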
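"""Cell summaries, diversity effects, ECDFs, subject effects, JZS BF."""

import math

import numpy as np
import pandas as pd
import pytest

from diverse_induction import (
    ExperimentDesign,
    GeneratorParams,
    ecdf_by_argument,
    effect_summary,
    generate_ratings,
    jzs_bf_from_t,
    jzs_paired_bf,
    marginal_means,
    pooled_condition_ecdf,
    subject_summaries,
    summarize_cells,
)
from diverse_induction.analysis import DegenerateDataError

from _oracles import jzs_bf_gform


def _hand_table():
    """Two participants with hand-chosen ratings (12 trials each)."""
    rows = []
    args = [
        ("mammals-diverse", "diverse_target"),
        ("sea_creatures-diverse", "diverse_target"),
        ("insects-diverse", "diverse_target"),
        ("mammals-nondiverse", "nondiverse_target"),
        ("sea_creatures-nondiverse", "nondiverse_target"),
        ("insects-nondiverse", "nondiverse_target"),
    ]
    ratings = {
        ("P001", "weak"): [5, 6, 7, 4, 4, 4],
        ("P002", "strong"): [3, 4, 5, 2, 2, 2],
    }
    for (pid, group), vals in ratings.items():
        for (arg, ttype), r in zip(args, vals):
            rows.append((pid, group, ttype, arg, r))
        for i in range(1, 7):
            rows.append((pid, group, "filler", f"{group}-filler-{i}", 4))
    return pd.DataFrame(
        rows, columns=["participant_id", "group", "trial_type", "argument_id", "rating"]
    )


class TestSummaries:
    def test_hand_computed_cell_means(self):
        design = ExperimentDesign(n_per_group=1)
        cells = summarize_cells(_hand_table(), design)
        by = {(c.group, c.condition): c for c in cells}
        assert by[("weak", "diverse")].mean == pytest.approx(6.0)
        assert by[("weak", "nondiverse")].mean == pytest.approx(4.0)
        assert by[("strong", "diverse")].mean == pytest.approx(4.0)
        assert by[("strong", "nondiverse")].mean == pytest.approx(2.0)
        assert all(c.se == 0.0 and c.n == 1 for c in cells)

    def test_noiseless_table_means_match_rounded_configuration(self):
        params = GeneratorParams(
            rating_sd=0.0, subject_sd=0.0, insensitive_fraction_strong=0.0
        )
        cells = summarize_cells(generate_ratings(params=params))
        by = {(c.group, c.condition): c for c in cells}
        assert by[("weak", "diverse")].mean == 5.0
        assert by[("strong", "nondiverse")].mean == 4.0
        assert all(c.se == 0.0 for c in cells)

    def test_marginals_are_weighted_cell_averages(self, default_table):
        cells = summarize_cells(default_table)
        marg = marginal_means(cells)
        by = {(c.group, c.condition): c.mean for c in cells}
        assert marg["diverse"] == pytest.approx(
            (by[("weak", "diverse")] + by[("strong", "diverse")]) / 2
        )
        assert marg["weak"] == pytest.approx(
            (by[("weak", "diverse")] + by[("weak", "nondiverse")]) / 2
        )

    def test_default_marginals_near_configuration(self, default_table):
        """Marginal means of generated data approach the configured
        population marginals (diverse 5.08, nondiverse 4.48)."""
        marg = marginal_means(summarize_cells(default_table))
        assert marg["diverse"] == pytest.approx(5.08, abs=0.25)
        assert marg["nondiverse"] == pytest.approx(4.48, abs=0.25)
        assert marg["weak"] > marg["strong"]

    def test_missing_group_rejected(self, default_table):
        weak_only = default_table[default_table.group == "weak"]
        with pytest.raises(DegenerateDataError):
            summarize_cells(weak_only, ExperimentDesign(n_per_group=92))


class TestEffects:
    def test_null_configuration_gives_null_effects(self):
        params = GeneratorParams(
            cell_means=(4.5, 4.5, 4.5, 4.5),
            insensitive_fraction_strong=0.0,
            seed=7,
        )
        eff = effect_summary(generate_ratings(params=params))
        assert abs(eff.weak_effect) < 0.1
        assert abs(eff.strong_effect) < 0.1

    def test_default_effect_ordering(self, default_table):
        eff = effect_summary(default_table)
        assert eff.strong_effect > eff.weak_effect > 0
        assert eff.interaction == pytest.approx(
            eff.strong_effect - eff.weak_effect, abs=1e-12
        )

    def test_condition_swap_negates_effects(self, default_table):
        swapped = default_table.copy()
        swapped["trial_type"] = swapped["trial_type"].map(
            {
                "diverse_target": "nondiverse_target",
                "nondiverse_target": "diverse_target",
                "filler": "filler",
            }
        )
        eff = effect_summary(default_table)
        eff_swapped = effect_summary(swapped)
        assert eff_swapped.weak_effect == pytest.approx(-eff.weak_effect)
        assert eff_swapped.strong_effect == pytest.approx(-eff.strong_effect)


class TestEcdf:
    def test_cdf_terminal_and_monotone(self, default_table):
        ecdf = ecdf_by_argument(default_table)
        for (_, _), sub in ecdf.groupby(["argument_id", "group"]):
            vals = sub.sort_values("x")["F"].to_numpy()
            assert vals[-1] == 1.0
            assert np.all(np.diff(vals) >= 0)

    def test_diverse_arguments_stochastically_dominate(self, default_table):
        """Diverse-condition ECDFs lie to the right of nondiverse ECDFs
        (pooled within condition) in both groups, up to the binomial
        sampling error of an empirical CDF at 92 participants."""
        pooled = pooled_condition_ecdf(default_table)
        n = 92
        for group in ("weak", "strong"):
            sub = pooled[pooled.group == group]
            div = sub[sub.condition == "diverse"].sort_values("x")["F"].to_numpy()
            non = sub[sub.condition == "nondiverse"].sort_values("x")["F"].to_numpy()
            p = np.maximum(div, non)
            tol = 2 * np.sqrt(np.clip(p * (1 - p), 0, None) / n)
            assert np.all(div <= non + tol + 1e-12)

    def test_pooled_ecdf_bounded_by_condition_ecdfs(self, default_table):
        from diverse_induction.analysis import _participant_condition_means

        per = _participant_condition_means(default_table)
        xs = np.arange(1, 8)
        for group, sub in per.groupby("group"):
            d = sub["mean_diverse"].to_numpy()
            n = sub["mean_nondiverse"].to_numpy()
            pooled_vals = np.concatenate([d, n])
            for x in xs:
                fd, fn = (d <= x).mean(), (n <= x).mean()
                fp = (pooled_vals <= x).mean()
                assert min(fd, fn) - 1e-12 <= fp <= max(fd, fn) + 1e-12


class TestSubjectSummaries:
    def test_effect_is_mean_difference(self, default_table):
        res = subject_summaries(default_table)
        s = res.summaries[0]
        assert s.effect == pytest.approx(s.mean_diverse - s.mean_nondiverse)
        assert len(res.summaries) == 184

    def test_closed_loop_recovers_insensitive_fraction(self):
        """With a 30% insensitive strong subpopulation, the fraction of
        strong-group participants showing little-to-no diversity effect
        approaches 0.30 (pooled over replicates)."""
        fracs = [
            subject_summaries(
                generate_ratings(params=GeneratorParams(seed=s))
            ).fraction_near_zero["strong"]
            for s in range(20)
        ]
        pooled_se = math.sqrt(0.3 * 0.7 / (20 * 92))
        assert np.mean(fracs) == pytest.approx(0.30, abs=4 * pooled_se)

    def test_zero_noise_zero_insensitive_gives_zero_fraction(self):
        params = GeneratorParams(
            rating_sd=0.0, subject_sd=0.0, insensitive_fraction_strong=0.0
        )
        res = subject_summaries(generate_ratings(params=params))
        assert res.fraction_nonpositive["strong"] == 0.0
        assert res.fraction_near_zero["strong"] == 0.0

    def test_boundary_zero_effect_counts_as_insensitive(self):
        design = ExperimentDesign(n_per_group=1)
        table = _hand_table()
        table.loc[
            table.participant_id.eq("P001")
            & table.trial_type.eq("diverse_target"),
            "rating",
        ] = 4
        res = subject_summaries(table, design)
        assert res.fraction_nonpositive["weak"] == 1.0


class TestJzsBayesFactor:
    def test_null_data_favor_null(self, rng):
        diffs = rng.normal(0.0, 1.0, 92)
        diffs = diffs - diffs.mean()  # exactly zero mean difference
        assert jzs_paired_bf(diffs) < 1.0

    def test_monotone_in_effect_size(self):
        bfs = [jzs_bf_from_t(t, 30) for t in (0.0, 0.5, 1.0, 2.0, 3.5, 5.0)]
        assert all(b2 > b1 for b1, b2 in zip(bfs, bfs[1:]))

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_independent_quadrature_oracle(self, seed):
        """Adaptive quadrature agrees with a dense-grid integration of
        the g-mixture representation to 1e-6 relative."""
        gen = np.random.default_rng(seed)
        n = int(gen.integers(5, 50))
        d = gen.normal(gen.uniform(-1, 1), gen.uniform(0.5, 2.0), n)
        t = d.mean() / (d.std(ddof=1) / math.sqrt(n))
        assert jzs_paired_bf(d) == pytest.approx(
            jzs_bf_gform(t, n), rel=1e-6
        )

    def test_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        for t, n in ((2.5, 30), (0.0, 92), (-1.7, 15), (4.2, 92)):
            theirs = float(pingouin.bayesfactor_ttest(t, n, paired=True))
            assert jzs_bf_from_t(t, n) == pytest.approx(theirs, rel=1e-3)

    def test_degenerate_input_rejected(self):
        with pytest.raises(DegenerateDataError):
            jzs_paired_bf([0.5, 0.5, 0.5])
        with pytest.raises(DegenerateDataError):
            jzs_paired_bf([1.0])
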
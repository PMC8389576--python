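"""ANOVA calibration, post-hoc procedures, and the letter display."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from pamflux.errors import DegenerateDataError, ValidationError
from pamflux.simulate import (
    CYTOTYPES,
    make_design,
    plant_rng,
    simulate_null_table,
    simulate_shifted_table,
)
from pamflux.stats import (
    analyze_coefficient,
    cell_label,
    compact_letter_display,
    duncan_mrt,
    studentized_range_cdf,
    studentized_range_quantile,
    tukey_hsd,
    two_way_anova,
)


def _dataset(seed=0, n=8, sd=1.0, cyto_shift=None):
    rng = np.random.default_rng(seed)
    rows = []
    for i, (pid, g) in enumerate(make_design(n, seed)):
        mu = 10.0 + (cyto_shift or {}).get(g.cytotype, 0.0)
        rows.append((pid, g.cytotype, g.photoperiod_h, "NPQ",
                     mu + sd * rng.normal()))
    return pd.DataFrame(
        rows, columns=["plant_id", "cytotype", "photoperiod_h", "coefficient", "value"])


class TestStudentizedRange:
    def test_quantile_cdf_round_trip(self):
        for k in range(2, 11):
            for df in (5, 10, 30, 120):
                q = studentized_range_quantile(0.95, k, df)
                assert studentized_range_cdf(q, k, df) == pytest.approx(
                    0.95, abs=1e-6)

    def test_k2_reduces_to_scaled_t(self):
        for df in (5, 10, 30, 120):
            want = np.sqrt(2.0) * sps.t.ppf(0.975, df)
            assert studentized_range_quantile(0.95, 2, df) == pytest.approx(
                want, abs=1e-4)

    def test_cdf_strictly_increasing(self):
        qs = np.linspace(0.5, 8.0, 25)
        ps = [studentized_range_cdf(q, 4, 12) for q in qs]
        assert np.all(np.diff(ps) > 0)

    def test_quantile_against_monte_carlo(self):
        """200k-draw Monte-Carlo 95th percentile of the studentized range
        (k=3, df=10) brackets the numerical quantile."""
        rng = np.random.default_rng(20260928)
        n = 200_000
        z = rng.normal(size=(n, 3))
        s = np.sqrt(rng.chisquare(10, size=n) / 10.0)
        q_draws = (z.max(axis=1) - z.min(axis=1)) / s
        mc = np.quantile(q_draws, 0.95)
        # simulation CI for a quantile via order statistics
        lo, hi = np.quantile(q_draws, [0.95 - 3 * 0.0005, 0.95 + 3 * 0.0005])
        q = studentized_range_quantile(0.95, 3, 10)
        assert lo <= q <= hi, (lo, q, hi, mc)

    def test_domain_errors(self):
        with pytest.raises(ValidationError):
            studentized_range_quantile(0.95, 1, 10)
        with pytest.raises(ValidationError):
            studentized_range_cdf(-1.0, 3, 10)


class TestTwoWayAnova:
    def test_constant_data_is_degenerate(self):
        table = _dataset(sd=0.0)
        with pytest.raises(DegenerateDataError):
            two_way_anova(table)

    def test_empty_cell_named(self):
        table = _dataset()
        table = table[~((table.cytotype == "4x") & (table.photoperiod_h == 16.5))]
        with pytest.raises(ValidationError, match="4x@16.5h"):
            two_way_anova(table)

    def test_df_sum_to_n_minus_one(self):
        a = two_way_anova(_dataset(n=5))
        assert a.table["df"].sum() == pytest.approx(a.n_obs - 1)
        assert (a.table["sum_sq"] >= 0).all()

    def test_matches_statsmodels_typ2_directly(self):
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        table = _dataset(seed=3)
        a = two_way_anova(table)
        fit = smf.ols("value ~ C(cytotype) * C(photoperiod_h)", table).fit()
        ref = sm.stats.anova_lm(fit, typ=2)
        assert a.p_value("cytotype") == pytest.approx(
            ref.loc["C(cytotype)", "PR(>F)"])

    def test_power_for_three_sd_cytotype_shift(self):
        """A pure 3-residual-SD cytotype shift at n=8/cell is detected with
        p < 0.001 in at least 95% of 200 replicates."""
        hits = 0
        for rep in range(200):
            table = _dataset(seed=1000 + rep, n=8, sd=1.0,
                             cyto_shift={"6x_35": 3.0})
            if two_way_anova(table).p_value("cytotype") < 1e-3:
                hits += 1
        assert hits >= 0.95 * 200

    def test_permutation_type_one_error(self):
        """Permuting group labels puts the cytotype test on its null: the
        rejection rate at alpha=0.05 stays within [0.035, 0.065]."""
        table = _dataset(seed=7, n=4)
        rng = np.random.default_rng(123)
        labels = table[["cytotype", "photoperiod_h"]].to_numpy()
        rejections = 0
        n_perm = 2000
        perm_table = table.copy()
        for _ in range(n_perm):
            idx = rng.permutation(len(table))
            perm_table[["cytotype", "photoperiod_h"]] = labels[idx]
            if two_way_anova(perm_table).p_value("cytotype") < 0.05:
                rejections += 1
        assert 0.035 <= rejections / n_perm <= 0.065


class TestTukey:
    def test_identical_cells_not_significant(self):
        table = _dataset(seed=2, sd=1.0)
        res = tukey_hsd(table, two_way_anova(table))
        # same generating distribution everywhere: expect shared letters
        assert res.pairwise["significant"].sum() <= 2

    def test_k2_margin_reduces_to_t_test(self):
        table = _dataset(seed=5, cyto_shift={"2x": 1.0})
        anova = two_way_anova(table)
        res = tukey_hsd(table, anova, by="photoperiod")
        assert len(res.cells) == 2
        row = res.pairwise.iloc[0]
        t_stat = abs(row["diff"]) / np.sqrt(
            anova.residual_ms * (1 / res.ns[row.cell_a] + 1 / res.ns[row.cell_b]))
        t_decision = t_stat > sps.t.ppf(0.975, anova.residual_df)
        assert bool(row["significant"]) == bool(t_decision)

    def test_decisions_match_monte_carlo_critical_value(self):
        """Brute-force oracle: decide each pair with a 300k-draw Monte-Carlo
        estimate of q(0.95; k, df) instead of the numerical quantile."""
        table = _dataset(seed=11, cyto_shift={"4x": 1.5, "6x_35": -1.5})
        anova = two_way_anova(table)
        res = tukey_hsd(table, anova)
        k, df = len(res.cells), int(anova.residual_df)
        rng = np.random.default_rng(42)
        z = rng.normal(size=(300_000, k))
        s = np.sqrt(rng.chisquare(df, size=300_000) / df)
        q_mc = np.quantile((z.max(axis=1) - z.min(axis=1)) / s, 0.95)
        for row in res.pairwise.itertuples():
            mc_sig = abs(row.diff) / row.se > q_mc
            assert mc_sig == row.significant

    def test_matches_statsmodels_on_balanced_cells(self):
        """Cross-check: with the cell-means model, decisions agree with
        statsmodels' one-way pairwise_tukeyhsd on cell labels."""
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        table = _dataset(seed=13, cyto_shift={"6x_35": -2.0})
        res = tukey_hsd(table, two_way_anova(table))
        labels = table.apply(
            lambda r: cell_label(r["cytotype"], r["photoperiod_h"]), axis=1)
        ref = pairwise_tukeyhsd(table["value"].to_numpy(), labels.to_numpy(),
                                alpha=0.05)
        ref_sig = {frozenset((a, b)): bool(s) for (a, b), s in
                   zip(itertools.combinations(ref.groupsunique, 2), ref.reject)}
        assert res.significance_matrix() == ref_sig


class TestDuncan:
    def test_two_group_margin_agrees_with_tukey(self):
        table = _dataset(seed=17, cyto_shift={"2x": 0.8})
        anova = two_way_anova(table)
        t = tukey_hsd(table, anova, by="photoperiod")
        d = duncan_mrt(table, anova, by="photoperiod")
        assert t.pairwise["significant"].tolist() == \
            d.pairwise["significant"].tolist()

    def test_well_separated_means_get_distinct_letters(self):
        table = _dataset(seed=19, sd=1.0,
                         cyto_shift={"2x": 0.0, "4x": 10.0,
                                     "6x_29": 20.0, "6x_35": 30.0})
        res = duncan_mrt(table, two_way_anova(table), by="cytotype")
        assert sorted(res.letters.values()) == ["a", "b", "c", "d"]

    def test_rejects_at_least_tukey_on_balanced_data(self):
        rng = np.random.default_rng(99)
        for _ in range(50):
            shift = {c: rng.normal(0, 1.2) for c in CYTOTYPES}
            table = _dataset(seed=int(rng.integers(2**31)), n=6,
                             cyto_shift=shift)
            anova = two_way_anova(table)
            t = tukey_hsd(table, anova, with_p=False)
            d = duncan_mrt(table, anova)
            dsig = d.significance_matrix()
            for pair, sig in t.significance_matrix().items():
                if sig:
                    assert dsig[pair], f"Tukey rejected {pair}, Duncan did not"

    def test_protection_level_intervals_reported(self):
        table = _dataset(seed=23)
        res = duncan_mrt(table, two_way_anova(table))
        pw = res.pairwise
        assert ((pw.p_low < pw.p_high) & (pw.protection_alpha >= 0.05 - 1e-12)).all()


class TestLetters:
    def test_no_significance_single_letter(self):
        cells = list("ABCD")
        sig = {frozenset(p): False for p in itertools.combinations(cells, 2)}
        assert set(compact_letter_display(cells, sig).values()) == {"a"}

    def test_all_significant_distinct_letters(self):
        cells = [f"c{i}" for i in range(8)]
        sig = {frozenset(p): True for p in itertools.combinations(cells, 2)}
        letters = compact_letter_display(cells, sig)
        assert len(set(letters.values())) == 8
        assert all(len(v) == 1 for v in letters.values())

    def test_chain_case_minimal_solution(self):
        # A != C but A = B and B = C: the classic overlap pattern
        cells = ["A", "B", "C"]
        sig = {frozenset(("A", "C")): True,
               frozenset(("A", "B")): False,
               frozenset(("B", "C")): False}
        assert compact_letter_display(cells, sig) == \
            {"A": "a", "B": "ab", "C": "b"}

    def test_missing_pair_rejected(self):
        with pytest.raises(ValidationError):
            compact_letter_display(["A", "B"], {})

    def test_random_matrices_stay_consistent(self):
        """The insert-and-absorb construction keeps letters consistent with
        any symmetric significance pattern (checked by its own tripwire)."""
        rng = np.random.default_rng(7)
        cells = [f"g{i}" for i in range(6)]
        for _ in range(200):
            sig = {frozenset(p): bool(rng.random() < 0.4)
                   for p in itertools.combinations(cells, 2)}
            letters = compact_letter_display(cells, sig)
            for a, b in itertools.combinations(cells, 2):
                share = bool(set(letters[a]) & set(letters[b]))
                assert share != sig[frozenset((a, b))]


class TestAnalyzeCoefficient:
    def test_missing_coefficient_lists_available(self):
        table = simulate_null_table(seed=1)
        with pytest.raises(ValidationError, match="phi_max"):
            analyze_coefficient(table, "NPQ")

    def test_shifted_cytotype_gets_disjoint_letter(self):
        table = simulate_shifted_table(seed=4)
        res = analyze_coefficient(table, "phi_max", method="tukey")
        letters = res.posthoc.letters
        shifted = [set(v) for c, v in letters.items() if c.startswith("6x_35")]
        others = set().union(*(set(v) for c, v in letters.items()
                               if not c.startswith("6x_35")))
        assert all(not s & others for s in shifted)

    def test_familywise_type_one_error_under_global_null(self):
        """Tukey familywise error over 2000 null datasets stays in the
        [0.02, 0.08] band at alpha=0.05."""
        false_alarms = 0
        n_rep = 2000
        for rep in range(n_rep):
            table = simulate_null_table(n_per_cell=3, seed=50_000 + rep)
            res = analyze_coefficient(table, "phi_max", method="tukey",
                                      with_p=False)
            if res.posthoc.pairwise["significant"].any():
                false_alarms += 1
        assert 0.02 <= false_alarms / n_rep <= 0.08
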
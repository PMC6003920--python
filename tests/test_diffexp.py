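"""Replicate-free DE: 2x2 chi-squared, BH-FDR, fold change, calls, categories."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from locustde.diffexp import (
    bh_fdr,
    call_de,
    categorize,
    chi2_contingency_2x2,
    de_summary,
    log2_fold_change,
)
from locustde.quantify import CountTable
from locustde.synthetic_data import SyntheticConfig, calibration_truth, generate_counts


def _brute_chi2(a, b, c, d):
    # closed-form 2x2 Pearson statistic
    a, b, c, d = float(a), float(b), float(c), float(d)
    n = a + b + c + d
    return n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))


class TestChi2:
    def test_equal_proportions_give_null(self):
        chi2, p = chi2_contingency_2x2(10, 20, 1000, 2000)
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_worked_table(self):
        chi2, p = chi2_contingency_2x2(20, 5, 1000, 990)
        assert chi2 == pytest.approx(_brute_chi2(20, 980, 5, 985), rel=1e-12)

    def test_symmetry_under_library_swap(self):
        c1, p1 = chi2_contingency_2x2(37, 11, 5000, 4000)
        c2, p2 = chi2_contingency_2x2(11, 37, 4000, 5000)
        assert c1 == pytest.approx(c2) and p1 == pytest.approx(p2)

    def test_degenerate_double_zero(self):
        chi2, p = chi2_contingency_2x2(0, 0, 1000, 2000)
        assert (chi2, p) == (0.0, 1.0)

    def test_count_exceeding_total_errors(self):
        with pytest.raises(ValueError):
            chi2_contingency_2x2(11, 5, 10, 100)

    def test_matches_brute_force_and_scipy_on_random_tables(self, rng):
        # oracle equivalence on 1000 random tables at 1e-9 relative tolerance
        for _ in range(1000):
            ta, tb = rng.integers(10, 10_000, size=2)
            a = int(rng.integers(0, ta + 1))
            c = int(rng.integers(0, tb + 1))
            chi2, p = chi2_contingency_2x2(a, c, ta, tb)
            expected = _brute_chi2(a, ta - a, c, tb - c)
            if np.isnan(expected):  # zero marginal: degenerate table
                assert (chi2, p) == (0.0, 1.0)
                continue
            assert chi2 == pytest.approx(expected, rel=1e-9)
        # independent library cross-check on one healthy table
        sp = sps.chi2_contingency(
            [[20, 980], [5, 985]], correction=False
        )
        chi2, p = chi2_contingency_2x2(20, 5, 1000, 990)
        assert chi2 == pytest.approx(sp.statistic, rel=1e-12)
        assert p == pytest.approx(sp.pvalue, rel=1e-9)

    def test_yates_reduces_statistic(self):
        plain, _ = chi2_contingency_2x2(20, 5, 1000, 990)
        corrected, _ = chi2_contingency_2x2(20, 5, 1000, 990, yates=True)
        assert corrected < plain


class TestBH:
    def test_single_p_unchanged(self):
        assert bh_fdr([0.2]) == pytest.approx([0.2])

    def test_hand_step_up(self):
        assert bh_fdr([0.01, 0.02, 0.04]) == pytest.approx([0.03, 0.03, 0.04])

    @settings(deadline=None, max_examples=200)
    @given(
        st.lists(
            st.floats(0.0, 1.0, allow_nan=False), min_size=1, max_size=100
        )
    )
    def test_matches_statsmodels_oracle(self, p_list):
        from statsmodels.stats.multitest import multipletests

        q = bh_fdr(p_list)
        _, q_ref, _, _ = multipletests(p_list, method="fdr_bh")
        assert np.allclose(q, q_ref, rtol=1e-12, atol=1e-12)
        assert np.all(q >= np.asarray(p_list) - 1e-15)

    def test_monotone_in_rank_order(self, rng):
        p = rng.random(50)
        q = bh_fdr(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-15)


class TestLog2FC:
    @pytest.mark.parametrize(
        "greg,sol,expected",
        [(40, 10, 2.0), (10, 40, -2.0), (5, 0, np.inf), (0, 5, -np.inf), (0, 0, 0.0)],
    )
    def test_conventions(self, greg, sol, expected):
        assert log2_fold_change(greg, sol) == pytest.approx(expected)


def _de_run(truth, seed, alpha=0.05):
    cfg = SyntheticConfig(
        seed=seed, lib_size_sol=1_000_000, lib_size_greg=1_000_000
    )
    table = generate_counts(truth, cfg)
    lengths = dict(zip(truth["transcript_id"], truth["length"]))
    return call_de(table, lengths, alpha=alpha)


class TestCallDE:
    def test_null_poisson_type_I_error_calibrated(self):
        """Raw p<0.05 at ~5% and essentially no BH calls under the null."""
        truth = calibration_truth(2000, base_mean=50.0, seed=101)
        de = _de_run(truth, seed=101)
        assert (de["p"] < 0.05).mean() == pytest.approx(0.05, abs=0.01)
        assert (de["call"] != "ns").mean() <= 0.01

    def test_power_and_direction_on_planted_fold_change(self):
        """Planted log2FC=2 at base mean 50 and 1e6 totals is recovered."""
        truth = calibration_truth(
            2000, base_mean=50.0, lfc=2.0, de_fraction=0.1, seed=102
        )
        de = _de_run(truth, seed=102).set_index("contig_id")
        joined = de.join(truth.set_index("transcript_id"))
        positives = joined[joined["is_de"]]
        assert (positives["call"] != "ns").mean() >= 0.95
        called = positives[positives["call"] != "ns"]
        assert (np.sign(called["log2fc"]) == np.sign(called["true_lfc"])).all()

    def test_identical_libraries_make_no_calls(self):
        counts = pd.DataFrame(
            {
                "contig_id": [f"c{i}" for i in range(20)],
                "count_sol": np.arange(20) * 7 + 3,
                "count_greg": np.arange(20) * 7 + 3,
            }
        )
        table = CountTable.from_counts(counts)
        de = call_de(table, {f"c{i}": 500 for i in range(20)})
        assert (de["p"] == 1.0).all()
        assert (de["call"] == "ns").all()

    def test_output_order_deterministic_and_sorted_by_abs_lfc(self):
        truth = calibration_truth(
            300, base_mean=50.0, lfc=2.0, de_fraction=0.3, seed=103
        )
        de1 = _de_run(truth, seed=103)
        de2 = _de_run(truth, seed=103)
        assert de1.equals(de2)
        abs_lfc = de1["log2fc"].abs().to_numpy()
        assert np.all(np.diff(abs_lfc) <= 1e-12)

    def test_empty_table_errors(self):
        table = CountTable(
            counts=pd.DataFrame(
                {"contig_id": [], "count_sol": [], "count_greg": []}
            ),
            total_sol=10,
            total_greg=10,
        )
        with pytest.raises(ValueError, match="empty"):
            call_de(table, {})


class TestCategorize:
    def _frame(self, rows):
        df = pd.DataFrame(
            rows,
            columns=["contig_id", "count_sol", "count_greg", "log2fc", "call"],
        )
        return df

    def test_rules(self):
        df = self._frame(
            [
                ("a", 15, 0, -np.inf, "sol_over"),  # absent from the other library
                ("b", 15, 3, -1.4, "sol_over"),  # strong fold change
                ("c", 15, 9, -0.6, "sol_over"),  # significant but modest
                ("d", 8, 0, -np.inf, "sol_over"),  # too few reads for absent_other
                ("e", 3, 40, 3.0, "greg_over"),
                ("f", 100, 90, 0.1, "ns"),
            ]
        )
        out = categorize(df)
        by_id = dict(zip(out["contig_id"], out["category"]))
        assert by_id == {
            "a": "absent_other",
            "b": "high_fold",
            "c": "remainder",
            "d": "remainder",
            "e": "high_fold",
            "f": "none",
        }

    def test_categories_partition_each_phase(self):
        truth = calibration_truth(
            1000, base_mean=30.0, lfc=2.5, de_fraction=0.3, seed=104
        )
        de = categorize(_de_run(truth, seed=104))
        for call in ("sol_over", "greg_over"):
            sub = de[de["call"] == call]
            assert set(sub["category"]) <= {"absent_other", "high_fold", "remainder"}
            assert len(sub) == sum(
                (sub["category"] == c).sum()
                for c in ("absent_other", "high_fold", "remainder")
            )
        assert (de.loc[de["call"] == "ns", "category"] == "none").all()

    def test_summary_counts_match(self):
        truth = calibration_truth(
            500, base_mean=30.0, lfc=2.0, de_fraction=0.2, seed=105
        )
        de = categorize(_de_run(truth, seed=105))
        summary = de_summary(de)
        totals = summary[summary["category"] == "total"].set_index("call")["n"]
        for call, n in totals.items():
            assert n == (de["call"] == call).sum()
        assert totals.sum() == len(de)
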
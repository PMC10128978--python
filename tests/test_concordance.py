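"""IHC dichotomy, contingency/concordance arithmetic, exact tests."""

import math
from itertools import product

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import hypergeom

from msipcr.concordance import (
    ContingencyTable,
    IHCResult,
    build_contingency,
    cohort_table,
    concordance_report,
    dichotomize_ihc,
    fisher_exact,
    freeman_halton,
    percent_concordance,
)


def brute_force_fisher(a, b, c, d):
    """Independent oracle: exhaustive hypergeometric enumeration."""
    n, r1, c1 = a + b + c + d, a + b, a + c
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    ks = np.arange(lo, hi + 1)
    pmf = hypergeom.pmf(ks, n, r1, c1)
    p_obs = hypergeom.pmf(a, n, r1, c1)
    return float(pmf[pmf <= p_obs * (1 + 1e-12)].sum())


class TestDichotomize:
    def test_all_preserved(self):
        r = IHCResult("c", "preserved", "preserved", "preserved", "preserved")
        assert dichotomize_ihc(r) == "Preserved"

    def test_isolated_msh6_loss_is_loss(self):
        r = IHCResult("c", "preserved", "preserved", "loss", "preserved")
        assert dichotomize_ihc(r) == "Loss"

    def test_mlh1_pms2_loss_is_loss(self):
        r = IHCResult("c", "loss", "preserved", "preserved", "loss")
        assert dichotomize_ihc(r) == "Loss"

    def test_missing_protein_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            dichotomize_ihc({"mlh1": "preserved", "msh2": "preserved",
                             "msh6": "preserved"})

    @given(base=st.lists(st.booleans(), min_size=4, max_size=4),
           flip=st.integers(0, 3))
    def test_monotone_in_loss(self, base, flip):
        # adding a loss never flips Loss -> Preserved
        names = ("mlh1", "msh2", "msh6", "pms2")
        labels = {n: ("loss" if b else "preserved") for n, b in zip(names, base)}
        before = dichotomize_ihc(dict(labels))
        labels[names[flip]] = "loss"
        after = dichotomize_ihc(labels)
        assert not (before == "Loss" and after == "Preserved")


class TestContingencyAndConcordance:
    def test_reported_cohort_counts(self):
        # 292 + 4 + 1 + 39 = 336 cases; diagonal 331
        t = ContingencyTable(292, 4, 1, 39)
        assert t.n == 336
        assert percent_concordance(t) == 98.5

    def test_build_from_case_maps(self):
        status = {"a": "MSS", "b": "MSI-H", "c": "MSI-L", "d": "MSI-H"}
        ihc = {"a": "Preserved", "b": "Loss", "c": "Loss", "d": "Preserved"}
        t = build_contingency(status, ihc)
        assert t.counts == (1, 1, 1, 1)

    def test_unmatched_cases_rejected(self):
        with pytest.raises(ValueError, match="unmatched"):
            build_contingency({"a": "MSS"}, {"b": "Preserved"})

    def test_empty_input_gives_zero_table(self):
        t = build_contingency({}, {})
        assert t.counts == (0, 0, 0, 0) and t.n == 0
        with pytest.raises(ValueError):
            percent_concordance(t)

    def test_single_concordant_case(self):
        t = build_contingency({"x": "MSI-H"}, {"x": "Loss"})
        assert t.counts == (0, 0, 0, 1)
        assert percent_concordance(t) == 100.0

    @pytest.mark.parametrize("counts,expected",
                             [((10, 0, 0, 10), 100.0), ((0, 5, 5, 0), 0.0)])
    def test_percent_extremes(self, counts, expected):
        assert percent_concordance(ContingencyTable(*counts)) == expected

    def test_percent_is_100_iff_off_diagonal_empty(self):
        assert percent_concordance(ContingencyTable(7, 0, 0, 2)) == 100.0
        assert percent_concordance(ContingencyTable(7, 1, 0, 2)) < 100.0

    def test_report_lists_discordant_cases(self):
        status = {"a": "MSS", "b": "MSI-H"}
        ihc = {
            "a": IHCResult("a", "preserved", "preserved", "loss", "preserved"),
            "b": IHCResult("b", "loss", "preserved", "preserved", "loss"),
        }
        rep = concordance_report(status, ihc)
        assert rep.percent == 50.0
        assert [d["case_id"] for d in rep.discordant_cases] == ["a"]


class TestFisher:
    def test_maximal_entropy_table(self):
        assert fisher_exact([[1, 1], [1, 1]]).p == 1.0

    def test_zero_margin_is_degenerate(self):
        r = fisher_exact([[0, 0], [3, 5]])
        assert r.p == 1.0 and r.degenerate

    def test_location_association_is_significant(self):
        # proximal-colon enrichment of MSI-H: (27,13 | 86,210)
        r = fisher_exact([[27, 86], [13, 210]])
        assert r.p < 0.001 and r.significant

    def test_gender_not_significant(self):
        r = fisher_exact([[19, 171], [21, 125]])
        assert r.p == pytest.approx(0.237, abs=5e-4)
        assert not r.significant

    @given(st.tuples(st.integers(0, 12), st.integers(0, 12),
                     st.integers(0, 12), st.integers(0, 12)))
    def test_agrees_with_enumeration_oracle(self, abcd):
        a, b, c, d = abcd
        r = fisher_exact([[a, b], [c, d]])
        if r.degenerate:
            return
        assert r.p == pytest.approx(brute_force_fisher(a, b, c, d), abs=1e-10)


class TestFreemanHalton:
    def brute(self, table):
        arr = np.asarray(table)
        row, col = arr.sum(1), arr.sum(0)
        n = arr.sum()

        def logp(first):
            lp = (math.lgamma(row[0] + 1) + math.lgamma(row[1] + 1)
                  - math.lgamma(n + 1))
            for j, c in enumerate(col):
                lp += (math.lgamma(c + 1) - math.lgamma(first[j] + 1)
                       - math.lgamma(c - first[j] + 1))
            return lp

        obs = logp(arr[0])
        total = 0.0
        for firsts in product(*[range(c + 1) for c in col]):
            if sum(firsts) != row[0]:
                continue
            lp = logp(firsts)
            if lp <= obs + 1e-9:
                total += math.exp(lp)
        return total

    @pytest.mark.parametrize("table", [
        [[3, 1, 4], [2, 5, 0]],
        [[1, 2, 3, 4], [4, 3, 2, 1]],
        [[5, 0, 1], [1, 4, 3]],
    ])
    def test_enumeration_matches_brute_force(self, table):
        assert freeman_halton(table).p == pytest.approx(self.brute(table),
                                                        abs=1e-10)

    def test_two_columns_falls_back_to_fisher(self):
        t = [[3, 7], [6, 2]]
        assert freeman_halton(t).p == fisher_exact(t).p

    def test_monte_carlo_close_to_enumeration(self):
        table = [[8, 3, 5], [2, 9, 6]]
        exact = freeman_halton(table).p
        mc = freeman_halton(table, max_enum_tables=1, n_mc=20000, seed=0).p
        assert mc == pytest.approx(exact, abs=0.02)


def _cohort_frame():
    # reconstruct per-case rows from the published location and BRAF counts
    rows = []

    def add(n, status, **cov):
        rows.extend([dict(status=status, **cov)] * n)

    add(27, "MSI-H", location="proximal")
    add(13, "MSI-H", location="distal")
    add(86, "MSS", location="proximal")
    add(210, "MSS", location="distal")
    df = pd.DataFrame(rows)
    braf = (["mutant"] * 12 + ["wild"] * 28) + (
        ["mutant"] * 10 + ["wild"] * 134 + ["NA"] * 152
    )
    df["braf"] = braf
    return df


class TestCohortTable:
    def test_location_row_percentages_and_p(self):
        out = cohort_table(_cohort_frame(), ["location"])
        prox = out[(out.covariate == "location") & (out.category == "proximal")]
        dist = out[(out.covariate == "location") & (out.category == "distal")]
        assert prox.msih_pct_total.iloc[0] == 67.5
        assert prox.mss_msil_pct_total.iloc[0] == 29.1
        assert dist.mss_msil_pct_total.iloc[0] == 70.9
        assert prox.p_value.iloc[0] < 0.001

    def test_braf_percentages_under_both_denominators(self):
        out = cohort_table(_cohort_frame(), ["braf"])
        mut = out[(out.covariate == "braf") & (out.category == "mutant")]
        assert mut.msih_pct_total.iloc[0] == 30.0
        assert mut.msih_pct_known.iloc[0] == 30.0
        assert mut.mss_msil_pct_total.iloc[0] == 3.4  # printed-table convention
        assert mut.mss_msil_pct_known.iloc[0] == 6.9  # known-status convention

    def test_single_category_covariate_has_no_test(self):
        df = _cohort_frame()
        df["site"] = "colon"
        out = cohort_table(df, ["site"])
        assert out.p_value.isna().all()

    def test_missing_covariate_rejected(self):
        with pytest.raises(ValueError, match="missing covariate"):
            cohort_table(_cohort_frame(), ["grade"])
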
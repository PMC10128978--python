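"""MSI-PCR x MMR-IHC concordance and cohort association statistics.

IHC enters as per-protein categorical labels (MLH1, MSH2, MSH6, PMS2, each
``preserved`` or ``loss``); a case is dichotomized to ``Loss`` when any
protein is lost.  MSI-PCR is dichotomized MSI-H vs MSS+MSI-L.  Concordance is
the diagonal fraction of the resulting 2x2 table; covariate associations are
tested with Fisher's exact test (two-sided, significance at p < 0.001),
extended to 2xk tables by the Freeman-Halton method.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import percent

__all__ = [
    "IHCResult",
    "ContingencyTable",
    "ConcordanceReport",
    "FisherResult",
    "dichotomize_ihc",
    "build_contingency",
    "percent_concordance",
    "fisher_exact",
    "freeman_halton",
    "concordance_report",
    "cohort_table",
    "SIGNIFICANCE_LEVEL",
]

SIGNIFICANCE_LEVEL = 0.001

_PROTEINS = ("mlh1", "msh2", "msh6", "pms2")


@dataclass(frozen=True)
class IHCResult:
    """Per-protein MMR immunostaining labels for one case."""

    case_id: str
    mlh1: str
    msh2: str
    msh6: str
    pms2: str

    def __post_init__(self) -> None:
        for prot in _PROTEINS:
            v = getattr(self, prot)
            if v not in ("preserved", "loss"):
                raise ValueError(f"{self.case_id}: {prot} must be preserved|loss, got {v!r}")


@dataclass(frozen=True)
class ContingencyTable:
    """(MSS+MSI-L, MSI-H) x (Preserved, Loss) counts."""

    mss_msil_preserved: int
    mss_msil_loss: int
    msih_preserved: int
    msih_loss: int

    def __post_init__(self) -> None:
        for c in self.counts:
            if c < 0 or c != int(c):
                raise ValueError("counts must be nonnegative integers")

    @property
    def counts(self) -> tuple[int, int, int, int]:
        return (
            self.mss_msil_preserved,
            self.mss_msil_loss,
            self.msih_preserved,
            self.msih_loss,
        )

    @property
    def n(self) -> int:
        return sum(self.counts)

    def as_array(self) -> np.ndarray:
        return np.array(
            [
                [self.mss_msil_preserved, self.mss_msil_loss],
                [self.msih_preserved, self.msih_loss],
            ]
        )


@dataclass(frozen=True)
class FisherResult:
    p: float
    degenerate: bool
    significant: bool


@dataclass
class ConcordanceReport:
    table: ContingencyTable
    concordant: int
    percent: float
    discordant_cases: list[dict] = field(default_factory=list)


def dichotomize_ihc(r: IHCResult | dict) -> str:
    """``Loss`` iff any of the four MMR proteins is lost."""
    if isinstance(r, dict):
        missing = [p for p in _PROTEINS if p not in r]
        if missing:
            raise ValueError(f"missing IHC proteins: {missing}")
        values = [r[p] for p in _PROTEINS]
        for v in values:
            if v not in ("preserved", "loss"):
                raise ValueError(f"invalid IHC label {v!r}")
    else:
        values = [getattr(r, p) for p in _PROTEINS]
    return "Loss" if "loss" in values else "Preserved"


def build_contingency(
    pcr_status: dict[str, str], ihc_dichotomy: dict[str, str]
) -> ContingencyTable:
    """Cross-tabulate per-case MSI status against dichotomized IHC."""
    only_pcr = sorted(set(pcr_status) - set(ihc_dichotomy))
    only_ihc = sorted(set(ihc_dichotomy) - set(pcr_status))
    if only_pcr or only_ihc:
        raise ValueError(
            f"unmatched cases: pcr-only {only_pcr}, ihc-only {only_ihc}"
        )
    counts = {(r, c): 0 for r in ("not_h", "h") for c in ("Preserved", "Loss")}
    for case, status in pcr_status.items():
        row = "h" if status == "MSI-H" else "not_h"
        col = ihc_dichotomy[case]
        if col not in ("Preserved", "Loss"):
            raise ValueError(f"{case}: invalid IHC dichotomy {col!r}")
        counts[(row, col)] += 1
    return ContingencyTable(
        counts[("not_h", "Preserved")],
        counts[("not_h", "Loss")],
        counts[("h", "Preserved")],
        counts[("h", "Loss")],
    )


def percent_concordance(t: ContingencyTable) -> float:
    """Diagonal percent of the 2x2, to 1 decimal."""
    if t.n == 0:
        raise ValueError("empty table")
    concordant = t.mss_msil_preserved + t.msih_loss
    return percent(concordant, t.n)


def concordance_report(
    pcr_status: dict[str, str],
    ihc: dict[str, IHCResult | dict],
    ihc_dichotomy: dict[str, str] | None = None,
) -> ConcordanceReport:
    """Full Table-2-style report with per-case discordance detail."""
    if ihc_dichotomy is None:
        ihc_dichotomy = {c: dichotomize_ihc(r) for c, r in ihc.items()}
    table = build_contingency(pcr_status, ihc_dichotomy)
    discordant = []
    for case, status in sorted(pcr_status.items()):
        is_h = status == "MSI-H"
        is_loss = ihc_dichotomy[case] == "Loss"
        if is_h != is_loss:
            discordant.append(
                {"case_id": case, "msi_pcr": status, "ihc": ihc_dichotomy[case]}
            )
    return ConcordanceReport(
        table=table,
        concordant=table.mss_msil_preserved + table.msih_loss,
        percent=percent_concordance(table),
        discordant_cases=discordant,
    )


def fisher_exact(table) -> FisherResult:
    """Two-sided Fisher's exact test on a 2x2 table.

    Degenerate tables (a zero row or column margin) return p = 1 by
    convention, flagged.  Significance at the study threshold (p < 0.001).
    """
    arr = np.asarray(table, dtype=int).reshape(2, 2)
    if (arr < 0).any():
        raise ValueError("counts must be nonnegative")
    degenerate = bool((arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any())
    if degenerate:
        return FisherResult(1.0, True, False)
    p = float(stats.fisher_exact(arr, alternative="two-sided")[1])
    return FisherResult(p, False, p < SIGNIFICANCE_LEVEL)


def freeman_halton(
    table, *, max_enum_tables: int = 2_000_000, n_mc: int = 20000, seed: int = 0
) -> FisherResult:
    """Freeman-Halton exact test for a 2xk table.

    Exact enumeration over all tables with the observed margins when the
    enumeration is small enough, otherwise a seeded Monte-Carlo estimate of
    the same tail (probability of tables no more probable than observed).
    """
    arr = np.asarray(table, dtype=int)
    if arr.ndim != 2 or arr.shape[0] != 2:
        raise ValueError("expected a 2xk table")
    if (arr < 0).any():
        raise ValueError("counts must be nonnegative")
    if arr.shape[1] == 2:
        return fisher_exact(arr)
    row = arr.sum(axis=1)
    col = arr.sum(axis=0)
    if (row == 0).any() or (col == 0).any():
        return FisherResult(1.0, True, False)
    n = int(arr.sum())

    def log_prob(first_row: np.ndarray) -> float:
        # multivariate hypergeometric log-pmf given margins
        lp = (
            math.lgamma(row[0] + 1)
            + math.lgamma(row[1] + 1)
            - math.lgamma(n + 1)
        )
        for j, c in enumerate(col):
            a = first_row[j]
            lp += math.lgamma(c + 1) - math.lgamma(a + 1) - math.lgamma(c - a + 1)
        return lp

    obs_lp = log_prob(arr[0])
    ranges = [range(min(row[0], c) + 1) for c in col[:-1]]
    n_tables = float(np.prod([len(r) for r in ranges])) if ranges else 1.0
    eps = 1e-9
    if n_tables <= max_enum_tables:
        total = 0.0
        for partial in product(*ranges):
            last = row[0] - sum(partial)
            if last < 0 or last > col[-1]:
                continue
            lp = log_prob(np.array(partial + (last,)))
            if lp <= obs_lp + eps:
                total += math.exp(lp)
        p = min(total, 1.0)
    else:
        rng = np.random.default_rng(seed)
        # sample tables from the null via permutation of group labels
        labels = np.repeat(np.arange(len(col)), col)
        hits = 0
        for _ in range(n_mc):
            rng.shuffle(labels)
            first = np.bincount(labels[: row[0]], minlength=len(col))
            if log_prob(first) <= obs_lp + eps:
                hits += 1
        p = (hits + 1) / (n_mc + 1)
    return FisherResult(float(p), False, p < SIGNIFICANCE_LEVEL)


def cohort_table(
    cases: pd.DataFrame,
    covariates: list[str],
    *,
    status_col: str = "status",
    na_token: str = "NA",
    seed: int = 0,
) -> pd.DataFrame:
    """Table-1-style per-covariate counts, percentages and Fisher p.

    ``cases`` needs one row per case with a Bethesda ``status`` column and
    categorical covariate columns (missing values as ``na_token`` or NaN).
    Percentages are reported under both denominator conventions: ``pct_total``
    divides by the full MSI column size (NA rows included, the printed-table
    convention) and ``pct_known`` by the non-NA count (the in-text
    convention).  The p-value comes from the non-NA 2xk table: Fisher's exact
    for k = 2, Freeman-Halton otherwise; single-category covariates get no
    test.
    """
    if status_col not in cases.columns:
        raise ValueError(f"missing status column {status_col!r}")
    is_h = cases[status_col] == "MSI-H"
    n_h, n_not = int(is_h.sum()), int((~is_h).sum())
    rows = []
    for cov in covariates:
        if cov not in cases.columns:
            raise ValueError(f"missing covariate column {cov!r}")
        col = cases[cov].astype(object).where(~cases[cov].isna(), na_token)
        if pd.api.types.is_numeric_dtype(cases[cov]) and cases[cov].nunique() > 12:
            raise ValueError(f"covariate {cov!r} is not categorical")
        known = col != na_token
        cats = [c for c in pd.unique(col[known])]
        counts = {
            cat: (
                int(((col == cat) & is_h).sum()),
                int(((col == cat) & ~is_h).sum()),
            )
            for cat in cats
        }
        known_h = int((known & is_h).sum())
        known_not = int((known & ~is_h).sum())
        if len(cats) >= 2:
            tab = np.array(
                [[counts[c][0] for c in cats], [counts[c][1] for c in cats]]
            )
            res = freeman_halton(tab, seed=seed)
            p_value, degenerate = res.p, res.degenerate
        else:
            p_value, degenerate = None, False
        for cat in cats:
            k_h, k_not = counts[cat]
            rows.append(
                {
                    "covariate": cov,
                    "category": cat,
                    "msih_n": k_h,
                    "msih_pct_total": percent(k_h, n_h) if n_h else None,
                    "msih_pct_known": percent(k_h, known_h) if known_h else None,
                    "mss_msil_n": k_not,
                    "mss_msil_pct_total": percent(k_not, n_not) if n_not else None,
                    "mss_msil_pct_known": percent(k_not, known_not) if known_not else None,
                    "p_value": p_value,
                    "degenerate": degenerate,
                }
            )
        n_na_h = int((~known & is_h).sum())
        n_na_not = int((~known & ~is_h).sum())
        if n_na_h or n_na_not:
            rows.append(
                {
                    "covariate": cov,
                    "category": na_token,
                    "msih_n": n_na_h,
                    "msih_pct_total": percent(n_na_h, n_h) if n_h else None,
                    "msih_pct_known": None,
                    "mss_msil_n": n_na_not,
                    "mss_msil_pct_total": percent(n_na_not, n_not) if n_not else None,
                    "mss_msil_pct_known": None,
                    "p_value": None,
                    "degenerate": False,
                }
            )
    return pd.DataFrame(rows)
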
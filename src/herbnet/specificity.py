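"""Disease-specific herb screening by relative risk and chi-square.

Case-cohort prescriptions form the exposure group, controls the non-exposure
group, and single herbs are the outcomes. All counts are herb *uses*, one use
per prescription containing the herb:

    RR = (n_ij / n_i) / ((n_j - n_ij) / (N - n_i))

with n_ij the uses of herb j in case prescriptions, n_i the total herb uses in
case prescriptions, n_j the total uses of herb j, and N the total herb uses
overall. Herbs with RR > 1 are screened by a Pearson chi-square on the 2x2
table (a, b, c, d) = (n_ij, n_i - n_ij, n_j - n_ij, N - n_i - n_j + n_ij) and
kept at p < 0.05 by default.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from scipy import stats

from .io import TransactionDB

__all__ = [
    "ExposureTable",
    "SpecificityResult",
    "exposure_tables",
    "relative_risk",
    "chi_square",
    "screen_specific_herbs",
]


@dataclass(frozen=True)
class ExposureTable:
    """Herb-use counts feeding the relative-risk contrast for one herb."""

    herb_id: str
    n_ij: int  # uses of the herb in case prescriptions
    n_i: int   # total herb uses in case prescriptions
    n_j: int   # total uses of the herb
    N: int     # total herb uses overall

    def __post_init__(self) -> None:
        if min(self.n_ij, self.n_i, self.n_j, self.N) < 0:
            raise ValueError("counts must be non-negative")
        if self.n_ij > min(self.n_i, self.n_j):
            raise ValueError(f"{self.herb_id}: n_ij exceeds a margin")
        if self.N < self.n_i + self.n_j - self.n_ij:
            raise ValueError(f"{self.herb_id}: N smaller than the union of margins")

    @property
    def cells(self) -> tuple[int, int, int, int]:
        """(a, b, c, d) of the 2x2 exposure-by-outcome table."""
        a = self.n_ij
        b = self.n_i - self.n_ij
        c = self.n_j - self.n_ij
        d = self.N - self.n_i - self.n_j + self.n_ij
        return a, b, c, d


def exposure_tables(db: TransactionDB) -> list[ExposureTable]:
    """One table per herb used in at least one case prescription.

    Counts are presence-based: a prescription containing the herb contributes
    one use regardless of repeated mentions.
    """
    counts = db.cohort_counts()
    if counts["case"] == 0 or counts["control"] == 0:
        raise ValueError("both cohorts must be present for a cohort contrast")
    case_db = db.filter_cohort("case")
    n_i = case_db.total_herb_uses()
    N = db.total_herb_uses()
    case_counts = case_db.herb_use_counts()
    all_counts = db.herb_use_counts()
    return [
        ExposureTable(herb_id=h, n_ij=case_counts[h], n_i=n_i, n_j=all_counts[h], N=N)
        for h in sorted(case_counts)
    ]


def relative_risk(t: ExposureTable) -> float:
    """Risk ratio of herb use, case vs control prescriptions.

    Returns ``math.inf`` (with a warning) when the herb never appears in the
    control group (n_j == n_ij) while being used in cases.
    """
    if t.n_i <= 0 or t.N <= t.n_i:
        raise ValueError("need n_i > 0 and N > n_i")
    numer = t.n_ij / t.n_i
    denom = (t.n_j - t.n_ij) / (t.N - t.n_i)
    if denom == 0.0:
        if numer == 0.0:
            return math.nan
        warnings.warn(
            f"{t.herb_id}: herb absent from control prescriptions; RR is infinite",
            stacklevel=2,
        )
        return math.inf
    return numer / denom


def chi_square(t: ExposureTable, correction: bool = False) -> tuple[float, float]:
    """Pearson chi-square (df=1) on the 2x2 table; returns (chi2, p).

    No continuity correction by default. Raises if any expected cell is zero
    (degenerate margins), matching the screen's exclusion rule.
    """
    a, b, c, d = t.cells
    n = a + b + c + d
    margins = ((a + b), (c + d), (a + c), (b + d))
    if any(m == 0 for m in margins):
        raise ValueError(f"{t.herb_id}: a margin is zero; expected cell count is 0")
    diff = a * d - b * c
    if correction:
        diff = max(abs(diff) - n / 2.0, 0.0)
    chi2 = n * diff * diff / (margins[0] * margins[1] * margins[2] * margins[3])
    p = float(stats.chi2.sf(chi2, df=1))
    return float(chi2), p


@dataclass(frozen=True)
class SpecificityResult:
    herb_id: str
    table: ExposureTable
    rr: float
    chi2: float
    p: float
    selected: bool


def screen_specific_herbs(
    db: TransactionDB,
    rr_min: float = 1.0,
    p_max: float = 0.05,
    correction: bool = False,
    bh: bool = False,
) -> list[SpecificityResult]:
    """Run the full RR + chi-square screen over every case-used herb.

    ``selected`` is True iff RR > ``rr_min`` and p < ``p_max`` (raw p by
    default; set ``bh`` to screen on Benjamini–Hochberg adjusted p instead).
    Herbs whose 2x2 table has a zero margin are excluded with a warning.
    """
    results: list[SpecificityResult] = []
    skipped: list[str] = []
    raw: list[tuple[ExposureTable, float, float, float]] = []
    for t in exposure_tables(db):
        try:
            chi2, p = chi_square(t, correction=correction)
        except ValueError:
            skipped.append(t.herb_id)
            continue
        raw.append((t, relative_risk(t), chi2, p))
    if skipped:
        warnings.warn(
            f"excluded {len(skipped)} herbs with degenerate 2x2 tables: "
            f"{skipped[:5]}...",
            stacklevel=2,
        )
    pvals = [p for *_, p in raw]
    if bh and pvals:
        from statsmodels.stats.multitest import multipletests

        _, p_adj, *_ = multipletests(pvals, method="fdr_bh")
    else:
        p_adj = pvals
    for (t, rr, chi2, p), padj in zip(raw, p_adj):
        selected = (rr > rr_min) and (padj < p_max)
        results.append(
            SpecificityResult(t.herb_id, t, rr=rr, chi2=chi2, p=float(p), selected=selected)
        )
    return results
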
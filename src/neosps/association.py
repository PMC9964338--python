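"""Per-variable association between indicators and blood-culture status.

Each of the eight indicators is cross-tabulated against culture result at
each timepoint and tested with the two-sided Fisher exact test.  The
two-sided p-value follows the point-probability rule: conditioning on both
margins, it sums the hypergeometric probabilities of every table whose
point probability does not exceed that of the observed table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .errors import ValidationError
from .scoring import INDICATOR_LABELS, INDICATORS

# Relative slack when comparing floating point probabilities, so exact
# ties in the hypergeometric pmf are counted as ties.
_GAMMA = 1e-7


def fisher_pvalues_for_margins(r1: int, r2: int, c1: int) -> tuple[np.ndarray, np.ndarray]:
    """Two-sided Fisher p for every table with row margins (r1, r2) and
    first-column margin c1.

    Returns the support of the top-left cell ``a`` and the matching p-values.
    Vectorised over the whole support: the pmf is computed once and the
    point-probability rule applied by sorting, which keeps exhaustive sweeps
    over margin sets fast.
    """
    n = r1 + r2
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = hypergeom.pmf(support, n, r1, c1)
    order = np.argsort(pmf, kind="stable")
    csum = np.cumsum(pmf[order])
    # For each observed a: sum of pmf over tables with pmf <= pmf(a)*(1+gamma)
    idx = np.searchsorted(pmf[order], pmf * (1 + _GAMMA), side="right")
    pvals = np.minimum(csum[idx - 1], 1.0)
    return support, pvals


def fisher_exact_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the 2x2 table [[a, b], [c, d]].

    ``a``/``b`` are the first row (e.g. indicator present/absent among
    culture-positives), ``c``/``d`` the second.  A table with an empty row
    or column carries no information and returns 1.0.
    """
    for name, v in zip("abcd", (a, b, c, d)):
        if v < 0 or int(v) != v:
            raise ValidationError(f"cell {name} must be a non-negative integer, got {v!r}")
    a, b, c, d = int(a), int(b), int(c), int(d)
    if a + b + c + d == 0:
        raise ValidationError("all four cells are zero; at least one margin must be positive")
    if min(a + b, c + d, a + c, b + d) == 0:
        return 1.0
    support, pvals = fisher_pvalues_for_margins(a + b, c + d, a + c)
    return float(pvals[support == a][0])


def render_p(p: float) -> str:
    """Report rendering: three decimals, '<0.001' below 0.0005."""
    return "<0.001" if p < 0.0005 else f"{p:.3f}"


@dataclass(frozen=True)
class VariableComparison:
    """One indicator's frequency comparison between culture groups."""

    variable: str
    timepoint: str
    count_pos: int
    n_pos: int
    count_neg: int
    n_neg: int
    p_value: float

    @property
    def frequency_pos(self) -> float:
        """Percent of culture-positive neonates with the indicator."""
        return 100.0 * self.count_pos / self.n_pos

    @property
    def frequency_neg(self) -> float:
        return 100.0 * self.count_neg / self.n_neg


def compare_counts(
    variable: str,
    timepoint: str,
    count_pos: int,
    n_pos: int,
    count_neg: int,
    n_neg: int,
) -> VariableComparison:
    """Build a comparison row from summary counts, testing with Fisher."""
    if not 0 <= count_pos <= n_pos:
        raise ValidationError(f"count_pos must be within [0, {n_pos}], got {count_pos}")
    if not 0 <= count_neg <= n_neg:
        raise ValidationError(f"count_neg must be within [0, {n_neg}], got {count_neg}")
    p = fisher_exact_two_sided(count_pos, n_pos - count_pos, count_neg, n_neg - count_neg)
    return VariableComparison(variable, timepoint, count_pos, n_pos, count_neg, n_neg, p)


def association_table(cohort: pd.DataFrame, timepoint: str) -> list[VariableComparison]:
    """Per-indicator comparison rows for one timepoint, in canonical order."""
    sel = cohort[cohort["timepoint"] == timepoint]
    if len(sel) == 0:
        raise ValidationError(f"no records for timepoint {timepoint!r}")
    pos = sel[sel["group"] == "pos"]
    neg = sel[sel["group"] == "neg"]
    rows = []
    for ind in INDICATORS:
        rows.append(
            compare_counts(
                ind,
                timepoint,
                int(pos[ind].sum()),
                len(pos),
                int(neg[ind].sum()),
                len(neg),
            )
        )
    return rows


def association_report(rows: list[VariableComparison]) -> pd.DataFrame:
    """Rendered comparison table: N (%) per group and p per row."""
    return pd.DataFrame(
        {
            "variable": [INDICATOR_LABELS.get(r.variable, r.variable) for r in rows],
            "timepoint": [r.timepoint for r in rows],
            "pos": [f"{r.count_pos} ({r.frequency_pos:.1f})" for r in rows],
            "neg": [f"{r.count_neg} ({r.frequency_neg:.1f})" for r in rows],
            "p": [render_p(r.p_value) for r in rows],
        }
    )
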
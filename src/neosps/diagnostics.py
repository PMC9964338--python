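"""2x2 confusion tables and diagnostic accuracy statistics.

A score cutoff cross-classified against blood-culture status yields a 2x2
table (TP/FP/FN/TN) from which the seven standard accuracy statistics are
computed:

    Se  = TP/(TP+FN)        Sp  = TN/(TN+FP)
    PPV = TP/(TP+FP)        NPV = TN/(TN+FN)
    PLR = Se/(1-Sp)         NLR = (1-Se)/Sp
    accuracy = (TP+TN)/N

Any statistic whose denominator is zero is *undefined* (``None``), rendered
as "-" in reports — in particular PLR when specificity is 1, the hallmark of
a cutoff no culture-negative neonate ever reached.

Tables can be built from patient-level records or reconstructed from a
published pair of summaries: the full score distribution of a cohort plus
the band-stratified counts of its culture-positive subgroup.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Iterable, Sequence

from scipy.stats import beta

from ._render import fmt_percent, fmt_ratio
from .errors import InconsistencyError, ValidationError
from .scoring import classify

if TYPE_CHECKING:  # pragma: no cover
    from .stratification import ScoreDistribution


@dataclass(frozen=True)
class TwoByTwo:
    """Cross-classification of predicted-septic (score >= cutoff) vs culture.

    ``tp``: cutoff-positive & culture-positive, ``fp``: cutoff-positive &
    culture-negative, ``fn``/``tn``: the cutoff-negative complements.
    """

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if isinstance(v, bool) or not float(v) == int(v) or v < 0:
                raise ValidationError(f"cell {name} must be a non-negative integer, got {v!r}")
            object.__setattr__(self, name, int(v))

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def n_positive(self) -> int:
        """Number of culture-positive neonates."""
        return self.tp + self.fn

    @property
    def n_negative(self) -> int:
        """Number of culture-negative neonates."""
        return self.fp + self.tn


@dataclass(frozen=True)
class DiagnosticMetrics:
    """The seven accuracy statistics; ``None`` marks an undefined value."""

    se: float | None
    sp: float | None
    plr: float | None
    nlr: float | None
    ppv: float | None
    npv: float | None
    accuracy: float | None

    def rendered(self) -> dict[str, str]:
        """Display form: percentages to 2 decimals half-up, ratios to 2."""
        return {
            "Se": fmt_percent(self.se),
            "Sp": fmt_percent(self.sp),
            "PLR": fmt_ratio(self.plr),
            "NLR": fmt_ratio(self.nlr),
            "PPV": fmt_percent(self.ppv),
            "NPV": fmt_percent(self.npv),
            "Accuracy": fmt_percent(self.accuracy),
        }


def _ratio(num: float, den: float) -> float | None:
    return None if den == 0 else num / den


def build_confusion(
    cohort: Iterable[tuple[int, bool]], cutoff: int
) -> TwoByTwo:
    """Tally a 2x2 table from (score, culture-positive) pairs at a cutoff."""
    tp = fp = fn = tn = 0
    n = 0
    for score, positive in cohort:
        n += 1
        predicted = classify(int(score), cutoff)
        if predicted and positive:
            tp += 1
        elif predicted and not positive:
            fp += 1
        elif positive:
            fn += 1
        else:
            tn += 1
    if n == 0:
        raise ValidationError("cannot build a confusion table from an empty cohort")
    return TwoByTwo(tp=tp, fp=fp, fn=fn, tn=tn)


def confusion_from_distributions(
    total_dist: "ScoreDistribution",
    septic_bands: "ScoreDistribution",
    cutoff: int,
) -> TwoByTwo:
    """Reconstruct a 2x2 table from published summary counts.

    ``total_dist`` carries the score distribution of the whole cohort at one
    timepoint; ``septic_bands`` the band-stratified counts of the
    culture-positive subgroup at the same timepoint.  The cutoff must fall on
    a band boundary of ``septic_bands`` so that septic counts at/above and
    below the cutoff are both derivable.
    """
    if septic_bands.bands is None:
        raise ValidationError("septic_bands must carry band counts")
    if not 1 <= cutoff <= 8:
        raise ValidationError(f"cutoff must be within [1, 8], got {cutoff!r}")
    if not any(lo == cutoff for (lo, _hi) in septic_bands.bands):
        raise ValidationError(
            f"cutoff {cutoff} does not align with a band boundary of "
            f"{sorted(septic_bands.bands)}"
        )
    tp = sum(c for (lo, _hi), c in septic_bands.bands.items() if lo >= cutoff)
    fn = sum(c for (lo, _hi), c in septic_bands.bands.items() if lo < cutoff)
    total_above = sum(c for s, c in total_dist.counts.items() if s >= cutoff)
    total_below = sum(c for s, c in total_dist.counts.items() if s < cutoff)
    fp = total_above - tp
    tn = total_below - fn
    if fp < 0:
        raise InconsistencyError(
            f"implied fp = {fp} < 0: septic count at/above cutoff exceeds cohort total"
        )
    if tn < 0:
        raise InconsistencyError(
            f"implied tn = {tn} < 0: septic count below cutoff exceeds cohort total"
        )
    return TwoByTwo(tp=tp, fp=fp, fn=fn, tn=tn)


def diagnostic_metrics(t: TwoByTwo) -> DiagnosticMetrics:
    """Compute the seven accuracy statistics from a 2x2 table.

    Zero-denominator statistics come back as ``None`` (undefined), never as
    an exception or an infinity; an all-zero table is rejected.
    """
    if t.n == 0:
        raise ValidationError("all-zero 2x2 table has no defined metrics")
    se = _ratio(t.tp, t.tp + t.fn)
    sp = _ratio(t.tn, t.tn + t.fp)
    plr = None if se is None or sp is None or sp == 1 else se / (1.0 - sp)
    nlr = None if se is None or sp is None or sp == 0 else (1.0 - se) / sp
    return DiagnosticMetrics(
        se=se,
        sp=sp,
        plr=plr,
        nlr=nlr,
        ppv=_ratio(t.tp, t.tp + t.fp),
        npv=_ratio(t.tn, t.tn + t.fn),
        accuracy=(t.tp + t.tn) / t.n,
    )


def clopper_pearson_ci(
    successes: int, n: int, level: float = 0.95
) -> tuple[float, float]:
    """Exact (Clopper-Pearson) binomial confidence interval for a proportion.

    Not part of the published analysis, which reports point estimates only;
    provided as an optional add-on for uncertainty statements.
    """
    if n < 1:
        raise ValidationError(f"n must be >= 1, got {n!r}")
    if not 0 <= successes <= n:
        raise ValidationError(f"successes must be within [0, {n}], got {successes!r}")
    if not 0.0 < level < 1.0:
        raise ValidationError(f"level must be in (0, 1), got {level!r}")
    alpha = 1.0 - level
    lower = 0.0 if successes == 0 else float(beta.ppf(alpha / 2, successes, n - successes + 1))
    upper = 1.0 if successes == n else float(beta.ppf(1 - alpha / 2, successes + 1, n - successes))
    return lower, upper


def metrics_report(rows: Sequence[tuple[str, DiagnosticMetrics]]):
    """Assemble labelled metric rows into a report table.

    Returns a pandas DataFrame shaped like the published diagnostic summary:
    one row per (cohort, timepoint) label with the seven rendered statistics.
    """
    import pandas as pd

    data = [{"label": label, **m.rendered()} for label, m in rows]
    return pd.DataFrame(data).set_index("label")
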
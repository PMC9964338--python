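"""Score distributions, risk-band stratification and cutoff sweeps.

The published analysis stratifies neonates into three risk bands — scores
0-2 (low suspicion), 3-4 (strong suspicion) and 5-8 (sepsis effectively
certain, since no culture-negative neonate ever reached 5) — and evaluates
every cutoff of interest against blood-culture status.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from ._render import truncate
from .diagnostics import DiagnosticMetrics, TwoByTwo, build_confusion, diagnostic_metrics
from .errors import ValidationError
from .scoring import MAX_SCORE, MIN_SCORE

#: The published risk bands: low / strong suspicion / definite.
DEFAULT_BANDS = ((0, 2), (3, 4), (5, 8))


def band_label(band: tuple[int, int]) -> str:
    return f"{band[0]}-{band[1]}"


@dataclass(frozen=True)
class ScoreDistribution:
    """Neonate counts per score value 0-8, for one cohort slice.

    All nine score values are always materialised (zero counts included).
    ``bands`` optionally carries band-aggregated counts keyed by
    ``(lo, hi)`` inclusive score ranges.
    """

    counts: dict[int, int]
    label: str = ""
    bands: dict[tuple[int, int], int] | None = field(default=None)

    def __post_init__(self) -> None:
        full = {s: 0 for s in range(MIN_SCORE, MAX_SCORE + 1)}
        for s, c in self.counts.items():
            if not MIN_SCORE <= int(s) <= MAX_SCORE:
                raise ValidationError(f"score {s!r} outside [0, 8]")
            if c < 0:
                raise ValidationError(f"count for score {s} must be >= 0, got {c!r}")
            full[int(s)] = int(c)
        object.__setattr__(self, "counts", full)

    @property
    def n(self) -> int:
        return sum(self.counts.values())

    def band_percentages(self, ndigits: int = 2) -> dict[tuple[int, int], float]:
        """Band shares of the cohort, as percentages truncated to ``ndigits``.

        Truncation (not rounding) matches the published stratification
        table's formatting.
        """
        if self.bands is None:
            raise ValidationError("distribution has no bands; call band_stratification first")
        # banded-only summaries (no per-score resolution) size from the bands
        n = self.n or sum(self.bands.values())
        if n == 0:
            raise ValidationError("cannot take percentages of an empty distribution")
        return {b: truncate(100.0 * c / n, ndigits) for b, c in self.bands.items()}


def score_distribution(
    cohort: pd.DataFrame,
    timepoint: str,
    group: str | None = None,
    label: str = "",
) -> ScoreDistribution:
    """Tally scores 0-8 for one timepoint, optionally one culture group.

    ``cohort`` is a tidy frame with one row per neonate-timepoint carrying
    ``timepoint``, ``group`` and ``score`` columns (see :mod:`neosps.io`).
    """
    sel = cohort[cohort["timepoint"] == timepoint]
    if group is not None:
        sel = sel[sel["group"] == group]
    if len(sel) == 0:
        raise ValidationError(
            f"no records for timepoint {timepoint!r}" + (f", group {group!r}" if group else "")
        )
    tally = sel["score"].value_counts().to_dict()
    return ScoreDistribution(
        counts={int(s): int(c) for s, c in tally.items()},
        label=label or f"{timepoint}" + (f"/{group}" if group else ""),
    )


def band_stratification(
    dist: ScoreDistribution,
    bands: tuple[tuple[int, int], ...] = DEFAULT_BANDS,
) -> ScoreDistribution:
    """Aggregate a score distribution into risk bands.

    ``bands`` must partition the score range 0-8 into contiguous inclusive
    intervals.
    """
    covered: list[int] = []
    for lo, hi in bands:
        if lo > hi:
            raise ValidationError(f"band ({lo}, {hi}) has lo > hi")
        covered.extend(range(lo, hi + 1))
    if sorted(covered) != list(range(MIN_SCORE, MAX_SCORE + 1)):
        raise ValidationError(f"bands {bands!r} do not partition the score range 0-8")
    band_counts = {
        (lo, hi): sum(dist.counts[s] for s in range(lo, hi + 1)) for lo, hi in bands
    }
    return ScoreDistribution(counts=dist.counts, label=dist.label, bands=band_counts)


def threshold_sweep(
    cohort: pd.DataFrame,
    timepoint: str,
    cutoffs: tuple[int, ...] = tuple(range(1, 9)),
) -> list[tuple[int, TwoByTwo, DiagnosticMetrics]]:
    """Evaluate every cutoff on a scored cohort at one timepoint.

    Raising the cutoff can only shrink the predicted-positive set, so tp is
    non-increasing and tn non-decreasing along the sweep.
    """
    sel = cohort[cohort["timepoint"] == timepoint]
    if len(sel) == 0:
        raise ValidationError(f"no records for timepoint {timepoint!r}")
    pairs = [
        (int(s), g == "pos") for s, g in zip(sel["score"], sel["group"])
    ]
    out = []
    for cutoff in cutoffs:
        table = build_confusion(pairs, cutoff)
        out.append((cutoff, table, diagnostic_metrics(table)))
    return out


def sweep_from_distributions(
    total_dist: ScoreDistribution,
    septic_dist: ScoreDistribution,
    cutoffs: tuple[int, ...] = tuple(range(1, 9)),
) -> list[tuple[int, TwoByTwo, DiagnosticMetrics]]:
    """Cutoff sweep from a cohort score distribution plus the septic-subgroup
    score distribution (score-resolved, not banded)."""
    out = []
    for cutoff in cutoffs:
        tp = sum(c for s, c in septic_dist.counts.items() if s >= cutoff)
        fn = septic_dist.n - tp
        above = sum(c for s, c in total_dist.counts.items() if s >= cutoff)
        table = TwoByTwo(tp=tp, fp=above - tp, fn=fn, tn=(total_dist.n - above) - fn)
        out.append((cutoff, table, diagnostic_metrics(table)))
    return out


def distribution_table(dists: list[ScoreDistribution], facsimile: bool = False) -> pd.DataFrame:
    """Side-by-side score-distribution columns, one per labelled slice.

    With ``facsimile=True`` zero counts render as "-" as in the published
    table; otherwise counts stay numeric.
    """
    frame = pd.DataFrame(
        {d.label: [d.counts[s] for s in range(MIN_SCORE, MAX_SCORE + 1)] for d in dists},
        index=pd.Index(range(MIN_SCORE, MAX_SCORE + 1), name="score"),
    )
    if facsimile:
        frame = frame.map(lambda c: "-" if c == 0 else str(c))
    return frame
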
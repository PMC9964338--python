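"""Published summary counts of the two score-evaluation cohorts, and the
machinery that reconstructs the diagnostic results from them.

The original patient-level data were never deposited; what the publication
prints are summary tables: per-variable counts by culture group and
timepoint, the score distribution of each cohort, the band-stratified
counts of the culture-positive subgroups, and a seven-statistic diagnostic
summary for the score >= 3 cutoff.  Those counts are transcribed here as
module constants — they are the only inputs the reconstruction needs.

Reconstruction cross-classifies band counts against the full score
distribution to recover each timepoint's 2x2 table, recomputes every
diagnostic statistic, and compares cell by cell with the printed values at
their printed precision.  Cells that cannot be reproduced from the printed
counts (two sensitivity cells whose printed values are decimal-shift typos
of the derivable ones, a scrambled p-value column, one frequency cell) are
flagged in a discrepancy report rather than silently corrected.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from ._render import round_half_up, truncate
from .association import compare_counts, render_p
from .diagnostics import (
    DiagnosticMetrics,
    TwoByTwo,
    confusion_from_distributions,
    diagnostic_metrics,
)
from .scoring import INDICATOR_LABELS, INDICATORS
from .stratification import DEFAULT_BANDS, ScoreDistribution, band_label

TIMEPOINTS = ("48h", "24h", "0h")

_METRIC_KINDS = {
    "Se": "percent",
    "Sp": "percent",
    "PLR": "ratio",
    "NLR": "ratio",
    "PPV": "percent",
    "NPV": "percent",
    "Accuracy": "percent",
}


@dataclass(frozen=True)
class StudyTables:
    """All printed summaries of one cohort."""

    name: str
    n_pos: int
    n_neg: int
    #: timepoint -> indicator -> (count in BC+ group, count in BC- group)
    indicator_counts: dict
    #: timepoint -> indicator -> printed p-value string
    printed_p: dict
    #: timepoint -> indicator -> (printed % in BC+ group, printed % in BC-)
    printed_freq: dict
    #: timepoint -> counts for scores 0..8 over the whole cohort
    score_counts: dict
    #: timepoint -> (count 0-2, count 3-4, count 5-8) among BC+ neonates
    septic_bands: dict
    #: timepoint -> printed band percentage strings ('-' for an empty band)
    printed_band_pct: dict
    #: timepoint -> metric name -> printed diagnostic cell for cutoff 3
    printed_diagnostics: dict
    #: per-group categorical probabilities for metadata sampling
    demographics: dict

    @property
    def n(self) -> int:
        return self.n_pos + self.n_neg


def _freqs(counts: dict, n: float) -> dict:
    return {k: v / n for k, v in counts.items()}


DERIVATION = StudyTables(
    name="derivation",
    n_pos=63,
    n_neg=57,
    indicator_counts={
        "48h": {"fever": (6, 0), "feeding": (6, 1), "circulation": (18, 4),
                "o2_increase": (18, 6), "respiratory": (20, 1), "glucose": (24, 1),
                "platelets": (17, 2), "crp": (11, 7)},
        "24h": {"fever": (8, 4), "feeding": (8, 1), "circulation": (24, 11),
                "o2_increase": (20, 3), "respiratory": (23, 1), "glucose": (24, 1),
                "platelets": (19, 5), "crp": (18, 12)},
        "0h": {"fever": (28, 9), "feeding": (23, 3), "circulation": (54, 8),
               "o2_increase": (29, 2), "respiratory": (28, 1), "glucose": (39, 2),
               "platelets": (24, 7), "crp": (40, 20)},
    },
    printed_p={
        "48h": {"fever": "0.029", "feeding": "<0.001", "circulation": "0.117",
                "o2_increase": "<0.001", "respiratory": "0.465", "glucose": "0.004",
                "platelets": "0.021", "crp": "<0.001"},
        "24h": {"fever": "0.370", "feeding": "0.034", "circulation": "0.028",
                "o2_increase": "<0.001", "respiratory": "<0.001", "glucose": "<0.001",
                "platelets": "0.005", "crp": "0.402"},
        "0h": {"fever": "0.001", "feeding": "<0.001", "circulation": "<0.001",
               "o2_increase": "<0.001", "respiratory": "<0.001", "glucose": "<0.001",
               "platelets": "0.002", "crp": "0.003"},
    },
    printed_freq={
        "48h": {"fever": ("9.5", "0"), "feeding": ("9.5", "1.8"),
                "circulation": ("28.6", "7"), "o2_increase": ("28.6", "10.5"),
                "respiratory": ("31.7", "1.8"), "glucose": ("38.1", "1.8"),
                "platelets": ("27", "3.5"), "crp": ("17.5", "12.3")},
        "24h": {"fever": ("12.7", "7"), "feeding": ("12.7", "1.8"),
                "circulation": ("38.1", "19.3"), "o2_increase": ("31.7", "5.3"),
                "respiratory": ("36.5", "1.8"), "glucose": ("38.1", "1.8"),
                "platelets": ("30.2", "8.8"), "crp": ("28.6", "21.1")},
        "0h": {"fever": ("44.4", "15.8"), "feeding": ("36.5", "5.3"),
               "circulation": ("87.5", "14"), "o2_increase": ("46", "3.5"),
               "respiratory": ("44.4", "1.8"), "glucose": ("61.9", "3.5"),
               "platelets": ("38.1", "12.3"), "crp": ("63.5", "35.1")},
    },
    score_counts={
        "48h": [65, 22, 8, 8, 9, 5, 2, 1, 0],
        "24h": [47, 26, 16, 15, 7, 5, 2, 2, 0],
        "0h": [31, 16, 13, 15, 16, 11, 15, 3, 0],
    },
    septic_bands={"48h": (40, 15, 8), "24h": (35, 19, 9), "0h": (11, 23, 29)},
    printed_band_pct={
        "48h": ("63.49", "23.8", "12.69"),
        "24h": ("55.55", "30.15", "14.28"),
        "0h": ("17.46", "36.50", "46.03"),
    },
    printed_diagnostics={
        "48h": {"Se": "36.51", "Sp": "96.49", "PLR": "10.40", "NLR": "0.66",
                "PPV": "92.00", "NPV": "57.89", "Accuracy": "65"},
        "24h": {"Se": "44.44", "Sp": "94.74", "PLR": "8.44", "NLR": "0.59",
                "PPV": "90.32", "NPV": "60.67", "Accuracy": "68.33"},
        "0h": {"Se": "82.54", "Sp": "85.96", "PLR": "5.88", "NLR": "0.20",
               "PPV": "86.67", "NPV": "81.67", "Accuracy": "84.17"},
    },
    demographics={
        "pos": {
            "sex": _freqs({"male": 40, "female": 23}, 63),
            "ga_class": _freqs({"term": 18, "extremely_preterm": 11,
                                "very_preterm": 13, "late_preterm": 21}, 63),
            "bw_class": _freqs({"normal": 23, "extremely_low": 10,
                                "very_low": 7, "low": 23}, 63),
        },
        "neg": {
            "sex": _freqs({"male": 30, "female": 27}, 57),
            "ga_class": _freqs({"term": 29, "extremely_preterm": 0,
                                "very_preterm": 7, "late_preterm": 21}, 57),
            "bw_class": _freqs({"normal": 43, "extremely_low": 0,
                                "very_low": 2, "low": 12}, 57),
        },
    },
)

VALIDATION = StudyTables(
    name="validation",
    n_pos=94,
    n_neg=51,
    indicator_counts={
        "48h": {"fever": (2, 1), "feeding": (7, 1), "circulation": (5, 0),
                "o2_increase": (5, 0), "respiratory": (4, 3), "glucose": (1, 0),
                "platelets": (0, 1), "crp": (7, 0)},
        "24h": {"fever": (2, 0), "feeding": (11, 7), "circulation": (9, 0),
                "o2_increase": (10, 4), "respiratory": (13, 7), "glucose": (4, 0),
                "platelets": (1, 1), "crp": (16, 1)},
        "0h": {"fever": (66, 16), "feeding": (28, 13), "circulation": (67, 22),
               "o2_increase": (19, 7), "respiratory": (26, 12), "glucose": (14, 4),
               "platelets": (19, 1), "crp": (87, 28)},
    },
    printed_p={
        "48h": {"fever": "1.000", "feeding": "0.260", "circulation": "0.162",
                "o2_increase": "0.162", "respiratory": "0.696", "glucose": "1.000",
                "platelets": "0.351", "crp": "0.052"},
        "24h": {"fever": "0.540", "feeding": "0.793", "circulation": "0.026",
                "o2_increase": "0.770", "respiratory": "1.000", "glucose": "0.297",
                "platelets": "1.000", "crp": "0.006"},
        "0h": {"fever": "<0.001", "feeding": "0.700", "circulation": "0.001",
               "o2_increase": "0.373", "respiratory": "0.693", "glucose": "0.294",
               "platelets": "0.002", "crp": "<0.001"},
    },
    printed_freq={
        "48h": {"fever": ("2.1", "2"), "feeding": ("7.4", "2"),
                "circulation": ("5.3", "0"), "o2_increase": ("5.3", "0"),
                "respiratory": ("4.2", "5.9"), "glucose": ("1.1", "0"),
                "platelets": ("0", "2"), "crp": ("7.4", "0")},
        "24h": {"fever": ("2.1", "0"), "feeding": ("11.7", "13.7"),
                "circulation": ("9.6", "0"), "o2_increase": ("10.6", "7.8"),
                "respiratory": ("13.8", "13.7"), "glucose": ("4.2", "0"),
                "platelets": ("1", "2"), "crp": ("17", "2")},
        "0h": {"fever": ("70.2", "31.4"), "feeding": ("29.8", "25.5"),
               "circulation": ("71.2", "43.1"), "o2_increase": ("20.2", "13.7"),
               "respiratory": ("27.6", "23.5"), "glucose": ("14.9", "7.8"),
               "platelets": ("20.2", "2"), "crp": ("92.5", "54.9")},
    },
    score_counts={
        "48h": [123, 15, 1, 4, 2, 0, 0, 0, 0],
        "24h": [92, 33, 12, 4, 3, 1, 0, 0, 0],
        "0h": [2, 16, 41, 42, 30, 4, 6, 3, 1],
    },
    septic_bands={"48h": (88, 6, 0), "24h": (86, 7, 1), "0h": (22, 58, 14)},
    printed_band_pct={
        "48h": ("93.61", "6.38", "-"),
        "24h": ("91.48", "7.44", "1.06"),
        "0h": ("23.4", "61.7", "14.89"),
    },
    printed_diagnostics={
        "48h": {"Se": "63.8", "Sp": "100", "PLR": "-", "NLR": "0.94",
                "PPV": "100", "NPV": "36.69", "Accuracy": "39.31"},
        "24h": {"Se": "85.1", "Sp": "100", "PLR": "-", "NLR": "0.91",
                "PPV": "100", "NPV": "37.23", "Accuracy": "40.69"},
        "0h": {"Se": "76.60", "Sp": "72.55", "PLR": "2.79", "NLR": "0.32",
               "PPV": "83.72", "NPV": "62.71", "Accuracy": "75.17"},
    },
    demographics={
        "pos": {
            "sex": _freqs({"male": 56, "female": 38}, 94),
            "ga_class": _freqs({"term": 24, "extremely_preterm": 4,
                                "very_preterm": 22, "late_preterm": 44}, 94),
            "bw_class": _freqs({"normal": 28, "extremely_low": 8,
                                "very_low": 14, "low": 44}, 94),
        },
        "neg": {
            "sex": _freqs({"male": 28, "female": 23}, 51),
            "ga_class": _freqs({"term": 5, "extremely_preterm": 9,
                                "very_preterm": 9, "late_preterm": 28}, 51),
            "bw_class": _freqs({"normal": 9, "extremely_low": 5,
                                "very_low": 17, "low": 20}, 51),
        },
    },
)

STUDIES = {"derivation": DERIVATION, "validation": VALIDATION}

#: Printed band percentages for the pooled culture-positive neonates (157).
POOLED_PRINTED_BAND_PCT = {
    "48h": ("81.52", "13.37", "5.09"),
    "24h": ("77.07", "16.56", "6.36"),
    "0h": ("21.01", "51.59", "27.38"),
}


def total_distribution(study: StudyTables, timepoint: str) -> ScoreDistribution:
    """Whole-cohort score distribution at one timepoint."""
    counts = dict(enumerate(study.score_counts[timepoint]))
    return ScoreDistribution(counts=counts, label=f"{study.name}/{timepoint}")


def septic_band_distribution(study: StudyTables, timepoint: str) -> ScoreDistribution:
    """Band-stratified counts of the culture-positive subgroup.

    The publication gives no per-score resolution for this subgroup, so the
    returned distribution carries bands only (score counts are all zero and
    must not be read).
    """
    bands = dict(zip(DEFAULT_BANDS, study.septic_bands[timepoint]))
    return ScoreDistribution(counts={}, label=f"{study.name}/{timepoint}/septic", bands=bands)


def pooled_septic_bands(timepoint: str) -> ScoreDistribution:
    """Band counts over both cohorts' culture-positive neonates combined."""
    bands = {
        b: DERIVATION.septic_bands[timepoint][i] + VALIDATION.septic_bands[timepoint][i]
        for i, b in enumerate(DEFAULT_BANDS)
    }
    dist = ScoreDistribution(counts={}, label=f"pooled/{timepoint}/septic", bands=bands)
    return dist


def reconstructed_confusion(study: StudyTables, timepoint: str, cutoff: int = 3) -> TwoByTwo:
    """Recover the timepoint's 2x2 table from the printed summaries."""
    return confusion_from_distributions(
        total_distribution(study, timepoint),
        septic_band_distribution(study, timepoint),
        cutoff,
    )


def _matches_printed(printed: str, value: float | None, kind: str) -> bool:
    """Compare a computed statistic with a printed cell at its precision."""
    if printed == "-":
        return value is None
    if value is None:
        return False
    ndigits = len(printed.split(".")[1]) if "." in printed else 0
    shown = value * 100.0 if kind == "percent" else value
    return round_half_up(shown, ndigits) == float(printed)


@dataclass(frozen=True)
class CellFlag:
    """A printed cell that the counts cannot reproduce."""

    table: str
    study: str
    timepoint: str
    cell: str
    printed: str
    computed: str


def reproduce_diagnostics(cutoff: int = 3):
    """Recompute every diagnostic cell from counts and diff against print.

    Returns ``(frame, flags)``: a six-row report with the reconstructed 2x2
    cells and rendered statistics, and the list of printed cells that do not
    match the reconstruction at their printed precision.
    """
    rows = []
    flags: list[CellFlag] = []
    for study in STUDIES.values():
        for tp in TIMEPOINTS:
            table = reconstructed_confusion(study, tp, cutoff)
            metrics = diagnostic_metrics(table)
            rendered = metrics.rendered()
            rows.append(
                {
                    "study": study.name,
                    "timepoint": tp,
                    "tp": table.tp,
                    "fp": table.fp,
                    "fn": table.fn,
                    "tn": table.tn,
                    **rendered,
                }
            )
            for metric, kind in _METRIC_KINDS.items():
                printed = study.printed_diagnostics[tp][metric]
                value = getattr(metrics, metric.lower())
                if not _matches_printed(printed, value, kind):
                    flags.append(
                        CellFlag(
                            table="diagnostics",
                            study=study.name,
                            timepoint=tp,
                            cell=metric,
                            printed=printed,
                            computed=rendered[metric],
                        )
                    )
    return pd.DataFrame(rows), flags


# Soft tolerance for printed p-values: the publication's statistics package
# truncated the third decimal in several cells, so agreement is judged to
# within one unit in the last printed digit.
_P_TOL = 0.001


def pvalue_report() -> pd.DataFrame:
    """Recompute every per-variable exact test and diff against printed p.

    A row is ``consistent`` when the recomputed two-sided Fisher p agrees
    with the printed value to within one unit in the third decimal (printed
    '<0.001' cells must recompute below 0.002).
    """
    rows = []
    for study in STUDIES.values():
        for tp in TIMEPOINTS:
            for ind in INDICATORS:
                cp, cn = study.indicator_counts[tp][ind]
                comp = compare_counts(ind, tp, cp, study.n_pos, cn, study.n_neg)
                printed = study.printed_p[tp][ind]
                if printed.startswith("<"):
                    consistent = comp.p_value < float(printed[1:]) + _P_TOL
                else:
                    consistent = abs(comp.p_value - float(printed)) <= _P_TOL + 1e-12
                rows.append(
                    {
                        "study": study.name,
                        "timepoint": tp,
                        "variable": ind,
                        "count_pos": cp,
                        "count_neg": cn,
                        "computed_p": render_p(comp.p_value),
                        "printed_p": printed,
                        "consistent": consistent,
                    }
                )
    return pd.DataFrame(rows)


def frequency_report() -> pd.DataFrame:
    """Diff printed group frequencies against count/n at printed precision.

    Agreement is judged to within one unit in the last printed digit, which
    absorbs truncate-versus-round ambiguity in the printed cells.
    """
    rows = []
    for study in STUDIES.values():
        for tp in TIMEPOINTS:
            for ind in INDICATORS:
                cp, cn = study.indicator_counts[tp][ind]
                for grp, count, n in (("pos", cp, study.n_pos), ("neg", cn, study.n_neg)):
                    printed = study.printed_freq[tp][ind][0 if grp == "pos" else 1]
                    ndigits = len(printed.split(".")[1]) if "." in printed else 0
                    ulp = 10.0**-ndigits
                    computed = 100.0 * count / n
                    rows.append(
                        {
                            "study": study.name,
                            "timepoint": tp,
                            "variable": ind,
                            "group": grp,
                            "computed_pct": round_half_up(computed, 2),
                            "printed_pct": printed,
                            "consistent": abs(computed - float(printed)) <= ulp + 1e-12,
                        }
                    )
    return pd.DataFrame(rows)


def band_percentage_report() -> pd.DataFrame:
    """Recompute septic band percentages (truncated) and diff against print."""
    rows = []
    sources = [(s.name, s.septic_bands, s.printed_band_pct, s.n_pos) for s in STUDIES.values()]
    sources.append(
        (
            "pooled",
            {
                tp: tuple(
                    DERIVATION.septic_bands[tp][i] + VALIDATION.septic_bands[tp][i]
                    for i in range(3)
                )
                for tp in TIMEPOINTS
            },
            POOLED_PRINTED_BAND_PCT,
            DERIVATION.n_pos + VALIDATION.n_pos,
        )
    )
    for name, bands, printed_pct, n in sources:
        for tp in TIMEPOINTS:
            for i, band in enumerate(DEFAULT_BANDS):
                count = bands[tp][i]
                printed = printed_pct[tp][i]
                computed = truncate(100.0 * count / n, 2)
                if printed == "-":
                    consistent = count == 0
                else:
                    ndigits = len(printed.split(".")[1]) if "." in printed else 0
                    consistent = truncate(100.0 * count / n, ndigits) == float(printed)
                rows.append(
                    {
                        "study": name,
                        "timepoint": tp,
                        "band": band_label(band),
                        "count": count,
                        "computed_pct": computed,
                        "printed_pct": printed,
                        "consistent": consistent,
                    }
                )
    return pd.DataFrame(rows)


def discrepancy_report() -> pd.DataFrame:
    """Every printed cell the counts cannot reproduce, across all tables."""
    _frame, flags = reproduce_diagnostics()
    rows = [
        {
            "table": f.table,
            "study": f.study,
            "timepoint": f.timepoint,
            "cell": f.cell,
            "printed": f.printed,
            "computed": f.computed,
        }
        for f in flags
    ]
    pv = pvalue_report()
    for _, r in pv[~pv["consistent"]].iterrows():
        rows.append(
            {
                "table": "per-variable p",
                "study": r["study"],
                "timepoint": r["timepoint"],
                "cell": r["variable"],
                "printed": r["printed_p"],
                "computed": r["computed_p"],
            }
        )
    fr = frequency_report()
    for _, r in fr[~fr["consistent"]].iterrows():
        rows.append(
            {
                "table": "per-variable frequency",
                "study": r["study"],
                "timepoint": r["timepoint"],
                "cell": f"{r['variable']}/{r['group']}",
                "printed": r["printed_pct"],
                "computed": f"{r['computed_pct']}",
            }
        )
    bp = band_percentage_report()
    for _, r in bp[~bp["consistent"]].iterrows():
        rows.append(
            {
                "table": "septic bands",
                "study": r["study"],
                "timepoint": r["timepoint"],
                "cell": r["band"],
                "printed": r["printed_pct"],
                "computed": f"{r['computed_pct']}",
            }
        )
    return pd.DataFrame(rows)
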
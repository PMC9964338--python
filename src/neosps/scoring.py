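"""Sepsis Prediction Score (SPS): indicator derivation and score computation.

The SPS summarises a septic-appearing neonate's state as the count of eight
equally weighted binary indicators: fever, feeding-volume decrease, peripheral
circulatory disturbance, increased oxygen requirement, respiratory
deterioration, blood-glucose change, thrombocytopenia and elevated CRP.
Raw clinical/laboratory measurements are dichotomised by strict threshold
comparisons; boundary values never score.  The score ranges 0-8 and a neonate
is classified as predicted-septic when the score reaches a chosen cutoff
(the primary operating point is a score of 3 or more).
"""

from __future__ import annotations

from dataclasses import dataclass, fields

from .errors import ValidationError

#: Canonical indicator order, matching the published per-variable tables.
INDICATORS = (
    "fever",
    "feeding",
    "circulation",
    "o2_increase",
    "respiratory",
    "glucose",
    "platelets",
    "crp",
)

#: Human-readable labels for reports, in canonical order.
INDICATOR_LABELS = {
    "fever": "Fever > 38 °C",
    "feeding": "Feeding volume decrease > 20%",
    "circulation": "Disturbances of peripheral circulation",
    "o2_increase": "Increase in O2 requirements",
    "respiratory": "Respiratory symptoms",
    "glucose": "Blood glucose change > 50%",
    "platelets": "Platelet count < 150,000/mm3",
    "crp": "CRP > 1 mg/dL",
}

MIN_SCORE = 0
MAX_SCORE = 8


@dataclass(frozen=True)
class ThresholdConfig:
    """Dichotomisation thresholds for the eight indicators.

    All comparisons against these values are strict (``>`` or ``<``): a
    temperature of exactly ``fever_temp`` does not count as fever, a platelet
    count of exactly ``platelet_floor`` does not count as thrombocytopenia.

    Parameters
    ----------
    fever_temp : float
        Body temperature above which the fever indicator fires (°C).
    feeding_decrease : float
        Relative decrease in feeding volume (or residuals) above which the
        feeding indicator fires (fraction, 0.20 = 20%).
    platelet_floor : float
        Platelet count below which the thrombocytopenia indicator fires
        (cells per mm³).
    glucose_change : float
        Absolute relative change of blood glucose from its reference above
        which the glucose indicator fires (fraction; covers both hyper- and
        hypoglycemia).
    crp_limit : float
        C-reactive protein level above which the CRP indicator fires (mg/dL).
    crt_limit : float
        Capillary refill time above which the circulation indicator fires
        (seconds); circulation also fires on hypotension regardless of CRT.
    """

    fever_temp: float = 38.0
    feeding_decrease: float = 0.20
    platelet_floor: float = 150_000.0
    glucose_change: float = 0.50
    crp_limit: float = 1.0
    crt_limit: float = 5.0

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not v > 0:
                raise ValidationError(f"threshold {f.name} must be strictly positive, got {v!r}")


@dataclass(frozen=True)
class RawObservation:
    """One neonate-timepoint's raw clinical/laboratory measurements.

    ``feeding_change`` and ``glucose_change`` are non-negative fractions
    relative to the caller-supplied reference (previous stable value); the
    package does not infer baselines.  ``o2_requirement_increase``, ``apnea``,
    ``hypotension`` and ``mech_vent_new_or_changed`` are clinical judgments
    carried as booleans — no numeric threshold exists for them.
    """

    temperature: float
    feeding_change: float
    platelet_count: float
    glucose_change: float
    crp: float
    crt: float
    hypotension: bool = False
    o2_requirement_increase: bool = False
    apnea: bool = False
    mech_vent_new_or_changed: bool = False

    def __post_init__(self) -> None:
        if not 30.0 <= self.temperature <= 45.0:
            raise ValidationError(
                f"temperature must be within [30, 45] °C, got {self.temperature!r}"
            )
        for name in ("feeding_change", "platelet_count", "glucose_change", "crp", "crt"):
            v = getattr(self, name)
            if not v >= 0:
                raise ValidationError(f"{name} must be non-negative, got {v!r}")


@dataclass(frozen=True)
class IndicatorVector:
    """The eight binary SPS indicators for one neonate-timepoint."""

    fever: bool = False
    feeding: bool = False
    circulation: bool = False
    o2_increase: bool = False
    respiratory: bool = False
    glucose: bool = False
    platelets: bool = False
    crp: bool = False

    def as_tuple(self) -> tuple[bool, ...]:
        """Indicator values in canonical order."""
        return tuple(bool(getattr(self, name)) for name in INDICATORS)

    @property
    def score(self) -> int:
        return compute_sps(self)


def derive_indicators(
    raw: RawObservation, cfg: ThresholdConfig | None = None
) -> IndicatorVector:
    """Dichotomise raw observations into the eight SPS indicators.

    All numeric comparisons are strict, so values exactly at a threshold do
    not score.  The circulation indicator fires on slow capillary refill OR
    hypotension; the respiratory indicator on apnea OR a new/changed need for
    mechanical ventilation.
    """
    if cfg is None:
        cfg = ThresholdConfig()
    return IndicatorVector(
        fever=raw.temperature > cfg.fever_temp,
        feeding=raw.feeding_change > cfg.feeding_decrease,
        circulation=(raw.crt > cfg.crt_limit) or raw.hypotension,
        o2_increase=raw.o2_requirement_increase,
        respiratory=raw.apnea or raw.mech_vent_new_or_changed,
        glucose=raw.glucose_change > cfg.glucose_change,
        platelets=raw.platelet_count < cfg.platelet_floor,
        crp=raw.crp > cfg.crp_limit,
    )


def compute_sps(ind: IndicatorVector) -> int:
    """Sum the indicators into the score (one point each; range 0-8)."""
    return sum(ind.as_tuple())


def classify(score: int, cutoff: int = 3) -> bool:
    """Classify a neonate as predicted-septic iff ``score >= cutoff``."""
    if not MIN_SCORE <= score <= MAX_SCORE:
        raise ValidationError(f"score must be within [0, 8], got {score!r}")
    if not 1 <= cutoff <= MAX_SCORE:
        raise ValidationError(f"cutoff must be within [1, 8], got {cutoff!r}")
    return score >= cutoff
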
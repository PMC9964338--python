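"""Synthetic neonatal cohorts with the statistical structure the score
analysis assumes.

Each neonate belongs to a culture-positive or culture-negative group and
carries the eight binary indicators at three timepoints (48 h prior, 24 h
prior, and the day the blood culture was taken).  Indicators are Bernoulli
draws at configurable per-group/per-timepoint prevalences; the packaged
default configurations use the prevalences observed in the published
derivation (63 positive / 57 negative) and validation (94 / 51) cohorts.

Dependence between indicators, absent from the published summaries, is
modelled by a single latent severity variable per neonate-timepoint under a
Gaussian-copula (latent-threshold) construction: with latent correlation
``rho`` = 0 the indicators are independent and the score follows the
Poisson-binomial distribution, for which an exact pmf and closed-form
expected diagnostics are provided as analytic oracles.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import ndtri

from .diagnostics import DiagnosticMetrics
from .errors import UnsupportedConfigurationError, ValidationError
from .scoring import INDICATORS, IndicatorVector

TIMEPOINTS = ("48h", "24h", "0h")
GROUPS = ("pos", "neg")

#: Prevalence mapping type: group -> timepoint -> indicator -> probability.
PrevalenceMap = Mapping[str, Mapping[str, Mapping[str, float]]]


@dataclass(frozen=True)
class NeonateRecord:
    """A neonate with culture result, metadata and indicators per timepoint."""

    id: str
    culture_result: bool
    indicators: dict[str, IndicatorVector]
    sex: str | None = None
    ga_class: str | None = None
    bw_class: str | None = None


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the cohort generator.

    Parameters
    ----------
    n_pos, n_neg : int
        Culture-positive and culture-negative group sizes.
    prevalence : mapping
        Bernoulli probability per (group, timepoint, indicator).
    rho : float
        Latent correlation in [0, 1); 0 makes indicators independent.
    persistence : float
        Probability that an indicator true at the previous timepoint stays
        true, before any fresh draw.  Purely synthetic: the published data
        report only marginal frequencies, no transitions.  Values > 0
        inflate later-timepoint marginals above the configured prevalences.
    seed : int
        Root seed of the cohort's random generator.
    demographics : mapping or None
        Optional per-group category probabilities for ``sex`` /
        ``ga_class`` / ``bw_class`` metadata; metadata never influences the
        indicators.
    """

    n_pos: int
    n_neg: int
    prevalence: PrevalenceMap
    rho: float = 0.0
    persistence: float = 0.0
    seed: int = 0
    demographics: Mapping[str, Mapping[str, Mapping[str, float]]] | None = None
    name: str = "custom"

    def __post_init__(self) -> None:
        if self.n_pos < 1 or self.n_neg < 1:
            raise ValidationError("group sizes n_pos and n_neg must be >= 1")
        if not 0.0 <= self.rho < 1.0:
            raise ValidationError(f"rho must be in [0, 1), got {self.rho!r}")
        if not 0.0 <= self.persistence <= 1.0:
            raise ValidationError(f"persistence must be in [0, 1], got {self.persistence!r}")
        for g in GROUPS:
            for tp in TIMEPOINTS:
                for ind in INDICATORS:
                    p = self.prevalence[g][tp][ind]
                    if not 0.0 <= p <= 1.0:
                        raise ValidationError(
                            f"prevalence[{g}][{tp}][{ind}] = {p!r} outside [0, 1]"
                        )

    def prevalence_vector(self, group: str, timepoint: str) -> np.ndarray:
        """The eight probabilities in canonical indicator order."""
        return np.array([self.prevalence[group][timepoint][i] for i in INDICATORS])


def _sample_categorical(rng: np.random.Generator, probs: Mapping[str, float], size: int):
    labels = list(probs)
    p = np.asarray([probs[k] for k in labels], dtype=float)
    p = p / p.sum()
    return rng.choice(labels, size=size, p=p)


def _draw_indicators(
    rng: np.random.Generator, probs: np.ndarray, size: int, rho: float
) -> np.ndarray:
    """Latent-threshold draw: z_i = sqrt(rho) u + sqrt(1-rho) e_i < Phi^-1(p_i)."""
    with np.errstate(divide="ignore"):
        thresh = ndtri(probs)  # -inf at p=0, +inf at p=1
    if rho == 0.0:
        return rng.random((size, len(probs))) < probs
    u = rng.standard_normal((size, 1))
    e = rng.standard_normal((size, len(probs)))
    z = np.sqrt(rho) * u + np.sqrt(1.0 - rho) * e
    return z < thresh


def generate_cohort(cfg: SimulationConfig) -> pd.DataFrame:
    """Generate a tidy cohort frame, one row per neonate-timepoint.

    Deterministic for a fixed config and seed.  Columns: ``id``, ``group``,
    ``timepoint``, optional metadata, the eight indicator columns (0/1) in
    canonical order, and the ``score``.
    """
    rng = np.random.default_rng(cfg.seed)
    frames = []
    counter = 0
    for group, size in (("pos", cfg.n_pos), ("neg", cfg.n_neg)):
        ids = [f"N{counter + i + 1:04d}" for i in range(size)]
        counter += size
        meta = {}
        if cfg.demographics is not None:
            for col, probs in cfg.demographics[group].items():
                meta[col] = _sample_categorical(rng, probs, size)
        prev_ind: np.ndarray | None = None
        for tp in TIMEPOINTS:
            probs = cfg.prevalence_vector(group, tp)
            ind = _draw_indicators(rng, probs, size, cfg.rho)
            if cfg.persistence > 0.0 and prev_ind is not None:
                keep = rng.random(ind.shape) < cfg.persistence
                ind = (prev_ind & keep) | ind
            prev_ind = ind
            frame = pd.DataFrame({"id": ids, "group": group, "timepoint": tp, **meta})
            for j, name in enumerate(INDICATORS):
                frame[name] = ind[:, j].astype(int)
            frame["score"] = ind.sum(axis=1).astype(int)
            frames.append(frame)
    out = pd.concat(frames, ignore_index=True)
    order = {tp: i for i, tp in enumerate(TIMEPOINTS)}
    out = out.sort_values(["id", "timepoint"], key=lambda s: s.map(order) if s.name == "timepoint" else s)
    return out.reset_index(drop=True)


def cohort_to_records(cohort: pd.DataFrame) -> list[NeonateRecord]:
    """Convert a tidy cohort frame into per-neonate records."""
    records = []
    for nid, sub in cohort.groupby("id", sort=True):
        first = sub.iloc[0]
        indicators = {
            row["timepoint"]: IndicatorVector(**{k: bool(row[k]) for k in INDICATORS})
            for _, row in sub.iterrows()
        }
        records.append(
            NeonateRecord(
                id=str(nid),
                culture_result=first["group"] == "pos",
                indicators=indicators,
                sex=first.get("sex"),
                ga_class=first.get("ga_class"),
                bw_class=first.get("bw_class"),
            )
        )
    return records


def poisson_binomial_pmf(probs) -> np.ndarray:
    """Exact pmf of the score: sum of 8 independent non-identical Bernoullis.

    Dynamic-programming convolution over the indicators; reduces to
    Binomial(8, p) when all probabilities are equal.
    """
    probs = np.asarray(probs, dtype=float)
    if probs.shape != (len(INDICATORS),):
        raise ValidationError(f"expected {len(INDICATORS)} probabilities, got shape {probs.shape}")
    if np.any((probs < 0) | (probs > 1)):
        raise ValidationError("probabilities must lie in [0, 1]")
    pmf = np.zeros(len(probs) + 1)
    pmf[0] = 1.0
    for k, p in enumerate(probs):
        pmf[1 : k + 2] = pmf[1 : k + 2] * (1 - p) + pmf[: k + 1] * p
        pmf[0] *= 1 - p
    return pmf


def score_tail(pmf: np.ndarray, cutoff: int) -> float:
    """P(score >= cutoff) under a score pmf."""
    return float(pmf[cutoff:].sum())


def expected_metrics(cfg: SimulationConfig, timepoint: str, cutoff: int) -> DiagnosticMetrics:
    """Closed-form expected diagnostics under indicator independence.

    Sensitivity is the upper tail of the positive group's Poisson-binomial
    score distribution at the cutoff; specificity the complementary lower
    tail for the negative group; predictive values and accuracy follow from
    Bayes' rule at the configured prevalence n_pos / (n_pos + n_neg).
    """
    if cfg.rho != 0.0 or cfg.persistence != 0.0:
        raise UnsupportedConfigurationError(
            "closed-form metrics require rho = 0 and persistence = 0; "
            "use Monte-Carlo estimation over generate_cohort for dependent indicators"
        )
    if timepoint not in TIMEPOINTS:
        raise ValidationError(f"unknown timepoint {timepoint!r}")
    if not 1 <= cutoff <= 8:
        raise ValidationError(f"cutoff must be within [1, 8], got {cutoff!r}")
    se = score_tail(poisson_binomial_pmf(cfg.prevalence_vector("pos", timepoint)), cutoff)
    sp = 1.0 - score_tail(poisson_binomial_pmf(cfg.prevalence_vector("neg", timepoint)), cutoff)
    pi = cfg.n_pos / (cfg.n_pos + cfg.n_neg)
    pos_rate = se * pi + (1 - sp) * (1 - pi)
    neg_rate = (1 - se) * pi + sp * (1 - pi)
    return DiagnosticMetrics(
        se=se,
        sp=sp,
        plr=None if sp == 1.0 else se / (1.0 - sp),
        nlr=None if sp == 0.0 else (1.0 - se) / sp,
        ppv=None if pos_rate == 0 else se * pi / pos_rate,
        npv=None if neg_rate == 0 else sp * (1 - pi) / neg_rate,
        accuracy=se * pi + sp * (1 - pi),
    )


def _prevalences_from_counts(counts, n_pos: int, n_neg: int) -> PrevalenceMap:
    """Build the prevalence map from per-variable (count_pos, count_neg)."""
    return {
        "pos": {tp: {ind: counts[tp][ind][0] / n_pos for ind in INDICATORS} for tp in TIMEPOINTS},
        "neg": {tp: {ind: counts[tp][ind][1] / n_neg for ind in INDICATORS} for tp in TIMEPOINTS},
    }


def derivation_config(seed: int = 0, **overrides) -> SimulationConfig:
    """Packaged config emulating the derivation cohort (63 BC+ / 57 BC-)."""
    from .published import DERIVATION

    cfg = SimulationConfig(
        n_pos=DERIVATION.n_pos,
        n_neg=DERIVATION.n_neg,
        prevalence=_prevalences_from_counts(
            DERIVATION.indicator_counts, DERIVATION.n_pos, DERIVATION.n_neg
        ),
        demographics=DERIVATION.demographics,
        seed=seed,
        name="derivation2010",
    )
    return replace(cfg, **overrides) if overrides else cfg


def validation_config(seed: int = 0, **overrides) -> SimulationConfig:
    """Packaged config emulating the validation cohort (94 BC+ / 51 BC-)."""
    from .published import VALIDATION

    cfg = SimulationConfig(
        n_pos=VALIDATION.n_pos,
        n_neg=VALIDATION.n_neg,
        prevalence=_prevalences_from_counts(
            VALIDATION.indicator_counts, VALIDATION.n_pos, VALIDATION.n_neg
        ),
        demographics=VALIDATION.demographics,
        seed=seed,
        name="validation2017",
    )
    return replace(cfg, **overrides) if overrides else cfg


def backfill_raw(cohort: pd.DataFrame) -> pd.DataFrame:
    """Rewrite an indicator-level cohort in the raw-observation CSV dialect.

    A testing aid for the dichotomisation step, not a physiological model:
    each raw value is placed clearly on the scoring side of its default
    threshold when the indicator is true and clearly on the normal side
    otherwise, so deriving indicators from the result recovers the input.
    """
    out = cohort[["id", "group", "timepoint"]].copy()
    out["temperature"] = np.where(cohort["fever"].astype(bool), 38.6, 37.0)
    out["feeding_change"] = np.where(cohort["feeding"].astype(bool), 0.40, 0.0)
    out["platelet_count"] = np.where(cohort["platelets"].astype(bool), 90_000, 250_000)
    out["glucose_change"] = np.where(cohort["glucose"].astype(bool), 0.80, 0.10)
    out["crp"] = np.where(cohort["crp"].astype(bool), 4.0, 0.3)
    out["crt"] = np.where(cohort["circulation"].astype(bool), 7.0, 2.0)
    out["hypotension"] = 0
    out["o2_requirement_increase"] = cohort["o2_increase"].astype(int)
    out["apnea"] = cohort["respiratory"].astype(int)
    out["mech_vent_new_or_changed"] = 0
    return out
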
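"""Synthetic cohort generator and its analytic oracles."""

import itertools

import numpy as np
import pytest
from scipy.stats import binom

from neosps.errors import UnsupportedConfigurationError, ValidationError
from neosps.scoring import INDICATORS
from neosps.simulate import (
    GROUPS,
    TIMEPOINTS,
    SimulationConfig,
    backfill_raw,
    cohort_to_records,
    derivation_config,
    expected_metrics,
    generate_cohort,
    poisson_binomial_pmf,
    score_tail,
    validation_config,
)


def uniform_prevalence(p):
    return {g: {tp: {i: p for i in INDICATORS} for tp in TIMEPOINTS} for g in GROUPS}


def small_config(**kw):
    defaults = dict(n_pos=20, n_neg=15, prevalence=uniform_prevalence(0.3), seed=7)
    defaults.update(kw)
    return SimulationConfig(**defaults)


class TestGenerateCohort:
    def test_validation_preset_sizes(self):
        cohort = generate_cohort(validation_config(seed=1))
        assert cohort["id"].nunique() == 145
        assert len(cohort) == 145 * 3
        assert cohort.groupby("group")["id"].nunique().to_dict() == {"neg": 51, "pos": 94}

    def test_zero_prevalence_gives_zero_scores(self):
        cohort = generate_cohort(small_config(prevalence=uniform_prevalence(0.0)))
        assert (cohort["score"] == 0).all()

    def test_seed_determinism_byte_for_byte(self, tmp_path):
        paths = []
        for run in range(2):
            cohort = generate_cohort(derivation_config(seed=42))
            p = tmp_path / f"run{run}.csv"
            cohort.to_csv(p, index=False)
            paths.append(p.read_bytes())
        assert paths[0] == paths[1]
        assert generate_cohort(derivation_config(seed=43)).to_csv() != \
            generate_cohort(derivation_config(seed=42)).to_csv()

    def test_marginal_prevalences_converge(self):
        cfg = small_config(n_pos=10_000, n_neg=10_000, seed=3)
        cohort = generate_cohort(cfg)
        p, n = 0.3, 10_000
        # 4-sigma band: 48 simultaneous marginals, so a 3-sigma band would
        # be exceeded by chance in >10% of seeds
        band = 4 * np.sqrt(p * (1 - p) / n)
        for g in GROUPS:
            for tp in TIMEPOINTS:
                sel = cohort[(cohort["group"] == g) & (cohort["timepoint"] == tp)]
                for ind in INDICATORS:
                    assert abs(sel[ind].mean() - p) < band

    def test_positive_latent_correlation_associates_indicators(self):
        cfg = small_config(n_pos=4000, n_neg=4000, rho=0.6, seed=5)
        cohort = generate_cohort(cfg)
        sel = cohort[cohort["timepoint"] == "0h"]
        a, b = sel["fever"].to_numpy().astype(bool), sel["crp"].to_numpy().astype(bool)
        tab = np.array([[(a & b).sum(), (a & ~b).sum()], [(~a & b).sum(), (~a & ~b).sum()]])
        odds_ratio = (tab[0, 0] * tab[1, 1]) / (tab[0, 1] * tab[1, 0])
        assert odds_ratio > 1.5

    def test_persistence_keeps_early_indicators(self):
        cfg = small_config(persistence=1.0, seed=11)
        cohort = generate_cohort(cfg)
        wide = cohort.pivot_table(index="id", columns="timepoint", values="fever")
        # with persistence 1 an indicator true at 48h stays true at 24h and 0h
        early = wide["48h"] == 1
        assert (wide.loc[early, "24h"] == 1).all()
        assert (wide.loc[early, "0h"] == 1).all()

    def test_demographics_sampled_when_configured(self):
        cohort = generate_cohort(validation_config(seed=2))
        assert {"sex", "ga_class", "bw_class"} <= set(cohort.columns)
        assert set(cohort["sex"].unique()) <= {"male", "female"}

    def test_invalid_probability_rejected(self):
        prev = uniform_prevalence(0.3)
        prev["pos"]["0h"]["fever"] = 1.5
        with pytest.raises(ValidationError, match="fever"):
            small_config(prevalence=prev)

    def test_records_round_trip(self):
        cohort = generate_cohort(small_config(n_pos=3, n_neg=2))
        records = cohort_to_records(cohort)
        assert len(records) == 5
        assert sum(r.culture_result for r in records) == 3
        first = records[0]
        assert set(first.indicators) == set(TIMEPOINTS)


class TestPoissonBinomial:
    def test_point_mass_at_zero(self):
        pmf = poisson_binomial_pmf([0.0] * 8)
        assert pmf[0] == 1.0 and pmf[1:].sum() == 0.0

    def test_equal_probs_reduce_to_binomial(self):
        pmf = poisson_binomial_pmf([0.5] * 8)
        assert np.allclose(pmf, binom.pmf(np.arange(9), 8, 0.5), atol=1e-14)

    def test_matches_exhaustive_enumeration(self, rng):
        """DP convolution vs direct sum over all 2^8 indicator outcomes."""
        for _ in range(10):
            probs = rng.random(8)
            expected = np.zeros(9)
            for bits in itertools.product([0, 1], repeat=8):
                w = np.prod([p if b else 1 - p for p, b in zip(probs, bits)])
                expected[sum(bits)] += w
            assert np.allclose(poisson_binomial_pmf(probs), expected, atol=1e-12)

    def test_wrong_length_rejected(self):
        with pytest.raises(ValidationError):
            poisson_binomial_pmf([0.5] * 7)

    def test_sums_to_one(self, rng):
        for _ in range(20):
            assert poisson_binomial_pmf(rng.random(8)).sum() == pytest.approx(1.0)


class TestExpectedMetrics:
    def test_all_zero_prevalence(self):
        m = expected_metrics(small_config(prevalence=uniform_prevalence(0.0)), "0h", 3)
        assert m.se == 0.0 and m.sp == 1.0 and m.plr is None

    def test_all_one_positive_prevalence(self):
        prev = uniform_prevalence(0.0)
        for tp in TIMEPOINTS:
            prev["pos"][tp] = {i: 1.0 for i in INDICATORS}
        m = expected_metrics(small_config(prevalence=prev), "0h", 8)
        assert m.se == 1.0

    def test_correlated_config_rejected(self):
        with pytest.raises(UnsupportedConfigurationError, match="Monte-Carlo"):
            expected_metrics(small_config(rho=0.4), "0h", 3)

    def test_bayes_identities(self):
        cfg = validation_config()
        m = expected_metrics(cfg, "0h", 3)
        pi = cfg.n_pos / (cfg.n_pos + cfg.n_neg)
        assert m.accuracy == pytest.approx(m.se * pi + m.sp * (1 - pi))
        assert m.ppv == pytest.approx(
            m.se * pi / (m.se * pi + (1 - m.sp) * (1 - pi))
        )

    def test_tail_consistency(self):
        cfg = derivation_config()
        pmf = poisson_binomial_pmf(cfg.prevalence_vector("pos", "0h"))
        m = expected_metrics(cfg, "0h", 3)
        assert m.se == pytest.approx(score_tail(pmf, 3))


class TestPresets:
    def test_preset_prevalences_are_published_frequencies(self):
        cfg = derivation_config()
        assert cfg.prevalence["pos"]["0h"]["fever"] == pytest.approx(28 / 63)
        assert cfg.prevalence["neg"]["48h"]["fever"] == 0.0
        vcfg = validation_config()
        assert vcfg.prevalence["pos"]["0h"]["crp"] == pytest.approx(87 / 94)
        assert (vcfg.n_pos, vcfg.n_neg) == (94, 51)

    def test_overrides(self):
        cfg = validation_config(seed=9, rho=0.2)
        assert cfg.rho == 0.2 and cfg.seed == 9


def test_backfill_raw_round_trips_through_derivation():
    from neosps.scoring import RawObservation, derive_indicators

    cohort = generate_cohort(small_config(n_pos=30, n_neg=30, seed=13))
    raw = backfill_raw(cohort)
    for (_, orig), (_, rawrow) in zip(cohort.iterrows(), raw.iterrows()):
        ind = derive_indicators(
            RawObservation(
                temperature=rawrow["temperature"],
                feeding_change=rawrow["feeding_change"],
                platelet_count=rawrow["platelet_count"],
                glucose_change=rawrow["glucose_change"],
                crp=rawrow["crp"],
                crt=rawrow["crt"],
                hypotension=bool(rawrow["hypotension"]),
                o2_requirement_increase=bool(rawrow["o2_requirement_increase"]),
                apnea=bool(rawrow["apnea"]),
                mech_vent_new_or_changed=bool(rawrow["mech_vent_new_or_changed"]),
            )
        )
        assert list(ind.as_tuple()) == [bool(orig[k]) for k in INDICATORS]
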
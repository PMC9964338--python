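"""Score a single neonate-timepoint from raw observations.

Builds one raw observation, dichotomises it into the eight indicators with
the default thresholds (all strict comparisons), sums the score and applies
the score >= 3 decision rule.
"""

from neosps import RawObservation, classify, compute_sps, derive_indicators

# A febrile, thrombocytopenic neonate with elevated CRP; feeding, glucose,
# circulation and respiration unremarkable.
obs = RawObservation(
    temperature=38.4,        # °C, above the 38.0 fever threshold
    feeding_change=0.10,     # 10% feeding decrease — below the 20% threshold
    platelet_count=120_000,  # per mm³, below the 150,000 floor
    glucose_change=0.15,     # 15% glucose change — below the 50% threshold
    crp=2.3,                 # mg/dL, above the 1.0 limit
    crt=3.0,                 # s, capillary refill under the 5 s limit
)

indicators = derive_indicators(obs)
score = compute_sps(indicators)

print("indicators:", {k: v for k, v in zip(
    ("fever", "feeding", "circulation", "o2_increase",
     "respiratory", "glucose", "platelets", "crp"), indicators.as_tuple())})
print("score:", score)
print("predicted septic at cutoff 3:", classify(score, cutoff=3))
# Three indicators fire (fever, platelets, CRP) -> score 3, which reaches
# the score >= 3 operating point: the neonate is flagged as likely septic.
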
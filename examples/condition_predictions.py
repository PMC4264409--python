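"""Per-condition retrieval predictions for the 2x2 complexity design.

Encodes the three noun phrases of an object-relative sentence (NP1 the
matrix subject, NP2 the retrieval target, NP3 the relative-clause
subject) as feature vectors, applies feature-overwriting encoding
interference, and reports the probability of sampling the target at the
retrieval-triggering verb.
"""

from cuemem import InterferenceParams, predict_conditions

print("without encoding interference (overwrite probability 0):")
for p in predict_conditions(params=InterferenceParams(overwrite_probability=0.0)):
    print(f"  {p.condition:16s} P(target) = {p.target_probability:.4f}")

print("\nwith feature overwriting (p = 0.3, 10,000 Monte-Carlo replicates):")
params = InterferenceParams(overwrite_probability=0.3, n_reps=10_000, seed=0)
for p in predict_conditions(params=params):
    print(
        f"  {p.condition:16s} P(target) = {p.target_probability:.4f}"
        f" +/- {p.mc_se:.4f}   intact target features: {p.intact_proportion:.3f}"
    )

# Without interference, only the target's own complexity matters: its two
# modifier features are contextually unique, so both NP2-complex
# conditions sit higher and NP1's complexity changes nothing (the exact
# invariance).  With overwriting, form-matched neighbours degrade a
# simple target: all-simple is worst, and a complex NP1 partially
# shields a simple NP2 — the indirect, encoding-side route by which
# non-target elaboration helps retrieval.
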
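"""End-to-end analysis of a synthetic experiment.

Generates a 20-participant complexity experiment, then runs the full
preprocessing and inference chain: outlier trimming, residual log reading
times (word length + log list position with by-participant intercepts,
fit on fillers too), and hierarchical Bayesian fits at the critical
regions with by-participant and by-item random intercepts and slopes.
"""

import warnings

warnings.filterwarnings("ignore")

from cuemem import (
    GeneratorParams,
    RegressionSpec,
    analyze_regions,
    covariate_check,
    generate_exp1,
    residualize,
    trim,
)

data = generate_exp1(GeneratorParams(n_participants=20, seed=1))
trimmed, removed = trim(data)
print(f"trimmed {removed:.4%} of words outside [100, 5000] ms")

res = residualize(trimmed)
print(f"nuisance fit: {res.coefficients}")

spec = RegressionSpec.scaled_down(seed=0)  # 2 chains x 1000 draws
table = analyze_regions(
    res.data, ["NP2_head", "RC_verb", "RC_verb+1"], spec
)
print("\nregion fits (residual log RT):")
print(table.round(3).to_string(index=False))

adj = covariate_check(res.data, "RC_verb", "NP3_head+1", spec)
p = adj.p_lt_0("NP2_complexity")
print(f"\nNP2 effect at the verb with the pre-verb region as covariate:"
      f" P(beta<0) = {p:.3f}")

# Read the table the way such analyses are reported: P(beta < 0) near 1
# means the posterior is confident the predictor speeds reading.  NP2
# complexity slows the NP2 head (encoding cost: p_lt_0 near 0) and speeds
# the verb and spillover regions (retrieval facilitation: p_lt_0 near 1);
# NP1 complexity, generated with no direct reading-time effect, stays
# uncertain.  The covariate check shows the verb effect is not mere
# spillover from the preceding region.
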
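"""Distinctiveness and competitor sweeps of the retrieval model.

Computes the target's sampling probability over grids of (m) probe
features shared with every competitor, (u) features unique to the target,
and (n) competitors, and prints the two headline contrasts: shared
features barely matter, competitor count matters a lot.
"""

from cuemem import SweepSpec, competitor_sweep, distinctiveness_sweep

# unique features help, with diminishing returns; the m=2 vs m=10 curves
# stay within 0.10 of each other everywhere
sweep = distinctiveness_sweep(
    SweepSpec(m_values=(2, 10), u_values=tuple(range(21)), n_values=(2,))
)
by_m = sweep.pivot(index="u", columns="m", values="target_probability")
print("target probability with two competitors (rows: unique features u)")
print(by_m.loc[[0, 1, 2, 5, 10, 20]].round(3).to_string())
print(f"\nmax gap between m=2 and m=10 curves: {(by_m[2] - by_m[10]).abs().max():.3f}")

# going from 1 to 3 competitors (two shared features, none unique) halves
# the retrieval probability: 0.50 -> 0.25
comp = competitor_sweep(m=2, u_values=[0], n_values=range(1, 11))
print("\ncompetitor effect (m=2, u=0):")
print(comp[["n_competitors", "target_probability"]].round(3).to_string(index=False))

# Optionally persist the full grid for plotting:
#   distinctiveness_sweep().to_csv("sweep.csv", index=False)
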
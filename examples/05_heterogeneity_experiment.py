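"""Does cell-to-cell geometric heterogeneity help or hurt inference?

Runs the repeated-inference comparison at slow degradation (mu=1): for each
of four scenarios (static geometry, random source location, random cell
size, both random), simulate M=100 cells, fit the posterior, and record the
89% HDPR area.  Paired seeds across scenarios isolate the effect of the
geometry distribution.  Reduced to 20 repeats to keep the demo quick; the
package default is 100.
"""

from poissnap import NondimParams, run_heterogeneity_experiment

df = run_heterogeneity_experiment(
    NondimParams(lam=500.0, mu=1.0),
    M=100,
    n_repeats=20,
    seed=11,
)
medians = df.groupby("scenario")["area"].median().sort_values()
print(df.groupby("scenario")["area"].describe()[["50%", "mean", "std"]])
print()
print("median HDPR area, smallest (least uncertainty) first:")
for name, area in medians.items():
    print(f"  {name:>10}: {area:8.2f}")
# At mu=1 geometric variability *adds* information about the rates: with the
# full 100 repeats every heterogeneous scenario has a smaller median HDPR
# area than the static one.  At the 20 demo repeats the size effect
# (random-L, both) is already clear while the source-location effect is
# within median noise of static.
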
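"""Find the climate window that predicts growth.

The generator plants an April sea-surface-temperature signal; the scan
searches all month spans within 24 months back from December of the growth
year and ranks them by ML-AICc against the intrinsic baseline.  A
randomization test then asks how often permuted data produce equal support.
Printed numbers: the best window (months back), its AICc improvement, and
the randomization percentile (small = unlikely by chance).
"""
import otochron as oc

roster = oc.simulate_population(250, range(1960, 2011),
                                age_at_catch_range=(8, 10), seed=11)
climate = oc.simulate_climate(1930, 2011, seed=12)
truth = oc.SimulationTruth(beta_w=0.2, beta_a=0.2, beta_age_w=0.0, seed=13)
table, _ = oc.simulate_increments(truth, roster, climate,
                                  window=oc.WindowDef(8, 8))  # April signal
table = oc.transform(table)

spec = oc.ModelSpec(
    "log_width", ("log_age_c",),
    (oc.RandomTerm("fish_id", slopes=("log_age_c",)),
     oc.RandomTerm("year", slopes=("log_age_c",)),
     oc.RandomTerm("cohort", slopes=("log_age_c",))), "REML")

res = oc.scan(table, climate, spec, max_back=23)
best = res.best
print(f"best window: {int(best['open'])}..{int(best['close'])} months back "
      f"from December (8 = April), age interaction={bool(best['interaction'])}")
print(f"AICc improvement over baseline: {-best['delta_aicc']:.1f}")

rand = oc.randomization_test(table, climate, spec, n_rand=99, seed=14,
                             max_back=11)
print(f"randomization percentile: {rand.percentile:.3f} "
      f"(over {rand.n_rand} permutations)")
print("\nThe planted April window (8 months back) should be inside the"
      "\nselected span, and the percentile near its minimum 1/100.")
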
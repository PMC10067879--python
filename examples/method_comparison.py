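"""Single-tube fractal compensation vs explicit-branch network.

Builds 20 seeded bifurcated phantoms whose daughter diameters satisfy the
HK law, solves each with (a) the single-tube marching solver with HK flow
splits and (b) the explicit side-branch network with Murray-scaled outflow,
then reports the paired agreement statistics — the phantom-scale analogue
of comparing a fast method against its slower reference.
"""

from ivusffr.branchnet import compare_methods
from ivusffr.suite import phantom_suite

pairs = phantom_suite(20, seed=1)
df, stats = compare_methods(pairs, law="hk")

print(df.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
print()
print(f"Pearson r:                  {stats['pearson_r']:.4f}")
print(f"bias (branch - fractal):    {stats['bias']:+.4f}")
print(f"95% limits of agreement:    [{stats['loa_low']:+.4f}, {stats['loa_high']:+.4f}]")
print(f"mean |difference|:          {stats['mean_abs_diff']:.4f}")
print(f"same ischemia call (0.80):  {stats['classification_agreement']:.0%}")
print("\nHigh r and a near-zero bias mean the fast single-tube method can")
print("stand in for the explicitly branched model on these vessels.")
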